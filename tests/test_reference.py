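"""Reference-class ladder: normalization, class assignment, plate rescaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platevol.reference import (
    ReferenceScheme,
    assign_class,
    class_boundaries,
    denormalize_volume,
    merge_manifests,
    normalize_volume,
    reference_volume,
    reference_volumes,
    rescale_scheme,
)

LARGE15 = ReferenceScheme(15, 400, 3400)
SMALL15 = ReferenceScheme(15, 200, 1700)


class TestScheme:
    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ReferenceScheme(1, 0, 100)
        with pytest.raises(ValueError):
            ReferenceScheme(5, 400, 400)
        with pytest.raises(ValueError):
            ReferenceScheme(5, -1, 100)

    def test_unit_is_range_over_n(self):
        assert ReferenceScheme(30, 400, 3400).unit == 100
        assert ReferenceScheme(30, 200, 1700).unit == 50
        assert LARGE15.unit == 200

    def test_roundtrip_serialization(self):
        assert ReferenceScheme.from_dict(LARGE15.to_dict()) == LARGE15


class TestNormalization:
    @pytest.mark.parametrize(
        "v,expected", [(400, 0.0), (3400, 1.0), (1900, 0.5)]
    )
    def test_endpoints_and_midpoint(self, v, expected):
        assert normalize_volume(v, LARGE15) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_volume(399.9, LARGE15)
        with pytest.raises(ValueError):
            normalize_volume(3400.1, LARGE15)

    @given(st.floats(min_value=400, max_value=3400, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_denormalize_roundtrip(self, v):
        assert denormalize_volume(normalize_volume(v, LARGE15), LARGE15) == pytest.approx(
            v, rel=1e-12
        )


class TestClassAssignment:
    @pytest.mark.parametrize(
        "v,expected",
        [(500, 1), (3300, 15), (600, 2), (400, 1), (3400, 15)],
    )
    def test_known_assignments(self, v, expected):
        assert assign_class(v, LARGE15) == expected

    def test_boundaries_of_first_and_last_class(self):
        assert class_boundaries(1, LARGE15) == (400, 600)
        assert class_boundaries(15, LARGE15) == (3200, 3400)

    @given(st.floats(min_value=200, max_value=1700, allow_nan=False))
    @settings(derandomize=True, max_examples=100)
    def test_assignment_consistent_with_boundaries(self, v):
        i = assign_class(v, SMALL15)
        lo, hi = class_boundaries(i, SMALL15)
        assert lo <= v < hi or (i == SMALL15.n_classes and v == hi)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            class_boundaries(0, LARGE15)
        with pytest.raises(ValueError):
            class_boundaries(16, LARGE15)


class TestReferenceVolumes:
    def test_normalized_midpoint_formula(self):
        # i/N - 1/(2N): the middle of a 15-class ladder is exactly one half
        assert reference_volume(8, LARGE15, normalized=True) == pytest.approx(0.5)
        assert reference_volume(15, LARGE15, normalized=True) == pytest.approx(1 - 1 / 30)

    def test_raw_form_is_interval_midpoint(self):
        assert reference_volume(1, LARGE15) == pytest.approx(500)
        for i in range(1, 16):
            lo, hi = class_boundaries(i, LARGE15)
            assert reference_volume(i, LARGE15) == pytest.approx((lo + hi) / 2)

    def test_vector_ordering(self):
        v = reference_volumes(SMALL15)
        assert np.all(np.diff(v) > 0)
        assert len(v) == 15


class TestRescaling:
    def test_identity_and_cubic_scaling(self):
        assert rescale_scheme(LARGE15, 10, 10) == LARGE15
        doubled = rescale_scheme(LARGE15, 10, 20)
        assert doubled == ReferenceScheme(15, 3200, 27200)
        halved = rescale_scheme(LARGE15, 10, 5)
        assert halved.v_min == pytest.approx(50)
        assert halved.v_max == pytest.approx(425)

    def test_composition(self):
        a = rescale_scheme(rescale_scheme(LARGE15, 1, 1.5), 1, 2.0)
        b = rescale_scheme(LARGE15, 1, 3.0)
        assert a.v_min == pytest.approx(b.v_min)
        assert a.v_max == pytest.approx(b.v_max)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            rescale_scheme(LARGE15, 0, 1)


def _fake_manifest(n: int, scheme: ReferenceScheme, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    v = rng.uniform(scheme.v_min, scheme.v_max, size=n)
    return pd.DataFrame(
        {
            "image_path": [f"img{i}.png" for i in range(n)],
            "volume_ml": v,
            "class": [assign_class(x, scheme) for x in v],
            "split": "train",
        }
    )


class TestMergeManifests:
    def test_row_counts_add(self):
        large = _fake_manifest(10_003, LARGE15, 0)
        small = _fake_manifest(9_205, SMALL15, 1)
        merged = merge_manifests([(large, LARGE15), (small, SMALL15)])
        assert len(merged) == 19_208

    def test_equal_normalized_volumes_share_labels(self):
        # 700 mL on the large ladder and 350 mL on the small one both
        # normalize to 0.1, hence the same class after merging
        a = pd.DataFrame({"image_path": ["a"], "volume_ml": [700.0], "class": [2], "split": ["train"]})
        b = pd.DataFrame({"image_path": ["b"], "volume_ml": [350.0], "class": [2], "split": ["train"]})
        merged = merge_manifests([(a, LARGE15), (b, SMALL15)])
        assert merged["class"].nunique() == 1

    def test_self_merge_preserves_labels(self):
        m = _fake_manifest(100, SMALL15, 2)
        merged = merge_manifests([(m, SMALL15), (m, SMALL15)])
        assert list(merged["class"]) == list(m["class"]) * 2

    def test_mismatched_n_refused(self):
        m = _fake_manifest(5, LARGE15, 3)
        other = ReferenceScheme(30, 400, 3400)
        with pytest.raises(ValueError):
            merge_manifests([(m, LARGE15), (_fake_manifest(5, other, 4), other)])
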