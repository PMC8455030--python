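"""Expectation decoding of soft class predictions into volumes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platevol.estimator import (
    estimate_for_plate,
    estimate_volume,
    estimate_volume_normalized,
    hard_estimate,
)
from platevol.reference import ReferenceScheme, reference_volumes

LARGE15 = ReferenceScheme(15, 400, 3400)


def random_probs(rng, n):
    p = rng.dirichlet(np.ones(n))
    return p


class TestInnerProduct:
    def test_one_hot_returns_reference_volume(self):
        refs = reference_volumes(LARGE15)
        p = np.zeros(15)
        p[0] = 1.0
        assert estimate_volume(p, refs).value == pytest.approx(500.0)

    def test_uniform_over_symmetric_refs_returns_centre(self):
        refs = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        p = np.full(5, 0.2)
        assert estimate_volume(p, refs).value == pytest.approx(300.0)

    def test_matches_term_by_term_summation(self, rng):
        refs = rng.uniform(100, 2000, size=5)
        for _ in range(50):
            p = random_probs(rng, 5)
            expected = 0.0
            for i in range(5):
                expected += p[i] * refs[i]
            assert estimate_volume(p, refs).value == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_volume(np.full(4, 0.25), np.arange(5.0))

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            estimate_volume(np.array([0.7, 0.7, -0.4]), np.arange(3.0))
        with pytest.raises(ValueError):
            estimate_volume(np.array([0.5, 0.2]), np.arange(2.0))


class TestNormalizedForm:
    def test_one_hot_class_one_gives_first_midpoint(self):
        p = np.zeros(15)
        p[0] = 1.0
        assert estimate_volume_normalized(p, LARGE15).value == pytest.approx(500.0)

    def test_uniform_probabilities_give_range_centre(self):
        p = np.full(15, 1 / 15)
        assert estimate_volume_normalized(p, LARGE15).value == pytest.approx(1900.0)

    def test_identical_to_midpoint_inner_product(self, rng):
        refs = reference_volumes(LARGE15)
        for _ in range(100):
            p = random_probs(rng, 15)
            a = estimate_volume_normalized(p, LARGE15).value
            b = estimate_volume(p, refs).value
            assert a == pytest.approx(b, abs=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_by_extreme_midpoints(self, seed):
        p = random_probs(np.random.default_rng(seed), 15)
        v = estimate_volume_normalized(p, LARGE15).value
        assert 500.0 - 1e-9 <= v <= 3300.0 + 1e-9

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_under_upward_mass_shift(self, seed):
        rng = np.random.default_rng(seed)
        p = random_probs(rng, 15)
        i = int(rng.integers(0, 14))
        j = int(rng.integers(i + 1, 15))
        q = p.copy()
        shift = p[i] * 0.5
        q[i] -= shift
        q[j] += shift
        assert (
            estimate_volume_normalized(q, LARGE15).value
            >= estimate_volume_normalized(p, LARGE15).value - 1e-12
        )


class TestPlateRescaling:
    def test_equal_radii_equal_estimate(self, rng):
        p = random_probs(rng, 15)
        base = estimate_volume_normalized(p, LARGE15).value
        assert estimate_for_plate(p, LARGE15, 10, 10).value == pytest.approx(base)

    def test_double_radius_gives_eightfold_volume(self, rng):
        p = random_probs(rng, 15)
        base = estimate_volume_normalized(p, LARGE15).value
        assert estimate_for_plate(p, LARGE15, 10, 20).value == pytest.approx(8 * base)

    def test_nonpositive_radius_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_for_plate(random_probs(rng, 15), LARGE15, 0, 1)


class TestHardBaseline:
    def test_hard_is_argmax_midpoint(self):
        p = np.array([0.1, 0.6, 0.3] + [0.0] * 12)
        assert hard_estimate(p, LARGE15).value == pytest.approx(700.0)

    def test_ties_break_to_lower_class(self):
        p = np.zeros(15)
        p[2] = p[7] = 0.5
        assert hard_estimate(p, LARGE15).value == pytest.approx(900.0)  # class 3

    def test_soft_differs_from_hard_when_not_one_hot(self, rng):
        # enumerate small two-class mixtures: expectation interpolates,
        # the argmax midpoint cannot
        for w in np.linspace(0.05, 0.45, 9):
            p = np.zeros(15)
            p[0], p[1] = 1 - w, w
            soft = estimate_volume_normalized(p, LARGE15).value
            hard = hard_estimate(p, LARGE15).value
            assert soft != pytest.approx(hard)
            assert soft == pytest.approx(500 + 200 * w)
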