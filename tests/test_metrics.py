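"""Evaluation metrics: neighbor-tolerant accuracy, RVE, reports, bias summary."""

import numpy as np
import pytest

from platevol.metrics import (
    EvaluationReport,
    error_distribution,
    evaluate_predictions,
    mean_rve,
    relative_volumetric_error,
    top_k_accuracy,
)
from platevol.reference import ReferenceScheme, reference_volumes

SMALL5 = ReferenceScheme(5, 200, 1700)


class TestTopK:
    def test_all_correct(self):
        pairs = [(i, i) for i in range(1, 6)]
        assert top_k_accuracy(pairs, 1, 5) == 1.0
        assert top_k_accuracy(pairs, 3, 5) == 1.0

    def test_off_by_one_counts_for_top3_only(self):
        pairs = [(2, 3), (4, 3), (1, 2), (5, 4)]
        assert top_k_accuracy(pairs, 1, 5) == 0.0
        assert top_k_accuracy(pairs, 3, 5) == 1.0

    def test_hand_enumerated_mixture(self):
        pairs = list(zip([2, 3, 5, 3], [3, 3, 3, 3]))
        assert top_k_accuracy(pairs, 1, 5) == 0.5
        assert top_k_accuracy(pairs, 3, 5) == 0.75

    def test_edge_classes_clip_neighborhood(self):
        # truth 1: neighborhood {1, 2}; truth N: {N-1, N}
        assert top_k_accuracy([(2, 1)], 3, 5) == 1.0
        assert top_k_accuracy([(4, 5)], 3, 5) == 1.0
        assert top_k_accuracy([(3, 1)], 3, 5) == 0.0
        assert top_k_accuracy([(3, 5)], 3, 5) == 0.0

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            top_k_accuracy([], 1, 5)
        with pytest.raises(ValueError):
            top_k_accuracy([(6, 1)], 1, 5)


class TestRVE:
    def test_exact_prediction_is_zero(self):
        assert relative_volumetric_error(100, 100) == 0.0

    def test_boundary_values_of_fixed_absolute_error(self):
        assert 100 * relative_volumetric_error(700, 600) == pytest.approx(16.7, abs=0.05)
        assert 100 * relative_volumetric_error(3300, 3400) == pytest.approx(2.9, abs=0.05)

    def test_mean_rve_symmetric_errors(self):
        assert mean_rve([(110, 100), (90, 100)]) == pytest.approx(0.10)

    def test_mean_rve_matches_vectorized_resummation(self, rng):
        preds = rng.uniform(100, 2000, 100)
        trues = rng.uniform(100, 2000, 100)
        expected = float(np.mean(np.abs(preds - trues) / trues))
        assert mean_rve(list(zip(preds, trues))) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_volumetric_error(10, 0)


def _oracle_probs(labels, n):
    p = np.zeros((len(labels), n))
    p[np.arange(len(labels)), np.asarray(labels) - 1] = 1.0
    return p


class TestEvaluatePredictions:
    def test_oracle_classifier_metrics(self, rng):
        labels = rng.integers(1, 6, 40)
        mids = reference_volumes(SMALL5)
        volumes = np.array([rng.uniform(*_bounds(i)) for i in labels])
        report = evaluate_predictions(_oracle_probs(labels, 5), labels, volumes, SMALL5)
        o = report.overall()
        assert o["top1"] == 1.0 and o["top3"] == 1.0
        expected = float(np.mean(np.abs(mids[labels - 1] - volumes) / volumes))
        assert o["mrve_soft"] == pytest.approx(expected)

    def test_oracle_mrve_below_quantization_bound(self, rng):
        labels = rng.integers(1, 6, 200)
        volumes = np.array([rng.uniform(*_bounds(i)) for i in labels])
        report = evaluate_predictions(_oracle_probs(labels, 5), labels, volumes, SMALL5)
        # within-class quantization: at worst half a unit at the lowest midpoint
        bound = (SMALL5.unit / 2) / reference_volumes(SMALL5)[0]
        assert report.overall()["mrve_soft"] <= bound

    def test_uniform_model_estimates_range_centre(self, rng):
        labels = rng.integers(1, 6, 10)
        volumes = np.array([rng.uniform(*_bounds(i)) for i in labels])
        probs = np.full((10, 5), 0.2)
        report = evaluate_predictions(probs, labels, volumes, SMALL5)
        assert np.allclose(report.soft_volumes, 950.0)

    def test_per_class_counts_match(self, rng):
        labels = rng.integers(1, 6, 60)
        volumes = np.array([rng.uniform(*_bounds(i)) for i in labels])
        report = evaluate_predictions(_oracle_probs(labels, 5), labels, volumes, SMALL5)
        per = report.per_class()
        assert sum(m["n"] for m in per.values()) == 60

    def test_top3_at_least_top1(self, rng):
        probs = rng.dirichlet(np.ones(5), size=80)
        labels = rng.integers(1, 6, 80)
        volumes = np.array([rng.uniform(*_bounds(i)) for i in labels])
        report = evaluate_predictions(probs, labels, volumes, SMALL5)
        o = report.overall()
        assert o["top3"] >= o["top1"]

    def test_report_table_layout(self, rng):
        labels = np.array(sorted(rng.integers(1, 6, 30)))
        volumes = np.array([rng.uniform(*_bounds(i)) for i in labels])
        report = evaluate_predictions(_oracle_probs(labels, 5), labels, volumes, SMALL5)
        table = report.to_table()
        assert list(table.index) == ["top1", "top3", "mrve_soft", "mrve_hard"]
        assert table.columns[-1] == "overall"

    def test_json_round_trip(self, rng):
        labels = rng.integers(1, 6, 12)
        volumes = np.array([rng.uniform(*_bounds(i)) for i in labels])
        report = evaluate_predictions(_oracle_probs(labels, 5), labels, volumes, SMALL5)
        back = EvaluationReport.from_json(report.to_json())
        assert back.overall() == report.overall()
        assert np.allclose(back.soft_volumes, report.soft_volumes)


def _bounds(i):
    lo = 200 + (i - 1) * 300
    return lo, lo + 300


class TestErrorDistribution:
    def _report(self, errors):
        n = len(errors)
        trues = np.full(n, 1000.0)
        return EvaluationReport(
            scheme=SMALL5,
            true_labels=np.full(n, 3),
            pred_labels=np.full(n, 3),
            true_volumes=trues,
            soft_volumes=trues + np.asarray(errors, dtype=float),
            hard_volumes=trues,
        )

    def test_symmetric_errors_flag_zero_centered(self):
        d = error_distribution(self._report([-50, 50, -20, 20]))
        assert d["mean"] == pytest.approx(0.0)
        assert d["zero_centered"]

    def test_constant_offset_flags_bias(self):
        d = error_distribution(self._report([30.0] * 100 + [31.0, 29.0]))
        assert d["mean"] == pytest.approx(30.0, abs=0.1)
        assert not d["zero_centered"]

    def test_bin_edges_spaced_by_bin_width(self):
        d = error_distribution(self._report([-90, -10, 5, 77]), bin_width=40)
        assert np.allclose(np.diff(d["bin_edges"]), 40.0)
        assert d["counts"].sum() == 4
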