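"""Evaluation protocol: neighbor-tolerant accuracy, relative volumetric error,
per-class report tables, and the error-distribution (bias) summary.

top1 is the exact-class hit rate; top3 counts a prediction as correct when
it lands within one class of the truth (for edge classes the neighbor set
is clipped to the valid range, so it has two members instead of three).
RVE is |Vp - Vt| / Vt and mRVE its mean over the test set — the headline
volume-estimation figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import estimate_volume_normalized, hard_estimate
from .reference import ReferenceScheme

__all__ = [
    "top_k_accuracy",
    "relative_volumetric_error",
    "mean_rve",
    "EvaluationReport",
    "evaluate",
    "evaluate_predictions",
    "error_distribution",
]


def top_k_accuracy(pairs: list[tuple[int, int]], k: int, n_classes: int) -> float:
    """Fraction of (predicted, truth) label pairs within the top-k neighborhood.

    k = 1 demands an exact match; k = 3 accepts {l-1, l, l+1}, with
    neighbors falling outside 1..N simply never matching.
    """
    if not pairs:
        raise ValueError("no label pairs")
    if k not in (1, 3):
        raise ValueError(f"k must be 1 or 3, got {k}")
    hits = 0
    for pred, truth in pairs:
        if not (1 <= pred <= n_classes and 1 <= truth <= n_classes):
            raise ValueError(f"label pair ({pred}, {truth}) outside 1..{n_classes}")
        if k == 1:
            hits += pred == truth
        else:
            hits += abs(pred - truth) <= 1
    return hits / len(pairs)


def relative_volumetric_error(v_pred: float, v_true: float) -> float:
    """RVE = |Vp - Vt| / Vt."""
    if v_true <= 0:
        raise ValueError(f"true volume must be positive, got {v_true}")
    return abs(v_pred - v_true) / v_true


def mean_rve(pairs: list[tuple[float, float]]) -> float:
    """Arithmetic mean of per-sample relative volumetric errors."""
    if not pairs:
        raise ValueError("no volume pairs")
    return float(np.mean([relative_volumetric_error(p, t) for p, t in pairs]))


@dataclass
class EvaluationReport:
    """Per-class and overall metrics plus raw error samples for bias analysis."""

    scheme: ReferenceScheme
    true_labels: np.ndarray  # (n,) int, 1..N
    pred_labels: np.ndarray  # (n,) int, argmax classes
    true_volumes: np.ndarray  # (n,) mL
    soft_volumes: np.ndarray  # (n,) mL, expectation decoding
    hard_volumes: np.ndarray  # (n,) mL, argmax midpoints

    @property
    def signed_errors(self) -> np.ndarray:
        """Soft-estimate errors V_hat - Vt in mL."""
        return self.soft_volumes - self.true_volumes

    @property
    def relative_errors(self) -> np.ndarray:
        return np.abs(self.signed_errors) / self.true_volumes

    def _class_mask(self, i: int) -> np.ndarray:
        return self.true_labels == i

    def _metrics(self, mask: np.ndarray) -> dict:
        pairs = list(zip(self.pred_labels[mask], self.true_labels[mask]))
        return {
            "n": int(mask.sum()),
            "top1": top_k_accuracy(pairs, 1, self.scheme.n_classes),
            "top3": top_k_accuracy(pairs, 3, self.scheme.n_classes),
            "mrve_soft": mean_rve(
                list(zip(self.soft_volumes[mask], self.true_volumes[mask]))
            ),
            "mrve_hard": mean_rve(
                list(zip(self.hard_volumes[mask], self.true_volumes[mask]))
            ),
        }

    def overall(self) -> dict:
        return self._metrics(np.ones_like(self.true_labels, dtype=bool))

    def per_class(self) -> dict[int, dict]:
        return {
            i: self._metrics(self._class_mask(i))
            for i in range(1, self.scheme.n_classes + 1)
            if self._class_mask(i).any()
        }

    def to_table(self) -> pd.DataFrame:
        """Report table: metric rows, one column per class plus 'overall' (percent, 1 d.p.)."""
        cols: dict[str, list] = {}
        for i, m in self.per_class().items():
            cols[str(i)] = [
                round(100 * m["top1"], 1),
                round(100 * m["top3"], 1),
                round(100 * m["mrve_soft"], 1),
                round(100 * m["mrve_hard"], 1),
            ]
        o = self.overall()
        cols["overall"] = [
            round(100 * o["top1"], 1),
            round(100 * o["top3"], 1),
            round(100 * o["mrve_soft"], 1),
            round(100 * o["mrve_hard"], 1),
        ]
        return pd.DataFrame(cols, index=["top1", "top3", "mrve_soft", "mrve_hard"])

    def to_json(self) -> str:
        payload = {
            "scheme": self.scheme.to_dict(),
            "true_labels": self.true_labels.tolist(),
            "pred_labels": self.pred_labels.tolist(),
            "true_volumes": self.true_volumes.tolist(),
            "soft_volumes": self.soft_volumes.tolist(),
            "hard_volumes": self.hard_volumes.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(
            scheme=ReferenceScheme.from_dict(d["scheme"]),
            true_labels=np.asarray(d["true_labels"], dtype=np.int64),
            pred_labels=np.asarray(d["pred_labels"], dtype=np.int64),
            true_volumes=np.asarray(d["true_volumes"], dtype=float),
            soft_volumes=np.asarray(d["soft_volumes"], dtype=float),
            hard_volumes=np.asarray(d["hard_volumes"], dtype=float),
        )


def evaluate_predictions(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    true_volumes: np.ndarray,
    scheme: ReferenceScheme,
) -> EvaluationReport:
    """Build a report from precomputed probability vectors.

    One pass yields both the soft (expectation) and hard (argmax midpoint)
    estimates, so the two mRVE rows come from the same predictions.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    true_labels = np.asarray(true_labels, dtype=np.int64)
    true_volumes = np.asarray(true_volumes, dtype=float)
    if len(true_labels) == 0:
        raise ValueError("empty evaluation set")
    soft = np.array(
        [estimate_volume_normalized(p, scheme).value for p in probabilities]
    )
    hard = np.array([hard_estimate(p, scheme).value for p in probabilities])
    pred = probabilities.argmax(axis=1) + 1
    return EvaluationReport(
        scheme=scheme,
        true_labels=true_labels,
        pred_labels=pred.astype(np.int64),
        true_volumes=true_volumes,
        soft_volumes=soft,
        hard_volumes=hard,
    )


def evaluate(
    model,
    manifest: pd.DataFrame,
    scheme: ReferenceScheme,
    images_dir: str = ".",
    batch_size: int = 64,
) -> EvaluationReport:
    """Run a trained model over a manifest's test split and score it."""
    from .nn.train import load_split_images

    images, labels = load_split_images(manifest, images_dir, "test")
    volumes = manifest[manifest["split"] == "test"]["volume_ml"].to_numpy(dtype=float)
    probs = np.vstack(
        [
            model.predict_probabilities(images[i : i + batch_size])
            for i in range(0, len(images), batch_size)
        ]
    )
    return evaluate_predictions(probs, labels, volumes, scheme)


def error_distribution(
    report: EvaluationReport, bin_width: float = 40.0, tolerance: float = 3.0
) -> dict:
    """Histogram and centre statistics of the signed errors (mL).

    The ``zero_centered`` flag is true when the mean error is within
    ``tolerance`` standard errors of zero — the unbiasedness check.
    """
    errors = report.signed_errors
    if errors.size == 0:
        raise ValueError("report has no error samples")
    lo = np.floor(errors.min() / bin_width) * bin_width
    hi = np.ceil(errors.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(errors, bins=edges)
    mean = float(errors.mean())
    std = float(errors.std(ddof=1)) if errors.size > 1 else 0.0
    stderr = std / np.sqrt(errors.size) if errors.size else np.inf
    return {
        "counts": counts,
        "bin_edges": edges,
        "mean": mean,
        "std": std,
        "stderr": float(stderr),
        "zero_centered": bool(abs(mean) <= tolerance * stderr),
    }
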