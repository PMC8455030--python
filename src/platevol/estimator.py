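"""Soft-prediction volume estimation.

The classifier outputs a probability vector p over the N reference
classes; the volume estimate is the inner product

    V_hat = sum_i p(i) * V(i)

with V(i) the reference (class-midpoint) volume.  In normalized form this
reads V_hat = Vmin + (Vmax - Vmin) * sum_i p(i) * (i/N - 1/(2N)), so only
Vmin and Vmax are needed to de-normalize — which is what makes a single
trained model transfer across plate sizes: for a plate whose radius is s
times the training plate's, both bounds simply scale by s**3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import ReferenceScheme, reference_volumes, rescale_scheme

__all__ = [
    "VolumeEstimate",
    "estimate_volume",
    "estimate_volume_normalized",
    "estimate_for_plate",
    "hard_estimate",
]


@dataclass(frozen=True)
class VolumeEstimate:
    value: float  # mL, or dimensionless in normalized mode
    scheme: ReferenceScheme | None
    mode: str  # "raw" | "normalized" | "rescaled"


def _check_probabilities(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"probability vector must be 1D, got shape {p.shape}")
    if np.any(p < -1e-9):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    return p


def estimate_volume(p: np.ndarray, volumes: np.ndarray) -> VolumeEstimate:
    """Inner product of a probability vector with reference volumes (mL)."""
    p = _check_probabilities(p)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape != p.shape:
        raise ValueError(
            f"length mismatch: {p.shape[0]} probabilities vs {volumes.shape[0]} volumes"
        )
    return VolumeEstimate(value=float(p @ volumes), scheme=None, mode="raw")


def estimate_volume_normalized(p: np.ndarray, scheme: ReferenceScheme) -> VolumeEstimate:
    """Expectation over normalized reference volumes, de-normalized to mL.

    Algebraically identical to :func:`estimate_volume` over the raw class
    midpoints of ``scheme``.
    """
    p = _check_probabilities(p)
    if p.shape[0] != scheme.n_classes:
        raise ValueError(
            f"length mismatch: {p.shape[0]} probabilities vs {scheme.n_classes} classes"
        )
    v_bar = float(p @ reference_volumes(scheme, normalized=True))
    value = scheme.v_min + (scheme.v_max - scheme.v_min) * v_bar
    return VolumeEstimate(value=value, scheme=scheme, mode="raw")


def estimate_for_plate(
    p: np.ndarray, scheme: ReferenceScheme, r_train: float, r_new: float
) -> VolumeEstimate:
    """Estimate for a plate of radius ``r_new`` with a model trained at ``r_train``.

    Rescales the scheme by s = r_new / r_train (volumes by s**3) and applies
    the normalized estimator; equals s**3 times the unrescaled estimate.
    """
    rescaled = rescale_scheme(scheme, r_train, r_new)
    est = estimate_volume_normalized(p, rescaled)
    mode = "rescaled" if r_new != r_train else "raw"
    return VolumeEstimate(value=est.value, scheme=rescaled, mode=mode)


def hard_estimate(p: np.ndarray, scheme: ReferenceScheme) -> VolumeEstimate:
    """Baseline: midpoint volume of the argmax class (ties -> lower index)."""
    p = _check_probabilities(p)
    if p.shape[0] != scheme.n_classes:
        raise ValueError("length mismatch")
    i = int(np.argmax(p)) + 1  # argmax returns the first (lowest) index on ties
    mids = reference_volumes(scheme)
    return VolumeEstimate(value=float(mids[i - 1]), scheme=scheme, mode="raw")
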