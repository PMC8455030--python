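"""Reference-class ladder over a food-volume range.

The estimator treats food images with similar volumes as one abstract
*reference class*.  A :class:`ReferenceScheme` divides the volume range
``[v_min, v_max]`` (mL) into ``n_classes`` equal intervals; the *reference
volume* of class ``i`` is the interval midpoint, which in normalized
(dimensionless) form equals ``i/N - 1/(2N)``.  Because volumes scale with
the cube of the plate radius, a scheme trained on plate radius ``r_t``
transfers to a plate of radius ``r_new = s * r_t`` by multiplying the
volume range by ``s**3``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceScheme",
    "normalize_volume",
    "denormalize_volume",
    "assign_class",
    "class_boundaries",
    "reference_volume",
    "reference_volumes",
    "rescale_scheme",
    "merge_manifests",
]


@dataclass(frozen=True)
class ReferenceScheme:
    """A ladder of ``n_classes`` equal-width volume classes over [v_min, v_max] mL.

    Class ``i`` (1-based) covers the half-open interval
    ``[v_min + (i-1)*unit, v_min + i*unit)``; the top class is closed at
    ``v_max`` so every in-range volume belongs to exactly one class.
    """

    n_classes: int
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if not (0 <= self.v_min < self.v_max):
            raise ValueError(
                f"need 0 <= v_min < v_max, got v_min={self.v_min}, v_max={self.v_max}"
            )

    @property
    def unit(self) -> float:
        """Volume interval between neighboring reference volumes, (v_max - v_min)/N."""
        return (self.v_max - self.v_min) / self.n_classes

    def to_dict(self) -> dict:
        return {"n_classes": self.n_classes, "v_min_ml": self.v_min, "v_max_ml": self.v_max}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceScheme":
        return cls(int(d["n_classes"]), float(d["v_min_ml"]), float(d["v_max_ml"]))


def _check_in_range(v: float, scheme: ReferenceScheme) -> None:
    if not (scheme.v_min <= v <= scheme.v_max):
        raise ValueError(
            f"volume {v} mL outside scheme range [{scheme.v_min}, {scheme.v_max}] mL"
        )


def normalize_volume(v: float, scheme: ReferenceScheme) -> float:
    """Map a raw volume (mL) to the dimensionless interval [0, 1]."""
    _check_in_range(v, scheme)
    return (v - scheme.v_min) / (scheme.v_max - scheme.v_min)


def denormalize_volume(v_bar: float, scheme: ReferenceScheme) -> float:
    """Inverse of :func:`normalize_volume`."""
    return scheme.v_min + (scheme.v_max - scheme.v_min) * v_bar


def assign_class(v: float, scheme: ReferenceScheme) -> int:
    """1-based index of the class interval containing ``v``; v_max maps to class N."""
    _check_in_range(v, scheme)
    i = int(np.floor((v - scheme.v_min) / scheme.unit)) + 1
    return min(i, scheme.n_classes)


def class_boundaries(i: int, scheme: ReferenceScheme) -> tuple[float, float]:
    """(low, high) boundaries in mL of class ``i``."""
    if not (1 <= i <= scheme.n_classes):
        raise ValueError(f"class index {i} outside 1..{scheme.n_classes}")
    return (scheme.v_min + (i - 1) * scheme.unit, scheme.v_min + i * scheme.unit)


def reference_volume(i: int, scheme: ReferenceScheme, normalized: bool = False) -> float:
    """Reference (midpoint) volume of class ``i``.

    Normalized form is ``i/N - 1/(2N)``; the raw form maps it back into mL and
    equals the arithmetic midpoint of the class interval.
    """
    if not (1 <= i <= scheme.n_classes):
        raise ValueError(f"class index {i} outside 1..{scheme.n_classes}")
    n = scheme.n_classes
    v_bar = i / n - 1.0 / (2 * n)
    if normalized:
        return v_bar
    return denormalize_volume(v_bar, scheme)


def reference_volumes(scheme: ReferenceScheme, normalized: bool = False) -> np.ndarray:
    """Vector of all N reference volumes, ordered by class index."""
    return np.array(
        [reference_volume(i, scheme, normalized) for i in range(1, scheme.n_classes + 1)]
    )


def rescale_scheme(
    scheme: ReferenceScheme, r_train: float, r_new: float
) -> ReferenceScheme:
    """Transfer a scheme to a plate of a different radius.

    With ``s = r_new / r_train`` every reference volume scales by ``s**3``
    (isotropic scaling of the underlying 3D models); N is unchanged.
    """
    if r_train <= 0 or r_new <= 0:
        raise ValueError("plate radii must be positive")
    s3 = (r_new / r_train) ** 3
    return replace(scheme, v_min=scheme.v_min * s3, v_max=scheme.v_max * s3)


def merge_manifests(manifests: list[tuple[pd.DataFrame, ReferenceScheme]]) -> pd.DataFrame:
    """Combine dataset manifests recorded under different volume ranges.

    Images whose *normalized* volumes are equal belong to the same class, so
    manifests sharing the same N can be pooled into one training table:
    class labels are recomputed on the normalized scale (which leaves them
    unchanged — normalization is affine and the ladders are uniform) and the
    rows concatenated.

    Parameters
    ----------
    manifests:
        List of ``(frame, scheme)`` pairs; frames follow the manifest layout
        of :mod:`platevol.simulate.dataset`.
    """
    if not manifests:
        raise ValueError("no manifests to merge")
    n = manifests[0][1].n_classes
    for _, scheme in manifests:
        if scheme.n_classes != n:
            raise ValueError(
                f"cannot merge schemes with different class counts ({scheme.n_classes} != {n})"
            )
    unit_scheme = ReferenceScheme(n, 0.0, 1.0)
    frames = []
    for frame, scheme in manifests:
        frame = frame.copy()
        v_bar = frame["volume_ml"].map(lambda v: normalize_volume(v, scheme))
        frame["normalized_volume"] = v_bar
        frame["class"] = v_bar.map(lambda x: assign_class(x, unit_scheme))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
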