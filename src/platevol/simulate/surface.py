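"""Random smooth food surfaces in spherical coordinates.

A food mound is modelled as a radial-distance field r(theta, phi) over
azimuth theta in [0, 360) and polar angle phi in [0, 90] (phi = 0 is the
apex, phi = 90 the plate plane).  Radii are drawn i.i.d. from a Gaussian
N(mean_radius, spread) and low-pass filtered with a small 2D mask until the
surface is smooth; the azimuth axis is cyclic and the polar axis
edge-replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_THETA = 8
MIN_PHI = 4

# radii are clipped below at this fraction of the mean so the surface stays
# strictly star-shaped about the origin
RADIUS_FLOOR_FRACTION = 0.05

__all__ = ["SphericalGrid", "SmoothingMask", "sample_radial_grid", "smooth_grid"]


@dataclass(frozen=True)
class SphericalGrid:
    """Radial distances on a regular (theta, phi) grid.

    ``radii[i, j]`` is the distance from the origin along azimuth
    ``theta_i = i * 360/n_theta`` degrees and polar angle
    ``phi_j = j * 90/(n_phi - 1)`` degrees.  The theta axis wraps; phi spans
    the closed range [0, 90] including both the apex ring and the base ring.
    """

    radii: np.ndarray  # (n_theta, n_phi)
    mean_radius: float
    spread: float
    seed: int

    def __post_init__(self) -> None:
        r = np.asarray(self.radii)
        if r.ndim != 2 or r.shape[0] < MIN_THETA or r.shape[1] < MIN_PHI:
            raise ValueError(
                f"grid must be at least {MIN_THETA} x {MIN_PHI} (theta x phi), got {r.shape}"
            )
        if not np.all(r > 0):
            raise ValueError("all radii must be strictly positive")

    @property
    def n_theta(self) -> int:
        return self.radii.shape[0]

    @property
    def n_phi(self) -> int:
        return self.radii.shape[1]

    @property
    def theta(self) -> np.ndarray:
        """Azimuth sample angles in radians, equally spaced over [0, 2*pi)."""
        return np.linspace(0.0, 2 * np.pi, self.n_theta, endpoint=False)

    @property
    def phi(self) -> np.ndarray:
        """Polar sample angles in radians, equally spaced over [0, pi/2]."""
        return np.linspace(0.0, np.pi / 2, self.n_phi)


@dataclass(frozen=True)
class SmoothingMask:
    """Small non-negative 2D low-pass kernel over (theta, phi) offsets.

    Coefficients must sum to 1 (so constants are preserved) and both side
    lengths must be odd (so the kernel is centred).
    """

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 2 or c.shape[0] % 2 == 0 or c.shape[1] % 2 == 0:
            raise ValueError(f"mask must be 2D with odd side lengths, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("mask coefficients must be non-negative")
        if not np.isclose(c.sum(), 1.0, atol=1e-9):
            raise ValueError(f"mask coefficients must sum to 1, got {c.sum()}")

    @classmethod
    def binomial(cls, size: int = 5) -> "SmoothingMask":
        """Separable binomial (approximately Gaussian) kernel of odd ``size``."""
        row = np.array([1.0])
        for _ in range(size - 1):
            row = np.convolve(row, [0.5, 0.5])
        return cls(np.outer(row, row))


def sample_radial_grid(
    mean_radius: float,
    spread: float,
    n_theta: int = 64,
    n_phi: int = 32,
    seed: int = 0,
) -> SphericalGrid:
    """Draw a raw (unsmoothed) radial field from N(mean_radius, spread).

    Each grid point gets an independent Gaussian draw, clipped below at
    ``RADIUS_FLOOR_FRACTION * mean_radius`` to keep the surface valid.  The
    same seed reproduces the identical grid.
    """
    if mean_radius <= 0:
        raise ValueError(f"mean_radius must be positive, got {mean_radius}")
    if spread < 0:
        raise ValueError(f"spread must be non-negative, got {spread}")
    if n_theta < MIN_THETA or n_phi < MIN_PHI:
        raise ValueError(
            f"grid must be at least {MIN_THETA} x {MIN_PHI}, got {n_theta} x {n_phi}"
        )
    rng = np.random.default_rng(seed)
    radii = rng.normal(mean_radius, spread, size=(n_theta, n_phi))
    radii = np.maximum(radii, RADIUS_FLOOR_FRACTION * mean_radius)
    return SphericalGrid(radii=radii, mean_radius=mean_radius, spread=spread, seed=seed)


def smooth_grid(
    grid: SphericalGrid, mask: SmoothingMask | None = None, passes: int = 2
) -> SphericalGrid:
    """Low-pass filter the radial field with a 2D mask.

    Each radius is replaced by the mask-weighted average of its
    neighbourhood; the theta axis wraps (the surface is periodic in azimuth)
    and the phi axis edge-replicates.  Unit-sum masks preserve constants and
    never increase the variance of the field.
    """
    if mask is None:
        mask = SmoothingMask.binomial(5)
    if passes < 1:
        raise ValueError(f"passes must be >= 1, got {passes}")
    c = np.asarray(mask.coefficients, dtype=float)
    kt, kp = c.shape
    ht, hp = kt // 2, kp // 2
    radii = np.asarray(grid.radii, dtype=float)
    for _ in range(passes):
        # pad: replicate in phi, wrap in theta, then correlate with the mask
        padded = np.pad(radii, ((0, 0), (hp, hp)), mode="edge")
        padded = np.pad(padded, ((ht, ht), (0, 0)), mode="wrap")
        out = np.zeros_like(radii)
        for di in range(kt):
            for dj in range(kp):
                if c[di, dj] == 0.0:
                    continue
                out += c[di, dj] * padded[di : di + radii.shape[0], dj : dj + radii.shape[1]]
        radii = out
    return SphericalGrid(
        radii=radii, mean_radius=grid.mean_radius, spread=grid.spread, seed=grid.seed
    )
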