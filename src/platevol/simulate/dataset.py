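"""Virtual food dataset generation.

Random shapes are sampled, smoothed, meshed and measured; a shape is
accepted into a class quota only when its exact mesh volume falls inside
that class's interval (rejection sampling), so every manifest row carries a
ground-truth volume consistent with its label.  Volumes outside
[v_min, v_max] are discarded.  The mean radius of each attempted shape is
drawn from the radius band implied by the target class's volume interval
(inverting the hemisphere volume formula), which keeps the rejection rate
low across the whole ladder.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from ..reference import ReferenceScheme, assign_class, class_boundaries
from .mesh import MeshDegenerateError, build_mesh, mesh_volume
from .render import CameraConfig, PlateOverhangError, render_sample
from .surface import SmoothingMask, sample_radial_grid, smooth_grid

MANIFEST_COLUMNS = [
    "image_path",
    "volume_ml",
    "class",
    "split",
    "plate_radius_px",
    "plate_radius_world",
    "seed",
]

__all__ = [
    "SimulatorParams",
    "QuotaError",
    "generate_dataset",
    "save_manifest",
    "load_manifest",
    "MANIFEST_COLUMNS",
]


class QuotaError(RuntimeError):
    """A class quota could not be filled within the attempt budget."""


def _radius_for_volume(v: float) -> float:
    """Mean radius of a hemisphere with volume v (length in cm, volume in mL)."""
    return (3.0 * v / (2.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SimulatorParams:
    """Settings of the synthetic food-shape simulator.

    Lengths are in cm so mesh volumes are in mL.  ``sigma_factor`` sets the
    Gaussian spread of the raw radial field as a fraction of its mean; the
    mean radius of each attempted shape is the hemisphere radius of a target
    volume drawn uniformly over the class interval, so exact volumes cover
    each class evenly.  ``r_hat_margin`` widens the largest plausible food
    when sizing the default plate.
    """

    n_theta: int = 64
    n_phi: int = 32
    sigma_factor: float = 0.15
    r_hat_margin: float = 0.06
    mask_size: int = 5
    smoothing_passes: int = 2
    out_size: int = 224
    plate_radius_world: float | None = None  # default: fits the largest food
    plate_margin: float = 1.18
    camera: CameraConfig = field(default_factory=CameraConfig)
    attempt_budget_factor: int = 60

    def plate_radius_for(self, scheme: ReferenceScheme) -> float:
        if self.plate_radius_world is not None:
            return self.plate_radius_world
        # the widest plausible food: max-volume hemisphere plus radial spread
        r_max = _radius_for_volume(scheme.v_max) * (1 + self.r_hat_margin)
        return r_max * self.plate_margin


def generate_dataset(
    scheme: ReferenceScheme,
    n_train_per_class: int,
    n_test_per_class: int,
    sim_params: SimulatorParams | None = None,
    seed: int = 0,
    out_dir: str = ".",
) -> pd.DataFrame:
    """Generate a labeled virtual food dataset.

    Renders ``n_classes * (n_train + n_test)`` PNG images under ``out_dir``
    and returns (and writes) the manifest.  Each class quota is filled by
    rejection sampling; the train/test assignment within a class follows the
    requested per-class counts.  The same seed reproduces the identical
    dataset.
    """
    if n_train_per_class < 1 or n_test_per_class < 1:
        raise ValueError("per-class counts must be >= 1")
    sim = sim_params or SimulatorParams()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    mask = SmoothingMask.binomial(sim.mask_size)
    plate_r = sim.plate_radius_for(scheme)
    quota = n_train_per_class + n_test_per_class
    budget = sim.attempt_budget_factor * quota

    rows = []
    for ci in range(1, scheme.n_classes + 1):
        lo, hi = class_boundaries(ci, scheme)
        accepted = 0
        attempts = 0
        while accepted < quota:
            if attempts >= budget:
                raise QuotaError(
                    f"class {ci} ({lo:.0f}-{hi:.0f} mL): only {accepted}/{quota} shapes "
                    f"accepted after {attempts} attempts; widen the simulator parameters"
                )
            attempts += 1
            grid_seed = int(rng.integers(2**31))
            texture_seed = int(rng.integers(2**31))
            # aim at a volume drawn uniformly over the class interval so true
            # volumes cover each class evenly; accept on the exact mesh volume
            v_target = float(rng.uniform(lo, hi))
            r_hat = _radius_for_volume(v_target)
            grid = sample_radial_grid(
                r_hat, sim.sigma_factor * r_hat, sim.n_theta, sim.n_phi, seed=grid_seed
            )
            grid = smooth_grid(grid, mask, passes=sim.smoothing_passes)
            try:
                mesh = build_mesh(grid)
            except MeshDegenerateError:
                continue
            volume = mesh_volume(mesh)
            if not (lo <= volume < hi or (ci == scheme.n_classes and volume == hi)):
                continue
            try:
                sample = render_sample(
                    mesh,
                    plate_radius_world=plate_r,
                    camera=sim.camera,
                    texture_seed=texture_seed,
                    out_size=sim.out_size,
                )
            except PlateOverhangError:
                continue
            split = "train" if accepted < n_train_per_class else "test"
            name = f"cls{ci:02d}_{accepted:04d}_{split}.png"
            Image.fromarray(sample.image).save(os.path.join(out_dir, name))
            rows.append(
                {
                    "image_path": name,
                    "volume_ml": volume,
                    "class": assign_class(volume, scheme),
                    "split": split,
                    "plate_radius_px": sample.plate_radius_px,
                    "plate_radius_world": plate_r,
                    "seed": grid_seed,
                }
            )
            accepted += 1

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    save_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest


def save_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def load_manifest(path: str) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    for p in manifest["image_path"]:
        if not os.path.exists(os.path.join(base, p)):
            raise FileNotFoundError(f"manifest references missing image: {p}")
    return manifest
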