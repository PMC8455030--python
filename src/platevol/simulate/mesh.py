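"""Triangulated food solids and exact volumes.

A :class:`SphericalGrid` is turned into a closed solid: the grid rings are
placed at polar angles ``phi_j = j * 90/n_phi`` for ``j = 1..n_phi`` (the
ring at 90 degrees lies in the plate plane z = 0), the apex at phi = 0 is a
single dedicated vertex, and the solid is closed by a triangle fan at the
apex and a flat base disk at z = 0.  This yields exactly
``n_theta * n_phi + 2`` vertices and a watertight, consistently oriented
surface whose volume is computed exactly by the signed-tetrahedron
(divergence-theorem) sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .surface import SphericalGrid

__all__ = [
    "FoodMesh",
    "MeshDegenerateError",
    "build_mesh",
    "mesh_volume",
    "scale_model",
    "voxel_volume",
]


class MeshDegenerateError(ValueError):
    """The generated surface is not a valid closed solid; resample the shape."""


@dataclass(frozen=True)
class FoodMesh:
    """Closed triangulated solid resting on the plate plane z = 0.

    ``vertices`` are Cartesian (n, 3) coordinates in the simulator's length
    unit; ``faces`` are (m, 3) vertex-index triples with consistent outward
    orientation (positive signed volume).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    @property
    def max_horizontal_radius(self) -> float:
        """Largest distance of any vertex from the vertical axis through the origin."""
        return float(np.hypot(self.vertices[:, 0], self.vertices[:, 1]).max())


def build_mesh(grid: SphericalGrid) -> FoodMesh:
    """Triangulate a radial field into a closed solid on the plate plane.

    Raises :class:`MeshDegenerateError` if the result is not watertight or
    has non-positive volume (a signal to resample the underlying grid).
    """
    radii = np.asarray(grid.radii, dtype=float)
    n_theta, n_phi = radii.shape
    theta = grid.theta  # (n_theta,)
    # rings at phi = delta, 2*delta, ..., 90 deg; apex handled separately
    phi = np.linspace(0.0, np.pi / 2, n_phi + 1)[1:]  # (n_phi,)

    sin_phi = np.sin(phi)[None, :]
    cos_phi = np.cos(phi)[None, :]
    cos_t = np.cos(theta)[:, None]
    sin_t = np.sin(theta)[:, None]
    x = radii * sin_phi * cos_t
    y = radii * sin_phi * sin_t
    z = radii * cos_phi
    # the phi = 90 ring lies exactly in the plate plane
    z[:, -1] = 0.0

    grid_verts = np.stack([x, y, z], axis=-1).reshape(n_theta * n_phi, 3)
    apex_r = float(radii[:, 0].mean())
    apex = np.array([[0.0, 0.0, apex_r]])
    base_center = np.array([[0.0, 0.0, 0.0]])
    vertices = np.vstack([grid_verts, apex, base_center])
    i_apex = n_theta * n_phi
    i_base = i_apex + 1

    def idx(i: int, j: int) -> int:
        return (i % n_theta) * n_phi + j

    faces: list[tuple[int, int, int]] = []
    # apex fan to the innermost ring (outward = counter-clockwise from above)
    for i in range(n_theta):
        faces.append((i_apex, idx(i, 0), idx(i + 1, 0)))
    # lateral surface between consecutive rings
    for j in range(n_phi - 1):
        for i in range(n_theta):
            a, b = idx(i, j), idx(i + 1, j)
            c, d = idx(i, j + 1), idx(i + 1, j + 1)
            faces.append((a, c, b))
            faces.append((b, c, d))
    # flat base disk sewn to the phi = 90 ring, normal pointing down
    for i in range(n_theta):
        faces.append((i_base, idx(i + 1, n_phi - 1), idx(i, n_phi - 1)))

    mesh = FoodMesh(vertices=vertices, faces=np.asarray(faces, dtype=np.int64))
    if not mesh.is_watertight:
        raise MeshDegenerateError("triangulated surface is not watertight")
    if _signed_volume(mesh.vertices, mesh.faces) <= 0:
        raise MeshDegenerateError("triangulated surface has non-positive volume")
    return mesh


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def mesh_volume(mesh: FoodMesh) -> float:
    """Exact volume of a watertight solid by the signed-tetrahedron sum.

    Each face spans a tetrahedron with the origin; signed volumes cancel
    outside the solid and add up to the enclosed volume (divergence theorem).
    """
    if not mesh.is_watertight:
        raise MeshDegenerateError("volume requires a watertight mesh")
    v = _signed_volume(mesh.vertices, mesh.faces)
    if v <= 0:
        raise MeshDegenerateError("mesh is inside-out (non-positive signed volume)")
    return v


def scale_model(mesh: FoodMesh, s: float) -> FoodMesh:
    """Scale a solid isotropically by ``s``; the volume scales by ``s**3``."""
    if s <= 0:
        raise ValueError(f"scale factor must be positive, got {s}")
    return FoodMesh(vertices=mesh.vertices * s, faces=mesh.faces)


def voxel_volume(grid: SphericalGrid, resolution: int = 256) -> float:
    """Independent voxel-counting volume of the solid defined by a radial field.

    The solid is star-shaped about the origin: a point with spherical
    coordinates (rho, theta, phi), z >= 0, is inside iff rho is at most the
    bilinearly interpolated surface radius at (theta, phi).  Voxel centres on
    a ``resolution**3`` lattice over the bounding box are tested and counted.
    This path shares no code with the signed-tetrahedron sum and serves as
    its oracle.
    """
    radii = np.asarray(grid.radii, dtype=float)
    n_theta, n_phi = radii.shape
    # extended field including the apex row at phi = 0 (mean of the inner ring)
    ext = np.empty((n_theta, n_phi + 1))
    ext[:, 0] = radii[:, 0].mean()
    ext[:, 1:] = radii
    d_theta = 2 * np.pi / n_theta
    d_phi = (np.pi / 2) / n_phi

    r_max = radii.max()
    half = r_max * 1.001
    xs = np.linspace(-half, half, resolution, endpoint=False) + half / resolution
    zs = np.linspace(0.0, half, resolution, endpoint=False) + half / (2 * resolution)
    voxel = (2 * half / resolution) ** 2 * (half / resolution)

    X, Y = np.meshgrid(xs, xs, indexing="ij")
    rho_xy2 = X**2 + Y**2
    theta = np.mod(np.arctan2(Y, X), 2 * np.pi)
    t = theta / d_theta
    t0 = np.floor(t).astype(np.int64) % n_theta
    t1 = (t0 + 1) % n_theta
    wt = t - np.floor(t)

    count = 0
    for z in zs:
        rho = np.sqrt(rho_xy2 + z * z)
        phi = np.arctan2(np.sqrt(rho_xy2), z)
        p = np.clip(phi / d_phi, 0.0, n_phi - 1e-9)
        p0 = np.floor(p).astype(np.int64)
        wp = p - p0
        r_surf = (
            ext[t0, p0] * (1 - wt) * (1 - wp)
            + ext[t1, p0] * wt * (1 - wp)
            + ext[t0, p0 + 1] * (1 - wt) * wp
            + ext[t1, p0 + 1] * wt * wp
        )
        count += int(np.count_nonzero(rho <= r_surf))
    return count * voxel
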