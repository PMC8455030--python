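"""Rendering of food solids on a circular plate.

Scenes are rasterized with a small z-buffer renderer (numba-compiled
triangle fill): the plate is a filled disk at z = 0, the food solid sits on
it, faces are shaded with a single directional light (flat Lambertian), and
surface albedo comes from seeded multi-octave value-noise colormaps so that
appearance varies across samples without any external image assets.  The
camera is perspective, placed at a configurable elevation above the plate
and framed so the plate spans a fixed fraction of the image width — the
rendered images are therefore already plate-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mesh import FoodMesh, mesh_volume

__all__ = ["CameraConfig", "RenderedSample", "PlateOverhangError", "render_sample"]


class PlateOverhangError(ValueError):
    """The food solid extends horizontally beyond the plate rim."""


@dataclass(frozen=True)
class CameraConfig:
    """Perspective view of the plate scene.

    elevation_deg:
        Angle of the camera above the plate plane; 45 degrees gives the
        oblique tabletop view typical of wearable-camera food images.
    azimuth_deg:
        Direction the camera looks from, in the plate plane.
    distance_factor:
        Camera distance from the plate centre, in units of plate radii.
    frame_fill:
        Fraction of the image width the plate diameter occupies.
    """

    elevation_deg: float = 45.0
    azimuth_deg: float = 0.0
    distance_factor: float = 4.0
    frame_fill: float = 0.95


@dataclass
class RenderedSample:
    """One rendered scene with its volumetric ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    true_volume: float  # mL
    plate_radius_px: float
    plate_radius_world: float
    food_fraction: float  # fraction of frame covered by food pixels
    scene_fraction: float  # fraction covered by food + plate
    seed: int
    class_label: int | None = None
    split: str = ""


@njit(cache=True)
def _rasterize(px, py, depth, faces, colors, ids, img, zbuf, idbuf):
    h, w = zbuf.shape
    for k in range(faces.shape[0]):
        i0, i1, i2 = faces[k, 0], faces[k, 1], faces[k, 2]
        z0, z1, z2 = depth[i0], depth[i1], depth[i2]
        if z0 <= 1e-3 or z1 <= 1e-3 or z2 <= 1e-3:
            continue
        x0, y0 = px[i0], py[i0]
        x1, y1 = px[i1], py[i1]
        x2, y2 = px[i2], py[i2]
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area > -1e-12 and area < 1e-12:
            continue
        inv = 1.0 / area
        minx = int(max(min(x0, min(x1, x2)), 0.0))
        maxx = int(min(max(x0, max(x1, x2)), w - 1.0))
        miny = int(max(min(y0, min(y1, y2)), 0.0))
        maxy = int(min(max(y0, max(y1, y2)), h - 1.0))
        for yy in range(miny, maxy + 1):
            pyc = yy + 0.5
            for xx in range(minx, maxx + 1):
                pxc = xx + 0.5
                w0 = ((x1 - pxc) * (y2 - pyc) - (x2 - pxc) * (y1 - pyc)) * inv
                w1 = ((x2 - pxc) * (y0 - pyc) - (x0 - pxc) * (y2 - pyc)) * inv
                w2 = 1.0 - w0 - w1
                if w0 >= 0.0 and w1 >= 0.0 and w2 >= 0.0:
                    zz = w0 * z0 + w1 * z1 + w2 * z2
                    if zz < zbuf[yy, xx]:
                        zbuf[yy, xx] = zz
                        idbuf[yy, xx] = ids[k]
                        img[yy, xx, 0] = colors[k, 0]
                        img[yy, xx, 1] = colors[k, 1]
                        img[yy, xx, 2] = colors[k, 2]


def _hash01(ix: np.ndarray, iy: np.ndarray, iz: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic lattice hash to [0, 1)."""
    h = (
        ix.astype(np.uint64) * np.uint64(73856093)
        ^ iy.astype(np.uint64) * np.uint64(19349663)
        ^ iz.astype(np.uint64) * np.uint64(83492791)
        ^ np.uint64(seed) * np.uint64(2654435761)
    )
    h = (h ^ (h >> np.uint64(13))) * np.uint64(0x5BD1E995)
    h = h ^ (h >> np.uint64(15))
    return (h & np.uint64(0xFFFFFF)).astype(np.float64) / float(0x1000000)


def _value_noise3(points: np.ndarray, seed: int, octaves: int = 3, freq: float = 1.0) -> np.ndarray:
    """Multi-octave trilinear value noise in [0, 1] at 3D points."""
    out = np.zeros(points.shape[0])
    amp, total = 1.0, 0.0
    for o in range(octaves):
        p = points * (freq * (2.0**o)) + 100.0
        ip = np.floor(p).astype(np.int64)
        fp = p - ip
        fp = fp * fp * (3 - 2 * fp)  # smoothstep
        acc = np.zeros(points.shape[0])
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = (
                        (fp[:, 0] if dx else 1 - fp[:, 0])
                        * (fp[:, 1] if dy else 1 - fp[:, 1])
                        * (fp[:, 2] if dz else 1 - fp[:, 2])
                    )
                    acc += wgt * _hash01(ip[:, 0] + dx, ip[:, 1] + dy, ip[:, 2] + dz, seed + o)
        out += amp * acc
        total += amp
        amp *= 0.5
    return out / total


def _background(out_size: int, seed: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:out_size, 0:out_size]
    pts = np.stack([xx.ravel() / out_size * 4, yy.ravel() / out_size * 4, np.zeros(out_size**2)], axis=1)
    t = _value_noise3(pts, seed + 9000, octaves=3).reshape(out_size, out_size)
    c1 = rng.uniform(0.15, 0.45, size=3)
    c2 = rng.uniform(0.25, 0.6, size=3)
    return c1[None, None, :] * (1 - t[..., None]) + c2[None, None, :] * t[..., None]


def _look_at(camera: CameraConfig, plate_radius: float):
    e = np.deg2rad(camera.elevation_deg)
    a = np.deg2rad(camera.azimuth_deg)
    d = camera.distance_factor * plate_radius
    pos = d * np.array([np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e)])
    fwd = -pos / np.linalg.norm(pos)
    right = np.cross(fwd, np.array([0.0, 0.0, 1.0]))
    right /= np.linalg.norm(right)
    up = np.cross(right, fwd)
    return pos, fwd, right, up, d


def _project(points: np.ndarray, pos, fwd, right, up, focal: float, out_size: int):
    q = points - pos[None, :]
    zc = q @ fwd
    xc = q @ right
    yc = q @ up
    px = focal * xc / zc + out_size / 2.0
    py = out_size / 2.0 - focal * yc / zc
    return px, py, zc


def _plate_disk(radius: float, segments: int = 72):
    ang = np.linspace(0, 2 * np.pi, segments, endpoint=False)
    ring = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(segments)], axis=1)
    verts = np.vstack([ring, [[0.0, 0.0, 0.0]]])
    faces = np.array([[segments, i, (i + 1) % segments] for i in range(segments)], dtype=np.int64)
    return verts, faces


def render_sample(
    mesh: FoodMesh,
    plate_radius_world: float,
    camera: CameraConfig | None = None,
    texture_seed: int = 0,
    out_size: int = 224,
    min_scene_fraction: float = 0.45,
) -> RenderedSample:
    """Render a food solid on a circular plate into an RGB image.

    Identical inputs and seed produce bit-identical images.  Raises
    :class:`PlateOverhangError` if the solid extends beyond the plate rim,
    and ``ValueError`` if food + plate cover less of the frame than
    ``min_scene_fraction``.
    """
    camera = camera or CameraConfig()
    if mesh.max_horizontal_radius > plate_radius_world * (1 + 1e-9):
        raise PlateOverhangError(
            f"food radius {mesh.max_horizontal_radius:.2f} exceeds plate radius "
            f"{plate_radius_world:.2f}"
        )
    rng = np.random.default_rng(texture_seed)
    pos, fwd, right, up, d = _look_at(camera, plate_radius_world)
    focal = camera.frame_fill * out_size * d / (2 * plate_radius_world)
    plate_radius_px = camera.frame_fill * out_size / 2.0

    pv, pf = _plate_disk(plate_radius_world)
    verts = np.vstack([pv, mesh.vertices])
    faces = np.vstack([pf, mesh.faces + len(pv)])
    obj_ids = np.concatenate(
        [np.ones(len(pf), dtype=np.uint8), np.full(len(mesh.faces), 2, dtype=np.uint8)]
    )

    # face normals and backface culling against the camera
    v0, v1, v2 = (verts[faces[:, i]] for i in range(3))
    normals = np.cross(v1 - v0, v2 - v0)
    nlen = np.linalg.norm(normals, axis=1, keepdims=True)
    nlen[nlen == 0] = 1.0
    normals = normals / nlen
    centroids = (v0 + v1 + v2) / 3.0
    facing = np.einsum("ij,ij->i", normals, pos[None, :] - centroids) > 0
    faces, normals, centroids, obj_ids = (
        faces[facing],
        normals[facing],
        centroids[facing],
        obj_ids[facing],
    )

    # flat Lambertian shading with one directional light
    light = np.array([0.4, 0.3, 0.85])
    light /= np.linalg.norm(light)
    shade = 0.35 + 0.65 * np.clip(normals @ light, 0.0, None)

    # albedo: plate is light gray; food gets a seeded value-noise colormap
    albedo = np.empty((len(faces), 3))
    albedo[obj_ids == 1] = np.array([0.88, 0.87, 0.85])
    food_sel = obj_ids == 2
    if food_sel.any():
        scale = 2.5 / max(plate_radius_world, 1e-9)
        t = _value_noise3(centroids[food_sel] * scale, texture_seed, octaves=3)
        c1 = rng.uniform([0.45, 0.25, 0.1], [0.95, 0.75, 0.45])
        c2 = rng.uniform([0.25, 0.12, 0.05], [0.8, 0.6, 0.4])
        albedo[food_sel] = c1[None, :] * (1 - t[:, None]) + c2[None, :] * t[:, None]
    colors = np.clip(albedo * shade[:, None], 0.0, 1.0).astype(np.float32)

    px, py, zc = _project(verts, pos, fwd, right, up, focal, out_size)
    img = _background(out_size, texture_seed, rng).astype(np.float32)
    zbuf = np.full((out_size, out_size), np.inf, dtype=np.float32)
    idbuf = np.zeros((out_size, out_size), dtype=np.uint8)
    _rasterize(
        px.astype(np.float32),
        py.astype(np.float32),
        zc.astype(np.float32),
        faces.astype(np.int64),
        colors,
        obj_ids,
        img,
        zbuf,
        idbuf,
    )

    food_fraction = float(np.count_nonzero(idbuf == 2)) / idbuf.size
    scene_fraction = float(np.count_nonzero(idbuf > 0)) / idbuf.size
    if scene_fraction < min_scene_fraction:
        raise ValueError(
            f"food + plate cover {scene_fraction:.2f} of the frame, "
            f"below the configured minimum {min_scene_fraction}"
        )
    image = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    return RenderedSample(
        image=image,
        true_volume=mesh_volume(mesh),
        plate_radius_px=plate_radius_px,
        plate_radius_world=plate_radius_world,
        food_fraction=food_fraction,
        scene_fraction=scene_fraction,
        seed=texture_seed,
    )
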