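"""Plate-anchored image normalization.

Cropping the plate (plus a small margin) out of a photograph and resizing
the crop to a fixed side length forces every plate to the same radius in
pixels — effectively normalizing plate size to 1 — so one trained model
serves plates of any physical size; only the reference volumes need
rescaling at estimation time.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = ["crop_and_resize"]


def crop_and_resize(
    image: np.ndarray,
    plate_center: tuple[float, float],
    plate_radius_px: float,
    out_size: int = 224,
    margin: float = 0.05,
) -> np.ndarray:
    """Square crop tightly enclosing the plate circle, resampled to ``out_size``.

    ``plate_center`` is (x, y) in pixels.  The crop side is
    ``2 * plate_radius_px * (1 + margin)``; after resampling the plate radius
    is the fixed fraction ``1 / (2 * (1 + margin))`` of ``out_size``.  Raises
    if the crop exceeds the image bounds.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {arr.shape}")
    if plate_radius_px <= 0:
        raise ValueError("plate_radius_px must be positive")
    cx, cy = plate_center
    half = plate_radius_px * (1 + margin)
    x0, x1 = cx - half, cx + half
    y0, y1 = cy - half, cy + half
    h, w = arr.shape[:2]
    if x0 < -0.51 or y0 < -0.51 or x1 > w + 0.51 or y1 > h + 0.51:
        raise ValueError(
            f"plate region [{x0:.1f}, {x1:.1f}] x [{y0:.1f}, {y1:.1f}] exceeds "
            f"image bounds {w} x {h}"
        )
    pil = Image.fromarray(np.asarray(arr, dtype=np.uint8))
    crop = pil.resize(
        (out_size, out_size), Image.BILINEAR, box=(x0, y0, x1, y1)
    )
    return np.asarray(crop)
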