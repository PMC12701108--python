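"""Automatic rectangular breast-region cropping.

The breast region is located from supra-background pixels of the
pre-contrast image: ``Y_min``/``Y_max`` are the first/last columns with
tissue, ``X_min`` the first tissue row anywhere, and ``X_mid`` the first
tissue row in the median column — between the breasts, where the scan hits
the chest wall.  ``X_mid`` plus a safety margin (10 px, about 6.5 mm at the
default resolution) bounds the window posteriorly so that internal organs
are largely excluded while both breasts are fully covered even when one is
larger than the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ContractError, CropWindow

__all__ = [
    "BreastBounds",
    "EmptyForegroundError",
    "find_breast_bounds",
    "build_crop_window",
    "crop_to_window",
    "estimate_background_level",
]

DEFAULT_MARGIN_PX = 10


class EmptyForegroundError(ValueError):
    """No pixel above the background level."""


@dataclass(frozen=True)
class BreastBounds:
    x_min: int
    y_min: int
    y_max: int
    x_mid: int


def estimate_background_level(img: np.ndarray, patch: int = 8, n_sigmas: float = 6.0) -> float:
    """Robust air-background level from the four corner patches.

    MR air background is near zero but noisy, and magnitude images clip the
    noise at zero, so the level is the corner-pixel 99th percentile plus
    ``n_sigmas`` IQR-based standard deviations: pure noise anywhere in the
    frame stays sub-threshold while tissue does not.  A noise-free zero
    background yields level 0 (any positive pixel is foreground).
    """
    img = np.asarray(img, dtype=float)
    p = min(patch, img.shape[0] // 2, img.shape[1] // 2)
    corners = np.concatenate(
        [
            img[:p, :p].ravel(),
            img[:p, -p:].ravel(),
            img[-p:, :p].ravel(),
            img[-p:, -p:].ravel(),
        ]
    )
    q25, q75, q99 = np.percentile(corners, [25, 75, 99])
    sigma = (q75 - q25) / 1.349
    return float(q99 + n_sigmas * sigma)


def find_breast_bounds(img: np.ndarray, background_level: float = 0.0) -> BreastBounds:
    """Scan for the supra-background extent of the anatomy.

    Returns the first tissue row (``x_min``), first/last tissue columns
    (``y_min``/``y_max``) and the first tissue row in the median column
    (``x_mid``).  Even image widths use the lower median column.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ContractError("empty image")
    fg = img > background_level
    if not fg.any():
        raise EmptyForegroundError("no pixel above the background level")
    rows, cols = np.nonzero(fg)
    x_min = int(rows.min())
    y_min = int(cols.min())
    y_max = int(cols.max())
    y_middle = (img.shape[1] - 1) // 2
    mid_rows = np.nonzero(fg[:, y_middle])[0]
    if mid_rows.size == 0:
        raise EmptyForegroundError(
            f"median column {y_middle} is entirely background; cannot bound the chest depth"
        )
    x_mid = int(mid_rows.min())
    return BreastBounds(x_min=x_min, y_min=y_min, y_max=y_max, x_mid=x_mid)


def build_crop_window(
    bounds: BreastBounds,
    image_shape: tuple[int, int],
    margin_px: int = DEFAULT_MARGIN_PX,
) -> CropWindow:
    """Window rows ``[x_min, x_mid + margin]`` x cols ``[y_min, y_max]``.

    The posterior bound is clamped to the last image row.
    """
    if margin_px < 0:
        raise ContractError("margin_px must be >= 0")
    x_max = min(bounds.x_mid + margin_px, image_shape[0] - 1)
    if x_max < bounds.x_min:
        raise ContractError(
            f"degenerate window: posterior bound {x_max} anterior to x_min {bounds.x_min}"
        )
    w = CropWindow(x_min=bounds.x_min, x_max=x_max, y_min=bounds.y_min, y_max=bounds.y_max)
    w.validate_inside(image_shape)
    return w


def crop_to_window(images, window: CropWindow):
    """Crop one array or a sequence of same-shape arrays to ``window``."""
    single = isinstance(images, np.ndarray)
    arrs = [images] if single else list(images)
    out = []
    for a in arrs:
        a = np.asarray(a)
        window.validate_inside(a.shape)
        rs, cs = window.as_slices()
        out.append(a[rs, cs])
    return out[0] if single else out
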