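"""Noise-reduction stage: exponential-target CLAHE then an alternating
sequential morphological filter.

CLAHE here remaps each tile's clipped histogram onto a *truncated
exponential* target distribution on [0, 1] (decay ``alpha``), rather than
the uniform target of plain adaptive equalisation; tile mappings are
blended by bilinear interpolation.  The alternating sequential filter (ASF)
is a grayscale opening followed by a closing for each structuring-element
radius in increasing order, removing bright/dark specks smaller than the
discs while preserving lesion-scale structures.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import closing, disk, opening

from .core import ContractError

__all__ = ["clahe_exponential", "asf_filter"]

DEFAULT_TILES = (8, 8)
DEFAULT_CLIP_LIMIT = 0.01
DEFAULT_ALPHA = 0.4
DEFAULT_ASF_RADII = (1, 2)
_NBINS = 256


def _clip_histogram(hist: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clip bin counts and redistribute the excess uniformly."""
    n = hist.sum()
    limit = max(clip_limit * n, 1.0)
    clipped = np.minimum(hist, limit)
    excess = n - clipped.sum()
    return clipped + excess / hist.size


def _exponential_map(cdf: np.ndarray, alpha: float) -> np.ndarray:
    """Inverse CDF of the exponential distribution truncated to [0, 1]."""
    scale = 1.0 - np.exp(-alpha)
    return -np.log1p(-cdf * scale) / alpha


def clahe_exponential(
    img: np.ndarray,
    tiles: tuple[int, int] = DEFAULT_TILES,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation, exponential target.

    Parameters
    ----------
    img : 2-D array in [0, 1].
    tiles : contextual-region grid (rows, cols).
    clip_limit : histogram clip limit as a fraction of the tile pixel count.
    alpha : decay rate of the truncated-exponential target distribution.

    Returns a same-shape array in [0, 1].
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ContractError("CLAHE input must be 2-D")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ContractError("CLAHE input must be unit-range")
    gr, gc = tiles
    n_r, n_c = img.shape
    if gr > n_r or gc > n_c:
        raise ContractError(f"tile grid {tiles} larger than image {img.shape}")
    if not 0 < clip_limit <= 1:
        raise ContractError("clip_limit must lie in (0, 1]")

    bins = np.minimum((img * _NBINS).astype(int), _NBINS - 1)
    # tile edges (last tile absorbs the remainder)
    r_edges = np.linspace(0, n_r, gr + 1).astype(int)
    c_edges = np.linspace(0, n_c, gc + 1).astype(int)

    luts = np.empty((gr, gc, _NBINS))
    r_centers = np.empty(gr)
    c_centers = np.empty(gc)
    for i in range(gr):
        r_centers[i] = 0.5 * (r_edges[i] + r_edges[i + 1] - 1)
        for j in range(gc):
            c_centers[j] = 0.5 * (c_edges[j] + c_edges[j + 1] - 1)
            tile_bins = bins[r_edges[i] : r_edges[i + 1], c_edges[j] : c_edges[j + 1]]
            hist = np.bincount(tile_bins.ravel(), minlength=_NBINS).astype(float)
            hist = _clip_histogram(hist, clip_limit)
            cdf = np.cumsum(hist) / hist.sum()
            luts[i, j] = _exponential_map(np.clip(cdf, 0.0, 1.0), alpha)

    # bilinear interpolation between the four surrounding tile mappings
    rows = np.arange(n_r)[:, None]
    cols = np.arange(n_c)[None, :]
    ri = np.clip(np.searchsorted(r_centers, rows.ravel(), side="right") - 1, 0, gr - 2) \
        if gr > 1 else np.zeros(n_r, dtype=int)
    ci = np.clip(np.searchsorted(c_centers, cols.ravel(), side="right") - 1, 0, gc - 2) \
        if gc > 1 else np.zeros(n_c, dtype=int)
    if gr > 1:
        wr = (rows.ravel() - r_centers[ri]) / (r_centers[ri + 1] - r_centers[ri])
        wr = np.clip(wr, 0.0, 1.0)
        ri1 = ri + 1
    else:
        wr = np.zeros(n_r)
        ri1 = ri
    if gc > 1:
        wc = (cols.ravel() - c_centers[ci]) / (c_centers[ci + 1] - c_centers[ci])
        wc = np.clip(wc, 0.0, 1.0)
        ci1 = ci + 1
    else:
        wc = np.zeros(n_c)
        ci1 = ci

    RI = ri[:, None]
    RI1 = ri1[:, None]
    CI = ci[None, :]
    CI1 = ci1[None, :]
    WR = wr[:, None]
    WC = wc[None, :]
    out = (
        (1 - WR) * (1 - WC) * luts[RI, CI, bins]
        + (1 - WR) * WC * luts[RI, CI1, bins]
        + WR * (1 - WC) * luts[RI1, CI, bins]
        + WR * WC * luts[RI1, CI1, bins]
    )
    return np.clip(out, 0.0, 1.0)


def asf_filter(img: np.ndarray, radii: tuple[int, ...] = DEFAULT_ASF_RADII) -> np.ndarray:
    """Alternating sequential filter: open-then-close with growing discs."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ContractError("ASF input must be 2-D")
    if len(radii) == 0 or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ContractError(f"radii must be strictly increasing and non-empty, got {radii}")
    out = img
    for r in radii:
        se = disk(r)
        out = closing(opening(out, se), se)
    return out
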