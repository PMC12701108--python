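"""Per-ROI feature extraction on the pre-contrast (Phase 0) image.

The default feature vector has 14 entries: six gray-level co-occurrence
statistics (contrast, correlation, energy, homogeneity, entropy, inverse
difference moment), each direction-averaged over 0/45/90/135 degrees at
pixel distances 1 and 2 (12 values), plus two ring-contrast ratios::

    CON = (I_in - I_r) / (I_in + I_r)
    C   = (I_in - I_r)^2 / (sigma_in^2 + sigma_r^2)

where ``I``/``sigma`` are the mean/SD of Phase 0 intensity inside the
(dilated) ROI and inside a surrounding ring.  The ROI mean and SD are
available as optional extras (off by default, keeping the vector at 14).

Co-occurrence counting is masked: only pixel pairs with *both* endpoints
inside the ROI contribute, so surrounding tissue never leaks into the
texture statistics.  Intensities are quantised to 8 levels over the ROI's
own min-max range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk

from .core import ContractError
from .fp_rules import RoiRecord

__all__ = [
    "FeatureVector",
    "DegeneratePairsError",
    "dilate_mask",
    "ring_mask",
    "glcm_features",
    "contrast_features",
    "extract_feature_vector",
    "GLCM_STAT_NAMES",
    "feature_names",
]

logger = logging.getLogger(__name__)

GLCM_STAT_NAMES = ("contrast", "correlation", "energy", "homogeneity", "entropy", "idm")
DEFAULT_LEVELS = 8
DEFAULT_DISTANCES = (1, 2)
# (drow, dcol) offsets; counting is symmetric so the sign convention is immaterial
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class DegeneratePairsError(ValueError):
    """Too few in-mask pixel pairs to form a co-occurrence matrix."""


def feature_names(distances=DEFAULT_DISTANCES, extras: bool = False) -> list[str]:
    names = [f"{s}_d{d}" for d in distances for s in GLCM_STAT_NAMES]
    names += ["con", "c"]
    if extras:
        names += ["roi_mean", "roi_sd"]
    return names


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ContractError("feature values/names length mismatch")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))

    def __len__(self) -> int:
        return len(self.values)


def dilate_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Binary dilation with a disc; radius 0 is the identity."""
    if radius < 0:
        raise ContractError("dilation radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return dilation(mask, disk(radius)).astype(bool)


def ring_mask(mask: np.ndarray, grow_radius: int = 4) -> np.ndarray:
    """Ring around the ROI: dilation by ``grow_radius`` minus the ROI itself.

    The default radius of 4 px matches the typical area-to-perimeter ratio
    of the detected lesions, giving rings of comparable area to the ROI.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return dilate_mask(mask, grow_radius) & ~mask


def _quantize(img: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray | None:
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return None
    q = np.floor((img - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def _glcm_stats(p: np.ndarray) -> dict:
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    pi = p.sum(axis=1)
    mu_i = float((np.arange(levels) * pi).sum())
    var_i = float(((np.arange(levels) - mu_i) ** 2 * pi).sum())
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    if var_i <= 0:
        logger.warning("constant quantised ROI: correlation undefined, returning 0")
        correlation = 0.0
    else:
        # symmetric matrix: row and column marginals coincide
        correlation = float((((i - mu_i) * (j - mu_i) * p).sum()) / var_i)
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
        "idm": idm,
    }


def glcm_features(
    img: np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> dict:
    """Direction-averaged Haralick statistics from masked co-occurrence matrices.

    For each distance, a symmetric normalised matrix is accumulated per
    angle over pixel pairs whose *both* endpoints lie in ``mask``; the six
    statistics are averaged over the angles.  Returns a dict keyed
    ``"<stat>_d<distance>"``.

    A constant-intensity ROI yields the degenerate single-cell statistics
    (contrast 0, energy 1, homogeneity 1, entropy 0, IDM 1, correlation 0).
    """
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ContractError("glcm_features requires a non-empty mask")
    q = _quantize(img, mask, levels)
    out: dict[str, float] = {}
    if q is None:
        logger.warning("ROI has constant intensity; returning degenerate GLCM statistics")
        degenerate = {"contrast": 0.0, "correlation": 0.0, "energy": 1.0,
                      "homogeneity": 1.0, "entropy": 0.0, "idm": 1.0}
        for d in distances:
            for s in GLCM_STAT_NAMES:
                out[f"{s}_d{d}"] = degenerate[s]
        return out
    n_r, n_c = img.shape
    for d in distances:
        per_angle = []
        for a in angles:
            dr, dc = _ANGLE_OFFSETS[a]
            dr, dc = dr * d, dc * d
            r0s, r0e = max(0, -dr), min(n_r, n_r - dr)
            c0s, c0e = max(0, -dc), min(n_c, n_c - dc)
            src_mask = mask[r0s:r0e, c0s:c0e]
            dst_mask = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
            both = src_mask & dst_mask
            if not both.any():
                continue
            a_vals = q[r0s:r0e, c0s:c0e][both]
            b_vals = q[r0s + dr : r0e + dr, c0s + dc : c0e + dc][both]
            counts = np.zeros((levels, levels))
            np.add.at(counts, (a_vals, b_vals), 1.0)
            counts = counts + counts.T          # symmetric counting
            per_angle.append(_glcm_stats(counts / counts.sum()))
        if not per_angle:
            raise DegeneratePairsError(f"no in-mask pixel pairs at distance {d}")
        for s in GLCM_STAT_NAMES:
            out[f"{s}_d{d}"] = float(np.mean([st[s] for st in per_angle]))
    return out


def contrast_features(img: np.ndarray, mask: np.ndarray, ring: np.ndarray) -> dict:
    """Ring-contrast ratios CON and C plus the in-ROI mean and SD."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    ring = np.asarray(ring, dtype=bool)
    if not mask.any() or not ring.any():
        raise ContractError("contrast_features requires non-empty mask and ring")
    if np.any(mask & ring):
        raise ContractError("mask and ring must be disjoint")
    i_in = float(img[mask].mean())
    i_r = float(img[ring].mean())
    sd_in = float(img[mask].std())
    sd_r = float(img[ring].std())
    if i_in + i_r == 0:
        raise ZeroDivisionError("CON undefined: I_in + I_r = 0")
    denom = sd_in**2 + sd_r**2
    if denom == 0:
        raise ZeroDivisionError("C undefined: both regions have zero variance")
    return {
        "con": (i_in - i_r) / (i_in + i_r),
        "c": (i_in - i_r) ** 2 / denom,
        "roi_mean": i_in,
        "roi_sd": sd_in,
    }


@dataclass
class FeatureConfig:
    dilate_radius: int = 1
    ring_grow_radius: int = 4
    levels: int = DEFAULT_LEVELS
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    include_extras: bool = False


def extract_feature_vector(
    img: np.ndarray, roi: RoiRecord, config: FeatureConfig | None = None
) -> FeatureVector:
    """Full 14-entry feature vector (16 with extras) for one ROI on Phase 0.

    The ROI mask is first dilated by 1 px (disc) to absorb minor patient
    movement between the pre- and post-contrast acquisitions; GLCM and the
    ring contrasts are computed on the dilated mask.
    """
    config = config or FeatureConfig()
    dil = dilate_mask(roi.mask, config.dilate_radius)
    ring = ring_mask(dil, config.ring_grow_radius)
    glcm = glcm_features(img, dil, levels=config.levels, distances=config.distances)
    con = contrast_features(img, dil, ring)
    names = feature_names(config.distances, extras=config.include_extras)
    values = [glcm[n] for n in names if n in glcm]
    values += [con["con"], con["c"]]
    if config.include_extras:
        values += [con["roi_mean"], con["roi_sd"]]
    return FeatureVector(values=np.array(values), names=names)
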