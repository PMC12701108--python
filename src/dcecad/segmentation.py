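"""Enhancing-ROI extraction via multilevel Otsu thresholding.

Each of the second and third post-contrast subtraction images is cropped,
pre-processed and thresholded into five intensity classes (four Otsu
thresholds); the binary image of the top class holds that phase's enhancing
regions.  Intersecting the two binary images keeps only regions that
enhance at *both* time points, which suppresses structures visible in only
one phase.

The threshold search is exact: between-class variance is maximised over the
256-bin histogram by dynamic programming on cumulative moments, so the
result provably equals exhaustive search over all threshold tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ContractError, CropWindow, DcePhaseStack, subtraction_image, to_unit_range
from .crop import build_crop_window, crop_to_window, estimate_background_level, find_breast_bounds
from .preprocess import asf_filter, clahe_exponential

__all__ = [
    "BinaryMask",
    "DegenerateHistogramError",
    "otsu_multilevel",
    "top_class_mask",
    "intersect_masks",
    "segment_slice",
]

DEFAULT_N_THRESHOLDS = 4
_NBINS = 256


class DegenerateHistogramError(ValueError):
    """Image has too few distinct gray levels for the requested classes."""


@dataclass
class BinaryMask:
    values: np.ndarray
    provenance: str  # otsu2 | otsu3 | intersection

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ContractError("mask must be 2-D")


def _histogram(img: np.ndarray, nbins: int) -> np.ndarray:
    bins = np.minimum((np.asarray(img, float) * nbins).astype(int), nbins - 1)
    return np.bincount(bins.ravel(), minlength=nbins).astype(float)


def otsu_multilevel(
    img: np.ndarray, n_thresholds: int = DEFAULT_N_THRESHOLDS, nbins: int = _NBINS
) -> np.ndarray:
    """Exact multilevel Otsu thresholds of a unit-range image.

    Maximises the between-class variance of the ``n_thresholds + 1`` classes
    induced on the ``nbins``-bin histogram.  Thresholds are returned as the
    bin-edge values separating consecutive classes, strictly increasing; a
    pixel belongs to the class above a threshold iff its value is strictly
    greater.  Ties in the objective resolve deterministically (first
    maximiser during the backtrack).
    """
    img = np.asarray(img, dtype=float)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ContractError("otsu_multilevel expects unit-range input")
    if img.max() == img.min():
        raise DegenerateHistogramError("constant image has no thresholds")
    hist = _histogram(img, nbins)
    if np.count_nonzero(hist) < n_thresholds + 1:
        raise DegenerateHistogramError(
            f"only {np.count_nonzero(hist)} distinct levels for {n_thresholds + 1} classes"
        )
    cut_bins = _otsu_dp(hist, n_thresholds)
    # threshold value = upper edge of the last bin of the lower class
    return (cut_bins + 1) / nbins


def _interval_score(hist: np.ndarray) -> np.ndarray:
    """S[i, j] = (sum of x*p over bins i..j)^2 / (sum of p over bins i..j).

    Between-class variance equals sum of these interval scores minus the
    squared global mean, so maximising the score sum maximises the variance.
    Bin "values" are bin indices; any affine bin-value convention yields the
    same argmax.
    """
    n = hist.size
    p = hist / hist.sum()
    x = np.arange(n)
    P = np.concatenate([[0.0], np.cumsum(p)])
    M = np.concatenate([[0.0], np.cumsum(p * x)])
    # W[i][j] for i<=j: total probability of bins i..j = P[j+1]-P[i]
    W = P[1:][None, :] - P[:-1][:, None]
    S1 = M[1:][None, :] - M[:-1][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        sc = np.where(W > 0, S1**2 / np.where(W > 0, W, 1.0), 0.0)
    return np.where(np.arange(n)[:, None] <= np.arange(n)[None, :], sc, -np.inf)


def _otsu_dp(hist: np.ndarray, n_thresholds: int) -> np.ndarray:
    """Exact maximiser over threshold tuples via dynamic programming.

    Returns the bin indices ending each of the first ``n_thresholds``
    classes (the "cut" bins), lexicographically smallest among maximisers.
    """
    n = hist.size
    sc = _interval_score(hist)
    m_classes = n_thresholds + 1
    # f[j] = best score covering bins 0..j with current number of classes
    f = sc[0].copy()                        # one class: interval [0, j]
    arg: list[np.ndarray] = []
    for _ in range(1, m_classes):
        g = np.full(n, -np.inf)
        a = np.zeros(n, dtype=int)
        for j in range(n):
            # previous classes cover 0..i-1, new class covers i..j
            cand = f[:j] + sc[1 : j + 1, j]
            if cand.size:
                best = int(np.argmax(cand))  # first maximiser -> lowest cuts
                g[j] = cand[best]
                a[j] = best                  # previous block ends at bin `best`
        arg.append(a)
        f = g
    cuts = []
    j = n - 1
    for a in reversed(arg):
        j = int(a[j])
        cuts.append(j)
    return np.array(sorted(cuts))


def top_class_mask(img: np.ndarray, thresholds: np.ndarray, provenance: str = "otsu") -> BinaryMask:
    """Binary image of the highest-intensity class: pixels strictly above the top threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ContractError("thresholds must be non-empty")
    return BinaryMask(values=np.asarray(img) > thresholds.max(), provenance=provenance)


def intersect_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    if a.values.shape != b.values.shape:
        raise ContractError(f"mask shapes differ: {a.values.shape} vs {b.values.shape}")
    return BinaryMask(values=a.values & b.values, provenance="intersection")


@dataclass
class SegmentationConfig:
    phases: tuple[int, int] = (2, 3)
    margin_px: int = 10
    background_level: float | None = None   # None -> robust corner estimate
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip_limit: float = 0.01
    clahe_alpha: float = 0.4
    asf_radii: tuple[int, ...] = (1, 2)
    n_thresholds: int = DEFAULT_N_THRESHOLDS


@dataclass
class SegmentationResult:
    mask: BinaryMask                        # intersection, cropped frame
    window: CropWindow
    per_phase_masks: dict = field(default_factory=dict)
    per_phase_filtered: dict = field(default_factory=dict)
    cropped_phase0: np.ndarray | None = None

    def mask_full_frame(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Intersection mask mapped back to full-slice coordinates."""
        full = np.zeros(image_shape, dtype=bool)
        rs, cs = self.window.as_slices()
        full[rs, cs] = self.mask.values
        return full


def preprocess_subtraction(cropped: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Unit-normalise, CLAHE and ASF one cropped subtraction image."""
    enh = clahe_exponential(
        to_unit_range(cropped),
        tiles=config.clahe_tiles,
        clip_limit=config.clahe_clip_limit,
        alpha=config.clahe_alpha,
    )
    return asf_filter(enh, radii=config.asf_radii)


def segment_slice(stack: DcePhaseStack, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Full enhancement-segmentation stage for one slice.

    Crops the breast region (bounds from Phase 0), then independently
    pre-processes and thresholds the subtraction images of the configured
    phases, and intersects their top-class masks.
    """
    config = config or SegmentationConfig()
    phase0 = to_unit_range(stack.phases[0])
    level = (
        estimate_background_level(phase0)
        if config.background_level is None
        else config.background_level
    )
    bounds = find_breast_bounds(phase0, background_level=level)
    window = build_crop_window(bounds, stack.shape, margin_px=config.margin_px)

    per_phase_masks: dict[int, BinaryMask] = {}
    per_phase_filtered: dict[int, np.ndarray] = {}
    for k in config.phases:
        sub = subtraction_image(stack, k)
        cropped = crop_to_window(sub.values, window)
        flt = preprocess_subtraction(cropped, config)
        thr = otsu_multilevel(to_unit_range(flt), n_thresholds=config.n_thresholds)
        per_phase_masks[k] = top_class_mask(to_unit_range(flt), thr, provenance=f"otsu{k}")
        per_phase_filtered[k] = flt

    ks = list(config.phases)
    mask = per_phase_masks[ks[0]]
    for k in ks[1:]:
        mask = intersect_masks(mask, per_phase_masks[k])
    return SegmentationResult(
        mask=mask,
        window=window,
        per_phase_masks=per_phase_masks,
        per_phase_filtered=per_phase_filtered,
        cropped_phase0=crop_to_window(stack.phases[0], window),
    )
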