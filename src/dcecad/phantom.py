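"""Seeded DCE-MRI phantom generator with pixel-level ground truth.

The real study data (axial breast DCE-MRI slices with histopathologically
confirmed enhancing lesions) cannot be redistributed, so every stage of the
pipeline is exercised on synthetic phantoms that reproduce the image
structure the algorithms rely on:

* two breast cross-sections (half-disks) at the anterior edge of the frame,
  resting on a flat chest band, with a thorax body and a strongly enhancing
  heart-like confounder posterior to it;
* enhancing lesions whose time-signal intensity curves follow the three
  canonical kinetic patterns — persistent (monotone rise), plateau (early
  rise then constant) and washout (rise to the second post-contrast phase,
  then strict decrease);
* thin, highly eccentric curvilinear vessel distractors that enhance early
  (these must be rejected by the eccentricity rule downstream);
* additive Gaussian noise.

All randomness flows from the config seed; a fixed seed yields bit-identical
stacks and truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import DcePhaseStack

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "LesionTruth",
    "GenerationError",
    "generate_phantom_series",
    "generate_benchmark",
    "separable_feature_clouds",
]

KINETIC_PATTERNS = ("persistent", "plateau", "washout")


class GenerationError(RuntimeError):
    """Raised when lesions/vessels cannot be placed disjointly."""


@dataclass
class PhantomConfig:
    """Parameters of one synthetic slice.

    ``lesion_radius_range`` is in pixels; a radius-1.8 disk has ~10 px area
    and a radius-4.4 disk ~60 px, spanning the sub-minimum to comfortably
    detectable sizes. ``kinetic_fractions`` must sum to 1. ``noise_sd`` is
    the standard deviation of the additive Gaussian noise relative to the
    unit intensity scale of the phantom.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (2.4, 4.4)
    kinetic_fractions: dict = field(
        default_factory=lambda: {"persistent": 1 / 3, "plateau": 1 / 3, "washout": 1 / 3}
    )
    n_vessels: int = 2
    include_thorax_confounder: bool = True
    noise_sd: float = 0.01
    n_post_phases: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.kinetic_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"kinetic fractions sum to {total}, expected 1")
        if self.lesion_radius_range[0] < 0.5:
            raise ValueError("lesion radius must give area >= 1 px")
        if self.n_post_phases < 3:
            raise ValueError("need >= 3 post-contrast phases")


@dataclass
class LesionTruth:
    mask: np.ndarray
    kinetic: str
    amplitude: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class PhantomTruth:
    """Ground-truth masks for one phantom slice."""

    lesions: list[LesionTruth]
    vessel_mask: np.ndarray
    breast_mask: np.ndarray
    thorax_mask: np.ndarray

    @property
    def lesion_masks(self) -> list[np.ndarray]:
        return [l.mask for l in self.lesions]


# ----------------------------------------------------------------- geometry

# Anatomy layout (row indices for the default 256x256 frame, scaled for
# other shapes): breasts are half-disks anterior to the chest line; the
# chest band spans the full body width so the mid-column depth scan used by
# the cropping stage hits it; heart/body lie posterior to the chest band.
_CHEST_ROW_FRAC = 0.39          # chest line at ~row 100 of 256
_BREAST_RADIUS_FRAC = (0.205, 0.19)
_BREAST_COL_FRAC = (0.25, 0.75)

_BASE_AIR = 0.0
_BASE_BREAST = 0.30
_BASE_LESION = 0.36
_BASE_BODY = 0.34
_PARENCHYMAL_AMP = 0.04         # mild background parenchymal enhancement


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _anatomy(shape: tuple[int, int]):
    """Breast, chest-band, body and heart masks for the frame."""
    n_r, n_c = shape
    chest_row = int(round(_CHEST_ROW_FRAC * n_r))
    rows = np.arange(n_r)[:, None]
    breast = np.zeros(shape, dtype=bool)
    for col_frac, rad_frac in zip(_BREAST_COL_FRAC, _BREAST_RADIUS_FRAC):
        center = (chest_row, col_frac * n_c)
        radius = rad_frac * min(n_r, n_c)
        breast |= _disk_mask(shape, center, radius) & (rows < chest_row)
    band = np.zeros(shape, dtype=bool)
    band[chest_row : chest_row + max(10, n_r // 20), int(0.05 * n_c) : int(0.95 * n_c)] = True
    body = np.zeros(shape, dtype=bool)
    body[chest_row : int(0.85 * n_r), int(0.07 * n_c) : int(0.93 * n_c)] = True
    heart = _disk_mask(shape, (int(0.55 * n_r), n_c / 2), 0.1 * min(n_r, n_c)) & body
    return breast, band, body, heart, chest_row


def _kinetic_fraction(kinetic: str, p: int) -> float:
    """Fraction of peak enhancement at post-contrast phase p (p >= 1)."""
    if kinetic == "persistent":
        return 0.78 + 0.0366 * p          # strictly increasing, strong early uptake
    if kinetic == "plateau":
        return min(0.9 + 0.1 * (p - 1), 1.0)
    if kinetic == "washout":
        return 0.8 + 0.2 * (p - 1) if p <= 2 else 1.0 - 0.12 * (p - 2)
    raise ValueError(f"unknown kinetic pattern {kinetic!r}")


def _place_lesions(rng, cfg: PhantomConfig, breast: np.ndarray, forbidden: np.ndarray):
    """Rejection-sample disjoint elliptical lesions inside the breast mask."""
    shape = breast.shape
    eroded = ndi.binary_erosion(breast, iterations=6)
    candidates = np.argwhere(eroded)
    if candidates.size == 0:
        raise GenerationError("breast interior too small for lesions")
    kinetics = list(cfg.kinetic_fractions)
    probs = np.array([cfg.kinetic_fractions[k] for k in kinetics])
    lesions: list[LesionTruth] = []
    occupied = forbidden.copy()
    # peak amplitudes within one exam share injection/acquisition factors,
    # so they are correlated: per-slice base level with small per-lesion jitter
    base_amp = rng.uniform(0.44, 0.55)
    for _ in range(cfg.n_lesions):
        placed = False
        for _attempt in range(200):
            r0, c0 = candidates[rng.integers(len(candidates))]
            radius = rng.uniform(*cfg.lesion_radius_range)
            ratio = rng.uniform(1.0, 1.5)       # mild ellipticity, ecc << 0.95
            theta = rng.uniform(0, np.pi)
            rr, cc = np.ogrid[: shape[0], : shape[1]]
            dr, dc = rr - r0, cc - c0
            u = dr * np.cos(theta) + dc * np.sin(theta)
            v = -dr * np.sin(theta) + dc * np.cos(theta)
            mask = (u / (radius * ratio)) ** 2 + (v / radius) ** 2 <= 1.0
            mask &= breast
            if mask.sum() < 3:
                continue
            grown = ndi.binary_dilation(mask, iterations=3)
            if np.any(grown & occupied) or not np.all(
                ndi.binary_dilation(mask, iterations=2) <= breast
            ):
                continue
            kinetic = kinetics[int(rng.choice(len(kinetics), p=probs))]
            amplitude = base_amp * rng.uniform(0.92, 1.08)
            lesions.append(LesionTruth(mask=mask, kinetic=kinetic, amplitude=amplitude))
            occupied |= grown
            placed = True
            break
        if not placed:
            raise GenerationError("could not place lesion disjointly after 200 tries")
    return lesions, occupied


def _place_vessels(rng, cfg: PhantomConfig, breast: np.ndarray, occupied: np.ndarray):
    """Thin curvilinear distractors: random walks of ~25 steps, 1-2 px wide."""
    shape = breast.shape
    eroded = ndi.binary_erosion(breast, iterations=5)
    candidates = np.argwhere(eroded)
    vessel = np.zeros(shape, dtype=bool)
    for _ in range(cfg.n_vessels):
        for _attempt in range(100):
            r, c = candidates[rng.integers(len(candidates))].astype(float)
            angle = rng.uniform(0, 2 * np.pi)
            pts = []
            for _step in range(int(rng.integers(26, 40))):
                angle += rng.normal(0.0, 0.05)
                r += np.sin(angle)
                c += np.cos(angle)
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < shape[0] and 0 <= ci < shape[1]) or not breast[ri, ci]:
                    break
                pts.append((ri, ci))
            if len(pts) < 22:
                continue
            m = np.zeros(shape, dtype=bool)
            m[tuple(np.array(pts).T)] = True
            m = ndi.binary_dilation(m, iterations=2)   # ~4-5 px wide, survives ASF
            m &= breast
            if np.any(ndi.binary_dilation(m, iterations=2) & occupied):
                continue
            vessel |= m
            occupied |= ndi.binary_dilation(m, iterations=2)
            break
        # silently generate fewer vessels if a slice is too crowded
    return vessel, occupied


# ---------------------------------------------------------------- generator

def generate_phantom_series(cfg: PhantomConfig) -> tuple[DcePhaseStack, PhantomTruth]:
    """Generate one phantom slice: a phase stack plus its ground truth.

    Phase 0 carries baseline anatomy with smooth parenchymal texture;
    post-contrast phases add per-structure enhancement following the
    structure's kinetic curve, plus iid Gaussian noise per phase.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.image_shape
    breast, band, body, heart, _ = _anatomy(shape)

    lesions, occupied = _place_lesions(rng, cfg, breast, forbidden=np.zeros(shape, bool))
    vessel, occupied = _place_vessels(rng, cfg, breast, occupied)

    # vessels enhance early, at strengths overlapping the lesions' —
    # that overlap is exactly why they confound the segmentation stage
    vessel_amp = (np.mean([l.amplitude for l in lesions]) if lesions else 0.5) * rng.uniform(
        0.9, 1.05
    )

    # Phase 0 baseline: smooth parenchymal texture inside the breast.
    texture = ndi.gaussian_filter(rng.normal(size=shape), sigma=6)
    texture /= max(np.abs(texture).max(), 1e-12)
    base = np.full(shape, _BASE_AIR)
    base[body] = _BASE_BODY
    base[band] = _BASE_BODY + 0.02
    base[breast] = _BASE_BREAST + 0.05 * texture[breast]
    for lesion in lesions:
        # lesions carry their own slightly brighter, rougher texture
        fine = ndi.gaussian_filter(rng.normal(size=shape), sigma=1.5)
        fine /= max(np.abs(fine).max(), 1e-12)
        base[lesion.mask] = _BASE_LESION + 0.04 * fine[lesion.mask]
    base[vessel] = _BASE_BREAST + 0.03

    # background parenchymal enhancement: mild, spatially varying, slow rise
    bpe = ndi.gaussian_filter(rng.normal(size=shape), sigma=10)
    bpe = np.clip(bpe / max(np.abs(bpe).max(), 1e-12), 0.0, None)  # patchy foci

    phases = []
    for p in range(cfg.n_post_phases + 1):
        img = base.copy()
        if p >= 1:
            img[breast] += (_PARENCHYMAL_AMP + 0.12 * bpe[breast]) * min(p / 3, 1.0)
            for lesion in lesions:
                img[lesion.mask] += lesion.amplitude * _kinetic_fraction(lesion.kinetic, p)
            img[vessel] += vessel_amp * _kinetic_fraction("plateau", p)
            if cfg.include_thorax_confounder:
                img[heart] += 0.6 * min(p / 2, 1.0)
                img[body & ~heart & ~band] += 0.05 * min(p / 3, 1.0)
        img = img + rng.normal(0.0, cfg.noise_sd, size=shape)
        phases.append(np.clip(img, 0.0, None))

    stack = DcePhaseStack(phases=phases)
    thorax = (body | band) & ~breast
    truth = PhantomTruth(
        lesions=lesions, vessel_mask=vessel, breast_mask=breast, thorax_mask=thorax
    )
    return stack, truth


def separable_feature_clouds(
    n: int = 400, dprime: float = 4.0, seed: int = 1, n_features: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly separable two-class Gaussian feature clouds.

    Class means sit ``dprime`` standard deviations apart along the first
    feature; the remaining features are pure noise.  Samples falling across
    the midpoint hyperplane are re-drawn (class-conditional truncation), so
    the *sample* is linearly separable by construction — classifier
    recovery bounds on it are then limited by estimation, not by Bayes
    error.  Used to validate the classification stage.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, n_features))
    X[:, 0] += y * dprime
    mid = dprime / 2.0
    for i in range(n):
        while (X[i, 0] > mid) != bool(y[i]):
            X[i, 0] = rng.normal() + y[i] * dprime
    return X, y


def generate_benchmark(n_slices: int = 20, seed: int = 0) -> list[tuple[DcePhaseStack, PhantomTruth]]:
    """Reproducible benchmark of ``n_slices`` phantom slices.

    Per-slice seeds derive deterministically from the master seed.  Lesion
    sizes span ~10-60 px; the first slice always contains a sub-15-px lesion
    and every slice contains at least one vessel, so the downstream
    rule-filter rejection paths are always exercised.
    """
    if n_slices < 1:
        raise ValueError("n_slices >= 1 required")
    master = np.random.SeedSequence(seed)
    out = []
    for i, ss in enumerate(master.spawn(n_slices)):
        slice_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(slice_seed)
        if i == 0:
            radius_range = (1.5, 1.75)      # <= ~14 px even at max ellipticity
        else:
            lo = float(rng.uniform(2.3, 2.8))
            radius_range = (lo, float(rng.uniform(3.4, 4.4)))
        cfg = PhantomConfig(
            n_lesions=int(rng.integers(1, 4)),
            lesion_radius_range=radius_range,
            n_vessels=int(rng.integers(1, 3)),
            seed=slice_seed,
        )
        out.append(generate_phantom_series(cfg))
    return out
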