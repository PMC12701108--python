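"""Shared image/geometry types and subtraction-image arithmetic.

Coordinate convention used throughout the package: ``X`` is the row index
(anterior chest wall at row 0, as the breasts appear at the top of an axial
slice), ``Y`` is the column index (patient right to left).  All indices are
0-based and :class:`CropWindow` bounds are inclusive, so a window spanning
columns ``y_min..y_max`` is ``y_max - y_min + 1`` pixels wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DcePhaseStack",
    "SubtractionImage",
    "CropWindow",
    "ContractError",
    "subtraction_image",
    "to_unit_range",
]

#: Default in-plane pixel size (micrometres per pixel).
DEFAULT_PIXEL_SIZE_UM = 654.762
#: Nominal spacing between successive post-contrast acquisitions (seconds).
DEFAULT_PHASE_INTERVAL_S = 70.0


class ContractError(ValueError):
    """An input violated one of the documented type invariants."""


@dataclass
class DcePhaseStack:
    """One axial slice across dynamic phases.

    ``phases[0]`` is the pre-contrast acquisition ("Phase 0"); subsequent
    entries are post-contrast acquisitions ordered in time.  Intensities are
    arbitrary units; the pipeline normalises internally.
    """

    phases: list[np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    phase_interval_s: float = DEFAULT_PHASE_INTERVAL_S

    def __post_init__(self) -> None:
        self.phases = [np.asarray(p, dtype=float) for p in self.phases]
        if len(self.phases) < 4:
            raise ContractError(
                f"need >= 4 phases (1 pre + >= 3 post), got {len(self.phases)}"
            )
        shape = self.phases[0].shape
        for i, p in enumerate(self.phases):
            if p.ndim != 2:
                raise ContractError(f"phase {i} is not 2-D")
            if p.shape != shape:
                raise ContractError(
                    f"phase {i} shape {p.shape} != phase 0 shape {shape}"
                )
            if not np.all(np.isfinite(p)):
                raise ContractError(f"phase {i} contains non-finite values")
            if np.any(p < 0):
                raise ContractError(f"phase {i} contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ContractError("pixel_size_um must be positive")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phases[0].shape


@dataclass
class SubtractionImage:
    """Post-contrast phase minus Phase 0, clipped at zero.

    Isolates contrast enhancement; ``phase_index`` records which
    post-contrast phase it derives from (2 and 3 in the default pipeline).
    """

    values: np.ndarray
    phase_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ContractError("subtraction image must be 2-D")
        if np.any(self.values < 0):
            raise ContractError("subtraction image must be non-negative")


@dataclass(frozen=True)
class CropWindow:
    """Inclusive rectangular sub-region: rows [x_min, x_max], cols [y_min, y_max]."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ContractError(f"degenerate window {self}")
        if min(self.x_min, self.y_min) < 0:
            raise ContractError(f"window has negative bounds {self}")

    @property
    def height(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def width(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def validate_inside(self, shape: tuple[int, int]) -> None:
        if self.x_max >= shape[0] or self.y_max >= shape[1]:
            raise ContractError(f"window {self} exceeds image shape {shape}")

    def as_slices(self) -> tuple[slice, slice]:
        return slice(self.x_min, self.x_max + 1), slice(self.y_min, self.y_max + 1)

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CropWindow":
        return cls(d["x_min"], d["x_max"], d["y_min"], d["y_max"])


def subtraction_image(stack: DcePhaseStack, k: int) -> SubtractionImage:
    """Subtraction image of post-contrast phase ``k``: ``max(phase_k - phase_0, 0)``.

    Negative differences (signal loss, noise) are clipped to zero, matching
    the visual subtraction-image convention.
    """
    if not 1 <= k < stack.n_phases:
        raise IndexError(f"post-contrast phase index {k} out of range [1, {stack.n_phases - 1}]")
    values = np.clip(stack.phases[k] - stack.phases[0], 0.0, None)
    return SubtractionImage(values=values, phase_index=k)


def to_unit_range(img: np.ndarray) -> np.ndarray:
    """Affinely rescale to [0, 1]; a constant image maps to all zeros."""
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ContractError("to_unit_range requires finite values")
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)
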