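"""Rule-based first false-positive reduction stage.

Connected components of the enhancement mask become candidate ROIs; a
candidate is rejected if it is smaller than 15 pixels (about 10 mm at the
default 654.762 um/px resolution — below the size conventional breast MRI
reliably detects) or more eccentric than 0.95 (thin elongated regions are
typically vessels or noise, not masses).  Both boundaries follow strict
inequality: area exactly 15 and eccentricity exactly 0.95 are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .core import ContractError
from .segmentation import BinaryMask

__all__ = ["RoiRecord", "region_props", "rule_filter"]

DEFAULT_MIN_AREA = 15
DEFAULT_MAX_ECC = 0.95


@dataclass(eq=False)
class RoiRecord:
    """One connected region with the geometry the rule stage needs."""

    mask: np.ndarray
    area_px: int
    eccentricity: float
    centroid: tuple[float, float]           # (row, col)
    provenance: str = "detected"            # detected | control
    label: str = "unknown"                  # lesion | healthy | unknown
    roi_id: int = -1
    source_roi_id: int | None = None        # for controls: the mirrored ROI

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area_px != int(self.mask.sum()):
            raise ContractError("area_px does not match mask pixel count")
        if not 0.0 <= self.eccentricity <= 1.0:
            raise ContractError(f"eccentricity {self.eccentricity} outside [0, 1]")


def region_props(mask: BinaryMask | np.ndarray, connectivity: int = 2) -> list[RoiRecord]:
    """Label connected components (8-connected by default) into RoiRecords.

    Eccentricity is that of the ellipse with the same second central
    moments as the region: sqrt(1 - (minor/major)^2); 0 for a perfect disc,
    approaching 1 for a line.  An empty mask yields an empty list.
    """
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    labeled = sk_label(values, connectivity=connectivity)
    records = []
    for i, rp in enumerate(regionprops(labeled)):
        m = labeled == rp.label
        records.append(
            RoiRecord(
                mask=m,
                area_px=int(rp.area),
                eccentricity=float(rp.eccentricity),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                roi_id=i,
            )
        )
    return records


def rule_filter(
    rois: list[RoiRecord],
    min_area: int = DEFAULT_MIN_AREA,
    max_ecc: float = DEFAULT_MAX_ECC,
) -> tuple[list[RoiRecord], list[RoiRecord]]:
    """Split ROIs into (kept, rejected): reject iff area < min_area or ecc > max_ecc."""
    if min_area < 0 or max_ecc < 0:
        raise ContractError("rule thresholds must be non-negative")
    kept, rejected = [], []
    for roi in rois:
        if roi.area_px < min_area or roi.eccentricity > max_ecc:
            rejected.append(roi)
        else:
            kept.append(roi)
    return kept, rejected
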