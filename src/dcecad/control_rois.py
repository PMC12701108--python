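"""Contralateral control-ROI construction.

For every kept suspicious ROI a same-shape, same-size "control" region is
placed at the mirror-symmetric position on the other breast: the ROI is
reflected about the vertical axis through the centre of the cropped frame,
then re-inverted about the vertical axis through the mirrored region's own
centroid so that its orientation relative to the underlying breast matches
the original.  Two reflections about parallel vertical axes compose to a
pure horizontal translation by ``2*(m - centroid_col)``, which is how the
construction is realised pixelwise (it conserves the pixel count exactly).

On synthetic data the radiologist's visual check of the controls is
replaced by a ground-truth overlap test: a control landing on a true lesion
is jittered vertically until clear, or skipped with a warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import ContractError, CropWindow
from .fp_rules import RoiRecord

__all__ = ["breast_midline", "make_control_roi", "build_control_set", "ControlPlacementError"]

logger = logging.getLogger(__name__)


class ControlPlacementError(ValueError):
    """Reflected footprint falls outside the cropped frame."""


def breast_midline(window: CropWindow) -> float:
    """Centre column of the cropped frame (real-valued midpoint)."""
    return (window.width - 1) / 2.0


def _translate_mask(mask: np.ndarray, shift_cols: int) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    new_cols = cols + shift_cols
    if new_cols.min() < 0 or new_cols.max() >= mask.shape[1]:
        raise ControlPlacementError(
            f"control footprint leaves the frame (column shift {shift_cols})"
        )
    out = np.zeros_like(mask)
    out[rows, new_cols] = True
    return out


def make_control_roi(roi: RoiRecord, m: float, row_jitter: int = 0) -> RoiRecord:
    """Mirror ``roi`` onto the contralateral breast.

    The double reflection (about the frame midline ``m``, then about the
    mirrored centroid's own column) reduces to a horizontal translation by
    ``2*(m - centroid_col)`` rounded to the nearest pixel, so shape and
    area are conserved exactly.  ``row_jitter`` shifts rows (used only when
    re-placing a conflicted control).
    """
    if roi.mask.sum() == 0:
        raise ContractError("cannot mirror an empty ROI")
    shift = int(round(2.0 * (m - roi.centroid[1])))
    mask = _translate_mask(roi.mask, shift)
    if row_jitter:
        rows, cols = np.nonzero(mask)
        new_rows = rows + row_jitter
        if new_rows.min() < 0 or new_rows.max() >= mask.shape[0]:
            raise ControlPlacementError(f"row jitter {row_jitter} leaves the frame")
        mask = np.zeros_like(mask)
        mask[new_rows, cols] = True
    return RoiRecord(
        mask=mask,
        area_px=roi.area_px,
        eccentricity=roi.eccentricity,
        centroid=(roi.centroid[0] + row_jitter, roi.centroid[1] + shift),
        provenance="control",
        label="healthy",
        roi_id=-1,
        source_roi_id=roi.roi_id,
    )


def build_control_set(
    kept_rois: list[RoiRecord],
    window: CropWindow,
    truth_lesion_mask: np.ndarray | None = None,
    max_jitter_tries: int = 10,
) -> list[RoiRecord]:
    """One control per kept ROI, skipping unplaceable ones with a warning.

    When a cropped-frame union of ground-truth lesion masks is supplied
    (synthetic mode), controls overlapping it are re-placed by jittering
    rows by +-3 px per try, up to ``max_jitter_tries`` tries.
    """
    m = breast_midline(window)
    controls = []
    for roi in kept_rois:
        control = None
        jitters = [0] + [s * 3 * step for step in range(1, max_jitter_tries // 2 + 1)
                         for s in (1, -1)][: max_jitter_tries - 1]
        for jitter in jitters:
            try:
                cand = make_control_roi(roi, m, row_jitter=jitter)
            except ControlPlacementError:
                continue
            if truth_lesion_mask is not None and np.any(cand.mask & truth_lesion_mask):
                logger.warning(
                    "control for ROI %d overlaps a true lesion (jitter %d); re-placing",
                    roi.roi_id, jitter,
                )
                continue
            control = cand
            break
        if control is None:
            logger.warning("could not place control for ROI %d; skipped", roi.roi_id)
            continue
        controls.append(control)
    return controls
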