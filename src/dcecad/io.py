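"""Readers and writers: phase stacks (NPZ / multi-frame DICOM), mask PNGs,
ROI/feature tables (CSV) and evaluation reports (JSON + text table).

The NPZ dialect stores the stack under key ``phases`` (n_phases x rows x
cols) with scalar ``pixel_size_um``; it is the fixture format for tests and
phantoms.  Multi-frame DICOM files are read with pydicom, taking frames in
stored order as phases (pre-contrast first) and PixelSpacing when present,
else the configured default resolution.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .classify import EvalReport
from .core import DEFAULT_PIXEL_SIZE_UM, DcePhaseStack

__all__ = ["read_series", "write_series_npz", "write_mask_png", "read_mask_png",
           "write_report", "FormatError"]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Unreadable or structurally invalid input file."""


def write_series_npz(stack: DcePhaseStack, path) -> None:
    np.savez(
        path,
        phases=np.stack(stack.phases),
        pixel_size_um=np.array(stack.pixel_size_um),
        phase_interval_s=np.array(stack.phase_interval_s),
    )


def _read_npz(path) -> DcePhaseStack:
    with np.load(path) as z:
        if "phases" not in z:
            raise FormatError(f"{path}: NPZ stack must contain key 'phases'")
        phases = [np.asarray(p, dtype=float) for p in z["phases"]]
        pixel = float(z["pixel_size_um"]) if "pixel_size_um" in z else DEFAULT_PIXEL_SIZE_UM
        interval = float(z["phase_interval_s"]) if "phase_interval_s" in z else 70.0
    return DcePhaseStack(phases=phases, pixel_size_um=pixel, phase_interval_s=interval)


def _dicom_pixel_spacing(ds) -> float | None:
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        try:
            fg = ds.SharedFunctionalGroupsSequence[0]
            spacing = fg.PixelMeasuresSequence[0].PixelSpacing
        except (AttributeError, IndexError):
            spacing = None
    if spacing is None:
        return None
    return float(spacing[0]) * 1000.0       # DICOM stores mm, we use um


def _read_dicom(path) -> DcePhaseStack:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a multi-frame DICOM (one frame per phase)")
    pixel = _dicom_pixel_spacing(ds)
    if pixel is None:
        warnings.warn(
            f"{path}: no PixelSpacing tag; assuming {DEFAULT_PIXEL_SIZE_UM} um/px",
            stacklevel=2,
        )
        pixel = DEFAULT_PIXEL_SIZE_UM
    try:
        return DcePhaseStack(phases=list(arr), pixel_size_um=pixel)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_series(path, dialect: str | None = None) -> DcePhaseStack:
    """Read a DCE phase stack; dialect inferred from the suffix when omitted."""
    path = Path(path)
    if dialect is None:
        dialect = "npz" if path.suffix.lower() == ".npz" else "dicom"
    if dialect == "npz":
        try:
            return _read_npz(path)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if dialect == "dicom":
        return _read_dicom(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def write_mask_png(mask: np.ndarray, path) -> None:
    """Binary mask as an 8-bit PNG (0/255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask_png(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 127


def write_report(report: EvalReport, path) -> tuple[Path, Path]:
    """Write an EvalReport as JSON plus a human-readable text table."""
    path = Path(path)
    json_path = path.with_suffix(".json")
    txt_path = path.with_suffix(".txt")
    json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    txt_path.write_text(report.summary() + "\n")
    return json_path, txt_path
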