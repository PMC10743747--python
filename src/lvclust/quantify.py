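"""Trabecular volume percentage (VT%) and the LVNC decision rule.

The diagnostic statistic is

    VT% = trabecular volume / (trabecular volume + compacted volume) * 100,

where trabecular volume is the TZ label total and compacted volume the EL
label total. The internal cavity is measured and reported but does not enter
the ratio. A patient whose VT% is strictly higher than the 27.4% threshold
is called LVNC-positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import EL, IC, TZ, SegmentationStack, ValidationError

__all__ = ["LVNC_THRESHOLD_PERCENT", "VolumeBreakdown", "DiagnosisRecord",
           "compute_volumes", "diagnose", "make_diagnosis_record", "normalized_slice"]

LVNC_THRESHOLD_PERCENT = 27.4


@dataclass(frozen=True)
class VolumeBreakdown:
    """Per-class volume totals (mm^3 when geometry is known, else pixel
    counts) and the resulting VT%."""

    el_volume: float
    ic_volume: float
    tz_volume: float
    vt_percent: float
    units: str = "mm^3"


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    vt_percent: float
    lvnc_positive: bool
    threshold_used: float = LVNC_THRESHOLD_PERCENT


def compute_volumes(stack: SegmentationStack) -> VolumeBreakdown:
    """Sum per-class pixels over all slices; scale by voxel volume if known.

    VT% is a pure ratio, so it is invariant to the voxel geometry; volumes
    are reported in mm^3 when geometry is present, raw pixel counts
    otherwise. An empty TZ+EL denominator yields VT% = 0.
    """
    counts = np.bincount(stack.voxels.reshape(-1), minlength=4)
    scale = stack.geometry.voxel_volume if stack.geometry is not None else 1.0
    units = "mm^3" if stack.geometry is not None else "pixels"
    el, ic, tz = (float(counts[c]) * scale for c in (EL, IC, TZ))
    denom = tz + el
    vt = 100.0 * tz / denom if denom > 0 else 0.0
    return VolumeBreakdown(el, ic, tz, vt, units=units)


def diagnose(vt_percent: float, threshold: float = LVNC_THRESHOLD_PERCENT) -> bool:
    """LVNC call: positive iff VT% strictly exceeds the threshold."""
    if not (0.0 <= vt_percent <= 100.0):
        raise ValidationError(f"vt_percent must lie in [0, 100], got {vt_percent}")
    return vt_percent > threshold


def make_diagnosis_record(stack: SegmentationStack,
                          threshold: float = LVNC_THRESHOLD_PERCENT) -> tuple[DiagnosisRecord, VolumeBreakdown]:
    vols = compute_volumes(stack)
    return (DiagnosisRecord(stack.patient_id, vols.vt_percent,
                            diagnose(vols.vt_percent, threshold), threshold), vols)


def normalized_slice(slice_index: int, patient_slice_indices: Sequence[int]) -> float:
    """Position of a slice within its patient's stack, rescaled to [0, 1].

    (slice - min) / (max - min) over the patient's slice numbers; 0 or 1
    means the slice sits at an end of the stack. Undefined for a
    single-slice patient (degenerate zero denominator).
    """
    indices = list(patient_slice_indices)
    if slice_index not in indices:
        raise ValidationError(f"slice {slice_index} not among patient slices {indices}")
    lo, hi = min(indices), max(indices)
    if hi == lo:
        raise ValidationError(
            f"normalized slice undefined: max(Slices) - min(Slices) = 0 for {indices}")
    return (slice_index - lo) / (hi - lo)
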