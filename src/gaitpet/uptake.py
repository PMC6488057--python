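"""Per-muscle uptake quantification: volume, SUV and AUV.

SUV (standardized uptake value, g/mL) normalizes the mean activity
concentration in a muscle by the injected activity per gram of body mass:

    SUV = (total activity in muscle [Bq] / muscle volume [mL])
          / (injected activity at scan start [Bq] / body mass [g])

The total activity is the mean ROI concentration times the ROI volume, so the
muscle SUV equals the mean of the voxelwise SUV map over the ROI. AUV
(absolute uptake value, g) is SUV x volume, removing the volume normalization
for between-limb comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import AcquisitionMeta, LabelMask, Unit, VolumeGrid, extract_roi_voxels

__all__ = [
    "MuscleRecord",
    "muscle_volume",
    "compute_suv",
    "voxelwise_suv",
    "compute_auv",
    "quantify_muscle",
]


@dataclass
class MuscleRecord:
    """Quantification result for one muscle ROI in one limb."""

    muscle_name: str
    side: str
    segment: str
    voxel_count: int
    volume_ml: float
    suv_mean: float
    auv_g: float
    voxel_suvs: np.ndarray = field(repr=False)
    subject_id: str = ""


def muscle_volume(voxel_count: int, spacing: tuple[float, float, float]) -> float:
    """ROI volume in mL from voxel count and spacing (mm)."""
    if voxel_count < 0:
        raise ValueError("voxel count must be non-negative")
    sx, sy, sz = spacing
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise ValueError("spacing components must be positive")
    return voxel_count * (sx * sy * sz) / 1000.0


def compute_suv(
    total_activity_bq: float,
    volume_ml: float,
    injected_at_scan_bq: float,
    body_mass_g: float,
) -> float:
    """Body-mass SUV in g/mL."""
    if volume_ml <= 0:
        raise ValueError("muscle volume must be positive")
    if injected_at_scan_bq <= 0:
        raise ValueError("injected activity must be positive")
    if body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    return (total_activity_bq / volume_ml) / (injected_at_scan_bq / body_mass_g)


def voxelwise_suv(volume: VolumeGrid, meta: AcquisitionMeta) -> VolumeGrid:
    """Convert a Bq/mL volume to an SUV map, voxel by voxel.

    The ROI mean of the returned map equals :func:`compute_suv` of the ROI.
    """
    if volume.unit is not Unit.BQ_PER_ML:
        raise ValueError("voxelwise_suv expects a Bq/mL volume")
    denom = meta.injected_at_scan_bq / meta.body_mass_g
    return VolumeGrid(volume.values / denom, volume.spacing, volume.origin, Unit.SUV)


def compute_auv(suv_mean: float, volume_ml: float) -> float:
    """Absolute uptake value (g): SUV times muscle volume."""
    if volume_ml < 0:
        raise ValueError("volume must be non-negative")
    return suv_mean * volume_ml


def quantify_muscle(
    volume: VolumeGrid,
    mask: LabelMask,
    label: int,
    meta: AcquisitionMeta,
    muscle_name: str = "",
    side: str = "",
    segment: str = "",
    subject_id: str = "",
) -> MuscleRecord:
    """Full per-muscle quantification from an activity volume and label mask."""
    conc, count = extract_roi_voxels(volume, mask, label)
    vol_ml = muscle_volume(count, volume.spacing)
    total_bq = float(conc.mean()) * vol_ml
    suv = compute_suv(total_bq, vol_ml, meta.injected_at_scan_bq, meta.body_mass_g)
    denom = meta.injected_at_scan_bq / meta.body_mass_g
    return MuscleRecord(
        muscle_name=muscle_name,
        side=side,
        segment=segment,
        voxel_count=count,
        volume_ml=vol_ml,
        suv_mean=suv,
        auv_g=compute_auv(suv, vol_ml),
        voxel_suvs=conc / denom,
        subject_id=subject_id,
    )
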