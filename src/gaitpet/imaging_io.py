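"""Volume and label-mask I/O, alignment checks, rescale/decay corrections, ROI extraction.

Arrays are indexed ``(x, y, z)``, 0-based, with x the fastest in-plane axis and
z the slice axis. World coordinates are millimetres; a voxel's centre is at
``origin + index * spacing``. Activity volumes are converted to Bq/mL
immediately on load (DICOM rescale slope/intercept applied once), so all
downstream maths works on a single canonical unit.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "VolumeGrid",
    "LabelMask",
    "AcquisitionMeta",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dicom_series",
    "apply_rescale",
    "decay_correct_activity",
    "extract_roi_voxels",
    "validate_aligned",
    "read_label_table",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

LABEL_TABLE_COLUMNS = ["label", "muscle_name", "side", "segment", "subject_id"]
SIDES = ("dominant", "non_dominant")
SEGMENTS = ("pelvis", "thigh", "lower_leg")


class Unit(enum.Enum):
    """Physical unit of the scalar field held by a :class:`VolumeGrid`."""

    BQ_PER_ML = "Bq/mL"
    SUV = "g/mL"


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel spacing and origin.

    Parameters
    ----------
    values
        3-D float array, indexed ``(x, y, z)``.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm; all positive.
    origin
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    unit
        Whether ``values`` holds activity concentration (Bq/mL) or SUV (g/mL).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: Unit = Unit.BQ_PER_ML

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.values.ndim} axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing product in mm^3 / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


@dataclass
class LabelMask:
    """Integer ROI labels on the same grid as a companion :class:`VolumeGrid`.

    0 is background; each positive integer identifies one muscle ROI.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.labels.ndim} axes")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("mask labels must be integers")
            self.labels = rounded.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("mask labels must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def present_labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the mask."""
        labs = np.unique(self.labels)
        return labs[labs > 0]


@dataclass
class AcquisitionMeta:
    """Acquisition metadata needed to turn activity concentration into SUV."""

    injected_activity_bq: float
    injection_time: datetime
    scan_start_time: datetime
    body_mass_g: float
    half_life_min: float = F18_HALF_LIFE_MIN
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.injected_activity_bq <= 0:
            raise ValueError("injected activity must be positive")
        if self.body_mass_g <= 0:
            raise ValueError("body mass must be positive")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.scan_start_time < self.injection_time:
            raise ValueError("scan start precedes injection")

    @property
    def uptake_minutes(self) -> float:
        """Minutes elapsed between injection and scan start."""
        return (self.scan_start_time - self.injection_time).total_seconds() / 60.0

    @property
    def injected_at_scan_bq(self) -> float:
        """Injected activity decay-corrected to scan start (SUV denominator)."""
        return decay_correct_activity(
            self.injected_activity_bq, self.uptake_minutes, self.half_life_min
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "injected_activity_bq": self.injected_activity_bq,
            "injection_time": self.injection_time.isoformat(),
            "scan_start_time": self.scan_start_time.isoformat(),
            "body_mass_g": self.body_mass_g,
            "half_life_min": self.half_life_min,
            "rescale_slope": self.rescale_slope,
            "rescale_intercept": self.rescale_intercept,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        payload = json.loads(Path(path).read_text())
        return cls(
            injected_activity_bq=float(payload["injected_activity_bq"]),
            injection_time=datetime.fromisoformat(payload["injection_time"]),
            scan_start_time=datetime.fromisoformat(payload["scan_start_time"]),
            body_mass_g=float(payload["body_mass_g"]),
            half_life_min=float(payload.get("half_life_min", F18_HALF_LIFE_MIN)),
            rescale_slope=float(payload.get("rescale_slope", 1.0)),
            rescale_intercept=float(payload.get("rescale_intercept", 0.0)),
        )


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with spacing/origin in the affine."""
    img = nib.Nifti1Image(volume.values, _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.labels.astype(np.int32), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str | Path, format: str = "NIFTI", unit: Unit = Unit.BQ_PER_ML) -> VolumeGrid:
    """Read an activity volume.

    ``format`` is ``"NIFTI"`` (single file) or ``"DICOM_SERIES"`` (a directory
    of slices; rescale slope/intercept from the headers are applied so the
    returned values are in Bq/mL).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format.upper()
    if fmt == "NIFTI":
        data, spacing, origin = _load_nifti(path)
        return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, origin, unit)
    if fmt == "DICOM_SERIES":
        vol, _ = read_dicom_series(path)
        return vol
    raise ValueError(f"unknown format {format!r}")


def read_mask(path: str | Path, reference: VolumeGrid | None = None) -> LabelMask:
    """Read a label mask (NIfTI); optionally validate alignment to a volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data, spacing, origin = _load_nifti(path)
    mask = LabelMask(np.asarray(data), spacing, origin)
    if reference is not None:
        validate_aligned(reference, mask)
    return mask


def read_dicom_series(directory: str | Path) -> tuple[VolumeGrid, dict]:
    """Read a single-frame DICOM image series into a Bq/mL volume.

    All slices must share ImageOrientationPatient and in-plane PixelSpacing,
    and be uniformly spaced along the slice normal. RescaleSlope/Intercept are
    applied per slice. Returns the volume and a header summary (slope,
    intercept, orientation).
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM stray file
    if not datasets:
        raise ValueError(f"no DICOM slices found in {directory}")

    orientations = {tuple(round(float(v), 6) for v in ds.ImageOrientationPatient) for ds in datasets}
    if len(orientations) != 1:
        raise ValueError("mixed-geometry series: slices differ in ImageOrientationPatient")
    spacings = {tuple(round(float(v), 6) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise ValueError("mixed-geometry series: slices differ in PixelSpacing")

    orient = np.array(next(iter(orientations)), dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    positions = [np.array([float(v) for v in ds.ImagePositionPatient]) for ds in datasets]
    order = np.argsort([p @ normal for p in positions])
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    along = np.array([p @ normal for p in positions])
    if len(along) > 1:
        gaps = np.diff(along)
        if gaps.min() <= 0:
            raise ValueError("duplicate or non-monotonic slice positions")
        if (gaps.max() - gaps.min()) > 1e-3 * gaps.mean() + 1e-6:
            raise ValueError("non-uniform slice gap in series")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    rows_cols = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(rows_cols) != 1:
        raise ValueError("mixed-geometry series: slices differ in matrix size")

    slices = []
    slope = intercept = None
    for ds in datasets:
        s = float(getattr(ds, "RescaleSlope", 1.0))
        b = float(getattr(ds, "RescaleIntercept", 0.0))
        slope, intercept = s, b
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        slices.append(apply_rescale(ds.pixel_array.T.astype(np.float64), s, b))
    values = np.stack(slices, axis=-1)

    dy, dx = (float(v) for v in next(iter(spacings)))  # PixelSpacing is (row, col)
    origin = tuple(float(v) for v in positions[0])
    vol = VolumeGrid(values, (dx, dy, dz), origin, Unit.BQ_PER_ML)
    header = {
        "rescale_slope": slope,
        "rescale_intercept": intercept,
        "orientation": tuple(orient.tolist()),
        "n_slices": len(datasets),
    }
    return vol, header


def apply_rescale(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Map stored integers to physical units: ``stored * slope + intercept``."""
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    return np.asarray(stored, dtype=np.float64) * slope + intercept


def decay_correct_activity(a0: float, elapsed_min: float, half_life_min: float) -> float:
    """Activity remaining after ``elapsed_min`` minutes: ``a0 * 2**(-t/T_half)``.

    Used to decay the injected dose from injection time to scan start; the
    decayed value is the denominator of the SUV.
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    if elapsed_min < 0:
        raise ValueError("elapsed time must be non-negative")
    return a0 * 2.0 ** (-elapsed_min / half_life_min)


def validate_aligned(volume: VolumeGrid, mask: LabelMask) -> None:
    """Raise ValueError unless mask and volume share shape, spacing and origin."""
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    if not np.allclose(mask.spacing, volume.spacing, rtol=1e-6):
        raise ValueError(f"mask spacing {mask.spacing} != volume spacing {volume.spacing}")
    if not np.allclose(mask.origin, volume.origin, atol=1e-3):
        raise ValueError(f"mask origin {mask.origin} != volume origin {volume.origin}")


def extract_roi_voxels(
    volume: VolumeGrid, mask: LabelMask, label: int
) -> tuple[np.ndarray, int]:
    """Values at all voxels carrying ``label``, in lexicographic index order.

    Returns ``(values, count)``. Order is C-order over (x, y, z) indices, so
    repeated calls are deterministic and per-voxel arrays elsewhere (hot flags,
    neighbour counts) can align positionally.
    """
    if label <= 0:
        raise ValueError("label must be a positive integer")
    validate_aligned(volume, mask)
    sel = mask.labels == label
    if not sel.any():
        raise ValueError(f"label {label} absent from mask")
    values = volume.values[sel]  # boolean indexing is C-order = lexicographic
    return values, int(sel.sum())


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read the label-table sidecar CSV mapping label ids to muscles.

    Required columns: label, muscle_name, side (dominant/non_dominant),
    segment (pelvis/thigh/lower_leg), subject_id.
    """
    df = pd.read_csv(path)
    missing = [c for c in LABEL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"label table missing columns: {missing}")
    bad_side = set(df["side"]) - set(SIDES)
    if bad_side:
        raise ValueError(f"unknown side values: {sorted(bad_side)}")
    bad_seg = set(df["segment"]) - set(SEGMENTS)
    if bad_seg:
        raise ValueError(f"unknown segment values: {sorted(bad_seg)}")
    if (df["label"] <= 0).any():
        raise ValueError("labels must be positive")
    return df
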