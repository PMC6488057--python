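"""Seeded paired-limb phantom studies with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, not anatomy: ellipsoidal muscle ROIs on an anisotropic PET grid
(1.6 x 1.6 x 2.0 mm voxels), right-skewed voxel uptake (gamma background —
skewness 2/sqrt(k) controls the tail with a single parameter), spherical
high-uptake blobs for spatial clustering, a controlled inter-limb asymmetry
(the non-dominant limb is the mirrored geometry with its mean concentration
scaled to hit a target symmetry index), and 3 mm FWHM Gaussian
post-smoothing applied after blob injection, emulating scanner
post-filtering. Every study carries a ground-truth block (true means, true
blob voxel sets, analytic SUV/SI) so recovery can be asserted in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import (
    F18_HALF_LIFE_MIN,
    AcquisitionMeta,
    LabelMask,
    Unit,
    VolumeGrid,
    write_mask,
    write_volume,
)

__all__ = [
    "MuscleShape",
    "PhantomSpec",
    "PairedStudy",
    "fwhm_to_sigma",
    "make_ellipsoid_mask",
    "add_ellipsoid",
    "mirror_mask",
    "sample_background",
    "inject_hot_clusters",
    "smooth_fwhm",
    "si_to_ratio",
    "make_paired_study",
    "default_phantom_spec",
    "make_fixture_study",
]

DEFAULT_SPACING = (1.6, 1.6, 2.0)
DEFAULT_GRID_SHAPE = (44, 44, 60)
DEFAULT_FWHM_MM = 3.0
DEFAULT_INJECTED_BQ = 53.6e6
DEFAULT_BODY_MASS_G = 70_000.0
DEFAULT_UPTAKE_MIN = 60.0


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class MuscleShape:
    """One muscle pair's generative parameters."""

    name: str
    segment: str
    semiaxes_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float]
    gamma_shape: float = 4.0
    mean_concentration: float = 500.0  # Bq/mL, pre-asymmetry dominant-limb mean
    n_clusters: int = 2
    cluster_radius_mm: float = 6.0
    cluster_amplitude: float = 2.0
    target_si: float = 0.0  # percent, dominant vs non-dominant

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.gamma_shape <= 0 or self.mean_concentration <= 0:
            raise ValueError("gamma shape and mean concentration must be positive")
        if not -200.0 < self.target_si < 200.0:
            raise ValueError("target SI must lie in (-200, 200)")

    @property
    def gamma_scale(self) -> float:
        return self.mean_concentration / self.gamma_shape


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic paired-limb subject."""

    muscles: list[MuscleShape]
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    fwhm_mm: float = DEFAULT_FWHM_MM
    injected_activity_bq: float = DEFAULT_INJECTED_BQ
    body_mass_g: float = DEFAULT_BODY_MASS_G
    uptake_minutes: float = DEFAULT_UPTAKE_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be non-negative")
        if not self.muscles:
            raise ValueError("at least one muscle required")


@dataclass
class PairedStudy:
    """Generated study: one volume+mask per limb plus metadata and ground truth."""

    volume_dominant: VolumeGrid
    mask_dominant: LabelMask
    volume_non_dominant: VolumeGrid
    mask_non_dominant: LabelMask
    meta: AcquisitionMeta
    label_table: pd.DataFrame
    ground_truth: dict = field(repr=False)


def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def add_ellipsoid(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
    label: int,
) -> np.ndarray:
    """Label all voxels whose centre lies inside the ellipsoid.

    The ellipsoid must fit inside the grid extent, mirroring the requirement
    that muscle ROIs are fully covered by the scan.
    """
    if any(a <= 0 for a in semiaxes_mm):
        raise ValueError("semi-axes must be positive")
    extent = [(n - 1) * s for n, s in zip(labels.shape, spacing)]
    for c, a, e in zip(center_mm, semiaxes_mm, extent):
        if c - a < 0 or c + a > e:
            raise ValueError(f"ellipsoid exceeds grid bounds: centre {c}, semi-axis {a}, extent {e}")
    xx, yy, zz = _voxel_centers(labels.shape, spacing)
    inside = (
        ((xx - center_mm[0]) / semiaxes_mm[0]) ** 2
        + ((yy - center_mm[1]) / semiaxes_mm[1]) ** 2
        + ((zz - center_mm[2]) / semiaxes_mm[2]) ** 2
    ) <= 1.0
    labels = labels.copy()
    labels[inside] = label
    return labels


def make_ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
    label: int = 1,
) -> LabelMask:
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels = add_ellipsoid(labels, spacing, center_mm, semiaxes_mm, label)
    return LabelMask(labels, spacing)


def mirror_mask(mask: LabelMask) -> LabelMask:
    """Mirror the geometry along the x axis (an involution)."""
    return LabelMask(np.flip(mask.labels, axis=0).copy(), mask.spacing, mask.origin)


def sample_background(
    mask: LabelMask,
    gamma_shape: float,
    gamma_scale: float,
    rng: np.random.Generator,
    label: int | None = None,
) -> VolumeGrid:
    """I.i.d. gamma(k, theta) activity on ROI voxels, zero outside.

    The gamma family realizes the right-skewed uptake the analysis targets:
    mean k*theta, skewness 2/sqrt(k).
    """
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    sel = mask.labels > 0 if label is None else mask.labels == label
    values = np.zeros(mask.shape, dtype=np.float64)
    values[sel] = rng.gamma(gamma_shape, gamma_scale, size=int(sel.sum()))
    return VolumeGrid(values, mask.spacing, mask.origin, Unit.BQ_PER_ML)


def inject_hot_clusters(
    volume: VolumeGrid,
    mask: LabelMask,
    n_clusters: int,
    radius_mm: float,
    amplitude: float,
    rng: np.random.Generator,
    label: int | None = None,
) -> tuple[VolumeGrid, list[np.ndarray]]:
    """Multiply spherical blobs (centres uniform over ROI voxels) by ``amplitude``.

    Returns the modified volume and, per blob, the flat C-order indices of its
    voxels (ground truth for hot-voxel recovery tests).
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be non-negative")
    if radius_mm <= 0:
        raise ValueError("blob radius must be positive")
    if n_clusters > 0 and amplitude <= 1:
        raise ValueError("amplitude must exceed 1")
    sel = mask.labels > 0 if label is None else mask.labels == label
    roi_extent = np.array(
        [(idx.max() - idx.min()) * s for idx, s in zip(np.nonzero(sel), mask.spacing)]
    )
    if n_clusters > 0 and 2 * radius_mm > roi_extent.max() + max(mask.spacing):
        raise ValueError("blob radius exceeds ROI extent")
    values = volume.values.copy()
    blob_index_sets: list[np.ndarray] = []
    if n_clusters > 0:
        roi_idx = np.argwhere(sel)
        xx, yy, zz = _voxel_centers(mask.shape, mask.spacing)
        for _ in range(n_clusters):
            c = roi_idx[rng.integers(len(roi_idx))]
            cx, cy, cz = (c[i] * mask.spacing[i] for i in range(3))
            inside = ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) <= radius_mm**2
            blob = inside & sel
            values[blob] *= amplitude
            blob_index_sets.append(np.flatnonzero(blob.ravel()))
    return VolumeGrid(values, volume.spacing, volume.origin, volume.unit), blob_index_sets


def smooth_fwhm(volume: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Gaussian smoothing with the kernel width given as FWHM in mm.

    Sigma per axis is converted to voxel units by that axis's spacing, so the
    kernel is isotropic in physical space on the anisotropic grid. FWHM 0 is
    the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return VolumeGrid(volume.values.copy(), volume.spacing, volume.origin, volume.unit)
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in volume.spacing]
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigma_vox, mode="constant")
    return VolumeGrid(smoothed, volume.spacing, volume.origin, volume.unit)


def si_to_ratio(target_si: float) -> float:
    """Non-dominant/dominant mean ratio r with SI = 200 (1 - r)/(1 + r)."""
    if not -200.0 < target_si < 200.0:
        raise ValueError("target SI must lie in (-200, 200)")
    return (200.0 - target_si) / (200.0 + target_si)


def make_paired_study(spec: PhantomSpec) -> PairedStudy:
    """Generate one subject: dominant limb plus mirrored, SI-scaled non-dominant limb.

    Ground truth records, per muscle and limb, the analytic pre-smoothing mean
    concentration (blob enrichment included in expectation), the analytic SUV
    and SI, and the blob voxel index sets.
    """
    rng = np.random.default_rng(spec.seed)
    labels_dom = np.zeros(spec.grid_shape, dtype=np.int32)
    for k, muscle in enumerate(spec.muscles, start=1):
        labels_dom = add_ellipsoid(
            labels_dom, spec.spacing, muscle.center_mm, muscle.semiaxes_mm, k
        )
    mask_dom = LabelMask(labels_dom, spec.spacing)
    mask_nd = mirror_mask(mask_dom)

    meta = AcquisitionMeta(
        injected_activity_bq=spec.injected_activity_bq,
        injection_time=datetime(2019, 1, 1, 9, 0, 0),
        scan_start_time=datetime(2019, 1, 1, 9, 0, 0)
        + timedelta(minutes=spec.uptake_minutes),
        body_mass_g=spec.body_mass_g,
        half_life_min=F18_HALF_LIFE_MIN,
    )
    suv_denom = meta.injected_at_scan_bq / meta.body_mass_g

    vol_dom = np.zeros(spec.grid_shape, dtype=np.float64)
    vol_nd = np.zeros(spec.grid_shape, dtype=np.float64)
    truth: dict = {"muscles": {}, "suv_denominator": suv_denom}
    for k, muscle in enumerate(spec.muscles, start=1):
        ratio = si_to_ratio(muscle.target_si)
        blob_sets = {}
        realized_mean = {}
        for side, mask, acc in (
            ("dominant", mask_dom, vol_dom),
            ("non_dominant", mask_nd, vol_nd),
        ):
            bg = sample_background(
                mask, muscle.gamma_shape, muscle.gamma_scale, rng, label=k
            )
            bumped, blobs = inject_hot_clusters(
                bg,
                mask,
                muscle.n_clusters,
                muscle.cluster_radius_mm,
                muscle.cluster_amplitude,
                rng,
                label=k,
            )
            sel = mask.labels == k
            acc[sel] = bumped.values[sel]
            realized_mean[side] = float(bumped.values[sel].mean())
            blob_sets[side] = blobs
        # rescale the mirrored limb so the realized pre-smoothing mean ratio
        # hits the target SI exactly (blob placement would otherwise jitter it)
        sel_nd = mask_nd.labels == k
        scale = ratio * realized_mean["dominant"] / realized_mean["non_dominant"]
        vol_nd[sel_nd] *= scale
        realized_mean["non_dominant"] = realized_mean["dominant"] * ratio
        truth["muscles"][muscle.name] = {
            "label": k,
            "mean_concentration_dominant": realized_mean["dominant"],
            "mean_concentration_non_dominant": realized_mean["non_dominant"],
            "suv_dominant": realized_mean["dominant"] / suv_denom,
            "suv_non_dominant": realized_mean["non_dominant"] / suv_denom,
            "target_si": muscle.target_si,
            "background_skewness": 2.0 / math.sqrt(muscle.gamma_shape),
            "blob_voxel_indices": blob_sets,
        }

    volume_dom = smooth_fwhm(
        VolumeGrid(vol_dom, spec.spacing, unit=Unit.BQ_PER_ML), spec.fwhm_mm
    )
    volume_nd = smooth_fwhm(
        VolumeGrid(vol_nd, spec.spacing, unit=Unit.BQ_PER_ML), spec.fwhm_mm
    )

    rows = []
    for k, muscle in enumerate(spec.muscles, start=1):
        for side in ("dominant", "non_dominant"):
            rows.append(
                {
                    "label": k,
                    "muscle_name": muscle.name,
                    "side": side,
                    "segment": muscle.segment,
                    "subject_id": "",
                }
            )
    return PairedStudy(
        volume_dominant=volume_dom,
        mask_dominant=mask_dom,
        volume_non_dominant=volume_nd,
        mask_non_dominant=mask_nd,
        meta=meta,
        label_table=pd.DataFrame(rows),
        ground_truth=truth,
    )


# --- default study conditions -------------------------------------------------

# Six muscle pairs (two per segment) spanning the reported ranges: mean SUV
# 0.6-2.4 g/mL, skewness ~0.7-2.6 via the gamma shape, and median ASI from 5%
# (thigh-like symmetry) to 42% (gastrocnemius-like asymmetry). Per-subject SI
# is drawn from Normal(0, median_asi/0.674): direction random across subjects,
# median |SI| equal to the listed median ASI.
DEFAULT_MUSCLES = [
    # name, segment, suv, gamma k, median ASI %, (cx, cy, cz) mm
    ("gluteus_maximus", "pelvis", 0.62, 2.0, 5.0, (17.6, 34.4, 20.0)),
    ("gluteus_medius", "pelvis", 0.85, 2.0, 15.0, (51.2, 34.4, 20.0)),
    ("adductor_magnus", "thigh", 0.72, 0.6, 6.0, (17.6, 34.4, 59.0)),
    ("vastus_lateralis", "thigh", 0.64, 8.0, 8.0, (51.2, 34.4, 59.0)),
    ("soleus", "lower_leg", 2.40, 2.0, 12.0, (17.6, 34.4, 98.0)),
    ("gastrocnemius_medialis", "lower_leg", 1.50, 2.0, 42.0, (51.2, 34.4, 98.0)),
]
_SEMIAXES = (12.0, 12.0, 16.0)
_MEDIAN_ABS_NORMAL = 0.6744897501960817  # median of |N(0,1)|


def default_phantom_spec(seed: int = 0, randomize_si: bool = True) -> PhantomSpec:
    """One subject under the default study conditions.

    With ``randomize_si`` the per-subject SI of each muscle is drawn so its
    across-subject median magnitude matches the muscle's listed median ASI;
    otherwise every target SI is 0.
    """
    rng = np.random.default_rng(seed)
    injected = float(np.clip(rng.normal(53.6e6, 1.8e6), 45e6, 62e6))
    body_mass = float(rng.uniform(55_500.0, 91_700.0))
    denom_ref = DEFAULT_INJECTED_BQ * 2 ** (-DEFAULT_UPTAKE_MIN / F18_HALF_LIFE_MIN) / DEFAULT_BODY_MASS_G
    muscles = []
    for name, segment, suv, k, asi_median, center in DEFAULT_MUSCLES:
        if randomize_si:
            si = float(np.clip(rng.normal(0.0, asi_median / _MEDIAN_ABS_NORMAL), -150, 150))
        else:
            si = 0.0
        muscles.append(
            MuscleShape(
                name=name,
                segment=segment,
                semiaxes_mm=_SEMIAXES,
                center_mm=center,
                gamma_shape=k,
                mean_concentration=suv * denom_ref,
                target_si=si,
            )
        )
    return PhantomSpec(
        muscles=muscles,
        injected_activity_bq=injected,
        body_mass_g=body_mass,
        seed=int(rng.integers(2**31 - 1)),
    )


def make_fixture_study(outdir: str | Path, n_subjects: int = 10, seed: int = 0) -> Path:
    """Materialize the default multi-subject study on disk.

    Writes, per subject, NIfTI volume+mask per limb and a metadata JSON, plus
    a study-wide label table CSV and a TOML manifest the ``analyze`` command
    consumes. Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    label_rows = []
    subject_blocks = []
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        spec = default_phantom_spec(seed=int(master.integers(2**31 - 1)))
        study = make_paired_study(spec)
        subdir = outdir / sid
        subdir.mkdir(exist_ok=True)
        paths = {}
        for side, vol, mask in (
            ("dominant", study.volume_dominant, study.mask_dominant),
            ("non_dominant", study.volume_non_dominant, study.mask_non_dominant),
        ):
            vp = subdir / f"{side}_volume.nii"
            mp = subdir / f"{side}_mask.nii"
            write_volume(vol, vp)
            write_mask(mask, mp)
            paths[f"{side}_volume"] = str(vp.relative_to(outdir))
            paths[f"{side}_mask"] = str(mp.relative_to(outdir))
        study.meta.to_json(subdir / "meta.json")
        paths["meta"] = str((subdir / "meta.json").relative_to(outdir))
        subject_blocks.append((sid, paths))
        tab = study.label_table.copy()
        tab["subject_id"] = sid
        label_rows.append(tab)
    pd.concat(label_rows, ignore_index=True).to_csv(outdir / "labels.csv", index=False)

    lines = [
        "[study]",
        f"seed = {seed}",
        'label_table = "labels.csv"',
        "hot_fraction = 0.05",
        "asi_threshold = 25.0",
        "alpha = 0.05",
        "histogram_bins = 50",
        "n_permutations = 0",
        "muscles_per_segment = 5",
        "",
    ]
    for sid, paths in subject_blocks:
        lines.append("[[subjects]]")
        lines.append(f'id = "{sid}"')
        for key, val in paths.items():
            lines.append(f'{key} = "{val}"')
        lines.append("")
    manifest = outdir / "study.toml"
    manifest.write_text("\n".join(lines))
    return manifest
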