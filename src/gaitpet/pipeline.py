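"""Study orchestration: run the full analysis from a TOML manifest.

Outputs, per run directory:

- ``per_muscle_records.csv`` — one row per subject/muscle/limb with voxel
  count, volume (mL), SUV (g/mL), AUV (g), skewness and cluster index.
- ``asi_summary.csv`` — per muscle: median/min/max ASI of SUV across subjects
  and the subjects exceeding the ASI threshold (default 25%).
- ``uptake_summary.csv`` — per muscle: median (range) SUV and AUV per limb,
  normality screen and paired signed-rank p-values (SUV and AUV).
- ``skewness_summary.csv`` / ``cluster_summary.csv`` — per muscle and limb,
  box-plot statistics (median, quartiles, whiskers, outliers).
- ``run_metadata.json`` — seed, parameters, package version, warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .heterogeneity import sample_skewness
from .imaging_io import AcquisitionMeta, read_label_table, read_mask, read_volume
from .spatial_clustering import compute_cluster_index, permutation_null
from .symmetry import (
    absolute_symmetry_index,
    normality_screen,
    paired_signed_rank_test,
    select_largest_muscles,
    summarize_asymmetry,
    symmetry_index,
)
from .uptake import quantify_muscle

logger = logging.getLogger("gaitpet")

__all__ = ["StudyConfig", "SubjectEntry", "load_config", "run_study", "boxplot_stats"]

MIN_SUBJECTS_FOR_TESTS = 2


@dataclass
class SubjectEntry:
    subject_id: str
    dominant_volume: Path
    dominant_mask: Path
    non_dominant_volume: Path
    non_dominant_mask: Path
    meta: Path


@dataclass
class StudyConfig:
    subjects: list[SubjectEntry]
    label_table: Path
    output_dir: Path
    hot_fraction: float = 0.05
    asi_threshold: float = 25.0
    alpha: float = 0.05
    histogram_bins: int = 50
    n_permutations: int = 0
    muscles_per_segment: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when permutations are requested")
        missing = []
        for sub in self.subjects:
            for p in (
                sub.dominant_volume,
                sub.dominant_mask,
                sub.non_dominant_volume,
                sub.non_dominant_mask,
                sub.meta,
            ):
                if not Path(p).exists():
                    missing.append(str(p))
        if not Path(self.label_table).exists():
            missing.append(str(self.label_table))
        if missing:
            raise FileNotFoundError(f"unresolvable study paths: {missing}")


def load_config(manifest: str | Path, output_dir: str | Path | None = None) -> StudyConfig:
    """Parse a TOML study manifest; relative paths resolve against its directory."""
    manifest = Path(manifest)
    payload = tomllib.loads(manifest.read_text())
    base = manifest.parent
    study = payload.get("study", {})
    subjects = []
    for block in payload.get("subjects", []):
        subjects.append(
            SubjectEntry(
                subject_id=str(block["id"]),
                dominant_volume=base / block["dominant_volume"],
                dominant_mask=base / block["dominant_mask"],
                non_dominant_volume=base / block["non_dominant_volume"],
                non_dominant_mask=base / block["non_dominant_mask"],
                meta=base / block["meta"],
            )
        )
    if not subjects:
        raise ValueError("manifest lists no subjects")
    out = Path(output_dir) if output_dir is not None else base / "results"
    return StudyConfig(
        subjects=subjects,
        label_table=base / study.get("label_table", "labels.csv"),
        output_dir=out,
        hot_fraction=float(study.get("hot_fraction", 0.05)),
        asi_threshold=float(study.get("asi_threshold", 25.0)),
        alpha=float(study.get("alpha", 0.05)),
        histogram_bins=int(study.get("histogram_bins", 50)),
        n_permutations=int(study.get("n_permutations", 0)),
        muscles_per_segment=int(study.get("muscles_per_segment", 5)),
        seed=int(study["seed"]) if "seed" in study else None,
    )


def boxplot_stats(values) -> dict:
    """Box-plot summary: quartiles by linear interpolation, Tukey 1.5 IQR whiskers.

    Outliers are points above q3 + 1.5 (q3 - q1) or below q1 - 1.5 (q3 - q1);
    whiskers extend to the most extreme non-outlier points.
    """
    x = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = x[(x >= lo) & (x <= hi)]
    outliers = x[(x < lo) | (x > hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(v) for v in outliers],
    }


def _quantify_subject(sub: SubjectEntry, labels: pd.DataFrame, cfg: StudyConfig) -> list[dict]:
    meta = AcquisitionMeta.from_json(sub.meta)
    rows = []
    for side, vol_path, mask_path in (
        ("dominant", sub.dominant_volume, sub.dominant_mask),
        ("non_dominant", sub.non_dominant_volume, sub.non_dominant_mask),
    ):
        volume = read_volume(vol_path)
        mask = read_mask(mask_path, reference=volume)
        side_tab = labels[(labels["subject_id"] == sub.subject_id) & (labels["side"] == side)]
        for _, lrow in side_tab.iterrows():
            rec = quantify_muscle(
                volume,
                mask,
                int(lrow["label"]),
                meta,
                muscle_name=lrow["muscle_name"],
                side=side,
                segment=lrow["segment"],
                subject_id=sub.subject_id,
            )
            roi = mask.labels == int(lrow["label"])
            labeling, cres = compute_cluster_index(rec.voxel_suvs, roi, cfg.hot_fraction)
            row = {
                "subject_id": sub.subject_id,
                "muscle": rec.muscle_name,
                "side": side,
                "segment": rec.segment,
                "voxel_count": rec.voxel_count,
                "volume_ml": rec.volume_ml,
                "suv_g_per_ml": rec.suv_mean,
                "auv_g": rec.auv_g,
                "skewness": sample_skewness(rec.voxel_suvs),
                "m_hot": labeling.m,
                "n_cold": labeling.n,
                "mean_nhn_hot": cres.mean_nhn_hot,
                "mean_nhn_cold": cres.mean_nhn_cold,
                "cluster_index": cres.cluster_index,
                "ties_flag": labeling.ties_broken,
            }
            if cfg.n_permutations > 0:
                null = permutation_null(
                    rec.voxel_suvs,
                    roi,
                    cfg.hot_fraction,
                    cfg.n_permutations,
                    seed=_perm_seed(cfg.seed, sub.subject_id, side, int(lrow["label"])),
                )
                row.update(
                    null_mean=null.null_mean, null_sd=null.null_sd, p_perm=null.p_value
                )
            rows.append(row)
    return rows


def _perm_seed(seed: int, subject_id: str, side: str, label: int) -> int:
    # process-independent (unlike hash()) so re-runs are byte-identical
    key = f"{seed}|{subject_id}|{side}|{label}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31 - 1)


def run_study(config: StudyConfig) -> dict:
    """Run the full paired-limb analysis and write the report bundle.

    Returns a dict of output paths plus the in-memory tables. Subjects missing
    a limb file would fail config validation up front; subjects whose muscles
    cannot be paired are dropped from paired analyses with a logged warning.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = read_label_table(config.label_table)
    warnings: list[str] = []

    records: list[dict] = []
    for sub in config.subjects:
        records.extend(_quantify_subject(sub, labels, config))
    rec_df = pd.DataFrame(records).sort_values(
        ["subject_id", "segment", "muscle", "side"], kind="stable"
    )

    # five largest muscles per segment, by mean volume across subjects and limbs
    mean_vol = rec_df.groupby("muscle")["volume_ml"].mean().to_dict()
    segments = rec_df.groupby("muscle")["segment"].first().to_dict()
    selected = select_largest_muscles(mean_vol, segments, config.muscles_per_segment)
    sel_df = rec_df[rec_df["muscle"].isin(selected)]

    wide = sel_df.pivot_table(
        index=["muscle", "subject_id"], columns="side", values=["suv_g_per_ml", "auv_g"]
    )
    n_subjects = rec_df["subject_id"].nunique()
    suppress_tests = n_subjects < MIN_SUBJECTS_FOR_TESTS
    if suppress_tests:
        msg = f"only {n_subjects} subject(s): group p-values suppressed"
        warnings.append(msg)
        logger.warning(msg)

    asi_rows, uptake_rows = [], []
    for muscle in sorted(set(sel_df["muscle"])):
        try:
            block = wide.xs(muscle, level="muscle").dropna()
        except KeyError:
            continue
        if block.empty:
            warnings.append(f"{muscle}: no complete limb pairs; skipped from paired analyses")
            continue
        suv_d = block[("suv_g_per_ml", "dominant")].to_numpy()
        suv_n = block[("suv_g_per_ml", "non_dominant")].to_numpy()
        auv_d = block[("auv_g", "dominant")].to_numpy()
        auv_n = block[("auv_g", "non_dominant")].to_numpy()
        sids = list(block.index)

        asi = [absolute_symmetry_index(d, n) for d, n in zip(suv_d, suv_n)]
        summ = summarize_asymmetry(asi, config.asi_threshold, sids)
        asi_rows.append(
            {
                "muscle": muscle,
                "median_asi": summ["median"],
                "min_asi": summ["min"],
                "max_asi": summ["max"],
                f"n_subjects_gt_{config.asi_threshold:g}": summ["n_above_threshold"],
                "subject_ids": ";".join(summ["subject_ids_above"]),
            }
        )

        row = {
            "muscle": muscle,
            "n_pairs": len(sids),
            "suv_dominant_median": float(np.median(suv_d)),
            "suv_dominant_min": float(suv_d.min()),
            "suv_dominant_max": float(suv_d.max()),
            "suv_non_dominant_median": float(np.median(suv_n)),
            "suv_non_dominant_min": float(suv_n.min()),
            "suv_non_dominant_max": float(suv_n.max()),
            "auv_dominant_median": float(np.median(auv_d)),
            "auv_dominant_min": float(auv_d.min()),
            "auv_dominant_max": float(auv_d.max()),
            "median_si": float(np.median([symmetry_index(d, n) for d, n in zip(suv_d, suv_n)])),
        }
        if not suppress_tests:
            row["p_suv"] = paired_signed_rank_test(suv_d - suv_n).p_value
            row["p_auv"] = paired_signed_rank_test(auv_d - auv_n).p_value
            if len(sids) >= 3:
                row["ks_reject_suv"] = normality_screen(
                    np.concatenate([suv_d, suv_n]), config.alpha
                )["reject_at_0.05"]
        uptake_rows.append(row)

    def _per_limb_box(df: pd.DataFrame, column: str) -> pd.DataFrame:
        rows = []
        for (muscle, side), grp in df.groupby(["muscle", "side"]):
            stats = boxplot_stats(grp[column].to_numpy())
            rows.append(
                {
                    "muscle": muscle,
                    "side": side,
                    "n": len(grp),
                    **{k: v for k, v in stats.items() if k != "outliers"},
                    "outliers": ";".join(f"{v:.6g}" for v in stats["outliers"]),
                }
            )
        return pd.DataFrame(rows).sort_values(["muscle", "side"], kind="stable")

    out_paths = {
        "records": outdir / "per_muscle_records.csv",
        "asi_summary": outdir / "asi_summary.csv",
        "uptake_summary": outdir / "uptake_summary.csv",
        "skewness_summary": outdir / "skewness_summary.csv",
        "cluster_summary": outdir / "cluster_summary.csv",
        "metadata": outdir / "run_metadata.json",
    }
    fmt = "%.17g"  # full round-trip precision so summaries recompute exactly from CSV
    rec_df.to_csv(out_paths["records"], index=False, float_format=fmt)
    pd.DataFrame(asi_rows).to_csv(out_paths["asi_summary"], index=False, float_format=fmt)
    pd.DataFrame(uptake_rows).to_csv(out_paths["uptake_summary"], index=False, float_format=fmt)
    _per_limb_box(sel_df, "skewness").to_csv(
        out_paths["skewness_summary"], index=False, float_format=fmt
    )
    _per_limb_box(sel_df, "cluster_index").to_csv(
        out_paths["cluster_summary"], index=False, float_format=fmt
    )
    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "n_subjects": int(n_subjects),
        "selected_muscles": selected,
        "hot_fraction": config.hot_fraction,
        "asi_threshold": config.asi_threshold,
        "alpha": config.alpha,
        "n_permutations": config.n_permutations,
        "ties_broken_anywhere": bool(rec_df["ties_flag"].any()),
        "warnings": warnings,
    }
    out_paths["metadata"].write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return {
        "paths": {k: str(v) for k, v in out_paths.items()},
        "records": rec_df,
        "asi_summary": pd.DataFrame(asi_rows),
        "uptake_summary": pd.DataFrame(uptake_rows),
        "metadata": metadata,
    }
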