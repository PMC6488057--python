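# gaitpet

Volumetric analysis of [¹⁸F]-fluorodeoxyglucose (FDG) uptake in paired
lower-limb muscles from PET, for researchers studying muscle activity during
gait. Given a 3-D activity volume (NIfTI, or a DICOM image series with rescale
slope/intercept), an aligned integer label mask of muscle ROIs, and the
acquisition metadata (injected dose, injection/scan times, body mass), the
package quantifies each muscle and asks three questions:

1. **Is uptake symmetric between the limbs?** Per muscle *i*, the mean
   standardized uptake value is

   SUVᵢ = (total activity in muscle [Bq] / muscle volume [mL]) /
   (injected activity at scan start [Bq] / body mass [g])  (g/mL),

   with the injected dose decay-corrected over the uptake interval
   (F-18 half-life 109.77 min). The absolute uptake value AUVᵢ = SUVᵢ ·
   volumeᵢ (g) removes volume normalization. Inter-limb asymmetry is the
   symmetry index

   SIᵢ = 100% · (SUVᵢ,dom − SUVᵢ,non-dom) / (½ (SUVᵢ,dom + SUVᵢ,non-dom)),
   ASIᵢ = |SIᵢ|,

   with paired dominant vs non-dominant comparison by an exact Wilcoxon
   matched-pair signed-rank test (full 2ⁿ enumeration, midranks for ties).

2. **Is uptake heterogeneous within a muscle?** The skewness g₁ = m₃/m₂^{3/2}
   of the voxelwise SUV distribution; right-skew means most voxels sit at low
   uptake with a high-uptake tail.

3. **Do high-uptake voxels cluster spatially?** The top 5% of ROI voxels are
   'hot', the rest 'cold'. With NHN(v) the number of face-adjacent
   (6-connectivity) hot neighbours of voxel v,

   cluster index = mean NHN over hot voxels / (mean NHN over cold voxels × 19),

   where 19 = 95/5 compensates the cold:hot count imbalance. Random scatter
   gives ≈ 1/19; compact hot blobs give values above 1. A seeded permutation
   null is provided to calibrate the index per muscle.

Because no suitable public dataset ships with paired-limb muscle masks, the
package includes a synthetic phantom generator (ellipsoidal muscle ROIs on the
1.6 × 1.6 × 2.0 mm PET grid, gamma-distributed uptake, spherical hot blobs,
controlled target SI, 3 mm FWHM Gaussian post-smoothing) with full ground
truth, so the entire pipeline is testable end to end.

## Worked example

```python
from gaitpet import (MuscleShape, PhantomSpec, make_paired_study,
                     quantify_muscle, symmetry_index, sample_skewness,
                     compute_cluster_index)

muscle = MuscleShape(
    name="gastrocnemius_medialis", segment="lower_leg",
    semiaxes_mm=(14.0, 14.0, 18.0), center_mm=(35.2, 35.2, 60.0),
    gamma_shape=4.0, mean_concentration=800.0, target_si=42.0,
)
study = make_paired_study(PhantomSpec(muscles=[muscle], seed=42))
dom  = quantify_muscle(study.volume_dominant, study.mask_dominant, 1, study.meta)
nond = quantify_muscle(study.volume_non_dominant, study.mask_non_dominant, 1, study.meta)
print(f"SUV dom {dom.suv_mean:.3f}  SUV non-dom {nond.suv_mean:.3f}")
print(f"SI {symmetry_index(dom.suv_mean, nond.suv_mean):+.1f} %")
print(f"skewness {sample_skewness(dom.voxel_suvs):.2f}")
lab, res = compute_cluster_index(dom.voxel_suvs, study.mask_dominant.labels == 1)
print(f"cluster index {res.cluster_index:.2f}")
```

prints

```
SUV dom 1.516  SUV non-dom 0.984
SI +42.6 %
skewness 1.37
cluster index 2.05
```

The phantom was built with a +42% target symmetry index and recovers +42.6%
after smoothing; the gamma background (shape 4) has true skewness
2/√4 = 1.0, raised to 1.37 by the injected hot blobs; the cluster index of
2.05 is far above the ≈ 0.053 random-scatter level, flagging the blobs.

## Command line

```sh
gaitpet make-fixtures study/ --subjects 10 --seed 0   # synthetic study on disk
gaitpet analyze study/study.toml --out results/       # full report bundle (CSV + JSON)
gaitpet cluster-index vol.nii mask.nii --label 3 --permutations 200 --seed 1
gaitpet symmetry results/per_muscle_records.csv
```

`analyze` writes per-muscle records, an ASI summary (median/range, subjects
above the 25% threshold), an SUV/AUV summary with signed-rank p-values, and
skewness/cluster-index box-plot statistics per muscle and limb. Runs are
byte-identical given the same seed.

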