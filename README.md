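# lesionmap

Lesion-based analytics for mesial temporal lobe epilepsy (mTLE) with
hippocampal sclerosis. Starting from co-registered binary masks of
hippocampal FLAIR hyperintensity (one per subject, on a common grid) plus a
clinical subject table, the package implements four analyses:

1. **Segmentation QC and rostro-caudal coding** — Sørensen–Dice overlap
   `DSC = 2|X ∩ Y| / (|X| + |Y|)` between duplicate segmentations, lesion
   volume in cc, and binary head/body/tail involvement flags from manually
   identified landmark slice indices (uncal apex and thalamus on coronal
   slices).
2. **Probabilistic severity mapping** — each lesion is weighted by its
   subject's 0–4 seizure-freedom score *s* (lower = worse prognosis) and
   size-normalized with weight `w_i = 1/|X_i|`; the average map at voxel v
   is the weighted mean `Σ w_i s_i / Σ w_i` over overlapping subjects, a
   frequency mask retains voxels touched by ≥ ⌈0.10·N⌉ subjects, and a
   two-sided one-sample Wilcoxon signed-rank test per voxel (exact sign-flip
   enumeration for n ≤ 25, Pratt normal approximation above) asks whether
   the overlapping subjects' scores deviate from the cohort mean. The final
   map is the average map masked at p < 0.05.
3. **Normative connectome contrast** — each subject's lesion mask seeds a
   resting-state normative dataset: per normative subject, Pearson r between
   the seed's mean BOLD series and every voxel, pooled across normative
   subjects by Fisher-z averaging. A voxel-wise logistic regression of seed
   laterality (right = 1) on Fisher-z connectivity yields a Wald-z effect
   map with likelihood-ratio p-values, corrected by Benjamini–Hochberg FDR
   at q = 0.01.
4. **Cortical-thickness models** — ordinary least squares of per-subject
   mean cortical thickness on disease duration, laterality, and their
   interaction, with age at diagnosis or age at surgery as alternative
   covariates; per-side duration slopes and the duration × tail-sclerosis
   interaction on the right-sided subgroup.

No clinical data ship with the package. The `synthetic_data` module
generates complete cohorts with planted effects — lesions extending a
variable distance into the posterior hippocampus, severity scores
anticorrelated with posterior extent, thickness declining faster with
right-sided foci, and a BOLD surrogate in which the right seed's network is
broadcast to a strictly larger target set — so every stage can be exercised
and validated offline.

## Worked example

```bash
lesionmap simulate --out demo --seed 7 --n-subjects 35
lesionmap thickness --subjects demo/subjects.csv
```

```
age_at_diagnosis: left slope -0.00625 mm/yr (p=0.000115), right slope -0.01206 mm/yr (p=3.54e-07), interaction p=0.0224
age_at_surgery: left slope -0.00750 mm/yr (p=0.0148), right slope -0.01331 mm/yr (p=8.99e-06), interaction p=0.0224
```

Mean cortical thickness declines with disease duration in both groups, and
the decline is roughly twice as steep for right-sided seizure foci (the
planted interaction; p ≈ 0.02 at n = 35) under either age covariate.

```bash
lesionmap map --subjects demo/subjects.csv --out demo/maps
cat demo/maps/severity_map.json
```

```json
{
  "alpha": 0.05,
  "fraction": 0.1,
  "mu0": 1.6571428571428573,
  "n_subjects": 35,
  "threshold_count": 4,
  ...
}
```

`demo/maps/` now holds `average_map.nii.gz` (mean weighted score per voxel),
`frequency_map.nii.gz` (overlap counts), `p_map.nii.gz` (signed-rank
p-values; −1 marks voxels outside the frequency mask), and
`final_map.nii.gz` (the average map masked to significant voxels, which
concentrates in the posterior hippocampus for the planted gradient). With
35 subjects the frequency threshold is ⌈0.10 × 35⌉ = 4 overlapping
subjects, and the Wilcoxon reference value μ0 defaults to the cohort mean
score (1.657 here).

`lesionmap summary --subjects demo/subjects.csv` prints the per-laterality
cohort table (group sizes, percent female, median/range onset and surgery
ages, score distribution, Engel-1 percentage), and
`lesionmap run-all --config config.json` chains every stage and writes a
manifest with a content hash per output; identical inputs give identical
manifests.

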