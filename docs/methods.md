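# Methods

This note documents the statistical procedures, the synthetic-data
generator that stands in for clinical data, the numerical choices, and the
known limitations of the package.

## Data model

All voxel-wise analyses operate on a single common grid (`VolumeGrid`:
3D array + 4×4 voxel-to-world affine). Lesion masks are strictly binary and
non-empty; grids are considered aligned when shape, voxel spacing, and
affine agree within 1e-6 — tight enough to catch a real grid mismatch,
loose enough to absorb float32 round-trips. Non-binary mask files are
binarized at value > 0.5. Spatial registration, resampling between grids,
and segmentation itself are outside the package's scope: masks arrive
already co-registered.

Rostro-caudal coding takes the manually identified landmark slices as
input (`SubfieldLandmarks`). The head–body boundary is the first body
slice and the body–tail boundary the first tail slice: a boundary slice
belongs to the more posterior segment, so the three ranges are half-open
and no slice is counted twice. The anterior direction along the slice axis
is explicit configuration, never inferred from the affine, because
synthetic grids carry no anatomical orientation.

## Probabilistic severity mapping

Given N aligned lesion masks with severity scores `s_i ∈ {0..4}` (a
seizure-freedom scale; lower = worse prognosis):

* **Frequency map** — per-voxel count of masks touching the voxel.
* **Frequency mask** — retain voxels with count ≥ ⌈fraction·N⌉ (default
  fraction 0.10; the ceiling keeps the threshold an achievable integer, and
  a floor of 1 keeps "fraction 0" meaning "any overlap").
* **Average map** — at voxel v, `Σ_{i∋v} w_i s_i / Σ_{i∋v} w_i` with
  `w_i = 1/|X_i|` (size normalization penalizes large, unfocal lesions
  while keeping the map on the 0–4 score scale). An alternative
  normalization that divides scores by lesion size before a plain mean is
  available behind a flag (`normalization="mean_of_scaled"`) but changes
  the map's scale; the weighted mean is the default.
* **Statistical map** — at each retained voxel, a two-sided one-sample
  Wilcoxon signed-rank test of the overlapping subjects' scores against a
  reference value μ0. μ0 defaults to the cohort mean score (testing "does
  overlap at this voxel carry information about severity?") and is
  configurable; comparing against the non-overlapping subjects instead is
  possible via the exposed primitives but is not the default.
* **Final map** — the average map masked to voxels passing both the
  frequency mask and p < α (default 0.05). Voxels outside the frequency
  mask carry NaN in memory and the sentinel −1.0 in written p-map files,
  distinguishing "untested" from "tested, null".

### Signed-rank details

Scores take five values, so ties dominate and textbook implementations
(which assume continuous data) do not apply directly. Zero differences are
dropped before ranking in the exact branch; the approximate branch uses the
Pratt convention (zeros ranked with the rest, then dropped from the
statistic). For n ≤ 25 nonzero differences the exact two-sided p-value is
computed from the full sign-flip distribution of the positive midrank sum:
a tied group of k elements with midrank r contributes a Binomial(k, ½)
factor at spacing 2r, and convolving the per-group factors yields exactly
the distribution the 2^n enumeration would give at polynomial cost. Above
n = 25 a normal reference is used whose mean Σr/2 and variance Σr²/4 are
the exact moments of the midrank statistic (this reproduces the textbook
tie correction; no continuity correction, so results are deterministic and
match `scipy.stats.wilcoxon(zero_method="pratt", correction=False)`).
Voxels with fewer than two nonzero differences get p = 1 and are counted
in a diagnostics log. Because a voxel's p-value depends only on the counts
of each score value among its overlapping subjects, voxels are grouped by
that count vector and each distinct configuration is evaluated once.

Two calibration caveats are inherent to this construction and are visible
in the permutation tests: (i) with a 5-point score the exact two-sided test
cannot reach p < 0.05 at voxels with ≤ 5 overlapping subjects, and (ii)
under score permutation a voxel's sample is drawn without replacement from
the finite cohort whose mean equals μ0, which shrinks the rank-sum
dispersion relative to the independent sign-flip null. Pooled over retained
voxels the permutation false-positive fraction at α = 0.05 therefore sits
near 0.02–0.03 rather than 0.05: the map's significance threshold is
conservative, not anti-conservative.

## Normative connectome contrast

For each subject, the lesion mask seeds the normative dataset: per
normative subject, the seed's unweighted mean time series is correlated
with every voxel's series (voxels with zero variance in a subject are
excluded from that subject's contribution), and per-voxel correlations are
pooled across normative subjects by the mean of Fisher z, transformed back
to r (variance-stabilized pooling). Seed voxels are flagged NaN in the
subject's own map. No temporal filtering or nuisance regression is applied;
the normative data are assumed preprocessed.

The group contrast regresses the laterality indicator (right = 1) on the
per-voxel Fisher-z connectivity values across subjects with a two-parameter
logistic model, fitted by Newton/IRLS (max 100 iterations, tolerance 1e-8)
on a per-voxel standardized covariate. The signed **Wald z** is reported as
the effect map. Inference, however, uses the **likelihood-ratio test** of
the same fit: at n = 35 the Wald statistic is non-monotone in the effect
size (the Hauck–Donner phenomenon — its magnitude *decreases* again for
strong effects and empirically never exceeds ≈ 3.2 at this sample size), so
Wald p-values cannot drive a voxel-level FDR step at q = 0.01 no matter how
strong the effect; the LR statistic remains monotone and its null tail is
essentially nominal at this n. Voxels with complete separation, detected as
a standardized coefficient magnitude > 50 or non-convergence, are flagged,
excluded from FDR, and counted in the diagnostics. Multiplicity is
controlled by Benjamini–Hochberg step-up over tested voxels at q = 0.01
(via `statsmodels.stats.multitest`, validated in the tests against a direct
O(m²) step-up). A two-sample Mann–Whitney alternative
(`method="ranksum"`) is exposed for comparison; its statistic agrees with
the logistic contrast in sign, though not in magnitude, at strongly
affected voxels (the Wald saturation above).

## Cortical-thickness models

Ordinary least squares of per-subject mean cortical thickness (mm) on a
configurable predictor set (`ModelSpec`). Disease duration equals age at
surgery minus age at onset, so the two age covariates are mutually
exclusive per fit; two presets mirror the alternative adjustments (age at
diagnosis vs age at surgery). Designs are rejected when any predictor has
zero variance or the condition number of the scaled design exceeds 1e10
(the error names near-duplicate columns). Per-side duration slopes come
from the interaction model — the right slope is the sum of the duration
and interaction coefficients with its exact linear-combination standard
error — and the duration × tail-sclerosis interaction is fitted on the
right-laterality subgroup. Note that with a single non-tail subject in the
subgroup that design is exactly singular (the interaction column becomes a
linear combination of the others); the pipeline reports the design error
rather than a fit in that case.

## Synthetic cohorts

The generator defines the study conditions under which the pipeline is
validated. Defaults: 35 subjects, P(right) = 15/35, a 48×56×48 grid at
1 mm, disease duration uniform on 2–46 years, onset age uniform on 1–30
years, Engel-class frequencies 29:2:0:2:2 (classes 1/2/3/4/unknown), and
P(female) = 16/35.

* **Lesions** — each mask occupies a contiguous run of coronal slices
  anchored at the anterior (head) end of its hemisphere's hippocampal
  footprint and extending a posterior fraction f ~ U(0.05, 1), with an
  elliptical in-plane cross-section (radii U(2.3, 4.3) voxels, jittered
  center). Anchoring at the head makes anterior voxels overlap nearly the
  whole cohort (so their score samples match the cohort and stay null)
  while posterior voxels are reached only by high-f subjects — the planted
  "posterior extent carries severity" signal.
* **Scores** — latent `3.5 − 3.0·f + N(0, 0.7)`, rounded and clipped to
  0–4. β = 3 spans the full scale over the f range; noise 0.7 keeps the
  rank correlation with f around −0.7 at n = 35, strong but not
  deterministic.
* **Thickness** — `3.0 − 0.008·duration − 0.006·duration·1[right] +
  N(0, 0.08)` mm: a baseline near healthy adult mean thickness, a decline
  of a few μm per year of disease, roughly doubled on the right, and a
  residual SD small enough for the interaction to be detectable (p ≈ 0.02)
  at n = 35 without being trivial.
* **Normative BOLD** — 20 normative subjects, 124 time points, on a
  separate 12×15×12 grid at 3 mm (typical EPI resolution). Each hemisphere
  has a 5×7×5 seed footprint; one latent time series per footprint slice
  and side, plus one global latent shared by both sides, plus a dominant
  per-voxel idiosyncratic signal inside the footprints (~90% of seed
  variance), plus unit white noise everywhere. Target regions (three boxes,
  108 voxels, for the right network; one box, 36 voxels, for the left) load
  on the posterior-weighted sum of their side's slice latents (ramp
  0.25→1.0 head→tail) and on the global latent. Patient seeds on this grid
  are fixed-size 2×2×3 sliding windows whose posterior end tracks the
  subject's posterior extent fraction — a deliberate simplification
  relative to the anterior-anchored 1 mm masks that keeps the idiosyncratic
  variance share identical across patients.

  These proportions are load-bearing. Because every patient's r-map is a
  deterministic function of the same normative data, any signal component
  shared by all same-side seeds becomes a class-common "fingerprint" at
  every brain voxel at the normative-sampling scale (~0.008 in r for 20
  subjects × 124 time points), and the voxel-wise contrast would declare it
  significant brain-wide. Keeping the shared network latents to ~10% of
  seed variance, splitting them per slice, and decorrelating seed voxel
  sets through the 5×5 in-plane footprints pushes that fingerprint well
  below the within-class spread; the global latent gives left-sided seeds a
  nonzero baseline correlation with right-sided targets, so the class
  distributions overlap and the logistic fit converges rather than
  separating.

What the surrogate does **not** model: anatomical structure and contrast,
spatial autocorrelation of noise, hemodynamics and physiological noise
spectra, multi-run averaging per normative subject, and any coupling
between the 1 mm mask grid and the BOLD grid (no resampling). Passing
tests therefore demonstrate the statistical machinery recovers planted
effects under these idealized conditions, not performance on clinical MRI.

All generators are deterministic: a configuration plus master seed
reproduces outputs bit-for-bit, with independent per-stage substreams so
changing one stage's model leaves the others' draws untouched.

## Validation sizes

The test suite exercises: Dice against a per-voxel loop on 200 random
pairs (grids ≤ 20³); signed-rank p-values against full 2^n enumeration for
n ≤ 10 and a 500-permutation calibration on one 35-subject cohort;
severity-map recovery over 20 cohorts (with ten score shuffles per cohort
for the null fraction); r-maps against direct Pearson computation; BH
against an O(m²) oracle on 1000 random vectors plus a 500-replicate
m = 2000 null calibration; laterality-contrast recovery over 20 simulations
with 100 label shuffles for the null; and 100-replicate CI coverage for the
thickness coefficients at n = 200. These sizes keep the full suite under
a few minutes while leaving Monte Carlo margins well clear of the asserted
bounds.

## Pipeline and reproducibility

`run_all` chains the stages on a directory layout like the one
`lesionmap simulate` writes and records a manifest with a SHA-256 hash per
output; identical configuration and inputs yield identical manifests
(NIfTI writing is deterministic, including gzip members). All thresholds
(α, frequency fraction, q, μ0 mode) live in configuration with the
analysis defaults; nothing is hard-coded.
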