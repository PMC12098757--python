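# Methods

## The analysis

`tremormap` implements convergent tremor-network mapping: given binary
seed regions per treated hemisphere (DBS stimulation volumes or lesions)
and per-hemisphere clinical tremor scores, it asks which whole-brain
functional connectivity profile characterizes seeds with good outcomes,
and whether that profile converges across stimulation targets, disorders,
and imaging modalities.

The chain of constructions:

1. **Group connectome.** Per subject, multi-run resting-state voxel time
   series are demeaned per voxel within each run, concatenated, and all
   pairwise Pearson correlations computed; subject matrices are averaged
   element-wise (raw correlations, no Fisher-z — a `fisher_z` option
   exists but is off by default, matching normative-connectome practice).
   Voxels with zero variance get correlation 0 (never NaN) and are
   flagged, so downstream averages stay finite.
2. **Seedmaps.** The connectivity profile of a seed is the mean of the
   connectome rows belonging to its voxels — one value per in-mask voxel,
   including the seed's own voxels (whose self-correlation contributes).
   Right-sided seeds are mirrored across the midsagittal plane first, so
   all hemispheres are analyzed in one frame.  The mirror is a pure index
   flip `i -> nx - 1 - i`; on the exactly symmetric synthetic grids this
   is exact, on asymmetric real templates it is an approximation the grid
   must opt into (`midsagittal_symmetric`).
3. **Outcomes.** Tremor scores enter as hemibody scores assigned to the
   contralateral electrode.  Hemispheres with baseline below 3 points are
   excluded (improvement cannot be measured without baseline symptoms).
   Because cohorts use different scales (MDS-UPDRS-III tremor items vs
   Fahn-Tolosa-Marin), pooled analyses use the improvement normalized by
   the maximum reachable score, a ratio in [-1, 1]; worsening is kept
   negative, never clipped.
4. **R-maps.** Per voxel, the correlation (Spearman by default; the
   voxel-wise method is selectable) between seed connectivity at that
   voxel and normalized improvement across a cohort's hemispheres.
   Voxels with degenerate connectivity variance are excluded from the
   map's coverage.
5. **Map similarity.** Two metrics: the voxel-wise multiplication sum
   (`similarity_dot`, used to score seedmaps against published a-priori
   maps) and the spatial rank correlation (`similarity_corr`, used
   between R-maps and for R-map-based outcome prediction).
6. **Inference.** Scalar associations are Spearman rank correlations
   with permutation p-values (5000 permutations by default, two-sided,
   `p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm)`, so p is never
   0) and 95% percentile-bootstrap CIs (2000 resamples).  Cohort
   membership is controlled either by residualizing the predictor on
   dummy-coded cohort labels (equivalently, within-cohort mean centering)
   or by a joint OLS with a cohort dummy (optionally a
   similarity-by-cohort interaction).  Degrees of freedom are reported as
   n − 2.
7. **Cross-validation.** Fivefold, at the patient level: both
   hemispheres of a patient share a fold, folds are stratified by cohort
   when cohorts are pooled, the R-map is rebuilt per fold on the training
   hemispheres only, and left-out hemispheres are scored by spatial
   correlation to it.  Pooled predictions are residualized on cohort
   (when pooled) and rank-correlated with observed improvements.
8. **R-map similarity permutation test.** The spatial correlation of two
   cohorts' R-maps is compared with a null built by shuffling outcomes
   within one (or both) cohorts and rebuilding the affected map(s) each
   iteration (10,000 by default); the p-value is one-sided (greater),
   matching the directional question "more similar than chance".
9. **Agreement maps.** Given N maps, a voxel is retained iff every map
   covering it is strictly positive there or every one strictly negative
   (zero counts as no sign).  Retained values are the product of absolute
   values with the common sign restored, after each map is divided by its
   maximum absolute covered value so maps on different scales
   (probabilities, z-scores, correlations) weigh comparably.  A map with
   partial coverage only informs the voxels it defines — a coverage gap
   never vetoes a voxel.  The result is z-scored over retained voxels
   (zeros elsewhere, coverage limited to retention).  Whether to z-score
   over retained voxels or the whole mask was an open choice; retained
   voxels were chosen because off-retention values are a constant 0 and
   would only shift the z-scale.
10. **Lesion network overlap.** Each lesion's seedmap is binarized at a
    user-chosen connectivity threshold (optionally two-sided) and the
    binarized maps summed: the per-voxel count of lesions connected to
    that voxel.  No default threshold is asserted.

## Numerical and reproducibility choices

* No resampling anywhere: all volumes must share one grid; mismatches are
  hard errors.  NaN on disk means "not covered", distinct from 0.
* Ties in rank correlations use average ranks.
* All permutation and bootstrap streams come from the Philox
  counter-based generator keyed by the user's seed; the synthetic module
  uses NumPy's default PCG64.  Same seed, same platform-independent
  results — reruns are bit-identical.
* Permutation p-values are valid by construction (minimum
  `1/(n_perm+1)`); comparisons use a 1e-12 slack so exact ties count.
* The connectome store is HDF5 (`/matrix` float32, `/voxel_index`,
  `/grid`); seeding a memory-mapped store reads only the required rows.
* Hold-out firewalling is mechanical: every map built from a cohort
  carries a content hash of that cohort's clinical data and seed
  geometry in its provenance (persisted in the NIfTI description field);
  the convergent/hold-out analysis refuses any input map whose
  provenance contains the hold-out cohort's hash.

## The synthetic study

Patient imaging and large normative connectomes cannot ship with a
package, so the generator builds a study with known ground truth.

**Connectome.** Voxel time series are linear mixtures of latent spatial
networks driven by unit-variance Gaussian temporal signals (fresh per
subject and run) plus white noise (SD 0.5).  The first network is the
*planted tremor circuit*: Gaussian nodes at fixed shape-relative
positions — a subcortical node lying between the two cohorts' stimulation
target boxes, two remote positive nodes, and two remote negative nodes,
arranged symmetrically about the subcortical node so both cohorts' targets
sample comparable circuit gradients (amplitude 1.3).  The remaining 15
networks are Gaussian random fields smoothed to 4.5 voxels (amplitude
0.55): structured background everywhere, smoother than the circuit so the
dominant connectivity gradient near the targets is circuit coupling.  All
patterns are spatially centered so no artificial global signal arises.
An early design used a few compact random dipoles instead; it left most
voxels without latent structure and made the hub profile unrecoverable in
principle, independent of sample size — the planted-circuit design
replaced it.

**Ground truth.** The truth map is the connectivity profile of a
two-voxel hub inside the circuit's subcortical node — exactly what the
analysis is supposed to recover as "optimal connectivity".

**Cohorts.** Per hemisphere, a spherical stimulation volume with center
uniform in the cohort's target box (mirrored in x for right-sided
electrodes) and radius uniform in 1.2–2.6 voxels.  The latent response is
the seedmap's rank correlation with the truth; the normalized improvement
is linear in that similarity (slope 0.5 around the cohort mean of 0.45)
plus Gaussian noise, clipped to [0, 1].  When `noise_sd` is not given it
is calibrated so similarity explains `target_r2` (default 50%) of the
outcome variance — the regime the validation suite is specified in.
Scores are bounded integers: baselines are drawn from the top 70–100% of
the scale (so improvements fit without truncation), post scores are
rounded to whole points and clipped to [0, baseline].  The two default
cohorts differ in target box (disjoint, on opposite sides of the hub) and
scale maximum (20, UPDRS-like hemibody, vs 40, FTM-like), forcing the
cohort-regressor code paths.  Baselines are ≥ 3 by construction, so the
inclusion rule is satisfied rather than tested by the generator.

**Scale.** 16 × 16 × 8 grid (2048 voxels, 2 mm), 20 subjects × 4 runs ×
60 samples, 30 patients per cohort with electrodes in both hemispheres
(60 hemispheres).  A full simulated study runs in seconds; the entire
validation suite in under two minutes.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: hemodynamics and temporal autocorrelation,
realistic spatial autocorrelation of fMRI noise, anatomically faithful
VTA geometry and template asymmetry, scanner/site effects, and clinical
raters.  Recovery results quantify the estimator under the generator's
assumptions, not field performance.

## What recovery the estimator supports

With 60 hemispheres and noise equal to signal, the per-voxel Spearman
sampling error (~0.12) alone caps the expected whole-brain spatial
correlation between an estimated R-map and the truth near 0.90; observed
per-cohort values run 0.8–0.95.  The validation therefore checks the
pooled two-cohort R-map (120 hemispheres, within-cohort-centered
normalized improvements) against the 0.8 recovery bar under 50% outcome
noise, and checks each single cohort's map against the same bar in the
low-noise regime (noise ≤ 25% of outcome SD), where it holds with margin.

A related structural point: any two hub profiles drawn from the same
connectome share latent structure, so R-maps from cohorts driven by
*different* truths are genuinely similar and the permutation test
correctly flags them.  Null calibration of the test is therefore
established with outcome-randomized cohorts (the null the test actually
permutes), and the independent-truth control instead uses a truth pattern
unrelated to the connectome and checks that hold-out prediction is not
systematically positive.

## Known limitations

* The hemisphere flip is a pure mirror; real MNI templates are slightly
  asymmetric and the source pipelines flip non-linearly.
* "Mean-averaging each run" in connectome construction is implemented as
  per-run per-voxel demeaning before concatenation — the reading under
  which the step changes the result; the alternative reading is not
  asserted.
* Whether published a-priori map similarities were multiplication sums or
  spatial correlations is ambiguous in the source descriptions; both are
  implemented (`dot` is the default for a-priori maps, `corr` for
  R-maps).
* Hemibody scale maxima differ across scale versions and are not
  hard-coded; they are a required input column.
* No voxel-wise multiple-comparison correction is applied anywhere, by
  design (the analyses are map-level, not mass-univariate inference).
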