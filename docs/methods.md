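# Methods

This note documents the models implemented in `parenkin`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions that affect results.

## Kinetic quantification

Inputs are one pre-contrast and three post-contrast volumes on a common
grid (co-registration is assumed, not performed), with binary breast and
fibroglandular-tissue (FGT) masks supplied as inputs; segmentation is out
of scope.  Subtraction volumes are `SUB_k = S_k − S0`; negative values are
retained, since clamping would discard information and no clinical
post-processing convention is assumed.

Per FGT voxel, with relative enhancement `E_k = (S_k − S0)/S0`:

- **Peak enhancement** is `max_k E_k`; ties break to the *earliest*
  timepoint for determinism.
- **Wash-in slope** is defined as peak enhancement divided by time to
  peak.  Normalising by `S0` makes the measure invariant to global
  intensity scaling, which matters because MR signal units are arbitrary.
- **Wash-out slope** is `(E_3 − peak)/(t_3 − TTP)` and set to 0 when the
  curve peaks at the last timepoint: no wash-out has been observed, and a
  zero keeps the voxel inside the aggregate statistics without a sentinel.
- **SER** is `SUB1/SUB3`.  The denominator is declared degenerate when
  `SUB3 ≤ 1e-6 ×` (median pre-contrast signal over valid FGT voxels); such
  voxels are excluded from SER-based quantities but retained in the
  wash-in/wash-out statistics, avoiding unbounded ratios without dropping
  the voxel entirely.
- Voxels with non-positive `S0` are flagged invalid, excluded from every
  aggregate, and counted.

Breast-wise aggregation uses the population variance (divide by `n`):
with voxel counts of order 10²–10⁶ the estimator choice is immaterial, and
the population form matches a plain second-moment oracle exactly in tests.
Thresholds are inclusive: enhancing means first-post enhancement ≥ 20%,
and the SER-volume rule is SER ≥ 0.9.  All thresholds (0.9, 1.3, 20%, and
the ±15% pair band) are configuration values with these defaults.

Two definitional ambiguities are resolved by documented switches:

- **SER volume** counts voxels that are *enhancing and* have SER ≥ 0.9
  (default).  The alternative — all valid-SER FGT voxels with SER ≥ 0.9
  regardless of the 20% gate — is available via
  `aggregate_measures(..., ser_volume_requires_enhancing=False)`.  The
  default was chosen because "enhancing voxels having SER ≥ 0.9" implies an
  enhancement gate and the 20% first-post rule is the only enhancement
  definition in play.
- **BPE%** counts enhancing voxels within the FGT mask (background
  parenchymal enhancement denotes fibroglandular enhancement), expressed
  as a percentage of whole-breast volume, so `0 ≤ BPE% ≤ 100` always holds.

WISV (wash-in slope variance) is stored unscaled; the conventional ×100
presentation is a property (`wisv_x100`) applied only at reporting time.

## Digital phantom

The phantom exists to make every downstream number exactly checkable, not
to look like a breast.  Geometry is an ellipsoidal breast containing a
concentric ellipsoidal FGT region.  Default acquisition times are 0, 1.5,
4.5, 7.5 min: a first post-contrast sequence centred around 90 s after
injection, then spacing by the ~3-minute duration of each acquisition;
times are configurable because protocols vary.

Each FGT voxel gets a kinetic class, a peak-enhancement draw `PE ~ U(pe_range)`
and an SER target `r ~ U(ser_range)`:

- washout/plateau: `E1 = PE`, `E3 = PE/r`, `E2` linear in time between
  them — so the noiseless SER equals `r` *exactly*, and the class bands
  (plateau `r ∈ [0.95, 1.25]`, washout `r ∈ [1.4, 2.4]` by default) map
  one-to-one onto the SER classification;
- persistent: monotone rise with `E3 = 1.1·PE` and `E1 = r·E3`
  (`r ∈ [0.15, 0.6]`), so SER < 0.9 analytically;
- non-enhancing: identically zero enhancement (fails the 20% rule and has
  a degenerate SER denominator).

Class counts are apportioned by largest remainder, so stated fractions are
hit exactly; validation rejects any SER range that leaves its class band.
Noise is additive Gaussian truncated at zero signal — sufficient for
recovery and monotonicity tests; Rician noise, coil inhomogeneity, motion
and anatomy are deliberately out of scope.  Consequently the ground truth
(`PhantomTruth.true_measures`) is computed directly from the generative
curve parameters with plain sums, independent of the image round-trip, and
noiseless phantoms must be recovered to ~1e-9 relative (observed ~1e-15).

## Cohort generation

Two modes share a covariate model (truncated-normal ages centred at 47,
MRI years 2009–2011, logistic age-to-menopause link centred at 50,
Bernoulli family history 0.56, ordinal density with probabilities
0.03/0.26/0.64/0.07, all in line with the cohort composition the measures
are calibrated to).

**Measures-only** draws (WISV, SER volume, BPE%) from log-normal marginals
— all three are positive and right-skewed — moment-matched to the control
group of the motivating cohort (WISV×100 1.75 ± 1.26, SERV 80.4 ± 42.9 cm³,
BPE% 39.8 ± 11.4).  Cases multiply the mean by the effect sizes
(defaults 1.66, 1.48, 1.12 — the observed case/control mean ratios) with
log-SDs scaled to match the reported case dispersions.  Dependence is
injected through a Gaussian copula whose latent correlations (0.17 between
the kinetic measures, 0.56/0.48 with BPE%) mirror the reported
rank-correlation pattern.  The reported distributions constrain but do not
determine the distributional form; log-normality is a modelling choice.
`CohortSpec.null()` sets every shift and dispersion scale to 1 so case and
control measures are identical in law, which is what the type-I-error
checks require.

**Full-image** builds one phantom per subject and routes it through the
quantification module.  Per-subject heterogeneity comes from a Dirichlet
draw of the class fractions (concentration 25), a ±25% jitter on the upper
peak-enhancement bound, and a ±10% jitter on FGT size.  Cases receive
larger plateau/washout fractions (0.20/0.17 vs 0.15/0.10) and a higher
peak-enhancement bound (1.05 vs 0.9).  These injected effects were fixed by
an a-priori power analysis at the design sample size of 40 pairs: they give
standardized within-pair effects of roughly 1.2 (WISV) and 0.9 (SERV),
large enough for ≥90% joint power in univariate conditional-logistic fits
yet small enough that complete separation (every pair difference
one-signed) remains improbable.  Default grids are 12×12×8 voxels at
1.5×1.5×2 mm — roughly 150 FGT voxels per subject — chosen so that a
40-pair cohort simulates in well under a second; absolute volumes are
therefore of order 0.1 cm³ rather than 100 cm³, and the pipeline switches
the SERV odds-ratio unit to 0.1 cm³ in this mode.

Matching is 1:1 by age (±3 years) and MRI year (±1).  The primary
algorithm is greedy nearest-age matching over cases sorted by age
(deterministic).  Greedy matching can strand a case even when a feasible
assignment exists, so a rescue pass solves the optimal assignment
(minimum total age difference, ineligible pairs excluded) before
infeasibility is declared; the error then lists every unmatched case.

## Statistical models

- **Conditional logistic regression.**  For 1:1 matching the conditional
  likelihood is `∏_i σ(βᵀd_i)` with `d_i` the case-minus-control
  difference: logistic regression without intercept on pair differences
  with outcome ≡ 1.  The solver is Newton–Raphson from β = 0 with analytic
  gradient and Hessian, step-halving on likelihood decrease, and
  convergence when the largest score component is below 1e-8 (max 50
  iterations).  Wald SEs come from the inverse observed information; CIs
  are Wald on the log-odds scale (symmetric in log-OR, the standard output
  convention for this model).  Odds ratios are reported per declared unit,
  `OR = exp(β·unit)`, defaulting to 0.01 (WISV), 100 cm³ (SERV) and 20
  percentage points (BPE%).  A covariate with all-zero differences raises
  a non-identifiability error.  Complete separation is detected through
  the fitted pair probabilities: if every discordant pair's conditional
  probability exceeds 1 − 1e-4 at the final iterate the MLE is diverging
  and the fit is flagged non-converged with a diagnostic; a raw
  coefficient bound is *not* used because it is covariate-scale dependent.
- **Unconditional logistic regression** (statsmodels `Logit`, Newton with
  an L-BFGS fallback) supplies fitted probabilities for ROC analysis and
  log-likelihoods for the LRT.
- **AUC** is the tie-corrected Mann–Whitney statistic (ties count ½); its
  95% CI uses DeLong's structural-component variance, clipped to [0, 1].
  Both are authored here and cross-checked in tests against exhaustive
  pair counting and the R `pROC` reference.
- **LOOCV AUC** refits the logistic model n times and pools all held-out
  probabilities into a single ROC (one number per model, matching the
  standard presentation), rather than averaging per-fold AUCs.  Folds
  with separation are flagged and counted.
- **LRT** between nested logistic models: `2(ℓ_full − ℓ_nested)` against
  χ² with df equal to the parameter-count difference.  Model comparisons
  phrased as "differences in AUC" are implemented as LRTs between the
  nested models that generate the scores, not as paired AUC-difference
  tests; the default comparisons are all nested.
- **Spearman correlation** uses average ranks for ties and the
  t-approximation for the two-sided p-value (scipy).
- No multiple-testing correction is applied anywhere, by design.
- All tests are two-sided with α = 0.05.

## Pipeline and reproducibility

`run_pipeline` executes simulate → (quantify) → analyze → report.  The
results JSON is serialized with sorted keys; the markdown report is
rendered from that JSON alone (no recomputation) in sorted order, so a
fixed configuration and seed reproduce both files byte-identically.  Every
stage derives its randomness from the single configured seed; provenance
(seed, mode, config hash) is embedded in the results.  Models that fail
identifiability on a given cohort are reported with an error entry instead
of aborting the run.

## Test and simulation sizes

The suite favours exact oracles at small sizes: per-voxel loop equivalence
on 8×8×4 grids, dense grid search of the conditional likelihood, exhaustive
AUC pair counting up to n = 50.  Calibration checks use 200 replicates of
500 pairs (parameter recovery and CI coverage), 1000 replicates at n = 100
(type-I error of the Wald and likelihood-ratio tests), and 20 replicates of
40-pair full-image cohorts (end-to-end power).  These sizes keep the whole
suite around a minute on one CPU while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

- The phantom has no anatomy, motion, coil profile or Rician noise; the
  exactness results validate the *software*, not robustness to real
  acquisition artifacts.
- Measures-only marginals are log-normal by assumption; only the first two
  moments and the rank-correlation pattern are calibrated.
- Only 1:1 matching is supported (no 1:m or variable-ratio designs, no
  exact conditional inference).
- Inter-sequence registration, DICOM ingestion and breast/FGT segmentation
  are out of scope; inputs are co-registered NIfTI volumes and masks.
- The Wald CIs and DeLong AUC CIs are conventional choices; other CI
  procedures would give slightly different intervals.
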