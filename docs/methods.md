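# Methods

This note documents the models and procedures implemented in
`stopthink`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Behavioural scoring

**Stop-signal task.**  SSRT uses the experiment-wide integration method
with replacement of go omissions: all go trials (correct and incorrect)
are pooled; omitted go RTs are replaced by the maximum observed go RT;
the rank is `n = round(N_go · p(respond|signal))` (half rounded away
from zero, clamped to `[1, N_go]`); SSRT is the *n*-th fastest go RT
minus the mean SSD over **all** stop trials.  Descriptives include
go-omission and choice-error probabilities and the independent-race
check (mean failed-stop RT < mean correct go RT).  The slowing check is
the mean of per-subject OLS slopes of correct go RT on run index with a
two-sided one-sample t-test; a pooled mixed-model coefficient would
differ slightly on unbalanced data, and we document the per-subject mean
as our definition.  A trigger-failure-corrected SSRT (ex-Gaussian
mixture) is a known extension and is not implemented; the generator's
`p_trigger_failure` parameter exists as a hook and defaults to 0.

**Think/No-Think task.**  Recall is conditionalized on the criterion
test (unlearned pairs can be neither suppressed nor retrieved), computed
separately for same-probe and independent-probe tests, then averaged;
`SIF = Baseline − No-Think`.  Filler pairs are never scored.

## Robust statistics

Correlations go through a method-selection tree: bagplot (halfspace-
depth bag inflated ×3 about the depth median) flags bivariate outliers
→ MCD-skipped Spearman; otherwise boxplot outliers (1.5 IQR fences) or
a failed Shapiro–Wilk test (α = 0.05) on either marginal → 20%
percentile-bend correlation; otherwise Pearson.  Choices made where the
convention is not fixed:

* the bagplot fence factor is the classical 3; the bag is the convex
  hull of the smallest depth level containing at least half the points
  (no interpolation between depth regions).  At n ≈ 24 this rule is
  deliberately sensitive — clean elongated samples are flagged
  occasionally — which matches how bivariate screening is used in
  practice (flag, inspect, then use the robust estimator);
* collinear (rank-deficient) input falls back to the boxplot rule on
  the principal axis, with a warning;
* MCD uses support fraction `h = ⌈(n+3)/2⌉/n` and a fixed internal seed
  so the flagged set is reproducible; points with robust distance above
  the χ²(2) 0.975 quantile are skipped;
* the percentile-bend p-value uses the t-approximation with n − 2 df.

**JZS one-sample Bayes factor.**  `B01 = t-density(null) / ∫ nct(t; δ√n)
π(δ) dδ` with `π = Cauchy(0, scale)`, folded to δ > 0 for one-tailed
tests.  The integral is adaptive quadrature (relative tolerance 1e-8);
posterior median and central 95% interval of δ come from a 40001-point
grid whose support scales with `|t|/√n` and the prior scale.  At the
reference inputs (t = −0.37 and −1.16, n = 24, scale 0.707) this
reproduces B01 = 6.02 and 9.16 with posterior medians 0.107 and 0.071.

## Behavioural PLS

X (subjects × voxels) and Y (subjects × behaviours) are column
mean-centred; each X row is scaled to unit sum of squares so overall
activation differences between subjects do not drive the solution.
`R = corr(X, Y)` columnwise; `R = U S Vᵀ`; saliences are U, behaviour
weights V, covariance share `s_k²/Σs²`, brain scores `X_raw · U`.

* Permutation test: rows of Y permuted; per-LV p compares singular
  values at the same sorted position (no Procrustes rotation — whether
  the original analysis rotated is unknown; unrotated comparison is the
  conservative, simpler choice and calibrates correctly under the null,
  verified by a KS test over 200 replicate null datasets).
* The add-one estimator `(1 + #exceed)/(1 + n_perm)` avoids zero p.
* Bootstrap: subjects resampled with replacement; resampled saliences
  sign-aligned to the original by dot product; ratio = original / SE.
  The ratio is an *asymptotic* z-score: under pure noise at n = 24 the
  |1.96| exceedance rate is inflated (~10–15%) because bootstrap
  resamples share subjects with the original fit; at n = 100 it is
  within a few points of the nominal 5%.  Interpret salience maps at
  small n qualitatively, or raise the threshold.

## Time-course analysis

The modulation index is the mean of the grid samples at 2, 4 and 6 s
post-stimulus minus the 0 s sample (TR = 2 s; no interpolation between
samples).  The 2×2 within-subject ANOVA (target region × stopping
modality) is computed by pingouin's repeated-measures ANOVA; the
implementation asserts the 2×2 identity `F_interaction = t²` on the
difference-of-differences as an internal cross-check on every call.
One-sample cell tests are one-tailed in the hypothesised
(downregulation) direction and Bonferroni-corrected over the four
cells.  A fully degenerate layout (zero interaction variance) reports
F = 0, p = 1 rather than 0/0.

## MVPA

Patterns are run × condition × voxel beta estimates (8 × 4 × V), with a
run mask for excluded runs.  Pre-whitening multiplies patterns by the
inverse square root of a shrinkage-regularised residual covariance
(`(1−γ)Σ + γ·(trΣ/V)·I`, default γ = 0.4); in synthetic mode the
generator's noise is white, so identity whitening is equivalent.

* **Cross-task**: per direction (train Stop/Go → test No-Think/Think
  and the reverse), each voxel is z-scored across the 16 training
  estimates and, separately, the 16 test estimates, removing each
  voxel's task-mean so only the relative Inhibit/Respond contribution
  remains.  Accuracy averages both directions and up to `n_subsets`
  unique random subsets of 90% of the voxels (subset count capped at
  C(V, ⌈0.9V⌉); duplicates are redrawn).
* **Between-task**: No-Think vs Stop with leave-one-run-out CV; each
  pattern is z-scored across voxels, which removes condition-specific
  univariate level differences (verified as an invariance test).
* **Per-run cross-task**: the Stop/Go-trained classifier is applied to
  each run's No-Think/Think pair; missing runs yield missing entries,
  and group summaries use available subjects per run.
* LDA uses a pooled within-class covariance with Ledoit–Wolf shrinkage
  (voxels ≥ the 16 patterns, so an unregularised covariance would be
  singular); `w = Σ⁻¹(μ₁ − μ₀)` with the midpoint threshold.
* The linear-trend statistic is the squared one-sample t on per-subject
  linear contrasts with weights proportional to each subject's centred
  available-run indices (df = (1, n−1)); with missing runs there is no
  single canonical pooled error term, and this per-subject contrast is
  the definition used throughout.  Slope–behaviour associations go
  through the robust correlation tree.
* Group inference: one-tailed t vs 50%, Bonferroni over ROIs; ROIs that
  do not beat chance additionally get a one-tailed JZS Bayes factor for
  the null (scale 0.707).

## Connectivity model space and BMS

Four nodes: rDLPFC and rVLPFC (sources), right hippocampus and left M1
(targets).  The intrinsic skeleton is bidirectional between all pairs
except hippocampus–M1, with task driving inputs into both prefrontal
nodes.  The space is a null model plus 72 modulatory models: 3 direction
families × 2 target families × a 12-model block = 73.  The 12-model
block is: independent pathways × 4 interaction variants, parallel
("both") × 4 interaction variants, and 2 interaction variants (none /
bidirectional) for each single-source pathway.  The full cross of four
pathways × four interactions × two targets would give 32 per direction,
not the 24 the space requires; restricting the single-source families to
the none/bidirectional interaction variants is this package's
resolution, isolated in one table (`_BLOCK`) so any alternative
composition can be injected.  All family-count invariants (73 total, 24
per direction, 8 parallel-bidirectional, ids 12/24 as the preferred /
non-preferred pair) are asserted in tests.

**RFX-BMS** follows the variational Dirichlet scheme: iterate subject
responsibilities `g_nk ∝ exp(ln E_nk + ψ(α_k) − ψ(Σα))` and counts
`α = α₀ + Σ_n g_n` to convergence (max |Δα| < 1e-6, capped at 10⁴
iterations, error on non-convergence).  Exceedance probabilities are
Monte-Carlo argmax frequencies over Dirichlet(α) draws (default 10⁶,
drawn in chunks; the MC standard error is reported).  Model-level
comparisons use a flat per-model prior α₀ = 1.  Family comparisons
default to a per-model prior of 1/|family| so every family has equal
prior mass regardless of size — without this, large families win on
prior mass alone at small n — and sum Dirichlet mass within families
before the argmax.  The mean-field posterior is exact enough for
inference but approximate: against exact enumeration on tiny fixtures
it agrees to TV < 0.01 in the weak-evidence regime and always agrees on
the winner; under strong evidence its expected frequencies are mildly
overconfident (an inherent property of the factorisation, not a bug).

**Evidence proxy.**  Full variational model inversion is out of scope.
For synthetic demonstrations, log evidence is approximated by −BIC/2
from per-node least squares on the discrete-time bilinear system
`x(t+1) = A x + Σ_j u_j B_j x + C u`, restricted to each model's
intrinsic and modulatory edges, after HRF deconvolution by regularised
Wiener filtering (regularisation λ = 0.001; larger values over-smooth
and erase the bilinear terms' discriminability, smaller values amplify
observation noise).  Singular designs fall back to a ridge solve.  The
proxy is labelled as such in every output; its only claims are the
synthetic recovery results the tests compute.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed
once:

* **Population**: 24 subjects; true mean SSRT ~ N(348, 51²) ms and true
  SIF ~ N(0.05, 0.09²), both loading on one standard-normal latent
  ability so that corr(SSRT, SIF) = −0.5.
* **Stop-signal trials**: 384 trials, 32% stop; ex-Gaussian go finish
  times (μ = 480, σ = 50, τ = 120 ms, matching a ~600 ms mean go RT);
  trial-wise SSRT truncated normal (>0) around the subject's true value
  with SD 30 ms; SSD staircase ±50 ms from 300 ms, floored at 0; go
  omissions at 0.002 and choice errors at 0.04.  These are the standard
  race-model generative choices; the staircase holds p(respond|stop)
  at 0.50 ± 0.02 and the integration estimator recovers a planted
  280 ms SSRT with < 10 ms mean bias (the estimator's known slight
  underestimation under staircased SSDs).
* **Recall**: 20 pairs per condition plus 6 fillers; learning rate 0.71
  (the criterion test leaves ~29% unlearned); baseline recall 0.77;
  No-Think recall = baseline − true SIF; same-probe and independent-
  probe outcomes drawn independently; fixed per-run trial counts (no
  jitter), since per-run counts do not enter any scored quantity.
* **ROI patterns**: per subject, a shared unit inhibition direction `u`
  common to both tasks (this is what makes cross-task transfer
  possible) expressed on Stop and No-Think, and a task direction `v`
  that differs between tasks; unit-variance white noise.  The No-Think
  expression of `u` decays geometrically per run (conflict-reduction
  benefit), only for thought suppression.  Default amplitudes
  (g = 1.6/1.8 for rDLPFC/rVLPFC at 60/80 voxels) were calibrated once
  so that group-mean cross-task accuracy falls in the mid-to-high 50s —
  the empirically realistic regime — and g = 0 for the target ROIs.
  Per-subject decline can be tied to true SIF
  (`decline_i = clip(base − coupling·(SIF_i − mean SIF), 0, 1)`),
  which plants the steeper-decline-with-more-forgetting association.
* **Time-courses**: canonical double-gamma HRF (zero at onset) scaled
  by signed per-(ROI, condition) amplitudes, subject random effects
  (SD 0.3) and white noise (SD 0.5) on the 0–12 s grid at TR = 2 s.
* **Network series**: 512 scans; A with self-decay 0.4 and intrinsic
  coupling 0.1 (stability checked: spectral radius < 1 or error);
  modulatory strength −0.35 (inhibitory); unit driving inputs into the
  prefrontal nodes during 30 s task blocks; unit state noise; BOLD =
  HRF-convolved activity + 0.1 observation noise.

What the generator does **not** emulate: spatial voxel correlations,
temporal autocorrelation and scanner drift (noise is white; a
low-frequency extension is possible but not needed for the planted
effects), trial-level pattern variability within runs (patterns are
run-level betas by construction), trigger failures, and any
whole-brain image structure.  Passing tests therefore show that the
estimators are correct and calibrated under these idealised conditions,
not that they are robust to realistic fMRI noise.

## Problem sizes in the shipped configuration

The default pipeline and test configuration use 500 permutations /
bootstrap resamples for PLS (the method's reference counts are 5000),
50 voxel subsets for MVPA (reference: up to 2000), and 10⁵ Dirichlet
samples in pipeline-level BMS (10⁶ in the library default).  These
sizes keep a full synthetic study under ten seconds while leaving every
calibration result unchanged; all counts are config fields.

## Known limitations

* The bagplot rule at n ≈ 24 flags some clean correlated samples;
  the decision tree then falls through to the (valid, slightly less
  efficient) skipped Spearman estimator.
* Bootstrap salience ratios are anti-conservative at small n (above).
* The BIC evidence proxy ignores parameter priors and hemodynamic
  parameter uncertainty; it is for synthetic recovery demonstrations
  only.
* The RM-ANOVA module covers the 2×2 within-subject layout the
  analysis needs, not general factorial designs.
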