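# stopthink

A tested, reusable Python implementation of the desk-scale analysis
chain used to study **domain-general inhibitory control** over actions
and thoughts: stop-signal and Think/No-Think behavioural scoring, robust
brain-behaviour statistics, behavioural partial least squares (PLS),
ROI time-course modulation analysis, cross-task multivoxel pattern
analysis (MVPA), and random-effects Bayesian model selection (BMS) over
a four-node effective-connectivity model space.  A synthetic-data module
generates every input the pipeline consumes, with planted ground truth,
so the whole chain is testable without any imaging data.

It is written for cognitive-neuroscience researchers who want the
individual estimators as a library (each stage is an importable module
with plain pandas/numpy containers) and for anyone who wants to run the
whole synthetic study from a shell (`stopthink all`).

## The statistics at the core

* **SSRT (integration method).**  Under the independent race model, the
  stop-signal reaction time is estimated as
  `SSRT = Q_go(p) − mean(SSD)`, where `Q_go(p)` is the *n*-th fastest go
  RT with `n = round(N_go · p(respond | signal))`, go omissions replaced
  by the maximum observed go RT, and the mean taken over all stop-trial
  delays.
* **SIF (suppression-induced forgetting).**  `SIF = recall(Baseline) −
  recall(No-Think)`, with recall conditionalized on criterion-test
  learning and averaged over same-probe and independent-probe tests.
* **Robust correlation decision tree.**  Pearson if outlier-free and
  normal; 20% percentile-bend if univariate outliers or non-normality;
  MCD-based skipped Spearman if bivariate (bagplot) outliers.
* **Behavioural PLS.**  SVD of the voxel-by-behaviour correlation matrix
  `R = corr(X, Y)`; LV significance by permutation of `Y` rows,
  voxel reliability by bootstrap salience ratios (`salience / SE`,
  thresholded at |1.96|).
* **Cross-task MVPA.**  Shrinkage LDA trained to separate Inhibit from
  Respond in one task and tested on the other (and the reverse),
  averaged over random 90% voxel subsets; between-task LDA separates
  No-Think from Stop under leave-one-run-out CV after pattern-wise
  z-scoring.
* **JZS Bayes factor.**  `B01` for the one-sample t-test with a
  Cauchy(0, 0.707) prior on the standardized effect, one-tailed where
  the hypothesis is directional.
* **RFX-BMS.**  Variational Dirichlet estimation of population model
  frequencies from per-subject log evidences; exceedance probabilities
  by Monte-Carlo Dirichlet sampling, with family-level comparison by
  summing Dirichlet mass within families.

## Worked example

```sh
python examples/05_bms_family_recovery.py
```

simulates 12 subjects' four-node BOLD series from the "parallel,
bidirectional-interaction, preferred-targets" connectivity model, scores
all 73 models with the least-squares + BIC evidence proxy, and runs the
staged family comparisons.  It prints:

```
model space: 73 models; generating from model 12 (both, bidirectional interaction, preferred targets)
  direction    exceedance: null = 0.000, bidirectional = 1.000, top_down = 0.000, bottom_up = 0.000
  pathway      exceedance: independent = 0.000, dlpfc_only = 0.000, vlpfc_only = 0.000, both = 1.000
  interaction  exceedance: none = 0.001, v_to_d = 0.020, d_to_v = 0.001, bidirectional = 0.978
  targets      exceedance: preferred = 1.000, non_preferred = 0.000
  all 73 models: winner id 12 (EP = 0.930)
```

Each line is one staged family comparison: the exceedance probability is
the posterior probability that a family of connectivity models is more
frequent in the population than the alternatives.  The planted family
wins every stage, and the generating model wins the side-by-side
comparison of all 73 models.

The other examples cover behavioural scoring (`01`), behavioural PLS
(`02`), ROI decoding with Bayes factors for null ROIs (`03`), the
region-by-modality time-course interaction (`04`), and the full pipeline
in one call (`06`).  The same stages are available from the shell:

```sh
stopthink all --seed 5 --out my-study     # full synthetic study + report
stopthink bms --evidence log_evidence.csv # staged BMS on any evidence matrix
```

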