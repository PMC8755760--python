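"""Run-wise LDA pattern classification within ROIs.

Two decoding schemes identify domain-general and domain-specific
components of inhibitory control:

* cross-task — train a linear discriminant to separate Inhibit from
  Respond in one task (Stop vs Go), test it on the other (No-Think vs
  Think), and vice versa; each voxel is z-scored across the 16 training
  estimates (and separately across the 16 test estimates) so only the
  relative Inhibit/Respond contribution within each voxel remains;
* between-task — separate No-Think from Stop patterns under
  leave-one-run-out cross-validation; each pattern is z-scored across
  voxels, removing univariate level differences between the tasks.

Accuracies are averaged over random subsets of 90% of the ROI's voxels
(up to a cap of unique subsets) to stabilise the estimate.  LDA uses a
shrinkage (Ledoit-Wolf) covariance because voxels typically outnumber
the 16 run-wise patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import linalg, stats
from sklearn.covariance import ledoit_wolf

from ._rng import substream
from .behavior import GroupTestResult
from .robust import jzs_bf_one_sample, select_and_correlate
from .synth.patterns import CONDITIONS, PatternSet

__all__ = [
    "DecodingResult",
    "prewhiten",
    "cross_task_accuracy",
    "between_task_accuracy",
    "per_run_cross_accuracy",
    "linear_trend_and_slope_correlations",
    "group_decoding_inference",
]

_COND_IDX = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass
class DecodingResult:
    subject: str
    roi: str
    scheme: str                      # cross_task | between_task | per_run_cross
    accuracy: float | np.ndarray     # scalar, or per-run array with NaN for masked runs
    n_subsets_used: int = 1


# ---------------------------------------------------------------------------
# pre-whitening


def prewhiten(ps: PatternSet, residual_cov: np.ndarray, shrinkage: float = 0.4) -> PatternSet:
    """Noise-normalise patterns by the inverse square root of a
    shrinkage-regularised residual covariance.

    ``cov_shrunk = (1 - shrinkage) * cov + shrinkage * mean_var * I``.
    Raises if the shrunk covariance is not positive definite.
    """
    cov = np.asarray(residual_cov, dtype=float)
    v = ps.n_voxels
    if cov.shape != (v, v):
        raise ValueError("covariance shape does not match voxel count")
    target = np.eye(v) * np.trace(cov) / v
    shrunk = (1 - shrinkage) * cov + shrinkage * target
    vals, vecs = linalg.eigh(shrunk)
    if np.min(vals) <= 0:
        raise ValueError("covariance not positive definite after shrinkage")
    inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
    return PatternSet(
        subject=ps.subject, roi=ps.roi,
        betas=ps.betas @ inv_sqrt,
        run_mask=ps.run_mask.copy(),
        conditions=ps.conditions,
        decline_rate=ps.decline_rate,
        residual_sd=ps.residual_sd,
    )


# ---------------------------------------------------------------------------
# LDA primitives


def _fit_lda(X: np.ndarray, y: np.ndarray, shrinkage="lw"):
    """Two-class LDA: returns (weights, threshold); predict 1 iff x.w > c."""
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    resid = np.vstack([X0 - mu0, X1 - mu1])
    p = X.shape[1]
    if shrinkage == "lw":
        cov = ledoit_wolf(resid, assume_centered=True)[0]
    else:
        gamma = float(shrinkage)
        emp = resid.T @ resid / resid.shape[0]
        cov = (1 - gamma) * emp + gamma * (np.trace(emp) / p) * np.eye(p)
    try:
        w = np.linalg.solve(cov, mu1 - mu0)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(cov) @ (mu1 - mu0)
    c = float(w @ (mu0 + mu1) / 2)
    return w, c


def _predict_lda(w, c, X):
    return (X @ w > c).astype(int)


def _zscore_per_voxel(X: np.ndarray) -> np.ndarray:
    """z-score each voxel (column) across the pattern estimates (rows)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _zscore_per_pattern(X: np.ndarray) -> np.ndarray:
    """z-score each pattern (row) across voxels."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _draw_subsets(n_voxels: int, frac: float, n_subsets: int, rng) -> list:
    k = int(np.ceil(frac * n_voxels))
    k = min(max(k, 2), n_voxels)
    total = comb(n_voxels, k)
    n_use = min(n_subsets, total)
    if n_use == 1 and k == n_voxels:
        return [np.arange(n_voxels)]
    seen = set()
    out = []
    while len(out) < n_use:
        cand = tuple(sorted(rng.choice(n_voxels, size=k, replace=False).tolist()))
        if cand in seen:
            continue
        seen.add(cand)
        out.append(np.array(cand))
    return out


def _task_patterns(ps: PatternSet, conds):
    """Stack run x condition patterns for the given conditions over
    available runs; labels are 1 for the first (inhibit) condition."""
    runs = ps.available_runs()
    rows, labels, run_of = [], [], []
    for r in runs:
        for li, cond in enumerate(conds):
            rows.append(ps.betas[r, _COND_IDX[cond]])
            labels.append(1 - li)  # first condition = inhibit = 1
            run_of.append(r)
    return np.array(rows), np.array(labels), np.array(run_of)


# ---------------------------------------------------------------------------
# decoding schemes


def cross_task_accuracy(
    ps: PatternSet,
    n_subsets: int = 2000,
    subset_frac: float = 0.9,
    seed: int = 0,
    shrinkage="lw",
) -> DecodingResult:
    """Cross-task (domain-general) decoding accuracy for one subject x ROI.

    Both train directions (Stop/Go -> No-Think/Think and reverse) are
    averaged, along with the random voxel subsets.
    """
    if ps.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    ss, y_ss, _ = _task_patterns(ps, ("Stop", "Go"))
    tnt, y_tnt, _ = _task_patterns(ps, ("No-Think", "Think"))
    ss_z, tnt_z = _zscore_per_voxel(ss), _zscore_per_voxel(tnt)
    rng = substream(seed, "cross", ps.roi, ps.subject)
    subsets = _draw_subsets(ps.n_voxels, subset_frac, n_subsets, rng)
    accs = []
    for sub in subsets:
        for train, y_tr, test, y_te in ((ss_z, y_ss, tnt_z, y_tnt),
                                        (tnt_z, y_tnt, ss_z, y_ss)):
            w, c = _fit_lda(train[:, sub], y_tr, shrinkage)
            accs.append(np.mean(_predict_lda(w, c, test[:, sub]) == y_te))
    return DecodingResult(ps.subject, ps.roi, "cross_task",
                          float(np.mean(accs)), len(subsets))


def between_task_accuracy(
    ps: PatternSet,
    n_subsets: int = 2000,
    subset_frac: float = 0.9,
    seed: int = 0,
    shrinkage="lw",
) -> DecodingResult:
    """Between-task (domain-specific) No-Think-vs-Stop decoding with
    leave-one-run-out cross-validation."""
    if ps.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    runs = ps.available_runs()
    if runs.size < 4:
        raise ValueError("need at least 4 available runs")
    X, y, run_of = _task_patterns(ps, ("No-Think", "Stop"))
    Xz = _zscore_per_pattern(X)
    rng = substream(seed, "between", ps.roi, ps.subject)
    subsets = _draw_subsets(ps.n_voxels, subset_frac, n_subsets, rng)
    accs = []
    for sub in subsets:
        for r in runs:
            train, test = run_of != r, run_of == r
            w, c = _fit_lda(Xz[train][:, sub], y[train], shrinkage)
            accs.append(np.mean(_predict_lda(w, c, Xz[test][:, sub]) == y[test]))
    return DecodingResult(ps.subject, ps.roi, "between_task",
                          float(np.mean(accs)), len(subsets))


def per_run_cross_accuracy(
    ps: PatternSet,
    n_subsets: int = 1,
    subset_frac: float = 1.0,
    seed: int = 0,
    shrinkage="lw",
) -> DecodingResult:
    """Per-run accuracy of the action-stopping classifier on thought
    suppression: train on all Stop/Go patterns, test each run's
    No-Think/Think pair (No-Think counted correct when classified as the
    inhibit class).  Masked runs yield NaN entries."""
    ss, y_ss, _ = _task_patterns(ps, ("Stop", "Go"))
    tnt, y_tnt, run_of = _task_patterns(ps, ("No-Think", "Think"))
    ss_z, tnt_z = _zscore_per_voxel(ss), _zscore_per_voxel(tnt)
    rng = substream(seed, "per-run", ps.roi, ps.subject)
    subsets = _draw_subsets(ps.n_voxels, subset_frac, n_subsets, rng)
    per_run = np.full(ps.n_runs, np.nan)
    for r in ps.available_runs():
        sel = run_of == r
        accs = []
        for sub in subsets:
            w, c = _fit_lda(ss_z[:, sub], y_ss, shrinkage)
            accs.append(np.mean(_predict_lda(w, c, tnt_z[sel][:, sub]) == y_tnt[sel]))
        per_run[r] = float(np.mean(accs))
    return DecodingResult(ps.subject, ps.roi, "per_run_cross", per_run, len(subsets))


# ---------------------------------------------------------------------------
# group-level analyses


@dataclass
class TrendResult:
    f: float
    df: tuple
    p: float
    slopes: dict                # subject -> accuracy slope per run
    correlations: dict          # behaviour name -> CorrelationResult
    excluded: list


def linear_trend_and_slope_correlations(per_run_results, behaviours=None):
    """Group linear-trend test on per-run accuracies plus slope-behaviour
    correlations.

    ``per_run_results``: list of per_run_cross DecodingResults (one per
    subject).  ``behaviours``: optional ``{name: {subject: value}}``.
    Subjects with fewer than 3 available runs are excluded with a warning.
    The trend statistic is a one-sample t (squared, reported as F) on the
    per-subject linear contrast with weights proportional to the centred
    run indices of that subject's available runs.
    """
    slopes, contrast_vals, excluded = {}, [], []
    for res in per_run_results:
        acc = np.asarray(res.accuracy, dtype=float)
        runs = np.nonzero(np.isfinite(acc))[0]
        if runs.size < 3:
            warnings.warn(f"subject {res.subject}: fewer than 3 runs, excluded",
                          stacklevel=2)
            excluded.append(res.subject)
            continue
        x = runs + 1.0
        slopes[res.subject] = float(np.polyfit(x, acc[runs], 1)[0])
        w = x - x.mean()
        contrast_vals.append(float(w @ acc[runs]))
    contrast_vals = np.array(contrast_vals)
    n = contrast_vals.size
    if n < 2:
        raise ValueError("need at least 2 subjects with 3+ runs")
    t = stats.ttest_1samp(contrast_vals, 0.0)
    f = float(t.statistic) ** 2
    correlations = {}
    if behaviours:
        for name, mapping in behaviours.items():
            pairs = [(slopes[s], mapping[s]) for s in slopes if s in mapping]
            sl, bv = map(np.array, zip(*pairs))
            correlations[name] = select_and_correlate(sl, bv)
    return TrendResult(f=f, df=(1, n - 1), p=float(t.pvalue), slopes=slopes,
                       correlations=correlations, excluded=excluded)


@dataclass
class GroupInference:
    roi: str
    mean_accuracy: float
    test: GroupTestResult       # one-tailed vs 0.5, p Bonferroni-adjusted
    b01: float | None           # JZS Bayes factor for non-significant ROIs


def group_decoding_inference(results_by_roi: dict, chance: float = 0.5,
                             alpha: float = 0.05) -> dict:
    """One-tailed one-sample t-tests of per-subject accuracies against
    chance, Bonferroni-corrected over ROIs; non-significant ROIs get a
    one-tailed JZS Bayes factor (Cauchy scale 0.707) for the null."""
    n_rois = len(results_by_roi)
    out = {}
    for roi, results in results_by_roi.items():
        accs = np.array([float(np.asarray(r.accuracy)) if np.isscalar(r.accuracy)
                         or np.asarray(r.accuracy).ndim == 0
                         else float(np.nanmean(r.accuracy)) for r in results])
        n = accs.size
        sd = accs.std(ddof=1)
        t = 0.0 if sd == 0 else float((accs.mean() - chance) / (sd / np.sqrt(n)))
        p = float(stats.t.sf(t, n - 1))
        p_adj = min(1.0, p * n_rois)
        test = GroupTestResult(t=t, df=n - 1, p=p_adj, d=t / np.sqrt(n))
        b01 = None
        if p_adj >= alpha:
            b01 = jzs_bf_one_sample(t, n, scale=0.707, tail="one").b01
        out[roi] = GroupInference(roi=roi, mean_accuracy=float(accs.mean()),
                                  test=test, b01=b01)
    return out
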