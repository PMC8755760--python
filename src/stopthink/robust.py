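"""Robust correlation utilities and default Bayes factors.

Implements the correlation-method decision tree used throughout the
pipeline (Pernet-style): Pearson when the data are outlier-free and
normal, a 20% percentile-bend correlation when there are univariate
outliers or non-normal marginals, and an MCD-based Spearman skipped
correlation when bivariate outliers are present.  Univariate outliers
are flagged by the boxplot rule, bivariate outliers by a halfspace-depth
bagplot fence.

Also provides the JZS (default) one-sample Bayes factor with a
Cauchy(0, scale) prior on the standardized effect, with posterior
summaries computed on a dense grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats
from scipy.spatial import ConvexHull, Delaunay, QhullError
from sklearn.covariance import MinCovDet

__all__ = [
    "CorrelationResult",
    "BayesFactorResult",
    "boxplot_outliers",
    "bagplot_outliers",
    "percentile_bend_corr",
    "skipped_spearman_mcd",
    "select_and_correlate",
    "jzs_bf_one_sample",
]


@dataclass
class CorrelationResult:
    """Correlation estimate with the method chosen by the decision tree."""

    method: str  # 'pearson' | 'percentile_bend_20' | 'skipped_spearman_mcd'
    estimate: float
    p_value: float
    n_used: int
    outliers_removed: list = field(default_factory=list)


@dataclass
class BayesFactorResult:
    """One-sample JZS Bayes factor (null over alternative) and posterior."""

    b01: float
    posterior_median_delta: float
    posterior_ci95: tuple


# ---------------------------------------------------------------------------
# outlier detection


def boxplot_outliers(x) -> np.ndarray:
    """Indices of points outside the Tukey fences Q1 - 1.5 IQR, Q3 + 1.5 IQR."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("boxplot rule needs at least 4 observations")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return np.nonzero((x < lo) | (x > hi))[0]


def _halfspace_depth(point: np.ndarray, pts: np.ndarray) -> int:
    """Exact bivariate Tukey (halfspace) depth of ``point`` w.r.t. ``pts``.

    Brute force over the data-driven critical directions; adequate for the
    sample sizes this pipeline sees (tens to a few hundred points).
    """
    d = pts - point
    r = np.hypot(d[:, 0], d[:, 1])
    coincident = int(np.sum(r < 1e-12))
    mask = r >= 1e-12
    v = d[mask]
    if v.shape[0] == 0:
        return coincident
    ang = np.arctan2(v[:, 1], v[:, 0])
    best = v.shape[0]
    for a in ang:
        # normal of the line through `point` in direction a
        u = np.array([-np.sin(a), np.cos(a)])
        s = v @ u
        best = min(best, int(np.sum(s <= 1e-9)), int(np.sum(s >= -1e-9)))
    return best + coincident


def bagplot_outliers(xy, fence_factor: float = 3.0) -> np.ndarray:
    """Indices of bivariate outliers by the bagplot rule.

    The bag is the convex hull of the 50% deepest points (halfspace depth);
    the fence inflates the bag by ``fence_factor`` about the depth median.
    Points outside the fence are flagged.  Degenerate (collinear) data fall
    back to the boxplot rule on the principal axis, with a warning.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) array")
    n = xy.shape[0]
    if n < 10:
        raise ValueError("bagplot rule needs at least 10 observations")

    centred = xy - xy.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        warnings.warn(
            "degenerate (collinear) data: falling back to the boxplot rule "
            "on the principal axis",
            stacklevel=2,
        )
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        scores = centred @ vt[0]
        return boxplot_outliers(scores)

    depths = np.array([_halfspace_depth(p, xy) for p in xy])
    dmax = depths.max()
    centre = xy[depths == dmax].mean(axis=0)

    # smallest depth level whose upper set holds at least half the points
    for level in range(dmax, 0, -1):
        bag_pts = xy[depths >= level]
        if bag_pts.shape[0] >= n / 2:
            break
    try:
        hull = ConvexHull(bag_pts)
        fence_pts = centre + fence_factor * (bag_pts[hull.vertices] - centre)
        tri = Delaunay(fence_pts)
        inside = tri.find_simplex(xy) >= 0
    except QhullError:  # bag nearly degenerate
        warnings.warn("bag degenerate: falling back to the boxplot rule", stacklevel=2)
        return np.union1d(boxplot_outliers(xy[:, 0]), boxplot_outliers(xy[:, 1]))
    return np.nonzero(~inside)[0]


# ---------------------------------------------------------------------------
# correlation methods


def _pb_location(x: np.ndarray, beta: float) -> float:
    """Percentile-bend measure of location (one-step M-estimate)."""
    n = x.size
    med = np.median(x)
    w = np.sort(np.abs(x - med))
    omega = w[int(np.floor((1 - beta) * n + 0.5)) - 1]
    if omega <= 0:
        return med
    psi = (x - med) / omega
    i1 = int(np.sum(psi < -1))
    i2 = int(np.sum(psi > 1))
    sx = np.where(np.abs(psi) <= 1, x, 0.0)
    return (np.sum(sx) + omega * (i2 - i1)) / (n - i1 - i2)


def _pb_scores(x: np.ndarray, beta: float) -> np.ndarray:
    n = x.size
    med = np.median(x)
    w = np.sort(np.abs(x - med))
    omega = w[int(np.floor((1 - beta) * n + 0.5)) - 1]
    if omega <= 0:
        omega = np.finfo(float).tiny
    a = (x - _pb_location(x, beta)) / omega
    return np.clip(a, -1.0, 1.0)


def percentile_bend_corr(x, y, beta: float = 0.2):
    """Percentile-bend correlation (Wilcox) with bend constant ``beta``.

    Returns ``(r, p)``; the p-value uses the Student-t approximation with
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    a = _pb_scores(x, beta)
    b = _pb_scores(y, beta)
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    r = float(np.sum(a * b) / denom) if denom > 0 else 0.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(tstat), n - 2)
    return r, float(p)


_MCD_SEED = 20211129  # fixed so that flagged points are reproducible


def skipped_spearman_mcd(x, y):
    """Spearman correlation after removing MCD-flagged bivariate outliers.

    Robust distances come from the minimum covariance determinant scatter
    with h = ceil((n + 3) / 2); points above the chi2(2, 0.975) quantile are
    skipped.  Returns ``(r, p, removed_indices)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xy = np.column_stack([x, y])
    h = int(np.ceil((n + 3) / 2))
    mcd = MinCovDet(support_fraction=h / n, random_state=_MCD_SEED).fit(xy)
    d2 = mcd.mahalanobis(xy)
    removed = np.nonzero(d2 > stats.chi2.ppf(0.975, df=2))[0]
    keep = np.setdiff1d(np.arange(n), removed)
    r, p = stats.spearmanr(x[keep], y[keep])
    return float(r), float(p), removed.tolist()


def select_and_correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Correlate two vectors with the method the data call for.

    Decision tree: bivariate outliers (bagplot) -> MCD-skipped Spearman;
    univariate outliers (boxplot) or a non-normal marginal (Shapiro-Wilk
    at ``alpha``) -> 20% percentile-bend; otherwise Pearson.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 10:
        raise ValueError("decision tree unreliable below n = 10")

    bivariate = bagplot_outliers(np.column_stack([x, y]))
    if bivariate.size > 0:
        r, p, removed = skipped_spearman_mcd(x, y)
        return CorrelationResult("skipped_spearman_mcd", r, p, n - len(removed), removed)

    univariate = np.union1d(boxplot_outliers(x), boxplot_outliers(y))
    normal_x = stats.shapiro(x).pvalue > alpha
    normal_y = stats.shapiro(y).pvalue > alpha
    if univariate.size == 0 and normal_x and normal_y:
        r, p = stats.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p), n)
    r, p = percentile_bend_corr(x, y)
    return CorrelationResult("percentile_bend_20", r, p, n)


# ---------------------------------------------------------------------------
# JZS one-sample Bayes factor


def jzs_bf_one_sample(
    t: float, n: int, scale: float = 0.707, tail: str = "one"
) -> BayesFactorResult:
    """JZS one-sample Bayes factor B01 (evidence for the null).

    The alternative places a Cauchy(0, ``scale``) prior on the standardized
    effect delta; ``tail='one'`` restricts the prior to delta > 0 (folded
    Cauchy).  The marginal likelihood is the noncentral-t density averaged
    over the prior, evaluated by adaptive quadrature; posterior median and
    central 95% interval of delta come from a dense grid.
    """
    if not np.isfinite(t):
        raise ValueError("non-finite t statistic")
    if n < 2:
        raise ValueError("need n >= 2")
    if scale <= 0:
        raise ValueError("Cauchy scale must be positive")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")

    df = n - 1
    sqrt_n = np.sqrt(n)

    def lik(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n)

    null = stats.t.pdf(t, df)
    if tail == "two":
        alt, _ = integrate.quad(
            lambda d: lik(d) * stats.cauchy.pdf(d, 0.0, scale),
            -np.inf, np.inf, epsrel=1e-8, limit=400,
        )
        lo, hi = -_grid_halfwidth(t, n, scale), _grid_halfwidth(t, n, scale)
    else:
        alt, _ = integrate.quad(
            lambda d: lik(d) * 2.0 * stats.cauchy.pdf(d, 0.0, scale),
            0.0, np.inf, epsrel=1e-8, limit=400,
        )
        lo, hi = 0.0, _grid_halfwidth(t, n, scale)
    b01 = float(null / alt)

    grid = np.linspace(lo + 1e-9, hi, 40001)
    post = lik(grid) * stats.cauchy.pdf(grid, 0.0, scale)
    cdf = np.cumsum(post)
    cdf /= cdf[-1]
    median = float(np.interp(0.5, cdf, grid))
    ci = (float(np.interp(0.025, cdf, grid)), float(np.interp(0.975, cdf, grid)))
    return BayesFactorResult(b01, median, ci)


def _grid_halfwidth(t: float, n: int, scale: float) -> float:
    return max(4.0, abs(t) / np.sqrt(n) + 8.0 / np.sqrt(n), 6.0 * scale)
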