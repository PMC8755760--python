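"""Behavioural partial least squares with permutation and bootstrap inference.

Relates a subjects x voxels contrast matrix X (e.g. Inhibit > Respond
values within a mask) to a subjects x behaviours matrix Y (e.g. SSRT and
SIF).  Both matrices are column mean-centred; each X row is scaled to
unit sum of squares so between-subject differences are not driven by
overall activation level.  The voxel-by-behaviour correlation matrix R
is decomposed by SVD; each latent variable (LV) carries a singular
value, a voxel salience image, a behaviour weight vector, and a
behaviour-correlation profile.  LV significance comes from permuting the
rows of Y; voxel reliability from bootstrap resampling of subjects
(salience / bootstrap SE, read as a z-score against |1.96|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = ["PLSInput", "PLSResult", "fit_behavioural_pls", "permutation_test",
           "bootstrap_saliences"]


@dataclass
class PLSInput:
    X: np.ndarray  # subjects x voxels
    Y: np.ndarray  # subjects x behaviours
    voxel_ids: list = field(default_factory=list)
    behaviour_names: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have equal row counts")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("missing values in X or Y")
        if not self.voxel_ids:
            self.voxel_ids = [f"vox-{j}" for j in range(self.X.shape[1])]
        if not self.behaviour_names:
            self.behaviour_names = [f"behaviour-{j}" for j in range(self.Y.shape[1])]


@dataclass
class PLSResult:
    singular_values: np.ndarray          # descending
    pct_covariance: np.ndarray           # per-LV share, sums to 1
    saliences: np.ndarray                # voxels x LVs
    behaviour_weights: np.ndarray        # behaviours x LVs
    brain_scores: np.ndarray             # subjects x LVs
    behaviour_corr: np.ndarray           # behaviours x LVs
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None
    behaviour_corr_ci: np.ndarray | None = None  # behaviours x LVs x 2


def _preprocess(X: np.ndarray, Y: np.ndarray):
    Xc = X - X.mean(axis=0)
    rows = np.sqrt(np.sum(Xc**2, axis=1, keepdims=True))
    if np.any(rows == 0):
        bad = int(np.nonzero(rows.ravel() == 0)[0][0])
        raise ValueError(f"subject row {bad} has zero variance after centring")
    Xn = Xc / rows
    Yc = Y - Y.mean(axis=0)
    return Xn, Yc


def _corr_matrix(Xn: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    """Columnwise correlation between X voxels and Y behaviours (voxels x behaviours)."""
    xs = Xn - Xn.mean(axis=0)
    ys = Yc - Yc.mean(axis=0)
    x_sd = xs.std(axis=0)
    y_sd = ys.std(axis=0)
    if np.any(x_sd == 0):
        bad = int(np.nonzero(x_sd == 0)[0][0])
        raise ValueError(f"zero-variance voxel column {bad}")
    if np.any(y_sd == 0):
        bad = int(np.nonzero(y_sd == 0)[0][0])
        raise ValueError(f"zero-variance behaviour column {bad}")
    n = xs.shape[0]
    return (xs / x_sd).T @ (ys / y_sd) / n


def _svd_lvs(R: np.ndarray):
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    return u, s, vt.T


def fit_behavioural_pls(inp: PLSInput) -> PLSResult:
    """Point estimates: saliences, singular values, covariance shares,
    brain scores (raw X dotted with the saliences), behaviour correlations.
    """
    if inp.X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if inp.X.shape[1] < 1 or inp.Y.shape[1] < 1:
        raise ValueError("need at least one voxel and one behaviour")
    Xn, Yc = _preprocess(inp.X, inp.Y)
    R = _corr_matrix(Xn, Yc)
    saliences, s, weights = _svd_lvs(R)
    brain_scores = inp.X @ saliences
    corr = np.zeros((inp.Y.shape[1], s.size))
    for k in range(s.size):
        bs = brain_scores[:, k]
        if bs.std() == 0:
            continue
        for j in range(inp.Y.shape[1]):
            corr[j, k] = np.corrcoef(bs, inp.Y[:, j])[0, 1]
    return PLSResult(
        singular_values=s,
        pct_covariance=s**2 / np.sum(s**2),
        saliences=saliences,
        behaviour_weights=weights,
        brain_scores=brain_scores,
        behaviour_corr=corr,
    )


def permutation_test(inp: PLSInput, n_perm: int = 5000, seed: int = 0) -> np.ndarray:
    """Per-LV permutation p-values from row-permuted Y.

    p_k = (1 + #{perm s_k >= observed s_k}) / (1 + n_perm); singular
    values are compared per sorted position (no Procrustes rotation).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    Xn, Yc = _preprocess(inp.X, inp.Y)
    observed = _svd_lvs(_corr_matrix(Xn, Yc))[1]
    rng = substream(seed, "pls-perm")
    n = inp.Y.shape[0]
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = _svd_lvs(_corr_matrix(Xn, Yc[perm]))[1]
        exceed += s >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def bootstrap_saliences(
    inp: PLSInput, n_boot: int = 5000, seed: int = 0, max_retries: int = 100
):
    """Bootstrap ratios and behaviour-correlation percentile CIs.

    Subjects are resampled with replacement; each resample's saliences
    are sign-aligned to the originals by the dot-product rule.  Ratio =
    original salience / bootstrap SE.  Returns ``(ratios, corr_ci)`` with
    ``corr_ci`` of shape behaviours x LVs x 2.
    """
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    base = fit_behavioural_pls(inp)
    n, n_lv = inp.X.shape[0], base.singular_values.size
    rng = substream(seed, "pls-boot")
    sal_draws = np.empty((n_boot, inp.X.shape[1], n_lv))
    corr_draws = np.empty((n_boot, inp.Y.shape[1], n_lv))
    for b in range(n_boot):
        for attempt in range(max_retries):
            take = rng.integers(0, n, size=n)
            try:
                Xn, Yc = _preprocess(inp.X[take], inp.Y[take])
                R = _corr_matrix(Xn, Yc)
            except ValueError:
                continue
            break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        sal, s, _ = _svd_lvs(R)
        signs = np.sign(np.sum(sal * base.saliences, axis=0))
        signs[signs == 0] = 1.0
        sal = sal * signs
        sal_draws[b] = sal
        scores = inp.X[take] @ sal
        for k in range(n_lv):
            sd = scores[:, k].std()
            for j in range(inp.Y.shape[1]):
                if sd == 0 or inp.Y[take, j].std() == 0:
                    corr_draws[b, j, k] = 0.0
                else:
                    corr_draws[b, j, k] = np.corrcoef(scores[:, k], inp.Y[take, j])[0, 1]
    se = sal_draws.std(axis=0, ddof=1)
    se[se == 0] = np.inf
    ratios = base.saliences / se
    ci = np.stack([np.percentile(corr_draws, 2.5, axis=0),
                   np.percentile(corr_draws, 97.5, axis=0)], axis=-1)
    return ratios, ci
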