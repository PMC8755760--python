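"""Effective-connectivity model space and random-effects Bayesian model selection.

The model space covers condition-specific modulatory coupling among four
nodes — rDLPFC (D) and rVLPFC (V) as prefrontal sources, right
hippocampus (H) and left M1 (M) as domain-specific targets — on a fixed
intrinsic skeleton: bidirectional connections between all node pairs
except H-M, with task driving inputs into D and V.  A null model plus 72
modulatory models (73 in total) vary along four family dimensions:

* direction — source-target modulation bidirectional, top-down, or
  bottom-up (24 models each);
* pathway — which prefrontal sources modulate targets: independent
  (D with H, V with M), D only, V only, or both in parallel;
* interaction — how the Stop and No-Think conditions modulate the D-V
  connection: none, V->D, D->V, or bidirectional;
* targets — preferred (Stop modulates the M1 pathway, No-Think the
  hippocampal pathway) or non-preferred (swapped).

Group inference is random-effects BMS: a variational Dirichlet update
over model frequencies, with exceedance probabilities estimated by
Monte-Carlo Dirichlet sampling; family comparisons sum Dirichlet mass
within families before taking the argmax.

Model inversion proper is out of scope here; log evidences come either
from the synthetic generator or from the BIC-based least-squares proxy
(`evidence_proxy_fit`), which is intended for synthetic demonstrations
only and is labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from ._rng import substream

__all__ = [
    "NODES",
    "ModelSpec",
    "ModelSpace",
    "EvidenceMatrix",
    "BMSResult",
    "build_model_space",
    "rfx_bms",
    "family_bms",
    "evidence_proxy_fit",
    "staged_family_comparisons",
]

NODES = ("rDLPFC", "rVLPFC", "hippocampus", "M1")
_D, _V, _H, _M = NODES
MODULATED_CONDITIONS = ("Stop", "No-Think")

_PATHWAY_PAIRS = {
    # (source, target) pairs eligible for modulation, before direction is applied
    "independent": ((_D, _H), (_V, _M)),
    "dlpfc_only": ((_D, _H), (_D, _M)),
    "vlpfc_only": ((_V, _H), (_V, _M)),
    "both": ((_D, _H), (_D, _M), (_V, _H), (_V, _M)),
}
_INTERACTION_EDGES = {
    "none": (),
    "v_to_d": ((_V, _D),),
    "d_to_v": ((_D, _V),),
    "bidirectional": ((_D, _V), (_V, _D)),
}


@dataclass(frozen=True)
class ModelSpec:
    id: int
    direction: str    # bidirectional | top_down | bottom_up | none (null)
    pathway: str | None
    interaction: str | None
    targets: str | None  # preferred | non_preferred | None (null)
    modulatory_edges: dict = field(default_factory=dict, hash=False, compare=False)

    def edge_set(self, condition: str) -> frozenset:
        return self.modulatory_edges.get(condition, frozenset())


@dataclass
class ModelSpace:
    models: list
    family_partitions: dict  # dimension -> {family_name: [model ids]}

    def __len__(self) -> int:
        return len(self.models)

    def by_id(self, model_id: int) -> ModelSpec:
        return self.models[model_id]

    def find(self, direction=None, pathway=None, interaction=None, targets=None):
        out = []
        for m in self.models:
            if direction is not None and m.direction != direction:
                continue
            if pathway is not None and m.pathway != pathway:
                continue
            if interaction is not None and m.interaction != interaction:
                continue
            if targets is not None and m.targets != targets:
                continue
            out.append(m)
        return out


@dataclass
class EvidenceMatrix:
    log_evidence: np.ndarray  # (n_subjects, n_models)
    model_ids: list

    def __post_init__(self):
        self.log_evidence = np.asarray(self.log_evidence, dtype=float)
        if self.log_evidence.ndim != 2:
            raise ValueError("log_evidence must be 2-D (subjects x models)")
        if self.log_evidence.shape[1] != len(self.model_ids):
            raise ValueError("column count must match model_ids")


@dataclass
class BMSResult:
    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    labels: list
    mc_error: float = 0.0
    converged: bool = True
    n_iterations: int = 0


def _directed(pairs, direction):
    edges = set()
    for s, t in pairs:
        if direction in ("bidirectional",):
            edges.update([(s, t), (t, s)])
        elif direction == "top_down":
            edges.add((s, t))
        elif direction == "bottom_up":
            edges.add((t, s))
        else:
            raise ValueError(f"unknown direction {direction!r}")
    return edges


def _model_edges(direction, pathway, interaction, targets):
    """Per-condition modulatory edge sets for one model."""
    pairs = _PATHWAY_PAIRS[pathway]
    to_m = [(s, t) for s, t in pairs if t == _M]
    to_h = [(s, t) for s, t in pairs if t == _H]
    if targets == "preferred":
        cond_pairs = {"Stop": to_m, "No-Think": to_h}
    else:
        cond_pairs = {"Stop": to_h, "No-Think": to_m}
    inter = set(_INTERACTION_EDGES[interaction])
    return {
        cond: frozenset(_directed(cond_pairs[cond], direction) | inter)
        for cond in MODULATED_CONDITIONS
    }


# Composition of the 12 models per (direction, targets) block.  The four
# family dimensions would yield 4 pathways x 4 interactions x 2 targets = 32
# per direction, but only 24 exist per direction: the single-source pathway
# families carry just the none/bidirectional interaction variants.  The
# block ordering places the parallel ("both") models last, so within each
# direction family the parallel models are ids 9-12 and 21-24 of the family.
_BLOCK = (
    [("independent", i) for i in ("none", "v_to_d", "d_to_v", "bidirectional")]
    + [("dlpfc_only", i) for i in ("none", "bidirectional")]
    + [("vlpfc_only", i) for i in ("none", "bidirectional")]
    + [("both", i) for i in ("none", "v_to_d", "d_to_v", "bidirectional")]
)


def build_model_space() -> ModelSpace:
    """Enumerate the 73-model space and its four family partitions."""
    models = [ModelSpec(0, "none", None, None, None, {})]
    for direction in ("bidirectional", "top_down", "bottom_up"):
        for targets in ("preferred", "non_preferred"):
            for pathway, interaction in _BLOCK:
                models.append(ModelSpec(
                    id=len(models),
                    direction=direction,
                    pathway=pathway,
                    interaction=interaction,
                    targets=targets,
                    modulatory_edges=_model_edges(direction, pathway, interaction, targets),
                ))
    assert len(models) == 73

    def ids(**kw):
        return [m.id for m in models[1:]
                if all(getattr(m, k) == v for k, v in kw.items())]

    partitions = {
        "direction": {
            "null": [0],
            "bidirectional": ids(direction="bidirectional"),
            "top_down": ids(direction="top_down"),
            "bottom_up": ids(direction="bottom_up"),
        },
        "pathway": {p: ids(pathway=p) for p in _PATHWAY_PAIRS},
        "interaction": {i: ids(interaction=i) for i in _INTERACTION_EDGES},
        "targets": {t: ids(targets=t) for t in ("preferred", "non_preferred")},
    }
    return ModelSpace(models=models, family_partitions=partitions)


# ---------------------------------------------------------------------------
# random-effects BMS


def _variational_dirichlet(log_ev: np.ndarray, alpha0: np.ndarray,
                           tol: float = 1e-6, max_iter: int = 10000):
    """Variational update of Dirichlet counts over model frequencies."""
    alpha = alpha0.copy()
    for it in range(1, max_iter + 1):
        w = log_ev + (digamma(alpha) - digamma(alpha.sum()))
        w = w - w.max(axis=1, keepdims=True)
        g = np.exp(w)
        g /= g.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + g.sum(axis=0)
        delta = np.max(np.abs(new_alpha - alpha))
        alpha = new_alpha
        if delta < tol:
            return alpha, True, it
    return alpha, False, max_iter


def _exceedance(alpha: np.ndarray, n_samples: int, rng: np.random.Generator,
                groups=None, chunk: int = 100000):
    """Monte-Carlo exceedance probabilities from Dirichlet(alpha) draws.

    ``groups``: optional list of index arrays; Dirichlet mass is summed
    within each group before the argmax (family-level exceedance).
    """
    k = len(groups) if groups is not None else alpha.size
    wins = np.zeros(k, dtype=np.int64)
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        if groups is not None:
            draws = np.column_stack([draws[:, g].sum(axis=1) for g in groups])
        wins += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    ep = wins / n_samples
    mc_err = float(np.max(np.sqrt(ep * (1 - ep) / n_samples)))
    return ep, mc_err


def rfx_bms(
    ev: EvidenceMatrix,
    prior_alpha: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS over the models of an evidence matrix.

    ``prior_alpha`` is the Dirichlet prior count per model (uniform 1 by
    default; pass ``1 / n_models`` for the occasionally used alternative).
    """
    log_ev = ev.log_evidence
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("non-finite log evidences")
    if log_ev.shape[0] < 1:
        raise ValueError("need at least one subject")
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")
    alpha0 = np.full(log_ev.shape[1], float(prior_alpha))
    alpha, converged, n_iter = _variational_dirichlet(log_ev, alpha0)
    if not converged:
        raise RuntimeError(
            f"variational BMS did not converge after {n_iter} iterations "
            f"(alpha range {alpha.min():.3g}..{alpha.max():.3g})")
    rng = substream(seed, "bms")
    if alpha.size == 1:
        ep, mc = np.array([1.0]), 0.0
    else:
        ep, mc = _exceedance(alpha, n_samples, rng)
    return BMSResult(
        alpha=alpha, expected_prob=alpha / alpha.sum(), exceedance_prob=ep,
        labels=list(ev.model_ids), mc_error=mc, converged=converged,
        n_iterations=n_iter,
    )


def family_bms(
    ev: EvidenceMatrix,
    partition: dict,
    prior_alpha: float | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Family-level random-effects BMS.

    ``partition`` maps family names to lists of model ids; the comparison
    is restricted to the models the partition covers, which must be
    disjoint.  Dirichlet mass is summed within families before the argmax.

    By default each model's prior count is 1 / |its family|, giving every
    family equal prior mass regardless of size (the standard convention
    for family inference); pass a scalar ``prior_alpha`` to override with
    a flat per-model prior.
    """
    all_ids = [mid for fam in partition.values() for mid in fam]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("overlapping family partition")
    id_to_col = {mid: j for j, mid in enumerate(ev.model_ids)}
    missing = [mid for mid in all_ids if mid not in id_to_col]
    if missing:
        raise ValueError(f"partition references models absent from the evidence matrix: {missing}")

    cols = [id_to_col[mid] for mid in all_ids]
    sub = EvidenceMatrix(ev.log_evidence[:, cols], all_ids)
    if prior_alpha is None:
        fam_size = {mid: len(fam) for fam in partition.values() for mid in fam}
        alpha0 = np.array([1.0 / fam_size[mid] for mid in all_ids])
    else:
        alpha0 = np.full(len(all_ids), float(prior_alpha))
    alpha, converged, n_iter = _variational_dirichlet(sub.log_evidence, alpha0)
    if not converged:
        raise RuntimeError("variational BMS did not converge")

    names = list(partition)
    pos = {mid: j for j, mid in enumerate(all_ids)}
    groups = [np.array([pos[mid] for mid in partition[name]]) for name in names]
    rng = substream(seed, "family-bms")
    ep, mc = _exceedance(alpha, n_samples, rng, groups=groups)
    expected = np.array([alpha[g].sum() for g in groups]) / alpha.sum()
    return BMSResult(
        alpha=alpha, expected_prob=expected, exceedance_prob=ep,
        labels=names, mc_error=mc, converged=converged, n_iterations=n_iter,
    )


def staged_family_comparisons(
    ev: EvidenceMatrix,
    space: ModelSpace,
    prior_alpha: float | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """Run the staged family-comparison sequence over an evidence matrix.

    Stage 1 compares the null model and the three direction families over
    all 73 models; stage 2 compares pathway families within the
    bidirectional models; stage 3 compares interaction families within the
    parallel (both-source) bidirectional models; stage 4 compares preferred
    vs non-preferred targets within the parallel bidirectional-interaction
    pair; stage 5 is model-level BMS over all 73 models side by side.
    """
    def ids(**kw):
        return [m.id for m in space.find(**kw)]

    stages = {}
    stages["direction"] = family_bms(
        ev, space.family_partitions["direction"], prior_alpha, n_samples,
        seed=seed)
    stages["pathway"] = family_bms(
        ev, {p: ids(direction="bidirectional", pathway=p)
             for p in ("independent", "dlpfc_only", "vlpfc_only", "both")},
        prior_alpha, n_samples, seed=seed + 1)
    stages["interaction"] = family_bms(
        ev, {i: ids(direction="bidirectional", pathway="both", interaction=i)
             for i in ("none", "v_to_d", "d_to_v", "bidirectional")},
        prior_alpha, n_samples, seed=seed + 2)
    stages["targets"] = family_bms(
        ev, {t: ids(direction="bidirectional", pathway="both",
                    interaction="bidirectional", targets=t)
             for t in ("preferred", "non_preferred")},
        prior_alpha, n_samples, seed=seed + 3)
    stages["all_models"] = rfx_bms(ev, 1.0 if prior_alpha is None else prior_alpha,
                                   n_samples, seed=seed + 4)
    return stages


# ---------------------------------------------------------------------------
# least-squares + BIC evidence proxy (synthetic demonstrations only)

_INTRINSIC_PAIRS = [
    (s, t) for s in NODES for t in NODES
    if s != t and {s, t} != {_H, _M}
]
_DRIVEN = (_D, _V)


def evidence_proxy_fit(
    series: np.ndarray,
    model: ModelSpec,
    inputs: dict,
    hrf_kernel: np.ndarray | None = None,
    wiener_lambda: float = 0.001,
    ridge: float = 1e-8,
) -> float:
    """Approximate log evidence of ``model`` for a four-node BOLD series.

    The series (T x 4, node order ``NODES``) is HRF-deconvolved by
    regularised Wiener filtering (skipped when ``hrf_kernel`` is None),
    then each node's next-step activity is regressed on the model's
    intrinsic inputs (self + intrinsic edges), condition-gated bilinear
    terms for the model's modulatory edges, and driving inputs.  The
    returned value is -BIC/2 summed over nodes.  This is a demonstration
    proxy for synthetic data, not a variational model inversion.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(NODES):
        raise ValueError("series must be T x 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite series")

    if hrf_kernel is not None:
        y = _wiener_deconvolve(y, hrf_kernel, wiener_lambda)

    T = y.shape[0]
    idx = {n: i for i, n in enumerate(NODES)}
    u = {c: np.asarray(inputs[c], dtype=float)[:T] for c in inputs}
    x_now, x_next = y[:-1], y[1:]

    total = 0.0
    for node in NODES:
        i = idx[node]
        cols = [x_now[:, i]]  # self connection
        for s, t in _INTRINSIC_PAIRS:
            if t == node:
                cols.append(x_now[:, idx[s]])
        for cond in MODULATED_CONDITIONS:
            for s, t in sorted(model.edge_set(cond)):
                if t == node:
                    cols.append(u[cond][:-1] * x_now[:, idx[s]])
        if node in _DRIVEN:
            for cond in sorted(u):
                cols.append(u[cond][:-1])
        X = np.column_stack(cols)
        k = X.shape[1]
        n = X.shape[0]
        gram = X.T @ X
        try:
            beta = np.linalg.solve(gram, X.T @ x_next[:, i])
        except np.linalg.LinAlgError:
            beta = np.linalg.solve(gram + ridge * np.eye(k), X.T @ x_next[:, i])
        rss = float(np.sum((x_next[:, i] - X @ beta) ** 2))
        rss = max(rss, 1e-300)
        bic = n * np.log(rss / n) + k * np.log(n)
        total += -bic / 2.0
    return total


def _wiener_deconvolve(y: np.ndarray, kernel: np.ndarray, lam: float) -> np.ndarray:
    T = y.shape[0]
    h = np.zeros(T)
    h[: min(kernel.size, T)] = kernel[:T]
    H = np.fft.rfft(h)
    filt = np.conj(H) / (np.abs(H) ** 2 + lam)
    out = np.empty_like(y)
    for j in range(y.shape[1]):
        out[:, j] = np.fft.irfft(np.fft.rfft(y[:, j]) * filt, n=T)
    return out
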