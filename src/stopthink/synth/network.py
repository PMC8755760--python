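"""Four-node network BOLD simulator (discrete-time bilinear dynamics).

Neural activity follows x(t+1) = A x(t) + sum_j u_j(t) B_j x(t) + C u(t)
plus innovation noise, on the fixed intrinsic skeleton of the model
space (bidirectional links between all node pairs except hippocampus-M1;
driving inputs into rDLPFC and rVLPFC).  The condition-specific B_j
matrices carry the modulatory edges of a given model.  BOLD is the
HRF-convolved activity plus observation noise.  Zero modulatory
matrices reduce the system to a linear one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import substream
from ..dcm import MODULATED_CONDITIONS, NODES, ModelSpec, _INTRINSIC_PAIRS, _DRIVEN
from .timecourses import canonical_hrf

__all__ = ["NetworkCoupling", "make_task_inputs", "simulate_network_timeseries", "hrf_kernel"]


@dataclass
class NetworkCoupling:
    a_self: float = 0.4        # self-connection (discrete-time decay)
    a_intrinsic: float = 0.1   # intrinsic coupling on skeleton edges
    b_mod: float = -0.35       # modulatory coupling (negative = inhibitory)
    c_drive: float = 1.0       # driving-input strength into D and V
    state_noise_sd: float = 1.0
    obs_noise_sd: float = 0.1


def make_task_inputs(n_scans: int, block_len: int = 15) -> dict:
    """Interleaved Stop / No-Think condition boxcars with rest gaps.

    Cycle: Stop block, rest, No-Think block, rest; each ``block_len``
    scans.  Returns ``{condition: 0/1 array of length n_scans}``.
    """
    u = {c: np.zeros(n_scans) for c in MODULATED_CONDITIONS}
    period = 4 * block_len
    for t in range(n_scans):
        phase = (t % period) // block_len
        if phase == 0:
            u["Stop"][t] = 1.0
        elif phase == 2:
            u["No-Think"][t] = 1.0
    return u


def hrf_kernel(tr_s: float = 2.0, duration_s: float = 30.0) -> np.ndarray:
    t = np.arange(0.0, duration_s, tr_s)
    return canonical_hrf(t)


def _intrinsic_matrix(coupling: NetworkCoupling) -> np.ndarray:
    idx = {n: i for i, n in enumerate(NODES)}
    a = coupling.a_self * np.eye(len(NODES))
    for s, t in _INTRINSIC_PAIRS:
        a[idx[t], idx[s]] = coupling.a_intrinsic
    return a


def simulate_network_timeseries(
    model: ModelSpec,
    coupling: NetworkCoupling | None = None,
    inputs: dict | None = None,
    n_scans: int = 512,
    tr_s: float = 2.0,
    seed: int = 0,
    convolve: bool = True,
) -> np.ndarray:
    """Simulate one subject's four-node BOLD series (n_scans x 4).

    Raises on unstable intrinsic coupling (spectral radius >= 1).
    ``convolve=False`` returns the neural series plus observation noise,
    which is useful for checking the dynamics directly.
    """
    if coupling is None:
        coupling = NetworkCoupling()
    if inputs is None:
        inputs = make_task_inputs(n_scans)
    A = _intrinsic_matrix(coupling)
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
        raise ValueError("unstable intrinsic coupling: spectral radius >= 1")

    idx = {n: i for i, n in enumerate(NODES)}
    B = {}
    for cond in MODULATED_CONDITIONS:
        b = np.zeros_like(A)
        for s, t in model.edge_set(cond):
            b[idx[t], idx[s]] = coupling.b_mod
        B[cond] = b
    C = np.zeros((len(NODES), len(inputs)))
    cond_order = sorted(inputs)
    for j, cond in enumerate(cond_order):
        for node in _DRIVEN:
            C[idx[node], j] = coupling.c_drive

    rng = substream(seed, "network")
    x = np.zeros((n_scans, len(NODES)))
    u_mat = np.column_stack([np.asarray(inputs[c], dtype=float)[:n_scans] for c in cond_order])
    for t in range(n_scans - 1):
        M = A.copy()
        for j, cond in enumerate(cond_order):
            if cond in B:
                M = M + u_mat[t, j] * B[cond]
        x[t + 1] = (M @ x[t] + C @ u_mat[t]
                    + coupling.state_noise_sd * rng.standard_normal(len(NODES)))

    if convolve:
        h = hrf_kernel(tr_s)
        y = np.empty_like(x)
        for j in range(x.shape[1]):
            y[:, j] = np.convolve(x[:, j], h)[:n_scans]
    else:
        y = x.copy()
    y += coupling.obs_noise_sd * rng.standard_normal(y.shape)
    return y
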