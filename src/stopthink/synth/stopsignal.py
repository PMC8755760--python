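"""Independent-race stop-signal trial generator with an SSD staircase.

Go finish times are ex-Gaussian; stop-process (SSRT) draws are truncated
normal above zero — the standard generative choices for race-model
simulation.  On a stop trial the subject responds iff the sampled go
finish beats SSD + sampled SSRT (or on a trigger failure).  The SSD
staircases in 50 ms steps — up after a successful stop, down after a
failed one, floored at 0 — holding stopping success near 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._rng import substream
from .population import PopulationTruth

__all__ = ["RaceModelParams", "simulate_stop_signal"]


@dataclass
class RaceModelParams:
    go_mu: float = 480.0      # ms, Gaussian component mean
    go_sigma: float = 50.0    # ms, Gaussian component SD
    go_tau: float = 120.0     # ms, exponential tail (go mean = mu + tau)
    ssrt_sd: float = 30.0     # ms, trial-to-trial SD about the subject's true SSRT
    ssd_start: float = 300.0  # ms, 250 or 300 by convention
    ssd_step: float = 50.0    # ms staircase step
    p_trigger_failure: float = 0.0
    p_go_omission: float = 0.002
    p_go_choice_error: float = 0.04

    def __post_init__(self):
        if min(self.go_sigma, self.go_tau, self.ssrt_sd, self.ssd_step) <= 0:
            raise ValueError("scale parameters must be positive")
        if not 0 <= self.p_trigger_failure < 1:
            raise ValueError("p_trigger_failure must be in [0, 1)")


def _ex_gauss(rng: np.random.Generator, mu: float, sigma: float, tau: float, size=None):
    return rng.normal(mu, sigma, size) + rng.exponential(tau, size)


def _trunc_normal_pos(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    return abs(rng.normal(mean, sd))  # pathological mean << 0


def simulate_stop_signal(
    truth: PopulationTruth,
    params: RaceModelParams | None = None,
    n_trials: int = 384,
    prop_stop: float = 0.32,
    n_runs: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate stop-signal trials for every subject in ``truth``.

    Returns a trial table with columns ``subject, run, trial_index,
    trial_type, ssd_ms, rt_ms, response, correct`` (NaN encodes absent
    SSD/RT).  Trials are split evenly into ``n_runs`` runs.
    """
    if params is None:
        params = RaceModelParams()
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 < prop_stop < 1:
        raise ValueError("prop_stop must be in (0, 1)")

    rows = []
    n_stop = int(round(n_trials * prop_stop))
    for si, subject in enumerate(truth.subjects):
        rng = substream(seed, "stopsignal", si)
        true_ssrt = float(truth.true_mean_ssrt[si])
        is_stop = np.zeros(n_trials, dtype=bool)
        is_stop[rng.choice(n_trials, size=n_stop, replace=False)] = True
        ssd = params.ssd_start
        run_edges = np.linspace(0, n_trials, n_runs + 1)
        for t in range(n_trials):
            run = int(np.searchsorted(run_edges, t, side="right"))
            if is_stop[t]:
                go_finish = _ex_gauss(rng, params.go_mu, params.go_sigma, params.go_tau)
                stop_finish = ssd + _trunc_normal_pos(rng, true_ssrt, params.ssrt_sd)
                trigger_fail = rng.random() < params.p_trigger_failure
                responded = trigger_fail or (go_finish < stop_finish)
                rows.append((subject, run, t, "stop", ssd,
                             go_finish if responded else np.nan,
                             "press" if responded else "none",
                             False if responded else True))
                ssd = max(0.0, ssd - params.ssd_step) if responded else ssd + params.ssd_step
            else:
                if rng.random() < params.p_go_omission:
                    rows.append((subject, run, t, "go", np.nan, np.nan, "none", False))
                else:
                    rt = _ex_gauss(rng, params.go_mu, params.go_sigma, params.go_tau)
                    correct = rng.random() >= params.p_go_choice_error
                    rows.append((subject, run, t, "go", np.nan, rt,
                                 "press" if correct else "wrong", correct))
    return pd.DataFrame(
        rows,
        columns=["subject", "run", "trial_index", "trial_type",
                 "ssd_ms", "rt_ms", "response", "correct"],
    )
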