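"""Subject population with a shared latent inhibition ability.

The latent ability induces the planted correlation between the two
behavioural endpoints: per-subject true mean SSRT (ms) and true
suppression-induced forgetting (recall-proportion difference).  Means
and spreads are anchored to typical group values for these tasks
(mean SSRT near 348 ms, mean SIF near 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import substream

__all__ = ["PopulationTruth", "make_population"]


@dataclass
class PopulationTruth:
    n_subjects: int
    latent_ability: np.ndarray  # standard-normal shared factor
    true_mean_ssrt: np.ndarray  # ms
    true_sif: np.ndarray        # recall-proportion difference, in [-1, 1]
    target_corr: float
    seed: int
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        if not self.subjects:
            self.subjects = [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]


def make_population(
    n_subjects: int,
    target_corr: float = -0.5,
    seed: int = 0,
    ssrt_mean: float = 348.0,
    ssrt_sd: float = 51.0,
    sif_mean: float = 0.05,
    sif_sd: float = 0.09,
) -> PopulationTruth:
    """Draw per-subject true SSRT and SIF with the given population correlation.

    Both endpoints load on a single standard-normal latent ability; the
    loading signs are chosen so that corr(SSRT, SIF) = ``target_corr``
    (faster stoppers forget more when the target is negative).
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    if abs(target_corr) > 1:
        raise ValueError("|target_corr| must be <= 1")

    rng = substream(seed, "population")
    ability = rng.standard_normal(n_subjects)
    e1 = rng.standard_normal(n_subjects)
    e2 = rng.standard_normal(n_subjects)

    rho = abs(target_corr)
    load = np.sqrt(rho)
    resid = np.sqrt(1.0 - rho)
    sign = -1.0 if target_corr < 0 else 1.0
    z_ssrt = sign * load * ability + resid * e1
    z_sif = load * ability + resid * e2

    true_sif = np.clip(sif_mean + sif_sd * z_sif, -1.0, 1.0)
    return PopulationTruth(
        n_subjects=n_subjects,
        latent_ability=ability,
        true_mean_ssrt=ssrt_mean + ssrt_sd * z_ssrt,
        true_sif=true_sif,
        target_corr=target_corr,
        seed=seed,
    )
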