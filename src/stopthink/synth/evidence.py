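"""Synthetic model log-evidence matrices with a planted winning family."""

from __future__ import annotations

import numpy as np

from .._rng import substream
from ..dcm import EvidenceMatrix, ModelSpace

__all__ = ["simulate_log_evidences"]


def simulate_log_evidences(
    n_subjects: int,
    space: ModelSpace,
    true_family: str | None = None,
    effect_lnB: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> EvidenceMatrix:
    """Each subject's evidences are i.i.d. Gaussian noise, plus
    ``effect_lnB`` added to every model of ``true_family`` (a family name
    from any of the space's partitions).  ``true_family=None`` plants no
    effect.
    """
    if effect_lnB < 0:
        raise ValueError("effect_lnB must be >= 0")
    member_ids: set = set()
    if true_family is not None:
        for partition in space.family_partitions.values():
            if true_family in partition:
                member_ids = set(partition[true_family])
                break
        else:
            raise ValueError(f"unknown family label {true_family!r}")

    rng = substream(seed, "evidence")
    n_models = len(space)
    log_ev = noise_sd * rng.standard_normal((n_subjects, n_models))
    for j, model in enumerate(space.models):
        if model.id in member_ids:
            log_ev[:, j] += effect_lnB
    return EvidenceMatrix(log_ev, [m.id for m in space.models])
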