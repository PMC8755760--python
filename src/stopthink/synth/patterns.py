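"""ROI voxel-pattern generator with planted multivariate structure.

Each ROI carries two separable components on fixed unit voxel
directions, per subject:

* a domain-general inhibition direction ``u``, shared by the two tasks
  (this is what makes cross-task transfer possible), expressed on the
  Stop and No-Think conditions only, with an optional run-wise
  multiplicative decline of the No-Think expression (conflict-reduction
  benefit);
* a domain-specific task direction ``v`` that differs between the
  stop-signal and Think/No-Think tasks, expressed on all conditions of
  its task (this is what a No-Think-vs-Stop classifier can use).

White Gaussian noise is added per run x condition x voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import substream
from .population import PopulationTruth

__all__ = ["ROIDesign", "PatternSet", "simulate_roi_patterns", "CONDITIONS"]

CONDITIONS = ("Stop", "Go", "No-Think", "Think")
_INHIBIT = ("Stop", "No-Think")
_SS_TASK = ("Stop", "Go")


@dataclass
class ROIDesign:
    name: str
    n_voxels: int = 60
    g_shared: float = 0.0      # domain-general signal amplitude
    s_specific: float = 0.0    # domain-specific signal amplitude
    decline_rate: float = 1.0  # per-run decay of the No-Think shared component
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.n_voxels < 2:
            raise ValueError("need at least 2 voxels")
        if self.g_shared < 0 or self.s_specific < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.decline_rate <= 1:
            raise ValueError("decline_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PatternSet:
    """Per subject x ROI: run x condition x voxel beta estimates."""

    subject: str
    roi: str
    betas: np.ndarray                 # (n_runs, 4, n_voxels)
    run_mask: np.ndarray              # (n_runs,) bool, True = run available
    conditions: tuple = CONDITIONS
    decline_rate: float = 1.0         # the planted value, for recovery checks
    residual_sd: float = field(default=1.0)

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    def available_runs(self) -> np.ndarray:
        return np.nonzero(self.run_mask)[0]


def _unit(rng: np.random.Generator, v: int) -> np.ndarray:
    x = rng.standard_normal(v)
    return x / np.linalg.norm(x)


def simulate_roi_patterns(
    designs,
    n_subjects: int | None = None,
    n_runs: int = 8,
    seed: int = 0,
    truth: PopulationTruth | None = None,
    sif_coupling: float = 0.0,
) -> dict:
    """Simulate pattern sets for each ROI design.

    Returns ``{roi_name: [PatternSet per subject]}``.  If ``truth`` is
    given with ``sif_coupling > 0``, each subject's No-Think decline rate
    is tied to their true SIF (more forgetting, steeper decline):
    ``decline_i = clip(decline_rate - sif_coupling * (sif_i - mean_sif), 0, 1)``.
    """
    if truth is not None:
        subjects = truth.subjects
    elif n_subjects is not None:
        subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    else:
        raise ValueError("provide n_subjects or truth")

    mean_sif = float(np.mean(truth.true_sif)) if truth is not None else 0.0
    out = {}
    for design in designs:
        sets = []
        for si, subject in enumerate(subjects):
            rng = substream(seed, "patterns", design.name, si)
            u = _unit(rng, design.n_voxels)
            v_ss = _unit(rng, design.n_voxels)
            v_tnt = _unit(rng, design.n_voxels)
            decline = design.decline_rate
            if truth is not None and sif_coupling != 0.0:
                decline = float(np.clip(
                    design.decline_rate - sif_coupling * (truth.true_sif[si] - mean_sif),
                    0.0, 1.0))
            betas = np.zeros((n_runs, len(CONDITIONS), design.n_voxels))
            for r in range(n_runs):
                for ci, cond in enumerate(CONDITIONS):
                    signal = np.zeros(design.n_voxels)
                    if cond in _INHIBIT:
                        decay = decline ** r if cond == "No-Think" else 1.0
                        signal = signal + design.g_shared * decay * u
                    signal = signal + design.s_specific * (v_ss if cond in _SS_TASK else v_tnt)
                    betas[r, ci] = signal + design.noise_sd * rng.standard_normal(design.n_voxels)
            sets.append(PatternSet(
                subject=subject, roi=design.name, betas=betas,
                run_mask=np.ones(n_runs, dtype=bool),
                decline_rate=decline, residual_sd=design.noise_sd,
            ))
        out[design.name] = sets
    return out
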