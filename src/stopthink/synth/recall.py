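"""Think/No-Think final-recall generator with planted forgetting.

Each word pair carries a learned flag (Bernoulli at the criterion-test
learning rate) and independent same-probe / independent-probe recall
outcomes.  Think and Baseline pairs are recalled at the baseline rate;
No-Think pairs at baseline minus the subject's true suppression-induced
forgetting.  Filler pairs are included so downstream scoring has
something to exclude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._rng import substream
from .population import PopulationTruth

__all__ = ["simulate_tnt_recall"]


def simulate_tnt_recall(
    truth: PopulationTruth,
    n_pairs_per_condition: int = 20,
    learning_rate: float = 0.71,
    baseline_recall: float = 0.77,
    n_filler: int = 6,
    unlearned_recall: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-subject recall table.

    Columns: ``subject, pair_id, condition, learned, sp_correct,
    ip_correct``.  Raises if any subject's No-Think recall probability
    (baseline minus true SIF) falls outside [0, 1].
    """
    if not 0 <= learning_rate <= 1 or not 0 <= baseline_recall <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    nothink_p = baseline_recall - truth.true_sif
    if np.any(nothink_p < 0) or np.any(nothink_p > 1):
        raise ValueError("baseline_recall - true_sif must stay within [0, 1]")

    rows = []
    conditions = (["Think"] * n_pairs_per_condition
                  + ["No-Think"] * n_pairs_per_condition
                  + ["Baseline"] * n_pairs_per_condition
                  + ["filler"] * n_filler)
    for si, subject in enumerate(truth.subjects):
        rng = substream(seed, "recall", si)
        for pi, cond in enumerate(conditions):
            learned = rng.random() < learning_rate
            if cond == "No-Think":
                p = float(nothink_p[si])
            else:
                p = baseline_recall
            if not learned:
                p = unlearned_recall
            rows.append((subject, f"pair-{pi + 1:03d}", cond, learned,
                         rng.random() < p, rng.random() < p))
    return pd.DataFrame(
        rows,
        columns=["subject", "pair_id", "condition", "learned", "sp_correct", "ip_correct"],
    )
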