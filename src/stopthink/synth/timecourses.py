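"""Peristimulus BOLD time-course generator.

Condition time-courses are a canonical double-gamma HRF scaled by a
signed amplitude, sampled on the peristimulus grid 0..12 s at the TR,
plus white noise.  The HRF is zero at onset by construction, so the
planted modulation index (mean over 2-6 s minus the onset value) has
the sign of the amplitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .._rng import substream

__all__ = ["canonical_hrf", "simulate_roi_timecourse"]


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma HRF (peak ~5 s, undershoot ~15 s), peak-normalised."""
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, 6)
    undershoot = stats.gamma.pdf(t, 16)
    h = peak - undershoot / 6.0
    return h / np.max(stats.gamma.pdf(np.linspace(0, 30, 3001), 6))


def simulate_roi_timecourse(
    modulation: dict,
    n_subjects: int = 24,
    tr_s: float = 2.0,
    t_max_s: float = 12.0,
    noise_sd: float = 0.5,
    subject_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate peristimulus time-courses for (roi, condition) amplitudes.

    ``modulation`` maps ``(roi, condition) -> signed amplitude``.  Each
    subject's amplitude is the population value plus a Gaussian random
    effect (``subject_sd``); samples add white noise (``noise_sd``).
    Returns tidy records: ``subject, roi, condition, time_s, bold``.
    """
    times = np.arange(0.0, t_max_s + 1e-9, tr_s)
    hrf = canonical_hrf(times)
    rows = []
    keys = sorted(modulation)
    for si in range(n_subjects):
        subject = f"sub-{si + 1:02d}"
        rng = substream(seed, "timecourse", si)
        for roi, cond in keys:
            amp = modulation[(roi, cond)] + subject_sd * rng.standard_normal()
            bold = amp * hrf + noise_sd * rng.standard_normal(times.size)
            for t, b in zip(times, bold):
                rows.append((subject, roi, cond, float(t), float(b)))
    return pd.DataFrame(rows, columns=["subject", "roi", "condition", "time_s", "bold"])
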