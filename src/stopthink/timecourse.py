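"""ROI peristimulus time-course summarisation and the region x modality
repeated-measures interaction analysis.

The modulation index for a condition is the mean BOLD over the 2-6 s
post-stimulus grid samples minus the onset (0 s) value, which removes
pretrial variability.  The 2 x 2 analysis crosses modulatory target
region (M1 vs hippocampus) with stopping modality (Stop-Go vs
No-Think-Think difference); for a 2 x 2 within-subject design the
interaction F equals the squared paired t on the difference of
differences, which is asserted internally as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .behavior import GroupTestResult, group_one_sample_test

__all__ = ["modulation_index", "modulation_table", "interaction_anova", "AnovaResult"]

_WINDOW = (2.0, 6.0)


def modulation_index(tc: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, roi, condition) modulation index.

    ``tc`` is tidy with columns ``subject, roi, condition, time_s, bold``
    on a uniform grid that includes 0 s and covers 2-6 s.
    """
    out = []
    for (subject, roi, cond), g in tc.groupby(["subject", "roi", "condition"]):
        times = g["time_s"].to_numpy(dtype=float)
        if not np.any(np.isclose(times, 0.0)):
            raise ValueError(f"missing onset sample for {subject}/{roi}/{cond}")
        window = (times >= _WINDOW[0] - 1e-9) & (times <= _WINDOW[1] + 1e-9)
        if not window.any():
            raise ValueError(f"no samples in the 2-6 s window for {subject}/{roi}/{cond}")
        bold = g["bold"].to_numpy(dtype=float)
        onset = float(bold[np.isclose(times, 0.0)][0])
        out.append((subject, roi, cond, float(bold[window].mean()) - onset))
    return pd.DataFrame(out, columns=["subject", "roi", "condition", "index"])


def modulation_table(indices: pd.DataFrame,
                     contrasts=(("Stop", "Go"), ("No-Think", "Think"))) -> pd.DataFrame:
    """Inhibit-minus-respond contrast of modulation indices per subject x roi."""
    wide = indices.pivot_table(index=["subject", "roi"], columns="condition",
                               values="index")
    rows = []
    for (subject, roi), r in wide.iterrows():
        for inhibit, respond in contrasts:
            rows.append((subject, roi, f"{inhibit}-{respond}",
                         float(r[inhibit] - r[respond])))
    return pd.DataFrame(rows, columns=["subject", "roi", "contrast", "index"])


@dataclass
class AnovaResult:
    table: pd.DataFrame                 # pingouin two-way RM-ANOVA table
    interaction_f: float
    interaction_p: float
    interaction_df: tuple
    paired_tests: dict                  # contrast -> GroupTestResult (roi A vs roi B)
    cell_tests: dict                    # (roi, contrast) -> GroupTestResult vs 0, Bonferroni
    bonferroni_m: int


def interaction_anova(table: pd.DataFrame, rois=None, contrasts=None,
                      tail_direction: float = -1.0) -> AnovaResult:
    """2 x 2 repeated-measures ANOVA (roi x contrast) on modulation indices.

    Post-hoc paired t-tests compare the two ROIs within each contrast;
    one-sample tests check each cell against 0, one-tailed in the
    hypothesised direction (negative for inhibitory downregulation when
    ``tail_direction`` is -1), Bonferroni-corrected over the four cells.
    """
    rois = list(rois) if rois is not None else sorted(table["roi"].unique())
    contrasts = (list(contrasts) if contrasts is not None
                 else sorted(table["contrast"].unique()))
    if len(rois) != 2 or len(contrasts) != 2:
        raise ValueError("expected exactly two ROIs and two contrasts")
    sub = table[table["roi"].isin(rois) & table["contrast"].isin(contrasts)]
    wide = sub.pivot_table(index="subject", columns=["roi", "contrast"], values="index")
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(f"missing cells for subjects: {incomplete}")

    aov = pg.rm_anova(data=sub, dv="index", within=["roi", "contrast"],
                      subject="subject", detailed=True)
    inter = aov[aov["Source"].str.contains("\\*")].iloc[0]

    # cross-check: for 2x2, interaction F = squared paired t on the
    # difference of differences
    dd = (wide[(rois[0], contrasts[0])] - wide[(rois[0], contrasts[1])]
          - wide[(rois[1], contrasts[0])] + wide[(rois[1], contrasts[1])])
    inter_f, inter_p = float(inter["F"]), float(inter["p_unc"])
    if np.allclose(dd, 0.0):
        # degenerate 0/0 cell layout: no interaction variance at all
        inter_f, inter_p = 0.0, 1.0
    else:
        t_dd = stats.ttest_1samp(dd, 0.0)
        if not np.isclose(inter_f, float(t_dd.statistic) ** 2,
                          rtol=1e-6, atol=1e-9):
            raise AssertionError(
                "RM-ANOVA interaction F does not match the paired-t identity")

    paired = {}
    for c in contrasts:
        diff = wide[(rois[0], c)] - wide[(rois[1], c)]
        paired[c] = group_one_sample_test(diff.to_numpy(), tail="two")
    cells = {}
    m = len(rois) * len(contrasts)
    for r in rois:
        for c in contrasts:
            res = group_one_sample_test(
                tail_direction * wide[(r, c)].to_numpy(), tail="one")
            cells[(r, c)] = GroupTestResult(t=res.t, df=res.df,
                                            p=min(1.0, res.p * m), d=res.d)
    return AnovaResult(
        table=aov,
        interaction_f=inter_f,
        interaction_p=inter_p,
        interaction_df=(int(inter["ddof1"]), int(inter["ddof2"])),
        paired_tests=paired,
        cell_tests=cells,
        bonferroni_m=m,
    )
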