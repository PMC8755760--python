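"""Trial-level and subject-level behavioural measures.

Stop-signal task: SSRT by the experiment-wide integration method with
replacement of Go omissions, descriptive stop statistics, the
independent-race assumption check, and the go-RT slowing slope across
runs.  Think/No-Think task: suppression-induced forgetting (SIF) from
final recall conditionalized on criterion-test learning.

Trial tables are plain pandas DataFrames.  A stop-trial table has columns
``subject, run, trial_index, trial_type, ssd_ms, rt_ms, response,
correct`` with NaN/None encoding absent SSD (go trials) and absent RT
(omissions and successful stops).  A recall table has columns
``subject, pair_id, condition, learned, sp_correct, ip_correct``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StopSummary",
    "SifScore",
    "GroupTestResult",
    "estimate_ssrt_integration",
    "go_rt_run_slope",
    "score_sif",
    "group_one_sample_test",
    "cohen_d_from_t",
    "one_tailed_p_from_t",
]


def cohen_d_from_t(t: float, n: int) -> float:
    """One-sample Cohen's d implied by a t statistic: d = t / sqrt(n)."""
    return t / np.sqrt(n)


def one_tailed_p_from_t(t: float, df: int) -> float:
    """Upper-tail p-value of a Student t statistic."""
    return float(stats.t.sf(t, df))

SCORED_CONDITIONS = ("Think", "No-Think", "Baseline")


@dataclass
class StopSummary:
    ssrt_ms: float
    p_respond_stop: float
    p_go_omission: float
    p_go_choice_error: float
    mean_ssd_ms: float
    mean_correct_go_rt_ms: float
    mean_failed_stop_rt_ms: float
    race_assumption_ok: bool


@dataclass
class SifScore:
    recall_baseline: float
    recall_nothink: float
    recall_think: float
    sif: float


@dataclass
class GroupTestResult:
    t: float
    df: int
    p: float
    d: float


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def estimate_ssrt_integration(trials: pd.DataFrame) -> StopSummary:
    """Integration-method SSRT for one subject's stop-signal trials.

    All go trials (correct and incorrect) enter the go-RT distribution;
    omitted go RTs are replaced by the maximum observed go RT.  The rank
    is n = round(N_go * p(respond|stop)), clamped to [1, N_go]; SSRT is
    the n-th fastest go RT minus the mean SSD over all stop trials.
    """
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    if len(stop) == 0:
        raise ValueError("no stop trials")
    if len(go) == 0:
        raise ValueError("no go trials")

    responded_stop = stop["rt_ms"].notna()
    p_respond = float(responded_stop.mean())
    if p_respond == 0:
        raise ValueError("SSRT undefined at zero respond rate")

    go_rts = go["rt_ms"].to_numpy(dtype=float)
    observed = go_rts[np.isfinite(go_rts)]
    if observed.size == 0:
        raise ValueError("all go trials omitted; go-RT distribution undefined")
    go_rts = np.where(np.isfinite(go_rts), go_rts, observed.max())

    n_go = go_rts.size
    rank = min(max(_round_half_away(n_go * p_respond), 1), n_go)
    nth_fastest = float(np.sort(go_rts)[rank - 1])
    mean_ssd = float(stop["ssd_ms"].mean())

    responded_go = go["rt_ms"].notna()
    correct_go = go[responded_go & go["correct"].astype(bool)]
    failed_stop_rt = float(stop.loc[responded_stop, "rt_ms"].mean()) if responded_stop.any() else np.nan
    mean_correct_go = float(correct_go["rt_ms"].mean()) if len(correct_go) else np.nan

    return StopSummary(
        ssrt_ms=nth_fastest - mean_ssd,
        p_respond_stop=p_respond,
        p_go_omission=float((~responded_go).mean()),
        p_go_choice_error=float((~go.loc[responded_go, "correct"].astype(bool)).mean())
        if responded_go.any() else np.nan,
        mean_ssd_ms=mean_ssd,
        mean_correct_go_rt_ms=mean_correct_go,
        mean_failed_stop_rt_ms=failed_stop_rt,
        race_assumption_ok=bool(failed_stop_rt < mean_correct_go),
    )


def go_rt_run_slope(trials: pd.DataFrame):
    """Group slowing slope: mean of per-subject OLS slopes of correct go RT
    on run index, with a two-sided one-sample t-test against 0.

    Returns ``(group_slope, test, per_subject_slopes)``.  The group
    coefficient is the average of subject-wise least-squares fits; a pooled
    mixed-model coefficient would differ slightly with unbalanced data.
    """
    slopes = {}
    for subject, sub in trials.groupby("subject"):
        go = sub[(sub["trial_type"] == "go") & sub["rt_ms"].notna() & sub["correct"].astype(bool)]
        runs = go["run"].to_numpy(dtype=float)
        if np.unique(runs).size < 2:
            raise ValueError(f"subject {subject}: need correct go trials in >= 2 runs")
        slopes[subject] = float(np.polyfit(runs, go["rt_ms"].to_numpy(dtype=float), 1)[0])
    values = np.array(list(slopes.values()))
    group = float(values.mean())
    test = group_one_sample_test(values, tail="two", mu0=0.0) if values.size >= 2 else None
    return group, test, slopes


def score_sif(recall: pd.DataFrame) -> SifScore:
    """Conditionalized suppression-induced forgetting for one subject.

    Filler pairs and pairs not learned at the criterion test are excluded.
    Per condition, recall is computed separately for the same-probe and
    independent-probe tests and averaged; SIF = Baseline - No-Think.
    """
    scored = recall[recall["condition"].isin(SCORED_CONDITIONS)]
    learned = scored[scored["learned"].astype(bool)]
    means = {}
    for cond in SCORED_CONDITIONS:
        sub = learned[learned["condition"] == cond]
        if len(sub) == 0:
            raise ValueError(f"no learned pairs in condition {cond!r}")
        means[cond] = float((sub["sp_correct"].astype(float).mean()
                             + sub["ip_correct"].astype(float).mean()) / 2)
    return SifScore(
        recall_baseline=means["Baseline"],
        recall_nothink=means["No-Think"],
        recall_think=means["Think"],
        sif=means["Baseline"] - means["No-Think"],
    )


def group_one_sample_test(values, tail: str = "two", mu0: float = 0.0) -> GroupTestResult:
    """One-sample Student t-test with Cohen's d = t / sqrt(n).

    ``tail='one'`` gives the upper-tail probability in the hypothesised
    (positive) direction; flip the sign of ``values - mu0`` for the other
    direction.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        t = 0.0
    else:
        t = float((values.mean() - mu0) / (sd / np.sqrt(n)))
    df = n - 1
    if tail == "one":
        p = float(stats.t.sf(t, df))
    elif tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return GroupTestResult(t=t, df=df, p=p, d=t / np.sqrt(n))
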