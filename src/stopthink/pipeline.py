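"""Study configuration and end-to-end orchestration.

One call (or the ``stopthink all`` CLI command) simulates a synthetic
study, scores behaviour, runs the PLS, time-course, MVPA, and BMS
stages, and writes a structured JSON report plus per-stage text tables
into the output directory.  All randomness flows from the single config
seed through named substreams, so re-running with the same config is
bit-identical and stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, dcm, io, mvpa, pls, robust, synth, timecourse

__all__ = ["StudyConfig", "default_roi_designs", "run_pipeline"]

ALL_STAGES = ("simulate", "behavior", "pls", "timecourse", "mvpa", "bms")


def default_roi_designs() -> list:
    """The four-ROI layout the study conditions assume.

    Prefrontal sources (rDLPFC, rVLPFC) carry a domain-general shared
    inhibition component (cross-task decodable) with a run-wise decline
    of its No-Think expression; the domain-specific targets (hippocampus,
    M1) carry only task-specific structure.
    """
    return [
        synth.ROIDesign("rDLPFC", n_voxels=60, g_shared=1.6, s_specific=1.2,
                        decline_rate=0.85, noise_sd=1.0),
        synth.ROIDesign("rVLPFC", n_voxels=80, g_shared=1.8, s_specific=1.5,
                        decline_rate=0.88, noise_sd=1.0),
        synth.ROIDesign("hippocampus", n_voxels=50, g_shared=0.0, s_specific=1.1,
                        decline_rate=1.0, noise_sd=1.0),
        synth.ROIDesign("M1", n_voxels=40, g_shared=0.0, s_specific=1.2,
                        decline_rate=1.0, noise_sd=1.0),
    ]


_DEFAULT_MODULATION = {
    ("M1", "Stop"): -1.0, ("M1", "Go"): 0.6,
    ("M1", "No-Think"): -0.1, ("M1", "Think"): 0.1,
    ("hippocampus", "Stop"): -0.1, ("hippocampus", "Go"): 0.1,
    ("hippocampus", "No-Think"): -0.6, ("hippocampus", "Think"): 0.8,
}


@dataclass
class StudyConfig:
    seed: int = 0
    n_subjects: int = 24
    out_dir: str = "study-out"
    stages: tuple = ALL_STAGES
    target_corr: float = -0.5
    n_trials: int = 384
    prop_stop: float = 0.32
    n_pairs_per_condition: int = 20
    learning_rate: float = 0.71
    baseline_recall: float = 0.77
    sif_coupling: float = 2.0        # ties per-subject pattern decline to SIF
    pls_n_perm: int = 500
    pls_n_boot: int = 500
    mvpa_n_subsets: int = 50
    mvpa_subset_frac: float = 0.9
    bms_n_samples: int = 100_000
    bms_effect_lnb: float = 3.0
    bms_true_family: str = "preferred"
    roi_designs: list = field(default_factory=default_roi_designs)
    modulation: dict = field(default_factory=lambda: dict(_DEFAULT_MODULATION))

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = dict(raw)
        if "roi_designs" in cfg:
            cfg["roi_designs"] = [synth.ROIDesign(**d) for d in cfg["roi_designs"]]
        if "modulation" in cfg:
            cfg["modulation"] = {(k.split("|")[0], k.split("|")[1]): v
                                 for k, v in cfg["modulation"].items()}
        if "stages" in cfg:
            bad = set(cfg["stages"]) - set(ALL_STAGES)
            if bad:
                raise ValueError(f"unknown stage(s): {sorted(bad)}")
            cfg["stages"] = tuple(cfg["stages"])
        return cls(**cfg)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_designs"] = [dataclasses.asdict(r) for r in self.roi_designs]
        d["modulation"] = {f"{k[0]}|{k[1]}": v for k, v in self.modulation.items()}
        d["stages"] = list(self.stages)
        return d


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: StudyConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the study report (also written to ``out_dir/report.json``).
    Any stage failure raises, after a partial report is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
    (out / "config.json").write_text(cfg_json)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_sha1": hashlib.sha1(cfg_json.encode()).hexdigest(),
        },
        "warnings": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            _run_stages(config, out, report)
        finally:
            report["warnings"] = sorted({str(w.message) for w in caught})
            (out / "report.json").write_text(
                json.dumps(_jsonable(report), indent=1, sort_keys=True))
    return report


def _run_stages(config: StudyConfig, out: Path, report: dict) -> None:
    seed = config.seed
    truth = synth.make_population(config.n_subjects, config.target_corr, seed)

    trials = recall = patterns = None
    if "simulate" in config.stages:
        trials = synth.simulate_stop_signal(
            truth, n_trials=config.n_trials, prop_stop=config.prop_stop, seed=seed)
        recall = synth.simulate_tnt_recall(
            truth, config.n_pairs_per_condition, config.learning_rate,
            config.baseline_recall, seed=seed)
        patterns = synth.simulate_roi_patterns(
            config.roi_designs, truth=truth, seed=seed,
            sif_coupling=config.sif_coupling)
        io.write_events_tsv(trials, out / "stop_events.tsv")
        io.write_recall_tsv(recall, out / "recall.tsv")
        pat_dir = out / "patterns"
        pat_dir.mkdir(exist_ok=True)
        for roi, sets in patterns.items():
            for ps in sets:
                io.write_pattern_set(ps, pat_dir / f"{ps.subject}_{roi}")
        report["simulate"] = {
            "n_subjects": config.n_subjects,
            "true_corr_ssrt_sif": float(np.corrcoef(
                truth.true_mean_ssrt, truth.true_sif)[0, 1])
            if config.n_subjects > 1 else None,
        }

    behaviour_df = None
    if "behavior" in config.stages:
        if trials is None:
            trials = io.read_events_tsv(out / "stop_events.tsv")
            recall = io.read_recall_tsv(out / "recall.tsv")
        rows = []
        for subject, sub in trials.groupby("subject"):
            summary = behavior.estimate_ssrt_integration(sub)
            sif = behavior.score_sif(recall[recall["subject"] == subject])
            rows.append({"subject": subject, "ssrt_ms": summary.ssrt_ms,
                         "p_respond_stop": summary.p_respond_stop,
                         "mean_ssd_ms": summary.mean_ssd_ms,
                         "mean_correct_go_rt_ms": summary.mean_correct_go_rt_ms,
                         "race_assumption_ok": summary.race_assumption_ok,
                         "sif": sif.sif,
                         "recall_baseline": sif.recall_baseline,
                         "recall_nothink": sif.recall_nothink})
        behaviour_df = pd.DataFrame(rows).sort_values("subject").reset_index(drop=True)
        behaviour_df.to_csv(out / "behaviour.csv", index=False)
        slope, slope_test, _ = behavior.go_rt_run_slope(trials)
        sif_test = behavior.group_one_sample_test(
            behaviour_df["sif"].to_numpy(), tail="one")
        x = behaviour_df["ssrt_ms"].to_numpy()
        y = behaviour_df["sif"].to_numpy()
        if len(x) >= 10:
            corr = robust.select_and_correlate(x, y)
        else:  # decision tree unreliable at tiny n; report plain Pearson
            warnings.warn("fewer than 10 subjects: reporting Pearson correlation")
            r, p = stats.pearsonr(x, y)
            corr = robust.CorrelationResult("pearson", float(r), float(p), len(x))
        report["behavior"] = {
            "group_mean_ssrt_ms": float(behaviour_df["ssrt_ms"].mean()),
            "group_mean_p_respond_stop": float(behaviour_df["p_respond_stop"].mean()),
            "group_mean_sif": float(behaviour_df["sif"].mean()),
            "sif_test": sif_test,
            "go_rt_run_slope": slope,
            "go_rt_run_slope_test": slope_test,
            "ssrt_sif_correlation": corr,
        }

    if "pls" in config.stages:
        if patterns is None or behaviour_df is None:
            raise RuntimeError("pls stage needs simulate and behavior stages")
        source_rois = [d.name for d in config.roi_designs if d.g_shared > 0] \
            or [d.name for d in config.roi_designs]
        X, voxel_ids = _inhibit_contrast_matrix(patterns, rois=source_rois)
        Y = behaviour_df[["ssrt_ms", "sif"]].to_numpy()
        inp = pls.PLSInput(X, Y, voxel_ids, ["ssrt_ms", "sif"])
        fit = pls.fit_behavioural_pls(inp)
        perm_p = pls.permutation_test(inp, config.pls_n_perm, seed=seed)
        ratios, ci = pls.bootstrap_saliences(inp, config.pls_n_boot, seed=seed)
        pd.DataFrame({"voxel": voxel_ids,
                      "salience_lv1": fit.saliences[:, 0],
                      "bootstrap_ratio_lv1": ratios[:, 0]}
                     ).to_csv(out / "pls_saliences.csv", index=False)
        report["pls"] = {
            "singular_values": fit.singular_values,
            "pct_covariance": fit.pct_covariance,
            "perm_p": perm_p,
            "behaviour_corr_lv1": fit.behaviour_corr[:, 0],
            "behaviour_corr_ci_lv1": ci[:, 0, :],
            "n_sig_voxels_lv1": int(np.sum(np.abs(ratios[:, 0]) > 1.96)),
        }

    if "timecourse" in config.stages:
        tc = synth.simulate_roi_timecourse(
            config.modulation, n_subjects=config.n_subjects, seed=seed)
        indices = timecourse.modulation_index(tc)
        table = timecourse.modulation_table(indices)
        table.to_csv(out / "modulation_table.csv", index=False)
        anova = timecourse.interaction_anova(
            table, rois=("M1", "hippocampus"),
            contrasts=("Stop-Go", "No-Think-Think"))
        report["timecourse"] = {
            "interaction_f": anova.interaction_f,
            "interaction_p": anova.interaction_p,
            "interaction_df": list(anova.interaction_df),
            "cell_tests": {f"{r}|{c}": t for (r, c), t in anova.cell_tests.items()},
        }

    if "mvpa" in config.stages:
        if patterns is None:
            raise RuntimeError("mvpa stage needs the simulate stage")
        cross = {roi: [mvpa.cross_task_accuracy(
                            ps, config.mvpa_n_subsets, config.mvpa_subset_frac,
                            seed=seed)
                       for ps in sets] for roi, sets in patterns.items()}
        between = {roi: [mvpa.between_task_accuracy(
                             ps, config.mvpa_n_subsets, config.mvpa_subset_frac,
                             seed=seed)
                         for ps in sets] for roi, sets in patterns.items()}
        rows = [{"subject": r.subject, "roi": roi, "scheme": r.scheme,
                 "accuracy": float(np.asarray(r.accuracy))}
                for res in (cross, between) for roi, lst in res.items() for r in lst]
        pd.DataFrame(rows).to_csv(out / "decoding.csv", index=False)
        report["mvpa"] = {
            "cross_task": mvpa.group_decoding_inference(cross),
            "between_task": mvpa.group_decoding_inference(between),
        }
        trend_roi = next((d.name for d in config.roi_designs if d.g_shared > 0),
                         config.roi_designs[0].name)
        per_run = [mvpa.per_run_cross_accuracy(ps, seed=seed)
                   for ps in patterns[trend_roi]]
        behaviours = None
        if behaviour_df is not None and len(behaviour_df) >= 10:
            behaviours = {
                "sif": dict(zip(behaviour_df["subject"], behaviour_df["sif"])),
                "ssrt_ms": dict(zip(behaviour_df["subject"], behaviour_df["ssrt_ms"])),
            }
        trend = mvpa.linear_trend_and_slope_correlations(per_run, behaviours)
        report["mvpa"][f"conflict_reduction_{trend_roi}"] = {
            "trend_f": trend.f, "trend_df": list(trend.df), "trend_p": trend.p,
            "mean_slope": float(np.mean(list(trend.slopes.values()))),
            "slope_correlations": trend.correlations,
        }

    if "bms" in config.stages:
        space = dcm.build_model_space()
        ev = synth.simulate_log_evidences(
            config.n_subjects, space, config.bms_true_family,
            config.bms_effect_lnb, seed=seed)
        io.write_evidence_csv(ev, out / "log_evidence.csv",
                              out / "model_space.json", space)
        stages = dcm.staged_family_comparisons(
            ev, space, n_samples=config.bms_n_samples, seed=seed)
        report["bms"] = {
            "evidence_source": "synthetic generator (planted family)"}
        for name, res in stages.items():
            if name == "all_models":
                continue
            report["bms"][name] = {"labels": res.labels,
                                   "exceedance_prob": res.exceedance_prob,
                                   "expected_prob": res.expected_prob}
        best = int(np.argmax(stages["all_models"].exceedance_prob))
        report["bms"]["all_models"] = {
            "winning_model_id": stages["all_models"].labels[best],
            "winning_exceedance": float(stages["all_models"].exceedance_prob[best]),
        }


def _inhibit_contrast_matrix(patterns: dict, rois) -> tuple:
    """Subjects x voxels Inhibit > Respond contrast, ROIs concatenated."""
    blocks, voxel_ids = [], []
    for roi in rois:
        sets = patterns[roi]
        mat = []
        for ps in sets:
            runs = ps.available_runs()
            b = ps.betas[runs]
            inhibit = (b[:, 0] + b[:, 2]) / 2   # Stop, No-Think
            respond = (b[:, 1] + b[:, 3]) / 2   # Go, Think
            mat.append((inhibit - respond).mean(axis=0))
        blocks.append(np.array(mat))
        voxel_ids += [f"{roi}:{j}" for j in range(sets[0].n_voxels)]
    return np.hstack(blocks), voxel_ids
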