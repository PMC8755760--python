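"""Readers and writers for the pipeline's text formats.

Trial-level behavioural data use an events-style tab-separated dialect
("n/a" encodes absent SSD/RT); recall tables and result tables are
TSV/CSV; voxel-pattern matrices are delimited with a JSON sidecar
carrying condition labels and the run mask; evidence matrices are CSV
with a JSON model-space manifest.  Every writer's output is parsed
losslessly by its paired reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dcm import EvidenceMatrix
from .synth.patterns import CONDITIONS, PatternSet

__all__ = [
    "read_events_tsv", "write_events_tsv",
    "read_recall_tsv", "write_recall_tsv",
    "read_pattern_set", "write_pattern_set",
    "read_evidence_csv", "write_evidence_csv",
]

_EVENT_COLUMNS = ["subject", "run", "trial_index", "trial_type",
                  "ssd_ms", "rt_ms", "response", "correct"]
_NUMERIC = {"ssd_ms", "rt_ms"}


def write_events_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in _NUMERIC:
        out[col] = out[col].map(lambda v: "n/a" if pd.isna(v) else f"{float(v):.6g}")
    out["correct"] = out["correct"].astype(bool)
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    for col in _NUMERIC:
        vals = []
        for lineno, raw in enumerate(df[col], start=2):
            if raw == "n/a":
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(raw))
                except ValueError:
                    raise ValueError(
                        f"{path}: malformed numeric {raw!r} in column "
                        f"{col!r} at line {lineno}") from None
        df[col] = vals
    df["run"] = df["run"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    df["correct"] = df["correct"].map({"True": True, "False": False})
    return df[_EVENT_COLUMNS]


def write_recall_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_recall_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("learned", "sp_correct", "ip_correct"):
        df[col] = df[col].astype(bool)
    return df


def write_pattern_set(ps: PatternSet, prefix) -> None:
    """Write one subject x ROI pattern set as ``<prefix>.csv`` (rows are
    run x condition in row-major order) plus ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    flat = ps.betas.reshape(ps.n_runs * len(ps.conditions), ps.n_voxels)
    np.savetxt(prefix.with_suffix(".csv"), flat, delimiter=",")
    sidecar = {
        "subject": ps.subject,
        "roi": ps.roi,
        "n_runs": int(ps.n_runs),
        "conditions": list(ps.conditions),
        "n_voxels": int(ps.n_voxels),
        "run_mask": [bool(b) for b in ps.run_mask],
        "decline_rate": float(ps.decline_rate),
        "residual_sd": float(ps.residual_sd),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_pattern_set(prefix) -> PatternSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    flat = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    n_runs, n_cond = meta["n_runs"], len(meta["conditions"])
    return PatternSet(
        subject=meta["subject"], roi=meta["roi"],
        betas=flat.reshape(n_runs, n_cond, meta["n_voxels"]),
        run_mask=np.array(meta["run_mask"], dtype=bool),
        conditions=tuple(meta["conditions"]),
        decline_rate=meta.get("decline_rate", 1.0),
        residual_sd=meta.get("residual_sd", 1.0),
    )


def write_evidence_csv(ev: EvidenceMatrix, path, manifest_path=None, space=None) -> None:
    df = pd.DataFrame(ev.log_evidence,
                      columns=[f"model_{mid}" for mid in ev.model_ids])
    df.to_csv(path, index=False)
    if manifest_path is not None:
        manifest = {"model_ids": [int(m) for m in ev.model_ids]}
        if space is not None:
            manifest["family_partitions"] = {
                dim: {fam: [int(i) for i in ids] for fam, ids in part.items()}
                for dim, part in space.family_partitions.items()
            }
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))


def read_evidence_csv(path) -> EvidenceMatrix:
    df = pd.read_csv(path)
    model_ids = [int(c.removeprefix("model_")) for c in df.columns]
    return EvidenceMatrix(df.to_numpy(dtype=float), model_ids)
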