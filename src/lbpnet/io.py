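"""Delimited-text readers and writers for every pipeline artifact.

All tabular output is comma-delimited UTF-8 with header rows; FC matrices
carry a node-ID header; every writer has a reader that round-trips without
loss of information.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCMatrix
from .simulate import SubjectRecord, SyntheticCohort

__all__ = [
    "read_subject_table",
    "write_subject_table",
    "read_series",
    "write_series",
    "read_fc",
    "write_fc",
    "write_metric_table",
    "read_metric_table",
    "write_cohort",
]

VALID_GROUPS = ("HC", "LBP")


class InputError(ValueError):
    """Malformed user input (maps to CLI exit code 1)."""


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read subject_id,group[,odi] CSV into validated records."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except Exception as exc:
        raise InputError(f"{path}: cannot parse subject table: {exc}") from exc
    required = {"subject_id", "group"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        sid = str(row["subject_id"])
        if sid in seen:
            raise InputError(f"{path}:{line}: duplicate subject_id {sid!r}")
        seen.add(sid)
        group = str(row["group"])
        if group not in VALID_GROUPS:
            raise InputError(
                f"{path}:{line}: unknown group {group!r} (expected one of {VALID_GROUPS})"
            )
        odi = None
        if "odi" in df.columns and not pd.isna(row["odi"]):
            odi = float(row["odi"])
            if not 0.0 <= odi <= 100.0:
                raise InputError(f"{path}:{line}: odi {odi} outside [0, 100]")
        records.append(SubjectRecord(subject_id=sid, group=group, odi=odi))
    return records


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "odi": [r.odi for r in records],
        }
    ).to_csv(path, index=False)


def write_series(series: np.ndarray, path: str | Path) -> None:
    """Nodes-by-timepoints matrix, one row per node, node_id leading column."""
    df = pd.DataFrame(series)
    df.index.name = "node_id"
    df.to_csv(path)


def read_series(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col="node_id").to_numpy(dtype=float)


def write_fc(fc: FCMatrix, path: str | Path) -> None:
    pd.DataFrame(fc.values, index=fc.node_ids, columns=fc.node_ids).to_csv(
        path, index_label="node_id"
    )


def read_fc(path: str | Path, subject_id: str | None = None) -> FCMatrix:
    df = pd.read_csv(path, index_col="node_id")
    return FCMatrix(
        values=df.to_numpy(dtype=float),
        node_ids=df.index.to_numpy(),
        subject_id=subject_id,
    )


def write_metric_table(table: pd.DataFrame, path: str | Path) -> None:
    """Long-format metric table: subject_id, node_id, metric, value."""
    long = (
        table.stack(["metric", "node_id"], future_stack=True)
        .rename("value")
        .reset_index()
    )
    long.to_csv(path, index=False)


def read_metric_table(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path)
    wide = long.pivot(index="subject_id", columns=["metric", "node_id"], values="value")
    return wide


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a synthetic cohort: per-subject series, subject table, and a
    ground-truth JSON (affected nodes are a construct of the generator)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_dir = outdir / "series"
    series_dir.mkdir(exist_ok=True)
    for sub in cohort.subjects:
        write_series(sub.series, series_dir / f"{sub.subject_id}.csv")
    write_subject_table(cohort.subjects, outdir / "subjects.csv")
    truth = {
        "affected_nodes": cohort.affected_nodes.tolist(),
        "note": "synthetic ground truth; affected nodes are a generator construct",
        "spec": {
            k: getattr(cohort.spec, k)
            for k in (
                "n_hc", "n_lbp", "n_nodes", "n_timepoints",
                "n_affected", "effect_size", "noise_sd", "seed",
            )
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
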