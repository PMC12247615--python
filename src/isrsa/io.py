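"""Delimited-text IO for behavioral tables, time courses and network maps."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import TimecourseSet

__all__ = ["read_behavior", "read_timecourses", "read_network_map"]

_REQUIRED = ("subject_id", "score", "age", "sex", "motion")


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python")


def read_behavior(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    score_column: str | None = None,
) -> pd.DataFrame:
    """Load a behavioral table, renaming columns to the canonical names.

    ``columns`` maps canonical name -> file column name for
    subject_id/age/sex/motion (and optionally max_displacement);
    ``score_column`` selects which phenotype column becomes ``score``.
    """
    df = _read_table(path)
    mapping = dict(columns or {})
    if score_column is not None:
        mapping.setdefault("score", score_column)
    rename = {src: dst for dst, src in mapping.items() if src in df.columns}
    missing_src = [src for src in mapping.values() if src not in df.columns]
    if missing_src:
        raise ValueError(f"behavioral table {path} lacks mapped columns {missing_src}")
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"behavioral table {path} lacks required columns {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject IDs in {path}: {dups[:5]}")
    if df[["score", "age", "motion"]].isna().any().any():
        raise ValueError(f"behavioral table {path} contains missing values")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_timecourses(
    path: str | Path,
    subject_ids: Sequence[str] | None = None,
    transpose: bool = False,
) -> TimecourseSet:
    """Load per-subject time-course TSVs from a directory, or one stacked file.

    Directory layout: one ``<subject_id>_timecourses.{tsv,csv}`` per
    subject, rows = timepoints, columns = node IDs, header row (pass
    ``transpose=True`` for the rows = nodes dialect).  A single file must
    carry a ``subject_id`` column with timepoints stacked per subject.
    Subjects requested but absent are an error, never silently dropped.
    """
    path = Path(path)
    if path.is_dir():
        files = {}
        for f in sorted(path.iterdir()):
            if f.suffix in (".tsv", ".csv") and f.stem.endswith("_timecourses"):
                files[f.stem[: -len("_timecourses")]] = f
        if subject_ids is None:
            subject_ids = sorted(files)
        missing = [s for s in subject_ids if s not in files]
        if missing:
            raise ValueError(f"no time-course file for subjects {missing[:5]} in {path}")
        arrays, node_ids = [], None
        for sid in subject_ids:
            df = _read_table(files[sid])
            mat = df.to_numpy(dtype=float)
            cols = list(df.columns)
            if transpose:
                mat, cols = mat.T, [f"node{i + 1}" for i in range(mat.shape[1])]
            if node_ids is None:
                node_ids = cols
            elif cols != node_ids:
                raise ValueError(f"node columns of {files[sid]} differ from first subject")
            arrays.append(mat.T)  # (n_nodes, T)
        values = np.stack(arrays)
        if len({a.shape[1] for a in arrays}) != 1:
            raise ValueError("subjects have differing timepoint counts")
        return TimecourseSet(list(subject_ids), list(node_ids), values)

    df = _read_table(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"stacked time-course file {path} lacks a 'subject_id' column")
    df["subject_id"] = df["subject_id"].astype(str)
    groups = dict(tuple(df.groupby("subject_id", sort=True)))
    if subject_ids is None:
        subject_ids = sorted(groups)
    missing = [s for s in subject_ids if s not in groups]
    if missing:
        raise ValueError(f"subjects {missing[:5]} absent from {path}")
    node_ids = [c for c in df.columns if c != "subject_id"]
    lengths = {len(groups[s]) for s in subject_ids}
    if len(lengths) != 1:
        raise ValueError("subjects have differing timepoint counts")
    values = np.stack([groups[s][node_ids].to_numpy(dtype=float).T for s in subject_ids])
    return TimecourseSet(list(subject_ids), node_ids, values)


def read_network_map(path: str | Path) -> pd.Series:
    """Two-column delimited map node_id -> network name."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"network map {path} needs two columns (node_id, network)")
    node_col, net_col = df.columns[:2]
    s = pd.Series(df[net_col].to_numpy(), index=df[node_col].astype(str), name="network")
    if s.index.duplicated().any():
        raise ValueError(f"duplicate node IDs in network map {path}")
    return s
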