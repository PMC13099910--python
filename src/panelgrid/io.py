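"""Readers for the plain-text formats the pipeline exchanges.

Expression matrices, labels and probe-level tables are tab-separated text;
gene sets use the standard GMT dialect (name, description, members, one set
per line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import ExpressionMatrix, ProbeLevelCollection, ProbeLevelSet


def read_expression(path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    labels = read_labels(labels_path)
    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    return ExpressionMatrix(values, labels.loc[values.columns])


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_probe_level(path: str | Path) -> ProbeLevelCollection:
    df = pd.read_csv(path, sep="\t")
    arrays = list(df.columns[2:])
    blocks = []
    for pset, grp in df.groupby("probeset_id", sort=False):
        blocks.append(
            ProbeLevelSet(
                probeset_id=str(pset),
                probe_ids=[str(p) for p in grp["probe_id"]],
                arrays=arrays,
                values=np.ascontiguousarray(grp[arrays].to_numpy(dtype=float)),
            )
        )
    return ProbeLevelCollection(blocks)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
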