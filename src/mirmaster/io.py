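"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are TSV with the feature id in the first column and one
column per sample; gene sets travel as GMT (set name, description, then
tab-separated members); survival and IC50 tables are plain TSV.  All writers
emit full-precision floats so a write → read cycle is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
    "read_annotation",
    "write_annotation",
    "read_table",
    "write_table",
    "read_json",
    "write_json",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a feature × sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: set of member ids}``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line (need name + description): {line!r}")
            name = fields[0]
            members = {m for m in fields[2:] if m}
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, set[str] | list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival table with columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    df = df.set_index("sample_id")
    df.index.name = None
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
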