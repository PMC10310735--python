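"""Standard-format readers and writers.

Canonical matrix format is TSV with a header row of sample ids and feature
ids in the first column; missing values are written as ``NA`` (empty fields
are accepted on read). Gene sets use the GMT convention (name, description,
then members, tab-separated). Clinical tables are CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
import yaml


class FormatError(ValueError):
    """Malformed input file (message carries the offending line number)."""


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix.

    Duplicate feature identifiers are rejected: downstream joins key on the
    identifier and silent collapsing would corrupt them.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""],
        float_precision="round_trip",
    )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample identifier {dup!r}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file into ``{name: (description, members)}``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name, desc = parts[0], parts[1]
            members = [m for m in parts[2:] if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(members)) != len(members):
                raise FormatError(f"{path}:{lineno}: duplicate members in {name!r}")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for name, (desc, members) in sets.items():
            writer.writerow([name, desc, *members])


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical annotation CSV keyed by sample id."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample identifier {dup!r}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a key-value mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
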