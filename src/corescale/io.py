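"""Delimited-text readers and writers for the package's data types.

Trait matrices are tab- or comma-delimited with a header row; the first
column holds accession ids, the remaining columns one trait each.  Observed
datasets use a long format with columns
``environment,row,column,accession,trait,value``.  Parsers report the
offending line number on malformed input.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data import OBSERVED_COLUMNS, ObservedDataset, TraitMatrix

__all__ = ["read_trait_matrix", "write_trait_matrix",
           "read_observed", "write_observed"]


def _detect_sep(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_trait_matrix(path, sep: str | None = None) -> TraitMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header line and at least one row")
    if sep is None:
        sep = _detect_sep(lines[0])
    header = lines[0].split(sep)
    if len(header) < 2:
        raise ValueError(f"{path}: line 1: header needs an id column and "
                         "at least one trait")
    trait_names = [h.strip() for h in header[1:]]
    ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(sep)
        if len(parts) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(parts)} (ragged row)")
        ids.append(parts[0].strip())
        vals = []
        for col, cell in enumerate(parts[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}, field {col}: "
                    f"non-numeric value {cell.strip()!r}") from None
        rows.append(vals)
    seen = {}
    for k, a in enumerate(ids):
        if a in seen:
            raise ValueError(
                f"{path}: line {k + 2}: duplicate accession id {a!r} "
                f"(first seen on line {seen[a] + 2})")
        seen[a] = k
    return TraitMatrix(ids, trait_names, rows)


def write_trait_matrix(matrix: TraitMatrix, path, sep: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(("accession",) + matrix.trait_names) + "\n")
        for i, acc in enumerate(matrix.accession_ids):
            cells = [f"{v:.10g}" for v in matrix.values[i]]
            fh.write(sep.join([acc] + cells) + "\n")


def read_observed(path, layout=None, sep: str | None = None) -> ObservedDataset:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if sep is None:
        sep = _detect_sep(header)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["value"].isna().any():
        lineno = int(df.index[df["value"].isna()][0]) + 2
        raise ValueError(f"{path}: line {lineno}: missing value")
    if layout is None:
        layout = (int(df["row"].max()) + 1, int(df["column"].max()) + 1)
    return ObservedDataset(df, tuple(layout))


def write_observed(observed: ObservedDataset, path, sep: str = "\t") -> None:
    observed.records.to_csv(path, sep=sep, index=False,
                            float_format="%.10g")
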