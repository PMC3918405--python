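"""Core in-memory containers shared by every stage of the pipeline.

A :class:`TraitMatrix` holds genotypic values (accessions x quantitative
traits); an :class:`ObservedDataset` holds raw multi-environment field
records in long format.  Both are thin, validated wrappers so that file
I/O, simulation and statistics all speak the same types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

OBSERVED_COLUMNS = ("environment", "row", "column", "accession", "trait", "value")


@dataclass(frozen=True)
class TraitMatrix:
    """Genotypic values of a germplasm group.

    Parameters
    ----------
    accession_ids : sequence of str
        Unique accession identifiers, one per row.
    trait_names : sequence of str
        Unique trait identifiers, one per column.
    values : ndarray, shape (n_accessions, n_traits)
        Trait values in their original (trait-specific) units.
    """

    accession_ids: tuple
    trait_names: tuple
    values: np.ndarray

    def __init__(self, accession_ids: Sequence[str], trait_names: Sequence[str],
                 values) -> None:
        ids = tuple(str(a) for a in accession_ids)
        names = tuple(str(t) for t in trait_names)
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if vals.shape != (len(ids), len(names)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(ids)} accessions x {len(names)} traits")
        if len(ids) < 2:
            raise ValueError("a trait matrix needs at least 2 accessions")
        if len(names) < 1:
            raise ValueError("a trait matrix needs at least 1 trait")
        if len(set(ids)) != len(ids):
            raise ValueError("accession ids must be unique")
        if len(set(names)) != len(names):
            raise ValueError("trait names must be unique")
        if not np.all(np.isfinite(vals)):
            raise ValueError("trait values must be finite (no missing values)")
        object.__setattr__(self, "accession_ids", ids)
        object.__setattr__(self, "trait_names", names)
        object.__setattr__(self, "values", vals)
        self.values.setflags(write=False)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def index_of(self, accession_id: str) -> int:
        try:
            return self.accession_ids.index(accession_id)
        except ValueError:
            raise KeyError(f"unknown accession id: {accession_id!r}") from None

    def subset(self, accession_ids: Iterable[str]) -> "TraitMatrix":
        """Row subset in the order of the *original* matrix."""
        wanted = set(accession_ids)
        unknown = wanted - set(self.accession_ids)
        if unknown:
            raise KeyError(f"unknown accession ids: {sorted(unknown)}")
        keep = [i for i, a in enumerate(self.accession_ids) if a in wanted]
        return TraitMatrix([self.accession_ids[i] for i in keep],
                           self.trait_names, self.values[keep])

    def select_traits(self, traits: Sequence) -> "TraitMatrix":
        """Column subset by trait name or integer position (order preserved)."""
        idx = []
        for t in traits:
            if isinstance(t, (int, np.integer)):
                idx.append(int(t))
            else:
                idx.append(self.trait_names.index(t))
        return TraitMatrix(self.accession_ids,
                           [self.trait_names[i] for i in idx],
                           self.values[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.accession_ids),
                            columns=list(self.trait_names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


@dataclass(frozen=True)
class ObservedDataset:
    """Long-format field observations from a multi-environment trial.

    ``records`` has columns ``environment, row, column, accession, trait,
    value``.  Each *environment* label identifies one planting (a year x
    replication combination counts as its own environment label), so one
    field cell holds at most one accession and every accession is planted
    in every environment.
    """

    records: pd.DataFrame
    layout: tuple  # (n_rows, n_columns) per environment

    def __post_init__(self):
        df = self.records
        missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observed records missing columns: {missing}")
        object.__setattr__(self, "records", df[list(OBSERVED_COLUMNS)].copy())
        df = self.records
        cells = df[["environment", "row", "column", "accession"]].drop_duplicates()
        dup = cells.duplicated(subset=["environment", "row", "column"])
        if dup.any():
            bad = cells[dup].iloc[0]
            raise ValueError(
                "field cell occupied by more than one accession: "
                f"environment={bad['environment']} row={bad['row']} "
                f"column={bad['column']}")
        envs = df["environment"].unique()
        per_env = df.groupby("environment")["accession"].apply(set)
        all_acc = set(df["accession"])
        for env in envs:
            lacking = all_acc - per_env[env]
            if lacking:
                raise ValueError(
                    f"accessions missing from environment {env}: "
                    f"{sorted(lacking)[:5]}...")
        n_rows, n_cols = self.layout
        if df["row"].max() >= n_rows or df["column"].max() >= n_cols:
            raise ValueError("record row/column index outside the declared layout")

    @property
    def environments(self) -> tuple:
        return tuple(pd.unique(self.records["environment"]))

    @property
    def accessions(self) -> tuple:
        return tuple(pd.unique(self.records["accession"]))

    @property
    def traits(self) -> tuple:
        return tuple(pd.unique(self.records["trait"]))
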