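"""Genotypic-value adjustment from multi-environment field observations.

Fits, per trait, the additive fixed-effects model

    y = mu + environment + row(environment) + column(environment) + genotype

by ordinary least squares with sum-to-zero constraints on every factor, and
reports each accession's genotypic value as ``mu + genotype effect``.  This
deliberately simple fixed-effects adjustment fills the pipeline slot that a
mixed-model analysis (variance-component estimation plus random-effect
prediction) would occupy in a full field-trial workflow; users who prefer a
mixed-model prediction can supply their own genotypic matrix downstream.
GE interaction is not modelled separately — averaging over environments
removes its expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ObservedDataset, TraitMatrix

__all__ = ["AdjustmentResult", "adjust"]

METHOD_LABEL = "lsmeans-standin"


@dataclass(frozen=True)
class AdjustmentResult:
    genotypic: TraitMatrix
    effects: dict          # factor name -> DataFrame (level x trait)
    method_label: str


def _sum_to_zero_block(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (effects) coding: n_levels - 1 columns; the last level
    carries -1 in every column."""
    n = len(codes)
    X = np.zeros((n, n_levels - 1))
    lead = codes < n_levels - 1
    X[np.flatnonzero(lead), codes[lead]] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


def _nested_block(env: pd.Series, inner: pd.Series):
    """Sum-to-zero coding of a factor nested within environment: each
    environment's observed levels get their own sum-to-zero constraint.

    Returns (design columns, list of (environment, level) labels grouped
    per environment) where each environment contributes L_h - 1 columns."""
    n = len(env)
    cols, labels = [], []
    for e in pd.unique(env):
        mask = (env == e).to_numpy()
        levels = pd.unique(inner[mask])
        if len(levels) < 2:
            labels.append((e, list(levels)))
            continue
        code = {lv: i for i, lv in enumerate(levels)}
        block = np.zeros((n, len(levels) - 1))
        for i in np.flatnonzero(mask):
            c = code[inner.iloc[i]]
            if c < len(levels) - 1:
                block[i, c] = 1.0
            else:
                block[i, :] = -1.0
        cols.append(block)
        labels.append((e, list(levels)))
    X = np.hstack(cols) if cols else np.zeros((n, 0))
    return X, labels


def adjust(observed: ObservedDataset) -> AdjustmentResult:
    """Estimate genotypic values for every accession and trait.

    Factor levels are taken from the data (only planted rows/columns enter
    the model).  Raises if the design is rank-deficient beyond the declared
    sum-to-zero constraints, naming the factor that fails to add rank.
    """
    df = observed.records
    traits = list(pd.unique(df["trait"]))
    accessions = list(pd.unique(df["accession"]))

    wide = df.pivot_table(index=["environment", "row", "column", "accession"],
                          columns="trait", values="value", sort=False)
    wide = wide.reset_index()
    n_obs = len(wide)

    env = pd.Categorical(wide["environment"])
    geno = pd.Categorical(wide["accession"], categories=accessions)

    blocks = [("intercept", np.ones((n_obs, 1)), ["mu"])]
    if len(env.categories) >= 2:
        blocks.append(("environment",
                       _sum_to_zero_block(env.codes.astype(int),
                                          len(env.categories)),
                       list(env.categories)))
    row_X, row_labels = _nested_block(wide["environment"], wide["row"])
    if row_X.shape[1]:
        blocks.append(("row", row_X, row_labels))
    col_X, col_labels = _nested_block(wide["environment"], wide["column"])
    if col_X.shape[1]:
        blocks.append(("column", col_X, col_labels))
    blocks.append(("genotype",
                   _sum_to_zero_block(geno.codes.astype(int), len(accessions)),
                   accessions))

    X = np.hstack([b[1] for b in blocks])
    # incremental rank check names the confounded factor
    rank_so_far, col_count = 0, 0
    for name, B, _ in blocks:
        col_count += B.shape[1]
        r = np.linalg.matrix_rank(X[:, :col_count])
        if r < rank_so_far + B.shape[1]:
            raise ValueError(
                f"design is rank-deficient: factor '{name}' is confounded "
                "with preceding factors under sum-to-zero constraints")
        rank_so_far = r

    Y = wide[traits].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("observed data has missing trait values")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    # unpack per-factor effect tables (last level = -sum of the others,
    # per environment for the nested positional factors)
    effects = {}
    offset = 1
    mu_hat = beta[0]
    for name, B, levels in blocks[1:]:
        k = B.shape[1]
        bet = beta[offset:offset + k]
        if name in ("row", "column"):
            idx, parts, pos = [], [], 0
            for e, lvls in levels:
                L = len(lvls)
                idx.extend((e, lv) for lv in lvls)
                if L < 2:
                    parts.append(np.zeros((L, len(traits))))
                    continue
                sub = bet[pos:pos + L - 1]
                parts.append(np.vstack([sub, -sub.sum(axis=0, keepdims=True)]))
                pos += L - 1
            effects[name] = pd.DataFrame(
                np.vstack(parts), index=pd.MultiIndex.from_tuples(idx),
                columns=traits)
        else:
            eff = np.vstack([bet, -bet.sum(axis=0, keepdims=True)])
            effects[name] = pd.DataFrame(eff, index=levels, columns=traits)
        offset += k

    geno_eff = effects["genotype"].loc[accessions].to_numpy()
    genotypic = TraitMatrix(accessions, traits, mu_hat[None, :] + geno_eff)
    return AdjustmentResult(genotypic=genotypic, effects=effects,
                            method_label=METHOD_LABEL)
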