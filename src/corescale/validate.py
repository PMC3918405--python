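"""Validation of chosen sampling percentages: LDSS-vs-random comparison and
principal-component projection of core vs reserve accessions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import TraitMatrix
from .distance import standardize
from .evaluate import evaluate
from .sampling import ldss_sample, random_sample

__all__ = ["PCAProjection", "compare_treat_ck", "project_pca"]

RATIO_PARAMS = ("CR", "VR", "CR_max", "CR_min", "CR_mea")


@dataclass(frozen=True)
class PCAProjection:
    accession_ids: tuple
    scores: np.ndarray            # (n, 2)
    explained_percent: np.ndarray  # per component, percent of total variance
    core_flags: tuple             # bool per accession

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "accession": list(self.accession_ids),
            "pc1": self.scores[:, 0],
            "pc2": self.scores[:, 1],
            "core": ["core" if c else "reserve" for c in self.core_flags],
        })


def compare_treat_ck(matrix: TraitMatrix, percentages, seeds,
                     metric: str = "seuclid", alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Mean evaluation parameters of LDSS subsets (treat) vs completely
    random subsets (CK) at each sampling percentage, averaged over seeds.

    Returns a tidy table with one row per (percentage, method): the mean
    and standard deviation of each ratio parameter across seeds.
    """
    rows = []
    for p in percentages:
        per_method = {"treat": [], "CK": []}
        for s in seeds:
            treat = ldss_sample(matrix, p, metric=metric, seed=int(s))
            ck = random_sample(matrix, p, seed=int(s))
            per_method["treat"].append(evaluate(matrix, treat.selected, alpha))
            per_method["CK"].append(evaluate(matrix, ck.selected, alpha))
        for method, reports in per_method.items():
            row = {"percentage": float(p), "method": method,
                   "n_seeds": len(reports)}
            for name in RATIO_PARAMS:
                vals = [r.parameter(name) for r in reports
                        if r.parameter(name) is not None]
                row[name] = float(np.mean(vals)) if vals else float("nan")
                row[name + "_sd"] = (float(np.std(vals, ddof=1))
                                     if len(vals) > 1 else float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)


def project_pca(matrix: TraitMatrix, core_ids) -> PCAProjection:
    """Project all accessions onto the first two principal components of
    the standardized initial collection.

    Traits are z-scored first (correlation-scale PCA) because they carry
    heterogeneous units.  Component signs are fixed by making the largest-
    magnitude loading of each component positive, so the projection is
    deterministic.
    """
    if matrix.n_accessions < 3:
        raise ValueError("PCA projection needs at least 3 accessions")
    if matrix.n_traits < 2:
        raise ValueError("PCA projection needs at least 2 traits")
    z = standardize(matrix).values
    sv = np.linalg.svd(z - z.mean(axis=0), compute_uv=False)
    if sv[1] <= 1e-10 * sv[0]:
        raise ValueError("standardized collection has rank < 2")

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    for c in range(2):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] = -scores[:, c]
    core = set(core_ids)
    unknown = core - set(matrix.accession_ids)
    if unknown:
        raise KeyError(f"unknown core accession ids: {sorted(unknown)}")
    flags = tuple(a in core for a in matrix.accession_ids)
    return PCAProjection(matrix.accession_ids, scores,
                         100.0 * pca.explained_variance_ratio_, flags)
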