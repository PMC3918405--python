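"""Trait standardization, the six genetic distances, and UPGMA clustering.

Distances operate on a :class:`~corescale.data.TraitMatrix` and return a
condensed pairwise matrix.  Scale-dependent metrics (``seuclid``, ``mahal``)
take their per-trait variances / covariance from a *reference* matrix —
normally the initial collection — so that deleting accessions leaves the
remaining pairwise distances untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .data import TraitMatrix

METRICS = ("euclid", "seuclid", "mahal", "cityblock", "cosine", "correlation")

__all__ = ["METRICS", "StandardizationParams", "DistanceMatrix", "UPGMATree",
           "standardization_params", "standardize", "pairwise_distance",
           "upgma"]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-trait mean and sample (n-1) standard deviation of a reference
    collection."""
    trait_names: tuple
    means: np.ndarray
    sds: np.ndarray


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise distances in SciPy condensed form."""
    accession_ids: tuple
    condensed: np.ndarray
    metric: str

    def __post_init__(self):
        n = len(self.accession_ids)
        if self.condensed.shape != (n * (n - 1) // 2,):
            raise ValueError("condensed length does not match id count")
        if not np.all(np.isfinite(self.condensed)) or np.any(self.condensed < -1e-12):
            raise ValueError("distances must be finite and non-negative")

    def square(self) -> np.ndarray:
        return squareform(self.condensed)


@dataclass(frozen=True)
class UPGMATree:
    """Average-linkage merge history: (members_a, members_b, height) triples,
    heights non-decreasing."""
    accession_ids: tuple
    merges: tuple
    linkage_matrix: np.ndarray


def standardization_params(reference: TraitMatrix) -> StandardizationParams:
    means = reference.values.mean(axis=0)
    sds = reference.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(
            "zero-variance trait(s) cannot be standardized: "
            f"{[reference.trait_names[i] for i in zero]}")
    return StandardizationParams(reference.trait_names, means, sds)


def standardize(matrix: TraitMatrix,
                params: StandardizationParams | None = None) -> TraitMatrix:
    """Z-score the matrix against reference means/sds (its own by default)."""
    if params is None:
        params = standardization_params(matrix)
    if params.trait_names != matrix.trait_names:
        raise ValueError("standardization params cover different traits")
    z = (matrix.values - params.means) / params.sds
    return TraitMatrix(matrix.accession_ids, matrix.trait_names, z)


def pairwise_distance(matrix: TraitMatrix, metric: str,
                      reference: TraitMatrix | None = None) -> DistanceMatrix:
    """Condensed pairwise distances under one of the six metrics.

    euclid       root sum of squared trait differences
    seuclid      Euclidean on z-scores w.r.t. the reference's trait sds
    mahal        Mahalanobis with the reference covariance (pseudo-inverse
                 when singular)
    cityblock    sum of absolute differences
    cosine       1 - cosine similarity of the trait vectors
    correlation  1 - Pearson correlation of the trait vectors
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = matrix.values
    ref = matrix if reference is None else reference
    if metric in ("mahal", "correlation") and matrix.n_traits < 2:
        raise ValueError(f"metric {metric!r} requires at least 2 traits")
    if metric == "euclid":
        d = pdist(X, "euclidean")
    elif metric == "cityblock":
        d = pdist(X, "cityblock")
    elif metric == "seuclid":
        sds = standardization_params(ref).sds
        d = pdist(X, "seuclidean", V=sds ** 2)
    elif metric == "mahal":
        cov = np.cov(ref.values, rowvar=False, ddof=1)
        try:
            VI = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            VI = np.linalg.pinv(cov)
        d = pdist(X, "mahalanobis", VI=VI)
        d = np.abs(d)  # guard tiny negative round-off under pinv
    elif metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(
                "cosine distance undefined for zero-norm accession(s): "
                f"{[matrix.accession_ids[i] for i in bad]}")
        d = pdist(X, "cosine")
    elif metric == "correlation":
        sds = X.std(axis=1)
        bad = np.flatnonzero(sds == 0)
        if bad.size:
            raise ValueError(
                "correlation distance undefined for constant accession(s): "
                f"{[matrix.accession_ids[i] for i in bad]}")
        d = pdist(X, "correlation")
    d = np.maximum(d, 0.0)
    return DistanceMatrix(matrix.accession_ids, d, metric)


def upgma(d: DistanceMatrix) -> UPGMATree:
    """Classic unweighted pair-group average agglomeration."""
    Z = linkage(d.condensed, method="average")
    n = len(d.accession_ids)
    members = {i: frozenset([d.accession_ids[i]]) for i in range(n)}
    merges = []
    for step, (a, b, height, _) in enumerate(Z):
        a, b = int(a), int(b)
        merges.append((members[a], members[b], float(height)))
        members[n + step] = members[a] | members[b]
    return UPGMATree(d.accession_ids, tuple(merges), Z)
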