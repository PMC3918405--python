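"""Least distance stepwise sampling (LDSS) and the random control sampler.

LDSS builds a subset by repeatedly locating the globally closest pair of
remaining accessions, keeping one member at random and discarding the
other, until the subset has shrunk to the target sampling percentage.
Because the closest pair is exactly the first merge of a UPGMA tree, the
procedure is insensitive to the clustering method while aggressively
removing redundant (near-duplicate) accessions.

Sampling runs on the standardized collection; evaluation downstream uses
the original (unstandardized) trait values of the selected ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TraitMatrix
from .distance import METRICS, pairwise_distance, standardize

__all__ = ["SubcoreResult", "target_count", "ldss_sample", "random_sample"]


@dataclass(frozen=True)
class SubcoreResult:
    """Outcome of one subset construction.

    ``trace`` records, per removal step, ``(removed_id, kept_id, distance)``
    where ``distance`` is the least pairwise distance at that step.
    """
    selected: tuple
    sampling_percentage: float
    metric: str
    seed: int
    trace: tuple


def target_count(n_accessions: int, percentage: float) -> int:
    """Subset size: percentage of N rounded half away from zero, floored
    at 2 (a one-accession 'collection' has no range or variance)."""
    if not (0 < percentage <= 100):
        raise ValueError("sampling percentage must be in (0, 100]")
    return max(2, int(np.floor(n_accessions * percentage / 100.0 + 0.5)))


def _condensed_square(matrix: TraitMatrix, metric: str) -> np.ndarray:
    z = standardize(matrix)
    d = pairwise_distance(z, metric, reference=z)
    return d.square()


def ldss_sample(matrix: TraitMatrix, percentage: float,
                metric: str = "seuclid", seed: int = 0,
                reestimate: bool = False) -> SubcoreResult:
    """Construct a subcore by least distance stepwise sampling.

    Parameters
    ----------
    matrix : TraitMatrix
        The initial collection (unstandardized values).
    percentage : float
        Target subset size as percent of the initial collection.
    metric : str
        One of ``corescale.distance.METRICS``.
    seed : int
        Seeds the keep-vs-remove coin flip at each step.
    reestimate : bool
        Re-standardize and recompute distances on the surviving accessions
        after every removal instead of holding the initial collection as
        the fixed reference.  Slower; default off.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    n = matrix.n_accessions
    m = target_count(n, percentage)
    rng = np.random.default_rng(seed)
    ids = matrix.accession_ids

    active = np.ones(n, dtype=bool)
    trace = []
    if not reestimate:
        W = _condensed_square(matrix, metric)
        W = W.astype(float, copy=True)
        # search only the strict upper triangle of active rows/columns
        W[np.tril_indices(n)] = np.inf
        while active.sum() > m:
            flat = int(np.argmin(W))
            i, j = np.unravel_index(flat, W.shape)
            dist = W[i, j]
            keep, drop = (i, j) if rng.random() < 0.5 else (j, i)
            trace.append((ids[drop], ids[keep], float(dist)))
            active[drop] = False
            W[drop, :] = np.inf
            W[:, drop] = np.inf
    else:
        while active.sum() > m:
            live = np.flatnonzero(active)
            sub = matrix.subset([ids[i] for i in live])
            S = _condensed_square(sub, metric)
            S[np.tril_indices(len(live))] = np.inf
            flat = int(np.argmin(S))
            a, b = np.unravel_index(flat, S.shape)
            i, j = live[a], live[b]
            dist = S[a, b]
            keep, drop = (i, j) if rng.random() < 0.5 else (j, i)
            trace.append((ids[drop], ids[keep], float(dist)))
            active[drop] = False

    selected = tuple(ids[i] for i in np.flatnonzero(active))
    return SubcoreResult(selected, float(percentage), metric, int(seed),
                         tuple(trace))


def random_sample(matrix: TraitMatrix, percentage: float,
                  seed: int = 0) -> SubcoreResult:
    """Completely random control subset (CK) of the same target size."""
    n = matrix.n_accessions
    m = target_count(n, percentage)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=m, replace=False))
    selected = tuple(matrix.accession_ids[i] for i in keep)
    return SubcoreResult(selected, float(percentage), "random", int(seed),
                         tuple())
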