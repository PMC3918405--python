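"""Monte Carlo simulation of an evaluation parameter over the
(sampling percentage x trait count) grid.

Each replication draws one random trait order; the trait subset for count
``k`` is the first ``k`` traits of that order, so subsets are nested within
a replication and the trait effect is homogenized across replications.  For
every (trait count, percentage) cell an LDSS subcore is constructed and the
chosen evaluation parameter computed; the surface holds the per-cell mean
over replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TraitMatrix
from .distance import METRICS
from .evaluate import PARAMETERS, evaluate
from .sampling import ldss_sample, target_count

__all__ = ["SurfaceConfig", "CRSurface", "simulate_surface"]


@dataclass(frozen=True)
class SurfaceConfig:
    """Simulation design. Defaults follow the reference design: sampling
    percentages 10-30% in 1% steps, trait counts 1-20, 20 replications,
    standardized Euclidean distance, CR as the response."""
    percentages: tuple = tuple(range(10, 31))
    trait_counts: tuple = tuple(range(1, 21))
    replications: int = 20
    metric: str = "seuclid"
    parameter: str = "CR"
    base_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "percentages", tuple(float(p) for p in self.percentages))
        object.__setattr__(self, "trait_counts", tuple(int(k) for k in self.trait_counts))
        if not self.percentages or not self.trait_counts:
            raise ValueError("grids must be non-empty")
        if list(self.percentages) != sorted(self.percentages):
            raise ValueError("percentage grid must be sorted ascending")
        if list(self.trait_counts) != sorted(self.trait_counts):
            raise ValueError("trait-count grid must be sorted ascending")
        if self.replications < 1:
            raise ValueError("need at least 1 replication")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown evaluation parameter {self.parameter!r}")

    @property
    def n_cells(self) -> int:
        return len(self.percentages) * len(self.trait_counts)


@dataclass(frozen=True)
class CRSurface:
    """Mean parameter values indexed by (trait count, sampling percentage),
    with all replicate values retained."""
    config: SurfaceConfig
    means: np.ndarray        # (n_trait_counts, n_percentages)
    replicates: np.ndarray   # (replications, n_trait_counts, n_percentages)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=list(self.config.trait_counts),
                            columns=list(self.config.percentages))

    def long_replicates(self) -> pd.DataFrame:
        reps, ks, ps = self.replicates.shape
        rep_i, k_i, p_i = np.meshgrid(np.arange(reps), np.arange(ks),
                                      np.arange(ps), indexing="ij")
        return pd.DataFrame({
            "replication": rep_i.ravel() + 1,
            "trait_count": np.array(self.config.trait_counts)[k_i.ravel()],
            "percentage": np.array(self.config.percentages)[p_i.ravel()],
            "value": self.replicates.ravel(),
        })


def _cell_seed(base_seed: int, rep: int, k: int, p_index: int) -> int:
    """Deterministic, order-independent seed for one (rep, k, p) cell."""
    ss = np.random.SeedSequence(entropy=int(base_seed),
                                spawn_key=(rep, k, p_index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_surface(matrix: TraitMatrix, config: SurfaceConfig) -> CRSurface:
    """Run the full Monte Carlo design and return the response surface."""
    if max(config.trait_counts) > matrix.n_traits:
        raise ValueError("trait-count grid exceeds the number of traits")
    n = matrix.n_accessions
    for p in config.percentages:
        target_count(n, p)  # raises on infeasible percentages before any work

    reps = config.replications
    out = np.empty((reps, len(config.trait_counts), len(config.percentages)))
    for rep in range(reps):
        rng = np.random.default_rng(int(config.base_seed) + rep)
        perm = rng.permutation(matrix.n_traits)
        for ki, k in enumerate(config.trait_counts):
            sub = matrix.select_traits(perm[:k])
            for pi, p in enumerate(config.percentages):
                res = ldss_sample(sub, p, metric=config.metric,
                                  seed=_cell_seed(config.base_seed, rep, k, pi))
                report = evaluate(sub, res.selected)
                value = report.parameter(config.parameter)
                if value is None:
                    raise ValueError(
                        f"parameter {config.parameter} undefined in cell "
                        f"(k={k}, p={p}, rep={rep})")
                out[rep, ki, pi] = value
    return CRSurface(config=config, means=out.mean(axis=0), replicates=out)
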