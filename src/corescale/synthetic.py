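"""Synthetic multi-environment germplasm trial generator.

Emulates a genebank field trial in which each observed trait value is the
sum of a population mean, a fixed environment effect, fixed row and column
effects nested within the environment, a random genotypic effect, a random
genotype-by-environment (GE) interaction and a residual:

    Y = mu + E_h + R_i(h) + C_j(h) + G_k + GE_hk + eps

Genotypic effects are drawn once per accession as a correlated multivariate
normal across traits; GE is drawn per (accession, year); the residual per
record.  A configurable fraction of accessions are near-duplicates of
earlier ones, because the downstream sampling algorithm exists precisely
to remove such redundancy.

The default configuration mirrors a published cotton genebank trial:
168 accessions, 20 quantitative traits, 2 years with 2 replications per
year, each planting laid out on 6 rows x 80 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import ObservedDataset, TraitMatrix

__all__ = ["SyntheticConfig", "generate", "plant_layout"]


def _default_mu(n_traits: int) -> np.ndarray:
    # heterogeneous positive scales, like a mix of heights (cm),
    # percentages and weights (g)
    return np.linspace(10.0, 150.0, n_traits)


def _ar1_correlation(n: int, rho: float = 0.3) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SyntheticConfig:
    """Parameters of the simulated trial.

    Variance components (``var_G``, ``var_GE``, ``var_eps``) and fixed-effect
    magnitudes (``env_sd``, ``row_sd``, ``col_sd``) are per-trait vectors in
    squared / plain trait units; scalars broadcast.  ``redundancy_fraction``
    of the accessions are copies of a distinct donor's genotypic vector plus
    Gaussian jitter of sd ``redundancy_jitter`` (in units of each trait's
    genotypic sd).
    """

    n_accessions: int = 168
    n_traits: int = 20
    n_environments: int = 2          # years
    n_replications: int = 2          # plantings per year
    n_rows: int = 6
    n_columns: int = 80
    mu: Optional[np.ndarray] = None
    var_G: object = None             # defaults to (0.12 * mu)**2
    var_GE: object = None            # defaults to (0.05 * mu)**2
    var_eps: object = None           # defaults to (0.08 * mu)**2
    env_sd: object = None            # defaults to 0.05 * mu
    row_sd: object = None            # defaults to 0.02 * mu
    col_sd: object = None            # defaults to 0.02 * mu
    trait_correlation: Optional[np.ndarray] = None
    redundancy_fraction: float = 0.3
    redundancy_jitter: float = 0.0
    separate_replication_randomization: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mu is None:
            self.mu = _default_mu(self.n_traits)
        self.mu = np.broadcast_to(np.asarray(self.mu, float),
                                  (self.n_traits,)).copy()
        def vec(x, default):
            v = default if x is None else np.asarray(x, float)
            return np.broadcast_to(v, (self.n_traits,)).copy()
        self.var_G = vec(self.var_G, (0.12 * self.mu) ** 2)
        self.var_GE = vec(self.var_GE, (0.05 * self.mu) ** 2)
        self.var_eps = vec(self.var_eps, (0.08 * self.mu) ** 2)
        self.env_sd = vec(self.env_sd, 0.05 * np.abs(self.mu))
        self.row_sd = vec(self.row_sd, 0.02 * np.abs(self.mu))
        self.col_sd = vec(self.col_sd, 0.02 * np.abs(self.mu))
        if self.trait_correlation is None:
            self.trait_correlation = _ar1_correlation(self.n_traits)
        self.trait_correlation = np.asarray(self.trait_correlation, float)
        self._validate()

    def _validate(self):
        for name in ("var_G", "var_GE", "var_eps"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        C = self.trait_correlation
        if C.shape != (self.n_traits, self.n_traits):
            raise ValueError("trait_correlation has the wrong shape")
        if not np.allclose(C, C.T):
            raise ValueError("trait_correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("trait_correlation must have unit diagonal")
        eig = np.linalg.eigvalsh(C)
        if eig.min() < -1e-10:
            raise ValueError("trait_correlation must be positive semidefinite")
        if not (0.0 <= self.redundancy_fraction < 1.0):
            raise ValueError("redundancy_fraction must be in [0, 1)")
        if self.n_accessions > self.n_rows * self.n_columns:
            raise ValueError(
                f"{self.n_accessions} accessions do not fit a "
                f"{self.n_rows} x {self.n_columns} layout")

    @property
    def accession_ids(self):
        width = len(str(self.n_accessions))
        return [f"A{k + 1:0{width}d}" for k in range(self.n_accessions)]

    @property
    def trait_labels(self):
        return [f"T{t + 1:02d}" for t in range(self.n_traits)]


def plant_layout(config: SyntheticConfig, rng=None):
    """Assign accessions to (environment label, row, column) field cells.

    Each planting (year x replication) gets its own seeded random
    permutation of the field cells; when
    ``separate_replication_randomization`` is off, the two replications
    of a year share one randomization.

    Returns a DataFrame with columns environment, row, column, accession.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cells = config.n_rows * config.n_columns
    if config.n_accessions > cells:
        raise ValueError("field overflow: more accessions than cells")
    frames = []
    for h in range(config.n_environments):
        shared = rng.permutation(cells)[: config.n_accessions]
        for r in range(config.n_replications):
            if config.separate_replication_randomization and r > 0:
                pos = rng.permutation(cells)[: config.n_accessions]
            else:
                pos = shared
            frames.append(pd.DataFrame({
                "environment": f"Y{h + 1}R{r + 1}",
                "row": pos // config.n_columns,
                "column": pos % config.n_columns,
                "accession": config.accession_ids,
            }))
    return pd.concat(frames, ignore_index=True)


def _genotypic_effects(config: SyntheticConfig, rng) -> np.ndarray:
    """Correlated genotypic deviations G (n_accessions x n_traits),
    with the trailing ``redundancy_fraction`` of accessions duplicated
    from donors among the leading distinct ones."""
    n, t = config.n_accessions, config.n_traits
    L = np.linalg.cholesky(config.trait_correlation +
                           1e-12 * np.eye(t))
    sd = np.sqrt(config.var_G)
    n_red = int(round(config.redundancy_fraction * n))
    n_distinct = n - n_red
    Z = rng.standard_normal((n_distinct, t))
    G = np.empty((n, t))
    G[:n_distinct] = (Z @ L.T) * sd
    if n_red:
        donors = rng.integers(0, n_distinct, size=n_red)
        jitter = config.redundancy_jitter * sd * rng.standard_normal((n_red, t))
        G[n_distinct:] = G[donors] + jitter
    return G


def generate(config: SyntheticConfig):
    """Simulate the trial.

    Returns
    -------
    observed : ObservedDataset
        One record per (environment label, accession, trait).
    truth : TraitMatrix
        The true genotypic values mu + G, the oracle for downstream tests.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_accessions, config.n_traits
    H, R = config.n_environments, config.n_replications

    G = _genotypic_effects(config, rng)
    truth = TraitMatrix(config.accession_ids, config.trait_labels,
                        config.mu + G)

    # fixed effects, centered exactly so the decomposition is identified
    def centered(shape, sd):
        x = rng.standard_normal(shape) * sd
        return x - x.mean(axis=0, keepdims=True)

    env_eff = centered((H, t), config.env_sd)               # per year
    row_eff = np.stack([centered((config.n_rows, t), config.row_sd)
                        for _ in range(H)])                  # (H, rows, t)
    col_eff = np.stack([centered((config.n_columns, t), config.col_sd)
                        for _ in range(H)])                  # (H, cols, t)
    ge = rng.standard_normal((H, n, t)) * np.sqrt(config.var_GE)

    layout = plant_layout(config, rng)
    acc_index = {a: k for k, a in enumerate(config.accession_ids)}

    frames = []
    for (env_label, sub) in layout.groupby("environment", sort=False):
        h = int(env_label[1:env_label.index("R")]) - 1
        rows = sub["row"].to_numpy()
        cols = sub["column"].to_numpy()
        accs = sub["accession"].to_numpy()
        k_idx = np.array([acc_index[a] for a in accs])
        eps = rng.standard_normal((len(sub), t)) * np.sqrt(config.var_eps)
        vals = (config.mu[None, :] + env_eff[h][None, :]
                + row_eff[h][rows] + col_eff[h][cols]
                + G[k_idx] + ge[h, k_idx] + eps)
        frames.append(pd.DataFrame({
            "environment": np.repeat(env_label, len(sub) * t),
            "row": np.repeat(rows, t),
            "column": np.repeat(cols, t),
            "accession": np.repeat(accs, t),
            "trait": np.tile(config.trait_labels, len(sub)),
            "value": vals.ravel(),
        }))
    records = pd.concat(frames, ignore_index=True)
    observed = ObservedDataset(records, (config.n_rows, config.n_columns))
    return observed, truth
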