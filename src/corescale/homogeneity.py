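"""Validity assessment of evaluation parameters by homogeneous-population
counting.

For one evaluation parameter measured at several sampling percentages with
replication: run a one-way ANOVA, test all pairs with the Tukey-Kramer
procedure, render the result as a compact letter display (CLD), and count
the distinct letters.  Two percentages share a letter exactly when their
difference is not significant, so the letter count — the "number of
homogeneous populations" — measures how many percentage levels the
parameter can tell apart: the larger the count, the more discriminating
(valid) the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_lowercase

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupedValues", "LetterDisplay", "tukey_groups",
           "assess_validity", "replication_design"]


@dataclass(frozen=True)
class GroupedValues:
    """Replicate values of one evaluation parameter per group label."""
    labels: tuple
    values: tuple  # tuple of 1-D arrays, aligned with labels

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("need at least 2 groups")
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values misaligned")
        for lab, v in zip(self.labels, self.values):
            if len(v) < 2:
                raise ValueError(
                    f"group {lab!r} has fewer than 2 replicates; "
                    "ANOVA needs replication")


@dataclass(frozen=True)
class LetterDisplay:
    labels: tuple
    letters: tuple                     # letter string per group, e.g. "ab"
    homogeneous_population_count: int
    anova_p: float


def _significance_matrix(groups: GroupedValues, alpha: float) -> np.ndarray:
    samples = [np.asarray(v, float) for v in groups.values]
    pooled_var = np.mean([s.var(ddof=1) for s in samples])
    means = np.array([s.mean() for s in samples])
    if pooled_var == 0:
        # no within-group noise: any mean difference separates perfectly
        sig = np.abs(means[:, None] - means[None, :]) > 0
        return sig
    res = stats.tukey_hsd(*samples)
    return res.pvalue < alpha


def tukey_groups(groups: GroupedValues, alpha: float = 0.05) -> LetterDisplay:
    """Tukey-Kramer all-pairs comparison rendered as a compact letter display.

    Letters correspond to the maximal cliques of the non-significance
    graph, so two groups share a letter iff their comparison is
    non-significant at ``alpha``.  Letters are assigned alphabetically
    with groups ordered by descending mean.
    """
    samples = [np.asarray(v, float) for v in groups.values]
    k = len(samples)
    flat = np.concatenate(samples)
    if np.ptp(flat) == 0:
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*samples).pvalue)
    sig = _significance_matrix(groups, alpha)

    order = np.argsort([-s.mean() for s in samples], kind="stable")
    G = nx.Graph()
    G.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                G.add_edge(i, j)
    cliques = [frozenset(c) for c in nx.find_cliques(G)]
    # letter order follows the highest-mean member of each clique
    rank = {g: r for r, g in enumerate(order)}
    cliques.sort(key=lambda c: sorted(rank[g] for g in c))
    if len(cliques) > len(ascii_lowercase):
        raise ValueError("more letter groups than available letters")

    letters = []
    for g in range(k):
        mine = [ascii_lowercase[ci] for ci, c in enumerate(cliques) if g in c]
        letters.append("".join(mine))
    return LetterDisplay(tuple(groups.labels), tuple(letters),
                         len(cliques), anova_p)


def replication_design(start: float = 10.0, stop: float = 30.0,
                       step: float = 1.0, replications: int = 4):
    """Enumerate the (sampling percentage, replicate) construction grid.

    The default — 10% to 30% in 1% steps with 4 replications — yields 84
    subcore constructions per genetic distance.
    """
    n_steps = int(round((stop - start) / step)) + 1
    percentages = [start + i * step for i in range(n_steps)]
    return [(p, r) for p in percentages for r in range(1, replications + 1)]


def assess_validity(surfaces: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Homogeneous-population counts for each (metric, parameter) cell.

    Parameters
    ----------
    surfaces : dict
        ``(metric, parameter) -> GroupedValues`` with groups = sampling
        percentages.  The grid must be complete over the crossed metric
        and parameter labels.

    Returns a parameters x metrics table of counts plus a ``Total`` row.
    """
    metrics = list(dict.fromkeys(m for m, _ in surfaces))
    params = list(dict.fromkeys(p for _, p in surfaces))
    missing = [(m, p) for m in metrics for p in params
               if (m, p) not in surfaces]
    if missing:
        raise ValueError(f"missing (metric, parameter) cells: {missing}")
    table = pd.DataFrame(index=params, columns=metrics, dtype=float)
    for (m, p), grouped in surfaces.items():
        table.loc[p, m] = tukey_groups(grouped, alpha).homogeneous_population_count
    table.loc["Total"] = table.sum(axis=0)
    return table.astype(int)
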