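"""Tukey multiple comparison, compact letter display, validity counting."""

import itertools

import numpy as np
import pytest
from scipy import stats

from corescale import (GroupedValues, assess_validity, replication_design,
                       tukey_groups)


def _grouped(means, sd, n, seed):
    rng = np.random.default_rng(seed)
    return GroupedValues(tuple(str(m) for m in means),
                         tuple(rng.normal(m, sd, n) for m in means))


def brute_force_letter_count(samples, alpha=0.05):
    """Minimum number of letters: enumerate candidate cliques of the
    non-significance graph, then search for the smallest cover such that
    two groups share a clique iff they are non-significant."""
    k = len(samples)
    pooled = np.mean([np.asarray(s).var(ddof=1) for s in samples])
    if pooled == 0:
        m = [np.mean(s) for s in samples]
        nonsig = {(i, j) for i in range(k) for j in range(i + 1, k)
                  if m[i] == m[j]}
    else:
        p = stats.tukey_hsd(*samples).pvalue
        nonsig = {(i, j) for i in range(k) for j in range(i + 1, k)
                  if p[i, j] >= alpha}

    def is_clique(sub):
        return all((min(a, b), max(a, b)) in nonsig
                   for a, b in itertools.combinations(sub, 2))

    cliques = [frozenset(sub) for r in range(1, k + 1)
               for sub in itertools.combinations(range(k), r)
               if is_clique(sub)]
    for size in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, size):
            covered_edges = {(min(a, b), max(a, b))
                             for c in combo
                             for a, b in itertools.combinations(sorted(c), 2)}
            covered_nodes = set().union(*combo)
            if covered_nodes == set(range(k)) and covered_edges == nonsig:
                return size
    raise AssertionError("no valid letter cover found")


def test_identical_groups_share_one_letter():
    g = _grouped([50, 50, 50], sd=1.0, n=4, seed=0)
    ld = tukey_groups(g)
    assert ld.homogeneous_population_count == 1
    assert len(set(ld.letters)) == 1


def test_three_separated_groups_get_three_letters():
    g = _grouped([0, 100, 200], sd=0.01, n=4, seed=1)
    ld = tukey_groups(g)
    assert ld.homogeneous_population_count == 3
    # letters follow descending means: the mean-200 group is 'a'
    assert dict(zip(g.labels, ld.letters)) == {"0": "c", "100": "b",
                                               "200": "a"}


def test_count_equals_index_of_largest_letter():
    g = _grouped([0, 5, 100, 200], sd=2.0, n=4, seed=2)
    ld = tukey_groups(g)
    largest = max(letter for group in ld.letters for letter in group)
    assert ld.homogeneous_population_count == ord(largest) - ord("a") + 1


def test_zero_variance_equal_means_is_single_letter():
    g = GroupedValues(("a", "b"), (np.full(4, 7.0), np.full(4, 7.0)))
    assert tukey_groups(g).homogeneous_population_count == 1


def test_single_replicate_group_rejected():
    with pytest.raises(ValueError, match="replicate"):
        GroupedValues(("a", "b"), (np.array([1.0]), np.array([1.0, 2.0])))


def test_letter_blocks_are_contiguous_over_sorted_means():
    rng = np.random.default_rng(9)
    for _ in range(30):
        k = int(rng.integers(3, 7))
        means = rng.uniform(0, 30, k)
        g = GroupedValues(tuple(f"g{i}" for i in range(k)),
                          tuple(rng.normal(m, 2.0, 4) for m in means))
        ld = tukey_groups(g)
        order = np.argsort([-np.mean(v) for v in g.values])
        for letter in set("".join(ld.letters)):
            pos = [r for r, gi in enumerate(order)
                   if letter in ld.letters[gi]]
            assert pos == list(range(min(pos), max(pos) + 1))


def test_letter_count_matches_brute_force_cover():
    rng = np.random.default_rng(4)
    for _ in range(40):
        k = int(rng.integers(2, 7))
        means = rng.uniform(0, 12, k)
        samples = tuple(rng.normal(m, 2.0, 4) for m in means)
        g = GroupedValues(tuple(f"g{i}" for i in range(k)), samples)
        assert tukey_groups(g).homogeneous_population_count == \
            brute_force_letter_count(samples)


def test_replication_design_enumerates_the_grid():
    design = replication_design()
    assert len(design) == 84  # 21 percentages x 4 replications
    assert design[0] == (10.0, 1) and design[-1] == (30.0, 4)


def test_assess_validity_bookkeeping():
    rng = np.random.default_rng(6)
    surfaces = {}
    for metric in ("euclid", "seuclid"):
        for par, spread in (("CR", 30.0), ("MD", 0.0)):
            means = [50 + spread * i for i in range(3)]
            surfaces[(metric, par)] = GroupedValues(
                ("10", "20", "30"),
                tuple(rng.normal(m, 1.0, 4) for m in means))
    table = assess_validity(surfaces)
    assert table.loc["MD", "euclid"] == 1  # constant parameter
    assert (table.loc["Total"] ==
            table.drop(index="Total").sum(axis=0)).all()
    with pytest.raises(ValueError, match="missing"):
        assess_validity({("euclid", "CR"): surfaces[("euclid", "CR")],
                         ("seuclid", "MD"): surfaces[("seuclid", "MD")]})
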