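"""Standardization, the six genetic distances, and UPGMA."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from corescale import (METRICS, TraitMatrix, pairwise_distance,
                       standardization_params, standardize, upgma)
from conftest import random_matrix


def test_standardize_self_gives_zero_mean_unit_sd(small_matrix):
    z = standardize(small_matrix)
    np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_standardize_is_shift_invariant(small_matrix):
    shifted = TraitMatrix(small_matrix.accession_ids,
                          small_matrix.trait_names,
                          small_matrix.values + 7.5)
    np.testing.assert_allclose(standardize(shifted).values,
                               standardize(small_matrix).values, atol=1e-10)


def test_standardize_arithmetic_and_zero_variance_error():
    m = TraitMatrix(["a", "b", "c"], ["t"], [[0.0], [4.0], [8.0]])
    z = standardize(m)  # mean 4, sd 4
    assert z.values[2, 0] == pytest.approx(1.0)
    m2 = TraitMatrix(["a", "b"], ["flat"], [[1.0], [1.0]])
    with pytest.raises(ValueError, match="flat"):
        standardize(m2)


def test_euclid_and_cityblock_arithmetic():
    m = TraitMatrix(["a", "b"], ["x", "y"], [[0.0, 0.0], [3.0, 4.0]])
    assert pairwise_distance(m, "euclid").condensed[0] == pytest.approx(5.0)
    assert pairwise_distance(m, "cityblock").condensed[0] == pytest.approx(7.0)


@pytest.mark.parametrize("metric", METRICS)
def test_identical_rows_are_at_distance_zero(metric):
    rng = np.random.default_rng(1)
    row = rng.normal(10, 3, 5)
    vals = np.vstack([row, row, rng.normal(10, 3, 5)])
    m = TraitMatrix(["a", "b", "c"], [f"t{j}" for j in range(5)], vals)
    d = pairwise_distance(m, metric).square()
    assert d[0, 1] == pytest.approx(0.0, abs=1e-10)


def test_mahalanobis_with_identity_covariance_equals_euclid():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 3))
    Xc = X - X.mean(axis=0)
    white = Xc @ np.linalg.inv(np.linalg.cholesky(np.cov(Xc, rowvar=False))).T
    m = TraitMatrix([f"a{i}" for i in range(20)], ["x", "y", "z"], white)
    np.testing.assert_allclose(pairwise_distance(m, "mahal").condensed,
                               pairwise_distance(m, "euclid").condensed,
                               atol=1e-8)


def test_seuclid_equals_euclid_on_zscores(small_matrix):
    params = standardization_params(small_matrix)
    z = standardize(small_matrix, params)
    np.testing.assert_allclose(
        pairwise_distance(small_matrix, "seuclid").condensed,
        pairwise_distance(z, "euclid").condensed, atol=1e-10)


@pytest.mark.parametrize("metric", ["euclid", "seuclid", "cityblock"])
def test_deleting_an_accession_leaves_a_submatrix(small_matrix, metric):
    full = squareform(pairwise_distance(small_matrix, metric,
                                        reference=small_matrix).condensed)
    keep = [a for a in small_matrix.accession_ids if a != "a5"]
    sub = pairwise_distance(small_matrix.subset(keep), metric,
                            reference=small_matrix)
    idx = [small_matrix.index_of(a) for a in keep]
    np.testing.assert_allclose(squareform(sub.condensed),
                               full[np.ix_(idx, idx)], atol=1e-12)


def test_metric_preconditions():
    one_trait = TraitMatrix(["a", "b", "c"], ["t"], [[1.0], [2.0], [4.0]])
    for metric in ("mahal", "correlation"):
        with pytest.raises(ValueError, match="2 traits"):
            pairwise_distance(one_trait, metric)
    with_zero = TraitMatrix(["a", "b"], ["x", "y"], [[0.0, 0.0], [1.0, 2.0]])
    with pytest.raises(ValueError, match="zero-norm"):
        pairwise_distance(with_zero, "cosine")
    constant_row = TraitMatrix(["a", "b"], ["x", "y"], [[3.0, 3.0], [1.0, 2.0]])
    with pytest.raises(ValueError, match="constant"):
        pairwise_distance(constant_row, "correlation")


def test_upgma_hand_agglomeration():
    # three points with pairwise distances (1, 5.5, 4.5): first merge at 1,
    # second at the average height 5
    from corescale import DistanceMatrix
    d = DistanceMatrix(("a", "b", "c"), np.array([1.0, 5.5, 4.5]), "euclid")
    tree = upgma(d)
    first_a, first_b, h1 = tree.merges[0]
    assert {first_a, first_b} == {frozenset({"a"}), frozenset({"b"})}
    assert h1 == pytest.approx(1.0)
    assert tree.merges[1][2] == pytest.approx((5.5 + 4.5) / 2)


def test_upgma_equal_distances_give_equal_heights():
    from corescale import DistanceMatrix
    n = 5
    d = DistanceMatrix(tuple(f"a{i}" for i in range(n)),
                       np.full(n * (n - 1) // 2, 3.0), "euclid")
    tree = upgma(d)
    heights = [m[2] for m in tree.merges]
    np.testing.assert_allclose(heights, 3.0)


def test_upgma_first_merge_is_global_minimum_and_heights_monotone():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(4, 13)
        m = random_matrix(rng, int(n), 3)
        d = pairwise_distance(m, "euclid")
        tree = upgma(d)
        # brute force closest pair
        sq = d.square() + np.diag(np.full(int(n), np.inf))
        i, j = np.unravel_index(np.argmin(sq), sq.shape)
        assert {tree.merges[0][0], tree.merges[0][1]} == {
            frozenset({m.accession_ids[i]}), frozenset({m.accession_ids[j]})}
        heights = [mg[2] for mg in tree.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        assert tree.merges[-1][0] | tree.merges[-1][1] == \
            frozenset(m.accession_ids)
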