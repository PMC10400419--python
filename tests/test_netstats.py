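import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mindnet import (
    DensityCurve,
    ParcellationScheme,
    SimilarityNetwork,
    between_subject_consistency,
    grouped_edge_fraction,
    interpolate_to_parent,
    threshold_top_density,
    vertex_projected_degree_correlation,
    weighted_degree,
)


def net_from_offdiag(pairs: dict, R: int, ids=None) -> SimilarityNetwork:
    W = np.eye(R)
    for (i, j), w in pairs.items():
        W[i, j] = W[j, i] = w
    return SimilarityNetwork(W, ids or list(range(R)))


@pytest.fixture
def tri_net():
    return net_from_offdiag({(0, 1): 0.2, (0, 2): 0.4, (1, 2): 0.6}, 3)


def test_weighted_degree_hand_values(tri_net):
    np.testing.assert_allclose(weighted_degree(tri_net), [0.3, 0.4, 0.5])


def test_weighted_degree_constant_and_equivariance(rng):
    W = np.full((4, 4), 0.7)
    np.fill_diagonal(W, 1.0)
    net = SimilarityNetwork(W, list("abcd"))
    np.testing.assert_allclose(weighted_degree(net), 0.7)

    M = rng.random((5, 5))
    W = (M + M.T) / 2
    np.fill_diagonal(W, 1.0)
    net = SimilarityNetwork(W, list(range(5)))
    perm = [3, 1, 4, 0, 2]
    net_p = SimilarityNetwork(W[np.ix_(perm, perm)], perm)
    np.testing.assert_allclose(weighted_degree(net_p), weighted_degree(net)[perm])


def test_threshold_full_density_keeps_all(tri_net):
    mask = threshold_top_density(tri_net, 1.0)
    assert mask.sum() == 6  # 3 undirected edges, symmetric mask


def test_threshold_single_edge_is_argmax(tri_net):
    mask = threshold_top_density(tri_net, 1 / 3)
    assert mask[1, 2] and mask[2, 1] and mask.sum() == 2


def test_threshold_tie_stability():
    net = net_from_offdiag({(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5}, 3)
    m1 = threshold_top_density(net, 1 / 3)
    m2 = threshold_top_density(net, 1 / 3)
    assert np.array_equal(m1, m2)
    assert m1[0, 1]  # deterministic (weight desc, then lowest indices)


def test_threshold_rejects_bad_density(tri_net):
    with pytest.raises(ValueError):
        threshold_top_density(tri_net, 0.0)
    with pytest.raises(ValueError):
        threshold_top_density(tri_net, 1.5)


def test_grouped_fraction_full_density_is_base_rate(rng):
    R = 8
    M = rng.random((R, R))
    W = (M + M.T) / 2
    np.fill_diagonal(W, 1.0)
    net = SimilarityNetwork(W, list(range(R)))
    labels = ["x"] * 4 + ["y"] * 4
    curve = grouped_edge_fraction(net, labels, "same_label", densities=[1.0])
    base_rate = (2 * 6) / 28  # 6 same-label pairs per group, 28 total pairs
    assert curve.values[0] == pytest.approx(base_rate)


def test_grouped_fraction_homotopic_construction():
    # strongest edges are exactly the cross-hemisphere pairs
    net = net_from_offdiag(
        {(0, 2): 0.9, (1, 3): 0.95, (0, 1): 0.1, (2, 3): 0.2, (0, 3): 0.15, (1, 2): 0.12}, 4
    )
    labels = ["left", "left", "right", "right"]
    curve = grouped_edge_fraction(net, labels, "different_label", densities=[2 / 6])
    assert curve.values[0] == 1.0


def test_grouped_fraction_missing_label_errors(tri_net):
    with pytest.raises(ValueError, match="missing"):
        grouped_edge_fraction(tri_net, ["a", None, "b"], "same_label", densities=[1.0])


def test_density_curve_validation():
    with pytest.raises(ValueError):
        DensityCurve(np.array([0.2, 0.1]), np.array([0.0, 0.0]))
    with pytest.raises(ValueError):
        DensityCurve(np.array([0.1]), np.array([0.0, 1.0]))


def test_consistency_identical_networks(tri_net):
    rs, mean = between_subject_consistency([tri_net, tri_net, tri_net])
    np.testing.assert_allclose(rs, 1.0)
    assert mean == pytest.approx(1.0)


def test_consistency_hand_pearson(tri_net):
    other = net_from_offdiag({(0, 1): 0.1, (0, 2): 0.5, (1, 2): 0.4}, 3)
    rs, _ = between_subject_consistency([tri_net, other])
    expected = stats.pearsonr([0.2, 0.4, 0.6], [0.1, 0.5, 0.4])[0]
    assert rs[0] == pytest.approx(expected)


def test_consistency_order_invariance(tri_net):
    other = net_from_offdiag({(0, 1): 0.1, (0, 2): 0.5, (1, 2): 0.4}, 3)
    third = net_from_offdiag({(0, 1): 0.9, (0, 2): 0.2, (1, 2): 0.3}, 3)
    _, m1 = between_subject_consistency([tri_net, other, third])
    _, m2 = between_subject_consistency([third, tri_net, other])
    assert m1 == pytest.approx(m2)


def test_consistency_node_mismatch_errors(tri_net):
    other = net_from_offdiag({(0, 1): 0.1}, 3, ids=["x", "y", "z"])
    with pytest.raises(ValueError, match="node set"):
        between_subject_consistency([tri_net, other])


def _fine_parc(parents: dict) -> ParcellationScheme:
    return ParcellationScheme(
        pd.DataFrame(
            {
                "region_id": list(parents),
                "hemisphere": ["left"] * len(parents),
                "parent_region": list(parents.values()),
            }
        )
    )


def test_interpolate_block_constant_exact():
    # parents of sizes 2 and 3; all cross edges equal 0.4
    fine_ids = ["a1", "a2", "b1", "b2", "b3"]
    W = np.full((5, 5), 0.4)
    W[:2, :2] = 0.9
    W[2:, 2:] = 0.8
    np.fill_diagonal(W, 1.0)
    net = SimilarityNetwork(W, fine_ids)
    parc = _fine_parc({"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"})
    parent = interpolate_to_parent(net, parc)
    assert parent.node_ids == ["A", "B"]
    assert parent.weights[0, 1] == pytest.approx(0.4, abs=1e-12)


def test_interpolate_hand_mean(rng):
    fine_ids = ["a1", "a2", "b1", "b2", "b3"]
    M = rng.random((5, 5))
    W = (M + M.T) / 2
    np.fill_diagonal(W, 1.0)
    net = SimilarityNetwork(W, fine_ids)
    parc = _fine_parc({"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"})
    parent = interpolate_to_parent(net, parc)
    assert parent.weights[0, 1] == pytest.approx(W[:2, 2:].mean())


def test_interpolate_identity_when_trivial(tri_net):
    parc = _fine_parc({0: "P0", 1: "P1", 2: "P2"})
    parent = interpolate_to_parent(tri_net, parc)
    np.testing.assert_allclose(parent.weights, tri_net.weights)


def test_interpolate_linearity(rng):
    fine_ids = list(range(6))
    parc = _fine_parc({0: "A", 1: "A", 2: "B", 3: "B", 4: "C", 5: "C"})

    def rand_net():
        M = rng.random((6, 6))
        W = (M + M.T) / 2
        np.fill_diagonal(W, 1.0)
        return SimilarityNetwork(W, fine_ids)

    X, Y = rand_net(), rand_net()
    combo = SimilarityNetwork(0.3 * X.weights + 0.7 * Y.weights, fine_ids)
    lhs = interpolate_to_parent(combo, parc).weights
    rhs = 0.3 * interpolate_to_parent(X, parc).weights + 0.7 * interpolate_to_parent(Y, parc).weights
    iu = np.triu_indices(3, 1)
    np.testing.assert_allclose(lhs[iu], rhs[iu], atol=1e-12)


def test_vertex_projection_self_is_one():
    labels = ["A", "A", "B", "B", "C", "C"]
    r = vertex_projected_degree_correlation(
        [0.1, 0.5, 0.9], ["A", "B", "C"], [0.1, 0.5, 0.9], ["A", "B", "C"], labels, labels
    )
    assert r == pytest.approx(1.0)


def test_vertex_projection_hand_case():
    lab1 = ["A", "A", "A", "B", "B", "B"]  # 2 coarse regions
    lab2 = ["x", "x", "y", "y", "z", "z"]  # 3 fine regions
    d1, d2 = [0.2, 0.8], [0.1, 0.5, 0.7]
    v1 = [0.2, 0.2, 0.2, 0.8, 0.8, 0.8]
    v2 = [0.1, 0.1, 0.5, 0.5, 0.7, 0.7]
    expected = stats.pearsonr(v1, v2)[0]
    r = vertex_projected_degree_correlation(d1, ["A", "B"], d2, ["x", "y", "z"], lab1, lab2)
    assert r == pytest.approx(expected)


def test_vertex_projection_excludes_uncovered():
    lab1 = ["A", "A", "B", "B", "Z"]  # Z not a region under parcellation 1
    lab2 = ["x", "y", "x", "y", "x"]
    r = vertex_projected_degree_correlation(
        [0.2, 0.8], ["A", "B"], [0.3, 0.6], ["x", "y"], lab1, lab2
    )
    expected = stats.pearsonr([0.2, 0.2, 0.8, 0.8], [0.3, 0.6, 0.3, 0.6])[0]
    assert r == pytest.approx(expected)
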