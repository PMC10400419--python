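import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mindnet import (
    SimilarityNetwork,
    edge_bootstrap_compare,
    fisher_mean,
    generate_spins,
    profile_correlation,
    spin_network,
    spin_pvalue,
    tract_edge_correlation,
)


@pytest.fixture(scope="module")
def layout(request):
    from mindnet import SyntheticCortexSpec

    spec = SyntheticCortexSpec.create(R_per_hemisphere=8, d=3, seed=21)
    return spec.centroids, list(spec.hemispheres)


def test_identity_rotation_gives_identity_permutation(layout):
    centroids, hemis = layout
    spins = generate_spins(centroids, hemis, rotations=[np.eye(3)])
    np.testing.assert_array_equal(spins.permutations[0], np.arange(len(hemis)))


def test_spins_are_bijections_within_hemisphere(layout):
    centroids, hemis = layout
    spins = generate_spins(centroids, hemis, n_perm=50, seed=5)
    hemis = np.asarray(hemis, dtype=object)
    left = set(np.where(hemis == "left")[0])
    for row in spins.permutations:
        assert sorted(row) == list(range(len(hemis)))
        assert {row[i] for i in left} == left  # left indices map within left


def test_spins_deterministic_under_seed(layout):
    centroids, hemis = layout
    a = generate_spins(centroids, hemis, n_perm=10, seed=7)
    b = generate_spins(centroids, hemis, n_perm=10, seed=7)
    np.testing.assert_array_equal(a.permutations, b.permutations)


def test_spins_need_two_regions_per_hemisphere():
    with pytest.raises(ValueError, match="at least 2"):
        generate_spins(np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1]]), ["left", "left", "right"], n_perm=2)


def test_spun_map_preserves_value_multiset(layout, rng):
    centroids, hemis = layout
    spins = generate_spins(centroids, hemis, n_perm=20, seed=3)
    values = rng.standard_normal(len(hemis))
    for row in spins.permutations:
        assert sorted(values[row]) == sorted(values)


def test_spin_pvalue_degenerate_identity_null(layout, rng):
    centroids, hemis = layout
    R = len(hemis)
    spins = generate_spins(centroids, hemis, rotations=[np.eye(3)] * 10)
    m = rng.standard_normal(R)
    assert spin_pvalue(m, m, spins) == 1.0


def test_spin_pvalue_detects_coupling(layout, rng):
    centroids, hemis = layout
    spins = generate_spins(centroids, hemis, n_perm=200, seed=13)
    a = rng.standard_normal(len(hemis))
    b = a + 0.1 * rng.standard_normal(len(hemis))
    assert spin_pvalue(a, b, spins) < 0.05


def test_spin_pvalue_rejects_constant_map(layout):
    centroids, hemis = layout
    spins = generate_spins(centroids, hemis, n_perm=5, seed=1)
    with pytest.raises(ValueError, match="constant"):
        spin_pvalue(np.ones(len(hemis)), np.arange(len(hemis)), spins)


def test_spin_network_group_properties(rng):
    R = 6
    M = rng.random((R, R))
    W = (M + M.T) / 2
    np.fill_diagonal(W, 1.0)
    net = SimilarityNetwork(W, list(range(R)))
    np.testing.assert_allclose(spin_network(net, np.arange(R)).weights, W)
    perm = rng.permutation(R)
    spun = spin_network(net, perm)
    inv = np.argsort(perm)
    np.testing.assert_allclose(spin_network(spun, inv).weights, W)
    assert sorted(spun.upper_triangle()) == pytest.approx(sorted(net.upper_triangle()))


def test_fisher_mean_values():
    assert fisher_mean(0.3, 0.3) == pytest.approx(0.3)
    assert fisher_mean(0.4, -0.4) == pytest.approx(0.0, abs=1e-12)
    direct = np.tanh((np.arctanh(0.6) + np.arctanh(0.2)) / 2)
    assert fisher_mean(0.6, 0.2) == pytest.approx(direct, abs=1e-12)
    lo, hi = sorted([0.6, 0.2])
    assert lo <= fisher_mean(0.6, 0.2) <= hi
    with pytest.warns(RuntimeWarning):
        assert fisher_mean(1.0, 0.0) < 1.0


def test_profile_correlation_with_missing_entries(rng):
    sim = rng.standard_normal(20)
    aff = sim + 0.5 * rng.standard_normal(20)
    eff = -sim + rng.standard_normal(20)
    aff[3] = np.nan
    ok = np.isfinite(aff)
    r_aff = stats.pearsonr(sim[ok], aff[ok])[0]
    r_eff = stats.pearsonr(sim, eff)[0]
    assert profile_correlation(sim, aff, eff) == pytest.approx(fisher_mean(r_aff, r_eff))


def test_bootstrap_dominance(rng):
    tract = rng.standard_normal(80)
    noise = rng.standard_normal(80)
    res = edge_bootstrap_compare(tract, tract, noise, n_boot=200, seed=1)
    assert res.p_value == 0.0
    assert not res.degenerate


def test_bootstrap_identical_inputs_degenerate(rng):
    tract = rng.standard_normal(50)
    sim = rng.standard_normal(50)
    res = edge_bootstrap_compare(tract, sim, sim, n_boot=100, seed=2)
    assert res.degenerate
    assert res.p_value == 0.0  # documented strict "< 0" rule


def test_bootstrap_exchangeable_near_half(rng):
    tract = rng.standard_normal(100)
    s1 = tract + rng.standard_normal(100)
    s2 = tract + rng.standard_normal(100)
    ps = [
        edge_bootstrap_compare(tract, s1, s2, n_boot=200, seed=s).p_value for s in range(6)
    ]
    assert 0.1 < np.mean(ps) < 0.9


def test_bootstrap_two_sided_doubles_tail(rng):
    tract = rng.standard_normal(60)
    s1 = tract + 0.5 * rng.standard_normal(60)
    s2 = rng.standard_normal(60)
    one = edge_bootstrap_compare(tract, s1, s2, n_boot=200, seed=3, alternative="one_sided")
    two = edge_bootstrap_compare(tract, s1, s2, n_boot=200, seed=3, alternative="two_sided")
    assert two.p_value == pytest.approx(min(1.0, 2 * min(one.p_value, 1 - one.p_value)), abs=1e-9)


def _toy_tract_and_net(rng, R=6):
    ids = [f"r{i}" for i in range(R)]
    M = rng.random((R, R))
    W = (M + M.T) / 2
    np.fill_diagonal(W, 1.0)
    net = SimilarityNetwork(W, ids)
    tract = pd.DataFrame(rng.standard_normal((R, R)), index=ids, columns=ids)
    np.fill_diagonal(tract.values, np.nan)
    return tract, net, ids


def test_tract_correlation_proportional_is_one(rng):
    _, net, ids = _toy_tract_and_net(rng)
    tract = net.to_dataframe() * 2.0 + 1.0
    np.fill_diagonal(tract.values, np.nan)
    assert tract_edge_correlation(tract, net) == pytest.approx(1.0)


def test_tract_correlation_matches_hand_pearson(rng):
    tract, net, ids = _toy_tract_and_net(rng, R=4)
    t_vals, s_vals = [], []
    for i, ti in enumerate(ids):
        for j, tj in enumerate(ids):
            if i != j and np.isfinite(tract.loc[ti, tj]):
                t_vals.append(tract.loc[ti, tj])
                s_vals.append(net.weights[i, j])
    expected = stats.pearsonr(t_vals, s_vals)[0]
    assert tract_edge_correlation(tract, net) == pytest.approx(expected)


def test_tract_density_one_equals_unthresholded(rng):
    tract, net, _ = _toy_tract_and_net(rng)
    curve = tract_edge_correlation(tract, net, densities=[0.5, 1.0])
    assert curve.values[-1] == pytest.approx(tract_edge_correlation(tract, net))


def test_tract_correlation_requires_overlap(rng):
    tract, net, _ = _toy_tract_and_net(rng)
    empty = tract.copy()
    empty.loc[:, :] = np.nan
    with pytest.raises(ValueError, match="overlap"):
        tract_edge_correlation(empty, net)
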