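"""Tests for R-vine structure selection, fitting, density and sampling."""

import itertools
import math

import numpy as np
import pytest

from vinecmc.copulas import PairCopula, empirical_kendall_tau, fit_pair_copula
from vinecmc.rvine import (
    RVineCopula,
    VineEdge,
    VineModel,
    build_rvine,
    max_spanning_tree,
    sample_rvine,
)

# ---------------------------------------------------------------------------
# maximum spanning tree
# ---------------------------------------------------------------------------


def brute_force_mst(W):
    """Enumerate all spanning trees of the complete graph, keep the heaviest."""
    n = W.shape[0]
    all_edges = list(itertools.combinations(range(n), 2))
    best, best_w = None, -np.inf
    for edges in itertools.combinations(all_edges, n - 1):
        # connectivity check by union-find
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for (i, j) in edges:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        w = sum(W[i, j] for (i, j) in edges)
        if w > best_w:
            best_w, best = w, set(edges)
    return best, best_w


def test_mst_worked_example():
    W = np.zeros((4, 4))
    for (i, j, w) in [(0, 1, 0.8), (0, 2, 0.1), (0, 3, 0.3), (1, 2, 0.5), (1, 3, 0.2), (2, 3, 0.6)]:
        W[i, j] = W[j, i] = w
    tree = sorted(max_spanning_tree(W))
    assert tree == [(0, 1), (1, 2), (2, 3)]
    assert sum(W[i, j] for (i, j) in tree) == pytest.approx(1.9)


def test_mst_two_nodes_and_ties():
    assert max_spanning_tree(np.ones((2, 2))) == [(0, 1)]
    # equal weights: lexicographically-first spanning tree (star from node 0)
    assert sorted(max_spanning_tree(np.ones((4, 4)))) == [(0, 1), (0, 2), (0, 3)]


@pytest.mark.parametrize("n", [3, 4, 5])
def test_mst_matches_brute_force(n):
    for rep in range(17):
        r = np.random.default_rng(97 * n + rep)
        W = r.uniform(0.0, 1.0, size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        tree = max_spanning_tree(W)
        bf, bf_w = brute_force_mst(W)
        assert sum(W[i, j] for (i, j) in tree) == pytest.approx(bf_w, abs=1e-12)
        assert set(tuple(sorted(e)) for e in tree) == bf


def test_mst_disconnected_names_components():
    W = np.ones((4, 4))
    with pytest.raises(ValueError, match="components"):
        max_spanning_tree(W, allowed=[(0, 1), (2, 3)])


# ---------------------------------------------------------------------------
# helpers: known vines
# ---------------------------------------------------------------------------


def gaussian_pc(rho):
    return PairCopula("gaussian", (rho,))


def dvine_5var(taus=(0.6, 0.5, 0.4, 0.3)):
    """Path vine 0-1-2-3-4, Gaussian tree 1, independence above."""
    edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
    t1 = [
        VineEdge(e, frozenset(), gaussian_pc(math.sin(math.pi * t / 2)), 1)
        for e, t in zip(edges, taus)
    ]
    t2 = [
        VineEdge((0, 2), frozenset({1}), PairCopula("independence"), 2),
        VineEdge((1, 3), frozenset({2}), PairCopula("independence"), 2),
        VineEdge((2, 4), frozenset({3}), PairCopula("independence"), 2),
    ]
    t3 = [
        VineEdge((0, 3), frozenset({1, 2}), PairCopula("independence"), 3),
        VineEdge((1, 4), frozenset({2, 3}), PairCopula("independence"), 3),
    ]
    t4 = [VineEdge((0, 4), frozenset({1, 2, 3}), PairCopula("independence"), 4)]
    return VineModel([t1, t2, t3, t4], 5)


def trivariate_gaussian_vine(rho12, rho23, rho13):
    rho13_2 = (rho13 - rho12 * rho23) / math.sqrt((1 - rho12**2) * (1 - rho23**2))
    t1 = [
        VineEdge((0, 1), frozenset(), gaussian_pc(rho12), 1),
        VineEdge((1, 2), frozenset(), gaussian_pc(rho23), 1),
    ]
    t2 = [VineEdge((0, 2), frozenset({1}), gaussian_pc(rho13_2), 2)]
    R = np.array([[1, rho12, rho13], [rho12, 1, rho23], [rho13, rho23, 1.0]])
    return VineModel([t1, t2], 3), R


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------


def test_validator_rejects_bad_edge_counts():
    t1 = [VineEdge((0, 1), frozenset(), PairCopula("independence"), 1)]
    with pytest.raises(ValueError):
        VineModel([t1], 3)  # tree 1 of 3 variables needs 2 edges


def test_validator_rejects_proximity_violation():
    t1 = [
        VineEdge((0, 1), frozenset(), PairCopula("independence"), 1),
        VineEdge((2, 3), frozenset(), PairCopula("independence"), 1),
        VineEdge((1, 2), frozenset(), PairCopula("independence"), 1),
    ]
    # (0,3 | 2) cannot be formed from two tree-1 edges sharing a node
    t2 = [
        VineEdge((0, 3), frozenset({2}), PairCopula("independence"), 2),
        VineEdge((1, 3), frozenset({2}), PairCopula("independence"), 2),
    ]
    t3 = [VineEdge((0, 1), frozenset({2, 3}), PairCopula("independence"), 3)]
    with pytest.raises(ValueError, match="proximity"):
        VineModel([t1, t2, t3], 4)


def test_built_vine_is_structurally_valid(rng):
    U = rng.uniform(size=(400, 5))
    res = build_rvine(U, candidates=("independence", "gaussian"), criterion="bic")
    res.model.validate()  # must not raise
    for j, tree in enumerate(res.trees, 1):
        assert len(tree) == 5 - j
        for e in tree:
            assert len(e.given) == j - 1


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------


def test_density_all_independence_is_zero(rng):
    vm = dvine_5var((0.3, 0.3, 0.3, 0.3))
    for tree in vm.trees:
        for e in tree:
            e.copula = PairCopula("independence")
    u = rng.uniform(0.05, 0.95, size=(20, 5))
    np.testing.assert_allclose(vm.log_density(u), 0.0, atol=1e-12)


def test_density_matches_trivariate_gaussian_oracle(rng):
    vm, R = trivariate_gaussian_vine(0.6, 0.5, 0.4)
    from scipy import special

    U = rng.uniform(0.05, 0.95, size=(50, 3))
    Z = special.ndtri(U)
    Ri = np.linalg.inv(R)
    oracle = -0.5 * np.log(np.linalg.det(R)) - 0.5 * np.einsum(
        "ni,ij,nj->n", Z, Ri - np.eye(3), Z
    )
    np.testing.assert_allclose(vm.log_density(U), oracle, atol=1e-6)


def test_density_integrates_to_one_on_grid():
    vm, _ = trivariate_gaussian_vine(0.6, 0.5, 0.4)
    g = (np.arange(40) + 0.5) / 40
    G = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
    assert np.exp(vm.log_density(G)).mean() == pytest.approx(1.0, abs=2e-2)


def test_tree1_only_density_is_sum_of_pair_densities(rng):
    vm = dvine_5var()
    from vinecmc.copulas import get_family

    U = rng.uniform(0.05, 0.95, size=(30, 5))
    direct = np.zeros(30)
    for e in vm.trees[0]:
        a, b = e.cond
        fam = get_family(e.copula.family)
        direct += fam.logpdf(U[:, a], U[:, b], e.copula.params)
    np.testing.assert_allclose(vm.log_density(U), direct, atol=1e-10)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def test_sampling_deterministic():
    vm = dvine_5var()
    a = vm.sample(200, seed=42)
    b = vm.sample(200, seed=42)
    np.testing.assert_array_equal(a, b)


def test_sample_independence_vine():
    vm = dvine_5var()
    for tree in vm.trees:
        for e in tree:
            e.copula = PairCopula("independence")
    U = vm.sample(5000, seed=9)
    for i, j in itertools.combinations(range(5), 2):
        assert abs(empirical_kendall_tau(U[:, i], U[:, j])) < 0.05


def test_sample_p2_clayton_tau():
    vm = VineModel(
        [[VineEdge((0, 1), frozenset(), PairCopula("clayton", (2.0,)), 1)]], 2
    )
    U = sample_rvine(vm, 5000, seed=11)
    assert empirical_kendall_tau(U[:, 0], U[:, 1]) == pytest.approx(0.5, abs=0.03)


def test_sample_margins_uniform():
    from scipy import stats

    vm = dvine_5var()
    U = vm.sample(4000, seed=13)
    for j in range(5):
        assert stats.kstest(U[:, j], "uniform").statistic < 0.03


def test_roundtrip_tau_recovery():
    """Fit on a sample of a known vine; tree-1 taus within 3 SE."""
    vm = dvine_5var()
    U = vm.sample(3000, seed=21)
    res = build_rvine(U, candidates=("independence", "gaussian"))
    se = math.sqrt(2 * (2 * 3000 + 5) / (9 * 3000 * 2999))
    true_taus = {tuple(e.cond): e.copula.tau for e in vm.trees[0]}
    got = {tuple(e.cond): e.tau_emp for e in res.trees[0]}
    assert set(got) == set(true_taus)
    for k, t in true_taus.items():
        assert abs(got[k] - t) < 3 * se + 0.02


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_build_p2_equals_direct_pair_fit(rng):
    U = sample_rvine(
        VineModel([[VineEdge((0, 1), frozenset(), gaussian_pc(0.7), 1)]], 2),
        1000,
        seed=rng,
    )
    res = build_rvine(U)
    direct = fit_pair_copula(U[:, 0], U[:, 1])
    edge = res.trees[0][0]
    assert edge.copula.family == direct.family
    assert edge.copula.params == pytest.approx(direct.params)
    assert res.loglik == pytest.approx(direct.loglik)


def test_independent_uniforms_mostly_independence_edges():
    hits = 0
    for rep in range(10):
        r = np.random.default_rng(7000 + rep)
        U = r.uniform(size=(2000, 4))
        res = build_rvine(U, criterion="bic")
        n_indep = sum(
            e.copula.family == "independence" for t in res.trees for e in t
        )
        hits += n_indep >= 5
    assert hits >= 8  # >= 80% of replicates have >= 5 of 6 independence edges


def test_constant_column_raises():
    U = np.random.default_rng(0).uniform(size=(100, 3))
    U[:, 1] = 0.5
    with pytest.raises(ValueError, match="column 1"):
        RVineCopula(U)


def test_truncation_fills_independence(rng):
    U = dvine_5var().sample(800, seed=3)
    res = build_rvine(U, trunc_level=1)
    assert all(
        e.copula.family == "independence" for t in res.trees[1:] for e in t
    )
    assert res.trunc_level == 1


# ---------------------------------------------------------------------------
# first-tree summary
# ---------------------------------------------------------------------------


def _tree1_vine(edges, p):
    t1 = [VineEdge(e, frozenset(), PairCopula("independence"), 1) for e in edges]
    from vinecmc.synth import _fill_independence_trees

    return VineModel(_fill_independence_trees(t1, p), p)


def test_summary_star_core():
    vm = _tree1_vine([(0, 1), (0, 2), (0, 3)], 4)
    s = vm.first_tree_summary(labels=["hub", "a", "b", "c"])
    assert s["core_nodes"] == ["hub"]


def test_summary_path_tie():
    vm = _tree1_vine([(0, 1), (1, 2), (2, 3)], 4)
    s = vm.first_tree_summary()
    assert sorted(s["core_nodes"]) == ["1", "2"]


def test_summary_bridge_edges():
    vm = _tree1_vine([(0, 1), (1, 2), (2, 3)], 4)
    s = vm.first_tree_summary(
        modalities=["EEG", "EEG", "EMG", "EMG"], labels=["Cz", "C3", "FDS", "BR"]
    )
    assert s["bridge_edges"] == [("C3", "FDS")]


def test_serialization_roundtrip(rng):
    vm, _ = trivariate_gaussian_vine(0.6, 0.5, 0.4)
    d = vm.to_dict()
    vm2 = VineModel.from_dict(d)
    u = rng.uniform(0.1, 0.9, size=(10, 3))
    np.testing.assert_allclose(vm.log_density(u), vm2.log_density(u))
    assert "graph tree1" in vm.tree1_dot()
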