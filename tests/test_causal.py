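"""PC-stable CPDAG estimation and local IDA against brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from _oracles import (
    class_parent_sets,
    markov_equivalence_classes,
    ols_coefficient,
    residual_partial_correlation,
)
from conftest import make_matrix
from spongenet.causal import (
    CiTestConfig,
    Cpdag,
    ci_test,
    cpdag_from_dag,
    cpdag_to_networkx,
    estimate_pair_effects,
    ida_local,
    partial_correlation,
    pc_stable_cpdag,
    read_effects,
    write_effects,
)


def sem_data(edges, nodes, n, rng, noise_sd=1.0):
    """Sample a linear-Gaussian SEM given (parent, child) -> coefficient."""
    parents = {v: [(a, w) for (a, b), w in edges.items() if b == v] for v in nodes}
    values = {}
    remaining = list(nodes)
    while remaining:
        v = next(v for v in remaining if all(a in values for a, _ in parents[v]))
        x = rng.normal(0, noise_sd, n)
        for a, w in parents[v]:
            x = x + w * values[a]
        values[v] = x
        remaining.remove(v)
    return make_matrix(np.array([values[v] for v in nodes]), gene_ids=list(nodes))


class TestPartialCorrelation:
    def test_empty_set_is_pearson(self, rng):
        data = make_matrix(rng.normal(size=(3, 200)), gene_ids=list("abc"))
        arr = data.values.to_numpy()
        assert partial_correlation(data, "a", "b") == pytest.approx(
            np.corrcoef(arr[0], arr[1])[0, 1], abs=1e-12
        )

    def test_chain_conditioning_removes_dependence(self):
        rng = np.random.default_rng(7)
        n = 5000
        data = sem_data({("i", "s"): 1.0, ("s", "j"): 1.0}, ["i", "s", "j"], n, rng)
        rho = partial_correlation(data, "i", "j", ["s"])
        assert abs(rho) < 3 / math.sqrt(n)
        oracle = residual_partial_correlation(data.values.to_numpy(), 0, 2, [1])
        assert rho == pytest.approx(oracle, abs=1e-6)

    def test_matches_residual_oracle_random_sets(self, rng):
        data = make_matrix(rng.normal(size=(6, 300)))
        arr = data.values.to_numpy()
        genes = data.gene_ids
        for S_idx in ([], [2], [2, 3], [2, 3, 4]):
            rho = partial_correlation(data, genes[0], genes[1], [genes[s] for s in S_idx])
            assert rho == pytest.approx(
                residual_partial_correlation(arr, 0, 1, S_idx), abs=1e-8
            )

    def test_duplicated_conditioning_gene_is_singular(self, rng):
        arr = rng.normal(size=(4, 100))
        arr[3] = arr[2]  # perfect duplicate
        data = make_matrix(arr)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(data, "G0", "G1", ["G2", "G3"])


class TestCiTest:
    def test_zero_correlation_gives_p_one(self):
        # two exactly orthogonal rows
        data = make_matrix([[1, -1, 1, -1, 1, -1, 1, -1, 1, -1, 1, -1],
                            [1, 1, -1, -1, 1, 1, -1, -1, 1, 1, -1, -1]])
        z, p, indep = ci_test(data, "G0", "G1", [], CiTestConfig(alpha=0.05))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert indep

    def test_study_scale_fisher_z_value(self):
        # r = 0.87 at the 22-sample design, |S| = 0
        from spongenet.causal import fisher_z_pvalue
        z, p = fisher_z_pvalue(0.87, 22, 0)
        z_expected = 0.5 * math.log(1.87 / 0.13) * math.sqrt(19)
        assert z == pytest.approx(z_expected, rel=1e-12)
        assert p == pytest.approx(2 * (1 - norm.cdf(abs(z_expected))), rel=1e-10)

    def test_saturated_correlation(self):
        from spongenet.causal import fisher_z_pvalue
        _, p = fisher_z_pvalue(1.0, 22, 0)
        assert p == 0.0

    def test_decision_flips_monotonically_in_alpha(self, rng):
        data = make_matrix(rng.normal(size=(2, 50)))
        _, p, _ = ci_test(data, "G0", "G1", [], CiTestConfig(alpha=0.5))
        for alpha in (0.001, 0.01, 0.1):
            _, _, indep = ci_test(data, "G0", "G1", [], CiTestConfig(alpha=alpha))
            assert indep == (p > alpha)


class TestPcStable:
    def test_independent_genes_empty_graph(self):
        rng = np.random.default_rng(11)
        data = make_matrix(rng.normal(size=(3, 2000)), gene_ids=list("abc"))
        g = pc_stable_cpdag(data, CiTestConfig(alpha=0.01))
        assert g.n_edges == 0

    def test_collider_is_oriented(self):
        rng = np.random.default_rng(12)
        data = sem_data({("x", "z"): 1.0, ("y", "z"): 1.0}, ["x", "y", "z"], 5000, rng)
        g = pc_stable_cpdag(data, CiTestConfig(alpha=0.01))
        assert g.directed == {("x", "z"), ("y", "z")}
        assert g.undirected == set()

    def test_chain_stays_undirected(self):
        rng = np.random.default_rng(13)
        data = sem_data({("x", "y"): 1.0, ("y", "z"): 1.0}, ["x", "y", "z"], 5000, rng)
        g = pc_stable_cpdag(data, CiTestConfig(alpha=0.01))
        assert g.directed == set()
        assert g.undirected == {frozenset(("x", "y")), frozenset(("y", "z"))}

    def test_order_invariance(self):
        """Permuting the gene rows leaves the PC-stable CPDAG unchanged."""
        rng = np.random.default_rng(14)
        edges = {("a", "c"): 0.9, ("b", "c"): -0.8, ("c", "d"): 1.1, ("b", "e"): 0.7}
        nodes = list("abcde")
        data = sem_data(edges, nodes, 3000, rng)
        g_ref = pc_stable_cpdag(data, CiTestConfig(alpha=0.01))
        for seed in range(3):
            perm = np.random.default_rng(seed).permutation(nodes)
            g_perm = pc_stable_cpdag(data.subset(list(perm)), CiTestConfig(alpha=0.01))
            assert g_perm == g_ref

    def test_too_few_samples_rejected(self, rng):
        data = make_matrix(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError, match="n_samples"):
            pc_stable_cpdag(data)


class TestCpdagFromDag:
    @pytest.mark.parametrize("n_nodes", [2, 3, 4])
    def test_matches_equivalence_class_consensus(self, n_nodes):
        """Meek closure of the v-structure pattern equals the consensus
        orientation over every DAG in the Markov equivalence class."""
        nodes = tuple(f"v{i}" for i in range(n_nodes))
        for directed, undirected, members in markov_equivalence_classes(nodes):
            for member in members:
                g = cpdag_from_dag(list(nodes), member)
                assert g.directed == set(directed), (member, g.directed)
                assert g.undirected == set(undirected)

    def test_invariants_hold(self):
        g = cpdag_from_dag(["a", "b", "c"], {("a", "c"), ("b", "c")})
        assert not (g.directed & {(b, a) for a, b in g.directed})
        assert all(frozenset(e) not in g.undirected for e in g.directed)


class TestIdaLocal:
    def test_single_directed_edge_recovers_coefficient(self):
        rng = np.random.default_rng(21)
        n = 5000
        data = sem_data({("x", "y"): 2.0}, ["x", "y"], n, rng)
        g = Cpdag(["x", "y"], directed=[("x", "y")])
        eff = ida_local(data, g, "x", "y")
        assert eff.n_parent_sets == 1
        assert eff.summary == pytest.approx(2.0, abs=5 / math.sqrt(n))

    def test_nonadjacent_separated_pair_has_zero_effect(self):
        rng = np.random.default_rng(22)
        n = 5000
        data = sem_data({("z", "x"): 1.0, ("z", "y"): 1.0}, ["z", "x", "y"], n, rng)
        g = Cpdag(["z", "x", "y"], directed=[("z", "x"), ("z", "y")])
        eff = ida_local(data, g, "x", "y")
        assert abs(eff.summary) < 5 / math.sqrt(n)

    def test_undirected_neighbor_enumerates_both_parent_sets(self):
        rng = np.random.default_rng(23)
        data = sem_data({("x", "y"): 1.0, ("z", "x"): 1.0}, ["x", "y", "z"], 2000, rng)
        g = Cpdag(["x", "y", "z"], directed=[("x", "y")], undirected=[("x", "z")])
        eff = ida_local(data, g, "x", "y")
        assert eff.n_parent_sets == 2  # S in {{}, {z}}

    def test_target_in_adjustment_set_contributes_zero(self):
        rng = np.random.default_rng(24)
        data = sem_data({("x", "y"): 1.0}, ["x", "y"], 500, rng)
        g = Cpdag(["x", "y"], undirected=[("x", "y")])
        eff = ida_local(data, g, "x", "y")
        assert 0.0 in eff.effects
        assert eff.summary == 0.0  # minimum-absolute summary

    @pytest.mark.parametrize("n_nodes", [2, 3, 4])
    def test_multiset_matches_dag_enumeration(self, n_nodes):
        """For every CPDAG on <= 4 nodes the locally valid parent sets (and
        their regression effects) coincide with exhaustive enumeration of
        the consistent DAG extensions."""
        nodes = tuple(f"v{i}" for i in range(n_nodes))
        rng = np.random.default_rng(25)
        data = make_matrix(rng.normal(size=(n_nodes, 80)), gene_ids=list(nodes))
        X = data.values.to_numpy()
        pos = {g: i for i, g in enumerate(nodes)}
        for directed, undirected, members in markov_equivalence_classes(nodes):
            g = Cpdag(list(nodes), directed, [tuple(sorted(e)) for e in undirected])
            for x, y in itertools.permutations(nodes, 2):
                eff = ida_local(data, g, x, y)
                oracle_sets = class_parent_sets(members, x)
                oracle_effects = sorted(
                    0.0 if y in ps else ols_coefficient(X, pos, x, y, sorted(ps))
                    for ps in oracle_sets
                )
                assert eff.n_parent_sets == len(oracle_sets)
                assert np.allclose(sorted(eff.effects), oracle_effects, atol=1e-8)


class TestEstimatePairEffects:
    class _Pair:
        def __init__(self, lnc_id, mrna_id):
            self.lnc_id, self.mrna_id = lnc_id, mrna_id

    def test_lone_pair_multiset_contains_coefficient(self):
        """With only the pair's two genes in scope the edge stays undirected:
        the multiset contains the regression coefficient and 0, and the
        minimum-absolute summary is 0."""
        rng = np.random.default_rng(31)
        n = 5000
        data = sem_data({("x", "y"): 2.0}, ["x", "y"], n, rng)
        [eff] = estimate_pair_effects(data, [self._Pair("x", "y")])
        assert eff.summary == 0.0
        assert max(eff.effects) == pytest.approx(2.0, abs=5 / math.sqrt(n))

    def test_collider_context_identifies_the_effect(self):
        rng = np.random.default_rng(31)
        n = 5000
        # z1 -> x <- z2 orients x, then Meek R1 orients x -> y
        edges = {("z1", "x"): 0.8, ("z2", "x"): 0.8, ("x", "y"): 2.0}
        data = sem_data(edges, ["z1", "z2", "x", "y"], n, rng)
        pairs = [self._Pair("x", "y"), self._Pair("z1", "y"), self._Pair("z2", "y")]
        effects = estimate_pair_effects(data, pairs)
        assert effects[0].summary == pytest.approx(2.0, abs=5 / math.sqrt(n))

    def test_duplicate_pairs_give_identical_outputs(self):
        rng = np.random.default_rng(32)
        data = sem_data({("x", "y"): 1.0}, ["x", "y"], 500, rng)
        pairs = [self._Pair("x", "y"), self._Pair("x", "y")]
        e1, e2 = estimate_pair_effects(data, pairs)
        assert e1 == e2

    def test_missing_gene_is_an_error(self, rng):
        data = make_matrix(rng.normal(size=(2, 50)), gene_ids=["x", "y"])
        with pytest.raises(KeyError, match="ghost"):
            estimate_pair_effects(data, [self._Pair("x", "ghost")])

    def test_repeated_runs_are_deterministic(self):
        rng = np.random.default_rng(33)
        edges = {("a", "c"): 0.9, ("b", "c"): -0.8, ("c", "d"): 1.0}
        data = sem_data(edges, list("abcd"), 1000, rng)
        pairs = [self._Pair("a", "c"), self._Pair("a", "d"), self._Pair("b", "d")]
        first = estimate_pair_effects(data, pairs)
        second = estimate_pair_effects(data, pairs)
        assert first == second


def test_effect_table_round_trip(tmp_path, rng):
    data = make_matrix(rng.normal(size=(2, 100)), gene_ids=["x", "y"])
    g = Cpdag(["x", "y"], directed=[("x", "y")])
    eff = ida_local(data, g, "x", "y")
    f = tmp_path / "effects.tsv"
    write_effects([eff], f)
    [back] = read_effects(f)
    assert back.lnc_id == "x" and back.n_parent_sets == 1
    assert back.summary == pytest.approx(eff.summary, rel=1e-5)


def test_cpdag_graphml_edge_attributes(tmp_path):
    import networkx as nx

    g = Cpdag(["a", "b", "c"], directed=[("a", "b")], undirected=[("b", "c")])
    nxg = cpdag_to_networkx(g)
    assert nxg.edges["a", "b"]["directed"] is True
    assert nxg.edges["b", "c"]["directed"] is False
    path = tmp_path / "g.graphml"
    nx.write_graphml(nxg, path)
    back = nx.read_graphml(path)
    assert back.edges[("a", "b")]["directed"]
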