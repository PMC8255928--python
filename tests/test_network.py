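import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from conftest import toy_matrix
from lncnet.network import (
    CoexpressionEdge,
    MarkovClustering,
    MclParams,
    correlate_pairs,
    edges_to_graph,
    mcl,
    select_top_edges,
)


def clique_edges(nodes_a, nodes_b, r=0.95):
    """Bipartite-complete block between two node groups."""
    return [
        CoexpressionEdge(a, b, r, 1e-6) for a, b in itertools.product(nodes_a, nodes_b)
    ]


class TestCorrelatePairs:
    def test_planted_module_pair_found(self, small_sim):
        mat, truth = small_sim
        lnc_set = set(truth.lnc_ids)
        mod = [g for g in truth.module_assignments]
        lnc = sorted(g for g in mod if g in lnc_set)
        mrna = sorted(g for g in mod if g not in lnc_set)
        edges = correlate_pairs(mat, lnc, mrna, r_min=0.8)
        keys = {(e.lnc_id, e.mrna_id) for e in edges}
        found = sum((l, m) in keys for l in lnc for m in mrna)
        assert found >= 0.8 * len(lnc) * len(mrna)

    def test_overlapping_id_sets_rejected(self, small_sim):
        mat, _ = small_sim
        with pytest.raises(ValueError, match="disjoint"):
            correlate_pairs(mat, ["LNC00001"], ["LNC00001"])

    def test_zero_variance_gene_excluded_with_warning(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                         [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                         [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]])
        mat = toy_matrix(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            edges = correlate_pairs(mat, ["g0", "g1"], ["g2"], r_min=0.8)
        assert {e.lnc_id for e in edges} == {"g1"}

    def test_null_inclusion_rate_matches_direct_estimate(self):
        """Edge-wise inclusion frequency for independent genes at n=6
        equals the frequency of |r|>=0.8 & p<0.05 computed pair-by-pair
        with scipy.stats.pearsonr on the same draws."""
        rng = np.random.default_rng(42)
        n_pairs, n = 400, 6
        a = rng.normal(5, 1, size=(n_pairs, n))
        b = rng.normal(5, 1, size=(n_pairs, n))
        direct = 0
        hits = 0
        for i in range(n_pairs):
            va, vb = 2.0 ** a[i], 2.0 ** b[i]
            mat = toy_matrix(np.vstack([va, vb]), n_control=3)
            edges = correlate_pairs(mat, ["g0"], ["g1"], r_min=0.8)
            hits += bool(edges)
            la, lb = np.log2(va + 1), np.log2(vb + 1)
            r, p = stats.pearsonr(la, lb)
            direct += (abs(r) >= 0.8) and (p < 0.05)
        assert hits == direct
        assert hits / n_pairs < 0.2  # rare under independence

    def test_too_few_samples_rejected(self):
        mat = toy_matrix(np.array([[1.0, 2.0], [2.0, 1.0]]), n_control=1)
        with pytest.raises(ValueError, match="3 samples"):
            correlate_pairs(mat, ["g0"], ["g1"])


class TestSelectTopEdges:
    def test_fewer_edges_than_k_returned_whole(self):
        edges = clique_edges(["l1"], ["m1", "m2", "m3"])
        assert len(select_top_edges(edges, k=500)) == 3

    def test_equal_p_breaks_by_larger_abs_r(self):
        e1 = CoexpressionEdge("l1", "m1", 0.85, 0.01)
        e2 = CoexpressionEdge("l1", "m2", -0.95, 0.01)
        assert select_top_edges([e1, e2], k=1) == [e2]

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        edges = [
            CoexpressionEdge(f"l{i}", f"m{j}", float(rng.uniform(0.8, 1)),
                             float(rng.uniform(0, 0.05)))
            for i in range(10) for j in range(10)
        ]
        ref = select_top_edges(edges, k=20)
        perm = list(edges)
        rng.shuffle(perm)
        assert select_top_edges(perm, k=20) == ref


class TestMcl:
    def test_disconnected_cliques_match_connected_components(self):
        edges = clique_edges(["a1", "a2"], ["a3", "a4"]) + clique_edges(
            ["b1", "b2"], ["b3", "b4"]
        )
        assignment = mcl(edges)
        g = edges_to_graph(edges)
        comps = list(nx.connected_components(g))
        assert len(assignment.sizes) == len(comps) == 2
        for comp in comps:
            assert len({assignment.assignments[n] for n in comp}) == 1

    def test_bridged_cliques_split_in_two(self):
        # two dense blocks joined by one weight-0.8 bridge: inflation 2
        # severs the bridge
        edges = clique_edges([f"a{i}" for i in range(3)], [f"x{i}" for i in range(2)])
        edges += clique_edges([f"b{i}" for i in range(3)], [f"y{i}" for i in range(2)])
        edges.append(CoexpressionEdge("a0", "y0", 0.8, 0.04))
        assignment = mcl(edges, MclParams(inflation=2.0))
        assert len(assignment.sizes) == 2
        block_a = {f"a{i}" for i in range(3)} | {f"x{i}" for i in range(2)}
        assert len({assignment.assignments[n] for n in block_a}) == 1

    def test_single_edge_single_cluster(self):
        assignment = mcl([CoexpressionEdge("l1", "m1", 0.9, 0.01)])
        assert assignment.sizes == {0: 2}

    def test_clusters_never_merge_across_components(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            e1 = clique_edges([f"a{i}" for i in range(rng.integers(1, 4))],
                              [f"x{i}" for i in range(rng.integers(1, 4))],
                              r=float(rng.uniform(0.8, 1)))
            e2 = clique_edges([f"b{i}" for i in range(rng.integers(1, 4))],
                              [f"y{i}" for i in range(rng.integers(1, 4))],
                              r=float(rng.uniform(0.8, 1)))
            assignment = mcl(e1 + e2)
            left = {assignment.assignments[n] for e in e1 for n in (e.lnc_id, e.mrna_id)}
            right = {assignment.assignments[n] for e in e2 for n in (e.lnc_id, e.mrna_id)}
            assert not (left & right)

    def test_recovers_planted_modules_from_synthetic_network(self):
        """Two planted modules driven by independent latent factors are
        returned as two MCL clusters with the correct memberships.

        The group shift is zeroed here so within-module correlation comes
        from the latent factors alone; otherwise every same-signed DE
        gene correlates with every other through the case/control shift
        and module boundaries are not identifiable from correlation.
        Inflation 1.5 sets the granularity appropriate for dense
        bipartite blocks: at 2.0 a near-complete lncRNA x mRNA block
        fragments into one hub-centred star per side.
        """
        from lncnet.simulate import SimConfig, simulate_expression

        cfg = SimConfig(
            n_genes=150, n_lnc=50, de_fraction=0.3, log2fc_effect=0.0,
            module_spec=((12, 0.92), (10, 0.9)), seed=13, noise_sd=0.3,
        )
        mat, truth = simulate_expression(cfg)
        lnc_set = set(truth.lnc_ids)
        module_genes = sorted(truth.module_assignments)
        edges = correlate_pairs(
            mat,
            [g for g in module_genes if g in lnc_set],
            [g for g in module_genes if g not in lnc_set],
        )
        assignment = mcl(select_top_edges(edges, k=500), MclParams(inflation=1.5))
        for mod_id in (0, 1):
            members = [g for g, m in truth.module_assignments.items()
                       if m == mod_id and g in assignment.assignments]
            assert len(members) >= 8
            labels = [assignment.assignments[g] for g in members]
            assert len(set(labels)) == 1
        all_labels = {assignment.assignments[g]
                      for g in module_genes if g in assignment.assignments}
        assert len(all_labels) == 2

    def test_empty_edge_list_rejected(self):
        with pytest.raises(ValueError):
            mcl([])

    def test_deterministic_across_runs(self):
        edges = clique_edges(["a1", "a2"], ["m1", "m2"]) + [
            CoexpressionEdge("a1", "m3", 0.81, 0.02)
        ]
        a1 = MarkovClustering().fit_predict(edges_to_graph(edges))
        a2 = MarkovClustering().fit_predict(edges_to_graph(edges))
        assert a1.assignments == a2.assignments

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MclParams(inflation=1.0)
        with pytest.raises(ValueError):
            MclParams(expansion=1)
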