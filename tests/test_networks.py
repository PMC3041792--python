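"""Network construction, sparsification, IPN and greedy builders."""

import numpy as np
import pytest

from gba_bias.annotations import AnnotationMatrix, GeneUniverse
from gba_bias.networks import (
    ExpressionMatrix,
    Network,
    aggregate,
    build_coexpression,
    build_ipn,
    build_shared_function_network,
    node_degree,
    read_edge_list,
    threshold_sparsify,
    top_overlap_sparsify,
    write_edge_list,
)
from tests.conftest import random_annotation


def net_from_edges(edges, n, weights=None):
    w = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        wij = 1.0 if weights is None else weights[k]
        w[i, j] = w[j, i] = wij
    return Network(
        GeneUniverse(tuple(f"g{i}" for i in range(n))), w, binary=weights is None
    )


def random_symmetric(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestNodeDegree:
    def test_triangle(self):
        net = net_from_edges([(0, 1), (1, 2), (0, 2)], 3)
        assert node_degree(net).degree.tolist() == [2, 2, 2]

    def test_star(self):
        net = net_from_edges([(0, 1), (0, 2), (0, 3)], 4)
        assert node_degree(net).degree.tolist() == [3, 1, 1, 1]

    def test_weighted_sum(self):
        net = net_from_edges([(0, 1), (1, 2)], 3, weights=[0.5, 2.0])
        assert node_degree(net).degree.tolist() == [0.5, 2.5, 2.0]

    def test_total_degree_is_twice_edge_weight(self, rng):
        m = random_symmetric(rng, 8)
        net = Network(GeneUniverse(tuple(f"g{i}" for i in range(8))), m)
        assert node_degree(net).degree.sum() == pytest.approx(2 * np.triu(m, 1).sum())


class TestThresholdSparsify:
    def test_equal_values_exact_edge_count(self):
        m = np.ones((5, 5))
        np.fill_diagonal(m, 0)
        out = threshold_sparsify(m, sparsity=0.5)
        assert out.n_edges == int(0.5 * 10)

    def test_binary_matrix_at_own_sparsity_is_identity(self, rng):
        net = net_from_edges([(0, 1), (2, 3), (1, 4)], 6)
        out = threshold_sparsify(net.weights, sparsity=net.sparsity)
        assert np.array_equal(out.weights, net.weights)

    def test_matches_brute_force_top_k(self, rng):
        n = 20
        m = random_symmetric(rng, n)
        out = threshold_sparsify(m, sparsity=0.10)
        n_keep = int(np.floor(0.10 * n * (n - 1) / 2))
        assert out.n_edges == n_keep == 19
        pairs = sorted(
            ((i, j) for i in range(n) for j in range(i + 1, n)),
            key=lambda p: (-m[p], p),
        )[:n_keep]
        expected = set(pairs)
        got = {tuple(e) for e in out.edge_array()}
        assert got == expected

    def test_rejects_asymmetric(self, rng):
        m = rng.random((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            threshold_sparsify(m, 0.1)

    def test_never_creates_weights(self, rng):
        m = random_symmetric(rng, 15)
        m[m < 0.8] = 0.0
        out = threshold_sparsify(m, 0.05)
        assert np.all(m[out.weights > 0] > 0)


class TestTopOverlapSparsify:
    def test_mutual_best_pair_kept(self):
        m = np.array(
            [[0, 9, 1], [9, 0, 1], [1, 1, 0]], dtype=float
        )
        out = top_overlap_sparsify(m, per_gene_sparsity=0.5)  # k=1 of 2
        assert {tuple(e) for e in out.edge_array()} == {(0, 1)}

    def test_one_sided_nomination_dropped(self):
        # gene 2's best is gene 0, but gene 0's top-1 is gene 1
        m = np.array(
            [[0, 9, 5], [9, 0, 1], [5, 1, 0]], dtype=float
        )
        out = top_overlap_sparsify(m, per_gene_sparsity=0.5)
        assert (2, 0) not in {tuple(e) for e in out.edge_array()}
        assert (0, 2) not in {tuple(e) for e in out.edge_array()}

    def test_matches_brute_force_and_narrows_degrees(self, rng):
        n = 30
        m = random_symmetric(rng, n)
        frac = 0.2
        out = top_overlap_sparsify(m, per_gene_sparsity=frac)
        k = int(np.floor(frac * (n - 1)))
        expected = set()
        tops = []
        for i in range(n):
            ranked = sorted(
                (j for j in range(n) if j != i), key=lambda j: (-m[i, j], j)
            )
            tops.append(set(ranked[:k]))
        for i in range(n):
            for j in range(i + 1, n):
                if j in tops[i] and i in tops[j]:
                    expected.add((i, j))
        assert {tuple(e) for e in out.edge_array()} == expected
        # degree variance narrower than global threshold at matched sparsity
        if out.n_edges > 0:
            thr = threshold_sparsify(m, sparsity=out.sparsity)
            assert node_degree(out).degree.var() <= node_degree(thr).degree.var()

    def test_symmetric_by_construction(self, rng):
        m = random_symmetric(rng, 12)
        out = top_overlap_sparsify(m, 0.3)
        assert np.array_equal(out.weights, out.weights.T)


class TestBuildCoexpression:
    def test_duplicate_genes_win(self, rng):
        x = rng.standard_normal((4, 30))
        x[1] = x[0]  # exact duplicates
        e = ExpressionMatrix(
            GeneUniverse(("a", "b", "c", "d")), tuple(f"s{k}" for k in range(30)), x
        )
        out = build_coexpression(e, sparsity=1 / 6 + 1e-9)  # keep exactly 1 edge
        assert {tuple(x) for x in out.edge_array()} == {(0, 1)}

    def test_zero_kept_is_valid_empty(self, rng):
        x = rng.standard_normal((5, 10))
        e = ExpressionMatrix(
            GeneUniverse(tuple("abcde")), tuple(f"s{k}" for k in range(10)), x
        )
        out = build_coexpression(e, sparsity=0.05)  # floor(0.05*10) = 0
        assert out.n_edges == 0

    def test_matches_brute_force_sort(self, rng):
        n, s = 20, 40
        factor = rng.standard_normal(s)
        x = 0.7 * factor + 0.5 * rng.standard_normal((n, s))
        e = ExpressionMatrix(
            GeneUniverse(tuple(f"g{i:02d}" for i in range(n))),
            tuple(f"s{k}" for k in range(s)),
            x,
        )
        sparsity = 0.10
        out = build_coexpression(e, sparsity=sparsity)
        corr = np.corrcoef(x)
        n_keep = int(np.floor(sparsity * n * (n - 1) / 2))
        pairs = sorted(
            ((i, j) for i in range(n) for j in range(i + 1, n)),
            key=lambda p: (-corr[p], p),
        )[:n_keep]
        assert {tuple(x) for x in out.edge_array()} == set(pairs)

    def test_constant_gene_contributes_no_edges(self, rng):
        x = rng.standard_normal((4, 20))
        x[2] = 1.0
        e = ExpressionMatrix(
            GeneUniverse(tuple("abcd")), tuple(f"s{k}" for k in range(20)), x
        )
        out = build_coexpression(e, sparsity=0.5)
        assert node_degree(out).degree[2] == 0

    def test_fisher_filter_more_stringent(self, rng):
        n, s = 10, 12
        x = rng.standard_normal((n, s))
        e = ExpressionMatrix(
            GeneUniverse(tuple(f"g{i}" for i in range(n))),
            tuple(f"s{k}" for k in range(s)),
            x,
        )
        loose = build_coexpression(e, sparsity=0.4)
        strict = build_coexpression(e, sparsity=0.4, max_fisher_p=1e-6)
        kept_loose = {tuple(x) for x in loose.edge_array()}
        kept_strict = {tuple(x) for x in strict.edge_array()}
        assert kept_strict <= kept_loose


class TestAggregate:
    def test_single_network_identity(self, rng):
        net = net_from_edges([(0, 1), (1, 2)], 4)
        out = aggregate([net])
        assert np.array_equal(out.weights, net.weights)

    def test_two_identical_binary_nets_sum_to_two(self):
        net = net_from_edges([(0, 1)], 3)
        out = aggregate([net, net])
        assert out.weights[0, 1] == 2.0

    def test_union_mode_matches_set_union(self, rng):
        nets = [
            net_from_edges([(0, 1), (1, 2)], 5),
            net_from_edges([(1, 2), (3, 4)], 5),
            net_from_edges([(0, 4)], 5),
        ]
        out = aggregate(nets, mode="union")
        union = set()
        for net in nets:
            union |= {tuple(e) for e in net.edge_array()}
        assert {tuple(e) for e in out.edge_array()} == union
        assert out.binary

    def test_commutative_and_associative(self, rng):
        a = net_from_edges([(0, 1)], 4)
        b = net_from_edges([(1, 2)], 4)
        c = net_from_edges([(2, 3)], 4)
        w1 = aggregate([a, aggregate([b, c]).binarize()]).weights
        # compare permutation invariance on plain sums
        s1 = aggregate([a, b, c]).weights
        s2 = aggregate([c, a, b]).weights
        assert np.array_equal(s1, s2)
        assert w1.sum() == s1.sum()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestBuildIpn:
    def test_hand_enumeration_budget(self):
        # degrees (3, 2, 1): g0-g1 (x2 weight to get degree), hand-crafted
        w = np.array(
            [[0, 2, 1], [2, 0, 0], [1, 0, 0]], dtype=float
        )
        net = Network(GeneUniverse(("a", "b", "c")), w)
        # degrees (3,2,1); one *binary-counted* edge budget: use n_edges=2
        # degree products incl self: aa=9 ab=6 ac=3 bb=4 bc=2 cc=1
        # budget = 2 edges + 3 self-pairs = 5 -> keep {aa,ab,bb,ac,bc}
        ipn = build_ipn(net)
        assert {tuple(e) for e in ipn.edge_array()} == {(0, 1), (0, 2), (1, 2)}

    def test_one_edge_original_follows_budget_rule(self):
        # degrees (3,2,1) with a single edge in the original: budget 1+3=4
        # sorted products 9(aa),6(ab),4(bb),3(ac),... -> non-self kept: ab, ac
        net = net_from_edges([(0, 1)], 3)
        d = np.array([3.0, 2.0, 1.0])
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        # fake the degree vector via weighted edges
        net = Network(
            GeneUniverse(("a", "b", "c")),
            np.array([[0, 2, 1], [2, 0, 0], [1, 0, 0]], dtype=float),
        )
        assert node_degree(net).degree.tolist() == d.tolist()
        # re-make with a single nonzero pair but same degrees is impossible;
        # instead check the budget arithmetic directly on a 1-edge binary net
        net1 = net_from_edges([(0, 1)], 3)
        ipn = build_ipn(net1)  # degrees (1,1,0): products aa=ab=bb=1, rest 0
        # budget 1+3 = 4: keep aa, ab, bb (ties lexicographic), ac=0 dropped
        assert {tuple(e) for e in ipn.edge_array()} == {(0, 1)}

    def test_regular_graph_ties_fill_to_exact_budget(self):
        net = net_from_edges([(0, 1), (1, 2), (2, 3), (3, 0)], 4)  # 4-cycle
        ipn = build_ipn(net)
        # all degree products tie; budget = 4 edges + 4 self = 8 pairs,
        # lexicographic fill: (0,0),(0,1),(0,2),(0,3),(1,1),(1,2),(1,3),(2,2)
        assert {tuple(e) for e in ipn.edge_array()} == {
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3),
        }

    def test_matches_brute_force_sort_oracle(self, rng):
        n = 50
        m = (random_symmetric(rng, n) > 0.85).astype(float)
        m = np.triu(m, 1) + np.triu(m, 1).T
        net = Network(GeneUniverse(tuple(f"g{i:02d}" for i in range(n))), m, binary=True)
        ipn = build_ipn(net)
        d = m.sum(axis=1)
        pairs = [(i, j) for i in range(n) for j in range(i, n)]
        pairs.sort(key=lambda p: (-(d[p[0]] * d[p[1]]), p))
        budget = net.n_edges + n
        expected = {
            p for p in pairs[:budget] if p[0] != p[1] and d[p[0]] * d[p[1]] > 0
        }
        assert {tuple(e) for e in ipn.edge_array()} == expected

    def test_depends_only_on_degree_vector(self, rng):
        # two different graphs with the same degree vector give identical IPNs
        n1 = net_from_edges([(0, 1), (2, 3)], 4)
        n2 = net_from_edges([(0, 3), (1, 2)], 4)
        assert np.array_equal(build_ipn(n1).weights, build_ipn(n2).weights)

    def test_ipn_degree_ranks_match_original(self, rng):
        import scipy.stats

        n = 40
        # heterogeneous degrees via propensity-like weights
        p = rng.random(n) ** 2
        m = (rng.random((n, n)) < np.outer(p, p) * 2).astype(float)
        m = np.triu(m, 1) + np.triu(m, 1).T
        net = Network(GeneUniverse(tuple(f"g{i:02d}" for i in range(n))), m, binary=True)
        d = m.sum(axis=1)
        if len(np.unique(d)) == n:  # distinct degrees
            ipn = build_ipn(net)
            rho = scipy.stats.spearmanr(d, node_degree(ipn).degree).statistic
            assert rho == pytest.approx(1.0)

    def test_all_zero_degree_rejected(self):
        net = Network(GeneUniverse(("a", "b")), np.zeros((2, 2)), binary=True)
        with pytest.raises(ValueError, match="IPN"):
            build_ipn(net)


class TestSharedFunctionNetwork:
    def test_first_edge_joins_biggest_sharers(self):
        a = random_annotation(np.random.default_rng(0), 6, 1)
        m = np.zeros((6, 4), dtype=bool)
        m[[0, 1], 0] = True
        m[[0, 1], 1] = True
        m[[0, 1], 2] = True
        m[[2, 3], 3] = True
        a = AnnotationMatrix(a.universe, ("A", "B", "C", "D"), m)
        net = build_shared_function_network(a, n_edges=1)
        assert {tuple(e) for e in net.edge_array()} == {(0, 1)}

    def test_reuse_downweights_groups(self):
        # groups: X = {0,1,2}; after edge (0,1) uses X once, pair (0,2) scores
        # 1/2 while a fresh single-group pair scores 1 -> fresh pair wins
        m = np.zeros((5, 2), dtype=bool)
        m[[0, 1, 2], 0] = True
        m[[3, 4], 1] = True
        a = AnnotationMatrix(
            GeneUniverse(tuple(f"g{i}" for i in range(5))), ("X", "Y"), m
        )
        net = build_shared_function_network(a, n_edges=2)
        edges = [tuple(e) for e in net.edge_array()]
        assert (0, 1) in edges and (3, 4) in edges

    def test_matches_step_by_step_greedy_oracle(self, rng):
        a = random_annotation(rng, 20, 6, p=0.25)
        net = build_shared_function_network(a, n_edges=5)
        # independent greedy simulation
        used = np.zeros(a.n_groups)
        chosen = set()
        for _ in range(5):
            best, best_score = None, 0.0
            for i in range(20):
                for j in range(i + 1, 20):
                    if (i, j) in chosen:
                        continue
                    score = sum(
                        1.0 / (1.0 + used[g])
                        for g in range(a.n_groups)
                        if a.membership[i, g] and a.membership[j, g]
                    )
                    if score > best_score + 1e-12:
                        best, best_score = (i, j), score
            if best is None:
                break
            chosen.add(best)
            for g in range(a.n_groups):
                if a.membership[best[0], g] and a.membership[best[1], g]:
                    used[g] += 1
        assert {tuple(e) for e in net.edge_array()} == chosen

    def test_runs_out_of_scoring_pairs(self):
        m = np.zeros((4, 1), dtype=bool)
        m[[0, 1], 0] = True
        a = AnnotationMatrix(
            GeneUniverse(tuple(f"g{i}" for i in range(4))), ("X",), m
        )
        net = build_shared_function_network(a, n_edges=10)
        assert net.n_edges == 1  # only one pair shares any group


class TestEdgeListIO:
    def test_round_trip(self, tmp_path, rng):
        net = net_from_edges([(0, 1), (1, 3), (2, 3)], 4)
        path = tmp_path / "net.tsv"
        write_edge_list(net, path)
        back = read_edge_list(path, universe=net.universe)
        assert np.array_equal(back.weights, net.weights)
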