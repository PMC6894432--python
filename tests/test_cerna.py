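import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lncsponge.cerna import (
    CeRNAPair,
    build_cerna_network,
    centralities,
    filter_cerna_pairs,
    hypergeometric_upper_p,
    pair_graph,
    pearson_with_p,
    rank_network_mirnas,
    score_cerna_pairs,
    shared_mirna_table,
)
from lncsponge.types import ExpressionMatrix, TargetEdgeTable, ValidationError


def edges(pairs):
    return TargetEdgeTable.from_edges(pd.DataFrame(pairs, columns=["mirna_id", "target_id"]))


def enumeration_tail(N, K, n, m):
    """Exhaustive oracle: fraction of n-subsets of N with >= m marked items."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += len(marked & set(draw)) >= m
    return hits / total if total else 1.0


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_upper_p(10, 3, 4, 0) == 1.0

    def test_worked_example(self):
        # N=10, K=5, n=4, m=4: 5 of the C(10,4)=210 draws contain 4 marked
        assert hypergeometric_upper_p(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_degenerate_full_margin(self):
        assert hypergeometric_upper_p(6, 6, 3, 3) == 1.0

    def test_invalid_margins_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_upper_p(5, 6, 2, 1)
        with pytest.raises(ValidationError):
            hypergeometric_upper_p(5, 2, 2, 3)

    def test_matches_enumeration_on_small_universe(self):
        for N in (4, 7):
            for K in range(N + 1):
                for n in range(N + 1):
                    for m in range(min(K, n) + 1):
                        assert hypergeometric_upper_p(N, K, n, m) == pytest.approx(
                            enumeration_tail(N, K, n, m), abs=1e-12
                        )

    def test_non_increasing_in_overlap(self):
        for N, K, n in [(12, 5, 7), (9, 9, 4), (20, 3, 3)]:
            ps = [hypergeometric_upper_p(N, K, n, m) for m in range(min(K, n) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestPearson:
    def test_affine_identity(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert (r, p) == (1.0, 0.0)

    def test_negation(self):
        x = np.arange(5.0)
        r, _ = pearson_with_p(x, -x)
        assert r == -1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_with_p(np.ones(5), np.arange(5.0))

    def test_p_matches_permutation_oracle(self):
        """r ~ 0.7 at n = 50: parametric p agrees with a permutation null."""
        rng = np.random.default_rng(11)
        n = 50
        x = rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n) * math.sqrt(1 - 0.49)
        r, p = pearson_with_p(x, y)
        B = 20000
        perms = np.array([rng.permutation(y) for _ in range(B)])
        xz = (x - x.mean()) / x.std()
        pz = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
        null_r = pz @ xz / n
        p_perm = (1 + np.sum(np.abs(null_r) >= abs(r))) / (B + 1)
        se = math.sqrt(max(p_perm, 1 / B) * (1 - p_perm) / B)
        assert abs(p - p_perm) < max(4 * se, 2 / B)


class TestSharedMirnaTable:
    def test_hand_counts(self):
        t = edges([("m1", "L"), ("m2", "L"), ("m2", "G"), ("m3", "G")])
        pairs = shared_mirna_table(t, ["L"], ["G"], ["m1", "m2", "m3"])
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.K, p.n, p.m, p.N) == (2, 2, 1, 3)

    def test_disjoint_sets_excluded(self):
        t = edges([("m1", "L"), ("m2", "G")])
        assert shared_mirna_table(t, ["L"], ["G"], ["m1", "m2"]) == []

    def test_identical_sets(self):
        rows = [(f"m{i}", g) for i in range(4) for g in ("L", "G")]
        t = edges(rows)
        p = shared_mirna_table(t, ["L"], ["G"], [f"m{i}" for i in range(4)])[0]
        assert (p.K, p.n, p.m) == (4, 4, 4)

    def test_non_universe_edges_ignored(self):
        t = edges([("m1", "L"), ("mX", "L"), ("m1", "G"), ("mY", "G")])
        p = shared_mirna_table(t, ["L"], ["G"], ["m1", "m2"])[0]
        assert (p.K, p.n, p.m, p.N) == (1, 1, 1, 2)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            shared_mirna_table(edges([("m1", "L")]), ["L"], ["G"], [])


def expr_from(rows: dict, role):
    df = pd.DataFrame(rows).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, role=role, unit="log2CPM")


class TestFilterPairs:
    def lnc_mrna(self, r_sign=1.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = r_sign * x + 0.3 * rng.standard_normal(n)
        return (
            expr_from({"L": x}, "lncRNA"),
            expr_from({"G": y}, "mRNA"),
        )

    def pair(self, **kw):
        base = dict(lncrna_id="L", mrna_id="G", K=3, n=3, m=3, N=20,
                    shared_mirnas=frozenset({"m1", "m2", "m3"}))
        base.update(kw)
        return CeRNAPair(**base)

    def test_strong_pair_passes(self):
        lnc, mrna = self.lnc_mrna()
        out = filter_cerna_pairs([self.pair()], lnc, mrna)
        assert len(out) == 1 and out[0].passes
        assert out[0].hyper_p < 0.05 and out[0].pcc > 0

    def test_negative_correlation_rejected(self):
        lnc, mrna = self.lnc_mrna(r_sign=-1.0)
        assert filter_cerna_pairs([self.pair()], lnc, mrna) == []

    def test_weak_overlap_rejected(self):
        lnc, mrna = self.lnc_mrna()
        weak = self.pair(K=2, n=2, m=1, shared_mirnas=frozenset({"m1"}))
        assert filter_cerna_pairs([weak], lnc, mrna) == []

    def test_output_subset_and_order_invariant(self):
        lnc, mrna = self.lnc_mrna()
        pairs = [self.pair(), self.pair(K=2, n=2, m=1)]
        a = filter_cerna_pairs(list(pairs), lnc, mrna)
        b = filter_cerna_pairs(list(reversed(pairs)), lnc, mrna)
        assert {(p.lncrna_id, p.mrna_id, p.m) for p in a} == {
            (p.lncrna_id, p.mrna_id, p.m) for p in b
        }
        assert all(p in pairs or p.passes for p in a)

    def test_missing_member_named(self):
        lnc, mrna = self.lnc_mrna()
        with pytest.raises(ValidationError, match="MISSING"):
            filter_cerna_pairs([self.pair(mrna_id="MISSING")], lnc, mrna)


class TestNetwork:
    def passing_pair(self):
        return CeRNAPair("L1", "G1", 2, 2, 2, 10,
                         shared_mirnas=frozenset({"m1", "m2"}), passes=True)

    def test_mirna_nodes_on(self):
        g = build_cerna_network([self.passing_pair()], include_mirna_nodes=True)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 5  # 1 pair edge + 2 miRNAs x 2 partners

    def test_mirna_nodes_off(self):
        g = build_cerna_network([self.passing_pair()], include_mirna_nodes=False)
        assert (g.number_of_nodes(), g.number_of_edges()) == (2, 1)

    def test_duplicate_pair_single_edge(self):
        g = build_cerna_network([self.passing_pair(), self.passing_pair()])
        assert g.number_of_edges() == 1

    def test_pair_graph_strips_mirnas(self):
        g = build_cerna_network([self.passing_pair()], include_mirna_nodes=True)
        pg = pair_graph(g)
        assert set(pg.nodes) == {"L1", "G1"}


def brute_force_betweenness(g: nx.Graph) -> dict:
    """All-pairs enumeration of shortest simple paths, counted through nodes."""
    nodes = list(g.nodes)
    bet = {v: 0.0 for v in nodes}

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in g.neighbors(v):
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_paths(s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for p in sp:
                for v in p[1:-1]:
                    bet[v] += 1.0 / len(sp)
    return bet


class TestCentralities:
    def test_path_graph(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")])
        c = centralities(g)
        assert list(c.loc[["a", "b", "c"], "degree"]) == [1, 2, 1]
        assert list(c.loc[["a", "b", "c"], "betweenness"]) == [0.0, 1.0, 0.0]
        assert c.loc["b", "closeness"] == pytest.approx(1.0)
        assert c.loc["a", "closeness"] == pytest.approx(2 / 3)

    def test_complete_graph_zero_betweenness(self):
        c = centralities(nx.complete_graph(4))
        assert (c["betweenness"] == 0).all()

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph()
        g.add_node("x")
        g.add_edge("a", "b")
        c = centralities(g)
        assert c.loc["x", "closeness"] == 0.0

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 30)))
            c = centralities(g)
            oracle = brute_force_betweenness(g)
            for v in g.nodes:
                assert c.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)


class TestRankMirnas:
    def network_with_mirnas(self, mirnas):
        pair = CeRNAPair("L1", "G1", 1, 1, 1, 10,
                         shared_mirnas=frozenset(mirnas), passes=True)
        return build_cerna_network([pair], include_mirna_nodes=True)

    def de_frame(self, lfcs):
        return pd.DataFrame({"log2fc": lfcs}, index=[f"m{i:02d}" for i in range(len(lfcs))])

    def test_truncation_and_short_lists(self):
        mirnas = [f"m{i:02d}" for i in range(25)]
        net = self.network_with_mirnas(mirnas)
        de = self.de_frame(list(np.linspace(-3, 3, 25)))
        assert len(rank_network_mirnas(net, de, k=20)) == 20
        assert len(rank_network_mirnas(net, de, k=40)) == 25

    def test_ranking_by_abs_lfc_deterministic(self):
        net = self.network_with_mirnas(["m00", "m01", "m02"])
        de = self.de_frame([1.0, -2.0, 2.0])
        # |lfc| tie between m01 and m02 -> lexicographic
        assert rank_network_mirnas(net, de, k=3) == ["m01", "m02", "m00"]
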