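"""Hierarchical consensus, networks and modularity clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pycatchr.align_profiles import Hit
from pycatchr.clustering import (
    Clade,
    HitTable,
    all_vs_all,
    build_graph,
    consensus_cladogram,
    consensus_clusters,
    cut_largest_gap,
    hclust_tree,
    modularity_partition,
    score_matrix,
    subcluster,
    weighted_modularity,
)
from pycatchr.align_profiles import profile_from_sequence
from pycatchr.records import AA, ProteinRecord


def make_table(ids, scores, p_values=None, aln_lens=None):
    """HitTable from dense matrices (dicts keyed by ordered pair)."""
    hits = []
    for a in ids:
        for b in ids:
            hits.append(
                Hit(
                    query_id=a,
                    target_id=b,
                    score=scores[(a, b)],
                    p_value=(p_values or {}).get((a, b), 1.0),
                    aln_len=(aln_lens or {}).get((a, b), 100),
                )
            )
    return HitTable(hits=hits, n_targets=len(ids))


class TestScoreMatrix:
    def test_hand_computed_distances(self):
        ids = ["a", "b", "c"]
        raw = {
            ("a", "a"): 10, ("b", "b"): 10, ("c", "c"): 10,
            ("a", "b"): 6, ("b", "a"): 4,   # mean 5
            ("a", "c"): 2, ("c", "a"): 2,   # mean 2
            ("b", "c"): 0, ("c", "b"): 2,   # mean 1
        }
        _, S, D = score_matrix(make_table(ids, raw))
        assert S[0, 1] == pytest.approx(5.0)
        # distances are relative to the best off-diagonal score (5.0)
        assert D[0, 1] == pytest.approx(5 - 5)
        assert D[0, 2] == pytest.approx(5 - 2)
        assert D[1, 2] == pytest.approx(5 - 1)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_missing_pair_raises(self):
        ids = ["a", "b"]
        table = make_table(ids, {(x, y): 1.0 for x in ids for y in ids})
        table.hits = table.hits[:-1]
        with pytest.raises(ValueError, match="missing pair"):
            score_matrix(table)


class TestHclust:
    def test_two_leaves_single_cherry(self):
        tree = hclust_tree(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert tree.root.leaves == frozenset({"a", "b"})
        assert len(tree.root.children) == 2

    def test_forced_topology(self):
        D = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        tree = hclust_tree(["A", "B", "C"], D)
        assert frozenset({"A", "B"}) in tree.clades()

    def test_recovers_ultrametric_topology(self):
        # known tree ((a,b),(c,d)),((e,f)) with ultrametric depths
        ids = list("abcdef")
        depth = {
            frozenset("ab"): 1, frozenset("cd"): 1, frozenset("ef"): 1,
            frozenset("abcd"): 3, frozenset("abcdef"): 5,
        }

        def pair_depth(x, y):
            for k in sorted(depth, key=len):
                if x in k and y in k:
                    return depth[k]

        D = np.zeros((6, 6))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    D[i, j] = 2 * pair_depth(x, y)
        tree = hclust_tree(ids, D)
        clades = set(map(frozenset, tree.clades()))
        for expected in ("ab", "cd", "ef", "abcd"):
            assert frozenset(expected) in clades


class TestConsensus:
    def make_tree(self, nested):
        """nested: tuples of tuples/strings -> Cladogram."""

        def build(n):
            if isinstance(n, str):
                return Clade(frozenset([n]))
            kids = tuple(build(c) for c in n)
            leaves = frozenset().union(*(k.leaves for k in kids))
            return Clade(leaves, children=kids)

        from pycatchr.clustering import Cladogram

        return Cladogram(build(nested))

    def test_identical_trees_identity_with_full_support(self):
        t = (("a", "b"), ("c", ("d", "e")))
        trees = [self.make_tree(t) for _ in range(3)]
        cons = consensus_cladogram(trees)
        assert set(cons.clades()) == set(trees[0].clades())

        def supports(node, acc):
            if not node.is_leaf and node.support is not None:
                acc.append(node.support)
            for c in node.children:
                supports(c, acc)
            return acc

        assert all(s == 1.0 for s in supports(cons.root, []))

    def test_incompatible_resolutions_give_star(self):
        trees = [
            self.make_tree((("a", "b"), "c")),
            self.make_tree((("a", "c"), "b")),
            self.make_tree((("b", "c"), "a")),
        ]
        cons = consensus_cladogram(trees)
        assert cons.clades() == []  # root polytomy only

    def test_two_thirds_majority_kept(self):
        trees = [
            self.make_tree((("a", "b"), "c")),
            self.make_tree((("a", "b"), "c")),
            self.make_tree((("a", "c"), "b")),
        ]
        cons = consensus_cladogram(trees)
        assert set(cons.clades()) == {frozenset({"a", "b"})}

        def find(node):
            if node.leaves == frozenset({"a", "b"}):
                return node
            for c in node.children:
                r = find(c)
                if r:
                    return r

        assert find(cons.root).support == pytest.approx(2 / 3)

    def test_leaf_mismatch_rejected(self):
        t1 = self.make_tree((("a", "b"), "c"))
        t2 = self.make_tree((("a", "b"), "d"))
        with pytest.raises(ValueError, match="leaf-set"):
            consensus_cladogram([t1, t2])


class TestGapCutClusters:
    def two_group_tree(self, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)]
        D = np.full((8, 8), 10.0)
        for i in range(8):
            D[i, i] = 0.0
        for i, j in itertools.combinations(range(4), 2):
            D[i, j] = D[j, i] = 1.0 + jitter * rng.random()
            D[i + 4, j + 4] = D[j + 4, i + 4] = 1.0 + jitter * rng.random()
        return hclust_tree(ids, D)

    def test_cut_recovers_groups(self):
        blocks = cut_largest_gap(self.two_group_tree())
        assert sorted(sorted(b) for b in blocks) == [
            ["x0", "x1", "x2", "x3"],
            ["y0", "y1", "y2", "y3"],
        ]

    def test_replicated_blocks_counted(self):
        trees = [self.two_group_tree(jitter=0.3, seed=s) for s in range(3)]
        blocks = consensus_clusters(trees, min_count=2)
        assert len(blocks) == 2


class TestBuildGraph:
    def random_table(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        scores, ps, lens = {}, {}, {}
        for a in ids:
            for b in ids:
                scores[(a, b)] = float(rng.uniform(0, 50))
                ps[(a, b)] = float(rng.uniform(1e-5, 1.0))
                lens[(a, b)] = int(rng.integers(50, 500))
        return make_table(ids, scores, ps, lens)

    def test_p_floor_gives_edgeless_graph(self):
        table = self.random_table()
        G = build_graph(table, p_max=1e-9)
        assert G.number_of_edges() == 0
        assert G.number_of_nodes() == 6

    def test_weight_cap(self):
        ids = ["a", "b"]
        table = make_table(
            ids,
            {(x, y): 1.0 for x in ids for y in ids},
            p_values={(x, y): 1e-30 for x in ids for y in ids},
        )
        G = build_graph(table, p_max=1e-2)
        assert G["a"]["b"]["weight"] == pytest.approx(20.0)

    def test_min_aln_len_removes_short_edges(self):
        ids = ["a", "b", "c"]
        ps = {(x, y): 1e-4 for x in ids for y in ids}
        lens = {(x, y): 500 for x in ids for y in ids}
        lens[("a", "b")] = lens[("b", "a")] = 120
        table = make_table(ids, {(x, y): 1.0 for x in ids for y in ids}, ps, lens)
        G = build_graph(table, p_max=1e-2, min_aln_len=300)
        assert not G.has_edge("a", "b")
        assert G.has_edge("a", "c") and G.has_edge("b", "c")

    def test_filters_commute(self):
        """The edge set equals the intersection of per-filter edge sets."""
        table = self.random_table(seed=3, n=7)
        full = set(build_graph(table, 5e-2, min_aln_len=250, top_k=2).edges)
        only_p = set(build_graph(table, 5e-2).edges)
        only_len = set(build_graph(table, 1.0 + 1e-9, min_aln_len=250).edges)
        only_k = set(build_graph(table, 1.0 + 1e-9, top_k=2).edges)

        def norm(edges):
            return {frozenset(e) for e in edges}

        assert norm(full) == norm(only_p) & norm(only_len) & norm(only_k)


class TestModularity:
    @staticmethod
    def _brute_best_q(G):
        """Exhaustive best modularity over all partitions (<= 8 nodes)."""
        nodes = sorted(G.nodes)

        def partitions(seq):
            if not seq:
                yield []
                return
            head, rest = seq[0], seq[1:]
            for part in partitions(rest):
                for k in range(len(part)):
                    yield part[:k] + [part[k] + [head]] + part[k + 1 :]
                yield part + [[head]]

        best, best_part = -np.inf, None
        for part in partitions(nodes):
            labels = {n: k for k, block in enumerate(part) for n in block}
            q = weighted_modularity(G, labels)
            if q > best:
                best, best_part = q, part
        return best, best_part

    def test_two_cliques_exact_recovery(self):
        G = nx.Graph()
        for base in (0, 4):
            for i, j in itertools.combinations(range(base, base + 4), 2):
                G.add_edge(i, j, weight=1.0)
        G.add_edge(0, 4, weight=1.0)  # one weak bridge
        part = modularity_partition(G)
        assert part.n_clusters == 2
        assert {frozenset(c) for c in part.clusters()} == {
            frozenset(range(4)),
            frozenset(range(4, 8)),
        }
        best_q, _ = self._brute_best_q(G)
        assert part.modularity_q == pytest.approx(best_q, abs=1e-12)

    def test_single_clique_one_cluster_nonpositive_q(self):
        G = nx.complete_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        part = modularity_partition(G)
        assert part.n_clusters == 1
        assert part.modularity_q <= 0.0

    def test_q_matches_networkx(self):
        """Recomputed Q agrees with networkx's independent implementation."""
        rng = np.random.default_rng(4)
        G = nx.gnp_random_graph(12, 0.4, seed=2)
        for a, b in G.edges:
            G[a][b]["weight"] = float(rng.uniform(0.5, 3.0))
        part = modularity_partition(G)
        comms = {}
        for n, lab in part.labels.items():
            comms.setdefault(lab, set()).add(n)
        q_nx = nx.algorithms.community.modularity(
            G, list(comms.values()), weight="weight"
        )
        assert part.modularity_q == pytest.approx(q_nx, abs=1e-12)

    def test_planted_partition_recovery(self):
        """ARI = 1 against the planted groups across 10 seeds."""
        from sklearn.metrics import adjusted_rand_score

        sizes = [5, 5, 5, 5]
        for seed in range(10):
            G = nx.stochastic_block_model(
                sizes,
                [[0.95 if i == j else 0.05 for j in range(4)] for i in range(4)],
                seed=seed,
            )
            nx.set_edge_attributes(G, 1.0, "weight")
            part = modularity_partition(G, seed=seed)
            truth = [k for k, s in enumerate(sizes) for _ in range(s)]
            pred = [part.labels[n] for n in range(sum(sizes))]
            assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)


class TestSubcluster:
    def planted_graph(self):
        # two 4-cliques joined by bridges; in the full graph the heavy
        # "ballast" cliques push total weight up so the resolution limit
        # merges the bridged pair, which separates again on the subset
        G = nx.Graph()
        for base in (0, 4):
            for i, j in itertools.combinations(range(base, base + 4), 2):
                G.add_edge(i, j, weight=2.0)
        for i in range(3):
            G.add_edge(i, i + 4, weight=1.0)
        for base in (10, 20):
            for i, j in itertools.combinations(range(base, base + 8), 2):
                G.add_edge(i, j, weight=3.0)
        return G

    def test_full_subset_equals_partition(self):
        G = self.planted_graph()
        assert (
            subcluster(G, list(G.nodes)).labels
            == modularity_partition(G).labels
        )

    def test_single_node_single_cluster(self):
        G = self.planted_graph()
        assert subcluster(G, [0]).n_clusters == 1

    def test_merged_community_splits_on_subset(self):
        G = self.planted_graph()
        part = modularity_partition(G)
        merged = max(part.clusters(), key=len)
        assert merged == frozenset(range(8))  # bridges merge the two cliques
        sub = subcluster(G, merged)
        assert sub.n_clusters == 2

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            subcluster(self.planted_graph(), [])


class TestAllVsAll:
    def test_n_squared_hits_and_self_dominance(self):
        rng = np.random.default_rng(6)
        profs = [
            profile_from_sequence(
                ProteinRecord(f"p{i}", "t", "".join(rng.choice(list(AA), 60)))
            )
            for i in range(3)
        ]
        table = all_vs_all(profs, n_shuffles=19, seed=0)
        assert len(table.hits) == 9
        by = table.by_pair()
        for p in profs:
            self_score = by[(p.source_id, p.source_id)].score
            for q in profs:
                if q.source_id != p.source_id:
                    assert by[(p.source_id, q.source_id)].score < self_score
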