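"""All-vs-all profile comparison, consensus cladograms, and modularity
clustering of thresholded similarity networks.

Three flat layers of evidence are produced from family profiles:

* an asymmetric hit table of all ordered profile pairs (alignment length and
  empirical p-value, the heatmap analogue);
* average-linkage cladograms per analysis, combined into a majority-rule
  consensus with per-clade congruence, plus a flat "replicated clusters"
  summary (each analysis's dendrogram cut at its largest merge-height gap,
  keeping leaf blocks recovered in a minimum number of analyses);
* a similarity network with edges at a p-value threshold (optionally an
  alignment-length floor and a top-k hit filter), partitioned by greedy
  modularity maximization, with re-clustering of induced subgraphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .align_profiles import Hit, Profile, empirical_significance, pp_local_align

MAX_EDGE_WEIGHT = 20.0  # -log10 p capped, matching the heatmap's p floor


# ---------------------------------------------------------------------------
# hit table


@dataclass
class HitTable:
    """Ordered hits over all n x n profile pairs (self-hits included)."""

    hits: list
    n_targets: int

    def by_pair(self) -> dict:
        return {(h.query_id, h.target_id): h for h in self.hits}

    @property
    def ids(self) -> list:
        seen = dict.fromkeys(h.query_id for h in self.hits)
        return list(seen)


def all_vs_all(
    profiles: list[Profile],
    n_shuffles: int = 200,
    seed: int = 0,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    significance: bool = True,
) -> HitTable:
    """Every ordered profile pair scored; empirical p via column shuffles.

    With ``significance=False`` only scores/spans are computed (enough for
    score-based cladograms). Deterministic given the seed: the shuffle seed of
    a pair is derived from the pair's position.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    hits = []
    for i, p1 in enumerate(profiles):
        for j, p2 in enumerate(profiles):
            if significance:
                h = empirical_significance(
                    p1,
                    p2,
                    n_shuffles=n_shuffles,
                    seed=(seed * 1_000_003 + i * len(profiles) + j) % (2**31),
                    n_targets=len(profiles),
                    gap_open=gap_open,
                    gap_extend=gap_extend,
                )
            else:
                h = pp_local_align(p1, p2, gap_open, gap_extend)
            hits.append(h)
    return HitTable(hits=hits, n_targets=len(profiles))


def significance_distance(table: HitTable, cap: float = 20.0) -> tuple[list, np.ndarray]:
    """Calibrated distance matrix from shuffle-null significance.

    ``w_ij = min(-log10(min over directions of the Gumbel-tail p), cap)``
    and ``D = cap - w`` (the cap matches the heatmap convention of limiting
    p at 1e-20). Raw local-alignment scores are not comparable across
    profile pairs of different length and composition, whereas each pair's
    null-calibrated significance is; the tail extrapolation keeps resolution
    above the rank floor of the empirical p.
    """
    ids = table.ids
    pos = {q: k for k, q in enumerate(ids)}
    by = table.by_pair()
    n = len(ids)
    W = np.zeros((n, n))
    for a in ids:
        for b in ids:
            if a == b:
                continue
            if (a, b) not in by or (b, a) not in by:
                raise ValueError(f"missing pair {(a, b)} in hit table")
            p = min(by[(a, b)].p_tail, by[(b, a)].p_tail)
            W[pos[a], pos[b]] = min(-np.log10(max(p, 1e-300)), cap)
    D = cap - W
    np.fill_diagonal(D, 0.0)
    return ids, 0.5 * (D + D.T)


def score_matrix(table: HitTable) -> tuple[list, np.ndarray, np.ndarray]:
    """Symmetrized scores and the rank-preserving distance transform.

    ``S_ij = mean(score_ij, score_ji)``; ``D = max_offdiag(S) - S`` with a
    zero diagonal. The maximum is taken over distinct pairs: self-hit scores
    are much larger than any cross-profile score and would otherwise compress
    every off-diagonal distance into a narrow band.
    """
    ids = table.ids
    pos = {q: k for k, q in enumerate(ids)}
    by = table.by_pair()
    n = len(ids)
    S = np.zeros((n, n))
    for a, b in itertools.product(ids, repeat=2):
        if (a, b) not in by:
            raise ValueError(f"missing pair {(a, b)} in hit table")
        S[pos[a], pos[b]] = by[(a, b)].score
    S = 0.5 * (S + S.T)
    off = ~np.eye(n, dtype=bool)
    D = (S[off].max() if n > 1 else 0.0) - S
    np.fill_diagonal(D, 0.0)
    return ids, S, D


# ---------------------------------------------------------------------------
# cladograms


@dataclass
class Clade:
    """Rooted tree node; ``support`` is the congruence fraction of the clade."""

    leaves: frozenset
    children: tuple = ()
    support: float | None = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: "Clade") -> str:
            if node.is_leaf:
                (leaf,) = node.leaves
                return str(leaf)
            inner = ",".join(fmt(c) for c in sorted(node.children, key=lambda c: min(c.leaves)))
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.2f}"
            return f"({inner}){label}"

        return fmt(self) + ";"


@dataclass
class Cladogram:
    root: Clade
    linkage: np.ndarray | None = None
    leaf_ids: list | None = None

    @property
    def leaves(self) -> frozenset:
        return self.root.leaves

    def clades(self) -> list[frozenset]:
        """All non-trivial clades (more than one leaf, not the full set)."""
        out = []

        def walk(node: Clade):
            if 1 < len(node.leaves) < len(self.root.leaves):
                out.append(node.leaves)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out


def hclust_tree(ids: list, D: np.ndarray) -> Cladogram:
    """Average-linkage (UPGMA-style) agglomeration of a distance matrix.

    scipy's deterministic linkage is used; the clade set is what downstream
    consensus logic consumes, and ties are resolved by scipy's fixed ordering
    with leaf labels sorted within each clade.
    """
    if len(ids) == 1:
        return Cladogram(Clade(frozenset(ids)), None, list(ids))
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    nodes: dict[int, Clade] = {
        i: Clade(frozenset([ids[i]])) for i in range(len(ids))
    }
    for k, (ia, ib, height, _) in enumerate(Z):
        a, b = nodes.pop(int(ia)), nodes.pop(int(ib))
        nodes[len(ids) + k] = Clade(
            a.leaves | b.leaves, children=(a, b), height=float(height)
        )
    (root,) = nodes.values()
    return Cladogram(root, Z, list(ids))


def consensus_cladogram(
    trees: list[Cladogram], min_frac: float = 2.0 / 3.0
) -> Cladogram:
    """Majority-rule consensus with per-clade congruence labels.

    Keeps exactly the clades present in at least ``ceil(min_frac * n)`` input
    trees (for three analyses and the default threshold: at least two);
    unsupported resolution collapses into polytomies.
    """
    if not trees:
        raise ValueError("need at least one tree")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            raise ValueError("leaf-set mismatch between cladograms")
    n = len(trees)
    need = int(np.ceil(min_frac * n))
    counts: dict[frozenset, int] = {}
    for t in trees:
        for clade in set(t.clades()):
            counts[clade] = counts.get(clade, 0) + 1
    kept = {c: k for c, k in counts.items() if k >= need}
    # majority clades (>50%) are pairwise compatible; nest them
    ordered = sorted(kept, key=len, reverse=True)

    def build(leafset: frozenset, inner: list) -> Clade:
        direct = []
        used: set = set()
        for c in inner:
            if c < leafset and not any(c < d for d in inner if d != c and d < leafset):
                if not used & c:
                    direct.append(c)
                    used |= c
        children = []
        for c in direct:
            sub = [d for d in inner if d < c]
            node = build(c, sub)
            node.support = kept[c] / n
            children.append(node)
        for leaf in sorted(leafset - used):
            children.append(Clade(frozenset([leaf])))
        return Clade(leafset, children=tuple(children), support=1.0)

    root = build(leaves, ordered)
    return Cladogram(root, None, sorted(leaves))


def cut_largest_gap(tree: Cladogram) -> list[frozenset]:
    """Flat partition of a dendrogram at its largest merge-height gap.

    In the twilight-zone regime, within-class merges sit far below the
    noise-level between-class merges; the largest gap in consecutive merge
    heights separates the two and recovers the class partition without
    choosing k. A single-leaf tree is its own block.
    """
    if tree.linkage is None:
        return [tree.leaves]
    Z = tree.linkage
    heights = Z[:, 2]
    if len(heights) == 1:
        cut = heights[0] + 1.0
    else:
        gaps = np.diff(heights)
        k = int(np.argmax(gaps))
        cut = 0.5 * (heights[k] + heights[k + 1])
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    blocks: dict[int, set] = {}
    for leaf, lab in zip(tree.leaf_ids, labels):
        blocks.setdefault(int(lab), set()).add(leaf)
    return [frozenset(b) for b in blocks.values()]


def cut_at_height(tree: Cladogram, height: float) -> list[frozenset]:
    """Flat partition merging everything below a fixed dendrogram height.

    With distances of the form ``cap - min(-log10 p, cap)``, cutting at
    ``cap - 2`` groups exactly the leaves whose average linkage is more
    significant than p = 1e-2 — the same criterion the similarity network
    applies to individual edges.
    """
    if tree.linkage is None:
        return [tree.leaves]
    labels = hierarchy.fcluster(tree.linkage, t=height, criterion="distance")
    blocks: dict[int, set] = {}
    for leaf, lab in zip(tree.leaf_ids, labels):
        blocks.setdefault(int(lab), set()).add(leaf)
    return [frozenset(b) for b in blocks.values()]


def consensus_clusters(
    trees: list[Cladogram],
    min_count: int = 2,
    cut=cut_largest_gap,
) -> list[frozenset]:
    """Clusters replicated across analyses.

    Each analysis's dendrogram is flattened with ``cut`` (largest
    merge-height gap by default, or a fixed significance height); blocks
    recovered identically in at least ``min_count`` analyses are the
    replicated clusters (sorted by size then lexicographically).
    """
    counts: dict[frozenset, int] = {}
    for t in trees:
        for block in cut(t):
            counts[block] = counts.get(block, 0) + 1
    kept = [b for b, k in counts.items() if k >= min_count]
    # keep blocks disjoint: prefer better-replicated, then larger blocks
    kept.sort(key=lambda b: (-counts[b], -len(b), sorted(b)))
    out: list[frozenset] = []
    used: set = set()
    for b in kept:
        if not (b & used):
            out.append(b)
            used |= b
    return sorted(out, key=lambda b: (-len(b), sorted(b)))


# ---------------------------------------------------------------------------
# similarity network and modularity


def build_graph(
    table: HitTable,
    p_max: float = 1e-2,
    min_aln_len: int | None = None,
    top_k: int | None = None,
    use_tail: bool = False,
) -> nx.Graph:
    """Undirected similarity network from the directed hit table.

    An edge (i, j) exists when either directed hit passes every filter:
    ``p < p_max``, optionally ``aln_len > min_aln_len``, optionally being
    among the query's ``top_k`` non-self hits by p-value. Edge weight is
    ``min(-log10(best p), 20)``. Self-hits are excluded; all profiles appear
    as nodes. The filters commute: each is a per-directed-hit predicate.
    """
    def pval(h):
        return h.p_tail if use_tail else h.p_value

    G = nx.Graph()
    for q in table.ids:
        G.add_node(q)
    allowed: set = set()
    if top_k is not None:
        by_query: dict = {}
        for h in table.hits:
            if h.query_id != h.target_id:
                by_query.setdefault(h.query_id, []).append(h)
        for q, hs in by_query.items():
            hs.sort(key=lambda h: (pval(h), -h.score, h.target_id))
            for h in hs[:top_k]:
                allowed.add((h.query_id, h.target_id))
    for h in table.hits:
        if h.query_id == h.target_id:
            continue
        if pval(h) >= p_max:
            continue
        if min_aln_len is not None and h.aln_len <= min_aln_len:
            continue
        if top_k is not None and (h.query_id, h.target_id) not in allowed:
            continue
        w = min(-np.log10(max(pval(h), 1e-300)), MAX_EDGE_WEIGHT)
        a, b = h.query_id, h.target_id
        if G.has_edge(a, b):
            G[a][b]["weight"] = max(G[a][b]["weight"], w)
            G[a][b]["p"] = min(G[a][b]["p"], pval(h))
            G[a][b]["aln_len"] = max(G[a][b]["aln_len"], h.aln_len)
        else:
            G.add_edge(a, b, weight=w, p=pval(h), aln_len=h.aln_len)
    return G


@dataclass
class Partition:
    labels: dict
    modularity_q: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> list[frozenset]:
        out: dict = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return [
            frozenset(c)
            for c in sorted(out.values(), key=lambda c: (-len(c), sorted(c)))
        ]


def weighted_modularity(G: nx.Graph, labels: dict) -> float:
    """Standard weighted modularity, recomputed from first principles."""
    W = sum(d["weight"] for _, _, d in G.edges(data=True))
    if W == 0:
        return 0.0
    deg = {n: 0.0 for n in G.nodes}
    for a, b, d in G.edges(data=True):
        deg[a] += d["weight"]
        deg[b] += d["weight"]
    q = 0.0
    for a, b, d in G.edges(data=True):
        if labels[a] == labels[b]:
            q += d["weight"] / W
    for com in set(labels.values()):
        k = sum(deg[n] for n in G.nodes if labels[n] == com)
        q -= (k / (2.0 * W)) ** 2
    return q


def modularity_partition(G: nx.Graph, seed: int = 0) -> Partition:
    """Greedy (CNM) modularity maximization with deterministic ordering.

    networkx's agglomerative greedy_modularity_communities is deterministic;
    the returned Q is recomputed from scratch with
    :func:`weighted_modularity`. Isolated nodes become singleton clusters.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if G.number_of_edges() == 0:
        labels = {n: k for k, n in enumerate(sorted(G.nodes))}
        return Partition(labels, 0.0)
    comms = nx.algorithms.community.greedy_modularity_communities(
        G, weight="weight"
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))
    labels = {}
    for k, com in enumerate(comms):
        for n in com:
            labels[n] = k
    return Partition(labels, weighted_modularity(G, labels))


def subcluster(G: nx.Graph, node_subset, seed: int = 0) -> Partition:
    """Re-partition the induced subgraph of ``node_subset``."""
    subset = set(node_subset)
    if not subset:
        raise ValueError("empty node subset")
    missing = subset - set(G.nodes)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(missing)}")
    return modularity_partition(G.subgraph(subset).copy(), seed=seed)


# ---------------------------------------------------------------------------
# serialization


def write_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tp\taln_len\n")
        for a, b, d in sorted(G.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{d['weight']:.3f}\t{d['p']:.3e}\t{d['aln_len']}\n"
            )


def write_clusters_tsv(partition: Partition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# modularity_q\t{partition.modularity_q:.6f}\n")
        fh.write("node\tcluster\n")
        for node in sorted(partition.labels):
            fh.write(f"{node}\t{partition.labels[node]}\n")


def write_heatmap_matrices(table: HitTable, aln_path, logp_path) -> None:
    """Asymmetric heatmap: alignment length above the diagonal, log10 p below
    (p capped at 1e-20, as in the figure convention)."""
    ids = table.ids
    by = table.by_pair()
    n = len(ids)
    aln = np.zeros((n, n), dtype=int)
    logp = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            h = by[(a, b)]
            aln[i, j] = h.aln_len
            logp[i, j] = np.log10(max(h.p_value, 1e-20))
    for path, M, fmt in ((aln_path, aln, "%d"), (logp_path, logp, "%.3f")):
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(ids) + "\n")
            for i, a in enumerate(ids):
                row = "\t".join(fmt % v for v in M[i])
                fh.write(f"{a}\t{row}\n")
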