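"""Simulator of deeply divergent paralogous protein families.

The generative model follows the ancestral-tetramer scenario for CATCHR-style
complexes: an ancestral dimer (one body-forming, one arm-forming subunit)
duplicates into a tetramer of four subunit classes (g51, g52, g53, g54; the
g53/g54 split being the shallowest and the g52 lineage the most remote), and
the whole tetramer is then duplicated repeatedly into five full complexes
plus one "half" complex that retains only its g53/g54 subunits. Each family
founder finally evolves along a shared species tree, with per-taxon family
losses and lineage-specific duplications.

Sequence evolution is a per-branch replacement process: a site of rate ``r``
is replaced over a branch of length ``d`` (substitutions/site) with
probability ``1 - exp(-r * d)``, the replacement drawn from a BLOSUM62-derived
conditional distribution. Site rates are gamma-distributed and inherited
through the whole gene tree, which is what leaves profile-detectable
conserved columns once average identity has decayed into the twilight zone.
An N-terminal heptad coiled-coil segment, evolved from one template shared by
*all* families at a quarter of the body rate (with replacements drawn from
heptad-position-specific preferences), provides the confounding shared signal
that motivates coiled-coil masking downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import AA, BACKGROUND, BLOSUM62, ProteinRecord
from .coiled_coil import propensity_table

CLASSES = ("g51", "g52", "g53", "g54")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Depths are in expected substitutions per site at unit rate. Class and
    complex split depths must decrease from the g52 (root) split toward the
    complex duplications; the species tree hangs below the family founders.
    """

    n_taxa: int = 7
    species_tree_depth: float = 6.0
    species_ladder_decay: float = 0.90
    species_pair_depth_frac: float = 0.15
    class_split_depths: dict = field(
        default_factory=lambda: {"g52": 26.0, "g51": 16.0, "g53_g54": 10.5}
    )
    complex_split_depths: dict = field(
        default_factory=lambda: {
            "cpxB": 5.8,
            "cpxC": 5.4,
            "cpxH": 5.0,
            "cpxD": 4.6,
            "cpxE": 4.2,
        }
    )
    half_complexes: tuple = ("cpxH",)
    seq_length: int = 700
    cc_length: int = 56
    cc_start: int = 1
    sub_rate_scale: float = 1.0
    site_rate_shape: float = 1.0
    site_rate_block_len: float = 15.0
    core_block_frac: float = 0.18
    core_block_rate: float = 0.11
    core_block_len: float = 25.0
    cc_rate_factor: float = 0.25
    indel_rate: float = 0.0015
    indel_len_mean: float = 3.0
    p_loss: float = 0.12
    p_lineage_dup: float = 0.04
    lineage_dup_depth: float = 0.3
    seed: int = 1

    def validate(self) -> None:
        for name in ("p_loss", "p_lineage_dup"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seq_length <= self.cc_start + self.cc_length:
            raise ValueError("seq_length must exceed cc_start + cc_length")
        if self.n_taxa < 1:
            raise ValueError("need at least one taxon")
        depths = dict(self.class_split_depths)
        if len(depths) >= 2:
            order = [d for d in ("g52", "g51", "g53_g54") if d in depths]
            vals = [depths[k] for k in order]
            if any(a <= b for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    "class split depths must strictly decrease g52 > g51 > g53_g54"
                )
        if self.complex_split_depths and depths:
            if max(self.complex_split_depths.values()) >= min(depths.values()):
                raise ValueError(
                    "complex duplications must be shallower than class splits"
                )
        for v in list(depths.values()) + list(self.complex_split_depths.values()):
            if v <= 0:
                raise ValueError("split depths must be positive")

    @property
    def taxa(self) -> list[str]:
        return [f"tax{i + 1:02d}" for i in range(self.n_taxa)]

    @property
    def cc_slice(self) -> slice:
        return slice(self.cc_start - 1, self.cc_start - 1 + self.cc_length)


# ---------------------------------------------------------------------------
# duplication history


@dataclass(frozen=True)
class HistoryEvent:
    kind: str  # dimer_origin | dimer_duplication | tetramer_duplication | subunit_loss
    parent_unit: str
    child_units: tuple
    time: float  # relative depth in [0, 1]; 1.0 at the root


@dataclass
class DuplicationHistory:
    """Rooted tree over subunit 'units' plus the event list that built it."""

    events: list[HistoryEvent]
    unit_labels: dict  # leaf unit id -> (complex_name, class_name)
    split_depth: dict  # internal node id -> absolute depth (subs/site)
    children: dict  # node id -> tuple of child node ids
    root: str = "dimer"

    @property
    def families(self) -> list[str]:
        return sorted(self.unit_labels)

    def classes_present(self, complex_name: str) -> list[str]:
        return sorted(
            cls for (cpx, cls) in self.unit_labels.values() if cpx == complex_name
        )

    def to_newick(self) -> str:
        def fmt(node: str, parent_depth: float) -> str:
            depth = self.split_depth.get(node, 0.0)
            blen = parent_depth - depth
            kids = self.children.get(node, ())
            if not kids:
                return f"{node}:{blen:.6g}"
            inner = ",".join(fmt(k, depth) for k in kids)
            return f"({inner}){node}:{blen:.6g}"

        root_depth = self.split_depth[self.root]
        kids = ",".join(fmt(k, root_depth) for k in self.children[self.root])
        return f"({kids}){self.root};"


def simulate_history(config: SimulationConfig) -> DuplicationHistory:
    """Build the duplication history implied by the configured split depths.

    Default structure: dimer origin (g52 ancestor vs body ancestor), dimer
    duplications resolving the four classes (g53/g54 shallowest), then one
    tetramer duplication per configured complex, with subunit losses turning
    the configured half-complexes into g53/g54-only survivors.
    """
    config.validate()
    depths = dict(config.class_split_depths)
    cpx_depths = dict(config.complex_split_depths)
    dup_order = sorted(cpx_depths, key=cpx_depths.get, reverse=True)
    classes = list(CLASSES) if depths else ["g51"]
    base_cpx = "cpxA"
    root_depth = depths.get("g52", max(list(cpx_depths.values()) or [1.0]) * 1.5)

    def rel(d: float) -> float:
        return d / root_depth

    # units removed from half-complexes (the DSL1-analogue keeps only g53/g54)
    lost = {
        f"{cpx}_{cls}"
        for cpx in config.half_complexes
        if cpx in cpx_depths
        for cls in ("g51", "g52")
        if cls in classes
    }

    children: dict = {}
    split_depth: dict = {}
    events: list[HistoryEvent] = []

    def class_subtree(cls: str) -> str:
        """Caterpillar of tetramer duplications for one class lineage."""
        lineage = f"{base_cpx}_{cls}"
        for cpx in reversed(dup_order):  # shallowest duplication first
            leaf = f"{cpx}_{cls}"
            if leaf in lost:
                continue
            node = f"dup_{cpx}_{cls}"
            split_depth[node] = cpx_depths[cpx]
            children[node] = (leaf, lineage)
            lineage = node
        return lineage

    if len(classes) == 1:
        root = "dimer"
        split_depth[root] = root_depth
        sub = class_subtree(classes[0])
        children[root] = (sub,)
        events.append(HistoryEvent("dimer_origin", root, (sub,), 1.0))
    else:
        split_depth["dimer"] = depths["g52"]
        split_depth["anc_body"] = depths["g51"]
        split_depth["anc_g5354"] = depths["g53_g54"]
        children["dimer"] = (class_subtree("g52"), "anc_body")
        children["anc_body"] = (class_subtree("g51"), "anc_g5354")
        children["anc_g5354"] = (class_subtree("g53"), class_subtree("g54"))
        events.append(
            HistoryEvent("dimer_origin", "dimer", ("anc_g52", "anc_body"), 1.0)
        )
        events.append(
            HistoryEvent(
                "dimer_duplication",
                "anc_body",
                ("anc_g51", "anc_g5354"),
                rel(depths["g51"]),
            )
        )
        events.append(
            HistoryEvent(
                "dimer_duplication",
                "anc_g5354",
                ("anc_g53", "anc_g54"),
                rel(depths["g53_g54"]),
            )
        )

    for cpx in dup_order:
        kept = tuple(f"{cpx}_{c}" for c in classes if f"{cpx}_{c}" not in lost)
        events.append(
            HistoryEvent("tetramer_duplication", "tetramer", kept, rel(cpx_depths[cpx]))
        )
    for unit in sorted(lost):
        cpx = unit.rsplit("_", 1)[0]
        events.append(
            HistoryEvent("subunit_loss", unit, (), rel(cpx_depths[cpx]) * 0.95)
        )

    unit_labels = {
        f"{cpx}_{cls}": (cpx, cls)
        for cpx in [base_cpx] + dup_order
        for cls in classes
        if f"{cpx}_{cls}" not in lost
    }
    return DuplicationHistory(
        events=events,
        unit_labels=unit_labels,
        split_depth=split_depth,
        children=children,
    )


# ---------------------------------------------------------------------------
# dataset containers


@dataclass(frozen=True)
class TruthRecord:
    protein_id: str
    taxon: str
    complex_name: str
    class_name: str
    family: str
    seed_ortholog: str
    events: tuple


@dataclass
class SyntheticDataset:
    proteomes: dict  # taxon -> list[ProteinRecord]
    truth: dict  # protein_id -> TruthRecord
    history: DuplicationHistory | None
    newick: str = ""
    site_maps: dict | None = None  # protein_id -> ancestral site ids (in-memory)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.proteomes)

    def all_records(self) -> list[ProteinRecord]:
        return [rec for taxon in self.taxa for rec in self.proteomes[taxon]]

    def family_members(self) -> dict:
        """family -> list of protein ids (from the truth table)."""
        out: dict = {}
        for pid, tr in sorted(self.truth.items()):
            out.setdefault(tr.family, []).append(pid)
        return out

    def records_for(self, taxon: str) -> dict:
        return {rec.id: rec for rec in self.proteomes[taxon]}

    def seed_proteins(self, taxon: str) -> dict:
        """family -> ProteinRecord for one taxon (primary copies only)."""
        by_id = self.records_for(taxon)
        out: dict = {}
        for pid, tr in sorted(self.truth.items()):
            if tr.taxon == taxon and "lineage_duplication" not in tr.events:
                if pid in by_id:
                    out[tr.family] = by_id[pid]
        return out


# ---------------------------------------------------------------------------
# sequence evolution


class _EvoSeq:
    """Residues plus per-site metadata carried through the simulation."""

    __slots__ = ("res", "site_id", "rate", "heptad")

    def __init__(self, res, site_id, rate, heptad):
        self.res = res
        self.site_id = site_id
        self.rate = rate
        self.heptad = heptad  # heptad position 0..6 for CC sites, -1 for body

    def copy(self) -> "_EvoSeq":
        return _EvoSeq(
            self.res.copy(), self.site_id.copy(), self.rate.copy(), self.heptad.copy()
        )


def _conditional_matrix() -> np.ndarray:
    """Replacement distribution P(b | a), b != a, from BLOSUM62 targets."""
    C = BACKGROUND[None, :] * np.exp2(BLOSUM62 / 2.0)
    np.fill_diagonal(C, 0.0)
    return C / C.sum(axis=1, keepdims=True)


_COND = _conditional_matrix()


def _cc_emission() -> np.ndarray:
    prop = propensity_table()
    em = prop * BACKGROUND[:, None]
    return em / em.sum(axis=0)


_CC_EM = _cc_emission()


def _block_rates(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Blockwise site rates: a slow conserved core plus a gamma bulk.

    Rates are shared within geometric-length blocks, producing contiguous
    conserved cores (helical-bundle packing motifs) rather than isolated
    slow sites. A fraction ``core_block_frac`` of blocks belongs to a
    near-frozen structural core evolving at ``core_block_rate``; the rest
    draws gamma(shape) rates. The core is what keeps remote families
    profile-detectable long after average identity has fallen into the
    twilight zone, while the gamma bulk controls how fast ortholog identity
    decays.
    """
    from scipy import stats

    shape = config.site_rate_shape
    # geometric-length blocks; block rates are a *stratified* sample of the
    # gamma distribution (quantiles at jittered, shuffled stratum positions).
    # The marginal law is unchanged, but every dataset realizes the same
    # rate spectrum: with iid draws the number of slow blocks — which
    # controls how detectable remote homologs are — would be a per-dataset
    # lottery with large variance.
    lengths = []
    total = 0
    p = 1.0 / max(config.site_rate_block_len, 1.0)
    while total < n:
        blen = int(rng.geometric(p))
        lengths.append(blen)
        total += blen
    lengths = np.array(lengths)
    # site-weighted stratification: blocks receive gamma quantiles at the
    # midpoints of their cumulative site spans, so the per-site rate
    # spectrum is (up to block granularity) identical in every dataset;
    # shuffling the (length, rate) pairs then randomizes physical placement
    # without disturbing that spectrum
    ends = np.cumsum(lengths)
    mids = (ends - lengths / 2.0) / total
    block_rates = stats.gamma.ppf(mids, a=shape, scale=1.0 / shape)
    order = rng.permutation(len(lengths))
    rates = np.empty(n)
    k0 = 0
    for idx in order:
        blen = int(lengths[idx])
        rates[k0 : min(k0 + blen, n)] = block_rates[idx]
        k0 += blen
        if k0 >= n:
            break
    # conserved core elements: a deterministic number of fixed-length
    # segments placed quasi-uniformly (jittered within strata) across the
    # body, i.e. downstream of the coiled-coil segment. Longer elements
    # concentrate the same conserved content into contiguous anchors, which
    # is what local alignment can actually chain
    blen = int(round(config.core_block_len))
    body_lo = config.cc_start - 1 + config.cc_length
    body_n = n - body_lo
    n_core = int(round(config.core_block_frac * n / max(blen, 1)))
    if n_core > 0 and body_n >= n_core * blen:
        stratum = body_n / n_core
        for j in range(n_core):
            lo = body_lo + int(j * stratum)
            hi = max(lo + 1, body_lo + int((j + 1) * stratum) - blen)
            start = int(rng.integers(lo, hi)) if hi > lo else lo
            rates[start : start + blen] = config.core_block_rate
    return rates


def _root_sequence(config: SimulationConfig, rng: np.random.Generator) -> _EvoSeq:
    L = config.seq_length
    res = rng.choice(20, size=L, p=BACKGROUND).astype(np.int8)
    heptad = np.full(L, -1, dtype=np.int8)
    cc = config.cc_slice
    pos = np.arange(config.cc_length) % 7
    for k, p in zip(range(cc.start, cc.stop), pos):
        res[k] = rng.choice(20, p=_CC_EM[:, p])
        heptad[k] = p
    rate = _block_rates(L, config, rng)
    rate[cc] = config.cc_rate_factor
    return _EvoSeq(res, np.arange(L, dtype=np.int64), rate, heptad)


class _Evolver:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self._next_site_id = config.seq_length

    def branch(self, seq: _EvoSeq, d: float) -> _EvoSeq:
        """Evolve a copy of ``seq`` along a branch of length ``d``."""
        cfg = self.config
        rng = self.rng
        out = seq.copy()
        d_eff = d * cfg.sub_rate_scale
        if d_eff > 0:
            p_sub = -np.expm1(-out.rate * d_eff)
            hit = np.nonzero(rng.random(len(out.res)) < p_sub)[0]
            for k in hit:
                if out.heptad[k] >= 0:
                    out.res[k] = rng.choice(20, p=_CC_EM[:, out.heptad[k]])
                else:
                    out.res[k] = rng.choice(20, p=_COND[out.res[k]])
        # indels (body only, geometric lengths), scaled by raw branch length
        if cfg.indel_rate > 0 and d > 0:
            n_events = rng.poisson(cfg.indel_rate * len(out.res) * d)
            for _ in range(n_events):
                out = self._one_indel(out)
        return out

    def _one_indel(self, seq: _EvoSeq) -> _EvoSeq:
        cfg = self.config
        rng = self.rng
        body = np.nonzero(seq.heptad < 0)[0]
        if len(body) < 10:
            return seq
        p_geom = 1.0 / cfg.indel_len_mean
        length = int(rng.geometric(p_geom))
        pos = int(rng.choice(body))
        if rng.random() < 0.5:  # deletion of body positions from pos
            run = body[body >= pos][:length]
            keep = np.ones(len(seq.res), dtype=bool)
            keep[run] = False
            return _EvoSeq(
                seq.res[keep], seq.site_id[keep], seq.rate[keep], seq.heptad[keep]
            )
        new_res = rng.choice(20, size=length, p=BACKGROUND).astype(np.int8)
        new_rate = rng.gamma(
            cfg.site_rate_shape, 1.0 / cfg.site_rate_shape, size=length
        )
        new_ids = np.arange(self._next_site_id, self._next_site_id + length)
        self._next_site_id += length
        return _EvoSeq(
            np.insert(seq.res, pos, new_res),
            np.insert(seq.site_id, pos, new_ids),
            np.insert(seq.rate, pos, new_rate),
            np.insert(seq.heptad, pos, np.full(length, -1, dtype=np.int8)),
        )


# ---------------------------------------------------------------------------
# species tree


def _species_tree(config: SimulationConfig, rng: np.random.Generator):
    """Ultrametric species tree with a paired panel design.

    Taxa are grouped into pairs of close relatives (each pair splitting at
    ``pair_depth_frac`` of the tree depth), and the pairs hang from a ladder
    of deep splits. This emulates the usual proteome panel for remote
    orthology: every deeply diverged lineage is represented by a couple of
    related proteomes, while lineages themselves sit at twilight-zone
    distances. Returned as nested (name, depth, children) tuples; leaves
    carry depth 0.
    """
    taxa = list(config.taxa)
    R = config.species_tree_depth
    decay = config.species_ladder_decay
    pair_depth = config.species_pair_depth_frac * R
    pairs: list = []
    n_pairs = (len(taxa) + 1) // 2
    for k in range(n_pairs):
        members = taxa[k::n_pairs]  # tax01+tax05, tax02+tax06, ...
        if len(members) == 1:
            pairs.append((members[0], 0.0, ()))
        else:
            kids = tuple((m, 0.0, ()) for m in members)
            pairs.append((None, pair_depth, kids))
    # unpaired lineages take the deepest ladder slots
    pairs.sort(key=lambda p: len(p[2]))
    if len(pairs) == 1:
        return pairs[0]
    node = pairs[-1]
    depth = R * (decay ** (len(pairs) - 2))
    for k in range(len(pairs) - 2, -1, -1):
        node = (None, depth, (pairs[k], node))
        depth /= decay
    return node


# ---------------------------------------------------------------------------
# main entry points


def evolve_dataset(
    history: DuplicationHistory, config: SimulationConfig
) -> SyntheticDataset:
    """Evolve sequences along the duplication history and the species tree."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    evolver = _Evolver(config, rng)
    root_seq = _root_sequence(config, rng)

    # founders: walk the unit tree from the root depth down to depth 0
    founders: dict = {}

    def walk_units(node: str, seq: _EvoSeq, node_depth: float):
        kids = history.children.get(node, ())
        if not kids:
            # leaf lineage: evolve the remaining depth down to the founder
            leaf_seq = evolver.branch(seq, node_depth)
            # map chain leaf names to family units
            founders[node] = leaf_seq
            return
        for kid in kids:
            kid_depth = history.split_depth.get(kid, 0.0)
            child_seq = evolver.branch(seq, node_depth - kid_depth)
            walk_units(kid, child_seq, kid_depth)

    root_depth = history.split_depth[history.root]
    walk_units(history.root, root_seq, root_depth)

    families = history.families
    sp_tree = _species_tree(config, rng)

    # per family, evolve the founder along the shared species tree
    tip_seqs: dict = {}  # (family, taxon) -> _EvoSeq

    def walk_species(node, seq: _EvoSeq, node_depth: float, family: str):
        name, depth, kids = node
        if not kids:
            tip_seqs[(family, name)] = seq
            return
        for kid in kids:
            _, kid_depth, _ = kid
            child_seq = evolver.branch(seq, node_depth - kid_depth)
            walk_species(kid, child_seq, kid_depth, family)

    for fam in families:
        walk_species(sp_tree, founders[fam], config.species_tree_depth, fam)

    # losses and lineage duplications, in fixed iteration order
    taxa = config.taxa
    losses: set = set()
    dups: set = set()
    for taxon in taxa:
        for fam in families:
            if rng.random() < config.p_loss:
                losses.add((fam, taxon))
    for taxon in taxa:
        for fam in families:
            if (fam, taxon) not in losses and rng.random() < config.p_lineage_dup:
                dups.add((fam, taxon))

    proteomes: dict = {}
    truth: dict = {}
    site_maps: dict = {}
    ref_taxon = taxa[0]
    seed_ids: dict = {}

    per_taxon_entries: dict = {t: [] for t in taxa}
    for taxon in taxa:
        for fam in families:
            if (fam, taxon) in losses:
                continue
            entries = [(fam, tip_seqs[(fam, taxon)], ("speciation",))]
            if (fam, taxon) in dups:
                extra = evolver.branch(
                    tip_seqs[(fam, taxon)],
                    config.lineage_dup_depth * config.species_tree_depth,
                )
                entries.append((fam, extra, ("speciation", "lineage_duplication")))
            per_taxon_entries[taxon].extend(entries)

    for taxon in taxa:
        entries = per_taxon_entries[taxon]
        order = rng.permutation(len(entries))
        records = []
        for k, idx in enumerate(order):
            fam, seq, events = entries[idx]
            pid = f"{taxon}_p{k + 1:03d}"
            residues = "".join(AA[i] for i in seq.res)
            records.append(ProteinRecord(pid, taxon, residues))
            cpx, cls = history.unit_labels[fam]
            truth[pid] = TruthRecord(
                protein_id=pid,
                taxon=taxon,
                complex_name=cpx,
                class_name=cls,
                family=fam,
                seed_ortholog="",
                events=events,
            )
            site_maps[pid] = seq.site_id.copy()
            if taxon == ref_taxon and "lineage_duplication" not in events:
                seed_ids[fam] = pid
        proteomes[taxon] = records

    # fill seed_ortholog now that the reference taxon is assigned
    for pid, tr in list(truth.items()):
        truth[pid] = replace(tr, seed_ortholog=seed_ids.get(tr.family, ""))

    newick = history.to_newick()
    return SyntheticDataset(
        proteomes=proteomes,
        truth=truth,
        history=history,
        newick=newick,
        site_maps=site_maps,
    )


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Convenience wrapper: history plus evolved dataset from one config."""
    config = config or SimulationConfig()
    return evolve_dataset(simulate_history(config), config)


# ---------------------------------------------------------------------------
# I/O


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """One wrapped FASTA per taxon, a truth table, and the unit-tree Newick."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for taxon in dataset.taxa:
        with open(os.path.join(out_dir, f"{taxon}.fasta"), "w") as fh:
            for rec in dataset.proteomes[taxon]:
                fh.write(f">{rec.id}\n")
                for k in range(0, len(rec.residues), 60):
                    fh.write(rec.residues[k : k + 60] + "\n")
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write(
            "protein_id\ttaxon\tcomplex\tclass\tfamily\tseed_ortholog\tevents\n"
        )
        for pid in sorted(dataset.truth):
            tr = dataset.truth[pid]
            fh.write(
                f"{pid}\t{tr.taxon}\t{tr.complex_name}\t{tr.class_name}\t"
                f"{tr.family}\t{tr.seed_ortholog}\t{';'.join(tr.events)}\n"
            )
    with open(os.path.join(out_dir, "history.nwk"), "w") as fh:
        fh.write(dataset.newick + "\n")


def read_dataset(in_dir) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    import glob
    import os

    proteomes: dict = {}
    for path in sorted(glob.glob(os.path.join(in_dir, "*.fasta"))):
        taxon = os.path.splitext(os.path.basename(path))[0]
        records = []
        rid = None
        chunks: list = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if rid is not None:
                        records.append(ProteinRecord(rid, taxon, "".join(chunks)))
                    rid = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
        if rid is not None:
            records.append(ProteinRecord(rid, taxon, "".join(chunks)))
        proteomes[taxon] = records
    truth: dict = {}
    with open(os.path.join(in_dir, "truth.tsv")) as fh:
        fh.readline()
        for line in fh:
            pid, taxon, cpx, cls, fam, seed_id, events = line.rstrip("\n").split("\t")
            truth[pid] = TruthRecord(
                protein_id=pid,
                taxon=taxon,
                complex_name=cpx,
                class_name=cls,
                family=fam,
                seed_ortholog=seed_id,
                events=tuple(events.split(";")) if events else (),
            )
    with open(os.path.join(in_dir, "history.nwk")) as fh:
        newick = fh.read().strip()
    return SyntheticDataset(
        proteomes=proteomes, truth=truth, history=None, newick=newick
    )
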