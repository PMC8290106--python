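"""One-command orchestration: simulate (or read) proteomes, annotate coiled
coils, run the three-seed reciprocal orthology workflow, build per-family
alignments and profiles (masked and unmasked), compare everything against
everything, and summarize cladograms, networks and ortholog tables.

Every stage writes plain-text artifacts into the output directory and logs
one line with its input/output counts; identical config + seed reproduce the
run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .align_profiles import (
    MSA,
    build_profile,
    pairwise_global_align,
    pairwise_stats,
    progressive_msa,
    trim_gappy_columns,
    write_hits_tsv,
)
from .clustering import (
    Partition,
    all_vs_all,
    build_graph,
    consensus_cladogram,
    hclust_tree,
    modularity_partition,
    significance_distance,
    subcluster,
    write_clusters_tsv,
    write_edge_list,
    write_heatmap_matrices,
)
from .coiled_coil import (
    cc_mask,
    fixed_nterm_mask,
    masked_record,
    mask_msa_columns,
    write_cc_tsv,
)
from .orthology import (
    ABSENT,
    ProfileSearch,
    SearchParams,
    SequenceSearch,
    apply_overrides,
    build_ortholog_table,
    build_search_profile,
    combine_seed_analyses,
    rescue_pass,
    run_seed_analysis,
    write_assignments_tsv,
)
from .records import ProteinRecord
from .synthetic_data import (
    SimulationConfig,
    SyntheticDataset,
    read_dataset,
    simulate_dataset,
    write_dataset,
)

log = logging.getLogger("pycatchr")


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the workflow's canonical thresholds
    (enrichment 3x/1e-5, forward 1e-3, reciprocal 4x/1e-2, sequence-level
    1e-2/1e-3 with coverage > 0.4, trimming at 80% gaps, 2/3 congruence,
    network p < 1e-2, alignment length > 300 and top-4 hits for the
    complex-level network variant)."""

    mode: str = "simulate"  # simulate | user
    input_dir: str | None = None  # user mode: proteomes/*.fasta + seeds/*.fasta
    out_dir: str = "pycatchr_run"
    seed: int = 1
    n_seed_taxa: int = 3
    # module thresholds
    search: SearchParams = field(default_factory=SearchParams)
    trim_max_gap_frac: float = 0.8
    cc_threshold: float = 0.5
    cc_window: int = 28
    #: if set, mask this many N-terminal residues instead of predicting
    cc_fixed_cut: int | None = None
    #: optional manual curation file applied after all automated stages
    overrides_path: str | None = None
    mask_searches: bool = True
    consensus_min_frac: float = 2.0 / 3.0
    network_p_max: float = 1e-2
    variant_min_aln_len: int = 300
    variant_top_k: int = 4
    n_shuffles: int = 100
    n_shuffles_cladograms: int = 50
    #: run the cladogram/network classification stages (off for
    #: orthology-only runs)
    run_classification: bool = True
    run_unmasked_network: bool = True
    run_single_seq: bool = True
    # identity/similarity report alignment penalties (stiff, to keep the
    # gapless-pair identity of unrelated sequences near the true mismatch rate)
    stats_gap_open: float = 25.0
    stats_gap_extend: float = 2.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "search" in d and isinstance(d["search"], dict):
            d["search"] = SearchParams(**d["search"])
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            if "half_complexes" in sim:
                sim["half_complexes"] = tuple(sim["half_complexes"])
            d["simulation"] = SimulationConfig(**sim)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: str
    dataset: SyntheticDataset
    combined: dict
    consensus_blocks: list
    network_partition: Partition
    sub_partitions: dict
    graph: "object"
    artifacts: dict
    trees: list = field(default_factory=list)
    analysis_partitions: list = field(default_factory=list)


def _stage(name):
    log.info("stage: %s", name)


def _load_user_inputs(input_dir: str):
    import glob

    proteome_paths = sorted(glob.glob(os.path.join(input_dir, "proteomes", "*.fasta")))
    seed_paths = sorted(glob.glob(os.path.join(input_dir, "seeds", "*.fasta")))
    if not proteome_paths or not seed_paths:
        raise FileNotFoundError(
            f"user mode expects {input_dir}/proteomes/*.fasta and {input_dir}/seeds/*.fasta"
        )
    proteomes: dict = {}
    for path in proteome_paths:
        taxon = os.path.splitext(os.path.basename(path))[0]
        msa = MSA.from_fasta(path)  # plain FASTA parses fine (no gaps)
        proteomes[taxon] = [
            ProteinRecord(rid, taxon, seq.replace("-", "")) for rid, seq in msa.rows
        ]
    seed_families: dict = {}  # family -> list[ProteinRecord (taxon from id prefix)]
    by_id = {r.id: r for recs in proteomes.values() for r in recs}
    for path in seed_paths:
        family = os.path.splitext(os.path.basename(path))[0]
        msa = MSA.from_fasta(path)
        members = []
        for rid, seq in msa.rows:
            if rid in by_id:
                members.append(by_id[rid])
            else:
                raise ValueError(
                    f"seed {rid!r} of family {family!r} not found in any proteome"
                )
        seed_families[family] = members
    return proteomes, seed_families


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t_start = time.time()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    artifacts: dict = {}

    handler = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(config, out, artifacts, t_start)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config, out, artifacts, t_start) -> PipelineResult:
    # ------------------------------------------------------------------ input
    _stage("input")
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    if config.mode == "simulate":
        dataset = simulate_dataset(sim)
        data_dir = os.path.join(out, "dataset")
        write_dataset(dataset, data_dir)
        artifacts["dataset"] = data_dir
        proteomes = dataset.proteomes
        taxa = dataset.taxa
        seed_taxa = taxa[: config.n_seed_taxa]
        seeds_by_taxon = {t: dataset.seed_proteins(t) for t in seed_taxa}
    elif config.mode == "user":
        proteomes, seed_families = _load_user_inputs(config.input_dir)
        dataset = SyntheticDataset(proteomes=proteomes, truth={}, history=None)
        taxa = sorted(proteomes)
        seeds_by_taxon = {}
        for family, members in seed_families.items():
            for rec in members:
                seeds_by_taxon.setdefault(rec.taxon, {})[family] = rec
        seed_taxa = sorted(seeds_by_taxon)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    log.info(
        "input: %d taxa, %d proteins, %d seed taxa",
        len(taxa),
        sum(len(v) for v in proteomes.values()),
        len(seed_taxa),
    )

    # ------------------------------------------------------------ cc annotate
    _stage("coiled-coil annotation")
    annotations = {}
    masked = {}
    for taxon in sorted(proteomes):
        for rec in proteomes[taxon]:
            if config.cc_fixed_cut is not None:
                ann = fixed_nterm_mask(rec, config.cc_fixed_cut)
            else:
                ann = cc_mask(
                    rec, threshold=config.cc_threshold, window=config.cc_window
                )
            annotations[rec.id] = ann
            masked[rec.id] = masked_record(rec, ann)
    write_cc_tsv(
        [annotations[r.id] for t in sorted(proteomes) for r in proteomes[t]],
        os.path.join(out, "cc.tsv"),
    )
    artifacts["cc"] = os.path.join(out, "cc.tsv")
    log.info("cc: %d proteins annotated", len(annotations))

    # -------------------------------------------------------------- orthology
    _stage("orthology")
    params = dataclasses.replace(config.search, seed=config.seed)
    search_recs = masked if config.mask_searches else {
        r.id: r for t in proteomes for r in proteomes[t]
    }
    sprot = {t: [search_recs[r.id] for r in proteomes[t]] for t in sorted(proteomes)}
    db = [rec for t in sorted(sprot) for rec in sprot[t]]
    search = ProfileSearch(db, params)
    seq_search = SequenceSearch(db, params) if config.run_single_seq else None
    cache: dict = {}
    enriched: dict = {}
    analyses = []
    for st in seed_taxa:
        seeds = {
            fam: search_recs[rec.id] for fam, rec in sorted(seeds_by_taxon[st].items())
        }
        analysis = run_seed_analysis(
            seeds, st, sprot, search, seq_search=seq_search,
            profile_cache=cache, enriched_out=enriched,
        )
        analyses.append(analysis)
        n_cells = sum(1 for a in analysis if a.method == "profile")
        n_ok = sum(1 for a in analysis if a.status == "reciprocal_ok")
        log.info(
            "orthology[%s]: %d cells, %d reciprocal_ok entries", st, n_cells, n_ok
        )
    combined = combine_seed_analyses(analyses)

    # second-generation rescue: pooled family profiles re-search cells that
    # no single analysis could validate
    by_id = {r.id: r for t in proteomes for r in proteomes[t]}

    def _family_profiles(assignments: dict) -> tuple[dict, dict, dict]:
        msas: dict = {}
        masked_profiles: dict = {}
        unmasked_profiles: dict = {}
        fams = sorted({fam for fam, _ in assignments})
        for fam in fams:
            member_ids = []
            for st in seed_taxa:
                rec = seeds_by_taxon[st].get(fam)
                if rec is not None:
                    member_ids.append(rec.id)
            for (f, tax), a in assignments.items():
                if (
                    f == fam
                    and a.status in ("reciprocal_ok", "conflict")
                    and a.target_id != ABSENT
                ):
                    member_ids.append(a.target_id)
                    member_ids.extend(a.co_ortholog_ids)
            member_ids = list(dict.fromkeys(member_ids))
            recs = [by_id[i] for i in member_ids]
            msa = progressive_msa(recs)
            msa = trim_gappy_columns(msa, config.trim_max_gap_frac)
            msas[fam] = msa
            pmsa = trim_gappy_columns(msa, params.profile_max_gap_frac)
            mask_cols = mask_msa_columns(pmsa, annotations)
            unmasked_profiles[fam] = build_profile(pmsa, source_id=fam)
            masked_profiles[fam] = build_profile(
                pmsa, cc_mask_cols=mask_cols, source_id=fam
            )
        return msas, masked_profiles, unmasked_profiles

    _, rescue_profiles, _ = _family_profiles(combined)
    seeds_masked = {
        st: {fam: search_recs[rec.id] for fam, rec in seeds_by_taxon[st].items()}
        for st in seed_taxa
    }
    n_before = sum(1 for a in combined.values() if a.status == "reciprocal_ok")
    combined = rescue_pass(
        combined, rescue_profiles, sprot, seeds_masked, search, cache
    )
    n_after = sum(1 for a in combined.values() if a.status == "reciprocal_ok")
    log.info("rescue: %d -> %d reciprocal_ok cells", n_before, n_after)
    if config.overrides_path:
        combined = apply_overrides(combined, config.overrides_path)
        log.info("overrides applied from %s", config.overrides_path)
    write_assignments_tsv(combined, os.path.join(out, "orthologs.tsv"))
    table = build_ortholog_table(combined)
    table.to_csv(os.path.join(out, "ortholog_matrix.tsv"), sep="\t")
    artifacts["orthologs"] = os.path.join(out, "orthologs.tsv")
    artifacts["ortholog_matrix"] = os.path.join(out, "ortholog_matrix.tsv")

    # ------------------------------------------- identity/similarity (report)
    _stage("ortholog pairwise stats")
    stats_rows = []
    for (fam, tax), a in sorted(combined.items()):
        if a.status not in ("reciprocal_ok", "conflict") or a.target_id == ABSENT:
            continue
        seed_rec = by_id[a.seed_id]
        target_rec = by_id[a.target_id]
        aln, _ = pairwise_global_align(
            seed_rec,
            target_rec,
            gap_open=config.stats_gap_open,
            gap_extend=config.stats_gap_extend,
        )
        try:
            ident, sim_pct = pairwise_stats(aln)
        except ValueError:
            continue
        stats_rows.append((fam, a.seed_taxon, tax, ident, sim_pct))
    with open(os.path.join(out, "ortholog_pairwise_stats.tsv"), "w") as fh:
        fh.write("family\tseed_taxon\ttarget_taxon\tidentity_pct\tsimilarity_pct\n")
        for row in stats_rows:
            fh.write("%s\t%s\t%s\t%.2f\t%.2f\n" % row)
    artifacts["pairwise_stats"] = os.path.join(out, "ortholog_pairwise_stats.tsv")
    log.info("stats: %d ortholog pairs", len(stats_rows))

    # ------------------------------------------------- per-family MSA/profile
    _stage("family alignments and profiles")
    families = sorted({fam for fam, _ in combined})
    family_msas, family_profiles_masked, family_profiles_unmasked = (
        _family_profiles(combined)
    )
    msa_dir = os.path.join(out, "msas")
    os.makedirs(msa_dir, exist_ok=True)
    for fam in families:
        family_msas[fam].to_fasta(os.path.join(msa_dir, f"{fam}.fasta"))
        family_profiles_masked[fam].to_tsv(
            os.path.join(msa_dir, f"{fam}.profile_masked.tsv")
        )
    artifacts["msas"] = msa_dir
    log.info("profiles: %d families", len(families))

    if not config.run_classification:
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "mode": config.mode,
            "n_taxa": len(taxa),
            "n_families": len(families),
            "elapsed_s": round(time.time() - t_start, 1),
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        config.save(os.path.join(out, "config.yaml"))
        log.info("done (orthology only) in %.1f s", time.time() - t_start)
        return PipelineResult(
            out_dir=out,
            dataset=dataset,
            combined=combined,
            consensus_blocks=[],
            network_partition=Partition({}, 0.0),
            sub_partitions={},
            graph=None,
            artifacts=artifacts,
        )

    # ------------------------------------------------------------- cladograms
    _stage("cladograms (three analyses)")
    common = [
        fam
        for fam in families
        if all(fam in seeds_by_taxon[st] for st in seed_taxa)
    ]
    # per-analysis family profiles: each seed taxon's own recovered ortholog
    # set (seed + validated targets and co-orthologs of that analysis only)
    members_by_analysis: dict = {}
    for st, analysis in zip(seed_taxa, analyses):
        for a in analysis:
            if a.method != "profile":
                continue
            key = (st, a.family)
            members_by_analysis.setdefault(
                key, [seeds_by_taxon[st][a.family].id]
            )
            if a.status == "reciprocal_ok" and a.target_id != ABSENT:
                members_by_analysis[key].append(a.target_id)
                members_by_analysis[key].extend(a.co_ortholog_ids)
    trees = []
    analysis_partitions: list = []
    for st in seed_taxa:
        profs = []
        for fam in common:
            ids_ = list(dict.fromkeys(members_by_analysis.get((st, fam), [])))
            recs = [by_id[i] for i in ids_]
            msa = trim_gappy_columns(
                progressive_msa(recs), params.profile_max_gap_frac
            )
            cols = mask_msa_columns(msa, annotations)
            profs.append(build_profile(msa, cc_mask_cols=cols, source_id=fam))
        tbl = all_vs_all(
            profs,
            n_shuffles=config.n_shuffles_cladograms,
            seed=config.seed * 31 + seed_taxa.index(st),
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
        )
        ids, D = significance_distance(tbl)
        tree = hclust_tree(ids, D)
        trees.append(tree)
        with open(os.path.join(out, f"cladogram_{st}.nwk"), "w") as fh:
            fh.write(tree.root.to_newick(with_support=False) + "\n")
        # flat clusters of this analysis: modularity communities of its
        # tail-significance graph (same edge criterion as the network)
        G_a = build_graph(tbl, p_max=config.network_p_max, use_tail=True)
        analysis_partitions.append(modularity_partition(G_a, seed=config.seed))
    consensus = consensus_cladogram(trees, min_frac=config.consensus_min_frac)
    with open(os.path.join(out, "consensus_cladogram.nwk"), "w") as fh:
        fh.write(consensus.root.to_newick() + "\n")
    # evidence accumulation: keep pairs co-clustered in >= 2/3 of the
    # analyses; replicated clusters are the connected components
    need = max(2, int(np.ceil(config.consensus_min_frac * len(trees))))
    import itertools as _it

    import networkx as _nx

    pair_counts: dict = {}
    for part in analysis_partitions:
        for com in part.clusters():
            for a_, b_ in _it.combinations(sorted(com), 2):
                pair_counts[(a_, b_)] = pair_counts.get((a_, b_), 0) + 1
    G_cons = _nx.Graph()
    G_cons.add_nodes_from(common)
    for (a_, b_), k in pair_counts.items():
        if k >= need:
            G_cons.add_edge(a_, b_)
    components = [frozenset(c) for c in _nx.connected_components(G_cons)]
    # a replicated cluster is a group: families that never co-cluster in
    # enough analyses stay unassigned rather than forming one-member clusters
    blocks = sorted(
        (b for b in components if len(b) > 1),
        key=lambda b: (-len(b), sorted(b)),
    )
    unassigned = sorted(f for b in components if len(b) == 1 for f in b)
    with open(os.path.join(out, "consensus_clusters.tsv"), "w") as fh:
        fh.write("cluster\tmembers\n")
        for k, b in enumerate(blocks):
            fh.write(f"{k}\t{','.join(sorted(b))}\n")
        if unassigned:
            fh.write(f"unassigned\t{','.join(unassigned)}\n")
    artifacts["consensus"] = os.path.join(out, "consensus_cladogram.nwk")
    artifacts["consensus_clusters"] = os.path.join(out, "consensus_clusters.tsv")
    log.info("consensus: %d replicated clusters over %d families", len(blocks), len(common))

    # ---------------------------------------------------------------- network
    _stage("similarity network (masked profiles)")
    profs_masked = [family_profiles_masked[fam] for fam in families]
    tbl_masked = all_vs_all(
        profs_masked,
        n_shuffles=config.n_shuffles,
        seed=config.seed,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    write_hits_tsv(tbl_masked.hits, os.path.join(out, "hits_masked.tsv"))
    write_heatmap_matrices(
        tbl_masked,
        os.path.join(out, "heatmap_aln_len.tsv"),
        os.path.join(out, "heatmap_log10p.tsv"),
    )
    G = build_graph(tbl_masked, p_max=config.network_p_max)
    write_edge_list(G, os.path.join(out, "network_edges.tsv"))
    partition = modularity_partition(G, seed=config.seed)
    write_clusters_tsv(partition, os.path.join(out, "clusters.tsv"))
    artifacts["clusters"] = os.path.join(out, "clusters.tsv")
    log.info(
        "network: %d nodes, %d edges, %d clusters (Q=%.3f)",
        G.number_of_nodes(), G.number_of_edges(),
        partition.n_clusters, partition.modularity_q,
    )

    # re-cluster network communities that merge several consensus clusters
    # (a cluster counts as inside when at least half its members are)
    sub_partitions: dict = {}
    for k, com in enumerate(partition.clusters()):
        contained = [
            b for b in blocks if len(b) > 1 and len(b & com) >= len(b) / 2
        ]
        if len(contained) >= 2:
            sub = subcluster(G, com, seed=config.seed)
            sub_partitions[k] = sub
            write_clusters_tsv(sub, os.path.join(out, f"subclusters_{k}.tsv"))
            log.info(
                "subcluster[%d]: %d nodes -> %d clusters", k, len(com), sub.n_clusters
            )

    # complex-level network variant (long alignments, top hits only)
    G_var = build_graph(
        tbl_masked,
        p_max=config.network_p_max,
        min_aln_len=config.variant_min_aln_len,
        top_k=config.variant_top_k,
    )
    write_edge_list(G_var, os.path.join(out, "network_edges_top4_long.tsv"))

    if config.run_unmasked_network:
        _stage("similarity network (unmasked profiles)")
        profs_un = [family_profiles_unmasked[fam] for fam in families]
        tbl_un = all_vs_all(
            profs_un,
            n_shuffles=config.n_shuffles,
            seed=config.seed + 1,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
        )
        write_hits_tsv(tbl_un.hits, os.path.join(out, "hits_unmasked.tsv"))
        G_un = build_graph(tbl_un, p_max=config.network_p_max)
        write_edge_list(G_un, os.path.join(out, "network_edges_unmasked.tsv"))
        p_un = modularity_partition(G_un, seed=config.seed)
        write_clusters_tsv(p_un, os.path.join(out, "clusters_unmasked.tsv"))

    # ---------------------------------------------------------------- manifest
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "n_taxa": len(taxa),
        "n_families": len(families),
        "elapsed_s": round(time.time() - t_start, 1),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.save(os.path.join(out, "config.yaml"))
    log.info("done in %.1f s", time.time() - t_start)
    return PipelineResult(
        out_dir=out,
        dataset=dataset,
        combined=combined,
        consensus_blocks=blocks,
        network_partition=partition,
        sub_partitions=sub_partitions,
        graph=G,
        artifacts=artifacts,
        trees=trees,
        analysis_partitions=analysis_partitions,
    )


# ---------------------------------------------------------------------------
# report


def export_report(out_dir: str) -> dict:
    """Summary tables from a completed run directory.

    Returns a dict with the ortholog count matrix, the identity/similarity
    distribution summary, the coiled-coil count table, and the cluster
    membership with a per-complex composition check (does every cluster
    contain one protein of each full complex; half complexes are expected to
    appear in only part of the clusters).
    """
    import pandas as pd

    needed = [
        "ortholog_matrix.tsv",
        "ortholog_pairwise_stats.tsv",
        "cc.tsv",
        "clusters.tsv",
        "consensus_clusters.tsv",
    ]
    missing = [f for f in needed if not os.path.exists(os.path.join(out_dir, f))]
    if missing:
        raise FileNotFoundError(f"missing artifacts in {out_dir}: {missing}")
    matrix = pd.read_csv(os.path.join(out_dir, "ortholog_matrix.tsv"), sep="\t", index_col=0)
    stats = pd.read_csv(os.path.join(out_dir, "ortholog_pairwise_stats.tsv"), sep="\t")
    cc = pd.read_csv(os.path.join(out_dir, "cc.tsv"), sep="\t")
    clusters = pd.read_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", comment="#")

    summary = {
        "ortholog_matrix": matrix,
        "identity_median": float(stats["identity_pct"].median()),
        "similarity_median": float(stats["similarity_pct"].median()),
        "cc_counts": cc,
        "clusters": clusters,
    }
    # composition check: complex = family-name prefix before the last '_'
    comp: dict = {}
    for _, row in clusters.iterrows():
        fam = str(row["node"])
        cpx = fam.rsplit("_", 1)[0] if "_" in fam else fam
        comp.setdefault(cpx, set()).add(int(row["cluster"]))
    n_clusters = int(clusters["cluster"].nunique())
    summary["complex_composition"] = {
        cpx: {
            "n_clusters_present": len(cl),
            "spans_all_clusters": len(cl) == n_clusters,
        }
        for cpx, cl in sorted(comp.items())
    }
    path = os.path.join(out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(
            {
                k: v
                for k, v in summary.items()
                if k in ("identity_median", "similarity_median", "complex_composition")
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return summary
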