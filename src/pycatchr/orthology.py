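"""Reciprocal profile-search orthology with multi-seed consensus.

The workflow mirrors the classic iterative-HMM recipe for deeply divergent
families: per seed protein, an iteratively enriched profile (inclusion
threshold on the e-value) is searched against every target proteome; the best
forward hit is validated by building an enriched profile of the hit and
checking that the back-search into the seed proteome returns the seed at rank
one. The same logic is run from three seed taxa and combined by best e-value,
and a sequence-level reciprocal search (global alignment with a coverage
floor) provides an independent second method; disagreements are flagged as
conflicts rather than resolved silently.

E-values: a rank-based p-value cannot resolve the small inclusion thresholds
this workflow uses, so search significance comes from a Gumbel (extreme value)
tail fitted to a null of column-shuffled-profile scores against sampled
database sequences -- the same family of calibration HMMER relies on.
``e = p * n_targets`` for the searched database.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import _dp
from .align_profiles import (
    MSA,
    Hit,
    Profile,
    align_msa_to_msa,
    build_profile,
    fit_gumbel,
    gumbel_sf,
    pairwise_global_align,
    ps_local_align,
    ps_local_score,
    trim_gappy_columns,
    _gap_multipliers,
    _ps_score_matrix,
    _seq_score_matrix,
)
from .records import BLOSUM62, GAP_CHAR, MASK_CHAR, ProteinRecord, encode

ABSENT = "ABSENT"


@dataclass(frozen=True)
class SearchParams:
    """Thresholds of the reciprocal search workflow (iterative enrichment
    3x at 1e-5; forward 1e-3; reciprocal enrichment 4x at 1e-2; sequence-level
    1e-2 forward / 1e-3 back with coverage > 0.4)."""

    iters: int = 3
    incl_e: float = 1e-5
    e_forward: float = 1e-3
    recip_iters: int = 4
    recip_incl_e: float = 1e-2
    single_e_fwd: float = 1e-2
    single_e_back: float = 1e-3
    min_cov: float = 0.4
    gap_open: float = 10.0
    gap_extend: float = 1.0
    n_null: int = 64
    max_enrich_hits: int = 12
    max_coorthologs: int = 2
    candidate_pool: int = 40
    profile_max_gap_frac: float = 0.5
    seed: int = 0


@dataclass
class OrthologAssignment:
    """One seed-family x target-taxon decision."""

    family: str
    seed_id: str
    seed_taxon: str
    target_taxon: str
    target_id: str  # protein id or ABSENT
    e_value: float
    method: str  # profile | single | both
    status: str  # reciprocal_ok | reciprocal_fail | conflict | absent
    co_ortholog_ids: tuple = ()


class ProfileSearch:
    """Profile-vs-database local search with EVD-calibrated significance."""

    def __init__(
        self,
        database: list[ProteinRecord],
        params: SearchParams | None = None,
    ):
        self.database = list(database)
        self.by_id = {r.id: r for r in self.database}
        self.params = params or SearchParams()
        self._enc = {
            r.id: encode(r.residues, allow_mask=True) for r in self.database
        }

    def _score_records(
        self, profile: Profile, records: list[ProteinRecord]
    ) -> np.ndarray:
        """Local scores of profile vs records, reusing cached encodings."""
        p = self.params
        lo = profile.log_odds()
        mul_x = _gap_multipliers(profile.col_gap_frac)
        out = np.empty(len(records))
        for i, rec in enumerate(records):
            idx = self._enc.get(rec.id)
            if idx is None:
                idx = encode(rec.residues, allow_mask=True)
            out[i] = _dp.sw_score_idx(lo, idx, p.gap_open, p.gap_extend, mul_x)
        return out

    def _null_scores(self, profile: Profile) -> np.ndarray:
        """Null: column-shuffled profile vs sampled database sequences.

        Shuffling profile columns preserves composition, so compositional
        confounders (e.g. coiled-coil residue bias) are absorbed by the null.
        """
        p = self.params
        rng = np.random.default_rng(
            (p.seed * 7919 + zlib.crc32(profile.source_id.encode())) % (2**31)
        )
        n_seq = min(len(self.database), 8)
        sample_idx = rng.choice(len(self.database), size=n_seq, replace=False)
        per_seq = max(1, p.n_null // n_seq)
        lo = profile.log_odds()
        mul_x = _gap_multipliers(profile.col_gap_frac)
        nulls = []
        for si in sample_idx:
            rec = self.database[si]
            idx = self._enc[rec.id]
            for _ in range(per_seq):
                perm = rng.permutation(profile.n_cols)
                nulls.append(
                    _dp.sw_score_idx(
                        np.ascontiguousarray(lo[perm]),
                        idx,
                        p.gap_open,
                        p.gap_extend,
                        mul_x[perm],
                    )
                )
        return np.asarray(nulls)

    def calibrate(self, profile: Profile) -> tuple[float, float]:
        return fit_gumbel(self._null_scores(profile))

    def search(
        self,
        profile: Profile,
        targets: list[ProteinRecord],
        calib: tuple[float, float] | None = None,
        n_total: int | None = None,
    ) -> list[Hit]:
        """Score ``targets``, attach Gumbel p and e = p * n_total.

        ``n_total`` defaults to the number of targets scored; pass the full
        database size when scoring a pre-filtered candidate subset so that
        e-values stay comparable. Hits are returned sorted by (e-value,
        -score, target id); spans are filled lazily via :meth:`refine`.
        """
        mu, beta = calib if calib is not None else self.calibrate(profile)
        n = n_total if n_total is not None else len(targets)
        scores = self._score_records(profile, targets)
        hits = []
        for rec, score in zip(targets, scores):
            pv = gumbel_sf(float(score), mu, beta)
            hits.append(
                Hit(
                    query_id=profile.source_id,
                    target_id=rec.id,
                    score=float(score),
                    p_value=pv,
                    e_value=min(pv * n, n),
                )
            )
        hits.sort(key=lambda h: (h.e_value, -h.score, h.target_id))
        return hits

    def rank_targets(
        self, profile: Profile, targets: list[ProteinRecord]
    ) -> list[tuple[float, str]]:
        """(score, id) pairs sorted best-first; used where only the ranking
        matters (thresholdless back-searches), avoiding null calibration."""
        scores = self._score_records(profile, targets)
        scored = [(float(s), rec.id) for s, rec in zip(scores, targets)]
        scored.sort(key=lambda t: (-t[0], t[1]))
        return scored

    def refine(self, profile: Profile, hit: Hit) -> Hit:
        """Fill spans/coverage of a hit via full traceback."""
        p = self.params
        full = ps_local_align(
            profile, self.by_id[hit.target_id], p.gap_open, p.gap_extend
        )
        hit.q_span, hit.t_span = full.q_span, full.t_span
        hit.aln_len, hit.q_coverage = full.aln_len, full.q_coverage
        return hit


def build_search_profile(
    seed: ProteinRecord,
    search: ProfileSearch,
    iters: int | None = None,
    incl_e: float | None = None,
) -> tuple[Profile, MSA]:
    """Iterative profile enrichment (jackhmmer-style).

    Each round searches the pooled database and adds hits at or below the
    inclusion e-value to the alignment (via profile-profile merging), then
    rebuilds the profile. ``iters`` rounds exactly; with no hits the profile
    stays the single-seed profile.
    """
    p = search.params
    iters = p.iters if iters is None else iters
    incl_e = p.incl_e if incl_e is None else incl_e
    msa = MSA([(seed.id, seed.residues)])
    profile = build_profile(msa, source_id=seed.id)
    prev_ids: tuple = ()
    n_db = len(search.database)
    candidates = search.database
    for it in range(iters):
        hits = search.search(profile, candidates, n_total=n_db)
        if it == 0 and iters > 1:
            # acceleration cascade: later rounds rescan only plausible
            # homologs of the first full-database pass (p below 0.5 or the
            # best-scoring tail); e-values stay Bonferroni over the full db
            keep = {h.target_id for h in hits if h.p_value < 0.5}
            keep.update(h.target_id for h in hits[: p.candidate_pool])
            candidates = [r for r in search.database if r.id in keep]
        incl = [
            h
            for h in hits
            if h.e_value <= incl_e and h.target_id != seed.id
        ][: p.max_enrich_hits]
        ids = tuple(h.target_id for h in incl)
        if ids == prev_ids:
            break  # exact fixed point: the rebuilt profile would be identical
        prev_ids = ids
        msa = MSA([(seed.id, seed.residues)])
        for h in incl:
            rec = search.by_id[h.target_id]
            msa = align_msa_to_msa(msa, MSA([(rec.id, rec.residues)]))
        # majority-gap columns carry no signal and inflate the DP matrices;
        # profiles are built from a harder-trimmed copy of the alignment
        profile = build_profile(
            trim_gappy_columns(msa, p.profile_max_gap_frac), source_id=seed.id
        )
    return profile, msa


def forward_best_hit(
    profile: Profile,
    target_proteome: list[ProteinRecord],
    search: ProfileSearch,
    e_max: float | None = None,
    calib: tuple[float, float] | None = None,
) -> Hit | None:
    """Best hit by e-value among targets passing the forward threshold.

    Ties on e-value are broken by longer alignment, then lexicographic id.
    Returns ``None`` (ABSENT) when nothing passes.
    """
    if not target_proteome:
        raise ValueError("empty target proteome")
    e_max = search.params.e_forward if e_max is None else e_max
    hits = search.search(profile, target_proteome, calib=calib)
    passing = [h for h in hits if h.e_value <= e_max]
    if not passing:
        return None
    best_e = passing[0].e_value
    tied = [h for h in passing if h.e_value <= best_e * (1 + 1e-9)]
    if len(tied) > 1:
        for h in tied:
            search.refine(profile, h)
        tied.sort(key=lambda h: (-h.aln_len, h.target_id))
        return tied[0]
    return search.refine(profile, passing[0])


def reciprocal_check(
    hit: Hit,
    seed_proteome: list[ProteinRecord],
    seed_id: str,
    search: ProfileSearch,
    profile_cache: dict | None = None,
) -> str:
    """Back-search validation: enrich a profile from the forward hit and ask
    whether the top-ranked protein of the seed proteome is the seed itself
    (no e-value threshold on the back search)."""
    if not seed_proteome:
        raise ValueError("empty seed proteome")
    p = search.params
    target_rec = search.by_id[hit.target_id]
    if profile_cache is not None and hit.target_id in profile_cache:
        back_profile = profile_cache[hit.target_id]
    else:
        back_profile, _ = build_search_profile(
            target_rec, search, iters=p.recip_iters, incl_e=p.recip_incl_e
        )
        if profile_cache is not None:
            profile_cache[hit.target_id] = back_profile
    ranked = search.rank_targets(back_profile, seed_proteome)
    return "reciprocal_ok" if ranked[0][1] == seed_id else "reciprocal_fail"


# ---------------------------------------------------------------------------
# sequence-level (single protein) reciprocal search


class SequenceSearch:
    """Global-alignment search with the same EVD significance recipe."""

    def __init__(self, database: list[ProteinRecord], params: SearchParams):
        self.database = list(database)
        self.by_id = {r.id: r for r in self.database}
        self.params = params
        self._calib: dict = {}

    def _score(self, a: ProteinRecord, b: ProteinRecord) -> float:
        ai = encode(a.residues, allow_mask=True)
        bi = encode(b.residues, allow_mask=True)
        S = _seq_score_matrix(ai, bi, BLOSUM62)
        return float(
            _dp.nw_score_only(S, self.params.gap_open, self.params.gap_extend)
        )

    def calibrate(self, query: ProteinRecord) -> tuple[float, float]:
        if query.id in self._calib:
            return self._calib[query.id]
        p = self.params
        rng = np.random.default_rng(
            (p.seed * 104729 + zlib.crc32(query.id.encode())) % (2**31)
        )
        residues = list(query.residues)
        n_seq = min(len(self.database), 6)
        sample_idx = rng.choice(len(self.database), size=n_seq, replace=False)
        per_seq = max(1, p.n_null // n_seq)
        nulls = []
        for si in sample_idx:
            rec = self.database[si]
            for _ in range(per_seq):
                rng.shuffle(residues)
                shuf = ProteinRecord(query.id, query.taxon, "".join(residues))
                nulls.append(self._score(shuf, rec))
        out = fit_gumbel(np.asarray(nulls))
        self._calib[query.id] = out
        return out

    def best_hit(
        self,
        query: ProteinRecord,
        proteome: list[ProteinRecord],
        e_max: float,
        min_cov: float,
    ) -> tuple[ProteinRecord | None, float]:
        """Best passing hit (coverage strictly above the floor) and e-value."""
        mu, beta = self.calibrate(query)
        scored = []
        for rec in proteome:
            s = self._score(query, rec)
            scored.append((s, rec))
        scored.sort(key=lambda t: (-t[0], t[1].id))
        for s, rec in scored:
            e = min(gumbel_sf(s, mu, beta) * len(proteome), len(proteome))
            if e > e_max:
                break  # sorted by score; nothing below can pass
            aln, _ = pairwise_global_align(
                query, rec, gap_open=self.params.gap_open,
                gap_extend=self.params.gap_extend,
            )
            aligned = sum(
                1
                for x, y in zip(aln.a_gapped, aln.b_gapped)
                if x != GAP_CHAR and y != GAP_CHAR
            )
            if aligned / len(query.residues) > min_cov:
                return rec, e
        return None, 1.0


def single_seq_reciprocal(
    seed: ProteinRecord,
    target_proteome: list[ProteinRecord],
    seed_proteome: list[ProteinRecord],
    seq_search: SequenceSearch,
    family: str | None = None,
) -> OrthologAssignment:
    """Sequence-level reciprocal best hit with a strict coverage floor."""
    p = seq_search.params
    fam = family or seed.id
    hit, e = seq_search.best_hit(
        seed, target_proteome, p.single_e_fwd, p.min_cov
    )
    taxon = target_proteome[0].taxon if target_proteome else ""
    if hit is None:
        return OrthologAssignment(
            fam, seed.id, seed.taxon, taxon, ABSENT, 1.0, "single", "absent"
        )
    back, e_back = seq_search.best_hit(
        hit, seed_proteome, p.single_e_back, p.min_cov
    )
    status = (
        "reciprocal_ok" if back is not None and back.id == seed.id else "reciprocal_fail"
    )
    return OrthologAssignment(
        fam, seed.id, seed.taxon, taxon, hit.id, e, "single", status
    )


# ---------------------------------------------------------------------------
# per-seed-taxon analysis and combination


def run_seed_analysis(
    seed_proteins: dict,
    seed_taxon: str,
    proteomes: dict,
    search: ProfileSearch,
    seq_search: SequenceSearch | None = None,
    profile_cache: dict | None = None,
    enriched_out: dict | None = None,
) -> list[OrthologAssignment]:
    """One full analysis from one seed taxon.

    ``seed_proteins`` maps family name -> seed ProteinRecord. For every
    family and every non-seed taxon the profile workflow (and optionally the
    sequence workflow) produces an assignment; profile/single disagreement on
    the target is flagged as a conflict. Co-orthologs (lineage duplications)
    are collected as additional reciprocally-valid hits passing the forward
    threshold.
    """
    p = search.params
    cache = profile_cache if profile_cache is not None else {}
    out: list[OrthologAssignment] = []
    seed_proteome = proteomes[seed_taxon]
    for family in sorted(seed_proteins):
        seed_rec = seed_proteins[family]
        profile, msa = build_search_profile(seed_rec, search)
        if enriched_out is not None:
            enriched_out[(seed_taxon, family)] = (profile, msa)
        calib = search.calibrate(profile)
        # one database-wide scan; per-proteome e-values derived from p
        db_hits = search.search(profile, search.database, calib=calib)
        hits_by_taxon: dict = {}
        for h in db_hits:
            hits_by_taxon.setdefault(search.by_id[h.target_id].taxon, []).append(h)
        for taxon in sorted(proteomes):
            if taxon == seed_taxon:
                continue
            proteome = proteomes[taxon]
            hits = [
                replace(h, e_value=min(h.p_value * len(proteome), len(proteome)))
                for h in hits_by_taxon.get(taxon, [])
            ]
            hits.sort(key=lambda h: (h.e_value, -h.score, h.target_id))
            passing = [h for h in hits if h.e_value <= p.e_forward]
            best: OrthologAssignment | None = None
            co_ids: list[str] = []
            for k, h in enumerate(passing[: p.max_coorthologs]):
                status = reciprocal_check(
                    h, seed_proteome, seed_rec.id, search, cache
                )
                if status == "reciprocal_ok":
                    if best is None:
                        search.refine(profile, h)
                        best = OrthologAssignment(
                            family,
                            seed_rec.id,
                            seed_taxon,
                            taxon,
                            h.target_id,
                            h.e_value,
                            "profile",
                            "reciprocal_ok",
                        )
                    else:
                        co_ids.append(h.target_id)
                elif best is None and k == 0:
                    best = OrthologAssignment(
                        family,
                        seed_rec.id,
                        seed_taxon,
                        taxon,
                        h.target_id,
                        h.e_value,
                        "profile",
                        "reciprocal_fail",
                    )
            if best is None:
                best = OrthologAssignment(
                    family, seed_rec.id, seed_taxon, taxon, ABSENT, 1.0,
                    "profile", "absent",
                )
            best.co_ortholog_ids = tuple(co_ids)
            out.append(best)
            if seq_search is not None:
                single = single_seq_reciprocal(
                    seed_rec, proteome, seed_proteome, seq_search, family
                )
                out.append(single)
    return out


def combine_seed_analyses(
    analyses: list[list[OrthologAssignment]],
) -> dict:
    """Combine per-seed (and per-method) assignments into one per cell.

    For every (family, target taxon), the reciprocally-validated candidates
    from all analyses vote by target id: the most widely validated target
    wins (ties prefer targets backed by the sequence-level method, whose
    validated hits are family-specific, then the lowest e-value), and the
    reported e-value is the best one supporting the winning target.
    Disagreement between validated candidates is flagged as a conflict, the
    machine-readable stand-in for the workflow's manual curation step.
    ABSENT only when every analysis came up absent or failed.
    """
    if not analyses:
        raise ValueError("need at least one seed analysis")
    cells: dict = {}
    for analysis in analyses:
        for a in analysis:
            cells.setdefault((a.family, a.target_taxon), []).append(a)
    combined: dict = {}
    for key, cands in sorted(cells.items()):
        ok = [a for a in cands if a.status == "reciprocal_ok"]
        if not ok:
            fallback = min(cands, key=lambda a: (a.e_value, a.target_id))
            combined[key] = fallback
            continue
        by_target: dict = {}
        for a in ok:
            by_target.setdefault(a.target_id, []).append(a)

        def rank(item):
            target, supp = item
            n_single = sum(1 for a in supp if a.method == "single")
            best_e = min(a.e_value for a in supp)
            return (-len(supp), -n_single, best_e, target)

        target, support = min(by_target.items(), key=rank)
        best = min(support, key=lambda a: (a.e_value, a.seed_taxon))
        methods = {a.method for a in support}
        status = "reciprocal_ok" if len(by_target) == 1 else "conflict"
        co = sorted(
            {c for a in ok for c in a.co_ortholog_ids} - {target}
        )
        combined[key] = replace(
            best,
            method="both" if len(methods) > 1 else best.method,
            status=status,
            co_ortholog_ids=tuple(co),
        )
    return combined


def rescue_pass(
    combined: dict,
    family_profiles: dict,
    proteomes: dict,
    seeds_by_taxon: dict,
    search: ProfileSearch,
    profile_cache: dict | None = None,
) -> dict:
    """Second-generation search for unresolved cells.

    Profiles pooled over every analysis's validated orthologs are stronger
    than any single seed's enrichment; cells that stayed absent or failed
    reciprocity are re-searched with the combined family profile and the
    usual reciprocal validation (back-search must return the family's seed
    protein in the closest seed proteome). Mirrors running the iterative
    search to convergence.
    """
    p = search.params
    out = dict(combined)
    calib_cache: dict = {}
    for (fam, taxon), a in sorted(combined.items()):
        if a.status == "reciprocal_ok" or fam not in family_profiles:
            continue
        profile = family_profiles[fam]
        if fam not in calib_cache:
            calib_cache[fam] = search.calibrate(profile)
        proteome = proteomes[taxon]
        hits = search.search(profile, proteome, calib=calib_cache[fam])
        passing = [h for h in hits if h.e_value <= p.e_forward]
        if not passing:
            continue
        hit = passing[0]
        # reciprocal: back into the seed taxon of the original assignment
        seed_taxon = a.seed_taxon
        seed_rec = seeds_by_taxon.get(seed_taxon, {}).get(fam)
        if seed_rec is None:
            continue
        status = reciprocal_check(
            hit, proteomes[seed_taxon], seed_rec.id, search, profile_cache
        )
        if status == "reciprocal_ok":
            out[(fam, taxon)] = replace(
                a,
                target_id=hit.target_id,
                e_value=hit.e_value,
                method="profile",
                status="reciprocal_ok",
                seed_id=seed_rec.id,
                seed_taxon=seed_taxon,
            )
    return out


def apply_overrides(combined: dict, path) -> dict:
    """Apply a manual curation file as the last step.

    Tab-separated with header ``family  target_taxon  target_id`` (use
    ABSENT to erase an assignment); overrides carry status
    ``curated`` and e-value 0 so they are always preferred downstream.
    """
    out = dict(combined)
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            fam, taxon, target = line.rstrip("\n").split("\t")[:3]
            key = (fam, taxon)
            base = out.get(key)
            if target == ABSENT:
                if base is not None:
                    out[key] = replace(
                        base, target_id=ABSENT, status="absent", method="curated"
                    )
                continue
            if base is None:
                base = OrthologAssignment(
                    fam, "", "", taxon, target, 0.0, "curated", "reciprocal_ok"
                )
                out[key] = base
            else:
                out[key] = replace(
                    base,
                    target_id=target,
                    e_value=0.0,
                    method="curated",
                    status="reciprocal_ok",
                )
    return out


def build_ortholog_table(combined: dict) -> "object":
    """Taxon x family co-ortholog count matrix (0 marks absence)."""
    import pandas as pd

    families = sorted({fam for fam, _ in combined})
    taxa = sorted({tax for _, tax in combined})
    seed_taxa = sorted({a.seed_taxon for a in combined.values()})
    mat = pd.DataFrame(0, index=taxa + seed_taxa, columns=families, dtype=int)
    for tax in seed_taxa:
        for fam in families:
            # the seed taxon trivially contains its own seed protein
            if any(
                a.seed_taxon == tax and a.family == fam for a in combined.values()
            ):
                mat.loc[tax, fam] = 1
    for (fam, tax), a in combined.items():
        if a.status in ("reciprocal_ok", "conflict") and a.target_id != ABSENT:
            mat.loc[tax, fam] = 1 + len(a.co_ortholog_ids)
    return mat.sort_index()


def write_assignments_tsv(combined: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family\tseed_taxon\ttarget_taxon\ttarget_id\te\tmethod\tstatus\tco_orthologs\n"
        )
        for (fam, tax), a in sorted(combined.items()):
            fh.write(
                f"{fam}\t{a.seed_taxon}\t{tax}\t{a.target_id}\t{a.e_value:.3e}\t"
                f"{a.method}\t{a.status}\t{';'.join(a.co_ortholog_ids)}\n"
            )
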