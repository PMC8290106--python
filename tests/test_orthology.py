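"""Reciprocal search workflow: enrichment, forward/reciprocal validation,
multi-seed combination and the ortholog count table."""

import dataclasses

import numpy as np
import pytest

from pycatchr.align_profiles import MSA, Hit, build_profile
from pycatchr.orthology import (
    ABSENT,
    OrthologAssignment,
    ProfileSearch,
    SearchParams,
    SequenceSearch,
    build_ortholog_table,
    build_search_profile,
    combine_seed_analyses,
    forward_best_hit,
    reciprocal_check,
    run_seed_analysis,
    single_seq_reciprocal,
)
from pycatchr.records import AA, ProteinRecord
from pycatchr.synthetic_data import SimulationConfig, simulate_dataset

PARAMS = SearchParams(n_null=24, seed=0)


def random_proteins(n, length, seed, taxon="t"):
    rng = np.random.default_rng(seed)
    return [
        ProteinRecord(f"{taxon}_r{i}", taxon, "".join(rng.choice(list(AA), length)))
        for i in range(n)
    ]


@pytest.fixture(scope="module")
def shallow_dataset():
    """Small, shallow-divergence dataset where recovery should be perfect."""
    cfg = SimulationConfig(
        n_taxa=3,
        species_tree_depth=0.4,
        class_split_depths={"g52": 8.0, "g51": 6.0, "g53_g54": 4.0},
        complex_split_depths={"cpxB": 2.0},
        seq_length=220,
        indel_rate=0.0,
        p_loss=0.0,
        p_lineage_dup=0.0,
        seed=2,
    )
    return simulate_dataset(cfg)


class TestBuildSearchProfile:
    def test_zero_iterations_single_sequence(self):
        db = random_proteins(5, 80, 1)
        search = ProfileSearch(db, PARAMS)
        prof, msa = build_search_profile(db[0], search, iters=0)
        assert msa.n_rows == 1
        assert prof.n_cols == len(db[0].residues)

    def test_seed_only_database_fixed_point(self):
        seed = random_proteins(1, 80, 2)[0]
        search = ProfileSearch([seed], PARAMS)
        prof, msa = build_search_profile(seed, search, iters=3)
        assert msa.n_rows == 1

    def test_enrichment_recruits_true_orthologs(self, shallow_dataset):
        ds = shallow_dataset
        db = ds.all_records()
        search = ProfileSearch(db, PARAMS)
        fams = ds.family_members()
        fam = ds.history.families[0]
        seed_rec = ds.seed_proteins("tax01")[fam]
        _, msa = build_search_profile(seed_rec, search)
        recruited = set(msa.ids) - {seed_rec.id}
        true_members = set(fams[fam]) - {seed_rec.id}
        assert len(recruited & true_members) >= len(true_members) / 2


class TestForwardBestHit:
    def test_self_sequence_dominates(self):
        db = random_proteins(6, 90, 3)
        search = ProfileSearch(db, PARAMS)
        prof, _ = build_search_profile(db[0], search, iters=0)
        hit = forward_best_hit(prof, db, search, e_max=len(db))
        assert hit.target_id == db[0].id

    def test_zero_threshold_always_absent(self):
        db = random_proteins(4, 90, 4)
        search = ProfileSearch(db, PARAMS)
        prof, _ = build_search_profile(db[0], search, iters=0)
        assert forward_best_hit(prof, db, search, e_max=0.0) is None

    def test_empty_proteome_rejected(self):
        db = random_proteins(2, 60, 5)
        search = ProfileSearch(db, PARAMS)
        prof, _ = build_search_profile(db[0], search, iters=0)
        with pytest.raises(ValueError):
            forward_best_hit(prof, [], search)


class TestReciprocalCheck:
    def test_seed_only_proteome_ok(self):
        db = random_proteins(5, 90, 6)
        search = ProfileSearch(db, PARAMS)
        hit = Hit(query_id=db[0].id, target_id=db[1].id, score=10.0)
        status = reciprocal_check(hit, [db[0]], db[0].id, search)
        assert status == "reciprocal_ok"

    def test_symmetric_identical_proteomes(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list(AA), 120)) for _ in range(3)]
        prot_a = [ProteinRecord(f"a{i}", "A", s) for i, s in enumerate(seqs)]
        prot_b = [ProteinRecord(f"b{i}", "B", s) for i, s in enumerate(seqs)]
        search = ProfileSearch(prot_a + prot_b, PARAMS)
        for i in range(3):
            hit_ab = Hit(query_id=f"a{i}", target_id=f"b{i}", score=1.0)
            hit_ba = Hit(query_id=f"b{i}", target_id=f"a{i}", score=1.0)
            assert reciprocal_check(hit_ab, prot_a, f"a{i}", search) == "reciprocal_ok"
            assert reciprocal_check(hit_ba, prot_b, f"b{i}", search) == "reciprocal_ok"

    def test_empty_seed_proteome_rejected(self):
        db = random_proteins(2, 60, 8)
        search = ProfileSearch(db, PARAMS)
        hit = Hit(query_id=db[0].id, target_id=db[1].id, score=1.0)
        with pytest.raises(ValueError):
            reciprocal_check(hit, [], db[0].id, search)


class TestSingleSeqReciprocal:
    def test_identical_ortholog_ok(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(AA), 150))
        seed = ProteinRecord("s0", "A", seq)
        target = ProteinRecord("t0", "B", seq)
        decoys = random_proteins(4, 150, 10, taxon="B")
        seq_search = SequenceSearch([seed, target] + decoys, PARAMS)
        a = single_seq_reciprocal(seed, [target] + decoys, [seed], seq_search)
        assert a.status == "reciprocal_ok"
        assert a.target_id == "t0"

    def test_fragment_coverage_rejected(self):
        """A hit covering less than 40% of the query is rejected outright."""
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(AA), 200))
        seed = ProteinRecord("s0", "A", seq)
        fragment = ProteinRecord("t0", "B", seq[:60])  # 30% coverage
        seq_search = SequenceSearch([seed, fragment], PARAMS)
        a = single_seq_reciprocal(seed, [fragment], [seed], seq_search)
        assert a.status == "absent"
        assert a.target_id == ABSENT

    def test_exact_forty_percent_is_rejected(self):
        """Coverage exactly 0.40 fails the strictly-greater-than rule."""
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list(AA), 100))
        seed = ProteinRecord("s0", "A", seq)
        fragment = ProteinRecord("t0", "B", seq[:40])  # exactly 40 residues
        seq_search = SequenceSearch([seed, fragment], PARAMS)
        rec, e = seq_search.best_hit(seed, [fragment], e_max=2.0, min_cov=0.4)
        assert rec is None


class TestCombine:
    def mk(self, fam, seed_tax, tax, target, e, status="reciprocal_ok"):
        return OrthologAssignment(
            family=fam, seed_id=f"{seed_tax}_seed", seed_taxon=seed_tax,
            target_taxon=tax, target_id=target, e_value=e,
            method="profile", status=status,
        )

    def test_single_analysis_passthrough(self):
        a = self.mk("f", "A", "B", "x", 1e-5)
        combined = combine_seed_analyses([[a]])
        assert combined[("f", "B")].target_id == "x"

    def test_agreement_keeps_min_e(self):
        analyses = [
            [self.mk("f", "A", "C", "x", 1e-4)],
            [self.mk("f", "B", "C", "x", 1e-8)],
        ]
        out = combine_seed_analyses(analyses)[("f", "C")]
        assert out.e_value == 1e-8
        assert out.seed_taxon == "B"
        assert out.status == "reciprocal_ok"

    def test_minimality_never_worse_than_any_input(self):
        rng = np.random.default_rng(13)
        analyses = [
            [self.mk("f", t, "C", "x", float(rng.uniform(1e-9, 1e-3)))]
            for t in "ABD"
        ]
        out = combine_seed_analyses(analyses)[("f", "C")]
        assert out.e_value <= min(a[0].e_value for a in analyses)

    def test_disagreement_flags_conflict(self):
        analyses = [
            [self.mk("f", "A", "C", "x", 1e-6)],
            [self.mk("f", "B", "C", "y", 1e-4)],
        ]
        out = combine_seed_analyses(analyses)[("f", "C")]
        assert out.status == "conflict"
        assert out.target_id == "x"  # lowest e wins

    def test_absent_only_when_all_absent(self):
        analyses = [
            [self.mk("f", "A", "C", ABSENT, 1.0, status="absent")],
            [self.mk("f", "B", "C", ABSENT, 1.0, status="reciprocal_fail")],
        ]
        out = combine_seed_analyses(analyses)[("f", "C")]
        assert out.status in ("absent", "reciprocal_fail")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_seed_analyses([])


class TestOrthologTable:
    def test_counts_losses_and_duplications(self):
        a1 = OrthologAssignment("f1", "s1", "A", "B", "b1", 1e-6, "profile",
                                "reciprocal_ok", co_ortholog_ids=("b2",))
        a2 = OrthologAssignment("f2", "s2", "A", "B", ABSENT, 1.0, "profile",
                                "absent")
        table = build_ortholog_table({("f1", "B"): a1, ("f2", "B"): a2})
        assert table.loc["B", "f1"] == 2  # lineage duplication -> co-ortholog
        assert table.loc["B", "f2"] == 0  # loss
        assert table.loc["A", "f1"] == 1  # seed taxon's own copy


class TestPerfectRecoveryLimit:
    def test_shallow_divergence_full_recovery(self, shallow_dataset):
        """Near the zero-divergence limit the combined (profile + sequence)
        workflow reaches precision = recall = 1; the profile method alone can
        drop cells when the generous reciprocal inclusion pulls paralogs into
        the back-profile, which the sequence-level method rescues."""
        ds = shallow_dataset
        db = ds.all_records()
        search = ProfileSearch(db, PARAMS)
        seqs = SequenceSearch(db, PARAMS)
        proteomes = {t: ds.proteomes[t] for t in ds.taxa}
        analysis = run_seed_analysis(
            ds.seed_proteins("tax01"), "tax01", proteomes, search,
            seq_search=seqs,
        )
        combined = combine_seed_analyses([analysis])
        truth = ds.truth
        fams = ds.family_members()
        for (fam, tax), a in combined.items():
            true_ids = {m for m in fams[fam] if truth[m].taxon == tax}
            assert a.status in ("reciprocal_ok", "conflict")
            assert a.target_id in true_ids
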