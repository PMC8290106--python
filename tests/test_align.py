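"""Alignment, profile and significance machinery."""

import numpy as np
import pytest

from pycatchr import (
    MSA,
    ProteinRecord,
    align_msa_to_msa,
    build_profile,
    empirical_significance,
    pairwise_global_align,
    pairwise_stats,
    pp_local_align,
    progressive_msa,
    trim_gappy_columns,
)
from pycatchr.align_profiles import (
    _gap_multipliers,
    _pp_score_matrix,
    profile_from_sequence,
)
from pycatchr.records import AA, AA_INDEX, BACKGROUND, BLOSUM62, InvalidResidueError
from pycatchr import _dp

from _oracles import brute_global, brute_local


def rec(seq, rid="q", taxon="t"):
    return ProteinRecord(rid, taxon, seq)


class TestPairwiseGlobal:
    def test_self_alignment_scores_diagonal_sum(self):
        aln, score = pairwise_global_align(rec("ACDE"), rec("ACDE", "s"))
        expected = sum(BLOSUM62[AA_INDEX[c], AA_INDEX[c]] for c in "ACDE")
        assert score == pytest.approx(expected)
        assert pairwise_stats(aln) == (100.0, 100.0)

    def test_length_one_substitution(self):
        aln, score = pairwise_global_align(rec("A"), rec("D", "s"))
        assert score == pytest.approx(BLOSUM62[AA_INDEX["A"], AA_INDEX["D"]])
        assert aln.a_gapped == "A" and aln.b_gapped == "D"

    def test_invalid_residue_is_named(self):
        with pytest.raises(InvalidResidueError, match="B"):
            pairwise_global_align(rec("AB"), rec("AA", "s"))

    def test_matches_brute_force_enumeration(self):
        """Global affine DP equals exhaustive path enumeration (lengths <= 6)."""
        rng = np.random.default_rng(7)
        for _ in range(150):
            m, n = rng.integers(1, 7, size=2)
            S = rng.normal(0.0, 4.0, (m, n))
            go = float(rng.uniform(1.0, 8.0))
            ge = float(rng.uniform(0.2, go))
            M, Ix, Iy = _dp.nw_fill(S, go, ge)
            score, xo, yo = _dp.nw_traceback(M, Ix, Iy, S, go, ge)
            assert score == pytest.approx(brute_global(S, go, ge), abs=1e-9)

    def test_traceback_is_a_valid_alignment(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(list(AA), la))
            b = "".join(rng.choice(list(AA), lb))
            aln, _ = pairwise_global_align(rec(a), rec(b, "s"))
            assert aln.a_gapped.replace("-", "") == a
            assert aln.b_gapped.replace("-", "") == b


class TestPairwiseStats:
    def test_disjoint_sequences_zero_identity(self):
        aln, _ = pairwise_global_align(rec("AAAA"), rec("GGGG", "s"))
        ident, _ = pairwise_stats(aln)
        assert ident == 0.0

    def test_similarity_bounds_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), 30))
            b = "".join(rng.choice(list(AA), 30))
            aln, _ = pairwise_global_align(rec(a), rec(b, "s"))
            ident, sim = pairwise_stats(aln)
            assert sim >= ident

    def test_all_gap_pairs_flagged(self):
        from pycatchr.align_profiles import Alignment

        aln = Alignment("a", "b", "A-", "-C", 0.0)
        with pytest.raises(ValueError, match="undefined"):
            pairwise_stats(aln)


class TestTrim:
    def test_boundary_is_strictly_greater_than(self):
        # column 1: 4/5 gaps (= 0.8, kept); with a 6th row 5/6 (> 0.8, dropped)
        rows5 = [(f"s{i}", "-A"[0] + "A") for i in range(4)] + [("s4", "AA")]
        msa5 = MSA(rows5)
        assert trim_gappy_columns(msa5, 0.8).n_cols == 2
        rows6 = rows5 + [("s5", "-A")]
        assert trim_gappy_columns(MSA(rows6), 0.8).n_cols == 1

    def test_gap_free_unchanged(self):
        msa = MSA([("a", "ACDE"), ("b", "ACDF")])
        assert trim_gappy_columns(msa).rows == msa.rows

    def test_counts_dropped_columns(self):
        # 10 columns, 3 of them with 9/10 gaps
        rng = np.random.default_rng(5)
        rows = []
        gappy = {2, 5, 7}
        for r in range(10):
            row = "".join(
                "-" if (j in gappy and r > 0) else rng.choice(list(AA))
                for j in range(10)
            )
            rows.append((f"s{r}", row))
        assert trim_gappy_columns(MSA(rows), 0.8).n_cols == 7


class TestBuildProfile:
    def test_single_sequence_zero_pseudocount_is_one_hot(self):
        p = build_profile(MSA([("a", "ACD")]), pseudocount_weight=0.0)
        expected = np.zeros((3, 20))
        for i, c in enumerate("ACD"):
            expected[i, AA_INDEX[c]] = 1.0
        assert np.allclose(p.col_freqs, expected)

    def test_columns_normalised(self):
        msa = MSA([("a", "AC-E"), ("b", "A-DE"), ("c", "GCDE")])
        p = build_profile(msa, pseudocount_weight=0.3)
        assert np.allclose(p.col_freqs.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(p.col_gap_frac, [0, 1 / 3, 1 / 3, 0])

    def test_hand_computed_pseudocounts(self):
        msa = MSA([("a", "AA"), ("b", "AC")])
        p = build_profile(msa, pseudocount_weight=0.1)
        bA = BACKGROUND[AA_INDEX["A"]]
        assert p.col_freqs[1, AA_INDEX["A"]] == pytest.approx(
            (1 + 0.1 * bA) / 2.1
        )

    def test_masked_columns_carry_background(self):
        msa = MSA([("a", "AAAA")])
        mask = np.array([True, False, False, True])
        p = build_profile(msa, cc_mask_cols=mask)
        assert np.allclose(p.col_freqs[0], BACKGROUND)
        assert p.col_freqs[1, AA_INDEX["A"]] > 0.9


class TestProfileLocal:
    def test_one_hot_identical_column_closed_form(self):
        p = build_profile(MSA([("a", "W")]), pseudocount_weight=0.0)
        S = _pp_score_matrix(p, p)
        bW = BACKGROUND[AA_INDEX["W"]]
        assert S[0, 0] == pytest.approx(2 * np.log2(1 / bW))

    def test_self_hit_dominates(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list(AA), 40)) for _ in range(4)]
        profs = [profile_from_sequence(rec(s, f"p{i}")) for i, s in enumerate(seqs)]
        h_self = pp_local_align(profs[0], profs[0])
        assert h_self.q_span == h_self.t_span
        for other in profs[1:]:
            assert pp_local_align(profs[0], other).score < h_self.score

    def test_matches_brute_force_enumeration(self):
        """Local affine DP (with gap-cost multipliers) equals enumeration."""
        rng = np.random.default_rng(13)
        for _ in range(80):
            m, n = rng.integers(1, 6, size=2)
            S = rng.normal(0.5, 3.0, (m, n))
            go = float(rng.uniform(1.0, 6.0))
            ge = float(rng.uniform(0.2, go))
            mx = rng.uniform(0.3, 1.0, m)
            my = rng.uniform(0.3, 1.0, n)
            H, Ix, Iy, best, bi, bj = _dp.sw_fill(S, go, ge, mx, my)
            assert best == pytest.approx(brute_local(S, go, ge, mx, my), abs=1e-9)

    def test_score_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = "".join(rng.choice(list(AA), 60))
            b = "".join(rng.choice(list(AA), 50))
            p1 = profile_from_sequence(rec(a, "a"))
            p2 = profile_from_sequence(rec(b, "b"))
            assert pp_local_align(p1, p2).score == pytest.approx(
                pp_local_align(p2, p1).score, abs=1e-6
            )


class TestEmpiricalSignificance:
    def test_p_floor_and_cap(self):
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list(AA), 50))
        p1 = profile_from_sequence(rec(a, "a"))
        h = empirical_significance(p1, p1, n_shuffles=19, seed=0, n_targets=7)
        assert h.p_value >= 1 / 20
        assert h.e_value == pytest.approx(h.p_value * 7)

    def test_score_below_all_nulls_gives_p_one(self):
        # two one-hot profiles over disjoint residues: observed local score 0
        p1 = build_profile(MSA([("a", "AAAA")]), pseudocount_weight=0.0)
        p2 = build_profile(MSA([("b", "GGGG")]), pseudocount_weight=0.0)
        h = empirical_significance(p1, p2, n_shuffles=19, seed=0)
        assert h.score == 0.0
        assert h.p_value == 1.0

    def test_rejects_too_few_shuffles(self):
        p = profile_from_sequence(rec("ACDEFG"))
        with pytest.raises(ValueError):
            empirical_significance(p, p, n_shuffles=5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        p1 = profile_from_sequence(rec("".join(rng.choice(list(AA), 40)), "a"))
        p2 = profile_from_sequence(rec("".join(rng.choice(list(AA), 40)), "b"))
        h1 = empirical_significance(p1, p2, n_shuffles=30, seed=5)
        h2 = empirical_significance(p1, p2, n_shuffles=30, seed=5)
        assert h1.p_value == h2.p_value


class TestProfileSerialization:
    def test_tsv_roundtrip(self, tmp_path):
        from pycatchr.align_profiles import Profile

        rng = np.random.default_rng(19)
        msa = MSA([("a", "ACD-EF"), ("b", "ACDWEF"), ("c", "AC--EF")])
        p = build_profile(msa, source_id="fam1")
        path = tmp_path / "p.tsv"
        p.to_tsv(path)
        back = Profile.from_tsv(path)
        assert back.source_id == "fam1"
        assert back.n_seqs == 3
        assert np.allclose(back.col_freqs, p.col_freqs, atol=1e-5)
        assert np.allclose(back.col_gap_frac, p.col_gap_frac, atol=1e-5)


class TestProgressiveMSA:
    def test_single_sequence_identity(self):
        msa = progressive_msa([rec("ACDEF")])
        assert msa.rows == [("q", "ACDEF")]

    def test_identical_sequences_gap_free(self):
        seqs = [rec("MKLVAE", f"s{i}") for i in range(3)]
        msa = progressive_msa(seqs)
        assert msa.n_cols == 6
        assert all("-" not in row for _, row in msa.rows)

    def test_msa_merge_row_and_column_bookkeeping(self):
        msa_a = MSA([("a1", "ACDE"), ("a2", "ACD-")])
        msa_b = MSA([("b1", "ACEF"), ("b2", "AC-F"), ("b3", "ACEF")])
        merged = align_msa_to_msa(msa_a, msa_b)
        assert merged.n_rows == 5
        # merging an MSA with itself keeps the column count
        self_merged = align_msa_to_msa(msa_a, msa_a)
        assert self_merged.n_cols == msa_a.n_cols

    def test_merge_preserves_original_columns(self):
        """Rows of msa_a, with all-gap columns dropped, equal msa_a exactly."""
        rng = np.random.default_rng(21)
        seqs_a = ["".join(rng.choice(list(AA), 30)) for _ in range(2)]
        seqs_b = ["".join(rng.choice(list(AA), 26)) for _ in range(3)]
        msa_a = progressive_msa([rec(s, f"a{i}") for i, s in enumerate(seqs_a)])
        msa_b = progressive_msa([rec(s, f"b{i}") for i, s in enumerate(seqs_b)])
        merged = align_msa_to_msa(msa_a, msa_b)
        sub = [row for row in merged.rows if row[0].startswith("a")]
        keep = [
            j
            for j in range(merged.n_cols)
            if any(seq[j] != "-" for _, seq in sub)
        ]
        restored = [(rid, "".join(seq[j] for j in keep)) for rid, seq in sub]
        assert restored == msa_a.rows
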