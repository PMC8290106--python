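"""Alignment, profiles and profile-profile comparison with empirical significance.

This module is the in-package search engine: global pairwise alignment with
affine gaps, progressive multiple alignment, gap-aware column profiles, local
profile-profile alignment scored in half-bits, and two significance providers:

* :func:`empirical_significance` -- a rank-based p-value from column-order
  shuffles of the target profile (used by the all-vs-all clustering stage);
* :func:`gumbel_pvalue` / :func:`calibrate_gumbel` -- an extreme-value tail fit
  to shuffle-null scores, which extrapolates beyond the rank floor and backs
  the e-values used by the iterative search workflow.

Scores between profile columns are ``s(i, j) = 2 * log2(sum_a f1_ia * f2_ja /
b_a)`` (half-bits). A sequence scored against a profile is treated as a
one-hot profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import _dp
from .records import (
    AA,
    BACKGROUND,
    BLOSUM62,
    GAP_CHAR,
    MASK_CHAR,
    ProteinRecord,
    encode,
)

_LOG2_FLOOR = 1.0e-9  # guards log2 of empty column products

# byte -> alphabet index lookup (-1 for gaps, 'X' and anything else)
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _a in enumerate(AA):
    _ENCODE_LUT[ord(_a)] = _i


# ---------------------------------------------------------------------------
# containers


@dataclass
class Alignment:
    """A pairwise global alignment of two sequences."""

    a_id: str
    b_id: str
    a_gapped: str
    b_gapped: str
    score: float

    @property
    def n_cols(self) -> int:
        return len(self.a_gapped)


@dataclass
class MSA:
    """A multiple sequence alignment: equal-length gapped rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("an MSA needs at least one row")
        n = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != n:
                raise ValueError(f"row {rid!r} length {len(seq)} != {n}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.rows:
                fh.write(f">{rid}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        rows: list[tuple[str, str]] = []
        rid = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if rid is not None:
                        rows.append((rid, "".join(chunks)))
                    rid = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
        if rid is not None:
            rows.append((rid, "".join(chunks)))
        return cls(rows)


@dataclass
class Profile:
    """Per-column residue frequency model of an MSA.

    ``col_freqs`` rows sum to one; ``col_gap_frac`` carries the gap fraction
    used to soften gap penalties in gap-rich columns.
    """

    source_id: str
    col_freqs: np.ndarray
    col_gap_frac: np.ndarray
    background: np.ndarray
    n_seqs: int

    @property
    def n_cols(self) -> int:
        return self.col_freqs.shape[0]

    def log_odds(self) -> np.ndarray:
        """Half-bit log-odds matrix (n_cols x 20); cached after first use."""
        lo = getattr(self, "_lo", None)
        if lo is None:
            lo = 2.0 * np.log2(
                np.maximum(self.col_freqs / self.background[None, :], _LOG2_FLOOR)
            )
            self._lo = lo
        return lo

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# profile\t{self.source_id}\tn_seqs={self.n_seqs}\n")
            fh.write("col\tgap_frac\t" + "\t".join(AA) + "\n")
            for i in range(self.n_cols):
                freqs = "\t".join(f"{v:.6g}" for v in self.col_freqs[i])
                fh.write(f"{i + 1}\t{self.col_gap_frac[i]:.6g}\t{freqs}\n")

    @classmethod
    def from_tsv(cls, path) -> "Profile":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            source_id = header[1]
            n_seqs = int(header[2].split("=")[1])
            fh.readline()  # column header
            gaps, freqs = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                gaps.append(float(parts[1]))
                freqs.append([float(v) for v in parts[2:]])
        return cls(
            source_id=source_id,
            col_freqs=np.array(freqs),
            col_gap_frac=np.array(gaps),
            background=BACKGROUND.copy(),
            n_seqs=n_seqs,
        )


@dataclass
class Hit:
    """One query -> target comparison.

    Spans are 1-based inclusive column intervals; ``None`` for an empty
    optimal alignment. ``q_coverage`` is aligned query columns over query
    length.
    """

    query_id: str
    target_id: str
    score: float
    p_value: float = 1.0
    e_value: float = 1.0
    q_span: tuple[int, int] | None = None
    t_span: tuple[int, int] | None = None
    aln_len: int = 0
    q_coverage: float = 0.0
    #: Gumbel-tail extrapolation of the shuffle null; resolves differences
    #: between hits whose rank-based p has saturated at the floor
    p_tail: float = 1.0


# ---------------------------------------------------------------------------
# pairwise sequence alignment


def _seq_score_matrix(a_idx: np.ndarray, b_idx: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Substitution score matrix; masked residues ('X', index -1) score 0."""
    S = np.zeros((len(a_idx), len(b_idx)))
    am = a_idx >= 0
    bm = b_idx >= 0
    S[np.ix_(am, bm)] = matrix[np.ix_(a_idx[am], b_idx[bm])]
    return S


def pairwise_global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: np.ndarray | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[Alignment, float]:
    """Needleman-Wunsch with affine gaps; deterministic traceback."""
    matrix = BLOSUM62 if matrix is None else matrix
    ai = encode(a.residues, allow_mask=True)
    bi = encode(b.residues, allow_mask=True)
    S = _seq_score_matrix(ai, bi, matrix)
    M, Ix, Iy = _dp.nw_fill(S, float(gap_open), float(gap_extend))
    score, xo, yo = _dp.nw_traceback(M, Ix, Iy, S, float(gap_open), float(gap_extend))
    ag = "".join(a.residues[i] if i >= 0 else GAP_CHAR for i in xo)
    bg = "".join(b.residues[j] if j >= 0 else GAP_CHAR for j in yo)
    aln = Alignment(a.id, b.id, ag, bg, float(score))
    return aln, float(score)


def pairwise_stats(
    alignment: Alignment, matrix: np.ndarray | None = None
) -> tuple[float, float]:
    """Percent identity and similarity over gapless aligned residue pairs.

    Similarity counts pairs with a strictly positive substitution score.
    Raises ``ValueError`` when the alignment has no gapless pair.
    """
    matrix = BLOSUM62 if matrix is None else matrix
    n_pairs = 0
    n_ident = 0
    n_sim = 0
    for ca, cb in zip(alignment.a_gapped, alignment.b_gapped):
        if ca == GAP_CHAR or cb == GAP_CHAR or ca == MASK_CHAR or cb == MASK_CHAR:
            continue
        n_pairs += 1
        if ca == cb:
            n_ident += 1
        if matrix[AA.index(ca), AA.index(cb)] > 0:
            n_sim += 1
    if n_pairs == 0:
        raise ValueError("alignment has no gapless residue pair; stats undefined")
    return 100.0 * n_ident / n_pairs, 100.0 * n_sim / n_pairs


# ---------------------------------------------------------------------------
# profiles


def build_profile(
    msa: MSA,
    pseudocount_weight: float = 0.1,
    background: np.ndarray | None = None,
    cc_mask_cols: np.ndarray | None = None,
    source_id: str | None = None,
) -> Profile:
    """Pseudocounted column frequencies from an MSA.

    ``col_freqs = (counts + w * background) / (n_eff + w)`` with gaps and 'X'
    excluded from the counts. Columns flagged in ``cc_mask_cols`` (and all-gap
    columns, with a warning) carry plain background frequencies.
    """
    bg = BACKGROUND if background is None else background
    n_cols = msa.n_cols
    counts = np.zeros((n_cols, 20))
    gaps = np.zeros(n_cols)
    cols = np.arange(n_cols)
    for _, seq in msa.rows:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        gaps += arr == ord(GAP_CHAR)
        idx = _ENCODE_LUT[arr]
        ok = idx >= 0
        np.add.at(counts, (cols[ok], idx[ok]), 1.0)
    n_eff = counts.sum(axis=1)
    w = float(pseudocount_weight)
    freqs = np.empty((n_cols, 20))
    empty = n_eff == 0
    if empty.any() and w == 0:
        warnings.warn("all-gap/masked column(s) given background frequencies")
    with np.errstate(invalid="ignore"):
        freqs = (counts + w * bg[None, :]) / (n_eff + w)[:, None]
    freqs[empty] = bg
    if empty.any() and w > 0:
        # pseudocounts already yield background there, but normalise exactly
        freqs[empty] = bg
    if cc_mask_cols is not None:
        freqs[np.asarray(cc_mask_cols, dtype=bool)] = bg
    gap_frac = gaps / msa.n_rows
    return Profile(
        source_id=source_id or msa.rows[0][0],
        col_freqs=freqs,
        col_gap_frac=gap_frac,
        background=np.asarray(bg, dtype=float),
        n_seqs=msa.n_rows,
    )


def profile_from_sequence(rec: ProteinRecord, pseudocount_weight: float = 0.1) -> Profile:
    return build_profile(
        MSA([(rec.id, rec.residues)]),
        pseudocount_weight=pseudocount_weight,
        source_id=rec.id,
    )


def _pp_score_matrix(p1: Profile, p2: Profile) -> np.ndarray:
    inner = p1.col_freqs @ (p2.col_freqs / p1.background[None, :]).T
    return 2.0 * np.log2(np.maximum(inner, _LOG2_FLOOR))


def _ps_score_matrix(p: Profile, seq_idx: np.ndarray) -> np.ndarray:
    """Profile columns vs one-hot sequence; masked residues score 0."""
    lo = p.log_odds()
    S = np.zeros((p.n_cols, len(seq_idx)))
    ok = seq_idx >= 0
    S[:, ok] = lo[:, seq_idx[ok]]
    return S


def _gap_multipliers(gap_frac: np.ndarray, floor: float = 0.05) -> np.ndarray:
    """1 - mean gap fraction of the flanking columns, floored away from zero."""
    left = np.concatenate(([gap_frac[0]], gap_frac[:-1]))
    mul = 1.0 - 0.5 * (gap_frac + left)
    return np.maximum(mul, floor)


def _local_hit(
    S: np.ndarray,
    q_id: str,
    t_id: str,
    gap_open: float,
    gap_extend: float,
    mul_x: np.ndarray,
    mul_y: np.ndarray,
    q_len: int,
) -> Hit:
    H, Ix, Iy, best, bi, bj = _dp.sw_fill(S, gap_open, gap_extend, mul_x, mul_y)
    if best <= 0.0:
        return Hit(q_id, t_id, 0.0)
    q0, q1, t0, t1, aln_len, _ = _dp.sw_traceback(
        H, Ix, Iy, S, gap_open, gap_extend, mul_x, mul_y, bi, bj
    )
    q_cov = (q1 - q0 + 1) / q_len
    return Hit(
        query_id=q_id,
        target_id=t_id,
        score=float(best),
        q_span=(q0 + 1, q1 + 1),
        t_span=(t0 + 1, t1 + 1),
        aln_len=int(aln_len),
        q_coverage=float(q_cov),
    )


def pp_local_align(
    p1: Profile,
    p2: Profile,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Hit:
    """Smith-Waterman between two column profiles, scored in half-bits.

    Gap costs are scaled by ``1 - mean gap fraction of the flanking columns``
    of the profile in which columns are skipped. An empty optimal alignment
    gives score 0 and empty spans.
    """
    S = _pp_score_matrix(p1, p2)
    return _local_hit(
        S,
        p1.source_id,
        p2.source_id,
        float(gap_open),
        float(gap_extend),
        _gap_multipliers(p1.col_gap_frac),
        _gap_multipliers(p2.col_gap_frac),
        p1.n_cols,
    )


def ps_local_score(
    p: Profile,
    rec: ProteinRecord,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Best local score of profile vs sequence (no traceback; fast path)."""
    seq_idx = encode(rec.residues, allow_mask=True)
    S = _ps_score_matrix(p, seq_idx)
    return float(
        _dp.sw_score_only(
            S,
            float(gap_open),
            float(gap_extend),
            _gap_multipliers(p.col_gap_frac),
            np.ones(len(seq_idx)),
        )
    )


def ps_local_align(
    p: Profile,
    rec: ProteinRecord,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Hit:
    """Local alignment of a profile against a plain sequence."""
    seq_idx = encode(rec.residues, allow_mask=True)
    S = _ps_score_matrix(p, seq_idx)
    return _local_hit(
        S,
        p.source_id,
        rec.id,
        float(gap_open),
        float(gap_extend),
        _gap_multipliers(p.col_gap_frac),
        np.ones(len(seq_idx)),
        p.n_cols,
    )


# ---------------------------------------------------------------------------
# significance


def fit_gumbel(null_scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit (location mu, scale beta)."""
    null_scores = np.asarray(null_scores, dtype=float)
    sd = float(null_scores.std())
    beta = max(sd * np.sqrt(6.0) / np.pi, 1e-6)
    mu = float(null_scores.mean()) - 0.5772156649 * beta
    return mu, beta

def gumbel_sf(score: float, mu: float, beta: float) -> float:
    """P(null >= score) under the fitted Gumbel; numerically safe tail."""
    z = (score - mu) / beta
    if z > 30.0:
        return float(np.exp(-z))
    return float(min(1.0, -np.expm1(-np.exp(-z))))


def empirical_significance(
    p1: Profile,
    p2: Profile,
    n_shuffles: int = 200,
    seed: int = 0,
    n_targets: int = 1,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Hit:
    """Rank-based p-value from column-order shuffles of ``p2``.

    ``p = (1 + #{null >= observed}) / (n_shuffles + 1)`` (never below the
    rank floor) and ``e = p * n_targets``. Deterministic given the seed.
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19 for a usable p-value")
    hit = pp_local_align(p1, p2, gap_open, gap_extend)
    S = _pp_score_matrix(p1, p2)
    mul_x = _gap_multipliers(p1.col_gap_frac)
    mul_y = _gap_multipliers(p2.col_gap_frac)
    # transpose so that shuffling target columns becomes contiguous row
    # fancy-indexing; the local score is symmetric under this swap
    ST = np.ascontiguousarray(S.T)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(p2.n_cols)
        nulls[k] = _dp.sw_score_only(
            ST[perm], float(gap_open), float(gap_extend), mul_y[perm], mul_x
        )
    n_ge = int(np.sum(nulls >= hit.score - 1e-12))
    p = (1 + n_ge) / (n_shuffles + 1)
    hit.p_value = float(p)
    hit.e_value = float(min(p * n_targets, n_targets))
    mu, beta = fit_gumbel(nulls)
    hit.p_tail = gumbel_sf(hit.score, mu, beta)
    return hit


# ---------------------------------------------------------------------------
# progressive alignment


# profile-merge gap penalties: stiffer than the pairwise defaults because
# half-bit column log-odds span roughly twice the substitution-matrix range,
# and cheap gaps would let merges detour around diverged blocks with
# staggered gap columns instead of aligning them
MERGE_GAP_OPEN = 16.0
MERGE_GAP_EXTEND = 2.0


def _merge_msas_global(
    msa_a: MSA,
    msa_b: MSA,
    gap_open: float = MERGE_GAP_OPEN,
    gap_extend: float = MERGE_GAP_EXTEND,
) -> MSA:
    """Profile-profile global alignment of two MSAs; original columns are
    preserved (only whole-column gaps inserted).

    Merge profiles use heavy pseudocounts: with a handful of rows, sharp
    one-hot columns would score mismatches so negatively that the global
    alignment prefers staggered gap-column detours over aligning genuinely
    homologous but diverged blocks.
    """
    pa = build_profile(msa_a, pseudocount_weight=1.0, source_id="A")
    pb = build_profile(msa_b, pseudocount_weight=1.0, source_id="B")
    S = _pp_score_matrix(pa, pb)
    # soften gaps in gap-rich columns, as in local comparison
    S_go = float(gap_open)
    S_ge = float(gap_extend)
    M, Ix, Iy = _dp.nw_fill(S, S_go, S_ge)
    _, xo, yo = _dp.nw_traceback(M, Ix, Iy, S, S_go, S_ge)
    rows: list[tuple[str, str]] = []
    for rid, seq in msa_a.rows:
        rows.append((rid, "".join(seq[i] if i >= 0 else GAP_CHAR for i in xo)))
    for rid, seq in msa_b.rows:
        rows.append((rid, "".join(seq[j] if j >= 0 else GAP_CHAR for j in yo)))
    return MSA(rows)


def align_msa_to_msa(
    msa_a: MSA,
    msa_b: MSA,
    gap_open: float = MERGE_GAP_OPEN,
    gap_extend: float = MERGE_GAP_EXTEND,
) -> MSA:
    """Merge two alignments by aligning their column profiles globally."""
    return _merge_msas_global(msa_a, msa_b, gap_open, gap_extend)


def progressive_msa(
    seqs: list[ProteinRecord],
    matrix: np.ndarray | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> MSA:
    """Progressive alignment with an average-linkage guide tree.

    Guide distances are ``1 - identity`` from global pairwise alignments;
    clusters are merged leaf-to-root with profile-profile global alignment.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if len(seqs) == 1:
        return MSA([(seqs[0].id, seqs[0].residues)])
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_global_align(seqs[i], seqs[j], matrix, gap_open, gap_extend)
            try:
                ident, _ = pairwise_stats(aln)
            except ValueError:
                ident = 0.0
            D[i, j] = D[j, i] = 1.0 - ident / 100.0
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    msas: dict[int, MSA] = {
        i: MSA([(seqs[i].id, seqs[i].residues)]) for i in range(n)
    }
    for k, (ia, ib, _, _) in enumerate(Z):
        a = msas.pop(int(ia))
        b = msas.pop(int(ib))
        msas[n + k] = _merge_msas_global(a, b)
    (msa,) = msas.values()
    return msa


def trim_gappy_columns(msa: MSA, max_gap_frac: float = 0.8) -> MSA:
    """Drop exactly the columns whose gap fraction is strictly above the cut."""
    n_rows = msa.n_rows
    keep = []
    for j in range(msa.n_cols):
        n_gap = sum(1 for _, seq in msa.rows if seq[j] == GAP_CHAR)
        if n_gap / n_rows <= max_gap_frac:
            keep.append(j)
    rows = [(rid, "".join(seq[j] for j in keep)) for rid, seq in msa.rows]
    return MSA(rows)


def write_hits_tsv(hits: list[Hit], path) -> None:
    """Serialize hits with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "query\ttarget\tscore\tp\te\tq_start\tq_end\tt_start\tt_end\taln_len\tcoverage\n"
        )
        for h in hits:
            qs, qe = h.q_span if h.q_span else (0, 0)
            ts, te = h.t_span if h.t_span else (0, 0)
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.score:.3f}\t{h.p_value:.3e}\t"
                f"{h.e_value:.3e}\t{qs}\t{qe}\t{ts}\t{te}\t{h.aln_len}\t{h.q_coverage:.3f}\n"
            )
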