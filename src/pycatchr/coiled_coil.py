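"""Sliding-window heptad coiled-coil scoring and masking.

The scorer follows the classic COILS recipe: for every window the best of the
seven heptad frames is taken, a frame's score being the geometric mean of
position-specific residue propensities; a residue's score is the best score
of any window covering it, and scores are mapped to probabilities with a
two-Gaussian (coiled-coil vs globular) decision rule.

The propensity table shipped with the package
(``data/cc_propensities_synthetic.tsv``) is a synthetic COILS-style table
derived from canonical heptad position preferences (hydrophobic a/d core,
charged e/g flanks), not a redistribution of any published tool's table. The
Gaussian parameters below were calibrated once against windows drawn from the
table's own emission model and from background frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .records import MASK_CHAR, ProteinRecord, encode
from .align_profiles import MSA

#: window length used throughout the package (exposed, not hard-wired)
DEFAULT_WINDOW = 28

# two-Gaussian decision parameters (window-score space), calibrated once
_MU_G, _SD_G = 0.8449, 0.1203
_MU_CC, _SD_CC = 1.3307, 0.1620
_PRIOR_RATIO = 30.0  # globular windows are assumed this much more common

_table_cache: np.ndarray | None = None


def propensity_table() -> np.ndarray:
    """20 x 7 heptad propensity table (AA order x positions a..g)."""
    global _table_cache
    if _table_cache is None:
        text = (
            resources.files("pycatchr")
            .joinpath("data/cc_propensities_synthetic.tsv")
            .read_text()
        )
        rows = []
        for line in text.splitlines():
            if line.startswith("#") or line.startswith("aa"):
                continue
            rows.append([float(v) for v in line.split("\t")[1:]])
        _table_cache = np.array(rows)
    return _table_cache


@dataclass
class CCAnnotation:
    """Per-residue coiled-coil probabilities and the thresholded mask."""

    protein_id: str
    per_residue_prob: np.ndarray
    mask: np.ndarray
    threshold: float

    @property
    def n_cc_residues(self) -> int:
        return int(self.mask.sum())

    def mask_runs(self) -> list[tuple[int, int]]:
        """Masked intervals as 1-based inclusive (start, end) pairs."""
        runs = []
        start = None
        for i, m in enumerate(self.mask):
            if m and start is None:
                start = i
            elif not m and start is not None:
                runs.append((start + 1, i))
                start = None
        if start is not None:
            runs.append((start + 1, len(self.mask)))
        return runs


def _window_prob(score: float | np.ndarray) -> np.ndarray:
    g_cc = np.exp(-0.5 * ((score - _MU_CC) / _SD_CC) ** 2) / _SD_CC
    g_gl = np.exp(-0.5 * ((score - _MU_G) / _SD_G) ** 2) / _SD_G
    # keep probabilities strictly inside (0, 1) so thresholds at the
    # boundaries behave as documented even when one density underflows
    return np.clip(g_cc / (g_cc + _PRIOR_RATIO * g_gl), 1e-12, 1.0 - 1e-9)


def cc_scores(
    seq: ProteinRecord, window: int = DEFAULT_WINDOW, threshold: float = 0.5
) -> CCAnnotation:
    """Score every residue for heptad coiled-coil character.

    Sequences shorter than the window are scored with a proportionally
    shortened window. Masked residues ('X') get the table's floor propensity.
    """
    idx = encode(seq.residues, allow_mask=True)
    L = len(idx)
    W = min(window, L)
    prop = propensity_table()
    floor = prop.min()
    # log-propensity of residue k under absolute heptad frame f
    lp = np.empty((L, 7))
    for f in range(7):
        pos = (np.arange(L) + f) % 7
        vals = np.where(idx >= 0, prop[np.maximum(idx, 0), pos], floor)
        lp[:, f] = np.log(vals)
    csum = np.vstack([np.zeros(7), np.cumsum(lp, axis=0)])
    win_means = (csum[W:] - csum[:-W]) / W  # (L - W + 1, 7)
    win_scores = np.exp(win_means.max(axis=1))
    # per-residue: best covering window
    res_scores = np.full(L, -np.inf)
    for w0 in range(L - W + 1):
        seg = res_scores[w0 : w0 + W]
        np.maximum(seg, win_scores[w0], out=seg)
    probs = _window_prob(res_scores)
    mask = probs > threshold
    return CCAnnotation(seq.id, probs, mask, threshold)


def cc_mask(
    seq: ProteinRecord,
    threshold: float = 0.5,
    window: int = DEFAULT_WINDOW,
) -> CCAnnotation:
    """Annotation with ``mask = probability > threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return cc_scores(seq, window=window, threshold=threshold)


def fixed_nterm_mask(seq: ProteinRecord, length: int) -> CCAnnotation:
    """Fallback annotation masking a fixed-length N-terminal segment.

    For inputs where the coiled coil's extent is known a priori (or the
    predictor is not trusted), the first ``length`` residues are flagged
    regardless of sequence content.
    """
    n = len(seq.residues)
    probs = np.zeros(n)
    probs[: min(length, n)] = 1.0 - 1e-9
    mask = probs > 0.5
    return CCAnnotation(seq.id, probs, mask, 0.5)


def masked_record(seq: ProteinRecord, ann: CCAnnotation) -> ProteinRecord:
    """Copy of the record with coiled-coil residues replaced by 'X'.

    'X' contributes zero counts to profile columns downstream, while keeping
    coordinates comparable between masked and unmasked runs.
    """
    residues = "".join(
        MASK_CHAR if m else c for c, m in zip(seq.residues, ann.mask)
    )
    return ProteinRecord(seq.id, seq.taxon, residues)


def mask_msa_columns(
    msa: MSA, annotations: dict[str, CCAnnotation], min_frac: float = 0.5
) -> np.ndarray:
    """Map per-sequence masks through an MSA to per-column flags.

    A column is masked when more than ``min_frac`` of its residues (gaps
    excluded) are coiled-coil flagged.
    """
    n_cols = msa.n_cols
    cc = np.zeros(n_cols)
    tot = np.zeros(n_cols)
    for rid, gapped in msa.rows:
        ann = annotations.get(rid)
        if ann is None:
            continue
        k = 0
        for j, c in enumerate(gapped):
            if c == "-":
                continue
            tot[j] += 1
            if ann.mask[k]:
                cc[j] += 1
            k += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(tot > 0, cc / np.maximum(tot, 1), 0.0)
    return frac > min_frac


def write_cc_tsv(annotations: list[CCAnnotation], path) -> None:
    """Per-protein summary: id, number of CC residues, mask intervals."""
    with open(path, "w") as fh:
        fh.write("protein_id\tn_cc_residues\tmask_runs\n")
        for ann in annotations:
            runs = ";".join(f"{a}-{b}" for a, b in ann.mask_runs())
            fh.write(f"{ann.protein_id}\t{ann.n_cc_residues}\t{runs}\n")
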