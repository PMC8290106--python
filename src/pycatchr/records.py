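"""Shared primitives: the amino-acid alphabet, substitution matrix and background
frequencies, and the :class:`ProteinRecord` container used across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical 20-letter amino-acid alphabet (alphabetical by one-letter code).
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

#: Residues tolerated in input sequences but excluded from profile counts.
MASK_CHAR = "X"
GAP_CHAR = "-"

# Standard BLOSUM62 background frequencies (Robinson & Robinson style), in AA order.
_BG = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}
BACKGROUND = np.array([_BG[a] for a in AA])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def _load_blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = mat[a, b]
    return out


#: BLOSUM62 scores restricted to the 20 standard residues, in AA order.
BLOSUM62 = _load_blosum62()


class InvalidResidueError(ValueError):
    """Raised when a sequence contains a character outside the 20-letter alphabet."""


_LUT = np.full(256, -2, dtype=np.int8)
for _i, _a in enumerate(AA):
    _LUT[ord(_a)] = _i
_LUT[ord("X")] = -1


def encode(seq: str, allow_mask: bool = False) -> np.ndarray:
    """Encode a protein sequence into int8 alphabet indices.

    Masked residues ('X') are encoded as -1 when ``allow_mask`` is set, and
    rejected otherwise.
    """
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    out = _LUT[arr]
    bad_floor = -1 if allow_mask else 0
    if (out < bad_floor).any():
        i = int(np.argmax(out < bad_floor))
        raise InvalidResidueError(f"invalid residue {seq[i]!r} at position {i + 1}")
    return out


def decode(indices: np.ndarray) -> str:
    return "".join(AA[i] if i >= 0 else MASK_CHAR for i in indices)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its taxon of origin."""

    id: str
    taxon: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        encode(self.residues, allow_mask=True)

    def __len__(self) -> int:
        return len(self.residues)
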