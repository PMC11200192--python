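"""Amino-acid sequence encodings for peptides and allele pseudosequences.

Three schemes: one-hot over the 20 amino acids plus a padding symbol X,
BLOSUM62 substitution-similarity rows, and a preferential-interaction
encoding of the full 269-residue HLA groove sequence built from a
residue-pair C-alpha distance table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .io import AA_ALPHABET, AA_SET, PAD_CHAR, AllelePseudosequence

AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_CHANNELS = 21  # 20 amino acids + padding X

PEPTIDE_PAD_TO = 19   # longest eluted-ligand length modelled
SHORT_PSEUDO_LEN = 34
FULL_PSEUDO_LEN = 269

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# rows/cols ordered by our alphabet
BLOSUM62_MATRIX = np.array(
    [[float(_BLOSUM62[a][b]) for b in AA_ALPHABET] for a in AA_ALPHABET])


@dataclass
class EncodedPeptide:
    matrix: np.ndarray      # (pad_to, C)
    length: int
    scheme: str


@dataclass
class EncodedAllele:
    matrix: np.ndarray      # (R, C)
    scheme: str


def _validate(seq: str, pad_to: int | None) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - AA_SET - {PAD_CHAR}
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in {seq!r}")
    if pad_to is not None and len(seq) > pad_to:
        raise ValueError(f"sequence length {len(seq)} exceeds pad_to={pad_to}")


def encode_onehot(seq: str, pad_to: int = PEPTIDE_PAD_TO) -> EncodedPeptide:
    """One-hot encode to a (pad_to, 21) matrix; channel 21 is X padding.

    Every row sums to one; rows beyond the true length are one-hot on
    the padding channel.
    """
    _validate(seq, pad_to)
    m = np.zeros((pad_to, N_CHANNELS))
    for i in range(pad_to):
        if i < len(seq) and seq[i] != PAD_CHAR:
            m[i, AA_INDEX[seq[i]]] = 1.0
        else:
            m[i, 20] = 1.0
    return EncodedPeptide(m, len(seq), "onehot")


def encode_blosum(seq: str, pad_to: int = PEPTIDE_PAD_TO) -> EncodedPeptide:
    """BLOSUM62 similarity rows, (pad_to, 21): 20 substitution scores
    plus a padding-indicator channel (1 on padded rows, else 0)."""
    _validate(seq, pad_to)
    m = np.zeros((pad_to, N_CHANNELS))
    for i in range(pad_to):
        if i < len(seq) and seq[i] != PAD_CHAR:
            m[i, :20] = BLOSUM62_MATRIX[AA_INDEX[seq[i]]]
        else:
            m[i, 20] = 1.0
    return EncodedPeptide(m, len(seq), "blosum62")


def encode_peptide(seq: str, pad_to: int = PEPTIDE_PAD_TO) -> np.ndarray:
    """Default sequence-branch peptide encoding: one-hot and BLOSUM62
    channel-concatenated, (pad_to, 42)."""
    return np.concatenate([encode_onehot(seq, pad_to).matrix,
                           encode_blosum(seq, pad_to).matrix], axis=1)


def encode_allele_short(allele: AllelePseudosequence,
                        scheme: str = "both") -> np.ndarray:
    """Encode the 34-residue contact pseudosequence (one-hot, BLOSUM62,
    or both concatenated)."""
    s = allele.short_seq
    if scheme == "onehot":
        return encode_onehot(s, SHORT_PSEUDO_LEN).matrix
    if scheme == "blosum62":
        return encode_blosum(s, SHORT_PSEUDO_LEN).matrix
    return np.concatenate([encode_onehot(s, SHORT_PSEUDO_LEN).matrix,
                           encode_blosum(s, SHORT_PSEUDO_LEN).matrix], axis=1)


def default_anchor_panel(n_anchors: int = 34,
                         length: int = FULL_PSEUDO_LEN) -> np.ndarray:
    """Evenly spaced groove anchor positions across the full sequence."""
    return np.linspace(0, length - 1, n_anchors).round().astype(int)


def encode_ca_distance(allele: AllelePseudosequence,
                       distance_table: np.ndarray,
                       anchors: np.ndarray | None = None,
                       sigma: float = 8.0) -> EncodedAllele:
    """Preferential-interaction encoding of the 269-residue groove sequence.

    Each residue i is represented by its proximity profile
    ``exp(-d(i, a)/sigma)`` over a fixed panel of 34 anchor positions
    (closer residues get larger weights), concatenated with the
    residue's BLOSUM62 row.  ``distance_table`` is the symmetric
    residue-pair C-alpha distance matrix in angstroms.
    """
    if not allele.full_seq:
        raise ValueError(
            f"{allele.name}: no 269-residue full sequence available; "
            "use the one-hot or BLOSUM62 encoding of the 34-mer instead")
    L = len(allele.full_seq)
    if L != FULL_PSEUDO_LEN:
        raise ValueError(f"full sequence must be {FULL_PSEUDO_LEN} residues")
    distance_table = np.asarray(distance_table, dtype=float)
    if distance_table.shape != (L, L):
        raise ValueError(
            f"distance table must be ({L}, {L}), got {distance_table.shape}")
    if anchors is None:
        anchors = default_anchor_panel()
    prox = np.exp(-distance_table[:, anchors] / sigma)   # (269, 34)
    blos = np.stack([BLOSUM62_MATRIX[AA_INDEX[a]] if a in AA_SET
                     else np.zeros(20) for a in allele.full_seq])
    return EncodedAllele(np.concatenate([prox, blos], axis=1), "ca_distance")


def encode_batch(seqs: list[str], pad_to: int = PEPTIDE_PAD_TO) -> np.ndarray:
    """Stack default peptide encodings into (B, pad_to, 42)."""
    return np.stack([encode_peptide(s, pad_to) for s in seqs])
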