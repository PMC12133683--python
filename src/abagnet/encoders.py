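"""Per-residue encoders and k-spaced amino-acid-pair (CKSAAP) features.

CKSAAP summarizes sequence-order information as the frequency of ordered
residue pairs (a, b) separated by g = 0..k intervening positions: 400 values
per gap, each gap block normalized by its number of valid windows.  The fused
variant weights each pair occurrence by the mean of the two window endpoints'
embedding values, yielding a D x (k+1) x 20 x 20 tensor whose gap slices
reduce exactly to the classic counts under a constant all-ones embedding.

Windows touching an 'X' (unknown/masked) residue are excluded from both the
numerator and the denominator, so masking a region cleanly deletes its pair
evidence instead of diluting it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AA_INDEX, ALPHABET, EmbeddingStore, SequenceRecord

N_AA = len(ALPHABET)  # spatial side of the pair grid


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding, rows aligned 1:1 with sequence positions."""

    seq_id: str
    values: np.ndarray  # L x D

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("embedding must be an L x D matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite embedding values for {self.seq_id!r}")


@dataclass(frozen=True)
class CKSAAPVector:
    """Classic CKSAAP feature: (k+1) gap blocks of 400 pair frequencies."""

    k: int
    values: np.ndarray  # length (k+1) * 400, blocked by gap then (a, b)

    def block(self, g: int) -> np.ndarray:
        """The 20 x 20 pair-frequency block for gap g."""
        return self.values[g * N_AA * N_AA:(g + 1) * N_AA * N_AA].reshape(N_AA, N_AA)


@dataclass(frozen=True)
class FusedCKSAAPTensor:
    """Embedding-fused CKSAAP tensor of shape D x (k+1) x 20 x 20."""

    k: int
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 4 or v.shape[1] != self.k + 1 or v.shape[2:] != (N_AA, N_AA):
            raise ValueError(f"expected D x {self.k + 1} x 20 x 20, got {v.shape}")

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def _residue_indices(seq: SequenceRecord) -> np.ndarray:
    """Alphabet indices per position; -1 for the mask residue 'X'."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.residues], dtype=np.int64)


def one_hot_encode(seq: SequenceRecord) -> EmbeddingMatrix:
    """L x 20 indicator matrix (alphabet ACDEFGHIKLMNPQRSTVWY); 'X' rows zero."""
    idx = _residue_indices(seq)
    mat = np.zeros((len(idx), N_AA), dtype=np.float64)
    known = idx >= 0
    mat[np.nonzero(known)[0], idx[known]] = 1.0
    return EmbeddingMatrix(seq.id, mat)


def cksaap_classic(seq: SequenceRecord, k: int) -> CKSAAPVector:
    """Pair frequencies for gaps 0..k; each non-empty block sums to 1."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    idx = _residue_indices(seq)
    blocks = np.zeros((k + 1, N_AA, N_AA), dtype=np.float64)
    for g in range(k + 1):
        if len(idx) < g + 2:
            continue
        first = idx[: len(idx) - g - 1]
        second = idx[g + 1:]
        valid = (first >= 0) & (second >= 0)
        n_windows = int(valid.sum())
        if n_windows == 0:
            continue
        np.add.at(blocks[g], (first[valid], second[valid]), 1.0)
        blocks[g] /= n_windows
    return CKSAAPVector(k, blocks.reshape(-1))


def cksaap_fused(seq: SequenceRecord, emb: EmbeddingMatrix, k: int) -> FusedCKSAAPTensor:
    """Embedding-weighted CKSAAP.

    Cell (d, g, a, b) accumulates, over every valid gap-g window whose
    endpoints read (a, b), the mean of the two endpoint embedding values in
    dimension d, normalized by the number of valid gap-g windows.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    E = np.asarray(emb.values, dtype=np.float64)
    if E.shape[0] != len(seq):
        raise ValueError(
            f"embedding rows ({E.shape[0]}) do not match sequence length "
            f"({len(seq)}) for {seq.id!r}"
        )
    D = E.shape[1]
    idx = _residue_indices(seq)
    out = np.zeros((D, k + 1, N_AA, N_AA), dtype=np.float64)
    for g in range(k + 1):
        if len(idx) < g + 2:
            continue
        first = idx[: len(idx) - g - 1]
        second = idx[g + 1:]
        valid = (first >= 0) & (second >= 0)
        n_windows = int(valid.sum())
        if n_windows == 0:
            continue
        weights = 0.5 * (E[: len(idx) - g - 1] + E[g + 1:])  # (L-g-1) x D
        acc = np.zeros((N_AA, N_AA, D), dtype=np.float64)
        np.add.at(acc, (first[valid], second[valid]), weights[valid])
        out[:, g] = acc.transpose(2, 0, 1) / n_windows
    return FusedCKSAAPTensor(k, out)


def lookup_embeddings(store: EmbeddingStore, seq: SequenceRecord) -> EmbeddingMatrix:
    """Fetch the stored matrix for ``seq``, checking the row count."""
    mat = store[seq.id]
    if mat.shape[0] != len(seq):
        raise ValueError(
            f"stored embedding for {seq.id!r} has {mat.shape[0]} rows but the "
            f"sequence has {len(seq)} residues"
        )
    return EmbeddingMatrix(seq.id, mat)
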