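"""Readers/writers for sequences, interaction pair lists, region annotations
and per-residue embedding stores, plus the train/test redundancy filter.

Conventions
-----------
* Sequence alphabet: the 20 standard amino acids plus ``X`` for
  unknown/masked residues.  Any other letter (B, Z, U, O, J, ``*`` ...)
  is canonicalized to ``X`` on input.
* All region coordinates are 0-based, half-open ``[start, end)``.
* Pair lists are TSV with a header row ``antibody_id  antigen_id  label``
  and labels strictly in {0, 1}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
MASK = "X"
FULL_ALPHABET = ALPHABET + MASK
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

REGION_NAMES = ("CDR1", "CDR2", "CDR3", "epitope", "other")

_VALID_RE = re.compile(f"^[{FULL_ALPHABET}]+$")


def canonicalize(residues: str) -> str:
    """Uppercase and map every letter outside the 21-letter alphabet to 'X'."""
    up = residues.upper()
    return "".join(c if c in AA_INDEX or c == MASK else MASK for c in up)


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino-acid sequence (canonical 21-letter alphabet)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if not _VALID_RE.match(self.residues):
            raise ValueError(
                f"sequence {self.id!r} contains non-canonical residues; "
                "apply canonicalize() first"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionPair:
    antibody_id: str
    antigen_id: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class RegionAnnotation:
    seq_id: str
    region_name: str
    start: int
    end: int

    def __post_init__(self):
        if self.region_name not in REGION_NAMES:
            raise ValueError(f"unknown region name {self.region_name!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into canonicalized :class:`SequenceRecord` objects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"empty FASTA header in {path}")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, canonicalize(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def sequence_index(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for r in records:
        if r.id in out:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        out[r.id] = r
    return out


# ---------------------------------------------------------------------------
# Pair lists

_PAIR_COLUMNS = ["antibody_id", "antigen_id", "label"]


def read_pairs(path) -> list[InteractionPair]:
    """Read an interaction pair TSV, preserving file order."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns) != _PAIR_COLUMNS:
        raise ValueError(
            f"expected columns {_PAIR_COLUMNS}, got {list(df.columns)}"
        )
    pairs = []
    for row in df.itertuples(index=False):
        label = int(row.label)
        if label not in (0, 1) or float(row.label) != label:
            raise ValueError(f"label outside {{0,1}}: {row.label!r}")
        pairs.append(InteractionPair(str(row.antibody_id), str(row.antigen_id), label))
    return pairs


def write_pairs(pairs: Iterable[InteractionPair], path) -> None:
    df = pd.DataFrame(
        [(p.antibody_id, p.antigen_id, p.label) for p in pairs],
        columns=_PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region annotations (BED-like TSV: seq_id, start, end, region_name)

def read_regions(path, sequences: Mapping[str, SequenceRecord] | None = None
                 ) -> list[RegionAnnotation]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["seq_id", "start", "end", "region_name"],
        dtype={"seq_id": str, "region_name": str},
    )
    annotations = [
        RegionAnnotation(row.seq_id, row.region_name, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    ]
    validate_regions(annotations, sequences)
    return annotations


def write_regions(annotations: Iterable[RegionAnnotation], path) -> None:
    df = pd.DataFrame(
        [(a.seq_id, a.start, a.end, a.region_name) for a in annotations],
        columns=["seq_id", "start", "end", "region_name"],
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def validate_regions(annotations: Sequence[RegionAnnotation],
                     sequences: Mapping[str, SequenceRecord] | None = None) -> None:
    """Check bounds against sequences (when given) and pairwise disjointness."""
    by_seq: dict[str, list[RegionAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_id, []).append(a)
        if sequences is not None:
            if a.seq_id not in sequences:
                raise KeyError(f"region on unknown sequence {a.seq_id!r}")
            if a.end > len(sequences[a.seq_id]):
                raise ValueError(
                    f"region [{a.start},{a.end}) exceeds length "
                    f"{len(sequences[a.seq_id])} of {a.seq_id!r}"
                )
    for seq_id, group in by_seq.items():
        ordered = sorted(group, key=lambda a: a.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping regions {prev.region_name}/{nxt.region_name} "
                    f"on {seq_id!r}"
                )


def regions_by_sequence(annotations: Iterable[RegionAnnotation]
                        ) -> dict[str, dict[str, RegionAnnotation]]:
    out: dict[str, dict[str, RegionAnnotation]] = {}
    for a in annotations:
        out.setdefault(a.seq_id, {})[a.region_name] = a
    return out


# ---------------------------------------------------------------------------
# Embedding stores (HDF5: one L x D float32 dataset per sequence id)

class EmbeddingStore:
    """In-memory mapping seq_id -> per-residue embedding matrix (L x D)."""

    def __init__(self, matrices: Mapping[str, np.ndarray]):
        dims = {m.shape[1] for m in matrices.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding widths: {sorted(dims)}")
        self._data = {k: np.asarray(v, dtype=np.float64) for k, v in matrices.items()}
        self.dim = dims.pop() if dims else 0

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._data

    def __getitem__(self, seq_id: str) -> np.ndarray:
        if seq_id not in self._data:
            raise KeyError(f"no embedding stored for sequence {seq_id!r}")
        return self._data[seq_id]

    def ids(self) -> list[str]:
        return list(self._data)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["dim"] = self.dim
            for seq_id, mat in self._data.items():
                f.create_dataset(seq_id, data=mat.astype(np.float32))

    @classmethod
    def load(cls, path) -> "EmbeddingStore":
        with h5py.File(path, "r") as f:
            matrices = {k: np.asarray(f[k], dtype=np.float64) for k in f.keys()}
        return cls(matrices)


# ---------------------------------------------------------------------------
# Redundancy filter

def _global_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Matches / alignment columns under global alignment."""
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / aln.length


def _make_aligner() -> Align.PairwiseAligner:
    # match +1, mismatch 0, linear gap -1
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def redundancy_filter(
    test_pairs: Sequence[InteractionPair],
    train_pairs: Sequence[InteractionPair],
    sequences: Mapping[str, SequenceRecord],
    cutoff: float,
) -> list[InteractionPair]:
    """Drop test pairs redundant with the training set.

    A test pair is removed iff some training pair has antibody identity >=
    ``cutoff`` AND antigen identity >= ``cutoff`` AND the same label, where
    identity = matches / alignment columns under global alignment.
    Survivors keep their input order.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    for p in list(test_pairs) + list(train_pairs):
        for sid in (p.antibody_id, p.antigen_id):
            if sid not in sequences:
                raise KeyError(f"pair references unknown sequence {sid!r}")

    aligner = _make_aligner()
    cache: dict[tuple[str, str], float] = {}

    def identity(id_a: str, id_b: str) -> float:
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        if key not in cache:
            cache[key] = _global_identity(
                sequences[key[0]].residues, sequences[key[1]].residues, aligner
            )
        return cache[key]

    survivors = []
    for tp in test_pairs:
        redundant = any(
            tp.label == rp.label
            and identity(tp.antibody_id, rp.antibody_id) >= cutoff
            and identity(tp.antigen_id, rp.antigen_id) >= cutoff
            for rp in train_pairs
        )
        if not redundant:
            survivors.append(tp)
    return survivors
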