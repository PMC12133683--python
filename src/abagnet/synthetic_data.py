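"""Synthetic paired antibody/antigen datasets with a planted, CDR-localized
interaction rule and known region annotations.

The generator emulates the shape of real interaction benchmarks — paired
sequences, binary labels, CDR annotations — with a ground truth that can be
re-derived exactly from the sequences:

* Backgrounds are i.i.d. uniform over the 20 standard residues.
* Complementarity is a fixed letter bijection (reverse-alphabet pairing),
  so "the CDR binds the epitope" means the CDR motif is the letterwise
  complement of the epitope motif.
* One epitope motif is drawn per dataset.  Intended positives carry it in
  the antigen's epitope window and the complementary motif in exactly one
  CDR window, chosen with probability proportional to the CDR importance
  weights.  Intended negatives may carry either half alone (decoys), so
  neither chain is informative on its own.
* The label is recomputed from the sequences: a weighted sum of per-CDR
  complementarity matches against the epitope window, thresholded; label
  noise flips it last.

Everything is reproducible bit-exactly from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    ALPHABET,
    InteractionPair,
    RegionAnnotation,
    SequenceRecord,
    validate_regions,
    write_fasta,
    write_pairs,
    write_regions,
)

COMPLEMENT = {a: b for a, b in zip(ALPHABET, reversed(ALPHABET))}

CDR_NAMES = ("CDR1", "CDR2", "CDR3")


@dataclass(frozen=True)
class SyntheticSpec:
    n_pairs: int = 1000
    ab_length: int = 60
    ag_length: int = 60
    cdr_windows: tuple[tuple[int, int], ...] = ((20, 26), (32, 38), (44, 52))
    epitope_window: tuple[int, int] = (24, 36)
    importance_weights: tuple[float, float, float] = (0.2, 0.5, 1.0)
    noise_rate: float = 0.05
    motif_length: int = 6
    balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.cdr_windows) != 3:
            raise ValueError("exactly three CDR windows required")
        ordered = sorted(self.cdr_windows)
        for (s, e) in list(self.cdr_windows) + [self.epitope_window]:
            if not 0 <= s < e:
                raise ValueError(f"invalid window [{s}, {e})")
        for (_, e1), (s2, _) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError("CDR windows overlap")
        if max(e for _, e in self.cdr_windows) > self.ab_length:
            raise ValueError("CDR window exceeds antibody length")
        if self.epitope_window[1] > self.ag_length:
            raise ValueError("epitope window exceeds antigen length")
        if all(w == 0 for w in self.importance_weights):
            raise ValueError("importance weights must not all be zero")
        if any(w < 0 for w in self.importance_weights):
            raise ValueError("importance weights must be >= 0")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise rate must be in [0, 0.5)")
        min_window = min(e - s for s, e in self.cdr_windows)
        if not 1 <= self.motif_length <= min(min_window,
                                             self.epitope_window[1]
                                             - self.epitope_window[0]):
            raise ValueError("motif must fit inside every window")


@dataclass(frozen=True)
class GroundTruthRule:
    """The relational labelling rule; re-checkable from sequences alone."""

    cdr_windows: tuple[tuple[int, int], ...]
    epitope_window: tuple[int, int]
    importance_weights: tuple[float, float, float]
    motif_length: int
    threshold: float
    epitope_motif: str  # the dataset's planted motif, for reference

    def match(self, ab_residues: str, ag_residues: str, cdr: int) -> bool:
        """Letterwise complementarity of CDR ``cdr``'s motif site against the
        epitope site; masked ('X') positions never match."""
        s, _ = self.cdr_windows[cdr]
        es, _ = self.epitope_window
        for t in range(self.motif_length):
            a, g = ab_residues[s + t], ag_residues[es + t]
            if a == "X" or g == "X" or COMPLEMENT.get(g) != a:
                return False
        return True

    def score(self, ab_residues: str, ag_residues: str) -> float:
        return sum(
            w for cdr, w in enumerate(self.importance_weights)
            if self.match(ab_residues, ag_residues, cdr)
        )

    def label(self, ab_residues: str, ag_residues: str) -> int:
        return int(self.score(ab_residues, ag_residues) >= self.threshold)


@dataclass
class SyntheticDataset:
    sequences: list[SequenceRecord]
    pairs: list[InteractionPair]
    regions: list[RegionAnnotation]
    rule: GroundTruthRule
    spec: SyntheticSpec

    def sequence_index(self) -> dict[str, SequenceRecord]:
        return {s.id: s for s in self.sequences}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "sequences.fasta",
            "pairs": outdir / "pairs.tsv",
            "regions": outdir / "regions.tsv",
        }
        write_fasta(self.sequences, paths["fasta"])
        write_pairs(self.pairs, paths["pairs"])
        write_regions(self.regions, paths["regions"])
        return paths


def _random_residues(rng: np.random.Generator, length: int) -> list[str]:
    return [ALPHABET[i] for i in rng.integers(0, len(ALPHABET), size=length)]


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a full dataset (sequences, pairs, regions, rule) from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    motif = "".join(_random_residues(rng, spec.motif_length))
    comp_motif = "".join(COMPLEMENT[c] for c in motif)
    weights = np.asarray(spec.importance_weights, dtype=np.float64)
    positive_weights = weights[weights > 0]
    rule = GroundTruthRule(
        cdr_windows=spec.cdr_windows,
        epitope_window=spec.epitope_window,
        importance_weights=spec.importance_weights,
        motif_length=spec.motif_length,
        threshold=0.5 * float(positive_weights.min()),
        epitope_motif=motif,
    )
    p_window = weights / weights.sum()

    sequences: list[SequenceRecord] = []
    pairs: list[InteractionPair] = []
    regions: list[RegionAnnotation] = []
    for i in range(spec.n_pairs):
        ab = _random_residues(rng, spec.ab_length)
        ag = _random_residues(rng, spec.ag_length)

        def plant_epitope():
            es = spec.epitope_window[0]
            ag[es:es + spec.motif_length] = list(motif)

        def plant_cdr():
            cdr = int(rng.choice(3, p=p_window))
            cs = spec.cdr_windows[cdr][0]
            ab[cs:cs + spec.motif_length] = list(comp_motif)

        if rng.random() < spec.balance:
            plant_epitope()
            plant_cdr()
        else:
            u = rng.random()
            if u < 0.35:
                plant_epitope()  # antigen-side decoy
            elif u < 0.70:
                plant_cdr()  # antibody-side decoy
        ab_str, ag_str = "".join(ab), "".join(ag)
        label = rule.label(ab_str, ag_str)
        if rng.random() < spec.noise_rate:
            label = 1 - label
        ab_id, ag_id = f"ab{i:05d}", f"ag{i:05d}"
        sequences.append(SequenceRecord(ab_id, ab_str))
        sequences.append(SequenceRecord(ag_id, ag_str))
        pairs.append(InteractionPair(ab_id, ag_id, label))
        for name, (s, e) in zip(CDR_NAMES, spec.cdr_windows):
            regions.append(RegionAnnotation(ab_id, name, s, e))
        es, ee = spec.epitope_window
        regions.append(RegionAnnotation(ag_id, "epitope", es, ee))
    validate_regions(regions, {s.id: s for s in sequences})
    return SyntheticDataset(sequences, pairs, regions, rule, spec)


def make_label_shuffled(pairs: list[InteractionPair],
                        seed: int = 0) -> list[InteractionPair]:
    """Permute the labels uniformly at random; label multiset preserved."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to shuffle")
    rng = np.random.default_rng(seed)
    labels = np.array([p.label for p in pairs])
    shuffled = labels[rng.permutation(len(labels))]
    return [
        InteractionPair(p.antibody_id, p.antigen_id, int(l))
        for p, l in zip(pairs, shuffled)
    ]
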