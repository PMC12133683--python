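"""CDR sensitivity analysis: masking and removal of complementarity-
determining regions, and the performance-bias measure.

Masking replaces the residues of targeted antibody regions with the mask
token 'X' (length preserved); the one-hot row of a masked position is zero,
pair windows touching it drop out of the CKSAAP features, and stored
embedding rows are zeroed — so features are genuinely recomputed from the
occluded sequence rather than zeroed at the model input.  The bias of a
masking condition is ``b = metric(baseline) - metric(condition)``; a larger
bias means the predictor leans more on the occluded region.  Models for the
region-removal experiment are retrained from scratch on the shortened
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .io_formats import (
    InteractionPair,
    MASK,
    RegionAnnotation,
    SequenceRecord,
    regions_by_sequence,
)
from .train_eval import metrics_report, pr_auc, roc_auc

CDR_NAMES = ("CDR1", "CDR2", "CDR3")


@dataclass(frozen=True)
class MaskCondition:
    name: str
    regions: tuple[str, ...]


MASK_CONDITIONS: tuple[MaskCondition, ...] = (
    MaskCondition("none", ()),
    MaskCondition("Mask-CDR1", ("CDR1",)),
    MaskCondition("Mask-CDR2", ("CDR2",)),
    MaskCondition("Mask-CDR3", ("CDR3",)),
    MaskCondition("Mask-CDRs", CDR_NAMES),
)

_CONDITION_BY_NAME = {c.name: c for c in MASK_CONDITIONS}


def get_condition(name: str) -> MaskCondition:
    if name not in _CONDITION_BY_NAME:
        raise KeyError(f"unknown mask condition {name!r}")
    return _CONDITION_BY_NAME[name]


def _spans_for(seq: SequenceRecord,
               annotations: Mapping[str, RegionAnnotation],
               which: Iterable[str]) -> list[tuple[int, int]]:
    spans = []
    for name in which:
        if name not in annotations:
            raise KeyError(f"no {name!r} annotation for sequence {seq.id!r}")
        a = annotations[name]
        if a.end > len(seq):
            raise ValueError(f"region {name!r} exceeds sequence {seq.id!r}")
        spans.append((a.start, a.end))
    return spans


def mask_regions(seq: SequenceRecord,
                 annotations: Mapping[str, RegionAnnotation],
                 condition: MaskCondition) -> SequenceRecord:
    """Replace residues inside the condition's regions with 'X'."""
    spans = _spans_for(seq, annotations, condition.regions)
    if not spans:
        return seq
    residues = list(seq.residues)
    for s, e in spans:
        residues[s:e] = MASK * (e - s)
    return SequenceRecord(seq.id, "".join(residues))


def remove_regions(seq: SequenceRecord,
                   annotations: Mapping[str, RegionAnnotation],
                   which: Iterable[str]) -> SequenceRecord:
    """Excise the targeted spans; length shrinks by their summed extent."""
    spans = sorted(_spans_for(seq, annotations, which))
    if not spans:
        return seq
    kept = []
    prev = 0
    for s, e in spans:
        kept.append(seq.residues[prev:s])
        prev = e
    kept.append(seq.residues[prev:])
    return SequenceRecord(seq.id, "".join(kept))


class PairScorer(Protocol):
    """Anything that scores interaction pairs against a sequence collection."""

    def predict_pairs(self, pairs: Sequence[InteractionPair],
                      sequences: Mapping[str, SequenceRecord]) -> np.ndarray:
        ...


@dataclass(frozen=True)
class BiasReport:
    metric: str
    baseline: float
    values: dict[str, float]  # condition name -> metric value
    bias: dict[str, float]    # condition name -> baseline - value

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "baseline": self.baseline,
            "values": dict(self.values),
            "bias": dict(self.bias),
        }


def _metric_value(name: str, scores: np.ndarray, labels: np.ndarray) -> float:
    if name == "MCC":
        return metrics_report(scores, labels).MCC
    if name == "AUC":
        return roc_auc(scores, labels)
    if name == "AUPR":
        return pr_auc(scores, labels)
    raise ValueError(f"metric must be one of MCC/AUC/AUPR, got {name!r}")


def sensitivity_bias(model: PairScorer,
                     pairs: Sequence[InteractionPair],
                     sequences: Mapping[str, SequenceRecord],
                     annotations: Sequence[RegionAnnotation],
                     metric: str = "AUC",
                     conditions: Sequence[MaskCondition] = MASK_CONDITIONS,
                     ) -> BiasReport:
    """Evaluate ``metric`` under each antibody-masking condition.

    Only antibody sequences are masked (CDRs are antibody features); the
    antigen side is untouched.  Features are recomputed from the masked
    sequences by the scorer.
    """
    by_seq = regions_by_sequence(annotations)
    labels = np.array([p.label for p in pairs], dtype=np.float64)
    antibody_ids = {p.antibody_id for p in pairs}
    values: dict[str, float] = {}
    for condition in conditions:
        masked = dict(sequences)
        for ab_id in antibody_ids:
            masked[ab_id] = mask_regions(
                sequences[ab_id], by_seq.get(ab_id, {}), condition
            )
        scores = model.predict_pairs(pairs, masked)
        values[condition.name] = _metric_value(metric, scores, labels)
    baseline = values["none"]
    bias = {name: baseline - v for name, v in values.items()}
    return BiasReport(metric=metric, baseline=baseline, values=values, bias=bias)
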