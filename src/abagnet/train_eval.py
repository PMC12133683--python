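"""Training loop, evaluation metrics and multi-run comparison.

Training minimizes binary cross-entropy with Adam.  The default
hyperparameters (80 epochs, learning rate 5e-4, batch size 128) target
full-scale datasets; the synthetic desk-scale studies use smaller, faster
settings chosen in :mod:`abagnet.study`.

Metrics: accuracy, precision, recall, specificity, F1 and the Matthews
correlation coefficient from thresholded confusion counts, plus ROC AUC and
the area under the precision-recall curve from the raw scores.  Zero
denominators follow the usual conventions (precision/recall/specificity/F1
and MCC fall back to 0) and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .autodiff import bce_with_logits
from .io_formats import InteractionPair, SequenceRecord
from .model import Featurizer, InteractionModel, assemble_batch
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 80
    learning_rate: float = 5e-4
    batch_size: int = 128
    optimizer: str = "adam"
    loss: str = "bce"
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 0 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("epochs/learning rate/batch size must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "bce":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.device not in ("cpu", "gpu"):
            raise ValueError(f"unknown device {self.device!r}")
        if self.device == "gpu":
            logger.warning("no GPU backend available; running on cpu")


@dataclass
class PairDataset:
    """Interaction pairs bound to their sequence collection and featurizer."""

    pairs: list[InteractionPair]
    sequences: Mapping[str, SequenceRecord]
    featurizer: Featurizer

    def __post_init__(self):
        for p in self.pairs:
            for sid in (p.antibody_id, p.antigen_id):
                if sid not in self.sequences:
                    raise KeyError(f"pair references unknown sequence {sid!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=np.float64)

    def subset(self, idx: Sequence[int]) -> list[InteractionPair]:
        return [self.pairs[i] for i in idx]


def train(model: InteractionModel, train_data: PairDataset,
          valid_data: PairDataset | None, cfg: TrainConfig
          ) -> tuple[InteractionModel, list[dict]]:
    """Train in place; returns the model and a per-epoch history.

    With ``epochs = 0`` the initialized model is returned unchanged.  There
    is no early stopping; the final-epoch model is the result.
    """
    if len(train_data) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    labels = train_data.labels
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_data))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            batch = assemble_batch(
                train_data.subset(idx), train_data.sequences,
                train_data.featurizer,
            )
            optimizer.zero_grad()
            logits = model.forward_logits(*batch)
            loss = bce_with_logits(logits, labels[idx])
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if valid_data is not None and len(valid_data) > 0:
            scores = model.predict_batch(
                valid_data.pairs, valid_data.sequences, valid_data.featurizer
            )
            report = metrics_report(scores, valid_data.labels)
            entry["valid_acc"] = report.ACC
            entry["valid_auc"] = report.AUC
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
    return model, history


def evaluate(model: InteractionModel, data: PairDataset,
             threshold: float = 0.5) -> "MetricsReport":
    scores = model.predict_batch(data.pairs, data.sequences, data.featurizer)
    return metrics_report(scores, data.labels, threshold)


# ---------------------------------------------------------------------------
# Metrics

def confusion_counts(scores: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with prediction = 1 iff score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores and labels differ in length: {scores.shape} vs {labels.shape}"
        )
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    pred = scores >= threshold
    pos = labels == 1
    TP = int(np.sum(pred & pos))
    FP = int(np.sum(pred & ~pos))
    TN = int(np.sum(~pred & ~pos))
    FN = int(np.sum(~pred & pos))
    return TP, FP, TN, FN


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; using convention value 0", name)
        return 0.0
    return num / den


def threshold_metrics(TP: int, FP: int, TN: int, FN: int
                      ) -> tuple[float, float, float, float, float, float]:
    """(ACC, Pre, Recall, Spe, F1, MCC) from confusion counts."""
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = TP + FP + TN + FN
    if total == 0:
        raise ValueError("at least one sample required")
    acc = (TP + TN) / total
    pre = _ratio(TP, TP + FP, "precision")
    rec = _ratio(TP, TP + FN, "recall")
    spe = _ratio(TN, TN + FP, "specificity")
    f1 = _ratio(2 * TP, 2 * TP + FN + FP, "F1")
    mcc_den = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = _ratio(float(TP) * TN - float(FP) * FN, mcc_den, "MCC")
    return acc, pre, rec, spe, f1, mcc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; requires both classes present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step summation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("PR AUC undefined for single-class labels")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class MetricsReport:
    TP: int
    FP: int
    TN: int
    FN: int
    ACC: float
    Pre: float
    Recall: float
    Spe: float
    F1: float
    MCC: float
    AUC: float
    AUPR: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def __getitem__(self, key: str):
        return getattr(self, key)


def metrics_report(scores: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.5) -> MetricsReport:
    """Full eight-metric report from scores and binary labels."""
    TP, FP, TN, FN = confusion_counts(scores, labels, threshold)
    acc, pre, rec, spe, f1, mcc = threshold_metrics(TP, FP, TN, FN)
    return MetricsReport(
        TP=TP, FP=FP, TN=TN, FN=FN,
        ACC=acc, Pre=pre, Recall=rec, Spe=spe, F1=f1, MCC=mcc,
        AUC=roc_auc(scores, labels), AUPR=pr_auc(scores, labels),
    )


def compare_runs(metric_samples_a: Sequence[float],
                 metric_samples_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between two groups of run metrics."""
    a = np.asarray(metric_samples_a, dtype=np.float64)
    b = np.asarray(metric_samples_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if a.std() == 0.0 and b.std() == 0.0:
        # degenerate: both groups constant; t statistic is 0/0
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
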