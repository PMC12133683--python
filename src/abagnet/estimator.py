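"""Scikit-learn style estimator wrapping the full interaction predictor.

:class:`AAIClassifier` exposes the antibody-antigen interaction model as a
binary classifier with ``fit`` / ``predict`` / ``predict_proba`` and the
usual ``get_params`` / ``set_params`` machinery, so it composes with sklearn
pipelines and model selection.  ``X`` is an array-like of shape (n, 2)
holding raw amino-acid strings ``[antibody, antigen]`` per row; ``y`` is the
binary interaction label.

Defaults are desk-scale (small widths, 15 epochs) so the estimator trains in
minutes on one CPU; published-scale settings are reachable through the
parameters (``k=3, lcnn_units=2`` mirror the published architecture and
``epochs=80, learning_rate=5e-4, batch_size=128`` its training schedule).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io_formats import (
    EmbeddingStore,
    InteractionPair,
    SequenceRecord,
    canonicalize,
)
from .lcnn import ConvSpec, LCNNConfig
from .model import Featurizer, InteractionModel, ModelConfig, build_model
from .rcca import RCCAConfig
from .train_eval import PairDataset, TrainConfig, train


class AAIClassifier(ClassifierMixin, BaseEstimator):
    """Antibody-antigen interaction classifier.

    Parameters mirror the model architecture (CKSAAP gap bound ``k``, the
    CNN-BiLSTM stack, the criss-cross attention block, the MLP head) and the
    training schedule.  ``encoder`` selects the per-residue representation:
    built-in one-hot, or an external per-residue embedding store.
    """

    def __init__(self, k=1, encoder="one_hot", embedding_store=None,
                 lcnn_units=1, kernel=3, conv_channels=32, pool=2,
                 hidden=16, projection_dim=32,
                 rcca_recurrences=2, rcca_reduction=8, rcca_pre_channels=16,
                 rcca_out_dim=32, mlp_hidden=(64, 16),
                 epochs=15, learning_rate=2e-3, batch_size=32,
                 threshold=0.5, random_state=0):
        self.k = k
        self.encoder = encoder
        self.embedding_store = embedding_store
        self.lcnn_units = lcnn_units
        self.kernel = kernel
        self.conv_channels = conv_channels
        self.pool = pool
        self.hidden = hidden
        self.projection_dim = projection_dim
        self.rcca_recurrences = rcca_recurrences
        self.rcca_reduction = rcca_reduction
        self.rcca_pre_channels = rcca_pre_channels
        self.rcca_out_dim = rcca_out_dim
        self.mlp_hidden = mlp_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    # -- configuration --------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            k=self.k,
            encoder=self.encoder,
            lcnn=LCNNConfig(
                n=self.lcnn_units,
                conv=ConvSpec(self.kernel, self.projection_dim,
                              self.conv_channels),
                pool_width=self.pool,
                hidden=self.hidden,
                projection_dim=self.projection_dim,
            ),
            rcca=RCCAConfig(
                recurrences=self.rcca_recurrences,
                reduction=self.rcca_reduction,
                pre_channels=self.rcca_pre_channels,
                out_dim=self.rcca_out_dim,
            ),
            mlp_hidden=tuple(self.mlp_hidden),
        )

    def _make_featurizer(self) -> Featurizer:
        store = self.embedding_store
        if isinstance(store, (str,)):
            store = EmbeddingStore.load(store)
        return Featurizer(self.k, self.encoder, store)

    # -- raw-string interface --------------------------------------------------
    @staticmethod
    def _to_pairs(X) -> tuple[list[InteractionPair], dict[str, SequenceRecord]]:
        rows = list(X)
        sequences: dict[str, SequenceRecord] = {}
        index: dict[str, str] = {}  # residues -> id
        pairs = []

        def intern(residues: str, side: str) -> str:
            residues = canonicalize(str(residues))
            key = side + ":" + residues
            if key not in index:
                sid = f"{side}{len(index):06d}"
                index[key] = sid
                sequences[sid] = SequenceRecord(sid, residues)
            return index[key]

        for row in rows:
            if len(row) != 2:
                raise ValueError("each sample must be [antibody, antigen]")
            ab, ag = row
            pairs.append(
                InteractionPair(intern(ab, "ab"), intern(ag, "ag"), 0)
            )
        return pairs, sequences

    def fit(self, X, y):
        """Fit on (antibody, antigen) string pairs with binary labels."""
        pairs, sequences = self._to_pairs(X)
        y = np.asarray(y)
        if y.shape[0] != len(pairs):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        labelled = [
            InteractionPair(p.antibody_id, p.antigen_id, int(lab))
            for p, lab in zip(pairs, y)
        ]
        return self.fit_pairs(labelled, sequences)

    def fit_pairs(self, pairs: Sequence[InteractionPair],
                  sequences: Mapping[str, SequenceRecord],
                  valid_pairs: Sequence[InteractionPair] | None = None):
        """Fit on id-based pairs resolved against a sequence collection."""
        cfg = self._model_config()
        featurizer = self._make_featurizer()
        self.model_: InteractionModel = build_model(
            cfg, seed=self.random_state, embed_dim=featurizer.embed_dim
        )
        train_cfg = TrainConfig(
            epochs=self.epochs, learning_rate=self.learning_rate,
            batch_size=self.batch_size, seed=self.random_state,
        )
        train_ds = PairDataset(list(pairs), sequences, featurizer)
        valid_ds = (PairDataset(list(valid_pairs), sequences, featurizer)
                    if valid_pairs else None)
        _, self.history_ = train(self.model_, train_ds, valid_ds, train_cfg)
        self.featurizer_ = featurizer
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        pairs, sequences = self._to_pairs(X)
        p1 = self.predict_pairs(pairs, sequences)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def predict_pairs(self, pairs: Sequence[InteractionPair],
                      sequences: Mapping[str, SequenceRecord]) -> np.ndarray:
        """Interaction probabilities for id-based pairs (PairScorer surface)."""
        check_is_fitted(self, "model_")
        # fresh featurizer: sequences may be masked variants of training ones
        featurizer = self._make_featurizer()
        return self.model_.predict_batch(pairs, sequences, featurizer,
                                         batch_size=self.batch_size)
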