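"""Assembly of the full interaction predictor.

Each chain (antibody, antigen) is featurized twice: its per-residue embedding
feeds a CNN-BiLSTM branch, and its embedding-fused CKSAAP tensor — flattened
over the embedding and gap axes into channels on the 20 x 20 pair grid —
feeds a criss-cross attention branch.  The four branch vectors are
concatenated and classified by an MLP with a sigmoid output.  Antibody and
antigen branches have separate parameters throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import (
    EmbeddingMatrix,
    cksaap_fused,
    lookup_embeddings,
    one_hot_encode,
)
from .io_formats import EmbeddingStore, InteractionPair, MASK, SequenceRecord
from .lcnn import LCNNBranch, LCNNConfig, ConvSpec
from .nn import Linear
from .rcca import RCCABranch, RCCAConfig

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    k: int = 3
    encoder: str = "one_hot"  # "one_hot" | "store"
    lcnn: LCNNConfig = field(default_factory=LCNNConfig)
    rcca: RCCAConfig = field(default_factory=RCCAConfig)
    mlp_hidden: tuple[int, ...] = (256, 64)

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.encoder not in ("one_hot", "store"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if len(self.mlp_hidden) == 0:
            raise ValueError("mlp_hidden needs at least one layer width")
        if any(w < 1 for w in self.mlp_hidden):
            raise ValueError("mlp widths must be positive")

    @staticmethod
    def tiny(k: int = 1, n: int = 1) -> "ModelConfig":
        """Desk-scale configuration used throughout the synthetic studies."""
        return ModelConfig(
            k=k,
            lcnn=LCNNConfig(
                n=n, conv=ConvSpec(3, 32, 32), pool_width=2,
                hidden=16, projection_dim=32,
            ),
            rcca=RCCAConfig(recurrences=2, reduction=8, pre_channels=16,
                            out_dim=32),
            mlp_hidden=(64, 16),
        )


class Featurizer:
    """Computes and caches per-sequence model inputs.

    For each sequence it produces the per-residue embedding (the CNN-BiLSTM
    branch input) and the fused CKSAAP grid with D * (k+1) channels (the
    attention branch input).  Results are cached by residue string, so a
    masked variant of a sequence gets its own entry.  When an external
    embedding store is used, rows at masked ('X') positions are zeroed.
    """

    def __init__(self, k: int, encoder: str = "one_hot",
                 store: EmbeddingStore | None = None):
        if encoder == "store" and store is None:
            raise ValueError("encoder='store' requires an embedding store")
        self.k = k
        self.encoder = encoder
        self.store = store
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def embed_dim(self) -> int:
        return 20 if self.encoder == "one_hot" else self.store.dim

    def embedding(self, seq: SequenceRecord) -> EmbeddingMatrix:
        if self.encoder == "one_hot":
            return one_hot_encode(seq)
        emb = lookup_embeddings(self.store, seq)
        masked_rows = np.array([c == MASK for c in seq.residues])
        if masked_rows.any():
            values = emb.values.copy()
            values[masked_rows] = 0.0
            emb = EmbeddingMatrix(seq.id, values)
        return emb

    def __call__(self, seq: SequenceRecord) -> tuple[np.ndarray, np.ndarray]:
        """Return (embedding L x D, grid C x 20 x 20) for one sequence."""
        key = seq.residues if self.encoder == "one_hot" else seq.id + ":" + seq.residues
        if key not in self._cache:
            emb = self.embedding(seq)
            fused = cksaap_fused(seq, emb, self.k)
            D = fused.values.shape[0]
            grid = fused.values.reshape(D * (self.k + 1), 20, 20)
            self._cache[key] = (emb.values, grid)
        return self._cache[key]


class MLPHead:
    """ReLU MLP ending in a single interaction logit."""

    def __init__(self, d_in: int, hidden: Sequence[int], rng: np.random.Generator):
        if len(hidden) == 0:
            raise ValueError("MLP head needs at least one hidden layer")
        self.layers: list[Linear] = []
        width = d_in
        for h in hidden:
            self.layers.append(Linear(width, h, rng))
            width = h
        self.out = Linear(width, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
        return self.out(x).reshape(x.shape[0])

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers:
            params += layer.parameters()
        return params + self.out.parameters()


class InteractionModel:
    """Four branch networks plus the fusion MLP."""

    def __init__(self, cfg: ModelConfig, seed: int, embed_dim: int | None = None):
        self.cfg = cfg
        self.seed = seed
        D = embed_dim if embed_dim is not None else 20
        self.embed_dim = D
        rng = np.random.default_rng(seed)
        channels = D * (cfg.k + 1)
        self.ab_lcnn = LCNNBranch(D, cfg.lcnn, rng)
        self.ag_lcnn = LCNNBranch(D, cfg.lcnn, rng)
        self.ab_rcca = RCCABranch(channels, cfg.rcca, rng)
        self.ag_rcca = RCCABranch(channels, cfg.rcca, rng)
        self.fusion_dim = (self.ab_rcca.out_dim + self.ab_lcnn.out_dim
                           + self.ag_rcca.out_dim + self.ag_lcnn.out_dim)
        self.head = MLPHead(self.fusion_dim, cfg.mlp_hidden, rng)
        logger.info(
            "built interaction model: %d parameters (fusion width %d)",
            self.parameter_count(), self.fusion_dim,
        )

    def parameters(self) -> list[Tensor]:
        return (self.ab_lcnn.parameters() + self.ag_lcnn.parameters()
                + self.ab_rcca.parameters() + self.ag_rcca.parameters()
                + self.head.parameters())

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- tensor-level forward -------------------------------------------------
    def forward_logits(
        self,
        ab_emb: np.ndarray, ab_lengths: np.ndarray, ab_grid: np.ndarray,
        ag_emb: np.ndarray, ag_lengths: np.ndarray, ag_grid: np.ndarray,
    ) -> Tensor:
        """Batched forward pass on pre-featurized, padded inputs."""
        vec_ab_rcca = self.ab_rcca(Tensor(ab_grid))
        vec_ab_lcnn = self.ab_lcnn(Tensor(ab_emb), ab_lengths)
        vec_ag_rcca = self.ag_rcca(Tensor(ag_grid))
        vec_ag_lcnn = self.ag_lcnn(Tensor(ag_emb), ag_lengths)
        fusion = ad.concat(
            [vec_ab_rcca, vec_ab_lcnn, vec_ag_rcca, vec_ag_lcnn], axis=1
        )
        return self.head(fusion)

    # -- sequence-level API ---------------------------------------------------
    def forward(self, ab: SequenceRecord, ab_emb: EmbeddingMatrix,
                ag: SequenceRecord, ag_emb: EmbeddingMatrix) -> float:
        """Interaction probability for one antibody/antigen pair."""
        for seq, emb in ((ab, ab_emb), (ag, ag_emb)):
            if emb.values.shape[0] != len(seq):
                raise ValueError(
                    f"embedding rows do not align with sequence {seq.id!r}"
                )
        def grid_of(seq, emb):
            fused = cksaap_fused(seq, emb, self.cfg.k)
            D = fused.values.shape[0]
            return fused.values.reshape(D * (self.cfg.k + 1), 20, 20)

        logit = self.forward_logits(
            ab_emb.values[None], np.array([len(ab)]), grid_of(ab, ab_emb)[None],
            ag_emb.values[None], np.array([len(ag)]), grid_of(ag, ag_emb)[None],
        )
        return float(1.0 / (1.0 + np.exp(-logit.data[0])))

    def predict_batch(self, pairs: Sequence[InteractionPair],
                      sequences: Mapping[str, SequenceRecord],
                      featurizer: Featurizer,
                      batch_size: int = 64) -> np.ndarray:
        """Probabilities aligned with pair order."""
        probs = np.empty(len(pairs))
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo:lo + batch_size]
            batch = assemble_batch(chunk, sequences, featurizer)
            logit = self.forward_logits(*batch)
            probs[lo:lo + len(chunk)] = 1.0 / (1.0 + np.exp(-logit.data))
        return probs


def assemble_batch(pairs: Sequence[InteractionPair],
                   sequences: Mapping[str, SequenceRecord],
                   featurizer: Featurizer):
    """Featurize and zero-pad a batch of pairs to the batch maximum length."""
    for p in pairs:
        for sid in (p.antibody_id, p.antigen_id):
            if sid not in sequences:
                raise KeyError(f"pair references unknown sequence {sid!r}")
    ab_seqs = [sequences[p.antibody_id] for p in pairs]
    ag_seqs = [sequences[p.antigen_id] for p in pairs]

    def side(seqs):
        feats = [featurizer(s) for s in seqs]
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        D = feats[0][0].shape[1]
        L = int(lengths.max())
        emb = np.zeros((len(seqs), L, D))
        for i, (e, _) in enumerate(feats):
            emb[i, : e.shape[0]] = e
        grid = np.stack([g for _, g in feats])
        return emb, lengths, grid

    ab_emb, ab_len, ab_grid = side(ab_seqs)
    ag_emb, ag_len, ag_grid = side(ag_seqs)
    return ab_emb, ab_len, ab_grid, ag_emb, ag_len, ag_grid


def build_model(cfg: ModelConfig, seed: int,
                embed_dim: int | None = None) -> InteractionModel:
    """Deterministically initialized model; same seed, same parameters."""
    return InteractionModel(cfg, seed, embed_dim)


# ---------------------------------------------------------------------------
# Checkpoints: one .npz file with the parameter arrays and embedded config

def config_to_dict(cfg: ModelConfig) -> dict:
    return {
        "k": cfg.k,
        "encoder": cfg.encoder,
        "lcnn": {
            "n": cfg.lcnn.n,
            "kernel": cfg.lcnn.conv.m,
            "channels": cfg.lcnn.conv.out_channels,
            "pool": cfg.lcnn.pool_width,
            "hidden": cfg.lcnn.hidden,
            "projection_dim": cfg.lcnn.projection_dim,
        },
        "rcca": {
            "recurrences": cfg.rcca.recurrences,
            "reduction": cfg.rcca.reduction,
            "pre_channels": cfg.rcca.pre_channels,
            "out_dim": cfg.rcca.out_dim,
        },
        "mlp_hidden": list(cfg.mlp_hidden),
    }


def config_from_dict(d: Mapping) -> ModelConfig:
    lc = d.get("lcnn", {})
    rc = d.get("rcca", {})
    projection_dim = lc.get("projection_dim", 256)
    return ModelConfig(
        k=d.get("k", 3),
        encoder=d.get("encoder", "one_hot"),
        lcnn=LCNNConfig(
            n=lc.get("n", 2),
            conv=ConvSpec(lc.get("kernel", 3), projection_dim,
                          lc.get("channels", 64)),
            pool_width=lc.get("pool", 2),
            hidden=lc.get("hidden", 128),
            projection_dim=projection_dim,
        ),
        rcca=RCCAConfig(
            recurrences=rc.get("recurrences", 2),
            reduction=rc.get("reduction", 8),
            pre_channels=rc.get("pre_channels", 256),
            out_dim=rc.get("out_dim", 64),
        ),
        mlp_hidden=tuple(d.get("mlp_hidden", (256, 64))),
    )


def save_checkpoint(model: InteractionModel, path) -> None:
    import json

    meta = {
        "config": config_to_dict(model.cfg),
        "seed": model.seed,
        "embed_dim": model.embed_dim,
    }
    arrays = {f"p{i:04d}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> InteractionModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        model = InteractionModel(config_from_dict(meta["config"]),
                                 seed=meta["seed"],
                                 embed_dim=meta["embed_dim"])
        params = model.parameters()
        for i, p in enumerate(params):
            stored = data[f"p{i:04d}"]
            if stored.shape != p.data.shape:
                raise ValueError("checkpoint does not match model architecture")
            p.data = stored.astype(np.float64)
    return model
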