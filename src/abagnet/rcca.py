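"""Recurrent criss-cross attention over a square feature grid.

Each grid position u attends to the 2n-1 positions sharing its row or column
(u itself counted once): affinities are dot products between u's query and the
keys at those positions, normalized by a softmax into a probability fiber,
and values are aggregated with an additive residual back onto the input.
Running the block twice (the default recurrence) propagates information
between any two grid cells, giving every output position a full-grid
receptive field.

Here the grid is the 20 x 20 ordered amino-acid-pair plane of the fused
CKSAAP tensor, whose embedding and gap axes are flattened into channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear, glorot


@dataclass
class RCCAConfig:
    recurrences: int = 2
    reduction: int = 8          # C' = max(1, C // reduction)
    pre_channels: int | None = 256  # optional 1x1 channel reduction before RCCA
    out_dim: int = 64           # branch output width after pooling

    def __post_init__(self):
        if self.recurrences < 1:
            raise ValueError("recurrences must be >= 1")
        if self.reduction < 1 or self.out_dim < 1:
            raise ValueError("invalid RCCA configuration")


@dataclass
class QKVBundle:
    Q: Tensor  # C' x n x n (leading batch axis when batched)
    K: Tensor
    V: Tensor


def _excluded_row_index(n: int) -> np.ndarray:
    """ex[m, i] = the m-th row index different from i (shape (n-1, n))."""
    ex = np.empty((n - 1, n), dtype=np.int64)
    for i in range(n):
        ex[:, i] = [r for r in range(n) if r != i]
    return ex


def _inverse_row_index(n: int) -> np.ndarray:
    """inv[l, i] = position of row l within the excluded-row list for i,
    or n-1 (the appended zero slot) when l == i (shape (n, n))."""
    ex = _excluded_row_index(n)
    inv = np.full((n, n), n - 1, dtype=np.int64)
    for i in range(n):
        for m in range(n - 1):
            inv[ex[m, i], i] = m
    return inv


class QKVProjection:
    """Three independent 1x1 convolutions producing queries, keys, values."""

    def __init__(self, channels: int, reduced: int, rng: np.random.Generator):
        if reduced >= channels:
            raise ValueError(
                f"reduced channel count {reduced} must be < channels {channels}"
            )
        if reduced < 1:
            raise ValueError("reduced channel count must be >= 1")
        self.channels = channels
        self.reduced = reduced
        self.W_q = glorot(rng, channels, reduced)
        self.W_k = glorot(rng, channels, reduced)
        self.W_v = glorot(rng, channels, channels)
        self.b_q = Tensor(np.zeros(reduced), requires_grad=True)
        self.b_k = Tensor(np.zeros(reduced), requires_grad=True)
        self.b_v = Tensor(np.zeros(channels), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W_q, self.W_k, self.W_v, self.b_q, self.b_k, self.b_v]


def _conv1x1(H: Tensor, W: Tensor, b: Tensor) -> Tensor:
    # (B, C, n, n) x (C, C_out) -> (B, C_out, n, n)
    out = ad.einsum("bcij,cd->bdij", H, W)
    return out + b.reshape(1, -1, 1, 1)


def qkv_project(H: Tensor, params: QKVProjection) -> QKVBundle:
    """Project grid features to Q, K (reduced channels) and V (full width)."""
    if H.ndim == 3:
        H = H.reshape(1, *H.shape)
    if H.shape[1] != params.channels:
        raise ValueError(f"expected {params.channels} channels, got {H.shape[1]}")
    return QKVBundle(
        Q=_conv1x1(H, params.W_q, params.b_q),
        K=_conv1x1(H, params.W_k, params.b_k),
        V=_conv1x1(H, params.W_v, params.b_v),
    )


def cc_affinity(Q: Tensor, K: Tensor) -> Tensor:
    """Criss-cross attention map of shape (B, 2n-1, n, n).

    Fiber A[:, :, i, j] is the softmax over the dot products between the query
    at (i, j) and the keys in row i (n entries, (i, j) itself included there)
    followed by the keys in column j excluding row i (n-1 entries).
    """
    if Q.ndim == 3:
        Q = Q.reshape(1, *Q.shape)
        K = K.reshape(1, *K.shape)
    if Q.shape != K.shape:
        raise ValueError(f"Q/K shape mismatch: {Q.shape} vs {K.shape}")
    n = Q.shape[2]
    if Q.shape[3] != n:
        raise ValueError(f"grid must be square, got {Q.shape[2:]}")
    # row part: for target column l in u's row i
    d_row = ad.einsum("bcij,bcil->blij", Q, K)
    # column part: for source row l in u's column j, then drop l == i
    d_col = ad.einsum("bcij,bclj->blij", Q, K)
    ex = _excluded_row_index(n)  # (n-1, n) indexed [m, i]
    d_col_ex = ad.gather(d_col, ex[None, :, :, None], axis=1)
    logits = ad.concat([d_row, d_col_ex], axis=1)  # (B, 2n-1, n, n)
    return logits.softmax(axis=1)


def cc_aggregate(A: Tensor, V: Tensor, H: Tensor) -> Tensor:
    """Attention-weighted sum of criss-cross values plus the residual input."""
    if V.ndim == 3:
        V = V.reshape(1, *V.shape)
        H = H.reshape(1, *H.shape)
        A = A.reshape(1, *A.shape) if A.ndim == 3 else A
    n = V.shape[2]
    if A.shape[1] != 2 * n - 1:
        raise ValueError(
            f"attention map has {A.shape[1]} positions per fiber, expected {2 * n - 1}"
        )
    if V.shape != H.shape:
        raise ValueError(f"V/H shape mismatch: {V.shape} vs {H.shape}")
    A_row = A[:, :n]
    A_col = A[:, n:]
    out_row = ad.einsum("blij,bcil->bcij", A_row, V)
    # Re-expand the self-excluded column weights to full column length with a
    # zero at the self slot, so aggregation is a plain einsum against V.
    B = A.shape[0]
    zeros = Tensor(np.zeros((B, 1, n, n)))
    A_ext = ad.concat([A_col, zeros], axis=1)
    inv = _inverse_row_index(n)
    A_colfull = ad.gather(A_ext, inv[None, :, :, None], axis=1)
    out_col = ad.einsum("blij,bclj->bcij", A_colfull, V)
    return out_row + out_col + H


class RCCABranch:
    """Optional 1x1 pre-reduction, R criss-cross passes (shared projections),
    global average pooling and a linear map to the branch output width."""

    def __init__(self, channels: int, cfg: RCCAConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.pre: Linear | None = None
        width = channels
        if cfg.pre_channels is not None and channels > cfg.pre_channels:
            self.pre = Linear(channels, cfg.pre_channels, rng)
            width = cfg.pre_channels
        reduced = max(1, width // cfg.reduction)
        if reduced >= width:
            raise ValueError(
                f"cannot reduce {width} channels for attention; need >= 2"
            )
        self.qkv = QKVProjection(width, reduced, rng)
        self.head = Linear(width, cfg.out_dim, rng)
        self.out_dim = cfg.out_dim

    def parameters(self) -> list[Tensor]:
        params = self.qkv.parameters() + self.head.parameters()
        if self.pre is not None:
            params += self.pre.parameters()
        return params

    def __call__(self, H: Tensor) -> Tensor:
        return rcca_forward(H, self.cfg.recurrences, self)


def rcca_forward(H: Tensor, R: int, branch: RCCABranch) -> Tensor:
    """R recurrences of [project -> affinity -> aggregate], then pooling."""
    if R < 1:
        raise ValueError(f"recurrence count must be >= 1, got {R}")
    squeeze = H.ndim == 3
    if squeeze:
        H = H.reshape(1, *H.shape)
    if branch.pre is not None:
        # 1x1 reduction: channels last for the linear layer, then back
        H = ad.einsum("bcij,cd->bdij", H, branch.pre.W) \
            + branch.pre.b.reshape(1, -1, 1, 1)
    for _ in range(R):
        bundle = qkv_project(H, branch.qkv)
        A = cc_affinity(bundle.Q, bundle.K)
        H = cc_aggregate(A, bundle.V, H)
    pooled = H.mean(axis=(2, 3))  # global average over the n x n grid
    out = branch.head(pooled)
    return out.reshape(out.shape[1]) if squeeze else out
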