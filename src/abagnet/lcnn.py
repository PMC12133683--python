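"""The local CNN branch: valid 1-D convolution, max-pooling and a BiLSTM
with an additive residual path, stacked ``n`` times behind an initial linear
projection and closed by masked mean pooling over the remaining positions.

Shape algebra per unit (kernel m, pool width w):
``T_out = floor((T_in - m + 1) / w)``; a sequence is too short for the stack
when any unit would produce zero positions.

Batches are padded to the maximum length with zero rows plus a length mask;
hidden and cell states are multiplied by the mask at every LSTM step, so
padding never leaks into valid positions (in either direction) and appending
pad rows leaves the branch output unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear, glorot


@dataclass(frozen=True)
class ConvSpec:
    m: int  # kernel width in residues
    in_channels: int
    out_channels: int

    def __post_init__(self):
        if self.m < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError(f"invalid ConvSpec {self}")


@dataclass
class LCNNConfig:
    n: int = 2
    conv: ConvSpec = field(default_factory=lambda: ConvSpec(3, 256, 64))
    pool_width: int = 2
    hidden: int = 128
    projection_dim: int = 256

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if min(self.pool_width, self.hidden, self.projection_dim) < 1:
            raise ValueError("all widths must be positive")
        if self.conv.in_channels != self.projection_dim:
            raise ValueError(
                "first conv unit must consume the projection width "
                f"({self.conv.in_channels} != {self.projection_dim})"
            )


class Conv1dValid:
    """Valid (no-padding) 1-D convolution over an L x C feature sequence."""

    def __init__(self, spec: ConvSpec, rng: np.random.Generator):
        self.spec = spec
        fan_in = spec.m * spec.in_channels
        self.W = glorot(rng, fan_in, spec.out_channels)
        self.b = Tensor(np.zeros(spec.out_channels), requires_grad=True)

    def __call__(self, X: Tensor) -> Tensor:
        return conv1d_valid(X, self.spec, (self.W, self.b))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def conv1d_valid(X: Tensor, spec: ConvSpec, params: tuple[Tensor, Tensor]) -> Tensor:
    """h_t = Conv(x_{t:t+m-1}); output has exactly L - m + 1 positions.

    ``X`` is (L, C) or batched (B, L, C); the kernel is given as a flattened
    (m * C, C_out) weight plus a (C_out,) bias.
    """
    W, b = params
    squeeze = X.ndim == 2
    if squeeze:
        X = X.reshape(1, *X.shape)
    B, L, C = X.shape
    m = spec.m
    if L < m:
        raise ValueError(f"sequence length {L} shorter than kernel width {m}")
    if C != spec.in_channels:
        raise ValueError(f"expected {spec.in_channels} input channels, got {C}")
    windows = ad.concat([X[:, j:L - m + 1 + j, :] for j in range(m)], axis=2)
    out = windows @ W + b
    return out.reshape(out.shape[1:]) if squeeze else out


def max_pool1d(X: Tensor, width: int) -> Tensor:
    """Non-overlapping max pooling along the time axis (remainder dropped)."""
    B, T, C = X.shape
    T_out = T // width
    if T_out < 1:
        raise ValueError(f"sequence of {T} positions too short for pool {width}")
    X = X[:, : T_out * width, :]
    return X.reshape(B, T_out, width, C).max(axis=2)


@dataclass
class LSTMParams:
    """Gate weights applied to the concatenation [h_prev, x_t]."""

    W_f: Tensor
    W_i: Tensor
    W_c: Tensor
    W_o: Tensor
    b_f: Tensor
    b_i: Tensor
    b_C: Tensor
    b_o: Tensor

    @classmethod
    def init(cls, d_in: int, hidden: int, rng: np.random.Generator) -> "LSTMParams":
        def w():
            return glorot(rng, d_in + hidden, hidden)

        def b():
            return Tensor(np.zeros(hidden), requires_grad=True)

        return cls(w(), w(), w(), w(), b(), b(), b(), b())

    @property
    def hidden(self) -> int:
        return self.W_f.shape[1]

    def parameters(self) -> list[Tensor]:
        return [self.W_f, self.W_i, self.W_c, self.W_o,
                self.b_f, self.b_i, self.b_C, self.b_o]


def lstm_step(x_t: Tensor, h_prev: Tensor, C_prev: Tensor,
              params: LSTMParams) -> tuple[Tensor, Tensor]:
    """One LSTM update: forget/input/output gates, candidate cell, new state."""
    hx = ad.concat([h_prev, x_t], axis=-1)
    f = (hx @ params.W_f + params.b_f).sigmoid()
    i = (hx @ params.W_i + params.b_i).sigmoid()
    c_tilde = (hx @ params.W_c + params.b_C).tanh()
    o = (hx @ params.W_o + params.b_o).sigmoid()
    C_t = f * C_prev + i * c_tilde
    h_t = o * C_t.tanh()
    return h_t, C_t


def _lstm_run(X: Tensor, params: LSTMParams, mask: np.ndarray | None,
              reverse: bool) -> Tensor:
    B, T, _ = X.shape
    h = Tensor(np.zeros((B, params.hidden)))
    C = Tensor(np.zeros((B, params.hidden)))
    outputs: list[Tensor | None] = [None] * T
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        h, C = lstm_step(X[:, t, :], h, C, params)
        if mask is not None:
            m_t = Tensor(mask[:, t:t + 1])
            h = h * m_t
            C = C * m_t
        outputs[t] = h
    return ad.stack(outputs, axis=1)


def bilstm(X: Tensor, params_fwd: LSTMParams, params_bwd: LSTMParams,
           mask: np.ndarray | None = None) -> Tensor:
    """Concatenated forward and backward LSTM hidden states, (B, T, 2h)."""
    fwd = _lstm_run(X, params_fwd, mask, reverse=False)
    bwd = _lstm_run(X, params_bwd, mask, reverse=True)
    return ad.concat([fwd, bwd], axis=2)


def _unit_out_length(length: np.ndarray, m: int, w: int) -> np.ndarray:
    return (length - m + 1) // w


class LCNNBranch:
    """Projection + n x [conv -> max-pool -> BiLSTM + residual] + mean pool."""

    def __init__(self, d_in: int, cfg: LCNNConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.projection = Linear(d_in, cfg.projection_dim, rng)
        self.convs: list[Conv1dValid] = []
        self.lstms_fwd: list[LSTMParams] = []
        self.lstms_bwd: list[LSTMParams] = []
        self.residual_proj: list[Linear | None] = []
        width = cfg.projection_dim
        for _ in range(cfg.n):
            spec = ConvSpec(cfg.conv.m, width, cfg.conv.out_channels)
            self.convs.append(Conv1dValid(spec, rng))
            self.lstms_fwd.append(LSTMParams.init(spec.out_channels, cfg.hidden, rng))
            self.lstms_bwd.append(LSTMParams.init(spec.out_channels, cfg.hidden, rng))
            out_width = 2 * cfg.hidden
            if spec.out_channels != out_width:
                self.residual_proj.append(Linear(spec.out_channels, out_width, rng))
            else:
                self.residual_proj.append(None)
            width = out_width
        self.out_dim = width

    def parameters(self) -> list[Tensor]:
        params = self.projection.parameters()
        for conv, lf, lb, rp in zip(self.convs, self.lstms_fwd,
                                    self.lstms_bwd, self.residual_proj):
            params += conv.parameters() + lf.parameters() + lb.parameters()
            if rp is not None:
                params += rp.parameters()
        return params

    def min_length(self) -> int:
        """Smallest input length the configured stack accepts."""
        m, w = self.cfg.conv.m, self.cfg.pool_width
        need = 1
        for _ in range(self.cfg.n):
            need = need * w + m - 1
        return need

    def __call__(self, X: Tensor, lengths: np.ndarray | None = None) -> Tensor:
        """Map padded (B, L, D) features (+ per-sample lengths) to (B, 2h)."""
        B, L, _ = X.shape
        if lengths is None:
            lengths = np.full(B, L, dtype=np.int64)
        lengths = np.asarray(lengths, dtype=np.int64)
        if lengths.min() < self.min_length():
            raise ValueError(
                f"sequence of length {int(lengths.min())} too short for "
                f"{self.cfg.n} conv/pool units (need >= {self.min_length()})"
            )
        mask = (np.arange(L)[None, :] < lengths[:, None]).astype(np.float64)
        H = self.projection(X) * Tensor(mask[:, :, None])
        for conv, lf, lb, rp in zip(self.convs, self.lstms_fwd,
                                    self.lstms_bwd, self.residual_proj):
            H = conv(H)
            H = max_pool1d(H, self.cfg.pool_width)
            lengths = _unit_out_length(lengths, conv.spec.m, self.cfg.pool_width)
            T = H.shape[1]
            mask = (np.arange(T)[None, :] < lengths[:, None]).astype(np.float64)
            H = H * Tensor(mask[:, :, None])
            Y = bilstm(H, lf, lb, mask)
            R = rp(H) if rp is not None else H
            H = (Y + R) * Tensor(mask[:, :, None])
        # masked mean over surviving positions
        total = H.sum(axis=1)
        return total * Tensor(1.0 / lengths[:, None])


def lcnn_forward(X: Tensor, branch: LCNNBranch,
                 lengths: np.ndarray | None = None) -> Tensor:
    """Functional alias for :meth:`LCNNBranch.__call__`."""
    return branch(X, lengths)
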