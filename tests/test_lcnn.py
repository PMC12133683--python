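"""Convolution, LSTM recurrence and the stacked CNN-BiLSTM branch."""

import numpy as np
import pytest

from abagnet.autodiff import Tensor
from abagnet.lcnn import (
    Conv1dValid,
    ConvSpec,
    LCNNBranch,
    LCNNConfig,
    LSTMParams,
    bilstm,
    conv1d_valid,
    lcnn_forward,
    lstm_step,
    max_pool1d,
)

RNG = np.random.default_rng(31)


def make_params(d_in, hidden, scale=0.5):
    rng = np.random.default_rng(5)
    p = LSTMParams.init(d_in, hidden, rng)
    for w in p.parameters():
        w.data = rng.normal(size=w.data.shape) * scale
    return p


# ---------------------------------------------------------------------------
# conv1d_valid

def test_conv_identity_kernel_reproduces_input():
    spec = ConvSpec(1, 3, 3)
    W = Tensor(np.eye(3))
    b = Tensor(np.zeros(3))
    X = RNG.normal(size=(6, 3))
    out = conv1d_valid(Tensor(X), spec, (W, b))
    np.testing.assert_allclose(out.data, X)


def test_conv_output_length_is_l_minus_m_plus_1():
    spec = ConvSpec(3, 2, 4)
    W = Tensor(RNG.normal(size=(6, 4)))
    b = Tensor(np.zeros(4))
    out = conv1d_valid(Tensor(RNG.normal(size=(5, 2))), spec, (W, b))
    assert out.shape == (3, 4)


def test_conv_matches_sliding_window_loop_oracle():
    for _ in range(50):
        L = int(RNG.integers(4, 12))
        C, Cout, m = 3, 5, int(RNG.integers(1, 4))
        X = RNG.normal(size=(L, C))
        W = RNG.normal(size=(m * C, Cout))
        b = RNG.normal(size=Cout)
        out = conv1d_valid(Tensor(X), ConvSpec(m, C, Cout),
                           (Tensor(W), Tensor(b))).data
        expected = np.empty((L - m + 1, Cout))
        for t in range(L - m + 1):
            window = X[t:t + m].reshape(-1, order="F")  # channel blocks
            # weight rows are ordered [offset j][channel c] -> flatten windows
            window = np.concatenate([X[t + j] for j in range(m)])
            expected[t] = window @ W + b
        np.testing.assert_allclose(out, expected, atol=1e-6)


def test_conv_rejects_too_short_input():
    spec = ConvSpec(4, 2, 2)
    W, b = Tensor(np.zeros((8, 2))), Tensor(np.zeros(2))
    with pytest.raises(ValueError, match="shorter"):
        conv1d_valid(Tensor(np.zeros((3, 2))), spec, (W, b))


def test_max_pool_width_and_remainder():
    X = Tensor(np.arange(14, dtype=float).reshape(1, 7, 2))
    out = max_pool1d(X, 2)
    assert out.shape == (1, 3, 2)
    np.testing.assert_allclose(out.data[0, 0], [2, 3])


# ---------------------------------------------------------------------------
# lstm_step

def test_lstm_step_zero_parameters_closed_form():
    p = LSTMParams.init(3, 2, np.random.default_rng(0))
    for w in p.parameters():
        w.data = np.zeros_like(w.data)
    x = Tensor(RNG.normal(size=(1, 3)))
    h0 = Tensor(np.zeros((1, 2)))
    # C_prev = 0: all gates sigmoid(0) = 0.5, candidate tanh(0) = 0
    h, C = lstm_step(x, h0, Tensor(np.zeros((1, 2))), p)
    np.testing.assert_allclose(C.data, 0.0)
    np.testing.assert_allclose(h.data, 0.0)
    # C_prev = c: C_t = 0.5 c, h_t = 0.5 tanh(0.5 c)
    c = np.array([[0.8, -1.2]])
    h, C = lstm_step(x, h0, Tensor(c), p)
    np.testing.assert_allclose(C.data, 0.5 * c)
    np.testing.assert_allclose(h.data, 0.5 * np.tanh(0.5 * c))


def test_lstm_step_matches_scalar_recurrence():
    """Independent scalar implementation of the gated update equations."""
    def sigmoid(z):
        return 1 / (1 + np.exp(-z))

    for _ in range(50):
        p = make_params(1, 1, scale=float(RNG.uniform(0.2, 1.5)))
        wf, wi, wc, wo = (float(w.data[0, 0]) for w in
                          (p.W_f, p.W_i, p.W_c, p.W_o))
        uf, ui, uc, uo = (float(w.data[1, 0]) for w in
                          (p.W_f, p.W_i, p.W_c, p.W_o))
        bf, bi, bC, bo = (float(b.data[0]) for b in
                          (p.b_f, p.b_i, p.b_C, p.b_o))
        x, h_prev, C_prev = RNG.normal(size=3)
        f = sigmoid(wf * h_prev + uf * x + bf)
        i = sigmoid(wi * h_prev + ui * x + bi)
        c_tilde = np.tanh(wc * h_prev + uc * x + bC)
        o = sigmoid(wo * h_prev + uo * x + bo)
        C_exp = f * C_prev + i * c_tilde
        h_exp = o * np.tanh(C_exp)
        h, C = lstm_step(Tensor([[x]]), Tensor([[h_prev]]),
                         Tensor([[C_prev]]), p)
        assert abs(float(C.data[0, 0]) - C_exp) < 1e-6
        assert abs(float(h.data[0, 0]) - h_exp) < 1e-6


def test_lstm_gates_strictly_in_unit_interval():
    p = make_params(2, 3, scale=2.0)
    X = Tensor(RNG.normal(size=(4, 2)) * 5)
    h, C = lstm_step(X, Tensor(np.zeros((4, 3))), Tensor(np.zeros((4, 3))), p)
    assert np.all(np.isfinite(h.data)) and np.all(np.isfinite(C.data))
    assert np.all(np.abs(h.data) < 1.0)  # |h| = |o * tanh(C)| < 1


# ---------------------------------------------------------------------------
# bilstm

def test_bilstm_width_is_twice_hidden():
    pf, pb = make_params(3, 4), make_params(3, 4)
    out = bilstm(Tensor(RNG.normal(size=(2, 6, 3))), pf, pb)
    assert out.shape == (2, 6, 8)


def test_bilstm_forward_half_equals_unidirectional_composition():
    pf, pb = make_params(2, 3), make_params(2, 3)
    X = RNG.normal(size=(1, 5, 2))
    out = bilstm(Tensor(X), pf, pb).data
    h = Tensor(np.zeros((1, 3)))
    C = Tensor(np.zeros((1, 3)))
    for t in range(5):
        h, C = lstm_step(Tensor(X[:, t]), h, C, pf)
        np.testing.assert_allclose(out[:, t, :3], h.data, atol=1e-12)


def test_bilstm_backward_half_is_reversed_forward_on_reversed_input():
    pf, pb = make_params(2, 3), make_params(2, 3)
    X = RNG.normal(size=(1, 5, 2))
    out = bilstm(Tensor(X), pf, pb).data
    rev = bilstm(Tensor(X[:, ::-1]), pb, pf).data
    np.testing.assert_allclose(out[:, :, 3:], rev[:, ::-1, :3], atol=1e-12)


# ---------------------------------------------------------------------------
# full branch

def tiny_cfg(n=1):
    return LCNNConfig(n=n, conv=ConvSpec(3, 8, 6), pool_width=2, hidden=4,
                      projection_dim=8)


def test_branch_single_unit_equals_manual_composition():
    cfg = tiny_cfg(1)
    branch = LCNNBranch(5, cfg, np.random.default_rng(3))
    X = RNG.normal(size=(2, 12, 5))
    out = branch(Tensor(X)).data

    H = Tensor(X) @ branch.projection.W + branch.projection.b
    H = branch.convs[0](H)
    H = max_pool1d(H, 2)
    Y = bilstm(H, branch.lstms_fwd[0], branch.lstms_bwd[0],
               np.ones((2, H.shape[1])))
    R = branch.residual_proj[0](H)
    manual = (Y + R).mean(axis=1).data
    np.testing.assert_allclose(out, manual, atol=1e-10)


def test_branch_output_width_and_default_depth():
    cfg = LCNNConfig(n=2, conv=ConvSpec(3, 8, 6), pool_width=2, hidden=4,
                     projection_dim=8)
    branch = LCNNBranch(5, cfg, np.random.default_rng(3))
    out = branch(Tensor(RNG.normal(size=(1, 64, 5))))
    assert out.shape == (1, 8)  # 2 * hidden


def test_branch_padding_invariance():
    cfg = tiny_cfg(1)
    branch = LCNNBranch(5, cfg, np.random.default_rng(3))
    X = RNG.normal(size=(1, 12, 5))
    base = branch(Tensor(X), np.array([12])).data
    padded = np.concatenate([X, RNG.normal(size=(1, 5, 5))], axis=1)
    out = branch(Tensor(padded), np.array([12])).data
    np.testing.assert_allclose(out, base, atol=1e-12)


def test_branch_rejects_too_short_sequences():
    cfg = tiny_cfg(2)
    branch = LCNNBranch(5, cfg, np.random.default_rng(3))
    with pytest.raises(ValueError, match="too short"):
        branch(Tensor(RNG.normal(size=(1, 5, 5))))


def test_branch_shape_algebra_min_length():
    # one unit: floor((L - 3 + 1) / 2) >= 1 requires L >= 4
    branch1 = LCNNBranch(5, tiny_cfg(1), np.random.default_rng(3))
    assert branch1.min_length() == 4
    branch2 = LCNNBranch(5, tiny_cfg(2), np.random.default_rng(3))
    assert branch2.min_length() == 10  # (1*2+2)*2+2


def test_lcnn_forward_deterministic():
    cfg = tiny_cfg(1)
    branch = LCNNBranch(5, cfg, np.random.default_rng(3))
    X = RNG.normal(size=(1, 10, 5))
    a = lcnn_forward(Tensor(X), branch).data
    b = lcnn_forward(Tensor(X), branch).data
    np.testing.assert_array_equal(a, b)
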