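"""ConvLSTM and Variant ConvLSTM cells against brute-force oracles.

The oracle implements every operation with explicit Python loops (scalar
convolutions, scalar pooling, matrix-vector gates) so that it shares no
array code with the implementation under test.
"""

import math

import numpy as np
import pytest

from semg.nn.autograd import Tensor
from semg.nn.convlstm import (ConvLSTMCell, VConvLSTMCell,
                              convlstm_param_count, convlstm_step,
                              init_convlstm_params, init_vconvlstm_params,
                              vconvlstm_param_count, vconvlstm_step)


# ---------------------------------------------------------------------------
# scalar oracle

def sig(v):
    return 1.0 / (1.0 + math.exp(-v))


def conv_same_loops(x, w):
    """Same-padding cross-correlation with quadruple loops."""
    co, ci, kh, kw = w.shape
    _, H, W = x.shape
    out = np.zeros((co, H, W))
    for o in range(co):
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for c in range(ci):
                    for a in range(kh):
                        for b in range(kw):
                            ii = i + a - kh // 2
                            jj = j + b - kw // 2
                            if 0 <= ii < H and 0 <= jj < W:
                                acc += x[c, ii, jj] * w[o, c, a, b]
                out[o, i, j] = acc
    return out


def gp_loops(x):
    c, H, W = x.shape
    out = np.zeros(c)
    for ch in range(c):
        s = 0.0
        for i in range(H):
            for j in range(W):
                s += x[ch, i, j]
        out[ch] = s / (H * W)
    return out


def convlstm_oracle(X, H, C, p):
    ch = p["b_f"].size
    f = np.vectorize(sig)(conv_same_loops(X, p["W_fx"]) + conv_same_loops(H, p["W_fh"])
                          + p["b_f"][:, None, None])
    i = np.vectorize(sig)(conv_same_loops(X, p["W_ix"]) + conv_same_loops(H, p["W_ih"])
                          + p["b_i"][:, None, None])
    g = np.tanh(conv_same_loops(X, p["W_cx"]) + conv_same_loops(H, p["W_ch"])
                + p["b_c"][:, None, None])
    Ct = f * C + i * g
    o = np.vectorize(sig)(conv_same_loops(X, p["W_ox"]) + conv_same_loops(H, p["W_oh"])
                          + p["b_o"][:, None, None])
    return o * np.tanh(Ct), Ct


def vconvlstm_oracle(X, H, C, p):
    gx, gh = gp_loops(X), gp_loops(H)
    ch = p["b_f"].size

    def gate(wx, wh, b):
        out = np.zeros(ch)
        for n in range(ch):
            acc = b[n]
            for m in range(gx.size):
                acc += gx[m] * wx[m, n]
            for m in range(gh.size):
                acc += gh[m] * wh[m, n]
            out[n] = sig(acc)
        return out

    f = gate(p["W_fx"], p["W_fh"], p["b_f"])
    i = gate(p["W_ix"], p["W_ih"], p["b_i"])
    o = gate(p["W_ox"], p["W_oh"], p["b_o"])
    g = np.tanh(conv_same_loops(X, p["W_cx"]) + conv_same_loops(H, p["W_ch"])
                + p["b_c"][:, None, None])
    Ct = f[:, None, None] * C + i[:, None, None] * g
    return o[:, None, None] * np.tanh(Ct), Ct


def random_instance(rng, ci, ch, H, W):
    X = rng.normal(size=(ci, H, W))
    Hp = rng.normal(size=(ch, H, W))
    Cp = rng.normal(size=(ch, H, W))
    return X, Hp, Cp


# ---------------------------------------------------------------------------
# oracle equivalence

@pytest.mark.parametrize("seed", range(5))
def test_convlstm_matches_scalar_oracle(seed):
    rng = np.random.default_rng(seed)
    ci, ch = rng.integers(1, 4), rng.integers(1, 4)
    H, W = rng.integers(2, 6), rng.integers(2, 6)
    p = init_convlstm_params(ci, ch, 3, rng)
    X, Hp, Cp = random_instance(rng, ci, ch, H, W)
    Ht, Ct = convlstm_step(X, Hp, Cp, p)
    Ho, Co = convlstm_oracle(X, Hp, Cp, p)
    assert np.max(np.abs(Ht - Ho)) < 1e-6
    assert np.max(np.abs(Ct - Co)) < 1e-6


@pytest.mark.parametrize("seed", range(5))
def test_vconvlstm_matches_scalar_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    ci, ch = rng.integers(1, 4), rng.integers(1, 4)
    H, W = rng.integers(2, 7), rng.integers(2, 7)
    p = init_vconvlstm_params(ci, ch, 3, rng)
    X, Hp, Cp = random_instance(rng, ci, ch, H, W)
    Ht, Ct = vconvlstm_step(X, Hp, Cp, p)
    Ho, Co = vconvlstm_oracle(X, Hp, Cp, p)
    assert np.max(np.abs(Ht - Ho)) < 1e-6
    assert np.max(np.abs(Ct - Co)) < 1e-6


# ---------------------------------------------------------------------------
# closed forms and limits

def zero_params(init, ci, ch, k):
    p = init(ci, ch, k, np.random.default_rng(0))
    return {key: np.zeros_like(v) for key, v in p.items()}


@pytest.mark.parametrize("step,init", [(convlstm_step, init_convlstm_params),
                                       (vconvlstm_step, init_vconvlstm_params)])
def test_zero_weights_closed_form(step, init):
    """All-zero weights: f=i=o=1/2, so H_t = 0.5*tanh(0.5*C_prev)."""
    rng = np.random.default_rng(1)
    p = zero_params(init, 2, 3, 3)
    X = rng.normal(size=(2, 4, 4))
    Hp = rng.normal(size=(3, 4, 4))
    Cp = rng.normal(size=(3, 4, 4))
    Ht, Ct = step(X, Hp, Cp, p)
    assert np.max(np.abs(Ct - 0.5 * Cp)) < 1e-12
    assert np.max(np.abs(Ht - 0.5 * np.tanh(0.5 * Cp))) < 1e-12


def test_gate_saturation_holds_memory():
    """Large +b_f, large -b_i: the cell state is carried through unchanged."""
    rng = np.random.default_rng(2)
    p = zero_params(init_convlstm_params, 1, 2, 3)
    p["b_f"][:] = 20.0
    p["b_i"][:] = -20.0
    X = rng.normal(size=(1, 3, 3))
    Hp = rng.normal(size=(2, 3, 3))
    Cp = rng.normal(size=(2, 3, 3))
    _, Ct = convlstm_step(X, Hp, Cp, p)
    assert np.max(np.abs(Ct - Cp)) < 1e-3


def test_vconvlstm_reduces_to_convlstm_on_1x1_maps():
    """GP of a 1x1 map is the map itself, so with 1x1 kernels the variant
    equals the fully convolutional cell under the weight correspondence."""
    rng = np.random.default_rng(3)
    ci, ch = 3, 2
    pv = init_vconvlstm_params(ci, ch, 1, rng)
    pc = {}
    for gate in "fio":
        pc[f"W_{gate}x"] = pv[f"W_{gate}x"].T.reshape(ch, ci, 1, 1)
        pc[f"W_{gate}h"] = pv[f"W_{gate}h"].T.reshape(ch, ch, 1, 1)
        pc[f"b_{gate}"] = pv[f"b_{gate}"]
    pc["W_cx"], pc["W_ch"], pc["b_c"] = pv["W_cx"], pv["W_ch"], pv["b_c"]
    X = rng.normal(size=(ci, 1, 1))
    Hp = rng.normal(size=(ch, 1, 1))
    Cp = rng.normal(size=(ch, 1, 1))
    Hv, Cv = vconvlstm_step(X, Hp, Cp, pv)
    Hc, Cc = convlstm_step(X, Hp, Cp, pc)
    assert np.max(np.abs(Hv - Hc)) < 1e-12
    assert np.max(np.abs(Cv - Cc)) < 1e-12


# ---------------------------------------------------------------------------
# parameter accounting

@pytest.mark.parametrize("ci,ch,k", [(4, 8, 3), (8, 8, 3), (16, 32, 3), (3, 5, 5)])
def test_param_counts_match_declared_shapes(ci, ch, k):
    rng = np.random.default_rng(0)
    pc = init_convlstm_params(ci, ch, k, rng)
    pv = init_vconvlstm_params(ci, ch, k, rng)
    assert sum(v.size for v in pc.values()) == convlstm_param_count(ci, ch, k)
    assert sum(v.size for v in pv.values()) == vconvlstm_param_count(ci, ch, k)


@pytest.mark.parametrize("ci,ch,k", [(4, 8, 3), (8, 16, 3), (16, 16, 5)])
def test_variant_has_strictly_fewer_parameters(ci, ch, k):
    assert vconvlstm_param_count(ci, ch, k) < convlstm_param_count(ci, ch, k)


def test_module_cells_match_functional_steps():
    """Batched trainable cells agree with the single-instance functions."""
    rng = np.random.default_rng(4)
    ci, ch, H, W = 3, 4, 5, 6
    for Cell, step, init in [(ConvLSTMCell, convlstm_step, init_convlstm_params),
                             (VConvLSTMCell, vconvlstm_step, init_vconvlstm_params)]:
        cell = Cell(ci, ch, 3, rng)
        p = {name: param.data for name, param in cell.named_parameters()}
        X = rng.normal(size=(2, ci, H, W))
        Hp = rng.normal(size=(2, ch, H, W))
        Cp = rng.normal(size=(2, ch, H, W))
        Hm, Cm = cell.step(Tensor(X), Tensor(Hp), Tensor(Cp))
        for b in range(2):
            Hf, Cf = step(X[b], Hp[b], Cp[b], p)
            assert np.max(np.abs(Hm.data[b] - Hf)) < 1e-10
            assert np.max(np.abs(Cm.data[b] - Cf)) < 1e-10


def test_forward_sequence_equals_repeated_steps():
    rng = np.random.default_rng(5)
    cell = VConvLSTMCell(4, 4, 3, rng)
    seq = rng.normal(size=(3, 5, 4, 4, 6))
    H_seq = cell.forward_sequence(Tensor(seq)).data
    H_t, C_t = cell.init_state(3, 4, 6)
    for t in range(5):
        H_t, C_t = cell.step(Tensor(seq[:, t]), H_t, C_t)
    assert np.max(np.abs(H_seq - H_t.data)) < 1e-10
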