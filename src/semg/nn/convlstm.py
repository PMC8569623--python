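"""ConvLSTM and Variant ConvLSTM recurrent cells.

The standard ConvLSTM computes every gate (forget f, input i, output o) and
the candidate update with convolutions of the input map X_t and the hidden
map H_{t-1}. The variant keeps the convolution only on the candidate path;
the three gates are computed from globally average-pooled (per-channel
scalar) descriptors of X_t and H_{t-1} through fully connected maps, and are
broadcast over space when applied:

    f_t = sigmoid(GP(H_{t-1}) W_fh + GP(X_t) W_fx + b_f)       (per channel)
    i_t = sigmoid(GP(H_{t-1}) W_ih + GP(X_t) W_ix + b_i)
    g_t = tanh(W_ch * H_{t-1} + W_cx * X_t + b_c)              (convolutional)
    C_t = f_t o C_{t-1} + i_t o g_t
    o_t = sigmoid(GP(H_{t-1}) W_oh + GP(X_t) W_ox + b_o)
    H_t = o_t o tanh(C_t)

This removes most of the recurrent parameters while keeping a spatial
candidate path. Functional single-instance steps (numpy dict-of-weights) are
provided alongside batched trainable ``Module`` cells; the two are checked
against each other and against brute-force oracles in the test suite.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import DimensionError
from .autograd import Parameter, Tensor, conv2d
from .layers import Module, _kaiming_uniform

__all__ = [
    "convlstm_step", "vconvlstm_step",
    "ConvLSTMCell", "VConvLSTMCell",
    "convlstm_param_count", "vconvlstm_param_count",
    "init_convlstm_params", "init_vconvlstm_params",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padding 2-D cross-correlation; x: [C,H,W], w: [Co,C,k,k], k odd."""
    co, ci, kh, kw = w.shape
    if x.shape[0] != ci:
        raise DimensionError(f"kernel expects {ci} channels, input has {x.shape[0]}")
    t = conv2d(Tensor(x[None]), Tensor(w), padding=(kh // 2, kw // 2))
    return t.data[0]


def _gp(x: np.ndarray) -> np.ndarray:
    """Global average pooling of a [C,H,W] map to a [C] descriptor."""
    return x.mean(axis=(1, 2))


def convlstm_step(X_t: np.ndarray, H_prev: np.ndarray, C_prev: np.ndarray,
                  params: dict[str, np.ndarray]):
    """One fully convolutional ConvLSTM step on a single instance.

    X_t: [C_in,H,W]; H_prev, C_prev: [C_h,H,W]. Conv weights:
    W_*x [C_h,C_in,k,k], W_*h [C_h,C_h,k,k], biases [C_h].
    """
    p = params
    def gate(wx, wh, b):
        pre = _conv_same(X_t, p[wx]) + _conv_same(H_prev, p[wh]) + p[b][:, None, None]
        return pre
    f = _sigmoid(gate("W_fx", "W_fh", "b_f"))
    i = _sigmoid(gate("W_ix", "W_ih", "b_i"))
    g = np.tanh(gate("W_cx", "W_ch", "b_c"))
    C_t = f * C_prev + i * g
    o = _sigmoid(gate("W_ox", "W_oh", "b_o"))
    H_t = o * np.tanh(C_t)
    return H_t, C_t


def vconvlstm_step(X_t: np.ndarray, H_prev: np.ndarray, C_prev: np.ndarray,
                   params: dict[str, np.ndarray]):
    """One Variant ConvLSTM step on a single instance.

    Gate weights act on pooled descriptors: W_*x [C_in,C_h], W_*h [C_h,C_h],
    biases [C_h]; only W_cx/W_ch are convolution kernels. Gates are
    per-channel scalars broadcast over the spatial grid.
    """
    p = params
    gx, gh = _gp(X_t), _gp(H_prev)
    f = _sigmoid(gh @ p["W_fh"] + gx @ p["W_fx"] + p["b_f"])
    i = _sigmoid(gh @ p["W_ih"] + gx @ p["W_ix"] + p["b_i"])
    g = np.tanh(_conv_same(H_prev, p["W_ch"]) + _conv_same(X_t, p["W_cx"])
                + p["b_c"][:, None, None])
    C_t = f[:, None, None] * C_prev + i[:, None, None] * g
    o = _sigmoid(gh @ p["W_oh"] + gx @ p["W_ox"] + p["b_o"])
    H_t = o[:, None, None] * np.tanh(C_t)
    return H_t, C_t


# ---------------------------------------------------------------------------
# parameter accounting

def convlstm_param_count(in_channels: int, hidden_channels: int, kernel: int) -> int:
    """Trainable parameters of a ConvLSTM cell: 4 convolutional gate pairs."""
    per_pair = (in_channels + hidden_channels) * hidden_channels * kernel * kernel
    return 4 * per_pair + 4 * hidden_channels


def vconvlstm_param_count(in_channels: int, hidden_channels: int, kernel: int) -> int:
    """Variant cell: 3 pooled-FC gate pairs + 1 convolutional candidate pair."""
    fc_pair = (in_channels + hidden_channels) * hidden_channels
    conv_pair = fc_pair * kernel * kernel
    return 3 * fc_pair + 3 * hidden_channels + conv_pair + hidden_channels


def init_convlstm_params(in_channels: int, hidden_channels: int, kernel: int,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    ci, ch, k = in_channels, hidden_channels, kernel
    p = {}
    for gate in "fioc":
        p[f"W_{gate}x"] = rng.normal(0, 0.1, (ch, ci, k, k))
        p[f"W_{gate}h"] = rng.normal(0, 0.1, (ch, ch, k, k))
        p[f"b_{gate}"] = np.zeros(ch)
    return p


def init_vconvlstm_params(in_channels: int, hidden_channels: int, kernel: int,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    ci, ch, k = in_channels, hidden_channels, kernel
    p = {}
    for gate in "fio":
        p[f"W_{gate}x"] = rng.normal(0, 0.1, (ci, ch))
        p[f"W_{gate}h"] = rng.normal(0, 0.1, (ch, ch))
        p[f"b_{gate}"] = np.zeros(ch)
    p["W_cx"] = rng.normal(0, 0.1, (ch, ci, k, k))
    p["W_ch"] = rng.normal(0, 0.1, (ch, ch, k, k))
    p["b_c"] = np.zeros(ch)
    return p


# ---------------------------------------------------------------------------
# trainable batched cells

class ConvLSTMCell(Module):
    """Batched fully convolutional LSTM cell (baseline)."""

    def __init__(self, in_channels: int, hidden_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.hidden_channels, self.kernel = \
            in_channels, hidden_channels, kernel
        fan_x = in_channels * kernel * kernel
        fan_h = hidden_channels * kernel * kernel
        for gate in "fioc":
            setattr(self, f"W_{gate}x", Parameter(_kaiming_uniform(
                rng, (hidden_channels, in_channels, kernel, kernel), fan_x)))
            setattr(self, f"W_{gate}h", Parameter(_kaiming_uniform(
                rng, (hidden_channels, hidden_channels, kernel, kernel), fan_h)))
            setattr(self, f"b_{gate}", Parameter(np.zeros(hidden_channels)))

    def init_state(self, batch: int, h: int, w: int):
        z = np.zeros((batch, self.hidden_channels, h, w))
        return Tensor(z), Tensor(z.copy())

    def step(self, X_t: Tensor, H_prev: Tensor, C_prev: Tensor):
        pad = (self.kernel // 2, self.kernel // 2)

        def pre(gate):
            wx = getattr(self, f"W_{gate}x")
            wh = getattr(self, f"W_{gate}h")
            b = getattr(self, f"b_{gate}")
            return (conv2d(X_t, wx, padding=pad) + conv2d(H_prev, wh, padding=pad)
                    + b.reshape(1, -1, 1, 1))

        f = pre("f").sigmoid()
        i = pre("i").sigmoid()
        g = pre("c").tanh()
        C_t = f * C_prev + i * g
        o = pre("o").sigmoid()
        return o * C_t.tanh(), C_t


class VConvLSTMCell(Module):
    """Batched Variant ConvLSTM cell: pooled-FC gates, convolutional candidate."""

    def __init__(self, in_channels: int, hidden_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.hidden_channels, self.kernel = \
            in_channels, hidden_channels, kernel
        for gate in "fio":
            setattr(self, f"W_{gate}x", Parameter(_kaiming_uniform(
                rng, (in_channels, hidden_channels), in_channels)))
            setattr(self, f"W_{gate}h", Parameter(_kaiming_uniform(
                rng, (hidden_channels, hidden_channels), hidden_channels)))
            setattr(self, f"b_{gate}", Parameter(np.zeros(hidden_channels)))
        fan_x = in_channels * kernel * kernel
        fan_h = hidden_channels * kernel * kernel
        self.W_cx = Parameter(_kaiming_uniform(
            rng, (hidden_channels, in_channels, kernel, kernel), fan_x))
        self.W_ch = Parameter(_kaiming_uniform(
            rng, (hidden_channels, hidden_channels, kernel, kernel), fan_h))
        self.b_c = Parameter(np.zeros(hidden_channels))

    def init_state(self, batch: int, h: int, w: int):
        z = np.zeros((batch, self.hidden_channels, h, w))
        return Tensor(z), Tensor(z.copy())

    def step(self, X_t: Tensor, H_prev: Tensor, C_prev: Tensor):
        pad = (self.kernel // 2, self.kernel // 2)
        gx = X_t.mean(axis=(2, 3))
        gh = H_prev.mean(axis=(2, 3))

        def gate(name):
            wx = getattr(self, f"W_{name}x")
            wh = getattr(self, f"W_{name}h")
            b = getattr(self, f"b_{name}")
            return ((gh @ wh) + (gx @ wx) + b).sigmoid()

        f, i, o = gate("f"), gate("i"), gate("o")
        g = (conv2d(H_prev, self.W_ch, padding=pad)
             + conv2d(X_t, self.W_cx, padding=pad)
             + self.b_c.reshape(1, -1, 1, 1)).tanh()
        B, C = f.shape
        C_t = f.reshape(B, C, 1, 1) * C_prev + i.reshape(B, C, 1, 1) * g
        return o.reshape(B, C, 1, 1) * C_t.tanh(), C_t

    def forward_sequence(self, seq: Tensor) -> Tensor:
        """Run the cell over a [B,T,C,H,W] sequence; return the final H_T.

        The input-side terms (candidate convolution of X_t and the pooled
        gate contributions of X_t) do not depend on the recurrence, so they
        are computed for all time steps in one batched pass; only the
        hidden-state path is iterated. Numerically identical to repeated
        :meth:`step` from a zero initial state.
        """
        B, T, C, Hh, Ww = seq.shape
        pad = (self.kernel // 2, self.kernel // 2)
        flat = seq.reshape(B * T, C, Hh, Ww)
        xconv = conv2d(flat, self.W_cx, padding=pad) \
            .reshape(B, T, self.hidden_channels, Hh, Ww)
        gx = flat.mean(axis=(2, 3))                        # [B*T, C]
        xg = {name: (gx @ getattr(self, f"W_{name}x")
                     + getattr(self, f"b_{name}")).reshape(B, T, -1)
              for name in "fio"}

        H_t, C_t = self.init_state(B, Hh, Ww)
        for t in range(T):
            gh = H_t.mean(axis=(2, 3))
            f = (gh @ self.W_fh + xg["f"][:, t]).sigmoid()
            i = (gh @ self.W_ih + xg["i"][:, t]).sigmoid()
            o = (gh @ self.W_oh + xg["o"][:, t]).sigmoid()
            g = (conv2d(H_t, self.W_ch, padding=pad) + xconv[:, t]
                 + self.b_c.reshape(1, -1, 1, 1)).tanh()
            Ch = f.shape[1]
            C_t = f.reshape(B, Ch, 1, 1) * C_t + i.reshape(B, Ch, 1, 1) * g
            H_t = o.reshape(B, Ch, 1, 1) * C_t.tanh()
        return H_t
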