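"""Bidirectional LSTM encoder in NumPy with exact manual backpropagation.

The forward pass caches gate activations and cell states per time step;
the backward pass replays them in reverse (backpropagation through time).
Right-padded batches use a boolean mask: at padded steps the hidden and
cell states are carried through unchanged, and the corresponding gate
gradients are zero.  Gradient correctness is enforced by finite-difference
checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["LSTMParams", "lstm_forward", "lstm_backward", "reverse_within_length"]


@dataclass
class LSTMParams:
    """One direction's weights; gate layout along the last axis is
    input / forget / cell / output."""

    Wx: np.ndarray  # (D, 4H)
    Wh: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator,
             dtype=np.float32) -> "LSTMParams":
        # uniform(-1/sqrt(H), 1/sqrt(H)), the standard recurrent-net default
        k = 1.0 / np.sqrt(hidden_dim)
        shape = lambda *s: rng.uniform(-k, k, s).astype(dtype)
        return cls(
            shape(input_dim, 4 * hidden_dim),
            shape(hidden_dim, 4 * hidden_dim),
            shape(4 * hidden_dim),
        )

    @property
    def hidden_dim(self) -> int:
        return self.Wh.shape[0]


def lstm_forward(
    x: np.ndarray, mask: np.ndarray, p: LSTMParams
) -> tuple[np.ndarray, dict]:
    """Run the LSTM over a right-padded batch.

    ``x`` is (B, L, D), ``mask`` (B, L).  Returns hidden states (B, L, H)
    and the cache needed by :func:`lstm_backward`.
    """
    B, L, D = x.shape
    H = p.hidden_dim
    dtype = x.dtype
    gates = np.empty((B, L, 4 * H), dtype=dtype)
    c_seq = np.empty((B, L, H), dtype=dtype)
    h_seq = np.empty((B, L, H), dtype=dtype)
    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    xW = x.reshape(B * L, D) @ p.Wx  # hoisted input projection
    xW = xW.reshape(B, L, 4 * H)
    for t in range(L):
        pre = xW[:, t] + h @ p.Wh + p.b
        i = _sigmoid(pre[:, :H])
        f = _sigmoid(pre[:, H : 2 * H])
        g = np.tanh(pre[:, 2 * H : 3 * H])
        o = _sigmoid(pre[:, 3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        m = mask[:, t, None]
        h = np.where(m, h_new, h)
        c = np.where(m, c_new, c)
        gates[:, t, :H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
        c_seq[:, t] = c
        h_seq[:, t] = h
    cache = {"x": x, "mask": mask, "gates": gates, "c_seq": c_seq, "h_seq": h_seq}
    return h_seq, cache


def lstm_backward(
    dh_out: np.ndarray, cache: dict, p: LSTMParams
) -> tuple[np.ndarray, LSTMParams]:
    """Backpropagate gradients ``dh_out`` (B, L, H) through the LSTM.

    Returns the gradient with respect to the inputs (B, L, D) and the
    parameter gradients (as an :class:`LSTMParams` of the same shapes).
    """
    x, mask, gates = cache["x"], cache["mask"], cache["gates"]
    c_seq, h_seq = cache["c_seq"], cache["h_seq"]
    B, L, D = x.shape
    H = p.hidden_dim
    dtype = x.dtype
    dWx = np.zeros_like(p.Wx)
    dWh = np.zeros_like(p.Wh)
    db = np.zeros_like(p.b)
    dx = np.empty_like(x)
    dh_carry = np.zeros((B, H), dtype=dtype)
    dc_carry = np.zeros((B, H), dtype=dtype)
    zeros = np.zeros((B, H), dtype=dtype)
    dpre = np.empty((B, 4 * H), dtype=dtype)
    for t in range(L - 1, -1, -1):
        m = mask[:, t, None]
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        c_prev = c_seq[:, t - 1] if t > 0 else zeros
        h_prev = h_seq[:, t - 1] if t > 0 else zeros
        c_new = f * c_prev + i * g
        tanh_c = np.tanh(c_new)

        dh_total = dh_out[:, t] + dh_carry
        dh_new = np.where(m, dh_total, 0)
        do = dh_new * tanh_c
        dc_new = np.where(m, dc_carry, 0) + dh_new * o * (1 - tanh_c**2)
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        np.multiply(di * i, 1 - i, out=dpre[:, :H])
        np.multiply(df * f, 1 - f, out=dpre[:, H : 2 * H])
        np.multiply(dg, 1 - g**2, out=dpre[:, 2 * H : 3 * H])
        np.multiply(do * o, 1 - o, out=dpre[:, 3 * H :])
        dWx += x[:, t].T @ dpre
        dWh += h_prev.T @ dpre
        db += dpre.sum(axis=0)
        dx[:, t] = dpre @ p.Wx.T
        dh_carry = np.where(m, 0, dh_total) + dpre @ p.Wh.T
        dc_carry = np.where(m, 0, dc_carry) + dc_new * f
    return dx, LSTMParams(dWx, dWh, db)


def reverse_within_length(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reverse each row of a right-padded (B, L, ...) array within its real
    length, leaving padding in place.  Involution: applying it twice is the
    identity."""
    B, L = mask.shape
    lengths = mask.sum(axis=1)
    j = np.arange(L)[None, :]
    idx = np.where(j < lengths[:, None], lengths[:, None] - 1 - j, j)
    rows = np.arange(B)[:, None]
    return arr[rows, idx]
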