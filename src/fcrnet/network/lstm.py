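"""LSTM cell and unrolled layer with backpropagation through time.

Two candidate/output conventions are supported:

* ``"tanh_standard"`` (default): the candidate cell input passes through tanh
  and the hidden state is ``o * tanh(c)`` — the usual LSTM.
* ``"linear_literal"``: the candidate is a purely linear combination that reuses
  the input gate's recurrent weights, and the hidden state is ``o * c`` with
  no output nonlinearity.  This literal variant is kept for fidelity
  experiments; it is not the default because the linear candidate removes the
  cell's squashing and the weight reuse ties two unrelated gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Layer, Param

__all__ = ["LSTMParams", "LSTMState", "lstm_step", "LSTMLayer", "sigmoid"]

GATES = ("i", "f", "o", "c")


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMParams:
    """Per-gate input weights W[H,d], recurrent weights U[H,H], biases b[H]."""

    W: dict
    U: dict
    b: dict
    hidden: int

    @classmethod
    def zeros(cls, d_in: int, hidden: int) -> "LSTMParams":
        return cls(
            W={g: np.zeros((hidden, d_in)) for g in GATES},
            U={g: np.zeros((hidden, hidden)) for g in GATES},
            b={g: np.zeros(hidden) for g in GATES},
            hidden=hidden,
        )

    @classmethod
    def random(cls, d_in: int, hidden: int,
               rng: np.random.Generator, scale: float = None) -> "LSTMParams":
        s_w = scale if scale is not None else np.sqrt(1.0 / d_in)
        s_u = scale if scale is not None else np.sqrt(1.0 / hidden)
        return cls(
            W={g: rng.normal(0, s_w, size=(hidden, d_in)) for g in GATES},
            U={g: rng.normal(0, s_u, size=(hidden, hidden)) for g in GATES},
            b={g: np.zeros(hidden) for g in GATES},
            hidden=hidden,
        )


@dataclass
class LSTMState:
    """Hidden and cell state (row-per-sample when batched)."""

    h: np.ndarray
    c: np.ndarray


def lstm_step(x_t: np.ndarray, state: LSTMState, params: LSTMParams,
              mode: str = "tanh_standard") -> LSTMState:
    """One LSTM time step.

    Gates: ``i = s(W_i x + U_i h + b_i)`` and likewise for ``f``, ``o``; the
    candidate is ``tanh(W_c x + U_c h + b_c)`` in standard mode or the linear
    ``W_c x + U_i h + b_c`` in literal mode.  The new cell state is
    ``f*c + i*candidate``; the hidden state is ``o*tanh(c)`` (standard) or
    ``o*c`` (literal).
    """
    if mode not in ("tanh_standard", "linear_literal"):
        raise ValueError(f"unknown candidate mode {mode!r}")
    h, c = state.h, state.c
    W, U, b = params.W, params.U, params.b
    i = sigmoid(x_t @ W["i"].T + h @ U["i"].T + b["i"])
    f = sigmoid(x_t @ W["f"].T + h @ U["f"].T + b["f"])
    o = sigmoid(x_t @ W["o"].T + h @ U["o"].T + b["o"])
    if mode == "tanh_standard":
        cand = np.tanh(x_t @ W["c"].T + h @ U["c"].T + b["c"])
    else:
        cand = x_t @ W["c"].T + h @ U["i"].T + b["c"]
    c_new = f * c + i * cand
    h_new = o * np.tanh(c_new) if mode == "tanh_standard" else o * c_new
    if not (np.all(np.isfinite(h_new)) and np.all(np.isfinite(c_new))):
        raise FloatingPointError("LSTM state is not finite")
    return LSTMState(h=h_new, c=c_new)


class LSTMLayer(Layer):
    """Unrolled LSTM over ``[B, S, d]`` sequences, returning the last hidden
    state; trained by full backpropagation through time."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 mode: str = "tanh_standard"):
        super().__init__()
        p = LSTMParams.random(d_in, hidden, rng)
        self.Wp = {g: Param(p.W[g], f"lstm.W_{g}") for g in GATES}
        self.Up = {g: Param(p.U[g], f"lstm.U_{g}") for g in GATES}
        self.bp = {g: Param(p.b[g], f"lstm.b_{g}") for g in GATES}
        self.params = (list(self.Wp.values()) + list(self.Up.values())
                       + list(self.bp.values()))
        self.hidden = hidden
        self.mode = mode

    def _as_params(self) -> LSTMParams:
        return LSTMParams(
            W={g: self.Wp[g].value for g in GATES},
            U={g: self.Up[g].value for g in GATES},
            b={g: self.bp[g].value for g in GATES},
            hidden=self.hidden,
        )

    def forward(self, x, training=False, rng=None):
        b, s, _ = x.shape
        h = np.zeros((b, self.hidden), dtype=x.dtype)
        c = np.zeros((b, self.hidden), dtype=x.dtype)
        self._x = x
        self._cache = []
        W, U, bb = ({g: self.Wp[g].value for g in GATES},
                    {g: self.Up[g].value for g in GATES},
                    {g: self.bp[g].value for g in GATES})
        std = self.mode == "tanh_standard"
        for t in range(s):
            xt = x[:, t, :]
            i = sigmoid(xt @ W["i"].T + h @ U["i"].T + bb["i"])
            f = sigmoid(xt @ W["f"].T + h @ U["f"].T + bb["f"])
            o = sigmoid(xt @ W["o"].T + h @ U["o"].T + bb["o"])
            if std:
                cand = np.tanh(xt @ W["c"].T + h @ U["c"].T + bb["c"])
            else:
                cand = xt @ W["c"].T + h @ U["i"].T + bb["c"]
            c_prev, h_prev = c, h
            c = f * c_prev + i * cand
            if std:
                tc = np.tanh(c)
                h = o * tc
            else:
                tc = None
                h = o * c
            self._cache.append((xt, h_prev, c_prev, i, f, o, cand, c, tc))
        return h

    def backward(self, g):
        std = self.mode == "tanh_standard"
        dh_next = g
        dc_next = np.zeros_like(g)
        dx = np.zeros_like(self._x)
        W = {k: p.value for k, p in self.Wp.items()}
        U = {k: p.value for k, p in self.Up.items()}
        for t in range(len(self._cache) - 1, -1, -1):
            xt, h_prev, c_prev, i, f, o, cand, c, tc = self._cache[t]
            dh = dh_next
            if std:
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc ** 2)
            else:
                do = dh * c
                dc = dc_next + dh * o
            di = dc * cand
            dcand = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = {
                "i": di * i * (1 - i),
                "f": df * f * (1 - f),
                "o": do * o * (1 - o),
                "c": dcand * (1 - cand ** 2) if std else dcand,
            }
            dh_next = np.zeros_like(dh)
            for gate in GATES:
                self.Wp[gate].grad += da[gate].T @ xt
                self.bp[gate].grad += da[gate].sum(axis=0)
                dx[:, t, :] += da[gate] @ W[gate]
                if not std and gate == "c":
                    # literal mode: candidate reuses the input gate's U
                    self.Up["i"].grad += da["c"].T @ h_prev
                    dh_next += da["c"] @ U["i"]
                else:
                    self.Up[gate].grad += da[gate].T @ h_prev
                    dh_next += da[gate] @ U[gate]
        return dx
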