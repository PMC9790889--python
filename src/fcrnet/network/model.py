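"""Compact CNN, the fuzzy convolutional-recurrent assembly, and Adam.

The compact CNN follows the EEGNet-style recipe: a bank of shared temporal
filters, a depthwise spatial convolution across all electrodes, and a
separable (depthwise + pointwise) temporal convolution, each followed by batch
normalization, ELU, average pooling and dropout.  For a (22, 288) input with
F1=8, D=2, F2=8 the per-layer trainable parameter counts are 512 / 16 / 352 /
32 / 384 / 16 and the flattened feature width is 72.

The full classifier feeds the CNN's pre-flatten feature map — a short sequence
of F2-dimensional vectors — to an LSTM; the last hidden state goes in parallel
through a fully connected branch and a fuzzy neural block, whose outputs are
merged (concatenation by default) and classified by a dense softmax head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    AvgPool, BatchNorm, Dense, DepthwiseSpatialConv, Dropout, ELU,
    Sequential, SeparableConv, TemporalConv, softmax, softmax_cross_entropy,
)
from .lstm import LSTMLayer
from .fnb import FNBLayer, update_fnb_centroids

__all__ = [
    "NetworkConfig", "CompactCNN", "FCRNet", "Adam",
    "build_compact_cnn", "assemble_fcrnet", "count_trainable_parameters",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_shape`` is (electrodes C, samples T).  ``input_mode`` records
    whether the model consumes raw epochs or stacked envelope rows; the
    network itself only sees the (C, T) rectangle.
    """

    input_shape: tuple = (22, 288)
    n_classes: int = 4
    F1: int = 8
    temporal_kernel: int = 64
    D: int = 2
    F2: int = 8
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5
    lstm_units: int = 32
    fc_units: int = 16
    fnb_rules: int = 8
    fnb_enabled: bool = True
    candidate_activation: str = "tanh_standard"
    head_merge: str = "concat"
    input_mode: str = "raw"

    def validate(self) -> None:
        c, t = self.input_shape
        if c < 1 or t < 1:
            raise ValueError("input shape must be positive")
        if t < self.temporal_kernel:
            raise ValueError(
                f"epoch of {t} samples shorter than temporal kernel "
                f"{self.temporal_kernel}"
            )
        for name in ("F1", "D", "F2", "lstm_units", "fnb_rules", "fc_units",
                     "n_classes", "pool1", "pool2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.head_merge not in ("concat", "sum"):
            raise ValueError(f"unknown head merge {self.head_merge!r}")
        if self.candidate_activation not in ("tanh_standard", "linear_literal"):
            raise ValueError("unknown candidate activation")

    @property
    def seq_len(self) -> int:
        """Time steps surviving both pools (remainders truncated)."""
        return (self.input_shape[1] // self.pool1) // self.pool2

    @property
    def flatten_width(self) -> int:
        return self.F2 * self.seq_len


def _cast_params(params, dtype) -> None:
    if dtype == np.float64:
        return
    for p in params:
        p.value = p.value.astype(dtype)
        p.grad = p.grad.astype(dtype)


class CompactCNN:
    """Feature extractor + optional dense softmax head (the stand-alone
    classifier configuration).

    ``dtype`` selects the compute precision: float64 by default (exact
    gradient checks), float32 for large training runs.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator,
                 include_head: bool = True, dtype=np.float64):
        config.validate()
        self.config = config
        self.dtype = np.dtype(dtype)
        c, _ = config.input_shape
        self.blocks = [
            ("temporal_conv", TemporalConv(config.F1, config.temporal_kernel, rng)),
            ("batchnorm_1", BatchNorm(config.F1)),
            ("depthwise_conv", DepthwiseSpatialConv(config.F1, config.D, c, rng)),
            ("batchnorm_2", BatchNorm(config.F1 * config.D)),
            ("elu_1", ELU()),
            ("avgpool_1", AvgPool(config.pool1)),
            ("dropout_1", Dropout(config.dropout)),
            ("separable_conv", SeparableConv(config.F1 * config.D, config.F2,
                                             config.separable_kernel, rng)),
            ("batchnorm_3", BatchNorm(config.F2)),
            ("elu_2", ELU()),
            ("avgpool_2", AvgPool(config.pool2)),
            ("dropout_2", Dropout(config.dropout)),
        ]
        self.body = Sequential([lay for _, lay in self.blocks])
        self.head = None
        if include_head:
            self.head = Dense(config.flatten_width, config.n_classes, rng)
        self.params = list(self.body.params)
        if self.head is not None:
            self.params += self.head.params
        _cast_params(self.params, self.dtype)

    def layer_shapes(self, batch: int = 1):
        """Named output shape of every stage for one forward pass."""
        c, t = self.config.input_shape
        x = np.zeros((batch, 1, c, t))
        shapes = [("input", x.shape[1:])]
        for name, lay in self.blocks:
            x = lay.forward(x, training=False)
            shapes.append((name, x.shape[1:]))
        shapes.append(("flatten", (x.shape[1] * x.shape[2] * x.shape[3],)))
        return shapes

    def forward_features(self, x, training=False, rng=None):
        """``[B, C, T] -> [B, F2, S]`` pre-flatten feature map."""
        x = np.asarray(x, dtype=self.dtype)
        y = self.body.forward(x[:, None, :, :], training=training, rng=rng)
        self._feat_shape = y.shape
        return y[:, :, 0, :]

    def backward_features(self, g):
        return self.body.backward(g[:, :, None, :])[:, 0, :, :]

    def forward_logits(self, x, training=False, rng=None):
        if self.head is None:
            raise RuntimeError("built without a classification head")
        feat = self.forward_features(x, training=training, rng=rng)
        self._flat_shape = feat.shape
        return self.head.forward(feat.reshape(feat.shape[0], -1))

    def backward_logits(self, g):
        gf = self.head.backward(g).reshape(self._flat_shape)
        return self.backward_features(gf)

    def predict_proba(self, x, batch_size: int = 64):
        out = [softmax(self.forward_logits(x[i:i + batch_size]))
               for i in range(0, x.shape[0], batch_size)]
        return np.vstack(out)


def build_compact_cnn(config: NetworkConfig, seed: int = 0,
                      include_head: bool = True) -> CompactCNN:
    """Construct the compact CNN with deterministic seeded initialization."""
    return CompactCNN(config, np.random.default_rng(seed),
                      include_head=include_head)


def count_trainable_parameters(model) -> dict:
    """Per-layer trainable parameter counts plus ``"total"``.

    Closed forms for the compact CNN: temporal conv ``F1*kernel``; each batch
    norm ``2*maps``; depthwise ``C*F1*D``; separable
    ``F1*D*sep_kernel + F1*D*F2``; dense ``(in+1)*K``.  Non-trainable
    parameters (FNB centroids) are excluded.
    """
    counts: dict = {}
    if isinstance(model, CompactCNN):
        named = [(name, lay) for name, lay in model.blocks]
        if model.head is not None:
            named.append(("dense", model.head))
    elif isinstance(model, FCRNet):
        named = [(name, lay) for name, lay in model.cnn.blocks]
        named += [("lstm", model.lstm), ("fc_branch", model.fc_branch)]
        if model.fnb is not None:
            named.append(("fnb", model.fnb))
        named.append(("head", model.head))
    else:
        named = [("model", model)]
    total = 0
    for name, lay in named:
        n = sum(p.size for p in getattr(lay, "params", []) if p.trainable)
        if n:
            counts[name] = n
            total += n
    counts["total"] = total
    return counts


class FCRNet:
    """Fuzzy convolutional-recurrent classifier.

    Compact-CNN feature sequence -> LSTM (last step) -> parallel dense branch
    and fuzzy neural block -> merged head -> softmax over classes.  With
    ``fnb_enabled=False`` the fuzzy branch is absent (the ablation
    configuration); the CNN and LSTM are unchanged.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator,
                 dtype=np.float64):
        config.validate()
        self.config = config
        self.dtype = np.dtype(dtype)
        self.cnn = CompactCNN(config, rng, include_head=False, dtype=dtype)
        self.lstm = LSTMLayer(config.F2, config.lstm_units, rng,
                              mode=config.candidate_activation)
        self.fc_branch = Dense(config.lstm_units, config.fc_units, rng)
        self.fc_act = ELU()
        self.fnb = FNBLayer(config.fnb_rules, config.lstm_units) \
            if config.fnb_enabled else None
        if config.head_merge == "concat":
            head_in = config.fc_units + (config.fnb_rules if self.fnb else 0)
        else:  # sum merge needs matching widths
            if self.fnb and config.fc_units != config.fnb_rules:
                raise ValueError("sum merge requires fc_units == fnb_rules")
            head_in = config.fc_units
        self.head = Dense(head_in, config.n_classes, rng)
        self.params = (self.cnn.params + self.lstm.params
                       + self.fc_branch.params
                       + (self.fnb.params if self.fnb else [])
                       + self.head.params)
        _cast_params(self.params, self.dtype)
        self.last_lstm_output = None

    def forward_logits(self, x, training=False, rng=None):
        feat = self.cnn.forward_features(x, training=training, rng=rng)
        seq = np.transpose(feat, (0, 2, 1))           # [B, S, F2]
        h = self.lstm.forward(seq, training=training, rng=rng)
        self.last_lstm_output = h
        fc = self.fc_act.forward(self.fc_branch.forward(h))
        if self.fnb is not None:
            fz = self.fnb.forward(h, training=training)
            merged = (np.concatenate([fc, fz], axis=1)
                      if self.config.head_merge == "concat" else fc + fz)
        else:
            merged = fc
        return self.head.forward(merged)

    def backward_logits(self, g):
        gm = self.head.backward(g)
        if self.fnb is not None and self.config.head_merge == "concat":
            g_fc = gm[:, : self.config.fc_units]
            g_fz = gm[:, self.config.fc_units:]
        elif self.fnb is not None:
            g_fc, g_fz = gm, gm
        else:
            g_fc, g_fz = gm, None
        gh = self.fc_branch.backward(self.fc_act.backward(g_fc))
        if self.fnb is not None:
            gh = gh + self.fnb.backward(g_fz)
        gseq = self.lstm.backward(gh)
        return self.cnn.backward_features(np.transpose(gseq, (0, 2, 1)))

    def loss_and_grads(self, x, y, training=True, rng=None):
        """Mean cross-entropy on a batch; gradients accumulate in params."""
        logits = self.forward_logits(x, training=training, rng=rng)
        loss, dlogits, probs = softmax_cross_entropy(logits, y)
        self.backward_logits(dlogits)
        return loss, probs

    def zero_grads(self) -> None:
        for p in self.params:
            p.zero_grad()

    def predict_proba(self, x, batch_size: int = 64):
        out = [softmax(self.forward_logits(x[i:i + batch_size]))
               for i in range(0, x.shape[0], batch_size)]
        return np.vstack(out)

    def predict(self, x, batch_size: int = 64):
        return np.argmax(self.predict_proba(x, batch_size), axis=1)

    def refresh_centroids(self, history: np.ndarray, epoch_index: int,
                          seed: int = 0) -> None:
        if self.fnb is None:
            return
        c = update_fnb_centroids(history, self.config.fnb_rules, epoch_index,
                                 seed=seed)
        self.fnb.set_centroids(c)


def assemble_fcrnet(config: NetworkConfig, seed: int = 0,
                    dtype=np.float64) -> FCRNet:
    """Build the full classifier with deterministic seeded initialization."""
    return FCRNet(config, np.random.default_rng(seed), dtype=dtype)


class Adam:
    """Adam over a parameter list; non-trainable params are skipped."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
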