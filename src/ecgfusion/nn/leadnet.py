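"""The per-lead deep model: parallel CNN branches over ten 6-s segments,
time-ordered splicing, a bidirectional LSTM, dropout, and a 9-way softmax.

One model serves one ECG lead.  Each of the ten segment branches is a
four-layer 1-D convolutional stack (conv -> batch-norm -> ReLU, with max
pooling after the first three blocks) finished by global average
pooling; the ten branch outputs, kept in segment time order, form the
length-10 input sequence of a BiLSTM whose final forward and backward
hidden states are concatenated and mapped to class logits.  Dropout
(keep probability 0.5) sits between the branch outputs and the
recurrent layer.  By default the branch weights are shared (one CNN
applied to every segment); ``share_branch_weights=False`` instantiates
ten independent branches.

Training is plain stochastic gradient descent with momentum on the
cross-entropy loss; a fixed seed makes initialization, dropout masks,
and shuffling — and therefore the whole loss history — reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..labels import N_CLASSES
from .core import (
    BatchNorm1D,
    BiLSTM,
    Conv1D,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool1D,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

#: Frozen architecture counts.
N_BRANCHES = 10
N_CONV_LAYERS = 4
N_POOL_LAYERS = 3


@dataclass
class LeadModelConfig:
    """Architecture and optimizer settings for one lead model.

    The branch count (10), convolutional depth (4), pooling depth (3)
    and class count (9) are frozen; filter counts, kernel size, pool
    size and the LSTM width are free.
    """

    conv_filters: tuple[int, ...] = (16, 32, 32, 64)
    conv_kernel: int = 7
    pool_size: int = 3
    lstm_units: int = 64
    dropout_keep_prob: float = 0.5
    n_classes: int = N_CLASSES
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    share_branch_weights: bool = True

    def __post_init__(self) -> None:
        self.conv_filters = tuple(self.conv_filters)
        if len(self.conv_filters) != N_CONV_LAYERS:
            raise ValueError(
                f"exactly {N_CONV_LAYERS} convolutional layers are required; "
                f"got filter counts {self.conv_filters}")
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes is frozen at {N_CLASSES}")
        if not 0 < self.dropout_keep_prob <= 1:
            raise ValueError("dropout_keep_prob must be in (0, 1]")
        if self.pool_size < 1 or self.conv_kernel < 1 or self.lstm_units < 1:
            raise ValueError("pool_size, conv_kernel, lstm_units must be >= 1")


def _build_branch(config: LeadModelConfig, rng: np.random.Generator) -> list:
    layers: list = []
    c_in = 1
    for li, c_out in enumerate(config.conv_filters):
        layers.append(Conv1D(c_in, c_out, config.conv_kernel, rng))
        layers.append(BatchNorm1D(c_out))
        layers.append(ReLU())
        if li < N_POOL_LAYERS:
            layers.append(MaxPool1D(config.pool_size))
        c_in = c_out
    layers.append(GlobalAvgPool())
    return layers


class LeadModel:
    """CNN-BiLSTM classifier for one lead's stack of ten segments.

    Forward input: ``(batch, 10, L)`` z-scored segments; output: 9-class
    probability rows summing to 1.
    """

    def __init__(self, config: LeadModelConfig, lead_index: int = 0) -> None:
        self.config = config
        self.lead_index = lead_index
        self.rng = np.random.default_rng(config.seed)
        n_branch_sets = 1 if config.share_branch_weights else N_BRANCHES
        self.branches = [_build_branch(config, self.rng)
                         for _ in range(n_branch_sets)]
        self.dropout = Dropout(config.dropout_keep_prob, self.rng)
        self.bilstm = BiLSTM(config.conv_filters[-1], config.lstm_units,
                             self.rng)
        self.head = Dense(2 * config.lstm_units, config.n_classes, self.rng)
        self.loss_history: list[float] = []

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for bi, branch in enumerate(self.branches):
            for li, layer in enumerate(branch):
                yield f"branch{bi}.{li}", layer
        yield "bilstm", self.bilstm
        yield "head", self.head

    def parameters(self):
        for prefix, layer in self._layers():
            for name, p, g in layer.parameters():
                yield f"{prefix}.{name}", p, g

    def zero_grads(self) -> None:
        for _, layer in self._layers():
            layer.zero_grads()

    # -- forward / backward -------------------------------------------------
    def _branch_forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """(batch, 10, L) -> (batch, 10, C) branch features."""
        b, n_seg, length = x.shape
        if n_seg != N_BRANCHES:
            raise ValueError(
                f"expected {N_BRANCHES} segments per stack, got {n_seg}")
        if self.config.share_branch_weights:
            h = x.reshape(b * n_seg, 1, length)
            for layer in self.branches[0]:
                h = layer.forward(h, train)
            return h.reshape(b, n_seg, -1)
        feats = []
        for s in range(n_seg):
            h = x[:, s][:, None, :]
            for layer in self.branches[s]:
                h = layer.forward(h, train)
            feats.append(h)
        return np.stack(feats, axis=1)

    def _branch_backward(self, dfeat: np.ndarray) -> None:
        b, n_seg, c = dfeat.shape
        if self.config.share_branch_weights:
            dh = dfeat.reshape(b * n_seg, c)
            for layer in reversed(self.branches[0]):
                dh = layer.backward(dh)
        else:
            for s in range(n_seg):
                dh = dfeat[:, s]
                for layer in reversed(self.branches[s]):
                    dh = layer.backward(dh)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class logits for a batch of segment stacks."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        feats = self._branch_forward(x, train)
        feats = self.dropout.forward(feats, train)
        rep = self.bilstm.forward(feats, train)
        return self.head.forward(rep, train)

    def backward(self, dlogits: np.ndarray) -> None:
        drep = self.head.backward(dlogits)
        dfeats = self.bilstm.backward(drep)
        dfeats = self.dropout.backward(dfeats)
        self._branch_backward(dfeats)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """9-class probabilities; dropout disabled, batch-norm in
        inference mode, hence deterministic."""
        p = softmax(self.forward(x, train=False))
        return p[0] if np.asarray(x).ndim == 2 else p


def build_lead_model(config: LeadModelConfig,
                     lead_index: int = 0) -> LeadModel:
    """Instantiate an (untrained) lead model from a validated config."""
    return LeadModel(config, lead_index=lead_index)


def train_lead_model(model: LeadModel,
                     x: np.ndarray,
                     y: np.ndarray,
                     config: LeadModelConfig | None = None,
                     ) -> tuple[LeadModel, list[float]]:
    """SGD + momentum training on (segment stack, class index) pairs.

    ``x`` has shape ``(n, 10, L)``; ``y`` holds integer class indices.
    Returns the model and its per-epoch mean loss history.  Raises on
    single-class data and aborts on divergence (NaN loss).
    """
    config = config or model.config
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 3 or len(x) != len(y):
        raise ValueError("x must be (n, 10, L) with matching labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")

    velocity = {name: np.zeros_like(p) for name, p, _ in model.parameters()}
    n = len(x)
    for _ in range(config.epochs):
        order = model.rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grads()
            logits = model.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training diverged (non-finite loss); "
                    "lower the learning rate")
            model.backward(dlogits)
            for name, p, g in model.parameters():
                v = velocity[name]
                v *= config.momentum
                v -= config.learning_rate * g
                p += v
            epoch_losses.append(loss)
        model.loss_history.append(float(np.mean(epoch_losses)))
    return model, model.loss_history


def predict_lead_proba(model: LeadModel, stack: np.ndarray) -> np.ndarray:
    """Probability vector(s) for one stack ``(10, L)`` or a batch."""
    return model.predict_proba(stack)
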