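"""Building blocks of the multitask network.

The graph branch follows principal neighborhood aggregation: messages from
neighboring atoms are transformed by an inner MLP, aggregated with four
aggregators (mean, population std, max, min), each rescaled by three degree
scalers (identity, amplification, attenuation), and the 12 blocks are
concatenated before the node-update MLP.  The degree scaler is

    S(d, alpha) = (ln(d + 1) / delta) ** alpha

with delta the mean of ln(d_i + 1) over all atoms of the training graphs
(natural log throughout).  Isolated atoms (d = 0) receive S = 1 for every
alpha, extending the d > 0 definition continuously.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._autograd import (
    Parameter,
    Tensor,
    concat,
    gather_rows,
    segment_max,
    segment_mean,
    segment_min,
    segment_std,
    segment_sum,
)
from .chem import MolGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ScalerParams",
    "compute_delta",
    "degree_scaler",
    "scaler_columns",
    "pna_aggregate",
    "Linear",
    "MLP",
    "Adam",
    "masked_multitask_loss",
    "EarlyStopping",
    "early_stop_epoch",
]

ALPHAS = (0, 1, -1)  # identity, amplification, attenuation
N_AGGREGATORS = 4    # mean, std, max, min


# ---------------------------------------------------------------------------
# degree scaler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalerParams:
    """Normalization of the degree scaler, estimated on training graphs only."""

    delta: float

    def __post_init__(self):
        if not self.delta > 0:
            raise ValueError("delta must be positive")


def compute_delta(train_graphs: Sequence[MolGraph]) -> ScalerParams:
    """delta = mean over all training atoms of ln(degree + 1)."""
    if not train_graphs:
        raise ValueError("need at least one training graph")
    degs = np.concatenate([g.degrees for g in train_graphs])
    delta = float(np.mean(np.log(degs + 1.0)))
    if delta <= 0:
        raise ValueError("all training atoms are isolated; degree scaler undefined")
    return ScalerParams(delta=delta)


def degree_scaler(d: int, alpha: int, scaler: ScalerParams) -> float:
    """S(d, alpha) = (ln(d+1)/delta)^alpha; S = 1 for isolated atoms."""
    if alpha not in ALPHAS:
        raise ValueError(f"alpha must be one of {ALPHAS}")
    if d < 0:
        raise ValueError("degree must be non-negative")
    if d == 0:
        logger.debug("degree-0 atom: scaler pinned to 1 for alpha=%d", alpha)
        return 1.0
    return float((math.log(d + 1.0) / scaler.delta) ** alpha)


def scaler_columns(degrees: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    """(n, 3) matrix of S(d_i, alpha) for alpha in (0, +1, -1)."""
    degrees = np.asarray(degrees, dtype=np.float64)
    s = np.log(degrees + 1.0) / scaler.delta
    s = np.where(degrees > 0, s, 1.0)
    return np.stack([np.ones_like(s), s, 1.0 / s], axis=1)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def pna_aggregate(
    messages: np.ndarray, degree: int, scaler: ScalerParams
) -> np.ndarray:
    """Reference (non-differentiable) aggregation for a single node.

    ``messages`` is (k, h): the inner-MLP-transformed neighbor messages.
    Returns the (12*h,) concatenation ordered scaler-major:
    [identity, amplification, attenuation] x [mean, std, max, min].
    Zero messages aggregate to zeros; a single message has std 0.
    """
    messages = np.atleast_2d(np.asarray(messages, dtype=np.float64))
    h = messages.shape[1]
    if messages.shape[0] == 0 or messages.size == 0:
        return np.zeros(12 * h)
    mean = messages.mean(axis=0)
    std = messages.std(axis=0)  # population convention
    mx = messages.max(axis=0)
    mn = messages.min(axis=0)
    base = np.concatenate([mean, std, mx, mn])
    return np.concatenate(
        [degree_scaler(degree, a, scaler) * base for a in ALPHAS]
    )


def pna_aggregate_batch(
    messages: Tensor, edge_dst: np.ndarray, n_nodes: int,
    scaler_cols: np.ndarray, std_eps: float,
) -> Tensor:
    """Differentiable, batched counterpart of :func:`pna_aggregate`."""
    aggs = concat([
        segment_mean(messages, edge_dst, n_nodes),
        segment_std(messages, edge_dst, n_nodes, eps=std_eps),
        segment_max(messages, edge_dst, n_nodes),
        segment_min(messages, edge_dst, n_nodes),
    ])
    blocks = [aggs * Tensor(scaler_cols[:, k:k + 1]) for k in range(len(ALPHAS))]
    return concat(blocks)


# ---------------------------------------------------------------------------
# dense layers
# ---------------------------------------------------------------------------

class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class MLP:
    """Stack of Linear layers with ReLU between (and optionally after) them."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator,
                 final_activation: bool = True):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if self.final_activation or i < len(self.layers) - 1:
                x = x.relu()
        return x

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2 regularization (weight decay added to the gradient)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# loss and early stopping
# ---------------------------------------------------------------------------

def _loss_weights(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("all-false mask: no training signal in the batch")
    n_t = mask.sum(axis=0).astype(np.float64)
    inv = np.zeros_like(n_t)
    nz = n_t > 0
    inv[nz] = 1.0 / n_t[nz]
    return mask * inv  # (n, T)


def masked_multitask_loss(pred, labels, mask) -> float:
    """Sum over tasks of the per-task mean squared error on observed labels.

    loss = sum_t (1/n_t) * sum_{i : mask[i,t]} (pred[i,t] - labels[i,t])^2,
    with tasks absent from the batch (n_t = 0) contributing 0.
    """
    pred = np.asarray(pred, dtype=np.float64)
    w = _loss_weights(mask)
    diff = np.where(w > 0, pred - np.asarray(labels, dtype=np.float64), 0.0)
    return float(np.sum(diff * diff * w))


def masked_loss_tensor(pred: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Differentiable version of :func:`masked_multitask_loss`."""
    w = _loss_weights(mask)
    y0 = np.where(mask, np.asarray(labels, dtype=np.float64), 0.0)
    diff = (pred - Tensor(y0)) * Tensor(mask.astype(np.float64))
    return ((diff * diff) * Tensor(w)).sum()


class EarlyStopping:
    """Stop after ``patience`` epochs with no improvement of the validation
    loss nor of its ``window``-epoch moving average; keep the best-loss epoch.
    """

    def __init__(self, patience: int = 10, window: int = 10):
        self.patience = patience
        self.window = window
        self.losses: list[float] = []
        self.best_loss = math.inf
        self.best_avg = math.inf
        self.best_index = 0
        self.wait = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; return True if training should stop."""
        e = len(self.losses)
        self.losses.append(float(loss))
        improved = False
        if loss < self.best_loss:
            self.best_loss, self.best_index = loss, e
            improved = True
        avg = float(np.mean(self.losses[max(0, e - self.window + 1):]))
        if avg < self.best_avg:
            self.best_avg = avg
            improved = True
        self.wait = 0 if improved else self.wait + 1
        return self.wait >= self.patience


def early_stop_epoch(
    val_losses: Sequence[float], patience: int = 10, window: int = 10
) -> tuple[int, int]:
    """Apply the stopping rule to a scripted validation-loss trajectory.

    Returns ``(stop_index, best_index)``: the index of the last epoch run
    (where the rule fires, or the final index if it never does) and the index
    of the best-validation epoch whose weights would be kept.
    """
    monitor = EarlyStopping(patience=patience, window=window)
    for e, loss in enumerate(val_losses):
        if monitor.update(loss):
            return e, monitor.best_index
    return len(val_losses) - 1, monitor.best_index
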