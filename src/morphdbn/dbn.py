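"""Greedy DBN pretraining and supervised fine-tuning.

A deep belief network is built layer by layer: the first RBM has
Gaussian visible units (the inputs are z-scored morphometric features),
every later RBM is Bernoulli and is trained on the deterministic hidden
activation probabilities of the layer below.  All hidden layers share
one width.

The pretrained stack initializes a feedforward classifier: logistic
hidden layers carrying the RBM weights verbatim, plus a two-unit
softmax output initialized at zero.  Fine-tuning minimizes
cross-entropy with an L2 penalty on the weights by minibatch stochastic
gradient descent with Nesterov momentum (ramped linearly from 0.5 to
its maximum over the first 10% of epochs) combined with RMSPROP
per-parameter scaling.  The minibatch loop is compiled with numba; the
pure-numpy forward/backward pass in :func:`loss_and_gradients` is kept
as the reference the compiled loop is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import expit

from .rbm import (
    BERNOULLI,
    GAUSSIAN,
    CDTrainingConfig,
    RBMParameters,
    hidden_conditional,
    train_rbm,
)


@dataclass
class DBNModel:
    """Ordered RBM stack; optionally with an associative top layer.

    ``layers[0]`` is Gaussian-visible, the rest Bernoulli.  The
    associative top, when present, is a Bernoulli RBM whose visible
    layer concatenates the penultimate activations with a one-hot
    2-class label block (see :mod:`morphdbn.probe`).
    """

    layers: list[RBMParameters]
    associative_top: RBMParameters | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a DBN needs at least one layer")
        if self.layers[0].visible_family != GAUSSIAN:
            raise ValueError("first layer must have gaussian visible units")
        widths = {p.n_hidden for p in self.layers}
        if len(widths) != 1:
            raise ValueError("all hidden layers must share one width")
        for lower, upper in zip(self.layers, self.layers[1:]):
            if upper.visible_family != BERNOULLI:
                raise ValueError("layers above the first must be bernoulli")
            if upper.n_visible != lower.n_hidden:
                raise ValueError("adjacent layer dimensions do not chain")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.layers[0].n_visible] + [p.n_hidden for p in self.layers]

    def propagate_up(self, data: np.ndarray) -> np.ndarray:
        """Deterministic activation probabilities of the top stacked layer."""
        acts = np.asarray(data, dtype=float)
        for params in self.layers:
            acts = hidden_conditional(params, acts)
        return acts


@dataclass
class FineTuneConfig:
    """Supervised training recipe for the fine-tuned classifier.

    Defaults are the full recipe: 200 epochs of minibatch-10 SGD with
    Nesterov momentum capped at 0.9, RMSPROP scaling (decay 0.9,
    epsilon 1e-6) and weight decay 5e-5 applied to weights only.
    """

    learning_rate: float = 0.01
    epochs: int = 200
    minibatch_size: int = 10
    momentum_max: float = 0.9
    momentum_start: float = 0.5
    momentum_ramp_fraction: float = 0.1
    rmsprop_decay: float = 0.9
    rmsprop_epsilon: float = 1e-6
    weight_decay: float = 5e-5
    rng_seed: int = 0

    def momentum_schedule(self) -> np.ndarray:
        """Per-epoch momentum: linear ramp then constant at the maximum."""
        ramp = max(1, int(round(self.momentum_ramp_fraction * self.epochs)))
        sched = np.full(self.epochs, self.momentum_max)
        for ep in range(min(ramp, self.epochs)):
            frac = ep / ramp
            sched[ep] = self.momentum_start + frac * (
                self.momentum_max - self.momentum_start)
        return sched


@dataclass
class FineTunedNetwork:
    """Feedforward classifier: logistic hidden layers + 2-unit softmax.

    ``W_first`` is (k x d); ``W_hidden`` stacks the (k x k) matrices of
    the remaining hidden layers; ``W_out`` is (2 x k).  Class order of
    the output units is (HC, SCZ).
    """

    W_first: np.ndarray
    b_first: np.ndarray
    W_hidden: np.ndarray
    b_hidden: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray
    config: FineTuneConfig = field(default_factory=FineTuneConfig)
    train_log: list[float] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.W_first.shape[1]

    @property
    def n_hidden_layers(self) -> int:
        return 1 + self.W_hidden.shape[0]

    def parameter_count(self) -> int:
        return int(self.W_first.size + self.b_first.size + self.W_hidden.size
                   + self.b_hidden.size + self.W_out.size + self.b_out.size)

    def copy(self) -> "FineTunedNetwork":
        return FineTunedNetwork(
            self.W_first.copy(), self.b_first.copy(), self.W_hidden.copy(),
            self.b_hidden.copy(), self.W_out.copy(), self.b_out.copy(),
            self.config, list(self.train_log))

    def hidden_activations(self, rows: np.ndarray) -> np.ndarray:
        """Activation probabilities of the last hidden layer."""
        rows = np.asarray(rows, dtype=float)
        if rows.ndim == 1:
            rows = rows[None, :]
        if rows.shape[1] != self.n_inputs:
            raise ValueError(
                f"input width {rows.shape[1]} != network width {self.n_inputs}")
        a = expit(rows @ self.W_first.T + self.b_first)
        for li in range(self.W_hidden.shape[0]):
            a = expit(a @ self.W_hidden[li].T + self.b_hidden[li])
        return a

    def save(self, path: str | Path) -> None:
        np.savez(path, W_first=self.W_first, b_first=self.b_first,
                 W_hidden=self.W_hidden, b_hidden=self.b_hidden,
                 W_out=self.W_out, b_out=self.b_out)

    @classmethod
    def load(cls, path: str | Path) -> "FineTunedNetwork":
        with np.load(path) as d:
            return cls(d["W_first"], d["b_first"], d["W_hidden"],
                       d["b_hidden"], d["W_out"], d["b_out"])


def pretrain_dbn(data: np.ndarray, layer_sizes: list[int],
                 pretrain_lr: float = 0.05, seed: int = 0,
                 cd_config: CDTrainingConfig | None = None) -> DBNModel:
    """Greedy layer-wise RBM pretraining.

    ``layer_sizes`` is [n_inputs, k, k, ...]; all hidden widths must be
    equal.  Each layer is trained by CD-1 and frozen; its deterministic
    activation probabilities become the next layer's training data.
    Warns if the input does not look standardized.
    """
    data = np.asarray(data, dtype=float)
    if len(layer_sizes) < 2:
        raise ValueError("need at least one hidden layer")
    if data.shape[1] != layer_sizes[0]:
        raise ValueError("layer_sizes[0] must equal the data width")
    if len(set(layer_sizes[1:])) != 1:
        raise ValueError("all hidden layers must share one width")
    off_center = np.abs(data.mean(axis=0)) > 0.5
    if off_center.mean() >= 0.10:
        import warnings
        warnings.warn("input does not look z-scored; the gaussian first "
                      "layer assumes standardized features", stacklevel=2)

    if cd_config is None:
        cd_config = CDTrainingConfig(learning_rate=pretrain_lr, rng_seed=seed)
    rng = np.random.default_rng(cd_config.rng_seed)
    layers: list[RBMParameters] = []
    acts = data
    for depth, width in enumerate(layer_sizes[1:]):
        family = GAUSSIAN if depth == 0 else BERNOULLI
        params, _ = train_rbm(acts, width, cd_config, visible_family=family,
                              rng=rng)
        layers.append(params)
        acts = hidden_conditional(params, acts)
    return DBNModel(layers=layers)


def initialize_network(dbn: DBNModel,
                       config: FineTuneConfig | None = None
                       ) -> FineTunedNetwork:
    """Copy DBN weights into a feedforward net; zero softmax on top."""
    if config is None:
        config = FineTuneConfig()
    k = dbn.layers[0].n_hidden
    W_first = dbn.layers[0].W.copy()
    b_first = dbn.layers[0].b_hid.copy()
    n_upper = len(dbn.layers) - 1
    W_hidden = np.empty((n_upper, k, k))
    b_hidden = np.empty((n_upper, k))
    for i, params in enumerate(dbn.layers[1:]):
        W_hidden[i] = params.W
        b_hidden[i] = params.b_hid
    return FineTunedNetwork(W_first, b_first, W_hidden, b_hidden,
                            np.zeros((2, k)), np.zeros(2), config)


def random_network(n_inputs: int, n_hidden_layers: int, width: int,
                   seed: int, init_sd: float = 0.01,
                   config: FineTuneConfig | None = None) -> FineTunedNetwork:
    """Randomly initialized network of the same shape (no pretraining)."""
    rng = np.random.default_rng(seed)
    if config is None:
        config = FineTuneConfig()
    W_first = rng.normal(0, init_sd, (width, n_inputs))
    W_hidden = rng.normal(0, init_sd, (n_hidden_layers - 1, width, width))
    return FineTunedNetwork(W_first, np.zeros(width), W_hidden,
                            np.zeros((n_hidden_layers - 1, width)),
                            np.zeros((2, width)), np.zeros(2), config)


def predict_proba(net: FineTunedNetwork, rows: np.ndarray) -> np.ndarray:
    """Per-row (P(HC), P(SCZ)); rows may be a single vector or a matrix."""
    rows = np.asarray(rows, dtype=float)
    single = rows.ndim == 1
    a = net.hidden_activations(rows)
    logits = a @ net.W_out.T + net.b_out
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if single else p


def predict(net: FineTunedNetwork, rows: np.ndarray) -> np.ndarray:
    """0/1 class labels (1 = SCZ); exact ties break toward HC."""
    p = np.atleast_2d(predict_proba(net, rows))
    return (p[:, 1] > p[:, 0]).astype(int)


def loss_and_gradients(net: FineTunedNetwork, X: np.ndarray, y: np.ndarray,
                       weight_decay: float | None = None):
    """Cross-entropy + L2 loss and its analytic gradients (reference path).

    Returns ``(loss, grads)`` with grads ordered like the parameter
    arrays of :class:`FineTunedNetwork`.  Used for finite-difference
    validation and as the uncompiled mirror of the training kernel.
    """
    if weight_decay is None:
        weight_decay = net.config.weight_decay
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    acts = [expit(X @ net.W_first.T + net.b_first)]
    for li in range(net.W_hidden.shape[0]):
        acts.append(expit(acts[-1] @ net.W_hidden[li].T + net.b_hidden[li]))
    p = np.atleast_2d(predict_proba(net, X))
    Y = np.zeros((m, 2))
    Y[np.arange(m), np.asarray(y, dtype=int)] = 1.0
    ce = -np.mean(np.log(np.clip(p[np.arange(m), np.asarray(y, dtype=int)],
                                 1e-300, None)))
    l2 = 0.5 * weight_decay * (np.sum(net.W_first ** 2)
                               + np.sum(net.W_hidden ** 2)
                               + np.sum(net.W_out ** 2))
    delta = (p - Y) / m
    gW_out = delta.T @ acts[-1] + weight_decay * net.W_out
    gb_out = delta.sum(axis=0)
    gW_hidden = np.zeros_like(net.W_hidden)
    gb_hidden = np.zeros_like(net.b_hidden)
    d = delta @ net.W_out
    for li in range(net.W_hidden.shape[0] - 1, -1, -1):
        d = d * acts[li + 1] * (1 - acts[li + 1])
        gW_hidden[li] = d.T @ acts[li] + weight_decay * net.W_hidden[li]
        gb_hidden[li] = d.sum(axis=0)
        d = d @ net.W_hidden[li]
    d = d * acts[0] * (1 - acts[0])
    gW_first = d.T @ X + weight_decay * net.W_first
    gb_first = d.sum(axis=0)
    loss = ce + l2
    return loss, (gW_first, gb_first, gW_hidden, gb_hidden, gW_out, gb_out)


@njit(cache=True)
def _finetune_kernel(X, Y, order, mom_sched, W1, b1, Wh, bh, Wo, bo,
                     lr, rho, eps, wd, mb, losses):  # pragma: no cover
    n_epochs, n = order.shape
    L1 = Wh.shape[0]
    k = W1.shape[0]
    d = W1.shape[1]
    vW1 = np.zeros((k, d)); cW1 = np.zeros((k, d))
    vb1 = np.zeros(k); cb1 = np.zeros(k)
    vWh = np.zeros((L1, k, k)); cWh = np.zeros((L1, k, k))
    vbh = np.zeros((L1, k)); cbh = np.zeros((L1, k))
    vWo = np.zeros((2, k)); cWo = np.zeros((2, k))
    vbo = np.zeros(2); cbo = np.zeros(2)
    acts = np.empty((L1 + 1, mb, k))
    a0 = np.empty((mb, d))
    Yb = np.empty((mb, 2))
    for ep in range(n_epochs):
        mom = mom_sched[ep]
        ep_loss = 0.0
        n_batches = 0
        for s in range(0, n, mb):
            m = min(mb, n - s)
            for i in range(m):
                idx = order[ep, s + i]
                for j in range(d):
                    a0[i, j] = X[idx, j]
                Yb[i, 0] = Y[idx, 0]
                Yb[i, 1] = Y[idx, 1]
            z = a0[:m] @ W1.T
            for i in range(m):
                for j in range(k):
                    acts[0, i, j] = 1.0 / (1.0 + np.exp(-(z[i, j] + b1[j])))
            for li in range(L1):
                z2 = acts[li, :m] @ Wh[li].T
                for i in range(m):
                    for j in range(k):
                        acts[li + 1, i, j] = 1.0 / (
                            1.0 + np.exp(-(z2[i, j] + bh[li, j])))
            logits = acts[L1, :m] @ Wo.T
            delta = np.empty((m, 2))
            for i in range(m):
                l0 = logits[i, 0] + bo[0]
                l1 = logits[i, 1] + bo[1]
                mx = l0 if l0 > l1 else l1
                e0 = np.exp(l0 - mx)
                e1 = np.exp(l1 - mx)
                ss = e0 + e1
                p0 = e0 / ss
                p1 = e1 / ss
                ep_loss -= (Yb[i, 0] * np.log(p0 + 1e-300)
                            + Yb[i, 1] * np.log(p1 + 1e-300)) / m
                delta[i, 0] = (p0 - Yb[i, 0]) / m
                delta[i, 1] = (p1 - Yb[i, 1]) / m
            n_batches += 1
            # output layer: RMSPROP-scaled Nesterov update
            gWo = delta.T @ acts[L1, :m]
            back = delta @ Wo
            for r in range(2):
                gb = 0.0
                for i in range(m):
                    gb += delta[i, r]
                cbo[r] = rho * cbo[r] + (1 - rho) * gb * gb
                step = lr * gb / np.sqrt(cbo[r] + eps)
                vbo[r] = mom * vbo[r] - step
                bo[r] += mom * vbo[r] - step
                for j in range(k):
                    g = gWo[r, j] + wd * Wo[r, j]
                    cWo[r, j] = rho * cWo[r, j] + (1 - rho) * g * g
                    step = lr * g / np.sqrt(cWo[r, j] + eps)
                    vWo[r, j] = mom * vWo[r, j] - step
                    Wo[r, j] += mom * vWo[r, j] - step
            for li in range(L1 - 1, -1, -1):
                for i in range(m):
                    for j in range(k):
                        a = acts[li + 1, i, j]
                        back[i, j] *= a * (1.0 - a)
                nxt = back @ np.ascontiguousarray(Wh[li])
                gW = back.T @ acts[li, :m]
                for r in range(k):
                    gb = 0.0
                    for i in range(m):
                        gb += back[i, r]
                    cbh[li, r] = rho * cbh[li, r] + (1 - rho) * gb * gb
                    step = lr * gb / np.sqrt(cbh[li, r] + eps)
                    vbh[li, r] = mom * vbh[li, r] - step
                    bh[li, r] += mom * vbh[li, r] - step
                    for j in range(k):
                        g = gW[r, j] + wd * Wh[li, r, j]
                        cWh[li, r, j] = rho * cWh[li, r, j] + (1 - rho) * g * g
                        step = lr * g / np.sqrt(cWh[li, r, j] + eps)
                        vWh[li, r, j] = mom * vWh[li, r, j] - step
                        Wh[li, r, j] += mom * vWh[li, r, j] - step
                back = nxt
            for i in range(m):
                for j in range(k):
                    a = acts[0, i, j]
                    back[i, j] *= a * (1.0 - a)
            gW1 = back.T @ a0[:m]
            for r in range(k):
                gb = 0.0
                for i in range(m):
                    gb += back[i, r]
                cb1[r] = rho * cb1[r] + (1 - rho) * gb * gb
                step = lr * gb / np.sqrt(cb1[r] + eps)
                vb1[r] = mom * vb1[r] - step
                b1[r] += mom * vb1[r] - step
                for j in range(d):
                    g = gW1[r, j] + wd * W1[r, j]
                    cW1[r, j] = rho * cW1[r, j] + (1 - rho) * g * g
                    step = lr * g / np.sqrt(cW1[r, j] + eps)
                    vW1[r, j] = mom * vW1[r, j] - step
                    W1[r, j] += mom * vW1[r, j] - step
        losses[ep] = ep_loss / max(n_batches, 1)


def fine_tune(net: FineTunedNetwork, data: np.ndarray, labels: np.ndarray,
              config: FineTuneConfig | None = None) -> FineTunedNetwork:
    """Supervised training of the full network; returns a new network.

    Minibatch order is reshuffled every epoch from ``config.rng_seed``;
    given the same seed the result is bit-reproducible on one platform.
    The per-epoch mean minibatch cross-entropy is recorded in
    ``train_log``.
    """
    if config is None:
        config = net.config
    X = np.ascontiguousarray(data, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] != net.n_inputs:
        raise ValueError(
            f"data width {X.shape[1]} != network width {net.n_inputs}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("fine-tuning requires both classes in the labels")
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("labels must be coded 0 (HC) / 1 (SCZ)")
    out = net.copy()
    out.config = config
    if config.epochs == 0 or config.learning_rate == 0.0:
        return out
    n = X.shape[0]
    Y = np.zeros((n, 2))
    Y[np.arange(n), y] = 1.0
    rng = np.random.default_rng(config.rng_seed)
    order = np.empty((config.epochs, n), dtype=np.int64)
    for ep in range(config.epochs):
        order[ep] = rng.permutation(n)
    losses = np.zeros(config.epochs)
    _finetune_kernel(X, Y, order, config.momentum_schedule(),
                     out.W_first, out.b_first, out.W_hidden, out.b_hidden,
                     out.W_out, out.b_out,
                     config.learning_rate, config.rmsprop_decay,
                     config.rmsprop_epsilon, config.weight_decay,
                     config.minibatch_size, losses)
    out.train_log = [float(v) for v in losses]
    return out
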