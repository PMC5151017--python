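"""Restricted Boltzmann machines with CD-1 training.

Two visible-unit families are supported: ``bernoulli`` for binary (or
probability-valued) inputs, and ``gaussian_unit_variance`` for
real-valued inputs that have been z-scored, the standard convention for
Gaussian RBMs on standardized data.  Hidden units are always Bernoulli.

Weights are stored as a (hidden x visible) matrix ``W``; hidden
activation probabilities are ``sigmoid(W v + b_hid)`` and the visible
conditional is ``sigmoid(W^T h + b_vis)`` (Bernoulli) or a unit-variance
Gaussian with mean ``W^T h + b_vis``.

Training uses contrastive divergence with one alternating Gibbs step
(CD-1): positive-phase statistics pair the data with hidden activation
probabilities; the negative phase samples the hidden layer once,
reconstructs the visible layer with its conditional mean, and pairs the
reconstruction with its hidden probabilities.  Using conditional means
rather than samples in the reconstruction statistics is a common
variance-reduction choice.

For models with at most 20 units the exact partition function is
enumerable, giving an exact average log-likelihood used as an
independent training oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp

BERNOULLI = "bernoulli"
GAUSSIAN = "gaussian_unit_variance"
_FAMILIES = (BERNOULLI, GAUSSIAN)


@dataclass
class RBMParameters:
    """Weights, biases and visible-unit family of one RBM layer."""

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray
    visible_family: str = BERNOULLI

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_vis = np.asarray(self.b_vis, dtype=float)
        self.b_hid = np.asarray(self.b_hid, dtype=float)
        if self.W.shape != (self.b_hid.shape[0], self.b_vis.shape[0]):
            raise ValueError(
                f"W must be (n_hidden, n_visible) = "
                f"({self.b_hid.shape[0]}, {self.b_vis.shape[0]}), got {self.W.shape}"
            )
        if self.visible_family not in _FAMILIES:
            raise ValueError(f"unknown visible family {self.visible_family!r}")
        for arr in (self.W, self.b_vis, self.b_hid):
            if not np.all(np.isfinite(arr)):
                raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.b_vis.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.b_hid.shape[0]

    def copy(self) -> "RBMParameters":
        return RBMParameters(self.W.copy(), self.b_vis.copy(),
                             self.b_hid.copy(), self.visible_family)

    def save(self, path: str | Path) -> None:
        np.savez(path, W=self.W, b_vis=self.b_vis, b_hid=self.b_hid,
                 visible_family=np.array(self.visible_family))

    @classmethod
    def load(cls, path: str | Path) -> "RBMParameters":
        with np.load(path) as data:
            return cls(data["W"], data["b_vis"], data["b_hid"],
                       str(data["visible_family"]))


@dataclass
class CDTrainingConfig:
    """Contrastive-divergence pretraining recipe.

    Defaults follow the standard DBN pretraining setup for this
    pipeline: CD-1, minibatches of 10, ten epochs, weights initialized
    from N(0, 0.01^2) and biases at zero.  Momentum defaults to 0 for
    pretraining (it is a fine-tuning device here) but is configurable.
    """

    learning_rate: float = 0.05
    epochs: int = 10
    minibatch_size: int = 10
    cd_steps: int = 1
    init_weight_sd: float = 0.01
    momentum: float = 0.0
    weight_decay: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 0 or self.minibatch_size < 1 or self.cd_steps < 1:
            raise ValueError("invalid epochs/minibatch_size/cd_steps")
        if not (0 <= self.momentum < 1) or self.weight_decay < 0:
            raise ValueError("invalid momentum/weight_decay")


def _check_visible(params: RBMParameters, v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError(
            f"visible vector has length {v.shape[-1]}, expected {params.n_visible}"
        )
    return v


def _check_hidden(params: RBMParameters, h: np.ndarray) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(
            f"hidden vector has length {h.shape[-1]}, expected {params.n_hidden}"
        )
    return h


def hidden_conditional(params: RBMParameters, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v), elementwise logistic of ``W v + b_hid``.

    Accepts a single visible vector or a (batch x visible) matrix.
    """
    v = _check_visible(params, v)
    return expit(v @ params.W.T + params.b_hid)


def visible_conditional(params: RBMParameters, h: np.ndarray) -> np.ndarray:
    """Visible conditional parameters given hidden states.

    Bernoulli family: activation probabilities; Gaussian family: the
    conditional mean (the variance is fixed at 1).
    """
    h = _check_hidden(params, h)
    pre = h @ params.W + params.b_vis
    if params.visible_family == BERNOULLI:
        return expit(pre)
    return pre


def gibbs_step(params: RBMParameters, v: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One alternating Gibbs update: sample h | v, then v' | h.

    Gaussian visible units are sampled as conditional mean plus
    unit-variance noise; Bernoulli units as coin flips.
    """
    v = _check_visible(params, v)
    h_prob = hidden_conditional(params, v)
    h_sample = (rng.random(h_prob.shape) < h_prob).astype(float)
    v_param = visible_conditional(params, h_sample)
    if params.visible_family == BERNOULLI:
        v_next = (rng.random(v_param.shape) < v_param).astype(float)
    else:
        v_next = v_param + rng.standard_normal(v_param.shape)
    return h_sample, v_next


@dataclass
class _Velocity:
    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray

    @classmethod
    def zeros_like(cls, params: RBMParameters) -> "_Velocity":
        return cls(np.zeros_like(params.W), np.zeros_like(params.b_vis),
                   np.zeros_like(params.b_hid))


def cd1_update(params: RBMParameters, minibatch: np.ndarray,
               config: CDTrainingConfig, rng: np.random.Generator,
               velocity: _Velocity | None = None,
               ) -> tuple[RBMParameters, _Velocity]:
    """One contrastive-divergence parameter update on a minibatch.

    The gradient estimate is the positive-phase minus negative-phase
    statistics averaged over the minibatch; weight decay subtracts
    ``weight_decay * W`` from the weight gradient; momentum accumulates
    a velocity.  Returns updated parameters and the velocity state.
    """
    v0 = np.atleast_2d(_check_visible(params, minibatch))
    if v0.shape[0] == 0:
        raise ValueError("empty minibatch")
    if velocity is None:
        velocity = _Velocity.zeros_like(params)
    m = v0.shape[0]

    h0_prob = hidden_conditional(params, v0)
    h_prob = h0_prob
    vk = v0
    for _ in range(config.cd_steps):
        h_sample = (rng.random(h_prob.shape) < h_prob).astype(float)
        vk = visible_conditional(params, h_sample)   # conditional mean
        h_prob = hidden_conditional(params, vk)

    grad_W = (h0_prob.T @ v0 - h_prob.T @ vk) / m - config.weight_decay * params.W
    grad_bv = (v0 - vk).mean(axis=0)
    grad_bh = (h0_prob - h_prob).mean(axis=0)

    velocity.W = config.momentum * velocity.W + config.learning_rate * grad_W
    velocity.b_vis = (config.momentum * velocity.b_vis
                      + config.learning_rate * grad_bv)
    velocity.b_hid = (config.momentum * velocity.b_hid
                      + config.learning_rate * grad_bh)
    updated = RBMParameters(params.W + velocity.W, params.b_vis + velocity.b_vis,
                            params.b_hid + velocity.b_hid, params.visible_family)
    return updated, velocity


def initialize_rbm(n_visible: int, n_hidden: int, visible_family: str,
                   init_weight_sd: float, rng: np.random.Generator
                   ) -> RBMParameters:
    """Gaussian N(0, sd^2) weights, zero biases."""
    W = rng.normal(0.0, init_weight_sd, size=(n_hidden, n_visible))
    return RBMParameters(W, np.zeros(n_visible), np.zeros(n_hidden),
                         visible_family)


def train_rbm(data: np.ndarray, n_hidden: int, config: CDTrainingConfig,
              visible_family: str = BERNOULLI,
              rng: np.random.Generator | None = None,
              ) -> tuple[RBMParameters, list[float]]:
    """Train an RBM by minibatch CD on shuffled epochs.

    Returns the final parameters and the per-epoch mean squared
    reconstruction error (one-step conditional-mean reconstruction).
    A short final minibatch is used with gradients averaged over its
    actual size.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("data must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("training data must be finite")
    if visible_family == BERNOULLI and (data.min() < 0 or data.max() > 1):
        raise ValueError("bernoulli training data must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    params = initialize_rbm(data.shape[1], n_hidden, visible_family,
                            config.init_weight_sd, rng)
    velocity = _Velocity.zeros_like(params)
    n = data.shape[0]
    log: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.minibatch_size):
            batch = data[order[start:start + config.minibatch_size]]
            params, velocity = cd1_update(params, batch, config, rng, velocity)
        recon = visible_conditional(
            params, hidden_conditional(params, data))
        log.append(float(np.mean((data - recon) ** 2)))
    return params, log


def free_energy(params: RBMParameters, v: np.ndarray) -> np.ndarray:
    """Free energy F(v) with hidden units marginalized out.

    Bernoulli: ``-v.b_vis - sum softplus(W v + b_hid)``;
    Gaussian:  ``||v - b_vis||^2 / 2 - sum softplus(W v + b_hid)``.
    """
    v = _check_visible(params, v)
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    pre = v2 @ params.W.T + params.b_hid
    softplus = np.logaddexp(0.0, pre).sum(axis=1)
    if params.visible_family == BERNOULLI:
        out = -(v2 @ params.b_vis) - softplus
    else:
        out = 0.5 * ((v2 - params.b_vis) ** 2).sum(axis=1) - softplus
    return float(out[0]) if single else out


def _all_binary_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n as a (2^n, n) float matrix."""
    idx = np.arange(2 ** n)
    return ((idx[:, None] >> np.arange(n)[::-1]) & 1).astype(float)


def exact_log_partition(params: RBMParameters) -> float:
    """log Z by enumeration of all visible states (Bernoulli only)."""
    if params.visible_family != BERNOULLI:
        raise ValueError("exact partition function requires bernoulli visibles")
    if params.n_visible + params.n_hidden > 20:
        raise ValueError(
            "model too large for exact enumeration (> 20 units); "
            "use reconstruction error as an approximate diagnostic"
        )
    states = _all_binary_states(params.n_visible)
    return float(logsumexp(-free_energy(params, states)))


def exact_log_likelihood(params: RBMParameters, data: np.ndarray) -> float:
    """Exact average log-likelihood of ``data`` under the RBM.

    Computed as ``mean(-F(v)) - log Z`` with the partition sum taken by
    brute-force enumeration; limited to models with at most 20 units.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    log_z = exact_log_partition(params)
    return float(np.mean(-free_energy(params, data)) - log_z)


def exact_loglik_gradient(params: RBMParameters, data: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient of the exact average log-likelihood.

    Returns (dW, db_vis, db_hid) as the data-expected minus
    model-expected sufficient statistics, the quantity CD approximates.
    Bernoulli models only; enumeration over all visible states.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    h_data = hidden_conditional(params, data)
    pos_W = h_data.T @ data / data.shape[0]
    pos_bv = data.mean(axis=0)
    pos_bh = h_data.mean(axis=0)

    states = _all_binary_states(params.n_visible)
    log_p = -free_energy(params, states)
    p = np.exp(log_p - logsumexp(log_p))
    h_model = hidden_conditional(params, states)
    neg_W = (h_model * p[:, None]).T @ states
    neg_bv = p @ states
    neg_bh = p @ h_model
    return pos_W - neg_W, pos_bv - neg_bv, pos_bh - neg_bh
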