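"""Restricted Boltzmann Machines with one-step contrastive divergence.

Two unit types are supported: binary-binary, and Gaussian-Bernoulli for
real-valued (standardized) inputs. With standardized data the visible
standard deviations are fixed at sigma = 1, under which the hidden
conditional coincides with the binary formula and the visible conditional
is Normal(W h + b, 1).

Energies:

    binary     E(v,h) = - v' W h - b' v - a' h
    gaussian   E(v,h) = sum_i (v_i - b_i)^2 / (2 sigma_i^2)
                        - sum_ij W_ij h_j v_i / sigma_i - a' h

CD-1 follows the standard recipe: hidden means from the data, a sampled
hidden state, a mean-field visible reconstruction, hidden means again; the
update is lr * (positive - negative statistics) / batch.

For small binary models (V + H <= 16) the exact log-likelihood gradient and
partition function are computed by enumeration - these are the test oracles
against which CD-1 is validated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

MAX_ENUM_UNITS = 16


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class RBMParams:
    """Weights W (V x H), visible biases b, hidden biases a, and for the
    Gaussian type the visible standard deviations sigma."""

    W: np.ndarray
    b: np.ndarray
    a: np.ndarray
    unit_type: str = "binary"  # "binary" | "gaussian"
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.unit_type not in ("binary", "gaussian"):
            raise ValueError(f"unknown unit_type {self.unit_type!r}")
        V, H = self.W.shape
        if self.b.shape != (V,) or self.a.shape != (H,):
            raise ValueError("bias shapes must match W")
        if self.unit_type == "gaussian":
            if self.sigma is None:
                self.sigma = np.ones(V)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


@dataclass
class TrainSchedule:
    lr: float = 0.01
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def init_rbm(
    n_visible: int,
    n_hidden: int,
    unit_type: str = "binary",
    seed: int = 0,
    weight_scale: float = 0.01,
) -> RBMParams:
    """Seeded N(0, scale^2) weights, zero biases."""
    rng = np.random.default_rng(seed)
    return RBMParams(
        W=weight_scale * rng.standard_normal((n_visible, n_hidden)),
        b=np.zeros(n_visible),
        a=np.zeros(n_hidden),
        unit_type=unit_type,
    )


def energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy of one (v, h) configuration."""
    v, h = np.asarray(v, float), np.asarray(h, float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("configuration shape mismatch")
    if params.unit_type == "binary":
        return float(-v @ params.W @ h - params.b @ v - params.a @ h)
    s = params.sigma
    quad = np.sum((v - params.b) ** 2 / (2.0 * s**2))
    inter = (v / s) @ params.W @ h
    return float(quad - inter - params.a @ h)


def p_h_given_v(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """Hidden Bernoulli means given visible data (row-wise for batches)."""
    v = np.asarray(v, float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    vin = v / params.sigma if params.unit_type == "gaussian" else v
    out = sigmoid(vin @ params.W + params.a)
    return out[0] if single else out


def p_v_given_h(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """Visible conditional parameters given hidden states.

    Binary: Bernoulli means sigmoid(W h + b). Gaussian: the Normal means
    sigma * (W h) + b (std = sigma).
    """
    h = np.asarray(h, float)
    single = h.ndim == 1
    h = np.atleast_2d(h)
    pre = h @ params.W.T
    if params.unit_type == "binary":
        out = sigmoid(pre + params.b)
    else:
        out = params.sigma * pre + params.b
    return out[0] if single else out


def cd1_statistics(
    params: RBMParams, batch: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dW, da, db) estimates of the log-likelihood gradient from CD-1."""
    batch = np.atleast_2d(np.asarray(batch, float))
    if batch.shape[0] == 0:
        raise ValueError("empty minibatch")
    B = batch.shape[0]
    vin = batch / params.sigma if params.unit_type == "gaussian" else batch

    h_mean = sigmoid(vin @ params.W + params.a)
    h_sample = (rng.uniform(size=h_mean.shape) < h_mean).astype(float)

    v_recon = p_v_given_h(params, h_sample)
    v_recon = np.atleast_2d(v_recon)
    vin_recon = v_recon / params.sigma if params.unit_type == "gaussian" else v_recon
    h_recon = sigmoid(vin_recon @ params.W + params.a)

    dW = (vin.T @ h_mean - vin_recon.T @ h_recon) / B
    da = (h_mean - h_recon).mean(axis=0)
    db = (vin - vin_recon).mean(axis=0)
    return dW, da, db


def cd1_step(
    params: RBMParams, batch: np.ndarray, lr: float, rng: np.random.Generator
) -> RBMParams:
    """One CD-1 parameter update; returns a new parameter set."""
    dW, da, db = cd1_statistics(params, batch, rng)
    return replace(
        params,
        W=params.W + lr * dW,
        a=params.a + lr * da,
        b=params.b + lr * db,
    )


# ---------------------------------------------------------------------------
# exact oracles for small binary models


def _check_enumerable(params: RBMParams) -> None:
    if params.unit_type != "binary":
        raise ValueError("exact enumeration requires a binary RBM")
    if params.n_visible + params.n_hidden > MAX_ENUM_UNITS:
        raise ValueError("model too large to enumerate")


def _all_binary(n: int) -> np.ndarray:
    return np.array(list(itertools.product([0.0, 1.0], repeat=n)))


def partition_function(params: RBMParams) -> float:
    """Exact Z by enumerating every (v, h) configuration."""
    _check_enumerable(params)
    vs = _all_binary(params.n_visible)
    hs = _all_binary(params.n_hidden)
    E = -(vs @ params.W @ hs.T) - (vs @ params.b)[:, None] - (hs @ params.a)[None, :]
    return float(np.exp(-E).sum())


def log_likelihood(params: RBMParams, data: np.ndarray) -> float:
    """Exact mean log p(v) over the data rows (enumerable models only)."""
    _check_enumerable(params)
    data = np.atleast_2d(np.asarray(data, float))
    hs = _all_binary(params.n_hidden)
    # unnormalized log p(v) = b'v + log sum_h exp(v'Wh + a'h)
    act = data @ params.W @ hs.T + (hs @ params.a)[None, :]
    m = act.max(axis=1, keepdims=True)
    log_unnorm = (data @ params.b) + (m[:, 0] + np.log(np.exp(act - m).sum(axis=1)))
    return float(log_unnorm.mean() - np.log(partition_function(params)))


def exact_gradient(
    params: RBMParams, data: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact mean log-likelihood gradient (dW, da, db) by enumeration.

    Data term uses the analytic hidden means; the model term sums over the
    exact model distribution of every visible configuration.
    """
    _check_enumerable(params)
    data = np.atleast_2d(np.asarray(data, float))
    h_data = sigmoid(data @ params.W + params.a)
    pos_W = data.T @ h_data / data.shape[0]
    pos_a = h_data.mean(axis=0)
    pos_b = data.mean(axis=0)

    vs = _all_binary(params.n_visible)
    hs = _all_binary(params.n_hidden)
    E = -(vs @ params.W @ hs.T) - (vs @ params.b)[:, None] - (hs @ params.a)[None, :]
    p_joint = np.exp(-E)
    p_joint /= p_joint.sum()
    p_v = p_joint.sum(axis=1)
    h_model = sigmoid(vs @ params.W + params.a)
    neg_W = (vs * p_v[:, None]).T @ h_model
    neg_a = p_v @ h_model
    neg_b = p_v @ vs
    return pos_W - neg_W, pos_a - neg_a, pos_b - neg_b


# ---------------------------------------------------------------------------


def reconstruction_error(params: RBMParams, data: np.ndarray) -> float:
    """Mean squared error of the mean-field one-step reconstruction."""
    data = np.atleast_2d(np.asarray(data, float))
    h = p_h_given_v(params, data)
    v = np.atleast_2d(p_v_given_h(params, np.atleast_2d(h)))
    return float(np.mean((data - v) ** 2))


def train_rbm(
    params: RBMParams, data: np.ndarray, schedule: TrainSchedule
) -> tuple[RBMParams, list[float]]:
    """Mini-batch CD-1 training with per-epoch reconstruction-error log."""
    data = np.atleast_2d(np.asarray(data, float))
    rng = np.random.default_rng(schedule.seed)
    history: list[float] = []
    for _ in range(schedule.epochs):
        order = rng.permutation(data.shape[0])
        for start in range(0, data.shape[0], schedule.batch_size):
            batch = data[order[start : start + schedule.batch_size]]
            params = cd1_step(params, batch, schedule.lr, rng)
        if not (
            np.all(np.isfinite(params.W))
            and np.all(np.isfinite(params.a))
            and np.all(np.isfinite(params.b))
        ):
            raise FloatingPointError("RBM training diverged (non-finite parameters)")
        history.append(reconstruction_error(params, data))
    return params, history
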