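"""Greedy DBN pretraining and the derived DNN over HMM states.

Pretraining stacks RBMs: the first layer is Gaussian-Bernoulli on the
standardized spliced features, upper layers are binary and train on the
previous layer's hidden expectations. When consecutive layer widths allow
it, a new layer is initialized by "unrolling" the previous one (W_k =
W_{k-1}') before its own CD refinement.

The DNN copies the DBN's weights as hidden layers (logistic sigmoid
activations), stacks a randomly initialized softmax output with one unit
per HMM state, and is fine-tuned by minibatch cross-entropy backprop
against forced-alignment state targets. For hybrid decoding the posteriors
are converted to scaled log likelihoods log p(s|x) - kappa log p(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rbm import RBMParams, TrainSchedule, init_rbm, p_h_given_v, sigmoid, train_rbm


@dataclass
class DBN:
    """Stack of RBMs; layer 1 Gaussian-visible, the rest binary."""

    layers: list[RBMParams]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers, self.layers[1:]):
            if lo.n_hidden != hi.n_visible:
                raise ValueError("layer dimensions do not chain")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.layers[0].n_visible] + [l.n_hidden for l in self.layers]


@dataclass
class DNN:
    """Sigmoid-hidden, softmax-output network over HMM states."""

    weights: list[np.ndarray]  # per hidden layer, (fan_in, fan_out)
    biases: list[np.ndarray]
    W_out: np.ndarray  # (H_last, S)
    b_out: np.ndarray  # (S,)

    @property
    def n_states(self) -> int:
        return self.b_out.size

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]


@dataclass
class FinetuneSchedule:
    """Fine-tuning hyperparameters.

    With the fixed small learning rate, held-out frame accuracy sits at
    the majority-state fraction for many epochs while the cross-entropy
    falls steadily, so early stopping watches the held-out cross-entropy;
    the returned parameters are the best-accuracy snapshot.
    """

    lr: float = 0.008
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be >= 0")


def train_dbn(
    data: np.ndarray,
    layer_sizes: list[int],
    schedules: list[TrainSchedule] | TrainSchedule,
) -> DBN:
    """Greedy layerwise pretraining.

    ``layer_sizes`` are the hidden widths; the visible width is the data
    dimension. ``schedules`` may be a single schedule reused for every
    layer or one per layer (the Gaussian bottom layer conventionally gets
    more epochs than the binary layers above it).
    """
    if not layer_sizes:
        raise ValueError("layer_sizes must be nonempty")
    data = np.atleast_2d(np.asarray(data, float))
    if isinstance(schedules, TrainSchedule):
        schedules = [schedules] * len(layer_sizes)
    if len(schedules) != len(layer_sizes):
        raise ValueError("need one schedule per layer")

    layers: list[RBMParams] = []
    cur = data
    for k, (h, sched) in enumerate(zip(layer_sizes, schedules)):
        unit = "gaussian" if k == 0 else "binary"
        params = init_rbm(cur.shape[1], h, unit_type=unit, seed=sched.seed + k)
        if k > 0 and layers[-1].W.T.shape == params.W.shape:
            # unroll: start the new layer from the transpose of the one below
            params.W = layers[-1].W.T.copy()
            params.b = layers[-1].a.copy()
        params, _ = train_rbm(params, cur, sched)
        layers.append(params)
        cur = p_h_given_v(params, cur)  # hidden expectations feed the next layer
    return DBN(layers=layers)


def init_dnn(dbn: DBN, n_states: int, seed: int = 0) -> DNN:
    """Copy DBN weights into a feedforward net, add a random softmax layer."""
    if n_states < 2:
        raise ValueError("need at least 2 output states")
    rng = np.random.default_rng(seed)
    weights = [layer.W.copy() for layer in dbn.layers]
    biases = [layer.a.copy() for layer in dbn.layers]
    H_last = dbn.layers[-1].n_hidden
    return DNN(
        weights=weights,
        biases=biases,
        W_out=0.01 * rng.standard_normal((H_last, n_states)),
        b_out=np.zeros(n_states),
    )


def init_dnn_random(
    input_dim: int, layer_sizes: list[int], n_states: int, seed: int = 0
) -> DNN:
    """Random-init counterpart of the pretrained network (the control arm)."""
    rng = np.random.default_rng(seed)
    dims = [input_dim] + list(layer_sizes)
    weights = [0.01 * rng.standard_normal((a, b)) for a, b in zip(dims, dims[1:])]
    biases = [np.zeros(b) for b in layer_sizes]
    return DNN(
        weights=weights,
        biases=biases,
        W_out=0.01 * rng.standard_normal((layer_sizes[-1], n_states)),
        b_out=np.zeros(n_states),
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_all(dnn: DNN, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """All hidden activations plus output posteriors (for backprop)."""
    acts = []
    cur = X
    for W, b in zip(dnn.weights, dnn.biases):
        cur = sigmoid(cur @ W + b)
        acts.append(cur)
    post = _softmax(cur @ dnn.W_out + dnn.b_out)
    return acts, post


def forward(dnn: DNN, X: np.ndarray) -> np.ndarray:
    """State posteriors p(s|x) for a batch of frames (rows sum to 1)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != dnn.input_dim:
        raise ValueError(f"input width {X.shape[1]} != network input {dnn.input_dim}")
    return _forward_all(dnn, X)[1]


def cross_entropy(dnn: DNN, X: np.ndarray, y: np.ndarray) -> float:
    post = forward(dnn, X)
    return float(-np.mean(np.log(np.maximum(post[np.arange(len(y)), y], 1e-300))))


def gradients(
    dnn: DNN, X: np.ndarray, y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray, np.ndarray]:
    """Mean cross-entropy gradients (dWs, dbs, dW_out, db_out) by backprop."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, int)
    B = X.shape[0]
    acts, post = _forward_all(dnn, X)
    delta = post.copy()
    delta[np.arange(B), y] -= 1.0
    delta /= B
    dW_out = acts[-1].T @ delta
    db_out = delta.sum(axis=0)
    dWs: list[np.ndarray] = [None] * len(dnn.weights)  # type: ignore[list-item]
    dbs: list[np.ndarray] = [None] * len(dnn.biases)  # type: ignore[list-item]
    back = delta @ dnn.W_out.T
    for k in range(len(dnn.weights) - 1, -1, -1):
        a = acts[k]
        dz = back * a * (1.0 - a)
        prev = X if k == 0 else acts[k - 1]
        dWs[k] = prev.T @ dz
        dbs[k] = dz.sum(axis=0)
        back = dz @ dnn.weights[k].T
    return dWs, dbs, dW_out, db_out


def _clone(dnn: DNN) -> DNN:
    return DNN(
        weights=[W.copy() for W in dnn.weights],
        biases=[b.copy() for b in dnn.biases],
        W_out=dnn.W_out.copy(),
        b_out=dnn.b_out.copy(),
    )


def frame_accuracy(dnn: DNN, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.argmax(forward(dnn, X), axis=1) == y))


def finetune(
    dnn: DNN,
    frames: np.ndarray,
    state_labels: np.ndarray,
    schedule: FinetuneSchedule,
) -> tuple[DNN, list[dict]]:
    """Cross-entropy SGD against forced-alignment state targets.

    A seeded ``val_fraction`` frame split is held out; training stops when
    the held-out cross-entropy has not improved for ``patience`` epochs,
    and the parameters with the best held-out frame accuracy are returned
    along with per-epoch logs.
    """
    frames = np.atleast_2d(np.asarray(frames, float))
    y = np.asarray(state_labels, int)
    if y.min() < 0 or y.max() >= dnn.n_states:
        raise ValueError("state label outside [0, n_states)")
    rng = np.random.default_rng(schedule.seed)
    n = frames.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(schedule.val_fraction * n))) if schedule.val_fraction > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, yt = frames[train_idx], y[train_idx]
    Xv, yv = frames[val_idx], y[val_idx]

    model = _clone(dnn)
    best = _clone(model)
    best_acc = -1.0
    best_ce = np.inf
    since_best = 0
    history: list[dict] = []
    for epoch in range(schedule.max_epochs):
        order = rng.permutation(Xt.shape[0])
        for start in range(0, Xt.shape[0], schedule.batch_size):
            idx = order[start : start + schedule.batch_size]
            dWs, dbs, dWo, dbo = gradients(model, Xt[idx], yt[idx])
            for k in range(len(model.weights)):
                model.weights[k] -= schedule.lr * dWs[k]
                model.biases[k] -= schedule.lr * dbs[k]
            model.W_out -= schedule.lr * dWo
            model.b_out -= schedule.lr * dbo
        val_acc = frame_accuracy(model, Xv, yv) if n_val else float("nan")
        val_ce = cross_entropy(model, Xv, yv) if n_val else float("nan")
        # train CE on a fixed subsample: the log stays cheap on large frame sets
        n_ce = min(Xt.shape[0], 2048)
        history.append(
            {
                "epoch": epoch,
                "train_ce": cross_entropy(model, Xt[:n_ce], yt[:n_ce]),
                "val_ce": val_ce,
                "val_acc": val_acc,
            }
        )
        if n_val:
            if val_acc > best_acc:
                best, best_acc = _clone(model), val_acc
            if val_ce < best_ce - 1e-6:
                best_ce, since_best = val_ce, 0
            else:
                since_best += 1
                if since_best >= schedule.patience:
                    break
    return (best if n_val and best_acc >= 0 else model), history


def state_counts(alignments: list, n_states: int) -> np.ndarray:
    """Frame counts per global state over a set of forced alignments."""
    if not alignments:
        raise ValueError("alignments must be nonempty")
    counts = np.zeros(n_states)
    for ali in alignments:
        states = ali.states if hasattr(ali, "states") else np.asarray(ali)
        counts += np.bincount(np.asarray(states, int), minlength=n_states)
    return counts


def estimate_priors(alignments: list, n_states: int, floor: float = 1e-8) -> np.ndarray:
    """State priors from forced-alignment frame counts (floored simplex)."""
    counts = state_counts(alignments, n_states)
    priors = counts / counts.sum()
    priors = np.maximum(priors, floor)
    return priors / priors.sum()


def mask_unseen_states(scores: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Bar states with zero alignment occupancy from hybrid decoding.

    The network has no targets for such states, so its posteriors there
    are untrained residue, and dividing by a floored prior turns that
    residue into a large spurious score. A state (hence a model) that was
    never realized in the training alignments cannot be hypothesized.
    """
    out = np.array(scores, dtype=float, copy=True)
    out[:, np.asarray(counts) == 0] = -np.inf
    return out


def scaled_loglik(
    posteriors: np.ndarray, priors: np.ndarray, kappa: float = 1.0
) -> np.ndarray:
    """Hybrid observation scores: log p(s|x) - kappa log p(s)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return np.log(np.maximum(posteriors, 1e-300)) - kappa * np.log(priors)[None, :]
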