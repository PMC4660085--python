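"""GMM-HMM baseline: left-to-right HMMs with diagonal-covariance GMM
emissions, segmental (Viterbi) training, forced alignment and decoding.

The model set holds three cough HMMs (different state counts, capturing the
variability of cough epochs) and one noncough HMM. Forced alignments from
this baseline provide the per-frame state targets that supervise the DNN;
its free-loop decoder is also the baseline classifier.

Training is hard-assignment EM (segmental k-means): align, re-estimate
Gaussian statistics and transition counts, repeat. Each cough clip is
re-assigned to its best-scoring cough model at every iteration, starting
from random thirds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .features import FeatureMatrix

log = logging.getLogger(__name__)

LOG_ZERO = -np.inf
COUGH_PREFIX = "cough"

#: default topology: three cough models of increasing length + one noncough
DEFAULT_STATE_COUNTS = {"cough1": 4, "cough2": 6, "cough3": 8, "noncough": 3}


def is_cough_model(model_label: str) -> bool:
    return model_label.startswith(COUGH_PREFIX)


@dataclass
class HMMTopology:
    """Left-to-right topology with non-emitting entry (0) and exit (n+1).

    ``log_trans`` is (n_states+2)^2; only entry->first, self-loops,
    state->next and last->exit arcs may be finite.
    """

    model_label: str
    n_states: int
    log_trans: np.ndarray

    @classmethod
    def uniform(cls, model_label: str, n_states: int) -> "HMMTopology":
        n = n_states
        A = np.full((n + 2, n + 2), LOG_ZERO)
        A[0, 1] = 0.0  # entry -> first emitting state
        for s in range(1, n + 1):
            A[s, s] = np.log(0.5)
            A[s, s + 1] = np.log(0.5)  # next state, or exit for the last
        return cls(model_label=model_label, n_states=n, log_trans=A)

    def validate(self) -> None:
        n = self.n_states
        probs = np.exp(self.log_trans)
        for s in range(0, n + 1):
            if not np.isclose(probs[s].sum(), 1.0, atol=1e-8):
                raise ValueError(f"{self.model_label}: row {s} not stochastic")
        legal = np.full_like(probs, False, dtype=bool)
        legal[0, 1] = True
        for s in range(1, n + 1):
            legal[s, s] = legal[s, s + 1] = True
        if np.any(probs[~legal] > 1e-12):
            raise ValueError(f"{self.model_label}: illegal transition mass")


@dataclass
class GMMState:
    """Diagonal-covariance Gaussian mixture emission for one HMM state."""

    weights: np.ndarray  # (M,)
    means: np.ndarray  # (M, D)
    variances: np.ndarray  # (M, D)

    @property
    def n_components(self) -> int:
        return self.weights.size

    def component_loglik(self, X: np.ndarray) -> np.ndarray:
        """(T, M) per-component log densities."""
        diff = X[:, None, :] - self.means[None, :, :]  # T x M x D
        quad = np.sum(diff * diff / self.variances[None], axis=2)
        logdet = np.sum(np.log(2 * np.pi * self.variances), axis=1)  # (M,)
        return -0.5 * (quad + logdet[None, :])

    def loglik(self, X: np.ndarray) -> np.ndarray:
        """(T,) mixture log densities."""
        lc = self.component_loglik(X) + np.log(self.weights)[None, :]
        return logsumexp(lc, axis=1)


@dataclass
class HMMModelSet:
    """The 3+1 model inventory with a global emitting-state index.

    Global ids run over models in order, states in order, so state g of the
    set maps to (model m, within-model state s) via ``state_map``.
    """

    topologies: list[HMMTopology]
    emissions: list[list[GMMState]]  # per model, per emitting state
    var_floor: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = [t.model_label for t in self.topologies]
        if len(set(labels)) != len(labels):
            raise ValueError("model labels must be unique")
        for topo, ems in zip(self.topologies, self.emissions):
            if len(ems) != topo.n_states:
                raise ValueError(f"{topo.model_label}: emissions/states mismatch")

    @property
    def n_global_states(self) -> int:
        return sum(t.n_states for t in self.topologies)

    @property
    def labels(self) -> list[str]:
        return [t.model_label for t in self.topologies]

    def model_index(self, model_label: str) -> int:
        return self.labels.index(model_label)

    def state_map(self) -> list[tuple[int, int]]:
        """global id -> (model index, within-model emitting state 0-based)."""
        out = []
        for m, topo in enumerate(self.topologies):
            out.extend((m, s) for s in range(topo.n_states))
        return out

    def global_offset(self, m: int) -> int:
        return sum(t.n_states for t in self.topologies[:m])

    def emission_loglik(self, X: np.ndarray) -> np.ndarray:
        """(T, S) log densities of every global state on a feature matrix."""
        cols = [st.loglik(X) for ems in self.emissions for st in ems]
        return np.stack(cols, axis=1)


def _features_array(feats) -> np.ndarray:
    return feats.values if isinstance(feats, FeatureMatrix) else np.asarray(feats)


@dataclass
class Alignment:
    """Per-frame global state ids from forced alignment of one clip."""

    clip_id: str
    states: np.ndarray  # (T,) global ids
    model_label: str
    log_score: float


@dataclass
class Transcription:
    """Decoded model-label sequence with frame spans; empty = no valid path."""

    clip_id: str
    segments: list[tuple[str, int, int]]  # (model_label, start_frame, end_frame)
    log_score: float

    def validate(self, n_frames: int) -> None:
        pos = 0
        for _, s, e in self.segments:
            if s != pos or e <= s:
                raise ValueError("segments must be contiguous and non-empty")
            pos = e
        if self.segments and pos != n_frames:
            raise ValueError("segments must cover all frames")


def classify(transcription: Transcription) -> str:
    """Sample-level decision: cough iff any cough model appears; an empty
    (no-valid-path) transcription counts as noncough."""
    for label, _, _ in transcription.segments:
        if is_cough_model(label):
            return "cough"
    return "noncough"


# ---------------------------------------------------------------------------
# initialization and training


def default_topologies(
    state_counts: dict[str, int] | None = None,
) -> list[HMMTopology]:
    counts = state_counts or DEFAULT_STATE_COUNTS
    return [HMMTopology.uniform(lbl, n) for lbl, n in counts.items()]


def _label_for_model(model_label: str) -> str:
    return "cough" if is_cough_model(model_label) else "noncough"


def flat_start(
    features: list,
    labels: list[str],
    topologies: list[HMMTopology] | None = None,
    seed: int = 0,
) -> HMMModelSet:
    """Initialize every model by uniform segmentation of its class's clips.

    Every model sees all clips of its class: the three cough models differ
    in state count, not in data. Within a model, each clip's frames are
    divided into n_states equal contiguous chunks and state s pools chunk
    s across clips - the classic uniform-segmentation start for
    left-to-right models. Initializing all states to identical global
    statistics instead makes the first forced alignment degenerate (every
    tie resolves the same way, transition re-estimation then locks the
    boundary), so temporal differentiation is built in from the start.
    One Gaussian per state. ``seed`` is kept for interface stability; the
    default initialization is deterministic without it.
    """
    topologies = topologies or default_topologies()
    if len(features) != len(labels):
        raise ValueError("features/labels length mismatch")

    arrays = [_features_array(f) for f in features]
    D = arrays[0].shape[1]
    all_var = np.concatenate(arrays).var(axis=0)
    var_floor = np.maximum(1e-3 * all_var, 1e-8)

    by_class: dict[str, list[int]] = {"cough": [], "noncough": []}
    for i, lbl in enumerate(labels):
        by_class[lbl].append(i)

    class_models: dict[str, list[int]] = {"cough": [], "noncough": []}
    for m, topo in enumerate(topologies):
        class_models[_label_for_model(topo.model_label)].append(m)

    assignment: dict[int, list[int]] = {m: [] for m in range(len(topologies))}
    for cls, idxs in by_class.items():
        models = class_models[cls]
        if not models:
            continue
        if not idxs:
            raise ValueError(f"no training data for class {cls!r}")
        for m in models:
            assignment[m] = list(idxs)

    emissions: list[list[GMMState]] = []
    for m, topo in enumerate(topologies):
        idxs = assignment[m]
        if not idxs:
            raise ValueError(f"no training data routed to model {topo.model_label}")
        X = np.concatenate([arrays[i] for i in idxs])
        glob_mean, glob_var = X.mean(axis=0), np.maximum(X.var(axis=0), var_floor)
        chunks: list[list[np.ndarray]] = [[] for _ in range(topo.n_states)]
        for i in idxs:
            for s, part in enumerate(np.array_split(arrays[i], topo.n_states)):
                if part.size:
                    chunks[s].append(part)
        states = []
        for s in range(topo.n_states):
            if chunks[s]:
                Xs = np.concatenate(chunks[s])
                mean = Xs.mean(axis=0)
                var = np.maximum(Xs.var(axis=0), var_floor)
            else:  # clips shorter than the state count: fall back to global
                mean, var = glob_mean, glob_var
            states.append(
                GMMState(
                    weights=np.array([1.0]),
                    means=mean[None, :].copy(),
                    variances=var[None, :].copy(),
                )
            )
        emissions.append(states)
    return HMMModelSet(topologies=topologies, emissions=emissions, var_floor=var_floor)


def _forced_align_single(
    topo: HMMTopology, ems: list[GMMState], X: np.ndarray
) -> tuple[np.ndarray, float]:
    """Viterbi path through one left-to-right model; returns (path, score).

    The path starts in state 0, may only stay or advance, and must end in
    the last state (paying its exit probability).
    """
    T, n = X.shape[0], topo.n_states
    if T < n:
        raise ValueError(f"clip too short: {T} frames < {n} states")
    obs = np.stack([ems[s].loglik(X) for s in range(n)], axis=1)  # T x n
    A = topo.log_trans
    delta = np.full((T, n), LOG_ZERO)
    psi = np.zeros((T, n), dtype=int)
    delta[0, 0] = A[0, 1] + obs[0, 0]
    for t in range(1, T):
        for s in range(n):
            stay = delta[t - 1, s] + A[s + 1, s + 1]
            if s > 0:
                adv = delta[t - 1, s - 1] + A[s, s + 1]
            else:
                adv = LOG_ZERO
            if stay >= adv:
                delta[t, s], psi[t, s] = stay + obs[t, s], s
            else:
                delta[t, s], psi[t, s] = adv + obs[t, s], s - 1
    score = delta[T - 1, n - 1] + A[n, n + 1]  # must exit from the last state
    path = np.empty(T, dtype=int)
    path[T - 1] = n - 1
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, float(score)


def viterbi_align(modelset: HMMModelSet, feats, label: str) -> Alignment:
    """Force-align one clip against its class's model(s).

    Cough clips are aligned against each cough model and the best-scoring
    one wins; noncough clips use the single noncough model.
    """
    X = _features_array(feats)
    clip_id = feats.clip_id if isinstance(feats, FeatureMatrix) else ""
    candidates = [
        m
        for m, topo in enumerate(modelset.topologies)
        if _label_for_model(topo.model_label) == label
    ]
    if not candidates:
        raise ValueError(f"no model for label {label!r}")
    best: tuple[float, int, np.ndarray] | None = None
    for m in candidates:
        topo = modelset.topologies[m]
        if X.shape[0] < topo.n_states:
            continue
        path, score = _forced_align_single(topo, modelset.emissions[m], X)
        if best is None or score > best[0]:
            best = (score, m, path)
    if best is None:
        raise ValueError(f"clip {clip_id!r} too short for every {label} model")
    score, m, path = best
    return Alignment(
        clip_id=clip_id,
        states=modelset.global_offset(m) + path,
        model_label=modelset.topologies[m].model_label,
        log_score=score,
    )


def viterbi_train(
    modelset: HMMModelSet,
    data: list[tuple[object, str]],
    iters: int,
    rel_tol: float = 1e-4,
) -> tuple[HMMModelSet, list[float]]:
    """Segmental k-means training: align then re-estimate, ``iters`` times.

    Every model of a clip's class is updated from its own forced alignment
    of that clip (the three cough models share all cough data, differing
    only in state count). Returns the trained set and the per-iteration
    total aligned log likelihood summed over all model/clip alignments
    (non-decreasing up to numerical tolerance). States that capture no
    frames keep their previous parameters. Stops early when the relative
    improvement falls below ``rel_tol``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    history: list[float] = []
    current = modelset
    for it in range(iters):
        S = current.n_global_states
        total = 0.0
        # per global state, per component accumulation
        frames_per_state: list[list[np.ndarray]] = [[] for _ in range(S)]
        stay_counts = np.zeros(S)
        adv_counts = np.zeros(S)
        for feats, label in data:
            X = _features_array(feats)
            for m, topo in enumerate(current.topologies):
                if _label_for_model(topo.model_label) != label:
                    continue
                if X.shape[0] < topo.n_states:
                    continue
                path, score = _forced_align_single(topo, current.emissions[m], X)
                states = current.global_offset(m) + path
                total += score
                for g in np.unique(states):
                    frames_per_state[g].append(X[states == g])
                stays = states[1:] == states[:-1]
                np.add.at(stay_counts, states[:-1][stays], 1)
                np.add.at(adv_counts, states[:-1][~stays], 1)
                adv_counts[states[-1]] += 1  # final frame exits its state
        history.append(total)

        new_emissions: list[list[GMMState]] = []
        new_topos: list[HMMTopology] = []
        for m, topo in enumerate(current.topologies):
            off = current.global_offset(m)
            states: list[GMMState] = []
            A = topo.log_trans.copy()
            for s in range(topo.n_states):
                g = off + s
                old = current.emissions[m][s]
                chunks = frames_per_state[g]
                if not chunks:
                    log.debug("state %s/%d captured no frames; kept", topo.model_label, s)
                    states.append(old)
                else:
                    Xg = np.concatenate(chunks)
                    states.append(_reestimate_gmm(old, Xg, current.var_floor))
                n_stay, n_adv = stay_counts[g], adv_counts[g]
                tot = n_stay + n_adv
                if tot > 0:
                    p_stay = min(max(n_stay / tot, 1e-3), 1 - 1e-3)
                    A[s + 1, s + 1] = np.log(p_stay)
                    A[s + 1, s + 2] = np.log(1 - p_stay)
            new_topos.append(
                HMMTopology(model_label=topo.model_label, n_states=topo.n_states, log_trans=A)
            )
            new_emissions.append(states)
        current = HMMModelSet(
            topologies=new_topos, emissions=new_emissions, var_floor=current.var_floor
        )
        if it > 0 and history[-2] != 0:
            rel = (history[-1] - history[-2]) / abs(history[-2])
            if rel < rel_tol:
                break
    return current, history


def _reestimate_gmm(
    old: GMMState, X: np.ndarray, var_floor: np.ndarray | None
) -> GMMState:
    """Hard-assignment GMM update: frames go to their best component."""
    M = old.n_components
    if M == 1:
        mean, var = X.mean(axis=0), X.var(axis=0)
        var = np.maximum(var, var_floor if var_floor is not None else 1e-8)
        return GMMState(
            weights=np.array([1.0]), means=mean[None], variances=var[None]
        )
    resp = old.component_loglik(X) + np.log(old.weights)[None]
    comp = np.argmax(resp, axis=1)
    weights = old.weights.copy()
    means = old.means.copy()
    variances = old.variances.copy()
    counts = np.bincount(comp, minlength=M).astype(float)
    for c in range(M):
        if counts[c] < 2:
            continue  # starving component keeps previous parameters
        Xc = X[comp == c]
        means[c] = Xc.mean(axis=0)
        v = Xc.var(axis=0)
        variances[c] = np.maximum(v, var_floor if var_floor is not None else 1e-8)
    weights = np.maximum(counts, 1.0)
    weights = weights / weights.sum()
    return GMMState(weights=weights, means=means, variances=variances)


def split_mixtures(modelset: HMMModelSet, target_m: int) -> HMMModelSet:
    """Grow every state's mixture to ``target_m`` components by splitting.

    The largest-weight component is split by perturbing its mean by
    +-0.2 std; the two halves share its weight. Retraining afterwards is
    the caller's job.
    """
    if target_m < max(st.n_components for ems in modelset.emissions for st in ems):
        raise ValueError("target_m must be >= current component count")
    new_emissions = []
    for ems in modelset.emissions:
        states = []
        for st in ems:
            w, mu, var = st.weights.copy(), st.means.copy(), st.variances.copy()
            while w.size < target_m:
                j = int(np.argmax(w))
                sd = np.sqrt(var[j])
                mu_a, mu_b = mu[j] + 0.2 * sd, mu[j] - 0.2 * sd
                w_half = w[j] / 2.0
                w = np.concatenate([np.delete(w, j), [w_half, w_half]])
                mu = np.vstack([np.delete(mu, j, axis=0), mu_a[None], mu_b[None]])
                var = np.vstack([np.delete(var, j, axis=0), var[j][None], var[j][None]])
            states.append(GMMState(weights=w, means=mu, variances=var))
        new_emissions.append(states)
    return HMMModelSet(
        topologies=[
            HMMTopology(t.model_label, t.n_states, t.log_trans.copy())
            for t in modelset.topologies
        ],
        emissions=new_emissions,
        var_floor=modelset.var_floor,
    )


def decode(modelset: HMMModelSet, feats, acoustic_scale: float = 1.0) -> Transcription:
    """Free-loop Viterbi decoding with GMM emission scores."""
    from .hybrid_decoder import build_graph, decode_hybrid

    X = _features_array(feats)
    clip_id = feats.clip_id if isinstance(feats, FeatureMatrix) else ""
    scores = modelset.emission_loglik(X)
    graph = build_graph(modelset)
    return decode_hybrid(graph, scores, acoustic_scale=acoustic_scale, clip_id=clip_id)


# ---------------------------------------------------------------------------
# persistence (versioned JSON archive)

_FORMAT_VERSION = 1


def save_modelset(modelset: HMMModelSet, path: str | Path) -> None:
    doc = {
        "format": "coughdnn-hmm",
        "version": _FORMAT_VERSION,
        "var_floor": None
        if modelset.var_floor is None
        else modelset.var_floor.tolist(),
        "models": [
            {
                "label": topo.model_label,
                "n_states": topo.n_states,
                "log_trans": topo.log_trans.tolist(),
                "states": [
                    {
                        "weights": st.weights.tolist(),
                        "means": st.means.tolist(),
                        "variances": st.variances.tolist(),
                    }
                    for st in ems
                ],
            }
            for topo, ems in zip(modelset.topologies, modelset.emissions)
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_modelset(path: str | Path) -> HMMModelSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "coughdnn-hmm":
        raise ValueError("not a coughdnn HMM archive")
    topologies, emissions = [], []
    for mdoc in doc["models"]:
        topologies.append(
            HMMTopology(
                model_label=mdoc["label"],
                n_states=mdoc["n_states"],
                log_trans=np.array(mdoc["log_trans"]),
            )
        )
        emissions.append(
            [
                GMMState(
                    weights=np.array(s["weights"]),
                    means=np.array(s["means"]),
                    variances=np.array(s["variances"]),
                )
                for s in mdoc["states"]
            ]
        )
    vf = doc.get("var_floor")
    return HMMModelSet(
        topologies=topologies,
        emissions=emissions,
        var_floor=None if vf is None else np.array(vf),
    )
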