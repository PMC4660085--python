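"""Free-loop Viterbi decoding over the 4-model graph.

The decoding graph composes all HMMs into a loop: from a virtual start the
path enters any model with uniform prior, walks its left-to-right states,
and on exit may re-enter any model. The decoder itself is score-source
agnostic: the same graph is driven by GMM log densities (baseline) or by
DNN scaled log likelihoods (hybrid system); only the T x S score matrix
differs.

Exact Viterbi is used throughout - the composed state space (a few tens of
states) makes beam pruning pointless. Ties are broken toward the lower
global state index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gmm_hmm import LOG_ZERO, HMMModelSet, Transcription


@dataclass
class DecodingGraph:
    """Flattened loop-of-models graph over global emitting states."""

    trans: np.ndarray  # (S, S) log transition probabilities
    entry: np.ndarray  # (S,) log prob of starting in each state
    exit: np.ndarray  # (S,) log prob of ending in each state
    is_cross: np.ndarray  # (S, S) bool: arc crosses a model boundary
    state_labels: list[str]  # model label of each global state

    @property
    def n_states(self) -> int:
        return self.entry.size

    def validate(self) -> None:
        # outgoing transition mass of every emitting state must be 1; rows
        # of 1-state models carry a dominated parallel arc (self-loop vs
        # exit-and-re-enter) of which only the better one is kept, so they
        # may fall short of 1 but never exceed it
        mass = np.exp(self.trans).sum(axis=1)
        from collections import Counter

        label_counts = Counter(self.state_labels)
        dropped = np.array([label_counts[l] == 1 for l in self.state_labels])
        full = ~dropped
        if not np.allclose(mass[full], 1.0, atol=1e-8):
            raise ValueError("outgoing probability mass must sum to 1 per state")
        if np.any(mass > 1.0 + 1e-8):
            raise ValueError("outgoing probability mass exceeds 1")
        reachable = np.isfinite(self.entry)
        for _ in range(self.n_states):
            reachable = reachable | (reachable @ np.isfinite(self.trans))
        if not reachable.all():
            raise ValueError("every emitting state must be reachable from start")


def build_graph(modelset: HMMModelSet) -> DecodingGraph:
    """Compose the model set into one loop graph with uniform model priors.

    Cross-model arcs fold together the exit probability of the source
    model's last state, the uniform model prior, and the target model's
    entry arc.
    """
    n_models = len(modelset.topologies)
    if n_models == 0:
        raise ValueError("empty model set")
    S = modelset.n_global_states
    log_prior = -np.log(n_models)

    trans = np.full((S, S), LOG_ZERO)
    entry = np.full(S, LOG_ZERO)
    exit_ = np.full(S, LOG_ZERO)
    is_cross = np.zeros((S, S), dtype=bool)
    state_labels: list[str] = []

    firsts, lasts, exits = [], [], []
    for m, topo in enumerate(modelset.topologies):
        off = modelset.global_offset(m)
        n = topo.n_states
        A = topo.log_trans
        state_labels.extend([topo.model_label] * n)
        entry[off] = log_prior + A[0, 1]
        for s in range(n):
            g = off + s
            trans[g, g] = A[s + 1, s + 1]
            if s + 1 < n:
                trans[g, off + s + 1] = A[s + 1, s + 2]
        last = off + n - 1
        firsts.append(off)
        lasts.append(last)
        exits.append(A[n, n + 1])
        exit_[last] = A[n, n + 1]  # ending the utterance at model exit

    for last, e in zip(lasts, exits):
        for m_dst, topo in enumerate(modelset.topologies):
            first = firsts[m_dst]
            arc = e + log_prior + topo.log_trans[0, 1]
            # a 1-state model re-entering itself runs parallel to its own
            # self-loop; Viterbi keeps whichever arc scores higher
            if arc > trans[last, first]:
                trans[last, first] = arc
                is_cross[last, first] = True

    return DecodingGraph(
        trans=trans, entry=entry, exit=exit_, is_cross=is_cross, state_labels=state_labels
    )


def decode_hybrid(
    graph: DecodingGraph,
    scores: np.ndarray,
    acoustic_scale: float = 1.0,
    clip_id: str = "",
) -> Transcription:
    """Best path through the graph given a T x S observation score matrix.

    Path score = transition log probs + acoustic_scale x observation
    scores, with the ending state paying its exit probability. When no
    finite-score complete path exists the transcription is empty (decision
    rule downstream: noncough).
    """
    scores = np.asarray(scores, dtype=float)
    T, S = scores.shape
    if S != graph.n_states:
        raise ValueError(f"score matrix has {S} states, graph has {graph.n_states}")
    obs = acoustic_scale * scores

    delta = np.empty((T, S))
    psi = np.zeros((T, S), dtype=int)
    delta[0] = graph.entry + obs[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + graph.trans  # pred x state
        psi[t] = np.argmax(cand, axis=0)  # argmax -> lowest index on ties
        delta[t] = cand[psi[t], np.arange(S)] + obs[t]
    final = delta[T - 1] + graph.exit
    best = int(np.argmax(final))
    if not np.isfinite(final[best]):
        return Transcription(clip_id=clip_id, segments=[], log_score=LOG_ZERO)

    path = np.empty(T, dtype=int)
    path[T - 1] = best
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]

    segments: list[tuple[str, int, int]] = []
    start = 0
    for t in range(1, T):
        if graph.is_cross[path[t - 1], path[t]]:
            segments.append((graph.state_labels[path[start]], start, t))
            start = t
    segments.append((graph.state_labels[path[start]], start, T))
    return Transcription(clip_id=clip_id, segments=segments, log_score=float(final[best]))
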