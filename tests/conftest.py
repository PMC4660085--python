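import numpy as np
import pytest

from coughdnn.synth_corpus import CorpusSpec, generate_corpus, manifest_frame


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small fully-deterministic corpus shared across tests."""
    spec = CorpusSpec(n_cough=12, n_noncough=24, seed=7)
    clips, anns = generate_corpus(spec)
    return spec, clips, anns


@pytest.fixture(scope="session")
def tiny_manifest(tiny_corpus):
    _, clips, anns = tiny_corpus
    return manifest_frame(clips, anns)


def random_left_to_right_modelset(rng, max_models=3, max_states=3, dim=2):
    """Random small model inventory for decoder oracle tests."""
    from coughdnn.gmm_hmm import GMMState, HMMModelSet, HMMTopology

    n_models = int(rng.integers(2, max_models + 1))
    labels = [f"cough{i+1}" for i in range(n_models - 1)] + ["noncough"]
    topologies, emissions = [], []
    total = 0
    for lbl in labels:
        n = int(rng.integers(1, max_states + 1))
        total += n
        topo = HMMTopology.uniform(lbl, n)
        # randomize self-loop probabilities while keeping rows stochastic
        A = topo.log_trans
        for s in range(1, n + 1):
            p = rng.uniform(0.2, 0.8)
            A[s, s] = np.log(p)
            A[s, s + 1] = np.log(1 - p)
        topologies.append(topo)
        emissions.append(
            [
                GMMState(
                    weights=np.array([1.0]),
                    means=rng.normal(size=(1, dim)),
                    variances=rng.uniform(0.5, 2.0, size=(1, dim)),
                )
                for _ in range(n)
            ]
        )
    if total > 6:
        return random_left_to_right_modelset(rng, max_models, max_states, dim)
    return HMMModelSet(topologies=topologies, emissions=emissions)


def brute_force_best_path(graph, scores, acoustic_scale=1.0):
    """Exhaustive enumeration over all legal complete paths.

    Independent of the Viterbi recursion: depth-first expansion over the
    graph's finite arcs, returning (best score, best path) with ties broken
    toward the lexicographically smallest state sequence.
    """
    T, S = scores.shape
    obs = acoustic_scale * scores
    best = [-np.inf, None]

    def extend(state, t, score, path):
        if t == T:
            total = score + graph.exit[state]
            if total > best[0]:
                best[0], best[1] = total, list(path)
            return
        for nxt in range(S):
            a = graph.trans[state, nxt]
            if np.isfinite(a):
                path.append(nxt)
                extend(nxt, t + 1, score + a + obs[t, nxt], path)
                path.pop()

    for s0 in range(S):
        if np.isfinite(graph.entry[s0]):
            extend(s0, 1, graph.entry[s0] + obs[0, s0], [s0])
    return best[0], best[1]
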