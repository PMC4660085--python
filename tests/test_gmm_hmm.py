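"""GMM-HMM baseline: initialization, alignment, training, decoding."""

import numpy as np
import pytest

from coughdnn import gmm_hmm
from coughdnn.gmm_hmm import (
    GMMState,
    HMMModelSet,
    HMMTopology,
    Transcription,
    classify,
    decode,
    default_topologies,
    flat_start,
    load_modelset,
    save_modelset,
    split_mixtures,
    viterbi_align,
    viterbi_train,
)

from conftest import brute_force_best_path, random_left_to_right_modelset


def _single_model(n_states, means, variances=None, label="noncough"):
    topo = HMMTopology.uniform(label, n_states)
    D = len(means[0])
    emissions = [
        GMMState(
            weights=np.array([1.0]),
            means=np.asarray([m], float),
            variances=np.asarray([variances[i] if variances else [1.0] * D], float),
        )
        for i, m in enumerate(means)
    ]
    return HMMModelSet(topologies=[topo], emissions=[emissions])


class TestFlatStart:
    def test_identical_frames_give_shared_mean_and_floored_variance(self):
        v = np.array([1.0, -2.0])
        feats = [np.tile(v, (10, 1)) for _ in range(4)]
        labels = ["cough", "cough", "cough", "noncough"]
        ms = flat_start(feats, labels)
        for ems in ms.emissions:
            for st in ems:
                np.testing.assert_allclose(st.means[0], v)
                np.testing.assert_allclose(st.variances[0], np.maximum(1e-3 * 0.0, 1e-8))

    def test_class_data_routing(self):
        rng = np.random.default_rng(0)
        cough_frames = [rng.normal(5.0, 1.0, size=(20, 2)) for _ in range(6)]
        noncough_frames = [rng.normal(-5.0, 1.0, size=(20, 2)) for _ in range(3)]
        ms = flat_start(
            cough_frames + noncough_frames, ["cough"] * 6 + ["noncough"] * 3
        )
        for topo, ems in zip(ms.topologies, ms.emissions):
            sign = 1.0 if topo.model_label.startswith("cough") else -1.0
            for st in ems:
                assert np.all(sign * st.means[0] > 0)

    def test_output_satisfies_invariants(self):
        rng = np.random.default_rng(1)
        feats = [rng.normal(size=(15, 3)) for _ in range(8)]
        ms = flat_start(feats, ["cough"] * 5 + ["noncough"] * 3)
        for topo in ms.topologies:
            topo.validate()
        assert ms.n_global_states == sum(t.n_states for t in ms.topologies)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            flat_start([np.zeros((5, 2))], ["cough"])


class TestForcedAlignment:
    def test_one_state_model_absorbs_all_frames(self):
        ms = _single_model(1, [[0.0, 0.0]])
        X = np.random.default_rng(0).normal(size=(7, 2))
        ali = viterbi_align(ms, X, "noncough")
        np.testing.assert_array_equal(ali.states, 0)
        assert ali.states.size == 7

    def test_matches_exhaustive_search_on_toy(self):
        """8-frame, 3-state forced alignment equals the max over every
        legal monotone state sequence."""
        ms = _single_model(3, [[-2.0], [0.0], [2.0]])
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 1))
        ali = viterbi_align(ms, X, "noncough")

        topo, ems = ms.topologies[0], ms.emissions[0]
        obs = np.stack([e.loglik(X) for e in ems], axis=1)
        A = topo.log_trans
        best_score, best_path = -np.inf, None

        def walk(t, s, score, path):
            nonlocal best_score, best_path
            if t == 8:
                if s == 2 and score + A[3, 4] > best_score:
                    best_score, best_path = score + A[3, 4], list(path)
                return
            for nxt in (s, s + 1):
                if nxt > 2:
                    continue
                a = A[s + 1, nxt + 1]
                walk(t + 1, nxt, score + a + obs[t, nxt], path + [nxt])

        walk(1, 0, A[0, 1] + obs[0, 0], [0])
        assert ali.log_score == pytest.approx(best_score)
        np.testing.assert_array_equal(ali.states, best_path)

    def test_monotone_topology_legal_path(self):
        ms = _single_model(3, [[-2.0], [0.0], [2.0]])
        X = np.random.default_rng(5).normal(size=(12, 1))
        ali = viterbi_align(ms, X, "noncough")
        steps = np.diff(ali.states)
        assert np.all((steps == 0) | (steps == 1))
        assert ali.states[0] == 0 and ali.states[-1] == 2

    def test_too_short_clip_rejected(self):
        ms = _single_model(3, [[0.0], [0.0], [0.0]])
        with pytest.raises(ValueError):
            viterbi_align(ms, np.zeros((2, 1)), "noncough")


def _simulate_left_to_right(rng, means, n_frames, stay=0.9):
    """Sample frames from a known left-to-right Gaussian HMM (sigma = 1)."""
    states = []
    s = 0
    for _ in range(n_frames):
        states.append(s)
        if s < len(means) - 1 and rng.uniform() > stay:
            s += 1
    return np.array([[rng.normal(means[s], 1.0)] for s in states]), np.array(states)


class TestViterbiTraining:
    def test_recovers_separated_state_means(self):
        """Segmental training on 500 frames from a 2-state HMM with means
        3 sigma apart recovers both means within 0.2."""
        rng = np.random.default_rng(11)
        true_means = [-1.5, 1.5]
        data = []
        for _ in range(10):
            X, _ = _simulate_left_to_right(rng, true_means, 50, stay=0.95)
            data.append((X, "noncough"))
        feats = [x for x, _ in data]
        ms = flat_start(
            feats + [np.zeros((4, 1))],  # dummy cough clip to satisfy routing
            ["noncough"] * 10 + ["cough"],
            topologies=[HMMTopology.uniform("noncough", 2), HMMTopology.uniform("cough1", 1)],
        )
        trained, hist = viterbi_train(ms, data, iters=10)
        m = trained.model_index("noncough")
        learned = sorted(st.means[0, 0] for st in trained.emissions[m])
        assert abs(learned[0] - true_means[0]) < 0.2
        assert abs(learned[1] - true_means[1]) < 0.2

    def test_aligned_likelihood_non_decreasing(self):
        rng = np.random.default_rng(2)
        data = [(rng.normal(size=(20, 2)), "noncough") for _ in range(4)] + [
            (rng.normal(3.0, 1.0, size=(20, 2)), "cough") for _ in range(4)
        ]
        ms = flat_start([x for x, _ in data], [l for _, l in data], seed=1)
        _, hist = viterbi_train(ms, data, iters=6, rel_tol=-1.0)
        diffs = np.diff(hist)
        assert np.all(diffs >= -1e-6 * np.abs(np.array(hist[:-1])))

    def test_transitions_remain_row_stochastic(self):
        rng = np.random.default_rng(4)
        data = [(rng.normal(size=(20, 2)), "noncough") for _ in range(4)] + [
            (rng.normal(3.0, 1.0, size=(20, 2)), "cough") for _ in range(4)
        ]
        ms = flat_start([x for x, _ in data], [l for _, l in data])
        trained, _ = viterbi_train(ms, data, iters=3)
        for topo in trained.topologies:
            topo.validate()

    def test_zero_iters_rejected(self):
        ms = _single_model(1, [[0.0]])
        with pytest.raises(ValueError):
            viterbi_train(ms, [(np.zeros((3, 1)), "noncough")], iters=0)


class TestSplitMixtures:
    def test_weights_renormalize(self):
        ms = _single_model(2, [[0.0, 0.0], [1.0, 1.0]])
        grown = split_mixtures(ms, 2)
        for st in grown.emissions[0]:
            assert st.n_components == 2
            assert st.weights.sum() == pytest.approx(1.0)

    def test_equal_target_is_identity(self):
        ms = _single_model(1, [[0.5, -0.5]])
        same = split_mixtures(ms, 1)
        np.testing.assert_array_equal(
            same.emissions[0][0].means, ms.emissions[0][0].means
        )

    def test_likelihood_not_hurt_after_retraining_on_bimodal_toy(self):
        """Splitting to 2 components then retraining on clearly bimodal
        1-D data never lowers the per-frame likelihood."""
        rng = np.random.default_rng(8)
        chunks = [
            np.concatenate(
                [rng.normal(-2.0, 0.3, size=25), rng.normal(2.0, 0.3, size=25)]
            )[:, None]
            for _ in range(4)
        ]
        data = [(c, "noncough") for c in chunks]
        ms = flat_start(
            chunks + [np.zeros((2, 1))],
            ["noncough"] * 4 + ["cough"],
            topologies=[HMMTopology.uniform("noncough", 1), HMMTopology.uniform("cough1", 1)],
        )
        ms, _ = viterbi_train(ms, data, iters=2)
        m = ms.model_index("noncough")
        X = np.vstack(chunks)
        before = ms.emissions[m][0].loglik(X).mean()
        grown = split_mixtures(ms, 2)
        grown, _ = viterbi_train(grown, data, iters=4)
        after = grown.emissions[grown.model_index("noncough")][0].loglik(X).mean()
        assert after >= before - 1e-9


class TestDecodeAndClassify:
    def test_single_one_state_model_spans_everything(self):
        ms = _single_model(1, [[0.0, 0.0]])
        X = np.random.default_rng(0).normal(size=(9, 2))
        tr = decode(ms, X)
        assert tr.segments == [("noncough", 0, 9)]

    def test_matches_brute_force_on_fixed_toy(self):
        from coughdnn.hybrid_decoder import build_graph

        rng = np.random.default_rng(42)
        ms = random_left_to_right_modelset(rng)
        T = 6
        X = rng.normal(size=(T, 2))
        tr = decode(ms, X)
        graph = build_graph(ms)
        scores = ms.emission_loglik(X)
        best_score, _ = brute_force_best_path(graph, scores)
        assert tr.log_score == pytest.approx(best_score)

    def test_classification_decision_rule(self):
        cough_mid = Transcription("x", [("noncough", 0, 3), ("cough1", 3, 8), ("noncough", 8, 10)], -1.0)
        assert classify(cough_mid) == "cough"
        assert classify(Transcription("x", [("noncough", 0, 10)], -1.0)) == "noncough"
        assert classify(Transcription("x", [], -np.inf)) == "noncough"

    def test_baseline_accuracy_on_synthetic_corpus(self, tiny_corpus, tiny_manifest):
        """Train-set sanity bound: the GMM-HMM baseline classifies >= 90%
        of the corpus it was trained on."""
        from coughdnn import features as F

        _, clips, _ = tiny_corpus
        feats = {c.id: F.mfcc(c) for c in clips}
        labels = dict(zip(tiny_manifest["clip_id"], tiny_manifest["label"]))
        ids = list(feats)
        ms = flat_start([feats[i] for i in ids], [labels[i] for i in ids], seed=0)
        ms, _ = viterbi_train(ms, [(feats[i], labels[i]) for i in ids], iters=4)
        preds = [classify(decode(ms, feats[i])) for i in ids]
        acc = np.mean([p == labels[i] for p, i in zip(preds, ids)])
        assert acc >= 0.90


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        ms = random_left_to_right_modelset(rng)
        path = tmp_path / "model.json"
        save_modelset(ms, path)
        back = load_modelset(path)
        assert back.labels == ms.labels
        X = rng.normal(size=(5, 2))
        np.testing.assert_allclose(back.emission_loglik(X), ms.emission_loglik(X))

    def test_default_topology_inventory(self):
        topos = default_topologies()
        assert [t.n_states for t in topos] == [4, 6, 8, 3]
        assert sum(t.model_label.startswith("cough") for t in topos) == 3
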