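"""Collapsed Gibbs conditionals, sweeps, estimation, train/predict."""

import numpy as np
import pytest

from pftp import (
    BagOfWordsCorpus,
    ConfigurationError,
    Hyperparameters,
    LabelMatrix,
    LabelSpace,
    SamplingSchedule,
    Vocabulary,
    binarize,
    estimate_from_state,
    make_partition,
    predict,
    train,
    training_conditional,
)
from pftp.inference import (
    PredictionMatrix,
    expand_tokens,
    gibbs_sweep,
    init_state,
)

from conftest import make_tiny_instance
from oracles import oracle_conditional


def _remove_token(state, t):
    d, w = int(state.doc_of[t]), int(state.word_of[t])
    l, k = int(state.label_of[t]), int(state.topic_of[t])
    state.N_dl[d, l] -= 1
    state.N_lk[l, k] -= 1
    state.N_kw[k, w] -= 1
    return d, w


class TestSchedule:
    def test_retained_count(self):
        s = SamplingSchedule(2000, 1000, 50)
        assert s.n_retained == 20
        assert s.retained_sweeps()[0] == 1050
        assert s.retained_sweeps()[-1] == 2000

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            SamplingSchedule(100, 100, 10)
        with pytest.raises(ConfigurationError):
            SamplingSchedule(100, 10, 0)


class TestInitState:
    def test_support_restriction(self, rng):
        inst = make_tiny_instance(rng, n_docs=1, n_labels=1, m=1, W=2)
        state = init_state(inst.corpus, inst.labels, inst.partition, rng)
        owner = inst.partition.label_of_topic()
        assert np.array_equal(owner[state.topic_of], state.label_of)
        state.validate(inst.labels)

    def test_seed_determinism(self, rng):
        inst = make_tiny_instance(rng, n_docs=3, n_labels=2, m=2, W=3)
        s1 = init_state(inst.corpus, inst.labels, inst.partition,
                        np.random.default_rng(5))
        s2 = init_state(inst.corpus, inst.labels, inst.partition,
                        np.random.default_rng(5))
        assert np.array_equal(s1.label_of, s2.label_of)
        assert np.array_equal(s1.topic_of, s2.topic_of)

    def test_uniform_label_split_binomial(self):
        # 10^4 tokens, two equally admissible labels: the label-1
        # fraction must sit within 5 sigma of 1/2.
        n = 10_000
        vocab = Vocabulary(("AA",))
        corpus = BagOfWordsCorpus(vocab, ("P0",), np.array([[n]]))
        space = LabelSpace(("l1",), background=True)
        labels = LabelMatrix(space, np.array([[1, 1]], dtype=np.uint8))
        part = make_partition(1, 1, 1)
        state = init_state(corpus, labels, part, np.random.default_rng(11))
        frac = (state.label_of == 0).mean()
        sigma = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) < 5 * sigma


class TestTrainingConditional:
    def test_symmetric_prior_zero_counts_uniform(self, rng):
        # With all counts zero and symmetric priors the conditional is
        # uniform over active labels (each label's mass spread over its
        # own subset); with equal subset sizes that is uniform over all
        # admissible (l, k) pairs.
        inst = make_tiny_instance(rng, n_docs=1, n_labels=2, m=2,
                                  background_topics=2, W=3)
        state = init_state(inst.corpus, inst.labels, inst.partition, rng)
        state.N_dl[:] = 0
        state.N_lk[:] = 0
        state.N_kw[:] = 0
        pairs, probs = training_conditional(
            state, 0, 0, Hyperparameters(0.7, 0.3, 1.1), inst.partition,
            inst.labels,
        )
        n_cand = sum(
            len(inst.partition.subset_of(int(l)))
            for l in inst.labels.active_labels(0)
        )
        assert len(pairs) == n_cand
        np.testing.assert_allclose(probs, np.full(n_cand, 1.0 / n_cand))
        # label marginals are uniform even with unequal subset sizes
        inst2 = make_tiny_instance(rng, n_docs=1, n_labels=2, m=2,
                                   background_topics=1, W=3)
        state2 = init_state(inst2.corpus, inst2.labels, inst2.partition, rng)
        state2.N_dl[:] = 0
        state2.N_lk[:] = 0
        state2.N_kw[:] = 0
        pairs2, probs2 = training_conditional(
            state2, 0, 0, Hyperparameters(0.7, 0.3, 1.1), inst2.partition,
            inst2.labels,
        )
        active = inst2.labels.active_labels(0)
        marg = {int(l): 0.0 for l in active}
        for (l, _), p in zip(pairs2, probs2):
            marg[l] += p
        np.testing.assert_allclose(
            list(marg.values()), 1.0 / len(active), atol=1e-12
        )

    def test_inadmissible_label_has_zero_probability(self, rng):
        inst = make_tiny_instance(rng, n_docs=2, n_labels=2, m=1, W=3)
        # force doc 0 to have only label 0 active (plus background)
        inst.labels.rows[0, :2] = [1, 0]
        state = init_state(inst.corpus, inst.labels, inst.partition, rng)
        d, w = _remove_token(state, 0)
        assert d == 0
        pairs, _ = training_conditional(
            state, d, w, inst.hyper, inst.partition, inst.labels
        )
        assert all(l != 1 for l, _ in pairs)

    @pytest.mark.parametrize("m", [1, 2])
    def test_matches_collapsed_joint_oracle(self, rng, m):
        # core correctness check: conditional == joint evaluated at every
        # candidate completion and normalized, to < 1e-12
        for trial in range(20):
            inst = make_tiny_instance(
                rng, n_docs=2, n_labels=2, m=m, W=3, max_tokens_per_doc=3
            )
            state = init_state(inst.corpus, inst.labels, inst.partition, rng)
            doc_of, word_of = expand_tokens(inst.corpus)
            t = int(rng.integers(0, state.n_tokens))
            la, za = state.label_of.copy(), state.topic_of.copy()
            d, w = _remove_token(state, t)
            pairs, probs = training_conditional(
                state, d, w, inst.hyper, inst.partition, inst.labels
            )
            o_pairs, o_probs = oracle_conditional(
                doc_of, word_of, la, za, t, inst.labels.rows, inst.subsets,
                inst.hyper.alpha, inst.hyper.beta, inst.hyper.lam, 3,
            )
            assert pairs == o_pairs
            assert np.max(np.abs(probs - o_probs)) < 1e-12


class TestSweep:
    def test_conservation_and_bookkeeping(self, rng):
        inst = make_tiny_instance(rng, n_docs=3, n_labels=3, m=2, W=4,
                                  max_tokens_per_doc=5)
        state = init_state(inst.corpus, inst.labels, inst.partition, rng)
        total = state.n_tokens
        for _ in range(10):
            gibbs_sweep(state, inst.hyper, inst.partition, inst.labels, rng)
        assert state.n_tokens == total
        assert state.N_d.sum() == state.N_l.sum() == state.N_k.sum() == total
        state.validate(inst.labels)


class TestEstimates:
    def test_all_zero_counts_give_uniform_distributions(self, rng):
        inst = make_tiny_instance(rng, n_docs=2, n_labels=2, m=2, W=3)
        state = init_state(inst.corpus, inst.labels, inst.partition, rng)
        state.N_dl[:] = 0
        state.N_lk[:] = 0
        state.N_kw[:] = 0
        est = estimate_from_state(state, inst.hyper, inst.partition, inst.labels)
        for l in range(inst.partition.n_extended):
            sub = list(inst.partition.subset_of(l))
            np.testing.assert_allclose(est.pi[l, sub], 1.0 / len(sub))
        np.testing.assert_allclose(est.theta, 1.0 / 3)
        for d in range(2):
            active = inst.labels.active_labels(d)
            np.testing.assert_allclose(
                est.psi_train[d, active], 1.0 / active.size
            )

    def test_single_token_posterior_mean(self):
        # one token assigned (label 0, its first topic, word 0) with
        # alpha=beta=lam=1: pi_{l0,k0} = (1+1)/(K_l + 1)
        part = make_partition(2, 2, 1)  # K_l = 2
        vocab = Vocabulary(("AA", "CC"))
        corpus = BagOfWordsCorpus(vocab, ("P0",), np.array([[1, 0]]))
        space = LabelSpace(("l1", "l2"))
        labels = LabelMatrix(space, np.array([[1, 0, 1]], dtype=np.uint8))
        state = init_state(corpus, labels, part, np.random.default_rng(0))
        k0 = part.subset_of(0)[0]
        state.label_of[0] = 0
        state.topic_of[0] = k0
        state.N_dl, state.N_lk, state.N_kw = state.recount()
        est = estimate_from_state(
            state, Hyperparameters(1.0, 1.0, 1.0), part, labels
        )
        assert est.pi[0, k0] == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_normalization(self, rng):
        inst = make_tiny_instance(rng, n_docs=3, n_labels=2, m=2, W=4,
                                  max_tokens_per_doc=4)
        state = init_state(inst.corpus, inst.labels, inst.partition, rng)
        est = estimate_from_state(state, inst.hyper, inst.partition, inst.labels)
        np.testing.assert_allclose(est.pi.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(est.theta.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(est.psi_train.sum(axis=1), 1.0, atol=1e-12)


class TestTrain:
    def test_strong_signal_recovers_topic_words(self):
        # label-1 documents contain only "AA", label-2 documents only
        # "CC"; each label's single topic must load >= 0.9 on its word.
        vocab = Vocabulary(("AA", "CC"))
        D = 20
        counts = np.zeros((D, 2), dtype=np.int64)
        rows = np.zeros((D, 3), dtype=np.uint8)
        for d in range(D):
            if d % 2 == 0:
                counts[d, 0] = 200
                rows[d] = [1, 0, 1]
            else:
                counts[d, 1] = 200
                rows[d] = [0, 1, 1]
        corpus = BagOfWordsCorpus(
            vocab, tuple(f"P{d}" for d in range(D)), counts
        )
        space = LabelSpace(("l1", "l2"))
        labels = LabelMatrix(space, rows)
        part = make_partition(2, 1, 1)
        hyper = Hyperparameters(alpha=50.0 / 3, beta=0.01, lam=200.0 / 2)
        res = train(corpus, labels, part, hyper,
                    SamplingSchedule(200, 100, 10, 1, 42))
        k1 = part.subset_of(0)[0]
        k2 = part.subset_of(1)[0]
        assert res.estimate.theta[k1, 0] >= 0.9
        assert res.estimate.theta[k2, 1] >= 0.9

    def test_same_seed_bitwise_identical(self, rng):
        inst = make_tiny_instance(rng, n_docs=4, n_labels=2, m=2, W=3,
                                  max_tokens_per_doc=5)
        sched = SamplingSchedule(50, 20, 10, 1, 9)
        r1 = train(inst.corpus, inst.labels, inst.partition, inst.hyper, sched)
        r2 = train(inst.corpus, inst.labels, inst.partition, inst.hyper, sched)
        assert np.array_equal(r1.estimate.pi, r2.estimate.pi)
        assert np.array_equal(r1.estimate.theta, r2.estimate.theta)
        assert np.array_equal(r1.estimate.psi_train, r2.estimate.psi_train)

    def test_log_joint_trace_recorded(self, rng):
        inst = make_tiny_instance(rng, n_docs=2, n_labels=2, m=1, W=3)
        res = train(inst.corpus, inst.labels, inst.partition, inst.hyper,
                    SamplingSchedule(100, 50, 25, 1, 1))
        sweeps = [s for s, _ in res.log_joint_trace]
        assert 100 in sweeps
        assert all(np.isfinite(v) for _, v in res.log_joint_trace)


class TestPredict:
    def test_degenerate_model_concentrates_on_true_label(self):
        # pi and theta degenerate on label 1's topic and word "AA": a
        # 100-token document of "AA" must score label 1 >= 0.95.
        part = make_partition(2, 1, 1)
        space = LabelSpace(("l1", "l2"))
        Lp, K, W = 3, 3, 2
        pi = np.zeros((Lp, K))
        for l in range(Lp):
            pi[l, part.subset_of(l)[0]] = 1.0
        theta = np.full((K, W), 1e-9)
        theta[part.subset_of(0)[0], 0] = 1.0  # label-1 topic -> word AA
        theta[part.subset_of(1)[0], 1] = 1.0
        theta[part.subset_of(2)[0], :] = 0.5
        theta /= theta.sum(axis=1, keepdims=True)
        from pftp.inference import ModelEstimate

        model = ModelEstimate(pi, theta, np.zeros((0, Lp)), part,
                              Hyperparameters(0.5, 0.01, 0.1))
        vocab = Vocabulary(("AA", "CC"))
        corpus = BagOfWordsCorpus(vocab, ("new",), np.array([[100, 0]]))
        pred = predict(corpus, model, SamplingSchedule(200, 100, 10, 1, 3),
                       space.labels)
        assert pred.scores[0, 0] >= 0.95

    def test_empty_document_prior_scores_flagged(self):
        part = make_partition(2, 1, 1)
        space = LabelSpace(("l1", "l2"))
        pi = np.zeros((3, 3))
        for l in range(3):
            pi[l, part.subset_of(l)[0]] = 1.0
        theta = np.full((3, 2), 0.5)
        from pftp.inference import ModelEstimate

        model = ModelEstimate(pi, theta, np.zeros((0, 3)), part,
                              Hyperparameters(0.5, 0.5, 0.1))
        vocab = Vocabulary(("AA", "CC"))
        corpus = BagOfWordsCorpus(vocab, ("empty",), np.array([[0, 0]]))
        pred = predict(corpus, model, SamplingSchedule(20, 10, 5, 1, 3),
                       space.labels)
        assert pred.empty_docs[0]
        # prior-only: psi uniform over the 3 extended labels
        np.testing.assert_allclose(pred.scores[0], 0.5, atol=1e-12)
        np.testing.assert_allclose(pred.background[0], 1.0 / 3, atol=1e-12)

    def test_scores_renormalized(self, rng):
        inst = make_tiny_instance(rng, n_docs=3, n_labels=2, m=2, W=3,
                                  max_tokens_per_doc=5)
        res = train(inst.corpus, inst.labels, inst.partition, inst.hyper,
                    SamplingSchedule(40, 20, 10, 1, 2))
        pred = predict(inst.corpus, res.estimate,
                       SamplingSchedule(40, 20, 10, 1, 2),
                       inst.labels.space.labels)
        np.testing.assert_allclose(pred.scores.sum(axis=1), 1.0, atol=1e-12)


class TestBinarize:
    def _pred(self, scores):
        L = scores.shape[1]
        return PredictionMatrix(
            doc_ids=tuple(f"P{i}" for i in range(scores.shape[0])),
            label_ids=tuple(f"l{j + 1}" for j in range(L)),
            scores=scores,
            background=np.zeros(scores.shape[0]),
            empty_docs=np.zeros(scores.shape[0], dtype=bool),
        )

    def test_above_threshold_predicted(self):
        pred = self._pred(np.array([[0.6, 0.3, 0.1]]))
        assert binarize(pred, 1.0 / 3) == [{"l1"}]

    def test_zero_threshold_predicts_everything(self):
        pred = self._pred(np.array([[0.6, 0.3, 0.1]]))
        assert binarize(pred, 0.0) == [{"l1", "l2", "l3"}]

    def test_uniform_scores_at_default_threshold_all_included(self):
        pred = self._pred(np.full((1, 4), 0.25))
        assert binarize(pred) == [{"l1", "l2", "l3", "l4"}]
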