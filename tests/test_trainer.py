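"""Loss terms, perplexity weighting, samplers and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p3msda.containers import EpochSet
from p3msda.errors import ConfigurationError
from p3msda.network import ModelConfig
from p3msda.trainer import (LossBundle, TrainConfig,
                            balanced_source_sample, classifier_weights,
                            domain_adv_loss, ensemble_predict,
                            perplexity_scores, predict, select_target_pool,
                            source_class_loss, target_pseudo_loss,
                            total_loss, train_p3msda)
from conftest import make_subject

LN2 = np.log(2.0)


def uniform_probs(k):
    return np.full((k, 2), 0.5)


def loop_cross_entropy(p, y):
    """Independent scalar-loop oracle for one-hot cross-entropy sums."""
    total = 0.0
    for k in range(len(y)):
        total -= np.log(max(p[k][int(y[k])], 1e-12))
    return total


class TestLossClosedForms:
    def test_certain_correct_discriminator_loss_near_zero(self):
        p_src = np.tile([1.0, 0.0], (10, 1))
        p_tgt = np.tile([0.0, 1.0], (10, 1))
        assert domain_adv_loss(p_src, p_tgt) <= 20 * 1e-11

    def test_uniform_discriminator_single_pair_is_2ln2(self):
        assert domain_adv_loss(uniform_probs(1), uniform_probs(1)) == \
            pytest.approx(2 * LN2, abs=1e-12)

    @pytest.mark.parametrize("K", [1, 5, 20])
    def test_uniform_discriminator_batch_scales_linearly(self, K):
        assert domain_adv_loss(uniform_probs(K), uniform_probs(K)) == \
            pytest.approx(2 * K * LN2, abs=1e-9)

    def test_uniform_classifier_batch_20_is_20ln2(self):
        y = np.zeros(20, dtype=int)
        assert source_class_loss(uniform_probs(20), y) == \
            pytest.approx(20 * LN2, abs=1e-9)

    def test_single_sample_quarter_prob_is_ln4(self):
        p = np.array([[0.25, 0.75]])
        assert source_class_loss(p, [0]) == pytest.approx(np.log(4.0),
                                                          abs=1e-12)

    def test_perfect_pseudo_predictions_near_zero(self):
        p = np.tile([0.0, 1.0], (5, 1))
        assert target_pseudo_loss(p, np.ones(5, dtype=int)) <= 5e-11

    def test_pseudo_loss_all_one_class_uniform_is_20ln2(self):
        assert target_pseudo_loss(uniform_probs(20),
                                  np.ones(20, dtype=int)) == \
            pytest.approx(20 * LN2, abs=1e-9)

    def test_losses_match_scalar_loop_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 30))
            p = rng.dirichlet([1, 1], size=k)
            y = rng.integers(0, 2, size=k)
            assert source_class_loss(p, y) == pytest.approx(
                loop_cross_entropy(p, y), abs=1e-6)
            q = rng.dirichlet([1, 1], size=k)
            expected = (loop_cross_entropy(p, np.zeros(k, dtype=int))
                        + loop_cross_entropy(q, np.ones(k, dtype=int)))
            assert domain_adv_loss(p, q) == pytest.approx(expected,
                                                          abs=1e-6)


class TestPerplexityAndWeights:
    def test_half_confident_discriminator_scores_ln2(self):
        pw = perplexity_scores(np.full((1, 8), 0.5), np.zeros(1))
        assert pw.p_s[0] == pytest.approx(LN2, abs=1e-12)

    def test_zero_confidence_reduces_to_mean_loss(self):
        pw = perplexity_scores(np.zeros((1, 8)), np.array([0.3]))
        assert pw.p_s[0] == pytest.approx(0.3, abs=1e-12)

    def test_score_monotone_in_discriminator_output(self, rng):
        d = rng.uniform(0.1, 0.8, size=(1, 10))
        lo = perplexity_scores(d, np.zeros(1)).p_s[0]
        hi = perplexity_scores(d + 0.1, np.zeros(1)).p_s[0]
        assert hi > lo

    @pytest.mark.parametrize("p_s, expected", [
        ([2.0, 2.0], [0.5, 0.5]),
        ([1.0, 3.0], [0.25, 0.75]),
    ])
    def test_weight_normalization(self, p_s, expected):
        np.testing.assert_allclose(classifier_weights(np.array(p_s)),
                                   expected, atol=1e-12)

    def test_weights_live_on_simplex(self, rng):
        for _ in range(200):
            p_s = rng.uniform(0, 5, size=rng.integers(1, 8))
            w = classifier_weights(p_s)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_scores_fall_back_to_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            w = classifier_weights(np.zeros(4))
        np.testing.assert_allclose(w, 0.25)


class TestEnsemblePredict:
    def test_single_classifier_passthrough(self):
        st_ = ensemble_predict(np.array([1.0]), np.array([[0.8]]))
        assert st_.p_hat[0] == pytest.approx(0.8)
        assert st_.pseudo_labels[0] == 1

    def test_two_classifier_arithmetic(self):
        st_ = ensemble_predict(np.array([0.5, 0.5]),
                               np.array([[0.8], [0.6]]))
        # literal (1/N)-scaled value vs the thresholded weighted mean
        assert st_.p_hat[0] == pytest.approx(0.35)
        assert st_.weighted[0] == pytest.approx(0.7)
        assert st_.pseudo_labels[0] == 1

    def test_identical_classifiers_preserve_single_ranking(self, rng):
        p = rng.uniform(size=12)
        single = ensemble_predict(np.array([1.0]), p[None]).ranking
        double = ensemble_predict(np.array([0.5, 0.5]),
                                  np.stack([p, p])).ranking
        np.testing.assert_array_equal(single, double)

    def test_ranking_is_descending_with_stable_ties(self):
        p = np.array([[0.5, 0.9, 0.5, 0.1]])
        st_ = ensemble_predict(np.array([1.0]), p)
        np.testing.assert_array_equal(st_.ranking, [1, 0, 2, 3])


class TestSamplers:
    def make_imbalanced(self, n_dev=100, n_std=430):
        n = n_dev + n_std
        labels = np.zeros(n, dtype=int)
        labels[:n_dev] = 1
        trials = np.arange(n, dtype=float)[:, None, None] * np.ones((1, 2, 5))
        return EpochSet(trials=trials, labels=labels, fs=100.0,
                        subject_id="s")

    def test_balanced_sample_exact_counts(self, rng):
        out = balanced_source_sample(self.make_imbalanced(), rng)
        assert out.n_trials == 200
        assert int(out.labels.sum()) == 100

    def test_already_balanced_fully_kept(self, rng):
        out = balanced_source_sample(self.make_imbalanced(50, 50), rng)
        assert out.n_trials == 100

    def test_fewer_standards_takes_all(self, rng):
        with pytest.warns(UserWarning, match="fewer standards"):
            out = balanced_source_sample(self.make_imbalanced(60, 30), rng)
        assert out.n_trials == 90

    def test_seeded_subset_reproducible(self):
        ep = self.make_imbalanced()
        a = balanced_source_sample(ep, np.random.default_rng(3))
        b = balanced_source_sample(ep, np.random.default_rng(3))
        np.testing.assert_array_equal(a.trials, b.trials)

    def test_top_q_pool_selection(self):
        p = np.array([0.9, 0.2, 0.8, 0.1, 0.5])
        st_ = ensemble_predict(np.array([1.0]), p[None])
        np.testing.assert_array_equal(select_target_pool(st_, 0.8),
                                      [0, 2, 4, 1])

    def test_q_one_returns_everything(self):
        st_ = ensemble_predict(np.array([1.0]),
                               np.array([[0.3, 0.1, 0.9]]))
        assert len(select_target_pool(st_, 1.0)) == 3

    def test_all_equal_probabilities_keep_original_order(self):
        st_ = ensemble_predict(np.array([1.0]), np.full((1, 5), 0.4))
        np.testing.assert_array_equal(select_target_pool(st_, 0.8),
                                      [0, 1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_pool_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        p = rng.uniform(size=n)
        q = float(rng.uniform(0.05, 1.0))
        base = select_target_pool(ensemble_predict(np.ones(1), p[None]), q)
        for f in (lambda x: 2 * x + 1, lambda x: x ** 3,
                  lambda x: np.tanh(3 * x)):
            alt = select_target_pool(
                ensemble_predict(np.ones(1), f(p)[None]), q)
            np.testing.assert_array_equal(alt, base)
        assert len(base) == int(np.ceil(q * n))


class TestTotalLoss:
    def test_weighted_sum_arithmetic(self):
        bundle = LossBundle(adv=np.ones(2), cls_src=np.ones(2),
                            cls_tgt=np.ones(2))
        cfg = TrainConfig()
        assert total_loss(bundle, cfg) == pytest.approx(2.4)

    def test_zero_losses_give_zero(self):
        bundle = LossBundle(adv=np.zeros(3), cls_src=np.zeros(3),
                            cls_tgt=np.zeros(3))
        assert total_loss(bundle, TrainConfig()) == 0.0

    def test_lambda_zero_removes_target_term(self):
        bundle = LossBundle(adv=np.ones(1), cls_src=np.ones(1),
                            cls_tgt=np.full(1, 100.0))
        cfg = TrainConfig(lam=0.0)
        assert total_loss(bundle, cfg) == pytest.approx(1.0)


class TestTrainConfig:
    @pytest.mark.parametrize("kwargs", [
        {"K": 15}, {"K": 0}, {"Q": 0.0}, {"Q": 1.5}, {"alpha": -0.1},
        {"epochs": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            TrainConfig(**kwargs)


@pytest.fixture(scope="module")
def tiny_problem():
    sources = [make_subject(f"src{i}", p3_gain=3.0, seed=30 + i,
                            n_trials=60) for i in range(2)]
    target = make_subject("tgt", p3_gain=2.0, seed=40, n_trials=60,
                          latency_shift_ms=100.0)
    mcfg = ModelConfig(F1=2, F2=3, p_dropout=0.2, ch=4, T=20, fs=20.0)
    return sources, target, mcfg


class TestTrainingLoop:
    def test_fixed_seed_reproduces_run_exactly(self, tiny_problem):
        sources, target, mcfg = tiny_problem
        tcfg = TrainConfig(K=8, epochs=3, seed=11)
        out1 = train_p3msda(sources, target, mcfg, tcfg)
        out2 = train_p3msda(sources, target, mcfg, tcfg)
        losses1 = [log.loss_total for log in out1.history]
        losses2 = [log.loss_total for log in out2.history]
        assert losses1 == losses2
        np.testing.assert_array_equal(out1.state.pseudo_labels,
                                      out2.state.pseudo_labels)
        np.testing.assert_array_equal(out1.weights.w, out2.weights.w)

    def test_weights_on_simplex_every_epoch(self, tiny_problem):
        sources, target, mcfg = tiny_problem
        out = train_p3msda(sources, target, mcfg,
                           TrainConfig(K=8, epochs=3, seed=2))
        for log in out.history:
            assert np.all(log.weights >= 0)
            assert log.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_predict_reproduces_final_state(self, tiny_problem):
        sources, target, mcfg = tiny_problem
        out = train_p3msda(sources, target, mcfg,
                           TrainConfig(K=8, epochs=2, seed=3))
        y, state = predict(out.net, out.weights, target)
        np.testing.assert_array_equal(y, out.state.pseudo_labels)
        assert np.all((state.weighted >= 0) & (state.weighted <= 1))

    def test_training_ignores_target_labels(self, tiny_problem):
        sources, target, mcfg = tiny_problem
        tcfg = TrainConfig(K=8, epochs=2, seed=5)
        out1 = train_p3msda(sources, target, mcfg, tcfg)
        scrambled = EpochSet(trials=target.trials,
                             labels=1 - target.labels, fs=target.fs,
                             subject_id=target.subject_id)
        out2 = train_p3msda(sources, scrambled, mcfg, tcfg)
        np.testing.assert_array_equal(out1.state.weighted,
                                      out2.state.weighted)

    def test_one_adam_step_decreases_total_loss_on_frozen_batch(
            self, tiny_problem):
        """A single small-lr update on a fixed batch reduces the total
        objective re-evaluated on that same batch."""
        from p3msda.network import P3MSDANet
        from p3msda.trainer import adversarial_step

        sources, target, mcfg_dropout = tiny_problem
        mcfg = ModelConfig(**{**mcfg_dropout.__dict__, "p_dropout": 0.0})
        tcfg = TrainConfig(K=8, epochs=1, seed=7, lr=1e-3)
        net = P3MSDANet(mcfg, n_sources=2, seed=13)
        opt = net.make_optimizer(tcfg.lr)
        rng = np.random.default_rng(0)
        src_data = []
        for s in sources:
            dev = np.flatnonzero(s.labels == 1)[:4]
            std = np.flatnonzero(s.labels == 0)[:4]
            idx = np.concatenate([dev, std])
            src_data.append((s.trials[idx], s.labels[idx]))
        xt = target.trials[rng.permutation(target.n_trials)[:8]]

        before, _, _ = adversarial_step(net, opt, src_data, xt, tcfg,
                                        np.zeros(2), 0, update=True)
        after, _, _ = adversarial_step(net, opt, src_data, xt, tcfg,
                                       np.zeros(2), 0, update=False)
        assert after.total < before.total

    def test_source_batches_are_class_balanced(self, rng):
        from p3msda.trainer import _stratified_batches
        labels = np.array([1] * 12 + [0] * 12)
        for idx in _stratified_batches(labels, n_batches=3, half=4, rng=rng):
            assert len(idx) == 8
            assert labels[idx].sum() == 4  # K/2 deviants per batch

    def test_dann_specialization_keeps_full_pool(self, tiny_problem):
        """N=1, Q=1, lambda=0 reduces to single-source adversarial
        training on the full target set every epoch."""
        sources, target, mcfg = tiny_problem
        tcfg = TrainConfig(K=8, epochs=2, seed=4, Q=1.0, lam=0.0)
        out = train_p3msda(sources[:1], target, mcfg, tcfg)
        for log in out.history:
            assert log.pool_size == target.n_trials
            np.testing.assert_array_equal(log.weights, [1.0])

    def test_needs_at_least_one_source(self, tiny_problem):
        _, target, mcfg = tiny_problem
        with pytest.raises(ConfigurationError):
            train_p3msda([], target, mcfg, TrainConfig(K=8, epochs=1))

    def test_batch_larger_than_target_rejected(self, tiny_problem):
        sources, target, mcfg = tiny_problem
        with pytest.raises(ConfigurationError):
            train_p3msda(sources, target.subset(np.arange(10)), mcfg,
                         TrainConfig(K=20, epochs=1))
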