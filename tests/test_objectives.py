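"""Losses: label smoothing, CTC vs brute force, KL direction, combination."""

import numpy as np
import pytest

from squeezecall import _autograd as ag
from squeezecall._autograd import Tensor, log_softmax
from squeezecall.objectives import (InfeasibleLabelError, LossWeights,
                                    combined_loss, ctc_loss, ctc_loss_batch,
                                    intermediate_ctc, kl_loss, kl_loss_batch,
                                    label_smooth)

from conftest import brute_force_ctc_loglik, random_posteriorgram


class TestLabelSmooth:
    def test_five_class_factor_point_one(self):
        target = label_smooth(1, 5, 0.1)
        np.testing.assert_allclose(target.probs,
                                   [0.025, 0.9, 0.025, 0.025, 0.025], atol=1e-15)

    def test_zero_factor_is_one_hot(self):
        np.testing.assert_array_equal(label_smooth(3, 5, 0.0).probs,
                                      [0, 0, 0, 1, 0])

    @pytest.mark.parametrize("cls,k,factor", [(0, 5, 0.1), (2, 4, 0.3), (4, 5, 0.05)])
    def test_sums_to_one(self, cls, k, factor):
        assert abs(label_smooth(cls, k, factor).probs.sum() - 1.0) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            label_smooth(5, 5, 0.1)
        with pytest.raises(ValueError):
            label_smooth(0, 5, 1.0)


class TestCTCLoss:
    def test_single_frame_single_base(self):
        logp = np.log(np.array([[0.5, 0.2, 0.1, 0.1, 0.1]]))
        assert ctc_loss(logp, "A") == pytest.approx(-np.log(0.5))

    def test_empty_label_is_all_blank_path(self):
        rng = np.random.default_rng(1)
        logp = random_posteriorgram(rng, 4)
        assert ctc_loss(logp, "") == pytest.approx(-logp[:, 4].sum())

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        T = int(rng.integers(1, 7))
        label = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 4)))
        logp = random_posteriorgram(rng, T)
        try:
            mine = ctc_loss(logp, label)
        except InfeasibleLabelError:
            assert 2 * len(label) - 1 > 2 * T - 1 or len(label) > T
            return
        assert mine == pytest.approx(-brute_force_ctc_loglik(logp, label), abs=1e-6)

    def test_loss_bounded_by_best_single_alignment(self):
        # total mass >= any single path's mass, so NLL <= best-path NLL
        rng = np.random.default_rng(5)
        logp = random_posteriorgram(rng, 6)
        label = "AC"
        loss = ctc_loss(logp, label)
        # one explicit alignment: A at frame 0, C at frame 3, blanks elsewhere
        path_lp = logp[0, 0] + logp[1, 4] + logp[2, 4] + logp[3, 1] + \
            logp[4, 4] + logp[5, 4]
        assert loss <= -path_lp + 1e-12

    def test_infeasible_label_signaled(self):
        logp = random_posteriorgram(np.random.default_rng(0), 2)
        with pytest.raises(InfeasibleLabelError):
            ctc_loss(logp, "AAA")
        with pytest.raises(InfeasibleLabelError):
            ctc_loss(logp, "AA")  # repeat needs a separating blank: 3 frames

    def test_batch_matches_per_item(self):
        rng = np.random.default_rng(9)
        logp = np.stack([random_posteriorgram(rng, 7) for _ in range(4)])
        labels = ["AC", "", "GGT", "T"]
        batch = ctc_loss_batch(logp, labels)
        singles = [ctc_loss(logp[i], labels[i]) for i in range(4)]
        np.testing.assert_allclose(batch, singles, atol=1e-10)


class TestIntermediateCTC:
    def test_single_tap_equals_plain_ctc(self):
        rng = np.random.default_rng(2)
        logp = random_posteriorgram(rng, 5)
        assert intermediate_ctc({2: logp}, "AC") == pytest.approx(ctc_loss(logp, "AC"))

    def test_two_taps_average(self):
        rng = np.random.default_rng(3)
        a, b = random_posteriorgram(rng, 5), random_posteriorgram(rng, 5)
        expected = 0.5 * (ctc_loss(a, "GT") + ctc_loss(b, "GT"))
        assert intermediate_ctc({1: a, 3: b}, "GT") == pytest.approx(expected, abs=1e-9)

    def test_missing_tap_raises(self):
        with pytest.raises(KeyError):
            intermediate_ctc({1: np.zeros((3, 5))}, "A", tap_set=(2,))


class TestKLLoss:
    def test_zero_when_prediction_equals_target(self):
        labels = np.array([0, 2, 1, 4])
        logp = np.log(np.stack([label_smooth(c).probs for c in labels]))
        assert kl_loss(logp, labels) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_closed_form(self):
        q = label_smooth(1).probs
        expected = float(np.sum(q * np.log(q / 0.2)))
        logp = np.full((3, 5), np.log(0.2))
        assert kl_loss(logp, [1, 1, 1]) == pytest.approx(expected, abs=1e-12)

    def test_direction_is_target_first(self):
        # KL(q || p) with q the smoothed target; the reverse direction gives
        # a different number on this asymmetric case
        q = label_smooth(0).probs
        p = np.array([0.4, 0.3, 0.1, 0.1, 0.1])
        forward = float(np.sum(q * np.log(q / p)))
        reverse = float(np.sum(p * np.log(p / q)))
        assert forward != pytest.approx(reverse)
        assert kl_loss(np.log(p)[None, :], [0]) == pytest.approx(forward, abs=1e-12)

    def test_mean_normalization_unchanged_by_repeats(self):
        rng = np.random.default_rng(4)
        logp = random_posteriorgram(rng, 5)
        labels = np.array([0, 1, 2, 3, 4])
        once = kl_loss(logp, labels)
        twice = kl_loss(np.vstack([logp, logp]), np.concatenate([labels, labels]))
        assert twice == pytest.approx(once, abs=1e-12)

    def test_unknown_frames_skipped(self):
        rng = np.random.default_rng(6)
        logp = random_posteriorgram(rng, 4)
        full = kl_loss(logp[:2], [1, 3])
        padded = kl_loss(logp, [1, 3, -1, -1])
        assert padded == pytest.approx(full, abs=1e-12)

    def test_batch_matches_mean_of_items(self):
        rng = np.random.default_rng(7)
        logp = np.stack([random_posteriorgram(rng, 6) for _ in range(3)])
        labels = np.array([[0, 1, 2, 3, 4, 0], [1, 1, -1, 2, 2, 3], [4, 0, 0, -1, 1, 2]])
        expected = np.mean([kl_loss(logp[i], labels[i]) for i in range(3)])
        assert kl_loss_batch(logp, labels) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_loss(np.zeros((3, 5)), [0, 1])


class TestCombinedLoss:
    @staticmethod
    def _instance(seed=0, T=7):
        rng = np.random.default_rng(seed)
        final = random_posteriorgram(rng, T)
        tap = random_posteriorgram(rng, T)
        labels = rng.integers(0, 5, size=T)
        return final, {2: tap}, labels, "ACG"

    def test_pure_ctc_when_gamma_one(self):
        final, taps, fl, label = self._instance()
        w = LossWeights(gamma=1.0, beta=0.0)
        assert combined_loss(final, taps, fl, label, w) == \
            pytest.approx(ctc_loss(final, label))

    def test_default_weights_hand_sum(self):
        final, taps, fl, label = self._instance(1)
        w = LossWeights()  # gamma 0.3, beta 0.35 -> KL weight 0.35
        assert w.kl_weight == pytest.approx(0.35)
        expected = 0.3 * ctc_loss(final, label) + \
            0.35 * intermediate_ctc(taps, label) + 0.35 * kl_loss(final, fl)
        assert combined_loss(final, taps, fl, label, w) == \
            pytest.approx(expected, abs=1e-9)

    def test_convex_combination_of_equal_losses(self):
        # if all three components equal L the combination equals L
        final, taps, fl, label = self._instance(2)
        w = LossWeights(gamma=0.2, beta=0.5)
        parts = np.array([ctc_loss(final, label), intermediate_ctc(taps, label),
                          kl_loss(final, fl)])
        combined = combined_loss(final, taps, fl, label, w)
        weights = np.array([w.gamma, w.beta, w.kl_weight])
        assert combined == pytest.approx(float(weights @ parts), abs=1e-9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(gamma=0.8, beta=0.3)
        with pytest.raises(ValueError):
            LossWeights(gamma=-0.1, beta=0.2)


class TestGradients:
    """Analytic gradients against central finite differences (<= 1e-4 rel)."""

    @staticmethod
    def _rel_err(analytic, numeric):
        scale = np.maximum(np.abs(analytic) + np.abs(numeric), 1e-8)
        return float(np.max(np.abs(analytic - numeric) / scale))

    @staticmethod
    def _numeric(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            g[idx] = (f(xp) - f(xm)) / (2 * eps)
        return g

    def test_ctc_gradient_wrt_logits(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 5))
        t = Tensor(x, requires_grad=True)
        ctc_loss(log_softmax(t), "ACA").backward()

        def f(v):
            return float(ctc_loss(log_softmax(Tensor(v)), "ACA").data)

        assert self._rel_err(t.grad, self._numeric(f, x)) < 1e-4

    def test_kl_gradient_wrt_logits(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(5, 5))
        labels = np.array([0, 4, 2, -1, 1])
        t = Tensor(x, requires_grad=True)
        kl_loss(log_softmax(t), labels).backward()

        def f(v):
            return float(kl_loss(log_softmax(Tensor(v)), labels).data)

        assert self._rel_err(t.grad, self._numeric(f, x)) < 1e-4

    def test_combined_gradient_wrt_both_heads(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(7, 5))
        y = rng.normal(size=(7, 5))
        labels = rng.integers(0, 5, size=7)
        w = LossWeights()
        tx = Tensor(x, requires_grad=True)
        ty = Tensor(y, requires_grad=True)
        combined_loss(log_softmax(tx), {2: log_softmax(ty)}, labels, "GT", w).backward()

        def f_final(v):
            return float(combined_loss(log_softmax(Tensor(v)),
                                       {2: log_softmax(Tensor(y))},
                                       labels, "GT", w).data)

        def f_tap(v):
            return float(combined_loss(log_softmax(Tensor(x)),
                                       {2: log_softmax(Tensor(v))},
                                       labels, "GT", w).data)

        assert self._rel_err(tx.grad, self._numeric(f_final, x)) < 1e-4
        assert self._rel_err(ty.grad, self._numeric(f_tap, y)) < 1e-4

    def test_batched_ctc_gradient(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(2, 5, 5))
        labels = ["AC", "G"]
        t = Tensor(x, requires_grad=True)
        ag.tsum(ctc_loss_batch(log_softmax(t), labels)).backward()

        def f(v):
            return float(np.sum(ctc_loss_batch(
                log_softmax(Tensor(v)).data, labels)))

        assert self._rel_err(t.grad, self._numeric(f, x)) < 1e-4
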