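"""Loss terms: closed forms, reductions, and independent numerical oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from bireplay import (
    GenerativePrior,
    LossWeights,
    SoftTarget,
    class_loss,
    combine,
    distill_loss,
    latent_loss_gmm_hard,
    latent_loss_gmm_soft,
    latent_loss_standard,
    recon_loss_internal,
    recon_loss_pixel,
    soft_targets_from_logits,
)
from bireplay._autodiff import Tensor


def _prior(mus, sigmas):
    mus = np.atleast_2d(np.asarray(mus, dtype=float))
    sigmas = np.atleast_2d(np.asarray(sigmas, dtype=float))
    prior = GenerativePrior(len(mus), mus.shape[1])
    prior.mu.data[:] = mus
    prior.log_sigma.data[:] = np.log(sigmas)
    prior.mark_seen(range(len(mus)))
    return prior


class TestClassLoss:
    def test_certain_prediction_gives_zero(self):
        logits = Tensor(np.array([[100.0, 0.0]]))
        assert class_loss(logits, {0, 1}, [0]).data[0] < 1e-10

    def test_two_equal_logits_gives_ln2(self):
        logits = Tensor(np.zeros((1, 2)))
        assert np.isclose(class_loss(logits, {0, 1}, [0]).data[0], np.log(2))

    def test_matches_log_softmax_oracle(self):
        z = np.array([[1.0, 0.0, -1.0]])
        expected = -(z[0, 0] - np.log(np.exp(z).sum()))
        got = class_loss(Tensor(z), {0, 1, 2}, [0]).data[0]
        assert np.isclose(got, expected, atol=1e-12)

    def test_inactive_label_raises(self):
        with pytest.raises(ValueError):
            class_loss(Tensor(np.zeros((1, 3))), {0, 1}, [2])


class TestSoftTargets:
    def test_equal_logits_uniform(self):
        st = soft_targets_from_logits(np.zeros((2, 4)), {0, 1, 3}, T=2.0)
        assert np.allclose(st.probs[:, [0, 1, 3]], 1 / 3)
        assert np.all(st.probs[:, 2] == 0.0)

    def test_high_temperature_limit_uniform(self):
        st = soft_targets_from_logits(np.array([[5.0, -5.0]]), {0, 1}, T=1e6)
        assert np.allclose(st.probs[0], 0.5, atol=1e-5)

    def test_matches_direct_computation(self):
        st = soft_targets_from_logits(np.array([[2.0, 0.0]]), {0, 1}, T=2.0)
        e = np.exp([1.0, 0.0])
        assert np.allclose(st.probs[0], e / e.sum())


class TestDistillLoss:
    def test_uniform_target_uniform_prediction(self):
        n_active = 10
        target = SoftTarget(np.full((1, n_active), 1 / n_active), 2.0,
                            tuple(range(n_active)))
        logits = Tensor(np.zeros((1, n_active)))
        val = distill_loss(logits, target).data[0]
        assert np.isclose(val, 4 * np.log(10))  # T^2 * ln(n_active)

    def test_reduces_to_class_loss_at_T1_one_hot(self):
        z = np.array([[0.4, -1.2, 2.0]])
        onehot = np.array([[0.0, 0.0, 1.0]])
        target = SoftTarget(onehot, 1.0, (0, 1, 2))
        d = distill_loss(Tensor(z), target).data[0]
        c = class_loss(Tensor(z), {0, 1, 2}, [2]).data[0]
        assert np.isclose(d, c, atol=1e-12)

    def test_matches_cross_entropy_oracle(self):
        target = SoftTarget(np.array([[0.7, 0.3]]), 2.0, (0, 1))
        z = np.array([[1.0, 0.0]])
        p = np.exp(z / 2.0)[0]
        p = p / p.sum()
        expected = -4.0 * (0.7 * np.log(p[0]) + 0.3 * np.log(p[1]))
        assert np.isclose(distill_loss(Tensor(z), target).data[0], expected)

    def test_cross_entropy_at_least_entropy(self, rng):
        for _ in range(20):
            probs = rng.dirichlet(np.ones(5)).reshape(1, -1)
            target = SoftTarget(probs, 2.0, tuple(range(5)))
            logits = Tensor(rng.standard_normal((1, 5)))
            entropy = -np.sum(probs * np.log(probs))
            assert distill_loss(logits, target).data[0] - 4.0 * entropy >= -1e-9


class TestLatentStandard:
    def test_standard_posterior_gives_zero(self):
        val = latent_loss_standard(Tensor(np.zeros((1, 100))), Tensor(np.zeros((1, 100))))
        assert np.isclose(val.data[0], 0.0)

    def test_unit_mean_single_dim(self):
        val = latent_loss_standard(Tensor(np.array([[1.0]])), Tensor(np.zeros((1, 1))))
        assert np.isclose(val.data[0], 0.5)

    def test_matches_numerical_kl_integration(self):
        # 1-d KL( N(0, 2) || N(0, 1) ) by direct quadrature
        sig2 = 2.0
        q = stats.norm(0.0, np.sqrt(sig2))
        kl, _ = integrate.quad(
            lambda z: q.pdf(z) * (q.logpdf(z) - stats.norm(0, 1).logpdf(z)), -20, 20
        )
        val = latent_loss_standard(
            Tensor(np.zeros((1, 1))), Tensor(np.array([[0.5 * np.log(sig2)]]))
        ).data[0]
        assert np.isclose(val, kl, atol=1e-8)

    def test_nonnegative_on_random_posteriors(self, rng):
        mu = Tensor(rng.standard_normal((200, 7)))
        ls = Tensor(rng.standard_normal((200, 7)))
        assert np.all(latent_loss_standard(mu, ls).data >= -1e-9)


class TestLatentGmmHard:
    def test_posterior_equals_mode_gives_zero(self, rng):
        mus = rng.standard_normal((2, 4))
        sigmas = np.exp(rng.standard_normal((2, 4)) * 0.3)
        prior = _prior(mus, sigmas)
        val = latent_loss_gmm_hard(Tensor(mus[[1]]), Tensor(np.log(sigmas[[1]])),
                                   [1], prior)
        assert np.isclose(val.data[0], 0.0, atol=1e-12)

    def test_standard_mode_reduces_to_standard_loss(self, rng):
        prior = _prior(np.zeros((1, 6)), np.ones((1, 6)))
        mu = Tensor(rng.standard_normal((1000, 6)))
        ls = Tensor(rng.standard_normal((1000, 6)) * 0.5)
        hard = latent_loss_gmm_hard(mu, ls, np.zeros(1000, dtype=int), prior).data
        std = latent_loss_standard(mu, ls).data
        assert np.allclose(hard, std, atol=1e-12)

    def test_matches_monte_carlo_kl(self, rng):
        """Closed form vs a 10^6-sample Monte-Carlo KL estimate in 3-d."""
        mu_x = rng.standard_normal(3)
        sd_x = np.exp(0.3 * rng.standard_normal(3))
        mu_y = rng.standard_normal(3)
        sd_y = np.exp(0.3 * rng.standard_normal(3))
        prior = _prior([mu_y], [sd_y])
        closed = latent_loss_gmm_hard(Tensor(mu_x[None]), Tensor(np.log(sd_x)[None]),
                                      [0], prior).data[0]
        z = mu_x + sd_x * rng.standard_normal((1_000_000, 3))
        logq = stats.norm(mu_x, sd_x).logpdf(z).sum(axis=1)
        logp = stats.norm(mu_y, sd_y).logpdf(z).sum(axis=1)
        mc = (logq - logp).mean()
        assert abs(closed - mc) < 1e-2

    def test_unseen_mode_raises(self):
        prior = GenerativePrior(2, 3)
        with pytest.raises(RuntimeError):
            latent_loss_gmm_hard(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3))),
                                 [0], prior)


class TestLatentGmmSoft:
    def test_one_hot_expectation_matches_closed_form(self, rng):
        """The sampled estimator with a one-hot target agrees with the
        closed-form mode KL within 3 standard errors over 10^5 draws."""
        d = 4
        mu_x = rng.standard_normal((1, d))
        ls_x = 0.3 * rng.standard_normal((1, d))
        prior = _prior(rng.standard_normal((2, d)), np.exp(0.2 * rng.standard_normal((2, d))))
        onehot = np.array([[0.0, 1.0]])
        n = 100_000
        eps = rng.standard_normal((n, d))
        vals = latent_loss_gmm_soft(
            Tensor(np.repeat(mu_x, n, axis=0)), Tensor(np.repeat(ls_x, n, axis=0)),
            np.repeat(onehot, n, axis=0), prior, eps,
        ).data
        closed = latent_loss_gmm_hard(Tensor(mu_x), Tensor(ls_x), [1], prior).data[0]
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean() - closed) < 3 * se

    def test_symmetric_modes_invariant_under_swap(self):
        d = 2
        mu = np.array([[1.0, -1.0], [-1.0, 1.0]])
        sd = np.ones((2, d))
        uniform = np.array([[0.5, 0.5]])
        eps = np.array([[0.3, -0.7]])
        a = latent_loss_gmm_soft(Tensor(np.zeros((1, d))), Tensor(np.zeros((1, d))),
                                 uniform, _prior(mu, sd), eps).data[0]
        b = latent_loss_gmm_soft(Tensor(np.zeros((1, d))), Tensor(np.zeros((1, d))),
                                 uniform, _prior(mu[::-1], sd), eps).data[0]
        assert np.isclose(a, b, atol=1e-12)

    def test_expectation_matches_quadrature_in_1d(self):
        """Gauss-Hermite average of the estimator vs direct quadrature of
        the underlying integral."""
        mu_x, sd_x = 0.4, 0.8
        mus = np.array([[-1.0], [1.5]])
        sds = np.array([[0.7], [1.2]])
        w = np.array([[0.3, 0.7]])
        prior = _prior(mus, sds)
        nodes, weights = np.polynomial.hermite_e.hermegauss(80)
        vals = latent_loss_gmm_soft(
            Tensor(np.full((80, 1), mu_x)), Tensor(np.full((80, 1), np.log(sd_x))),
            np.repeat(w, 80, axis=0), prior, nodes[:, None],
        ).data
        estimate = (weights * vals).sum() / weights.sum()

        def mix_logpdf(z):
            return np.log(0.3 * stats.norm(mus[0, 0], sds[0, 0]).pdf(z)
                          + 0.7 * stats.norm(mus[1, 0], sds[1, 0]).pdf(z))

        q = stats.norm(mu_x, sd_x)
        cross, _ = integrate.quad(lambda z: q.pdf(z) * mix_logpdf(z), -15, 15)
        expected = -0.5 * (1 + np.log(2 * np.pi) + np.log(sd_x**2)) - cross
        assert abs(estimate - expected) < 1e-3

    def test_mass_on_unseen_class_raises(self):
        prior = GenerativePrior(2, 1)
        prior.mark_seen([0])
        with pytest.raises(RuntimeError):
            latent_loss_gmm_soft(Tensor(np.zeros((1, 1))), Tensor(np.zeros((1, 1))),
                                 np.array([[0.5, 0.5]]), prior, np.zeros((1, 1)))


class TestReconLosses:
    def test_binary_perfect_reconstruction_near_zero(self):
        x = np.array([[0.0, 1.0, 1.0]])
        x_hat = Tensor(np.array([[1e-9, 1 - 1e-9, 1 - 1e-9]]))
        assert recon_loss_pixel(x, x_hat).data[0] < 1e-5

    def test_half_half_single_pixel_is_ln2(self):
        val = recon_loss_pixel(np.array([[0.5]]), Tensor(np.array([[0.5]])))
        assert np.isclose(val.data[0], np.log(2))

    def test_matches_direct_summation(self, rng):
        x = rng.random((1, 4))
        xh = np.clip(rng.random((1, 4)), 0.05, 0.95)
        expected = -np.sum(x * np.log(xh) + (1 - x) * np.log(1 - xh))
        assert np.isclose(recon_loss_pixel(x, Tensor(xh)).data[0], expected)

    def test_out_of_range_target_raises(self):
        with pytest.raises(ValueError):
            recon_loss_pixel(np.array([[1.5]]), Tensor(np.array([[0.5]])))

    def test_internal_zero_and_arithmetic(self):
        h = np.array([[1.0, 0.0]])
        assert recon_loss_internal(h, Tensor(h.copy())).data[0] == 0.0
        assert recon_loss_internal(h, Tensor(np.array([[0.0, 1.0]]))).data[0] == 2.0

    def test_internal_matches_elementwise_oracle(self, rng):
        h = rng.standard_normal((1, 10))
        hh = rng.standard_normal((1, 10))
        assert np.isclose(recon_loss_internal(h, Tensor(hh)).data[0],
                          ((h - hh) ** 2).sum())

    def test_internal_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            recon_loss_internal(np.zeros((1, 3)), Tensor(np.zeros((1, 4))))


class TestCombine:
    def test_first_task_is_current_only(self):
        assert combine(3.0, 99.0, LossWeights(1)) == 3.0

    def test_second_task_is_mean(self):
        assert np.isclose(combine(2.0, 4.0, LossWeights(2)), 3.0)

    def test_fifth_task_weighting(self):
        assert np.isclose(combine(10.0, 0.0, LossWeights(5)), 2.0)

    def test_weights_always_sum_to_one(self):
        for n in range(1, 50):
            w = LossWeights(n)
            assert np.isclose(w.current + w.replay, 1.0)

    def test_invalid_task_count_raises(self):
        with pytest.raises(ValueError):
            LossWeights(0)


# ---------------------------------------------------------------------------
# property-based invariants

from hypothesis import given, settings
from hypothesis import strategies as st

finite = st.floats(min_value=-3.0, max_value=3.0, allow_nan=False)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(finite, min_size=1, max_size=8), st.lists(finite, min_size=1, max_size=8))
def test_latent_kl_nonnegative_and_gmm_reduction(mu_vals, ls_vals):
    d = min(len(mu_vals), len(ls_vals))
    mu = Tensor(np.array([mu_vals[:d]]))
    ls = Tensor(np.array([ls_vals[:d]]))
    std = latent_loss_standard(mu, ls).data[0]
    assert std >= -1e-9
    prior = _prior(np.zeros((1, d)), np.ones((1, d)))
    hard = latent_loss_gmm_hard(mu, ls, [0], prior).data[0]
    assert np.isclose(hard, std, atol=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=200))
def test_loss_weights_partition_unity(n):
    w = LossWeights(n)
    assert np.isclose(w.current + w.replay, 1.0)
    assert 0.0 <= w.replay < 1.0
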