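"""Growth mixture model: softmax weights, EM behavior, K selection,
membership-ratio inference, surfaces, posterior classification."""
import numpy as np
import pytest

from growthmix import (
    BasisSpec,
    GMMOptions,
    MeanModelSpec,
    MembershipModelSpec,
    RandomEffectsSpec,
    class_weights,
    fit_gmm,
    fit_lme,
    gmm_mean_surface,
    lme_mean_surface,
    membership_ratio,
    posterior_classify,
    select_K,
)
from growthmix.gmm import permute_classes
from growthmix.simulate import default_condition, generate_dataset

FAST = GMMOptions(n_starts=2, seed=0)


@pytest.fixture(scope="module")
def class_mean_spec():
    return MeanModelSpec(basis=BasisSpec("linear"))


@pytest.fixture(scope="module")
def sep_dataset(separated_3class_condition):
    return generate_dataset(separated_3class_condition, "training", 0)


@pytest.fixture(scope="module")
def sep_fit(sep_dataset, class_mean_spec, membership_w1w2):
    return fit_gmm(sep_dataset, class_mean_spec, RandomEffectsSpec(),
                   membership_w1w2, K=3, options=FAST)


class TestClassWeights:
    def test_zero_gamma_uniform(self):
        np.testing.assert_allclose(
            class_weights(np.zeros((3, 2)), np.array([1.0, 0.3])), np.full(4, 0.25)
        )

    def test_two_class_log3(self):
        pi = class_weights(np.array([[0.0, np.log(3)]]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(pi, [0.75, 0.25])

    def test_ratio_identity_random(self):
        rng = np.random.default_rng(3)
        gamma = rng.normal(size=(3, 4))
        W = rng.normal(size=(20, 4))
        pi = class_weights(gamma, W)
        np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-12)
        for k in range(3):
            np.testing.assert_allclose(
                pi[:, k] / pi[:, 3], np.exp(W @ gamma[k]), rtol=1e-10
            )

    def test_extreme_logits_stable(self):
        pi = class_weights(np.array([[500.0, 0.0]]), np.array([1.0, 1.0]))
        assert np.isfinite(pi).all() and pi.sum() == pytest.approx(1.0)


class TestFitGmm:
    def test_k1_reduces_to_lme(self, sep_dataset, class_mean_spec):
        lme = fit_lme(sep_dataset, class_mean_spec)
        gmm = fit_gmm(sep_dataset, class_mean_spec, K=1,
                      options=GMMOptions(n_starts=1, tol=1e-12, max_iter=2000,
                                         var_maxiter=50))
        assert abs(lme.loglik - gmm.loglik) < 1e-4
        np.testing.assert_allclose(gmm.betas.to_numpy()[0], lme.beta.to_numpy(),
                                   atol=1e-4)

    def test_em_loglik_nondecreasing_all_starts(self, sep_fit):
        for trace in sep_fit.loglik_traces:
            diffs = np.diff(trace)
            assert (diffs >= -1e-6 * (np.abs(trace[:-1]) + 1)).all()

    def test_recovers_separated_class_means(self, sep_fit):
        truth = np.array([[12.0, 0.2], [17.0, 0.5], [22.0, 0.8]])
        est = sep_fit.betas.to_numpy()
        order = np.argsort(est[:, 0])
        np.testing.assert_allclose(est[order], truth, atol=0.25)

    def test_posterior_rows_sum_to_one(self, sep_fit):
        np.testing.assert_allclose(sep_fit.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_canonical_order_descending_size(self, sep_fit):
        sizes = sep_fit.class_sizes
        assert (np.diff(sizes) <= 1e-9).all()

    def test_n_params_formula(self, sep_fit):
        # K*p + (K-1)*q_w + q(q+1)/2 + 1
        assert sep_fit.n_params == 3 * 2 + 2 * 3 + 1 + 1

    def test_permutation_leaves_softmax_invariant(self, sep_fit, sep_dataset):
        perm = [2, 0, 1]
        permuted = permute_classes(sep_fit, perm)
        W = sep_fit._W
        pi_old = class_weights(sep_fit.gamma, W)
        pi_new = class_weights(permuted.gamma, W)
        np.testing.assert_allclose(pi_new, pi_old[:, perm], atol=1e-12)

    def test_fit_invariant_to_start_perturbation(self, sep_dataset, class_mean_spec,
                                                 membership_w1w2):
        """Well-separated data: different multi-start seeds, same optimum."""
        a = fit_gmm(sep_dataset, class_mean_spec, RandomEffectsSpec(),
                    membership_w1w2, K=3, options=GMMOptions(n_starts=2, seed=0))
        b = fit_gmm(sep_dataset, class_mean_spec, RandomEffectsSpec(),
                    membership_w1w2, K=3, options=GMMOptions(n_starts=3, seed=99))
        assert abs(a.loglik - b.loglik) < 1e-3
        np.testing.assert_allclose(a.betas.to_numpy(), b.betas.to_numpy(), atol=1e-2)


class TestSelectK:
    def test_default_range_is_2_to_5(self):
        import inspect

        sig = inspect.signature(select_K)
        assert list(sig.parameters["K_range"].default) == [2, 3, 4, 5]

    def test_returned_fit_attains_table_minimum(self, sep_dataset, class_mean_spec,
                                                membership_w1w2):
        fit, table = select_K(sep_dataset, class_mean_spec, RandomEffectsSpec(),
                              membership_w1w2, K_range=(2, 3, 4), options=FAST)
        assert fit.bic == pytest.approx(table["bic"].min())
        assert fit.K == 3


class TestMembershipRatio:
    def test_zero_gamma_gives_unit_ratio(self, sep_fit):
        from dataclasses import replace

        zeroed = replace(sep_fit, gamma=np.zeros_like(sep_fit.gamma), _psi_cov=None)
        r = membership_ratio(zeroed, 1, "w2")
        assert r["ratio"] == pytest.approx(1.0)
        assert r["lower"] < 1.0 < r["upper"]

    def test_exp_reporting_convention(self, sep_fit):
        from dataclasses import replace

        gamma = sep_fit.gamma.copy()
        j = sep_fit.gamma_names.index("w2")
        gamma[0, j] = np.log(1.31)
        forced = replace(sep_fit, gamma=gamma, _psi_cov=None)
        assert membership_ratio(forced, 1, "w2", delta=1.0)["ratio"] == pytest.approx(1.31)

    def test_reference_class_rejected(self, sep_fit):
        with pytest.raises(ValueError, match="reference"):
            membership_ratio(sep_fit, sep_fit.K, "w2")

    def test_interval_level_ordering(self, sep_fit):
        r90 = membership_ratio(sep_fit, 1, "w2", level=0.90)
        r95 = membership_ratio(sep_fit, 1, "w2", level=0.95)
        assert r95["lower"] < r90["lower"] < r90["upper"] < r95["upper"]


class TestGmmSurface:
    def test_k1_matches_lme_surface(self, sep_dataset, class_mean_spec):
        gmm = fit_gmm(sep_dataset, class_mean_spec, K=1,
                      options=GMMOptions(n_starts=1, tol=1e-12, max_iter=2000,
                                         var_maxiter=50))
        lme = fit_lme(sep_dataset, class_mean_spec)
        t = np.linspace(1, 10, 7)
        np.testing.assert_allclose(
            gmm_mean_surface(gmm).mu(t, w1=1, w2=0.3),
            lme_mean_surface(lme).mu(t, w1=1, w2=0.3),
            atol=1e-3,
        )

    def test_identical_class_curves_kill_w_dependence(self, sep_fit):
        from dataclasses import replace

        betas = sep_fit.betas.copy()
        betas.iloc[1] = betas.iloc[0]
        betas.iloc[2] = betas.iloc[0]
        flat = replace(sep_fit, betas=betas)
        s = gmm_mean_surface(flat)
        np.testing.assert_allclose(
            s.mu(5.0, w1=1, w2=-2.0), s.mu(5.0, w1=1, w2=2.0), atol=1e-10
        )

    def test_velocity_matches_finite_difference(self, sep_fit):
        s = gmm_mean_surface(sep_fit)
        t = np.linspace(1.5, 9.5, 17)
        h = 1e-6
        fd = (s.mu(t + h, w1=0, w2=1.2) - s.mu(t - h, w1=0, w2=1.2)) / (2 * h)
        np.testing.assert_allclose(s.v(t, w1=0, w2=1.2), fd, atol=1e-6)


class TestPosteriorClassify:
    def test_argmax_and_sizes(self, sep_fit):
        assign, table = posterior_classify(sep_fit)
        assert table["size"].sum() == sep_fit.n_subjects
        np.testing.assert_array_equal(
            assign.to_numpy(), np.argmax(sep_fit.posterior, axis=1) + 1
        )

    def test_agreement_with_generating_labels(self, separated_3class_condition,
                                              sep_dataset, sep_fit):
        """>=95% agreement after the best label permutation."""
        p = separated_3class_condition.params
        # regenerate latent labels by replaying the generator's stream
        rng = np.random.default_rng(
            np.random.SeedSequence([p.seed, separated_3class_condition.data_type, 0, 0])
        )
        n = p.n_subjects
        w1 = (rng.random(n) < p.w1_prob).astype(float)
        w2 = rng.standard_normal(n)
        logits = np.column_stack([np.ones(n), w1, w2]) @ np.asarray(p.class_logits).T
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        pi = e / e.sum(axis=1, keepdims=True)
        z_true = (rng.random(n)[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
        assign, _ = posterior_classify(sep_fit)
        est = assign.to_numpy() - 1
        from itertools import permutations

        best = max(
            np.mean(np.asarray(perm)[est] == z_true) for perm in permutations(range(3))
        )
        assert best >= 0.95
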