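"""ML mixed-effects fitting: exactness limits, oracle likelihoods,
surfaces, BIC arithmetic, and calibration of model-based SEs."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from growthmix import (
    BasisSpec,
    LMEOptions,
    MeanModelSpec,
    RandomEffectsSpec,
    bic_of,
    fit_lme,
    lme_mean_surface,
)
from growthmix import LongitudinalDataset
from growthmix.simulate import default_condition, generate_dataset
from growthmix import _likelihood as lk


@pytest.fixture(scope="module")
def sim_dataset():
    return generate_dataset(default_condition(1, seed=4, n_subjects=100), "training", 0)


@pytest.fixture(scope="module")
def sim_fit(sim_dataset, linear_mean_spec):
    return fit_lme(sim_dataset, linear_mean_spec, RandomEffectsSpec("all"))


def _noiseless_dataset(beta=(14.0, 0.8, 0.3, -0.1)):
    """y = b0 + b1 t + b2 w2 + b3 t*w2 exactly, no noise."""
    rng = np.random.default_rng(0)
    rows, bl = [], {}
    for i in range(12):
        sid = f"s{i:02d}"
        w2 = float(rng.normal())
        bl[sid] = {"w2": w2}
        for t in (1.0, 4.0, 7.0, 10.0):
            y = beta[0] + beta[1] * t + beta[2] * w2 + beta[3] * t * w2
            rows.append({"subject": sid, "time": t, "y": y})
    return LongitudinalDataset.from_frames(
        pd.DataFrame(rows), pd.DataFrame.from_dict(bl, orient="index")
    )


class TestFitLme:
    def test_noiseless_interpolation_with_zero_G(self):
        ds = _noiseless_dataset()
        spec = MeanModelSpec(basis=BasisSpec("linear"), modifiers=("w2",))
        fit = fit_lme(ds, spec, options=LMEOptions(force_zero_G=True))
        np.testing.assert_allclose(fit.beta.to_numpy(), [14.0, 0.8, 0.3, -0.1], atol=1e-8)

    def test_zero_G_equals_pooled_ols(self, sim_dataset, linear_mean_spec):
        fit = fit_lme(sim_dataset, linear_mean_spec, options=LMEOptions(force_zero_G=True))
        obs = sim_dataset.obs
        t = obs["time"].to_numpy()
        w1 = sim_dataset.baselines.loc[obs["subject"], "w1"].to_numpy()
        w2 = sim_dataset.baselines.loc[obs["subject"], "w2"].to_numpy()
        X = np.column_stack([np.ones_like(t), t, w1, w2, t * w1, t * w2])
        ols, *_ = np.linalg.lstsq(X, obs["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=1e-6)

    def test_loglik_matches_mvn_density(self, sim_dataset, linear_mean_spec, sim_fit):
        fit = sim_fit
        ll = 0.0
        for sid in sim_dataset.subject_ids:
            t = sim_dataset.times_of(sid)
            y = sim_dataset.outcomes_of(sid)
            w = sim_dataset.baselines.loc[sid]
            Z = np.column_stack([np.ones_like(t), t])
            V = Z @ fit.G @ Z.T + fit.sigma2 * np.eye(len(t))
            x = fit.design_info.fixed_row(t, {"w1": w["w1"], "w2": w["w2"]})
            ll += multivariate_normal.logpdf(y, x @ fit.beta.to_numpy(), V)
        assert abs(ll - fit.loglik) < 1e-8

    def test_fitted_loglik_dominates_random_parameters(self, sim_dataset, linear_mean_spec,
                                                       sim_fit):
        """ML estimate beats 100 random draws of (theta, beta)."""
        design = sim_fit._design
        rng = np.random.default_rng(9)
        theta_hat = lk.theta_from_G_sigma(sim_fit.G, sim_fit.sigma2)
        beta_hat = sim_fit.beta.to_numpy()
        for _ in range(100):
            theta = theta_hat + rng.normal(scale=0.3, size=theta_hat.shape)
            beta = beta_hat + rng.normal(scale=0.2, size=beta_hat.shape)
            vt = lk.variance_terms(theta, design)
            ll = float(np.sum(lk.class_logdens(design, vt, beta[None, :])))
            assert ll <= sim_fit.loglik + 1e-8

    def test_invariant_to_subject_relabeling_and_row_order(self, sim_dataset,
                                                           linear_mean_spec, sim_fit):
        relabel = {s: f"zz{int(s[1:]):04d}" for s in sim_dataset.subject_ids}
        obs = sim_dataset.obs.copy()
        obs["subject"] = obs["subject"].map(relabel)
        obs = obs.sample(frac=1.0, random_state=0)
        bl = sim_dataset.baselines.rename(index=relabel)
        shuffled = LongitudinalDataset.from_frames(obs, bl)
        refit = fit_lme(shuffled, linear_mean_spec, RandomEffectsSpec("all"))
        np.testing.assert_allclose(refit.loglik, sim_fit.loglik, atol=1e-6)
        np.testing.assert_allclose(refit.beta.to_numpy(), sim_fit.beta.to_numpy(), atol=1e-6)

    def test_marginal_covariance_psd(self, sim_fit):
        for blk in sim_fit._design.blocks:
            V = blk.Z @ sim_fit.G @ blk.Z.T + sim_fit.sigma2 * np.eye(len(blk.times))
            assert np.linalg.eigvalsh(V).min() > 0

    def test_matches_statsmodels_mixedlm(self, sim_dataset):
        """Independent cross-check: same ML fit from statsmodels MixedLM."""
        import statsmodels.api as sm

        spec = MeanModelSpec(basis=BasisSpec("linear"), modifiers=("w2",))
        fit = fit_lme(sim_dataset, spec, RandomEffectsSpec("intercept_only"))
        obs = sim_dataset.obs
        w2 = sim_dataset.baselines.loc[obs["subject"], "w2"].to_numpy()
        t = obs["time"].to_numpy()
        X = np.column_stack([np.ones_like(t), t, w2, t * w2])
        m = sm.MixedLM(obs["y"].to_numpy(), X, groups=obs["subject"].to_numpy())
        ref = m.fit(reml=False)
        np.testing.assert_allclose(fit.loglik, ref.llf, atol=1e-5)
        np.testing.assert_allclose(fit.beta.to_numpy(), ref.fe_params, atol=1e-5)

    def test_rank_deficient_design_raises(self, sim_dataset):
        spec = MeanModelSpec(basis=BasisSpec("linear"), modifiers=("w2", "w2dup"))
        bl = sim_dataset.baselines.assign(w2dup=sim_dataset.baselines["w2"])
        ds = LongitudinalDataset(sim_dataset.obs, bl)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_lme(ds, spec)

    def test_se_calibration_monte_carlo(self):
        """beta-hat within 3 model-based SEs of truth in nearly all replicates."""
        true = {"Intercept": 16.0, "t": 0.35, "w1": 0.5, "w2": 0.4,
                "t:w1": 0.05, "t:w2": 0.12}
        spec = MeanModelSpec(basis=BasisSpec("linear"), modifiers=("w1", "w2"))
        hits = total = 0
        for rep in range(40):
            ds = generate_dataset(default_condition(1, seed=77, n_subjects=120),
                                  "training", rep)
            fit = fit_lme(ds, spec, RandomEffectsSpec("all"))
            z = (fit.beta - pd.Series(true)) / fit.beta_se
            hits += int((z.abs() <= 3).sum())
            total += len(z)
        assert hits / total >= 0.95


class TestMeanSurface:
    def test_affine_in_continuous_modifier(self, sim_fit):
        s = lme_mean_surface(sim_fit)
        t = 6.0
        m0 = s.mu(t, w1=1.0, w2=0.0)
        m1 = s.mu(t, w1=1.0, w2=1.0)
        m2 = s.mu(t, w1=1.0, w2=2.0)
        np.testing.assert_allclose(m2 - m1, m1 - m0, atol=1e-10)

    def test_velocity_zero_when_growth_coefs_zero(self, sim_fit):
        from dataclasses import replace

        beta = sim_fit.beta.copy()
        beta[["t", "t:w1", "t:w2"]] = 0.0
        flat = replace(sim_fit, beta=beta)
        s = lme_mean_surface(flat)
        np.testing.assert_allclose(s.v([2.0, 5.0, 8.0], w1=1, w2=0.7), 0.0, atol=1e-12)

    def test_velocity_matches_finite_difference(self, sim_fit):
        s = lme_mean_surface(sim_fit)
        t = np.linspace(1.5, 9.5, 23)
        h = 1e-6
        fd = (s.mu(t + h, w1=1, w2=-0.4) - s.mu(t - h, w1=1, w2=-0.4)) / (2 * h)
        np.testing.assert_allclose(s.v(t, w1=1, w2=-0.4), fd, atol=1e-6)


class TestBic:
    def test_arithmetic(self):
        assert bic_of(-3000.0, 10, 250) == pytest.approx(6055.21, abs=0.01)

    def test_zero_params(self):
        assert bic_of(-123.4, 0, 50) == pytest.approx(246.8)

    def test_monotone_in_params(self):
        vals = [bic_of(-100.0, p, 30) for p in range(5)]
        assert vals == sorted(vals)
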