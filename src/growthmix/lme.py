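"""Maximum-likelihood linear mixed-effects model with exposure interactions.

The model for subject i is y_i = X_i beta + Z_i u_i + eps_i with
u_i ~ N(0, G), eps_i ~ N(0, sigma^2 I).  X_i carries the time basis plus
main effects and basis-by-covariate interactions for baseline modifiers,
which is the standard way of letting a baseline exposure shift the growth
curve deterministically.  Estimation is plain ML (never REML) on the
profiled deviance so log-likelihoods and BIC values are directly
comparable across mean structures and with the growth mixture model.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from . import _likelihood as lk
from .basis import DesignInfo, MeanModelSpec, RandomEffectsSpec
from .data import LongitudinalDataset
from .surfaces import MeanSurface, _broadcast

logger = logging.getLogger("growthmix.lme")

__all__ = ["LMEOptions", "LMEFit", "fit_lme", "lme_mean_surface", "bic_of"]


def bic_of(loglik: float, n_params: int, n_subjects: int) -> float:
    """BIC = -2 loglik + n_params * log(N).

    N is the number of *subjects* (the latent-class mixed-model
    convention), not the number of observations; pass a different N
    explicitly if the observation-count convention is wanted.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_subjects)


@dataclass(frozen=True)
class LMEOptions:
    max_iter: int = 500
    gtol: float = 1e-8
    force_zero_G: bool = False   # degenerate G = 0: beta reduces to pooled OLS/GLS


@dataclass
class LMEFit:
    """Fitted LME: coefficients, variance components, likelihood, BIC."""

    beta: pd.Series
    G: np.ndarray
    sigma2: float
    loglik: float
    n_params: int
    bic: float
    converged: bool
    n_iter: int
    beta_se: pd.Series
    beta_cov: np.ndarray
    design_info: DesignInfo
    n_subjects: int
    n_obs: int
    _design: lk.BlockDesign = field(repr=False, default=None)

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        z = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"coef": self.beta, "se": self.beta_se,
             "lower": self.beta - z * self.beta_se,
             "upper": self.beta + z * self.beta_se}
        )

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": {k: float(v) for k, v in self.beta.items()},
            "se": {k: float(v) for k, v in self.beta_se.items()},
            "G": self.G.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _initial_theta(design: lk.BlockDesign) -> np.ndarray:
    """Start from pooled OLS residual variance split between levels."""
    q = design.q
    Xall = np.concatenate([blk.X.reshape(-1, design.p) for blk in design.blocks])
    yall = np.concatenate([blk.Y.ravel() for blk in design.blocks])
    coef, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    resid_var = float(np.var(yall - Xall @ coef)) or 1.0
    if q == 0:
        return np.array([0.5 * np.log(resid_var)])
    G0 = np.eye(q) * resid_var / 2.0
    return lk.theta_from_G_sigma(G0, resid_var / 2.0)


def fit_lme(
    dataset: LongitudinalDataset,
    mean_spec: MeanModelSpec,
    re_spec: RandomEffectsSpec | None = None,
    options: LMEOptions | None = None,
) -> LMEFit:
    """Fit by ML: beta profiled out by GLS at each variance evaluation,
    variance parameters optimized by quasi-Newton in log-Cholesky
    coordinates (G positive semi-definite by construction)."""
    re_spec = re_spec or RandomEffectsSpec()
    options = options or LMEOptions()
    design = lk.BlockDesign.build(dataset, mean_spec, re_spec,
                                  force_zero_G=options.force_zero_G)
    names = design.info.column_names
    if design.n_obs <= design.p:
        raise ValueError("fewer observations than fixed-effect columns")
    rank = np.linalg.matrix_rank(
        np.concatenate([blk.X.reshape(-1, design.p) for blk in design.blocks])
    )
    if rank < design.p:
        raise np.linalg.LinAlgError(
            f"rank-deficient fixed-effect design ({rank} < {design.p}); "
            f"columns: {names}"
        )

    theta0 = _initial_theta(design)

    def objective(theta):
        nll, grad, _ = lk.profiled_nll_grad(theta, design)
        return nll, grad

    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        bounds=lk.theta_bounds(design.q)[: len(theta0)],
        options={"maxiter": options.max_iter, "gtol": options.gtol, "ftol": 1e-12},
    )
    converged = bool(res.success)
    if not converged:
        logger.warning("LME optimizer did not converge: %s", res.message)

    theta = res.x
    vt = lk.variance_terms(theta, design)
    beta = lk.weighted_gls(design, vt, np.ones((design.n_subjects, 1)))[0]
    loglik = float(np.sum(lk.class_logdens(design, vt, beta[None, :])))
    G, sigma2 = lk.G_sigma_from_theta(theta, design.q)
    cov = np.linalg.inv(lk.gls_information(design, vt))
    se = np.sqrt(np.diag(cov))
    q = design.q
    n_params = design.p + q * (q + 1) // 2 + 1
    return LMEFit(
        beta=pd.Series(beta, index=names),
        G=G,
        sigma2=sigma2,
        loglik=loglik,
        n_params=n_params,
        bic=bic_of(loglik, n_params, design.n_subjects),
        converged=converged,
        n_iter=int(res.nit),
        beta_se=pd.Series(se, index=names),
        beta_cov=cov,
        design_info=design.info,
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        _design=design,
    )


def lme_mean_surface(fit: LMEFit) -> MeanSurface:
    """Marginal mean surface mu(t, w) = x(t, w)' beta and its velocity.

    Velocity uses the analytic basis derivative; intercept and
    main-effect-of-w columns contribute zero.  Random effects integrate
    to zero, so this is the population-level prediction used for
    out-of-sample subjects.
    """
    info = fit.design_info
    beta = fit.beta.to_numpy()

    def mu(t, **covs):
        t, covs = _broadcast(t, covs)
        flat = {k: v.ravel() for k, v in covs.items()}
        return (info.fixed_row(t.ravel(), flat) @ beta).reshape(t.shape)

    def v(t, **covs):
        t, covs = _broadcast(t, covs)
        flat = {k: v_.ravel() for k, v_ in covs.items()}
        return (info.fixed_row_deriv(t.ravel(), flat) @ beta).reshape(t.shape)

    return MeanSurface(mu=mu, v=v)
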