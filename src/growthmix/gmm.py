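"""Growth mixture model: EM estimation of a K-class mixture of mixed
models with multinomial-logistic class membership in baseline covariates.

Each latent class k has its own fixed-effect growth curve beta_k; the
random-effect covariance G and residual variance sigma^2 are shared
across classes.  Class membership probabilities follow a softmax
pi_k(w) = exp(w' gamma_k) / sum_l exp(w' gamma_l) with gamma_K = 0, so
exposure shifts the *probability* of a growth pattern rather than the
pattern itself (a stochastic effect-modification mechanism).  The number
of classes is chosen by BIC over K = 2..5.

Estimation treats class membership as missing data.  The M-step is split
into conditional maximizations (responsibility-weighted GLS for each
beta_k, Newton-Raphson with step halving for gamma, quasi-Newton in
log-Cholesky coordinates for the variance parameters), each of which can
only increase the EM objective, so the observed-data log-likelihood is
non-decreasing across iterations.  Multiple random starts guard against
local maxima; a class whose maximal responsibility collapses below a
floor triggers a restart.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.cluster import KMeans

from . import _likelihood as lk
from .basis import DesignInfo, MeanModelSpec, RandomEffectsSpec, _Coder, tertile_code
from .data import LongitudinalDataset
from .lme import _initial_theta, bic_of
from .surfaces import MeanSurface, _broadcast

logger = logging.getLogger("growthmix.gmm")

__all__ = [
    "MembershipModelSpec",
    "GMMOptions",
    "GMMFit",
    "class_weights",
    "fit_gmm",
    "select_K",
    "membership_ratio",
    "gmm_mean_surface",
    "posterior_classify",
    "permute_classes",
]


class DegenerateClassError(RuntimeError):
    """Every EM start collapsed a class below the responsibility floor."""


class _DegenerateStart(Exception):
    pass


@dataclass(frozen=True)
class MembershipModelSpec:
    """Baseline covariates entering the multinomial-logistic class model.

    An intercept is always included (first column of the membership
    design).  ``codings`` selects continuous or tertile coding per
    covariate, mirroring the mean-model convention.
    """

    covariates: tuple[str, ...] = ()
    codings: Mapping[str, str] = field(default_factory=dict)

    def build(self, dataset: LongitudinalDataset) -> tuple[np.ndarray, list[str], tuple]:
        for name in self.covariates:
            if name not in dataset.baseline_names:
                raise KeyError(f"unknown membership covariate {name!r}")
        coders = []
        cols = [np.ones((dataset.n_subjects, 1))]
        names = ["Intercept"]
        for name in self.covariates:
            coding = self.codings.get(name, "continuous")
            cuts = None
            if coding == "tertile":
                _, cuts = tertile_code(dataset.baselines[name].to_numpy(float))
            coder = _Coder(name, coding, cuts)
            coders.append(coder)
            cols.append(coder.transform(dataset.baselines[name].to_numpy(float)))
            names += coder.column_names
        return np.concatenate(cols, axis=1), names, tuple(coders)


@dataclass(frozen=True)
class GMMOptions:
    n_starts: int = 20
    tol: float = 1e-6              # relative loglik change
    max_iter: int = 500
    seed: int = 0
    degenerate_floor: float = 1e-6
    var_maxiter: int = 12          # inner quasi-Newton steps per M-step
    perturb_frac: float = 0.25     # fraction of labels resampled per extra start


def class_weights(gamma: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Softmax membership probabilities pi(w), reference class last.

    ``gamma`` holds the K-1 free coefficient vectors (shape (K-1, q_w));
    gamma_K = 0 is appended internally.  Log-sum-exp stabilized; rows sum
    to one.
    """
    gamma = np.atleast_2d(gamma)
    W = np.atleast_2d(np.asarray(w, float))
    full = np.vstack([gamma, np.zeros((1, gamma.shape[1]))])
    logits = W @ full.T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    out = e / e.sum(axis=1, keepdims=True)
    return out[0] if np.ndim(w) == 1 else out


def _log_class_weights(gamma: np.ndarray | None, W: np.ndarray, K: int) -> np.ndarray:
    if K == 1 or gamma is None:
        return np.zeros((W.shape[0], K))
    full = np.vstack([gamma, np.zeros((1, gamma.shape[1]))])
    logits = W @ full.T
    return logits - logsumexp(logits, axis=1, keepdims=True)


def _fit_weighted_multinomial(
    W: np.ndarray, tau: np.ndarray, gamma0: np.ndarray,
    max_iter: int = 60, tol: float = 1e-11,
) -> np.ndarray:
    """Newton-Raphson with step halving on the tau-weighted multinomial
    log-likelihood; only ascent steps are accepted."""
    K = tau.shape[1]
    qw = W.shape[1]
    gamma = gamma0.copy()

    def value(g):
        return float(np.sum(tau * _log_class_weights(g, W, K)))

    f = value(gamma)
    for _ in range(max_iter):
        P = class_weights(gamma, W)
        grad = ((tau - P)[:, : K - 1].T @ W).ravel()
        H = np.zeros(((K - 1) * qw, (K - 1) * qw))
        for k in range(K - 1):
            for l in range(K - 1):
                wts = P[:, k] * ((k == l) - P[:, l])
                H[k * qw:(k + 1) * qw, l * qw:(l + 1) * qw] = -(W * wts[:, None]).T @ W
        step = np.linalg.solve(-(H - 1e-10 * np.eye(H.shape[0])), grad).reshape(K - 1, qw)
        scale = 1.0
        for _ in range(30):
            cand = gamma + scale * step
            f_new = value(cand)
            if f_new >= f:
                break
            scale *= 0.5
        else:
            return gamma
        if f_new - f < tol * (abs(f) + 1.0):
            return cand
        gamma, f = cand, f_new
    return gamma


@dataclass
class GMMFit:
    """Fitted K-class growth mixture model.

    Classes are reported in canonical order (descending class size) to
    tame label switching; gamma is re-expressed against the new
    reference class after reordering, which leaves the softmax invariant.
    """

    K: int
    betas: pd.DataFrame               # K rows, p coefficient columns
    gamma: np.ndarray | None          # (K-1, q_w); reference class K fixed at 0
    gamma_names: list[str]
    G: np.ndarray
    sigma2: float
    posterior: np.ndarray             # (n_subjects, K)
    loglik: float
    n_params: int
    bic: float
    converged: bool
    n_iter: int
    n_starts_used: int
    n_restarts: int
    loglik_trace: np.ndarray
    loglik_traces: list[np.ndarray]
    design_info: DesignInfo
    subject_ids: list[str]
    n_subjects: int
    n_obs: int
    _design: lk.BlockDesign = field(repr=False, default=None)
    _W: np.ndarray = field(repr=False, default=None)
    _w_coders: tuple = field(repr=False, default=())
    _psi_cov: np.ndarray | None = field(repr=False, default=None)

    @property
    def class_sizes(self) -> np.ndarray:
        return self.posterior.sum(axis=0)

    def membership_row(self, covs: Mapping[str, float | np.ndarray]) -> np.ndarray:
        """Membership design rows (1, coded covariates) for given values."""
        sizes = [np.size(np.asarray(covs[c.name])) for c in self._w_coders] or [1]
        n = max(sizes)
        cols = [np.ones((n, 1))]
        for c in self._w_coders:
            v = np.broadcast_to(np.atleast_1d(np.asarray(covs[c.name], float)), (n,))
            cols.append(c.transform(v))
        return np.concatenate(cols, axis=1)

    # -- observed information (inverse covariance of all free params) --

    def _pack(self) -> np.ndarray:
        parts = [self.betas.to_numpy().ravel()]
        if self.K > 1:
            parts.append(self.gamma.ravel())
        parts.append(lk.theta_from_G_sigma(self.G, self.sigma2))
        return np.concatenate(parts)

    def _loglik_grad(self, psi: np.ndarray) -> tuple[float, np.ndarray]:
        design, W, K = self._design, self._W, self.K
        p, qw = design.p, (W.shape[1] if K > 1 else 0)
        betas = psi[: K * p].reshape(K, p)
        gamma = psi[K * p: K * p + (K - 1) * qw].reshape(K - 1, qw) if K > 1 else None
        theta = psi[K * p + (K - 1) * qw:]
        vt = lk.variance_terms(theta, design)
        A = lk.class_logdens(design, vt, betas)
        a = A + _log_class_weights(gamma, W if K > 1 else np.ones((design.n_subjects, 1)), K)
        ll_i = logsumexp(a, axis=1)
        tau = np.exp(a - ll_i[:, None])
        g_beta = np.zeros((K, p))
        for blk, Vi in zip(design.blocks, vt.Vinv):
            mu = np.einsum("mip,kp->kmi", blk.X, betas)
            r = blk.Y[None, :, :] - mu
            Vr = np.einsum("ij,kmj->kmi", Vi, r)
            g_beta += np.einsum("mk,mip,kmi->kp", tau[blk.idx], blk.X, Vr)
        parts = [g_beta.ravel()]
        if K > 1:
            P = class_weights(gamma, W)
            parts.append(((tau - P)[:, : K - 1].T @ W).ravel())
        parts.append(lk._theta_grad_pieces(design, vt, betas, tau, theta))
        return float(ll_i.sum()), np.concatenate(parts)

    def observed_information(self) -> np.ndarray:
        """Negative Hessian of the observed-data log-likelihood at the
        fit, via central differences of the analytic score."""
        psi = self._pack()
        n = len(psi)
        H = np.zeros((n, n))
        for j in range(n):
            h = 1e-5 * max(1.0, abs(psi[j]))
            up, dn = psi.copy(), psi.copy()
            up[j] += h
            dn[j] -= h
            _, gu = self._loglik_grad(up)
            _, gd = self._loglik_grad(dn)
            H[j] = (gu - gd) / (2.0 * h)
        H = 0.5 * (H + H.T)
        return -H

    def parameter_covariance(self) -> np.ndarray:
        if self._psi_cov is None:
            self._psi_cov = np.linalg.inv(self.observed_information())
        return self._psi_cov

    def gamma_cov(self) -> np.ndarray:
        """Covariance of vec(gamma) from the inverse observed information."""
        K, p = self.K, self._design.p
        qw = self._W.shape[1]
        cov = self.parameter_covariance()
        sl = slice(K * p, K * p + (K - 1) * qw)
        return cov[sl, sl]

    def to_json(self, path=None) -> str:
        payload = {
            "K": self.K,
            "class_coefficients": {
                f"class_{k + 1}": {c: float(v) for c, v in row.items()}
                for k, (_, row) in enumerate(self.betas.iterrows())
            },
            "gamma": self.gamma.tolist() if self.gamma is not None else None,
            "gamma_names": self.gamma_names,
            "G": self.G.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "class_sizes": self.class_sizes.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _derived_init_coefs(design: lk.BlockDesign) -> np.ndarray:
    """Per-subject OLS coefficients on [1, basis] used to seed k-means."""
    d = design.info.basis.n_columns + 1
    out = np.zeros((design.n_subjects, d))
    for blk in design.blocks:
        M = blk.X[0][:, :d]  # intercept + basis columns are shared layout
        coefs, *_ = np.linalg.lstsq(M, blk.Y.T, rcond=None)
        out[blk.idx] = coefs.T
    return out


def _em_run(
    design: lk.BlockDesign,
    W: np.ndarray | None,
    K: int,
    tau: np.ndarray,
    theta: np.ndarray,
    options: GMMOptions,
) -> dict:
    qw = W.shape[1] if (W is not None and K > 1) else 0
    gamma = np.zeros((K - 1, qw)) if K > 1 else None
    bounds = lk.theta_bounds(design.q)[: len(theta)]
    trace = []
    prev_ll = -np.inf
    converged = False
    for it in range(options.max_iter):
        vt = lk.variance_terms(theta, design)
        betas = lk.weighted_gls(design, vt, tau)
        if K > 1:
            gamma = _fit_weighted_multinomial(W, tau, gamma)
        q0 = lk.q_variance(theta, design, betas, tau)
        res = minimize(
            lk.q_variance_neg_grad, theta, args=(design, betas, tau),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.var_maxiter},
        )
        if -res.fun > q0:
            theta = res.x
            vt = lk.variance_terms(theta, design)
        A = lk.class_logdens(design, vt, betas)
        a = A + _log_class_weights(gamma, W if K > 1 else np.ones((design.n_subjects, 1)), K)
        ll_i = logsumexp(a, axis=1)
        ll = float(ll_i.sum())
        tau = np.exp(a - ll_i[:, None])
        trace.append(ll)
        if K > 1 and np.any(tau.max(axis=0) < options.degenerate_floor):
            raise _DegenerateStart
        if it > 0 and abs(ll - prev_ll) < options.tol * (abs(prev_ll) + 1.0):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return {
        "betas": betas, "gamma": gamma, "theta": theta, "tau": tau,
        "loglik": prev_ll, "trace": np.asarray(trace), "converged": converged,
        "n_iter": len(trace),
    }


def _initial_tau(labels: np.ndarray, K: int) -> np.ndarray:
    n = len(labels)
    tau = np.full((n, K), 0.1 / K)
    tau[np.arange(n), labels] += 0.9
    return tau / tau.sum(axis=1, keepdims=True)


def permute_classes(fit: GMMFit, perm: Iterable[int]) -> GMMFit:
    """Relabel classes by ``perm`` (new index k holds old class perm[k]).

    gamma is re-expressed relative to the new reference class; the
    cached parameter covariance is dropped (it indexes the old layout).
    """
    perm = list(perm)
    K = fit.K
    betas = fit.betas.iloc[perm].reset_index(drop=True)
    gamma = fit.gamma
    if K > 1:
        full = np.vstack([fit.gamma, np.zeros((1, fit.gamma.shape[1]))])
        full = full[perm]
        gamma = full[:-1] - full[-1]
    return dc_replace(
        fit, betas=betas, gamma=gamma,
        posterior=fit.posterior[:, perm], _psi_cov=None,
    )


def fit_gmm(
    dataset: LongitudinalDataset,
    mean_spec: MeanModelSpec,
    re_spec: RandomEffectsSpec | None = None,
    membership_spec: MembershipModelSpec | None = None,
    K: int = 2,
    options: GMMOptions | None = None,
) -> GMMFit:
    """Fit the K-class growth mixture model by multi-start EM.

    With K = 1 the model has no membership component and reduces exactly
    to the ML linear mixed-effects model.  Initialization clusters
    per-subject OLS growth coefficients into K groups (k-means); extra
    starts perturb the initial labels.  The best converged start by
    log-likelihood is returned, classes ordered by descending size.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    re_spec = re_spec or RandomEffectsSpec()
    membership_spec = membership_spec or MembershipModelSpec()
    options = options or GMMOptions()
    design = lk.BlockDesign.build(dataset, mean_spec, re_spec)
    W, w_names, w_coders = membership_spec.build(dataset)
    qw = W.shape[1] if K > 1 else 0
    q = design.q
    n_params = K * design.p + (K - 1) * qw + q * (q + 1) // 2 + 1
    if dataset.n_subjects <= n_params:
        logger.warning(
            "n_subjects (%d) <= free parameters (%d); fit may be unstable",
            dataset.n_subjects, n_params,
        )

    theta0 = _initial_theta(design)
    coefs = _derived_init_coefs(design)
    scaled = (coefs - coefs.mean(axis=0)) / (coefs.std(axis=0) + 1e-12)
    ss = np.random.SeedSequence([options.seed, K])
    rngs = [np.random.default_rng(s) for s in ss.spawn(max(options.n_starts, 1))]
    base_labels = (
        KMeans(n_clusters=K, n_init=4, random_state=int(ss.generate_state(1)[0] % (2**31)))
        .fit(scaled).labels_
        if K > 1 else np.zeros(design.n_subjects, int)
    )

    best = None
    traces = []
    n_restarts = 0
    n_used = 0
    for s, rng in enumerate(rngs):
        labels = base_labels.copy()
        if s > 0 and K > 1:
            flip = rng.random(len(labels)) < options.perturb_frac
            labels[flip] = rng.integers(0, K, flip.sum())
        n_used += 1
        try:
            res = _em_run(design, W, K, _initial_tau(labels, K), theta0.copy(), options)
        except _DegenerateStart:
            n_restarts += 1
            continue
        traces.append(res["trace"])
        if best is None or res["loglik"] > best["loglik"]:
            best = res
    if best is None:
        raise DegenerateClassError(
            f"all {n_used} EM starts produced a degenerate class; try smaller K than {K}"
        )
    if not best["converged"]:
        logger.warning("EM did not converge in %d iterations (K=%d)", options.max_iter, K)

    # canonical order: descending class size
    sizes = best["tau"].sum(axis=0)
    perm = list(np.argsort(-sizes, kind="stable"))
    names = design.info.column_names
    G, sigma2 = lk.G_sigma_from_theta(best["theta"], q)
    fit = GMMFit(
        K=K,
        betas=pd.DataFrame(best["betas"], columns=names),
        gamma=best["gamma"],
        gamma_names=w_names,
        G=G,
        sigma2=sigma2,
        posterior=best["tau"],
        loglik=best["loglik"],
        n_params=n_params,
        bic=bic_of(best["loglik"], n_params, design.n_subjects),
        converged=best["converged"],
        n_iter=best["n_iter"],
        n_starts_used=n_used,
        n_restarts=n_restarts,
        loglik_trace=best["trace"],
        loglik_traces=traces,
        design_info=design.info,
        subject_ids=design.subject_ids,
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        _design=design,
        _W=W,
        _w_coders=w_coders,
    )
    if perm != list(range(K)):
        fit = permute_classes(fit, perm)
    return fit


def select_K(
    dataset: LongitudinalDataset,
    mean_spec: MeanModelSpec,
    re_spec: RandomEffectsSpec | None = None,
    membership_spec: MembershipModelSpec | None = None,
    K_range: Iterable[int] = range(2, 6),
    options: GMMOptions | None = None,
) -> tuple[GMMFit, pd.DataFrame]:
    """Fit over a K grid and keep the lowest-BIC converged fit.

    Ties break toward smaller K.  Returns the winning fit plus the full
    BIC-by-K table (non-converging K values recorded with NaN BIC).
    """
    Ks = sorted(set(int(k) for k in K_range))
    if not Ks:
        raise ValueError("K_range must be nonempty")
    rows = []
    best_fit = None
    for K in Ks:
        try:
            fit = fit_gmm(dataset, mean_spec, re_spec, membership_spec, K, options)
        except DegenerateClassError:
            rows.append({"K": K, "bic": np.nan, "loglik": np.nan, "converged": False})
            continue
        rows.append({"K": K, "bic": fit.bic, "loglik": fit.loglik,
                     "converged": fit.converged})
        if fit.converged and (best_fit is None or fit.bic < best_fit.bic):
            best_fit = fit
    if best_fit is None:
        raise RuntimeError(f"no converged growth mixture fit for any K in {Ks}")
    return best_fit, pd.DataFrame(rows)


def membership_ratio(
    fit: GMMFit, class_k: int, covariate: str, delta: float = 1.0, level: float = 0.90
) -> dict:
    """Multiplicative change in pi_k / pi_K per ``delta``-unit increase in
    a membership covariate, with a Wald confidence interval.

    On a log2-scaled exposure, delta = 1 corresponds to a doubling.  The
    reference class (class K) has ratio identically 1 and is rejected.
    """
    if fit.K < 2:
        raise ValueError("membership ratios require K >= 2")
    if not 1 <= class_k <= fit.K:
        raise ValueError(f"class_k must be in 1..{fit.K}")
    if class_k == fit.K:
        raise ValueError("reference class requested: its ratio is identically 1")
    j = fit.gamma_names.index(covariate)
    qw = len(fit.gamma_names)
    g = fit.gamma[class_k - 1, j]
    cov = fit.gamma_cov()
    se = float(np.sqrt(cov[(class_k - 1) * qw + j, (class_k - 1) * qw + j]))
    z = norm.ppf(0.5 + level / 2.0)
    return {
        "class": class_k,
        "covariate": covariate,
        "delta": delta,
        "ratio": float(np.exp(delta * g)),
        "lower": float(np.exp(delta * (g - z * se))),
        "upper": float(np.exp(delta * (g + z * se))),
        "gamma": float(g),
        "se": se,
        "level": level,
    }


def gmm_mean_surface(fit: GMMFit) -> MeanSurface:
    """Marginal mean mu(t, w) = sum_k pi_k(w) x(t)' beta_k and velocity.

    Class weights depend on w only, so velocity is the pi-weighted
    average of the class velocities (exact, analytic)."""
    info = fit.design_info
    betas = fit.betas.to_numpy()

    def _weights(covs, n):
        if fit.K == 1:
            return np.ones((n, 1))
        pi = np.atleast_2d(class_weights(fit.gamma, fit.membership_row(covs)))
        if pi.shape[0] == 1 and n > 1:  # intercept-only membership model
            pi = np.broadcast_to(pi, (n, fit.K))
        return pi

    def mu(t, **covs):
        t, covs = _broadcast(t, covs)
        flat = {k: v.ravel() for k, v in covs.items()}
        Xrows = info.fixed_row(t.ravel(), flat)
        pi = _weights(flat, t.size)
        return np.einsum("nk,nk->n", pi, Xrows @ betas.T).reshape(t.shape)

    def v(t, **covs):
        t, covs = _broadcast(t, covs)
        flat = {k: v_.ravel() for k, v_ in covs.items()}
        Drows = info.fixed_row_deriv(t.ravel(), flat)
        pi = _weights(flat, t.size)
        return np.einsum("nk,nk->n", pi, Drows @ betas.T).reshape(t.shape)

    return MeanSurface(mu=mu, v=v)


def posterior_classify(fit: GMMFit) -> tuple[pd.Series, pd.DataFrame]:
    """Hard assignments (argmax posterior, ties toward the lower class
    index) plus a per-class size / mean-confidence table."""
    assign = np.argmax(fit.posterior, axis=1) + 1  # argmax takes first max: low index wins ties
    series = pd.Series(assign, index=fit.subject_ids, name="class")
    rows = []
    for k in range(1, fit.K + 1):
        mask = assign == k
        rows.append({
            "class": k,
            "size": int(mask.sum()),
            "mean_posterior": float(fit.posterior[mask, k - 1].mean()) if mask.any() else np.nan,
        })
    return series, pd.DataFrame(rows)
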