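"""Synthetic longitudinal growth data under eight generating conditions.

The generator emulates childhood-BMI-style trajectories: n subjects
observed at fixed ages, a binary baseline covariate w1 ~ Bernoulli(0.5)
(sex-like), and a continuous standardized exposure w2 ~ N(0, 1)
(log2-metabolite-like).  Conditions cross three axes:

* mechanism — deterministic (exposure shifts each subject's growth
  coefficients by a fixed function) vs stochastic (exposure shifts the
  probabilities of discrete latent growth classes);
* growth form — linear vs quadratic (J-shaped, adiposity-rebound-like)
  mean curves;
* exposure form — linear (monotonic) vs nonlinear (non-monotonic,
  implemented as a quadratic-in-w2 term).

Data types 1..8 enumerate the 2x2x2 grid in the order
(D/L/L, S/L/L, D/L/NL, S/L/NL, D/Q/L, S/Q/L, D/Q/NL, S/Q/NL).
Numeric effect sizes are the package's documented defaults (see
docs/methods.md); every parameter can be overridden.  Each condition
also yields an exact oracle mean surface mu(t, w1, w2) and velocity
v(t, w1, w2) for error metrics.

Replicate streams are independent substreams of the master seed keyed by
(data type, role, replicate index), so any single replicate is
reproducible in isolation and results are independent of generation
order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .data import LongitudinalDataset
from .surfaces import MeanSurface, _broadcast

__all__ = [
    "ConditionParams",
    "SimulationCondition",
    "default_condition_params",
    "default_condition",
    "generate_dataset",
    "oracle_surface",
    "DEFAULT_TIMES",
]

DEFAULT_TIMES = (1.0, 3.25, 5.5, 7.75, 10.0)
_ROLE_CODE = {"training": 0, "validation": 1}


@dataclass(frozen=True)
class ConditionParams:
    """Numeric bundle for one generating condition.

    Deterministic mechanism: subject coefficients are
    base + w1 * w1_shift + exposure_effect * e(w2) + u_i with
    e(w2) = w2 (linear) or w2^2 (nonlinear) and u_i ~ N(0, diag(re_sd^2))
    on every generating coefficient.

    Stochastic mechanism: a latent class with curve coefficients
    class_coefs[k] is drawn from softmax(class_logits @ g(w)) with
    g(w) = (1, w1, w2) or (1, w1, w2, w2^2); subjects get a random
    intercept only (re_sd[0]).
    """

    n_subjects: int = 250
    times: tuple[float, ...] = DEFAULT_TIMES
    w1_prob: float = 0.5
    base_coefs: tuple[float, ...] | None = None
    w1_shift: tuple[float, ...] | None = None
    exposure_effect: tuple[float, ...] | None = None
    class_coefs: tuple[tuple[float, ...], ...] | None = None
    class_logits: tuple[tuple[float, ...], ...] | None = None
    re_sd: tuple[float, ...] = (1.0,)
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0 or any(s <= 0 for s in self.re_sd):
            raise ValueError("variance components must be positive")
        t = np.asarray(self.times)
        if len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.w1_prob < 1:
            raise ValueError("w1_prob must be in (0, 1)")


@dataclass(frozen=True)
class SimulationCondition:
    mechanism: Literal["deterministic", "stochastic"]
    growth_form: Literal["linear", "quadratic"]
    exposure_form: Literal["linear", "nonlinear"]
    params: ConditionParams = field(default_factory=ConditionParams)

    def __post_init__(self) -> None:
        p = self.params
        ncoef = 2 if self.growth_form == "linear" else 3
        if self.mechanism == "deterministic":
            for name in ("base_coefs", "w1_shift", "exposure_effect"):
                v = getattr(p, name)
                if v is None or len(v) != ncoef:
                    raise ValueError(f"deterministic condition needs {name} of length {ncoef}")
            if len(p.re_sd) != ncoef:
                raise ValueError("deterministic re_sd must cover every generating coefficient")
        else:
            if p.class_coefs is None or p.class_logits is None:
                raise ValueError("stochastic condition needs class_coefs and class_logits")
            if any(len(m) != ncoef for m in p.class_coefs):
                raise ValueError(f"class_coefs rows must have length {ncoef}")
            qg = 4 if self.exposure_form == "nonlinear" else 3
            if any(len(g) != qg for g in p.class_logits):
                raise ValueError(f"class_logits rows must have length {qg}")
            if len(p.class_logits) != len(p.class_coefs):
                raise ValueError("one logit row per class required")

    @property
    def data_type(self) -> int:
        """Index 1..8 in the (exposure within growth, D before S) order."""
        i = 1
        i += {"deterministic": 0, "stochastic": 1}[self.mechanism]
        i += {"linear": 0, "nonlinear": 2}[self.exposure_form]
        i += {"linear": 0, "quadratic": 4}[self.growth_form]
        return i

    @property
    def label(self) -> str:
        return "{}/{}/{}".format(
            self.mechanism[0].upper(),
            "L" if self.growth_form == "linear" else "NL",
            "L" if self.exposure_form == "linear" else "NL",
        )


# -- documented default parameter bundles ------------------------------

_LIN_BASE = (16.0, 0.35)
_LIN_SHIFT = (0.5, 0.05)
_QUAD_BASE = (17.5, -1.0, 0.10)        # J-shape: rebound near age 5
_QUAD_SHIFT = (0.5, 0.0, 0.0)
_LIN_CLASSES = ((18.5, 0.7), (16.5, 0.45), (14.5, 0.2))
_QUAD_CLASSES = ((19.0, -1.3, 0.13), (16.5, -0.6, 0.07), (14.0, 0.45, 0.0))
_MONO_LOGITS = ((0.3, 0.1, 0.8), (0.2, 0.0, 0.3), (0.0, 0.0, 0.0))
_NONMONO_LOGITS = ((0.2, 0.1, 0.2, 0.7), (0.4, 0.0, 0.6, -0.5), (0.0, 0.0, 0.0, 0.0))

_DEFAULTS: dict[int, dict] = {
    1: dict(base_coefs=_LIN_BASE, w1_shift=_LIN_SHIFT, exposure_effect=(0.4, 0.12),
            re_sd=(1.2, 0.12)),
    3: dict(base_coefs=_LIN_BASE, w1_shift=_LIN_SHIFT, exposure_effect=(0.3, 0.10),
            re_sd=(1.2, 0.12)),
    5: dict(base_coefs=_QUAD_BASE, w1_shift=_QUAD_SHIFT, exposure_effect=(0.3, 0.08, 0.0),
            re_sd=(1.2, 0.12, 0.015)),
    7: dict(base_coefs=_QUAD_BASE, w1_shift=_QUAD_SHIFT, exposure_effect=(0.25, 0.06, 0.0),
            re_sd=(1.2, 0.12, 0.015)),
    2: dict(class_coefs=_LIN_CLASSES, class_logits=_MONO_LOGITS, re_sd=(1.0,)),
    4: dict(class_coefs=_LIN_CLASSES, class_logits=_NONMONO_LOGITS, re_sd=(1.0,)),
    6: dict(class_coefs=_QUAD_CLASSES, class_logits=_MONO_LOGITS, re_sd=(1.0,)),
    8: dict(class_coefs=_QUAD_CLASSES, class_logits=_NONMONO_LOGITS, re_sd=(1.0,)),
}


def default_condition_params(data_type: int, seed: int = 0, **overrides) -> ConditionParams:
    """The package's documented default bundle for data type 1..8."""
    if data_type not in _DEFAULTS:
        raise ValueError("data_type must be in 1..8")
    kwargs = dict(_DEFAULTS[data_type])
    kwargs.update(overrides)
    return ConditionParams(seed=seed, **kwargs)


def default_condition(data_type: int, seed: int = 0, **overrides) -> SimulationCondition:
    mechanism = "deterministic" if data_type % 2 == 1 else "stochastic"
    growth = "linear" if data_type <= 4 else "quadratic"
    exposure = "linear" if ((data_type - 1) % 4) < 2 else "nonlinear"
    return SimulationCondition(
        mechanism, growth, exposure, default_condition_params(data_type, seed, **overrides)
    )


# -- generation --------------------------------------------------------

def _poly(times: np.ndarray, ncoef: int) -> np.ndarray:
    return np.column_stack([times**p for p in range(ncoef)])


def _membership_design(w1: np.ndarray, w2: np.ndarray, nonlinear: bool) -> np.ndarray:
    cols = [np.ones_like(w2), w1, w2]
    if nonlinear:
        cols.append(w2**2)
    return np.column_stack(cols)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def generate_dataset(
    condition: SimulationCondition,
    role: Literal["training", "validation"] = "training",
    replicate_index: int = 0,
) -> LongitudinalDataset:
    """Draw one replicate dataset for a condition.

    Deterministic conditions put subject-level random effects on every
    generating coefficient; stochastic conditions use a random intercept
    within class.  Residuals are iid Gaussian.
    """
    p = condition.params
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(p.seed), int(condition.data_type), _ROLE_CODE[role], int(replicate_index)]
        )
    )
    n = p.n_subjects
    times = np.asarray(p.times, float)
    ncoef = 2 if condition.growth_form == "linear" else 3
    M = _poly(times, ncoef)

    w1 = (rng.random(n) < p.w1_prob).astype(float)
    w2 = rng.standard_normal(n)

    if condition.mechanism == "deterministic":
        e = w2 if condition.exposure_form == "linear" else w2**2
        coefs = (
            np.asarray(p.base_coefs)[None, :]
            + w1[:, None] * np.asarray(p.w1_shift)[None, :]
            + e[:, None] * np.asarray(p.exposure_effect)[None, :]
        )
        u = rng.standard_normal((n, ncoef)) * np.asarray(p.re_sd)[None, :]
        mean = (coefs + u) @ M.T
    else:
        Wd = _membership_design(w1, w2, condition.exposure_form == "nonlinear")
        pi = _softmax(Wd @ np.asarray(p.class_logits).T)
        cum = np.cumsum(pi, axis=1)
        draw = rng.random(n)[:, None]
        z = (draw > cum).sum(axis=1)
        u0 = rng.standard_normal(n) * p.re_sd[0]
        mean = np.asarray(p.class_coefs)[z] @ M.T + u0[:, None]

    y = mean + rng.standard_normal((n, len(times))) * p.noise_sd

    width = len(str(n))
    ids = np.array([f"s{i + 1:0{width}d}" for i in range(n)])
    obs = pd.DataFrame({
        "subject": np.repeat(ids, len(times)),
        "time": np.tile(times, n),
        "y": y.ravel(),
    })
    baselines = pd.DataFrame({"w1": w1, "w2": w2}, index=pd.Index(ids, name="subject"))
    return LongitudinalDataset.from_frames(obs, baselines)


def oracle_surface(condition: SimulationCondition) -> MeanSurface:
    """Exact mu(t, w1, w2) = E(Y | t, w1, w2) and v = d/dt mu.

    Random effects and noise have mean zero, so only the fixed part of
    the generator appears.  For stochastic conditions the class weights
    depend on w alone and multiply the class curves.
    """
    p = condition.params
    ncoef = 2 if condition.growth_form == "linear" else 3
    nonlinear = condition.exposure_form == "nonlinear"

    if condition.mechanism == "deterministic":
        base = np.asarray(p.base_coefs)
        shift = np.asarray(p.w1_shift)
        eff = np.asarray(p.exposure_effect)

        def coef_fn(w1, w2):
            e = w2 if not nonlinear else w2**2
            return base + np.multiply.outer(w1, shift) + np.multiply.outer(e, eff)

        def mu(t, **covs):
            t, covs = _broadcast(t, covs)
            c = coef_fn(covs["w1"], covs["w2"])
            return np.einsum("...p,...p->...", c, np.stack([t**k for k in range(ncoef)], axis=-1))

        def v(t, **covs):
            t, covs = _broadcast(t, covs)
            c = coef_fn(covs["w1"], covs["w2"])
            dT = np.stack([k * t ** (k - 1) if k else np.zeros_like(t) for k in range(ncoef)], axis=-1)
            return np.einsum("...p,...p->...", c, dT)

        return MeanSurface(mu=mu, v=v)

    m = np.asarray(p.class_coefs)            # (K0, ncoef)
    g = np.asarray(p.class_logits)           # (K0, qg)

    def weights(w1, w2):
        cols = [np.ones_like(w2), w1, w2] + ([w2**2] if nonlinear else [])
        Wd = np.stack(cols, axis=-1)
        return _softmax(Wd @ g.T)

    def mu(t, **covs):
        t, covs = _broadcast(t, covs)
        pi = weights(covs["w1"], covs["w2"])
        curves = np.stack([t**k for k in range(ncoef)], axis=-1) @ m.T
        return np.einsum("...k,...k->...", pi, curves)

    def v(t, **covs):
        t, covs = _broadcast(t, covs)
        pi = weights(covs["w1"], covs["w2"])
        dT = np.stack([k * t ** (k - 1) if k else np.zeros_like(t) for k in range(ncoef)], axis=-1)
        return np.einsum("...k,...k->...", pi, dT @ m.T)

    return MeanSurface(mu=mu, v=v)
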