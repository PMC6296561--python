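"""Time bases (linear, quadratic, B-spline), design assembly, exposure coding.

The mean growth curve is a linear combination of basis functions of age.
B-spline bases follow the common statistical-software convention: the
first spline function is dropped and a separate intercept column is
carried, so a quadratic spline with one interior knot contributes three
columns (the X1-X3 layout seen in fitted-coefficient tables).  Baseline
covariates named as *modifiers* enter as main effects and as pairwise
interactions with every basis column, which is how a linear mixed-effects
model encodes effect modification of growth by a baseline exposure.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.interpolate import BSpline

from .data import LongitudinalDataset

__all__ = [
    "BasisSpec",
    "MeanModelSpec",
    "RandomEffectsSpec",
    "DesignInfo",
    "build_basis",
    "basis_derivative",
    "build_design",
    "tertile_code",
    "spline_sse_report",
]

BasisKind = Literal["linear", "quadratic", "bspline"]


class BasisDomainError(ValueError):
    """Evaluation point outside the spline boundary interval."""


@dataclass(frozen=True)
class BasisSpec:
    """Functional form of growth over time.

    For polynomial kinds an optional ``center`` offset is subtracted from
    time before evaluation; centering at a meaningful age makes the
    polynomial coefficients interpretable as level/velocity/acceleration
    at that age.  Boundary knots for B-splines default to the data range
    at design-build time (``resolve``).
    """

    kind: BasisKind = "linear"
    degree: int = 1
    interior_knots: tuple[float, ...] = ()
    boundary_knots: tuple[float, float] | None = None
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic", "bspline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "linear":
            object.__setattr__(self, "degree", 1)
        elif self.kind == "quadratic":
            object.__setattr__(self, "degree", 2)
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.kind != "bspline" and self.interior_knots:
            raise ValueError("interior knots only apply to kind='bspline'")
        ik = tuple(float(k) for k in self.interior_knots)
        object.__setattr__(self, "interior_knots", ik)
        if any(b >= a for a, b in zip(ik[1:], ik[:-1])):
            raise ValueError("interior knots must be strictly increasing")
        if self.boundary_knots is not None:
            lo, hi = self.boundary_knots
            if not lo < hi:
                raise ValueError("boundary knots must satisfy lower < upper")
            if ik and not (lo < ik[0] and ik[-1] < hi):
                raise ValueError("interior knots must lie strictly inside boundary interval")
            object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def n_columns(self) -> int:
        if self.kind == "bspline":
            return self.degree + len(self.interior_knots)
        return self.degree

    @property
    def column_names(self) -> list[str]:
        if self.kind == "linear":
            return ["t"]
        if self.kind == "quadratic":
            return ["t", "t2"]
        return [f"X{j + 1}" for j in range(self.n_columns)]

    def resolve(self, t: np.ndarray) -> "BasisSpec":
        """Fill missing boundary knots from the data range."""
        if self.kind != "bspline" or self.boundary_knots is not None:
            return self
        t = np.asarray(t, float)
        return replace(self, boundary_knots=(float(t.min()), float(t.max())))

    def _knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.concatenate(
            [[lo] * (self.degree + 1), self.interior_knots, [hi] * (self.degree + 1)]
        )


def _check_domain(spec: BasisSpec, t: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, float))
    if spec.kind != "bspline":
        return t - spec.center
    if spec.boundary_knots is None:
        raise ValueError("bspline basis has unresolved boundary knots; call spec.resolve(t)")
    lo, hi = spec.boundary_knots
    bad = (t < lo - tol) | (t > hi + tol)
    if bad.any():
        raise BasisDomainError(
            f"time values outside spline boundary [{lo}, {hi}]: {np.unique(t[bad])[:10]}"
        )
    return np.clip(t, lo, hi)


def _full_bspline(spec: BasisSpec, t: np.ndarray, deriv: int = 0) -> np.ndarray:
    """All degree+m+1 spline functions (no function dropped)."""
    kts = spec._knot_vector()
    n_funcs = len(kts) - spec.degree - 1
    if deriv == 0:
        return BSpline.design_matrix(t, kts, spec.degree, extrapolate=False).toarray()
    cols = []
    for j in range(n_funcs):
        coef = np.zeros(n_funcs)
        coef[j] = 1.0
        bj = BSpline(kts, coef, spec.degree, extrapolate=False).derivative(deriv)
        # closed right endpoint: evaluate the derivative from the left
        lo, hi = spec.boundary_knots
        tt = np.where(t >= hi, np.nextafter(hi, lo), t)
        cols.append(bj(tt))
    return np.column_stack(cols)


def build_basis(spec: BasisSpec, t_values) -> np.ndarray:
    """Basis matrix: one row per time value, one column per basis function.

    Deterministic function of (spec, t) only.  The intercept is *not*
    included; for B-splines the first spline function is dropped (it is
    absorbed by the intercept carried separately in the design).
    """
    t = _check_domain(spec, t_values)
    if spec.kind == "bspline":
        return _full_bspline(spec, t)[:, 1:]
    return np.column_stack([t ** (p + 1) for p in range(spec.degree)])


def basis_derivative(spec: BasisSpec, t_values) -> np.ndarray:
    """d/dt of each basis column, same shape as :func:`build_basis` output."""
    t = _check_domain(spec, t_values)
    if spec.kind == "bspline":
        return _full_bspline(spec, t, deriv=1)[:, 1:]
    return np.column_stack([(p + 1) * t ** p for p in range(spec.degree)])


@dataclass(frozen=True)
class MeanModelSpec:
    """Mean structure: time basis plus baseline modifiers of growth.

    Column order is fixed as [intercept, basis columns, modifier main
    effects, modifier x basis interactions] so coefficient labels are
    stable across fits.  ``codings`` selects continuous (default) or
    tertile coding per modifier.
    """

    basis: BasisSpec = field(default_factory=BasisSpec)
    modifiers: tuple[str, ...] = ()
    codings: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mods = tuple(self.modifiers)
        if len(set(mods)) != len(mods):
            raise ValueError("modifier names must be unique")
        object.__setattr__(self, "modifiers", mods)
        for name, coding in self.codings.items():
            if coding not in ("continuous", "tertile"):
                raise ValueError(f"unknown exposure coding {coding!r} for {name!r}")

    def coding_of(self, name: str) -> str:
        return self.codings.get(name, "continuous")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Which coefficients get subject-level random effects.

    ``intercept_only`` gives a scalar random intercept; ``all`` lets the
    intercept and every growth coefficient vary with an unstructured
    covariance.
    """

    which: Literal["intercept_only", "all"] = "intercept_only"

    def q(self, basis: BasisSpec) -> int:
        return 1 if self.which == "intercept_only" else 1 + basis.n_columns


def tertile_code(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Two indicator columns (middle, upper tertile; lowest = reference).

    Cut points are the empirical 1/3 and 2/3 linear-interpolation
    quantiles; ties go to the lower group.
    """
    v = np.asarray(values, float)
    if len(np.unique(v)) < 3:
        raise ValueError("degenerate exposure: fewer than 3 distinct values")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3], method="linear")
    mid = (v > q1) & (v <= q2)
    hi = v > q2
    return np.column_stack([mid, hi]).astype(float), (float(q1), float(q2))


class _Coder:
    """Maps raw covariate values to design columns."""

    def __init__(self, name: str, coding: str, cuts: tuple[float, float] | None = None):
        self.name, self.coding, self.cuts = name, coding, cuts
        if coding == "tertile":
            self.column_names = [f"{name}_T2", f"{name}_T3"]
        else:
            self.column_names = [name]

    def transform(self, values) -> np.ndarray:
        v = np.atleast_1d(np.asarray(values, float))
        if self.coding == "continuous":
            return v[:, None]
        q1, q2 = self.cuts
        return np.column_stack([(v > q1) & (v <= q2), v > q2]).astype(float)


@dataclass(frozen=True)
class DesignInfo:
    """A mean spec resolved against a dataset: boundary knots and tertile
    cut points frozen, ready to produce design rows for any (t, w)."""

    mean_spec: MeanModelSpec
    re_spec: RandomEffectsSpec
    coders: tuple[_Coder, ...]

    @classmethod
    def from_dataset(
        cls,
        mean_spec: MeanModelSpec,
        dataset: LongitudinalDataset,
        re_spec: RandomEffectsSpec | None = None,
    ) -> "DesignInfo":
        for name in mean_spec.modifiers:
            if name not in dataset.baseline_names:
                raise KeyError(f"unknown modifier covariate {name!r}")
        basis = mean_spec.basis.resolve(dataset.obs["time"].to_numpy(float))
        coders = []
        for name in mean_spec.modifiers:
            coding = mean_spec.coding_of(name)
            cuts = None
            if coding == "tertile":
                _, cuts = tertile_code(dataset.baselines[name].to_numpy(float))
            coders.append(_Coder(name, coding, cuts))
        spec = replace(mean_spec, basis=basis)
        return cls(spec, re_spec or RandomEffectsSpec(), tuple(coders))

    @property
    def basis(self) -> BasisSpec:
        return self.mean_spec.basis

    @property
    def column_names(self) -> list[str]:
        bnames = self.basis.column_names
        names = ["Intercept"] + bnames
        for c in self.coders:
            names += c.column_names
        for c in self.coders:
            names += [f"{b}:{cn}" for cn in c.column_names for b in bnames]
        return names

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    @property
    def q(self) -> int:
        return self.re_spec.q(self.basis)

    def _assemble(self, B: np.ndarray, covs: Mapping[str, float | np.ndarray]) -> np.ndarray:
        n = B.shape[0]
        blocks = [np.ones((n, 1)), B]
        coded = []
        for c in self.coders:
            w = np.broadcast_to(np.atleast_1d(np.asarray(covs[c.name], float)), (n,))
            coded.append(c.transform(w))
        blocks += coded
        for cd in coded:
            for j in range(cd.shape[1]):
                blocks.append(B * cd[:, j][:, None])
        return np.concatenate(blocks, axis=1)

    def fixed_row(self, t, covs: Mapping[str, float | np.ndarray]) -> np.ndarray:
        """Design rows x(t, w) for arbitrary times/covariate values."""
        t = np.atleast_1d(np.asarray(t, float))
        return self._assemble(build_basis(self.basis, t), covs)

    def fixed_row_deriv(self, t, covs) -> np.ndarray:
        """d/dt of the design rows: intercept and main effects drop out."""
        t = np.atleast_1d(np.asarray(t, float))
        D = self._assemble(basis_derivative(self.basis, t), covs)
        D[:, 0] = 0.0  # intercept
        k = 1 + self.basis.n_columns
        for c in self.coders:  # main effects are constant in t
            D[:, k : k + len(c.column_names)] = 0.0
            k += len(c.column_names)
        return D

    def z_matrix(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        if self.re_spec.which == "intercept_only":
            return np.ones((len(t), 1))
        return np.concatenate([np.ones((len(t), 1)), build_basis(self.basis, t)], axis=1)

    def subject_designs(self, dataset: LongitudinalDataset):
        """Per time-group stacked designs: yields (times, ids, Y, X, Z).

        ``X`` has shape (m, n_i, p); ``Z`` shape (n_i, q) is shared by the
        group because it depends on times only.
        """
        for times, ids, Y in dataset.time_groups():
            B = build_basis(self.basis, times)
            Xs = []
            for sid in ids:
                covs = {c.name: float(dataset.baselines.loc[sid, c.name]) for c in self.coders}
                Xs.append(self._assemble(B, covs))
            yield times, ids, Y, np.stack(Xs), self.z_matrix(times)


def build_design(
    mean_spec: MeanModelSpec,
    dataset: LongitudinalDataset,
    re_spec: RandomEffectsSpec | None = None,
) -> tuple[DesignInfo, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Assemble per-subject fixed-effect (X_i) and random-effect (Z_i)
    design matrices.

    Returns the resolved :class:`DesignInfo` plus dicts subject -> X_i
    and subject -> Z_i.
    """
    info = DesignInfo.from_dataset(mean_spec, dataset, re_spec)
    X: dict[str, np.ndarray] = {}
    Z: dict[str, np.ndarray] = {}
    for times, ids, Y, Xg, Zg in info.subject_designs(dataset):
        for i, sid in enumerate(ids):
            X[sid] = Xg[i]
            Z[sid] = Zg
    return info, X, Z


def spline_sse_report(
    dataset: LongitudinalDataset, specs: list[BasisSpec], min_obs: int | None = None
) -> "pd.DataFrame":
    """Sum of squared errors from per-subject OLS fits under each basis.

    A helper for manual knot selection: knots are chosen by inspecting
    which candidate basis minimizes the total SSE of individual
    trajectory fits.  Subjects with fewer observations than columns+1
    are skipped for that basis.
    """
    import pandas as pd

    rows = []
    for spec in specs:
        rspec = spec.resolve(dataset.obs["time"].to_numpy(float))
        sse = 0.0
        n_used = 0
        for times, ids, Y, *_ in (
            (t, i, y) for t, i, y in dataset.time_groups()
        ):
            if len(times) < rspec.n_columns + 1:
                continue
            M = np.concatenate([np.ones((len(times), 1)), build_basis(rspec, times)], axis=1)
            coef, *_ = np.linalg.lstsq(M, Y.T, rcond=None)
            resid = Y.T - M @ coef
            sse += float(np.sum(resid**2))
            n_used += Y.shape[0]
        rows.append(
            {"kind": rspec.kind, "degree": rspec.degree,
             "interior_knots": rspec.interior_knots, "n_subjects": n_used, "sse": sse}
        )
    return pd.DataFrame(rows)
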