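"""Model-comparison metrics: out-of-sample MSE and grid-integrated
mean absolute error (MAE) / mean absolute velocity error (MAVE).

MAE and MAVE average the absolute discrepancy between an estimated and
the true mean (or velocity) surface over a uniform rectangular
(t, w2) grid with w1 held fixed, approximating
(1/C) \\int\\int |delta| dt dw2 by the plain mean over grid nodes.
Unlike validation MSE these metrics weight the domain uniformly rather
than by the observation/exposure distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LongitudinalDataset
from .surfaces import MeanSurface

__all__ = ["EvaluationGrid", "MetricResult", "validation_mse", "mae_mave"]


@dataclass(frozen=True)
class EvaluationGrid:
    """Uniform inclusive grid over time and continuous exposure."""

    t_range: tuple[float, float] = (1.0, 9.0)
    w2_range: tuple[float, float] = (-2.0, 2.0)
    w1_fixed: float = 1.0
    resolution: int = 81

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.t_range[0] >= self.t_range[1] or self.w2_range[0] >= self.w2_range[1]:
            raise ValueError("grid ranges must be nonempty")

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(*self.t_range, self.resolution)
        w2 = np.linspace(*self.w2_range, self.resolution)
        return np.meshgrid(t, w2, indexing="ij")


@dataclass
class MetricResult:
    model_label: str
    condition_label: str
    replicate_index: int
    bic: float
    mse: float
    mae: float
    mave: float

    def __post_init__(self) -> None:
        for name in ("mse", "mae", "mave"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be nonnegative")


def validation_mse(fit_surface: MeanSurface, validation: LongitudinalDataset) -> float:
    """Mean over all observations of (y_ij - mu_hat(t_ij, w_i))^2.

    Uses the marginal (population-level) mean: out-of-sample subjects
    carry no estimated random effects.
    """
    obs = validation.obs
    covs = {
        name: validation.baselines.loc[obs["subject"], name].to_numpy(float)
        for name in validation.baseline_names
    }
    pred = fit_surface.mu(obs["time"].to_numpy(float), **covs)
    return float(np.mean((obs["y"].to_numpy(float) - pred) ** 2))


def mae_mave(
    fit_surface: MeanSurface,
    oracle_surface: MeanSurface,
    grid: EvaluationGrid | None = None,
) -> tuple[float, float]:
    """Grid-mean absolute error of the mean surface and of its velocity."""
    grid = grid or EvaluationGrid()
    T, W2 = grid.mesh()
    covs = dict(w1=np.full_like(T, grid.w1_fixed), w2=W2)
    mae = float(np.mean(np.abs(fit_surface.mu(T, **covs) - oracle_surface.mu(T, **covs))))
    mave = float(np.mean(np.abs(fit_surface.v(T, **covs) - oracle_surface.v(T, **covs))))
    return mae, mave
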