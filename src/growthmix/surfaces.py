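"""Mean/velocity surface protocol shared by fitted models and oracles.

A surface is a pair of vectorized callables mu(t, **covariates) and
v(t, **covariates) returning the expected outcome and its time
derivative (growth velocity).  Covariates are passed by name (e.g.
``w1=1, w2=grid``) and broadcast against ``t``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class MeanSurface:
    mu: Callable[..., np.ndarray]
    v: Callable[..., np.ndarray]

    def shifted(self, offset: float) -> "MeanSurface":
        """Surface with a constant added to the mean (velocity unchanged)."""
        base_mu, base_v = self.mu, self.v
        return MeanSurface(
            mu=lambda t, **w: base_mu(t, **w) + offset,
            v=lambda t, **w: base_v(t, **w),
        )


def _broadcast(t, covs: dict) -> tuple[np.ndarray, dict]:
    t = np.atleast_1d(np.asarray(t, float))
    shape = np.broadcast_shapes(t.shape, *(np.shape(np.asarray(v)) for v in covs.values()))
    t = np.broadcast_to(t, shape)
    covs = {k: np.broadcast_to(np.asarray(v, float), shape) for k, v in covs.items()}
    return t, covs
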