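"""Exploratory derived-variable analysis.

Each subject's trajectory is projected onto a quadratic in age by
ordinary least squares; the resulting per-subject (level, linear,
quadratic) coefficients are then screened against a baseline exposure.
This mirrors the standard exploratory step of scatter-plotting derived
growth parameters against exposure to inform model choice: a clear
polynomial relationship suggests a mixed-effects model with interaction
terms, its absence a growth mixture model.  The screens are exploratory,
not inferential — they ignore the estimation error carried by the
derived coefficients.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import LongitudinalDataset

logger = logging.getLogger("growthmix.derived")

__all__ = ["per_subject_quadratic", "coefficient_exposure_summary"]

COEF_NAMES = ("intercept", "linear", "quadratic")


def per_subject_quadratic(dataset: LongitudinalDataset) -> pd.DataFrame:
    """OLS fit of y on (1, t, t^2) within each qualifying subject.

    Subjects with fewer than three distinct observation times are
    excluded (logged).  Returns one row per retained subject with the
    three coefficients, the observation count and the residual SD.
    """
    rows = []
    excluded = []
    for times, ids, Y in dataset.time_groups():
        if len(np.unique(times)) < 3:
            excluded.extend(ids)
            continue
        M = np.column_stack([np.ones_like(times), times, times**2])
        coefs, *_ = np.linalg.lstsq(M, Y.T, rcond=None)
        resid = Y.T - M @ coefs
        dof = max(len(times) - 3, 1)
        rsd = np.sqrt((resid**2).sum(axis=0) / dof)
        for i, sid in enumerate(ids):
            rows.append({
                "subject": sid,
                "intercept": coefs[0, i],
                "linear": coefs[1, i],
                "quadratic": coefs[2, i],
                "n_obs": len(times),
                "resid_sd": rsd[i],
            })
    if excluded:
        logger.info(
            "per_subject_quadratic: excluded %d subjects with <3 distinct times: %s",
            len(excluded), excluded[:10],
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("subject").sort_index()
    return out


def coefficient_exposure_summary(
    derived: pd.DataFrame, dataset: LongitudinalDataset, exposure_name: str
) -> pd.DataFrame:
    """Per-coefficient association screens against a baseline exposure.

    For each derived growth coefficient two OLS fits are run: coefficient
    on exposure (reporting the least-squares slope) and coefficient on
    exposure + exposure^2 (reporting the quadratic term as a
    non-linearity / non-monotonicity screen).  Output is labeled
    exploratory: the derived coefficients are estimates, not data.
    """
    if exposure_name not in dataset.baseline_names:
        raise KeyError(f"unknown exposure {exposure_name!r}")
    if len(derived) < 3:
        raise ValueError("need at least 3 subjects in the derived table")
    w = dataset.baselines.loc[derived.index, exposure_name].to_numpy(float)
    if np.ptp(w) == 0:
        raise ValueError(f"degenerate exposure {exposure_name!r}: constant")
    rows = []
    for name in COEF_NAMES:
        c = derived[name].to_numpy(float)
        lin = sm.OLS(c, sm.add_constant(w)).fit()
        quad = sm.OLS(c, sm.add_constant(np.column_stack([w, w**2]))).fit()
        rows.append({
            "coefficient": name,
            "slope": lin.params[1],
            "slope_se": lin.bse[1],
            "quad_term": quad.params[2],
            "quad_term_se": quad.bse[2],
            "note": "exploratory screen",
        })
    return pd.DataFrame(rows).set_index("coefficient")
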