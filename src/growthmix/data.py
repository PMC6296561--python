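"""Long-format longitudinal data containers and CSV I/O.

The central container is :class:`LongitudinalDataset`: repeated
(time, outcome) measures per subject plus baseline covariates that are
constant within subject.  Input is long format only (one row per visit);
wide tables are rejected rather than auto-detected so the mapping from
rows to the per-subject vectors (y_i, t_i) is unambiguous.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("growthmix.data")

__all__ = [
    "LongitudinalDataset",
    "SubjectFilter",
    "read_long_csv",
    "write_long_csv",
    "filter_subjects",
]


class DataFormatError(ValueError):
    """Malformed input table (missing columns, non-numeric fields...)."""


class DataValidationError(ValueError):
    """Structurally valid table violating dataset invariants."""


@dataclass(frozen=True)
class LongitudinalDataset:
    """Repeated measures for a set of subjects plus baseline covariates.

    Attributes
    ----------
    obs
        Long-format frame with canonical columns ``subject``, ``time``,
        ``y``, sorted by (subject, time).  Subject ids are opaque strings;
        all internal ordering is by sorted id so results are invariant to
        input permutation.
    baselines
        One row per subject (index = subject id, sorted), one column per
        baseline covariate.
    """

    obs: pd.DataFrame
    baselines: pd.DataFrame

    def __post_init__(self) -> None:
        obs = self.obs
        if list(obs.columns) != ["subject", "time", "y"]:
            raise DataFormatError("obs must have columns ['subject', 'time', 'y']")
        if not np.isfinite(obs["time"].to_numpy(float)).all():
            raise DataValidationError("non-finite time values")
        if not np.isfinite(obs["y"].to_numpy(float)).all():
            raise DataValidationError("non-finite outcome values")
        if obs.duplicated(["subject", "time"]).any():
            dup = obs[obs.duplicated(["subject", "time"])].iloc[0]
            raise DataValidationError(
                f"duplicate (subject, time) pair: ({dup['subject']}, {dup['time']})"
            )
        if not self.baselines.empty:
            vals = self.baselines.to_numpy(float)
            if not np.isfinite(vals).all():
                raise DataValidationError("non-finite baseline covariate values")
        missing = set(obs["subject"]) - set(self.baselines.index)
        if missing:
            raise DataValidationError(f"subjects without baseline rows: {sorted(missing)[:5]}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_frames(cls, obs: pd.DataFrame, baselines: pd.DataFrame) -> "LongitudinalDataset":
        """Build a validated dataset from canonical frames (copies, sorts)."""
        obs = obs[["subject", "time", "y"]].copy()
        obs["subject"] = obs["subject"].astype(str)
        obs = obs.sort_values(["subject", "time"], kind="mergesort").reset_index(drop=True)
        baselines = baselines.copy()
        baselines.index = baselines.index.astype(str)
        baselines = baselines.loc[sorted(baselines.index.unique())]
        baselines = baselines.loc[baselines.index.isin(obs["subject"].unique())]
        return cls(obs, baselines)

    @classmethod
    def from_arrays(
        cls,
        subject: np.ndarray,
        time: np.ndarray,
        y: np.ndarray,
        baselines: Mapping[str, Mapping[str, float]] | pd.DataFrame | None = None,
    ) -> "LongitudinalDataset":
        obs = pd.DataFrame({"subject": np.asarray(subject).astype(str),
                            "time": np.asarray(time, float),
                            "y": np.asarray(y, float)})
        if baselines is None:
            bl = pd.DataFrame(index=pd.Index(sorted(obs["subject"].unique()), name="subject"))
        elif isinstance(baselines, pd.DataFrame):
            bl = baselines
        else:
            bl = pd.DataFrame(baselines)
        return cls.from_frames(obs, bl)

    # -- accessors ----------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return list(self.baselines.index)

    @property
    def n_subjects(self) -> int:
        return len(self.baselines.index)

    @property
    def n_obs(self) -> int:
        return len(self.obs)

    @property
    def baseline_names(self) -> list[str]:
        return list(self.baselines.columns)

    def times_of(self, subject: str) -> np.ndarray:
        return self.obs.loc[self.obs["subject"] == subject, "time"].to_numpy(float)

    def outcomes_of(self, subject: str) -> np.ndarray:
        return self.obs.loc[self.obs["subject"] == subject, "y"].to_numpy(float)

    def obs_counts(self) -> pd.Series:
        """Observation count per subject, indexed like :attr:`baselines`."""
        counts = self.obs.groupby("subject").size()
        return counts.reindex(self.baselines.index, fill_value=0)

    def subset(self, ids: list[str]) -> "LongitudinalDataset":
        keep = set(ids)
        obs = self.obs[self.obs["subject"].isin(keep)].reset_index(drop=True)
        return LongitudinalDataset(obs, self.baselines.loc[sorted(keep)])

    def time_groups(self):
        """Group subjects by identical time vectors.

        Yields ``(times, ids, Y)`` with ``Y`` of shape (m, n_i): subjects
        sharing an observation schedule can share one marginal covariance
        matrix, which is what makes balanced designs cheap to fit.
        """
        key_of: dict[str, tuple] = {}
        for sid, grp in self.obs.groupby("subject", sort=True):
            key_of[sid] = tuple(grp["time"].to_numpy(float))
        by_key: dict[tuple, list[str]] = {}
        for sid in self.subject_ids:
            by_key.setdefault(key_of[sid], []).append(sid)
        piv = self.obs.pivot(index="subject", columns="time", values="y")
        for key, ids in sorted(by_key.items()):
            times = np.asarray(key, float)
            if len(ids) > 1 and len(set(key)) == len(key):
                Y = piv.loc[ids, list(key)].to_numpy(float)
            else:
                Y = np.vstack([self.outcomes_of(s) for s in ids])
            yield times, ids, Y


@dataclass(frozen=True)
class SubjectFilter:
    """Inclusion rules: minimum visit count and baseline predicates.

    ``covariate_predicates`` maps covariate name to either a required
    value (equality) or a callable returning a boolean mask.
    """

    min_observations: int = 1
    covariate_predicates: Mapping[str, float | Callable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_observations < 1:
            raise ValueError("min_observations must be >= 1")


def read_long_csv(
    path,
    id_col: str = "id",
    time_col: str = "time",
    y_col: str = "y",
    baseline_cols: list[str] | None = None,
) -> LongitudinalDataset:
    """Read a long-format CSV into a validated :class:`LongitudinalDataset`.

    Columns other than id/time/outcome are treated as baseline covariates
    (restricted to ``baseline_cols`` when given).  Rows with missing
    outcome are dropped with a logged count; a covariate that varies
    within a subject is a hard error naming the subject and covariate.
    """
    raw = pd.read_csv(path)
    for col in (id_col, time_col, y_col):
        if col not in raw.columns:
            raise DataFormatError(f"required column {col!r} not found in {path}")
    if baseline_cols is None:
        baseline_cols = [c for c in raw.columns if c not in (id_col, time_col, y_col)]
    for col in baseline_cols:
        if col not in raw.columns:
            raise DataFormatError(f"baseline column {col!r} not found in {path}")

    for col, label in ((time_col, "time"), (y_col, "outcome")):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
        raw[col] = coerced
        if bad.any():
            raise DataFormatError(f"non-numeric {label} value at line {row} of {path}")

    n_missing = int(raw[y_col].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with missing outcome", n_missing)
        raw = raw[raw[y_col].notna()]

    raw = raw.copy()
    raw[id_col] = raw[id_col].astype(str)
    for col in baseline_cols:
        per_subj = raw.groupby(id_col)[col].nunique(dropna=False)
        varying = per_subj[per_subj > 1]
        if len(varying):
            raise DataValidationError(
                f"baseline covariate {col!r} varies within subject {varying.index[0]!r}"
            )

    obs = raw[[id_col, time_col, y_col]].rename(
        columns={id_col: "subject", time_col: "time", y_col: "y"}
    )
    bl = raw.groupby(id_col)[baseline_cols].first() if baseline_cols else pd.DataFrame(
        index=raw[id_col].unique()
    )
    bl.index.name = "subject"
    return LongitudinalDataset.from_frames(obs, bl)


def write_long_csv(dataset: LongitudinalDataset, path) -> None:
    """Write the dataset back to a long CSV (columns id, time, y, baselines)."""
    out = dataset.obs.rename(columns={"subject": "id"})
    if dataset.baseline_names:
        out = out.merge(
            dataset.baselines.rename_axis("id").reset_index(), on="id", how="left"
        )
    out.to_csv(path, index=False)


def filter_subjects(dataset: LongitudinalDataset, flt: SubjectFilter) -> LongitudinalDataset:
    """Apply visit-count and baseline predicates, logging dropped subjects."""
    for name in flt.covariate_predicates:
        if name not in dataset.baseline_names:
            raise KeyError(f"unknown baseline covariate {name!r}")
    keep = dataset.obs_counts() >= flt.min_observations
    for name, pred in flt.covariate_predicates.items():
        col = dataset.baselines[name]
        mask = col.map(pred).astype(bool) if callable(pred) else (col == pred)
        keep &= mask.reindex(keep.index, fill_value=False)
    kept_ids = list(keep.index[keep])
    dropped = dataset.n_subjects - len(kept_ids)
    if dropped:
        logger.info("filter_subjects: dropped %d of %d subjects", dropped, dataset.n_subjects)
    return dataset.subset(kept_ids)
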