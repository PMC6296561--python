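"""Simulation-study orchestration: conditions x model grid x replicates.

For each (condition, replicate) a training and a validation set are
generated; every model specification in the grid is fitted on the
training set (growth mixture specs select K by BIC) and scored by BIC,
out-of-sample MSE and grid MAE/MAVE against the condition's oracle
surface.  Metrics are averaged over replicates per (condition, model).

Model labels follow the ME1-ME4 / M1-M4 convention: 1 = linear mean +
random intercept, 2 = quadratic mean + random intercept, 3 = linear mean
+ random intercept and slopes, 4 = quadratic mean + random intercept and
slopes; ME = mixed effects, M = growth mixture; a trailing ``T`` marks
the tertile-coded-exposure variant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .basis import BasisSpec, MeanModelSpec, RandomEffectsSpec
from .evaluate import EvaluationGrid, mae_mave, validation_mse
from .gmm import DegenerateClassError, GMMOptions, MembershipModelSpec, fit_gmm, select_K
from .lme import fit_lme, lme_mean_surface
from .gmm import gmm_mean_surface
from .simulate import default_condition, generate_dataset, oracle_surface

logger = logging.getLogger("growthmix.benchmark")

__all__ = ["ModelSpec", "ModelSpecGrid", "BenchmarkConfig", "BenchmarkResult",
           "run_benchmark", "render_tables"]

_METRICS = ("bic", "mse", "mae", "mave")


@dataclass(frozen=True)
class ModelSpec:
    model_type: str          # 'lme' | 'gmm'
    mean_form: str           # 'linear' | 'quadratic'
    random_effects: str      # 'intercept_only' | 'all'
    exposure_coding: str     # 'continuous' | 'tertile'

    @property
    def label(self) -> str:
        idx = 1 + (self.mean_form == "quadratic") + 2 * (self.random_effects == "all")
        prefix = "ME" if self.model_type == "lme" else "M"
        suffix = "T" if self.exposure_coding == "tertile" else ""
        return f"{prefix}{idx}{suffix}"


@dataclass(frozen=True)
class ModelSpecGrid:
    model_types: tuple[str, ...] = ("lme", "gmm")
    mean_forms: tuple[str, ...] = ("linear", "quadratic")
    random_effects: tuple[str, ...] = ("intercept_only", "all")
    exposure_codings: tuple[str, ...] = ("continuous",)

    def specs(self) -> list[ModelSpec]:
        out = []
        for coding in self.exposure_codings:
            for mt in self.model_types:
                for re_ in self.random_effects:
                    for mf in self.mean_forms:
                        out.append(ModelSpec(mt, mf, re_, coding))
        return out


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study configuration.

    ``replicates`` defaults to the quick-benchmark scale (100); the full
    1000-replicate scale of a publication-grade run is available but
    slow.  ``condition_overrides`` feeds straight into the generator
    defaults (e.g. ``{"n_subjects": 100}`` for smoke tests).
    """

    conditions: tuple[int, ...] = tuple(range(1, 9))
    replicates: int = 100
    model_grid: ModelSpecGrid = field(default_factory=ModelSpecGrid)
    seed: int = 0
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_starts: int = 3
    eval_grid: EvaluationGrid = field(default_factory=EvaluationGrid)
    condition_overrides: dict = field(default_factory=dict)
    retry_rounds: int = 3
    n_jobs: int = 1
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1 or not self.conditions:
            raise ValueError("need replicates >= 1 and a nonempty condition set")
        if self.replicates >= 1000:
            logger.warning("replicates=%d: full-scale run, expect a long runtime",
                           self.replicates)


@dataclass
class BenchmarkResult:
    per_replicate: pd.DataFrame
    aggregate: pd.DataFrame
    exclusions: pd.DataFrame


def _spec_objects(spec: ModelSpec):
    basis = BasisSpec(spec.mean_form)
    re_spec = RandomEffectsSpec("intercept_only" if spec.random_effects == "intercept_only" else "all")
    codings = {"w2": spec.exposure_coding}
    if spec.model_type == "lme":
        mean = MeanModelSpec(basis=basis, modifiers=("w1", "w2"), codings=codings)
        return mean, re_spec, None
    mean = MeanModelSpec(basis=basis)
    membership = MembershipModelSpec(("w1", "w2"), codings=codings)
    return mean, re_spec, membership


def _fit_and_score(train, val, oracle, spec: ModelSpec, config: BenchmarkConfig,
                   fit_seed: int) -> dict:
    mean, re_spec, membership = _spec_objects(spec)
    row = {"selected_K": np.nan, "excluded": False}
    n_starts = config.n_starts
    for attempt in range(config.retry_rounds + 1):
        opts = GMMOptions(n_starts=n_starts, seed=fit_seed + 1000 * attempt)
        try:
            if spec.model_type == "lme":
                fit = fit_lme(train, mean, re_spec)
                surface = lme_mean_surface(fit)
            else:
                fit, _ = select_K(train, mean, re_spec, membership,
                                  K_range=config.k_range, options=opts)
                surface = gmm_mean_surface(fit)
                row["selected_K"] = fit.K
            if fit.converged:
                break
        except (DegenerateClassError, RuntimeError, np.linalg.LinAlgError) as err:
            logger.warning("fit failed (%s, attempt %d): %s", spec.label, attempt, err)
            fit = None
        n_starts *= 2
    if fit is None or not fit.converged:
        row.update(excluded=True, bic=np.nan, mse=np.nan, mae=np.nan, mave=np.nan)
        return row
    mae, mave = mae_mave(surface, oracle, config.eval_grid)
    row.update(bic=fit.bic, mse=validation_mse(surface, val), mae=mae, mave=mave)
    return row


def _run_replicate(cond_index: int, rep: int, config: BenchmarkConfig) -> list[dict]:
    cond = default_condition(cond_index, seed=config.seed, **config.condition_overrides)
    train = generate_dataset(cond, "training", rep)
    val = generate_dataset(cond, "validation", rep)
    oracle = oracle_surface(cond)
    rows = []
    for j, spec in enumerate(config.model_grid.specs()):
        fit_seed = int(
            np.random.SeedSequence([config.seed, cond_index, rep, j]).generate_state(1)[0]
            % (2**31)
        )
        row = _fit_and_score(train, val, oracle, spec, config, fit_seed)
        row.update(condition=cond_index, condition_label=cond.label,
                   model=spec.label, replicate=rep)
        rows.append(row)
    return rows


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Run the study.  Per-replicate seeds are substreams keyed by
    (seed, condition, replicate, model), so results are independent of
    execution order and parallelism; with ``output_dir`` set, finished
    replicates are written to disk and skipped on re-run."""
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    tasks = [(c, r) for c in config.conditions for r in range(config.replicates)]

    def one(c, r):
        if out_dir:
            cache = out_dir / f"rep_c{c}_r{r}.csv"
            if cache.exists():
                return pd.read_csv(cache).to_dict("records")
        rows = _run_replicate(c, r, config)
        if out_dir:
            pd.DataFrame(rows).to_csv(out_dir / f"rep_c{c}_r{r}.csv", index=False)
        return rows

    if config.n_jobs != 1:
        chunks = Parallel(n_jobs=config.n_jobs)(delayed(one)(c, r) for c, r in tasks)
    else:
        chunks = [one(c, r) for c, r in tasks]
    per_rep = pd.DataFrame([row for chunk in chunks for row in chunk])
    per_rep = per_rep.sort_values(["condition", "model", "replicate"]).reset_index(drop=True)

    ok = per_rep[~per_rep["excluded"]]
    agg = ok.groupby(["condition", "condition_label", "model"], as_index=False)[
        list(_METRICS)
    ].mean()
    counts = per_rep.groupby(["condition", "condition_label", "model"]).agg(
        n_total=("excluded", "size"), n_excluded=("excluded", "sum")
    ).reset_index()
    agg = counts.merge(agg, on=["condition", "condition_label", "model"], how="left")
    agg["flagged"] = agg["n_excluded"] > 0.1 * agg["n_total"]
    if agg["flagged"].any():
        logger.warning("cells with >10%% non-convergent fits:\n%s",
                       agg.loc[agg["flagged"], ["condition", "model", "n_excluded"]])
    for metric in _METRICS:
        best = agg.loc[agg.groupby("condition")[metric].idxmin(), ["condition", "model"]]
        flag_col = f"best_{metric}"
        agg[flag_col] = False
        for _, r in best.iterrows():
            agg.loc[(agg["condition"] == r["condition"]) & (agg["model"] == r["model"]),
                    flag_col] = True
    exclusions = per_rep.loc[per_rep["excluded"], ["condition", "model", "replicate"]]
    if out_dir:
        per_rep.to_csv(out_dir / "metrics_per_rep.csv", index=False)
        for metric in _METRICS:
            tab, _ = render_tables(BenchmarkResult(per_rep, agg, exclusions), metric)
            tab.to_csv(out_dir / f"table_{metric}.csv")
    return BenchmarkResult(per_rep, agg, exclusions.reset_index(drop=True))


def _label_order(labels) -> list[str]:
    def key(lab: str):
        tert = lab.endswith("T")
        core = lab[:-1] if tert else lab
        prefix = "ME" if core.startswith("ME") else "M"
        return (tert, 0 if prefix == "ME" else 1, int(core.replace(prefix, "")))

    return sorted(set(labels), key=key)


def render_tables(result: BenchmarkResult, metric: str) -> tuple[pd.DataFrame, str]:
    """One row per condition, one column per model label (ME1..ME4 then
    M1..M4, tertile variants after), per-row minima flagged.

    Returns the numeric pivot table and an aligned text rendering in
    which the row minimum is marked with ``*``.
    """
    if metric not in _METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {_METRICS}")
    agg = result.aggregate
    piv = agg.pivot_table(index="condition_label", values=metric, columns="model",
                          sort=False)
    cond_order = (
        agg[["condition", "condition_label"]].drop_duplicates().sort_values("condition")
    )["condition_label"]
    piv = piv.loc[cond_order, _label_order(piv.columns)]
    lines = [metric.upper() + "  (row minimum marked *)"]
    header = "condition".ljust(10) + "".join(c.rjust(10) for c in piv.columns)
    lines.append(header)
    for label, row in piv.iterrows():
        best = row.idxmin()
        cells = []
        for c in piv.columns:
            mark = "*" if c == best else " "
            cells.append(f"{row[c]:9.2f}{mark}")
        lines.append(label.ljust(10) + "".join(cells))
    return piv, "\n".join(lines)
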