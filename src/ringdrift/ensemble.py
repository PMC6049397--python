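"""Replicate ensembles: group means, half-lives and survival of mosaicism.

Each combination of set-up parameters is evaluated with a batch of repeat
simulations (20 by default) run from independent child streams of one
master seed.  Per-generation group means and two-sided 95% t-intervals are
computed over *defined* values only, following the exclusion rules of the
underlying model: a replicate in which one population has been lost
contributes a percentage of 0 or 100 and an uncorrected stripe number of 1
but no corrected stripe number; a replicate in which every cell has been
lost contributes nothing.

Survival of mosaicism treats the first generation at which only one
population remains as the event time; replicates still mosaic at the end of
the run are censored at the horizon.  The median survival is, by default,
the empirical half-count median — the first generation by which at least
half the replicates have lost mosaicism, reported as ``> horizon`` when
more than half are censored.  A Kaplan-Meier median (identical here, since
there is no competing censoring before the horizon) is available behind the
``method`` switch; log-rank comparisons are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .dynamics import SimulationTrace, replicate_rng, run_simulation
from .ring import ConfigError, SimConfig
from .stats import HalfLife, half_life

__all__ = [
    "EnsembleResult",
    "SurvivalTable",
    "run_ensemble",
    "survival_of_mosaicism",
    "experiment_grid",
    "available_presets",
    "logrank_mosaicism",
]

logger = logging.getLogger(__name__)

#: Summary fields aggregated per generation (field name -> trace summary attribute).
_STATISTICS = {
    "pct_blue": "pct_blue",
    "uncorrected": "uncorrected_stripes",
    "corrected": "corrected_stripes",
    "n_cells": "n_total",
}


@dataclass
class SurvivalTable:
    """Per-replicate loss-of-mosaicism times with censoring at the horizon.

    ``loss_generation[i]`` is the first generation at which replicate ``i``
    had only one population left, or ``None`` if it was still mosaic at
    ``horizon`` (censored).
    """

    loss_generation: list[Optional[int]]
    horizon: int

    @property
    def n_replicates(self) -> int:
        return len(self.loss_generation)

    @property
    def n_lost(self) -> int:
        return sum(g is not None for g in self.loss_generation)

    @property
    def durations(self) -> np.ndarray:
        """Observed or censored duration per replicate (for survival routines)."""
        return np.array(
            [self.horizon if g is None else g for g in self.loss_generation],
            dtype=float,
        )

    @property
    def observed(self) -> np.ndarray:
        return np.array([g is not None for g in self.loss_generation], dtype=bool)

    def n_lost_by(self, generation: int) -> int:
        return sum(g is not None and g <= generation for g in self.loss_generation)

    def median_survival(self, method: str = "empirical") -> Union[int, str]:
        """Median survival of mosaicism in generations, or ``"> horizon"``.

        ``method="empirical"`` returns the first generation by which at least
        half the replicates have lost mosaicism; ``method="km"`` reads the
        median off a Kaplan-Meier fit.  With no censoring before the horizon
        the two coincide.
        """
        n = self.n_replicates
        if method == "empirical":
            needed = -(-n // 2)  # ceil(n / 2)
            events = sorted(g for g in self.loss_generation if g is not None)
            if len(events) < needed:
                return f">{self.horizon}"
            return int(events[needed - 1])
        if method == "km":
            from lifelines import KaplanMeierFitter

            km = KaplanMeierFitter().fit(self.durations, self.observed)
            med = km.median_survival_time_
            if not np.isfinite(med):
                return f">{self.horizon}"
            return int(med)
        raise ValueError(f"unknown median method: {method!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(self.n_replicates),
                "loss_generation": [
                    "" if g is None else g for g in self.loss_generation
                ],
                "censored": [int(g is None) for g in self.loss_generation],
                "duration": self.durations.astype(int),
            }
        )


@dataclass
class EnsembleResult:
    """Aggregate of one batch of replicate simulations.

    ``per_generation`` has one row per generation and, for each statistic in
    ``pct_blue, uncorrected, corrected, n_cells``, columns ``<stat>_mean``,
    ``<stat>_ci95`` (half-width of the two-sided 95% t-interval) and
    ``<stat>_n`` (replicates contributing a defined value).
    """

    config: SimConfig
    per_generation: pd.DataFrame
    half_lives: dict[str, HalfLife]
    per_replicate_half_life: list[HalfLife]
    survived_both: int
    survival: SurvivalTable
    traces: Optional[list[SimulationTrace]] = None
    label: Optional[str] = None

    def mean_series(self, statistic: str) -> np.ndarray:
        return self.per_generation[f"{statistic}_mean"].to_numpy()


def _aggregate(values: np.ndarray) -> tuple[float, float, int]:
    """Mean, 95% t-interval half-width and count of the defined entries."""
    defined = values[~np.isnan(values)]
    n = defined.size
    if n == 0:
        return (np.nan, np.nan, 0)
    mean = float(defined.mean())
    if n == 1:
        return (mean, np.nan, 1)
    sem = defined.std(ddof=1) / np.sqrt(n)
    half = float(scipy.stats.t.ppf(0.975, n - 1) * sem)
    return (mean, half, n)


def survival_of_mosaicism(traces: Sequence[SimulationTrace]) -> SurvivalTable:
    """Tabulate loss-of-mosaicism generations across a set of replicates.

    The event time of a replicate is the smallest generation at which the
    ring is non-empty and one population's percentage is 0 or 100.  Every
    trace must start mosaic.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("at least one trace is required")
    horizon = traces[0].n_generations
    loss: list[Optional[int]] = []
    for trace in traces:
        if not trace.summaries[0].mosaic:
            raise ValueError("every trace must be mosaic at G0")
        event = None
        for s in trace.summaries[1:]:
            if s.n_total > 0 and not s.mosaic:
                event = s.generation
                break
        loss.append(event)
    return SurvivalTable(loss_generation=loss, horizon=horizon)


def run_ensemble(
    config: SimConfig,
    keep_traces: bool = False,
    label: Optional[str] = None,
) -> EnsembleResult:
    """Run ``config.replicates`` independent traces and aggregate them.

    Replicate ``i`` draws from a child stream derived deterministically from
    ``(config.seed, i)``, so the whole ensemble is reproducible from the
    master seed.
    """
    traces = [
        run_simulation(config, replicate_rng(config.seed, i))
        for i in range(config.replicates)
    ]
    n_gen = config.generations + 1
    columns: dict[str, np.ndarray] = {"generation": np.arange(n_gen)}
    matrices: dict[str, np.ndarray] = {}
    for stat, attr in _STATISTICS.items():
        mat = np.full((config.replicates, n_gen), np.nan)
        for i, trace in enumerate(traces):
            for g, s in enumerate(trace.summaries):
                v = getattr(s, attr)
                if v is not None:
                    mat[i, g] = v
        matrices[stat] = mat
        agg = np.array([_aggregate(mat[:, g]) for g in range(n_gen)])
        columns[f"{stat}_mean"] = agg[:, 0]
        columns[f"{stat}_ci95"] = agg[:, 1]
        columns[f"{stat}_n"] = agg[:, 2].astype(int)
    per_generation = pd.DataFrame(columns)

    half_lives = {
        stat: half_life(
            per_generation[f"{stat}_mean"].tolist(), basis=stat, mode="ensemble-mean"
        )
        for stat in ("corrected", "uncorrected", "n_cells")
    }
    per_replicate = []
    for i in range(config.replicates):
        series = matrices["corrected"][i, :]
        per_replicate.append(
            half_life(series.tolist(), basis="corrected", mode="per-replicate")
        )
    survived_both = sum(t.summaries[-1].mosaic for t in traces)
    survival = (
        survival_of_mosaicism(traces)
        if all(t.summaries[0].mosaic for t in traces)
        else SurvivalTable(loss_generation=[0] * config.replicates, horizon=config.generations)
    )
    logger.info(
        "ensemble %s: n=%d k=%d r=%.3g q=%.3g reps=%d G=%d -> t1/2(corrected)=%s, "
        "survived_both=%d/%d, median survival=%s",
        label or "",
        config.n_cells,
        config.clone_size,
        config.p_replace,
        config.p_loss,
        config.replicates,
        config.generations,
        half_lives["corrected"].value,
        survived_both,
        config.replicates,
        survival.median_survival(),
    )
    return EnsembleResult(
        config=config,
        per_generation=per_generation,
        half_lives=half_lives,
        per_replicate_half_life=per_replicate,
        survived_both=survived_both,
        survival=survival,
        traces=traces if keep_traces else None,
        label=label,
    )


# ---------------------------------------------------------------------------
# Preset experiment grids
# ---------------------------------------------------------------------------


def _load_presets() -> dict:
    text = resources.files("ringdrift").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_load_presets())


def experiment_grid(
    preset: str,
    seed: int = 0,
    replicates: Optional[int] = None,
    keep_traces: bool = False,
) -> list[EnsembleResult]:
    """Run every cell of a named preset parameter grid.

    Each grid cell gets its own master seed derived from ``seed``, so the
    whole grid is reproducible.  ``replicates`` overrides the preset's
    replicate count (e.g. for high-replicate property checks).
    """
    presets = _load_presets()
    if preset not in presets:
        raise ConfigError(
            f"unknown preset {preset!r}; available: {', '.join(sorted(presets))}"
        )
    spec = presets[preset]
    defaults = {k: v for k, v in spec.items() if k not in ("description", "cells")}
    cells = spec["cells"]
    # one independent 31-bit master seed per grid cell
    cell_seeds = np.random.SeedSequence(seed).generate_state(len(cells)) & 0x7FFFFFFF
    results = []
    for cell, cell_seed in zip(cells, cell_seeds):
        params = dict(defaults)
        params.update({k: v for k, v in cell.items() if k != "label"})
        if replicates is not None:
            params["replicates"] = replicates
        config = SimConfig(seed=int(cell_seed), **params)
        results.append(run_ensemble(config, keep_traces=keep_traces, label=cell["label"]))
    return results


def logrank_mosaicism(
    tables: Sequence[SurvivalTable], trend: bool = False
) -> float:
    """Log-rank p-value comparing survival-of-mosaicism curves (via lifelines).

    Two tables give the standard two-sample log-rank (Mantel-Cox) test; more
    give the multivariate log-rank.  With ``trend=True`` the group labels are
    treated as ordered scores (log-rank test for trend).
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    if len(tables) < 2:
        raise ValueError("need at least two survival tables")
    durations = np.concatenate([t.durations for t in tables])
    observed = np.concatenate([t.observed for t in tables])
    groups = np.concatenate(
        [np.full(t.n_replicates, i, dtype=float) for i, t in enumerate(tables)]
    )
    if trend:
        # log-rank for trend == score test of a Cox fit on the ordinal score
        df = pd.DataFrame({"duration": durations, "event": observed, "score": groups})
        cph = CoxPHFitter().fit(df, duration_col="duration", event_col="event")
        return float(cph.summary.loc["score", "p"])
    if len(tables) == 2:
        a, b = tables
        res = logrank_test(a.durations, b.durations, a.observed, b.observed)
        return float(res.p_value)
    res = multivariate_logrank_test(durations, groups, observed)
    return float(res.p_value)
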