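"""Factorial-grid orchestration, seed management, and results persistence.

The full study is a factorial design over number of events (13 levels),
marginal hazard ratio (3), treatment prevalence (3) and
treatment-selection c-statistic (5): 585 observational cells, each with
a matched randomized cell.  ``run_grid`` executes any sub-grid of it,
caches the expensive marginal-effect calibrations (one per hazard-ratio
level), and appends one CSV row per (cell, analysis).

Seeds are derived from a single base seed through ``SeedSequence`` keyed
on the cell's factor levels, never on execution order, so cells are
reproducible individually and the grid can be interrupted and resumed.
Since the randomized design does not depend on the c-statistic, the
matched randomized cell is simulated once per (events, hazard ratio,
prevalence) triple and its row is replicated across c-statistic levels.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import (
    AUC_GRID,
    EVENTS_GRID,
    HR_GRID,
    PREVALENCE_GRID,
    Scenario,
    calibrate_conditional_beta,
    treatment_model_for,
)
from .dgp import OutcomeModelParams
from .power import BiasResult, _power_from_fits, run_replicates

__all__ = [
    "ExperimentGrid",
    "RESULT_COLUMNS",
    "expand_grid",
    "run_grid",
    "write_results",
    "read_results",
    "marginal_power_summary",
    "table1_summary",
]

RESULT_COLUMNS = [
    "scenario_id",
    "design",
    "analysis",
    "n_events",
    "marginal_hr",
    "prevalence",
    "auc",
    "n_reps",
    "n_failed",
    "power",
    "mc_se",
    "mean_loghr",
    "rel_bias_pct",
    "seed",
]

DESK_EVENTS = (200, 500, 1000, 5000)


@dataclass(frozen=True)
class ExperimentGrid:
    """Factor levels and execution settings for one grid run."""

    events: tuple[int, ...] = DESK_EVENTS
    marginal_hrs: tuple[float, ...] = HR_GRID
    prevalences: tuple[float, ...] = PREVALENCE_GRID
    aucs: tuple[float, ...] = AUC_GRID
    designs: tuple[str, ...] = ("observational", "rct")
    include_crude: bool = False
    n_reps: int = 200
    base_seed: int = 0
    alpha: float = 0.05
    beta_population: int = 1_000_000
    beta_tolerance: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("events", "marginal_hrs", "prevalences", "aucs", "designs"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"factor list {name!r} must not be empty")
        for d in self.designs:
            if d not in ("observational", "rct"):
                raise ValueError(f"unknown design {d!r}")

    @property
    def n_cells(self) -> int:
        return len(self.events) * len(self.marginal_hrs) * len(self.prevalences) * len(self.aucs)

    def scenarios(self, design: str) -> list[Scenario]:
        """Factorial expansion, in fixed (events, hr, prevalence, auc) order."""
        return [
            Scenario(
                n_events=e, marginal_hr=hr, prevalence=p, auc=a,
                design=design, alpha=self.alpha,
            )
            for e in self.events
            for hr in self.marginal_hrs
            for p in self.prevalences
            for a in self.aucs
        ]


def expand_grid(config: Optional[dict] = None, paper_mode: bool = False) -> ExperimentGrid:
    """Build an :class:`ExperimentGrid` from a flat config mapping.

    ``paper_mode=True`` starts from the full published factorial (13 x 3
    x 3 x 5 = 585 observational cells, 1000 replicates); the default
    desk mode uses a reduced events list and 200 replicates.  Any config
    key overrides the mode's default.
    """
    defaults: dict = {}
    if paper_mode:
        defaults.update(events=EVENTS_GRID, n_reps=1000)
    cfg = {**defaults, **(config or {})}
    known = set(ExperimentGrid.__dataclass_fields__)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("events", "marginal_hrs", "prevalences", "aucs", "designs"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    grid = ExperimentGrid(**cfg)
    if paper_mode:
        for s in grid.scenarios("observational"):
            s.validate_paper_grid()
    return grid


def _cell_seed(base_seed: int, *key_parts) -> np.random.SeedSequence:
    """Order-independent stream for one cell, keyed on its factor levels."""
    digest = hashlib.sha256(repr(key_parts).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(words))


def _scenario_id(s: Scenario) -> str:
    return f"e{s.n_events}_hr{s.marginal_hr:g}_p{s.prevalence:g}_auc{s.auc:g}"


class CalibrationCache:
    """Memoizes the marginal-effect calibration (one solve per hazard-ratio level)."""

    def __init__(self, grid: ExperimentGrid, oparams: OutcomeModelParams | None = None):
        self.grid = grid
        self.oparams = oparams if oparams is not None else OutcomeModelParams()
        self._betas: dict[float, float] = {}
        self._tmodels: dict[tuple[float, float], object] = {}
        self.n_beta_solves = 0

    def beta_treat(self, marginal_hr: float) -> float:
        if marginal_hr not in self._betas:
            rng = np.random.default_rng(
                _cell_seed(self.grid.base_seed, "beta", round(marginal_hr, 10))
            )
            beta, _ = calibrate_conditional_beta(
                marginal_hr,
                self.oparams,
                population_size=self.grid.beta_population,
                tolerance=self.grid.beta_tolerance,
                rng=rng,
            )
            self._betas[marginal_hr] = beta
            self.n_beta_solves += 1
        return self._betas[marginal_hr]

    def outcome_model(self, marginal_hr: float) -> OutcomeModelParams:
        return self.oparams.with_beta_treat(self.beta_treat(marginal_hr))

    def treatment_model(self, auc: float, prevalence: float):
        key = (auc, prevalence)
        if key not in self._tmodels:
            self._tmodels[key] = treatment_model_for(auc, prevalence)
        return self._tmodels[key]


def _run_cell(grid: ExperimentGrid, scenario: Scenario, cache: CalibrationCache) -> list[dict]:
    """Simulate one cell and return one result row per analysis."""
    oparams = cache.outcome_model(scenario.marginal_hr)
    if scenario.design == "observational":
        analyses = ("iptw", "crude") if grid.include_crude else ("iptw",)
        tparams = cache.treatment_model(scenario.auc, scenario.prevalence)
        key = ("obs", scenario.n_events, scenario.marginal_hr, scenario.prevalence, scenario.auc)
    else:
        analyses = ("rct",)
        tparams = None
        # the randomized design is auc-free: key (and hence the stream) omits it
        key = ("rct", scenario.n_events, scenario.marginal_hr, scenario.prevalence)
    ss = _cell_seed(grid.base_seed, *key)
    rng = np.random.default_rng(ss)
    fits, n_failed = run_replicates(scenario, tparams, oparams, grid.n_reps, rng, analyses)
    rows = []
    for analysis in analyses:
        pr = _power_from_fits(scenario, analysis, fits[analysis], grid.n_reps, n_failed)
        bias = BiasResult(scenario, analysis, grid.n_reps, n_failed, pr.mean_log_hr)
        rows.append(
            {
                "scenario_id": _scenario_id(scenario),
                "design": scenario.design,
                "analysis": analysis,
                "n_events": scenario.n_events,
                "marginal_hr": scenario.marginal_hr,
                "prevalence": scenario.prevalence,
                "auc": scenario.auc,
                "n_reps": grid.n_reps,
                "n_failed": n_failed,
                "power": pr.power,
                "mc_se": pr.mc_se,
                "mean_loghr": pr.mean_log_hr,
                "rel_bias_pct": bias.relative_bias_pct,
                "seed": int(ss.entropy),
            }
        )
    return rows


def run_grid(
    grid: ExperimentGrid,
    out_csv: Optional[str | Path] = None,
    resume: bool = True,
    progress: bool = False,
    cache: Optional[CalibrationCache] = None,
) -> pd.DataFrame:
    """Execute every requested (cell, design), returning the results table.

    Deterministic given ``base_seed``.  If ``out_csv`` exists and
    ``resume`` is true, rows already present are kept and their cells are
    skipped; results are flushed to disk after every cell so an
    interrupted run loses at most one cell.
    """
    if cache is None:
        cache = CalibrationCache(grid)
    done: set[tuple[str, str]] = set()
    rows: list[dict] = []
    if out_csv is not None and resume and Path(out_csv).exists():
        prior = read_results(out_csv)
        rows = prior.to_dict("records")
        done = {(r["scenario_id"], r["analysis"]) for r in rows}

    all_cells: list[Scenario] = []
    for design in grid.designs:
        all_cells.extend(grid.scenarios(design))

    rct_cache: dict[tuple, list[dict]] = {}
    iterator = all_cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(all_cells, desc="cells")
    for scenario in iterator:
        sid = _scenario_id(scenario)
        wanted = ("rct",) if scenario.design == "rct" else (
            ("iptw", "crude") if grid.include_crude else ("iptw",)
        )
        if all((sid, a) in done for a in wanted):
            continue
        if scenario.design == "rct":
            rkey = (scenario.n_events, scenario.marginal_hr, scenario.prevalence)
            if rkey in rct_cache:
                cell_rows = [dict(r, scenario_id=sid, auc=scenario.auc) for r in rct_cache[rkey]]
            else:
                cell_rows = _run_cell(grid, scenario, cache)
                rct_cache[rkey] = cell_rows
        else:
            cell_rows = _run_cell(grid, scenario, cache)
        rows.extend(cell_rows)
        done.update((sid, r["analysis"]) for r in cell_rows)
        if out_csv is not None:
            write_results(pd.DataFrame(rows, columns=RESULT_COLUMNS), out_csv, grid)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if out_csv is not None:
        write_results(df, out_csv, grid)
    return df


def _grid_meta(grid: ExperimentGrid) -> dict:
    cfg = {k: getattr(grid, k) for k in grid.__dataclass_fields__}
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "version": __version__,
        "base_seed": grid.base_seed,
    }


def write_results(df: pd.DataFrame, path: str | Path, grid: Optional[ExperimentGrid] = None) -> None:
    """Write a results table as CSV with a commented metadata header."""
    buf = io.StringIO()
    if grid is not None:
        for k, v in _grid_meta(grid).items():
            buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")


def marginal_power_summary(results: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Mean power by level of one design factor, per analysis.

    The unweighted mean is taken over every cell sharing the factor
    level, mirroring the study's marginal power summaries.
    """
    if factor not in ("auc", "prevalence", "marginal_hr"):
        raise ValueError(f"unknown factor {factor!r}; expected auc, prevalence or marginal_hr")
    if results.empty:
        raise ValueError("results table is empty")
    out = (
        results.groupby([factor, "analysis"])["power"]
        .mean()
        .unstack("analysis")
        .sort_index()
    )
    out.columns.name = None
    return out


def table1_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Min/median/max crude relative bias (%) per c-statistic at 5000 events.

    Expects crude-analysis rows for every (hazard ratio x prevalence)
    cell with 5000 events; raises listing any missing cells.
    """
    crude = results[(results["analysis"] == "crude") & (results["n_events"] == 5000)]
    if crude.empty:
        raise ValueError("no crude-analysis rows with 5000 events in the results table")
    rows = []
    for auc, g in crude.groupby("auc"):
        have = {(hr, p) for hr, p in zip(g["marginal_hr"], g["prevalence"])}
        expected = {(hr, p) for hr in HR_GRID for p in PREVALENCE_GRID}
        missing = expected - have
        if missing:
            raise ValueError(f"incomplete bias grid at auc={auc}: missing cells {sorted(missing)}")
        cells = g.drop_duplicates(subset=["marginal_hr", "prevalence"])["rel_bias_pct"]
        rows.append(
            {
                "auc": auc,
                "min_bias_pct": float(cells.min()),
                "median_bias_pct": float(cells.median()),
                "max_bias_pct": float(cells.max()),
            }
        )
    return pd.DataFrame(rows).set_index("auc").sort_index()
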