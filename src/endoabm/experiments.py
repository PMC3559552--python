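"""Reproducible experiment drivers: homeostasis runs, endotoxin challenges,
time-of-day sweeps and sensitivity scans, with seeded replicates.

Every experiment is a pure function of (configuration, base seed):
replicate ``r`` runs on seed ``base_seed + r`` from a shared homeostatic
snapshot, so repeated execution is bit-identical.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import species as sp
from .config import ProductionParams, SimulationConfig, config_to_dict
from .engine import Engine, HourlyRecorder, TimeSeriesPanel
from .stats import (CountPanel, FitnessSeries, effective_concentration,
                    sensitivity_sweep, synchronization, variability_fitness)
from .world import WorldState, build_world

__all__ = [
    "ExperimentSpec", "HomeostasisResult", "ChallengeResult", "SweepSummary",
    "prepare_homeostatic_world", "make_replicate", "run_homeostasis",
    "run_challenge", "run_dose_time_sweep", "run_sensitivity",
    "challenge_peak_curve", "emit_outputs",
]


@dataclass
class ExperimentSpec:
    """What to run and at which scale."""

    kind: str = "homeostasis"        # homeostasis | challenge | dose_time_sweep | sensitivity
    duration_days: float = 2.0
    dose: int = 1000
    injection_time: float = 9.0      # clock hour
    sweep_times: tuple = tuple(range(0, 25, 3))
    replicates: int = 100
    base_seed: int = 1000
    time_scale: int = 50
    contraction: int = 5             # F_var range-contraction divisor

    def seed_for(self, replicate: int) -> int:
        return self.base_seed + replicate


# --------------------------------------------------------------------------
# world preparation


def prepare_homeostatic_world(config: SimulationConfig | None = None,
                              relax_days: float = 2.0,
                              circadian_days: float = 1.0,
                              time_scale: int = 50) -> WorldState:
    """Build and relax a world into its saved homeostatic configuration.

    The initial tabulated state is first relaxed for ``relax_days``
    unstimulated days (no circadian drivers) so that reaction-formed pools
    (free NFkB, plasma cytokines) reach their self-consistent levels, then
    run for ``circadian_days`` with circadian drivers at the experiment
    time-scale so the snapshot ends at midnight of a circadian steady day.
    """
    if config is None:
        config = SimulationConfig()
    quiet = config.replace(
        circadian=dataclasses.replace(config.circadian, enabled=False))
    world = build_world(quiet)
    Engine(world).run(24.0 * relax_days)
    world.tick = 0
    world.config = config.replace(
        circadian=dataclasses.replace(config.circadian, enabled=True),
        clock=dataclasses.replace(config.clock, time_scale=float(time_scale)))
    Engine(world).run(24.0 * circadian_days)
    world.tick = 0
    return world


def make_replicate(base: WorldState, seed: int,
                   params: ProductionParams | None = None,
                   circadian: bool | None = None) -> WorldState:
    """Deep-copy the snapshot and restart its random stream from ``seed``."""
    w = copy.deepcopy(base)
    w.tick = 0
    w.event_counts = {}
    cfg = w.config.replace(seed=seed)
    if params is not None:
        cfg = cfg.replace(params=params)
    if circadian is not None:
        cfg = cfg.replace(
            circadian=dataclasses.replace(cfg.circadian, enabled=circadian))
    w.config = cfg
    w.rng = np.random.default_rng(seed)
    return w


def _panel_of(panel: TimeSeriesPanel, species_name: str) -> CountPanel:
    return CountPanel(times=panel.hours,
                      per_cell=panel.per_cell[species_name],
                      system=panel.system[species_name].to_numpy())


# --------------------------------------------------------------------------
# homeostasis


@dataclass
class HomeostasisResult:
    spec: ExperimentSpec
    config: SimulationConfig
    panels: list                        # per-replicate TimeSeriesPanel
    hours: np.ndarray
    clock_hours: np.ndarray
    mean: pd.DataFrame                  # replicate-mean hourly counts
    se: pd.DataFrame

    def clock_profile(self, name: str, day: int = 1) -> pd.Series:
        """Replicate-mean counts of one species over one day, by clock hour."""
        sel = (self.hours >= 24 * day) & (self.hours < 24 * (day + 1))
        return pd.Series(self.mean[name].to_numpy()[sel],
                         index=self.clock_hours[sel])


def run_homeostasis(spec: ExperimentSpec,
                    base: WorldState | None = None,
                    config: SimulationConfig | None = None) -> HomeostasisResult:
    """Circadian homeostasis: ``duration_days`` days, no endotoxin."""
    if base is None:
        base = prepare_homeostatic_world(config, time_scale=spec.time_scale)
    panels = []
    for r in range(spec.replicates):
        w = make_replicate(base, spec.seed_for(r))
        rec = HourlyRecorder()
        Engine(w).run(24.0 * spec.duration_days, recorder=rec)
        panels.append(rec.to_panel())
    stack = np.stack([p.system.to_numpy() for p in panels])
    mean = pd.DataFrame(stack.mean(axis=0), columns=sp.SPECIES_NAMES)
    se = pd.DataFrame(stack.std(axis=0, ddof=1) / np.sqrt(len(panels)),
                      columns=sp.SPECIES_NAMES) if len(panels) > 1 else mean * 0
    return HomeostasisResult(spec=spec, config=base.config, panels=panels,
                             hours=panels[0].hours,
                             clock_hours=panels[0].clock_hours, mean=mean, se=se)


# --------------------------------------------------------------------------
# endotoxin challenge


@dataclass
class ChallengeResult:
    spec: ExperimentSpec
    config: SimulationConfig
    panels: list
    hours: np.ndarray                   # elapsed hours; injection at spec.injection_time
    clock_hours: np.ndarray
    mean: pd.DataFrame
    se: pd.DataFrame
    fitness: FitnessSeries              # replicate-mean F_var
    fitness_per_rep: np.ndarray         # (reps, hours)
    sync_p: pd.Series                   # post-injection windows t=3,6..24
    sync_a: pd.Series
    ec: np.ndarray                      # replicate-mean effective concentration %

    @property
    def post_hours(self) -> np.ndarray:
        return self.hours - self.spec.injection_time

    def peak_time(self, name: str = "P", horizon: float = 12.0) -> float:
        """Hours from injection to the replicate-mean peak within the
        response horizon."""
        y = self.mean[name].to_numpy()
        sel = (self.post_hours >= 0) & (self.post_hours <= horizon)
        return float(self.post_hours[sel][np.argmax(y[sel])])

    def fitness_min_time(self, horizon: float = 12.0) -> float:
        sel = (self.post_hours >= 0) & (self.post_hours <= horizon)
        return float(self.post_hours[sel][np.argmin(self.fitness.values[sel])])

    def ec_peak(self) -> float:
        return float(self.ec.max())

    def response_peak(self, name: str = "P", horizon: float = 12.0) -> float:
        y = self.mean[name].to_numpy()
        sel = (self.post_hours >= 0) & (self.post_hours <= horizon)
        return float(y[sel].max())


def run_challenge(spec: ExperimentSpec,
                  base: WorldState | None = None,
                  config: SimulationConfig | None = None,
                  duration_hours: float | None = None) -> ChallengeResult:
    """Endotoxin bolus at ``spec.injection_time`` on a circadian day.

    The run starts at midnight of the injection day and spans
    ``duration_hours`` (default: 24 h plus a 12 h follow-up, at least
    30 h).  Panels, the variability-based fitness, synchronization windows
    and the effective concentration are replicate-averaged.
    """
    if base is None:
        base = prepare_homeostatic_world(config, time_scale=spec.time_scale)
    if duration_hours is None:
        duration_hours = max(30.0, spec.injection_time + 15.0)
    if spec.injection_time > duration_hours:
        raise ValueError("injection lies outside the simulated span")
    panels = []
    for r in range(spec.replicates):
        w = make_replicate(base, spec.seed_for(r))
        rec = HourlyRecorder()
        Engine(w).run(duration_hours, recorder=rec,
                      injections=[(spec.injection_time, spec.dose)])
        panels.append(rec.to_panel())
    stack = np.stack([p.system.to_numpy() for p in panels])
    mean = pd.DataFrame(stack.mean(axis=0), columns=sp.SPECIES_NAMES)
    se = pd.DataFrame(stack.std(axis=0, ddof=1) / np.sqrt(len(panels)),
                      columns=sp.SPECIES_NAMES) if len(panels) > 1 else mean * 0

    fits = np.stack([
        variability_fitness(_panel_of(p, "P"), _panel_of(p, "A"),
                            spec.contraction).values
        for p in panels])
    fitness = FitnessSeries(times=panels[0].hours, values=fits.mean(axis=0),
                            contraction=spec.contraction)
    windows = [spec.injection_time + t for t in range(3, 25, 3)
               if spec.injection_time + t <= duration_hours]
    sync_p = pd.Series({t - spec.injection_time: np.nanmean(
        [synchronization(_panel_of(p, "P"), t) for p in panels])
        for t in windows})
    sync_a = pd.Series({t - spec.injection_time: np.nanmean(
        [synchronization(_panel_of(p, "A"), t) for p in panels])
        for t in windows})
    g = base.config.geometry
    ec = effective_concentration(mean["LPSR"].to_numpy(), g.n_cells, g.cell_area)
    return ChallengeResult(spec=spec, config=base.config, panels=panels,
                           hours=panels[0].hours,
                           clock_hours=panels[0].clock_hours, mean=mean, se=se,
                           fitness=fitness, fitness_per_rep=fits,
                           sync_p=sync_p, sync_a=sync_a, ec=ec)


# --------------------------------------------------------------------------
# time-of-day sweep


@dataclass
class SweepSummary:
    spec: ExperimentSpec
    config: SimulationConfig
    table: pd.DataFrame     # injection_time, p_max, p_max_se, a_max, a_max_se,
    #                         fvar_min, fvar_min_se

    def p_max(self) -> pd.Series:
        return self.table.set_index("injection_time")["p_max"]

    def a_max(self) -> pd.Series:
        return self.table.set_index("injection_time")["a_max"]


def run_dose_time_sweep(spec: ExperimentSpec,
                        base: WorldState | None = None,
                        config: SimulationConfig | None = None,
                        horizon: float = 12.0) -> SweepSummary:
    """Challenge at each sweep time; summarize response peaks.

    ``p_max``/``a_max`` are the maxima of each replicate's system counts in
    the ``horizon`` hours following injection, averaged over replicates;
    ``fvar_min`` is the minimum of each replicate's fitness series there.
    """
    if base is None:
        base = prepare_homeostatic_world(config, time_scale=spec.time_scale)
    rows = []
    for t_inj in spec.sweep_times:
        sub = dataclasses.replace(spec, injection_time=float(t_inj) % 24.0)
        # injections later than 24:00 wrap to the same clock hour next day
        res = run_challenge(sub, base=base,
                            duration_hours=sub.injection_time + horizon + 3)
        post = res.post_hours
        sel = (post >= 0) & (post <= horizon)
        p_peaks = [p.system["P"].to_numpy()[sel].max() for p in res.panels]
        a_peaks = [p.system["A"].to_numpy()[sel].max() for p in res.panels]
        f_mins = res.fitness_per_rep[:, sel].min(axis=1)
        n = len(p_peaks)
        rows.append({
            "injection_time": float(t_inj),
            "p_max": float(np.mean(p_peaks)),
            "p_max_se": float(np.std(p_peaks, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "a_max": float(np.mean(a_peaks)),
            "a_max_se": float(np.std(a_peaks, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "fvar_min": float(np.mean(f_mins)),
            "fvar_min_se": float(np.std(f_mins, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        })
    return SweepSummary(spec=spec, config=base.config, table=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# sensitivity


def run_sensitivity(spec: ExperimentSpec,
                    base: WorldState | None = None,
                    config: SimulationConfig | None = None,
                    horizon_days: float = 10.0,
                    dp: float = 0.75):
    """Perturb each production parameter and rank fitness sensitivities.

    The fitness of a parameter set is the replicate-mean hourly F_var over
    ``horizon_days`` circadian days without endotoxin.
    """
    if base is None:
        base = prepare_homeostatic_world(config, time_scale=spec.time_scale)

    def fitness_of(params: ProductionParams) -> np.ndarray:
        runs = []
        for r in range(spec.replicates):
            w = make_replicate(base, spec.seed_for(r), params=params)
            rec = HourlyRecorder()
            Engine(w).run(24.0 * horizon_days, recorder=rec)
            p = rec.to_panel()
            runs.append(variability_fitness(
                _panel_of(p, "P"), _panel_of(p, "A"), spec.contraction).values)
        return np.mean(runs, axis=0)

    return sensitivity_sweep(base.config.params, fitness_of, dp=dp)


# --------------------------------------------------------------------------
# time-scale search support


def challenge_peak_curve(scale: int, replicates: int = 5,
                         base_seed: int = 77000,
                         config: SimulationConfig | None = None):
    """Replicate-mean P response to the 9:00 AM bolus at one time-scale.

    Returns (hours post injection, mean P counts) for the time-scale search.
    """
    base = prepare_homeostatic_world(config, time_scale=scale)
    spec = ExperimentSpec(kind="challenge", replicates=replicates,
                          base_seed=base_seed, time_scale=scale)
    res = run_challenge(spec, base=base)
    sel = res.post_hours >= 0
    return res.post_hours[sel], res.mean["P"].to_numpy()[sel]


# --------------------------------------------------------------------------
# output plumbing


def emit_outputs(result, out_dir: str | Path, name: str | None = None) -> list[Path]:
    """Write tidy tables and a run manifest sufficient for bit-identical re-runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, fname: str):
        path = out / fname
        df.to_csv(path, index=False)
        written.append(path)

    spec = result.spec
    tag = name or spec.kind
    if isinstance(result, (HomeostasisResult, ChallengeResult)):
        mean = result.mean.copy()
        mean.insert(0, "hour", result.hours)
        mean.insert(1, "clock_hour", result.clock_hours)
        save(mean, f"{tag}_mean_counts.csv")
        se = result.se.copy()
        se.insert(0, "hour", result.hours)
        save(se, f"{tag}_se_counts.csv")
        long = []
        for r, p in enumerate(result.panels):
            for species_name, matrix in p.per_cell.items():
                df = pd.DataFrame(matrix)
                df.insert(0, "hour", p.hours)
                df = df.melt(id_vars="hour", var_name="cell", value_name="count")
                df.insert(0, "replicate", r)
                df.insert(1, "species", species_name)
                long.append(df)
        save(pd.concat(long, ignore_index=True), f"{tag}_per_cell_counts.csv")
    if isinstance(result, ChallengeResult):
        save(pd.DataFrame({"hour": result.hours,
                           "f_var": result.fitness.values,
                           "ec_percent": result.ec}), f"{tag}_fitness_ec.csv")
        save(pd.DataFrame({"window_end": result.sync_p.index,
                           "sync_P": result.sync_p.values,
                           "sync_A": result.sync_a.values}),
             f"{tag}_synchronization.csv")
    if isinstance(result, SweepSummary):
        save(result.table, f"{tag}_summary.csv")

    manifest = {
        "experiment": dataclasses.asdict(spec),
        "config": config_to_dict(result.config),
        "files": [p.name for p in written],
    }
    mpath = out / f"{tag}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(mpath)
    return written
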