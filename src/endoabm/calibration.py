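"""Homeostatic parameter tuning by trend analysis, and the time-scale search.

The nine production probabilities are calibrated so that no molecule type
shows a significant daily trend without stimulation: each simulated day the
hourly counts of every species are regressed on time (ordinary least
squares); a trend is significant when the 95% CI of the slope excludes zero
*or* the half-day mean shift exceeds 10%.  A significant trend adjusts the
responsible production parameter(s) proportionally, in the opposite
direction; tuning converges when no parameter changes for three consecutive
simulated days.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from . import species as sp
from .config import ProductionParams, SimulationConfig
from .engine import Engine, HourlyRecorder
from .world import WorldState, build_world

__all__ = [
    "TrendVerdict", "TuningConfig", "TuningReport", "fit_trend",
    "adjust_parameter", "tune_homeostasis", "search_time_scale",
    "PARAMS_FOR_SPECIES",
]

# which production parameters answer for which species' trend; species with
# two parameters split the adjustment in half
PARAMS_FOR_SPECIES: dict[str, tuple[str, ...]] = {
    "P": ("kp", "mp"),
    "IkB": ("ki", "fi"),
    "A": ("fa",),
    "E": ("ae",),
    "TLR4": ("pt",),
    "F": ("pf",),
    "M": ("fm",),
}


@dataclass(frozen=True)
class TrendVerdict:
    """OLS trend assessment of one species' daily sample vector."""

    slope: float
    slope_ci: tuple[float, float]
    m1: float                   # mean of the first half-day
    m2: float                   # mean of the last half-day
    pct_change: float           # (m2 - m1) / m1, nan when m1 == 0
    significant: bool

    @property
    def increasing(self) -> bool:
        return self.m2 > self.m1


def fit_trend(samples: Sequence[float], ci_level: float = 0.95,
              pct_threshold: float = 0.10,
              min_abs_shift: float = 0.0) -> TrendVerdict:
    """OLS slope with a t confidence interval, plus the half-day mean shift.

    The trend is significant when 0 lies outside the CI or the relative
    mean shift between the two half-vectors exceeds ``pct_threshold``.
    A zero-variance (constant) series is never significant.

    ``min_abs_shift`` additionally requires the half-day means to differ by
    that many molecules before the *relative* test may fire: a percentage
    change of a ~20-copy pool is sampling noise, not a trend (the slope-CI
    test is unaffected -- it calibrates itself to the series' variance).
    """
    y = np.asarray(samples, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 hourly samples")
    x = np.arange(n, dtype=float)
    res = stats.linregress(x, y)
    if np.isfinite(res.stderr) and res.stderr > 0:
        tq = stats.t.ppf(0.5 + ci_level / 2.0, n - 2)
        ci = (res.slope - tq * res.stderr, res.slope + tq * res.stderr)
    else:
        ci = (res.slope, res.slope)
    half = n // 2
    m1 = float(y[:half].mean())
    m2 = float(y[n - half:].mean())
    pct = (m2 - m1) / m1 if m1 != 0 else float("nan")
    slope_sig = not (ci[0] <= 0.0 <= ci[1])
    shift_sig = np.isfinite(pct) and abs(pct) > pct_threshold and \
        abs(m2 - m1) >= min_abs_shift
    # a trend counts as significant when the regression finds a consistent
    # slope AND the half-day means moved by more than the threshold: either
    # test alone fires spuriously on autocorrelated stochastic counts
    return TrendVerdict(slope=float(res.slope), slope_ci=ci, m1=m1, m2=m2,
                        pct_change=pct,
                        significant=bool(slope_sig and shift_sig))


def adjust_parameter(p: float, m1: float, m2: float, shared: bool = False,
                     eps: float = 1e-3) -> float:
    """Opposite-direction proportional update of a production probability.

    The parameter moves by the relative change of the molecule level,
    ``delta = (m2 - m1)/m1``, with opposite sign: an increasing level lowers
    the parameter, ``p' = p (1 - delta)``.  When two parameters share the
    responsibility each takes half the adjustment.  The result is clamped
    into (eps, 1].
    """
    if m1 <= 0:
        return p
    delta = (m2 - m1) / m1
    if shared:
        delta /= 2.0
    return float(min(1.0, max(eps, p * (1.0 - delta))))


@dataclass
class TuningConfig:
    """Stopping rules of the tuning loop."""

    max_rounds: int = 40
    convergence_days: int = 3
    pct_threshold: float = 0.10
    ci_level: float = 0.95
    relax_days: int = 2          # days simulated before adjustments begin
    min_abs_shift: float = 10.0  # molecules; floor for the relative-shift test


@dataclass
class TuningReport:
    """Per-round diagnostics of the tuning loop."""

    rounds: list[dict] = field(default_factory=list)
    converged: bool = False
    stable_days: int = 0

    def to_frame(self):
        import pandas as pd
        rows = []
        for r in self.rounds:
            for name, v in r["verdicts"].items():
                rows.append({
                    "round": r["round"], "species": name, "slope": v.slope,
                    "ci_lo": v.slope_ci[0], "ci_hi": v.slope_ci[1],
                    "pct_change": v.pct_change, "significant": v.significant,
                })
        return pd.DataFrame(rows)


def _simulate_day(world: WorldState) -> dict[str, np.ndarray]:
    """One simulated day without stimulation; hourly system counts."""
    rec = HourlyRecorder()
    Engine(world).run(24.0, recorder=rec)
    panel = rec.to_panel()
    return {name: panel.system[name].to_numpy() for name in sp.SPECIES_NAMES}


def tune_homeostasis(
    config: SimulationConfig | None = None,
    tuning: TuningConfig | None = None,
    simulate_day: Callable[[WorldState], dict[str, np.ndarray]] | None = None,
    world: WorldState | None = None,
) -> tuple[ProductionParams, WorldState, TuningReport]:
    """Calibrate production parameters to homeostasis.

    Simulates consecutive unstimulated days (no LPS, circadian drivers off).
    After an initial relaxation period, each day's hourly counts are trend-
    tested per species and the responsible parameters adjusted; the loop
    stops once no parameter changes for ``convergence_days`` consecutive
    days (or at ``max_rounds``, reporting non-convergence).  Returns the
    adjusted parameters, the world in its saved homeostatic configuration,
    and a per-round report.

    ``simulate_day`` may be injected for testing; it receives the world
    (whose ``config.params`` carries the current parameters) and returns
    hourly count vectors per species name.
    """
    if config is None:
        config = SimulationConfig()
    cc = dataclasses.replace(config.circadian, enabled=False)
    config = config.replace(circadian=cc)
    if tuning is None:
        tuning = TuningConfig()
    if simulate_day is None:
        simulate_day = _simulate_day
    if world is None:
        world = build_world(config)
    else:
        world.config = config

    report = TuningReport()
    stable = 0
    params = config.params
    for rnd in range(tuning.max_rounds):
        world.config = world.config.replace(params=params)
        counts = simulate_day(world)
        verdicts = {name: fit_trend(series, tuning.ci_level,
                                    tuning.pct_threshold,
                                    tuning.min_abs_shift)
                    for name, series in counts.items()}
        changes: dict[str, tuple[float, float]] = {}
        if rnd >= tuning.relax_days:
            updates: dict[str, float] = {}
            for name, pnames in PARAMS_FOR_SPECIES.items():
                v = verdicts[name]
                if not v.significant or not np.isfinite(v.pct_change):
                    continue
                shared = len(pnames) > 1
                for pname in pnames:
                    old = getattr(params, pname)
                    new = adjust_parameter(old, v.m1, v.m2, shared=shared)
                    if abs(new - old) > 1e-12:
                        updates[pname] = new
                        changes[pname] = (old, new)
            if updates:
                params = params.replace(**updates)
                stable = 0
            else:
                stable += 1
        report.rounds.append({"round": rnd, "verdicts": verdicts,
                              "changes": changes, "params": params.as_dict()})
        if stable >= tuning.convergence_days:
            report.converged = True
            break
    report.stable_days = stable
    world.config = world.config.replace(params=params)
    return params, world, report


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average (edges keep the raw value)."""
    if len(y) < 3:
        return y.astype(float)
    out = y.astype(float).copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def peak_time_hours(hours: np.ndarray, counts: np.ndarray,
                    after: float = 0.0) -> float:
    """Elapsed hour of the maximum of a smoothed hourly series."""
    sm = _smooth3(np.asarray(counts, dtype=float))
    sel = np.asarray(hours) >= after
    i = int(np.argmax(sm[sel]))
    return float(np.asarray(hours)[sel][i])


def search_time_scale(
    candidate_scales: Sequence[int],
    reference_window: tuple[float, float] = (2.0, 6.0),
    challenge: Callable[[int], tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[int | None, dict[int, float]]:
    """Choose the smallest time-scale whose P-response timing matches in vivo.

    ``challenge(scale)`` runs the 9:00 AM endotoxin challenge at the given
    ticks-per-hour scale and returns (hours_post_injection, mean P counts);
    the peak is read from the replicate-averaged, 3-point-smoothed series.
    Returns the selected scale (None if no candidate lands in the window)
    together with every candidate's peak time.
    """
    if challenge is None:
        from .experiments import challenge_peak_curve
        challenge = challenge_peak_curve
    peaks: dict[int, float] = {}
    chosen = None
    for scale in sorted(candidate_scales):
        hours, p_counts = challenge(scale)
        peaks[scale] = peak_time_hours(hours, p_counts)
        if chosen is None and \
                reference_window[0] <= peaks[scale] <= reference_window[1]:
            chosen = scale
    return chosen, peaks
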