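"""Population statistics: variability-based fitness, synchronization,
percentage change of fitness, sensitivity coefficients, and the effective
endotoxin concentration.

The central quantity is the variability-based fitness F_var: the ratio of
the Shannon entropies of the cross-cell distributions of anti- and
pro-inflammatory counts.  Entropy is computed on range-contracted counts
(whole-number division by C) so that sparsely spread counts bin together;
the ratio is invariant to the logarithm base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountPanel", "FitnessSeries", "SensitivityResult", "entropy_of_counts",
    "variability_fitness", "synchronization", "synchronization_series",
    "pct_change_fitness", "effective_concentration", "sensitivity_sweep",
    "replicate_mean_se",
]


@dataclass
class CountPanel:
    """Per-cell counts of one species on an hourly grid.

    ``per_cell`` has shape (n_times, n_cells); ``system`` is the per-time
    system-wide total (which may exceed the cell sum -- it includes plasma).
    """

    times: np.ndarray
    per_cell: np.ndarray
    system: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.per_cell = np.asarray(self.per_cell)
        if self.per_cell.shape[0] != len(self.times):
            raise ValueError("per_cell rows must align with times")
        if self.system is None:
            self.system = self.per_cell.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return self.per_cell.shape[1]


@dataclass
class FitnessSeries:
    """F_var(t) with the contraction divisor that produced it."""

    times: np.ndarray
    values: np.ndarray
    contraction: int = 5


def entropy_of_counts(counts: Sequence[int], contraction: int = 5,
                      base: float = 2.0) -> float:
    """Shannon entropy of the cross-cell distribution of contracted counts.

    Counts are first contracted by whole-number division (``floor(x / C)``),
    then the entropy of the empirical distribution over the distinct
    contracted values is returned.  Zero iff all contracted values agree;
    at most log(#cells).
    """
    x = np.asarray(counts)
    if x.size == 0:
        raise ValueError("empty count vector")
    if contraction < 1:
        raise ValueError("contraction divisor must be >= 1")
    v = x // contraction
    _, freq = np.unique(v, return_counts=True)
    p = freq / freq.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def variability_fitness(panel_p: CountPanel, panel_a: CountPanel,
                        contraction: int = 5) -> FitnessSeries:
    """Variability-based fitness F_var(t) = H_A(t) / H_P(t).

    The anti-inflammatory entropy is the numerator, so the fitness falls
    when the pro-inflammatory arm spreads out across cells after an
    endotoxin challenge.  Hours where H_P vanishes carry the last finite
    value forward (0 at the start).
    """
    if len(panel_p.times) != len(panel_a.times) or \
            not np.allclose(panel_p.times, panel_a.times):
        raise ValueError("panels are on different time grids")
    out = np.zeros(len(panel_p.times))
    last = 0.0
    for i in range(len(out)):
        hp = entropy_of_counts(panel_p.per_cell[i], contraction)
        ha = entropy_of_counts(panel_a.per_cell[i], contraction)
        if hp > 0:
            last = ha / hp
        out[i] = last
    return FitnessSeries(times=panel_p.times.copy(), values=out,
                         contraction=contraction)


def synchronization(panel: CountPanel, t_end: float,
                    window: float = 3.0) -> float:
    """Mean per-cell Pearson correlation with the population-average
    trajectory over the window [t_end - window, t_end].

    Cells whose trajectory is constant over the window have no defined
    correlation and are skipped; if every cell (or the population mean) is
    constant the level is undefined and NaN is returned.
    """
    sel = (panel.times >= t_end - window - 1e-9) & (panel.times <= t_end + 1e-9)
    if sel.sum() < 3:
        raise ValueError("window must contain at least 3 samples")
    x = panel.per_cell[sel].astype(float)          # (t, cells)
    mean_traj = x.mean(axis=1)
    if np.ptp(mean_traj) == 0:
        return float("nan")
    mc = mean_traj - mean_traj.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum(axis=0) * (mc ** 2).sum())
    ok = denom > 0
    if not ok.any():
        return float("nan")
    r = (xc[:, ok] * mc[:, None]).sum(axis=0) / denom[ok]
    return float(r.mean())


def synchronization_series(panel: CountPanel, t_ends: Sequence[float],
                           window: float = 3.0) -> pd.Series:
    """Synchronization level at several window endpoints."""
    return pd.Series({t: synchronization(panel, t, window) for t in t_ends})


def pct_change_fitness(f_orig: np.ndarray, f_new: np.ndarray) -> float:
    """Percentage change of the fitness DF_var.

    The total absolute change between the two fitness series over the
    horizon, normalized by the total fitness of the original system:
    ``sum_t |F_orig - F_new| / sum_t F_orig``.
    """
    a = np.asarray(f_orig, dtype=float)
    b = np.asarray(f_new, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fitness series are misaligned")
    denom = a.sum()
    if denom == 0:
        raise ValueError("original fitness series sums to zero")
    return float(np.abs(a - b).sum() / denom)


def effective_concentration(lpsr_in_cells: np.ndarray | int,
                            n_cells: int = 50,
                            cell_area: int = 1200) -> np.ndarray | float:
    """Effective endotoxin concentration, percent.

    ``EC(t) = 100 * total LPSR across cells / (n_cells * cell_area)`` --
    the fraction of the summed cell volume occupied by active LPS-receptor
    complexes.
    """
    return 100.0 * np.asarray(lpsr_in_cells, dtype=float) / (n_cells * cell_area)


@dataclass
class SensitivityResult:
    """Sensitivity of the fitness to one production-parameter perturbation."""

    parameter: str
    direction: str                  # "down" | "up"
    nominal_dp: float
    realized_dp: float              # relative change actually applied (capped)
    df_var: float
    coefficient: float              # df_var / realized_dp


def sensitivity_sweep(
    baseline_params,
    fitness_of: Callable[[object], np.ndarray],
    dp: float = 0.75,
    parameters: Sequence[str] | None = None,
    directions: Sequence[str] = ("down", "up"),
) -> list[SensitivityResult]:
    """Perturb each production parameter by ±dp and measure DF_var.

    ``fitness_of(params)`` simulates the system at the given parameters and
    returns its hourly F_var series (the caller fixes horizon, replicates
    and seeds).  Up-perturbed probabilities are capped at 1.0 and the
    realized relative change replaces the nominal one in the coefficient's
    denominator.  Results are sorted by coefficient, largest first.
    """
    from .config import PRODUCTION_PARAM_NAMES
    if parameters is None:
        parameters = PRODUCTION_PARAM_NAMES
    f0 = np.asarray(fitness_of(baseline_params), dtype=float)
    results: list[SensitivityResult] = []
    for name in parameters:
        p0 = getattr(baseline_params, name)
        for direction in directions:
            p1 = p0 * (1.0 - dp) if direction == "down" else p0 * (1.0 + dp)
            p1 = min(p1, 1.0)
            realized = abs(p1 - p0) / p0 if p0 > 0 else 0.0
            if realized == 0.0:
                results.append(SensitivityResult(name, direction, dp, 0.0,
                                                 0.0, 0.0))
                continue
            f1 = np.asarray(fitness_of(baseline_params.replace(**{name: p1})),
                            dtype=float)
            dfv = pct_change_fitness(f0, f1)
            results.append(SensitivityResult(
                name, direction, dp, realized, dfv, dfv / realized))
    results.sort(key=lambda r: r.coefficient, reverse=True)
    return results


def replicate_mean_se(samples: Sequence[np.ndarray | float]):
    """Mean and standard error (sd/sqrt(N)) over replicate runs."""
    arr = np.asarray(samples, dtype=float)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, se
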