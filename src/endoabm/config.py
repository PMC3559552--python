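"""Configuration of the simulated world: geometry, clocks, and rule probabilities.

Every number here is overridable from a YAML file (see :func:`load_config` /
:func:`save_config`); the defaults are the model's published operating point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GridGeometry", "ClockConfig", "ProductionParams", "MovementParams",
    "CircadianConfig", "SimulationConfig", "load_config", "save_config",
    "PRODUCTION_PARAM_NAMES",
]


@dataclass(frozen=True)
class GridGeometry:
    """Lattice dimensions of the plasma and cell compartments.

    The plasma is an 80 x 50 unitless grid containing an 11 x 11 brain region
    and one lattice point per cell; each cell has its own 40 x 30 grid with an
    11 x 11 nucleus region (the nucleus occupies ~10% of the cell area, so its
    side is round(sqrt(0.10 * 1200)) = 11).
    """

    plasma_w: int = 80
    plasma_h: int = 50
    cell_w: int = 40
    cell_h: int = 30
    nucleus_side: int = 11
    brain_side: int = 11
    n_cells: int = 50
    # top-left corners of the square regions
    brain_x0: int = 2
    brain_y0: int = 2

    def __post_init__(self):
        if self.nucleus_side > min(self.cell_w, self.cell_h):
            raise ValueError("nucleus does not fit in the cell grid")
        if self.brain_x0 + self.brain_side > self.plasma_w or \
           self.brain_y0 + self.brain_side > self.plasma_h:
            raise ValueError("brain region does not fit in the plasma grid")

    @property
    def cell_area(self) -> int:
        return self.cell_w * self.cell_h

    @property
    def nucleus_x0(self) -> int:
        return (self.cell_w - self.nucleus_side) // 2

    @property
    def nucleus_y0(self) -> int:
        return (self.cell_h - self.nucleus_side) // 2

    @property
    def n_boundary(self) -> int:
        """Number of membrane positions of a cell grid (136 for 40 x 30)."""
        return 2 * (self.cell_w + self.cell_h) - 4


@dataclass
class ClockConfig:
    """Two tick-per-hour scales and the wall clock.

    ``life_scale`` governs production/degradation rates (f/R = 20 ticks/hour);
    ``time_scale`` maps ticks to wall-clock hours and therefore paces movement,
    circadian windows and responses.  Life processes are evaluated per tick
    with probabilities scaled by life_scale/time_scale so per-hour rates are
    preserved whatever the time-scale.
    """

    life_scale: float = 20.0
    time_scale: float = 20.0
    start_hour: float = 0.0     # simulations start at midnight unless configured

    def hour_of_tick(self, tick: int) -> float:
        """Wall-clock time of day in [0, 24) at a given tick."""
        return (self.start_hour + tick / self.time_scale) % 24.0

    def tick_of_hour(self, hour: float) -> int:
        """First tick at or after the given elapsed simulation hour."""
        return int(round(hour * self.time_scale))

    @property
    def life_fraction(self) -> float:
        """Per-tick scaling of per-life-step probabilities."""
        return self.life_scale / self.time_scale


# names of the nine tunable production probabilities, in the published order
PRODUCTION_PARAM_NAMES = ("kp", "ki", "fi", "fa", "fm", "mp", "pf", "pt", "ae")


@dataclass
class ProductionParams:
    """Stochastic production probabilities and import/addition constants.

    The nine tunable probabilities are Bernoulli parameters drawn once per
    nucleus (or brain) entry of the producing molecule:

    ==== ==========================================  ================
    name produces                                    default
    ==== ==========================================  ================
    kp   NFkB in nucleus -> P                        0.6944
    ki   NFkB in nucleus -> IkB                      0.7008
    fi   FR in nucleus -> IkB                        0.7008
    fa   FR in nucleus -> A                          0.7477
    fm   F in brain -> M                             0.2748
    mp   active M in nucleus -> P                    0.6944
    pf   P in brain -> F                             0.2498
    pt   active P in nucleus -> TLR4                 0.7000
    ae   active A in nucleus -> E                    0.7572
    ==== ==========================================  ================

    ``R`` is the default homeostatic production probability per life-scale
    step; ``import_prob`` the probability that a non-LPS plasma molecule
    hitting a cell (or entering the brain) is imported, approximating the
    initial TLR4 membrane coverage 40/136 ~= 30%; ``c_fm`` the batch size of
    circadian hormone additions.
    """

    kp: float = 0.6944
    ki: float = 0.7008
    fi: float = 0.7008
    fa: float = 0.7477
    fm: float = 0.2748
    mp: float = 0.6944
    pf: float = 0.2498
    pt: float = 0.7000
    ae: float = 0.7572
    R: float = 0.5
    import_prob: float = 0.30
    c_fm: int = 3

    def __post_init__(self):
        for name in PRODUCTION_PARAM_NAMES + ("R", "import_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability {name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PRODUCTION_PARAM_NAMES}

    def replace(self, **kw) -> "ProductionParams":
        return dataclasses.replace(self, **kw)

    @classmethod
    def initial_guess(cls, p0: float = 0.70) -> "ProductionParams":
        """All nine tunables at the untuned starting probability (70%)."""
        return cls(**{name: p0 for name in PRODUCTION_PARAM_NAMES})


@dataclass
class MovementParams:
    """Random-walk and attraction parameters.

    A molecule waits ``w ~ U{0..max_wait}`` ticks between bursts and keeps a
    uniformly drawn Moore direction for ``n ~ U{1..max_persist}`` steps.
    Interactive pairs closer than ``attraction_theta`` (Chebyshev) steer
    toward each other; headings are refreshed every
    ``attraction_refresh`` ticks.
    """

    max_wait: int = 2
    max_persist: int = 5
    attraction_theta: int = 3
    attraction_refresh: int = 3


@dataclass
class CircadianConfig:
    """Windows of the sine-ramped hormone additions (wall-clock hours).

    Cortisol is added from 3:00 to its 9:00 peak, melatonin from 22:00 to its
    2:00 peak (wrapping midnight); the per-draw probability ramps as
    sin(pi/2 * elapsed/window) from 0 at onset to 1 at the peak.
    """

    enabled: bool = True
    f_start: float = 3.0
    f_peak: float = 9.0
    m_start: float = 22.0
    m_peak: float = 2.0


@dataclass
class SimulationConfig:
    """Complete, seedable description of one simulation."""

    geometry: GridGeometry = field(default_factory=GridGeometry)
    clock: ClockConfig = field(default_factory=ClockConfig)
    params: ProductionParams = field(default_factory=ProductionParams)
    movement: MovementParams = field(default_factory=MovementParams)
    circadian: CircadianConfig = field(default_factory=CircadianConfig)
    seed: int = 0
    plasma_pool_fraction: float = 0.10   # initial plasma P/A as a share of cellular P/A

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def with_time_scale(self, time_scale: float) -> "SimulationConfig":
        return self.replace(clock=dataclasses.replace(self.clock, time_scale=time_scale))


_SECTIONS = {
    "geometry": GridGeometry,
    "clock": ClockConfig,
    "params": ProductionParams,
    "movement": MovementParams,
    "circadian": CircadianConfig,
}


def config_to_dict(cfg: SimulationConfig) -> dict:
    out: dict = {}
    for name, cls in _SECTIONS.items():
        out[name] = dataclasses.asdict(getattr(cfg, name))
    out["seed"] = cfg.seed
    out["plasma_pool_fraction"] = cfg.plasma_pool_fraction
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    kw: dict = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kw[name] = cls(**data[name])
    for scalar in ("seed", "plasma_pool_fraction"):
        if scalar in data:
            kw[scalar] = data[scalar]
    return SimulationConfig(**kw)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a (possibly partial) YAML configuration; unset keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
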