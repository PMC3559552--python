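"""Molecular species of the endotoxemia model.

The model tracks 14 molecule types: the endotoxin signal (LPS, its receptor
TLR4 and the bound complex LPSR), the NFkB signalling proxy (IKK, NFkB.IkB,
NFkB, IkB), aggregate transcriptional-response proxies (P pro-inflammatory,
A anti-inflammatory, E bio-energetic), and the circadian hormonal layer
(cortisol F, its receptor GR, the complex FR, melatonin M).

Each species carries an approximate half-life in hours; a molecule is removed
once it has gone ``lifetime = 2 * half_life`` hours without any event other
than movement.  Initial intracellular copy numbers follow from a homeostatic
occupancy argument, see :func:`derive_initial_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LPS", "TLR4", "LPSR", "IKK", "NFKB_IKB", "NFKB", "IKB", "P", "A", "E",
    "F", "GR", "FR", "M", "N_SPECIES", "SPECIES_NAMES", "SPECIES_INDEX",
    "SpeciesSpec", "SPECIES", "HALF_LIFE_HOURS", "INIT_PER_CELL",
    "LIFETIME_WEIGHTS", "derive_initial_counts", "InitialCountDerivation",
]

# Integer codes, used throughout the vectorized engine.
LPS, TLR4, LPSR, IKK, NFKB_IKB, NFKB, IKB, P, A, E, F, GR, FR, M = range(14)
N_SPECIES = 14

SPECIES_NAMES = (
    "LPS", "TLR4", "LPSR", "IKK", "NFkB.IkB", "NFkB", "IkB",
    "P", "A", "E", "F", "GR", "FR", "M",
)
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES_NAMES)}

PLASMA_C, BRAIN_C, CYTO_C, NUCLEUS_C = "plasma", "brain", "cytoplasm", "nucleus"


@dataclass(frozen=True)
class SpeciesSpec:
    """Static description of one molecule type."""

    name: str
    code: int
    half_life: float                    # hours
    init_per_cell: int | None           # Table-style initial copy number, None for plasma pools
    allowed_compartments: frozenset[str]
    membrane_bound: bool = False        # only TLR4: fixed on the cell boundary

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError(f"half-life of {self.name} must be positive")

    @property
    def lifetime(self) -> float:
        """Idle lifetime in hours, exactly twice the half-life."""
        return 2.0 * self.half_life


def _spec(name, half_life, init, compartments, membrane=False):
    return SpeciesSpec(name, SPECIES_INDEX[name], half_life, init,
                       frozenset(compartments), membrane)


# Compartment permissions: LPS plasma-only; LPSR/IKK/NFkB.IkB/E/GR cytoplasm-only;
# NFkB/IkB/FR cytoplasm+nucleus; P anywhere; A anywhere but brain; F everywhere
# but the nucleus; M anywhere but brain.
SPECIES: tuple[SpeciesSpec, ...] = (
    _spec("LPS", 1.0, None, {PLASMA_C}),
    _spec("TLR4", 2.0, 40, {CYTO_C}, membrane=True),
    _spec("LPSR", 2.0, None, {CYTO_C}),
    _spec("IKK", 2.5, 50, {CYTO_C}),
    _spec("NFkB.IkB", 2.5, 50, {CYTO_C}),
    _spec("NFkB", 2.0, None, {CYTO_C, NUCLEUS_C}),
    _spec("IkB", 0.5, 10, {CYTO_C, NUCLEUS_C}),
    _spec("P", 1.5, 30, {PLASMA_C, BRAIN_C, CYTO_C, NUCLEUS_C}),
    _spec("A", 1.5, 30, {PLASMA_C, CYTO_C, NUCLEUS_C}),
    _spec("E", 2.0, 40, {CYTO_C}),
    _spec("F", 1.0, None, {PLASMA_C, BRAIN_C, CYTO_C}),
    _spec("GR", 2.0, 40, {CYTO_C}),
    _spec("FR", 2.0, None, {CYTO_C, NUCLEUS_C}),
    _spec("M", 1.0, None, {PLASMA_C, CYTO_C, NUCLEUS_C}),
)

HALF_LIFE_HOURS = tuple(s.half_life for s in SPECIES)
INIT_PER_CELL = {s.code: s.init_per_cell for s in SPECIES if s.init_per_cell}

# Lifetime of each initialized intracellular species relative to IkB (the
# shortest-lived species): these are the integer weights of the copy-number
# budget.  lifetime ratios: IkB 1h -> 1; NFkB.IkB 5h -> 5; IKK 5h -> 5;
# P 3h -> 3; A 3h -> 3; E 4h -> 4; TLR4 4h -> 4; GR 4h -> 4.
LIFETIME_WEIGHTS = {IKB: 1, NFKB_IKB: 5, IKK: 5, P: 3, A: 3, E: 4, TLR4: 4, GR: 4}


@dataclass(frozen=True)
class InitialCountDerivation:
    """Result of the homeostatic copy-number derivation."""

    budget: float                       # molecules allowed by the occupancy assumption
    weights: dict[int, int] = field(default_factory=dict)
    f: int = 0                          # copies of the unit-weight species (IkB)
    counts: dict[int, int] = field(default_factory=dict)
    life_scale: float = 0.0             # ticks per hour on the production clock


def derive_initial_counts(
    half_lives: dict[int, float] | None = None,
    occupancy_fraction: float = 0.25,
    cell_area: int = 40 * 30,
    production_rate: float = 0.5,
) -> InitialCountDerivation:
    """Derive homeostatic per-cell copy numbers and the life-scale.

    A homeostatic cell is assumed to hold molecules on ``occupancy_fraction``
    of its grid area.  Copy numbers are proportional to molecular lifetimes
    (a species living twice as long accumulates twice the copies at equal
    production), expressed as integer weights relative to the shortest-lived
    species.  With the default table the weights sum to 29, the budget is
    0.25 * 1200 = 300, hence ``f = floor(300 / 29) = 10`` copies of IkB and
    the familiar 10/50/50/30/30/40/40/40 column.  The life-scale, the number
    of ticks per hour of the production/degradation clock, is ``f / R``.

    Parameters
    ----------
    half_lives:
        Mapping species code -> half-life in hours; defaults to the built-in
        table restricted to species with initial populations.
    occupancy_fraction:
        Fraction of the cell grid occupied by molecules, in (0, 1).
    cell_area:
        Number of lattice sites in one cell grid.
    production_rate:
        Default per-life-step production probability R.
    """
    if half_lives is None:
        half_lives = {c: HALF_LIFE_HOURS[c] for c in LIFETIME_WEIGHTS}
    if not 0 < occupancy_fraction < 1:
        raise ValueError("occupancy_fraction must lie in (0, 1)")
    for code, hl in half_lives.items():
        if hl <= 0:
            raise ValueError(f"invalid species: non-positive half-life for code {code}")

    ref = min(half_lives.values())
    weights = {c: round((2 * hl) / (2 * ref)) for c, hl in half_lives.items()}
    budget = occupancy_fraction * cell_area
    total_w = sum(weights.values())
    if budget < total_w:
        raise ValueError(
            f"infeasible budget: {budget:.1f} molecules cannot carry total weight {total_w}")
    f = int(budget // total_w)
    counts = {c: w * f for c, w in weights.items()}
    return InitialCountDerivation(
        budget=budget, weights=weights, f=f, counts=counts,
        life_scale=f / production_rate,
    )
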