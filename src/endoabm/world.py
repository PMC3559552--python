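"""World construction: molecule store, compartment geometry and the initial state.

The engine is vectorized: all molecules live in a structure-of-arrays
(:class:`MoleculeStore`).  A molecule's compartment is encoded by ``cell``
(-1 for the systemic plasma grid, otherwise the owning cell index) together
with its position: a plasma molecule inside the brain region *is* in the
brain (entry is gated by import), and a cell molecule inside the nucleus
region is in the nucleus (entry is restricted to nucleus-eligible species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import species as sp
from .config import GridGeometry, SimulationConfig

__all__ = [
    "MoleculeStore", "WorldState", "build_world", "classify_cell_state",
    "classify_cells", "nucleus_eligible", "snapshot_frame",
]

# species that may reside in the nucleus unconditionally / only when active
_NUCLEUS_ALWAYS = frozenset({sp.NFKB, sp.IKB, sp.FR})
_NUCLEUS_ACTIVE = frozenset({sp.P, sp.A, sp.M})
# species importable from plasma into cells / into the brain
CELL_IMPORTABLE = (sp.P, sp.A, sp.F, sp.M)
BRAIN_IMPORTABLE = (sp.P, sp.F)


_NUC_ALWAYS_LUT = np.zeros(sp.N_SPECIES, dtype=bool)
_NUC_ALWAYS_LUT[list(_NUCLEUS_ALWAYS)] = True
_NUC_ACTIVE_LUT = np.zeros(sp.N_SPECIES, dtype=bool)
_NUC_ACTIVE_LUT[list(_NUCLEUS_ACTIVE)] = True
CELL_IMPORT_LUT = np.zeros(sp.N_SPECIES, dtype=bool)
CELL_IMPORT_LUT[list(CELL_IMPORTABLE)] = True
BRAIN_IMPORT_LUT = np.zeros(sp.N_SPECIES, dtype=bool)
BRAIN_IMPORT_LUT[list(BRAIN_IMPORTABLE)] = True


def nucleus_eligible(species: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Boolean mask of molecules allowed into the nucleus region.

    NFkB, IkB and FR translocate freely; P, A and M must be in the active
    (imported) state; everything else is excluded.
    """
    species = np.asarray(species)
    active = np.asarray(active)
    return _NUC_ALWAYS_LUT[species] | (_NUC_ACTIVE_LUT[species] & active)


def classify_cell_state(n_p: int, n_a: int) -> str:
    """Inflammatory state of a cell from its P and A counts.

    ``pro`` if P > 1.5 A, ``anti`` if A > 1.5 P, else ``homeostatic``
    (exact 1.5-fold ties are homeostatic because the comparisons are strict).
    """
    if n_p < 0 or n_a < 0:
        raise ValueError("counts must be non-negative")
    if n_p > 1.5 * n_a:
        return "pro"
    if n_a > 1.5 * n_p:
        return "anti"
    return "homeostatic"


def classify_cells(n_p: np.ndarray, n_a: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_cell_state`; returns int codes 1/-1/0."""
    n_p = np.asarray(n_p)
    n_a = np.asarray(n_a)
    out = np.zeros(n_p.shape, dtype=np.int8)
    out[n_p > 1.5 * n_a] = 1
    out[n_a > 1.5 * n_p] = -1
    return out


class MoleculeStore:
    """Structure-of-arrays container for every molecule in the system."""

    _FIELDS = ("species", "cell", "x", "y", "active", "immobile",
               "last_event", "dirx", "diry", "steps", "wait", "bslot")
    _DTYPES = {"species": np.int16, "cell": np.int16, "x": np.int16,
               "y": np.int16, "active": bool, "immobile": bool,
               "last_event": np.int32, "dirx": np.int8, "diry": np.int8,
               "steps": np.int16, "wait": np.int16, "bslot": np.int16}

    def __init__(self, **arrays: np.ndarray):
        n = len(arrays.get("species", ()))
        for name in self._FIELDS:
            arr = arrays.get(name)
            if arr is None:
                fill = -1 if name == "bslot" else 0
                arr = np.full(n, fill, dtype=self._DTYPES[name])
            else:
                arr = np.asarray(arr, dtype=self._DTYPES[name])
            if len(arr) != n:
                raise ValueError(f"field {name} has length {len(arr)} != {n}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.species)

    def compact(self, keep: np.ndarray) -> None:
        """Drop molecules where ``keep`` is False."""
        for name in self._FIELDS:
            setattr(self, name, getattr(self, name)[keep])

    def append(self, other: "MoleculeStore") -> None:
        if len(other) == 0:
            return
        for name in self._FIELDS:
            setattr(self, name, np.concatenate(
                [getattr(self, name), getattr(other, name)]))

    def copy(self) -> "MoleculeStore":
        return MoleculeStore(**{f: getattr(self, f).copy() for f in self._FIELDS})


@dataclass
class WorldState:
    """Full mutable simulation state."""

    config: SimulationConfig
    mol: MoleculeStore
    cell_px: np.ndarray                 # plasma x of each cell
    cell_py: np.ndarray
    cell_map: np.ndarray                # (plasma_w, plasma_h) -> cell id or -1
    rng: np.random.Generator
    tick: int = 0
    # per-cell bookkeeping: stimulated productions and the E molecules they
    # burned (the two columns must always agree -- energy bookkeeping)
    stim_productions: np.ndarray = field(default=None)
    e_deletions: np.ndarray = field(default=None)

    event_counts: dict = field(default_factory=dict)

    def count_event(self, kind: str, n: int = 1) -> None:
        if n:
            self.event_counts[kind] = self.event_counts.get(kind, 0) + int(n)

    def __post_init__(self):
        n = self.config.geometry.n_cells
        if self.stim_productions is None:
            self.stim_productions = np.zeros(n, dtype=np.int64)
        if self.e_deletions is None:
            self.e_deletions = np.zeros(n, dtype=np.int64)

    # -- geometry helpers ---------------------------------------------------

    @property
    def geometry(self) -> GridGeometry:
        return self.config.geometry

    def in_brain(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        g = self.geometry
        return ((x >= g.brain_x0) & (x < g.brain_x0 + g.brain_side) &
                (y >= g.brain_y0) & (y < g.brain_y0 + g.brain_side))

    def in_nucleus_region(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        g = self.geometry
        return ((x >= g.nucleus_x0) & (x < g.nucleus_x0 + g.nucleus_side) &
                (y >= g.nucleus_y0) & (y < g.nucleus_y0 + g.nucleus_side))

    # -- masks --------------------------------------------------------------

    def plasma_mask(self) -> np.ndarray:
        """Plasma residents outside the brain region."""
        m = self.mol
        return (m.cell < 0) & ~self.in_brain(m.x, m.y)

    def brain_mask(self) -> np.ndarray:
        m = self.mol
        return (m.cell < 0) & self.in_brain(m.x, m.y)

    def nucleus_mask(self) -> np.ndarray:
        m = self.mol
        return (m.cell >= 0) & self.in_nucleus_region(m.x, m.y)

    # -- counts -------------------------------------------------------------

    def counts_by_species(self) -> np.ndarray:
        """System-wide molecule count per species (length 14)."""
        return np.bincount(self.mol.species, minlength=sp.N_SPECIES)

    def per_cell_counts(self, species_code: int) -> np.ndarray:
        m = self.mol
        sel = (m.species == species_code) & (m.cell >= 0)
        return np.bincount(m.cell[sel], minlength=self.geometry.n_cells)

    def brain_counts(self, species_code: int) -> int:
        m = self.mol
        return int(np.count_nonzero(self.brain_mask() & (m.species == species_code)))

    def nucleus_counts(self, species_code: int) -> np.ndarray:
        """Per-cell count of a species currently inside the nucleus region."""
        m = self.mol
        sel = (m.species == species_code) & (m.cell >= 0) & \
            self.in_nucleus_region(m.x, m.y)
        return np.bincount(m.cell[sel], minlength=self.geometry.n_cells)

    def tlr4_occupancy(self) -> np.ndarray:
        """(n_cells, n_boundary) boolean membrane TLR4 occupancy."""
        g = self.geometry
        occ = np.zeros((g.n_cells, g.n_boundary), dtype=bool)
        m = self.mol
        sel = (m.species == sp.TLR4) & (m.bslot >= 0)
        occ[m.cell[sel], m.bslot[sel]] = True
        return occ

    def cell_states(self) -> np.ndarray:
        return classify_cells(self.per_cell_counts(sp.P), self.per_cell_counts(sp.A))

    # -- integrity ----------------------------------------------------------

    def check_permissions(self) -> None:
        """Assert the species-compartment permission matrix; raises on breach."""
        m = self.mol
        brain = self.brain_mask()
        plasma = self.plasma_mask()
        nuc = self.nucleus_mask()
        cyto = (m.cell >= 0) & ~nuc
        for spec in sp.SPECIES:
            here = m.species == spec.code
            for mask, comp in ((plasma, sp.PLASMA_C), (brain, sp.BRAIN_C),
                               (cyto, sp.CYTO_C), (nuc, sp.NUCLEUS_C)):
                bad = here & mask
                if comp not in spec.allowed_compartments and bad.any():
                    idx = np.flatnonzero(bad)[0]
                    raise AssertionError(
                        f"{spec.name} found in forbidden compartment {comp} "
                        f"at index {idx}, tick {self.tick}")
        # nucleus residency additionally requires the active flag for P/A/M
        bad = nuc & ~nucleus_eligible(m.species, m.active)
        if bad.any():
            raise AssertionError("inactive molecule inside a nucleus region")


# ---------------------------------------------------------------------------
# boundary-slot geometry


def boundary_slots(geom: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (bx, by) of the n_boundary membrane positions of a cell grid.

    Slots are enumerated clockwise from (0, 0); the enumeration is fixed so a
    slot index identifies a membrane position across the whole simulation.
    """
    w, h = geom.cell_w, geom.cell_h
    xs, ys = [], []
    for x in range(w):                   # top row
        xs.append(x); ys.append(0)
    for y in range(1, h):                # right column
        xs.append(w - 1); ys.append(y)
    for x in range(w - 2, -1, -1):       # bottom row
        xs.append(x); ys.append(h - 1)
    for y in range(h - 2, 0, -1):        # left column
        xs.append(0); ys.append(y)
    return np.array(xs, dtype=np.int16), np.array(ys, dtype=np.int16)


# ---------------------------------------------------------------------------
# construction


def _draw_walk(n: int, rng: np.random.Generator, mv) -> dict[str, np.ndarray]:
    from .movement import draw_directions
    dirx, diry = draw_directions(n, rng)
    return dict(
        dirx=dirx, diry=diry,
        steps=rng.integers(1, mv.max_persist + 1, n).astype(np.int16),
        wait=rng.integers(0, mv.max_wait + 1, n).astype(np.int16),
    )


def _staggered_ages(species_codes: np.ndarray, rng: np.random.Generator,
                    life_scale: float) -> np.ndarray:
    """Initial last-event ticks drawn uniformly over [-lifetime, 0].

    Seeds the steady-state age distribution so the initial population does not
    degrade in one synchronized wave at t = lifetime.  Lifetimes are measured
    on the life-scale tick clock.
    """
    lifetimes = np.array([2.0 * hl for hl in sp.HALF_LIFE_HOURS])
    lt_ticks = np.maximum((lifetimes[species_codes] * life_scale).astype(np.int64), 1)
    return (-rng.integers(0, lt_ticks)).astype(np.int32)


def build_world(config: SimulationConfig | None = None,
                seed: int | None = None) -> WorldState:
    """Construct the homeostatic initial state.

    Places ``n_cells`` cells on distinct plasma lattice points outside the
    brain region, fills each cell with the derived initial copy numbers
    (TLR4 on distinct membrane slots, everything else uniform over the
    cytoplasm), and seeds the plasma P and A pools at 10% of the summed
    cellular counts.  Construction is a pure function of the seed.
    """
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = config.replace(seed=seed)
    g = config.geometry
    rng = np.random.default_rng(config.seed)

    # --- cell placement: distinct plasma points, disjoint from the brain
    brain = np.zeros((g.plasma_w, g.plasma_h), dtype=bool)
    brain[g.brain_x0:g.brain_x0 + g.brain_side,
          g.brain_y0:g.brain_y0 + g.brain_side] = True
    free = np.flatnonzero(~brain.ravel())
    if len(free) < g.n_cells:
        raise ValueError("cannot place cells disjointly: plasma grid too small")
    pos = rng.choice(free, size=g.n_cells, replace=False)
    cell_px = (pos // g.plasma_h).astype(np.int16)
    cell_py = (pos % g.plasma_h).astype(np.int16)
    cell_map = np.full((g.plasma_w, g.plasma_h), -1, dtype=np.int16)
    cell_map[cell_px, cell_py] = np.arange(g.n_cells)

    bx, by = boundary_slots(g)
    nuc_x0, nuc_y0, side = g.nucleus_x0, g.nucleus_y0, g.nucleus_side
    # flattened cytoplasm positions outside the nucleus region
    xx, yy = np.meshgrid(np.arange(g.cell_w), np.arange(g.cell_h), indexing="ij")
    outside_nuc = ~((xx >= nuc_x0) & (xx < nuc_x0 + side) &
                    (yy >= nuc_y0) & (yy < nuc_y0 + side))
    cyto_x = xx[outside_nuc].astype(np.int16)
    cyto_y = yy[outside_nuc].astype(np.int16)

    specs, cells, X, Y, bslots = [], [], [], [], []

    for cid in range(g.n_cells):
        for code, count in sp.INIT_PER_CELL.items():
            specs.append(np.full(count, code, dtype=np.int16))
            cells.append(np.full(count, cid, dtype=np.int16))
            if code == sp.TLR4:
                slots = rng.choice(g.n_boundary, size=count, replace=False)
                X.append(bx[slots]); Y.append(by[slots])
                bslots.append(slots.astype(np.int16))
            else:
                idx = rng.integers(0, len(cyto_x), count)
                X.append(cyto_x[idx]); Y.append(cyto_y[idx])
                bslots.append(np.full(count, -1, dtype=np.int16))

    # --- plasma pools: 10% of summed cellular P (resp. A), inactive
    pool = int(round(config.plasma_pool_fraction * g.n_cells * sp.INIT_PER_CELL[sp.P]))
    pool_a = int(round(config.plasma_pool_fraction * g.n_cells * sp.INIT_PER_CELL[sp.A]))
    plasma_free_x = (free // g.plasma_h).astype(np.int16)
    plasma_free_y = (free % g.plasma_h).astype(np.int16)
    for code, count in ((sp.P, pool), (sp.A, pool_a)):
        specs.append(np.full(count, code, dtype=np.int16))
        cells.append(np.full(count, -1, dtype=np.int16))
        idx = rng.integers(0, len(plasma_free_x), count)
        X.append(plasma_free_x[idx]); Y.append(plasma_free_y[idx])
        bslots.append(np.full(count, -1, dtype=np.int16))

    species_arr = np.concatenate(specs)
    n = len(species_arr)
    store = MoleculeStore(
        species=species_arr,
        cell=np.concatenate(cells),
        x=np.concatenate(X),
        y=np.concatenate(Y),
        active=np.zeros(n, dtype=bool),
        immobile=species_arr == sp.TLR4,
        last_event=_staggered_ages(species_arr, rng, config.clock.life_scale),
        bslot=np.concatenate(bslots),
        **_draw_walk(n, rng, config.movement),
    )
    return WorldState(config=config, mol=store, cell_px=cell_px,
                      cell_py=cell_py, cell_map=cell_map, rng=rng)


def snapshot_frame(world: WorldState) -> pd.DataFrame:
    """One row per molecule: species, compartment, cell, x, y, active."""
    m = world.mol
    comp = np.where(m.cell < 0,
                    np.where(world.in_brain(m.x, m.y), "brain", "plasma"),
                    np.where(world.in_nucleus_region(m.x, m.y) & (m.cell >= 0),
                             "nucleus", "cytoplasm"))
    return pd.DataFrame({
        "species": np.array(sp.SPECIES_NAMES)[m.species],
        "compartment": comp,
        "cell": m.cell,
        "x": m.x, "y": m.y,
        "active": m.active,
    })
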