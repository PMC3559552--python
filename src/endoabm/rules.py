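"""The interaction, production, degradation and circadian rules.

This module holds the rule *semantics* -- which pairs react and what they
produce, the per-entry production draws, the idle-lifetime degradation test
and the sine-ramped circadian additions.  The vectorized tick loop in
:mod:`endoabm.engine` executes these rules over the whole population; the
functions here are the single-event contracts used directly by tests and by
the engine's vector kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import species as sp
from .config import ProductionParams

__all__ = [
    "RuleEvent", "resolve_collision", "nucleus_draw_table", "brain_draw_table",
    "CircadianDriver", "circadian_probability", "lifetime_ticks",
    "should_degrade", "inject_lps",
]


@dataclass(frozen=True)
class RuleEvent:
    """Outcome of a pairwise collision."""

    kind: str                        # activation | inhibition | degradation | production
    consumed: tuple[int, ...]        # species codes removed
    produced: tuple[int, ...]        # species codes created
    activated: int | None = None     # species whose active flag is set


# outcomes of co-located pairs; keys are frozensets of (species, active) tuples
def resolve_collision(species_a: int, active_a: bool,
                      species_b: int, active_b: bool,
                      in_cell: bool = True) -> RuleEvent | None:
    """Resolve one co-located molecule pair to a rule event (or None).

    The reactive pairs are: P+A of equal status (mutual annihilation,
    any compartment); LPSR + inactive IKK and imported P + inactive IKK
    (IKK activation); active IKK + NFkB.IkB (complex split, free NFkB);
    NFkB + IkB (re-complexation); active F + GR (receptor binding to FR).
    All intracellular pairs require ``in_cell``.
    """
    pair = {(species_a, bool(active_a)), (species_b, bool(active_b))}
    a_codes = {species_a, species_b}

    if a_codes == {sp.P, sp.A} and active_a == active_b:
        return RuleEvent("degradation", consumed=(sp.P, sp.A), produced=())
    if not in_cell:
        return None
    if a_codes == {sp.LPSR, sp.IKK} and (sp.IKK, False) in pair:
        return RuleEvent("activation", consumed=(), produced=(), activated=sp.IKK)
    if a_codes == {sp.P, sp.IKK} and (sp.P, True) in pair and (sp.IKK, False) in pair:
        return RuleEvent("activation", consumed=(), produced=(), activated=sp.IKK)
    if a_codes == {sp.IKK, sp.NFKB_IKB} and (sp.IKK, True) in pair:
        return RuleEvent("activation", consumed=(sp.NFKB_IKB,), produced=(sp.NFKB,))
    if a_codes == {sp.NFKB, sp.IKB}:
        return RuleEvent("inhibition", consumed=(sp.NFKB, sp.IKB),
                         produced=(sp.NFKB_IKB,))
    if a_codes == {sp.F, sp.GR} and (sp.F, True) in pair:
        return RuleEvent("inhibition", consumed=(sp.F, sp.GR), produced=(sp.FR,))
    return None


def nucleus_draw_table(params: ProductionParams) -> dict[int, list[tuple[float, int]]]:
    """Nucleus production draws: producer species -> [(prob, product)].

    Each producer resident in a nucleus rolls its Bernoulli draws once per
    tick of residence; draws for one producer are independent.  NFkB draws
    are additionally suppressed while the nucleus holds fewer NFkB than FR,
    and every successful draw must be paid for with one of the cell's
    bio-energetic molecules (the engine rations successes by available E,
    which makes the resident species compete for a fixed energy budget).
    """
    return {
        sp.NFKB: [(params.kp, sp.P), (params.ki, sp.IKB)],
        sp.P: [(params.pt, sp.TLR4)],
        sp.A: [(params.ae, sp.E)],
        sp.FR: [(params.fa, sp.A), (params.fi, sp.IKB)],
        sp.M: [(params.mp, sp.P)],
    }


def brain_draw_table(params: ProductionParams) -> dict[int, list[tuple[float, int]]]:
    """Per-brain-entry draws: F makes melatonin, P makes cortisol.

    The F -> M draw is blocked while brain P exceeds twice brain F.
    """
    return {
        sp.F: [(params.fm, sp.M)],
        sp.P: [(params.pf, sp.F)],
    }


@dataclass(frozen=True)
class CircadianDriver:
    """Sine-ramped addition window for one hormone.

    The probability of an addition draw ramps as sin(pi/2 * elapsed/window)
    from 0 at ``window_start`` to 1 at ``window_peak`` (clock hours; the
    melatonin window wraps midnight).  Each successful draw adds ``batch``
    units in the brain compartment's production domain.
    """

    species: int
    window_start: float
    window_peak: float
    batch: int = 3


def circadian_probability(hour: float, start: float, peak: float) -> float:
    """sin(pi/2 * elapsed fraction) inside the window, 0 outside.

    ``hour`` is wall-clock time of day; the window may wrap midnight
    (e.g. 22:00 -> 2:00).
    """
    width = (peak - start) % 24.0
    elapsed = (hour - start) % 24.0
    if width == 0 or elapsed > width:
        return 0.0
    return math.sin(0.5 * math.pi * elapsed / width)


_LIFETIMES_H = np.array([2.0 * hl for hl in sp.HALF_LIFE_HOURS])


def lifetime_ticks(life_scale: float) -> np.ndarray:
    """Idle lifetime of each species in ticks on the life-scale clock.

    Lifetimes are anchored to the life-scale (20 ticks per hour of molecular
    life): a molecule's tick budget does not change when the wall-clock
    time-scale is re-calibrated.
    """
    return np.maximum(np.round(_LIFETIMES_H * life_scale), 1).astype(np.int64)


def should_degrade(age_ticks, species_code, life_scale: float):
    """True when a molecule has been idle for at least its lifetime."""
    lt = lifetime_ticks(life_scale)
    return np.asarray(age_ticks) >= lt[np.asarray(species_code)]


def inject_lps(world, dose: int) -> None:
    """Place ``dose`` LPS molecules at uniform random plasma positions.

    Positions avoid the brain region (LPS is plasma-only).  Doses are
    additive; a zero dose leaves the world unchanged.
    """
    from .world import MoleculeStore
    if dose < 0:
        raise ValueError("LPS dose must be non-negative")
    if dose == 0:
        return
    g = world.geometry
    rng = world.rng
    xs = np.empty(dose, dtype=np.int16)
    ys = np.empty(dose, dtype=np.int16)
    filled = 0
    while filled < dose:
        need = dose - filled
        cx = rng.integers(0, g.plasma_w, need)
        cy = rng.integers(0, g.plasma_h, need)
        ok = ~world.in_brain(cx, cy)
        k = int(ok.sum())
        xs[filled:filled + k] = cx[ok]
        ys[filled:filled + k] = cy[ok]
        filled += k
    from .world import _draw_walk
    store = MoleculeStore(
        species=np.full(dose, sp.LPS, dtype=np.int16),
        cell=np.full(dose, -1, dtype=np.int16),
        x=xs, y=ys,
        active=np.zeros(dose, dtype=bool),
        immobile=np.zeros(dose, dtype=bool),
        last_event=np.full(dose, world.tick, dtype=np.int32),
        bslot=np.full(dose, -1, dtype=np.int16),
        **_draw_walk(dose, rng, world.config.movement),
    )
    world.mol.append(store)
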