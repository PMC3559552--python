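"""Vectorized tick loop: movement, imports, collisions, production, degradation.

One tick advances every molecule one walk step (subject to compartment
restrictions), resolves imports and co-location interactions, fires the
per-entry production draws, applies default and circadian production, and
removes idle molecules past their lifetime.  All randomness flows from the
world's single seeded generator, so a run is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import species as sp
from .movement import advance_walk, attraction_field
from .rules import (brain_draw_table, circadian_probability, inject_lps,
                    lifetime_ticks, nucleus_draw_table)
from .world import (BRAIN_IMPORT_LUT, CELL_IMPORT_LUT, MoleculeStore,
                    WorldState, boundary_slots, nucleus_eligible)

__all__ = ["Engine", "HourlyRecorder", "TimeSeriesPanel", "run_hours"]


def _grouped_ranges(counts: np.ndarray) -> np.ndarray:
    """[0..c0-1, 0..c1-1, ...] for group sizes ``counts``."""
    total = int(counts.sum())
    return np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)


def _match_pairs(gid_a: np.ndarray, gid_b: np.ndarray, rng: np.random.Generator):
    """1-1 matching of equal grid ids between two groups, random within ties.

    Returns positional indices (into gid_a and gid_b) of matched pairs; at a
    position holding ``ca`` of A and ``cb`` of B, ``min(ca, cb)`` random
    pairs form.
    """
    if len(gid_a) == 0 or len(gid_b) == 0:
        return (np.empty(0, dtype=np.intp),) * 2
    pa = rng.permutation(len(gid_a))
    pb = rng.permutation(len(gid_b))
    oa = pa[np.argsort(gid_a[pa], kind="stable")]
    ob = pb[np.argsort(gid_b[pb], kind="stable")]
    ua, sa, ca = np.unique(gid_a[oa], return_index=True, return_counts=True)
    ub, sb, cb = np.unique(gid_b[ob], return_index=True, return_counts=True)
    common, ia, ib = np.intersect1d(ua, ub, assume_unique=True,
                                    return_indices=True)
    if len(common) == 0:
        return (np.empty(0, dtype=np.intp),) * 2
    k = np.minimum(ca[ia], cb[ib])
    within = _grouped_ranges(k)
    sel_a = oa[np.repeat(sa[ia], k) + within]
    sel_b = ob[np.repeat(sb[ib], k) + within]
    return sel_a, sel_b


class _Newborns:
    """Per-tick accumulator for created molecules (scalar or bulk adds)."""

    def __init__(self):
        self._chunks: list[tuple] = []

    def add(self, species, cell, x, y, active=False, bslot=-1):
        self._chunks.append((
            np.array([species]), np.array([cell]), np.array([x]),
            np.array([y]), np.array([active], dtype=bool),
            np.array([bslot])))

    def add_bulk(self, species, cell, x, y, active=None, bslot=None):
        species = np.asarray(species)
        n = len(species)
        if n == 0:
            return
        if active is None:
            active = np.zeros(n, dtype=bool)
        if bslot is None:
            bslot = np.full(n, -1)
        self._chunks.append((species, np.asarray(cell), np.asarray(x),
                             np.asarray(y), np.asarray(active, dtype=bool),
                             np.asarray(bslot)))

    def build(self, tick: int, rng, mv) -> MoleculeStore | None:
        if not self._chunks:
            return None
        from .world import _draw_walk
        species, cell, x, y, active, bslot = (
            np.concatenate(cols) for cols in zip(*self._chunks))
        species = species.astype(np.int16)
        n = len(species)
        return MoleculeStore(
            species=species,
            cell=cell.astype(np.int16),
            x=x.astype(np.int16),
            y=y.astype(np.int16),
            active=active,
            immobile=species == sp.TLR4,
            last_event=np.full(n, tick, dtype=np.int32),
            bslot=bslot.astype(np.int16),
            **_draw_walk(n, rng, mv),
        )


# species whose nucleus residence drives stimulated production
_PRODUCER_LUT = np.zeros(sp.N_SPECIES, dtype=bool)
_PRODUCER_LUT[[sp.NFKB, sp.P, sp.A, sp.FR, sp.M]] = True


class Engine:
    """Executes ticks on a :class:`WorldState`."""

    def __init__(self, world: WorldState):
        self.world = world
        cfg = world.config
        g = cfg.geometry
        self.T = int(round(cfg.clock.time_scale))
        if abs(self.T - cfg.clock.time_scale) > 1e-9:
            raise ValueError("time_scale must be an integer tick count per hour")
        # life processes are anchored to the life-scale tick clock: changing
        # the time-scale relabels ticks as hours (stretching circadian windows
        # and compressing response times) without disturbing the tuned
        # per-tick production/degradation balance
        self.p_life = cfg.params.R
        self.lifetimes = lifetime_ticks(cfg.clock.life_scale)
        self.bx, self.by = boundary_slots(g)
        # cytoplasm spawn positions (outside the nucleus region)
        xx, yy = np.meshgrid(np.arange(g.cell_w), np.arange(g.cell_h),
                             indexing="ij")
        nuc = ((xx >= g.nucleus_x0) & (xx < g.nucleus_x0 + g.nucleus_side) &
               (yy >= g.nucleus_y0) & (yy < g.nucleus_y0 + g.nucleus_side))
        self.cyto_x = xx[~nuc].astype(np.int16)
        self.cyto_y = yy[~nuc].astype(np.int16)
        # plasma spawn positions (outside the brain region)
        px, py = np.meshgrid(np.arange(g.plasma_w), np.arange(g.plasma_h),
                             indexing="ij")
        brain = ((px >= g.brain_x0) & (px < g.brain_x0 + g.brain_side) &
                 (py >= g.brain_y0) & (py < g.brain_y0 + g.brain_side))
        self.plasma_x = px[~brain].astype(np.int16)
        self.plasma_y = py[~brain].astype(np.int16)
        self.brain_x = px[brain].astype(np.int16)
        self.brain_y = py[brain].astype(np.int16)
        # static steering field toward cells on the plasma grid
        occ = np.zeros((g.plasma_w, g.plasma_h), dtype=np.float32)
        occ[world.cell_px, world.cell_py] = 1.0
        theta = cfg.movement.attraction_theta
        self.cell_cnt, self.cell_sdx, self.cell_sdy = attraction_field(occ, theta)
        self.theta = theta
        self.injections: list[tuple[int, int]] = []   # (tick, dose)
        # rule names that experiments may switch off ("pa_annihilation")
        self.disabled_rules: frozenset[str] = frozenset()

    # ------------------------------------------------------------------ utils

    def _spawn_cyto_bulk(self, nb: _Newborns, species_arr, cell_arr, rng):
        species_arr = np.asarray(species_arr)
        if len(species_arr) == 0:
            return
        idx = rng.integers(0, len(self.cyto_x), len(species_arr))
        nb.add_bulk(species_arr, cell_arr, self.cyto_x[idx], self.cyto_y[idx])

    def _spawn_cyto(self, nb: _Newborns, species: int, cell: int, rng):
        self._spawn_cyto_bulk(nb, np.array([species]), np.array([cell]), rng)

    def _spawn_plasma(self, nb: _Newborns, species: int, rng, n: int = 1):
        idx = rng.integers(0, len(self.plasma_x), n)
        nb.add_bulk(np.full(n, species), np.full(n, -1),
                    self.plasma_x[idx], self.plasma_y[idx])

    def _spawn_brain(self, nb: _Newborns, species: int, rng, n: int = 1):
        idx = rng.integers(0, len(self.brain_x), n)
        nb.add_bulk(np.full(n, species), np.full(n, -1),
                    self.brain_x[idx], self.brain_y[idx])

    def _spawn_tlr4(self, nb: _Newborns, cell: int, occ_row: np.ndarray, rng):
        free = np.flatnonzero(~occ_row)
        if len(free) == 0:
            return
        slot = int(free[rng.integers(0, len(free))])
        occ_row[slot] = True
        nb.add(sp.TLR4, cell, int(self.bx[slot]), int(self.by[slot]), bslot=slot)

    # ------------------------------------------------------------------- tick

    def step(self) -> None:
        w = self.world
        m = w.mol
        g = w.geometry
        cfg = w.config
        rng = w.rng
        tick = w.tick
        mv = cfg.movement


        n = len(m)
        gone = np.zeros(n, dtype=bool)
        nb = _Newborns()

        # ---------------- movement ----------------------------------------
        in_cell = m.cell >= 0
        was_nuc = in_cell & w.in_nucleus_region(m.x, m.y)
        was_brain = ~in_cell & w.in_brain(m.x, m.y)

        px, py, moved = advance_walk(
            m.x, m.y, m.dirx, m.diry, m.steps, m.wait, ~m.immobile, rng,
            mv.max_persist, mv.max_wait)

        # cell residents: clamp to the cell grid
        cm = moved & in_cell
        px[cm] = np.clip(px[cm], 0, g.cell_w - 1)
        py[cm] = np.clip(py[cm], 0, g.cell_h - 1)
        new_nuc = in_cell & w.in_nucleus_region(px, py)
        eligible = nucleus_eligible(m.species, m.active)
        # forbidden nucleus entry -> stay put
        block = cm & ~was_nuc & new_nuc & ~eligible
        px[block] = m.x[block]
        py[block] = m.y[block]
        new_nuc &= ~block

        # plasma domain: clamp to the plasma grid
        pm = moved & ~in_cell
        px[pm] = np.clip(px[pm], 0, g.plasma_w - 1)
        py[pm] = np.clip(py[pm], 0, g.plasma_h - 1)
        new_brain = ~in_cell & w.in_brain(px, py)
        crossing = pm & ~was_brain & new_brain
        # brain import: P and F enter with the receptor-binding probability
        brain_ok = crossing & BRAIN_IMPORT_LUT[m.species]
        attempt = np.flatnonzero(brain_ok)
        if len(attempt):
            admitted = rng.random(len(attempt)) < cfg.params.import_prob
            rejected = attempt[~admitted]
            brain_ok[rejected] = False
        blocked = crossing & ~brain_ok
        px[blocked] = m.x[blocked]
        py[blocked] = m.y[blocked]
        new_brain = ~in_cell & w.in_brain(px, py)
        entered_brain = np.flatnonzero(crossing & brain_ok)
        # imported-to-brain P may not leave; F circulates freely
        leaving = pm & was_brain & ~new_brain & (m.species == sp.P)
        px[leaving] = m.x[leaving]
        py[leaving] = m.y[leaving]

        arrived = moved & (px != m.x) | (moved & (py != m.y))
        m.x[:] = px
        m.y[:] = py
        # brain entry is a translocation: no status change, no idle-clock
        # reset; the production draws (pf, fm) fire on the entry event

        # membrane release: locally produced (inactive) P/A reaching the
        # cell boundary are exported to plasma at the cell's lattice point
        on_boundary = in_cell & ((m.x == 0) | (m.x == g.cell_w - 1) |
                                 (m.y == 0) | (m.y == g.cell_h - 1))
        release = on_boundary & arrived & ~m.active & \
            ((m.species == sp.P) | (m.species == sp.A))
        rel_idx = np.flatnonzero(release)
        if len(rel_idx):
            cids = m.cell[rel_idx]
            m.x[rel_idx] = w.cell_px[cids]
            m.y[rel_idx] = w.cell_py[cids]
            m.cell[rel_idx] = -1

        # translocation is movement: it does NOT reset the idle clock
        # (only imports, productions and interactions count as actions)

        # ---------------- imports from plasma into cells -------------------
        plasma_now = (m.cell < 0) & ~w.in_brain(m.x, m.y)
        hit = plasma_now & arrived
        if len(rel_idx):
            # molecules just released to plasma must not re-import this tick
            hit[rel_idx] = False
        cid_at = np.full(n, -1, dtype=np.int16)
        cid_at[hit] = w.cell_map[m.x[hit], m.y[hit]]
        on_cell = cid_at >= 0

        imp = on_cell & CELL_IMPORT_LUT[m.species]
        imp_idx = np.flatnonzero(imp)
        if len(imp_idx):
            ok = rng.random(len(imp_idx)) < cfg.params.import_prob
            imp_idx = imp_idx[ok]
        if len(imp_idx):
            m.cell[imp_idx] = cid_at[imp_idx]
            m.active[imp_idx] = True
            m.last_event[imp_idx] = tick
            # imported molecules land uniformly on the cell grid; nucleus-
            # eligible actives (P, A, M) may land inside the nucleus region
            # and immediately count as a nucleus entry; F may not
            elig = nucleus_eligible(m.species[imp_idx], m.active[imp_idx])
            ne = imp_idx[elig]
            m.x[ne] = rng.integers(0, g.cell_w, len(ne))
            m.y[ne] = rng.integers(0, g.cell_h, len(ne))
            rest = imp_idx[~elig]
            pos = rng.integers(0, len(self.cyto_x), len(rest))
            m.x[rest] = self.cyto_x[pos]
            m.y[rest] = self.cyto_y[pos]

        # LPS: a random membrane position is probed; import iff a TLR4 is there
        lps_idx = np.flatnonzero(on_cell & (m.species == sp.LPS))
        if len(lps_idx):
            occ = w.tlr4_occupancy()
            slots = rng.integers(0, g.n_boundary, len(lps_idx))
            cids = cid_at[lps_idx]
            bound = occ[cids, slots]
            if bound.any():
                want = cids[bound].astype(np.int64) * g.n_boundary + slots[bound]
                # two LPS probing the same receptor: only one binds
                want, first = np.unique(want, return_index=True)
                lps_in = lps_idx[bound][first]
                gone[lps_in] = True
                w.count_event("lps_import", len(lps_in))
                # consume the TLR4 occupying the probed slot
                tsel = m.species == sp.TLR4
                tkey = np.full(n, -1, dtype=np.int64)
                tkey[tsel] = m.cell[tsel].astype(np.int64) * g.n_boundary + \
                    m.bslot[tsel]
                order = np.argsort(tkey)
                tlr_idx = order[np.searchsorted(tkey[order], want)]
                gone[tlr_idx] = True
                for c, s in zip(cids[bound][first], slots[bound][first]):
                    nb.add(sp.LPSR, int(c), int(self.bx[s]), int(self.by[s]),
                           active=True)

        # ---------------- co-location interactions -------------------------
        in_cell = m.cell >= 0      # refreshed after imports/releases
        local = np.where(in_cell,
                         m.x.astype(np.int64) * g.cell_h + m.y,
                         m.x.astype(np.int64) * g.plasma_h + m.y)
        gid = np.where(in_cell,
                       g.plasma_w * g.plasma_h +
                       m.cell.astype(np.int64) * g.cell_area + local,
                       local)
        alive = ~gone & ~m.immobile

        def members(mask):
            return np.flatnonzero(mask & alive & ~gone)

        species = m.species
        act = m.active

        def _do_annihilate(status):
            if "pa_annihilation" in self.disabled_rules:
                return
            a = members((species == sp.P) & (act == status))
            if len(a) == 0:
                return
            b = members((species == sp.A) & (act == status))
            ia, ib = _match_pairs(gid[a], gid[b], rng)
            gone[a[ia]] = True
            gone[b[ib]] = True
            w.count_event("pa_annihilation", len(ia))

        def _do_activate_ikk(src_species, src_active):
            srcs = members((species == src_species) & (act == src_active) &
                           (in_cell if src_species == sp.P else np.True_))
            if len(srcs) == 0:
                return
            ikk = members((species == sp.IKK) & ~act)
            isrc, iikk = _match_pairs(gid[srcs], gid[ikk], rng)
            tgt = ikk[iikk]
            m.active[tgt] = True
            m.last_event[tgt] = tick
            w.count_event("ikk_activation", len(tgt))
            if src_species == sp.P:
                # the cytokine signal is spent by the activation (ligand
                # consumption); the receptor complex LPSR stays catalytic
                gone[srcs[isrc]] = True

        def _do_liberate():
            ikk = members((species == sp.IKK) & act)
            if len(ikk) == 0:
                return
            cplx = members(species == sp.NFKB_IKB)
            ik_i, ic = _match_pairs(gid[ikk], gid[cplx], rng)
            freed = cplx[ic]
            gone[freed] = True
            # the liberation spends the kinase charge: IKK reverts to the
            # inactive state and must be hit by LPSR/imported P again
            spent = ikk[ik_i]
            m.active[spent] = False
            m.last_event[spent] = tick
            w.count_event("nfkb_liberation", len(spent))
            nb.add_bulk(np.full(len(freed), sp.NFKB), m.cell[freed],
                        m.x[freed], m.y[freed])

        def _do_complex():
            nf = members(species == sp.NFKB)
            if len(nf) == 0:
                return
            ik = members(species == sp.IKB)
            ia, ib = _match_pairs(gid[nf], gid[ik], rng)
            gone[nf[ia]] = True
            gone[ik[ib]] = True
            w.count_event("complexation", len(ia))
            # the complex is cytoplasmic: spawn outside the nucleus region
            self._spawn_cyto_bulk(nb, np.full(len(ia), sp.NFKB_IKB),
                                  m.cell[nf[ia]], rng)

        def _do_bind_gr():
            f = members((species == sp.F) & act & in_cell)
            if len(f) == 0:
                return
            gr = members(species == sp.GR)
            ia, ib = _match_pairs(gid[f], gid[gr], rng)
            gone[f[ia]] = True
            gone[gr[ib]] = True
            bound = f[ia]
            nb.add_bulk(np.full(len(bound), sp.FR), m.cell[bound],
                        m.x[bound], m.y[bound])

        handlers = [
            lambda: _do_annihilate(False),
            lambda: _do_annihilate(True),
            lambda: _do_activate_ikk(sp.LPSR, True),
            lambda: _do_activate_ikk(sp.P, True),
            _do_liberate,
            _do_complex,
            _do_bind_gr,
        ]
        for i in rng.permutation(len(handlers)):
            handlers[i]()

        # ---------------- nucleus production (per residence tick) ----------
        # every producer currently resident in a nucleus rolls its Bernoulli
        # draws this tick; the cell's bio-energetic pool rations successes
        residents = np.flatnonzero((m.cell >= 0) & ~gone &
                                   w.in_nucleus_region(m.x, m.y) &
                                   _PRODUCER_LUT[m.species])
        if len(residents):
            self._nucleus_production(residents, gone, nb)

        # ---------------- brain-entry production ---------------------------
        if len(entered_brain):
            entered_brain = entered_brain[~gone[entered_brain]]
        if len(entered_brain):
            self._brain_production(entered_brain, nb)

        # ---------------- default homeostatic production --------------------
        self._default_production(nb)

        # ---------------- circadian additions ------------------------------
        if cfg.circadian.enabled:
            self._circadian_additions(nb)

        # ---------------- degradation ---------------------------------------
        age = tick - m.last_event
        gone |= age >= self.lifetimes[m.species]

        # ---------------- commit --------------------------------------------
        if gone.any():
            m.compact(~gone)
        born = nb.build(tick, rng, mv)
        if born is not None:
            m.append(born)

        # ---------------- attraction steering -------------------------------
        if mv.attraction_theta > 0 and tick % mv.attraction_refresh == 0:
            self._steer()

        w.tick = tick + 1

    # --------------------------------------------------------- production

    def _nucleus_production(self, entries: np.ndarray, gone: np.ndarray,
                            nb: _Newborns) -> None:
        w = self.world
        m = w.mol
        rng = w.rng
        table = nucleus_draw_table(w.config.params)

        nf_nuc = w.nucleus_counts(sp.NFKB)
        fr_nuc = w.nucleus_counts(sp.FR)
        suppressed_cells = nf_nuc < fr_nuc      # rule: FR outnumbers NFkB

        cell_chunks, spec_chunks, producer_chunks = [], [], []
        entry_species = m.species[entries]
        for code, draws in table.items():
            sel = entries[entry_species == code]
            if len(sel) == 0:
                continue
            if code == sp.NFKB:
                sel = sel[~suppressed_cells[m.cell[sel]]]
                if len(sel) == 0:
                    continue
            for prob, product in draws:
                hit = sel[rng.random(len(sel)) < prob]
                if len(hit):
                    cell_chunks.append(m.cell[hit])
                    spec_chunks.append(np.full(len(hit), product))
                    producer_chunks.append(hit)
        if not cell_chunks:
            return
        prod_cell = np.concatenate(cell_chunks)
        prod_species = np.concatenate(spec_chunks)
        producer = np.concatenate(producer_chunks)

        # energy gate: each stimulated production burns one E of the cell
        e_sel = np.flatnonzero((m.species == sp.E) & (m.cell >= 0) & ~gone)
        e_cells = m.cell[e_sel]
        e_avail = np.bincount(e_cells, minlength=w.geometry.n_cells)

        order = rng.permutation(len(prod_cell))
        cells_arr = np.asarray(prod_cell)[order]
        spec_arr = np.asarray(prod_species)[order]
        producer_arr = np.asarray(producer)[order]
        # rank successes within each cell, keep while energy remains
        sort_by_cell = np.argsort(cells_arr, kind="stable")
        ranked = cells_arr[sort_by_cell]
        _, rcounts = np.unique(ranked, return_counts=True)
        keep_sorted = _grouped_ranges(rcounts) < e_avail[ranked]
        keep = np.zeros(len(cells_arr), dtype=bool)
        keep[sort_by_cell] = keep_sorted
        if not keep.any():
            return
        cells_arr = cells_arr[keep]
        spec_arr = spec_arr[keep]
        producer_arr = producer_arr[keep]

        # consume one E per kept production, chosen at random per cell
        burn = np.bincount(cells_arr, minlength=w.geometry.n_cells)
        pe = rng.permutation(len(e_sel))
        e_order = pe[np.argsort(e_cells[pe], kind="stable")]
        e_sorted_cells = e_cells[e_order]
        _, ecounts = np.unique(e_sorted_cells, return_counts=True)
        burn_mask = _grouped_ranges(ecounts) < burn[e_sorted_cells]
        gone[e_sel[e_order[burn_mask]]] = True

        np.add.at(w.stim_productions, cells_arr, 1)
        np.add.at(w.e_deletions, cells_arr, 1)
        for code in np.unique(spec_arr):
            w.count_event(f"stim_prod_{int(code)}",
                          int((spec_arr == code).sum()))
        prod_species_arr = m.species[producer_arr]
        for pc in np.unique(prod_species_arr):
            for code in np.unique(spec_arr[prod_species_arr == pc]):
                w.count_event(f"prod_{int(pc)}_to_{int(code)}",
                              int(((prod_species_arr == pc) & (spec_arr == code)).sum()))
        m.last_event[producer_arr] = w.tick

        is_tlr = spec_arr == sp.TLR4
        self._spawn_cyto_bulk(nb, spec_arr[~is_tlr], cells_arr[~is_tlr], rng)
        if is_tlr.any():
            occ = w.tlr4_occupancy()
            for cell in cells_arr[is_tlr]:
                self._spawn_tlr4(nb, int(cell), occ[int(cell)], rng)

    def _brain_production(self, entries: np.ndarray, nb: _Newborns) -> None:
        w = self.world
        m = w.mol
        rng = w.rng
        table = brain_draw_table(w.config.params)
        brain_p = w.brain_counts(sp.P)
        brain_f = w.brain_counts(sp.F)
        m_blocked = brain_p > 2 * brain_f      # P crowds out melatonin synthesis
        for i in entries:
            code = int(m.species[i])
            for prob, product in table.get(code, ()):
                if product == sp.M and m_blocked:
                    continue
                if rng.random() < prob:
                    if product == sp.M:
                        self._spawn_plasma(nb, sp.M, rng)
                    else:
                        self._spawn_brain(nb, sp.F, rng)
                    m.last_event[i] = w.tick

    def _default_production(self, nb: _Newborns) -> None:
        w = self.world
        g = w.geometry
        rng = w.rng
        codes = list(sp.INIT_PER_CELL)            # 8 intracellular species
        hits = rng.random((g.n_cells, len(codes))) < self.p_life
        fr_nuc = w.nucleus_counts(sp.FR)
        for j, code in enumerate(codes):
            if code == sp.GR:
                hits[fr_nuc > 0, j] = False       # FR in nucleus blocks GR
        cells_hit, js = np.nonzero(hits)
        code_arr = np.array(codes, dtype=np.int16)[js]
        is_tlr = code_arr == sp.TLR4
        self._spawn_cyto_bulk(nb, code_arr[~is_tlr], cells_hit[~is_tlr], rng)
        if is_tlr.any():
            occ = w.tlr4_occupancy()
            for cell in cells_hit[is_tlr]:
                self._spawn_tlr4(nb, int(cell), occ[int(cell)], rng)
        # the brain supplies the default production of both hormones;
        # melatonin is secreted into circulation (it cannot reside in the brain)
        if rng.random() < self.p_life:
            self._spawn_brain(nb, sp.F, rng)
        if rng.random() < self.p_life:
            self._spawn_plasma(nb, sp.M, rng)

    def _circadian_additions(self, nb: _Newborns) -> None:
        w = self.world
        cc = w.config.circadian
        params = w.config.params
        hour = w.config.clock.hour_of_tick(w.tick)
        # additions ride the per-tick production clock in batches of c_fm,
        # scaled so the hormone's total production rate at the window peak is
        # c_fm times its default rate; since hormone lifetimes are much
        # shorter than the windows, the peak *level* is then ~c_fm times the
        # ambient level (the stated design criterion for c_fm)
        gain = self.p_life * (1.0 - 1.0 / params.c_fm) if params.c_fm > 0 else 0.0
        p_f = gain * circadian_probability(hour, cc.f_start, cc.f_peak)
        if p_f > 0 and w.rng.random() < p_f:
            self._spawn_brain(nb, sp.F, w.rng, n=params.c_fm)
        p_m = gain * circadian_probability(hour, cc.m_start, cc.m_peak)
        if p_m > 0 and w.rng.random() < p_m:
            self._spawn_plasma(nb, sp.M, w.rng, n=params.c_fm)

    # --------------------------------------------------------- attraction

    def _steer_pair(self, ia: np.ndarray, ib: np.ndarray) -> None:
        """Steer both members of an interactive pair toward their nearest
        partner within the attraction threshold (same compartment only).

        Nearest partners are found with a KD-tree under the Chebyshev metric;
        compartments are separated by offsetting each cell's coordinates into
        a disjoint band so cross-compartment pairs are never within range.
        """
        if len(ia) == 0 or len(ib) == 0:
            return
        from scipy.spatial import cKDTree
        m = self.world.mol
        theta = self.theta
        span = self.world.geometry.cell_w + 4 * theta
        pa = np.column_stack((
            m.x[ia].astype(np.float64) +
            (m.cell[ia].astype(np.float64) + 1) * span,
            m.y[ia].astype(np.float64)))
        pb = np.column_stack((
            m.x[ib].astype(np.float64) +
            (m.cell[ib].astype(np.float64) + 1) * span,
            m.y[ib].astype(np.float64)))
        for src, src_pts, tgt, tgt_pts in ((ia, pa, ib, pb), (ib, pb, ia, pa)):
            tree = cKDTree(tgt_pts)
            dist, j = tree.query(src_pts, k=1, p=np.inf,
                                 distance_upper_bound=theta - 1e-9)
            near = np.isfinite(dist) & (dist > 0)
            sel = src[near]
            if len(sel):
                delta = tgt_pts[j[near]] - src_pts[near]
                m.dirx[sel] = np.sign(delta[:, 0]).astype(np.int8)
                m.diry[sel] = np.sign(delta[:, 1]).astype(np.int8)
                m.wait[sel] = 0

    def _steer(self) -> None:
        """Refresh headings: interactive pairs within theta home on each other,
        and plasma molecules near a cell home on the cell."""
        w = self.world
        m = w.mol
        s, a = m.species, m.active
        in_cell = m.cell >= 0
        plasma = ~in_cell & ~w.in_brain(m.x, m.y)

        def idx(mask):
            return np.flatnonzero(mask)

        pairs = (
            (idx(in_cell & (s == sp.LPSR)), idx(in_cell & (s == sp.IKK) & ~a)),
            (idx(in_cell & (s == sp.IKK) & a), idx(in_cell & (s == sp.NFKB_IKB))),
            (idx(in_cell & (s == sp.NFKB)), idx(in_cell & (s == sp.IKB))),
            (idx(in_cell & (s == sp.F) & a), idx(in_cell & (s == sp.GR))),
            (idx(in_cell & (s == sp.P) & ~a), idx(in_cell & (s == sp.A) & ~a)),
            (idx(in_cell & (s == sp.P) & a), idx(in_cell & (s == sp.A) & a)),
            (idx(plasma & (s == sp.P)), idx(plasma & (s == sp.A))),
        )
        for ia, ib in pairs:
            self._steer_pair(ia, ib)

        # cells capture circulating mediators (receptor-bound import pathway):
        # overrides partner steering; LPS is excluded -- its import requires
        # direct membrane contact with a TLR4, not chemotactic capture
        importable = plasma & CELL_IMPORT_LUT[s]
        sel = np.flatnonzero(importable)
        if len(sel):
            c = self.cell_cnt[m.x[sel], m.y[sel]]
            sel = sel[c > 0]
            if len(sel):
                m.dirx[sel] = np.sign(
                    self.cell_sdx[m.x[sel], m.y[sel]]).astype(np.int8)
                m.diry[sel] = np.sign(
                    self.cell_sdy[m.x[sel], m.y[sel]]).astype(np.int8)
                m.wait[sel] = 0

    # --------------------------------------------------------------- runner

    def run(self, hours: float, recorder: "HourlyRecorder | None" = None,
            injections: list[tuple[float, int]] | None = None) -> None:
        """Advance the world by ``hours`` simulated hours.

        ``injections`` lists (elapsed_hour, dose) LPS boluses.  The recorder,
        if given, samples at every hour boundary including the start.
        """
        sched = sorted((self.world.config.clock.tick_of_hour(h), d)
                       for h, d in (injections or []))
        end_tick = self.world.tick + int(round(hours * self.T))
        si = 0
        while self.world.tick <= end_tick:
            t = self.world.tick
            while si < len(sched) and sched[si][0] == t:
                inject_lps(self.world, sched[si][1])
                si += 1
            if recorder is not None and t % self.T == 0:
                recorder.record(self.world)
            if t == end_tick:
                break
            self.step()


# ---------------------------------------------------------------------------
# recording


@dataclass
class TimeSeriesPanel:
    """Hourly counts of the whole system and of every cell."""

    hours: np.ndarray                  # elapsed simulation hours
    clock_hours: np.ndarray            # wall-clock time of day
    system: pd.DataFrame               # hours x species
    per_cell: dict[str, np.ndarray]    # species name -> (n_hours, n_cells)
    cell_states: pd.DataFrame          # hours x {pro, anti, homeostatic}

    def species_counts(self, name: str) -> np.ndarray:
        return self.system[name].to_numpy()

    def lpsr_in_cells(self) -> np.ndarray:
        return self.system["LPSR"].to_numpy()


class HourlyRecorder:
    """Collects hourly samples during a run."""

    PER_CELL = (sp.P, sp.A)

    def __init__(self):
        self.hours: list[float] = []
        self.clock_hours: list[float] = []
        self.system: list[np.ndarray] = []
        self.per_cell: dict[int, list[np.ndarray]] = {c: [] for c in self.PER_CELL}
        self.states: list[tuple[int, int, int]] = []

    def record(self, world: WorldState) -> None:
        clock = world.config.clock
        self.hours.append(world.tick / clock.time_scale)
        self.clock_hours.append(clock.hour_of_tick(world.tick))
        self.system.append(world.counts_by_species())
        for c in self.PER_CELL:
            self.per_cell[c].append(world.per_cell_counts(c))
        s = world.cell_states()
        self.states.append((int((s == 1).sum()), int((s == -1).sum()),
                            int((s == 0).sum())))

    def to_panel(self) -> TimeSeriesPanel:
        system = pd.DataFrame(np.array(self.system), columns=sp.SPECIES_NAMES)
        states = pd.DataFrame(self.states, columns=["pro", "anti", "homeostatic"])
        return TimeSeriesPanel(
            hours=np.array(self.hours),
            clock_hours=np.array(self.clock_hours),
            system=system,
            per_cell={sp.SPECIES_NAMES[c]: np.array(v)
                      for c, v in self.per_cell.items()},
            cell_states=states,
        )


def run_hours(world: WorldState, hours: float,
              injections: list[tuple[float, int]] | None = None,
              record: bool = True) -> TimeSeriesPanel | None:
    """Convenience driver: run and return the hourly panel."""
    engine = Engine(world)
    rec = HourlyRecorder() if record else None
    engine.run(hours, recorder=rec, injections=injections)
    return rec.to_panel() if record else None
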