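"""Random walk, attraction and import mechanics."""

import numpy as np
import pytest
from scipy import stats as sps

from endoabm import species as sp
from endoabm.config import GridGeometry, SimulationConfig
from endoabm.engine import Engine
from endoabm.movement import (MOORE_OFFSETS, advance_walk, apply_attraction,
                              attraction_field, draw_directions, import_mask,
                              step_walk)
from endoabm.world import build_world


class TestStepWalk:
    def test_moves_one_step_along_heading(self, rng):
        walk = {"dirx": 1, "diry": 0, "steps": 2, "wait": 0}
        assert step_walk((5, 5), walk, (40, 30), rng) == (6, 5)
        assert walk["steps"] == 1

    def test_waiting_agent_stays(self, rng):
        walk = {"dirx": 1, "diry": 0, "steps": 2, "wait": 3}
        assert step_walk((5, 5), walk, (40, 30), rng) == (5, 5)
        assert walk["wait"] == 2

    def test_redraw_after_persistence_exhausted(self, rng):
        walk = {"dirx": 0, "diry": 1, "steps": 1, "wait": 0}
        step_walk((5, 5), walk, (40, 30), rng)
        assert 1 <= walk["steps"] <= 5 and 0 <= walk["wait"] <= 2
        assert (walk["dirx"], walk["diry"]) != (0, 0)

    def test_clamped_at_grid_edge(self, rng):
        walk = {"dirx": -1, "diry": -1, "steps": 5, "wait": 0}
        assert step_walk((0, 0), walk, (40, 30), rng) == (0, 0)

    def test_direction_draw_uniform(self, rng):
        """Across many redraws the eight Moore directions are equally likely."""
        dirx, diry = draw_directions(100_000, rng)
        keys = (dirx.astype(int) + 1) * 3 + (diry.astype(int) + 1)
        counts = np.bincount(keys, minlength=9)
        counts = counts[counts > 0]
        assert len(counts) == 8
        assert sps.chisquare(counts).pvalue > 0.01


class TestAdvanceWalk:
    def test_vectorized_bookkeeping(self, rng):
        n = 1000
        x = np.zeros(n, np.int16); y = np.zeros(n, np.int16)
        dirx = np.ones(n, np.int8); diry = np.zeros(n, np.int8)
        steps = np.full(n, 3, np.int16)
        wait = np.zeros(n, np.int16)
        mobile = np.ones(n, bool)
        px, py, moved = advance_walk(x, y, dirx, diry, steps, wait, mobile,
                                     rng)
        assert moved.all()
        assert (px == 1).all() and (py == 0).all()
        assert (steps == 2).all()

    def test_immobile_agents_never_move(self, rng):
        x = np.zeros(3, np.int16); y = np.zeros(3, np.int16)
        px, py, moved = advance_walk(
            x, y, np.ones(3, np.int8), np.ones(3, np.int8),
            np.full(3, 2, np.int16), np.zeros(3, np.int16),
            np.zeros(3, bool), rng)
        assert not moved.any()
        assert (px == 0).all()


class TestAttraction:
    def test_pair_heads_toward_each_other(self):
        heads = apply_attraction(3, 3, 5, 3, theta=3)
        assert heads is not None
        (adx, ady), (bdx, bdy) = heads
        assert (adx, ady) == (1, 0)
        assert (bdx, bdy) == (-1, 0)
        # one step each strictly reduces the Chebyshev distance
        assert max(abs((5 + bdx) - (3 + adx)), abs(0)) < 2

    def test_beyond_threshold_unchanged(self):
        assert apply_attraction(0, 0, 5, 5, theta=3) is None

    def test_colocated_pair_stays(self):
        (a, b) = apply_attraction(4, 4, 4, 4, theta=3)
        assert a == (0, 0) and b == (0, 0)

    def test_distance_nonincreasing_until_contact(self, rng):
        """Iterating attraction steps never increases the pair distance."""
        ax, ay, bx, by = 2, 9, 6, 7
        d = max(abs(bx - ax), abs(by - ay))
        for _ in range(10):
            heads = apply_attraction(ax, ay, bx, by, theta=5)
            if heads is None or d == 0:
                break
            (adx, ady), (bdx, bdy) = heads
            ax, ay, bx, by = ax + adx, ay + ady, bx + bdx, by + bdy
            d_new = max(abs(bx - ax), abs(by - ay))
            assert d_new <= d
            d = d_new
        assert d == 0

    def test_field_matches_brute_force(self, rng):
        occ = (rng.random((20, 15)) < 0.1).astype(np.float32)
        theta = 3
        cnt, sdx, sdy = attraction_field(occ, theta)
        tx, ty = np.nonzero(occ)
        for x in range(20):
            for y in range(15):
                near = (np.maximum(np.abs(tx - x), np.abs(ty - y)) < theta)
                assert cnt[x, y] == pytest.approx(near.sum())
                assert sdx[x, y] == pytest.approx((tx[near] - x).sum())
                assert sdy[x, y] == pytest.approx((ty[near] - y).sum())


class TestImport:
    def test_bernoulli_rate(self, rng):
        """Import frequency converges to the receptor-binding probability."""
        taken = import_mask(100_000, 0.30, rng)
        assert taken.mean() == pytest.approx(0.30, abs=0.005)

    @staticmethod
    def _quiet_config(seed=3):
        """No default production or stimulated TLR4, so the membrane
        receptor population is exactly what the test installs."""
        from endoabm.config import ProductionParams
        return SimulationConfig(seed=seed, params=ProductionParams(
            R=0.0, pt=0.0))

    def test_lps_without_tlr4_never_imported(self):
        w = build_world(self._quiet_config())
        m = w.mol
        m.compact(m.species != sp.TLR4)
        m.last_event[:] = 10**6          # keep the rest of the world alive
        from endoabm.rules import inject_lps
        inject_lps(w, 200)
        eng = Engine(w)
        for _ in range(60):
            eng.step()
        assert w.counts_by_species()[sp.LPSR] == 0

    def test_lps_with_full_membrane_always_binds(self):
        w = build_world(self._quiet_config())
        g = w.geometry
        m = w.mol
        # fill every boundary slot of every cell with a receptor
        from endoabm.world import boundary_slots, MoleculeStore
        bx, by = boundary_slots(g)
        n = g.n_cells * g.n_boundary
        cells = np.repeat(np.arange(g.n_cells), g.n_boundary)
        slots = np.tile(np.arange(g.n_boundary), g.n_cells)
        extra = MoleculeStore(
            species=np.full(n, sp.TLR4, np.int16), cell=cells.astype(np.int16),
            x=bx[slots], y=by[slots], active=np.zeros(n, bool),
            immobile=np.ones(n, bool),
            last_event=np.full(n, 10**6, np.int32),
            dirx=np.zeros(n, np.int8), diry=np.zeros(n, np.int8),
            steps=np.ones(n, np.int16), wait=np.zeros(n, np.int16),
            bslot=slots.astype(np.int16))
        m.compact(m.species != sp.TLR4)
        m.last_event[:] = 10**6
        m.append(extra)
        from endoabm.rules import inject_lps
        inject_lps(w, 500)
        eng = Engine(w)
        for _ in range(80):
            eng.step()
        lpsr = int(w.event_counts.get("lps_import", 0))
        assert lpsr > 0
        # with a saturated membrane every cell arrival binds: each import
        # consumed exactly one receptor
        remaining = int((w.mol.species == sp.TLR4).sum())
        assert remaining == n - lpsr


class TestCompartmentRules:
    def test_permissions_hold_over_trajectory(self):
        w = build_world(SimulationConfig(seed=21))
        eng = Engine(w)
        for k in range(120):
            eng.step()
            if k % 40 == 0:
                w.check_permissions()
        w.check_permissions()

    def test_closed_system_conserves_molecules(self):
        """With production, degradation and interactions disabled, movement
        alone never changes the molecule count."""
        from endoabm.config import MovementParams, ProductionParams
        cfg = SimulationConfig(seed=9, params=ProductionParams(
            kp=0, ki=0, fi=0, fa=0, fm=0, mp=0, pf=0, pt=0, ae=0, R=0,
            import_prob=0))
        w = build_world(cfg)
        w.mol.last_event[:] = 10**6      # effectively immortal
        # remove annihilation partners so no pair events fire
        w.mol.compact(w.mol.species != sp.A)
        n0 = len(w.mol)
        eng = Engine(w)
        for _ in range(100):
            eng.step()
        assert len(w.mol) == n0


class TestTranslocation:
    """Compartment crossing rules: nucleus entry, membrane release, retention."""

    def test_nucleus_eligibility_matrix(self):
        from endoabm.world import nucleus_eligible
        assert nucleus_eligible(np.array([sp.NFKB]), np.array([False]))[0]
        assert nucleus_eligible(np.array([sp.IKB]), np.array([False]))[0]
        assert nucleus_eligible(np.array([sp.FR]), np.array([False]))[0]
        # cytokines and melatonin need the imported (active) status
        for code in (sp.P, sp.A, sp.M):
            assert nucleus_eligible(np.array([code]), np.array([True]))[0]
            assert not nucleus_eligible(np.array([code]), np.array([False]))[0]
        # cortisol may never enter the nucleus
        assert not nucleus_eligible(np.array([sp.F]), np.array([True]))[0]

    @staticmethod
    def _world_with(code, active, x, y):
        from endoabm.config import ProductionParams, CircadianConfig
        from endoabm.world import MoleculeStore
        # import_prob 0 so molecules released to plasma are not re-imported
        cfg = SimulationConfig(
            seed=17, params=ProductionParams(R=0.0, import_prob=0.0),
            circadian=CircadianConfig(enabled=False))
        w = build_world(cfg)
        w.mol.compact(np.zeros(len(w.mol), bool))      # empty world
        n = 30
        store = MoleculeStore(
            species=np.full(n, code, np.int16), cell=np.zeros(n, np.int16),
            x=np.full(n, x, np.int16), y=np.full(n, y, np.int16),
            active=np.full(n, active, bool), immobile=np.zeros(n, bool),
            last_event=np.full(n, 10**6, np.int32),
            dirx=np.zeros(n, np.int8), diry=np.zeros(n, np.int8),
            steps=np.ones(n, np.int16), wait=np.zeros(n, np.int16),
            bslot=np.full(n, -1, np.int16))
        w.mol.append(store)
        return w

    def test_active_nfkb_reaches_nucleus(self):
        """Free NFkB walking the cytoplasm translocates into the nucleus."""
        g = SimulationConfig().geometry
        w = self._world_with(sp.NFKB, False, g.nucleus_x0 - 2, g.cell_h // 2)
        eng = Engine(w)
        for _ in range(120):
            eng.step()
        assert w.nucleus_counts(sp.NFKB).sum() > 0

    def test_imported_p_never_released(self):
        """Active (imported) P reaching the membrane stays in its cell."""
        w = self._world_with(sp.P, True, 1, 1)        # next to the boundary
        eng = Engine(w)
        for _ in range(150):
            eng.step()
        assert (w.mol.cell >= 0).all()                # nobody escaped

    def test_inactive_a_released_at_membrane(self):
        """Locally produced A reaching the boundary is exported to plasma."""
        w = self._world_with(sp.A, False, 1, 1)
        eng = Engine(w)
        for _ in range(150):
            eng.step()
        assert (w.mol.cell < 0).any()                 # some reached plasma
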