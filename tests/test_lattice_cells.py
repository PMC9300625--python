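"""Cell agents, subcellular ODEs and the cellular-automaton update rules."""

import numpy as np
import pytest

from angiomet.config import CellsConfig, CellTypeParams, default_config
from angiomet.errors import PreconditionError
from angiomet.lattice import (CELL_CANCER, CELL_NORMAL, STATE_PROLIFERATING,
                              STATE_QUIESCENT, Cell, CellPopulation, Lattice,
                              advance_subcellular, ca_step, implant_tumour)


@pytest.fixture
def params():
    return CellTypeParams()


def saturating_cells_config(**overrides):
    """Cells config with apoptosis and movement disabled (pure growth)."""
    cfg = CellsConfig()
    for p in (cfg.normal, cfg.cancer):
        p.p53_thr_low_density = np.inf
        p.p53_thr_high_density = np.inf
        p.movement_rate = 0.0
        p.ox_quiesce_enter = 0.0   # never quiesce at positive oxygen
        p.ox_quiesce_leave = 0.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class TestSubcellular:
    def test_zero_oxygen_freezes_cycle(self, params):
        cell = Cell(CELL_NORMAL, (0, 0, 0), phase=0.5)
        out = advance_subcellular(cell, 0.0, 5.0, params)
        assert out.phase == 0.5

    def test_saturating_oxygen_gain_over_one_cycle_time(self, params):
        # at oxygen >> half-saturation the phase gain over t_cycle -> ox/(ox+k)
        ox = 1000.0 * params.k_phi_ox
        cell = Cell(CELL_NORMAL, (0, 0, 0), phase=0.0)
        n_steps = 96
        dt = params.t_cycle / n_steps
        for _ in range(n_steps):
            cell = advance_subcellular(cell, ox, dt, params)
        assert cell.phase == pytest.approx(ox / (ox + params.k_phi_ox), abs=1e-12)

    def test_p53_fixed_point_and_closed_form(self, params):
        """The linear p53 ODE matches its closed-form exponential solution."""
        ox = 0.1
        f_ox = ox / (ox + params.k_p53_ox)
        b = params.p53_deg * f_ox
        a = params.p53_prod
        # fixed point: production = degradation * level
        cell = Cell(CELL_NORMAL, (0, 0, 0), phase=0.0, p53_level=a / b)
        out = advance_subcellular(cell, ox, 0.5, params)
        assert out.p53_level == pytest.approx(a / b, rel=1e-12)
        # off the fixed point: p(t) = p0 e^{-bt} + (a/b)(1 - e^{-bt})
        p0 = 3.0
        cell = Cell(CELL_NORMAL, (0, 0, 0), phase=0.0, p53_level=p0)
        dt = 0.5
        out = advance_subcellular(cell, ox, dt, params)
        expected = p0 * np.exp(-b * dt) + (a / b) * (1 - np.exp(-b * dt))
        assert out.p53_level == pytest.approx(expected, rel=1e-12)

    def test_hypoxia_raises_intracellular_vegf(self, params):
        hypoxic = Cell(CELL_NORMAL, (0, 0, 0), phase=0.0)
        normoxic = Cell(CELL_NORMAL, (0, 0, 0), phase=0.0)
        for _ in range(100):
            hypoxic = advance_subcellular(hypoxic, 1e-4, 0.5, params)
            normoxic = advance_subcellular(normoxic, 0.13, 0.5, params)
        assert hypoxic.intracellular_vegf > 5 * normoxic.intracellular_vegf

    def test_preconditions(self, params):
        cell = Cell(CELL_NORMAL, (0, 0, 0), phase=0.0)
        with pytest.raises(PreconditionError):
            advance_subcellular(cell, 0.1, -1.0, params)
        with pytest.raises(PreconditionError):
            advance_subcellular(cell, -0.1, 1.0, params)

    def test_stability_at_large_dt(self, params):
        # the exponential update must stay bounded for dt up to 0.5 h and beyond
        cell = Cell(CELL_NORMAL, (0, 0, 0), phase=0.0, p53_level=100.0,
                    intracellular_vegf=100.0)
        out = advance_subcellular(cell, 0.13, 0.5, params)
        assert 0 <= out.p53_level <= 100.0
        assert 0 <= out.intracellular_vegf <= 100.0


class TestAutomaton:
    def test_unconstrained_division(self, rng):
        lattice = Lattice((5, 5, 5), 20.0)
        pop = CellPopulation(lattice)
        pop.add_cell((2, 2, 2), CELL_NORMAL, phase=1.0)
        ox = np.full(lattice.dims, 1.0)
        stats = ca_step(pop, ox, saturating_cells_config(), 0.5, rng)
        assert stats["divisions"] == 1
        assert pop.n == 2
        assert np.all(pop.phase == 0.0)
        pop.check_occupancy()

    def test_contact_inhibition_defers_division(self, rng):
        lattice = Lattice((3, 3, 3), 20.0)
        pop = CellPopulation(lattice)
        for x in range(3):
            for y in range(3):
                for z in range(3):
                    pop.add_cell((x, y, z), CELL_NORMAL,
                                 phase=1.0 if (x, y, z) == (1, 1, 1) else 0.0)
        ox = np.full(lattice.dims, 1.0)
        stats = ca_step(pop, ox, saturating_cells_config(), 0.5, rng)
        assert stats["divisions"] == 0
        assert stats["deferred_divisions"] == 1
        assert pop.n == 27
        # phase stays ready for the next opportunity
        assert np.sum(pop.phase >= 1.0) == 1

    def test_growth_doubles_then_saturates(self, rng):
        """Against a scalar birth recursion: the population doubles each
        completed cycle while space is unconstrained, then saturates at the
        lattice capacity."""
        lattice = Lattice((8, 8, 8), 20.0)
        pop = CellPopulation(lattice)
        pop.add_cell((4, 4, 4), CELL_CANCER, phase=0.0)
        cfg = saturating_cells_config()
        cfg.cancer.t_cycle = 2.0
        ox = np.full(lattice.dims, 1e3)   # saturating oxygen: deterministic cycling
        dt = 0.5
        from angiomet.lattice import _advance_arrays
        counts = [pop.n]
        for step in range(400):
            oxc = pop.site_values(ox)
            pop.phase, pop.p53, pop.ivegf = _advance_arrays(
                pop.phase, pop.state, pop.p53, pop.ivegf, pop.ctype, oxc, dt,
                cfg.normal, cfg.cancer)
            ca_step(pop, ox, cfg, dt, rng)
            counts.append(pop.n)
        counts = np.array(counts)
        assert counts[-1] == lattice.n_sites                  # space exhausted
        assert np.all(np.diff(counts) >= 0)                   # monotone fill
        assert 2 in counts and 4 in counts and 8 in counts

    def test_quiescence_entry_exit_and_death(self, rng):
        lattice = Lattice((4, 4, 4), 20.0)
        cfg = CellsConfig()
        cfg.normal.movement_rate = 0.0
        pop = CellPopulation(lattice)
        pop.add_cell((1, 1, 1), CELL_NORMAL, phase=0.2)
        hypoxic = np.full(lattice.dims, 0.0)
        ca_step(pop, hypoxic, cfg, 0.5, rng)
        assert pop.state[0] == STATE_QUIESCENT
        # re-oxygenate: cell wakes up
        rich = np.full(lattice.dims, 1.0)
        ca_step(pop, rich, cfg, 0.5, rng)
        assert pop.state[0] == STATE_PROLIFERATING
        # prolonged hypoxia kills
        ca_step(pop, hypoxic, cfg, 0.5, rng)
        for _ in range(int(cfg.normal.t_quiesce_max / 0.5) + 2):
            ca_step(pop, hypoxic, cfg, 0.5, rng)
        assert pop.n == 0

    def test_p53_apoptosis_density_dependent_threshold(self, rng):
        lattice = Lattice((4, 4, 4), 20.0)
        cfg = CellsConfig()
        cfg.normal.p53_thr_low_density = 0.5
        cfg.normal.p53_thr_high_density = 2.0
        cfg.normal.movement_rate = 0.0
        ox = np.full(lattice.dims, 1.0)
        # isolated cell (low density context): p53 = 1.0 > 0.5 -> dies
        pop = CellPopulation(lattice)
        pop.add_cell((1, 1, 1), CELL_NORMAL, phase=0.0, p53=1.0)
        ca_step(pop, ox, cfg, 0.5, rng)
        assert pop.n == 0
        # crowded cell (high density context): 1.0 < 2.0 -> survives
        pop = CellPopulation(lattice)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    pop.add_cell((1 + dx, 1 + dy, 1 + dz), CELL_NORMAL,
                                 phase=0.0, p53=1.0 if (dx, dy, dz) == (0, 0, 0) else 0.0)
        ca_step(pop, ox, cfg, 0.5, rng)
        assert pop.occupancy[1, 1, 1] != -1

    def test_zero_oxygen_never_divides(self, rng):
        lattice = Lattice((6, 6, 6), 20.0)
        pop = CellPopulation(lattice)
        pop.add_cell((3, 3, 3), CELL_CANCER, phase=0.99)
        cfg = saturating_cells_config()
        ox = np.zeros(lattice.dims)
        from angiomet.lattice import _advance_arrays
        for _ in range(50):
            oxc = pop.site_values(ox)
            pop.phase, pop.p53, pop.ivegf = _advance_arrays(
                pop.phase, pop.state, pop.p53, pop.ivegf, pop.ctype, oxc, 0.5,
                cfg.normal, cfg.cancer)
            stats = ca_step(pop, ox, cfg, 0.5, rng)
            assert stats["divisions"] == 0
        assert pop.n == 1

    def test_occupancy_invariant_and_count_accounting(self, rng):
        lattice = Lattice((6, 6, 6), 20.0)
        cfg = default_config().cells
        pop = CellPopulation(lattice)
        sites = rng.choice(lattice.n_sites, size=60, replace=False)
        for s in sites:
            pop.add_cell(np.unravel_index(s, lattice.dims), CELL_NORMAL,
                         phase=float(rng.random()))
        ox = np.full(lattice.dims, 0.05)
        for _ in range(30):
            n_before = pop.n
            stats = ca_step(pop, ox, cfg, 0.5, rng)
            pop.check_occupancy()
            births = stats["divisions"]
            deaths = stats["quiescence_deaths"] + stats["apoptoses"]
            assert pop.n == n_before + births - deaths

    def test_bitwise_determinism_over_100_steps(self):
        def trajectory(seed):
            rng = np.random.default_rng(seed)
            lattice = Lattice((6, 6, 6), 20.0)
            pop = CellPopulation(lattice)
            for s in np.random.default_rng(0).choice(216, size=40, replace=False):
                pop.add_cell(np.unravel_index(s, lattice.dims), CELL_NORMAL,
                             phase=0.9)
            cfg = default_config().cells
            ox = np.full(lattice.dims, 0.1)
            from angiomet.lattice import _advance_arrays
            for _ in range(100):
                oxc = pop.site_values(ox)
                pop.phase, pop.p53, pop.ivegf = _advance_arrays(
                    pop.phase, pop.state, pop.p53, pop.ivegf, pop.ctype, oxc,
                    0.5, cfg.normal, cfg.cancer)
                ca_step(pop, ox, cfg, 0.5, rng)
            return pop
        a, b = trajectory(99), trajectory(99)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.p53, b.p53)
        assert np.array_equal(a.state, b.state)

    def test_hypoxia_reduces_proliferating_count(self, rng):
        """Uniform oxygen below the quiescence-entry threshold makes the
        proliferating count non-increasing."""
        lattice = Lattice((6, 6, 6), 20.0)
        cfg = default_config().cells
        pop = CellPopulation(lattice)
        for s in rng.choice(216, size=80, replace=False):
            pop.add_cell(np.unravel_index(s, lattice.dims), CELL_NORMAL,
                         phase=float(rng.random()))
        low_ox = np.full(lattice.dims, 0.5 * cfg.normal.ox_quiesce_enter)
        prev = int(np.sum(pop.state == STATE_PROLIFERATING))
        for _ in range(20):
            ca_step(pop, low_ox, cfg, 0.5, rng)
            cur = int(np.sum(pop.state == STATE_PROLIFERATING))
            assert cur <= prev
            prev = cur


class TestImplantTumour:
    def test_radius_zero_single_cell(self, small_lattice, rng):
        pop = CellPopulation(small_lattice)
        n = implant_tumour(pop, (4, 4, 4), 0, rng)
        assert n == 1
        assert pop.n == 1
        assert pop.ctype[0] == CELL_CANCER

    def test_ball_cardinality_matches_enumeration(self, small_lattice, rng):
        # independent integer-distance enumeration oracle
        for radius in (1, 2):
            expected = sum(
                1
                for dx in range(-radius, radius + 1)
                for dy in range(-radius, radius + 1)
                for dz in range(-radius, radius + 1)
                if dx * dx + dy * dy + dz * dz <= radius * radius
            )
            pop = CellPopulation(small_lattice)
            n = implant_tumour(pop, (4, 4, 4), radius, rng)
            assert n == expected == pop.n
        # Euclidean radius 1 is the 6-connected ball: 7 sites
        pop = CellPopulation(small_lattice)
        assert implant_tumour(pop, (4, 4, 4), 1, rng) == 7

    def test_replaces_normal_cells(self, small_lattice, rng):
        pop = CellPopulation(small_lattice)
        pop.add_cell((4, 4, 4), 0, phase=0.5)   # normal occupant
        implant_tumour(pop, (4, 4, 4), 1, rng)
        assert np.all(pop.ctype == CELL_CANCER)
        assert np.all(pop.phase < 1.0)

    def test_idempotent_occupancy(self, small_lattice, rng):
        pop = CellPopulation(small_lattice)
        implant_tumour(pop, (4, 4, 4), 1, rng)
        n1 = pop.n
        implant_tumour(pop, (4, 4, 4), 1, rng)
        assert pop.n == n1
        pop.check_occupancy()

    def test_clipped_ball_warns(self, small_lattice, rng, caplog):
        pop = CellPopulation(small_lattice)
        import logging
        with caplog.at_level(logging.WARNING, logger="angiomet.lattice"):
            implant_tumour(pop, (0, 0, 0), 3, rng)
        assert any("clipped" in r.message for r in caplog.records)
        pop.check_occupancy()

    def test_centre_outside_lattice_rejected(self, small_lattice, rng):
        pop = CellPopulation(small_lattice)
        with pytest.raises(PreconditionError):
            implant_tumour(pop, (99, 0, 0), 1, rng)
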