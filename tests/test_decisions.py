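import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellcompete as cc
from cellcompete.engine import PHASE_APOPTOTIC, PHASE_G1, PHASE_S_G2_M
from cellcompete.simulation import scan_contacts

from conftest import build_square_cell


@pytest.fixture(scope="session")
def params_a(default_params):
    return default_params[0][cc.TYPE_A]


class TestGrowthIncrement:
    def test_newborn_grows_at_uncrowded_rate(self, params_a):
        """At A = A_T the damping exponent is zero: dA_T = G."""
        g = params_a.growth_rate
        assert cc.growth_increment(650, 650, g, params_a.crowding_k) == \
            pytest.approx(650 + g)
        assert g == pytest.approx(7.0933, abs=1e-3)

    def test_zero_crowding_sensitivity_ignores_compression(self, params_a):
        g = params_a.growth_rate
        assert cc.growth_increment(600, 650, g, 0.0) == pytest.approx(650 + g)

    def test_compressed_cell_growth_effectively_halts(self, params_a):
        """10 sites of compression at k = 0.1 damps growth by e^-10."""
        g = params_a.growth_rate
        new = cc.growth_increment(640, 650, g, 0.1)
        assert new - 650 == pytest.approx(g * math.exp(-10), rel=1e-12)
        assert new - 650 < 4e-4

    def test_no_growth_when_area_exceeds_target(self, params_a):
        assert cc.growth_increment(700, 650, params_a.growth_rate,
                                   params_a.crowding_k) == 650.0

    def test_rejects_negative_inputs(self, params_a):
        with pytest.raises(ValueError):
            cc.growth_increment(-1, 650, params_a.growth_rate, 0.1)
        with pytest.raises(ValueError):
            cc.growth_increment(650, 650, -1.0, 0.1)

    @given(deficit=st.floats(0, 50), deficit2=st.floats(0, 50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_increment_nonincreasing_in_compression(self, deficit, deficit2):
        lo, hi = sorted([deficit, deficit2])
        inc_lo = cc.growth_increment(650 - lo, 650, 7.0, 0.1) - 650
        inc_hi = cc.growth_increment(650 - hi, 650, 7.0, 0.1) - 650
        assert inc_hi <= inc_lo + 1e-12


class TestCycleUpdate:
    def _registry_with_cell(self, area, sizer, phase=PHASE_G1, timer=5.0):
        reg = cc.CellRegistry()
        reg.new_cell(type_code=cc.TYPE_A, area=area, target_area=float(area),
                     lam=1.0, sizer_threshold=sizer, timer_remaining=timer,
                     phase=phase)
        return reg

    def test_below_sizer_stays_in_g1(self):
        reg = self._registry_with_cell(area=1399, sizer=1400)
        assert cc.cycle_update(reg, 1) is False
        assert reg.phase[1] == PHASE_G1

    def test_at_sizer_enters_s_phase(self):
        reg = self._registry_with_cell(area=1400, sizer=1400)
        cc.cycle_update(reg, 1)
        assert reg.phase[1] == PHASE_S_G2_M

    def test_timer_expiry_triggers_division(self):
        reg = self._registry_with_cell(area=1400, sizer=1400,
                                       phase=PHASE_S_G2_M, timer=1.0)
        assert cc.cycle_update(reg, 1) is True

    def test_transition_step_does_not_consume_timer(self):
        reg = self._registry_with_cell(area=1400, sizer=1400, timer=2.0)
        assert cc.cycle_update(reg, 1) is False      # G1 -> S this step
        assert reg.timer_remaining[1] == 2.0
        assert cc.cycle_update(reg, 1) is False      # first countdown tick
        assert cc.cycle_update(reg, 1) is True


class TestDivideCell:
    def test_rectangle_splits_across_long_axis(self, default_params):
        params_by_code, _, _ = default_params
        grid = np.zeros((6, 14), dtype=np.int32)
        grid[2:4, 2:12] = 1
        state = cc.LatticeState(grid)
        reg = cc.CellRegistry()
        reg.new_cell(type_code=cc.TYPE_A, area=20, target_area=20.0, lam=1.0,
                     sizer_threshold=1400.0, generation=3)
        d1, d2 = cc.divide_cell(state, reg, 1, params_by_code,
                                np.random.default_rng(0))
        assert reg.area[d1] == 10 and reg.area[d2] == 10
        # cleavage perpendicular to the long (column) axis: daughters occupy
        # disjoint column ranges
        cols1 = set(np.argwhere(state.grid == d1)[:, 1])
        cols2 = set(np.argwhere(state.grid == d2)[:, 1])
        assert max(cols1) < min(cols2)
        for d in (d1, d2):
            assert reg.target_area[d] == reg.area[d]  # equilibrium at birth
            assert reg.phase[d] == PHASE_G1
            assert reg.generation[d] == 4
        assert not reg.alive[1]

    def test_daughter_areas_sum_to_mother(self, default_params):
        params_by_code, _, _ = default_params
        state, reg = build_square_cell(side=9)
        d1, d2 = cc.divide_cell(state, reg, 1, params_by_code,
                                np.random.default_rng(1))
        assert reg.area[d1] + reg.area[d2] == 81
        assert abs(reg.area[d1] - reg.area[d2]) <= 1

    def test_fresh_cycle_draws_near_table_values(self, default_params):
        params_by_code, _, _ = default_params
        state, reg = build_square_cell(side=9)
        d1, _ = cc.divide_cell(state, reg, 1, params_by_code,
                               np.random.default_rng(2))
        assert abs(reg.sizer_threshold[d1] - 1400) < 6 * 35
        assert abs(reg.timer_remaining[d1] - 225) < 6 * 5.625

    def test_area_below_two_raises(self, default_params):
        params_by_code, _, _ = default_params
        grid = np.zeros((4, 4), dtype=np.int32)
        grid[1, 1] = 1
        state = cc.LatticeState(grid)
        reg = cc.CellRegistry()
        reg.new_cell(type_code=cc.TYPE_A, area=1, target_area=1.0, lam=1.0,
                     sizer_threshold=1400.0)
        with pytest.raises(ValueError):
            cc.divide_cell(state, reg, 1, params_by_code,
                           np.random.default_rng(0))


class TestLocalDensity:
    def _registry(self, areas):
        reg = cc.CellRegistry()
        for a in areas:
            reg.new_cell(type_code=cc.TYPE_A, area=a, target_area=float(a),
                         lam=1.0, sizer_threshold=1e9)
        return reg

    def test_isolated_cell(self):
        reg = self._registry([1000])
        assert cc.local_density(reg, [], 1) == pytest.approx(1e-3)

    def test_homogeneous_closed_form(self):
        reg = self._registry([500] * 7)
        rho = cc.local_density(reg, [2, 3, 4, 5, 6, 7], 1)
        assert rho == pytest.approx(7 / 500)

    def test_three_cell_fixture(self):
        reg = self._registry([800, 1000, 1200])
        rho = cc.local_density(reg, [2, 3], 1)
        assert rho == pytest.approx(1 / 800 + 1 / 1000 + 1 / 1200)
        assert rho == pytest.approx(3.083e-3, abs=1e-6)

    def test_zero_area_neighbour_excluded(self):
        reg = self._registry([800, 1000])
        reg.area[2] = 0
        assert cc.local_density(reg, [2], 1) == pytest.approx(1 / 800)


class TestApoptosisHazards:
    def test_density_saturates_at_table_maximum(self, params_a):
        assert cc.p_apoptosis_density(10.0, params_a) == pytest.approx(0.0015)

    def test_density_midpoint_is_half_maximum(self, params_a):
        assert cc.p_apoptosis_density(params_a.rho_half, params_a) == \
            pytest.approx(0.0015 / 2)

    def test_density_at_zero(self, params_a):
        # 0.0015 / (1 + exp(0.104*1400 * 14.01/1400)), independent arithmetic
        expected = 0.0015 / (1.0 + math.exp(0.104 * 14.01))
        assert cc.p_apoptosis_density(0.0, params_a) == pytest.approx(expected)
        assert cc.p_apoptosis_density(0.0, params_a) == pytest.approx(
            2.83e-4, abs=2e-6)

    def test_contact_zero_without_heterotypic_contact(self, params_a):
        assert cc.p_apoptosis_contact(0.0, params_a) == 0.0

    @pytest.mark.parametrize("hill_n", [1.8, 3.6, 7.2])
    def test_contact_midpoint_invariant_under_hill_coefficient(self, params_a,
                                                               hill_n):
        """P(S) = p_con_max/2 exactly, for any Hill coefficient."""
        p = params_a.with_overrides(hill_n=hill_n)
        assert cc.p_apoptosis_contact(p.steepness_S, p) == \
            pytest.approx(p.p_con_max / 2, rel=1e-14)

    def test_contact_at_full_heterotypic_contact(self, params_a):
        assert cc.p_apoptosis_contact(1.0, params_a) == pytest.approx(
            1.0 / (1.0 + 1.35**3.6), rel=1e-12)
        assert cc.p_apoptosis_contact(1.0, params_a) == pytest.approx(
            0.2534, abs=1e-4)

    @given(p1=st.floats(0, 1), p2=st.floats(0, 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_contact_hazard_monotone(self, params_a, p1, p2):
        lo, hi = sorted([p1, p2])
        assert cc.p_apoptosis_contact(lo, params_a) <= \
            cc.p_apoptosis_contact(hi, params_a) + 1e-15

    @given(r1=st.floats(0, 0.05), r2=st.floats(0, 0.05))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_density_hazard_monotone(self, params_a, r1, r2):
        lo, hi = sorted([r1, r2])
        assert cc.p_apoptosis_density(lo, params_a) <= \
            cc.p_apoptosis_density(hi, params_a) + 1e-15

    def test_domain_validation(self, params_a):
        with pytest.raises(ValueError):
            cc.p_apoptosis_density(-0.1, params_a)
        with pytest.raises(ValueError):
            cc.p_apoptosis_contact(-0.5, params_a)


class TestCycleDraws:
    def test_sample_moments_match_table_within_3_se(self, params_a):
        rng = np.random.default_rng(11)
        n = 100_000
        sizer = cc.draw_sizer(params_a, rng, size=n)
        timer = cc.draw_timer(params_a, rng, size=n)
        for sample, mean, sd in ((sizer, 1400, 35), (timer, 225, 5.625)):
            se_mean = sd / math.sqrt(n)
            assert abs(sample.mean() - mean) <= 3 * se_mean
            se_sd = sd / math.sqrt(2 * (n - 1))
            assert abs(sample.std(ddof=1) - sd) <= 3 * se_sd
            assert sample.min() >= 1.0


def _block_lattice(areas, code=cc.TYPE_A, params=None):
    """Horizontal strip cells of given areas (height 10), plus registry."""
    widths = [a // 10 for a in areas]
    L = sum(widths) + 2
    grid = np.zeros((12, L), dtype=np.int32)
    x = 1
    reg = cc.CellRegistry()
    for w, a in zip(widths, areas):
        cid = reg.new_cell(type_code=code, area=a, target_area=float(a),
                           lam=1.0, sizer_threshold=1e9)
        grid[1:11, x:x + w] = cid
        x += w
    return cc.LatticeState(grid), reg


class TestEliminationSweep:
    def _sweep(self, state, reg, params, seed=0):
        potts = cc.PottsParams()
        scan = scan_contacts(state, reg, potts)
        return cc.elimination_sweep(
            state, reg, scan.cell_ids, scan.rho, scan.p_AB,
            {cc.TYPE_A: params, cc.TYPE_B: params},
            np.random.default_rng(seed))

    def test_extrusion_threshold_is_strict(self, params_a):
        """Mean 800 -> threshold 200; a 200-site cell survives (A < mean/4)."""
        p = params_a.with_overrides(p_den_max=0.0, p_con_max=0.0)
        state, reg = _block_lattice([1000, 1000, 1000, 200])
        tallies = self._sweep(state, reg, p)
        assert tallies["extrusions"] == {}
        assert reg.alive[4]

    def test_cell_below_quarter_mean_is_extruded(self, params_a):
        p = params_a.with_overrides(p_den_max=0.0, p_con_max=0.0)
        state, reg = _block_lattice([1000, 1000, 1000, 100])
        tallies = self._sweep(state, reg, p)
        assert tallies["extrusions"] == {cc.TYPE_A: 1}
        assert not reg.alive[4]
        assert np.sum(state.grid == 4) == 0  # sites returned to medium

    def test_lone_cell_never_self_extrudes(self, params_a):
        p = params_a.with_overrides(p_den_max=0.0, p_con_max=0.0)
        state, reg = _block_lattice([500])
        tallies = self._sweep(state, reg, p)
        assert tallies["extrusions"] == {}
        assert reg.alive[1]

    def test_certain_apoptosis_zeroes_target(self, params_a):
        p = params_a.with_overrides(p_den_max=1.0, rho_half=0.0, beta=1e9,
                                    p_con_max=0.0)
        state, reg = _block_lattice([1000, 1000])
        self._sweep(state, reg, p)
        assert all(reg.phase[cid] == PHASE_APOPTOTIC for cid in (1, 2))
        assert all(reg.target_area[cid] == 0.0 for cid in (1, 2))

    def test_extrusion_mean_is_per_type(self, params_a):
        """A 100-site B cell is judged against the B mean only."""
        p = params_a.with_overrides(p_den_max=0.0, p_con_max=0.0)
        state, reg = _block_lattice([1000, 1000, 1000, 100])
        reg.type_code[4] = cc.TYPE_B  # lone B cell: mean_B = 100, survives
        tallies = self._sweep(state, reg, p)
        assert tallies["extrusions"] == {}


class TestApoptoticShrinkage:
    def test_apoptotic_cell_removed_in_finite_time(self, default_params):
        """Once target area is zero the lattice erodes the cell away."""
        params_by_code, contact, potts = default_params
        cfg = cc.SimulationConfig(domain_size=100, colony_radius=0.0,
                                  relax_steps=2)
        rng = np.random.default_rng(5)
        state, reg = cc.make_initial_state(cfg.initial_condition_spec(),
                                           params_by_code, contact, potts, rng)
        sim = cc.Simulation(state, reg, params_by_code, contact, potts,
                            seed=9, record_every=10)
        victim = int(reg.alive_ids()[len(reg.alive_ids()) // 2])
        reg.phase[victim] = PHASE_APOPTOTIC
        reg.target_area[victim] = 0.0
        area0 = reg.area[victim]
        for _ in range(400):
            sim.step()
            if not reg.alive[victim]:
                break
        assert not reg.alive[victim], "apoptotic cell was never removed"
        assert sim.step_count < 400
        assert area0 > 0


class TestBookkeepingClosure:
    def test_population_balance_every_step(self, default_params):
        """N(t+1) - N(t) == divisions - deaths, per type, at every step."""
        params_by_code, contact, potts = default_params
        cfg = cc.SimulationConfig(domain_size=100, mode="tiled_mixture",
                                  relax_steps=2)
        rng = np.random.default_rng(3)
        state, reg = cc.make_initial_state(cfg.initial_condition_spec(),
                                           params_by_code, contact, potts, rng)
        sim = cc.Simulation(state, reg, params_by_code, contact, potts,
                            seed=4, record_every=1)
        prev = sim.counts()
        for _ in range(150):
            sim.step()
            now = sim.counts()
            ev = sim.event_log.rows[-1]
            for i, tag in enumerate(("A", "B")):
                delta = now[i] - prev[i]
                assert delta == (ev.get(f"divisions_{tag}", 0)
                                 - ev.get(f"deaths_total_{tag}", 0)), \
                    f"bookkeeping broke at step {sim.step_count} for {tag}"
            prev = now
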