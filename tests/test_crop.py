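"""Phenology, canopy assimilation, growth, leaf area, roots and N uptake."""

import numpy as np
import pytest

from leachsim import crop
from leachsim import soil_water as sw


@pytest.fixture()
def maize(ncp_a):
    return ncp_a.crops["maize"]


@pytest.fixture()
def wheat(ncp_a):
    return ncp_a.crops["winter_wheat"]


def _emerged_state(params, **organs):
    state = crop.sow(params)
    state.emerged = True
    for organ, dm in organs.items():
        state.dm[organ] = dm
    state.LAI = crop.update_leaf_area(state)
    return state


class TestPhenology:
    def test_emergence_after_soil_temperature_sum(self, maize):
        # EmrTSum 200 degC d at constant 20 degC soil -> emergence on day 10
        state = crop.sow(maize)
        days = 0
        while not state.emerged:
            state = crop.phenology_step(state, t_mean=20.0, soil_t=20.0)
            days += 1
        assert days == 10

    def test_days_to_flowering_at_modifier_plateau(self, maize):
        # f_T = 1 at the plateau; DSRate1 = 0.0265 -> DS reaches 1 on day 38
        state = _emerged_state(maize)
        days = 0
        while state.DS < 1.0:
            state = crop.phenology_step(state, t_mean=maize.dev_temp_plateau)
            days += 1
        assert days == int(np.ceil(1.0 / 0.0265)) == 38

    def test_no_development_below_base_temperature(self, wheat):
        state = _emerged_state(wheat)
        state.DS = 0.4
        state = crop.phenology_step(state, t_mean=wheat.dev_temp_base - 5.0)
        assert state.DS == 0.4

    def test_ds_monotone_and_capped(self, maize):
        state = _emerged_state(maize)
        prev = 0.0
        for _ in range(200):
            state = crop.phenology_step(state, t_mean=30.0)
            assert state.DS >= prev
            prev = state.DS
        assert state.DS == 2.0


class TestPhotosynthesis:
    def test_zero_radiation_or_lai(self, maize):
        s = crop.StressFactors()
        assert crop.canopy_gross_photosynthesis(3.0, 0.0, 14.0, 25.0, 0.5, s, maize) == 0.0
        assert crop.canopy_gross_photosynthesis(0.0, 300.0, 14.0, 25.0, 0.5, s, maize) == 0.0

    def test_refinement_oracle(self, maize):
        """Default quadrature agrees with a 1000-layer fine quadrature."""
        s = crop.StressFactors()
        coarse = crop.canopy_gross_photosynthesis(3.0, 255.0, 14.0, 25.0, 0.5, s, maize)
        fine = crop.canopy_gross_photosynthesis(3.0, 255.0, 14.0, 25.0, 0.5, s, maize,
                                                n_layers=1000, n_time=64)
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_stress_scales_output(self, maize):
        full = crop.canopy_gross_photosynthesis(
            3.0, 255.0, 14.0, 25.0, 0.5, crop.StressFactors(), maize)
        half = crop.canopy_gross_photosynthesis(
            3.0, 255.0, 14.0, 25.0, 0.5, crop.StressFactors(water=0.5), maize)
        assert half == pytest.approx(0.5 * full, rel=1e-12)


class TestGrowth:
    def test_zero_assimilate_zero_maintenance_is_identity(self, maize):
        from dataclasses import replace
        p = replace(maize, r_Leaf=0.0, r_Stem=0.0, r_SOrg=0.0)
        state = _emerged_state(p, leaf=100.0, stem=50.0)
        before = dict(state.dm)
        state, ledger = crop.daily_growth(state, 0.0, 20.0)
        assert state.dm == before
        assert ledger["supply"] == 0.0

    def test_storage_organ_conversion_efficiency(self, maize):
        # all partition to grain at DS 2; E_SOrg 0.75; 10 g CH2O -> 7.5 g grain
        from dataclasses import replace
        p = replace(maize, r_Leaf=0.0, r_Stem=0.0, r_SOrg=0.0)
        state = _emerged_state(p)
        state.DS = 2.0
        assim_co2 = 10.0 / crop.CH2O_PER_CO2
        state, ledger = crop.daily_growth(state, assim_co2, p.maintenance_t_ref)
        assert state.dm["sorg"] == pytest.approx(7.5, abs=1e-9)
        assert ledger["growth_respiration"] == pytest.approx(2.5, abs=1e-9)

    def test_carbon_ledger_closes(self, maize):
        state = _emerged_state(maize, leaf=120.0, stem=80.0, root=40.0)
        state.DS = 0.8
        state, ledger = crop.daily_growth(state, 30.0, 25.0)
        total = ledger["maintenance"] + ledger["growth_respiration"] + ledger["structural"]
        assert total == pytest.approx(ledger["supply"], abs=1e-9)

    def test_maintenance_deficit_truncated_not_negative(self, maize):
        state = _emerged_state(maize, leaf=1000.0, stem=1000.0)
        before = dict(state.dm)
        state, ledger = crop.daily_growth(state, 0.0, 35.0)
        assert ledger["deficit"] > 0.0
        assert all(state.dm[o] >= 0.0 for o in crop.ORGANS)
        assert state.dm == before   # deficit does not shrink organs


class TestLeafArea:
    def test_direct_arithmetic(self, maize):
        state = _emerged_state(maize, leaf=100.0)
        state.DS = 1.0   # maize LeafAIMod at DS 1 is 1.2
        assert crop.update_leaf_area(state) == pytest.approx(100.0 * 0.02 * 1.2)

    def test_senescence_modifier_at_maturity(self, maize):
        state = _emerged_state(maize, leaf=100.0)
        state.DS = 2.0
        assert crop.update_leaf_area(state) == pytest.approx(100.0 * 0.02 * 0.2)

    def test_interpolated_modifier(self, maize):
        # DS 0.25 sits midway between knots (0.0, 0.7) and (0.5, 0.8)
        state = _emerged_state(maize, leaf=100.0)
        state.DS = 0.25
        assert crop.update_leaf_area(state) == pytest.approx(100.0 * 0.02 * 0.75)


class TestRoots:
    def test_length_conservation(self, maize, ncp_a):
        grid = sw.make_default_grid(ncp_a.soil)
        state = _emerged_state(maize, root=50.0)
        state.root_depth = 80.0
        state = crop.root_growth_and_distribution(state, grid, 190.0)
        total_cm = float(np.sum(state.rld * grid.dz * 1e4))
        expected = 50.0 * maize.SpRtLength * 100.0
        assert total_cm == pytest.approx(expected, rel=1e-12)

    def test_depth_capped_by_limits(self, wheat, ncp_a):
        grid = sw.make_default_grid(ncp_a.soil)
        state = _emerged_state(wheat, root=10.0)
        for _ in range(400):
            state = crop.root_growth_and_distribution(state, grid, 190.0)
        # wheat MaxPen is 210 cm but the root zone ends at 190 cm
        assert state.root_depth == pytest.approx(190.0)
        assert state.root_depth <= 210.0

    def test_exponential_profile_against_integral(self, maize, ncp_a):
        grid = sw.make_default_grid(ncp_a.soil)
        state = _emerged_state(maize, root=50.0)
        state.root_depth = 100.0 - maize.root_penetration_rate  # advances to 100
        state = crop.root_growth_and_distribution(state, grid, 300.0)
        zr = state.root_depth
        a = -np.log(1.0 - maize.root_depth_fraction) / zr
        length = state.rld * grid.dz * 1e4
        above = grid.edges[1:] <= zr / 2.0 + 1e-9
        frac = length[above].sum() / length.sum()
        # closed-form integral of the truncated exponential over [0, zr/2]
        expected = (1.0 - np.exp(-a * zr / 2.0)) / (1.0 - np.exp(-a * zr))
        assert frac == pytest.approx(expected, rel=1e-6)


class TestNitrogenUptake:
    def test_no_roots_or_no_demand_means_no_uptake(self, maize, ncp_a):
        grid = sw.make_default_grid(ncp_a.soil)
        nh4 = np.full(grid.n_cells, 1.0)
        no3 = np.full(grid.n_cells, 1.0)
        state = crop.sow(maize)   # not emerged
        _, t1, t2 = crop.crop_n_uptake(state, nh4, no3, grid)
        assert t1.sum() == t2.sum() == 0.0
        state = _emerged_state(maize, leaf=10.0)
        state.rld = np.full(grid.n_cells, 0.1)
        for o in crop.ORGANS:   # saturate N -> zero demand
            state.n[o] = 10.0
        _, t1, t2 = crop.crop_n_uptake(state, nh4, no3, grid)
        assert t1.sum() == t2.sum() == 0.0

    def test_single_cell_potential_rate_oracle(self, maize, ncp_a):
        grid = sw.make_default_grid(ncp_a.soil)
        n = grid.n_cells
        state = _emerged_state(maize, leaf=1000.0)   # huge unmet demand
        rld = np.zeros(n)
        rld[0] = 0.5                                  # cm/cm3 in the 2 cm top cell
        state.rld = rld
        nh4 = np.full(n, 100.0)
        no3 = np.full(n, 100.0)
        state, t_nh4, t_no3 = crop.crop_n_uptake(state, nh4, no3, grid)
        length = 0.5 * 2.0 * 1e4                      # cm root per m2
        assert t_nh4[0] == pytest.approx(maize.MxNH4Up * length * 24.0, rel=1e-12)
        assert t_no3[0] == pytest.approx(maize.MxNO3Up * length * 24.0, rel=1e-12)

    def test_uptake_never_exceeds_availability_or_demand(self, maize, ncp_a):
        grid = sw.make_default_grid(ncp_a.soil)
        n = grid.n_cells
        state = _emerged_state(maize, leaf=50.0)
        state.rld = np.full(n, 2.0)
        nh4 = np.full(n, 1e-4)
        no3 = np.full(n, 1e-4)
        demand_before = crop.nitrogen_demand(state)
        state, t_nh4, t_no3 = crop.crop_n_uptake(state, nh4, no3, grid)
        assert np.all(t_nh4 <= nh4 + 1e-15)
        assert np.all(t_no3 <= no3 + 1e-15)
        assert t_nh4.sum() + t_no3.sum() <= demand_before + 1e-12
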