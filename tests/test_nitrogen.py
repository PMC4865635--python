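"""Organic matter pools, mineral N processes and solute transport."""

from dataclasses import replace

import numpy as np
import pytest

from leachsim import nitrogen as nitro
from leachsim import soil_water as sw
from leachsim.errors import ConfigurationError, DomainError
from leachsim.nitrogen import POOLS
from leachsim.parameters import TurnoverParameters


def _single_pool_params(pool="AOM2", k=2.08e-3, **over):
    base = dict(
        maintenance_rates={},
        pool_rate_coefficients={pool: k},
        substrate_efficiencies={pool: 0.6},
        partition_fractions={pool: {"SMB2": 1.0}},
        smb_C_per_N=4.8,
        water_factor_table=((0.89, 0.01), (0.98, 0.01), (1.0, 0.01)),
        MaxRootingDepth=190.0, annual_C_input_total=0.0,
        annual_C_input_root=0.0, nonroot_input_depth=25.0,
    )
    base.update(over)
    return TurnoverParameters(**base)


@pytest.fixture()
def grid_a(ncp_a):
    return sw.make_default_grid(ncp_a.soil)


class TestInitialisation:
    def test_pool_total_matches_measured_carbon(self, ncp_a, grid_a):
        tp = ncp_a.turnover
        pools = nitro.initialise_som(ncp_a.soil, grid_a, tp)
        for i in range(grid_a.n_cells):
            hz = ncp_a.soil[grid_a.horizon_index[i]]
            soil_mass = tp.bulk_density * grid_a.dz[i] * 1e4
            expected = hz.humus / 100.0 * tp.humus_carbon_fraction * soil_mass
            assert pools.C[:, i].sum() == pytest.approx(expected, rel=1e-12)

    def test_topsoil_split_follows_som_fractions(self, ncp_a, grid_a):
        pools = nitro.initialise_som(ncp_a.soil, grid_a, ncp_a.turnover)
        c = pools.C[:, 0]
        total = c.sum()
        som3_frac = c[POOLS.index("SOM3")] / total
        assert som3_frac == pytest.approx(0.10, rel=1e-9)
        # slow and fast shares match 0.48/0.42 after the SMB carve-out
        slow = c[POOLS.index("SOM1")]
        fast = c[POOLS.index("SOM2")]
        assert slow / fast == pytest.approx(0.48 / 0.42, rel=1e-9)

    def test_fully_inert_horizon_has_no_biomass_and_no_turnover(self, ncp_a, grid_a):
        tp = ncp_a.turnover
        pools = nitro.initialise_som(ncp_a.soil, grid_a, tp)
        deep = grid_a.centers > 110.0   # SOM_fractions (0, 0, 1)
        for name in ("SOM1", "SOM2", "SMB1", "SMB2"):
            assert np.all(pools.C[POOLS.index(name)][deep] == 0.0)
        soil_n = nitro.SoilNState(nh4=np.zeros(grid_a.n_cells),
                                  no3=np.zeros(grid_a.n_cells))
        before = pools.C.copy()
        pools, soil_n, _ = nitro.turnover_step(
            pools, soil_n, 20.0, np.full(grid_a.n_cells, 0.28),
            np.full(grid_a.n_cells, 0.4), 0.17, tp, 1.0)
        np.testing.assert_array_equal(pools.C[:, deep], before[:, deep])


class TestAddOrganicMatter:
    def test_slow_pool_receives_cn_bound_nitrogen(self, ncp_a, grid_a):
        pools = nitro.initialise_som(ncp_a.soil, grid_a, ncp_a.turnover)
        c0, n0 = pools.total_c, pools.total_n
        # 100 g C/m2 residue, C/N 60 slow pool, half to AOM1
        pools, shortfall = nitro.add_organic_matter(
            pools, grid_a, 100.0, 100.0 / 60.0, 0.5, 60.0, 0.0, 25.0)
        i1, i2 = POOLS.index("AOM1"), POOLS.index("AOM2")
        assert pools.C[i1].sum() == pytest.approx(50.0, rel=1e-12)
        assert pools.N[i1].sum() == pytest.approx(50.0 / 60.0, rel=1e-12)
        assert pools.C[i2].sum() == pytest.approx(50.0, rel=1e-12)
        assert shortfall == 0.0
        assert pools.total_c - c0 == pytest.approx(100.0, rel=1e-12)
        assert pools.total_n - n0 == pytest.approx(100.0 / 60.0, rel=1e-12)

    def test_zero_addition_is_identity(self, ncp_a, grid_a):
        pools = nitro.initialise_som(ncp_a.soil, grid_a, ncp_a.turnover)
        before = pools.C.copy()
        pools, _ = nitro.add_organic_matter(pools, grid_a, 0.0, 0.0, 0.5, 60.0)
        np.testing.assert_array_equal(pools.C, before)

    def test_nitrogen_shortfall_clamped_and_reported(self, ncp_a, grid_a):
        pools = nitro.initialise_som(ncp_a.soil, grid_a, ncp_a.turnover)
        pools, shortfall = nitro.add_organic_matter(
            pools, grid_a, 100.0, 0.1, 0.5, 60.0)
        assert shortfall == pytest.approx(50.0 / 60.0 - 0.1, rel=1e-12)
        assert np.all(pools.N >= 0.0)


class TestTurnover:
    def test_zero_rates_no_change(self, ncp_a, grid_a):
        tp = _single_pool_params(k=0.0)
        pools = nitro.initialise_som(ncp_a.soil, grid_a, tp)
        soil_n = nitro.SoilNState(nh4=np.ones(grid_a.n_cells), no3=np.ones(grid_a.n_cells))
        before = pools.C.copy()
        pools, soil_n, led = nitro.turnover_step(
            pools, soil_n, 20.0, 0.28, 0.4, 0.17, tp, 1.0)
        np.testing.assert_array_equal(pools.C, before)
        assert led["co2"] == 0.0

    def test_single_pool_exponential_decay_oracle(self, uniform_profile):
        """Donor pool C(t) matches C0 exp(-k_eff t) at dt = 1 h over 30 d."""
        grid = sw.make_grid(uniform_profile, ((10.0, 210.0),))
        n = grid.n_cells
        k_h = 2.08e-3                       # 1/h
        tp = _single_pool_params(k=k_h)
        pools = nitro.OMPoolState(C=np.zeros((len(POOLS), n)), N=np.zeros((len(POOLS), n)))
        j = POOLS.index("AOM2")
        pools.C[j, 0] = 100.0
        pools.N[j, 0] = 2.0
        soil_n = nitro.SoilNState(nh4=np.full(n, 50.0), no3=np.full(n, 50.0))
        # T at the reference and moisture on the plateau -> modifiers = 1
        theta, theta_sat = 0.7 * 0.40, 0.40
        dt = 1.0 / 24.0
        for _ in range(30 * 24):
            pools, soil_n, _ = nitro.turnover_step(
                pools, soil_n, tp.turnover_t_ref, theta, theta_sat, 0.0, tp, dt)
        expected = 100.0 * np.exp(-k_h * 24.0 * 30.0)
        assert pools.C[j, 0] == pytest.approx(expected, rel=1e-3)

    def test_high_cn_straw_immobilises_mineral_n(self, ncp_a, grid_a):
        """Residue at C/N 60 draws down soil mineral N over the first weeks."""
        tp = ncp_a.turnover
        pools = nitro.initialise_som(ncp_a.soil, grid_a, tp)
        n = grid_a.n_cells
        soil_n = nitro.SoilNState(nh4=np.zeros(n), no3=np.zeros(n))
        soil_n.no3 += 8.0 * nitro._depth_weights(grid_a, 0.0, 25.0)  # 80 kg/ha
        pools, _ = nitro.add_organic_matter(pools, grid_a, 300.0, 5.0, 0.5, 60.0)
        mineral0 = soil_n.nh4.sum() + soil_n.no3.sum()
        for _ in range(21):
            pools, soil_n, _ = nitro.turnover_step(
                pools, soil_n, 20.0, 0.7 * 0.39, 0.39, 0.17, tp, 1.0)
        assert soil_n.nh4.sum() + soil_n.no3.sum() < mineral0

    def test_nitrogen_conserved_across_step(self, ncp_a, grid_a):
        tp = ncp_a.turnover
        pools = nitro.initialise_som(ncp_a.soil, grid_a, tp)
        n = grid_a.n_cells
        soil_n = nitro.SoilNState(nh4=np.full(n, 0.2), no3=np.full(n, 0.5))
        total0 = pools.total_n + soil_n.nh4.sum() + soil_n.no3.sum()
        pools, soil_n, _ = nitro.turnover_step(
            pools, soil_n, 25.0, 0.28, 0.4, 0.17, tp, 1.0)
        total1 = pools.total_n + soil_n.nh4.sum() + soil_n.no3.sum()
        assert total1 == pytest.approx(total0, rel=1e-12)

    def test_som3_is_inert(self, ncp_a, grid_a):
        tp = ncp_a.turnover
        pools = nitro.initialise_som(ncp_a.soil, grid_a, tp)
        j = POOLS.index("SOM3")
        before = pools.C[j].copy()
        soil_n = nitro.SoilNState(nh4=np.full(grid_a.n_cells, 1.0),
                                  no3=np.full(grid_a.n_cells, 1.0))
        for _ in range(10):
            pools, soil_n, _ = nitro.turnover_step(
                pools, soil_n, 25.0, 0.28, 0.4, 0.17, tp, 1.0)
        np.testing.assert_array_equal(pools.C[j], before)


class TestNitrificationDenitrification:
    def test_nitrification_exponential_oracle(self, grid_a, ncp_a):
        tp = ncp_a.turnover   # nitrification_rate 0.1 /d
        n = grid_a.n_cells
        soil_n = nitro.SoilNState(nh4=np.full(n, 10.0), no3=np.zeros(n))
        theta, theta_sat = 0.7 * 0.40, 0.40
        for _ in range(10):
            soil_n, _ = nitro.nitrification_step(soil_n, tp.turnover_t_ref,
                                                 theta, theta_sat, tp, 1.0)
        assert soil_n.nh4[0] == pytest.approx(10.0 * np.exp(-0.1 * 10.0), rel=1e-9)

    def test_mineral_n_conserved_minus_n2o(self, grid_a, ncp_a):
        tp = ncp_a.turnover
        n = grid_a.n_cells
        soil_n = nitro.SoilNState(nh4=np.full(n, 2.0), no3=np.full(n, 1.0))
        t0 = soil_n.nh4.sum() + soil_n.no3.sum()
        soil_n, _ = nitro.nitrification_step(soil_n, 20.0, 0.28, 0.4, tp, 1.0)
        t1 = soil_n.nh4.sum() + soil_n.no3.sum()
        n2o = soil_n.cum_n2o / nitro.KG_HA_PER_G_M2
        assert t1 + n2o == pytest.approx(t0, rel=1e-12)

    def test_water_factor_flat_below_first_knot_and_at_saturation(self, ncp_a):
        tp = ncp_a.turnover
        assert nitro.denitrification_water_factor(0.3, tp) == pytest.approx(0.01)
        assert nitro.denitrification_water_factor(1.0, tp) == pytest.approx(0.01)

    def test_denitrification_ledgered_and_zero_no3_stable(self, grid_a, ncp_a):
        tp = ncp_a.turnover
        n = grid_a.n_cells
        soil_n = nitro.SoilNState(nh4=np.zeros(n), no3=np.full(n, 1.0))
        t0 = soil_n.no3.sum()
        soil_n, loss = nitro.denitrification_step(soil_n, 0.95, 20.0, tp, 1.0)
        assert loss > 0
        assert soil_n.no3.sum() + loss == pytest.approx(t0, rel=1e-12)
        empty = nitro.SoilNState(nh4=np.zeros(n), no3=np.zeros(n))
        empty, loss0 = nitro.denitrification_step(empty, 0.95, 20.0, tp, 1.0)
        assert loss0 == 0.0


class TestFertiliser:
    def test_300_kg_urea_volatilisation(self, grid_a, ncp_a):
        n = grid_a.n_cells
        soil_n = nitro.SoilNState(nh4=np.zeros(n), no3=np.zeros(n))
        soil_n, volat = nitro.apply_fertiliser(soil_n, grid_a, 300.0, "urea",
                                               ncp_a.volatilisation)
        assert volat == pytest.approx(51.0, rel=1e-12)
        assert soil_n.nh4.sum() * nitro.KG_HA_PER_G_M2 == pytest.approx(249.0, rel=1e-12)
        assert volat + soil_n.nh4.sum() * nitro.KG_HA_PER_G_M2 == pytest.approx(300.0)

    def test_zero_and_unknown_type(self, grid_a, ncp_a):
        n = grid_a.n_cells
        soil_n = nitro.SoilNState(nh4=np.zeros(n), no3=np.zeros(n))
        soil_n, volat = nitro.apply_fertiliser(soil_n, grid_a, 0.0, "urea",
                                               ncp_a.volatilisation)
        assert volat == 0.0 and soil_n.nh4.sum() == 0.0
        with pytest.raises(ConfigurationError):
            nitro.apply_fertiliser(soil_n, grid_a, 10.0, "guano", ncp_a.volatilisation)


class TestTransport:
    def _uniform_setup(self, uniform_profile, q_cm_d, theta=0.30):
        grid = sw.make_grid(uniform_profile, ((2.0, 210.0),))
        n = grid.n_cells
        fluxes = sw.FluxProfile(
            edges=grid.edges.copy(),
            q_edges_mm=np.full(n + 1, q_cm_d * 10.0),
            sink_mm=np.zeros(n), evaporation_mm=0.0, infiltration_mm=0.0,
            runoff_mm=0.0)
        return grid, fluxes, np.full(n, theta)

    def test_no_flow_uniform_concentration_unchanged(self, uniform_profile, ncp_a):
        tp = replace(ncp_a.turnover, molecular_diffusion=0.0)
        grid, fluxes, theta = self._uniform_setup(uniform_profile, 0.0)
        n = grid.n_cells
        soil_n = nitro.SoilNState(nh4=np.full(n, 0.3), no3=np.full(n, 0.7))
        soil_n, res = nitro.cde_transport_step(soil_n, fluxes, theta, grid, tp, 1.0)
        np.testing.assert_allclose(soil_n.no3, 0.7, rtol=1e-12)
        assert res["leached_no3"] == 0.0

    def test_pulse_centre_of_mass_moves_at_pore_velocity(self, uniform_profile, ncp_a):
        tp = ncp_a.turnover
        q, theta_val = 1.0, 0.30
        grid, fluxes, theta = self._uniform_setup(uniform_profile, q, theta_val)
        n = grid.n_cells
        soil_n = nitro.SoilNState(nh4=np.zeros(n), no3=np.zeros(n))
        soil_n.no3[20] = 5.0                      # pulse at 41 cm
        z = grid.centers

        def com():
            return float(np.sum(z * soil_n.no3) / np.sum(soil_n.no3))

        c0 = com()
        days = 15
        for _ in range(days):
            soil_n, _ = nitro.cde_transport_step(soil_n, fluxes, theta, grid, tp, 1.0)
        v = (com() - c0) / days
        assert v == pytest.approx(q / theta_val, rel=0.02)

    def test_total_mass_conserved_including_leachate(self, uniform_profile, ncp_a):
        tp = ncp_a.turnover
        grid, fluxes, theta = self._uniform_setup(uniform_profile, 2.0)
        n = grid.n_cells
        soil_n = nitro.SoilNState(nh4=np.full(n, 0.1), no3=np.full(n, 0.4))
        total0 = soil_n.nh4.sum() + soil_n.no3.sum()
        leached = 0.0
        for _ in range(30):
            soil_n, res = nitro.cde_transport_step(soil_n, fluxes, theta, grid, tp, 1.0)
            leached += res["leached_nh4"] + res["leached_no3"]
        total1 = soil_n.nh4.sum() + soil_n.no3.sum()
        assert total1 + leached == pytest.approx(total0, rel=1e-6)

    def test_nh4_retarded_relative_to_no3(self, uniform_profile, ncp_a):
        tp = ncp_a.turnover
        grid, fluxes, theta = self._uniform_setup(uniform_profile, 1.0)
        n = grid.n_cells
        soil_n = nitro.SoilNState(nh4=np.zeros(n), no3=np.zeros(n))
        soil_n.nh4[20] = 5.0
        soil_n.no3[20] = 5.0
        z = grid.centers
        for _ in range(10):
            soil_n, _ = nitro.cde_transport_step(soil_n, fluxes, theta, grid, tp, 1.0)
        com_nh4 = np.sum(z * soil_n.nh4) / soil_n.nh4.sum()
        com_no3 = np.sum(z * soil_n.no3) / soil_n.no3.sum()
        assert com_nh4 < com_no3
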