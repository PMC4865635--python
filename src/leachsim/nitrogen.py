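"""Soil organic matter turnover, mineral N processes and solute transport.

The organic pool network follows the classical slow/fast scheme: soil
organic matter (SOM1 slow, SOM2 fast, SOM3 inert), soil microbial
biomass (SMB1, SMB2) and added organic matter from residues (AOM1 slow,
AOM2 fast).  Each donor pool decays by first-order kinetics modified by
temperature, moisture and (for the protected pools SOM1, SOM2, SMB1)
clay; decayed carbon is routed to receiver pools with a substrate-use
efficiency, the rest respired as CO2.  Nitrogen follows carbon: a
receiver with a lower C/N than its donor immobilises mineral N (NH4
before NO3), otherwise the surplus mineralises to NH4.  Mineral N moves
with the water by convection-dispersion; the bottom-edge export is the
simulated nitrate leaching.

Internal unit for per-cell amounts is g N (or g C) per m2 ground per
cell; divide by the cell thickness in metres for concentrations per m3
of soil.  Areal totals convert to kg/ha by multiplying by 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from ._util import piecewise_linear
from .errors import ConfigurationError, DomainError, SolverError, ValidationError
from .parameters import (SoilHorizon, TurnoverParameters, VolatilisationScheme,
                         volatilisation_fraction)
from .soil_water import FluxProfile, SoilGrid

POOLS = ("SOM1", "SOM2", "SOM3", "SMB1", "SMB2", "AOM1", "AOM2")
_CLAY_PROTECTED = ("SOM1", "SOM2", "SMB1")

#: g/m2 <-> kg/ha
KG_HA_PER_G_M2 = 10.0


@dataclass
class OMPoolState:
    """Per-cell, per-pool organic carbon and nitrogen (g/m2 per cell)."""

    C: np.ndarray   # shape (n_pools, n_cells)
    N: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.C.shape != self.N.shape or self.C.shape[0] != len(POOLS):
            raise ValidationError("pool arrays must be (n_pools, n_cells) and congruent")
        if np.any(self.C < -1e-12) or np.any(self.N < -1e-12):
            raise ValidationError("pool contents must be non-negative")

    def pool(self, name: str) -> int:
        return POOLS.index(name)

    @property
    def total_c(self) -> float:
        return float(self.C.sum())

    @property
    def total_n(self) -> float:
        return float(self.N.sum())


@dataclass
class SoilNState:
    """Per-cell mineral N (g/m2 per cell) and cumulative ledgers (kg N/ha)."""

    nh4: np.ndarray
    no3: np.ndarray
    cum_mineralisation: float = 0.0     # gross
    cum_immobilisation: float = 0.0
    cum_nitrification: float = 0.0
    cum_denitrification: float = 0.0
    cum_n2o: float = 0.0
    cum_volatilisation: float = 0.0
    cum_leaching: float = 0.0           # bottom-of-column export
    cum_deposition: float = 0.0
    cum_fertiliser: float = 0.0

    def __post_init__(self):
        self.nh4 = np.asarray(self.nh4, dtype=float)
        self.no3 = np.asarray(self.no3, dtype=float)

    @property
    def mineral_n_kg_ha(self) -> float:
        return float((self.nh4.sum() + self.no3.sum()) * KG_HA_PER_G_M2)


def initialise_som(profile: Sequence[SoilHorizon], grid: SoilGrid,
                   params: TurnoverParameters,
                   bulk_density: float | None = None) -> OMPoolState:
    """Distribute measured humus into the pool network.

    Total C per cell comes from the horizon humus percentage, the bulk
    density and the carbon fraction of humus; it is split by the horizon
    SOM_fractions with the microbial biomass carved out of the active
    (slow + fast) share so that the pool total matches the measured C
    exactly.  Horizons with fractions (0, 0, 1) start fully inert with no
    live biomass.
    """
    bd = bulk_density if bulk_density is not None else params.bulk_density
    horizons = sorted(profile, key=lambda hz: hz.depth_top)
    n_cells = grid.n_cells
    C = np.zeros((len(POOLS), n_cells))
    N = np.zeros_like(C)
    for i in range(n_cells):
        hz = horizons[grid.horizon_index[i]]
        f_slow, f_fast, f_inert = hz.SOM_fractions
        if abs(f_slow + f_fast + f_inert - 1.0) > 1e-9:
            raise ValidationError(f"SOM_fractions must sum to 1, got {hz.SOM_fractions}")
        soil_mass = bd * grid.dz[i] * 1e4                    # g soil / m2
        total_c = hz.humus / 100.0 * params.humus_carbon_fraction * soil_mass
        active = f_slow + f_fast
        smb_c = params.smb_init_fraction * total_c * active
        smb1_c = smb_c * params.smb_init_split[0]
        smb2_c = smb_c * params.smb_init_split[1]
        carve = smb_c / active if active > 0 else 0.0
        som1_c = f_slow * (total_c - carve)
        som2_c = f_fast * (total_c - carve)
        som3_c = f_inert * total_c
        for name, c in (("SOM1", som1_c), ("SOM2", som2_c), ("SOM3", som3_c)):
            j = POOLS.index(name)
            C[j, i] = c
            N[j, i] = c / hz.C_per_N
        for name, c in (("SMB1", smb1_c), ("SMB2", smb2_c)):
            j = POOLS.index(name)
            C[j, i] = c
            N[j, i] = c / params.smb_C_per_N
    return OMPoolState(C=C, N=N)


def _depth_weights(grid: SoilGrid, depth_top: float, depth_bottom: float) -> np.ndarray:
    """Fraction of an addition received by each cell for a uniform
    distribution over [depth_top, depth_bottom] cm."""
    if depth_bottom <= depth_top:
        raise DomainError("depth range must have positive thickness")
    top = np.maximum(grid.edges[:-1], depth_top)
    bot = np.minimum(grid.edges[1:], depth_bottom)
    overlap = np.maximum(bot - top, 0.0)
    total = overlap.sum()
    if total <= 0:
        raise DomainError(f"depth range {depth_top}-{depth_bottom} cm misses the grid")
    return overlap / total


def add_organic_matter(pools: OMPoolState, grid: SoilGrid, c_total: float, n_total: float,
                       partition_slow: float, c_per_n_slow: float,
                       depth_top: float = 0.0, depth_bottom: float = 25.0) -> tuple[OMPoolState, float]:
    """Add residue/amendment C and N (g/m2) over a depth range.

    C is split into AOM1 (slow, share ``partition_slow``) and AOM2; AOM1
    receives N at the slow pool's C/N, the remainder goes to AOM2.  If
    the material's N is insufficient for the slow pool, AOM2 starts at
    zero N and the shortfall is returned (clamped, second return value).
    """
    if c_total < 0 or n_total < 0:
        raise DomainError("additions must be non-negative")
    if c_total == 0.0 and n_total == 0.0:
        return pools, 0.0
    w = _depth_weights(grid, depth_top, depth_bottom)
    aom1_c = partition_slow * c_total
    aom1_n = min(aom1_c / c_per_n_slow, n_total)
    shortfall = max(aom1_c / c_per_n_slow - n_total, 0.0)
    aom2_c = c_total - aom1_c
    aom2_n = n_total - aom1_n
    i1, i2 = POOLS.index("AOM1"), POOLS.index("AOM2")
    pools.C[i1] += aom1_c * w
    pools.N[i1] += aom1_n * w
    pools.C[i2] += aom2_c * w
    pools.N[i2] += aom2_n * w
    return pools, shortfall


def temperature_factor(t, params: TurnoverParameters):
    """Exponential rise normalised to 1 at the reference (10 degC); 0 below 0."""
    t = np.asarray(t, dtype=float)
    f = params.turnover_q10 ** ((t - params.turnover_t_ref) / 10.0)
    return np.where(t <= 0.0, 0.0, f)


def moisture_factor(theta, theta_sat, params: TurnoverParameters):
    se = np.clip(np.asarray(theta) / np.asarray(theta_sat), 0.0, 1.0)
    return piecewise_linear(se, params.moisture_factor_knots)


def turnover_step(pools: OMPoolState, soil_n: SoilNState, temperature, theta, theta_sat,
                  clay, params: TurnoverParameters, dt: float) -> tuple[OMPoolState, SoilNState, dict]:
    """One turnover step (dt in days, at most 1).

    Returns the updated pools and mineral state plus a ledger dict with
    per-cell ``net_mineralisation`` (g N/m2, positive = release), and
    scalars ``co2`` (g C/m2), ``gross_mineralisation`` and
    ``immobilisation`` (g N/m2).
    """
    if dt > 1.0 + 1e-9:
        raise DomainError("turnover dt must not exceed one day")
    n_cells = pools.C.shape[1]
    t_arr = np.broadcast_to(np.asarray(temperature, dtype=float), (n_cells,))
    f_t = temperature_factor(t_arr, params)
    f_m = moisture_factor(theta, theta_sat, params)
    clay_arr = np.broadcast_to(np.asarray(clay, dtype=float), (n_cells,))
    f_clay = np.maximum(1.0 - params.clay_factor_slope * clay_arr, params.clay_factor_min)

    # cell-wise receiver C/N for the SOM pools: inherit the donor-cell soil C/N
    with np.errstate(invalid="ignore", divide="ignore"):
        som1_cn = np.where(pools.N[0] > 0, pools.C[0] / np.maximum(pools.N[0], 1e-30), 10.0)
        som2_cn = np.where(pools.N[1] > 0, pools.C[1] / np.maximum(pools.N[1], 1e-30), 10.0)
    receiver_cn = {"SMB1": np.full(n_cells, params.smb_C_per_N),
                   "SMB2": np.full(n_cells, params.smb_C_per_N),
                   "SOM1": som1_cn, "SOM2": som2_cn}

    # microbial maintenance: C respired to CO2, N released to NH4 at the
    # pool's own C/N; a pure-mineralisation flow that keeps the biomass
    # near steady state
    maint_co2 = 0.0
    maint_n = np.zeros(n_cells)
    for pool, m_rate in params.maintenance_rates.items():
        j = POOLS.index(pool)
        if m_rate <= 0.0 or not np.any(pools.C[j] > 0):
            continue
        f = f_t * f_m * (f_clay if pool in _CLAY_PROTECTED else 1.0)
        dc = pools.C[j] * (1.0 - np.exp(-m_rate * 24.0 * f * dt))
        with np.errstate(invalid="ignore", divide="ignore"):
            nc = np.where(pools.C[j] > 0, pools.N[j] / np.maximum(pools.C[j], 1e-30), 0.0)
        dn = dc * nc
        pools.C[j] -= dc
        pools.N[j] -= dn
        maint_co2 += float(dc.sum())
        maint_n += dn

    # potential decays (exact exponential decrement, unconditionally stable)
    decay = np.zeros_like(pools.C)
    for j, pool in enumerate(POOLS):
        k = params.pool_rate_coefficients.get(pool, 0.0)   # 1/h
        if k <= 0.0 or pool == "SOM3":
            continue
        f = f_t * f_m * (f_clay if pool in _CLAY_PROTECTED else 1.0)
        decay[j] = pools.C[j] * (1.0 - np.exp(-k * 24.0 * f * dt))

    # N release and demand per cell at full potential
    release = np.zeros(n_cells)
    demand = np.zeros(n_cells)
    for j, pool in enumerate(POOLS):
        d = decay[j]
        if not np.any(d > 0):
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            nc = np.where(pools.C[j] > 0, pools.N[j] / np.maximum(pools.C[j], 1e-30), 0.0)
        release += d * nc
        eff = params.substrate_efficiencies.get(pool, 0.0)
        for recv, frac in params.partition_fractions.get(pool, {}).items():
            demand += eff * d * frac / receiver_cn[recv]

    # throttle where immobilisation would exceed available mineral N
    avail = np.maximum(soil_n.nh4, 0.0) + np.maximum(soil_n.no3, 0.0)
    deficit = demand - release
    scale = np.ones(n_cells)
    mask = deficit > avail + 1e-15
    scale[mask] = np.where(deficit[mask] > 0, avail[mask] / deficit[mask], 1.0)
    decay *= scale

    # apply scaled flows
    co2 = maint_co2
    net_min = maint_n.copy()
    gross_min = maint_n.copy()
    gross_immob = np.zeros(n_cells)
    for j, pool in enumerate(POOLS):
        d = decay[j]
        if not np.any(d > 0):
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            nc = np.where(pools.C[j] > 0, pools.N[j] / np.maximum(pools.C[j], 1e-30), 0.0)
        n_out = d * nc
        pools.C[j] -= d
        pools.N[j] -= n_out
        eff = params.substrate_efficiencies.get(pool, 0.0)
        co2 += float(np.sum((1.0 - eff) * d))
        net_min += n_out
        gross_min += n_out
        for recv, frac in params.partition_fractions.get(pool, {}).items():
            r = POOLS.index(recv)
            c_in = eff * d * frac
            n_need = c_in / receiver_cn[recv]
            pools.C[r] += c_in
            pools.N[r] += n_need
            net_min -= n_need
            gross_immob += n_need

    # mineral N update: NH4 first, then NO3 for the immobilised share
    positive = np.maximum(net_min, 0.0)
    negative = np.maximum(-net_min, 0.0)
    soil_n.nh4 += positive
    from_nh4 = np.minimum(negative, np.maximum(soil_n.nh4, 0.0))
    soil_n.nh4 -= from_nh4
    rest = negative - from_nh4
    soil_n.no3 -= np.minimum(rest, np.maximum(soil_n.no3, 0.0))
    if np.any(soil_n.no3 < -1e-9) or np.any(soil_n.nh4 < -1e-9):
        raise SolverError("mineral N went negative despite throttling")
    soil_n.nh4 = np.maximum(soil_n.nh4, 0.0)
    soil_n.no3 = np.maximum(soil_n.no3, 0.0)

    soil_n.cum_mineralisation += float(gross_min.sum()) * KG_HA_PER_G_M2
    soil_n.cum_immobilisation += float(gross_immob.sum()) * KG_HA_PER_G_M2
    ledger = {"net_mineralisation": net_min, "co2": co2,
              "gross_mineralisation": float(gross_min.sum()),
              "immobilisation": float(gross_immob.sum())}
    return pools, soil_n, ledger


def nitrification_step(soil_n: SoilNState, temperature, theta, theta_sat,
                       params: TurnoverParameters, dt: float) -> tuple[SoilNState, float]:
    """First-order NH4 -> NO3 with a fixed N2O side fraction.

    Returns the state and the nitrified amount (g N/m2 summed)."""
    if dt > 1.0 + 1e-9:
        raise DomainError("nitrification dt must not exceed one day")
    f = temperature_factor(temperature, params) * moisture_factor(theta, theta_sat, params)
    amount = soil_n.nh4 * (1.0 - np.exp(-params.nitrification_rate * f * dt))
    soil_n.nh4 = soil_n.nh4 - amount
    n2o = amount * params.n2o_fraction_of_nitrification
    soil_n.no3 = soil_n.no3 + (amount - n2o)
    soil_n.cum_nitrification += float(amount.sum()) * KG_HA_PER_G_M2
    soil_n.cum_n2o += float(n2o.sum()) * KG_HA_PER_G_M2
    return soil_n, float(amount.sum())


def denitrification_water_factor(rel_saturation, params: TurnoverParameters):
    """Tabulated factor vs relative saturation; flat below the first knot."""
    return piecewise_linear(rel_saturation, params.water_factor_table,
                            left="flat", right="flat")


def denitrification_step(soil_n: SoilNState, rel_saturation, temperature,
                         params: TurnoverParameters, dt: float) -> tuple[SoilNState, float]:
    """NO3 loss to N2/N2O at the water-factor-modified potential rate."""
    if dt > 1.0 + 1e-9:
        raise DomainError("denitrification dt must not exceed one day")
    wf = denitrification_water_factor(rel_saturation, params)
    f_t = temperature_factor(temperature, params)
    loss = soil_n.no3 * (1.0 - np.exp(-params.denitrification_rate * wf * f_t * dt))
    soil_n.no3 = soil_n.no3 - loss
    soil_n.cum_denitrification += float(loss.sum()) * KG_HA_PER_G_M2
    return soil_n, float(loss.sum())


def apply_fertiliser(soil_n: SoilNState, grid: SoilGrid, amount: float, fert_type: str,
                     scheme: VolatilisationScheme,
                     incorporation_depth: float = 5.0) -> tuple[SoilNState, float]:
    """Apply a mineral N dressing (kg N/ha).

    Urea and ammonium dressings enter the NH4 pool after the amount-
    dependent ammonia loss; nitrate enters NO3 without volatilisation.
    Returns the state and the volatilised amount (kg N/ha).
    """
    if amount < 0:
        raise DomainError("fertiliser amount must be >= 0")
    if amount == 0.0:
        return soil_n, 0.0
    w = _depth_weights(grid, 0.0, incorporation_depth)
    if fert_type in ("urea", "ammonium"):
        frac = volatilisation_fraction(amount, scheme)
        volatilised = amount * frac
        soil_n.nh4 = soil_n.nh4 + (amount - volatilised) / KG_HA_PER_G_M2 * w
        soil_n.cum_volatilisation += volatilised
        soil_n.cum_fertiliser += amount
        return soil_n, volatilised
    if fert_type == "nitrate":
        soil_n.no3 = soil_n.no3 + amount / KG_HA_PER_G_M2 * w
        soil_n.cum_fertiliser += amount
        return soil_n, 0.0
    raise ConfigurationError(f"unknown fertiliser type '{fert_type}'")


def cde_transport_step(soil_n: SoilNState, fluxes: FluxProfile, theta: np.ndarray,
                       grid: SoilGrid, params: TurnoverParameters, dt: float,
                       leaching_depth: float | None = None) -> tuple[SoilNState, dict]:
    """Implicit convection-dispersion update of NH4 and NO3.

    Water fluxes come from the same step's Richards solution
    (mm over the step, downward positive).  NH4 mobility is reduced by
    the linear sorption retardation factor.  The bottom-edge export is
    ledgered as leaching; if ``leaching_depth`` is given the (upwind)
    flux through that edge is also returned.
    """
    n = grid.n_cells
    dz = grid.dz
    dzc = np.diff(grid.centers)
    q = fluxes.q_edges_mm / 10.0 / dt                      # cm/d
    theta = np.asarray(theta, dtype=float)
    water = np.maximum(theta * dz, 1e-6)                   # cm of water per cell
    v_int = np.abs(q[1:-1])                                # interior interface fluxes
    v_pore = v_int / np.maximum(0.5 * (theta[:-1] + theta[1:]), 1e-6)
    disp = params.dispersivity * v_pore + params.molecular_diffusion   # cm2/d
    theta_int = 0.5 * (theta[:-1] + theta[1:])

    results = {}
    for species, retard in (("nh4", params.nh4_retardation), ("no3", 1.0)):
        m_old = getattr(soil_n, species)
        mob = 1.0 / retard
        # linear system A m^{n+1} = m^n  (fluxes in g/m2/d, linear in m)
        lower = np.zeros(n)
        diag = np.ones(n) / dt
        upper = np.zeros(n)
        q_int = q[1:-1]
        qp = np.maximum(q_int, 0.0)
        qm = np.maximum(-q_int, 0.0)
        dcoef = theta_int * disp / dzc                     # cm/d
        # F_{i+1/2} = (qp+dcoef) * mob * m_i / water_i - (qm+dcoef) * mob * m_{i+1}/water_{i+1}
        out_up = (qp + dcoef) * mob / water[:-1]
        out_dn = (qm + dcoef) * mob / water[1:]
        diag[:-1] += out_up
        upper[:-1] = -out_dn
        diag[1:] += out_dn
        lower[1:] = -out_up
        # bottom: upwind export with the (non-negative) bottom flux
        q_bot = max(q[-1], 0.0)
        diag[-1] += q_bot * mob / water[-1]
        ab = np.zeros((3, n))
        ab[0, 1:] = upper[:-1]
        ab[1, :] = diag
        ab[2, :-1] = lower[1:]
        m_new = solve_banded((1, 1), ab, m_old / dt)
        leached = q_bot * mob * m_new[-1] / water[-1] * dt     # g/m2
        setattr(soil_n, species, np.maximum(m_new, 0.0))
        results[f"leached_{species}"] = leached
        if leaching_depth is not None:
            idx = np.where(np.abs(grid.edges - leaching_depth) < 1e-6)[0]
            if len(idx) == 0:
                raise DomainError(f"leaching depth {leaching_depth} cm is not a cell edge")
            e = int(idx[0])
            if e == 0:
                results[f"flux_{species}_at_depth"] = 0.0
            elif e == n:
                results[f"flux_{species}_at_depth"] = leached
            else:
                i = e - 1   # interface between cells i and i+1
                flux = (out_up[i] * m_new[i] - out_dn[i] * m_new[i + 1]) * dt
                results[f"flux_{species}_at_depth"] = flux
    soil_n.cum_leaching += (results["leached_nh4"] + results["leached_no3"]) * KG_HA_PER_G_M2
    return soil_n, results
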