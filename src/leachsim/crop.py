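"""Crop phenology, canopy assimilation, growth, roots and N uptake.

Development stage (DS) runs from emergence (0) through flowering (1) to
maturity (2), advanced by temperature-modified daily rates.  Leaf
photosynthesis follows a saturating light-response curve integrated over
canopy layers (exponential light extinction) and daylight hours; net
assimilate after growth and maintenance respiration is partitioned to
root, leaf, stem and storage organ by DS-dependent fractions.  Root
length decreases exponentially with depth; N uptake per cell is capped
by a per-root-length maximum, soil availability and crop demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import piecewise_linear
from .errors import DomainError
from .parameters import CropParameters
from .soil_water import SoilGrid

ORGANS = ("root", "leaf", "stem", "sorg")

#: g CH2O per g CO2
CH2O_PER_CO2 = 30.0 / 44.0


@dataclass
class CropState:
    """Live crop state: phenology, organ pools and the root system."""

    params: CropParameters
    emerged: bool = False
    t_sum: float = 0.0                  # degC d toward emergence
    DS: float = 0.0
    dm: dict = field(default_factory=lambda: {o: 0.0 for o in ORGANS})   # g DM/m2
    n: dict = field(default_factory=lambda: {o: 0.0 for o in ORGANS})    # g N/m2
    LAI: float = 0.0
    root_depth: float = 0.0             # cm
    rld: np.ndarray | None = None       # cm root / cm3 soil per cell
    maintenance_deficit: float = 0.0    # g CH2O/m2, unmet maintenance

    @property
    def aboveground_dm(self) -> float:
        return self.dm["leaf"] + self.dm["stem"] + self.dm["sorg"]

    @property
    def aboveground_n(self) -> float:
        return self.n["leaf"] + self.n["stem"] + self.n["sorg"]

    @property
    def total_n(self) -> float:
        return sum(self.n.values())


def sow(params: CropParameters, seed_dm: float = 2.0) -> CropState:
    """A freshly sown crop; ``seed_dm`` (g DM/m2) is the seed reserve that
    becomes the initial organ mass at emergence."""
    state = CropState(params=params)
    state._seed_dm = seed_dm  # type: ignore[attr-defined]
    return state


@dataclass(frozen=True)
class StressFactors:
    water: float = 1.0
    nitrogen: float = 1.0

    def __post_init__(self):
        for v in (self.water, self.nitrogen):
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"stress factors must lie in [0,1], got {v}")


def development_temperature_factor(t: float, params: CropParameters) -> float:
    """Piecewise-linear modifier: 0 at/below the base, 1 at the plateau."""
    if params.dev_temp_plateau <= params.dev_temp_base:
        return 1.0
    return float(np.clip((t - params.dev_temp_base)
                         / (params.dev_temp_plateau - params.dev_temp_base), 0.0, 1.0))


def phenology_step(state: CropState, t_mean: float, soil_t: float | None = None) -> CropState:
    """One day of development.

    Pre-emergence the soil temperature sum accumulates (above the base
    temperature); after emergence DS advances at DSRate1 (DS < 1) or
    DSRate2 (DS >= 1) times the temperature modifier, capped at 2.
    """
    p = state.params
    if not state.emerged:
        t_eff = soil_t if soil_t is not None else t_mean
        state.t_sum += max(t_eff, 0.0)
        if state.t_sum >= p.EmrTSum:
            state.emerged = True
            seed = getattr(state, "_seed_dm", 2.0)
            part = p.partition_at(0.0)
            for o in ORGANS:
                state.dm[o] = seed * part[o]
                # organ N starts at zero and is drawn from soil mineral N by
                # the first uptake call, keeping the system N ledger closed
                state.n[o] = 0.0
            state.LAI = update_leaf_area(state)
        return state
    f_t = development_temperature_factor(t_mean, p)
    rate = p.DSRate1 if state.DS < 1.0 else p.DSRate2
    state.DS = min(state.DS + rate * f_t, 2.0)
    return state


def photosynthesis_temperature_factor(t: float, params: CropParameters) -> float:
    return piecewise_linear(t, params.photo_temp_knots)


def canopy_gross_photosynthesis(LAI: float, global_radiation: float, day_length_h: float,
                                t_mean: float, DS: float, stresses: StressFactors,
                                params: CropParameters, n_layers: int = 20,
                                n_time: int = 5) -> float:
    """Gross canopy assimilation, g CO2/m2 ground/d.

    The leaf light response F(S) = Fm (1 - exp(-QEff S / Fm)) is applied
    per canopy layer under exponential extinction of a sinusoidal
    daylight irradiance course, integrated by Gauss-Legendre quadrature
    over both canopy depth and daylight time, then scaled by the
    temperature and senescence modifiers and min(water, N) stress.
    """
    if LAI <= 0.0 or global_radiation <= 0.0 or day_length_h <= 0.0:
        return 0.0
    p = params
    k = p.extinction_coefficient
    daily_light = global_radiation * p.par_fraction * 24.0   # Wh/m2 of PAR
    i_max = (np.pi / 2.0) * daily_light / day_length_h       # W/m2 PAR at solar noon

    # Gauss-Legendre nodes over daylight time and canopy depth
    xt, wt = np.polynomial.legendre.leggauss(n_time)
    t_nodes = 0.5 * day_length_h * (xt + 1.0)
    t_weights = 0.5 * day_length_h * wt
    xl, wl = np.polynomial.legendre.leggauss(n_layers)
    lai_nodes = 0.5 * LAI * (xl + 1.0)
    lai_weights = 0.5 * LAI * wl

    i0 = i_max * np.sin(np.pi * t_nodes / day_length_h)          # (n_time,)
    absorbed = k * i0[:, None] * np.exp(-k * lai_nodes[None, :])  # per unit LAI
    f = p.Fm * (1.0 - np.exp(-p.QEff * absorbed / p.Fm))          # g CO2/m2 leaf/h
    gross = float(np.sum(t_weights[:, None] * lai_weights[None, :] * f))

    f_t = photosynthesis_temperature_factor(t_mean, p)
    f_ds = piecewise_linear(DS, p.photo_ds_knots)
    stress = min(stresses.water, stresses.nitrogen)
    return gross * f_t * f_ds * stress


def daily_growth(state: CropState, assimilate: float, t_mean: float) -> tuple[CropState, dict]:
    """Allocate one day's gross assimilate (g CO2/m2/d).

    Returns the updated state and a carbon ledger with keys ``supply``
    (g CH2O), ``maintenance``, ``growth_respiration``, ``structural`` and
    ``deficit`` (unmet maintenance, truncated rather than shrinking any
    organ below zero).
    """
    p = state.params
    supply = assimilate * CH2O_PER_CO2
    q10_f = p.q10_maintenance ** ((t_mean - p.maintenance_t_ref) / 10.0)
    r = {"leaf": p.r_Leaf, "stem": p.r_Stem, "sorg": p.r_SOrg, "root": p.r_Leaf}
    maintenance_demand = sum(r[o] * state.dm[o] for o in ORGANS) * q10_f
    maintenance = min(maintenance_demand, supply)
    deficit = maintenance_demand - maintenance
    net = supply - maintenance

    part = p.partition_at(state.DS)
    eff = {"root": p.E_Leaf, "leaf": p.E_Leaf, "stem": p.E_Stem, "sorg": p.E_SOrg}
    structural = 0.0
    growth_resp = 0.0
    for o in ORGANS:
        share = net * part[o]
        grown = share * eff[o]
        state.dm[o] += grown
        structural += grown
        growth_resp += share - grown
    state.maintenance_deficit += deficit
    state.LAI = update_leaf_area(state)
    ledger = {"supply": supply, "maintenance": maintenance,
              "growth_respiration": growth_resp, "structural": structural,
              "deficit": deficit}
    return state, ledger


def update_leaf_area(state: CropState) -> float:
    """LAI = leaf DM x SpLAI x LeafAIMod(DS)."""
    p = state.params
    mod = piecewise_linear(state.DS, p.LeafAIMod_by_DS)
    return state.dm["leaf"] * p.SpLAI * mod


def root_growth_and_distribution(state: CropState, grid: SoilGrid,
                                 max_rooting_depth: float) -> CropState:
    """Advance rooting depth and redistribute root length over the profile.

    Total root length is root DM x SpRtLength; its density decreases
    exponentially with depth, scaled so that ``root_depth_fraction``
    (default 95 %) of the length lies above the rooting depth.
    """
    p = state.params
    limit = min(p.MaxPen, max_rooting_depth, grid.edges[-1])
    if state.emerged:
        f_t = 1.0  # depth advance uses the phenology modifier upstream if desired
        state.root_depth = min(max(state.root_depth, 2.0) + p.root_penetration_rate * f_t, limit)
    zr = max(state.root_depth, 1.0)
    a = -np.log(1.0 - p.root_depth_fraction) / zr        # 1/cm decay of density
    total_length_cm = state.dm["root"] * p.SpRtLength * 100.0   # cm root per m2 ground

    # exponential density truncated at the rooting depth
    top = np.minimum(grid.edges[:-1], zr)
    bot = np.minimum(grid.edges[1:], zr)
    frac = np.exp(-a * top) - np.exp(-a * bot)
    frac = frac / frac.sum()
    length_per_cell = total_length_cm * frac              # cm root / m2 ground
    volume_cm3 = grid.dz * 1e4                            # cm3 soil / m2 ground per cell
    state.rld = length_per_cell / volume_cm3              # cm/cm3
    return state


def nitrogen_demand(state: CropState) -> float:
    """Remaining N demand (g N/m2) toward DS-dependent target concentrations."""
    p = state.params
    demand = 0.0
    for o in ORGANS:
        target = piecewise_linear(state.DS, p.n_conc_by_DS[o]) * state.dm[o]
        demand += max(target - state.n[o], 0.0)
    return demand


def crop_n_uptake(state: CropState, nh4_avail: np.ndarray, no3_avail: np.ndarray,
                  grid: SoilGrid) -> tuple[CropState, np.ndarray, np.ndarray]:
    """Daily N uptake.

    ``nh4_avail``/``no3_avail`` are the extractable mineral N per cell in
    g N/m2.  Potential uptake per cell and species is the per-root-length
    maximum times root length times 24 h; actual uptake is capped by
    availability and by the remaining crop demand (NH4 drawn first).
    Returns the state and the per-cell removals (g N/m2).
    """
    n_cells = grid.n_cells
    zeros = np.zeros(n_cells)
    if not state.emerged or state.rld is None:
        return state, zeros, zeros
    demand = nitrogen_demand(state)
    if demand <= 0.0:
        return state, zeros, zeros
    p = state.params
    length_cm = state.rld * grid.dz * 1e4                 # cm root per m2 per cell
    pot_nh4 = p.MxNH4Up * length_cm * 24.0                # g N/m2/d
    pot_no3 = p.MxNO3Up * length_cm * 24.0
    take_nh4 = np.minimum(pot_nh4, np.maximum(nh4_avail, 0.0))
    take_no3 = np.minimum(pot_no3, np.maximum(no3_avail, 0.0))
    total = take_nh4.sum() + take_no3.sum()
    if total > demand > 0.0:
        scale = demand / total
        take_nh4 *= scale
        take_no3 *= scale
        total = demand
    if total <= 0.0:
        return state, zeros, zeros
    # distribute over organs proportionally to their unmet demand
    deficits = {}
    for o in ORGANS:
        target = piecewise_linear(state.DS, p.n_conc_by_DS[o]) * state.dm[o]
        deficits[o] = max(target - state.n[o], 0.0)
    dsum = sum(deficits.values())
    for o in ORGANS:
        state.n[o] += total * (deficits[o] / dsum if dsum > 0 else 0.25)
    return state, take_nh4, take_no3


def nitrogen_stress(state: CropState) -> float:
    """1 at the target N concentration, falling linearly to 0 at half of it."""
    p = state.params
    target = sum(piecewise_linear(state.DS, p.n_conc_by_DS[o]) * state.dm[o] for o in ORGANS)
    if target <= 0.0:
        return 1.0
    ratio = state.total_n / target
    return float(np.clip(2.0 * ratio - 1.0, 0.0, 1.0))
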