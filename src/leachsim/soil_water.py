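"""One-dimensional soil water: grid construction, van Genuchten-Mualem
constitutive relations, a mass-conservative Richards-equation stepper and
an analytic damped-sinusoid soil temperature profile.

Conventions: depth z in cm, positive downward; pressure head h in cm
(negative unsaturated); fluxes positive downward in cm per day inside the
solver, converted to mm at the module boundary.  The Richards stepper is
implicit in time with a Newton iteration (analytic tridiagonal Jacobian,
L2 line search) and adaptive sub-daily stepping; convergence is judged on
the true per-cell mass residual, and the reported edge fluxes are
reconciled with the realised storage change so the water ledger closes
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConfigurationError, DomainError, SolverError
from .parameters import SoilHorizon

#: default grid refinement: (cell size cm, down-to depth cm)
DEFAULT_GRID_SPEC = ((2.0, 60.0), (5.0, 170.0), (10.0, 210.0))

_H_DRY = -1.0e7   # cm, driest head considered

_last_failure_diagnostics: dict = {}

#: specific storage (1/cm) giving saturated cells a small compressible
#: capacity; regularises the h = 0 kink for the Newton iteration.  The
#: stored excess (a softplus of h, smooth across saturation) is carried
#: in the water ledger.
SPECIFIC_STORAGE = 1e-4
_REG_WIDTH = 0.5   # cm, smoothing width of the excess-storage transition


def _excess_storage(h):
    """Smooth excess storage (cm3/cm3): ~0 unsaturated, Ss*h saturated."""
    x = np.asarray(h, dtype=float) / _REG_WIDTH
    soft = np.where(x > 30.0, x, np.log1p(np.exp(np.minimum(x, 30.0))))
    return SPECIFIC_STORAGE * _REG_WIDTH * soft


def _excess_capacity(h):
    x = np.clip(np.asarray(h, dtype=float) / _REG_WIDTH, -500.0, 500.0)
    return SPECIFIC_STORAGE / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SoilGrid:
    """Cell edges (cm below surface) and the cell-to-horizon mapping."""

    edges: np.ndarray
    horizon_index: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges[0] != 0.0 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("grid edges must increase strictly from 0")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "horizon_index", np.asarray(self.horizon_index, dtype=int))

    @property
    def n_cells(self) -> int:
        return len(self.edges) - 1

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def make_grid(profile: Sequence[SoilHorizon], spec=DEFAULT_GRID_SPEC) -> SoilGrid:
    """Build a grid from a refinement spec and map cells onto horizons."""
    edges = [0.0]
    for size, down_to in spec:
        while edges[-1] + size <= down_to + 1e-9:
            edges.append(round(edges[-1] + size, 9))
    edges = np.array(edges)
    bottom = edges[-1]
    horizons = sorted(profile, key=lambda hz: hz.depth_top)
    if horizons[0].depth_top > 0 or horizons[-1].depth_bottom < bottom - 1e-9:
        raise ConfigurationError(
            f"soil horizons cover {horizons[0].depth_top}-{horizons[-1].depth_bottom} cm "
            f"but the grid needs 0-{bottom} cm"
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.empty(len(centers), dtype=int)
    for i, c in enumerate(centers):
        for j, hz in enumerate(horizons):
            if hz.depth_top <= c < hz.depth_bottom:
                idx[i] = j
                break
        else:
            raise ConfigurationError(f"no horizon covers depth {c} cm")
    return SoilGrid(edges=edges, horizon_index=idx)


def make_default_grid(profile: Sequence[SoilHorizon]) -> SoilGrid:
    """The standard column: 2 cm cells to 60 cm, 5 cm to 170 cm, 10 cm to 210 cm."""
    return make_grid(profile, DEFAULT_GRID_SPEC)


# ---------------------------------------------------------------------------
# van Genuchten-Mualem relations

def vg_theta(h, horizon: SoilHorizon):
    """Water content at pressure head h (cm); theta_sat for h >= 0."""
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / horizon.n
    se = (1.0 + (horizon.alpha * np.abs(np.minimum(h, 0.0))) ** horizon.n) ** (-m)
    theta = horizon.theta_res + (horizon.theta_sat - horizon.theta_res) * se
    theta = np.where(h >= 0.0, horizon.theta_sat, theta)
    return float(theta) if theta.ndim == 0 else theta


def vg_head(theta, horizon: SoilHorizon):
    """Inverse retention: head (cm) for theta in (theta_res, theta_sat]."""
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr <= horizon.theta_res) or np.any(theta_arr > horizon.theta_sat + 1e-12):
        raise DomainError(
            f"theta must lie in ({horizon.theta_res}, {horizon.theta_sat}], got {theta}"
        )
    se = np.clip((theta_arr - horizon.theta_res) / (horizon.theta_sat - horizon.theta_res),
                 1e-15, 1.0)
    m = 1.0 - 1.0 / horizon.n
    h = -(1.0 / horizon.alpha) * (se ** (-1.0 / m) - 1.0) ** (1.0 / horizon.n)
    h = np.where(se >= 1.0, 0.0, h)
    return float(h) if h.ndim == 0 else h


def vg_conductivity(h, horizon: SoilHorizon):
    """Unsaturated conductivity (cm/h), Mualem form; Ksat at saturation."""
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / horizon.n
    se = (1.0 + (horizon.alpha * np.abs(np.minimum(h, 0.0))) ** horizon.n) ** (-m)
    se = np.clip(se, 1e-12, 1.0)
    k = horizon.Ksat * se ** horizon.l * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    k = np.where(h >= 0.0, horizon.Ksat, k)
    return float(k) if k.ndim == 0 else k


class HydraulicArrays:
    """Per-cell vG parameter arrays for vectorised solver evaluation."""

    def __init__(self, grid: SoilGrid, profile: Sequence[SoilHorizon]):
        horizons = sorted(profile, key=lambda hz: hz.depth_top)
        idx = grid.horizon_index
        take = lambda attr: np.array([getattr(horizons[j], attr) for j in idx])
        self.theta_sat = take("theta_sat")
        self.theta_res = take("theta_res")
        self.alpha = take("alpha")
        self.n = take("n")
        self.m = 1.0 - 1.0 / self.n
        self.l = take("l")
        self.ksat_cm_d = take("Ksat") * 24.0
        self.horizons = horizons

    def theta(self, h):
        se = (1.0 + (self.alpha * np.abs(np.minimum(h, 0.0))) ** self.n) ** (-self.m)
        return np.where(h >= 0.0, self.theta_sat,
                        self.theta_res + (self.theta_sat - self.theta_res) * se)

    def theta_eff(self, h):
        """Water content plus compressible excess storage near saturation."""
        return self.theta(h) + _excess_storage(h)

    def capacity_eff(self, h):
        return self.capacity(h) + _excess_capacity(h)

    def capacity(self, h):
        """d theta / d h, zero at saturation."""
        hn = np.minimum(h, -1e-9)
        ah = self.alpha * np.abs(hn)
        se_inner = (1.0 + ah ** self.n)
        dse = self.m * self.n * self.alpha * ah ** (self.n - 1.0) * se_inner ** (-self.m - 1.0)
        c = (self.theta_sat - self.theta_res) * dse
        return np.where(h >= 0.0, 0.0, c)

    def conductivity(self, h):
        se = (1.0 + (self.alpha * np.abs(np.minimum(h, 0.0))) ** self.n) ** (-self.m)
        se = np.clip(se, 1e-12, 1.0)
        k = self.ksat_cm_d * se ** self.l * (1.0 - (1.0 - se ** (1.0 / self.m)) ** self.m) ** 2
        return np.where(h >= 0.0, self.ksat_cm_d, k)

    def head(self, theta):
        se = np.clip((theta - self.theta_res) / (self.theta_sat - self.theta_res), 1e-12, 1.0)
        h = -(1.0 / self.alpha) * (se ** (-1.0 / self.m) - 1.0) ** (1.0 / self.n)
        return np.where(se >= 1.0, 0.0, h)

    def conductivity_slope(self, h):
        """dK/dh (cm/d per cm); zero at and above saturation."""
        hn = np.minimum(h, -1e-9)
        se = (1.0 + (self.alpha * np.abs(hn)) ** self.n) ** (-self.m)
        se = np.clip(se, 1e-12, 1.0 - 1e-12)
        x = se ** (1.0 / self.m)
        b = 1.0 - (1.0 - x) ** self.m
        db = se ** (1.0 / self.m - 1.0) * (1.0 - x) ** (self.m - 1.0)
        dk_dse = self.ksat_cm_d * (self.l * se ** (self.l - 1.0) * b ** 2
                                   + se ** self.l * 2.0 * b * db)
        dse_dh = self.capacity(h) / (self.theta_sat - self.theta_res)
        return np.where(h >= 0.0, 0.0, dk_dse * dse_dh)


@dataclass
class SoilWaterState:
    """Per-cell head and water content plus cumulative boundary ledgers (mm)."""

    h: np.ndarray
    theta: np.ndarray
    cum_infiltration: float = 0.0
    cum_evaporation: float = 0.0
    cum_transpiration: float = 0.0
    cum_bottom_drainage: float = 0.0
    cum_runoff: float = 0.0

    def storage_mm(self, grid: SoilGrid) -> float:
        return float(np.sum((self.theta + _excess_storage(self.h)) * grid.dz) * 10.0)


def initial_state(grid: SoilGrid, profile: Sequence[SoilHorizon],
                  pF: float = 2.3) -> SoilWaterState:
    """Uniform-suction initial state (default pF 2.3, near field capacity)."""
    hyd = HydraulicArrays(grid, profile)
    h = np.full(grid.n_cells, -(10.0 ** pF))
    return SoilWaterState(h=h, theta=hyd.theta(h))


def hydrostatic_state(grid: SoilGrid, profile: Sequence[SoilHorizon],
                      water_table_cm: float) -> SoilWaterState:
    """Hydrostatic equilibrium with a water table at the given depth."""
    hyd = HydraulicArrays(grid, profile)
    h = grid.centers - water_table_cm   # >= 0 below the table
    return SoilWaterState(h=h, theta=hyd.theta(h))


@dataclass
class FluxProfile:
    """Edge fluxes and sink terms integrated over one stepping call.

    ``q_edges_mm`` is the downward-positive Darcy flux through every cell
    edge (length n_cells + 1) in mm over the step; element 0 is the actual
    surface flux, the last element the bottom drainage.
    """

    edges: np.ndarray
    q_edges_mm: np.ndarray
    sink_mm: np.ndarray           # per-cell transpiration extraction
    evaporation_mm: float
    infiltration_mm: float
    runoff_mm: float
    substeps: int = 0
    soft_accepts: int = 0   # sub-steps accepted at a stalled residual floor


def _tridiag_solve(lower, diag, upper, rhs):
    ab = np.zeros((3, len(diag)))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return solve_banded((1, 1), ab, rhs)


def richards_step(state: SoilWaterState, grid: SoilGrid, profile: Sequence[SoilHorizon],
                  dt: float, surface_flux: float, lower_bc: str = "free_drainage",
                  sink: np.ndarray | None = None, hyd: HydraulicArrays | None = None,
                  mass_tol: float = 1e-9, max_substeps: int = 5000) -> tuple[SoilWaterState, FluxProfile]:
    """Advance the column by ``dt`` days under a prescribed surface flux.

    ``surface_flux`` (mm over the step) is infiltration minus soil
    evaporation demand; a positive demand that exceeds the infiltration
    capacity is diverted to the runoff ledger, an evaporative demand that
    would dry the top cell below residual is reduced (the shortfall is
    reported through the actual-evaporation ledger).  ``sink`` is a
    per-cell transpiration demand in mm over the step, reduced where
    cells approach residual water content.

    Lower boundary: "free_drainage" (unit gradient) or "fixed_head:<cm>",
    the head prescribed at the lower edge of the column.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    hyd = hyd or HydraulicArrays(grid, profile)
    n = grid.n_cells
    dz = grid.dz
    dzc = np.diff(grid.centers)                       # between-centre distances
    h = state.h.copy()
    theta = hyd.theta_eff(h)

    q_net_cm = surface_flux / 10.0 / dt               # cm/d net surface demand
    sink_cm_d = (np.zeros(n) if sink is None else np.asarray(sink) / 10.0 / dt)

    fixed_head = None
    if lower_bc.startswith("fixed_head"):
        fixed_head = float(lower_bc.split(":")[1])
    elif lower_bc != "free_drainage":
        raise ConfigurationError(f"unknown lower boundary condition '{lower_bc}'")

    q_edges_cm = np.zeros(n + 1)
    sink_taken_cm = np.zeros(n)
    runoff_cm = 0.0
    evap_shortfall_cm = 0.0

    # extraction floors: air-dry for surface evaporation, wilting for roots
    theta_airdry = hyd.theta(np.full(n, -1.0e5))
    theta_wilt = hyd.theta(np.full(n, -1.5e4))

    t = 0.0
    dt_sub = min(dt, 0.1)
    n_sub = 0
    soft_accepts = 0
    attempts = 0
    floor_prev = np.inf
    while t < dt - 1e-12:
        dt_sub = min(dt_sub, dt - t)
        h_old = h.copy()
        theta_old = theta.copy()

        # per-substep surface flux limiting; during infiltration the surface
        # itself is wet, so the capacity uses the ponded-surface/top-cell
        # mean conductivity rather than the (possibly air-dry) cell value
        k_top = hyd.conductivity(h[:1])[0]
        if q_net_cm >= 0.0:
            k_surf = 0.5 * (hyd.ksat_cm_d[0] + k_top)
            cap = k_surf * ((0.0 - h[0]) / (0.5 * dz[0]) + 1.0)
            q_top = min(q_net_cm, max(cap, 0.0))
            excess = q_net_cm - q_top
        else:
            avail = max(theta[0] - theta_airdry[0], 0.0) * dz[0] / dt_sub
            q_top = -min(-q_net_cm, avail)
            excess = 0.0

        # transpiration sink limited by extractable water above wilting
        avail_cells = np.maximum(theta - theta_wilt, 0.0) * dz / dt_sub
        s_eff = np.minimum(sink_cm_d, avail_cells)

        def residual(hh):
            """F_i = storage change rate - flux divergence + sink (cm/d),
            with the interior fluxes and bottom flux at hh."""
            k = hyd.conductivity(hh)
            k_int = 0.5 * (k[:-1] + k[1:])
            q_int = k_int * ((hh[:-1] - hh[1:]) / dzc + 1.0)
            if fixed_head is None:
                q_bot = k[-1]
            else:
                q_bot = k[-1] * ((hh[-1] - fixed_head) / (0.5 * dz[-1]) + 1.0)
            div = np.empty(n)
            div[0] = q_top - q_int[0]
            div[1:-1] = q_int[:-1] - q_int[1:]
            div[-1] = q_int[-1] - q_bot
            f = (hyd.theta_eff(hh) - theta_old) * dz / dt_sub - div + s_eff
            return f, q_int, q_bot

        # Newton iteration with analytic tridiagonal Jacobian; the line
        # search descends on the L2 residual norm (the max norm is not
        # monotone along Newton paths near saturation kinks), while
        # acceptance uses the max-norm mass criterion
        converged = False
        f, q_int, q_bot = residual(h)
        fnorm = float(np.linalg.norm(f))
        for _ in range(40):
            if np.max(np.abs(f)) * dt_sub < mass_tol:
                converged = True
                break
            k = hyd.conductivity(h)
            dk = hyd.conductivity_slope(h)
            c = hyd.capacity_eff(h)
            k_int = 0.5 * (k[:-1] + k[1:])
            grad = (h[:-1] - h[1:]) / dzc + 1.0
            # d q_{i+1/2} / d h_i and / d h_{i+1}
            dq_up = 0.5 * dk[:-1] * grad + k_int / dzc
            dq_dn = 0.5 * dk[1:] * grad - k_int / dzc
            diag = np.maximum(c, 0.0) * dz / dt_sub
            lower = np.zeros(n)
            upper = np.zeros(n)
            diag[:-1] += dq_up
            upper[:-1] = dq_dn
            diag[1:] -= dq_dn
            lower[1:] = -dq_up
            if fixed_head is None:
                diag[-1] += dk[-1]
            else:
                diag[-1] += dk[-1] * ((h[-1] - fixed_head) / (0.5 * dz[-1]) + 1.0) \
                    + k[-1] / (0.5 * dz[-1])
            diag += 1e-12
            delta = _tridiag_solve(lower, diag, upper, -f)
            # line search on the residual norm
            lam = 1.0
            for _ in range(20):
                h_try = np.maximum(h + lam * delta, _H_DRY)
                f_try, q_int, q_bot = residual(h_try)
                fnorm_try = float(np.linalg.norm(f_try))
                if fnorm_try < fnorm * (1.0 - 1e-4 * lam) \
                        or np.max(np.abs(f_try)) * dt_sub < mass_tol:
                    break
                lam *= 0.5
            else:
                break     # no descent: give up, halve the time step
            h = h_try
            f = f_try
            fnorm = fnorm_try
        resid = f
        theta_new = hyd.theta_eff(h)
        if not converged:
            # Newton stalled at a residual floor.  In media whose K(h)
            # drops near-discontinuously below saturation (small vG n)
            # the floor is often independent of dt; halve the step only
            # while that visibly helps, then accept the stalled iterate
            # - the flux reconciliation below keeps the ledger exact and
            # the floor only mis-places flux locally around the front.
            floor = float(np.max(np.abs(f)))
            if floor * dt_sub < 1e-6:
                converged = True            # negligible volume error
            elif floor < 1.0 and (attempts >= 8 or floor > 0.5 * floor_prev):
                converged = True
                soft_accepts += 1
            else:
                floor_prev = floor
                attempts += 1
                dt_sub *= 0.5
                h = h_old
                theta = theta_old
                n_sub += 1
                if n_sub > max_substeps or dt_sub < 1e-10:
                    i_bad = int(np.argmax(np.abs(resid)))
                    raise SolverError(
                        f"Richards iteration failed to converge (dt_sub={dt_sub:.2e} d, "
                        f"max residual {np.max(np.abs(resid)):.2e} cm/d in cell {i_bad} "
                        f"at {grid.centers[i_bad]:.0f} cm, h={h[i_bad]:.3g} cm)"
                    )
                continue
        attempts = 0
        floor_prev = np.inf

        theta = theta_new
        # flux reconciliation: report edge fluxes consistent with the
        # realised storage change (Darcy fluxes minus the cumulative
        # iteration residual), so the water ledger closes exactly
        balance = (theta_new - theta_old) * dz / dt_sub + s_eff
        q_corr = q_top - np.cumsum(balance)
        q_edges_cm[0] += q_top * dt_sub
        q_edges_cm[1:-1] += q_corr[:-1] * dt_sub
        q_edges_cm[-1] += q_corr[-1] * dt_sub
        sink_taken_cm += s_eff * dt_sub
        runoff_cm += excess * dt_sub
        if q_net_cm < 0.0:
            evap_shortfall_cm += (-q_net_cm - (-q_top)) * dt_sub
        t += dt_sub
        n_sub += 1
        if n_sub > max_substeps:
            raise SolverError("Richards stepping exceeded the sub-step budget")
        dt_sub = min(dt_sub * 1.5, dt - t if dt - t > 0 else dt_sub, 0.5)
        if dt_sub <= 0:
            break

    infiltration_mm = max(q_edges_cm[0], 0.0) * 10.0
    evaporation_mm = max(-q_edges_cm[0], 0.0) * 10.0
    new_state = SoilWaterState(
        h=h, theta=hyd.theta(h),
        cum_infiltration=state.cum_infiltration + infiltration_mm,
        cum_evaporation=state.cum_evaporation + evaporation_mm,
        cum_transpiration=state.cum_transpiration + float(np.sum(sink_taken_cm)) * 10.0,
        cum_bottom_drainage=state.cum_bottom_drainage + q_edges_cm[-1] * 10.0,
        cum_runoff=state.cum_runoff + runoff_cm * 10.0,
    )
    fluxes = FluxProfile(
        edges=grid.edges.copy(), q_edges_mm=q_edges_cm * 10.0,
        sink_mm=sink_taken_cm * 10.0, evaporation_mm=evaporation_mm,
        infiltration_mm=infiltration_mm, runoff_mm=runoff_cm * 10.0,
        substeps=n_sub, soft_accepts=soft_accepts,
    )
    return new_state, fluxes


def drainage_at_depth(fluxes: FluxProfile, z: float) -> float:
    """Downward water flux (mm over the step) through the edge at depth z."""
    matches = np.where(np.abs(fluxes.edges - z) < 1e-6)[0]
    if len(matches) == 0:
        raise DomainError(f"depth {z} cm is not a cell edge; no interpolation performed")
    return float(fluxes.q_edges_mm[matches[0]])


def soil_temperature_profile(day_of_year: float, depth: float, annual_mean: float,
                             annual_amplitude: float, damping_depth: float,
                             phase_doy: float = 105.0) -> float:
    """Damped annual sinusoid: T(z, t) = mean + A exp(-z/d) sin(w(t-t0) - z/d).

    ``phase_doy`` fixes the surface maximum about mid July for the
    default value.  ``damping_depth`` d is where the amplitude drops to
    1/e of its surface value.
    """
    if damping_depth <= 0:
        raise DomainError("damping depth must be positive")
    omega = 2.0 * np.pi / 365.0
    zd = depth / damping_depth
    return float(annual_mean + annual_amplitude * np.exp(-zd)
                 * np.sin(omega * (day_of_year - phase_doy) - zd))
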