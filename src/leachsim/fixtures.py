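"""Ready-made, fully synthetic-forcing simulation fixtures and the
water-retention fitting used to derive van Genuchten parameters.

The fixtures pair the packaged field A/B parameter sets and the recorded
management pattern (sowing/harvest dates, fertiliser split, straw
handling) with seed-pinned synthetic weather whose annual totals match
the station climate envelope.  They are "paper-shaped" study conditions,
not measured data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .engine import ManagementEvent, SimulationConfig
from .errors import DomainError
from .parameters import SoilHorizon, default_ncp_parameters
from .soil_water import vg_theta
from .weather import synthetic_ncp_weather


def build_rotation_schedule(start_year: int, n_years: int, n_rate: float,
                            field: str = "A", irrigation_annual: float = 300.0,
                            straw_incorporated: bool | None = None,
                            sow_final_wheat: bool = False) -> list[ManagementEvent]:
    """A maize-winter wheat double-crop schedule for ``n_years`` rotation
    years starting with maize sowing in June of ``start_year``.

    The annual N rate is split half between the crops: maize is dressed
    at flowering (field A) or at sowing (field B), wheat at sowing.
    Straw handling defaults to the field's practice (A incorporated 80 %,
    B removed 80 %).  Irrigation events share the annual amount evenly.
    """
    field = field.upper()
    if straw_incorporated is None:
        straw_incorporated = field == "A"
    straw_frac = 0.8 if straw_incorporated else 0.2
    events: list[ManagementEvent] = []
    half = n_rate / 2.0

    for k in range(n_years):
        y = start_year + k
        irr = irrigation_annual / 5.0
        # maize season
        events.append(ManagementEvent(dt.date(y, 6, 15), "sow", crop="maize"))
        events.append(ManagementEvent(dt.date(y, 6, 20), "irrigate", amount=irr))
        fert_date = dt.date(y, 8, 1) if field == "A" else dt.date(y, 6, 15)
        if half > 0:
            events.append(ManagementEvent(fert_date, "fertilise", amount=half))
        events.append(ManagementEvent(dt.date(y, 8, 1), "irrigate", amount=irr))
        events.append(ManagementEvent(dt.date(y, 10, 1), "harvest",
                                      straw_incorporated_fraction=straw_frac))
        events.append(ManagementEvent(dt.date(y, 10, 8), "till", depth=20.0))
        # winter wheat (harvested the following June)
        if k < n_years - 1 or sow_final_wheat:
            events.append(ManagementEvent(dt.date(y, 10, 10), "sow", crop="winter_wheat"))
            if half > 0:
                events.append(ManagementEvent(dt.date(y, 10, 10), "fertilise", amount=half))
            events.append(ManagementEvent(dt.date(y, 10, 10), "irrigate", amount=irr))
            events.append(ManagementEvent(dt.date(y + 1, 4, 10), "irrigate", amount=irr))
            events.append(ManagementEvent(dt.date(y + 1, 5, 19), "irrigate", amount=irr))
            events.append(ManagementEvent(dt.date(y + 1, 6, 14), "harvest",
                                          straw_incorporated_fraction=straw_frac))
    return events


def build_field_fixture(field: str = "A", n_rate: float = 400.0, n_years: int = 2,
                        seed: int = 11, start_year: int = 2008,
                        warm_up_years: int = 0) -> SimulationConfig:
    """A complete simulation config for one field and N treatment.

    ``n_years`` counts rotation years (maize + following wheat); the
    simulation spans enough calendar years to cover them plus any
    warm-up, with synthetic weather pinned to ``seed``.
    """
    params = default_ncp_parameters(field)
    sim_start_year = start_year - warm_up_years
    n_weather_years = warm_up_years + n_years + 1
    weather = synthetic_ncp_weather(seed, n_weather_years, start_year=sim_start_year)
    schedule = build_rotation_schedule(start_year, n_years, n_rate, field=field)
    return SimulationConfig(
        params=params,
        weather=weather,
        schedule=schedule,
        start=dt.date(sim_start_year, 1, 1),
        end=dt.date(start_year + n_years, 6, 30),
        warm_up_years=warm_up_years,
        output_depth=200.0,
    )


# ---------------------------------------------------------------------------
# retention data and van Genuchten fitting

def toy_retention_dataset(horizon: SoilHorizon, noise_sd: float, seed: int,
                          n_samples: int = 20,
                          pf_range: tuple[float, float] = (0.5, 4.2)) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (h, theta) retention samples from a horizon's true curve
    with Gaussian noise on theta.  h in cm (negative), theta fraction."""
    rng = np.random.default_rng(seed)
    pf = np.linspace(pf_range[0], pf_range[1], n_samples)
    h = -(10.0 ** pf)
    theta = np.asarray(vg_theta(h, horizon))
    theta = theta + rng.normal(0.0, noise_sd, size=theta.shape)
    return h, np.clip(theta, 1e-4, 1.0)


@dataclass(frozen=True)
class VGFitResult:
    theta_res: float
    theta_sat: float
    alpha: float
    n: float
    residual_norm: float
    converged: bool


def vg_fit(h: np.ndarray, theta: np.ndarray) -> VGFitResult:
    """Least-squares fit of the van Genuchten retention parameters.

    Requires at least 6 samples spanning at least 3 pF units.  Bound-
    constrained trust-region least squares on (theta_res, theta_sat,
    alpha, n); non-convergence is reported, not silent.
    """
    h = np.asarray(h, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if len(h) < 6:
        raise DomainError(f"need at least 6 retention samples, got {len(h)}")
    pf = np.log10(np.abs(h[h < 0]))
    if len(pf) == 0 or pf.max() - pf.min() < 3.0:
        raise DomainError("retention samples must span at least 3 pF units")

    def model(hh, tr, ts, alpha, n):
        m = 1.0 - 1.0 / n
        se = (1.0 + (alpha * np.abs(np.minimum(hh, 0.0))) ** n) ** (-m)
        return np.where(hh >= 0, ts, tr + (ts - tr) * se)

    p0 = (0.05, max(theta.max(), 0.3), 0.01, 1.3)
    bounds = ([0.0, 0.2, 1e-5, 1.01], [0.3, 0.65, 1.0, 4.0])
    try:
        popt, _ = curve_fit(model, h, theta, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    resid = float(np.linalg.norm(model(h, *popt) - theta))
    return VGFitResult(theta_res=float(popt[0]), theta_sat=float(popt[1]),
                       alpha=float(popt[2]), n=float(popt[3]),
                       residual_norm=resid, converged=converged)


#: named fixture builders for the CLI
CATALOG = {
    "fieldA_N0": lambda seed=11: build_field_fixture("A", 0.0, seed=seed),
    "fieldA_N200": lambda seed=11: build_field_fixture("A", 200.0, seed=seed),
    "fieldA_N400": lambda seed=11: build_field_fixture("A", 400.0, seed=seed),
    "fieldA_N600": lambda seed=11: build_field_fixture("A", 600.0, seed=seed),
    "fieldB_N400": lambda seed=11: build_field_fixture("B", 400.0, seed=seed),
}
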