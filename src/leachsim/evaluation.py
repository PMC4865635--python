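"""Model evaluation: goodness-of-fit statistics, hold-out splitting,
one-at-a-time (mono-factor) sensitivity analysis and the fertiliser-
ladder scenario analysis of residual soil mineral N trends.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class PairedSeries:
    """Observed and simulated values on shared time labels."""

    observed: np.ndarray
    simulated: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=float)
        sim = np.asarray(self.simulated, dtype=float)
        if obs.shape != sim.shape or obs.ndim != 1:
            raise DomainError("observed and simulated must be equal-length 1-D series")
        if len(obs) < 2:
            raise DomainError("need at least two pairs")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "simulated", sim)


def rmsr(pairs: PairedSeries) -> float:
    """Root mean squared residuals."""
    return float(np.sqrt(np.mean((pairs.simulated - pairs.observed) ** 2)))


def dev(pairs: PairedSeries) -> float:
    """Mean deviation (simulated minus observed)."""
    return float(np.mean(pairs.simulated - pairs.observed))


def nash_sutcliffe(pairs: PairedSeries) -> float:
    """Model efficiency ME = 1 - sum((obs-sim)^2) / sum((obs-mean(obs))^2)."""
    obs, sim = pairs.observed, pairs.simulated
    denom = float(np.sum((obs - obs.mean()) ** 2))
    if denom == 0.0:
        raise DomainError("ME undefined: observed values have zero variance")
    return float(1.0 - np.sum((obs - sim) ** 2) / denom)


def r2(pairs: PairedSeries) -> float:
    """Squared Pearson correlation between observed and simulated."""
    obs, sim = pairs.observed, pairs.simulated
    so = float(np.sum((obs - obs.mean()) ** 2))
    ss = float(np.sum((sim - sim.mean()) ** 2))
    if so == 0.0 or ss == 0.0:
        raise DomainError("R2 undefined: a series has zero variance")
    r = float(np.corrcoef(obs, sim)[0, 1])
    return r * r


def evaluate_all(pairs: PairedSeries) -> dict[str, float]:
    return {"RMSR": rmsr(pairs), "Dev": dev(pairs),
            "ME": nash_sutcliffe(pairs), "R2": r2(pairs)}


def holdout_split(dataset: Mapping, assignment: Mapping[str, str]) -> tuple[dict, dict]:
    """Split a keyed dataset into calibration and validation subsets.

    ``assignment`` maps each key to "calibration" or "validation"; the
    split must be exhaustive and non-overlapping by construction of the
    mapping.  Returns (calibration, validation).
    """
    cal, val = {}, {}
    for key, value in dataset.items():
        if key not in assignment:
            raise DomainError(f"no calibration/validation assignment for '{key}'")
        target = assignment[key]
        if target == "calibration":
            cal[key] = value
        elif target == "validation":
            val[key] = value
        else:
            raise DomainError(f"assignment for '{key}' must be calibration|validation, got {target}")
    if not val or not cal:
        raise DomainError("both subsets must be non-empty")
    return cal, val


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    baseline_output: float
    output_plus: float
    output_minus: float
    sensitivity_plus: float
    sensitivity_minus: float


def _get_path(config, path: Sequence[str]):
    node = config
    for key in path:
        node = node[key] if isinstance(node, Mapping) else getattr(node, key)
    return node


def _set_path(config, path: Sequence[str], value):
    node = config
    for key in path[:-1]:
        node = node[key] if isinstance(node, Mapping) else getattr(node, key)
    if isinstance(node, Mapping):
        node[path[-1]] = value
    else:
        setattr(node, path[-1], value)


def mono_factor_sensitivity(model: Callable, parameter_path: str, baseline_config,
                            perturbation: float = 0.10) -> SensitivityResult:
    """Relative sensitivity of a scalar model output to one parameter.

    The parameter (dotted path into a nested dict/attribute config) is
    increased and decreased by ``perturbation`` (default 10 %) with all
    other parameters untouched; the relative sensitivity per direction is
    (dY/Y0) / (dX/X0).
    """
    path = parameter_path.split(".")
    x0 = float(_get_path(baseline_config, path))
    if x0 == 0.0:
        raise DomainError(f"parameter {parameter_path} is zero; relative sensitivity undefined")
    y0 = float(model(baseline_config))
    if y0 == 0.0:
        raise DomainError("baseline output is zero; relative sensitivity undefined")

    outputs = {}
    for sign in (+1.0, -1.0):
        cfg = copy.deepcopy(baseline_config)
        _set_path(cfg, path, x0 * (1.0 + sign * perturbation))
        outputs[sign] = float(model(cfg))
    s_plus = ((outputs[+1.0] - y0) / y0) / perturbation
    s_minus = ((y0 - outputs[-1.0]) / y0) / perturbation
    return SensitivityResult(
        parameter=parameter_path, baseline_output=y0,
        output_plus=outputs[+1.0], output_minus=outputs[-1.0],
        sensitivity_plus=s_plus, sensitivity_minus=s_minus,
    )


def ols_slope(years: Sequence[float], values: Sequence[float]) -> float:
    """Ordinary least squares slope of values against years."""
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DomainError("need at least three years for a trend slope")
    xd = x - x.mean()
    return float(np.sum(xd * (y - y.mean())) / np.sum(xd ** 2))


def scenario_ladder(run_scenario: Callable[[float, bool], Sequence[tuple[float, float]]],
                    n_rates: Sequence[float],
                    straw_options: Sequence[bool] = (True, False)) -> list[dict]:
    """Residual soil mineral N trend per (N rate, straw handling) scenario.

    ``run_scenario(rate, straw_incorporated)`` must return a sequence of
    (year, post-harvest 0-2 m soil mineral N in kg N/ha) samples; an OLS
    slope (kg N/ha/y) is fitted per scenario.
    """
    if any(r < 0 for r in n_rates):
        raise DomainError("N rates must be >= 0")
    table = []
    for straw in straw_options:
        for rate in n_rates:
            samples = list(run_scenario(rate, straw))
            if len(samples) < 3:
                raise DomainError("fewer than three years of post-harvest samples")
            years = [s[0] for s in samples]
            values = [s[1] for s in samples]
            table.append({"n_rate": float(rate), "straw_incorporated": bool(straw),
                          "slope_kg_n_ha_y": ols_slope(years, values),
                          "n_years": len(samples)})
    return table
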