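"""Field-scale estimators: water-balance drainage and concentration-based
nitrate leaching.

Drainage past a reference depth z over a balance interval is estimated
from the water balance D_z = P + I + dSW_z - AET, assuming no surface
runoff and negligible upward water movement; nitrate leaching is the sum
over intervals of drainage times the measured nitrate concentration,
N_leach = sum_i D_{z,i} c_i, with mm x mg N/L converting to kg N/ha by
the factor 0.01.

The storage-change term dSW is entered with the sign convention of the
balance itself: storage at interval start minus storage at the end, so
that depletion adds to drainage.  Negative drainage estimates (upward
flow, violating the assumption) are reported as-is with a warning flag
by the drainage estimator and clamped to zero inside the leaching sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class BalanceInterval:
    """One balance interval: precipitation, irrigation, storage change and
    actual evapotranspiration, all in mm; z is the reference depth (cm)."""

    label: str
    P: float
    I: float
    dSW: float
    AET: float
    z: float = 200.0

    def __post_init__(self):
        for name in ("P", "I", "AET"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ConcentrationSample:
    """Measured nitrate concentration (mg NO3-N/L) for interval i."""

    interval: int
    c: float

    def __post_init__(self):
        if self.c < 0:
            raise DomainError(f"concentration must be >= 0, got {self.c}")


@dataclass(frozen=True)
class DrainageEstimate:
    drainage_mm: float
    upward_flow_flag: bool


def drainage_water_balance(interval: BalanceInterval) -> DrainageEstimate:
    """D = P + I + dSW - AET (mm); negative values are flagged, not hidden."""
    d = interval.P + interval.I + interval.dSW - interval.AET
    return DrainageEstimate(drainage_mm=d, upward_flow_flag=d < 0.0)


#: mm x (mg N/L) -> kg N/ha
MM_MGL_TO_KG_HA = 0.01


def nitrate_leaching_estimate(drainage: Sequence[float],
                              conc: Sequence[float]) -> tuple[float, bool]:
    """N_leach = sum_i max(D_i, 0) c_i x 0.01 (kg N/ha).

    Negative drainage intervals contribute nothing (consistent with the
    negligible-upward-flow assumption); the second return value flags
    whether any interval was clamped.
    """
    d = np.asarray(drainage, dtype=float)
    c = np.asarray(conc, dtype=float)
    if d.shape != c.shape:
        raise DomainError(f"drainage and concentration lengths differ: {d.shape} vs {c.shape}")
    if np.any(c < 0):
        raise DomainError("concentrations must be >= 0")
    clamped = bool(np.any(d < 0))
    total = float(np.sum(np.maximum(d, 0.0) * c) * MM_MGL_TO_KG_HA)
    return total, clamped
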