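"""Typed parameter containers and config I/O for the packaged NCP set.

All constants of the calibrated North China Plain parameterisation (soil
hydraulics and organic-matter profile, crop parameters for "Pioneer maize"
and "Winter wheat", turnover settings, atmospheric deposition and the
ammonia-volatilisation scheme) are shipped as human-readable YAML files
under :mod:`leachsim.data` and surface here as validated dataclasses.

Each value carries a provenance tag (measured / calibrated / literature /
default) retained from the config files so that a full
:class:`ParameterSet` can be exported to JSON as a provenance record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from ._util import piecewise_linear
from .errors import ConfigurationError, DomainError, ValidationError

_POOLS = ("SOM1", "SOM2", "SOM3", "SMB1", "SMB2", "AOM1", "AOM2")


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ConfigurationError(f"missing mandatory field '{key}' in {context}")
    return mapping[key]


@dataclass(frozen=True)
class SoilHorizon:
    """One soil horizon: van Genuchten-Mualem hydraulics plus the
    organic-matter description used to initialise the turnover pools.

    Units: depths cm, Ksat cm/h, water contents volume fraction, alpha
    1/cm, humus mass %, clay mass fraction.  ``l`` is the Mualem
    tortuosity exponent and may be negative.
    """

    depth_top: float
    depth_bottom: float
    Ksat: float
    theta_sat: float
    theta_res: float
    alpha: float
    n: float
    l: float
    humus: float
    SOM_fractions: tuple[float, float, float]
    C_per_N: float
    clay: float

    def __post_init__(self):
        object.__setattr__(self, "SOM_fractions", tuple(float(f) for f in self.SOM_fractions))
        if not self.depth_top < self.depth_bottom:
            raise ValidationError(
                f"horizon depth_top {self.depth_top} must be above depth_bottom {self.depth_bottom}"
            )
        if not (0.0 <= self.theta_res < self.theta_sat <= 1.0):
            raise ValidationError(
                f"require 0 <= theta_res < theta_sat <= 1, got ({self.theta_res}, {self.theta_sat})"
            )
        if self.n <= 1.0:
            raise ValidationError(f"van Genuchten n must exceed 1, got {self.n}")
        if self.alpha <= 0.0:
            raise ValidationError(f"van Genuchten alpha must be positive, got {self.alpha}")
        if self.Ksat <= 0.0:
            raise ValidationError(f"Ksat must be positive, got {self.Ksat}")
        if len(self.SOM_fractions) != 3 or any(f < 0 for f in self.SOM_fractions):
            raise ValidationError(f"SOM_fractions must be three non-negative values, got {self.SOM_fractions}")
        if abs(sum(self.SOM_fractions) - 1.0) > 1e-9:
            raise ValidationError(
                f"SOM_fractions must sum to 1, got {self.SOM_fractions} (sum {sum(self.SOM_fractions)})"
            )


@dataclass(frozen=True)
class CropParameters:
    """Crop constants: phenology, photosynthesis, partitioning, roots, N.

    The calibrated Table-style values are mandatory; quantities the field
    parameterisation does not pin down (DSRate2, temperature modifiers,
    partitioning tables, target N concentrations) ship as package
    defaults in the config's ``defaults`` section.
    """

    name: str
    EmrTSum: float            # deg C d soil temperature sum to emergence
    DSRate1: float            # 1/d development rate, DS 0 -> 1
    DSRate2: float            # 1/d development rate, DS 1 -> 2
    Fm: float                 # g CO2 / m2 leaf / h
    QEff: float               # (g CO2 m-2 h-1) / (W m-2)
    SpLAI: float              # (m2/m2) / (g DM/m2)
    E_Leaf: float
    E_Stem: float
    E_SOrg: float
    r_Leaf: float             # 1/d maintenance coefficients
    r_Stem: float
    r_SOrg: float
    MaxPen: float             # cm
    MxNH4Up: float            # g N / cm root / h
    MxNO3Up: float
    SpRtLength: float         # m / g
    C_per_N_slow_residue: float
    pet_factor_by_DS: tuple
    LeafAIMod_by_DS: tuple
    partitioning_by_DS: tuple     # rows (DS, root, leaf, stem, sorg)
    n_conc_by_DS: Mapping[str, tuple]
    dev_temp_base: float
    dev_temp_plateau: float
    photo_temp_knots: tuple
    photo_ds_knots: tuple
    extinction_coefficient: float = 0.6
    par_fraction: float = 0.48     # photosynthetically active share of global radiation
    q10_maintenance: float = 2.0
    maintenance_t_ref: float = 20.0
    root_penetration_rate: float = 1.5
    root_depth_fraction: float = 0.95
    aom_partition_slow: float = 0.5
    dm_carbon_fraction: float = 0.45

    def __post_init__(self):
        for attr in ("EmrTSum", "DSRate1", "DSRate2", "Fm", "QEff", "SpLAI",
                     "r_Leaf", "r_Stem", "r_SOrg", "MaxPen", "MxNH4Up",
                     "MxNO3Up", "SpRtLength"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{self.name}: {attr} must be >= 0, got {getattr(self, attr)}")
        for attr in ("E_Leaf", "E_Stem", "E_SOrg"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.name}: conversion efficiency {attr} must be in [0,1], got {v}")
        for tbl in ("pet_factor_by_DS", "LeafAIMod_by_DS", "partitioning_by_DS",
                    "photo_temp_knots", "photo_ds_knots"):
            object.__setattr__(self, tbl, tuple(tuple(float(v) for v in row) for row in getattr(self, tbl)))
        object.__setattr__(self, "n_conc_by_DS", {
            k: tuple(tuple(float(v) for v in row) for row in rows)
            for k, rows in self.n_conc_by_DS.items()
        })
        for _, mod in self.LeafAIMod_by_DS:
            if mod <= 0:
                raise ValidationError(f"{self.name}: LeafAIMod values must be > 0, got {mod}")
        for row in self.partitioning_by_DS:
            if len(row) != 5:
                raise ValidationError(f"{self.name}: partitioning rows are (DS, root, leaf, stem, sorg)")
            if any(f < 0 for f in row[1:]):
                raise ValidationError(f"{self.name}: negative partitioning fraction in {row}")
            if abs(sum(row[1:]) - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.name}: partitioning fractions at DS {row[0]} sum to {sum(row[1:])}, not 1"
                )

    def partition_at(self, ds: float) -> dict[str, float]:
        """DS-interpolated allocation fractions, renormalised to sum 1."""
        rows = self.partitioning_by_DS
        organs = ("root", "leaf", "stem", "sorg")
        raw = {
            org: piecewise_linear(ds, [(r[0], r[i + 1]) for r in rows])
            for i, org in enumerate(organs)
        }
        total = sum(raw.values())
        return {k: v / total for k, v in raw.items()}


@dataclass(frozen=True)
class TurnoverParameters:
    """Organic-matter pool kinetics, abiotic rate modifiers and the
    transport/denitrification settings of the nitrogen module."""

    pool_rate_coefficients: Mapping[str, float]   # 1/h
    substrate_efficiencies: Mapping[str, float]
    partition_fractions: Mapping[str, Mapping[str, float]]
    smb_C_per_N: float
    water_factor_table: tuple                     # (relative saturation, factor)
    MaxRootingDepth: float                        # cm
    annual_C_input_total: float                   # kg C / ha / y (warm-up)
    annual_C_input_root: float
    nonroot_input_depth: float                    # cm
    maintenance_rates: Mapping[str, float] = field(
        default_factory=lambda: {"SMB1": 7.5e-5, "SMB2": 4.17e-4})  # 1/h
    smb_init_fraction: float = 0.02
    smb_init_split: tuple[float, float] = (0.7, 0.3)
    humus_carbon_fraction: float = 0.587
    clay_factor_slope: float = 1.0
    clay_factor_min: float = 0.25
    turnover_t_ref: float = 10.0
    turnover_q10: float = 2.0
    moisture_factor_knots: tuple = ((0.0, 0.0), (0.2, 0.2), (0.6, 1.0), (0.8, 1.0), (1.0, 0.5))
    nitrification_rate: float = 0.1               # 1/d
    denitrification_rate: float = 0.1             # 1/d
    n2o_fraction_of_nitrification: float = 0.02
    dispersivity: float = 5.0                     # cm
    molecular_diffusion: float = 0.05             # cm2/d
    nh4_retardation: float = 3.0
    bulk_density: float = 1.4                     # g/cm3

    def __post_init__(self):
        object.__setattr__(self, "maintenance_rates", dict(self.maintenance_rates))
        object.__setattr__(self, "pool_rate_coefficients", dict(self.pool_rate_coefficients))
        object.__setattr__(self, "substrate_efficiencies", dict(self.substrate_efficiencies))
        object.__setattr__(self, "partition_fractions",
                           {k: dict(v) for k, v in self.partition_fractions.items()})
        object.__setattr__(self, "water_factor_table",
                           tuple(tuple(float(v) for v in row) for row in self.water_factor_table))
        object.__setattr__(self, "moisture_factor_knots",
                           tuple(tuple(float(v) for v in row) for row in self.moisture_factor_knots))
        object.__setattr__(self, "smb_init_split", tuple(float(v) for v in self.smb_init_split))
        for pool, k in self.pool_rate_coefficients.items():
            if pool not in _POOLS:
                raise ValidationError(f"unknown pool '{pool}' in rate coefficients")
            if k < 0:
                raise ValidationError(f"rate coefficient for {pool} must be >= 0, got {k}")
        for pool, e in self.substrate_efficiencies.items():
            if not 0.0 < e <= 1.0:
                raise ValidationError(f"substrate efficiency for {pool} must be in (0,1], got {e}")
        for donor, recv in self.partition_fractions.items():
            s = sum(recv.values())
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"partition fractions for {donor} sum to {s}, not 1")
        for _, f in self.water_factor_table:
            if f < 0:
                raise ValidationError(f"water_factor values must be >= 0, got {f}")


@dataclass(frozen=True)
class VolatilisationScheme:
    """Ammonia loss fraction as a function of the N dressing size."""

    knots: tuple

    def __post_init__(self):
        object.__setattr__(self, "knots", tuple(tuple(float(v) for v in row) for row in self.knots))
        amounts = [a for a, _ in self.knots]
        fracs = [f for _, f in self.knots]
        if any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise ValidationError(f"volatilisation amounts must strictly increase, got {amounts}")
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValidationError(f"volatilisation fractions must lie in [0,1], got {fracs}")
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ValidationError(f"volatilisation fractions must be non-decreasing, got {fracs}")


@dataclass(frozen=True)
class DepositionConfig:
    """Atmospheric N deposition: wet as ppm (mg N/L rain), dry as kg N/ha/y."""

    wet_nh4: float
    dry_nh4: float
    wet_no3: float
    dry_no3: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"deposition {f.name} must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Everything needed to parameterise one field's simulations."""

    name: str
    field_id: str
    soil: tuple[SoilHorizon, ...]
    crops: Mapping[str, CropParameters]
    turnover: TurnoverParameters
    deposition: DepositionConfig
    volatilisation: VolatilisationScheme
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "soil", tuple(self.soil))
        object.__setattr__(self, "crops", dict(self.crops))
        object.__setattr__(self, "provenance", dict(self.provenance))


def volatilisation_fraction(applied_n: float, scheme: VolatilisationScheme) -> float:
    """Fraction of an N dressing lost to ammonia volatilisation.

    Exact at the tabulated knots, piecewise linear between them, linear
    from (0, 0) below the first knot, constant above the last.
    """
    if applied_n < 0:
        raise DomainError(f"applied N must be >= 0, got {applied_n}")
    return piecewise_linear(applied_n, scheme.knots, left="zero", right="flat")


# ---------------------------------------------------------------------------
# config I/O

def _build_crop(doc: Mapping, context: str) -> CropParameters:
    doc = dict(doc)
    defaults = dict(doc.pop("defaults", {}))
    doc.pop("provenance", None)
    merged = {**defaults, **doc}
    kwargs = {}
    for f in dataclasses.fields(CropParameters):
        if f.name in merged:
            kwargs[f.name] = merged[f.name]
        elif f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING:
            raise ConfigurationError(f"missing mandatory field '{f.name}' in {context}")
    return CropParameters(**kwargs)


def _build_turnover(doc: Mapping, field_id: str, context: str) -> TurnoverParameters:
    doc = dict(doc)
    defaults = dict(doc.pop("defaults", {}))
    doc.pop("provenance", None)
    merged = {**defaults, **doc}
    for key in ("annual_C_input_total", "annual_C_input_root"):
        val = _require(merged, key, context)
        if isinstance(val, Mapping):
            if field_id not in val:
                raise ConfigurationError(f"no entry for field '{field_id}' under {key} in {context}")
            merged[key] = float(val[field_id])
    merged["water_factor_table"] = merged.pop("water_factor")
    kwargs = {}
    for f in dataclasses.fields(TurnoverParameters):
        if f.name in merged:
            kwargs[f.name] = merged[f.name]
        elif f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING:
            raise ConfigurationError(f"missing mandatory field '{f.name}' in {context}")
    return TurnoverParameters(**kwargs)


def _load_section(entry, base: Path | None, opener):
    """A section is either an inline mapping or a sibling-file reference."""
    if isinstance(entry, str):
        with opener(entry) as fh:
            return yaml.safe_load(fh)
    if isinstance(entry, Mapping):
        return entry
    raise ConfigurationError(f"config section must be a mapping or filename, got {type(entry).__name__}")


def _horizon_fields():
    return [f.name for f in dataclasses.fields(SoilHorizon)]


def _parameter_set_from_doc(doc: Mapping, opener, context: str) -> ParameterSet:
    name = _require(doc, "name", context)
    field_id = str(doc.get("field", "A"))
    provenance: dict[str, str] = {}

    soil_doc = _load_section(_require(doc, "soil", context), None, opener)
    horizons = []
    for hdoc in _require(soil_doc, "horizons", context):
        kwargs = {}
        for fname in _horizon_fields():
            kwargs[fname] = _require(hdoc, fname, f"soil horizon of {context}")
        horizons.append(SoilHorizon(**kwargs))
    for k, v in soil_doc.get("provenance", {}).items():
        provenance[f"soil.{k}"] = v

    crops = {}
    for cname, centry in _require(doc, "crops", context).items():
        cdoc = _load_section(centry, None, opener)
        crops[cname] = _build_crop(cdoc, f"crop '{cname}' of {context}")
        for k, v in cdoc.get("provenance", {}).items():
            provenance[f"crops.{cname}.{k}"] = v
        for k in cdoc.get("defaults", {}):
            provenance.setdefault(f"crops.{cname}.{k}", "default")

    tdoc = _load_section(_require(doc, "turnover", context), None, opener)
    turnover = _build_turnover(tdoc, field_id, f"turnover of {context}")
    for k, v in tdoc.get("provenance", {}).items():
        provenance[f"turnover.{k}"] = v
    for k in tdoc.get("defaults", {}):
        provenance.setdefault(f"turnover.{k}", "default")

    ddoc = _load_section(_require(doc, "deposition", context), None, opener)
    deposition = DepositionConfig(**{
        f.name: _require(ddoc, f.name, f"deposition of {context}")
        for f in dataclasses.fields(DepositionConfig)
    })
    for k, v in ddoc.get("provenance", {}).items():
        provenance[f"deposition.{k}"] = v

    vdoc = _load_section(_require(doc, "volatilisation", context), None, opener)
    volat = VolatilisationScheme(knots=_require(vdoc, "knots", context))
    for k, v in vdoc.get("provenance", {}).items():
        provenance[f"volatilisation.{k}"] = v

    return ParameterSet(
        name=name, field_id=field_id, soil=tuple(horizons), crops=crops,
        turnover=turnover, deposition=deposition, volatilisation=volat,
        provenance=provenance,
    )


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load a parameter-set config file (sections inline or as sibling files)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"parameter file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def opener(rel):
        target = path.parent / rel
        if not target.exists():
            raise ConfigurationError(f"referenced config file not found: {target}")
        return open(target)

    return _parameter_set_from_doc(doc, opener, str(path))


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    """Plain-data (JSON/YAML-ready) view of a full parameter set."""
    return _as_plain(ps)


def write_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as one combined, inline YAML file."""
    doc = {
        "name": ps.name,
        "field": ps.field_id,
        "soil": {
            "horizons": [_as_plain(h) for h in ps.soil],
            "provenance": {k[len("soil."):]: v for k, v in ps.provenance.items()
                           if k.startswith("soil.")},
        },
        "crops": {},
        "turnover": {**_as_plain(ps.turnover), "water_factor": _as_plain(ps.turnover.water_factor_table)},
        "deposition": _as_plain(ps.deposition),
        "volatilisation": {"knots": _as_plain(ps.volatilisation.knots)},
    }
    doc["turnover"].pop("water_factor_table")

    def _section_prov(prefix):
        return {k[len(prefix):]: v for k, v in ps.provenance.items() if k.startswith(prefix)}

    doc["turnover"]["provenance"] = _section_prov("turnover.")
    doc["deposition"]["provenance"] = _section_prov("deposition.")
    doc["volatilisation"]["provenance"] = _section_prov("volatilisation.")
    for cname, cp in ps.crops.items():
        doc["crops"][cname] = _as_plain(cp)
        doc["crops"][cname]["provenance"] = _section_prov(f"crops.{cname}.")
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def export_json(ps: ParameterSet, path: str | Path) -> None:
    """JSON export of the full set with provenance, for run manifests."""
    payload = parameter_set_to_dict(ps)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("leachsim").joinpath("data", name)))


def default_ncp_parameters(field: str = "A") -> ParameterSet:
    """The packaged, calibrated North China Plain parameter set."""
    field = field.upper()
    if field not in ("A", "B"):
        raise ConfigurationError(f"field must be 'A' or 'B', got {field!r}")
    return load_parameter_set(_data_path(f"ncp_field_{field.lower()}.yaml"))


def validate_parameter_file(path: str | Path) -> list[str]:
    """Validate a config file; returns a list of problems (empty if OK)."""
    try:
        load_parameter_set(path)
    except (ConfigurationError, ValidationError) as exc:
        return [str(exc)]
    return []
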