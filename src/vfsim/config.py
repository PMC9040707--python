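"""Run configuration: schema, validation, unit handling, serialization.

Configuration files are YAML with nested sections mirroring the parameter
dataclasses.  A top-level ``units`` header declares the unit system of the
file: ``SI`` (m, s, Pa) or ``cgs_phon`` (cm, cs, kPa — the customary units
of the phonation literature).  All internal computation is SI; conversion
happens once at load time.  Tissue density is always kg/m^3.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields as dc_fields

import yaml

from .coupling import CouplingConfig
from .errors import ConfigError, VfsimError
from .geometry import GeometryParams, sample_preset
from .solid import MaterialParams

CONFIG_VERSION = "1"

_LENGTH = {
    "geometry": {"duct_length_sub", "duct_length_sup", "duct_width",
                 "duct_depth", "fold_thickness", "glottal_half_gap",
                 "cover_thickness", "false_fold_gap", "ventricle_length",
                 "mesh_resolution"},
}
_TIME = {"coupling": {"dt", "t_end", "ramp_time"}}
_TIME_SEQ = {"coupling": {"snapshot_times"}}
_PRESSURE = {"material": {"E_body", "E_cover"},
             "top": {"inlet_pressure", "outlet_pressure"}}

# cgs_phon -> SI multipliers
_CM, _CS, _KPA = 1e-2, 1e-2, 1e3


@dataclass
class RunConfig:
    """Fully resolved simulation configuration (SI units internally)."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    material: MaterialParams = field(default_factory=MaterialParams)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    preset_id: int | None = None
    inlet_pressure: float = 720.0   # Pa
    outlet_pressure: float = 0.0    # Pa
    unit_system: str = "SI"
    output_dir: str = "out"
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        try:
            self.geometry.validate()
            self.material.validate()
            self.coupling.validate()
        except VfsimError as exc:
            raise ConfigError(str(exc)) from exc
        if self.preset_id is not None and self.preset_id not in range(1, 6):
            raise ConfigError(f"preset_id must be 1..5, got {self.preset_id}")

    def resolved(self) -> "RunConfig":
        """Apply the sample preset (driving pressure, moduli, inclination)."""
        if self.preset_id is None:
            return self
        p = sample_preset(self.preset_id)
        out = RunConfig(**{**asdict_shallow(self)})
        out.inlet_pressure = p.inlet_pressure
        out.material = MaterialParams(**{**asdict(self.material),
                                         "E_body": p.E_body,
                                         "E_cover": p.E_cover})
        out.geometry = GeometryParams(**{**asdict(self.geometry),
                                         "inclination_theta": p.theta})
        return out

    def hash(self) -> str:
        """Provenance hash of the resolved SI configuration."""
        blob = json.dumps(to_dict(self.resolved()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_shallow(cfg: RunConfig) -> dict:
    return {f.name: getattr(cfg, f.name) for f in dc_fields(cfg)}


def to_dict(cfg: RunConfig) -> dict:
    d = asdict_shallow(cfg)
    d["geometry"] = asdict(cfg.geometry)
    d["material"] = asdict(cfg.material)
    d["coupling"] = asdict(cfg.coupling)
    d["coupling"]["snapshot_times"] = list(cfg.coupling.snapshot_times)
    d["units"] = "SI"
    d.pop("unit_system")
    d["version"] = CONFIG_VERSION
    return d


def _build_section(cls, data: dict, name: str):
    valid = {f.name for f in dc_fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{name}': {sorted(unknown)}")
    return cls(**data)


def _convert(data: dict, section: str, factor_map) -> dict:
    out = dict(data)
    for key, factor in factor_map.items():
        if key in out and out[key] is not None:
            out[key] = out[key] * factor
    return out


def from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    raw.pop("version", None)
    units = raw.pop("units", "SI")
    if units not in ("SI", "cgs_phon"):
        raise ConfigError(f"unknown unit system {units!r} "
                          "(expected 'SI' or 'cgs_phon')")
    cgs = units == "cgs_phon"

    geo = dict(raw.pop("geometry", {}))
    mat = dict(raw.pop("material", {}))
    cpl = dict(raw.pop("coupling", {}))
    if cgs:
        geo = _convert(geo, "geometry",
                       {k: _CM for k in _LENGTH["geometry"]})
        mat = _convert(mat, "material",
                       {k: _KPA for k in _PRESSURE["material"]})
        cpl = _convert(cpl, "coupling", {k: _CS for k in _TIME["coupling"]})
        if "snapshot_times" in cpl:
            cpl["snapshot_times"] = [t * _CS for t in cpl["snapshot_times"]]
        for k in _PRESSURE["top"]:
            if k in raw and raw[k] is not None:
                raw[k] = raw[k] * _KPA
    if "snapshot_times" in cpl:
        cpl["snapshot_times"] = tuple(cpl["snapshot_times"])

    top_fields = {f.name for f in dc_fields(RunConfig)} \
        - {"geometry", "material", "coupling", "unit_system"}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    cfg = RunConfig(
        geometry=_build_section(GeometryParams, geo, "geometry"),
        material=_build_section(MaterialParams, mat, "material"),
        coupling=_build_section(CouplingConfig, cpl, "coupling"),
        unit_system="SI", **raw)
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    """Load, unit-normalize and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    """Serialize in SI units; save -> load is the identity."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)
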