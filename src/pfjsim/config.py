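"""Validated run configuration (YAML/JSON) with paper-faithful defaults."""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .contact import ContactParams
from .geometry import JointParams
from .ligaments import (ALLOWED_PAIRS, calibrate_area, load_length_profiles,
                        load_tissue_table)


class ConfigError(ValueError):
    """Configuration parse or schema failure."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    sulcus_angle: float = 138.0
    groove_depth: float = 5.5
    condyle_radius: float = 32.0
    patella_width: float = 42.0
    patella_height: float = 32.0
    wiberg_ratio: float = 0.4
    cartilage_thickness_femur: float = 3.0
    cartilage_thickness_patella: float = 3.0
    mesh_resolution: int = 5000


class TissueConfig(_Strict):
    #: stiffness overrides by tissue name (see data/material_properties.csv)
    stiffness: dict = Field(default_factory=dict)
    #: shared ligament cross-section override (mm^2); default: calibrated
    cross_section: float | None = None


class ContactConfig(_Strict):
    E_cartilage: float = 10.0
    poisson: float = 0.45
    total_thickness: float = 6.0
    friction_mu: float = 0.02
    approach_depth: float = 0.3
    regularization_velocity: float = 0.01


class StudyConfig(_Strict):
    angles: list = Field(default_factory=lambda: [0.0, 30.0, 60.0, 90.0, 120.0])
    #: (technique, graft) pairs; default: the full 7-configuration study
    cases: list = Field(default_factory=lambda: [
        ["intact", "native"],
        ["static_anatomic", "semitendinosus"],
        ["static_anatomic", "gracilis"],
        ["amt_pulley", "semitendinosus"],
        ["amt_pulley", "gracilis"],
        ["mqtfl", "semitendinosus"],
        ["mqtfl", "tibialis_posterior_allograft"],
    ])
    n_steps: int = 10
    comparison_band: float = 0.2


class CohortConfig(_Strict):
    n: int = 24
    cv: float = 0.05
    seed: int = 0


class OutputConfig(_Strict):
    directory: str = "results"
    export_vtk: bool = False
    export_csv: bool = True


class Config(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    tissues: TissueConfig = Field(default_factory=TissueConfig)
    contact: ContactConfig = Field(default_factory=ContactConfig)
    study: StudyConfig = Field(default_factory=StudyConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    def joint_params(self) -> JointParams:
        return JointParams(**self.geometry.model_dump())

    def contact_params(self) -> ContactParams:
        return ContactParams(**self.contact.model_dump())

    def tissue_table(self):
        table = load_tissue_table()
        for name, K in self.tissues.stiffness.items():
            if name not in table.index:
                raise ConfigError(
                    f"unknown tissue {name!r}; known: {list(table.index)}")
            table.loc[name, "stiffness_K"] = float(K)
        return table

    def length_profiles(self):
        return load_length_profiles()

    def cross_section(self) -> float:
        if self.tissues.cross_section is not None:
            return float(self.tissues.cross_section)
        return calibrate_area()

    def validate_cases(self) -> None:
        for tech, graft in self.study.cases:
            if tech not in ALLOWED_PAIRS or graft not in ALLOWED_PAIRS[tech]:
                raise ConfigError(f"case ({tech}, {graft}) is not a tested pair")

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _suggest(err: ValidationError) -> str:
    msgs = []
    for e in err.errors():
        if e["type"] == "extra_forbidden":
            loc = e["loc"]
            bad = str(loc[-1])
            parent = Config
            for part in loc[:-1]:
                fld = parent.model_fields.get(str(part))
                if fld is not None and isinstance(fld.annotation, type) and \
                        issubclass(fld.annotation, BaseModel):
                    parent = fld.annotation
            close = difflib.get_close_matches(bad, list(parent.model_fields), n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            msgs.append(f"unknown key {'.'.join(map(str, loc))!r}{hint}")
        else:
            msgs.append(f"{'.'.join(map(str, e['loc']))}: {e['msg']}")
    return "; ".join(msgs)


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML/JSON config; empty or missing -> defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        cfg = Config(**data)
    except ValidationError as exc:
        raise ConfigError(_suggest(exc)) from exc
    cfg.validate_cases()
    return cfg
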