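"""Config schema and tabular output writers.

The configuration is a single human-readable YAML file with sections
``physiology`` (including nested ``energy``), ``conditions``, ``policy`` and
``sweep``.  Unknown keys, unit mismatches and out-of-range values are
rejected with the offending key path in the message; omitted keys fall back
to the shipped defaults (the calibrated eps_m among them) and the applied
defaults are logged.

Sweep tables are written either as CSV with a documented header plus a units
row, or as JSON with full parameter provenance; the JSON path round-trips
bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import constants as C
from .sweeps import SWEEP_UNITS
from .types import (
    AmbientEnvironment,
    CellPhysiology,
    CultureConditions,
    ElementalFormula,
    EnergyParameters,
    RespirationPolicy,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "write_table_csv",
    "read_table_csv",
    "write_table_json",
    "read_table_json",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Schema violation in a configuration file, with key-path messages."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class FormulaConfig(_Model):
    c: int = Field(ge=0)
    h: int = Field(ge=0)
    o: int = Field(ge=0)
    n: int = Field(default=0, ge=0)


class EnergyConfig(_Model):
    eps_nh4: float = Field(default=C.EPS_NH4, gt=0, le=1)
    eps_n2: float = Field(default=C.EPS_N2, gt=0, le=1)
    atp_per_electron_pair_to_o2: float = Field(default=C.ATP_PER_ELECTRON_PAIR_TO_O2, gt=0)
    atp_per_n2_fixed: float = Field(default=C.ATP_PER_N2_FIXED, ge=0)
    electrons_per_n2_fixed: float = Field(default=C.ELECTRONS_PER_N2_FIXED, ge=0)
    atp_per_biomass_c: float = Field(default=C.ATP_PER_BIOMASS_C, gt=0)


class PhysiologyConfig(_Model):
    radius_m: float = Field(default=C.CELL_RADIUS, gt=0)
    eps_m: float = Field(default=C.EPS_M, gt=0, le=1)
    diffusivity_o2_m2_h: float = Field(default=C.DIFFUSIVITY_O2, gt=0)
    diffusivity_sucrose_m2_h: float = Field(default=C.DIFFUSIVITY_SUCROSE, gt=0)
    diffusivity_nh4_m2_h: float = Field(default=C.DIFFUSIVITY_NH4, gt=0)
    diffusivity_n2_m2_h: float = Field(default=C.DIFFUSIVITY_N2, gt=0)
    carbon_per_cell_mol: float = Field(default=C.CARBON_PER_CELL, gt=0)
    protein_mass_fraction: float = Field(default=C.PROTEIN_MASS_FRACTION, gt=0, lt=1)
    biomass_formula: FormulaConfig = FormulaConfig(c=5, h=7, o=2, n=1)
    energy: EnergyConfig = EnergyConfig()


class ConditionsConfig(_Model):
    dilution_rate_per_h: float = Field(default=C.DILUTION_RATE, gt=0)
    sucrose_in_mM: float = Field(default=0.0, ge=0)
    ammonium_in_mM: float = Field(default=C.AMMONIUM_IN, ge=0)
    o2_fraction: float = Field(default=0.05, ge=0)
    o2_saturation_mM: float = Field(default=C.O2_SATURATION, gt=0)
    n2_concentration_mM: float = Field(default=C.N2_CONCENTRATION, ge=0)


class SweepConfig(_Model):
    sucrose_in_mM: list[float] = []
    ammonium_in_mM: list[float] = []
    o2_fraction: list[float] = []


class RunConfig(_Model):
    physiology: PhysiologyConfig = PhysiologyConfig()
    conditions: ConditionsConfig = ConditionsConfig()
    policy: Literal["sim1", "sim2"] = "sim1"
    sweep: SweepConfig = SweepConfig()

    def to_physiology(self) -> CellPhysiology:
        p, e = self.physiology, self.physiology.energy
        return CellPhysiology(
            radius=p.radius_m,
            eps_m=p.eps_m,
            diffusivity_o2=p.diffusivity_o2_m2_h,
            diffusivity_sucrose=p.diffusivity_sucrose_m2_h,
            diffusivity_nh4=p.diffusivity_nh4_m2_h,
            diffusivity_n2=p.diffusivity_n2_m2_h,
            carbon_per_cell=p.carbon_per_cell_mol,
            protein_mass_fraction=p.protein_mass_fraction,
            biomass_formula=ElementalFormula(
                c=p.biomass_formula.c, h=p.biomass_formula.h,
                o=p.biomass_formula.o, n=p.biomass_formula.n,
            ),
            energy=EnergyParameters(
                eps_nh4=e.eps_nh4, eps_n2=e.eps_n2,
                atp_per_electron_pair_to_o2=e.atp_per_electron_pair_to_o2,
                atp_per_n2_fixed=e.atp_per_n2_fixed,
                electrons_per_n2_fixed=e.electrons_per_n2_fixed,
                atp_per_biomass_c=e.atp_per_biomass_c,
            ),
        )

    def to_conditions(self) -> CultureConditions:
        c = self.conditions
        return CultureConditions(
            sucrose_in=c.sucrose_in_mM,
            ammonium_in=c.ammonium_in_mM,
            dilution_rate=c.dilution_rate_per_h,
            env=AmbientEnvironment(
                o2_fraction=c.o2_fraction,
                o2_saturation=c.o2_saturation_mM,
                n2_concentration=c.n2_concentration_mM,
            ),
        )

    def to_policy(self) -> RespirationPolicy:
        return RespirationPolicy(self.policy)

    def provenance(self) -> dict[str, Any]:
        """Per-key provenance: user-set, calibrated default, or plain default."""

        def walk(model: BaseModel, prefix: str = "") -> dict[str, str]:
            out: dict[str, str] = {}
            for name in type(model).model_fields:
                value = getattr(model, name)
                path = f"{prefix}{name}"
                if isinstance(value, BaseModel):
                    out.update(walk(value, path + "."))
                elif name in model.model_fields_set:
                    out[path] = "user"
                elif path == "physiology.eps_m":
                    out[path] = "calibrated-default"
                else:
                    out[path] = "default"
            return out

        return walk(self)


def read_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid configuration:\n" + "\n".join(lines)) from None
    if "conditions" not in cfg.model_fields_set or (
        "dilution_rate_per_h" not in cfg.conditions.model_fields_set
    ):
        log.info("dilution_rate_per_h not set; default %.2f h-1 applied", C.DILUTION_RATE)
    return cfg


def write_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with a header row and a units row ('.' decimal, UTF-8)."""
    path = Path(path)
    units = pd.DataFrame([[SWEEP_UNITS.get(c, "-") for c in table.columns]], columns=table.columns)
    with path.open("w", encoding="utf-8", newline="") as fh:
        units_then_data = pd.concat([units, table.astype(object)], ignore_index=True)
        units_then_data.to_csv(fh, index=False)


def read_table_csv(path: str | Path, expected_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a table written by :func:`write_table_csv`, validating the header."""
    path = Path(path)
    df = pd.read_csv(path, skiprows=[1])
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise ConfigError(
            f"{path}: malformed header: expected columns {expected_columns}, got {list(df.columns)}"
        )
    return df


def write_table_json(
    table: pd.DataFrame, path: str | Path, provenance: dict[str, Any] | None = None
) -> None:
    """JSON output: column units, rows, and parameter provenance."""
    payload = {
        "units": {c: SWEEP_UNITS.get(c, "-") for c in table.columns},
        "provenance": provenance or {},
        "rows": table.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_table_json(path: str | Path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    return pd.DataFrame(payload["rows"])
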