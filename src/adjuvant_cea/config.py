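"""Run configuration schema: parsing, validation, and strategy construction.

A run configuration is a YAML/JSON document with exactly two strategy
blocks (intervention and comparator), the cycle grid, discount rate,
willingness-to-pay threshold, reference patient, and PSA settings.
Validation is strict: unknown keys are rejected with the offending path,
utilities must lie in [0, 1], and each strategy's survival curves must
be specified exactly one way (printed median, explicit scale/shape, or a
Kaplan-Meier CSV to fit).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import markov, survival
from .markov import CISPLATIN, VINORELBINE, PatientProfile, StrategySpec
from .survival import CycleSpec, KMCurve, WeibullFit, WeibullParams

__all__ = [
    "ConfigError",
    "RunConfig",
    "StrategyConfig",
    "validate_config",
    "load_config",
    "build_strategy",
    "config_hash",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration failed validation; message carries the offending paths."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurvivalCurveConfig(_StrictModel):
    """One survival curve: a median (with shape), explicit parameters, or a KM CSV."""

    median_months: Optional[float] = Field(default=None, gt=0)
    shape: float = Field(default=1.0, gt=0)
    scale: Optional[float] = Field(default=None, gt=0)
    km_csv: Optional[str] = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "SurvivalCurveConfig":
        sources = [self.median_months is not None, self.scale is not None, self.km_csv is not None]
        if sum(sources) != 1:
            raise ValueError("specify exactly one of median_months, scale, or km_csv")
        return self

    def resolve(self, base_dir: Path | None = None, curve_id: str | None = None) -> tuple[WeibullParams, WeibullFit | None]:
        """Turn the declaration into WeibullParams (fit report if a CSV was fitted)."""
        if self.median_months is not None:
            return survival.params_from_median(self.median_months, self.shape), None
        if self.scale is not None:
            return WeibullParams(scale=self.scale, shape=self.shape), None
        path = Path(self.km_csv)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        fit = survival.fit_weibull_to_km(KMCurve.from_csv(path), curve_id=curve_id)
        return fit.params, fit


class SurvivalConfig(_StrictModel):
    dfs: SurvivalCurveConfig
    os: SurvivalCurveConfig


class OralScheduleConfig(_StrictModel):
    kind: Literal["oral"]
    unit_cost_usd: float = Field(ge=0)
    units_per_day: float = Field(default=1.0, gt=0)
    duration_months: float = Field(gt=0)


class InfusionComponentConfig(_StrictModel):
    drug: str
    dose_mg_per_m2: float = Field(gt=0)
    vial_mg: float = Field(gt=0)
    vial_cost_usd: float = Field(ge=0)
    administrations_per_cycle: int = Field(default=1, ge=1)


class InfusionScheduleConfig(_StrictModel):
    kind: Literal["infusion"]
    n_regimen_cycles: int = Field(ge=0)
    interval_days: float = Field(default=21.0, gt=0)
    components: list[InfusionComponentConfig]


ScheduleConfig = Union[OralScheduleConfig, InfusionScheduleConfig]


class StrategyConfig(_StrictModel):
    """Everything arm-specific, mirroring the engine's StrategySpec."""

    name: str
    role: Literal["intervention", "comparator"]
    survival: SurvivalConfig
    schedule: ScheduleConfig = Field(discriminator="kind")
    followup_cost_usd: float = Field(default=55.60, ge=0)
    supportive_cost_usd: float = Field(default=337.50, ge=0)
    pd_entry_cost_usd: float = Field(default=1877.25, ge=0)
    ae_cost_usd: float = Field(default=507.40, ge=0)
    ae_incidence_g34: float = Field(ge=0, le=1)
    ae_disutility: float = Field(default=0.0731, ge=0, le=1)
    dfs_utility: float = Field(ge=0, le=1)
    pd_utility: float = Field(default=0.70, ge=0, le=1)


class CyclesConfig(_StrictModel):
    cycle_length_days: float = Field(default=21.0, gt=0)
    horizon_years: float = Field(default=10.0, gt=0)

    def to_spec(self) -> CycleSpec:
        return CycleSpec(self.cycle_length_days, self.horizon_years)


class DiscountConfig(_StrictModel):
    annual_rate: float = Field(default=0.03, ge=0)


class PatientConfig(_StrictModel):
    height_m: float = Field(default=1.64, gt=0)
    weight_kg: float = Field(default=65.0, gt=0)
    bsa_m2: float = Field(default=1.72, gt=0)

    def to_profile(self) -> PatientProfile:
        return PatientProfile(self.height_m, self.weight_kg, self.bsa_m2)


class PSAConfig(_StrictModel):
    n_iterations: int = Field(default=1000, ge=1)
    seed: int = Field(default=20210325, ge=0)


class RunConfig(_StrictModel):
    """Validated two-arm run configuration."""

    schema_version: int = SCHEMA_VERSION
    wtp_usd_per_qaly: float = Field(default=30_828.0, ge=0)
    cycles: CyclesConfig = CyclesConfig()
    discount: DiscountConfig = DiscountConfig()
    patient: PatientConfig = PatientConfig()
    psa: PSAConfig = PSAConfig()
    strategies: list[StrategyConfig]
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _two_arms(self) -> "RunConfig":
        if len(self.strategies) != 2:
            raise ValueError(f"exactly two strategies required (two-arm model), got {len(self.strategies)}")
        roles = sorted(s.role for s in self.strategies)
        if roles != ["comparator", "intervention"]:
            raise ValueError("strategies must comprise one intervention and one comparator")
        return self

    @property
    def intervention(self) -> StrategyConfig:
        return next(s for s in self.strategies if s.role == "intervention")

    @property
    def comparator(self) -> StrategyConfig:
        return next(s for s in self.strategies if s.role == "comparator")


def _format_pydantic_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        path = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {path}: {e['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate raw YAML/JSON text (or an already-parsed mapping)."""
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable YAML/JSON: {exc}") from exc
    else:
        data = raw
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping at top level")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_pydantic_error(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a configuration file."""
    return validate_config(Path(path).read_text())


def _schedule_costs(
    cfg: ScheduleConfig, profile: PatientProfile, cycles: CycleSpec
) -> tuple["np.ndarray", int]:
    import math

    import numpy as np  # noqa: F401  (type comment convenience)

    if cfg.kind == "oral":
        costs = markov.oral_schedule(cfg.unit_cost_usd, cfg.duration_months, cycles, cfg.units_per_day)
        treatment_days = cfg.duration_months * survival.DAYS_PER_MONTH
    else:
        regimen = sum(
            markov.vial_cost(c.dose_mg_per_m2, profile.bsa_m2, c.vial_mg, c.vial_cost_usd)
            * c.administrations_per_cycle
            for c in cfg.components
        )
        costs = markov.infusion_schedule(regimen, cfg.n_regimen_cycles, cycles, cfg.interval_days)
        treatment_days = cfg.n_regimen_cycles * cfg.interval_days
    treatment_cycles = math.ceil(treatment_days / cycles.cycle_length_days)
    return costs, min(treatment_cycles, cycles.n_cycles)


def build_strategy(
    cfg: StrategyConfig,
    cycles: CycleSpec,
    profile: PatientProfile,
    base_dir: Path | None = None,
) -> tuple[StrategySpec, list[WeibullFit]]:
    """Construct an engine StrategySpec (resolving survival curves) from config."""
    dfs_params, dfs_fit = cfg.survival.dfs.resolve(base_dir, curve_id=f"{cfg.name}_dfs")
    os_params, os_fit = cfg.survival.os.resolve(base_dir, curve_id=f"{cfg.name}_os")
    drug_costs, treatment_cycles = _schedule_costs(cfg.schedule, profile, cycles)
    spec = StrategySpec(
        name=cfg.name,
        dfs_params=dfs_params,
        os_params=os_params,
        drug_costs=drug_costs,
        treatment_cycles=treatment_cycles,
        ae_incidence_g34=cfg.ae_incidence_g34,
        dfs_utility=cfg.dfs_utility,
        pd_utility=cfg.pd_utility,
        ae_disutility=cfg.ae_disutility,
        followup_cost=cfg.followup_cost_usd,
        supportive_cost=cfg.supportive_cost_usd,
        pd_entry_cost=cfg.pd_entry_cost_usd,
        ae_cost=cfg.ae_cost_usd,
    )
    fits = [f for f in (dfs_fit, os_fit) if f is not None]
    return spec, fits


def config_hash(config: RunConfig) -> str:
    """SHA-256 over the semantically meaningful fields (metadata excluded)."""
    payload = config.model_dump(mode="json", exclude={"metadata"})
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()
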