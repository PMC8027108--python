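"""Run orchestration: the re-runnable two-arm model and the staged pipeline.

``TwoArmModel`` binds a validated configuration to the Markov engine and
exposes the override surface the sensitivity analyses need: every cost,
utility, AE incidence, and per-cycle survival probability of each arm is
addressable as ``"<arm>.<parameter>"``.  Survival probabilities are
overridden on the probability scale (the arm's base per-cycle event
probability) and converted internally to a multiplicative factor on the
per-cycle probabilities, clamped to [0, 1].

``run_pipeline`` executes the requested stages — ``fit``, ``base-case``,
``owsa``, ``psa`` — writing a deterministic file set (fitted-parameter
report, per-arm traces, results table, tornado, PSA draws, CEAC) plus a
manifest with the seed, config hash and library versions.  Monetary
amounts are rounded to cents only at serialization.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, RunConfig, build_strategy, config_hash
from .markov import DiscountSpec, StrategySpec, accumulate, run_cohort
from .outcomes import ArmResult, compare, results_table
from .sensitivity import (
    InvalidModelError,
    ParamSpec,
    ceac,
    ceac_frame,
    cost_param,
    draws_frame,
    fraction_param,
    make_wtp_grid,
    owsa,
    run_psa,
    tornado_frame,
)
from .survival import transition_probability

__all__ = ["TwoArmModel", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("adjuvant_cea")

STAGES = ("fit", "base-case", "owsa", "psa")
_STAGE_DEPS = {"fit": (), "base-case": ("fit",), "owsa": ("fit", "base-case"), "psa": ("fit", "base-case")}


class PipelineError(RuntimeError):
    """A pipeline stage could not run (unmet dependencies or bad state)."""


class TwoArmModel:
    """The configured decision model, re-runnable under parameter overrides."""

    # strategy fields overridable as plain values
    _DIRECT_FIELDS = {
        "followup_cost": "followup_cost",
        "supportive_cost": "supportive_cost",
        "pd_entry_cost": "pd_entry_cost",
        "ae_cost": "ae_cost",
        "dfs_utility": "dfs_utility",
        "pd_utility": "pd_utility",
        "ae_disutility": "ae_disutility",
        "ae_incidence": "ae_incidence_g34",
    }

    def __init__(self, config: RunConfig, base_dir: Path | None = None):
        self.config = config
        self.cycles = config.cycles.to_spec()
        self.discount = DiscountSpec(config.discount.annual_rate)
        self.wtp = config.wtp_usd_per_qaly
        profile = config.patient.to_profile()
        self.fits = []
        self.strategies: dict[str, StrategySpec] = {}
        self.roles: dict[str, str] = {}
        for cfg in (config.intervention, config.comparator):
            spec, fits = build_strategy(cfg, self.cycles, profile, base_dir)
            self.strategies[cfg.name] = spec
            self.roles[cfg.role] = cfg.name
            self.fits.extend(fits)

    # -- parameter surface -------------------------------------------------

    def _base_event_prob(self, strategy: StrategySpec, which: str) -> float:
        u = self.cycles.cycle_months
        params = strategy.dfs_params if which == "dfs" else strategy.os_params
        return transition_probability(params, u, u)

    def param_specs(self) -> list[ParamSpec]:
        """All sensitivity parameters: costs +/-30%, utilities/probabilities +/-20%."""
        specs: list[ParamSpec] = []
        for name, s in self.strategies.items():
            drug_base = float(s.drug_costs[1]) if s.drug_costs.size > 1 else 0.0
            if drug_base > 0:
                specs.append(cost_param(f"{name}.drug_cost", drug_base))
            specs.append(cost_param(f"{name}.followup_cost", s.followup_cost))
            specs.append(cost_param(f"{name}.supportive_cost", s.supportive_cost))
            specs.append(cost_param(f"{name}.pd_entry_cost", s.pd_entry_cost))
            specs.append(cost_param(f"{name}.ae_cost", s.ae_cost))
            specs.append(fraction_param(f"{name}.dfs_utility", s.dfs_utility, "utility"))
            specs.append(fraction_param(f"{name}.pd_utility", s.pd_utility, "utility"))
            specs.append(fraction_param(f"{name}.ae_disutility", s.ae_disutility, "utility"))
            specs.append(fraction_param(f"{name}.ae_incidence", s.ae_incidence_g34, "probability"))
            specs.append(
                fraction_param(f"{name}.dfs_event_prob", self._base_event_prob(s, "dfs"), "probability")
            )
            specs.append(
                fraction_param(f"{name}.os_death_prob", self._base_event_prob(s, "os"), "probability")
            )
        return specs

    def _apply_overrides(self, overrides: Mapping[str, float]) -> dict[str, StrategySpec]:
        patched = dict(self.strategies)
        by_arm: dict[str, dict[str, float]] = {}
        for key, value in overrides.items():
            arm, _, param = key.partition(".")
            if arm not in self.strategies or not param:
                raise KeyError(f"unknown parameter {key!r}")
            by_arm.setdefault(arm, {})[param] = value
        for arm, fields in by_arm.items():
            s = self.strategies[arm]
            kwargs: dict = {}
            for param, value in fields.items():
                if param in self._DIRECT_FIELDS:
                    kwargs[self._DIRECT_FIELDS[param]] = value
                elif param == "drug_cost":
                    base = float(s.drug_costs[1])
                    if base <= 0:
                        raise KeyError(f"{arm} has no drug cost to vary")
                    kwargs["drug_costs"] = s.drug_costs * (value / base)
                elif param == "dfs_event_prob":
                    kwargs["dfs_event_multiplier"] = value / self._base_event_prob(s, "dfs")
                elif param == "os_death_prob":
                    kwargs["os_event_multiplier"] = value / self._base_event_prob(s, "os")
                else:
                    raise KeyError(f"unknown parameter {arm}.{param}")
            try:
                patched[arm] = replace(s, **kwargs)
            except ValueError as exc:
                raise InvalidModelError(str(exc)) from exc
        return patched

    # -- execution ---------------------------------------------------------

    def run_traces(self, overrides: Mapping[str, float] | None = None):
        strategies = self._apply_overrides(overrides) if overrides else self.strategies
        return {
            name: run_cohort(s, self.cycles, self.discount) for name, s in strategies.items()
        }

    def run(self, overrides: Mapping[str, float] | None = None) -> tuple[ArmResult, ArmResult]:
        """(intervention, comparator) totals under optional overrides."""
        traces = self.run_traces(overrides)
        return (
            accumulate(traces[self.roles["intervention"]]),
            accumulate(traces[self.roles["comparator"]]),
        )


# -- serialization helpers -------------------------------------------------


def _fmt_cell(value, fmt: str) -> str:
    if value == "" or value is None:
        return ""
    if isinstance(value, str):
        return value
    return fmt % value


def _write_csv(df: pd.DataFrame, path: Path, formats: Mapping[str, str]) -> None:
    out = df.copy()
    for col, fmt in formats.items():
        if col in out.columns:
            out[col] = out[col].map(lambda v: _fmt_cell(v, fmt))
    out.to_csv(path, index=False, lineterminator="\n")


_TRACE_FMT = {
    "p_dfs": "%.12f",
    "p_pd": "%.12f",
    "p_death": "%.12f",
    "new_pd": "%.12f",
    "disc_cost_usd": "%.2f",
    "disc_qaly": "%.6f",
}
_RESULTS_FMT = {
    "qaly": "%.6f",
    "ie": "%.6f",
    "cost": "%.2f",
    "ic": "%.2f",
    "icer": "%.2f",
    "acer": "%.2f",
    "net_benefit": "%.2f",
}
_TORNADO_FMT = {"low_outcome": "%.2f", "high_outcome": "%.2f", "spread": "%.2f"}
_CEAC_FMT = {"wtp": "%.2f", "prob_cost_effective": "%.4f", "mean_inc_nmb": "%.2f"}


def _resolve_stages(stages: Sequence[str] | None) -> list[str]:
    if stages is None:
        requested = set(STAGES)
    else:
        requested = set(stages)
        unknown = requested - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}; valid stages are {list(STAGES)}")
        for stage in sorted(requested):
            missing = [d for d in _STAGE_DEPS[stage] if d not in requested]
            if missing:
                raise PipelineError(
                    f"stage {stage!r} requires stages {missing} to run in the same pipeline"
                )
    return [s for s in STAGES if s in requested]


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: Sequence[str] | None = None,
    seed: int | None = None,
    psa_n: int | None = None,
    base_dir: Path | None = None,
) -> dict:
    """Execute the requested stages and write the report bundle to ``out_dir``.

    Returns a summary dict with the in-memory results and the manifest.
    Identical config + seed reproduce every CSV byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = _resolve_stages(stages)
    seed = config.psa.seed if seed is None else seed
    psa_n = config.psa.n_iterations if psa_n is None else psa_n

    summary: dict = {"stages": ordered}
    outputs: list[str] = []
    model: TwoArmModel | None = None

    for stage in ordered:
        t0 = time.perf_counter()
        if stage == "fit":
            model = TwoArmModel(config, base_dir=base_dir)
            report = []
            for name, s in model.strategies.items():
                for which, params in (("dfs", s.dfs_params), ("os", s.os_params)):
                    curve_id = f"{name}_{which}"
                    fit = next((f for f in model.fits if f.curve_id == curve_id), None)
                    report.append(
                        {
                            "curve_id": curve_id,
                            "scale": params.scale,
                            "shape": params.shape,
                            "r_squared": None if fit is None else fit.r_squared,
                            "n_points": None if fit is None else fit.n_points,
                        }
                    )
            path = out / "fitted_params.json"
            path.write_text(json.dumps(report, indent=2) + "\n")
            outputs.append(path.name)
            summary["fitted_params"] = report
        elif stage == "base-case":
            assert model is not None
            traces = model.run_traces()
            for name, trace in traces.items():
                path = out / f"trace_{name}.csv"
                _write_csv(trace.to_frame(), path, _TRACE_FMT)
                outputs.append(path.name)
            arm_i = accumulate(traces[model.roles["intervention"]])
            arm_c = accumulate(traces[model.roles["comparator"]])
            result = compare(arm_i, arm_c, model.wtp)
            path = out / "results.csv"
            _write_csv(results_table(result), path, _RESULTS_FMT)
            outputs.append(path.name)
            summary["base_case"] = result
        elif stage == "owsa":
            assert model is not None
            entries = owsa(model, model.param_specs(), model.wtp)
            path = out / "tornado.csv"
            _write_csv(tornado_frame(entries), path, _TORNADO_FMT)
            outputs.append(path.name)
            summary["owsa"] = entries
        elif stage == "psa":
            assert model is not None
            draws = run_psa(model, model.param_specs(), n=psa_n, seed=seed)
            dpath = out / "psa_draws.csv"
            dframe = draws_frame(draws)
            fmts = {c: "%.6f" for c in dframe.columns if c != "draw"}
            fmts.update({"cost_int": "%.2f", "cost_comp": "%.2f"})
            _write_csv(dframe, dpath, fmts)
            outputs.append(dpath.name)
            points = ceac(draws, make_wtp_grid(model.wtp))
            cpath = out / "ceac.csv"
            _write_csv(ceac_frame(points), cpath, _CEAC_FMT)
            outputs.append(cpath.name)
            summary["psa_draws"] = draws
            summary["ceac"] = points
        log.info("stage %s finished in %.3f s", stage, time.perf_counter() - t0)

    manifest = {
        "schema_version": config.schema_version,
        "package_version": __version__,
        "seed": seed,
        "psa_n": psa_n,
        "config_hash": config_hash(config),
        "stages": ordered,
        "outputs": outputs,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    summary["manifest"] = manifest
    return summary
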