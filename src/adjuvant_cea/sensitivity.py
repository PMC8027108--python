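"""Deterministic (tornado) and probabilistic sensitivity analyses.

One-way sensitivity analysis (OWSA) reruns the two-arm model with one
parameter at a time set to its low and high bound, holding the rest at
base case; the outcome is the incremental net monetary benefit at the
default willingness-to-pay, and entries sorted by spread form the
tornado diagram.  Costs get a +/-30% range, utilities and per-cycle
survival probabilities +/-20% (clamped to [0, 1]).

Probabilistic sensitivity analysis (PSA) samples every parameter each
iteration — costs from gamma distributions, utilities and probabilities
from beta distributions, both moment-matched to the base value and a
standard error — reruns both arms, and summarises the draws as a
cost-effectiveness acceptability curve (CEAC) and a mean-incremental-NMB
series over a WTP grid.  Unless given explicitly, the standard error
treats the OWSA range as a 95% central interval: se = (high - low)/(2 * 1.96).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .outcomes import ArmResult, net_benefit

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSADraw",
    "CEACPoint",
    "TwoArmModelProtocol",
    "InvalidModelError",
    "cost_param",
    "fraction_param",
    "gamma_from_moments",
    "beta_from_moments",
    "owsa",
    "run_psa",
    "ceac",
    "make_wtp_grid",
    "tornado_frame",
    "draws_frame",
    "ceac_frame",
]

COST_RANGE = 0.30
FRACTION_RANGE = 0.20
_BETA_PARAM_CAP = 1e7


class InvalidModelError(RuntimeError):
    """A sampled/overridden parameter set produced an invalid model."""


class TwoArmModelProtocol(Protocol):
    """A re-runnable two-arm model: overrides map parameter names to values."""

    def run(self, overrides: Mapping[str, float] | None = None) -> tuple[ArmResult, ArmResult]:
        ...


@dataclass(frozen=True)
class ParamSpec:
    """One sensitivity parameter: base value, low/high range, distribution family.

    ``role`` is one of ``cost`` (gamma-distributed), ``utility`` or
    ``probability`` (beta-distributed).  ``se`` overrides the default
    dispersion derived from the range.
    """

    name: str
    role: str
    base: float
    low: float
    high: float
    family: str
    se: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("cost", "utility", "probability"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.family not in ("gamma", "beta"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be nonnegative")

    @property
    def effective_se(self) -> float:
        """Standard error: explicit, else range interpreted as a 95% interval."""
        if self.se is not None:
            return self.se
        return (self.high - self.low) / (2.0 * 1.96)


def cost_param(name: str, base: float, se: float | None = None) -> ParamSpec:
    """Cost parameter with the standard +/-30% deterministic range, gamma PSA."""
    if base < 0:
        raise ValueError("cost base must be nonnegative")
    return ParamSpec(
        name=name,
        role="cost",
        base=base,
        low=(1 - COST_RANGE) * base,
        high=(1 + COST_RANGE) * base,
        family="gamma",
        se=se,
    )


def fraction_param(name: str, base: float, role: str, se: float | None = None) -> ParamSpec:
    """Utility/probability parameter with a +/-20% range clamped to [0, 1], beta PSA."""
    if not 0.0 <= base <= 1.0:
        raise ValueError("fraction base must lie in [0, 1]")
    return ParamSpec(
        name=name,
        role=role,
        base=base,
        low=max(0.0, (1 - FRACTION_RANGE) * base),
        high=min(1.0, (1 + FRACTION_RANGE) * base),
        family="beta",
        se=se,
    )


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: incremental NMB at the parameter's low and high bound."""

    name: str
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


@dataclass(frozen=True)
class PSADraw:
    """One Monte-Carlo realization: sampled parameters and both arm outcomes."""

    params: dict[str, float]
    intervention: ArmResult
    comparator: ArmResult

    @property
    def inc_cost(self) -> float:
        return self.intervention.cost - self.comparator.cost

    @property
    def inc_qaly(self) -> float:
        return self.intervention.qaly - self.comparator.qaly

    def inc_nmb(self, wtp: float) -> float:
        return net_benefit(self.intervention, wtp) - net_benefit(self.comparator, wtp)


@dataclass(frozen=True)
class CEACPoint:
    """Probability the intervention is cost-effective at one WTP threshold."""

    wtp: float
    prob_cost_effective: float
    mean_inc_nmb: float


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, rate) matching a mean and standard error.

    shape = mean^2/se^2, rate = mean/se^2; mean = se gives shape 1
    (exponential).
    """
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    return mean**2 / se**2, mean / se**2


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean in (0, 1) and standard error.

    Requires se^2 < mean(1 - mean).  Near-degenerate dispersions are
    capped (with a warning) to keep the sampler numerically safe.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly inside (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    v = se**2
    if v >= mean * (1.0 - mean):
        raise ValueError(f"se {se} too large for mean {mean}: need se^2 < mean(1-mean)")
    nu = mean * (1.0 - mean) / v - 1.0
    alpha, beta = mean * nu, (1.0 - mean) * nu
    if alpha > _BETA_PARAM_CAP or beta > _BETA_PARAM_CAP:
        warnings.warn(
            f"beta parameters capped at {_BETA_PARAM_CAP:g} (near point mass)", RuntimeWarning
        )
        scale = _BETA_PARAM_CAP / max(alpha, beta)
        alpha, beta = alpha * scale, beta * scale
    return alpha, beta


def owsa(
    model: TwoArmModelProtocol, params: Sequence[ParamSpec], wtp: float
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every parameter.

    Each parameter is set to its low and its high bound (others at base)
    and the incremental NMB recomputed; entries come back sorted by
    spread descending, ties broken by parameter name.
    """
    entries = []
    for spec in params:
        outcomes = []
        for value in (spec.low, spec.high):
            arm_i, arm_c = model.run({spec.name: value})
            outcomes.append(net_benefit(arm_i, wtp) - net_benefit(arm_c, wtp))
        entries.append(TornadoEntry(name=spec.name, outcome_low=outcomes[0], outcome_high=outcomes[1]))
    return sorted(entries, key=lambda e: (-e.spread, e.name))


def _sample_param(rng: np.random.Generator, spec: ParamSpec) -> float:
    se = spec.effective_se
    if se == 0.0:
        return spec.base
    if spec.family == "gamma":
        if spec.base == 0.0:
            return 0.0
        shape, rate = gamma_from_moments(spec.base, se)
        return float(rng.gamma(shape, 1.0 / rate))
    # beta on the magnitude; degenerate endpoints stay fixed
    if spec.base in (0.0, 1.0):
        return spec.base
    alpha, beta = beta_from_moments(spec.base, se)
    return float(rng.beta(alpha, beta))


def run_psa(
    model: TwoArmModelProtocol,
    params: Sequence[ParamSpec],
    n: int,
    seed: int,
    max_resamples: int = 100,
) -> list[PSADraw]:
    """Monte-Carlo PSA: ``n`` seeded draws over all parameters.

    Parameters are sampled in sorted-name order from a single generator,
    so draws are reproducible and invariant to configuration ordering.
    A draw whose sampled values produce an invalid model is resampled,
    up to ``max_resamples`` times.
    """
    if n < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    ordered = sorted(params, key=lambda p: p.name)
    draws: list[PSADraw] = []
    for _ in range(n):
        for attempt in range(max_resamples + 1):
            sampled = {spec.name: _sample_param(rng, spec) for spec in ordered}
            try:
                arm_i, arm_c = model.run(sampled)
            except InvalidModelError:
                if attempt == max_resamples:
                    raise InvalidModelError(
                        f"draw still invalid after {max_resamples} resamples"
                    )
                continue
            draws.append(PSADraw(params=sampled, intervention=arm_i, comparator=arm_c))
            break
    return draws


def ceac(draws: Sequence[PSADraw], wtp_grid: Iterable[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each threshold: the fraction of draws with positive incremental
    NMB, plus the mean incremental NMB (the NMB-acceptability series).
    """
    if not draws:
        raise ValueError("need at least one PSA draw")
    inc_cost = np.array([d.inc_cost for d in draws])
    inc_qaly = np.array([d.inc_qaly for d in draws])
    points = []
    for wtp in wtp_grid:
        if wtp < 0:
            raise ValueError("WTP values must be nonnegative")
        inc_nmb = wtp * inc_qaly - inc_cost
        points.append(
            CEACPoint(
                wtp=float(wtp),
                prob_cost_effective=float(np.mean(inc_nmb > 0)),
                mean_inc_nmb=float(inc_nmb.mean()),
            )
        )
    return points


def make_wtp_grid(wtp_default: float, n_steps: int = 100) -> np.ndarray:
    """WTP grid 0..2x default in ``n_steps`` steps, always including 1,500 and 30,828."""
    grid = np.linspace(0.0, 2.0 * wtp_default, n_steps + 1)
    grid = np.union1d(grid, [1_500.0, 30_828.0])
    return grid


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "param": e.name,
                "low_outcome": e.outcome_low,
                "high_outcome": e.outcome_high,
                "spread": e.spread,
            }
            for e in entries
        ],
        columns=["param", "low_outcome", "high_outcome", "spread"],
    )


def draws_frame(draws: Sequence[PSADraw]) -> pd.DataFrame:
    """PSA draws table: one row per draw, sorted parameter columns then outcomes."""
    if not draws:
        raise ValueError("no draws")
    names = sorted(draws[0].params)
    rows = []
    for i, d in enumerate(draws, start=1):
        row = {"draw": i}
        row.update({name: d.params[name] for name in names})
        row.update(
            {
                "cost_int": d.intervention.cost,
                "qaly_int": d.intervention.qaly,
                "cost_comp": d.comparator.cost,
                "qaly_comp": d.comparator.qaly,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"wtp": p.wtp, "prob_cost_effective": p.prob_cost_effective, "mean_inc_nmb": p.mean_inc_nmb}
            for p in points
        ],
        columns=["wtp", "prob_cost_effective", "mean_inc_nmb"],
    )
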