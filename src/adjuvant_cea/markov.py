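"""Three-state Markov cohort engine with cost and QALY accumulation.

States are DFS (disease-free), PD (progressive disease) and Death.  The
whole cohort starts in DFS.  Each 21-day cycle the per-cycle conditional
probabilities derived from the fitted DFS and OS Weibull curves move
cohort mass between states:

* the death probability ``d`` (from the OS curve) applies to both alive
  states, so cohort survival 1 - p_death tracks the fitted OS curve
  exactly at cycle boundaries;
* the DFS-event probability ``e`` (from the DFS curve) counts both
  progressions and deaths, so the DFS -> PD flow is ``max(0, e - d)``
  and DFS -> Death is ``min(d, e)`` — subtracting avoids double counting.

Costs and utilities accrue on start-of-cycle occupancy; transitions are
applied at cycle end; discounting uses start-of-cycle time.  No
half-cycle correction is applied (switchable via ``half_cycle``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .outcomes import ArmResult
from .survival import CycleSpec, DAYS_PER_MONTH, WeibullParams, transition_probability

__all__ = [
    "DiscountSpec",
    "PatientProfile",
    "StrategySpec",
    "MarkovTrace",
    "CycleState",
    "ModelError",
    "discount_factor",
    "drug_schedule",
    "oral_schedule",
    "infusion_schedule",
    "transition_matrix",
    "cycle_cost",
    "cycle_utility",
    "run_cohort",
    "accumulate",
]

GEFITINIB_TABLET_COST = 23.33  # USD per 0.25 g tablet, one per day
GEFITINIB_DURATION_MONTHS = 24.0
VINORELBINE = dict(dose_mg_per_m2=25.0, vial_mg=10.0, vial_cost=8.16, administrations=2)
CISPLATIN = dict(dose_mg_per_m2=75.0, vial_mg=30.0, vial_cost=2.80, administrations=1)
CHEMO_REGIMEN_CYCLES = 4
CHEMO_INTERVAL_DAYS = 21.0


class ModelError(RuntimeError):
    """Raised when combined transition probabilities or utilities are invalid."""


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied to both costs and QALYs (default 3%/year)."""

    annual_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("discount rate must be nonnegative")


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for body-surface-area drug dosing."""

    height_m: float = 1.64
    weight_kg: float = 65.0
    bsa_m2: float = 1.72

    def __post_init__(self) -> None:
        if self.bsa_m2 <= 0:
            raise ValueError("body surface area must be positive")


def discount_factor(cycle: int, discount: DiscountSpec, cycle_length_days: float = 21.0) -> float:
    """Discount multiplier (1 + r)^(-cycle * cycle_length / 365.25).

    ``cycle`` indexes elapsed cycles, so the factor is 1 at cycle 0 and
    strictly decreasing for positive rates.
    """
    if cycle < 0:
        raise ValueError("cycle index must be nonnegative")
    years = cycle * cycle_length_days / 365.25
    return (1.0 + discount.annual_rate) ** (-years)


def oral_schedule(
    daily_cost: float,
    duration_months: float,
    cycles: CycleSpec,
    units_per_day: float = 1.0,
) -> np.ndarray:
    """Per-cycle drug cost for a daily oral regimen, prorating the final cycle.

    Returns an array indexed by cycle (entry 0 unused).  Cycle ``k``
    covers days [(k-1)*L, k*L); the cost is the number of treated days in
    that window times the daily price.
    """
    n = cycles.n_cycles
    L = cycles.cycle_length_days
    duration_days = duration_months * DAYS_PER_MONTH
    costs = np.zeros(n + 1)
    for k in range(1, n + 1):
        days_on = min(max(duration_days - (k - 1) * L, 0.0), L)
        costs[k] = days_on * daily_cost * units_per_day
    return costs


def infusion_schedule(
    regimen_cost: float,
    n_regimen_cycles: int,
    cycles: CycleSpec,
    interval_days: float = CHEMO_INTERVAL_DAYS,
) -> np.ndarray:
    """Per-cycle cost for an infusion regimen given every ``interval_days``.

    Administration ``j`` (j = 0..n-1) occurs on day ``j * interval_days``
    and is charged to the model cycle containing that day.
    """
    n = cycles.n_cycles
    L = cycles.cycle_length_days
    costs = np.zeros(n + 1)
    for j in range(n_regimen_cycles):
        day = j * interval_days
        k = int(day // L) + 1
        if k <= n:
            costs[k] += regimen_cost
    return costs


def vial_cost(dose_mg_per_m2: float, bsa_m2: float, vial_mg: float, vial_cost_usd: float) -> float:
    """Cost of one administration: whole vials only, no sharing."""
    dose = dose_mg_per_m2 * bsa_m2
    return math.ceil(dose / vial_mg) * vial_cost_usd


def drug_schedule(
    profile: PatientProfile, arm: str, cycles: CycleSpec | None = None
) -> np.ndarray:
    """Per-cycle drug costs (USD) for the two trial regimens.

    ``gefitinib``: one 0.25 g tablet daily for 24 months — 21 x $23.33 =
    $489.93 per full cycle, with the last partial cycle prorated by day.
    ``chemotherapy``: vinorelbine 25 mg/m2 days 1 and 8 plus cisplatin
    75 mg/m2 day 1, every 3 weeks for four cycles, priced per whole vial.
    """
    cycles = cycles or CycleSpec()
    if arm == "gefitinib":
        return oral_schedule(GEFITINIB_TABLET_COST, GEFITINIB_DURATION_MONTHS, cycles)
    if arm == "chemotherapy":
        regimen = vial_cost(
            VINORELBINE["dose_mg_per_m2"], profile.bsa_m2, VINORELBINE["vial_mg"], VINORELBINE["vial_cost"]
        ) * VINORELBINE["administrations"] + vial_cost(
            CISPLATIN["dose_mg_per_m2"], profile.bsa_m2, CISPLATIN["vial_mg"], CISPLATIN["vial_cost"]
        ) * CISPLATIN["administrations"]
        return infusion_schedule(regimen, CHEMO_REGIMEN_CYCLES, cycles)
    raise ValueError(f"unknown arm {arm!r}; expected 'gefitinib' or 'chemotherapy'")


@dataclass(frozen=True)
class StrategySpec:
    """Everything arm-specific: survival curves, drug schedule, costs, utilities.

    Costs are USD; utilities are preference weights in [0, 1];
    ``ae_disutility`` is the (positive) decrement applied to the DFS
    utility during treatment cycles, scaled by the grade 3-4 AE
    incidence.  ``dfs_event_multiplier`` / ``os_event_multiplier`` scale
    the per-cycle event probabilities (clamped to [0, 1]) and exist for
    sensitivity analyses.
    """

    name: str
    dfs_params: WeibullParams
    os_params: WeibullParams
    drug_costs: np.ndarray
    treatment_cycles: int
    ae_incidence_g34: float
    dfs_utility: float
    pd_utility: float = 0.70
    ae_disutility: float = 0.0731
    followup_cost: float = 55.60
    supportive_cost: float = 337.50
    pd_entry_cost: float = 1877.25
    ae_cost: float = 507.40
    dfs_event_multiplier: float = 1.0
    os_event_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for label in ("followup_cost", "supportive_cost", "pd_entry_cost", "ae_cost"):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be nonnegative")
        for label in ("dfs_utility", "pd_utility", "ae_incidence_g34"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {v}")
        if not 0.0 <= self.ae_disutility <= 1.0:
            raise ValueError("ae_disutility must lie in [0, 1]")
        if self.treatment_cycles < 0:
            raise ValueError("treatment_cycles must be nonnegative")
        if self.dfs_event_multiplier < 0 or self.os_event_multiplier < 0:
            raise ValueError("event multipliers must be nonnegative")
        dc = np.asarray(self.drug_costs, dtype=float)
        if np.any(dc < 0):
            raise ValueError("drug costs must be nonnegative")
        object.__setattr__(self, "drug_costs", dc)

    def with_overrides(self, **kwargs) -> "StrategySpec":
        return replace(self, **kwargs)


class CycleState(NamedTuple):
    """Start-of-cycle occupancy plus the PD inflow during the cycle."""

    p_dfs: float
    p_pd: float
    p_death: float
    new_pd: float


def _event_probs(strategy: StrategySpec, cycle: int, cycles: CycleSpec) -> tuple[float, float]:
    u = cycles.cycle_months
    t = cycle * u
    e = transition_probability(strategy.dfs_params, t, u) * strategy.dfs_event_multiplier
    d = transition_probability(strategy.os_params, t, u) * strategy.os_event_multiplier
    e = min(max(e, 0.0), 1.0)
    d = min(max(d, 0.0), 1.0)
    return e, d


def transition_matrix(strategy: StrategySpec, cycle: int, cycles: CycleSpec | None = None) -> np.ndarray:
    """Row-stochastic 3x3 matrix for the given cycle (states DFS, PD, Death).

    DFS loses the DFS-event probability ``e``; of that, deaths take
    ``min(d, e)`` (``d`` = OS-derived death probability shared by both
    alive states) and progressions the remainder.  PD loses ``d`` to
    Death; Death is absorbing.
    """
    if cycle < 1:
        raise ValueError("cycle index must be >= 1")
    cycles = cycles or CycleSpec()
    e, d = _event_probs(strategy, cycle, cycles)
    to_death = min(d, e)
    to_pd = max(0.0, e - d)
    m = np.array(
        [
            [1.0 - e, to_pd, to_death],
            [0.0, 1.0 - d, d],
            [0.0, 0.0, 1.0],
        ]
    )
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        raise ModelError(f"transition probabilities outside [0, 1] at cycle {cycle}: {m}")
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
        raise ModelError(f"transition rows do not sum to 1 at cycle {cycle}")
    return m


def cycle_cost(strategy: StrategySpec, state: CycleState, cycle: int) -> float:
    """Undiscounted cost accrued during one cycle (USD).

    Disease-free patients pay follow-up, any scheduled drug cost, and —
    during treatment cycles — the expected AE management cost
    (incidence x per-cycle AE cost).  Progression incurs a one-off entry
    cost on the incident fraction; prevalent PD pays supportive care.
    """
    if cycle < 1:
        raise ValueError("cycle index must be >= 1")
    on_treatment = cycle <= strategy.treatment_cycles
    drug = strategy.drug_costs[cycle] if cycle < strategy.drug_costs.size else 0.0
    dfs_cost = strategy.followup_cost + drug
    if on_treatment:
        dfs_cost += strategy.ae_incidence_g34 * strategy.ae_cost
    return (
        state.p_dfs * dfs_cost
        + state.new_pd * strategy.pd_entry_cost
        + state.p_pd * strategy.supportive_cost
    )


def cycle_utility(
    strategy: StrategySpec, state: CycleState, cycle: int, cycles: CycleSpec | None = None
) -> float:
    """Undiscounted QALY accrued during one cycle.

    The occupancy-weighted utility (DFS utility less the expected AE
    decrement while on treatment; PD utility; zero for death) times the
    cycle length in years.
    """
    if cycle < 1:
        raise ValueError("cycle index must be >= 1")
    cycles = cycles or CycleSpec()
    dfs_u = strategy.dfs_utility
    if cycle <= strategy.treatment_cycles:
        dfs_u -= strategy.ae_incidence_g34 * strategy.ae_disutility
    weight = state.p_dfs * dfs_u + state.p_pd * strategy.pd_utility
    if not -1.0 <= weight <= 1.0:
        raise ModelError(f"utility weight {weight} outside [-1, 1] at cycle {cycle}")
    return weight * cycles.cycle_years


@dataclass
class MarkovTrace:
    """Per-cycle record of a cohort run (row 0 is the initial state).

    ``occupancy`` has one (p_dfs, p_pd, p_death) row per cycle boundary;
    ``new_pd`` is the incident PD fraction during each cycle; ``cost``
    and ``qaly`` are undiscounted per-cycle accruals, ``disc_cost`` and
    ``disc_qaly`` their discounted counterparts.
    """

    occupancy: np.ndarray
    new_pd: np.ndarray
    cost: np.ndarray
    qaly: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    name: str = ""

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self, include_total: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                "p_dfs": self.occupancy[:, 0],
                "p_pd": self.occupancy[:, 1],
                "p_death": self.occupancy[:, 2],
                "new_pd": self.new_pd,
                "disc_cost_usd": self.disc_cost,
                "disc_qaly": self.disc_qaly,
            }
        )
        if include_total:
            total = pd.DataFrame(
                [
                    {
                        "cycle": "total",
                        "p_dfs": "",
                        "p_pd": "",
                        "p_death": "",
                        "new_pd": self.new_pd.sum(),
                        "disc_cost_usd": self.disc_cost.sum(),
                        "disc_qaly": self.disc_qaly.sum(),
                    }
                ]
            )
            df = pd.concat([df, total], ignore_index=True)
        return df


_START_STATES = {"dfs": 0, "pd": 1, "death": 2}


def run_cohort(
    strategy: StrategySpec,
    cycles: CycleSpec | None = None,
    discount: DiscountSpec | None = None,
    start_state: str = "dfs",
    half_cycle: bool = False,
) -> MarkovTrace:
    """Run the cohort through every cycle, accumulating discounted outcomes.

    Costs and utilities accrue on start-of-cycle occupancy and are
    discounted to the start-of-cycle time; transitions apply at cycle
    end.  ``half_cycle=True`` averages start- and end-of-cycle occupancy
    for the accruals instead (off by default).
    """
    cycles = cycles or CycleSpec()
    discount = discount or DiscountSpec()
    n = cycles.n_cycles
    if strategy.drug_costs.size < n + 1:
        raise ValueError(
            f"drug cost schedule covers {strategy.drug_costs.size - 1} cycles, model needs {n}"
        )

    occ = np.zeros((n + 1, 3))
    occ[0, _START_STATES[start_state]] = 1.0
    new_pd = np.zeros(n + 1)
    cost = np.zeros(n + 1)
    qaly = np.zeros(n + 1)
    disc_cost = np.zeros(n + 1)
    disc_qaly = np.zeros(n + 1)

    u = cycles.cycle_months
    grid = np.arange(1, n + 1) * u
    e_all = np.clip(
        transition_probability(strategy.dfs_params, grid, u) * strategy.dfs_event_multiplier, 0.0, 1.0
    )
    d_all = np.clip(
        transition_probability(strategy.os_params, grid, u) * strategy.os_event_multiplier, 0.0, 1.0
    )

    p_dfs, p_pd, p_death = occ[0]
    for k in range(1, n + 1):
        e, d = e_all[k - 1], d_all[k - 1]
        inflow = p_dfs * max(0.0, e - d)
        new_pd[k] = inflow

        nxt_dfs = p_dfs * (1.0 - e)
        nxt_pd = p_pd * (1.0 - d) + inflow
        nxt_death = 1.0 - nxt_dfs - nxt_pd

        if half_cycle:
            state = CycleState(
                0.5 * (p_dfs + nxt_dfs), 0.5 * (p_pd + nxt_pd), 0.5 * (p_death + nxt_death), inflow
            )
        else:
            state = CycleState(p_dfs, p_pd, p_death, inflow)
        c = cycle_cost(strategy, state, k)
        q = cycle_utility(strategy, state, k, cycles)
        df = discount_factor(k - 1, discount, cycles.cycle_length_days)
        cost[k], qaly[k] = c, q
        disc_cost[k], disc_qaly[k] = df * c, df * q

        p_dfs, p_pd, p_death = nxt_dfs, nxt_pd, nxt_death
        occ[k] = (p_dfs, p_pd, p_death)

    return MarkovTrace(
        occupancy=occ,
        new_pd=new_pd,
        cost=cost,
        qaly=qaly,
        disc_cost=disc_cost,
        disc_qaly=disc_qaly,
        name=strategy.name,
    )


def accumulate(trace: MarkovTrace) -> ArmResult:
    """Total discounted cost and QALY for one arm."""
    return ArmResult(
        name=trace.name, cost=float(trace.disc_cost.sum()), qaly=float(trace.disc_qaly.sum())
    )
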