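"""Cost-effectiveness arithmetic: ICER, ACER, net monetary benefit, dominance.

Given per-arm totals (discounted cost in USD, effect in QALYs), the
incremental cost-effectiveness ratio ICER = (C_int - C_comp)/(E_int - E_comp)
is compared against a willingness-to-pay (WTP) threshold; the average
cost-effectiveness ratio ACER = C/E and the net monetary benefit
NMB = WTP * E - C summarise each arm on its own.  When one arm is both
cheaper and more effective the ICER is not reported as a ratio: a
dominance label is emitted instead, and the NMB ordering carries the
cost-effectiveness verdict in every case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["ArmResult", "CEAResult", "acer", "net_benefit", "compare", "results_table"]

DEFAULT_WTP = 30_828.0  # USD/QALY, three times Chinese per-capita GDP


@dataclass(frozen=True)
class ArmResult:
    """Total discounted cost (USD) and effect (QALY) for one strategy arm."""

    name: str
    cost: float
    qaly: float

    def __post_init__(self) -> None:
        for label, v in (("cost", self.cost), ("qaly", self.qaly)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{label} must be finite and nonnegative, got {v}")


@dataclass(frozen=True)
class CEAResult:
    """Paired-arm comparison: incremental cost/effect, ICER, ACERs, NMBs."""

    intervention: ArmResult
    comparator: ArmResult
    wtp: float
    ic: float
    ie: float
    icer: float | None
    acer_intervention: float
    acer_comparator: float
    nmb_intervention: float
    nmb_comparator: float
    dominance: str  # "none" | "intervention-dominant" | "intervention-dominated"
    cost_effective: bool


def acer(arm: ArmResult) -> float:
    """Average cost-effectiveness ratio cost/QALY for a single arm."""
    if arm.qaly == 0:
        raise ValueError(f"ACER undefined for arm {arm.name!r}: zero QALY")
    return arm.cost / arm.qaly


def net_benefit(arm: ArmResult, wtp: float) -> float:
    """Net monetary benefit WTP * QALY - cost (USD; may be negative)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * arm.qaly - arm.cost


def compare(intervention: ArmResult, comparator: ArmResult, wtp: float = DEFAULT_WTP) -> CEAResult:
    """Incremental comparison of intervention against comparator at a WTP.

    The ICER is reported as a ratio only when neither arm dominates and
    the incremental effect is nonzero; the cost-effectiveness verdict is
    always the NMB ordering (for positive incremental effect this
    coincides with ICER < WTP).
    """
    ic = intervention.cost - comparator.cost
    ie = intervention.qaly - comparator.qaly
    nmb_i = net_benefit(intervention, wtp)
    nmb_c = net_benefit(comparator, wtp)

    dominance = "none"
    icer: float | None = None
    if ie > 0 and ic <= 0:
        dominance = "intervention-dominant"
    elif ie < 0 and ic >= 0:
        dominance = "intervention-dominated"
    elif ie != 0:
        icer = ic / ie
    # ie == 0 with ic != 0: icer undefined, verdict from NMB (= sign of -ic)

    return CEAResult(
        intervention=intervention,
        comparator=comparator,
        wtp=wtp,
        ic=ic,
        ie=ie,
        icer=icer,
        acer_intervention=acer(intervention),
        acer_comparator=acer(comparator),
        nmb_intervention=nmb_i,
        nmb_comparator=nmb_c,
        dominance=dominance,
        cost_effective=nmb_i > nmb_c,
    )


def results_table(result: CEAResult) -> pd.DataFrame:
    """Two-row results table (intervention first) in the standard column order.

    Incremental columns and the ICER appear on the comparator row, the
    convention used when a two-arm comparison is printed.
    """
    icer_repr: float | str
    if result.icer is not None:
        icer_repr = result.icer
    else:
        icer_repr = result.dominance if result.dominance != "none" else "undefined"
    rows = [
        {
            "arm": result.intervention.name,
            "qaly": result.intervention.qaly,
            "ie": "",
            "cost": result.intervention.cost,
            "ic": "",
            "icer": "",
            "acer": result.acer_intervention,
            "net_benefit": result.nmb_intervention,
        },
        {
            "arm": result.comparator.name,
            "qaly": result.comparator.qaly,
            "ie": result.ie,
            "cost": result.comparator.cost,
            "ic": result.ic,
            "icer": icer_repr,
            "acer": result.acer_comparator,
            "net_benefit": result.nmb_comparator,
        },
    ]
    return pd.DataFrame(rows, columns=["arm", "qaly", "ie", "cost", "ic", "icer", "acer", "net_benefit"])
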