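"""Pairwise cost-effectiveness metrics: ICER, dominance and net monetary benefit.

The incremental cost-effectiveness ratio (ICER) is only meaningful when the
incremental cost and effect point into the trade-off quadrants; when the
intervention is cheaper *and* more effective it dominates (and the reverse is
dominated), and no ratio is reported.  Net monetary benefit converts effect
to money at the willingness-to-pay: ``NMB = effect * wtp - cost``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import ArmResult

__all__ = ["CEAResult", "compare", "nmb", "comparison_table"]

_EQUIV_TOL = 1e-12


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    status: str  # icer_defined | intervention_dominant | intervention_dominated | equivalent
    nmb_intervention: float
    nmb_comparator: float

    @property
    def incremental_nmb(self) -> float:
        return self.nmb_intervention - self.nmb_comparator


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return effect * wtp - cost


def compare(intervention: ArmResult, comparator: ArmResult, wtp: float) -> CEAResult:
    """Incremental cost, effect, ICER/dominance status and NMB per arm."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_eff = intervention.total_qaly - comparator.total_qaly
    icer: float | None = None
    if abs(d_eff) < _EQUIV_TOL:
        status = "equivalent"
    elif d_cost < 0 and d_eff > 0:
        status = "intervention_dominant"
    elif d_cost > 0 and d_eff < 0:
        status = "intervention_dominated"
    else:
        status = "icer_defined"
        icer = d_cost / d_eff
    return CEAResult(
        intervention=intervention.name,
        comparator=comparator.name,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=icer,
        status=status,
        nmb_intervention=nmb(intervention.total_cost, intervention.total_qaly, wtp),
        nmb_comparator=nmb(comparator.total_cost, comparator.total_qaly, wtp),
    )


def comparison_table(intervention: ArmResult, comparator: ArmResult, wtp: float):
    """Two-row DataFrame mirroring the usual CEA report layout
    (Cost, IC, Effect, IE, NMB, ICER)."""
    import pandas as pd

    res = compare(intervention, comparator, wtp)
    icer_cell = res.icer if res.status == "icer_defined" else res.status
    return pd.DataFrame(
        [
            {
                "arm": intervention.name,
                "cost": intervention.total_cost,
                "incremental_cost": res.delta_cost,
                "effect": intervention.total_qaly,
                "incremental_effect": res.delta_effect,
                "nmb": res.nmb_intervention,
                "icer": icer_cell,
            },
            {
                "arm": comparator.name,
                "cost": comparator.total_cost,
                "incremental_cost": None,
                "effect": comparator.total_qaly,
                "incremental_effect": None,
                "nmb": res.nmb_comparator,
                "icer": None,
            },
        ]
    )
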