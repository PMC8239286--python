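"""Partitioned-survival engine: state occupancy and discounted accrual.

State occupancy is read directly off the survival curves each month:

    OMD (progression-free)  = PFS
    PMD (progressed)        = OS - PFS
    dead                    = 1 - OS

Costs and QALYs accrue per monthly cycle with mid-cycle evaluation: state
membership for month ``m`` is the mean of the month-start and month-end
occupancy, and the discount factor is evaluated at ``t = m - 0.5`` months —
a half-cycle correction that approximates the continuous-time integral.

Cost components:

* ongoing state costs: annual OMD/PMD costs, prorated per month and (by
  default) scaled by the arm's systemic-therapy fraction;
* one-time items at t = 0, undiscounted: primary SABR delivery, per-patient
  expected salvage radiotherapy / salvage SABR, adverse-event treatment;
* end-of-life costs: a lump sum charged at the cycle of death on the
  incremental death probability.  Patients alive at the horizon never accrue
  it.

QALYs accrue as occupancy x utility per month, minus the one-time
adverse-event disutility at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import MonthlySurvival, enforce_dominance, interpolate_monthly
from .inputs import ArmSpec, EconSettings, ModelInputs, StateCosts, Utilities

__all__ = [
    "OccupancyTrace",
    "ArmResult",
    "compute_trace",
    "discount_factor",
    "accrue_qalys",
    "accrue_costs",
    "run_arm",
    "run_model",
]


@dataclass(frozen=True)
class OccupancyTrace:
    """State occupancy at every month boundary ``0..horizon``.

    Each row satisfies ``omd + pmd + dead = 1`` and ``dead`` is
    non-decreasing.
    """

    omd: np.ndarray
    pmd: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        omd = np.asarray(self.omd, float)
        pmd = np.asarray(self.pmd, float)
        dead = np.asarray(self.dead, float)
        for name, arr in (("omd", omd), ("pmd", pmd), ("dead", dead)):
            if np.any(arr < -1e-9):
                raise ValueError(f"{name} occupancy negative")
        if np.any(np.abs(omd + pmd + dead - 1.0) > 1e-9):
            raise ValueError("occupancy does not sum to 1 at some month")
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("dead-state occupancy must be non-decreasing")
        object.__setattr__(self, "omd", omd)
        object.__setattr__(self, "pmd", pmd)
        object.__setattr__(self, "dead", dead)

    @property
    def horizon(self) -> int:
        return len(self.omd) - 1


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one arm, with the cost breakdown and trace."""

    name: str
    total_cost: float
    total_qaly: float
    trace: OccupancyTrace
    cost_breakdown: dict[str, float]


def compute_trace(os: MonthlySurvival, pfs: MonthlySurvival) -> OccupancyTrace:
    """Partition survival into OMD / PMD / dead occupancy per month."""
    if len(os) != len(pfs):
        raise ValueError("OS and PFS must share a horizon")
    if np.any(pfs.values > os.values + 1e-12):
        raise ValueError("PFS exceeds OS: enforce dominance before tracing")
    pfs_v = np.minimum(pfs.values, os.values)
    return OccupancyTrace(omd=pfs_v, pmd=os.values - pfs_v, dead=1.0 - os.values)


def discount_factor(t_months, annual_rate: float):
    """Discount factor ``(1 + rate) ** (-t / 12)`` at accrual time t (months).

    The engine passes mid-cycle times ``m - 0.5``.  Accepts scalars or
    arrays; negative times are rejected.
    """
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("accrual time must be non-negative")
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    out = (1.0 + annual_rate) ** (-t / 12.0)
    return float(out) if np.isscalar(t_months) else out


def _mid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (x[:-1] + x[1:])


def accrue_qalys(
    trace: OccupancyTrace,
    utilities: Utilities,
    ae_disutility: float,
    settings: EconSettings,
) -> float:
    """Discounted QALY total: mid-cycle occupancy x utility, minus the
    one-time adverse-event disutility."""
    H = trace.horizon
    disc = discount_factor(np.arange(1, H + 1) - 0.5, settings.annual_discount_rate)
    monthly = (_mid(trace.omd) * utilities.u_omd + _mid(trace.pmd) * utilities.u_pmd) / 12.0
    return float(np.sum(monthly * disc) - ae_disutility)


def accrue_costs(
    trace: OccupancyTrace,
    state_costs: StateCosts,
    arm: ArmSpec,
    settings: EconSettings,
) -> tuple[float, dict[str, float]]:
    """Discounted cost total and its breakdown for one arm.

    Breakdown keys: ``state`` (ongoing OMD/PMD costs), ``one_time`` (t = 0
    items, undiscounted), ``end_of_life``.
    """
    if arm.arm_size == 0:
        raise ValueError("arm_size must be positive")
    H = trace.horizon
    disc = discount_factor(np.arange(1, H + 1) - 0.5, settings.annual_discount_rate)

    scale = (
        arm.systemic_therapy_fraction
        if settings.cost_scaling_mode == "systemic_fraction"
        else 1.0
    )
    monthly_state = (
        _mid(trace.omd) * state_costs.annual_omd_cost
        + _mid(trace.pmd) * state_costs.annual_pmd_cost
    ) * scale / 12.0
    state = float(np.sum(monthly_state * disc))

    one_time = arm.ae_onetime_cost
    if arm.receives_primary_sabr:
        one_time += state_costs.sabr_unit_cost
    one_time += (arm.salvage_rt_count / arm.arm_size) * state_costs.palliative_rt_unit_cost
    one_time += (arm.salvage_sabr_count / arm.arm_size) * state_costs.sabr_unit_cost

    eol = float(np.sum(np.diff(trace.dead) * state_costs.end_of_life_cost * disc))

    breakdown = {"state": state, "one_time": one_time, "end_of_life": eol}
    return state + one_time + eol, breakdown


def run_arm(
    arm: ArmSpec,
    state_costs: StateCosts,
    utilities: Utilities,
    settings: EconSettings,
) -> ArmResult:
    """Full deterministic pipeline for one arm.

    interpolate -> enforce dominance -> trace -> accrue costs and QALYs.
    """
    H = settings.horizon_months
    os_m = interpolate_monthly(arm.os, H)
    pfs_m = enforce_dominance(os_m, interpolate_monthly(arm.pfs, H))
    trace = compute_trace(os_m, pfs_m)
    qaly = accrue_qalys(trace, utilities, arm.ae_onetime_disutility, settings)
    cost, breakdown = accrue_costs(trace, state_costs, arm, settings)
    return ArmResult(
        name=arm.name,
        total_cost=cost,
        total_qaly=qaly,
        trace=trace,
        cost_breakdown=breakdown,
    )


def run_model(inputs: ModelInputs) -> dict[str, ArmResult]:
    """Run both arms; returns results keyed by arm name."""
    return {
        arm.name: run_arm(arm, inputs.costs, inputs.utilities, inputs.settings)
        for arm in inputs.arms
    }
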