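"""Survival-curve operations: monthly expansion, dominance, extrapolation.

Anchored survival curves (annual Kaplan-Meier estimates) are expanded to the
model's monthly grid with constant-hazard (piecewise-exponential)
interpolation: between anchors ``(a, S_a)`` and ``(b, S_b)``,

    S(t) = S_a * (S_b / S_a) ** ((t - a) / (b - a)),

the standard convention for converting interval survival probabilities to
cycle probabilities in state-transition models.  Beyond the last anchor the
last value is carried flat.

Long-term extrapolation splices a registry reference curve onto the trial
curve: the reference is entered at the point where it passes through the
trial's final survival level and followed from there, so the combined curve
is continuous and monotone.  PFS, for which no registry data exist, is
extended by carrying forward the trial-end PFS/OS ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inputs import SurvivalCurve

__all__ = [
    "MonthlySurvival",
    "interpolate_monthly",
    "curve_value",
    "enforce_dominance",
    "splice_extrapolate",
    "extrapolate_pfs_proportional",
    "pool_reference_curves",
    "read_curve_csv",
    "write_curve_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonthlySurvival:
    """Survival probabilities on a monthly grid, months ``0..horizon``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("monthly survival needs a 1-D array of >= 2 values")
        if abs(v[0] - 1.0) > 1e-12:
            raise ValueError(f"survival at month 0 must be 1.0, got {v[0]}")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("monthly survival values must lie in [0, 1]")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("monthly survival must be non-increasing")

    @property
    def horizon(self) -> int:
        return len(self.values) - 1

    def __len__(self) -> int:
        return len(self.values)


def _segment_value(sa: float, sb: float, frac: float) -> float:
    """Constant-hazard interpolation within one anchor segment."""
    if frac <= 0.0:
        return sa
    if frac >= 1.0:
        return sb
    if sa <= 0.0 or sb <= 0.0:
        # zero is absorbing: once a curve touches 0 it stays there; a segment
        # ending at 0 carries infinite hazard, so any interior point is 0
        return 0.0
    return sa * (sb / sa) ** frac


def curve_value(curve: SurvivalCurve, t_years: float) -> float:
    """Evaluate a curve at an arbitrary time (years), flat beyond the end."""
    if t_years < 0:
        raise ValueError("time must be non-negative")
    times = curve.times
    values = curve.values
    if t_years >= times[-1]:
        return values[-1]
    i = int(np.searchsorted(times, t_years, side="right")) - 1
    a, b = times[i], times[i + 1]
    return _segment_value(values[i], values[i + 1], (t_years - a) / (b - a))


def interpolate_monthly(curve: SurvivalCurve, horizon_months: int) -> MonthlySurvival:
    """Expand an anchored curve to monthly survival over ``0..horizon_months``.

    Anchor months are reproduced exactly; between anchors the constant-hazard
    rule applies; beyond the last anchor the last value is carried flat.
    """
    if horizon_months <= 0:
        raise ValueError(f"horizon must be positive, got {horizon_months}")
    t_months = np.array(curve.times, dtype=float) * 12.0
    s = np.array(curve.values, dtype=float)
    m = np.arange(horizon_months + 1, dtype=float)
    out = np.empty_like(m)

    inside = m < t_months[-1]
    out[~inside] = s[-1]
    if np.any(inside):
        mi = m[inside]
        seg = np.searchsorted(t_months, mi, side="right") - 1
        a = t_months[seg]
        b = t_months[seg + 1]
        sa = s[seg]
        sb = s[seg + 1]
        frac = (mi - a) / (b - a)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sa > 0, sb / np.where(sa > 0, sa, 1.0), 0.0)
            vals = sa * np.power(ratio, frac)
        vals = np.where(frac <= 0.0, sa, vals)
        vals = np.where((sb <= 0.0) & (frac > 0.0), 0.0, vals)
        vals = np.where(sa <= 0.0, 0.0, vals)
        out[inside] = vals
    return MonthlySurvival(out)


def enforce_dominance(os: MonthlySurvival, pfs: MonthlySurvival) -> MonthlySurvival:
    """Clip PFS to OS pointwise so the state partition stays non-negative.

    Returns the adjusted PFS; logs a warning naming the first clipped month.
    """
    if len(os) != len(pfs):
        raise ValueError(
            f"length mismatch: OS has {len(os)} months, PFS has {len(pfs)}"
        )
    violating = pfs.values > os.values + 1e-15
    if np.any(violating):
        first = int(np.argmax(violating))
        logger.warning(
            "PFS exceeds OS starting at month %d (PFS=%.6f > OS=%.6f); clipping",
            first, pfs.values[first], os.values[first],
        )
        return MonthlySurvival(np.minimum(pfs.values, os.values))
    return pfs


def _invert_reference(reference: SurvivalCurve, s_target: float) -> float:
    """Earliest time (years) at which the reference passes through s_target."""
    times = reference.times
    values = reference.values
    if s_target > values[0] + 1e-12:
        raise ValueError(
            f"reference starts below the target survival {s_target}"
        )
    for i in range(len(times) - 1):
        sa, sb = values[i], values[i + 1]
        if abs(sa - s_target) <= 1e-12:
            return times[i]
        if sb <= s_target <= sa:
            if abs(sa - sb) <= 1e-15:
                return times[i]
            if sb <= 0.0:
                # hazard is infinite on this segment; the level is reached at
                # the segment end
                return times[i + 1] if s_target <= 0.0 else times[i + 1]
            frac = math.log(s_target / sa) / math.log(sb / sa)
            return times[i] + frac * (times[i + 1] - times[i])
    if abs(values[-1] - s_target) <= 1e-12:
        return times[-1]
    raise ValueError(
        f"reference curve never reaches survival {s_target:.6g} "
        f"(last value {values[-1]:.6g} at {times[-1]:.6g} y); supply a "
        "reference with longer support"
    )


def splice_extrapolate(
    trial: SurvivalCurve, reference: SurvivalCurve, horizon_years: float
) -> SurvivalCurve:
    """Extend a trial curve beyond its end by following a reference curve.

    The reference is entered at the earliest time ``t*`` where it equals the
    trial's final survival ``S_end``; for ``t`` beyond the trial end ``T`` the
    output is ``reference(t* + (t - T))``.  The result is continuous at ``T``
    and monotone.  Raises if the reference never declines through ``S_end`` or
    its support ends before ``t* + (horizon - T)``.
    """
    T = trial.end_time
    if horizon_years <= T:
        return trial
    s_end = trial.end_value
    t_star = _invert_reference(reference, s_end)
    need = t_star + (horizon_years - T)
    if need > reference.end_time + 1e-9 and reference.end_value > 0:
        # flat-tail convention covers the remainder; only warn when the
        # reference ends above zero well before the requested horizon
        logger.info(
            "reference support ends at %.3g y; carrying its last value flat "
            "to cover the %.3g-y horizon", reference.end_time, horizon_years,
        )
    anchors: list[tuple[float, float]] = list(trial.anchors)
    ref_times = reference.times
    for tau, s in zip(ref_times, reference.values):
        if tau <= t_star + 1e-12:
            continue
        t_out = T + (tau - t_star)
        if t_out >= horizon_years - 1e-12:
            break
        anchors.append((t_out, min(s, anchors[-1][1])))
    s_h = curve_value(reference, t_star + (horizon_years - T))
    anchors.append((horizon_years, min(s_h, anchors[-1][1])))
    return SurvivalCurve(tuple(anchors))


def extrapolate_pfs_proportional(
    os_ext: SurvivalCurve, trial_pfs: SurvivalCurve, trial_os: SurvivalCurve
) -> SurvivalCurve:
    """Extend PFS beyond the trial by keeping the trial-end PFS/OS ratio.

    With ``r = PFS(T) / OS(T)`` at the shared trial end ``T``, the output is
    the trial PFS up to ``T`` and ``r * os_ext(t)`` after.  ``r = 0`` when
    PFS(T) = 0; an error is raised when OS(T) = 0 with PFS(T) > 0.
    """
    T = trial_pfs.end_time
    if abs(trial_os.end_time - T) > 1e-9:
        raise ValueError(
            f"trial OS and PFS must share an end time, got {trial_os.end_time} "
            f"and {T}"
        )
    pfs_T = trial_pfs.end_value
    os_T = trial_os.end_value
    if os_T <= 0.0:
        if pfs_T > 0.0:
            raise ValueError("OS(T) = 0 with PFS(T) > 0: proportionality ratio undefined")
        r = 0.0
    else:
        r = pfs_T / os_T
    anchors: list[tuple[float, float]] = list(trial_pfs.anchors)
    for t, s in os_ext.anchors:
        if t <= T + 1e-12:
            continue
        anchors.append((t, min(r * s, anchors[-1][1])))
    return SurvivalCurve(tuple(anchors))


def pool_reference_curves(
    curves: Sequence[SurvivalCurve], weights: Sequence[float]
) -> SurvivalCurve:
    """Pointwise weighted mean of survival curves (cohort mixture).

    Curves on different anchor grids are first resampled (constant-hazard)
    onto the union of all grids.  Weights must be non-negative and sum to 1
    within 1e-9.
    """
    if len(curves) != len(weights):
        raise ValueError("need one weight per curve")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum():.12g}")
    grid = sorted({t for c in curves for t in c.times})
    pooled = []
    for t in grid:
        pooled.append((t, float(sum(wi * curve_value(c, t) for wi, c in zip(w, curves)))))
    # numerical guard: a convex combination of monotone curves is monotone,
    # but resampling round-off can leave 1e-17-scale wiggles
    repaired = []
    running = 1.0
    for t, s in pooled:
        s = min(s, running)
        running = s
        repaired.append((t, s))
    return SurvivalCurve(tuple(repaired))


def write_curve_csv(curve: SurvivalCurve, path) -> None:
    """Two-column CSV (time_years, survival)."""
    import pandas as pd

    pd.DataFrame(curve.anchors, columns=["time_years", "survival"]).to_csv(
        path, index=False
    )


def read_curve_csv(path) -> SurvivalCurve:
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_years", "survival"]:
        raise ValueError(
            "curve CSV must have columns time_years,survival; got "
            f"{list(df.columns)}"
        )
    return SurvivalCurve(tuple(zip(df["time_years"], df["survival"])))
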