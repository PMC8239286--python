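"""Validated model inputs for the partitioned-survival cost-effectiveness model.

The model compares stereotactic ablative radiotherapy (SABR) added to standard
care (SC) against SC alone for oligometastatic cancer, in a US health-care
perspective.  All quantities needed to run the model live here: per-arm
overall-survival (OS) and progression-free-survival (PFS) anchor curves,
annual state costs, one-time cost items, utility weights, and the economic
settings (discount rate, horizon, willingness-to-pay).

:func:`reference_inputs` returns the bundled published input set;
:func:`read_config` / :func:`write_config` round-trip the same content through
a YAML file so users can run the model on their own numbers.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "SurvivalCurve",
    "StateCosts",
    "Utilities",
    "ArmSpec",
    "EconSettings",
    "ModelInputs",
    "ConfigError",
    "reference_inputs",
    "read_config",
    "write_config",
    "set_parameter",
    "get_parameter",
    "export_inputs_csv",
]


class ConfigError(ValueError):
    """Raised when a configuration file or input object fails validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalCurve:
    """A monotone survival function defined by (time, survival) anchors.

    Parameters
    ----------
    anchors
        Ordered sequence of ``(time_years, survival_probability)`` pairs.
        The first anchor must be ``(0, 1.0)``, times must be strictly
        increasing and survival non-increasing within ``[0, 1]``.
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        anchors = tuple((float(t), float(s)) for t, s in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if not anchors:
            raise ConfigError("survival curve needs at least one anchor")
        t0, s0 = anchors[0]
        if t0 != 0.0 or abs(s0 - 1.0) > 1e-12:
            raise ConfigError(
                f"first survival anchor must be (0, 1.0), got ({t0}, {s0})"
            )
        for i, (t, s) in enumerate(anchors):
            if not 0.0 <= s <= 1.0:
                raise ConfigError(
                    f"survival value out of [0, 1] at anchor index {i}: {s}"
                )
            if i > 0:
                tp, sp = anchors[i - 1]
                if t <= tp:
                    raise ConfigError(
                        f"anchor times not strictly increasing at index {i}: "
                        f"{tp} -> {t}"
                    )
                if s > sp + 1e-12:
                    raise ConfigError(
                        f"survival not non-increasing at anchor index {i}: "
                        f"{sp} -> {s}"
                    )

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.anchors)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(s for _, s in self.anchors)

    @property
    def end_time(self) -> float:
        return self.anchors[-1][0]

    @property
    def end_value(self) -> float:
        return self.anchors[-1][1]


def _require_nonneg(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise ConfigError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class StateCosts:
    """Cost inputs shared by both arms, in US dollars.

    ``annual_omd_cost`` / ``annual_pmd_cost`` are cumulative annual health
    expenditures in the oligometastatic (progression-free) and polymetastatic
    (progressed) states.  ``end_of_life_cost`` is a lump sum for the last 180
    days before death; ``palliative_rt_unit_cost`` and ``sabr_unit_cost`` are
    per-course treatment prices.
    """

    annual_omd_cost: float
    annual_pmd_cost: float
    end_of_life_cost: float
    palliative_rt_unit_cost: float
    sabr_unit_cost: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            object.__setattr__(
                self, f.name, _require_nonneg(f.name, getattr(self, f.name))
            )


@dataclass(frozen=True)
class Utilities:
    """Health-state utility weights on the 0 (death) to 1 (full health) scale."""

    u_omd: float
    u_pmd: float

    def __post_init__(self) -> None:
        for name in ("u_omd", "u_pmd"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
            object.__setattr__(self, name, v)
        if self.u_pmd > self.u_omd:
            warnings.warn(
                "u_pmd exceeds u_omd: progressed disease is usually valued "
                "below the progression-free state",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ArmSpec:
    """Everything specific to one strategy arm.

    ``ae_onetime_cost`` and ``ae_onetime_disutility`` are per-patient expected
    adverse-event burdens applied once at the start of the simulation; the
    disutility is stored as a positive magnitude and subtracted from the QALY
    total.  Salvage head-counts are trial counts; dividing by ``arm_size``
    yields the per-patient expected salvage cost charged at time zero.
    """

    name: str
    os: SurvivalCurve
    pfs: SurvivalCurve
    arm_size: int
    systemic_therapy_fraction: float
    ae_onetime_cost: float
    ae_onetime_disutility: float
    salvage_rt_count: int
    salvage_sabr_count: int
    receives_primary_sabr: bool

    def __post_init__(self) -> None:
        if self.arm_size <= 0:
            raise ConfigError(f"arm_size must be positive, got {self.arm_size}")
        if not 0.0 <= self.systemic_therapy_fraction <= 1.0:
            raise ConfigError(
                "systemic_therapy_fraction must lie in [0, 1], got "
                f"{self.systemic_therapy_fraction}"
            )
        for cname in ("salvage_rt_count", "salvage_sabr_count"):
            c = getattr(self, cname)
            if c < 0 or c > self.arm_size:
                raise ConfigError(
                    f"{cname}={c} must lie in [0, arm_size={self.arm_size}]"
                )
        _require_nonneg("ae_onetime_cost", self.ae_onetime_cost)
        _require_nonneg("ae_onetime_disutility", self.ae_onetime_disutility)


@dataclass(frozen=True)
class EconSettings:
    """Economic conventions: discounting, cycle structure, horizon and WTP.

    ``cost_scaling_mode`` controls whether annual state costs are multiplied
    by the arm's systemic-therapy fraction (``"systemic_fraction"``, the
    default) or applied to every patient (``"none"``).
    """

    annual_discount_rate: float = 0.03
    cycle_length_months: int = 1
    horizon_months: int = 72
    wtp: float = 100_000.0
    cost_scaling_mode: str = "systemic_fraction"

    def __post_init__(self) -> None:
        if self.annual_discount_rate < 0:
            raise ConfigError("annual_discount_rate must be >= 0")
        if self.cycle_length_months != 1:
            raise ConfigError("cycle_length_months is fixed at 1 month")
        if self.horizon_months <= 0 or self.horizon_months % self.cycle_length_months:
            raise ConfigError(
                "horizon_months must be a positive multiple of the cycle length"
            )
        if self.cost_scaling_mode not in ("systemic_fraction", "none"):
            raise ConfigError(
                "cost_scaling_mode must be 'systemic_fraction' or 'none', got "
                f"{self.cost_scaling_mode!r}"
            )
        _require_nonneg("wtp", self.wtp)


@dataclass(frozen=True)
class ModelInputs:
    """A complete, validated input set: two arms plus shared parameters."""

    arms: tuple[ArmSpec, ArmSpec]
    costs: StateCosts
    utilities: Utilities
    settings: EconSettings

    def arm(self, name: str) -> ArmSpec:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"no arm named {name!r}")

    @property
    def intervention(self) -> ArmSpec:
        """The arm that receives primary SABR."""
        for a in self.arms:
            if a.receives_primary_sabr:
                return a
        raise ValueError("no arm flagged receives_primary_sabr")

    @property
    def comparator(self) -> ArmSpec:
        for a in self.arms:
            if not a.receives_primary_sabr:
                return a
        raise ValueError("every arm is flagged receives_primary_sabr")


# ---------------------------------------------------------------------------
# Bundled published input set
# ---------------------------------------------------------------------------

# Annual OS/PFS anchors per arm, digitized at yearly resolution from the
# SABR-COMET Kaplan-Meier analysis; years 5-6 repeat the year-4/5 values
# (flat tail).  Times in years.
_SC_OS = ((0, 1.0), (1, 0.88), (2, 0.58), (3, 0.38), (4, 0.18), (5, 0.18), (6, 0.18))
_SC_PFS = ((0, 1.0), (1, 0.19), (2, 0.13), (3, 0.07), (4, 0.04), (5, 0.0), (6, 0.0))
_SABR_OS = ((0, 1.0), (1, 0.88), (2, 0.69), (3, 0.62), (4, 0.52), (5, 0.42), (6, 0.42))
_SABR_PFS = ((0, 1.0), (1, 0.5), (2, 0.38), (3, 0.3), (4, 0.21), (5, 0.18), (6, 0.18))


def reference_inputs() -> ModelInputs:
    """The bundled published input set for SABR versus standard care.

    Costs are 2019 US dollars.  Arm sizes (66 SABR / 33 SC) are the trial's
    randomization; they serve only as denominators for per-patient expected
    salvage costs.
    """
    sabr = ArmSpec(
        name="SABR",
        os=SurvivalCurve(_SABR_OS),
        pfs=SurvivalCurve(_SABR_PFS),
        arm_size=66,
        systemic_therapy_fraction=0.55,
        ae_onetime_cost=1_443.0,
        ae_onetime_disutility=0.002,
        salvage_rt_count=16,
        salvage_sabr_count=9,
        receives_primary_sabr=True,
    )
    sc = ArmSpec(
        name="SC",
        os=SurvivalCurve(_SC_OS),
        pfs=SurvivalCurve(_SC_PFS),
        arm_size=33,
        systemic_therapy_fraction=0.636,
        ae_onetime_cost=997.0,
        ae_onetime_disutility=0.0008,
        salvage_rt_count=23,
        salvage_sabr_count=0,
        receives_primary_sabr=False,
    )
    costs = StateCosts(
        annual_omd_cost=97_440.0,
        annual_pmd_cost=189_840.0,
        end_of_life_cost=19_174.0,
        palliative_rt_unit_cost=11_070.0,
        sabr_unit_cost=11_700.0,
    )
    utilities = Utilities(u_omd=0.82, u_pmd=0.59)
    settings = EconSettings()
    return ModelInputs(arms=(sabr, sc), costs=costs, utilities=utilities, settings=settings)



# ---------------------------------------------------------------------------
# Configuration file round-trip
# ---------------------------------------------------------------------------

_SETTINGS_KEYS = {
    "annual_discount_rate",
    "cycle_length_months",
    "horizon_months",
    "wtp",
    "cost_scaling_mode",
}
_COSTS_KEYS = {
    "annual_omd_cost",
    "annual_pmd_cost",
    "end_of_life_cost",
    "palliative_rt_unit_cost",
    "sabr_unit_cost",
}
_UTILITIES_KEYS = {"u_omd", "u_pmd"}
_ARM_KEYS = {
    "name",
    "arm_size",
    "systemic_therapy_fraction",
    "ae_onetime_cost",
    "ae_onetime_disutility",
    "salvage_rt_count",
    "salvage_sabr_count",
    "receives_primary_sabr",
    "os",
    "pfs",
}


def _check_keys(section: str, mapping: dict, allowed: set[str], required: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {', '.join(sorted(unknown))}"
        )
    missing = required - set(mapping)
    if missing:
        raise ConfigError(
            f"missing field(s) in {section}: {', '.join(sorted(missing))}"
        )


def _curve_from_config(section: str, rows: object) -> SurvivalCurve:
    if not isinstance(rows, list) or not all(
        isinstance(r, (list, tuple)) and len(r) == 2 for r in rows
    ):
        raise ConfigError(f"{section} must be a list of [time_years, survival] pairs")
    try:
        return SurvivalCurve(tuple((float(t), float(s)) for t, s in rows))
    except ConfigError as exc:
        raise ConfigError(f"{section}: {exc}") from None


def read_config(path: str | Path) -> ModelInputs:
    """Read a YAML model configuration and return validated inputs.

    Unknown keys are rejected by name; missing required fields are reported
    by name.  ``settings`` is optional and individual settings fall back to
    their defaults (3% discount, 72-month horizon, WTP $100,000/QALY).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys("config", raw, {"settings", "costs", "utilities", "arms"},
                {"costs", "utilities", "arms"})

    settings_raw = raw.get("settings", {}) or {}
    _check_keys("settings", settings_raw, _SETTINGS_KEYS, set())
    settings = EconSettings(**settings_raw)

    _check_keys("costs", raw["costs"], _COSTS_KEYS, _COSTS_KEYS)
    costs = StateCosts(**raw["costs"])

    _check_keys("utilities", raw["utilities"], _UTILITIES_KEYS, _UTILITIES_KEYS)
    utilities = Utilities(**raw["utilities"])

    arms_raw = raw["arms"]
    if not isinstance(arms_raw, list) or len(arms_raw) != 2:
        raise ConfigError("arms must be a list of exactly two arm mappings")
    arms = []
    for i, arm_raw in enumerate(arms_raw):
        section = f"arms[{i}]"
        _check_keys(section, arm_raw, _ARM_KEYS, _ARM_KEYS)
        arm_raw = dict(arm_raw)
        os_curve = _curve_from_config(f"{section}.os", arm_raw.pop("os"))
        pfs_curve = _curve_from_config(f"{section}.pfs", arm_raw.pop("pfs"))
        arms.append(ArmSpec(os=os_curve, pfs=pfs_curve, **arm_raw))
    return ModelInputs(arms=tuple(arms), costs=costs, utilities=utilities,
                       settings=settings)


def _curve_to_config(curve: SurvivalCurve) -> list[list[float]]:
    return [[t, s] for t, s in curve.anchors]


def write_config(inputs: ModelInputs, path: str | Path) -> None:
    """Serialize inputs to YAML such that :func:`read_config` round-trips."""
    doc = {
        "settings": dataclasses.asdict(inputs.settings),
        "costs": dataclasses.asdict(inputs.costs),
        "utilities": dataclasses.asdict(inputs.utilities),
        "arms": [],
    }
    for arm in inputs.arms:
        d = dataclasses.asdict(arm)
        d["os"] = _curve_to_config(arm.os)
        d["pfs"] = _curve_to_config(arm.pfs)
        # asdict turns the curve dataclasses into nested dicts; replace them
        d.pop("anchors", None)
        doc["arms"].append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def export_inputs_csv(inputs: ModelInputs, path: str | Path) -> None:
    """Flat CSV dump of every scalar input and curve anchor, for inspection."""
    import pandas as pd

    rows: list[tuple[str, float]] = []
    for f in dataclasses.fields(inputs.costs):
        rows.append((f.name, getattr(inputs.costs, f.name)))
    for f in dataclasses.fields(inputs.utilities):
        rows.append((f.name, getattr(inputs.utilities, f.name)))
    for f in dataclasses.fields(inputs.settings):
        v = getattr(inputs.settings, f.name)
        if isinstance(v, (int, float)):
            rows.append((f.name, v))
    for arm in inputs.arms:
        for f in (
            "arm_size",
            "systemic_therapy_fraction",
            "ae_onetime_cost",
            "ae_onetime_disutility",
            "salvage_rt_count",
            "salvage_sabr_count",
        ):
            rows.append((f"{arm.name}.{f}", getattr(arm, f)))
        for cname in ("os", "pfs"):
            curve: SurvivalCurve = getattr(arm, cname)
            for i, (t, s) in enumerate(curve.anchors):
                rows.append((f"{arm.name}.{cname}[{i}]@{t:g}y", s))
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameter addressing (used by the deterministic and probabilistic
# sensitivity analyses)
# ---------------------------------------------------------------------------

_ANCHOR_RE = re.compile(r"^(?P<arm>[^.]+)\.(?P<curve>os|pfs)\[(?P<idx>\d+)\]$")
_FACTOR_RE = re.compile(r"^(?P<arm>[^.]+)\.(?P<curve>os|pfs)_factor$")


def _repair_anchors(anchors: Sequence[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    """Clip survival values to [0, 1] and restore monotone non-increase.

    The first anchor is pinned to survival 1; later anchors are lowered to the
    running minimum (sequential-minimum repair).
    """
    out: list[tuple[float, float]] = []
    running = 1.0
    for i, (t, s) in enumerate(anchors):
        s = min(max(float(s), 0.0), 1.0)
        if i == 0:
            s = 1.0
        s = min(s, running)
        running = s
        out.append((float(t), s))
    return tuple(out)


def _replace_arm(inputs: ModelInputs, arm_name: str, **changes) -> ModelInputs:
    arms = tuple(
        dataclasses.replace(a, **changes) if a.name == arm_name else a
        for a in inputs.arms
    )
    if not any(a.name == arm_name for a in inputs.arms):
        raise KeyError(f"no arm named {arm_name!r}")
    return dataclasses.replace(inputs, arms=arms)


def set_parameter(inputs: ModelInputs, param_id: str, value: float) -> ModelInputs:
    """Return a copy of *inputs* with one addressed parameter replaced.

    Supported addresses::

        annual_omd_cost, annual_pmd_cost, end_of_life_cost,
        palliative_rt_unit_cost, sabr_unit_cost         # shared costs
        u_omd, u_pmd                                     # utilities
        <ARM>.ae_onetime_cost, <ARM>.ae_onetime_disutility
        <ARM>.systemic_therapy_fraction
        <ARM>.os[<i>], <ARM>.pfs[<i>]    # one anchor's survival value
        <ARM>.os_factor, <ARM>.pfs_factor  # multiply all anchors (t > 0)

    Curve edits are clipped to [0, 1] and monotonicity is restored by the
    sequential-minimum repair.
    """
    if param_id in _COSTS_KEYS:
        return dataclasses.replace(
            inputs, costs=dataclasses.replace(inputs.costs, **{param_id: value})
        )
    if param_id in _UTILITIES_KEYS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            utilities = dataclasses.replace(inputs.utilities, **{param_id: value})
        return dataclasses.replace(inputs, utilities=utilities)

    m = _ANCHOR_RE.match(param_id)
    if m:
        arm = inputs.arm(m["arm"])
        curve: SurvivalCurve = getattr(arm, m["curve"])
        idx = int(m["idx"])
        if not 0 < idx < len(curve.anchors):
            raise KeyError(
                f"anchor index {idx} out of range for {m['arm']}.{m['curve']}"
            )
        anchors = list(curve.anchors)
        anchors[idx] = (anchors[idx][0], float(value))
        new_curve = SurvivalCurve(_repair_anchors(anchors))
        return _replace_arm(inputs, m["arm"], **{m["curve"]: new_curve})

    m = _FACTOR_RE.match(param_id)
    if m:
        arm = inputs.arm(m["arm"])
        curve = getattr(arm, m["curve"])
        anchors = [(t, s * float(value)) if t > 0 else (t, s) for t, s in curve.anchors]
        new_curve = SurvivalCurve(_repair_anchors(anchors))
        return _replace_arm(inputs, m["arm"], **{m["curve"]: new_curve})

    if "." in param_id:
        arm_name, field_name = param_id.split(".", 1)
        if field_name in ("ae_onetime_cost", "ae_onetime_disutility",
                          "systemic_therapy_fraction"):
            return _replace_arm(inputs, arm_name, **{field_name: float(value)})

    raise KeyError(f"unknown parameter id: {param_id!r}")


def get_parameter(inputs: ModelInputs, param_id: str) -> float:
    """Current value of an addressed scalar parameter (factors read as 1.0)."""
    if param_id in _COSTS_KEYS:
        return getattr(inputs.costs, param_id)
    if param_id in _UTILITIES_KEYS:
        return getattr(inputs.utilities, param_id)
    m = _ANCHOR_RE.match(param_id)
    if m:
        curve: SurvivalCurve = getattr(inputs.arm(m["arm"]), m["curve"])
        return curve.anchors[int(m["idx"])][1]
    if _FACTOR_RE.match(param_id):
        return 1.0
    if "." in param_id:
        arm_name, field_name = param_id.split(".", 1)
        if field_name in ("ae_onetime_cost", "ae_onetime_disutility",
                          "systemic_therapy_fraction"):
            return getattr(inputs.arm(arm_name), field_name)
    raise KeyError(f"unknown parameter id: {param_id!r}")
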