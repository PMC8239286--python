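"""Probabilistic sensitivity analysis: second-order Monte Carlo.

Each parameter's published (mean, low, high) triple is converted to a
distribution by moment matching, reading the range as a 95% interval:
``sd = (high - low) / (2 * 1.96)``.  Utilities, disutilities and survival
anchors get beta distributions; costs get gamma distributions.  Parameters
with zero spread (or boundary means like a survival anchor of 0) are
degenerate and stay at their base value.

Per iteration, one joint draw perturbs the model: shared parameters (state
costs, utilities, end-of-life and radiotherapy unit prices) are drawn once
and applied to both arms — the arms face the same price and preference
environment — while arm-specific items (adverse-event burden, each arm's
OS/PFS anchors) are drawn per arm.  Sampled anchors are repaired to a valid
survival curve (clip to [0, 1], sequential-minimum monotonicity; PFS > OS is
clipped downstream by the engine).  The full model then runs on the
perturbed inputs.

Summaries: acceptability (share of iterations with positive incremental NMB
at the willingness-to-pay), dominant-strategy share (cheaper and more
effective), mean incremental cost/effect, and the ICER of mean outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import run_model
from .inputs import ModelInputs, get_parameter, set_parameter
from .metrics import compare

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "fit_beta_from_mean_range",
    "fit_gamma_from_mean_range",
    "reference_psa_specs",
    "sample_inputs",
    "run_psa",
    "ceac_table",
]

logger = logging.getLogger(__name__)

_REPAIR_WARN = 0.2  # warn when monotonicity repair moves an anchor this much


@dataclass(frozen=True)
class DistributionSpec:
    """(family, mean, low, high) for one varied parameter.

    ``family`` is ``"beta"``, ``"gamma"`` or ``"degenerate"``.
    """

    param_id: str
    family: str
    mean: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "degenerate"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.low <= self.mean <= self.high:
            raise ValueError(
                f"{self.param_id}: need low <= mean <= high, got "
                f"({self.low}, {self.mean}, {self.high})"
            )
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValueError(f"{self.param_id}: beta mean must lie in (0, 1)")
        if self.family == "gamma" and self.mean <= 0.0:
            raise ValueError(f"{self.param_id}: gamma mean must be positive")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / (2.0 * 1.96)


def fit_beta_from_mean_range(mean: float, low: float, high: float) -> tuple[float, float]:
    """Moment-matched beta shape parameters from a mean and 95% range."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if high <= low:
        raise ValueError("need high > low for a non-degenerate beta")
    sd = (high - low) / (2.0 * 1.96)
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"implied variance {var:.4g} >= mean*(1-mean) = "
            f"{mean * (1 - mean):.4g}: infeasible for a beta; use a "
            "degenerate spec instead"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma_from_mean_range(mean: float, low: float, high: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale) from a mean and 95% range."""
    if mean <= 0.0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    sd = (high - low) / (2.0 * 1.96)
    if sd <= 0.0:
        raise ValueError("zero spread: use a degenerate spec instead")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def _curve_anchor_spec(param_id: str, value: float, rel: float = 0.15) -> DistributionSpec:
    """Beta spec for one survival anchor with a ±`rel` 95% range.

    Anchors at 0 or 1 cannot carry a beta and are kept degenerate.
    """
    if value <= 0.0 or value >= 1.0:
        return DistributionSpec(param_id, "degenerate", value, value, value)
    low = max(0.0, value * (1.0 - rel))
    high = min(1.0, value * (1.0 + rel))
    return DistributionSpec(param_id, "beta", value, low, high)


def reference_psa_specs(inputs: ModelInputs) -> list[DistributionSpec]:
    """The published PSA parameterization.

    Gamma for every cost input (printed ranges), beta for utilities (printed
    ranges), disutilities (±10%) and each survival anchor (±15%).
    """
    specs = [
        DistributionSpec("annual_omd_cost", "gamma", 97_440.0, 77_952.0, 116_928.0),
        DistributionSpec("annual_pmd_cost", "gamma", 189_840.0, 151_872.0, 227_808.0),
        DistributionSpec("end_of_life_cost", "gamma", 19_174.0, 15_339.0, 23_009.0),
        DistributionSpec("palliative_rt_unit_cost", "gamma", 11_070.0, 8_856.0, 13_284.0),
        DistributionSpec("sabr_unit_cost", "gamma", 11_700.0, 8_190.0, 14_040.0),
        DistributionSpec("u_omd", "beta", 0.82, 0.70, 0.90),
        DistributionSpec("u_pmd", "beta", 0.59, 0.50, 0.70),
    ]
    for arm in inputs.arms:
        c = arm.ae_onetime_cost
        specs.append(
            DistributionSpec(
                f"{arm.name}.ae_onetime_cost", "gamma" if c > 0 else "degenerate",
                c, round(c * 0.8), round(c * 1.2),
            )
        )
        d = arm.ae_onetime_disutility
        specs.append(
            DistributionSpec(
                f"{arm.name}.ae_onetime_disutility",
                "beta" if 0 < d < 1 else "degenerate",
                d, d * 0.9, min(1.0, d * 1.1),
            )
        )
        for cname in ("os", "pfs"):
            for i, (t, s) in enumerate(getattr(arm, cname).anchors):
                if i == 0:
                    continue
                specs.append(_curve_anchor_spec(f"{arm.name}.{cname}[{i}]", s))
    return specs


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "degenerate" or spec.high == spec.low:
        return spec.mean
    if spec.family == "beta":
        a, b = fit_beta_from_mean_range(spec.mean, spec.low, spec.high)
        return float(rng.beta(a, b))
    shape, scale = fit_gamma_from_mean_range(spec.mean, spec.low, spec.high)
    return float(rng.gamma(shape, scale))


def sample_inputs(
    specs: Sequence[DistributionSpec],
    inputs: ModelInputs,
    rng: np.random.Generator | int,
) -> ModelInputs:
    """One joint draw of all varied parameters, applied to the base inputs.

    Draw order follows the spec list, so a fixed seed reproduces the sample.
    Survival anchors are repaired after sampling (clip to [0, 1], sequential
    minimum); a repair that moves any anchor by more than 0.2 in absolute
    survival is logged as a warning.  All draws are applied in one pass so a
    10,000-iteration PSA stays cheap.
    """
    import dataclasses

    from .inputs import SurvivalCurve, _repair_anchors

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = {spec.param_id: _draw(spec, rng) for spec in specs}

    cost_changes = {k: draws.pop(k) for k in list(draws) if hasattr(inputs.costs, k)}
    util_changes = {k: draws.pop(k) for k in list(draws) if k in ("u_omd", "u_pmd")}
    costs = dataclasses.replace(inputs.costs, **cost_changes) if cost_changes else inputs.costs
    if util_changes:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            utilities = dataclasses.replace(inputs.utilities, **util_changes)
    else:
        utilities = inputs.utilities

    arms = []
    for arm in inputs.arms:
        changes: dict = {}
        for fname in ("ae_onetime_cost", "ae_onetime_disutility",
                      "systemic_therapy_fraction"):
            key = f"{arm.name}.{fname}"
            if key in draws:
                changes[fname] = draws.pop(key)
        for cname in ("os", "pfs"):
            curve = getattr(arm, cname)
            anchors = list(curve.anchors)
            touched = False
            for i in range(1, len(anchors)):
                key = f"{arm.name}.{cname}[{i}]"
                if key in draws:
                    anchors[i] = (anchors[i][0], draws.pop(key))
                    touched = True
            if touched:
                repaired = _repair_anchors(anchors)
                worst = max(
                    abs(a[1] - b[1]) for a, b in zip(repaired, anchors)
                )
                if worst > _REPAIR_WARN:
                    logger.warning(
                        "monotonicity repair moved a %s.%s anchor by %.3f",
                        arm.name, cname, worst,
                    )
                changes[cname] = SurvivalCurve(repaired)
        arms.append(dataclasses.replace(arm, **changes) if changes else arm)

    if draws:
        # anything left addresses a parameter outside the fast path
        out = dataclasses.replace(
            inputs, arms=tuple(arms), costs=costs, utilities=utilities
        )
        for key, value in draws.items():
            out = set_parameter(out, key, value)
        return out
    return dataclasses.replace(
        inputs, arms=tuple(arms), costs=costs, utilities=utilities
    )


@dataclass(frozen=True)
class PSAResult:
    """Iteration-level PSA outcomes plus summary statistics.

    Percentages are on the 0-100 scale.
    """

    intervention: str
    comparator: str
    wtp: float
    seed: int
    cost_intervention: np.ndarray
    qaly_intervention: np.ndarray
    cost_comparator: np.ndarray
    qaly_comparator: np.ndarray

    @property
    def n(self) -> int:
        return len(self.cost_intervention)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_effect(self) -> np.ndarray:
        return self.qaly_intervention - self.qaly_comparator

    @property
    def incremental_nmb(self) -> np.ndarray:
        return self.delta_effect * self.wtp - self.delta_cost

    def acceptability(self, wtp: float | None = None) -> float:
        """Share of iterations with positive incremental NMB, in percent."""
        wtp = self.wtp if wtp is None else wtp
        return float(np.mean(self.delta_effect * wtp - self.delta_cost > 0) * 100.0)

    @property
    def dominant_share(self) -> float:
        """Share of iterations where the intervention dominates, in percent."""
        return float(
            np.mean((self.delta_cost < 0) & (self.delta_effect > 0)) * 100.0
        )

    @property
    def mean_delta_cost(self) -> float:
        return float(np.mean(self.delta_cost))

    @property
    def mean_delta_effect(self) -> float:
        return float(np.mean(self.delta_effect))

    @property
    def icer_of_means(self) -> float:
        return self.mean_delta_cost / self.mean_delta_effect

    def iterations_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(self.n),
                f"cost_{self.intervention}": self.cost_intervention,
                f"qaly_{self.intervention}": self.qaly_intervention,
                f"cost_{self.comparator}": self.cost_comparator,
                f"qaly_{self.comparator}": self.qaly_comparator,
            }
        )


def run_psa(
    inputs: ModelInputs,
    specs: Sequence[DistributionSpec],
    n: int,
    wtp: float | None = None,
    seed: int = 0,
) -> PSAResult:
    """Run *n* Monte Carlo iterations of the full model.

    Every iteration draws one coherent input set via :func:`sample_inputs`
    and evaluates both arms on it.  A failed iteration aborts with its draw
    index and seed in the error message.
    """
    if n < 1:
        raise ValueError("need at least one iteration")
    wtp = inputs.settings.wtp if wtp is None else wtp
    rng = np.random.default_rng(seed)
    iv_name = inputs.intervention.name
    cp_name = inputs.comparator.name
    ci = np.empty(n)
    qi = np.empty(n)
    cc = np.empty(n)
    qc = np.empty(n)
    for k in range(n):
        try:
            drawn = sample_inputs(specs, inputs, rng)
            results = run_model(drawn)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(
                f"PSA iteration {k} failed (seed {seed}): {exc}"
            ) from exc
        ci[k] = results[iv_name].total_cost
        qi[k] = results[iv_name].total_qaly
        cc[k] = results[cp_name].total_cost
        qc[k] = results[cp_name].total_qaly
    return PSAResult(
        intervention=iv_name,
        comparator=cp_name,
        wtp=wtp,
        seed=seed,
        cost_intervention=ci,
        qaly_intervention=qi,
        cost_comparator=cc,
        qaly_comparator=qc,
    )


def ceac_table(result: PSAResult, wtp_grid: Sequence[float]):
    """Cost-effectiveness acceptability curve over a WTP grid."""
    import pandas as pd

    return pd.DataFrame(
        {
            "wtp": list(wtp_grid),
            "acceptability_pct": [result.acceptability(w) for w in wtp_grid],
        }
    )
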