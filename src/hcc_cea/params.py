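"""Validated model inputs and the bundled default parameter set.

Every quantity the decision model consumes lives in one human-editable YAML
file whose row names mirror the published input table, so each value can be
grepped back to its source. :func:`load_parameters` parses and validates the
file (unknown keys are rejected, every bound is checked); :func:`default_bundle`
returns the built-in CARES-310 input set.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DistributionSpec",
    "StochasticValue",
    "AdverseEventSpec",
    "SurvivalParams",
    "ModelSettings",
    "StrategyInputs",
    "ParameterBundle",
    "load_parameters",
    "save_parameters",
    "default_bundle",
    "default_parameter_path",
    "distribution_moment_check",
    "iter_owsa_parameters",
    "set_parameter",
]

#: Relative tolerance used when auditing that a PSA distribution's mean
#: reproduces its baseline value.
MOMENT_TOLERANCE = 0.005


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DistributionSpec(_StrictModel):
    """PSA sampling distribution for one parameter.

    ``gamma``: p1 = shape, p2 = scale (mean = shape * scale).
    ``beta``:  p1 = alpha, p2 = beta  (mean = alpha / (alpha + beta)).
    ``fixed``: degenerate point mass at the baseline value.
    """

    family: Literal["gamma", "beta", "fixed"]
    p1: Optional[float] = None
    p2: Optional[float] = None
    clamp: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check_params(self) -> "DistributionSpec":
        if self.family != "fixed":
            if self.p1 is None or self.p2 is None:
                raise ValueError(f"{self.family} distribution requires p1 and p2")
            if self.p1 <= 0 or self.p2 <= 0:
                raise ValueError(f"{self.family} parameters must be positive")
        return self

    def mean(self) -> Optional[float]:
        if self.family == "gamma":
            return self.p1 * self.p2
        if self.family == "beta":
            return self.p1 / (self.p1 + self.p2)
        return None  # fixed: mean equals whatever baseline it decorates


class StochasticValue(_StrictModel):
    """A baseline value with an optional OWSA range and PSA distribution."""

    value: float = Field(ge=0)
    range: Optional[tuple[float, float]] = None
    dist: DistributionSpec = DistributionSpec(family="fixed")

    @model_validator(mode="after")
    def _check_range(self) -> "StochasticValue":
        if self.range is not None:
            lo, hi = self.range
            if lo > hi:
                raise ValueError(f"range lower bound {lo} exceeds upper bound {hi}")
        return self


class SurvivalParams(_StrictModel):
    """Log-logistic survival curve S(t) = 1 / (1 + lam * t^gamma), t in months.

    ``gamma`` is the dimensionless shape exponent, ``lam`` the rate-like scale
    in month^-gamma. The implied median is lam^(-1/gamma) months.
    """

    gamma: float = Field(gt=0)
    lam: float = Field(gt=0)
    label: str = ""

    def median(self) -> float:
        return self.lam ** (-1.0 / self.gamma)


class AdverseEventSpec(_StrictModel):
    """One grade 3/4 adverse event: incidence, management cost, disutility."""

    name: str
    incidence: float = Field(ge=0, le=1)
    range: Optional[tuple[float, float]] = None
    dist: DistributionSpec = DistributionSpec(family="fixed")
    one_time_cost: float = Field(default=0.0, ge=0)
    disutility: float = Field(default=0.0, ge=0, le=1)


class ModelSettings(_StrictModel):
    cycle_length_months: float = Field(default=1.0, gt=0)
    horizon_cycles: int = Field(default=120, ge=1)
    annual_discount_rate: float = Field(default=0.03, ge=0, le=1)
    discount_rate_range: tuple[float, float] = (0.0, 0.05)
    discount_rate_dist: DistributionSpec = DistributionSpec(family="fixed")
    wtp_thresholds: dict[str, float] = Field(
        default_factory=lambda: {"low": 16426.80, "medium": 34319.01, "high": 81036.63}
    )
    half_cycle_correction: bool = False
    days_per_cycle: float = Field(default=30.4375, gt=0)
    subsequent_duration_cycles: Optional[int] = Field(default=None, ge=1)
    exchange_rate_rmb_per_usd: float = Field(default=7.05, gt=0)
    seed: int = 20240

    @model_validator(mode="after")
    def _check_wtp(self) -> "ModelSettings":
        for region, wtp in self.wtp_thresholds.items():
            if wtp <= 0:
                raise ValueError(f"WTP threshold for region '{region}' must be > 0")
        return self


class StrategyDef(_StrictModel):
    """One treatment arm: survival curves, AE profile, downstream therapy."""

    display_name: str = ""
    os: SurvivalParams
    pfs: SurvivalParams
    p_subsequent_therapy: float = Field(ge=0, le=1)
    subsequent_mix: dict[str, float]
    adverse_events: dict[str, "_AdverseEventRow"]

    @model_validator(mode="after")
    def _check_mix(self) -> "StrategyDef":
        total = sum(self.subsequent_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subsequent_mix weights sum to {total}, expected 1")
        known = {"lenvatinib", "sintilimab_bevacizumab"}
        unknown = set(self.subsequent_mix) - known
        if unknown:
            raise ValueError(f"unknown subsequent therapies: {sorted(unknown)}")
        return self


class _AdverseEventRow(_StrictModel):
    incidence: float = Field(ge=0, le=1)
    range: Optional[tuple[float, float]] = None
    dist: DistributionSpec = DistributionSpec(family="fixed")


# Backwards-compatible public alias used by the engine layer
StrategyInputs = StrategyDef


class ParameterBundle(_StrictModel):
    """The complete, validated input set for one model run."""

    settings: ModelSettings
    costs: dict[str, StochasticValue]
    utilities: dict[str, StochasticValue]
    disutilities: dict[str, StochasticValue]
    strategies: dict[str, StrategyDef]

    @model_validator(mode="after")
    def _cross_checks(self) -> "ParameterBundle":
        required_costs = {
            "camrelizumab_200mg",
            "rivoceranib_250mg",
            "sorafenib_200mg",
            "subsequent_lenvatinib",
            "subsequent_sintilimab_bevacizumab",
            "follow_up",
            "best_supportive_care",
        }
        missing = required_costs - set(self.costs)
        if missing:
            raise ValueError(f"missing required cost rows: {sorted(missing)}")
        for key in ("progression_free", "progressed", "death"):
            if key not in self.utilities:
                raise ValueError(f"missing utility row '{key}'")
        u_pfs = self.utilities["progression_free"].value
        u_pd = self.utilities["progressed"].value
        u_death = self.utilities["death"].value
        if not (0 <= u_pd <= u_pfs <= 1):
            raise ValueError(
                f"utilities must satisfy 0 <= progressed ({u_pd}) <= "
                f"progression_free ({u_pfs}) <= 1"
            )
        if u_death != 0:
            raise ValueError(f"death utility must be 0, got {u_death}")
        for name, d in self.disutilities.items():
            if d.value > u_pfs:
                raise ValueError(
                    f"disutility '{name}' ({d.value}) exceeds the progression-free "
                    f"utility ({u_pfs})"
                )
        for arm, strat in self.strategies.items():
            for ae_name in strat.adverse_events:
                if ae_name not in self.costs:
                    raise ValueError(
                        f"adverse event '{ae_name}' in arm '{arm}' has no cost row"
                    )
                if ae_name not in self.disutilities:
                    raise ValueError(
                        f"adverse event '{ae_name}' in arm '{arm}' has no "
                        f"disutility row (use value 0 for cost-only events)"
                    )
        return self

    # -- convenience accessors -------------------------------------------------

    def utility(self, key: str) -> float:
        return self.utilities[key].value

    def cost(self, key: str) -> float:
        return self.costs[key].value

    def ae_profile(self, arm: str) -> list[AdverseEventSpec]:
        """Materialize the AE rows of one arm with their cost/disutility joins."""
        strat = self.strategies[arm]
        return [
            AdverseEventSpec(
                name=name,
                incidence=row.incidence,
                range=row.range,
                dist=row.dist,
                one_time_cost=self.costs[name].value,
                disutility=self.disutilities[name].value,
            )
            for name, row in strat.adverse_events.items()
        ]

    def subsequent_mix_cost(self, arm: str) -> float:
        """Mix-weighted per-cycle cost of second-line therapy for one arm."""
        mix = self.strategies[arm].subsequent_mix
        price = {
            "lenvatinib": self.costs["subsequent_lenvatinib"].value,
            "sintilimab_bevacizumab": self.costs["subsequent_sintilimab_bevacizumab"].value,
        }
        return sum(w * price[k] for k, w in mix.items())


def default_parameter_path() -> Path:
    """Path of the bundled CARES-310 default parameter file."""
    return Path(str(resources.files("hcc_cea").joinpath("data/cares310_inputs.yaml")))


def load_parameters(path: str | Path) -> ParameterBundle:
    """Load and validate a parameter file.

    Raises ``FileNotFoundError`` for a missing file and
    ``pydantic.ValidationError`` (naming the offending field and bound) for
    schema or invariant violations, including unknown keys.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} did not parse to a mapping")
    return ParameterBundle.model_validate(raw)


def save_parameters(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle back to YAML; load/save round-trips are lossless."""
    data = bundle.model_dump(exclude_none=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def default_bundle() -> ParameterBundle:
    return load_parameters(default_parameter_path())


def distribution_moment_check(
    spec: DistributionSpec, baseline: float, tolerance: float = MOMENT_TOLERANCE
) -> tuple[bool, float]:
    """Audit that a PSA distribution's mean reproduces its baseline value.

    Returns ``(passed, relative_error)``. Fixed distributions pass with error
    0 by definition. Raises ``ValueError`` for unsupported families (cannot
    occur for validated specs, but guards hand-built ones).
    """
    if spec.family not in ("gamma", "beta", "fixed"):
        raise ValueError(f"unsupported distribution family '{spec.family}'")
    mean = spec.mean()
    if mean is None:
        return True, 0.0
    if baseline == 0:
        return mean == 0, float("inf") if mean != 0 else 0.0
    rel_err = abs(mean - baseline) / abs(baseline)
    return rel_err <= tolerance, rel_err


# ---------------------------------------------------------------------------
# Flat parameter addressing (used by the sensitivity module)
# ---------------------------------------------------------------------------

class OWSAParameter(BaseModel):
    """One deterministically varied input: its address, baseline and bounds."""

    path: tuple[str, ...]
    label: str
    baseline: float
    low: float
    high: float


def iter_owsa_parameters(
    bundle: ParameterBundle, perturbation: float = 0.20
) -> Iterator[OWSAParameter]:
    """Enumerate every input with a deterministic-sensitivity range.

    The printed range is used where present; otherwise baseline +/- the given
    fractional perturbation. The discount rate is included with its own sweep
    range. Survival parameters carry no range and are held fixed.
    """

    def bounds(value: float, rng: Optional[tuple[float, float]]) -> tuple[float, float]:
        if rng is not None:
            return rng
        return value * (1 - perturbation), value * (1 + perturbation)

    for section in ("costs", "utilities", "disutilities"):
        for key, sv in getattr(bundle, section).items():
            if section == "utilities" and key == "death":
                continue
            if sv.range is None and sv.value == 0.0:
                continue  # rangeless zero rows (cost-only AEs) are no-ops
            lo, hi = bounds(sv.value, sv.range)
            yield OWSAParameter(
                path=(section, key), label=f"{section[:-1] if section != 'utilities' else 'utility'}: {key}",
                baseline=sv.value, low=lo, high=hi,
            )
    for arm, strat in bundle.strategies.items():
        for name, row in strat.adverse_events.items():
            lo, hi = bounds(row.incidence, row.range)
            yield OWSAParameter(
                path=("strategies", arm, "adverse_events", name, "incidence"),
                label=f"incidence ({arm}): {name}",
                baseline=row.incidence, low=lo, high=hi,
            )
    s = bundle.settings
    yield OWSAParameter(
        path=("settings", "annual_discount_rate"),
        label="annual discount rate",
        baseline=s.annual_discount_rate,
        low=s.discount_rate_range[0],
        high=s.discount_rate_range[1],
    )


def set_parameter(
    bundle: ParameterBundle, path: tuple[str, ...], value: float
) -> ParameterBundle:
    """Return a copy of the bundle with the addressed scalar replaced.

    Probabilities and utilities are the caller's responsibility to keep in
    range; validation re-runs on construction so violations surface
    immediately.
    """
    data = bundle.model_dump(exclude_none=True)
    node = data
    for key in path[:-1]:
        node = node[key]
    leaf = path[-1]
    if isinstance(node[leaf], dict) and "value" in node[leaf]:
        node[leaf]["value"] = value
    elif leaf == "incidence" or not isinstance(node[leaf], dict):
        node[leaf] = value
    else:
        raise KeyError(f"path {path} does not address a scalar")
    return ParameterBundle.model_validate(data)


def perturbed(
    bundle: ParameterBundle, path: tuple[str, ...], value: float
) -> ParameterBundle:
    """Alias of :func:`set_parameter` kept for readability at call sites."""
    return set_parameter(bundle, path, value)
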