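"""Model parameter registry: loading, validation, uncertainty and PSA sampling.

The decision model is driven by a flat registry of named scalar parameters
(prevalence, per-strategy test operating characteristics, per-cycle transition
probabilities, costs in 2019 USD, health-state utilities, intervention
efficacy, discount rate) plus run-level settings (time horizon, cohort size,
willingness-to-pay threshold, accounting conventions).

Each scalar carries an uncertainty specification for probabilistic sensitivity
analysis: a distribution family (``beta`` for probabilities and utilities,
``gamma`` for costs, ``fixed`` for point values) and either a standard
deviation, a 95% confidence interval, or nothing — in which case the standard
deviation defaults to a stated fraction of the mean (10–15%, default 12.5%).
Beta and Gamma distributions are moment-matched so the fitted distribution
reproduces the stated mean and SD exactly.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "ValidationError",
    "RangeError",
    "ConfigurationError",
    "InfeasibleMomentsError",
    "UncertainParameter",
    "Conventions",
    "ParameterSet",
    "default_sd_rule",
    "fit_beta_moments",
    "fit_gamma_moments",
    "load_parameters",
    "sample_parameter_set",
    "sample_parameter_set_counted",
    "default_config_path",
    "load_default_parameters",
]


class ParameterError(Exception):
    """Base class for parameter-configuration problems."""


class ValidationError(ParameterError):
    """A required key is missing or a value fails a structural check."""


class RangeError(ParameterError):
    """A value lies outside its admissible domain (probability, utility, cost)."""


class ConfigurationError(ParameterError):
    """A run-level setting is outside its permitted band."""


class InfeasibleMomentsError(ParameterError):
    """No distribution of the requested family has the requested mean and SD."""


# ----------------------------------------------------------------------------
# Moment matching
# ----------------------------------------------------------------------------

SD_FRACTION_BAND = (0.10, 0.15)


def default_sd_rule(base: float, fraction: float = 0.125) -> float:
    """Default standard deviation for a parameter with no stated uncertainty.

    Parameters with a distribution family but no printed SD or CI receive
    ``sd = fraction * |base|`` with ``fraction`` restricted to the 10–15% band.
    """
    if not math.isfinite(base):
        raise ConfigurationError(f"base value must be finite, got {base!r}")
    lo, hi = SD_FRACTION_BAND
    if not (lo <= fraction <= hi):
        raise ConfigurationError(
            f"default SD fraction {fraction} outside the permitted band [{lo}, {hi}]"
        )
    return fraction * abs(base)


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta(alpha, beta) with the given mean and SD.

    Solves ``mean = a/(a+b)`` and ``var = ab/((a+b)^2 (a+b+1))``:
    ``a = mean*(mean(1-mean)/sd^2 - 1)``, ``b = (1-mean)*(same factor)``.
    Feasible iff ``sd^2 < mean(1-mean)``.
    """
    if not (0.0 < mean < 1.0):
        raise RangeError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0.0:
        raise RangeError(f"beta sd must be positive, got {sd}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise InfeasibleMomentsError(
            f"no Beta distribution has mean {mean} and sd {sd} "
            f"(requires sd^2 < mean(1-mean) = {bound:.6g})"
        )
    k = bound / var - 1.0
    return mean * k, (1.0 - mean) * k


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Gamma(shape, scale): shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0.0 or sd <= 0.0:
        raise RangeError(f"gamma moments require mean > 0 and sd > 0, got {mean}, {sd}")
    var = sd * sd
    return mean * mean / var, var / mean


# ----------------------------------------------------------------------------
# Uncertain parameters
# ----------------------------------------------------------------------------

#: kind -> admissible closed domain for base values
_KIND_DOMAIN = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "cost": (0.0, math.inf),
}


def _kind_of(name: str) -> str:
    if name.startswith(("u_",)):
        return "utility"
    if name.startswith(("cost_",)):
        return "cost"
    # prevalence, discount_rate, efficacy, p_*, sens_*, spec_*
    return "probability"


@dataclass(frozen=True)
class UncertainParameter:
    """One named scalar with its base value and uncertainty specification.

    ``sd`` takes precedence if given; otherwise a 95% CI ``(ci_low, ci_high)``
    is converted with the normal-approximation convention
    ``sd = (ci_high - ci_low) / (2 * 1.96)``; otherwise the default-SD rule
    applies (unless the family is ``fixed``).
    """

    name: str
    base: float
    family: str  # "beta" | "gamma" | "fixed"
    sd: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    sd_defaulted: bool = False  # True when sd came from the default rule

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"{self.name}: unknown distribution family {self.family!r}")
        lo, hi = _KIND_DOMAIN[self.kind]
        if not (lo <= self.base <= hi):
            raise RangeError(
                f"{self.name}: base value {self.base} outside [{lo}, {hi}] for a {self.kind}"
            )
        if self.family == "beta" and not (0.0 < self.base < 1.0):
            raise RangeError(
                f"{self.name}: Beta family requires base in (0, 1), got {self.base}"
            )
        if self.family == "gamma" and self.base <= 0.0:
            raise RangeError(f"{self.name}: Gamma family requires base > 0, got {self.base}")
        if self.sd is not None and self.sd < 0.0:
            raise RangeError(f"{self.name}: sd must be >= 0, got {self.sd}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError(f"{self.name}: CI must give both bounds")
        if self.ci_low is not None and self.ci_low > self.ci_high:  # type: ignore[operator]
            raise ValidationError(f"{self.name}: CI bounds out of order")

    @property
    def kind(self) -> str:
        return _kind_of(self.name)

    def resolved_sd(self, default_fraction: float = 0.125) -> float:
        """SD after applying the CI conversion or the default rule."""
        if self.family == "fixed":
            return 0.0
        if self.sd is not None:
            return self.sd
        if self.ci_low is not None and self.ci_high is not None:
            return (self.ci_high - self.ci_low) / (2.0 * 1.96)
        return default_sd_rule(self.base, default_fraction)

    def dsa_range(self, default_fraction: float = 0.125) -> tuple[float, float]:
        """(low, high) for one-way sensitivity analysis: the printed CI where
        available, else base ± 1 SD, clipped to the parameter's domain."""
        if self.ci_low is not None and self.ci_high is not None:
            lo, hi = self.ci_low, self.ci_high
        else:
            s = self.resolved_sd(default_fraction)
            lo, hi = self.base - s, self.base + s
        dlo, dhi = _KIND_DOMAIN[self.kind]
        return max(lo, dlo), min(hi, dhi)

    def fit(self, default_fraction: float = 0.125):
        """(family, dist params) for sampling; None for fixed parameters."""
        if self.family == "fixed":
            return None
        s = self.resolved_sd(default_fraction)
        if s == 0.0:
            return None
        if self.family == "beta":
            return ("beta", fit_beta_moments(self.base, s))
        return ("gamma", fit_gamma_moments(self.base, s))

    def sample(self, rng: np.random.Generator, default_fraction: float = 0.125) -> float:
        spec = self.fit(default_fraction)
        if spec is None:
            return self.base
        family, (a, b) = spec
        if family == "beta":
            return float(rng.beta(a, b))
        return float(rng.gamma(a) * b)


# ----------------------------------------------------------------------------
# Run-level conventions and the full parameter set
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class Conventions:
    """Accounting conventions shared by the cohort engine and the microsimulation.

    half_cycle
        ``"trapezoid"`` (average of start- and end-of-cycle occupancy; a death
        mid-cycle contributes half a cycle of utility) or ``"none"``.
    mortality_mode
        ``"constant"`` uses the scalar healthy-population death probability per
        cycle; ``"vector"`` uses an age-indexed annual vector instead.
    risk_order
        Within a cycle the fall/fracture event is resolved first (it sets that
        cycle's death probability and utility), then death, then — among
        survivors of the sarcopenia state — the transition to the
        sarcopenia-with-CVD state. This is the only order implemented; the
        field exists so traces record the convention they were produced under.
    """

    half_cycle: str = "trapezoid"
    mortality_mode: str = "constant"
    risk_order: str = "event-death-cvd"

    def __post_init__(self) -> None:
        if self.half_cycle not in ("trapezoid", "none"):
            raise ConfigurationError(f"unknown half-cycle variant {self.half_cycle!r}")
        if self.mortality_mode not in ("constant", "vector"):
            raise ConfigurationError(f"unknown mortality mode {self.mortality_mode!r}")
        if self.risk_order != "event-death-cvd":
            raise ConfigurationError(f"unsupported risk order {self.risk_order!r}")


#: registry names, grouped as in the input document; order is the sampling order
PARAMETER_NAMES: tuple[str, ...] = (
    "prevalence",
    "discount_rate",
    "sens_ewgsop", "sens_sarsamod", "sens_msra", "sens_sarcf",
    "spec_ewgsop", "spec_sarsamod", "spec_msra", "spec_sarcf",
    "p_death_healthy", "p_death_sarc", "p_death_sarc_cvd", "p_death_fracture",
    "p_fall", "p_fracture_given_fall", "p_cvd",
    "cost_treatment_annual",
    "cost_gait", "cost_handgrip", "cost_dxa", "cost_msra", "cost_sarcf",
    "cost_sarcf_high_risk", "cost_sarsamod", "cost_ewgsop_stage1",
    "cost_ewgsop_stage2",
    "cost_fracture", "cost_cvd_initial", "cost_cvd_incremental",
    "u_healthy", "u_sarc", "u_sarc_fracture", "u_sarc_cvd", "u_sarc_cvd_fracture",
    "efficacy",
)

#: strategy slug -> display name
STRATEGY_NAMES: dict[str, str] = {
    "ewgsop": "EWGSOP",
    "sarsamod": "SarSA-Mod",
    "msra": "MSRA",
    "sarcf": "SARC-F",
    "noscreening": "NoScreening",
}


@dataclass
class ParameterSet:
    """The complete, validated model input: uncertain scalars plus run settings."""

    params: dict[str, UncertainParameter]
    horizon_cycles: int = 25
    cycle_length: float = 1.0
    cohort_size: int = 1000
    wtp: float = 5520.311
    default_sd_fraction: float = 0.125
    conventions: Conventions = field(default_factory=Conventions)
    mortality_vector: tuple[float, ...] | None = None
    #: fraction of screen-positives charged the second-stage test (DSA hook)
    stage2_charge_multiplier: float = 1.0
    #: record of parameters whose SD came from the default rule
    defaulted_sds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [n for n in PARAMETER_NAMES if n not in self.params]
        if missing:
            raise ValidationError(f"missing parameters: {', '.join(missing)}")
        extra = [n for n in self.params if n not in PARAMETER_NAMES]
        if extra:
            raise ValidationError(f"unknown parameters: {', '.join(extra)}")
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        if self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1")
        if self.wtp < 0:
            raise RangeError("willingness-to-pay threshold must be >= 0")
        if not (0.0 <= self.stage2_charge_multiplier):
            raise RangeError("stage2_charge_multiplier must be >= 0")
        lo, hi = SD_FRACTION_BAND
        if not (lo <= self.default_sd_fraction <= hi):
            raise ConfigurationError(
                f"default_sd_fraction {self.default_sd_fraction} outside [{lo}, {hi}]"
            )
        if self.conventions.mortality_mode == "vector":
            if not self.mortality_vector:
                raise ValidationError("mortality_mode 'vector' requires mortality_vector")
            if any(not (0.0 <= q <= 1.0) for q in self.mortality_vector):
                raise RangeError("mortality_vector entries must be probabilities")
        # structural sanity of the utility ordering
        v = self.value
        if v("u_sarc_cvd_fracture") > min(v("u_sarc_cvd"), v("u_sarc_fracture")) + 1e-12:
            raise ValidationError(
                "u_sarc_cvd_fracture must not exceed u_sarc_cvd or u_sarc_fracture"
            )
        if v("u_healthy") < v("u_sarc") - 1e-12:
            raise ValidationError("u_healthy must be >= u_sarc")

    # -- access ---------------------------------------------------------

    def value(self, name: str) -> float:
        return self.params[name].base

    def __getattr__(self, name: str):
        # dataclass fields resolve normally; fall through to the registry
        try:
            return object.__getattribute__(self, "params")[name].base
        except KeyError:
            raise AttributeError(name) from None

    def p_death_healthy_at(self, cycle: int) -> float:
        """Healthy-population death probability for cycle ``cycle`` (1-based).

        In vector mode, cycles beyond the vector's length reuse its last entry.
        """
        if self.conventions.mortality_mode == "vector":
            vec = self.mortality_vector or ()
            return vec[min(cycle - 1, len(vec) - 1)]
        return self.value("p_death_healthy")

    # -- derived --------------------------------------------------------

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """A copy with some base values replaced (uncertainty specs retained)."""
        new = dict(self.params)
        for name, val in updates.items():
            if name not in new:
                raise ValidationError(f"unknown parameter {name!r}")
            new[name] = replace(new[name], base=float(val))
        out = copy.copy(self)
        out.params = new
        out.__post_init__()
        return out

    def with_mortality_mode(self, mode: str) -> "ParameterSet":
        """A copy using the given healthy-arm mortality mode."""
        out = copy.copy(self)
        out.params = dict(self.params)
        out.conventions = replace(self.conventions, mortality_mode=mode)
        out.__post_init__()
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        def pdict(p: UncertainParameter) -> dict:
            d: dict = {"base": p.base, "family": p.family}
            if p.sd is not None and not p.sd_defaulted:
                d["sd"] = p.sd
            if p.ci_low is not None:
                d["ci"] = [p.ci_low, p.ci_high]
            return d

        doc: dict = {
            "run": {
                "horizon_cycles": self.horizon_cycles,
                "cycle_length": self.cycle_length,
                "cohort_size": self.cohort_size,
                "wtp": self.wtp,
                "default_sd_fraction": self.default_sd_fraction,
                "stage2_charge_multiplier": self.stage2_charge_multiplier,
            },
            "conventions": {
                "half_cycle": self.conventions.half_cycle,
                "mortality_mode": self.conventions.mortality_mode,
            },
            "parameters": {n: pdict(self.params[n]) for n in PARAMETER_NAMES},
        }
        if self.mortality_vector is not None:
            doc["mortality_vector"] = list(self.mortality_vector)
        return doc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


# ----------------------------------------------------------------------------
# Loading
# ----------------------------------------------------------------------------


def _load_one(name: str, raw, defaulted: list[str]) -> UncertainParameter:
    if isinstance(raw, (int, float)):
        raw = {"base": float(raw)}
    if not isinstance(raw, Mapping) or "base" not in raw:
        raise ValidationError(f"{name}: expected a mapping with a 'base' value")
    allowed = {"base", "sd", "ci", "family"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"{name}: unknown keys {sorted(unknown)}")
    base = float(raw["base"])
    family = raw.get("family")
    if family is None:
        # infer from the parameter's kind; degenerate bases fall back to fixed
        if name.startswith("cost_"):
            family = "gamma" if base > 0.0 else "fixed"
        else:
            family = "beta" if 0.0 < base < 1.0 else "fixed"
    sd = raw.get("sd")
    ci = raw.get("ci")
    ci_low = ci_high = None
    if ci is not None:
        if len(ci) != 2:
            raise ValidationError(f"{name}: CI must be a pair")
        ci_low, ci_high = float(ci[0]), float(ci[1])
    sd_defaulted = family != "fixed" and sd is None and ci is None
    if sd_defaulted:
        defaulted.append(name)
    return UncertainParameter(
        name=name,
        base=base,
        family=family,
        sd=None if sd is None else float(sd),
        ci_low=ci_low,
        ci_high=ci_high,
        sd_defaulted=sd_defaulted,
    )


def load_parameters(source) -> ParameterSet:
    """Load and validate a parameter document (YAML path, YAML text, or dict).

    Missing uncertainty specifications are filled by the default-SD rule; the
    returned set records which parameters were defaulted in ``defaulted_sds``.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if isinstance(source, Path) or "\n" not in str(source):
            text = p.read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(io.StringIO(text))
    elif isinstance(source, Mapping):
        doc = source
    else:
        raise ValidationError(f"cannot load parameters from {type(source).__name__}")
    if not isinstance(doc, Mapping):
        raise ValidationError("parameter document must be a mapping")
    if "parameters" not in doc:
        raise ValidationError("missing required section 'parameters'")

    defaulted: list[str] = []
    raw_params = doc["parameters"]
    params = {}
    for name in PARAMETER_NAMES:
        if name not in raw_params:
            raise ValidationError(f"missing parameter {name!r}")
        params[name] = _load_one(name, raw_params[name], defaulted)
    extra = set(raw_params) - set(PARAMETER_NAMES)
    if extra:
        raise ValidationError(f"unknown parameters: {sorted(extra)}")

    run = doc.get("run", {})
    conv = doc.get("conventions", {})
    conventions = Conventions(
        half_cycle=conv.get("half_cycle", "trapezoid"),
        mortality_mode=conv.get("mortality_mode", "constant"),
    )
    vec = doc.get("mortality_vector")
    return ParameterSet(
        params=params,
        horizon_cycles=int(run.get("horizon_cycles", 25)),
        cycle_length=float(run.get("cycle_length", 1.0)),
        cohort_size=int(run.get("cohort_size", 1000)),
        wtp=float(run.get("wtp", 5520.311)),
        default_sd_fraction=float(run.get("default_sd_fraction", 0.125)),
        conventions=conventions,
        mortality_vector=None if vec is None else tuple(float(q) for q in vec),
        stage2_charge_multiplier=float(run.get("stage2_charge_multiplier", 1.0)),
        defaulted_sds=tuple(defaulted),
    )


def default_config_path() -> Path:
    """Path of the canonical base-case configuration shipped with the package."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def load_default_parameters() -> ParameterSet:
    return load_parameters(default_config_path())


# ----------------------------------------------------------------------------
# PSA sampling
# ----------------------------------------------------------------------------


def sample_parameter_set_counted(
    params: ParameterSet, rng_seed, max_rejects: int = 100_000
) -> tuple[ParameterSet, int]:
    """One joint draw plus the number of rejected (infeasible) attempts.

    Independent marginal draws can violate the structural invariants of a
    parameter set (e.g. the sampled healthy-state utility falling below the
    sampled sarcopenia utility); such joint draws are rejected and redrawn
    from the same stream, which preserves the stated marginal distributions
    conditional on feasibility.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    frac = params.default_sd_fraction
    rejected = 0
    while True:
        draws = {name: params.params[name].sample(rng, frac) for name in PARAMETER_NAMES}
        try:
            return params.with_values(draws), rejected
        except ParameterError:
            rejected += 1
            if rejected > max_rejects:
                raise InfeasibleMomentsError(
                    "could not draw a feasible parameter set "
                    f"after {max_rejects} rejections"
                ) from None


def sample_parameter_set(params: ParameterSet, rng_seed) -> ParameterSet:
    """One joint, independent draw of every uncertain parameter.

    ``rng_seed`` may be an integer or a ``numpy.random.Generator``. Parameters
    with a ``fixed`` family (or zero SD) keep their base value. The draw is
    deterministic for a given seed because the registry order is fixed.
    Structurally infeasible joint draws are rejected and redrawn.
    """
    drawn, _ = sample_parameter_set_counted(params, rng_seed)
    return drawn
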