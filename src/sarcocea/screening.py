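"""Screening decision tree: cohort classification and expected test costs.

Each screening strategy is reduced to its operating characteristics
(sensitivity, specificity) and its staged test costs: a first-stage cost paid
by everyone screened and a second-stage cost paid by screen-positives only
(DXA confirmation for the two-stage EWGSOP algorithm, the high-risk
supplementary assessment for SARC-F; zero for the single-stage questionnaires).
Screening happens once, before the first Markov cycle, so its cost is
undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet, RangeError

__all__ = [
    "StrategyDefinition",
    "ClassificationResult",
    "classify_cohort",
    "expected_screening_cost",
    "strategies_from_parameters",
    "STRATEGY_ORDER",
]

#: canonical roster order (used for reports and PSA matrices)
STRATEGY_ORDER: tuple[str, ...] = ("NoScreening", "SARC-F", "SarSA-Mod", "MSRA", "EWGSOP")


@dataclass(frozen=True)
class StrategyDefinition:
    """A screening strategy's test characteristics and staged costs.

    ``NoScreening`` is the null strategy: sensitivity 0 and specificity 1
    (nobody is labelled positive) with zero costs.
    """

    name: str
    sensitivity: float
    specificity: float
    stage1_cost: float = 0.0  # paid by every screened person
    stage2_cost: float = 0.0  # paid by screen-positives

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise RangeError(f"{self.name}: sensitivity/specificity must lie in [0, 1]")
        if self.stage1_cost < 0.0 or self.stage2_cost < 0.0:
            raise RangeError(f"{self.name}: test costs must be >= 0")


@dataclass(frozen=True)
class ClassificationResult:
    """Cohort partition into the four decision-tree branches (fractions of 1)."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def positive_rate(self) -> float:
        return self.tp + self.fp

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "positive_rate": self.positive_rate,
        }


def classify_cohort(strategy: StrategyDefinition, prevalence: float) -> ClassificationResult:
    """Partition a screened cohort by true status x test result.

    tp = prev*sens, fn = prev*(1-sens), fp = (1-prev)*(1-spec), tn = (1-prev)*spec.
    """
    if not (0.0 <= prevalence <= 1.0):
        raise RangeError(f"prevalence must lie in [0, 1], got {prevalence}")
    sens, spec = strategy.sensitivity, strategy.specificity
    return ClassificationResult(
        tp=prevalence * sens,
        fn=prevalence * (1.0 - sens),
        fp=(1.0 - prevalence) * (1.0 - spec),
        tn=(1.0 - prevalence) * spec,
    )


def expected_screening_cost(
    strategy: StrategyDefinition,
    result: ClassificationResult,
    stage2_charge_multiplier: float = 1.0,
) -> float:
    """Expected per-person screening cost: stage1 + positive_rate * stage2.

    The second-stage cost is charged to the overall positive rate; the
    multiplier scales the charged fraction (capped at 1) for sensitivity
    analysis of the unobserved first-stage referral rate in staged algorithms.
    """
    charged = min(result.positive_rate * stage2_charge_multiplier, 1.0)
    return strategy.stage1_cost + charged * strategy.stage2_cost


def strategies_from_parameters(params: ParameterSet) -> list[StrategyDefinition]:
    """The five-strategy roster built from a parameter set, in roster order."""
    v = params.value
    by_name = {
        "NoScreening": StrategyDefinition("NoScreening", 0.0, 1.0, 0.0, 0.0),
        "SARC-F": StrategyDefinition(
            "SARC-F", v("sens_sarcf"), v("spec_sarcf"),
            v("cost_sarcf"), v("cost_sarcf_high_risk"),
        ),
        "SarSA-Mod": StrategyDefinition(
            "SarSA-Mod", v("sens_sarsamod"), v("spec_sarsamod"), v("cost_sarsamod"), 0.0
        ),
        "MSRA": StrategyDefinition(
            "MSRA", v("sens_msra"), v("spec_msra"), v("cost_msra"), 0.0
        ),
        "EWGSOP": StrategyDefinition(
            "EWGSOP", v("sens_ewgsop"), v("spec_ewgsop"),
            v("cost_ewgsop_stage1"), v("cost_ewgsop_stage2"),
        ),
    }
    return [by_name[n] for n in STRATEGY_ORDER]
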