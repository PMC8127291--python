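"""Markov cohort engine: state transitions, half-cycle accounting, discounting.

Health states
-------------
``HEALTHY`` (non-sarcopenic), ``SARC`` (sarcopenia without cardiovascular
disease), ``SARC_CVD`` (sarcopenia with cardiovascular disease) and the
absorbing ``DEAD``. Disease progression is forward-only: healthy people never
become sarcopenic after the single screening round, sarcopenia is
irreversible, and cardiovascular disease, once acquired, persists.

Decision-tree arms
------------------
The screening tree routes everyone into one of four arms that share this
state space: ``TP`` (sarcopenic, detected, treated for life), ``FN``
(sarcopenic, missed, untreated), ``TN`` (healthy, correctly negative) and
``FP`` (healthy, falsely positive — clinically re-examined and charged one
cycle of the intervention, with no other consequence).

Within-cycle mechanics
----------------------
Falls leading to fracture are an *event*, not a state: with per-cycle
probability ``p_fall x p_fracture_given_fall`` a person in a sarcopenia state
has a fracture cycle, during which their utility drops to the fracture
utility of their state and their death probability for that cycle is the
fracture-specific value (replacing, not compounding, the state value). The
event is resolved first, then death, then — among survivors of ``SARC`` —
the transition into ``SARC_CVD``.

Treatment multiplies the fall probability, the CVD incidence and the
sarcopenia-attributable *excess* mortality (state minus healthy, floored at
zero) by ``(1 - efficacy)``, so a treated patient's risk never falls below
the healthy baseline; the fracture-cycle case fatality is not modified.

Accounting
----------
QALYs use a trapezoidal half-cycle correction per within-cycle subcohort
(a mid-cycle death earns half a cycle at the cycle's utility). Recurring
costs (treatment, continuing CVD care) are charged on start-of-cycle
occupancy; one-off costs (fracture, first CVD cycle) on the event mass.
Everything accrued in cycle ``t`` is discounted by ``(1+d)^-t``; screening
costs fall at model start and are undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .screening import (
    StrategyDefinition,
    classify_cohort,
    expected_screening_cost,
    strategies_from_parameters,
)

__all__ = [
    "HealthState",
    "ArmSpec",
    "ARMS",
    "TransitionModel",
    "CohortTrace",
    "ModelConstructionError",
    "build_transition_probabilities",
    "run_cohort",
    "accumulate_outcomes",
    "evaluate_arm",
    "evaluate_arms",
    "evaluate_strategy",
    "evaluate_all_strategies",
]


class ModelConstructionError(Exception):
    """A derived transition probability left the unit interval."""


class HealthState(IntEnum):
    HEALTHY = 0
    SARC = 1
    SARC_CVD = 2
    DEAD = 3


@dataclass(frozen=True)
class ArmSpec:
    """One decision-tree arm entering the Markov model."""

    arm: str  # "TP" | "FN" | "TN" | "FP"
    treated: bool
    initial_state: HealthState
    treatment_cost_cycles: int | None  # None = every alive cycle (lifelong)

    def __post_init__(self) -> None:
        if self.treated and self.arm != "TP":
            raise ModelConstructionError("only the TP arm is treated")
        if self.arm in ("TP", "FN") and self.initial_state is not HealthState.SARC:
            raise ModelConstructionError(f"{self.arm} must start in SARC")
        if self.arm in ("TN", "FP") and self.initial_state is not HealthState.HEALTHY:
            raise ModelConstructionError(f"{self.arm} must start in HEALTHY")


ARMS: dict[str, ArmSpec] = {
    "TP": ArmSpec("TP", True, HealthState.SARC, None),
    "FN": ArmSpec("FN", False, HealthState.SARC, 0),
    "TN": ArmSpec("TN", False, HealthState.HEALTHY, 0),
    "FP": ArmSpec("FP", False, HealthState.HEALTHY, 1),
}

#: classification field feeding each arm
ARM_FRACTION_FIELD = {"TP": "tp", "FN": "fn", "TN": "tn", "FP": "fp"}


@dataclass(frozen=True)
class TransitionModel:
    """Per-cycle event/transition probabilities for one arm.

    Mortality entries are stored as per-cycle vectors (length 1 in
    constant-mortality mode; cycles beyond a vector's length reuse its last
    entry). The treated arm's state mortality blends the cycle's healthy
    baseline with the efficacy-scaled sarcopenia excess, so it is
    cycle-varying whenever the healthy baseline is.
    """

    arm: str
    treated: bool
    p_event_sarc: float       # fracture-event probability in SARC
    p_event_cvd: float        # fracture-event probability in SARC_CVD
    p_death_event: float      # death probability in a fracture-event cycle
    p_cvd_transition: float   # SARC survivors -> SARC_CVD
    _healthy_mortality: tuple[float, ...] = field(repr=False, default=(0.0,))
    _sarc_mortality: tuple[float, ...] = field(repr=False, default=(0.0,))
    _cvd_mortality: tuple[float, ...] = field(repr=False, default=(0.0,))

    def __post_init__(self) -> None:
        entries = {
            "p_event_sarc": self.p_event_sarc,
            "p_event_cvd": self.p_event_cvd,
            "p_death_event": self.p_death_event,
            "p_cvd_transition": self.p_cvd_transition,
            **{f"p_death_healthy[{i}]": q for i, q in enumerate(self._healthy_mortality)},
            **{f"p_death_sarc[{i}]": q for i, q in enumerate(self._sarc_mortality)},
            **{f"p_death_cvd[{i}]": q for i, q in enumerate(self._cvd_mortality)},
        }
        bad = {k: v for k, v in entries.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ModelConstructionError(f"probabilities outside [0, 1]: {bad}")

    @staticmethod
    def _at(vec: tuple[float, ...], cycle: int) -> float:
        return vec[min(cycle - 1, len(vec) - 1)]

    def p_death_healthy(self, cycle: int) -> float:
        """Healthy-state death probability for 1-based ``cycle``."""
        return self._at(self._healthy_mortality, cycle)

    def p_death_sarc(self, cycle: int) -> float:
        """Non-event-cycle death probability in SARC for 1-based ``cycle``."""
        return self._at(self._sarc_mortality, cycle)

    def p_death_cvd(self, cycle: int) -> float:
        """Non-event-cycle death probability in SARC_CVD for 1-based ``cycle``."""
        return self._at(self._cvd_mortality, cycle)


def build_transition_probabilities(params: ParameterSet, arm: ArmSpec) -> TransitionModel:
    """Derive the arm's per-cycle probabilities from the base parameters.

    For the treated arm the fall probability, the CVD incidence and the
    excess (above-healthy) state mortality are each scaled by
    ``1 - efficacy``; untreated state mortality uses the absolute input
    values. The fracture-cycle case fatality is never scaled.
    """
    v = params.value
    scale = (1.0 - v("efficacy")) if arm.treated else 1.0
    if params.conventions.mortality_mode == "vector":
        healthy = tuple(params.mortality_vector or ())
    else:
        healthy = (v("p_death_healthy"),)

    def state_mortality(p_state: float) -> tuple[float, ...]:
        if not arm.treated:
            return (p_state,)
        return tuple(q + scale * max(p_state - q, 0.0) for q in healthy)

    p_event = v("p_fall") * scale * v("p_fracture_given_fall")
    return TransitionModel(
        arm=arm.arm,
        treated=arm.treated,
        p_event_sarc=p_event,
        p_event_cvd=p_event,
        p_death_event=v("p_death_fracture"),
        p_cvd_transition=v("p_cvd") * scale,
        _healthy_mortality=healthy,
        _sarc_mortality=state_mortality(v("p_death_sarc")),
        _cvd_mortality=state_mortality(v("p_death_sarc_cvd")),
    )


@dataclass
class CohortTrace:
    """Cohort propagation record, normalized to unit mass (per person).

    ``occupancy`` has ``horizon + 1`` rows (time points 0..T) over the four
    states; ``events`` and ``cvd_entrants`` are per cycle (1..T).
    """

    arm: str
    occupancy: np.ndarray        # (T+1, 4), unit mass
    events_sarc: np.ndarray      # (T,) fracture events among SARC starters
    events_cvd: np.ndarray       # (T,) fracture events among SARC_CVD starters
    cvd_entrants: np.ndarray     # (T,) arrivals into SARC_CVD at end of cycle t
    cost_stream: np.ndarray | None = None   # (T,) discounted USD per person
    qaly_stream: np.ndarray | None = None   # (T,) discounted QALYs per person
    total_cost: float | None = None
    total_qalys: float | None = None

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def validate(self, atol: float = 1e-9) -> None:
        mass = self.occupancy.sum(axis=1)
        if not np.allclose(mass, 1.0, atol=atol):
            raise ModelConstructionError("occupancy mass not conserved")
        dead = self.occupancy[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -atol):
            raise ModelConstructionError("dead occupancy must be non-decreasing")

    def to_frame(self, cohort_size: float = 1.0) -> pd.DataFrame:
        """Long trace (one row per time point) scaled to ``cohort_size``."""
        t = np.arange(self.horizon + 1)
        df = pd.DataFrame(
            {
                "cycle": t,
                "healthy": self.occupancy[:, 0] * cohort_size,
                "sarc": self.occupancy[:, 1] * cohort_size,
                "sarc_cvd": self.occupancy[:, 2] * cohort_size,
                "dead": self.occupancy[:, 3] * cohort_size,
            }
        )
        pad = lambda a: np.concatenate([[0.0], a])  # noqa: E731 - cycle 0 has no flows
        df["fracture_events"] = pad(self.events_sarc + self.events_cvd) * cohort_size
        df["cvd_entrants"] = pad(self.cvd_entrants) * cohort_size
        if self.cost_stream is not None:
            df["disc_cost"] = pad(self.cost_stream) * cohort_size
            df["disc_qaly"] = pad(self.qaly_stream) * cohort_size
        return df


def run_cohort(model: TransitionModel, arm: ArmSpec, params: ParameterSet) -> CohortTrace:
    """Propagate a unit cohort through ``horizon_cycles`` annual cycles.

    Deterministic expectation propagation — no sampling. Event masses and
    CVD arrivals are recorded per cycle for the cost accounting.
    """
    T = params.horizon_cycles
    occ = np.zeros((T + 1, 4))
    occ[0, arm.initial_state] = 1.0
    ev_s = np.zeros(T)
    ev_c = np.zeros(T)
    entrants = np.zeros(T)

    for t in range(1, T + 1):
        nH, nS, nC, nD = occ[t - 1]
        # healthy state: background mortality only, no events
        dH = nH * model.p_death_healthy(t)
        # sarcopenia state: event layer sets the cycle's death probability
        evS = nS * model.p_event_sarc
        dS = evS * model.p_death_event + (nS - evS) * model.p_death_sarc(t)
        surv_S = nS - dS
        to_cvd = surv_S * model.p_cvd_transition
        # sarcopenia + CVD state
        evC = nC * model.p_event_cvd
        dC = evC * model.p_death_event + (nC - evC) * model.p_death_cvd(t)
        occ[t] = (nH - dH, surv_S - to_cvd, nC - dC + to_cvd, nD + dH + dS + dC)
        ev_s[t - 1], ev_c[t - 1], entrants[t - 1] = evS, evC, to_cvd

    trace = CohortTrace(arm.arm, occ, ev_s, ev_c, entrants)
    trace.validate()
    return trace


def accumulate_outcomes(
    trace: CohortTrace, params: ParameterSet, arm: ArmSpec
) -> tuple[float, float]:
    """Discounted per-person (cost, QALYs) over the trace's horizon.

    Fills the trace's cost/QALY streams in place and returns the totals.
    Screening costs are *not* included here — they belong to the strategy
    level (`evaluate_strategy`).
    """
    model = build_transition_probabilities(params, arm)
    v = params.value
    d = v("discount_rate")
    T = trace.horizon
    trapezoid = params.conventions.half_cycle == "trapezoid"

    u_h, u_s = v("u_healthy"), v("u_sarc")
    u_sf, u_c, u_cf = v("u_sarc_fracture"), v("u_sarc_cvd"), v("u_sarc_cvd_fracture")
    rate_tx = v("cost_treatment_annual")
    c_frac, c_cvd0, c_cvd1 = v("cost_fracture"), v("cost_cvd_initial"), v("cost_cvd_incremental")

    def credit(mass: float, p_die: float) -> float:
        """Cycle occupancy credit for a subcohort entering with ``mass``."""
        return mass * (1.0 + (1.0 - p_die)) / 2.0 if trapezoid else mass

    cost = np.zeros(T)
    qaly = np.zeros(T)
    for t in range(1, T + 1):
        nH, nS, nC, _ = trace.occupancy[t - 1]
        evS, evC = trace.events_sarc[t - 1], trace.events_cvd[t - 1]
        disc = (1.0 + d) ** (-t)

        q = u_h * credit(nH, model.p_death_healthy(t))
        q += u_s * credit(nS - evS, model.p_death_sarc(t))
        q += u_sf * credit(evS, model.p_death_event)
        q += u_c * credit(nC - evC, model.p_death_cvd(t))
        q += u_cf * credit(evC, model.p_death_event)
        qaly[t - 1] = q * disc

        c = c_frac * (evS + evC)
        first_cvd = trace.cvd_entrants[t - 2] if t >= 2 else 0.0
        c += c_cvd0 * first_cvd + c_cvd1 * max(nC - first_cvd, 0.0)
        if arm.treatment_cost_cycles is None or t <= arm.treatment_cost_cycles:
            c += rate_tx * (nH + nS + nC)
        cost[t - 1] = c * disc

    trace.cost_stream = cost
    trace.qaly_stream = qaly
    trace.total_cost = float(cost.sum())
    trace.total_qalys = float(qaly.sum())
    return trace.total_cost, trace.total_qalys


def evaluate_arm(params: ParameterSet, arm: ArmSpec) -> CohortTrace:
    """Run one arm end to end: transitions, propagation, accounting."""
    model = build_transition_probabilities(params, arm)
    trace = run_cohort(model, arm, params)
    accumulate_outcomes(trace, params, arm)
    return trace


def evaluate_arms(params: ParameterSet) -> dict[str, CohortTrace]:
    """All four arms (they are strategy-independent; strategies reweight them)."""
    return {name: evaluate_arm(params, spec) for name, spec in ARMS.items()}


def evaluate_strategy(
    strategy: StrategyDefinition,
    params: ParameterSet,
    arm_traces: dict[str, CohortTrace] | None = None,
) -> tuple[float, float]:
    """Per-person (cost, QALYs) of a strategy: classification-weighted arm
    mixture plus the undiscounted expected screening cost."""
    if arm_traces is None:
        arm_traces = evaluate_arms(params)
    result = classify_cohort(strategy, params.value("prevalence"))
    fracs = result.as_dict()
    cost = expected_screening_cost(strategy, result, params.stage2_charge_multiplier)
    qalys = 0.0
    for arm_name, fieldname in ARM_FRACTION_FIELD.items():
        tr = arm_traces[arm_name]
        cost += fracs[fieldname] * tr.total_cost
        qalys += fracs[fieldname] * tr.total_qalys
    return cost, qalys


def evaluate_all_strategies(
    params: ParameterSet,
    strategies: list[StrategyDefinition] | None = None,
) -> pd.DataFrame:
    """Per-person cost and effect for the full roster (arms computed once)."""
    if strategies is None:
        strategies = strategies_from_parameters(params)
    arm_traces = evaluate_arms(params)
    rows = []
    for s in strategies:
        c, e = evaluate_strategy(s, params, arm_traces)
        rows.append({"strategy": s.name, "cost": c, "effect": e})
    return pd.DataFrame(rows).set_index("strategy")
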