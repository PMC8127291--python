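"""Individual-level microsimulation: synthetic trajectories and cohort oracle.

Simulates patients one by one through the screening decision tree (Bernoulli
draws for true sarcopenia status and the test result) and then cycle by cycle
through the same transition structure as the deterministic cohort engine —
identical event layer, competing-risk order, treatment-efficacy modifiers and
half-cycle/discounting conventions, all taken from the shared
`TransitionModel` and `Conventions` objects so the two engines cannot drift
apart.

Uses: (a) generating realistic individual-level synthetic data (state paths,
event logs, per-person discounted costs and QALYs) from a configuration and a
seed; (b) an independent stochastic check of the cohort engine — the mean
cost and QALY over many simulated individuals must agree with the cohort
result within Monte-Carlo error, arm by arm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markov import ARMS, HealthState, build_transition_probabilities
from .parameters import ParameterSet
from .screening import StrategyDefinition

__all__ = ["simulate_individuals", "summarize", "EmptySummaryError"]


class EmptySummaryError(Exception):
    """summarize() called with no records."""


_ARM_CODES = np.array(["TN", "FP", "FN", "TP"])  # index = status*2 + positive


def simulate_individuals(
    params: ParameterSet,
    strategy: StrategyDefinition,
    n: int,
    seed,
    return_paths: bool = False,
):
    """Simulate ``n`` individuals under one screening strategy.

    Returns a DataFrame with one row per person: true status, test result,
    decision-tree arm, death cycle (<NA> if alive at the horizon), fracture
    count, first cycle spent in the CVD state (<NA> if never), cycles spent in
    a sarcopenia state, screening cost, and discounted/undiscounted Markov
    cost and QALYs. With ``return_paths=True`` also returns the
    ``(n, horizon+1)`` state-path matrix (time point 0 is the initial state).

    Reproducible under a fixed seed; pass distinct seeds for independent
    batches.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = params.value
    T = params.horizon_cycles
    d = v("discount_rate")
    trapezoid = params.conventions.half_cycle == "trapezoid"

    # --- decision tree ---------------------------------------------------
    status = rng.random(n) < v("prevalence")  # True = sarcopenic
    p_pos = np.where(status, strategy.sensitivity, 1.0 - strategy.specificity)
    positive = rng.random(n) < p_pos
    arm = _ARM_CODES[status.astype(int) * 2 + positive.astype(int)]
    screening_cost = strategy.stage1_cost + positive * (
        strategy.stage2_cost * min(params.stage2_charge_multiplier, 1.0)
    )

    treated = arm == "TP"
    models = {
        True: build_transition_probabilities(params, ARMS["TP"]),
        False: build_transition_probabilities(params, ARMS["FN"]),
    }

    # --- Markov cycles ---------------------------------------------------
    state = np.where(status, int(HealthState.SARC), int(HealthState.HEALTHY)).astype(np.int8)
    paths = np.empty((n, T + 1), dtype=np.int8) if return_paths else None
    if paths is not None:
        paths[:, 0] = state

    u_h, u_s = v("u_healthy"), v("u_sarc")
    u_sf, u_c, u_cf = v("u_sarc_fracture"), v("u_sarc_cvd"), v("u_sarc_cvd_fracture")
    rate_tx = v("cost_treatment_annual")
    c_frac, c_cvd0, c_cvd1 = v("cost_fracture"), v("cost_cvd_initial"), v("cost_cvd_incremental")

    def per_person(attr: str) -> np.ndarray:
        return np.where(treated, getattr(models[True], attr), getattr(models[False], attr))

    p_event_sarc = per_person("p_event_sarc")
    p_death_event = per_person("p_death_event")
    p_cvd_tr = per_person("p_cvd_transition")

    def per_person_cycle(method: str, t: int) -> np.ndarray:
        return np.where(
            treated,
            getattr(models[True], method)(t),
            getattr(models[False], method)(t),
        )

    cost = np.zeros(n)
    qaly = np.zeros(n)
    cost_undisc = np.zeros(n)
    qaly_undisc = np.zeros(n)
    fractures = np.zeros(n, dtype=np.int32)
    sarc_cycles = np.zeros(n, dtype=np.int32)
    death_cycle = np.zeros(n, dtype=np.int32)       # 0 = alive at horizon
    cvd_entry_cycle = np.zeros(n, dtype=np.int32)   # 0 = never
    entered_last = np.zeros(n, dtype=bool)          # transitioned at end of previous cycle

    for t in range(1, T + 1):
        alive = state != HealthState.DEAD
        in_h = state == HealthState.HEALTHY
        in_s = state == HealthState.SARC
        in_c = state == HealthState.SARC_CVD
        in_sarc = in_s | in_c

        # fixed-size draws each cycle keep the stream layout deterministic
        event = (rng.random(n) < p_event_sarc) & in_sarc
        p_dh = per_person_cycle("p_death_healthy", t)
        p_death_sarc = per_person_cycle("p_death_sarc", t)
        p_death_cvd = per_person_cycle("p_death_cvd", t)
        p_die = np.where(in_h, p_dh, 0.0)
        p_die = np.where(in_s, np.where(event, p_death_event, p_death_sarc), p_die)
        p_die = np.where(in_c, np.where(event, p_death_event, p_death_cvd), p_die)
        die = (rng.random(n) < p_die) & alive
        to_cvd = (rng.random(n) < p_cvd_tr) & in_s & ~die

        disc = (1.0 + d) ** (-t)
        util = np.where(in_h, u_h, 0.0)
        util = np.where(in_s, np.where(event, u_sf, u_s), util)
        util = np.where(in_c, np.where(event, u_cf, u_c), util)
        credit = np.where(die, 0.5 if trapezoid else 1.0, 1.0)
        q = util * credit * alive
        qaly += q * disc
        qaly_undisc += q

        c = c_frac * event.astype(float)
        first_cvd = in_c & entered_last
        c += c_cvd0 * first_cvd + c_cvd1 * (in_c & ~entered_last)
        tx_due = np.where(treated, True, (arm == "FP") & (t <= 1)) & alive
        c += rate_tx * tx_due
        cost += c * disc
        cost_undisc += c

        fractures += event
        sarc_cycles += in_sarc
        death_cycle[die] = t
        state = state.copy()
        state[die] = HealthState.DEAD
        state[to_cvd] = HealthState.SARC_CVD
        cvd_entry_cycle[to_cvd] = t + 1  # their first cycle spent in the CVD state
        entered_last = to_cvd
        if paths is not None:
            paths[:, t] = state

    records = pd.DataFrame(
        {
            "id": np.arange(n),
            "true_status": np.where(status, "sarcopenic", "healthy"),
            "test_result": np.where(positive, "positive", "negative"),
            "arm": arm,
            "death_cycle": pd.array(
                np.where(death_cycle > 0, death_cycle, -1), dtype="Int32"
            ),
            "n_fractures": fractures,
            "cvd_entry_cycle": pd.array(
                np.where(cvd_entry_cycle > 0, cvd_entry_cycle, -1), dtype="Int32"
            ),
            "sarc_cycles": sarc_cycles,
            "screening_cost": screening_cost,
            "markov_cost_disc": cost,
            "markov_cost_undisc": cost_undisc,
            "qaly_disc": qaly,
            "qaly_undisc": qaly_undisc,
        }
    )
    records["death_cycle"] = records["death_cycle"].mask(records["death_cycle"] < 0)
    records["cvd_entry_cycle"] = records["cvd_entry_cycle"].mask(records["cvd_entry_cycle"] < 0)
    records["total_cost_disc"] = records["screening_cost"] + records["markov_cost_disc"]
    if return_paths:
        return records, paths
    return records


def paths_to_long(records: pd.DataFrame, paths: np.ndarray) -> pd.DataFrame:
    """Long-format per-cycle table (id, cycle, state) for export."""
    n, tp1 = paths.shape
    names = np.array(["HEALTHY", "SARC", "SARC_CVD", "DEAD"])
    return pd.DataFrame(
        {
            "id": np.repeat(records["id"].to_numpy(), tp1),
            "cycle": np.tile(np.arange(tp1), n),
            "state": names[paths.ravel()],
        }
    )


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return m, se


def summarize(records: pd.DataFrame) -> dict:
    """Per-arm and overall means with standard errors, plus event rates.

    Arm-level costs exclude the screening cost (screening is a strategy-level
    quantity); the overall summary includes it. The fracture-event rate is
    fractures per person-cycle spent in a sarcopenia state, reported
    separately for treated and untreated individuals with a binomial SE.
    """
    if records is None or len(records) == 0:
        raise EmptySummaryError("no records to summarize")

    per_arm = []
    for arm_name, grp in records.groupby("arm", sort=True):
        mc, sec = _mean_se(grp["markov_cost_disc"].to_numpy())
        mq, seq = _mean_se(grp["qaly_disc"].to_numpy())
        per_arm.append(
            {
                "arm": arm_name, "n": len(grp),
                "mean_cost": mc, "se_cost": sec,
                "mean_qaly": mq, "se_qaly": seq,
            }
        )
    per_arm = pd.DataFrame(per_arm).set_index("arm")

    mc, sec = _mean_se(records["total_cost_disc"].to_numpy())
    mq, seq = _mean_se(records["qaly_disc"].to_numpy())
    overall = {"n": len(records), "mean_cost": mc, "se_cost": sec,
               "mean_qaly": mq, "se_qaly": seq}

    rates = []
    for label, mask in (("treated", records["arm"] == "TP"),
                        ("untreated", records["arm"].isin(["FN"]))):
        grp = records[mask]
        pc = int(grp["sarc_cycles"].sum())
        ev = int(grp["n_fractures"].sum())
        if pc > 0:
            p = ev / pc
            rates.append({"group": label, "person_cycles": pc, "events": ev,
                          "rate": p, "se": np.sqrt(p * (1 - p) / pc)})
    event_rates = pd.DataFrame(rates).set_index("group") if rates else pd.DataFrame()

    return {"per_arm": per_arm, "overall": overall, "event_rates": event_rates}
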