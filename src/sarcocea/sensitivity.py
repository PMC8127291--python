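"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA re-evaluates the full model at each parameter's low and high
bound (printed 95% CI where available, otherwise base ± 1 SD, clipped to the
parameter's feasible domain) holding everything else at base, and sorts
parameters by the width of the induced change in the outcome. The default
outcome is the net-monetary-benefit gap of the focal strategy over its best
alternative at the willingness-to-pay threshold; the ICER against a reference
strategy is available instead.

PSA draws every uncertain parameter jointly (independent moment-matched
marginals, infeasible joint draws rejected and redrawn), re-evaluates all
strategies per draw, and derives the cost-effectiveness acceptability curve
(CEAC) — the probability each strategy has the highest NMB as a function of
the willingness-to-pay — and the strategy-selection probabilities at the
threshold itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import net_monetary_benefit
from .markov import ModelConstructionError, evaluate_all_strategies
from .parameters import (
    PARAMETER_NAMES,
    ParameterError,
    ParameterSet,
    sample_parameter_set_counted,
)
from .screening import STRATEGY_ORDER

__all__ = ["one_way_dsa", "PSAResult", "run_psa", "ceac", "selection_probabilities",
           "default_lambda_grid"]


# ----------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ----------------------------------------------------------------------------

#: structural couplings that a one-at-a-time perturbation must respect
_STRUCTURAL_BOUNDS = {
    "u_healthy": lambda v: (v("u_sarc"), 1.0),
    "u_sarc": lambda v: (0.0, v("u_healthy")),
    "u_sarc_cvd": lambda v: (v("u_sarc_cvd_fracture"), 1.0),
    "u_sarc_fracture": lambda v: (v("u_sarc_cvd_fracture"), 1.0),
    "u_sarc_cvd_fracture": lambda v: (0.0, min(v("u_sarc_cvd"), v("u_sarc_fracture"))),
}


def _clip_bound(params: ParameterSet, name: str, value: float) -> float:
    lo, hi = -np.inf, np.inf
    if name in _STRUCTURAL_BOUNDS:
        lo, hi = _STRUCTURAL_BOUNDS[name](params.value)
    clipped = min(max(value, lo), hi)
    if clipped != value:
        warnings.warn(
            f"DSA bound {value:.6g} for {name} clipped to {clipped:.6g} "
            "to keep the parameter set structurally feasible",
            stacklevel=3,
        )
    return clipped


def _outcome_fn(outcome: str, strategy: str, reference: str, wtp: float):
    def compute(ps: ParameterSet) -> float:
        table = evaluate_all_strategies(ps)
        if outcome == "nmb_gap":
            nmb = {
                name: net_monetary_benefit(row["cost"], row["effect"], wtp)
                for name, row in table.iterrows()
            }
            best_other = max(v for k, v in nmb.items() if k != strategy)
            return nmb[strategy] - best_other
        if outcome == "icer":
            dc = table.at[strategy, "cost"] - table.at[reference, "cost"]
            de = table.at[strategy, "effect"] - table.at[reference, "effect"]
            return dc / de if de != 0 else np.nan
        raise ValueError(f"unknown DSA outcome {outcome!r}")

    return compute


def one_way_dsa(
    params: ParameterSet,
    parameters: list[str] | None = None,
    outcome: str = "nmb_gap",
    strategy: str = "EWGSOP",
    reference: str = "NoScreening",
    wtp: float | None = None,
) -> pd.DataFrame:
    """Tornado table: one row per varied parameter, sorted by bar width.

    Columns: low, high (input bounds actually used), outcome_low,
    outcome_high, outcome_base, width. The sort is stable, descending by
    ``width = |outcome_high - outcome_low|``.
    """
    if parameters is None:
        parameters = [
            n for n in PARAMETER_NAMES if params.params[n].family != "fixed"
        ]
    if wtp is None:
        wtp = params.wtp
    fn = _outcome_fn(outcome, strategy, reference, wtp)
    base_val = fn(params)

    rows = []
    for name in parameters:
        up = params.params[name]
        lo, hi = up.dsa_range(params.default_sd_fraction)
        lo = _clip_bound(params, name, lo)
        hi = _clip_bound(params, name, hi)
        out_lo = fn(params.with_values({name: lo}))
        out_hi = fn(params.with_values({name: hi}))
        rows.append(
            {
                "parameter": name, "low": lo, "high": hi,
                "outcome_low": out_lo, "outcome_high": out_hi,
                "outcome_base": base_val,
                "width": abs(out_hi - out_lo),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("width", ascending=False, kind="mergesort").set_index("parameter")


# ----------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ----------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Monte-Carlo PSA output.

    ``draws``: one row per iteration, one column per sampled parameter.
    ``costs`` / ``effects``: one row per iteration, one column per strategy
    (roster order). ``n_rejected`` counts infeasible joint draws that were
    rejected and redrawn.
    """

    draws: pd.DataFrame
    costs: pd.DataFrame
    effects: pd.DataFrame
    seed: int
    wtp: float
    n_rejected: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.costs)


def run_psa(params: ParameterSet, n_iter: int = 1000, seed: int = 0) -> PSAResult:
    """Sample ``n_iter`` parameter sets and evaluate all five strategies on each.

    A single RNG stream drives all iterations, so the result is bit-identical
    under a fixed seed. Joint draws that violate structural feasibility
    (including any derived transition probability leaving [0, 1]) are
    rejected and redrawn from the same stream.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draws, costs, effects = [], [], []
    rejected = 0
    for _ in range(n_iter):
        while True:
            sampled, rej = sample_parameter_set_counted(params, rng)
            rejected += rej
            try:
                table = evaluate_all_strategies(sampled)
                break
            except (ParameterError, ModelConstructionError):
                rejected += 1
        draws.append({n: sampled.value(n) for n in PARAMETER_NAMES})
        costs.append(table["cost"].reindex(list(STRATEGY_ORDER)).to_numpy())
        effects.append(table["effect"].reindex(list(STRATEGY_ORDER)).to_numpy())
    cols = list(STRATEGY_ORDER)
    return PSAResult(
        draws=pd.DataFrame(draws),
        costs=pd.DataFrame(costs, columns=cols),
        effects=pd.DataFrame(effects, columns=cols),
        seed=int(seed) if np.isscalar(seed) else 0,
        wtp=params.wtp,
        n_rejected=rejected,
    )


def default_lambda_grid(wtp: float, n_steps: int = 100) -> np.ndarray:
    """0 to 3x the willingness-to-pay threshold in ``n_steps`` steps."""
    return np.linspace(0.0, 3.0 * wtp, n_steps + 1)


def ceac(psa: PSAResult, lambda_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the probability that each strategy has
    the strictly highest NMB across PSA iterations; exact ties split their
    iteration's mass equally.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(psa.wtp)
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0:
        raise ValueError("lambda grid must be non-empty")
    C = psa.costs.to_numpy()    # (n_iter, n_strat)
    E = psa.effects.to_numpy()
    out = np.zeros((lam.size, C.shape[1]))
    for j, l in enumerate(lam):
        nmb = l * E - C
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        out[j] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return pd.DataFrame(out, index=pd.Index(lam, name="lambda"), columns=psa.costs.columns)


def selection_probabilities(psa: PSAResult, wtp: float | None = None) -> pd.Series:
    """CEAC evaluated at the single willingness-to-pay threshold."""
    if psa.n_iterations == 0:
        raise ValueError("empty PSA result")
    if wtp is None:
        wtp = psa.wtp
    return ceac(psa, [wtp]).iloc[0].rename("probability")
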