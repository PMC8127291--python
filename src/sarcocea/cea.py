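"""Incremental cost-effectiveness analysis: ICER table, dominance, NMB, frontier.

Two ICER conventions are supported because both are standard:

* **common-reference** — every strategy's incremental cost and effect are taken
  against one named reference strategy (here typically no screening);
* **frontier** — strategies are sorted by cost, strongly/weakly dominated ones
  (costlier and no more effective) are removed, then extendedly dominated ones
  (a strategy whose sequential ICER exceeds that of the next more effective
  option) are removed iteratively; sequential ICERs are then strictly
  increasing along the efficiency frontier, which is the lower-right convex
  hull of the (effect, cost) cloud.

Net monetary benefit at willingness-to-pay ``lambda`` is ``lambda*E - C``;
maximizing NMB is equivalent to the frontier/ICER decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CEAError",
    "FrontierResult",
    "net_monetary_benefit",
    "icer_table",
    "frontier",
]


class CEAError(Exception):
    """Invalid input to the incremental analysis."""


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """NMB = wtp * effect - cost (USD)."""
    if not (np.isfinite(cost) and np.isfinite(effect) and np.isfinite(wtp)):
        raise CEAError("NMB requires finite cost, effect and willingness-to-pay")
    return wtp * effect - cost


@dataclass(frozen=True)
class FrontierResult:
    """Efficiency frontier: retained strategies (by ascending effect) and the
    removed ones with their removal reason."""

    frontier: tuple[str, ...]
    removed: dict[str, str]  # name -> "dominated" | "extendedly_dominated"
    sequential_icers: tuple[float, ...]  # between consecutive frontier members


def _as_frame(results) -> pd.DataFrame:
    """Normalize (strategy, cost, effect) input to a DataFrame."""
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if "strategy" not in df.columns:
            df = df.reset_index()
        df = df[["strategy", "cost", "effect"]]
    else:
        df = pd.DataFrame(list(results), columns=["strategy", "cost", "effect"])
    if df["strategy"].duplicated().any():
        raise CEAError("duplicate strategy names")
    if not np.isfinite(df[["cost", "effect"]].to_numpy()).all():
        raise CEAError("costs and effects must be finite")
    return df


def _dominance_pass(df: pd.DataFrame) -> dict[str, str]:
    """Strong/weak dominance: removed if another strategy has cost <= and
    effect >= with at least one strict inequality (equal-equal ties survive)."""
    removed: dict[str, str] = {}
    rows = df.to_dict("records")
    for a in rows:
        for b in rows:
            if a["strategy"] == b["strategy"]:
                continue
            if (
                b["cost"] <= a["cost"]
                and b["effect"] >= a["effect"]
                and (b["cost"] < a["cost"] or b["effect"] > a["effect"])
            ):
                removed[a["strategy"]] = "dominated"
                break
    return removed


def frontier(results) -> FrontierResult:
    """Efficiency frontier with removal reasons.

    After the dominance pass, survivors are ordered by ascending effect and
    any member whose incremental ICER (vs the previous survivor) is >= the
    next member's is removed as extendedly dominated, repeating until the
    sequential ICERs are strictly increasing. Exactly collinear triples keep
    the middle point (removal requires a strict inequality).
    """
    df = _as_frame(results)
    if len(df) == 0:
        raise CEAError("at least one strategy required")
    removed = _dominance_pass(df)
    live = df[~df["strategy"].isin(removed)].sort_values(
        ["effect", "cost"], kind="mergesort"
    )

    def seq_icers(fr: pd.DataFrame) -> np.ndarray:
        de = np.diff(fr["effect"].to_numpy())
        dc = np.diff(fr["cost"].to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(de > 0, dc / np.where(de > 0, de, 1.0), np.inf)

    while len(live) >= 3:
        icers = seq_icers(live)
        # first interior member with a non-increasing step is extendedly dominated
        drop = None
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                drop = live.iloc[i + 1]["strategy"]
                break
        if drop is None:
            break
        removed[drop] = "extendedly_dominated"
        live = live[live["strategy"] != drop]

    return FrontierResult(
        frontier=tuple(live["strategy"]),
        removed=removed,
        sequential_icers=tuple(seq_icers(live)) if len(live) >= 2 else (),
    )


def icer_table(results, reference: str = "pairwise-frontier", wtp: float = 5520.311) -> pd.DataFrame:
    """Incremental CEA table, sorted by ascending cost.

    ``reference``
        A strategy name for common-reference mode (that strategy's row gets
        zero increments and no ICER), or ``"pairwise-frontier"`` for frontier
        mode (increments against the previous non-dominated strategy).

    Columns: cost, effect, incr_cost, incr_effect, icer, dominance, nmb.
    The ICER is NaN where the incremental effect is zero (flagged via the
    dominance column rather than divided).
    """
    df = _as_frame(results)
    if len(df) < 2:
        raise CEAError("ICER table requires at least two strategies")
    df = df.sort_values(["cost", "effect"], kind="mergesort").reset_index(drop=True)
    df["nmb"] = [net_monetary_benefit(c, e, wtp) for c, e in zip(df["cost"], df["effect"])]

    fr = frontier(df[["strategy", "cost", "effect"]])
    df["dominance"] = [
        fr.removed.get(name, "nondominated") for name in df["strategy"]
    ]

    incr_cost = np.full(len(df), np.nan)
    incr_effect = np.full(len(df), np.nan)
    icer = np.full(len(df), np.nan)

    if reference == "pairwise-frontier":
        order = list(fr.frontier)  # ascending effect == ascending cost on frontier
        prev = None
        for name in order:
            i = df.index[df["strategy"] == name][0]
            if prev is not None:
                dc = df.at[i, "cost"] - df.at[prev, "cost"]
                de = df.at[i, "effect"] - df.at[prev, "effect"]
                incr_cost[i], incr_effect[i] = dc, de
                if de != 0.0:
                    icer[i] = dc / de
            else:
                incr_cost[i] = incr_effect[i] = 0.0
            prev = i
    else:
        if reference not in set(df["strategy"]):
            raise CEAError(f"reference strategy {reference!r} not among results")
        r = df.index[df["strategy"] == reference][0]
        for i in df.index:
            dc = df.at[i, "cost"] - df.at[r, "cost"]
            de = df.at[i, "effect"] - df.at[r, "effect"]
            incr_cost[i], incr_effect[i] = dc, de
            if i != r and de != 0.0:
                icer[i] = dc / de
            elif i != r and dc > 0.0:
                df.at[i, "dominance"] = "dominated"  # more cost, same effect
            elif i != r and dc == 0.0:
                df.at[i, "dominance"] = "tie"  # identical (cost, effect)

    df["incr_cost"] = incr_cost
    df["incr_effect"] = incr_effect
    df["icer"] = icer
    cols = ["strategy", "cost", "incr_cost", "effect", "incr_effect", "icer", "dominance", "nmb"]
    return df[cols].set_index("strategy")
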