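"""Report generation: base-case tables, DSA/PSA artifacts, oracle check, manifest.

Every runner writes plain CSV ('.' decimal, UTF-8, header row), JSON for
structured results, and PNG figures, and records what it wrote in a JSON run
manifest together with the configuration hash, seeds and package version, so
a run can be reproduced byte-for-byte from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from . import __version__  # noqa: E402
from .cea import frontier, icer_table, net_monetary_benefit  # noqa: E402
from .markov import evaluate_all_strategies, evaluate_arms  # noqa: E402
from .microsim import simulate_individuals, summarize  # noqa: E402
from .parameters import ParameterSet  # noqa: E402
from .screening import classify_cohort, expected_screening_cost, strategies_from_parameters  # noqa: E402
from .sensitivity import ceac, one_way_dsa, run_psa, selection_probabilities  # noqa: E402

log = logging.getLogger("sarcocea")

__all__ = ["RunManifest", "run_base", "run_dsa", "run_psa_report", "run_oracle"]


class RunManifest:
    """Accumulates run metadata and produced files; written as manifest JSON."""

    def __init__(self, params: ParameterSet, out_dir: Path, seeds: dict | None = None):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.config_hash = hashlib.sha256(params.to_yaml().encode()).hexdigest()
        self.seeds = seeds or {}
        self.files: list[str] = []
        self.started = datetime.now(timezone.utc).isoformat()

    def path(self, name: str) -> Path:
        self.files.append(name)
        return self.out_dir / name

    def write(self, name: str = "manifest.json") -> Path:
        doc = {
            "package": "sarcocea",
            "version": __version__,
            "config_sha256": self.config_hash,
            "seeds": self.seeds,
            "started_utc": self.started,
            "finished_utc": datetime.now(timezone.utc).isoformat(),
            "files": sorted(set(self.files)),
        }
        p = self.out_dir / name
        p.write_text(json.dumps(doc, indent=2) + "\n")
        return p


def _save_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.10g")
    log.info("wrote %s", path)


def run_base(params: ParameterSet, out_dir) -> dict:
    """Base-case analysis: classification, per-strategy outcomes, both ICER
    tables, NMB, frontier and cost-effectiveness-plane coordinates."""
    manifest = RunManifest(params, out_dir)
    strategies = strategies_from_parameters(params)
    prev = params.value("prevalence")

    rows = []
    for s in strategies:
        r = classify_cohort(s, prev)
        rows.append(
            {"strategy": s.name, **r.as_dict(),
             "screening_cost": expected_screening_cost(s, r, params.stage2_charge_multiplier)}
        )
    _save_csv(pd.DataFrame(rows).set_index("strategy"), manifest.path("classification.csv"))

    outcomes = evaluate_all_strategies(params, strategies)
    outcomes["nmb"] = [
        net_monetary_benefit(c, e, params.wtp)
        for c, e in zip(outcomes["cost"], outcomes["effect"])
    ]
    _save_csv(outcomes, manifest.path("strategy_outcomes.csv"))

    ref_table = icer_table(outcomes, reference="NoScreening", wtp=params.wtp)
    _save_csv(ref_table, manifest.path("cea_table_reference.csv"))
    fr_table = icer_table(outcomes, reference="pairwise-frontier", wtp=params.wtp)
    _save_csv(fr_table, manifest.path("cea_table_frontier.csv"))

    fr = frontier(outcomes)
    manifest.path("frontier.json").write_text(
        json.dumps(
            {"frontier": list(fr.frontier), "removed": fr.removed,
             "sequential_icers": list(fr.sequential_icers)},
            indent=2,
        )
        + "\n"
    )

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(outcomes["effect"], outcomes["cost"])
    for name, row in outcomes.iterrows():
        ax.annotate(name, (row["effect"], row["cost"]), fontsize=8,
                    xytext=(4, 4), textcoords="offset points")
    on_front = outcomes.loc[list(fr.frontier)].sort_values("effect")
    ax.plot(on_front["effect"], on_front["cost"], "-", color="tab:blue", alpha=0.6)
    ax.set_xlabel("Effect (QALYs per person)")
    ax.set_ylabel("Cost (USD per person)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(manifest.path("ce_plane.png"), dpi=150)
    plt.close(fig)

    manifest.write()
    return {"outcomes": outcomes, "reference_table": ref_table,
            "frontier_table": fr_table, "frontier": fr}


def run_dsa(params: ParameterSet, out_dir, outcome: str = "nmb_gap") -> pd.DataFrame:
    """Tornado analysis: CSV plus the tornado bar figure."""
    manifest = RunManifest(params, out_dir)
    tor = one_way_dsa(params, outcome=outcome)
    _save_csv(tor, manifest.path("tornado.csv"))

    top = tor.head(15).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(top) + 1.5))
    base = top["outcome_base"].iloc[0] if len(top) else 0.0
    lo = np.minimum(top["outcome_low"], top["outcome_high"])
    hi = np.maximum(top["outcome_low"], top["outcome_high"])
    ax.barh(top.index, hi - lo, left=lo, color="tab:orange", alpha=0.8)
    ax.axvline(base, color="k", lw=1)
    ax.set_xlabel(f"DSA outcome ({outcome})")
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(manifest.path("tornado.png"), dpi=150)
    plt.close(fig)
    manifest.write()
    return tor


def run_psa_report(params: ParameterSet, out_dir, n_iter: int = 1000, seed: int = 0) -> dict:
    """PSA: draw file, CEAC table+figure, selection probabilities, CE scatter."""
    manifest = RunManifest(params, out_dir, seeds={"psa": seed})
    psa = run_psa(params, n_iter=n_iter, seed=seed)
    log.info("PSA: %d iterations, %d rejected draws", psa.n_iterations, psa.n_rejected)

    draws = psa.draws.copy()
    draws.index.name = "iteration"
    for s in psa.costs.columns:
        draws[f"cost_{s}"] = psa.costs[s].to_numpy()
        draws[f"effect_{s}"] = psa.effects[s].to_numpy()
    _save_csv(draws, manifest.path("psa_draws.csv"))

    curve = ceac(psa)
    _save_csv(curve, manifest.path("ceac.csv"))
    sel = selection_probabilities(psa)
    sel.index.name = "strategy"
    _save_csv(sel.to_frame(), manifest.path("selection_probabilities.csv"))

    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for s in curve.columns:
        ax.plot(curve.index, curve[s], label=s)
    ax.axvline(params.wtp, color="k", ls="--", lw=1, label="WTP threshold")
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(highest NMB)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    ax.set_title("Cost-effectiveness acceptability curves")
    fig.tight_layout()
    fig.savefig(manifest.path("ceac.png"), dpi=150)
    plt.close(fig)

    base = evaluate_all_strategies(params)
    ref = "NoScreening"
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for s in psa.costs.columns:
        if s == ref:
            continue
        ax.scatter(
            psa.effects[s] - psa.effects[ref], psa.costs[s] - psa.costs[ref],
            s=4, alpha=0.35, label=s,
        )
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"Incremental effect vs {ref} (QALYs)")
    ax.set_ylabel(f"Incremental cost vs {ref} (USD)")
    ax.legend(fontsize=8, markerscale=2)
    ax.set_title("Incremental cost-effectiveness scatter")
    fig.tight_layout()
    fig.savefig(manifest.path("ce_scatter.png"), dpi=150)
    plt.close(fig)

    manifest.write()
    return {"psa": psa, "ceac": curve, "selection": sel, "base": base}


def run_oracle(params: ParameterSet, out_dir, n: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Cohort-vs-microsimulation comparison table with per-arm z-scores.

    Simulates individuals under the SarSA-Mod strategy (an imperfect test, so
    its classification populates all four arms) and compares per-arm mean
    discounted cost and QALYs against the deterministic cohort engine;
    |z| < 3 per cell passes. Cells with zero Monte-Carlo variance (e.g. the
    false-positive arm's cost, which is one fixed treatment cycle) must match
    the cohort value exactly.
    """
    manifest = RunManifest(params, out_dir, seeds={"oracle": seed})
    strategies = {s.name: s for s in strategies_from_parameters(params)}
    records = simulate_individuals(params, strategies["SarSA-Mod"], n, seed)
    summary = summarize(records)
    arm_traces = evaluate_arms(params)

    rows = []
    for arm_name, row in summary["per_arm"].iterrows():
        tr = arm_traces[arm_name]
        for metric, mean_col, se_col, cohort_val in (
            ("cost", "mean_cost", "se_cost", tr.total_cost),
            ("qaly", "mean_qaly", "se_qaly", tr.total_qalys),
        ):
            if row[se_col] > 1e-12 * max(1.0, abs(cohort_val)):
                z = (row[mean_col] - cohort_val) / row[se_col]
                ok = bool(abs(z) < 3)
            else:  # degenerate cell: no sampling variance, must match exactly
                z = np.nan
                ok = bool(abs(row[mean_col] - cohort_val) < 1e-9)
            rows.append(
                {"arm": arm_name, "metric": metric, "n": int(row["n"]),
                 "microsim_mean": row[mean_col], "microsim_se": row[se_col],
                 "cohort_value": cohort_val, "z": z, "pass": ok}
            )
    table = pd.DataFrame(rows).set_index(["arm", "metric"])
    _save_csv(table, manifest.path("oracle_comparison.csv"))

    _save_csv(records, manifest.path("individuals.csv"))
    manifest.write()
    return table
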