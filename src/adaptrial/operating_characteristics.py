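"""Monte-Carlo operating characteristics, the candidate-design grid, and
shortlisting against the fixed-design benchmark.

Operating characteristics (OCs) of a design under a scenario are the
frequentist properties estimated by simulating many trials: the
probabilities of concluding success / futility / inconclusive, and the
distributions of enrolled sample size and trial duration.  Shortlisting
keeps designs whose simulated success probability beats the fixed
design's both under the null (lower false-positive rate) and across the
target-effect region (higher power), then picks, per decision method,
the survivor with the lowest mean sample size and the one with the
highest power.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .designs import TrialDesign, FixedDesign, ScenarioConfig
from .decision_methods import Continuation
from .trial_engine import run_adaptive_trial, run_fixed_trial, simulate_dataset

__all__ = [
    "OCSummary",
    "estimate_oc",
    "oc_curve",
    "enumerate_grid",
    "grid_search",
    "shortlist",
    "GRID_VALUES",
]


@dataclass(frozen=True)
class OCSummary:
    """Monte-Carlo operating characteristics of one design under one
    scenario.  Probabilities are percentages and partition to 100 before
    rounding; ``se_*`` are Monte-Carlo standard errors."""

    design: str
    scenario: str
    n_sims: int
    p_success: float
    p_futility: float
    p_inconclusive: float
    se_success: float
    mean_n: float
    sd_n: float
    se_mean_n: float
    mean_duration: float
    sd_duration: float
    se_mean_duration: float

    def to_dict(self) -> dict:
        return asdict(self)


def _binom_se_pct(p_pct: float, n: int) -> float:
    p = p_pct / 100.0
    return 100.0 * math.sqrt(max(p * (1 - p), 0.0) / n)


def estimate_oc(design: TrialDesign | FixedDesign, scenario: ScenarioConfig,
                n_sims: int, rng: np.random.Generator,
                continuation: Continuation | None = None,
                n_roster: int | None = None,
                n_draws: int | None = None) -> OCSummary:
    """Simulate ``n_sims`` independent trials of a design under a
    scenario and aggregate their operating characteristics.

    Each replicate draws its own dataset from the scenario with a child
    generator spawned from ``rng``, so runs are reproducible given the
    seed and can be sharded by spawning.  ``continuation`` defaults to
    the scenario's accrual/dropout/horizon assumptions (the design-time
    projection assumptions of the case study).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    fixed = isinstance(design, FixedDesign)
    if continuation is None:
        continuation = Continuation(
            accrual_rate=scenario.accrual_rate,
            dropout_rate=scenario.dropout_rate,
            max_duration=scenario.max_duration,
            n_draws=n_draws or Continuation.n_draws)
    elif n_draws is not None:
        raise ValueError("pass n_draws inside the continuation")
    if n_roster is None:
        if fixed:
            n_roster = design.n_total + 40
        else:
            n_roster = 2 * design.max_n_per_arm + 40
    conclusions = np.empty(n_sims, dtype=object)
    n_tot = np.empty(n_sims)
    dur = np.empty(n_sims)
    for i, child in enumerate(rng.spawn(n_sims)):
        ds = simulate_dataset(scenario, n_roster, child)
        if fixed:
            res = run_fixed_trial(ds, design)
        else:
            res = run_adaptive_trial(design, ds, continuation, rng=child)
        conclusions[i] = res.conclusion
        n_tot[i] = res.n_total
        dur[i] = res.stop_time
    p_s = 100.0 * np.count_nonzero(conclusions == "success") / n_sims
    p_f = 100.0 * np.count_nonzero(conclusions == "futility") / n_sims
    p_i = 100.0 - p_s - p_f
    return OCSummary(
        design=(design.name or design.method) if not fixed
        else (design.name or "fixed"),
        scenario=scenario.name or f"{scenario.median_C}v{scenario.median_E}",
        n_sims=n_sims,
        p_success=p_s, p_futility=p_f, p_inconclusive=p_i,
        se_success=_binom_se_pct(p_s, n_sims),
        mean_n=float(n_tot.mean()), sd_n=float(n_tot.std(ddof=1)),
        se_mean_n=float(n_tot.std(ddof=1) / math.sqrt(n_sims)),
        mean_duration=float(dur.mean()), sd_duration=float(dur.std(ddof=1)),
        se_mean_duration=float(dur.std(ddof=1) / math.sqrt(n_sims)),
    )


def oc_curve(design: TrialDesign | FixedDesign, scenario: ScenarioConfig,
             experimental_medians, n_sims: int, rng: np.random.Generator,
             **kw) -> pd.DataFrame:
    """Operating characteristics across a family of effect sizes: one
    :class:`OCSummary` row per experimental-arm median (months), holding
    the control arm at the base scenario's median."""
    medians = list(experimental_medians)
    if len(medians) < 2:
        raise ValueError("need at least two scenario points")
    rows = []
    for med in medians:
        sc = scenario.replace(median_E=float(med),
                              name=f"E{med}vC{scenario.median_C}")
        s = estimate_oc(design, sc, n_sims, rng, **kw)
        row = s.to_dict()
        row["median_E"] = float(med)
        row["median_C"] = scenario.median_C
        rows.append(row)
    return pd.DataFrame(rows)


#: Candidate values per design parameter for the grid search.
GRID_VALUES = {
    "k_F": [10, 20, 30, 40, 50],
    "k_S": [10, 20, 30, 40, 50],
    "d_L_posterior": [0.05, 0.1, 0.2, 0.3, 0.4, 0.5],
    "d_U_posterior": [round(0.99 + 0.001 * i, 3) for i in range(10)],
    "d_L_predictive": [0.005, 0.01, 0.025, 0.05, 0.1, 0.2],
    "d_U_predictive": [0.95, 0.975, 0.99, 0.995, 0.999, 0.9995],
    "d_alpha": [0.03, 0.04, 0.05, 0.06, 0.07],
    "d_S": [0.965, 0.97, 0.975, 0.98, 0.985],
}


def enumerate_grid(method: str) -> list[TrialDesign]:
    """Full cartesian product of a method's candidate settings
    (posterior: 1,500 designs; pps/cps/goldilocks/ppbs: 4,500 each;
    19,500 in total across the five methods)."""
    g = GRID_VALUES
    if method == "posterior":
        combos = itertools.product(g["k_F"], g["k_S"], g["d_L_posterior"],
                                   g["d_U_posterior"], [None], [None])
    elif method in ("pps", "cps", "goldilocks"):
        combos = itertools.product(g["k_F"], g["k_S"], g["d_L_predictive"],
                                   g["d_U_predictive"], g["d_alpha"], [None])
    elif method == "ppbs":
        combos = itertools.product(g["k_F"], g["k_S"], g["d_L_predictive"],
                                   g["d_U_predictive"], [None], g["d_S"])
    else:
        raise ValueError(f"unknown decision method {method!r}")
    return [TrialDesign(method=method, k_F=kf, k_S=ks, d_L=dl, d_U=du,
                        d_alpha=da, d_S=dS)
            for kf, ks, dl, du, da, dS in combos]


_PARAM_COLS = ["method", "k_F", "k_S", "d_L", "d_U", "d_alpha", "d_S"]


def grid_search(designs, scenarios, n_sims: int, rng: np.random.Generator,
                **kw) -> pd.DataFrame:
    """Estimate OCs for every design x scenario pair; returns a long
    table with one row per pair (design parameters included, so the
    output is self-describing)."""
    rows = []
    for i, design in enumerate(designs):
        for sc in scenarios:
            s = estimate_oc(design, sc, n_sims, rng, **kw)
            row = s.to_dict()
            row["design_id"] = i
            row["median_E"] = sc.median_E
            row["median_C"] = sc.median_C
            for c in _PARAM_COLS:
                row[c] = getattr(design, c, None)
            rows.append(row)
    return pd.DataFrame(rows)


def shortlist(oc_table: pd.DataFrame, fixed_table: pd.DataFrame,
              target_medians=(14.0, 15.0, 16.0),
              objective_median: float = 15.0,
              region_rule: str = "all") -> pd.DataFrame:
    """Filter and rank candidate designs against the fixed benchmark.

    A design survives when (1) its success probability under the null
    scenario (``median_E == median_C``) is strictly below the fixed
    design's, and (2) its success probability strictly exceeds the fixed
    design's in the target-effect region -- at every median in
    ``target_medians`` (``region_rule="all"``, the default) or at least
    one (``"any"``).  Among survivors, per decision method, the design
    minimising mean sample size and the one maximising success
    probability at ``objective_median`` are returned (strategies
    ``"small"`` and ``"high"``), with lexicographic tie-breaking on the
    design parameters.  An empty survivor set yields an empty frame.
    """
    if region_rule not in ("all", "any"):
        raise ValueError("region_rule must be 'all' or 'any'")

    def fixed_at(med_E):
        row = fixed_table[np.isclose(fixed_table["median_E"], med_E)]
        if row.empty:
            raise ValueError(f"fixed benchmark missing median_E={med_E}")
        return float(row["p_success"].iloc[0])

    null_rows = oc_table[np.isclose(oc_table["median_E"],
                                    oc_table["median_C"])]
    fixed_null = fixed_at(float(fixed_table["median_C"].iloc[0]))
    ok_null = set(null_rows.loc[null_rows["p_success"] < fixed_null,
                                "design_id"])
    region_ok = None
    for med in target_medians:
        rows = oc_table[np.isclose(oc_table["median_E"], med)]
        ok = set(rows.loc[rows["p_success"] > fixed_at(med), "design_id"])
        if region_ok is None:
            region_ok = ok
        elif region_rule == "all":
            region_ok &= ok
        else:
            region_ok |= ok
    survivors = ok_null & (region_ok or set())

    obj = oc_table[np.isclose(oc_table["median_E"], objective_median)]
    obj = obj[obj["design_id"].isin(survivors)].copy()
    if obj.empty:
        return pd.DataFrame(columns=_PARAM_COLS + ["strategy", "mean_n",
                                                   "p_success"])
    sort_keys = [c for c in ("k_F", "k_S", "d_L", "d_U", "d_alpha", "d_S")
                 if c in obj.columns]
    picks = []
    for method, sub in obj.groupby("method", sort=True):
        for strategy, by, asc in (("small", "mean_n", True),
                                  ("high", "p_success", False)):
            best = sub.sort_values([by] + sort_keys,
                                   ascending=[asc] + [True] * len(sort_keys))
            row = best.iloc[0].to_dict()
            row["strategy"] = strategy
            picks.append(row)
    out = pd.DataFrame(picks)
    # every pick satisfies both criteria by construction
    assert set(out["design_id"]) <= survivors
    return out.reset_index(drop=True)
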