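"""Execute a single trial -- simulated or replayed -- through the
28-day interim schedule.

The engine is replay-first: it consumes a :class:`SurvivalDataset`
(simulated or real) in recruitment order, so virtual re-execution of a
recorded trial and Monte-Carlo simulation share one code path.  Interim
analyses sit on a fixed calendar grid (every ``interim_interval_days``
from trial start, which is the first randomisation).  At each interim
the snapshot uses exactly the data that would have been known at the
time.

Stopping logic per interim (success checked before futility):

* success  -- decision probability > ``d_U`` and both arms have at least
  ``k_S`` events;
* futility -- decision probability < ``d_L`` and both arms have at least
  ``k_F`` events;
* enrolment is capped at ``max_n_per_arm`` per arm (in simulation a
  subject randomised to a full arm joins the open one; in replay the
  recorded allocations close recruitment when an arm fills);
* the trial ends inconclusive at the first interim at or past the
  follow-up horizon (``continuation.max_duration``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr as _ndtr

from .designs import TrialDesign, FixedDesign, ScenarioConfig
from .decision_methods import (Continuation, InterimSnapshot, DecisionProbs,
                               _log_hazard_ratio_posterior, evaluate_decision)
from .survival_core import (ArmSummary, ScoreStat, SurvivalDataset,
                            cox_score_fit)

__all__ = [
    "TrialResult",
    "simulate_dataset",
    "assign_arms",
    "run_adaptive_trial",
    "run_fixed_trial",
]

_SCORE_METHODS = frozenset({"pps", "cps", "goldilocks"})


@dataclass
class TrialResult:
    """Outcome of one executed trial."""

    conclusion: str            # "success" | "futility" | "inconclusive"
    stop_time: float           # months from trial start
    n_total: int
    n_E: int
    n_C: int
    d_E: int
    d_C: int
    trace: pd.DataFrame | None = None
    hr: float | None = None
    hr_ci: tuple[float, float] | None = None
    events_flagged_short: bool = False  # fixed design: event target unmet

    @property
    def events(self) -> int:
        return self.d_E + self.d_C


def assign_arms(n: int, rng: np.random.Generator) -> np.ndarray:
    """Equal randomisation: an independent fair coin per subject
    (True = experimental).  Arm caps are enforced by the engine, not
    here."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.random(n) < 0.5


def simulate_dataset(scenario: ScenarioConfig, n_max_total: int,
                     rng: np.random.Generator) -> SurvivalDataset:
    """Draw a roster of ``n_max_total`` potential participants.

    Recruitment times are the cumulative sums of exponential
    inter-arrival gaps (a Poisson process at the accrual rate); arms are
    assigned by equal randomisation; death times are exponential at the
    arm hazard and dropout times exponential at the dropout rate.  The
    observed record is ``min(death, dropout)``; no administrative
    horizon is baked in, so a snapshot at any analysis time is
    computable.
    """
    gaps = rng.exponential(1.0 / scenario.accrual_rate, n_max_total)
    recruit = np.cumsum(gaps)
    is_exp = assign_arms(n_max_total, rng)
    mean_time = np.where(is_exp, scenario.median_E / math.log(2.0),
                         scenario.median_C / math.log(2.0))
    death = rng.standard_exponential(n_max_total) * mean_time
    if scenario.dropout_rate > 0:
        drop = rng.exponential(1.0 / scenario.dropout_rate, n_max_total)
    else:
        drop = np.full(n_max_total, np.inf)
    time = np.minimum(death, drop)
    event = death <= drop
    return SurvivalDataset(recruit=recruit, is_exp=is_exp, time=time,
                           event=event, dropout=~event)


def _apply_arm_caps(is_exp: np.ndarray, max_n: int):
    """Sequential cap handling: a subject whose assigned arm is full is
    allocated to the open arm; once both arms are full, later subjects
    are not enrolled.  Returns (effective_arm, enrollable)."""
    eff = is_exp.copy()
    ok = np.ones(len(is_exp), dtype=bool)
    cum_e = np.cumsum(eff)
    cum_c = np.cumsum(~eff)
    full = np.flatnonzero((cum_e >= max_n) | (cum_c >= max_n))
    if full.size == 0:
        return eff, ok
    start = full[0]
    n_e = int(cum_e[start - 1]) if start > 0 else 0
    n_c = start - n_e
    for i in range(start, len(eff)):
        want_e = eff[i]
        if want_e and n_e < max_n:
            n_e += 1
        elif not want_e and n_c < max_n:
            n_c += 1
        elif n_e < max_n:
            eff[i] = True
            n_e += 1
        elif n_c < max_n:
            eff[i] = False
            n_c += 1
        else:
            ok[i] = False
    return eff, ok


def _replay_enrolment(is_exp: np.ndarray, max_n: int):
    """Replay-mode enrolment: recorded arm allocations are immutable, so
    recruitment closes outright at the first subject whose recorded arm
    is already full (the trial has reached maximum sample size in that
    arm)."""
    cum_e = np.cumsum(is_exp)
    cum_c = np.cumsum(~is_exp)
    viol = (is_exp & (cum_e > max_n)) | (~is_exp & (cum_c > max_n))
    ok = np.ones(len(is_exp), dtype=bool)
    hits = np.flatnonzero(viol)
    if hits.size:
        ok[hits[0]:] = False
    return is_exp.copy(), ok


def run_adaptive_trial(design: TrialDesign, dataset: SurvivalDataset,
                       continuation: Continuation | None = None,
                       rng: np.random.Generator | None = None,
                       trace: bool = False,
                       replay_arms: bool = False) -> TrialResult:
    """Run one adaptive trial over the dataset (simulation and replay
    use the same semantics).

    With ``replay_arms=False`` (simulation) the randomisation respects
    the per-arm cap: a subject whose assigned arm is full joins the open
    arm, so recruitment continues until both arms are full.  With
    ``replay_arms=True`` recorded allocations are kept as they were and
    recruitment closes when either recorded arm would exceed its cap.

    ``rng`` is required for the ppbs method (its decision probability is
    a Monte-Carlo estimate); the other methods are deterministic given
    the dataset.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    continuation = continuation or Continuation()
    if design.method == "ppbs" and rng is None:
        raise ValueError("method 'ppbs' requires a seeded random generator")

    ds = dataset.sorted_by_recruit()
    if replay_arms:
        eff_exp, ok = _replay_enrolment(ds.is_exp, design.max_n_per_arm)
    else:
        eff_exp, ok = _apply_arm_caps(ds.is_exp, design.max_n_per_arm)
    # trial start (the interim-grid origin) is the first randomisation
    recruit = ds.recruit[ok] - ds.recruit[0]
    ftime = ds.time[ok]
    event = ds.event[ok]
    is_exp = eff_exp[ok]
    cum_e = np.concatenate(([0], np.cumsum(is_exp)))

    dt = design.interim_interval_months
    need_score = design.method in _SCORE_METHODS
    rows = [] if trace else None
    k = 0
    while True:
        k += 1
        t = k * dt
        idx = int(np.searchsorted(recruit, t, side="right"))
        n_e = int(cum_e[idx])
        n_c = idx - n_e
        since = t - recruit[:idx]
        arm = is_exp[:idx]
        resolved = ftime[:idx] <= since
        died = event[:idx] & resolved
        d_e = int(np.count_nonzero(died & arm))
        d_c = int(np.count_nonzero(died)) - d_e
        gate_f = d_e >= design.k_F and d_c >= design.k_F
        gate_s = d_e >= design.k_S and d_c >= design.k_S
        probs: DecisionProbs | None = None
        action = ""
        if gate_f or gate_s:
            age = np.minimum(ftime[:idx], since)
            T_e = float(age[arm].sum())
            T_c = float(age.sum()) - T_e
            active = ~resolved
            summ_e = ArmSummary(n_e, d_e, T_e)
            summ_c = ArmSummary(n_c, d_c, T_c)
            if need_score:
                score, theta, info = cox_score_fit(age, died, arm)
                dmean, dvar = _log_hazard_ratio_posterior(
                    summ_e, summ_c, continuation.prior)
            else:
                score, theta, info = ScoreStat(0.0, 0.0), 0.0, 0.0
                dmean = dvar = 0.0
            snap = InterimSnapshot(
                time=t,
                summary_E=summ_e,
                summary_C=summ_c,
                at_risk_E=int(np.count_nonzero(active & arm)),
                at_risk_C=int(np.count_nonzero(active)) -
                int(np.count_nonzero(active & arm)),
                score=score, theta=theta, info=info,
                drift_mean=dmean, drift_var=dvar)
            probs = evaluate_decision(design.method, snap, design,
                                      continuation, rng)
            success_hit = gate_s and probs.success > design.d_U
            futility_hit = gate_f and probs.futility < design.d_L
            if success_hit:
                action = "stop-success" + ("+futility" if futility_hit else "")
            elif futility_hit:
                action = "stop-futility"
        else:
            success_hit = futility_hit = False
        if rows is not None:
            rows.append({
                "time": t, "n_E": n_e, "n_C": n_c, "d_E": d_e, "d_C": d_c,
                "p_futility": probs.futility if probs else np.nan,
                "p_success": probs.success if probs else np.nan,
                "gate_F": gate_f, "gate_S": gate_s, "action": action,
            })
        if success_hit or futility_hit:
            conclusion = "success" if success_hit else "futility"
            break
        if t >= continuation.max_duration:
            conclusion = "inconclusive"
            break
    return TrialResult(
        conclusion=conclusion, stop_time=t, n_total=idx, n_E=n_e, n_C=n_c,
        d_E=d_e, d_C=d_c,
        trace=pd.DataFrame(rows) if rows is not None else None)


def run_fixed_trial(dataset: SurvivalDataset,
                    design: FixedDesign | None = None,
                    max_duration: float | None = None) -> TrialResult:
    """Run the fixed-design benchmark on a dataset.

    Recruitment closes at the first interim boundary after ``n_total``
    participants have been recruited; the single analysis happens at the
    calendar time of the ``required_events``-th death.  Success requires
    the two-sided Cox-model p-value below ``alpha`` *and* the
    experimental-favouring sign -- the same success definition the
    adaptive designs project forward to; otherwise the conclusion is
    futility.  If the event target is never reached within the data,
    the analysis falls back to the last observed calendar time
    (flagged).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    design = design or FixedDesign()
    ds = dataset.sorted_by_recruit()
    dt = design.interim_interval_months
    recruit0 = ds.recruit - ds.recruit[0]  # trial start = first randomisation
    if len(ds) >= design.n_total:
        t_close = math.ceil(recruit0[design.n_total - 1] / dt) * dt
    else:
        t_close = math.inf
    m = recruit0 <= t_close
    recruit = recruit0[m]
    ftime = ds.time[m]
    event = ds.event[m]
    is_exp = ds.is_exp[m]

    death_cal = np.sort(recruit[event] + ftime[event])
    flagged = death_cal.size < design.required_events
    if not flagged:
        # the analysis is performed at the first scheduled look at or
        # after the target event count is reached
        t_final = math.ceil(death_cal[design.required_events - 1] / dt) * dt
    else:
        t_final = float(np.max(recruit + ftime))
    if max_duration is not None and t_final > max_duration:
        t_final = max_duration
        flagged = True

    since = t_final - recruit
    on_study = recruit <= t_final
    age = np.minimum(ftime, since)[on_study]
    died = (event & (ftime <= since))[on_study]
    arm = is_exp[on_study]
    score, theta, info = cox_score_fit(age, died, arm)
    if info > 0:
        z = theta * math.sqrt(info)
        success = bool(z < 0 and 2.0 * _ndtr(-abs(z)) < design.alpha)
    else:
        success = False
    d_e = int(np.count_nonzero(died & arm))
    return TrialResult(
        conclusion="success" if success else "futility",
        stop_time=t_final, n_total=int(np.count_nonzero(on_study)),
        n_E=int(arm.sum()), n_C=int(np.count_nonzero(~arm)),
        d_E=d_e, d_C=int(np.count_nonzero(died)) - d_e,
        events_flagged_short=flagged)
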