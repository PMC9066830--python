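"""Virtual re-execution and bootstrap re-execution.

Virtual re-execution replays a recorded (or fixture) trial dataset
through a design's decision rules: recruitment times, arm allocations
and outcomes stay exactly as recorded, and each interim uses only the
data that would have been known at the time.  Bootstrap re-execution
estimates how *reproducible* such a result is: recruitment times are
kept, arms are re-randomised, and each subject's outcome is resampled
with replacement from the observed outcomes of their newly assigned
arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import TrialDesign, FixedDesign
from .decision_methods import Continuation
from .survival_core import SurvivalDataset, cox_hazard_ratio
from .trial_engine import TrialResult, run_adaptive_trial, run_fixed_trial

__all__ = [
    "BootstrapSpec",
    "BootstrapResult",
    "observed_accrual_rate",
    "continuation_from_dataset",
    "reexecute",
    "bootstrap_dataset",
    "bootstrap_reexecution",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Replication settings for bootstrap re-execution.  The accrual
    extension rate (subjects/month) is used when a replay exhausts the
    original roster; None means the observed average rate."""

    n_replicates: int
    seed: int
    extension_rate: float | None = None

    def __post_init__(self):
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100")


@dataclass
class BootstrapResult:
    """Aggregate of a bootstrap re-execution: conclusion probabilities
    (percent, partitioning to 100), sample-size and duration moments,
    and the median/IQR of the per-replicate illustrative hazard
    ratios (None when hazard ratios were not computed)."""

    n_replicates: int
    p_success: float
    p_futility: float
    p_inconclusive: float
    mean_n: float
    sd_n: float
    mean_duration: float
    sd_duration: float
    hr_median: float | None = None
    hr_iqr: tuple[float, float] | None = None


def observed_accrual_rate(dataset: SurvivalDataset) -> float:
    """Average recruitment rate of the recorded trial, subjects/month."""
    span = float(np.max(dataset.recruit))
    if span <= 0:
        raise ValueError("degenerate recruitment window")
    return len(dataset) / span


def continuation_from_dataset(dataset: SurvivalDataset,
                              **overrides) -> Continuation:
    """Continuation assumptions for replay: observed accrual rate plus
    the package defaults for dropout/horizon unless overridden."""
    kw = {"accrual_rate": observed_accrual_rate(dataset)}
    kw.update(overrides)
    return Continuation(**kw)


def reexecute(design: TrialDesign | FixedDesign, dataset: SurvivalDataset,
              continuation: Continuation | None = None,
              rng: np.random.Generator | None = None,
              trace: bool = False, compute_hr: bool = True,
              replay_arms: bool = True) -> TrialResult:
    """Replay a design over a fixed dataset.

    No outcome data are generated: the engine consumes the dataset in
    recruitment order, so the result is deterministic (ppbs: given the
    seed).  Recorded arm allocations are kept as recorded by default
    (``replay_arms``); bootstrap replicates, whose arms are freshly
    re-randomised, run with cap-respecting randomisation instead.  A
    dataset too small to ever satisfy a gate simply runs to the
    inconclusive horizon.
    """
    if isinstance(design, FixedDesign):
        res = run_fixed_trial(dataset, design)
    else:
        if continuation is None:
            continuation = continuation_from_dataset(dataset)
        res = run_adaptive_trial(design, dataset, continuation, rng=rng,
                                 trace=trace, replay_arms=replay_arms)
    if compute_hr:
        res.hr, res.hr_ci = cox_hazard_ratio(dataset, res.stop_time)
    return res


def bootstrap_dataset(original: SurvivalDataset, rng: np.random.Generator,
                      extension_rate: float | None = None,
                      min_total: int | None = None) -> SurvivalDataset:
    """One bootstrap replicate of a recorded trial.

    Recruitment times are copied exactly; every subject is independently
    re-randomised 1:1; their (time, event) outcome pair is drawn
    uniformly with replacement from the *original* outcomes of the newly
    assigned arm (censored outcomes stay censored).  If ``min_total``
    exceeds the roster, extra recruitment times extend the Poisson
    process at ``extension_rate`` (default: the observed average rate)
    and take resampled outcomes the same way.
    """
    n0 = len(original)
    pools = {}
    for label, mask in (("E", original.is_exp), ("C", ~original.is_exp)):
        if not mask.any():
            raise ValueError(f"original dataset has no subjects in arm "
                             f"{label}")
        pools[label] = (original.time[mask], original.event[mask])
    recruit = np.sort(original.recruit)
    if min_total is not None and min_total > n0:
        rate = extension_rate or observed_accrual_rate(original)
        gaps = rng.exponential(1.0 / rate, min_total - n0)
        extra = float(recruit[-1]) + np.cumsum(gaps)
        recruit = np.concatenate([recruit, extra])
    n = len(recruit)
    is_exp = rng.random(n) < 0.5
    time = np.empty(n)
    event = np.empty(n, dtype=bool)
    for label, mask in (("E", is_exp), ("C", ~is_exp)):
        pool_t, pool_e = pools[label]
        k = int(mask.sum())
        pick = rng.integers(0, len(pool_t), k)
        time[mask] = pool_t[pick]
        event[mask] = pool_e[pick]
    return SurvivalDataset(recruit=recruit, is_exp=is_exp, time=time,
                           event=event)


def bootstrap_reexecution(design: TrialDesign | FixedDesign,
                          original: SurvivalDataset, spec: BootstrapSpec,
                          continuation: Continuation | None = None,
                          compute_hr: bool = False) -> BootstrapResult:
    """Replay a design over bootstrap replicates of a recorded trial and
    aggregate the resulting operating characteristics."""
    if continuation is None and not isinstance(design, FixedDesign):
        continuation = continuation_from_dataset(original)
    min_total = (design.n_total + 20 if isinstance(design, FixedDesign)
                 else 2 * design.max_n_per_arm + 20)
    rng = np.random.default_rng(spec.seed)
    concl, n_tot, dur, hrs = [], [], [], []
    for child in rng.spawn(spec.n_replicates):
        ds = bootstrap_dataset(original, child,
                               extension_rate=spec.extension_rate,
                               min_total=min_total)
        res = reexecute(design, ds, continuation, rng=child,
                        compute_hr=compute_hr, replay_arms=False)
        concl.append(res.conclusion)
        n_tot.append(res.n_total)
        dur.append(res.stop_time)
        if compute_hr and res.hr is not None:
            hrs.append(res.hr)
    concl = np.asarray(concl, dtype=object)
    n_tot = np.asarray(n_tot, dtype=float)
    dur = np.asarray(dur, dtype=float)
    m = spec.n_replicates
    p_s = 100.0 * np.count_nonzero(concl == "success") / m
    p_f = 100.0 * np.count_nonzero(concl == "futility") / m
    hr_median = hr_iqr = None
    if hrs:
        q25, q50, q75 = np.percentile(hrs, [25, 50, 75])
        hr_median, hr_iqr = float(q50), (float(q25), float(q75))
    return BootstrapResult(
        n_replicates=m, p_success=p_s, p_futility=p_f,
        p_inconclusive=100.0 - p_s - p_f,
        mean_n=float(n_tot.mean()), sd_n=float(n_tot.std(ddof=1)),
        mean_duration=float(dur.mean()), sd_duration=float(dur.std(ddof=1)),
        hr_median=hr_median, hr_iqr=hr_iqr)
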