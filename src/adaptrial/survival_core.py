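"""Survival-data containers and the statistics every decision method uses.

The central object is :class:`SurvivalDataset`: patient-level recruitment
times, arm labels, and follow-up outcomes.  All interim machinery works on
*snapshots* of a dataset at a calendar analysis time: a subject recruited
by then contributes exposure ``min(followup_time, analysis_time -
recruit_time)`` and counts as an event only if the death had occurred by
the analysis time (events exactly at the analysis time are included).

On top of snapshots this module provides

* per-arm sufficient statistics ``(n, d, T)`` for the exponential model
  (:func:`summarize_arm`),
* the two-sample logrank score ``U`` and information ``V``
  (:func:`logrank_score`), with the sign convention that ``U < 0``
  (fewer experimental-arm deaths than expected) favours the experimental
  arm,
* the conjugate posterior probability that the experimental arm has the
  larger mean survival under exponential survival with an inverse-gamma
  prior on each arm mean (:func:`posterior_prob_experimental_better`),
* an illustrative unadjusted Cox hazard-ratio estimate
  (:func:`cox_hazard_ratio`), and
* the classical event-count and sample-size formulae used to size the
  fixed-design benchmark (:func:`freedman_required_events`,
  :func:`kim_tsiatis_sample_size`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc, ndtr

from .designs import ScenarioConfig

__all__ = [
    "CONTROL",
    "EXPERIMENTAL",
    "SurvivalDataset",
    "ArmSummary",
    "ScoreStat",
    "ExpInvGammaPrior",
    "summarize_arm",
    "logrank_score",
    "cox_hazard_ratio",
    "posterior_prob_experimental_better",
    "freedman_required_events",
    "kim_tsiatis_sample_size",
    "expected_events",
    "uniform_accrual_death_prob",
]

CONTROL = "C"
EXPERIMENTAL = "E"

_CSV_COLUMNS = ["subject_id", "recruit_time_months", "arm", "time_months", "event"]


@dataclass
class SurvivalDataset:
    """Patient-level two-arm survival data.

    Attributes
    ----------
    recruit : ndarray of float
        Recruitment time in months from trial start (>= 0).
    is_exp : ndarray of bool
        True for the experimental arm, False for control.
    time : ndarray of float
        Observed follow-up time in months from recruitment (> 0).
    event : ndarray of bool
        True if the follow-up ended in death, False if censored.
    dropout : ndarray of bool, optional
        For censored records, True if the censoring was loss to follow-up
        rather than administrative truncation.  Informational only.
    """

    recruit: np.ndarray
    is_exp: np.ndarray
    time: np.ndarray
    event: np.ndarray
    dropout: np.ndarray | None = None

    def __post_init__(self):
        self.recruit = np.asarray(self.recruit, dtype=float)
        self.is_exp = np.asarray(self.is_exp, dtype=bool)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.dropout is not None:
            self.dropout = np.asarray(self.dropout, dtype=bool)
        self.validate()

    def validate(self):
        n = len(self.recruit)
        for name in ("is_exp", "time", "event"):
            if len(getattr(self, name)) != n:
                raise ValueError("all columns must have equal length")
        if n and (not np.all(np.isfinite(self.recruit)) or np.any(self.recruit < 0)):
            raise ValueError("recruit times must be finite and >= 0")
        if n and np.any(self.time <= 0):
            raise ValueError("follow-up times must be > 0")

    def __len__(self):
        return len(self.recruit)

    @property
    def arm_labels(self) -> np.ndarray:
        return np.where(self.is_exp, EXPERIMENTAL, CONTROL)

    def sorted_by_recruit(self) -> "SurvivalDataset":
        """Return a copy ordered by recruitment time (stable)."""
        order = np.argsort(self.recruit, kind="stable")
        return SurvivalDataset(
            self.recruit[order], self.is_exp[order], self.time[order],
            self.event[order],
            None if self.dropout is None else self.dropout[order])

    # -- patient-level CSV schema -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": np.arange(1, len(self) + 1),
            "recruit_time_months": self.recruit,
            "arm": self.arm_labels,
            "time_months": self.time,
            "event": self.event.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        arm = df["arm"].astype(str).to_numpy()
        bad = set(np.unique(arm)) - {CONTROL, EXPERIMENTAL}
        if bad:
            raise ValueError(f"unknown arm labels {sorted(bad)}; expected "
                             f"{CONTROL!r} or {EXPERIMENTAL!r}")
        return cls(
            recruit=df["recruit_time_months"].to_numpy(float),
            is_exp=arm == EXPERIMENTAL,
            time=df["time_months"].to_numpy(float),
            event=df["event"].to_numpy(int).astype(bool),
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SurvivalDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient statistics of one arm at an analysis time: recruited
    count ``n``, observed deaths ``d``, and total exposure ``T`` (months
    at risk)."""

    n: int
    d: int
    T: float


@dataclass(frozen=True)
class ScoreStat:
    """Logrank score ``U`` (observed minus expected experimental-arm
    deaths; negative favours experimental) and its hypergeometric
    variance ``V`` (the statistical information)."""

    U: float
    V: float

    @property
    def z(self) -> float | None:
        """Standardised statistic ``U / sqrt(V)``; None when V = 0."""
        if self.V <= 0:
            return None
        return self.U / math.sqrt(self.V)

    @property
    def p_two_sided(self) -> float | None:
        """Two-sided normal p-value; None (undefined) when V = 0."""
        z = self.z
        if z is None:
            return None
        return 2.0 * ndtr(-abs(z))


@dataclass(frozen=True)
class ExpInvGammaPrior:
    """Conjugate prior for exponential survival: the arm mean survival
    has an InverseGamma(shape, scale) prior, equivalently the hazard has
    a Gamma(shape, rate=scale) prior, applied identically to both arms.
    The default (0.01, 0.01) is weakly informative: its weight is
    negligible against the >= 10 events present at any gated decision."""

    shape: float = 0.01
    scale: float = 0.01

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("prior shape and scale must be positive")


# ---------------------------------------------------------------------
# snapshot statistics
# ---------------------------------------------------------------------

def snapshot_arrays(dataset: SurvivalDataset, analysis_time: float):
    """Internal: (age, died, is_exp) for subjects recruited by
    ``analysis_time``, with administrative truncation applied."""
    if analysis_time < 0:
        raise ValueError("analysis_time must be >= 0")
    m = dataset.recruit <= analysis_time
    since = analysis_time - dataset.recruit[m]
    age = np.minimum(dataset.time[m], since)
    died = dataset.event[m] & (dataset.time[m] <= since)
    return age, died, dataset.is_exp[m]


def summarize_arm(dataset: SurvivalDataset, arm: str,
                  analysis_time: float) -> ArmSummary:
    """Per-arm sufficient statistics at an analysis time.

    Only subjects recruited by ``analysis_time`` are counted; each
    contributes exposure ``min(followup_time, analysis_time - recruit)``
    and an event only if the death had occurred by then.
    """
    if arm not in (CONTROL, EXPERIMENTAL):
        raise ValueError(f"unknown arm label {arm!r}")
    age, died, is_exp = snapshot_arrays(dataset, analysis_time)
    pick = is_exp if arm == EXPERIMENTAL else ~is_exp
    return ArmSummary(n=int(pick.sum()), d=int(died[pick].sum()),
                      T=float(age[pick].sum()))


def _risk_tables(age: np.ndarray, died: np.ndarray, is_exp: np.ndarray):
    """Distinct event times with per-time death counts and at-risk
    counts per arm."""
    ev_t = age[died]
    ev_e = is_exp[died].astype(float)
    order = np.argsort(ev_t, kind="stable")
    ev_t = ev_t[order]
    ev_e = ev_e[order]
    uniq, start = np.unique(ev_t, return_index=True)
    d_tot = np.diff(np.append(start, len(ev_t))).astype(float)
    d_exp = np.add.reduceat(ev_e, start)
    a_exp = np.sort(age[is_exp])
    a_ctl = np.sort(age[~is_exp])
    n_exp = (a_exp.size - np.searchsorted(a_exp, uniq, side="left")).astype(float)
    n_ctl = (a_ctl.size - np.searchsorted(a_ctl, uniq, side="left")).astype(float)
    return d_tot, d_exp, n_exp, n_ctl


def logrank_from_arrays(age: np.ndarray, died: np.ndarray,
                        is_exp: np.ndarray) -> ScoreStat:
    """Two-sample logrank O-E and variance over distinct event times.

    ``age`` is the follow-up consumed at the analysis snapshot, ``died``
    flags deaths observed by then.  Ties are handled by the standard
    hypergeometric treatment on the pooled risk set.
    """
    if not died.any():
        return ScoreStat(0.0, 0.0)
    d_tot, d_exp, n_exp, n_ctl = _risk_tables(age, died, is_exp)
    n_tot = n_exp + n_ctl
    frac = n_exp / n_tot
    U = float(np.sum(d_exp - d_tot * frac))
    denom = np.maximum(n_tot - 1.0, 1.0)
    V = float(np.sum(d_tot * frac * (n_ctl / n_tot)
                     * (n_tot - d_tot) / denom))
    return ScoreStat(U, V)


_BETA_BOUND = 8.0


def cox_score_fit(age: np.ndarray, died: np.ndarray, is_exp: np.ndarray
                  ) -> tuple[ScoreStat, float, float]:
    """Logrank score statistic plus the two-group Cox partial-likelihood
    MLE and its observed information.

    Returns ``(score, beta, info)`` where ``beta`` is the Breslow
    partial-likelihood estimate of the log hazard ratio (experimental vs
    control; negative favours experimental) and ``info`` the observed
    information at ``beta`` -- the quantities behind the Cox model's
    Wald test.  When either arm has no events the MLE diverges; ``beta``
    is then clamped to +/-8 (such snapshots are gated out of decisions).
    """
    if not died.any():
        return ScoreStat(0.0, 0.0), 0.0, 0.0
    d_tot, d_exp, n_exp, n_ctl = _risk_tables(age, died, is_exp)
    n_tot = n_exp + n_ctl
    frac = n_exp / n_tot
    U = float(np.sum(d_exp - d_tot * frac))
    denom = np.maximum(n_tot - 1.0, 1.0)
    V = float(np.sum(d_tot * frac * (n_ctl / n_tot)
                     * (n_tot - d_tot) / denom))
    score = ScoreStat(U, V)
    beta = 0.0
    info = 0.0
    for _ in range(40):
        w = n_exp * math.exp(beta)
        p = w / (w + n_ctl)
        grad = float(np.sum(d_exp - d_tot * p))
        info = float(np.sum(d_tot * p * (1.0 - p)))
        if info <= 1e-12:
            break
        step = grad / info
        beta += min(max(step, -1.5), 1.5)
        if abs(beta) > _BETA_BOUND:
            beta = math.copysign(_BETA_BOUND, beta)
            w = n_exp * math.exp(beta)
            p = w / (w + n_ctl)
            info = float(np.sum(d_tot * p * (1.0 - p)))
            break
        if abs(step) < 1e-9:
            break
    return score, beta, info


def logrank_score(dataset: SurvivalDataset, analysis_time: float) -> ScoreStat:
    """Logrank score statistic of the snapshot at ``analysis_time``.

    Returns ``ScoreStat(0, 0)`` (p undefined) when no events have been
    observed, rather than raising.
    """
    age, died, is_exp = snapshot_arrays(dataset, analysis_time)
    return logrank_from_arrays(age, died, is_exp)


def cox_hazard_ratio(dataset: SurvivalDataset, analysis_time: float = math.inf):
    """Unadjusted Cox proportional-hazards estimate for the arm indicator.

    Reporting only -- never used by any stopping rule.  Returns
    ``(hr, (lo, hi))`` with a 95% Wald interval, or ``(None, None)``
    when either arm has no events (flagged by a warning).
    """
    from lifelines import CoxPHFitter

    age, died, is_exp = snapshot_arrays(dataset, analysis_time)
    if died[is_exp].sum() == 0 or died[~is_exp].sum() == 0:
        warnings.warn("hazard ratio unavailable: an arm has no events")
        return None, None
    df = pd.DataFrame({"T": age, "E": died.astype(int),
                       "arm": is_exp.astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E",
            fit_options={"precision": 1e-10})
    hr = float(np.exp(cph.params_["arm"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["arm"]).to_numpy()
    return hr, (float(lo), float(hi))


def posterior_prob_experimental_better(summ_E: ArmSummary, summ_C: ArmSummary,
                                       prior: ExpInvGammaPrior | None = None
                                       ) -> float:
    """P(mean survival in E exceeds mean survival in C | data).

    Under exponential survival with the conjugate prior, the arm hazard
    has posterior Gamma(shape + d, rate = scale + T); the mean is better
    in E exactly when its hazard is smaller, and for independent gammas
    P(lambda_E < lambda_C) is a regularised incomplete beta function.
    """
    prior = prior or ExpInvGammaPrior()
    return _posterior_prob_raw(summ_E.d, summ_E.T, summ_C.d, summ_C.T, prior)


def _posterior_prob_raw(d_E, T_E, d_C, T_C, prior: ExpInvGammaPrior):
    a_E = prior.shape + d_E
    a_C = prior.shape + d_C
    b_E = prior.scale + T_E
    b_C = prior.scale + T_C
    if np.any(np.asarray(b_E) <= 0) or np.any(np.asarray(b_C) <= 0):
        raise ValueError("non-positive posterior rate parameter")
    return betainc(a_E, a_C, b_E / (b_E + b_C))


# ---------------------------------------------------------------------
# classical design formulae
# ---------------------------------------------------------------------

def _z(p):
    from scipy.stats import norm
    return float(norm.ppf(p))


def freedman_required_events(hr: float, alpha: float = 0.05,
                             power: float = 0.80) -> int:
    """Freedman's required death count for a two-sided logrank test.

    ``d = ceil[(z_{1-alpha/2} + z_power)^2 ((1+hr)/(1-hr))^2]`` for a
    hazard ratio ``hr < 1`` favouring the experimental arm.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if not 0 < hr < 1:
        raise ValueError("hazard ratio must lie in (0, 1); hr = 1 needs "
                         "infinitely many events")
    z = _z(1 - alpha / 2) + _z(power)
    return int(math.ceil(z * z * ((1 + hr) / (1 - hr)) ** 2))


def uniform_accrual_death_prob(lam: float, eta: float,
                               accrual_duration: float,
                               horizon: float) -> float:
    """P(death observed by calendar ``horizon``) for a subject recruited
    uniformly over ``[0, accrual_duration]``, with exponential death
    hazard ``lam`` and exponential dropout hazard ``eta``.

    Subjects whose recruitment falls after the horizon contribute zero.
    """
    if horizon <= 0 or lam <= 0:
        return 0.0
    x = lam + eta
    if accrual_duration <= 0:
        return lam / x * -math.expm1(-x * horizon)
    A = min(accrual_duration, horizon)
    xA = x * A
    if xA < 1e-12:
        mean_exp = math.exp(-x * (horizon - A / 2))
    else:
        mean_exp = math.exp(-x * horizon) * math.expm1(xA) / xA
    frac = A / accrual_duration
    return frac * lam / x * (1.0 - mean_exp)


def expected_events(n_total: int, scenario: ScenarioConfig,
                    analysis_time: float,
                    accrual_duration: float | None = None) -> float:
    """Expected number of deaths observed by ``analysis_time`` when
    ``n_total`` subjects accrue at a uniform rate (1:1 allocation) under
    the scenario's exponential survival and dropout."""
    A = n_total / scenario.accrual_rate if accrual_duration is None \
        else accrual_duration
    p_C = uniform_accrual_death_prob(scenario.hazard_C, scenario.dropout_rate,
                                     A, analysis_time)
    p_E = uniform_accrual_death_prob(scenario.hazard_E, scenario.dropout_rate,
                                     A, analysis_time)
    return n_total / 2.0 * (p_C + p_E)


def kim_tsiatis_sample_size(scenario: ScenarioConfig, alpha: float = 0.05,
                            power: float = 0.80,
                            max_duration: float | None = None,
                            min_followup: float | None = None
                            ) -> tuple[int, int]:
    """Accrual/follow-up sample size for the fixed-design benchmark.

    The required death count comes from :func:`freedman_required_events`
    at the scenario's hazard ratio.  The returned ``n_total`` is the
    smallest even total such that the *expected* number of deaths at the
    planned final analysis reaches that count, where the final analysis
    is scheduled at the end of accrual (duration ``n/accrual_rate``)
    plus ``min_followup`` months of additional follow-up, capped at
    ``max_duration``.  By default ``min_followup`` equals the
    anticipated experimental-arm median survival and ``max_duration``
    the scenario horizon.

    Raises
    ------
    ValueError
        If the event target cannot be reached within the horizon at any
        achievable sample size.
    """
    if scenario.median_E <= scenario.median_C:
        raise ValueError("expected experimental median > control median")
    hr = scenario.median_C / scenario.median_E
    d_req = freedman_required_events(hr, alpha=alpha, power=power)
    horizon = scenario.max_duration if max_duration is None else max_duration
    F = scenario.median_E if min_followup is None else min_followup
    # no point recruiting subjects who cannot arrive within the horizon
    n_cap = max(2, 2 * int(scenario.accrual_rate * horizon / 2) + 2) \
        if math.isfinite(horizon) else 10 ** 7
    n = 2
    while n <= n_cap:
        A = n / scenario.accrual_rate
        tau = min(A + F, horizon)
        if expected_events(n, scenario, tau) >= d_req:
            return n, d_req
        n += 2
    raise ValueError(
        f"required events ({d_req}) unreachable within the "
        f"{horizon}-month horizon at any sample size")
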