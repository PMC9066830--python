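"""The five interim decision probabilities.

Each method maps an interim snapshot of the trial to a probability that
is compared against the design's decision thresholds ``d_L`` (futility)
and ``d_U`` (success):

``posterior``
    Posterior probability that the experimental arm's mean survival
    exceeds the control arm's, under the exponential/inverse-gamma
    conjugate model.
``pps``
    Predictive probability of success: probability that the final
    analysis (at maximum sample size, after the follow-up horizon) will
    show a two-sided logrank p-value below ``d_alpha`` in favour of the
    experimental arm, integrating over the posterior of the treatment
    effect.
``cps``
    Conditional probability of success: as ``pps`` but with the drift of
    the score process fixed at its posterior median instead of
    integrated over.
``goldilocks``
    A pair of predictive probabilities: futility is judged with
    recruitment assumed to continue to the maximum sample size, success
    with recruitment assumed closed at the current sample size.
``ppbs``
    Predictive probability of *Bayesian* success: Monte-Carlo
    probability that the final posterior probability of benefit exceeds
    the Bayesian success threshold ``d_S``.

The frequentist predictive forms (pps/cps) use the standard Brownian
approximation of the Cox score process.  At an interim, ``theta_hat``
is the Cox partial-likelihood estimate of the log hazard ratio and
``I_n`` its observed information; final-analysis success means the Cox
Wald statistic ``theta_hat_final * sqrt(I_max)`` exceeding the
two-sided critical value of ``d_alpha`` in the experimental-favouring
direction.  Future information accrues at roughly one quarter per
additional death (equal allocation), so the projected final information
is ``I_max = I_n + (D_max - D_n) / 4``.  The future score increment
over the remaining information ``dI = I_max - I_n`` is normal with
drift integrated against the conjugate exponential model's posterior of
the log hazard ratio (exact log-gamma moments): mean
``drift_mean * dI`` and variance ``dI + dI^2 * drift_var`` -- the same
posterior the ppbs method simulates completions from, so the predictive
forms and their forward-simulation oracle agree.  A forward-simulation
oracle in the test-suite checks these closed forms on seeded snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import digamma, ndtr, polygamma
from scipy.stats import norm

from .designs import TrialDesign, DEFAULT_DROPOUT_RATE
from .survival_core import (ArmSummary, ExpInvGammaPrior, ScoreStat,
                            SurvivalDataset, _posterior_prob_raw,
                            snapshot_arrays, cox_score_fit,
                            uniform_accrual_death_prob,
                            posterior_prob_experimental_better)

__all__ = [
    "Continuation",
    "InterimSnapshot",
    "HorizonProjection",
    "DecisionProbs",
    "take_snapshot",
    "project_final_information",
    "pps_frequentist",
    "cps_median",
    "goldilocks_probs",
    "ppbs",
    "evaluate_decision",
]


@dataclass(frozen=True)
class Continuation:
    """Design-time assumptions about how the trial would continue after
    an interim: accrual rate of *future* subjects (pooled over arms),
    dropout hazard, the calendar horizon of the final analysis, the
    conjugate prior used for projections, and the Monte-Carlo draw count
    for the ppbs method."""

    accrual_rate: float = 4.5
    dropout_rate: float = DEFAULT_DROPOUT_RATE
    max_duration: float = 120.0
    prior: ExpInvGammaPrior = field(default_factory=ExpInvGammaPrior)
    n_draws: int = 500

    def __post_init__(self):
        if self.accrual_rate < 0 or self.dropout_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be positive")


@dataclass(frozen=True)
class InterimSnapshot:
    """Everything the decision methods need about the trial at one
    interim: per-arm sufficient statistics, subjects still under active
    follow-up, and the logrank score statistic."""

    time: float
    summary_E: ArmSummary
    summary_C: ArmSummary
    at_risk_E: int
    at_risk_C: int
    score: ScoreStat
    #: Cox partial-likelihood log-hazard-ratio estimate and its observed
    #: information (the Wald-test quantities); 0/0 when no events
    theta: float = 0.0
    info: float = 0.0
    #: posterior mean and variance of the log hazard ratio under the
    #: conjugate exponential model (exact log-gamma moments); the future
    #: score drift is integrated against this posterior
    drift_mean: float = 0.0
    drift_var: float = 0.0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("analysis time must be >= 0")

    @property
    def events(self) -> int:
        return self.summary_E.d + self.summary_C.d

    @property
    def U(self) -> float:
        return self.score.U

    @property
    def V(self) -> float:
        return self.score.V


@dataclass(frozen=True)
class HorizonProjection:
    """Projected final event count ``D_max`` and final statistical
    information ``V_max`` (current observed information plus one quarter
    per projected additional death, under equal allocation) at the
    continuation horizon."""

    D_max: float
    V_max: float
    recruitment_open: bool


def take_snapshot(dataset: SurvivalDataset, analysis_time: float,
                  prior: ExpInvGammaPrior | None = None
                  ) -> InterimSnapshot:
    """Interim snapshot of a dataset at a calendar analysis time."""
    age, died, is_exp = snapshot_arrays(dataset, analysis_time)
    m = dataset.recruit <= analysis_time
    # still under active follow-up: the recorded outcome (death or
    # dropout) has not yet been reached by the analysis time
    active = dataset.time[m] > (analysis_time - dataset.recruit[m])
    return snapshot_from_parts(analysis_time, age, died, is_exp, active,
                               prior=prior)


def _log_hazard_ratio_posterior(summ_E: ArmSummary, summ_C: ArmSummary,
                                prior: ExpInvGammaPrior):
    """Exact mean and variance of log(lambda_E / lambda_C) under the
    independent gamma posteriors of the conjugate exponential model."""
    a_E, a_C = prior.shape + summ_E.d, prior.shape + summ_C.d
    mean = (float(digamma(a_E)) - math.log(prior.scale + summ_E.T)
            - float(digamma(a_C)) + math.log(prior.scale + summ_C.T))
    var = float(polygamma(1, a_E)) + float(polygamma(1, a_C))
    return mean, var


def snapshot_from_parts(analysis_time, age, died, is_exp, active,
                        prior: ExpInvGammaPrior | None = None
                        ) -> InterimSnapshot:
    """Internal constructor from snapshot arrays (see
    :func:`adaptrial.survival_core.snapshot_arrays`)."""
    prior = prior or ExpInvGammaPrior()
    summ_E = ArmSummary(n=int(is_exp.sum()), d=int(died[is_exp].sum()),
                        T=float(age[is_exp].sum()))
    summ_C = ArmSummary(n=int((~is_exp).sum()), d=int(died[~is_exp].sum()),
                        T=float(age[~is_exp].sum()))
    score, theta, info = cox_score_fit(age, died, is_exp)
    dmean, dvar = _log_hazard_ratio_posterior(summ_E, summ_C, prior)
    return InterimSnapshot(time=analysis_time, summary_E=summ_E,
                           summary_C=summ_C,
                           at_risk_E=int(active[is_exp].sum()),
                           at_risk_C=int(active[~is_exp].sum()),
                           score=score, theta=theta, info=info,
                           drift_mean=dmean, drift_var=dvar)


# ---------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------

def _posterior_mean_hazards(snap: InterimSnapshot, prior: ExpInvGammaPrior):
    lam_E = (snap.summary_E.d + prior.shape) / (snap.summary_E.T + prior.scale)
    lam_C = (snap.summary_C.d + prior.shape) / (snap.summary_C.T + prior.scale)
    return lam_E, lam_C


def project_final_information(snapshot: InterimSnapshot, design: TrialDesign,
                              continuation: Continuation,
                              recruitment_open: bool = True
                              ) -> HorizonProjection:
    """Expected final death count and information at the continuation
    horizon.

    Per-arm hazards are estimated by their posterior means (so zero-event
    arms are well defined); subjects under follow-up contribute their
    remaining death probability by memorylessness, and -- when
    recruitment is open -- future subjects accrue at half the pooled
    rate per arm up to the per-arm cap, each followed to the horizon.
    """
    prior = continuation.prior
    lam_E, lam_C = _posterior_mean_hazards(snapshot, prior)
    eta = continuation.dropout_rate
    h = max(continuation.max_duration - snapshot.time, 0.0)
    D = float(snapshot.events)
    for lam, summ, at_risk in ((lam_E, snapshot.summary_E, snapshot.at_risk_E),
                               (lam_C, snapshot.summary_C, snapshot.at_risk_C)):
        if h > 0 and at_risk > 0:
            D += at_risk * uniform_accrual_death_prob(lam, eta, 0.0, h)
        if recruitment_open and h > 0:
            m = max(design.max_n_per_arm - summ.n, 0)
            if m > 0 and continuation.accrual_rate > 0:
                arm_rate = continuation.accrual_rate / 2.0
                A = m / arm_rate
                A_eff = min(A, h)
                m_eff = m * A_eff / A
                D += m_eff * uniform_accrual_death_prob(lam, eta, A_eff, h)
    D = max(D, float(snapshot.events))
    # future information accrues at ~1/4 per death (equal allocation);
    # anchoring at the observed information makes the projection
    # degenerate exactly onto the current Wald statistic when nothing
    # is left to observe
    I_n = snapshot.info if snapshot.info > 0 else snapshot.events / 4.0
    V_max = I_n + (D - snapshot.events) / 4.0
    return HorizonProjection(D_max=D, V_max=V_max,
                             recruitment_open=recruitment_open)


# ---------------------------------------------------------------------
# frequentist predictive probabilities
# ---------------------------------------------------------------------

def _critical_value(d_alpha: float) -> float:
    if not 0 < d_alpha < 1:
        raise ValueError("d_alpha must lie in (0, 1)")
    return float(norm.ppf(1 - d_alpha / 2))


def _drift_and_information(snapshot: InterimSnapshot):
    """Cox-model log-hazard-ratio estimate and observed information of
    a snapshot; (None, 0) when no events have been observed.  Falls back
    to the score-based estimate U/V with information D/4 for snapshots
    built without a Cox fit."""
    if snapshot.info > 0:
        return snapshot.theta, snapshot.info
    if snapshot.V <= 0 or snapshot.events == 0:
        return None, 0.0
    return snapshot.U / snapshot.V, snapshot.events / 4.0


def _predictive_success(snapshot: InterimSnapshot,
                        projection: HorizonProjection, d_alpha: float,
                        drift_uncertainty: bool) -> float:
    z_crit = _critical_value(d_alpha)
    theta, I_n = _drift_and_information(snapshot)
    if theta is None:
        # no events: the drift is unidentified (gated out in practice)
        return 0.5
    I_max = max(projection.V_max, I_n)
    dI = I_max - I_n
    if dI <= 1e-9:
        return 1.0 if theta * math.sqrt(I_n) <= -z_crit else 0.0
    # current score state theta * I_n plus a future increment whose
    # drift is integrated against the conjugate-model posterior of the
    # log hazard ratio
    mean = theta * I_n + snapshot.drift_mean * dI
    var = dI + (dI * dI * snapshot.drift_var if drift_uncertainty else 0.0)
    return float(ndtr((-z_crit * math.sqrt(I_max) - mean) / math.sqrt(var)))


def pps_frequentist(snapshot: InterimSnapshot,
                    projection: HorizonProjection,
                    d_alpha: float) -> float:
    """Predictive probability that the final Cox-scale test is
    significant in favour of the experimental arm.

    Integrates over the flat-prior normal posterior of the score-process
    drift.  With no events yet the drift is unidentified and 0.5 is
    returned (such snapshots are gated out by ``k_F``/``k_S`` in any
    practical design).
    """
    return _predictive_success(snapshot, projection, d_alpha,
                               drift_uncertainty=True)


def cps_median(snapshot: InterimSnapshot, projection: HorizonProjection,
               d_alpha: float) -> float:
    """Conditional probability of final success at the posterior-median
    drift (``theta_hat = U_n / V_n`` under the flat-prior normal
    posterior); ignores drift uncertainty."""
    return _predictive_success(snapshot, projection, d_alpha,
                               drift_uncertainty=False)


class DecisionProbs(NamedTuple):
    """Probabilities compared against d_L (futility) and d_U (success)."""

    futility: float
    success: float


def goldilocks_probs(snapshot: InterimSnapshot, design: TrialDesign,
                     continuation: Continuation) -> DecisionProbs:
    """The dual predictive probabilities of the Goldilocks rule:
    futility assumes recruitment continues to the maximum sample size,
    success assumes recruitment closes at the current sample size."""
    proj_open = project_final_information(snapshot, design, continuation,
                                          recruitment_open=True)
    proj_closed = project_final_information(snapshot, design, continuation,
                                            recruitment_open=False)
    return DecisionProbs(
        futility=pps_frequentist(snapshot, proj_open, design.d_alpha),
        success=pps_frequentist(snapshot, proj_closed, design.d_alpha))


# ---------------------------------------------------------------------
# predictive probability of Bayesian success (nested Monte Carlo)
# ---------------------------------------------------------------------

def _simulate_completion_counts(snapshot: InterimSnapshot,
                                design: TrialDesign,
                                continuation: Continuation,
                                rates_E: np.ndarray, rates_C: np.ndarray,
                                rng: np.random.Generator,
                                recruitment_open: bool = True):
    """Final per-arm (d, T) for each draw, completing the trial from the
    snapshot to the continuation horizon with per-draw hazards.

    Future accrual uses the deterministic uniform-rate arrival grid at
    half the pooled accrual rate per arm; death and dropout are
    exponential.  Returns arrays (d_E, T_E, d_C, T_C) of shape
    (n_draws,).
    """
    n_draws = rates_E.shape[0]
    eta = continuation.dropout_rate
    h = max(continuation.max_duration - snapshot.time, 0.0)
    out = []
    for rates, summ, at_risk in ((rates_E, snapshot.summary_E, snapshot.at_risk_E),
                                 (rates_C, snapshot.summary_C, snapshot.at_risk_C)):
        d_fin = np.full(n_draws, float(summ.d))
        T_fin = np.full(n_draws, float(summ.T))
        horizons = []
        if h > 0 and at_risk > 0:
            horizons.append(np.full(at_risk, h))
        if recruitment_open and h > 0 and continuation.accrual_rate > 0:
            m = max(design.max_n_per_arm - summ.n, 0)
            if m > 0:
                arm_rate = continuation.accrual_rate / 2.0
                arrive = (np.arange(1, m + 1) - 0.5) / arm_rate
                rem = h - arrive
                horizons.append(rem[rem > 0])
        if horizons:
            hz = np.concatenate(horizons)[None, :]
            death = rng.standard_exponential((n_draws, hz.shape[1])) \
                / rates[:, None]
            if eta > 0:
                drop = rng.standard_exponential((n_draws, hz.shape[1])) / eta
            else:
                drop = np.inf
            exposure = np.minimum(np.minimum(death, drop), hz)
            died = death <= np.minimum(drop, hz)
            d_fin += died.sum(axis=1)
            T_fin += exposure.sum(axis=1)
        out.extend((d_fin, T_fin))
    return out[0], out[1], out[2], out[3]


def ppbs(snapshot: InterimSnapshot, design: TrialDesign,
         continuation: Continuation, n_draws: int | None = None,
         rng: np.random.Generator | None = None,
         recruitment_open: bool = False) -> float:
    """Monte-Carlo predictive probability that the *final* posterior
    probability of benefit exceeds the Bayesian success threshold d_S.

    Each draw samples the arm hazards from their current conjugate
    posteriors, completes the follow-up of the subjects on study to the
    continuation horizon (with dropout), and evaluates the closed-form
    final posterior probability.  By default the completion assumes
    recruitment is closed at the current sample size; pass
    ``recruitment_open=True`` to also accrue future subjects up to the
    per-arm cap.  Reproducible given the generator.
    """
    if design.d_S is None:
        raise ValueError("ppbs requires a design with d_S")
    n_draws = continuation.n_draws if n_draws is None else n_draws
    if n_draws < 100:
        raise ValueError("n_draws < 100 gives an unstable estimate")
    if rng is None:
        raise ValueError("ppbs requires a seeded random generator")
    prior = continuation.prior
    h = max(continuation.max_duration - snapshot.time, 0.0)
    open_slots = recruitment_open and (
        design.max_n_per_arm - snapshot.summary_E.n > 0
        or design.max_n_per_arm - snapshot.summary_C.n > 0)
    nothing_left = (h <= 0
                    or (snapshot.at_risk_E == 0 and snapshot.at_risk_C == 0
                        and not open_slots))
    if nothing_left:
        p = posterior_prob_experimental_better(
            snapshot.summary_E, snapshot.summary_C, prior)
        return float(p > design.d_S)
    rates_E = rng.gamma(prior.shape + snapshot.summary_E.d, size=n_draws) \
        / (prior.scale + snapshot.summary_E.T)
    rates_C = rng.gamma(prior.shape + snapshot.summary_C.d, size=n_draws) \
        / (prior.scale + snapshot.summary_C.T)
    d_E, T_E, d_C, T_C = _simulate_completion_counts(
        snapshot, design, continuation, rates_E, rates_C, rng,
        recruitment_open=recruitment_open)
    p_fin = _posterior_prob_raw(d_E, T_E, d_C, T_C, prior)
    return float(np.mean(p_fin > design.d_S))


# ---------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------

def evaluate_decision(method: str, snapshot: InterimSnapshot,
                      design: TrialDesign, continuation: Continuation,
                      rng: np.random.Generator | None = None
                      ) -> DecisionProbs:
    """Route a snapshot to the decision method and return the pair of
    probabilities compared against (d_L, d_U).  For every method except
    goldilocks the two entries are the same number."""
    if method == "posterior":
        p = float(posterior_prob_experimental_better(
            snapshot.summary_E, snapshot.summary_C, continuation.prior))
        return DecisionProbs(p, p)
    if method in ("pps", "cps"):
        proj = project_final_information(snapshot, design, continuation,
                                         recruitment_open=True)
        fn = pps_frequentist if method == "pps" else cps_median
        p = fn(snapshot, proj, design.d_alpha)
        return DecisionProbs(p, p)
    if method == "goldilocks":
        return goldilocks_probs(snapshot, design, continuation)
    if method == "ppbs":
        p = ppbs(snapshot, design, continuation, rng=rng)
        return DecisionProbs(p, p)
    raise ValueError(f"unknown decision method {method!r}")
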