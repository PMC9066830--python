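"""Trial design and scenario configuration objects.

A :class:`TrialDesign` bundles an interim decision method with its event
gates (``k_F``, ``k_S``), decision thresholds (``d_L``, ``d_U``) and any
method-specific threshold (``d_alpha`` for p-value-based success,
``d_S`` for Bayesian success).  A :class:`ScenarioConfig` describes the
data-generating truth used in simulation: exponential median survival per
arm, Poisson accrual rate, and exponential loss-to-follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "METHODS",
    "DAYS_PER_MONTH",
    "DEFAULT_DROPOUT_RATE",
    "annual_dropout_prob_to_rate",
    "TrialDesign",
    "FixedDesign",
    "ScenarioConfig",
    "SHORTLISTED_DESIGNS",
    "shortlisted_design",
]

#: Interim decision methods understood by the engine.
METHODS = ("posterior", "pps", "cps", "goldilocks", "ppbs")

#: Mean Gregorian month length, used to convert the 28-day interim grid
#: to months (the unit used everywhere else).
DAYS_PER_MONTH = 30.4375


def annual_dropout_prob_to_rate(p: float) -> float:
    """Monthly exponential dropout rate giving annual dropout probability ``p``."""
    if not 0 <= p < 1:
        raise ValueError("annual dropout probability must be in [0, 1)")
    return -math.log1p(-p) / 12.0


#: "1% chance of loss to follow-up per year" as a monthly exponential rate.
DEFAULT_DROPOUT_RATE = annual_dropout_prob_to_rate(0.01)

# Which threshold fields each method requires beyond (d_L, d_U).
_REQUIRED_EXTRAS = {
    "posterior": (),
    "pps": ("d_alpha",),
    "cps": ("d_alpha",),
    "goldilocks": ("d_alpha",),
    "ppbs": ("d_S",),
}


@dataclass(frozen=True)
class TrialDesign:
    """One adaptive design: a decision method plus its gates and thresholds.

    Parameters
    ----------
    method
        One of ``"posterior"``, ``"pps"``, ``"cps"``, ``"goldilocks"``,
        ``"ppbs"``.
    k_F, k_S
        Minimum number of events required *in each arm* before a futility
        (resp. success) stop is allowed.
    d_L, d_U
        Lower/upper decision thresholds for the interim probability.
    d_alpha
        Two-sided significance level defining final-analysis success for
        the p-value-based methods (pps/cps/goldilocks).
    d_S
        Bayesian success threshold on the final posterior probability
        (ppbs only).
    max_n_per_arm
        Recruitment cap per arm; recruitment closes once either arm
        reaches it (evaluated at interim boundaries).
    interim_interval_days
        Spacing of the interim-analysis grid, in days.
    """

    method: str
    k_F: int
    k_S: int
    d_L: float
    d_U: float
    d_alpha: float | None = None
    d_S: float | None = None
    max_n_per_arm: int = 117
    interim_interval_days: float = 28.0
    name: str | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown decision method {self.method!r}; "
                             f"expected one of {METHODS}")
        if not (self.k_F >= 1 and self.k_S >= 1):
            raise ValueError("event gates k_F and k_S must be >= 1")
        if not (0.0 < self.d_L < self.d_U < 1.0):
            raise ValueError("thresholds must satisfy 0 < d_L < d_U < 1")
        required = _REQUIRED_EXTRAS[self.method]
        for key in ("d_alpha", "d_S"):
            val = getattr(self, key)
            if key in required:
                if val is None:
                    raise ValueError(f"method {self.method!r} requires {key}")
                if not 0.0 < val < 1.0:
                    raise ValueError(f"{key} must lie in (0, 1)")
            elif val is not None:
                raise ValueError(f"{key} is not a parameter of method "
                                 f"{self.method!r}")
        if self.max_n_per_arm < 1:
            raise ValueError("max_n_per_arm must be >= 1")
        if self.interim_interval_days <= 0:
            raise ValueError("interim_interval_days must be > 0")

    @property
    def interim_interval_months(self) -> float:
        return self.interim_interval_days / DAYS_PER_MONTH

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    def replace(self, **kw) -> "TrialDesign":
        return replace(self, **kw)


@dataclass(frozen=True)
class FixedDesign:
    """The non-adaptive benchmark: recruit ``n_total`` participants, analyse
    once at the calendar time of the ``required_events``-th death using a
    two-sided logrank test at level ``alpha`` (success requires the
    experimental-favouring sign)."""

    n_total: int = 234
    required_events: int = 197
    alpha: float = 0.05
    interim_interval_days: float = 28.0
    name: str | None = "fixed"

    def __post_init__(self):
        if self.n_total < 2 or self.required_events < 1:
            raise ValueError("n_total >= 2 and required_events >= 1 required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def interim_interval_months(self) -> float:
        return self.interim_interval_days / DAYS_PER_MONTH


@dataclass(frozen=True)
class ScenarioConfig:
    """Data-generating truth for simulated trials.

    Survival in each arm is exponential with the given median (months);
    recruitment is a Poisson process at ``accrual_rate`` subjects/month
    with 1:1 randomisation; loss to follow-up is exponential at
    ``dropout_rate`` per month (default: 1%/year).  ``max_duration`` is
    the trial horizon in months at which an undecided trial is declared
    inconclusive.
    """

    median_C: float
    median_E: float
    accrual_rate: float = 4.5
    dropout_rate: float = DEFAULT_DROPOUT_RATE
    max_duration: float = 120.0
    name: str | None = None

    def __post_init__(self):
        if self.median_C <= 0 or self.median_E <= 0:
            raise ValueError("arm medians must be positive")
        if self.accrual_rate <= 0:
            raise ValueError("accrual_rate must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be positive")

    @property
    def hazard_C(self) -> float:
        return math.log(2.0) / self.median_C

    @property
    def hazard_E(self) -> float:
        return math.log(2.0) / self.median_E

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


def _d(method, k_F, k_S, d_L, d_U, d_alpha=None, d_S=None, name=None):
    return TrialDesign(method=method, k_F=k_F, k_S=k_S, d_L=d_L, d_U=d_U,
                       d_alpha=d_alpha, d_S=d_S, name=name)


#: The ten shortlisted designs of the metastatic breast cancer case study,
#: keyed by (method, strategy) with strategy "small" (prioritising low
#: average sample size) or "high" (prioritising high power).
SHORTLISTED_DESIGNS: dict[tuple[str, str], TrialDesign] = {
    ("posterior", "small"): _d("posterior", 20, 50, 0.2, 0.993, name="posterior-small"),
    ("pps", "small"): _d("pps", 10, 10, 0.025, 0.99, d_alpha=0.04, name="pps-small"),
    ("cps", "small"): _d("cps", 30, 40, 0.01, 0.999, d_alpha=0.05, name="cps-small"),
    ("goldilocks", "small"): _d("goldilocks", 10, 20, 0.025, 0.975, d_alpha=0.04,
                                name="goldilocks-small"),
    ("ppbs", "small"): _d("ppbs", 30, 50, 0.01, 0.975, d_S=0.98, name="ppbs-small"),
    ("posterior", "high"): _d("posterior", 30, 50, 0.05, 0.993, name="posterior-high"),
    ("pps", "high"): _d("pps", 50, 10, 0.01, 0.9995, d_alpha=0.05, name="pps-high"),
    ("cps", "high"): _d("cps", 50, 50, 0.01, 0.9995, d_alpha=0.05, name="cps-high"),
    ("goldilocks", "high"): _d("goldilocks", 50, 50, 0.01, 0.995, d_alpha=0.05,
                               name="goldilocks-high"),
    ("ppbs", "high"): _d("ppbs", 50, 50, 0.005, 0.9995, d_S=0.975, name="ppbs-high"),
}


def shortlisted_design(method: str, strategy: str) -> TrialDesign:
    """Look up one of the ten case-study shortlisted designs."""
    try:
        return SHORTLISTED_DESIGNS[(method, strategy)]
    except KeyError:
        raise KeyError(f"no shortlisted design for method={method!r}, "
                       f"strategy={strategy!r}") from None
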