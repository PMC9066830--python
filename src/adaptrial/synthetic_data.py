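"""Synthetic fixture datasets.

The real patient-level data of the motivating case study (a metastatic
breast cancer trial of 235 participants) are restricted, so
:func:`generate_anz_like` emulates a dataset with the same reported
marginals: 235 participants accrued over ~53 months (about 4.6/month),
exponential survival with medians 16.5 (control) and 14.5 months
(experimental), ~1.7% loss to follow-up, and a long administrative
horizon so nearly all deaths are observed.  It is plumbing realism for
replay and bootstrap machinery, not a reconstruction of any real
patient.
"""

from __future__ import annotations

import math

import numpy as np

from .designs import ScenarioConfig
from .survival_core import SurvivalDataset
from .trial_engine import assign_arms, simulate_dataset

__all__ = ["generate_anz_like", "generate_scenario_batch"]


def generate_anz_like(rng: np.random.Generator, n: int = 235,
                      accrual_months: float = 53.0,
                      median_control: float = 16.5,
                      median_experimental: float = 14.5,
                      ltfu_fraction: float = 0.017,
                      admin_horizon: float = 231.0) -> SurvivalDataset:
    """Synthetic case-study-like dataset (see module docstring).

    Recruitment is a Poisson process conditioned on ``n`` arrivals in
    the accrual window (i.e. sorted uniforms); allocation is 1:1; deaths
    are exponential at ``ln 2 / median`` per arm; a random
    ``ltfu_fraction`` of subjects are instead censored at a uniform
    fraction of their death time; any follow-up extending past
    ``admin_horizon`` months from trial start is administratively
    truncated there.
    """
    if min(n, accrual_months, median_control, median_experimental) <= 0:
        raise ValueError("parameters must be positive")
    recruit = np.sort(rng.uniform(0.0, accrual_months, n))
    is_exp = assign_arms(n, rng)
    mean_time = np.where(is_exp, median_experimental / math.log(2.0),
                         median_control / math.log(2.0))
    death = rng.standard_exponential(n) * mean_time
    time = death.copy()
    event = np.ones(n, dtype=bool)
    lost = rng.random(n) < ltfu_fraction
    time[lost] = death[lost] * rng.uniform(0.0, 1.0, int(lost.sum()))
    event[lost] = False
    admin = admin_horizon - recruit
    over = time > admin
    time[over] = admin[over]
    event[over] = False
    return SurvivalDataset(recruit=recruit, is_exp=is_exp, time=time,
                           event=event, dropout=lost & ~over)


def generate_scenario_batch(scenario: ScenarioConfig, n_trials: int,
                            rng: np.random.Generator,
                            n_max_total: int = 274):
    """Yield ``n_trials`` independent scenario datasets, deterministic
    and stably ordered under a fixed seed."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for child in rng.spawn(n_trials):
        yield simulate_dataset(scenario, n_max_total, child)
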