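"""Interim decision probabilities: closed forms, degenerate limits, and
forward-simulation oracles."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import adaptrial as at
from adaptrial import (ArmSummary, Continuation, ScoreStat, TrialDesign,
                       evaluate_decision, goldilocks_probs, ppbs,
                       pps_frequentist, cps_median, project_final_information,
                       take_snapshot)
from adaptrial.decision_methods import InterimSnapshot
from adaptrial.survival_core import cox_score_fit, snapshot_arrays

CONT = Continuation()
PPS_DESIGN = at.shortlisted_design("pps", "small")
TARGET = at.ScenarioConfig(10.0, 15.0)


def make_snapshot(time, d_E, T_E, d_C, T_C, at_risk_E, at_risk_C,
                  U=None, V=None):
    """Hand-constructed snapshot with score/drift quantities derived
    from the given sufficient statistics (score optional)."""
    from adaptrial.decision_methods import _log_hazard_ratio_posterior
    summ_E = ArmSummary(at_risk_E + d_E, d_E, T_E)
    summ_C = ArmSummary(at_risk_C + d_C, d_C, T_C)
    if U is None:
        theta, info = 0.0, (d_E + d_C) / 4.0
        U, V = 0.0, (d_E + d_C) / 4.0
    else:
        theta, info = U / V, (d_E + d_C) / 4.0
    dm, dv = _log_hazard_ratio_posterior(summ_E, summ_C, CONT.prior)
    return InterimSnapshot(time=time, summary_E=summ_E, summary_C=summ_C,
                           at_risk_E=at_risk_E, at_risk_C=at_risk_C,
                           score=ScoreStat(U, V), theta=theta, info=info,
                           drift_mean=dm, drift_var=dv)


def forward_completion_oracle(ds, t, design, cont, n_sims, rng, mode="pps",
                              recruitment_open=True):
    """Brute-force predictive-probability oracle: draw hazards (from the
    conjugate posteriors for pps; fixed at the posterior-median effect
    for cps), simulate the completion of the trial subject by subject,
    and test the final Cox-scale statistic."""
    age, died, is_exp = snapshot_arrays(ds, t)
    m = ds.recruit <= t
    active = ds.time[m] > (t - ds.recruit[m])
    h = cont.max_duration - t
    a, b = cont.prior.shape, cont.prior.scale
    d_E, d_C = int(died[is_exp].sum()), int(died[~is_exp].sum())
    T_E, T_C = float(age[is_exp].sum()), float(age[~is_exp].sum())
    snap = take_snapshot(ds, t)
    z_crit = norm.ppf(1 - design.d_alpha / 2)
    succ = 0
    for _ in range(n_sims):
        if mode == "pps":
            lam_E = rng.gamma(a + d_E) / (b + T_E)
            lam_C = rng.gamma(a + d_C) / (b + T_C)
        else:
            lam_C = (a + d_C) / (b + T_C)
            lam_E = lam_C * math.exp(snap.drift_mean)
        lam = np.where(is_exp, lam_E, lam_C)
        extra_d = rng.exponential(1 / lam[active])
        extra_c = rng.exponential(1 / cont.dropout_rate, int(active.sum()))
        age2 = age.copy()
        died2 = died.copy()
        arm2 = is_exp.copy()
        age2[active] += np.minimum(np.minimum(extra_d, extra_c), h)
        died2[active] = extra_d <= np.minimum(extra_c, h)
        parts_a, parts_d, parts_m = [age2], [died2], [arm2]
        if recruitment_open:
            for lab, lam_v, n_now in ((True, lam_E, int(is_exp.sum())),
                                      (False, lam_C, int((~is_exp).sum()))):
                free = design.max_n_per_arm - n_now
                if free <= 0:
                    continue
                arrive = t + np.cumsum(
                    rng.exponential(2 / cont.accrual_rate, free))
                arrive = arrive[arrive < cont.max_duration]
                hh = cont.max_duration - arrive
                dd = rng.exponential(1 / lam_v, len(arrive))
                cc = rng.exponential(1 / cont.dropout_rate, len(arrive))
                parts_a.append(np.minimum(np.minimum(dd, cc), hh))
                parts_d.append(dd <= np.minimum(cc, hh))
                parts_m.append(np.full(len(arrive), lab))
        age3 = np.concatenate(parts_a)
        died3 = np.concatenate(parts_d)
        arm3 = np.concatenate(parts_m)
        _, theta, info = cox_score_fit(age3, died3, arm3)
        succ += bool(info > 0 and theta * math.sqrt(info) < -z_crit)
    return succ / n_sims


def _se(p, n):
    # Agresti-style adjusted SE so extreme estimates keep a finite band
    q = (p * n + 2) / (n + 4)
    return math.sqrt(q * (1 - q) / n)


class TestProjection:
    def test_all_resolved_degenerates_to_current(self):
        snap = make_snapshot(119.8, 40, 500.0, 50, 450.0, 0, 0)
        proj = project_final_information(snap, PPS_DESIGN, CONT,
                                         recruitment_open=False)
        assert proj.D_max == snap.events
        assert proj.V_max == pytest.approx(snap.info)

    def test_full_arms_make_open_equal_closed(self):
        snap = make_snapshot(60.0, 80, 1500.0, 90, 1300.0, 37, 27)
        proj_o = project_final_information(snap, PPS_DESIGN, CONT, True)
        proj_c = project_final_information(snap, PPS_DESIGN, CONT, False)
        # n already at 117/arm: no accrual possible either way
        assert proj_o.D_max == pytest.approx(proj_c.D_max)
        assert proj_o.V_max == pytest.approx(proj_c.V_max)

    def test_matches_forward_simulated_event_count(self):
        ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(12))
        t = 30.0
        snap = take_snapshot(ds, t)
        proj = project_final_information(snap, PPS_DESIGN, CONT, True)
        # forward-simulate the same continuation with hazards fixed at
        # their posterior means and count deaths at the horizon
        a, b = CONT.prior.shape, CONT.prior.scale
        lam_E = (a + snap.summary_E.d) / (b + snap.summary_E.T)
        lam_C = (a + snap.summary_C.d) / (b + snap.summary_C.T)
        rng = np.random.default_rng(13)
        h = CONT.max_duration - t
        tot = []
        for _ in range(3000):
            D = snap.events
            for lam, at_risk, n_now in ((lam_E, snap.at_risk_E,
                                         snap.summary_E.n),
                                        (lam_C, snap.at_risk_C,
                                         snap.summary_C.n)):
                d_t = rng.exponential(1 / lam, at_risk)
                c_t = rng.exponential(1 / CONT.dropout_rate, at_risk)
                D += int(np.sum(d_t <= np.minimum(c_t, h)))
                free = PPS_DESIGN.max_n_per_arm - n_now
                arrive = np.cumsum(
                    rng.exponential(2 / CONT.accrual_rate, free))
                hh = h - arrive[arrive < h]
                dn = rng.exponential(1 / lam, len(hh))
                cn = rng.exponential(1 / CONT.dropout_rate, len(hh))
                D += int(np.sum(dn <= np.minimum(cn, hh)))
            tot.append(D)
        mc = np.mean(tot)
        se = np.std(tot) / math.sqrt(len(tot))
        assert abs(proj.D_max - mc) < 3 * se + 0.5


class TestPredictiveClosedForms:
    def test_no_remaining_information_is_current_indicator(self):
        win = make_snapshot(100.0, 100, 900.0, 120, 700.0, 0, 0,
                            U=-25.0, V=50.0)
        lose = make_snapshot(100.0, 110, 800.0, 110, 800.0, 0, 0,
                             U=-1.0, V=50.0)
        for snap, expect in ((win, 1.0), (lose, 0.0)):
            proj = project_final_information(snap, PPS_DESIGN, CONT, False)
            assert pps_frequentist(snap, proj, 0.05) == expect
            assert cps_median(snap, proj, 0.05) == expect

    def test_no_events_returns_half(self):
        snap = make_snapshot(2.0, 0, 30.0, 0, 30.0, 15, 15)
        proj = project_final_information(snap, PPS_DESIGN, CONT, True)
        assert pps_frequentist(snap, proj, 0.05) == 0.5
        assert cps_median(snap, proj, 0.05) == 0.5

    def test_monotone_in_favourable_score(self):
        proj = None
        vals_pps, vals_cps = [], []
        for U in (5.0, 0.0, -5.0, -10.0, -15.0):
            snap = make_snapshot(30.0, 30, 400.0, 30, 400.0, 40, 40,
                                 U=U, V=15.0)
            proj = project_final_information(snap, PPS_DESIGN, CONT, True)
            vals_pps.append(pps_frequentist(snap, proj, 0.05))
            vals_cps.append(cps_median(snap, proj, 0.05))
        assert all(a <= b for a, b in zip(vals_pps, vals_pps[1:]))
        assert all(a <= b for a, b in zip(vals_cps, vals_cps[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals_pps + vals_cps)

    def test_cps_below_pps_at_null_drift(self):
        # with theta = 0 and little current information, ignoring drift
        # uncertainty makes success look less likely than integrating
        snap = make_snapshot(10.0, 6, 80.0, 6, 80.0, 40, 40, U=0.0, V=3.0)
        proj = project_final_information(snap, PPS_DESIGN, CONT, True)
        d_alpha = 0.05
        assert cps_median(snap, proj, d_alpha) < pps_frequentist(
            snap, proj, d_alpha)

    def test_invalid_d_alpha_raises(self):
        snap = make_snapshot(30.0, 20, 300.0, 20, 300.0, 40, 40,
                             U=-3.0, V=10.0)
        proj = project_final_information(snap, PPS_DESIGN, CONT, True)
        with pytest.raises(ValueError):
            pps_frequentist(snap, proj, 1.5)


@pytest.mark.parametrize("seed,t", [(1, 25.0), (2, 35.0), (3, 20.0),
                                    (4, 45.0), (5, 30.0)])
def test_pps_matches_forward_simulation_oracle(seed, t):
    """Closed-form predictive probability of success vs brute-force
    completion simulation from the conjugate posterior, on reachable
    seeded snapshots."""
    ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(seed))
    snap = take_snapshot(ds, t)
    proj = project_final_information(snap, PPS_DESIGN, CONT, True)
    cf = pps_frequentist(snap, proj, PPS_DESIGN.d_alpha)
    n = 1500
    oracle = forward_completion_oracle(ds, t, PPS_DESIGN, CONT, n,
                                       np.random.default_rng(1000 + seed))
    assert abs(cf - oracle) < 3 * _se(oracle, n)


@pytest.mark.parametrize("seed,t", [(1, 25.0), (2, 35.0), (3, 20.0),
                                    (4, 45.0), (5, 30.0)])
def test_cps_matches_conditional_simulation_oracle(seed, t):
    """Conditional power at the posterior-median effect vs forward
    simulation with the hazards fixed at that effect."""
    ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(seed))
    snap = take_snapshot(ds, t)
    proj = project_final_information(snap, PPS_DESIGN, CONT, True)
    cf = cps_median(snap, proj, PPS_DESIGN.d_alpha)
    n = 1500
    oracle = forward_completion_oracle(ds, t, PPS_DESIGN, CONT, n,
                                       np.random.default_rng(2000 + seed),
                                       mode="cps")
    assert abs(cf - oracle) < 3 * _se(oracle, n)


class TestGoldilocks:
    def test_closed_projection_never_larger(self):
        design = at.shortlisted_design("goldilocks", "small")
        ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(6))
        for t in (15.0, 25.0, 35.0, 50.0):
            snap = take_snapshot(ds, t)
            proj_o = project_final_information(snap, design, CONT, True)
            proj_c = project_final_information(snap, design, CONT, False)
            assert proj_c.V_max <= proj_o.V_max + 1e-9
            assert proj_c.D_max <= proj_o.D_max + 1e-9

    def test_pair_in_unit_interval(self):
        design = at.shortlisted_design("goldilocks", "small")
        ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(6))
        probs = goldilocks_probs(take_snapshot(ds, 30.0), design, CONT)
        assert 0.0 <= probs.futility <= 1.0
        assert 0.0 <= probs.success <= 1.0

    def test_success_component_matches_closed_recruitment_oracle(self):
        design = at.shortlisted_design("goldilocks", "small")
        ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(8))
        t = 30.0
        probs = goldilocks_probs(take_snapshot(ds, t), design, CONT)
        n = 1500
        oracle = forward_completion_oracle(
            ds, t, design, CONT, n, np.random.default_rng(3000),
            recruitment_open=False)
        assert abs(probs.success - oracle) < 3 * _se(oracle, n)


class TestPPBS:
    DESIGN = at.shortlisted_design("ppbs", "small")

    def test_completed_trial_is_indicator(self):
        late = Continuation(max_duration=50.0)
        strong = make_snapshot(60.0, 10, 2000.0, 60, 500.0, 0, 0)
        weak = make_snapshot(60.0, 40, 600.0, 40, 600.0, 0, 0)
        rng = np.random.default_rng(0)
        assert ppbs(strong, self.DESIGN, late, rng=rng) == 1.0
        assert ppbs(weak, self.DESIGN, late, rng=rng) == 0.0

    def test_overwhelming_evidence(self):
        snap = make_snapshot(30.0, 0, 5e4, 50, 300.0, 10, 10)
        p = ppbs(snap, self.DESIGN, CONT, n_draws=300,
                 rng=np.random.default_rng(1))
        assert p > 0.99

    def test_self_consistency_across_draw_counts(self):
        ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(9))
        snap = take_snapshot(ds, 30.0)
        p1 = ppbs(snap, self.DESIGN, CONT, n_draws=1000,
                  rng=np.random.default_rng(2))
        p2 = ppbs(snap, self.DESIGN, CONT, n_draws=10000,
                  rng=np.random.default_rng(3))
        assert abs(p1 - p2) < 3 * _se(p1, 1000)

    def test_too_few_draws_rejected(self):
        snap = make_snapshot(30.0, 20, 300.0, 20, 300.0, 10, 10)
        with pytest.raises(ValueError, match="n_draws"):
            ppbs(snap, self.DESIGN, CONT, n_draws=50,
                 rng=np.random.default_rng(0))

    def test_requires_generator(self):
        snap = make_snapshot(30.0, 20, 300.0, 20, 300.0, 10, 10)
        with pytest.raises(ValueError, match="generator"):
            ppbs(snap, self.DESIGN, CONT)


class TestEvaluateDecision:
    def test_posterior_symmetric_arms(self):
        design = at.shortlisted_design("posterior", "small")
        snap = make_snapshot(30.0, 20, 300.0, 20, 300.0, 10, 10)
        probs = evaluate_decision("posterior", snap, design, CONT)
        assert probs.futility == probs.success == pytest.approx(0.5)

    def test_pps_degenerate_delegation(self):
        snap = make_snapshot(119.9, 100, 900.0, 120, 700.0, 0, 0,
                             U=-25.0, V=50.0)
        probs = evaluate_decision("pps", snap, PPS_DESIGN,
                                  Continuation(max_duration=119.9))
        assert probs.success == 1.0

    def test_unknown_method_raises(self):
        snap = make_snapshot(30.0, 20, 300.0, 20, 300.0, 10, 10)
        with pytest.raises(ValueError, match="unknown"):
            evaluate_decision("bogus", snap, PPS_DESIGN, CONT)

    def test_all_methods_finite_probabilities_on_seeded_snapshot(self):
        ds = at.simulate_dataset(TARGET, 274, np.random.default_rng(14))
        snap = take_snapshot(ds, 35.0)
        rng = np.random.default_rng(15)
        for method, strategy in (("posterior", "small"), ("pps", "small"),
                                 ("cps", "small"), ("goldilocks", "small"),
                                 ("ppbs", "small")):
            design = at.shortlisted_design(method, strategy)
            probs = evaluate_decision(method, snap, design, CONT, rng)
            assert 0.0 <= probs.futility <= 1.0
            assert 0.0 <= probs.success <= 1.0
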