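"""Pseudo-IPD simulation, Kaplan-Meier artifacts, reconstruction, fitting."""

import math

import numpy as np
import pytest
from lifelines import LogLogisticFitter, WeibullFitter

from hcc_cea.ipd import (
    KMArtifact,
    PseudoIPD,
    fit_all_families,
    fit_family,
    km_estimate,
    pipeline,
    reconstruct_ipd,
    select_distribution,
    simulate_ipd,
)
from hcc_cea.params import SurvivalParams
from hcc_cea.survival import ParametricCurve

COMBO_OS = SurvivalParams(gamma=1.516, lam=0.008)
COMBO_PFS = SurvivalParams(gamma=1.916, lam=0.036)


def _sup_norm(a: KMArtifact, b: KMArtifact, t_max: float) -> float:
    grid = np.linspace(0.0, t_max, 721)
    return max(abs(a.survival_at(t) - b.survival_at(t)) for t in grid)


class TestSimulate:
    def test_same_seed_identical_dataset(self):
        a = simulate_ipd(COMBO_OS, 200, 36.0, seed=4)
        b = simulate_ipd(COMBO_OS, 200, 36.0, seed=4)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.event, b.event)

    def test_empirical_survival_matches_curve(self):
        ipd = simulate_ipd(COMBO_OS, 1000, 36.0, seed=11)
        emp = float(np.mean(ipd.time > 12.0))
        se = math.sqrt(0.743 * (1 - 0.743) / 1000)
        assert abs(emp - 0.743) < 3 * se

    def test_tiny_censor_time_censors_everyone(self):
        ipd = simulate_ipd(COMBO_OS, 50, 1e-6, seed=0)
        assert ipd.n_events == 0
        assert np.all(ipd.time == 1e-6)
        assert np.all(ipd.time > 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_ipd(COMBO_OS, 0, 36.0, seed=0)
        with pytest.raises(ValueError):
            simulate_ipd(COMBO_OS, 10, 0.0, seed=0)


class TestKMEstimate:
    def test_hand_computed_product_limit(self):
        # events at t=1 (3 at risk) and t=3 (1 at risk); censoring at t=2
        ipd = PseudoIPD(time=[1.0, 2.0, 3.0], event=[1, 0, 1])
        km = km_estimate(ipd, checkpoints=[0.0, 2.5])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.9) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)
        np.testing.assert_array_equal(km.n_risk, [3, 1])

    def test_no_events_gives_flat_curve_with_warning(self):
        ipd = PseudoIPD(time=[5.0, 6.0], event=[0, 0])
        with pytest.warns(UserWarning, match="censored"):
            km = km_estimate(ipd)
        assert km.survival_at(100.0) == 1.0

    def test_replicating_every_subject_leaves_curve_unchanged(self):
        ipd = simulate_ipd(COMBO_PFS, 150, 24.0, seed=3)
        doubled = PseudoIPD(
            time=np.concatenate([ipd.time, ipd.time]),
            event=np.concatenate([ipd.event, ipd.event]),
        )
        km1, km2 = km_estimate(ipd), km_estimate(doubled)
        assert _sup_norm(km1, km2, 24.0) < 1e-12
        np.testing.assert_array_equal(2 * km1.n_risk, km2.n_risk)

    def test_risk_table_counts_subjects_still_at_risk(self):
        ipd = simulate_ipd(COMBO_OS, 300, 36.0, seed=8)
        km = km_estimate(ipd, checkpoints=np.arange(0.0, 37.0, 6.0))
        for t, n in zip(km.checkpoints, km.n_risk):
            assert n == np.sum(ipd.time >= t)


class TestReconstruct:
    def test_round_trip_recovers_the_curve(self):
        ipd = simulate_ipd(COMBO_OS, 300, 36.0, seed=21)
        km = km_estimate(ipd)
        recon = reconstruct_ipd(km)
        assert recon.n == ipd.n
        assert _sup_norm(km, km_estimate(recon), 36.0) < 0.02

    def test_round_trip_with_interior_censoring(self):
        # non-administrative dropout inside intervals, the hard case
        rng = np.random.default_rng(17)
        base = simulate_ipd(COMBO_OS, 400, 60.0, seed=17)
        dropout = rng.exponential(40.0, size=base.n)
        time = np.minimum(base.time, dropout)
        event = base.event * (base.time <= dropout)
        ipd = PseudoIPD(time=time, event=event)
        km = km_estimate(ipd, checkpoints=np.arange(0.0, 61.0, 6.0))
        recon = reconstruct_ipd(km)
        assert _sup_norm(km, km_estimate(recon), 60.0) < 0.02

    def test_single_step_everyone_dies(self):
        km = KMArtifact(times=[1.0], survival=[0.0], checkpoints=[0.0],
                        n_risk=[40], n_total=40, max_time=1.0)
        recon = reconstruct_ipd(km)
        assert recon.n_events == 40
        assert np.all(recon.time[recon.event == 1] == 1.0)

    def test_flat_curve_reconstructs_all_censored(self):
        km = KMArtifact(times=[], survival=[], checkpoints=[0.0, 6.0, 12.0],
                        n_risk=[30, 20, 10], n_total=30, max_time=12.0)
        recon = reconstruct_ipd(km)
        assert recon.n_events == 0
        assert recon.n == 30

    def test_increasing_risk_counts_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            KMArtifact(times=[1.0], survival=[0.9], checkpoints=[0.0, 6.0],
                       n_risk=[30, 35], n_total=30, max_time=6.0)


@pytest.fixture(scope="module")
def big_loglogistic():
    # uncensored: administrative censoring far beyond every draw
    return simulate_ipd(COMBO_PFS, 5000, 1e6, seed=42)


class TestFitting:
    def test_loglogistic_recovery_within_5_percent(self, big_loglogistic):
        fit = fit_family(big_loglogistic, "loglogistic")
        assert fit.converged
        g, lam = fit.params
        assert g == pytest.approx(1.916, rel=0.05)
        assert lam == pytest.approx(0.036, rel=0.05)

    def test_agrees_with_lifelines_on_censored_data(self):
        ipd = simulate_ipd(COMBO_PFS, 2000, 12.0, seed=9)
        ours = fit_family(ipd, "loglogistic")
        llf = LogLogisticFitter().fit(ipd.time, ipd.event)
        # lifelines: S = 1/(1+(t/alpha)^beta) -> gamma = beta, lam = alpha^-beta
        assert ours.params[0] == pytest.approx(llf.beta_, rel=5e-3)
        assert ours.params[1] == pytest.approx(llf.alpha_**-llf.beta_, rel=2e-2)
        wf = WeibullFitter().fit(ipd.time, ipd.event)
        ours_w = fit_family(ipd, "weibull")
        assert ours_w.params[0] == pytest.approx(wf.rho_, rel=5e-3)
        assert ours_w.params[1] == pytest.approx(wf.lambda_**-wf.rho_, rel=2e-2)

    def test_exponential_closed_form_rate(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10.0, size=4000)
        ipd = PseudoIPD(time=t, event=np.ones_like(t, dtype=int))
        fit = fit_family(ipd, "exponential")
        assert fit.params[0] == pytest.approx(1.0 / t.mean(), rel=1e-12)

    def test_truth_outscores_perturbed_parameters(self, big_loglogistic):
        t_ev = big_loglogistic.time

        def loglik(g, lam):
            c = ParametricCurve("loglogistic", (g, lam))
            return float(np.sum(c.log_density(t_ev)))

        assert loglik(1.916, 0.036) > loglik(1.916 * 1.3, 0.036)
        assert loglik(1.916, 0.036) > loglik(1.916, 0.036 * 2.0)

    def test_requires_an_event(self):
        ipd = PseudoIPD(time=[1.0, 2.0], event=[0, 0])
        with pytest.raises(ValueError, match="event"):
            fit_family(ipd, "weibull")

    def test_unknown_family_rejected(self, big_loglogistic):
        with pytest.raises(ValueError, match="unknown family"):
            fit_family(big_loglogistic, "spline")


class TestSelection:
    def test_loglogistic_self_selects_at_large_n(self):
        ipd = simulate_ipd(COMBO_PFS, 5000, 1e6, seed=13)
        report = select_distribution(fit_all_families(ipd))
        assert report.selected == "loglogistic"
        table = report.table()
        assert table.iloc[0]["family"] == "loglogistic"
        assert table["aic"].is_monotonic_increasing

    def test_exponential_data_stays_in_exponential_weibull_class(self):
        rng = np.random.default_rng(31)
        t = rng.exponential(8.0, size=3000)
        ipd = PseudoIPD(time=t, event=np.ones_like(t, dtype=int))
        fits = fit_all_families(ipd)
        report = select_distribution(fits)
        # nesting: anything beating the true exponential does so by < 2 AIC
        assert report.fits[report.selected].aic <= fits["exponential"].aic
        assert fits["exponential"].aic - report.fits[report.selected].aic < 2.0
        if report.selected == "weibull":
            assert fits["weibull"].params[0] == pytest.approx(1.0, abs=0.05)

    def test_exact_tie_broken_by_family_order(self):
        fits = fit_all_families(simulate_ipd(COMBO_PFS, 300, 1e6, seed=2))
        a = fits["loglogistic"]
        b = fits["weibull"]
        b.loglik = a.loglik          # force an exact criterion tie
        b.__post_init__()
        report = select_distribution({"weibull": b, "loglogistic": a})
        assert report.selected == "loglogistic"

    def test_all_failed_fits_raise(self):
        bad = fit_all_families(simulate_ipd(COMBO_PFS, 200, 1e6, seed=1))
        for f in bad.values():
            f.converged = False
        with pytest.raises(ValueError, match="converged"):
            select_distribution(bad)

    def test_criterion_validated(self):
        with pytest.raises(ValueError):
            select_distribution({}, criterion="dic")


def test_pipeline_round_trip_smoke():
    res = pipeline(COMBO_PFS, 400, 24.0, seed=6)
    assert res["report"].selected in ("loglogistic", "gamma", "lognormal", "weibull")
    fit = res["fits"]["loglogistic"]
    truth_median = COMBO_PFS.median()
    fit_median = fit.params[1] ** (-1.0 / fit.params[0])
    assert fit_median == pytest.approx(truth_median, rel=0.15)
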