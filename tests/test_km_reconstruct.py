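"""Curve reconstruction, maximum likelihood and model selection."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from mesocea import (
    DigitizedKM,
    ParametricModel,
    PseudoIPD,
    fit_mle,
    information_criteria,
    reconstruct_ipd,
    sample,
    select_best,
    survival,
)
from mesocea.km import FamilyFit, FitReport
from mesocea.synth import digitize


def _report(entries):
    rep = FitReport(n=100)
    for fam, aic, bic, k in entries:
        rep.fits[fam] = FamilyFit(fam, None, 0.0, k, aic, bic, True)
    return rep


class TestInformationCriteria:
    def test_closed_forms(self):
        aic, bic = information_criteria(loglik=-100.0, k=2, n=100)
        assert aic == 204.0
        assert bic == pytest.approx(2 * np.log(100.0) + 200.0, abs=1e-10)  # 209.2103

    def test_extra_parameter_costs_exactly_two_aic(self):
        aic2, _ = information_criteria(-50.0, 2, 80)
        aic3, _ = information_criteria(-50.0, 3, 80)
        assert aic3 - aic2 == 2.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 0, 50)


class TestSelectBest:
    def test_single_family(self):
        assert select_best(_report([("weibull_aft", 120.0, 125.0, 2)])) == "weibull_aft"

    def test_published_style_aic_ordering(self):
        # 1413.186 (log-logistic) beats 1421.216 (gamma) for the intervention OS
        rep = _report([("gamma", 1421.216, 1428.022, 2), ("loglogistic", 1413.186, 1419.992, 2)])
        assert select_best(rep) == "loglogistic"

    def test_aic_tie_broken_by_bic(self):
        rep = _report([("gamma", 100.0, 12.0, 2), ("lognormal", 100.0, 10.0, 2)])
        assert select_best(rep) == "lognormal"

    def test_empty_report_raises(self):
        with pytest.raises(ValueError):
            select_best(FitReport(n=10))


class TestFitMLE:
    def test_exponential_closed_form_on_uncensored_data(self, rng):
        t = rng.exponential(10.0, size=200)
        model, ll = fit_mle(PseudoIPD(t, np.ones(200, int)), "exponential")
        assert model["rate"] == pytest.approx(200 / t.sum(), rel=1e-12)

    def test_loglogistic_recovery_within_ten_percent(self):
        truth = ParametricModel("loglogistic", {"shape": 2.347, "scale": 7.678})
        t = sample(truth, 500, seed=5)
        model, _ = fit_mle(PseudoIPD(t, np.ones(500, int)), "loglogistic")
        assert model["shape"] == pytest.approx(2.347, rel=0.10)
        assert model["scale"] == pytest.approx(7.678, rel=0.10)

    def test_fitted_loglik_at_least_truth_loglik(self):
        truth = ParametricModel("gamma", {"shape": 1.686, "rate": 0.0743})
        t = sample(truth, 300, seed=9)
        ipd = PseudoIPD(t, np.ones(300, int))
        _, ll_fit = fit_mle(ipd, "gamma")
        from mesocea.distributions import density

        ll_truth = np.log(density(truth, np.maximum(t, 1e-6))).sum()
        assert ll_fit >= ll_truth - 1e-6

    def test_requires_events_and_size(self):
        with pytest.raises(ValueError):
            fit_mle(PseudoIPD(np.ones(5), np.ones(5, int)), "exponential")
        with pytest.raises(ValueError):
            fit_mle(PseudoIPD(np.ones(20), np.zeros(20, int)), "exponential")


class TestReconstruct:
    def test_pure_event_interval_bookkeeping(self):
        """n at risk 10 -> 5 with survival 1 -> 0.5: five events at the step."""
        km = DigitizedKM(
            times=[0.0, 3.0], surv=[1.0, 0.5], risk_times=[0.0, 6.0], n_risk=[10, 5]
        )
        ipd = reconstruct_ipd(km)
        assert ipd.n_events == 5
        assert np.all(ipd.times[ipd.events == 1] == 3.0)
        # the five still at risk leave as end-of-follow-up censorings, not events
        assert np.all(ipd.times[ipd.events == 0] >= 3.0)

    def test_flat_survival_interval_is_pure_censoring(self):
        km = DigitizedKM(
            times=[0.0, 6.0], surv=[1.0, 1.0], risk_times=[0.0, 6.0], n_risk=[10, 8]
        )
        ipd = reconstruct_ipd(km)
        assert ipd.n_events == 0
        assert (ipd.events == 0).sum() == 10  # 2 in-interval + 8 administrative

    def test_inconsistent_risk_table_rejected(self):
        with pytest.raises(ValueError):
            DigitizedKM(times=[0, 3], surv=[1.0, 0.6], risk_times=[0, 6], n_risk=[10, 12])

    def test_survival_increase_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError):
            DigitizedKM(
                times=[0, 3, 6], surv=[1.0, 0.5, 0.6], risk_times=[0, 6], n_risk=[10, 5]
            )

    def test_small_digitization_noise_is_clamped(self):
        km = DigitizedKM(
            times=[0, 3, 6], surv=[1.0, 0.5, 0.5005], risk_times=[0, 9], n_risk=[10, 2]
        )
        assert np.all(np.diff(km.surv) <= 0)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_km_round_trip_matches_at_anchors(self, seed):
        """digitize -> reconstruct reproduces the KM curve at the risk anchors."""
        truth = ParametricModel("weibull_aft", {"shape": 1.5, "scale": 12.0})
        rng = np.random.default_rng(seed)
        t = sample(truth, 200, rng)
        cens = rng.exponential(4.5 * 12.0, size=200)
        ipd = PseudoIPD(np.minimum(t, cens), (t <= cens).astype(int))
        km = digitize(ipd, anchor_spacing=3.0)
        rec = reconstruct_ipd(km)
        kmf_in = KaplanMeierFitter().fit(ipd.times, ipd.events)
        kmf_out = KaplanMeierFitter().fit(rec.times, rec.events)
        for a in km.risk_times:
            assert float(kmf_out.predict(a)) == pytest.approx(
                float(kmf_in.predict(a)), abs=0.02
            )

    def test_end_to_end_refit_recovers_weibull(self):
        """Weibull(1.5, 12), n=200, ~20% censoring: refit within 15% of truth."""
        truth = ParametricModel("weibull_aft", {"shape": 1.5, "scale": 12.0})
        rng = np.random.default_rng(42)
        t = sample(truth, 200, rng)
        cens = rng.exponential(4.5 * 12.0, size=200)
        ipd = PseudoIPD(np.minimum(t, cens), (t <= cens).astype(int))
        rec = reconstruct_ipd(digitize(ipd, anchor_spacing=3.0))
        model, _ = fit_mle(rec, "weibull_aft")
        assert model["shape"] == pytest.approx(1.5, rel=0.15)
        assert model["scale"] == pytest.approx(12.0, rel=0.15)


def test_select_best_recovers_generating_family():
    """Exponential vs log-logistic are well separated at n=300: the generating
    family should win the AIC comparison in at least 70% of replicates."""
    from mesocea.km import fit_all

    wins = 0
    n_rep = 50
    for seed in range(n_rep):
        fam = "exponential" if seed % 2 == 0 else "loglogistic"
        truth = (
            ParametricModel("exponential", {"rate": 0.08})
            if fam == "exponential"
            else ParametricModel("loglogistic", {"shape": 2.5, "scale": 9.0})
        )
        t = sample(truth, 300, seed=1000 + seed)
        ipd = PseudoIPD(t, np.ones(300, int))
        rep = fit_all(ipd, families=("exponential", "loglogistic"))
        if select_best(rep) == fam:
            wins += 1
    assert wins / n_rep >= 0.70
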