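"""Partitioned-survival cohort trace and accrual arithmetic."""

import numpy as np
import pytest

from mesocea import (
    AEItem,
    ArmConfig,
    CohortTrace,
    DrugCost,
    EngineSettings,
    MonitoringCosts,
    ParametricModel,
    SubsequentTreatment,
    UtilitySet,
    accrue_costs,
    accrue_qalys,
    build_trace,
    discount_factor,
    life_years,
    run_arm,
    survival,
)

from conftest import TABLE1_MODELS


def _arm(os_model, pfs_model, **kw):
    base = dict(
        name="test",
        os_model=os_model,
        pfs_model=pfs_model,
        drugs=(DrugCost("pembrolizumab", 4654.66, 6),),
        subsequent=SubsequentTreatment("nivolumab", 3279.69, 6.0),
        ae_profile=(),
    )
    base.update(kw)
    return ArmConfig(**base)


PEMBRO_ARM = _arm(
    TABLE1_MODELS[("whole", "pembro", "os")], TABLE1_MODELS[("whole", "pembro", "pfs")]
)

PEMBRO_AES = (
    AEItem("fatigue", 0.0676, 103.00, 0.29),
    AEItem("anemia", 0.2387, 921.10, 0.12),
    AEItem("thrombocytopenia", 0.1081, 1523.82, 0.11),
    AEItem("neutropenia", 0.3198, 411.93, 0.09),
    AEItem("lipase_increase", 0.0721, 44.30, 0.47),
    AEItem("hyperglycemia", 0.0631, 361.91, 0.20),
)


class TestDiscounting:
    def test_closed_forms(self):
        assert discount_factor(1.0, 0.05) == pytest.approx(0.952381, abs=1e-6)
        assert discount_factor(10.0, 0.05) == pytest.approx(0.613913, abs=1e-6)
        assert np.all(discount_factor(np.arange(5), 0.0) == 1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1.0, -0.01)


class TestTrace:
    @pytest.mark.parametrize("basis", ["cycle_months", "calendar"])
    def test_everyone_starts_progression_free(self, basis):
        tr = build_trace(PEMBRO_ARM, EngineSettings(curve_basis=basis))
        assert (tr.pfs[0], tr.pd[0], tr.dead[0]) == (1.0, 0.0, 0.0)

    @pytest.mark.parametrize("basis", ["cycle_months", "calendar"])
    def test_occupancy_conserved_and_dead_monotone(self, basis):
        tr = build_trace(PEMBRO_ARM, EngineSettings(curve_basis=basis))
        assert np.max(np.abs(tr.pfs + tr.pd + tr.dead - 1.0)) <= 1e-12
        assert np.all(np.diff(tr.dead) >= 0)

    def test_occupancy_equals_direct_curve_evaluation(self):
        """Occupancy at every boundary equals min(S_PFS, S_OS) / S_OS - . / 1 - S_OS
        recomputed directly from the distributions layer (1e-12)."""
        tr = build_trace(PEMBRO_ARM, EngineSettings())
        s_os = survival(PEMBRO_ARM.os_model, tr.lookup_months)
        s_pfs = np.minimum(survival(PEMBRO_ARM.pfs_model, tr.lookup_months), s_os)
        assert np.allclose(tr.pfs, s_pfs, atol=1e-12)
        assert np.allclose(tr.pd, s_os - s_pfs, atol=1e-12)
        assert np.allclose(tr.dead, 1.0 - s_os, atol=1e-12)

    def test_pd_clamped_when_pfs_curve_crosses_os(self):
        """If the raw PFS curve exceeds OS, PD occupancy clamps at zero."""
        arm = _arm(
            ParametricModel("exponential", {"rate": 0.30}),
            ParametricModel("exponential", {"rate": 0.05}),
        )
        tr = build_trace(arm, EngineSettings())
        assert np.all(tr.pd >= 0.0)
        assert np.all(tr.pfs <= 1.0 - tr.dead + 1e-15)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            EngineSettings(horizon_years=0.0)
        with pytest.raises(ValueError):
            EngineSettings(cycle_days=-1.0)
        with pytest.raises(ValueError):
            EngineSettings(curve_basis="weeks")


def _unit_trace(n_cycles=20, alive_frac=None):
    """A hand-built trace: everyone progression-free, no deaths, no discounting,
    horizon exactly one year."""
    K = n_cycles
    ones = np.ones(K + 1) if alive_frac is None else alive_frac
    zeros = np.zeros(K + 1)
    return CohortTrace(
        time_months=np.linspace(0.0, 12.0, K + 1),
        lookup_months=np.linspace(0.0, 12.0, K + 1),
        pfs=ones,
        pd=zeros,
        dead=1.0 - ones,
        discount=np.ones(K + 1),
        cycle_years=1.0 / K,
    )


class TestQALYs:
    def test_one_undiscounted_progression_free_year(self):
        """A full year in PFS at utility 0.706 with no AEs is 0.706 QALYs."""
        q = accrue_qalys(_unit_trace(), UtilitySet(pfs=0.706, pd=0.565))
        assert q == pytest.approx(0.706, abs=1e-12)

    def test_first_cycle_ae_decrement_matches_hand_sum(self):
        """Sum(incidence x disutility) for the intervention AE profile is
        0.135428, applied once for one cycle's duration."""
        tr = _unit_trace()
        q_no = accrue_qalys(tr, UtilitySet(), ())
        q_ae = accrue_qalys(tr, UtilitySet(), PEMBRO_AES)
        assert q_no - q_ae == pytest.approx(0.135428 * tr.cycle_years, abs=1e-12)

    def test_unit_utility_equals_discounted_life_years(self):
        settings = EngineSettings()
        tr = build_trace(PEMBRO_ARM, settings)
        q = accrue_qalys(tr, UtilitySet(pfs=1.0, pd=1.0), ())
        assert q == pytest.approx(life_years(tr, discounted=True), abs=1e-12)

    def test_half_cycle_correction_reduces_accrual_by_half_first_cycle(self):
        tr = _unit_trace()
        q_start = accrue_qalys(tr, UtilitySet(pfs=1.0, pd=0.5), half_cycle=False)
        q_half = accrue_qalys(tr, UtilitySet(pfs=1.0, pd=0.5), half_cycle=True)
        # flat occupancy: trapezoid == start-of-cycle accrual
        assert q_start == pytest.approx(q_half, abs=1e-12)


class TestLifeYears:
    def test_undiscounted_life_years_match_trapezoid_integral(self):
        """Life-years equal the trapezoid integral of S_OS within one half-cycle."""
        settings = EngineSettings(curve_basis="calendar")
        tr = build_trace(PEMBRO_ARM, settings)
        ly = life_years(tr, discounted=False)
        grid = np.linspace(0.0, tr.time_months[-1], 4001)
        integral = np.trapezoid(survival(PEMBRO_ARM.os_model, grid), grid) / 12.0
        assert abs(ly - integral) <= 0.5 * tr.cycle_years + 1e-9


class TestCosts:
    def test_zero_costs_zero_total(self):
        arm = _arm(
            PEMBRO_ARM.os_model,
            PEMBRO_ARM.pfs_model,
            drugs=(DrugCost("x", 0.0, 6),),
            subsequent=SubsequentTreatment("y", 0.0, 6.0),
            monitoring=MonitoringCosts(0.0, 0.0),
            admin_chemo_phase=0.0,
            admin_antibody_phase=0.0,
            end_of_life_cost=0.0,
        )
        total, ledger = accrue_costs(build_trace(arm, EngineSettings()), arm)
        assert total == 0.0

    def test_expected_ae_cost_matches_hand_sum(self):
        """Sum(incidence x management cost) for the intervention profile is
        549.32 USD, charged once in the first cycle."""
        arm = _arm(PEMBRO_ARM.os_model, PEMBRO_ARM.pfs_model, ae_profile=PEMBRO_AES)
        _, ledger = accrue_costs(build_trace(arm, EngineSettings()), arm)
        assert ledger["adverse_events"] == pytest.approx(549.32, abs=0.005)

    def test_drug_cost_only_in_first_cycle_when_cohort_empties(self):
        """With the cohort gone after cycle 0 and nobody dying inside the
        horizon, only cycle-boundary-0 charges remain."""
        K = 10
        tr = CohortTrace(
            time_months=np.arange(K + 1.0),
            lookup_months=np.arange(K + 1.0),
            pfs=np.array([1.0] + [0.0] * K),
            pd=np.zeros(K + 1),
            dead=np.array([0.0] + [1.0] * K),
            discount=np.ones(K + 1),
            cycle_years=1.0 / 12,
        )
        arm = _arm(PEMBRO_ARM.os_model, PEMBRO_ARM.pfs_model, end_of_life_cost=0.0)
        total, ledger = accrue_costs(tr, arm)
        assert ledger["drug:pembrolizumab"] == pytest.approx(4654.66)
        assert ledger["administration"] == pytest.approx(93.93 + 1.86)
        assert ledger["laboratory"] == pytest.approx(120.96)
        assert ledger["subsequent_treatment"] == 0.0

    def test_end_of_life_cost_follows_incident_deaths(self):
        arm = _arm(PEMBRO_ARM.os_model, PEMBRO_ARM.pfs_model)
        tr = build_trace(arm, EngineSettings(discount_rate=0.0))
        _, ledger = accrue_costs(tr, arm)
        assert ledger["end_of_life"] == pytest.approx(1460.30 * tr.dead[-1], rel=1e-12)

    def test_imaging_schedule_cycles(self):
        mon = MonitoringCosts()
        ct = mon.ct_cycles(20)
        assert list(ct[:5]) == [2, 4, 6, 10, 14]


class TestTenYearHorizonMortality:
    @pytest.mark.parametrize("key", sorted({k for k in TABLE1_MODELS if k[2] == "os"}))
    def test_cumulative_mortality_at_horizon(self, key):
        """Cumulative mortality over the 10-year horizon per OS model.

        The gamma and log-normal OS curves concentrate >99% of deaths inside
        the horizon; the log-logistic and right-skewed generalized-gamma
        curves have polynomial tails, and this documents how much mortality
        the horizon captures for them (95-98%).
        """
        model = TABLE1_MODELS[key]
        arm = _arm(model, TABLE1_MODELS[(key[0], key[1], "pfs")])
        tr = build_trace(arm, EngineSettings())
        assert tr.dead[-1] > 0.95  # every model is nearly exhausted
        if model.family in ("gamma", "lognormal"):
            assert tr.dead[-1] > 0.99
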