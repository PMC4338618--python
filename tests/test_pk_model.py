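"""Closed-form infusion kinetics: frozen examples, superposition, steady state."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crrtpk.pk_model import (
    DoseEvent,
    PKParams,
    PopulationPK,
    Regimen,
    conc_regimen,
    conc_single_infusion,
    simulate_population_profiles,
    steady_state_metrics,
    time_to_steady_state,
)


def brute_infusion(t, amount, dur, cl, v):
    """Independent closed-form oracle for a single infusion."""
    k = cl / v
    r0 = amount / dur
    if t <= dur:
        return (r0 / cl) * (1 - math.exp(-k * t))
    c_end = (r0 / cl) * (1 - math.exp(-k * dur))
    return c_end * math.exp(-k * (t - dur))


class TestSingleInfusion:
    def test_zero_time_and_zero_dose(self, p80):
        d = DoseEvent("SBECD", 5120.0, 0.0, 1.0)
        assert conc_single_infusion(0.0, d, p80) == 0.0
        z = DoseEvent("SBECD", 0.0, 0.0, 1.0)
        assert all(conc_single_infusion(np.array([0.0, 1.0, 5.0, 24.0]), z, p80) == 0.0)

    def test_frozen_values(self, p80):
        # (5120/2.4)(1 - e^-0.1) and its 12-h washout, evaluated independently
        d = DoseEvent("SBECD", 5120.0, 0.0, 1.0)
        assert conc_single_infusion(1.0, d, p80) == pytest.approx(203.0135, rel=1e-5)
        assert conc_single_infusion(13.0, d, p80) == pytest.approx(61.1465, rel=1e-4)
        assert conc_single_infusion(13.0, d, p80) == pytest.approx(
            203.0135 * math.exp(-1.2), rel=1e-4
        )

    def test_continuity_at_infusion_end(self, p80):
        d = DoseEvent("SBECD", 5120.0, 0.0, 1.0)
        eps = 1e-9
        left = conc_single_infusion(1.0 - eps, d, p80)
        right = conc_single_infusion(1.0 + eps, d, p80)
        assert abs(left - right) < 1e-6 * left

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PKParams(clearance=0.0, volume=24.0)
        with pytest.raises(ValueError):
            PKParams(clearance=2.4, volume=-1.0)
        with pytest.raises(ValueError):
            DoseEvent("SBECD", 100.0, 0.0, 0.0)

    def test_half_life_identity(self):
        p = PKParams(clearance=3.3, volume=17.0)
        assert p.half_life * p.elimination_rate == pytest.approx(math.log(2), rel=1e-12)


class TestRegimenSuperposition:
    def test_single_event_equals_single_infusion(self, p80):
        d = DoseEvent("SBECD", 5120.0, 0.0, 1.0)
        reg = Regimen(events=(d,), tau=12.0)
        for t in (0.5, 1.0, 7.0, 11.99):
            assert conc_regimen(t, reg, p80) == conc_single_infusion(t, d, p80)

    def test_two_half_doses_equal_one_full(self, p80):
        full = Regimen(events=(DoseEvent("SBECD", 5120.0, 0.0, 1.0),))
        halves = Regimen(
            events=(
                DoseEvent("SBECD", 2560.0, 0.0, 1.0),
                DoseEvent("voriconazole", 2560.0, 0.0, 1.0),
            )
        )
        t = np.linspace(0, 24, 49)
        np.testing.assert_allclose(
            conc_regimen(t, full, p80), conc_regimen(t, halves, p80), rtol=1e-12
        )

    def test_q12h_brute_force_at_48h(self, p80):
        reg = Regimen.intermittent(64.0, 80.0, n_doses=4, analyte="SBECD")
        expected = sum(
            brute_infusion(47.99 - s, 5120.0, 1.0, 2.4, 24.0) for s in (0.0, 12.0, 24.0, 36.0)
        )
        assert conc_regimen(47.99, reg, p80) == pytest.approx(expected, rel=1e-10)

    @settings(deadline=None, max_examples=40)
    @given(
        starts=st.lists(
            st.floats(0.0, 60.0), min_size=1, max_size=6, unique_by=lambda s: round(s, 3)
        ),
        amounts=st.lists(st.floats(0.0, 8000.0), min_size=6, max_size=6),
        t=st.floats(0.0, 100.0),
        cl=st.floats(0.5, 10.0),
        v=st.floats(5.0, 100.0),
    )
    def test_superposition_property(self, starts, amounts, t, cl, v):
        events = tuple(
            DoseEvent("SBECD", a, s, 1.0) for s, a in zip(sorted(starts), amounts)
        )
        reg = Regimen(events=events)
        p = PKParams(cl, v)
        expected = sum(
            brute_infusion(t - e.start, e.amount, e.duration, cl, v)
            for e in events
            if e.start <= t
        )
        assert conc_regimen(t, reg, p) == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_dose_linearity(self, p80, sbecd_regimen):
        t = np.linspace(0, 96, 97)
        base = conc_regimen(t, sbecd_regimen, p80)
        np.testing.assert_allclose(
            conc_regimen(t, sbecd_regimen.scaled(3.7), p80), 3.7 * base, rtol=1e-12
        )

    def test_monotone_washout_after_last_dose(self, p80):
        reg = Regimen.intermittent(64.0, 80.0, n_doses=3, analyte="SBECD")
        t = np.arange(25.0, 120.0, 0.5)  # past the last infusion end (24-25 h)
        c = conc_regimen(t, reg, p80)
        assert np.all(np.diff(c) < 0)

    def test_duplicate_start_same_analyte_rejected(self):
        with pytest.raises(ValueError, match="share start"):
            Regimen(
                events=(
                    DoseEvent("SBECD", 100.0, 0.0, 1.0),
                    DoseEvent("SBECD", 200.0, 0.0, 1.0),
                )
            )


class TestSteadyState:
    def test_auc_ss_is_dose_over_cl(self, p80):
        m = steady_state_metrics(5120.0, 12.0, 1.0, p80)
        assert m.auc_ss == pytest.approx(2133.333, rel=1e-5)
        assert m.auc_ss * p80.clearance == pytest.approx(5120.0, rel=1e-12)

    def test_doubling_cl_halves_auc(self, p80):
        double = PKParams(2 * p80.clearance, p80.volume)
        assert steady_state_metrics(5120.0, 12.0, 1.0, double).auc_ss == pytest.approx(
            steady_state_metrics(5120.0, 12.0, 1.0, p80).auc_ss / 2, rel=1e-12
        )

    def test_accumulation_factor(self, p80):
        # 1/(1 - e^-1.2) for k = 0.1/hr, tau = 12 h
        m = steady_state_metrics(5120.0, 12.0, 1.0, p80)
        assert m.accumulation_factor == pytest.approx(1.4310128, rel=1e-6)

    def test_interval_auc_matches_dose_over_cl_numerically(self, p80):
        # dense trapezoid over a late interval of the simulated regimen
        reg = Regimen.intermittent(64.0, 80.0, n_doses=30, analyte="SBECD")
        t = np.arange(288.0, 300.0 + 0.01, 0.01)
        c = conc_regimen(t, reg, p80)
        auc = np.trapezoid(c, t)
        assert auc == pytest.approx(5120.0 / 2.4, rel=1e-3)

    def test_cmin_cmax_consistency(self, p80, sbecd_regimen):
        m = steady_state_metrics(5120.0, 12.0, 1.0, p80)
        assert m.cmin_ss == pytest.approx(m.cmax_ss * math.exp(-0.1 * 11.0), rel=1e-12)
        assert m.cmax_ss > m.cmin_ss > 0

    def test_tau_not_exceeding_duration_rejected(self, p80):
        with pytest.raises(ValueError, match="exceed"):
            steady_state_metrics(5120.0, 1.0, 1.0, p80)


class TestTimeToSteadyState:
    def test_tiny_threshold_gives_first_trough(self, p80, sbecd_regimen):
        assert time_to_steady_state(sbecd_regimen, p80, threshold=1e-9) == 12.0

    def test_mean_parameters_reach_steady_state_at_48h(self, p80, sbecd_regimen):
        # 1 - e^(-0.1*48) = 0.9918 >= 0.99 while 1 - e^(-0.1*36) = 0.9727 < 0.99
        assert time_to_steady_state(sbecd_regimen, p80, threshold=0.99) == 48.0

    def test_short_half_life_reaches_by_first_trough(self):
        fast = PKParams(clearance=24.0, volume=24.0 / math.log(2))  # T1/2 = 1 h
        reg = Regimen.intermittent(64.0, 80.0, n_doses=10, analyte="SBECD")
        assert time_to_steady_state(reg, fast, threshold=0.99) == 12.0

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.5, 1.5])
    def test_threshold_domain(self, p80, sbecd_regimen, threshold):
        with pytest.raises(ValueError):
            time_to_steady_state(sbecd_regimen, p80, threshold=threshold)

    def test_aperiodic_regimen_rejected(self, p80):
        reg = Regimen(events=(DoseEvent("SBECD", 100.0, 0.0, 1.0),), tau=None)
        with pytest.raises(ValueError, match="periodic"):
            time_to_steady_state(reg, p80)


class TestPopulationSimulation:
    def test_zero_variance_collapses_to_deterministic_profile(self, p80, sbecd_regimen):
        pop = PopulationPK(
            log_cl_mean=math.log(2.4),
            log_cl_sd=0.0,
            log_v_mean=math.log(24.0),
            log_v_sd=0.0,
            prop_sd=0.0,
            add_sd=0.0,
        )
        grid = np.arange(0.0, 97.0)
        env = simulate_population_profiles(pop, sbecd_regimen, n=5, grid=grid, seed=1)
        np.testing.assert_allclose(
            env["mean_mg_L"].to_numpy(), conc_regimen(grid, sbecd_regimen, p80), rtol=1e-12
        )
        # identical rows: SD vanishes up to summation round-off
        assert np.all(env["sd_mg_L"] <= 1e-9)

    def test_seed_reproducibility(self, sbecd_regimen):
        pop = PopulationPK.from_moments(2.4, 0.8, 24.0, 8.0)
        a = simulate_population_profiles(pop, sbecd_regimen, n=50, seed=42)
        b = simulate_population_profiles(pop, sbecd_regimen, n=50, seed=42)
        assert a.equals(b)

    def test_uf_strata_trough_ratio_matches_closed_form(self, sbecd_regimen):
        """Mean steady-state troughs under the printed stratum clearances
        (1.75 vs 4.69 L/hr) scale as the closed-form Dose/CL x accumulation."""
        grid = np.array([168.0])  # steady-state trough: one full interval after the last dose
        troughs = {}
        for cl in (1.75, 4.69):
            pop = PopulationPK.from_moments(cl, 0.15 * cl, 24.0, 2.0, prop_sd=0.05)
            env, sims = simulate_population_profiles(
                pop, sbecd_regimen, n=400, grid=grid, seed=5, return_samples=True
            )
            troughs[cl] = (env["mean_mg_L"].iloc[0], sims[:, 0].std(ddof=1) / math.sqrt(400))
        ratio = troughs[1.75][0] / troughs[4.69][0]
        expected = {}
        for cl in (1.75, 4.69):
            m = steady_state_metrics(5120.0, 12.0, 1.0, PKParams(cl, 24.0))
            expected[cl] = m.cmin_ss
        # log-normal CL: E[trough(CL)] differs from trough(E[CL]) by Jensen
        # curvature; allow that bias plus Monte Carlo error
        for cl in (1.75, 4.69):
            assert troughs[cl][0] == pytest.approx(expected[cl], rel=0.12)
        assert ratio == pytest.approx(expected[1.75] / expected[4.69], rel=0.15)
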