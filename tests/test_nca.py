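"""Noncompartmental analysis: AUC rules, terminal fit, recovery, paired test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crrtpk.nca import (
    accumulation_test,
    auc_interval,
    nca_summary,
    terminal_slope,
)
from crrtpk.pk_model import PKParams, Regimen, conc_regimen


class TestAUC:
    def test_rectangle_and_triangle(self):
        assert auc_interval([0.0, 12.0], [10.0, 10.0]) == pytest.approx(120.0)
        assert auc_interval([0.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_log_down_on_exponential(self):
        # C(t) = 100 e^(-0.1 t) sampled every 2 h; analytic AUC0-12 = 698.81
        t = np.arange(0.0, 12.1, 2.0)
        c = 100.0 * np.exp(-0.1 * t)
        analytic = 100.0 * (1 - math.exp(-1.2)) / 0.1
        assert auc_interval(t, c) == pytest.approx(analytic, rel=2e-3)
        assert analytic == pytest.approx(698.806, rel=1e-5)

    def test_unsorted_or_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            auc_interval([0.0, 2.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            auc_interval([0.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=40)
    @given(
        concs=st.lists(st.floats(0.0, 500.0), min_size=5, max_size=9),
    )
    def test_additivity_at_interior_point(self, concs):
        t = np.linspace(0.0, 12.0, len(concs))
        mid = len(concs) // 2
        total = auc_interval(t, concs)
        parts = auc_interval(t[: mid + 1], concs[: mid + 1]) + auc_interval(
            t[mid:], concs[mid:]
        )
        assert total == pytest.approx(parts, rel=1e-12, abs=1e-12)


class TestTerminalSlope:
    def test_exact_exponential_recovered(self):
        t = np.array([0.0, 4.0, 6.0, 8.0, 12.0])
        c = np.concatenate([[200.0], 150.0 * np.exp(-0.1 * t[1:])])  # peak at t=0
        fit = terminal_slope(t, c)
        assert fit is not None
        assert fit.lambda_z == pytest.approx(0.1, rel=1e-9)
        assert fit.half_life == pytest.approx(6.9315, rel=1e-4)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_profile_not_estimable(self):
        t = np.arange(0.0, 13.0, 2.0)
        assert terminal_slope(t, np.full(t.size, 5.0)) is None

    def test_short_tail_not_estimable(self):
        assert terminal_slope([0.0, 6.0, 12.0], [10.0, 5.0, 2.0]) is None  # 2 post-peak pts

    def test_noisy_tail_window_selection_prefers_clean_fit(self):
        # early distribution phase then clean mono-exponential tail
        t = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0])
        c = np.array([100.0, 60.0, 45.0, 40.0 * math.exp(-0.4), *(40.0 * np.exp(-0.1 * (np.array([6.0, 8.0, 12.0]) - 0.0)))])
        fit = terminal_slope(t, c)
        assert fit is not None and fit.lambda_z > 0


class TestNCASummary:
    def simulate_ss_profile(self, cl_per_kg, v_per_kg, weight=80.0, dose_per_kg=64.0):
        p = PKParams.from_per_kg(cl_per_kg, v_per_kg, weight)
        reg = Regimen.intermittent(dose_per_kg, weight, n_doses=11, analyte="SBECD")
        t = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0])
        c = conc_regimen(120.0 + t, reg, p)  # day 6: far past steady state
        return t, c

    @pytest.mark.parametrize("cl,v", [(0.03, 0.3), (0.01, 0.1), (0.05, 0.4), (0.02, 0.2)])
    def test_parameter_recovery_on_noise_free_steady_state(self, cl, v):
        t, c = self.simulate_ss_profile(cl, v)
        res = nca_summary(t, c, dose_mg_per_kg=64.0, weight_kg=80.0, analyte="SBECD")
        assert res.cl_per_kg == pytest.approx(cl, rel=0.01)
        assert res.vd_per_kg == pytest.approx(v, rel=0.05)

    def test_scale_equivariance(self):
        t, c = self.simulate_ss_profile(0.03, 0.3)
        a = nca_summary(t, c, 64.0, 80.0, analyte="SBECD")
        b = nca_summary(t, 2 * c, 64.0, 80.0, analyte="SBECD")
        assert b.cmax == pytest.approx(2 * a.cmax, rel=1e-12)
        assert b.cl_per_kg == pytest.approx(a.cl_per_kg / 2, rel=1e-12)
        # lambda_z is scale-invariant, so Vd = CL/lambda_z halves with CL
        assert b.lambda_z == pytest.approx(a.lambda_z, rel=1e-9)
        assert b.vd_per_kg == pytest.approx(a.vd_per_kg / 2, rel=1e-9)
        assert b.half_life == pytest.approx(a.half_life, rel=1e-9)

    def test_half_life_identity_within_result(self):
        t, c = self.simulate_ss_profile(0.03, 0.3)
        res = nca_summary(t, c, 64.0, 80.0, analyte="SBECD")
        assert res.half_life == pytest.approx(
            math.log(2) * res.vd_per_kg / res.cl_per_kg, rel=1e-6
        )

    def test_dose_normalization_idempotent_at_reference(self):
        t, c = self.simulate_ss_profile(0.03, 0.3, dose_per_kg=64.0)
        res = nca_summary(t, c, 64.0, 80.0, analyte="SBECD")
        assert res.dn_auc0_12 == pytest.approx(res.auc0_12, rel=1e-12)
        assert res.dn_cmax == pytest.approx(res.cmax, rel=1e-12)

    def test_dose_normalization_rescales_loading_dose(self):
        t, c = self.simulate_ss_profile(0.03, 0.3, dose_per_kg=96.0)
        res = nca_summary(t, c, 96.0, 80.0, analyte="SBECD")
        assert res.dn_auc0_12 == pytest.approx(res.auc0_12 * 64.0 / 96.0, rel=1e-12)

    def test_missing_trough_extrapolated_with_warning(self):
        t, c = self.simulate_ss_profile(0.03, 0.3)
        with pytest.warns(UserWarning, match="extrapolated"):
            res = nca_summary(t[:-1], c[:-1], 64.0, 80.0, analyte="SBECD")
        assert res.cmin_extrapolated
        assert res.cmin == pytest.approx(c[-1], rel=0.02)

    def test_bql_handling(self):
        t, c = self.simulate_ss_profile(0.03, 0.3)
        bql = np.zeros(t.size, dtype=bool)
        bql[4] = True  # interior flagged sample carries the limit, halved in AUC
        res_flag = nca_summary(t, c, 64.0, 80.0, analyte="SBECD", bql=bql)
        res_clean = nca_summary(t, c, 64.0, 80.0, analyte="SBECD")
        assert res_flag.auc0_12 < res_clean.auc0_12

    def test_sparse_profile_rejected(self):
        with pytest.raises(ValueError, match="rich"):
            nca_summary([0.0, 2.0, 8.0], [1.0, 5.0, 2.0], 64.0, 80.0)


def paired_t_oracle(x, y):
    """Textbook paired t: mean(d) / (sd(d)/sqrt(n)), two-sided P from t_{n-1}."""
    from scipy import stats

    d = np.asarray(y, float) - np.asarray(x, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return t, 2 * stats.t.sf(abs(t), n - 1)


class TestAccumulation:
    def test_identical_pairs_give_t0_p1(self):
        day1 = {"a": 10.0, "b": 20.0, "c": 30.0}
        later = {k: [v] for k, v in day1.items()}
        res = accumulation_test(day1, later)
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_matches_hand_computed_oracle(self):
        day1 = {"a": 100.0, "b": 110.0, "c": 90.0}
        later = {"a": [102.0], "b": [108.0], "c": [92.0]}
        res = accumulation_test(day1, later)
        t, p = paired_t_oracle([100, 110, 90], [102, 108, 92])
        assert res.t_stat == pytest.approx(t, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    @settings(deadline=None, max_examples=40)
    @given(
        pairs=st.lists(
            st.tuples(st.floats(1.0, 1e4), st.floats(1.0, 1e4)), min_size=3, max_size=12
        )
    )
    def test_random_pairs_match_oracle(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        if np.std(np.subtract(y, x), ddof=1) < 1e-9:
            return
        day1 = {str(i): a for i, a in enumerate(x)}
        later = {str(i): [b] for i, b in enumerate(y)}
        res = accumulation_test(day1, later)
        t, p = paired_t_oracle(x, y)
        assert res.t_stat == pytest.approx(t, rel=1e-10, abs=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_later_days_averaged_within_subject(self):
        day1 = {"a": 100.0, "b": 100.0}
        later = {"a": [110.0, 130.0], "b": [90.0, 110.0]}
        res = accumulation_test(day1, later)
        assert res.later_mean == pytest.approx(110.0)

    def test_single_pair_not_estimable(self):
        res = accumulation_test({"a": 1.0}, {"a": [2.0]})
        assert not res.estimable and res.n_pairs == 1

    def test_incomplete_subjects_excluded_and_counted(self):
        res = accumulation_test(
            {"a": 1.0, "b": 2.0, "c": 3.0}, {"a": [1.0], "b": [2.0], "d": [9.0]}
        )
        assert res.n_pairs == 2
        assert set(res.excluded_subjects) == {"c", "d"}
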