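"""Gel-densitometry kinetics: yields, closed forms, exponential fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from inteinkit import pts
from inteinkit.exceptions import ConfigurationError, DomainError, FitError
from inteinkit.synthetic import gel_table_to_timecourse, generate_pts_gel

rates = st.floats(min_value=1e-4, max_value=10.0)


def make_tc(times, traces, masses=None):
    return pts.TimeCourse(times=times, intensities=traces,
                          masses=masses or {})


class TestNormalization:
    def test_intensity_equal_to_mass_gives_unit_abundance(self):
        tc = make_tc([0.0, 10.0], {"P": [70.1, 70.1], "A": [58.2, 58.2]},
                     masses={"P": 70.1, "A": 58.2})
        norm = pts.normalize_densitometry(tc)
        assert norm.normalized
        np.testing.assert_allclose(norm.intensities["P"], 1.0)
        np.testing.assert_allclose(norm.intensities["A"], 1.0)

    def test_half_mass_intensities_give_half_abundance(self):
        tc = make_tc([0.0], {"P": [35.05], "A": [29.1]},
                     masses={"P": 70.1, "A": 58.2})
        norm = pts.normalize_densitometry(tc)
        assert norm.intensities["P"][0] == pytest.approx(0.5)
        assert norm.intensities["A"][0] == pytest.approx(0.5)

    def test_zero_intensity_stays_zero(self):
        tc = make_tc([0.0], {"P": [0.0]}, masses={"P": 70.1})
        assert pts.normalize_densitometry(tc).intensities["P"][0] == 0.0

    def test_missing_mass_names_the_species(self):
        tc = make_tc([0.0], {"P": [1.0], "BI": [1.0]}, masses={"P": 70.1})
        with pytest.raises(ConfigurationError, match="BI"):
            pts.normalize_densitometry(tc)


class TestSpliceYield:
    @pytest.mark.parametrize("sp, a, expected", [
        (1.0, 1.0, 50.0),   # equal amounts -> 50%
        (0.0, 1.0, 0.0),
        (3.0, 1.0, 75.0),   # x = 300 -> P = 75
    ])
    def test_known_yields(self, sp, a, expected):
        assert pts.splice_yield(sp, a).percent == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        with pytest.raises(DomainError):
            pts.splice_yield(0.0, 0.0)

    @given(sp1=st.floats(1e-6, 1e3), sp2=st.floats(1e-6, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_and_strictly_increasing_in_product(self, sp1, sp2):
        lo, hi = sorted([sp1, sp2])
        y_lo = pts.splice_yield(lo, 1.0).percent
        y_hi = pts.splice_yield(hi, 1.0).percent
        assert 0.0 <= y_lo < 100.0 and 0.0 <= y_hi < 100.0
        if hi > lo:
            assert y_hi > y_lo


class TestHalfLife:
    @pytest.mark.parametrize("k, t_half", [
        (0.1387, 5.0),    # ultra-fast wildtype pairing
        (0.0913, 7.6),    # three-fold N-precursor excess pairing
    ])
    def test_printed_rate_half_life_pairs(self, k, t_half):
        assert round(pts.half_life(k), 1) == t_half

    def test_ln2_rate_gives_unit_half_life(self):
        assert pts.half_life(math.log(2.0)) == pytest.approx(1.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DomainError):
            pts.half_life(0.0)


def ode_profiles(k1, k2, k3, p_max, times):
    """Independent oracle: stiff-accurate integration of the rate equations."""

    def rhs(_t, x):
        a, bi, _p = x
        return [-k1 * a + k2 * bi, k1 * a - (k2 + k3) * bi, k3 * bi]

    sol = solve_ivp(rhs, (0.0, times[-1]), [p_max, 0.0, 0.0], t_eval=times,
                    rtol=1e-12, atol=1e-14, method="LSODA")
    return dict(zip(["A", "BI", "P"], sol.y))


class TestThreeStateClosedForm:
    def test_initial_condition_is_intact_precursor(self):
        prof = pts.three_state_profiles(0.1, 0.05, 0.2, 0.7, [0.0])
        assert prof["A"][0] == pytest.approx(0.7, abs=1e-12)
        assert prof["BI"][0] == pytest.approx(0.0, abs=1e-12)
        assert prof["P"][0] == pytest.approx(0.0, abs=1e-12)

    def test_product_is_the_absorbing_state(self):
        prof = pts.three_state_profiles(0.1, 0.05, 0.2, 0.7, [1e5])
        assert prof["P"][-1] == pytest.approx(0.7, abs=1e-9)

    def test_matches_numerical_integration(self):
        t = np.array([1.0, 5.0, 10.0, 50.0])
        prof = pts.three_state_profiles(0.1, 0.05, 0.2, 1.0, t)
        oracle = ode_profiles(0.1, 0.05, 0.2, 1.0, t)
        for s in ("A", "BI", "P"):
            np.testing.assert_allclose(prof[s], oracle[s], atol=1e-8)

    def test_repeated_eigenvalue_limit_matches_ode(self):
        # k2 = 0 with k1 = k3 makes p^2 - 4 k1 k3 exactly zero
        k = 0.1
        t = np.linspace(0.0, 80.0, 30)[1:]
        prof = pts.three_state_profiles(k, 0.0, k, 1.0, t)
        oracle = ode_profiles(k, 0.0, k, 1.0, t)
        for s in ("A", "BI", "P"):
            np.testing.assert_allclose(prof[s], oracle[s], atol=1e-8)

    @given(k1=rates, k2=rates, k3=rates)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation_and_real_eigenvalues(self, k1, k2, k3):
        p = k1 + k2 + k3
        assert p * p - 4.0 * k1 * k3 >= -1e-15 * p * p
        t = np.linspace(0.0, 10.0 / min(k1, k3), 25)
        prof = pts.three_state_profiles(k1, k2, k3, 1.0, t)
        total = prof["A"] + prof["BI"] + prof["P"]
        np.testing.assert_allclose(total, 1.0, rtol=1e-10)
        assert np.all(np.diff(prof["P"]) >= -1e-12)


class TestSingleExponentialFit:
    def test_noiseless_generative_identity(self, pts_times):
        table, _ = generate_pts_gel(0, 0, 0, pts_times, active_fraction=0.30,
                                    noise_sd=0.0, scheme="single_exponential",
                                    k_total=0.05, seed=0)
        fit = pts.fit_single_exponential(gel_table_to_timecourse(table))
        assert fit.k_total == pytest.approx(0.05, rel=1e-3)
        assert fit.P_max == pytest.approx(0.30, rel=1e-3)
        assert fit.half_life == pytest.approx(math.log(2) / 0.05, rel=1e-3)

    def test_noisy_recovery_within_five_percent(self, pts_times):
        table, truth = generate_pts_gel(
            0, 0, 0, pts_times, active_fraction=0.30, noise_sd=0.05,
            scheme="single_exponential", k_total=0.05, seed=42)
        fit = pts.fit_single_exponential(gel_table_to_timecourse(table))
        assert fit.k_total == pytest.approx(truth["k_total"], rel=0.05)

    def test_all_zero_product_trace_errors(self):
        tc = make_tc(np.arange(5.0), {"P": np.zeros(5)})
        with pytest.raises(FitError):
            pts.fit_single_exponential(tc)

    def test_decreasing_trace_errors(self):
        tc = make_tc(np.arange(5.0), {"P": [1.0, 0.8, 0.6, 0.4, 0.2]})
        with pytest.raises(FitError, match="non-increasing"):
            pts.fit_single_exponential(tc)


class TestThreeStateFit:
    TRUTH = dict(k1=0.02, k2=0.01, k3=0.1, active_fraction=0.3)

    def test_noiseless_generative_identity(self, pts_times):
        table, _ = generate_pts_gel(times=pts_times, noise_sd=0.0, seed=0,
                                    **self.TRUTH)
        fit = pts.fit_three_state(gel_table_to_timecourse(table))
        assert fit.k1 == pytest.approx(0.02, rel=1e-3)
        assert fit.k2 == pytest.approx(0.01, rel=1e-3)
        assert fit.k3 == pytest.approx(0.1, rel=1e-3)
        assert fit.P_max == pytest.approx(0.3, rel=1e-3)
        # derived eigen-quantities satisfy their defining algebra
        assert fit.a * fit.b == pytest.approx(fit.k1 * fit.k3, rel=1e-9)
        assert fit.p == pytest.approx(fit.k1 + fit.k2 + fit.k3, rel=1e-12)

    def test_noisy_recovery(self, pts_times):
        table, _ = generate_pts_gel(times=pts_times, noise_sd=0.05, seed=5,
                                    **self.TRUTH)
        fit = pts.fit_three_state(gel_table_to_timecourse(table))
        assert fit.k1 == pytest.approx(0.02, rel=0.10)
        assert fit.k3 == pytest.approx(0.1, rel=0.10)
        assert abs(fit.P_max - 0.3) < 0.02

    def test_missing_branched_intermediate_errors(self, pts_times):
        tc = make_tc(pts_times, {"A": np.ones_like(pts_times),
                                 "P": np.zeros_like(pts_times)})
        with pytest.raises(ConfigurationError, match="BI"):
            pts.fit_three_state(tc)

    def test_summary_reports_parameters(self, pts_times):
        table, _ = generate_pts_gel(times=pts_times, noise_sd=0.0, seed=0,
                                    **self.TRUTH)
        fit = pts.fit_three_state(gel_table_to_timecourse(table))
        text = fit.summary()
        assert "k1" in text and "P_max" in text
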