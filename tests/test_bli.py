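"""Biphasic sensorgram fitting and rate-constant extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inteinkit import bli
from inteinkit.exceptions import (ConfigurationError, FitError,
                                  ModelInconsistencyError)
from inteinkit.synthetic import BLI_DILUTION_SERIES_M, generate_sensorgrams

R = dict(ka=1e5, kd=1e-2, kf=1e-2, ku=1e-3)

log_rate = st.floats(min_value=-4, max_value=0)


def phase_fit_from_eigenvalues(s1, s2, conc, phase="association"):
    """Construct an exact PhaseFitResults as a forward oracle would."""
    return bli.PhaseFitResults(phase=phase, sigma1=s1, sigma2=s2,
                               E=-0.5, F=-0.5, conc=conc, resid_norm=0.0)


class TestEigenvalueIdentities:
    @given(ka=st.floats(1e3, 1e7), kd=log_rate, kf=log_rate, ku=log_rate,
           conc=st.floats(1e-9, 1e-6))
    @settings(max_examples=50, derandomize=True)
    def test_trace_and_determinant(self, ka, kd, kf, ku, conc):
        kd, kf, ku = 10.0 ** kd, 10.0 ** kf, 10.0 ** ku
        m = bli.two_step_matrix(ka, kd, kf, ku, conc)
        s1, s2 = bli.two_step_eigenvalues(ka, kd, kf, ku, conc)
        assert s1 + s2 == pytest.approx(-np.trace(m), rel=1e-9)
        assert s1 * s2 == pytest.approx(np.linalg.det(m), rel=1e-9)
        assert s1 >= s2 > 0

    def test_locked_complex_limit_has_vanishing_slow_gamma(self):
        # ku -> 0: gamma1*gamma2 = kd*ku -> 0, complex never fully releases
        g1, g2 = bli.two_step_eigenvalues(R["ka"], R["kd"], R["kf"], 0.0, 0.0)
        assert g2 == pytest.approx(0.0, abs=1e-15)
        assert g1 == pytest.approx(R["kd"] + R["kf"])


class TestPhaseFits:
    def test_association_response_is_zero_at_phase_start(self):
        traces, _ = generate_sensorgrams(noise_sd=0.0, seed=0, **R)
        fit = bli.fit_association(traces[0])
        assert fit.D == pytest.approx(-(fit.E + fit.F))
        assert fit.predict(0.0) == pytest.approx(0.0, abs=1e-12)
        assert fit.sigma1 >= fit.sigma2

    def test_association_exponent_sum_matches_eigenvalues(self):
        traces, _ = generate_sensorgrams(
            concentrations=[100e-9], noise_sd=0.0, seed=0, **R)
        fit = bli.fit_association(traces[0])
        s1, s2 = bli.two_step_eigenvalues(conc=100e-9, **R)
        assert fit.sigma1 + fit.sigma2 == pytest.approx(s1 + s2, rel=0.005)
        assert fit.sigma1 * fit.sigma2 == pytest.approx(s1 * s2, rel=0.005)

    def test_one_to_one_limit_recovers_single_exponent(self):
        traces, _ = generate_sensorgrams(
            ka=R["ka"], kd=R["kd"], kf=0.0, ku=0.0,
            concentrations=[100e-9], noise_sd=0.0, seed=0)
        fit = bli.fit_association(traces[0])
        assert fit.mono_exponential
        assert fit.sigma1 == pytest.approx(R["ka"] * 100e-9 + R["kd"],
                                           rel=0.005)

    def test_dissociation_eigenvalues_at_zero_concentration(self):
        traces, _ = generate_sensorgrams(
            concentrations=[100e-9], noise_sd=0.0, seed=0, **R)
        fit = bli.fit_dissociation(traces[0])
        g1, g2 = bli.two_step_eigenvalues(conc=0.0, **R)
        assert fit.sigma1 + fit.sigma2 == pytest.approx(g1 + g2, rel=0.005)
        assert fit.sigma1 * fit.sigma2 == pytest.approx(g1 * g2, rel=0.005)

    def test_flat_zero_trace_errors(self):
        tr = bli.Sensorgram(times=np.arange(100.0),
                            response=np.zeros(100), conc=1e-8,
                            t_dissoc_start=50.0)
        with pytest.raises(FitError):
            bli.fit_dissociation(tr)

    def test_short_segment_rejected(self):
        tr = bli.Sensorgram(times=np.arange(10.0),
                            response=np.arange(10.0), conc=1e-8)
        with pytest.raises(ConfigurationError, match="20"):
            bli.fit_association(tr)


class TestRateExtraction:
    def test_exact_eigenvalues_recover_rates(self):
        """Forward eigenvalue computation as oracle: exact sigma/gamma at
        the seven-step dilution series must invert to the true rates."""
        assoc = [phase_fit_from_eigenvalues(
            *bli.two_step_eigenvalues(conc=c, **R), conc=c)
            for c in BLI_DILUTION_SERIES_M]
        dissoc = [phase_fit_from_eigenvalues(
            *bli.two_step_eigenvalues(conc=0.0, **R), conc=c,
            phase="dissociation") for c in BLI_DILUTION_SERIES_M]
        res = bli.extract_rate_constants(assoc, dissoc)
        for name, true in R.items():
            assert getattr(res, name) == pytest.approx(true, rel=1e-3)
        # gamma-sum identity holds by construction of kf
        assert res.kd + res.kf + res.ku == pytest.approx(res.gamma_sum,
                                                         rel=1e-12)

    def test_concentration_independent_sigmas_error(self):
        assoc = [phase_fit_from_eigenvalues(0.02, 0.001, conc=c)
                 for c in (1e-9, 1e-8, 1e-7)]
        dissoc = [phase_fit_from_eigenvalues(0.02, 0.001, conc=1e-9,
                                             phase="dissociation")]
        with pytest.raises(ModelInconsistencyError):
            bli.extract_rate_constants(assoc, dissoc)

    def test_too_few_concentrations_rejected(self):
        assoc = [phase_fit_from_eigenvalues(0.02, 0.001, conc=c)
                 for c in (1e-9, 1e-8)]
        with pytest.raises(ConfigurationError):
            bli.extract_rate_constants(assoc, assoc)

    def test_end_to_end_noiseless_recovery(self):
        traces, truth = generate_sensorgrams(noise_sd=0.0, seed=0, **R)
        assoc = [bli.fit_association(t) for t in traces]
        dissoc = [bli.fit_dissociation(t) for t in traces]
        res = bli.extract_rate_constants(assoc, dissoc)
        for name in ("ka", "kd", "kf", "ku"):
            assert getattr(res, name) == pytest.approx(truth[name], rel=0.01)


class TestDerivedConstants:
    def test_equilibrium_constants_worked_example(self):
        rates = bli.RateConstantSet(**R)
        eq = bli.equilibrium_constants(rates)
        assert eq["Ka1"] == pytest.approx(1e7)
        assert eq["Ka2"] == pytest.approx(10.0)
        assert eq["Ka"] == pytest.approx(1.1e8)
        assert eq["Kd"] == pytest.approx(9.09e-9, rel=1e-3)

    def test_macroscopic_rates_worked_example(self):
        rates = bli.RateConstantSet(**R)
        mac = bli.macroscopic_rates(rates)
        assert mac["kon"] == pytest.approx(5e4)
        assert mac["koff"] == pytest.approx(5e-4)

    def test_folding_equal_to_dissociation_halves_kon(self):
        rates = bli.RateConstantSet(ka=1e5, kd=1e-2, kf=1e-2, ku=1e-3)
        assert rates.kon == pytest.approx(rates.ka / 2)

    def test_no_folding_limit_reduces_to_one_to_one(self):
        rates = bli.RateConstantSet(ka=1e5, kd=1e-2, kf=1e-9, ku=1e-3)
        assert rates.Kd == pytest.approx(rates.kd / rates.ka, rel=1e-5)

    @given(ka=st.floats(1e3, 1e7), kd=log_rate, kf=log_rate, ku=log_rate)
    @settings(max_examples=50, derandomize=True)
    def test_kd_never_exceeds_koff_over_kon(self, ka, kd, kf, ku):
        rates = bli.RateConstantSet(ka=ka, kd=10.0 ** kd, kf=10.0 ** kf,
                                    ku=10.0 ** ku)
        assert rates.Kd <= rates.koff / rates.kon * (1 + 1e-12)
        # identity: koff/kon = 1/(Ka1 Ka2)
        assert rates.koff / rates.kon == pytest.approx(
            1.0 / (rates.Ka1 * rates.Ka2), rel=1e-9)


class TestSteadyState:
    def test_exact_hyperbola_recovery(self):
        x = np.array([2e-9, 5e-9, 12e-9, 30e-9, 100e-9, 300e-9])
        y = 1.0 * x / (12e-9 + x)
        fit = bli.fit_steady_state(x, y)
        assert fit.Kd == pytest.approx(12e-9, rel=1e-6)
        assert fit.Ymax == pytest.approx(1.0, rel=1e-6)
        assert fit.predict(fit.Kd) == pytest.approx(fit.Ymax / 2, rel=1e-9)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(3)
        x = np.array(BLI_DILUTION_SERIES_M)
        y = 1.0 * x / (12e-9 + x)
        y = y + rng.normal(0.0, 0.02 * y.max(), size=y.shape)
        fit = bli.fit_steady_state(x, y)
        assert fit.Kd == pytest.approx(12e-9, rel=0.10)

    def test_proportional_responses_unidentifiable(self):
        x = np.array([1e-9, 2e-9, 4e-9, 8e-9])
        with pytest.raises(FitError):
            bli.fit_steady_state(x, 5e7 * x)


class TestModelValidation:
    def test_two_step_data_passes_with_high_linearity(self):
        traces, _ = generate_sensorgrams(noise_sd=0.0, seed=0, **R)
        assoc = [bli.fit_association(t) for t in traces]
        diag = bli.validate_biphasic_model(assoc)
        assert diag["passes"]
        assert diag["r2_sum"] > 0.999 and diag["r2_product"] > 0.999

    def test_one_to_one_data_flagged_mono_exponential(self):
        traces, _ = generate_sensorgrams(
            ka=R["ka"], kd=R["kd"], kf=0.0, ku=0.0, noise_sd=0.0, seed=0)
        assoc = [bli.fit_association(t) for t in traces]
        diag = bli.validate_biphasic_model(assoc)
        assert diag["mono_exponential"]
        assert not diag["passes"]

    def test_shuffled_eigenvalues_fail(self):
        concs = list(BLI_DILUTION_SERIES_M)
        eigs = [bli.two_step_eigenvalues(conc=c, **R) for c in concs]
        shuffled = [eigs[i] for i in (3, 0, 5, 1, 6, 2, 4)]
        assoc = [phase_fit_from_eigenvalues(s1, s2, conc=c)
                 for (s1, s2), c in zip(shuffled, concs)]
        assert not bli.validate_biphasic_model(assoc)["passes"]
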