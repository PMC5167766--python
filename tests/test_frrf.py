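"""Single-turnover FRR model: fits, derived photophysiology, invariants."""
import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import Avogadro

from phytoalloc import frrf, synthdata
from phytoalloc.frrf import FrrFitError


def make_trace(protocol, truth, **kw):
    return synthdata.gen_frr_trace(protocol, truth, **kw)


class TestInductionModel:
    def test_poisson_limit_matches_closed_form(self, protocol):
        """At p=0 the closure model is the single-hit Poisson form."""
        doses = protocol.flashlet_dose_quanta_m2 * np.arange(1, 41)
        for sigma in (200e-20, 400e-20, 800e-20):
            expected = 1.0 - np.exp(-sigma * doses)  # independent oracle
            got = frrf.closure_fraction(doses, sigma, p=0.0)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_first_flashlet_closure(self, protocol):
        """0.12 umol photons m^-2 per flashlet at sigma=400e-20 closes ~25 %."""
        dose = protocol.flashlet_dose_quanta_m2
        assert dose == pytest.approx(0.12e-6 * Avogadro, rel=1e-12)
        c1 = frrf.closure_fraction(dose, 400e-20)
        assert c1 == pytest.approx(1.0 - np.exp(-400e-20 * dose), rel=1e-12)
        assert c1 == pytest.approx(0.251, abs=5e-4)

    def test_connectivity_slows_early_closure(self, protocol):
        """Excitonic connectivity drains excitation to open neighbours, so the
        early rise is faster per remaining open center but the curve reaches
        saturation later than the Poisson limit at matched sigma."""
        doses = protocol.flashlet_dose_quanta_m2 * np.arange(1, 41)
        c0 = frrf.closure_fraction(doses, 400e-20, p=0.0)
        cp = frrf.closure_fraction(doses, 400e-20, p=0.4)
        assert np.all(np.diff(cp) > 0)
        assert cp[0] < c0[0]  # (1-p) prefactor dominates at C ~ 0

    def test_monotone_and_bounded(self, protocol):
        doses = protocol.flashlet_dose_quanta_m2 * np.arange(1, 41)
        for p in (0.0, 0.3, 0.59):
            c = frrf.closure_fraction(doses, 800e-20, p=p, c0=0.2)
            assert np.all((c >= 0.2) & (c < 1.0))
            assert np.all(np.diff(c) > 0)


class TestFitInduction:
    def test_noiseless_recovery(self, protocol, truth):
        trace = make_trace(protocol, truth, light_state="dark").induction
        fit = frrf.fit_induction(trace)
        assert fit.converged
        assert fit.sigma_psii == pytest.approx(truth.sigma_psii, rel=1e-6)
        assert fit.f0 == pytest.approx(truth.f0, rel=1e-6)
        assert fit.fm == pytest.approx(truth.fm, rel=1e-6)
        assert fit.connectivity_p == pytest.approx(truth.connectivity_p, abs=1e-6)

    def test_fitted_curve_matches_poisson_oracle(self, protocol, truth):
        """With p fixed at 0 the fitted model reproduces 1 - exp(-sigma E)."""
        t = copy.copy(truth)
        t.connectivity_p = 0.0
        trace = make_trace(protocol, t, light_state="dark").induction
        fit = frrf.fit_induction(trace, fix_p=0.0)
        cum = trace.cumulative_dose
        fitted = frrf.induction_fluorescence(cum, fit.f0, fit.fm, fit.sigma_psii, 0.0)
        oracle = t.f0 + (t.fm - t.f0) * (1.0 - np.exp(-t.sigma_psii * 1e-20 * cum))
        np.testing.assert_allclose(fitted, oracle, rtol=1e-9)

    def test_actinic_state_baseline_recovery(self, protocol, truth):
        """The light-state fit recovers sigma', FM' and the steady-state
        closure through the free initial-closure parameter."""
        rec = make_trace(protocol, truth, light_state="actinic", actinic_umol=180.0)
        fit = frrf.fit_induction(rec.induction, fix_p=truth.connectivity_p,
                                 fit_initial_closure=True)
        assert fit.sigma_psii == pytest.approx(truth.sigma_prime, rel=1e-6)
        assert fit.fm == pytest.approx(truth.fm_prime, rel=1e-6)
        css = truth.steady_state_closure(180.0)
        assert fit.initial_closure == pytest.approx(css, abs=1e-6)
        fs_true = truth.f0_prime + (truth.fm_prime - truth.f0_prime) * css
        assert fit.fs == pytest.approx(fs_true, rel=1e-6)

    def test_too_few_points_rejected(self, protocol, truth):
        trace = make_trace(protocol, truth, light_state="dark").induction
        short = frrf.FlashletTrace(
            phase="induction",
            time_s=trace.time_s[:8],
            excitation_umol_m2_s=trace.excitation_umol_m2_s[:8],
            fluorescence=trace.fluorescence[:8],
        )
        with pytest.raises(FrrFitError, match=">= 10"):
            frrf.fit_induction(short)

    def test_relaxation_trace_rejected(self, protocol, truth):
        rec = make_trace(protocol, truth, light_state="dark")
        with pytest.raises(FrrFitError, match="induction"):
            frrf.fit_induction(rec.relaxation)

    def test_dark_fm_exceeds_actinic_fm_prime(self, protocol, truth):
        """Dark-adapted FM bounds the quenched light-state FM' from above."""
        dark = frrf.fit_induction(make_trace(protocol, truth, light_state="dark").induction)
        light = frrf.fit_induction(
            make_trace(protocol, truth, light_state="actinic", actinic_umol=180.0).induction,
            fix_p=dark.connectivity_p, fit_initial_closure=True,
        )
        assert dark.fm >= light.fm


class TestFitRelaxation:
    def test_noiseless_biphasic_recovery(self, protocol, truth):
        t = copy.copy(truth)
        t.tau1_s, t.tau2_s, t.amp1, t.amp2 = 400e-6, 5e-3, 0.7, 0.3
        rec = make_trace(protocol, t, light_state="dark")
        fit = frrf.fit_relaxation(rec.relaxation, frrf.fit_induction(rec.induction))
        assert fit.tau1 == pytest.approx(400e-6, rel=1e-6)
        assert fit.tau2 == pytest.approx(5e-3, rel=1e-6)
        assert fit.amp1 == pytest.approx(0.7, abs=1e-6)
        assert fit.amp1 + fit.amp2 == pytest.approx(1.0, abs=1e-12)
        assert fit.tau1 <= fit.tau2

    def test_single_exponential_degeneracy_flag(self, protocol, truth):
        t = copy.copy(truth)
        t.amp1, t.amp2 = 1.0, 0.0
        rec = make_trace(protocol, t, light_state="dark")
        fit = frrf.fit_relaxation(rec.relaxation, frrf.fit_induction(rec.induction))
        assert "single_exponential" in fit.flags
        assert fit.amp2 == 0.0
        assert fit.tau1 == pytest.approx(t.tau1_s, rel=1e-6)


class TestDerivedQuantities:
    def test_fv_fm_values(self):
        assert frrf.compute_fv_fm(1.0, 1.0) == 0.0
        assert frrf.compute_fv_fm(0.42, 1.0) == pytest.approx(0.58, rel=1e-12)
        # scale invariance
        assert frrf.compute_fv_fm(0.84, 2.0) == pytest.approx(0.58, rel=1e-12)

    def test_fv_fm_rejects_bad_inputs(self):
        with pytest.raises(FrrFitError):
            frrf.compute_fv_fm(0.5, 0.0)
        with pytest.raises(FrrFitError):
            frrf.compute_fv_fm(1.2, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(f0=st.floats(0.01, 1.0), gain=st.floats(0.1, 100.0))
    def test_fv_fm_scale_invariance(self, f0, gain):
        fm = 1.0
        a = frrf.compute_fv_fm(f0, fm)
        b = frrf.compute_fv_fm(f0 * gain, fm * gain)
        assert b == pytest.approx(a, rel=1e-9)

    def test_f0_prime_correction(self):
        # no 2-s recovery: correction is the identity
        assert frrf.correct_f0_prime(0.5, 1.0, 1.0) == pytest.approx(0.5)
        # worked case: 0.50 * (1 - 0.1/1.1)
        expected = 0.50 * (1.0 - (1.10 - 1.00) / 1.10)
        assert frrf.correct_f0_prime(0.50, 1.00, 1.10) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.454545, abs=1e-6)
        assert frrf.correct_f0_prime(0.0, 1.0, 1.1) == 0.0

    def test_qp_endpoints_and_worked_case(self):
        assert frrf.compute_qp(0.6, 1.2, 0.6) == pytest.approx(1.0)
        assert frrf.compute_qp(1.2, 1.2, 0.6) == pytest.approx(0.0)
        assert frrf.compute_qp(0.8, 1.2, 0.6) == pytest.approx(2.0 / 3.0, rel=1e-12)
        with pytest.raises(FrrFitError):
            frrf.compute_qp(0.5, 0.6, 0.7)

    def test_qp_outside_unit_interval_warns_not_clips(self):
        with pytest.warns(UserWarning, match="outside"):
            qp = frrf.compute_qp(0.55, 1.0, 0.6)
        assert qp > 1.0

    def test_etr_worked_case(self):
        expected = 500e-20 * (180e-6 * Avogadro) * 0.5  # independent chain
        got = frrf.compute_etr(500.0, 180.0, 0.5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(271.0, abs=0.1)
        assert frrf.compute_etr(500.0, 180.0, 0.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(sigma=st.floats(10.0, 3000.0), irr=st.floats(1.0, 2000.0),
           qp=st.floats(0.0, 1.0), k=st.floats(0.1, 10.0))
    def test_etr_linearity(self, sigma, irr, qp, k):
        base = frrf.compute_etr(sigma, irr, qp)
        assert frrf.compute_etr(sigma * k, irr, qp) == pytest.approx(k * base, rel=1e-9)
        assert frrf.compute_etr(sigma, irr * k, qp) == pytest.approx(k * base, rel=1e-9)

    def test_derive_photophysiology_round_trip(self, protocol, truth):
        dark = make_trace(protocol, truth, light_state="dark")
        dark_fit = frrf.fit_relaxation(dark.relaxation, frrf.fit_induction(dark.induction))
        light = make_trace(protocol, truth, light_state="actinic", actinic_umol=180.0)
        light_fit = frrf.fit_induction(light.induction, fix_p=dark_fit.connectivity_p,
                                       fit_initial_closure=True)
        light2s_fit = frrf.fit_induction(light.induction_2s, fix_p=dark_fit.connectivity_p)
        photo = frrf.derive_photophysiology(dark_fit, light_fit, light2s_fit, 180.0)
        assert photo.fv_fm == pytest.approx(0.58, rel=1e-6)
        assert photo.f0_prime == pytest.approx(truth.f0_prime, rel=1e-6)
        assert photo.qp == pytest.approx(truth.qp_true(180.0), rel=1e-6)
        assert photo.etr == pytest.approx(truth.etr_true(180.0), rel=1e-6)
        assert photo.inv_tau1 == pytest.approx(1.0 / truth.tau1_s, rel=1e-6)


class TestTraceIO:
    def test_recording_round_trip(self, protocol, truth, tmp_path):
        rec = make_trace(protocol, truth, light_state="actinic", actinic_umol=90.0)
        path = tmp_path / "rec.csv"
        frrf.write_recording(rec, path)
        back = frrf.read_recording(path)
        np.testing.assert_allclose(back.induction.fluorescence,
                                   rec.induction.fluorescence, rtol=1e-10)
        assert back.induction_2s is not None
        assert back.relaxation is None
        assert back.induction.actinic_umol_m2_s == pytest.approx(90.0)

    def test_trace_validation(self):
        with pytest.raises(FrrFitError, match="increasing"):
            frrf.FlashletTrace("induction", [1.0, 1.0], [1e5, 1e5], [0.5, 0.6])
        with pytest.raises(FrrFitError, match="> 0"):
            frrf.FlashletTrace("induction", [1.0, 2.0], [1e5, 1e5], [0.5, -0.1])
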