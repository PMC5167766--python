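"""Generator contracts: protocol constants, round trips, determinism."""
import copy
import json

import numpy as np
import pytest

from phytoalloc import frrf, quantify, synthdata
from phytoalloc.synthdata import (
    FrrProtocol,
    NoiseModel,
    ScenarioConfig,
    StudyConfig,
    SynthError,
    default_study_config,
    gen_absorbance,
    gen_blot_table,
    gen_frr_trace,
    gen_study,
    gen_turbidostat_log,
)


class TestProtocol:
    def test_default_flashlet_train(self, protocol):
        assert protocol.n_flashlets == 40
        assert protocol.flashlet_duration_s == pytest.approx(1.2e-6)
        times = protocol.flashlet_times_s
        assert len(times) == 40
        assert times[-1] == pytest.approx(128e-6)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(SynthError, match="fit"):
            FrrProtocol(n_flashlets=200)  # 200 x 1.2 us > 128 us
        with pytest.raises(SynthError, match="increasing"):
            FrrProtocol(relaxation_start_s=0.1, relaxation_window_s=1e-4)


class TestFrrTraceGeneration:
    def test_induction_has_one_point_per_flashlet(self, protocol, truth):
        rec = gen_frr_trace(protocol, truth, "dark")
        assert len(rec.induction.fluorescence) == 40
        assert len(rec.relaxation.fluorescence) == protocol.n_relaxation

    def test_flat_trace_when_no_variable_fluorescence(self, protocol, truth):
        t = copy.copy(truth)
        t.f0 = t.fm = 0.5
        rec = gen_frr_trace(protocol, t, "dark")
        np.testing.assert_allclose(rec.induction.fluorescence, 0.5, rtol=1e-12)

    def test_actinic_baseline_at_steady_state(self, protocol, truth):
        rec = gen_frr_trace(protocol, truth, "actinic", actinic_umol=180.0)
        css = truth.steady_state_closure(180.0)
        fs = truth.f0_prime + (truth.fm_prime - truth.f0_prime) * css
        first = rec.induction.fluorescence[0]
        # the first flashlet has already deposited one dose above FS
        assert first > fs
        assert rec.induction_2s is not None

    def test_noise_reproducible(self, protocol, truth):
        a = gen_frr_trace(protocol, truth, "dark", noise_cv=0.02, seed=5)
        b = gen_frr_trace(protocol, truth, "dark", noise_cv=0.02, seed=5)
        np.testing.assert_array_equal(a.induction.fluorescence, b.induction.fluorescence)


class TestTurbidostatGeneration:
    def test_dilution_ratio_exact(self, truth):
        log = gen_turbidostat_log(truth, sampling_interval_s=30.0)
        events = log.annotated_dilutions
        assert len(events) >= 12
        # OD immediately after vs before each event: exactly 1/1.1 in truth
        for e in events[:5]:
            pre = np.max(log.od680[log.time_h < e])
            post = log.od680[np.searchsorted(log.time_h, e)]
            assert post / pre == pytest.approx(1.0 / 1.1, rel=2e-3)

    def test_noiseless_segments_are_exact_exponentials(self, truth):
        log = gen_turbidostat_log(truth)
        events = log.annotated_dilutions
        inside = (log.time_h > 0) & (log.time_h < events[0])
        t = log.time_h[inside] / 24.0
        y = np.log(log.od680[inside])
        slope = np.polyfit(t, y, 1)[0]
        assert slope == pytest.approx(truth.mu_day, rel=1e-9)

    def test_zero_growth_flagged_without_events(self, truth):
        t = copy.copy(truth)
        t.mu_day = 0.0
        log = gen_turbidostat_log(t)
        assert len(log.annotated_dilutions) == 0
        assert "no_growth" in log.flags

    def test_study_duration_matches_run_length_scale(self, truth):
        """~160-200 h runs at slow growth hold about 9-12 regrowth cycles."""
        t = copy.copy(truth)
        t.mu_day = 0.13
        log = gen_turbidostat_log(t, duration_h=180.0, sampling_interval_s=120.0)
        assert 9 <= len(log.annotated_dilutions) <= 12
        assert "short_run" in log.flags


class TestBlotGeneration:
    def test_ladders_match_protocol(self, truth):
        rbcl = gen_blot_table(truth, "RbcL")
        assert tuple(rbcl.standards["amount_fmol"]) == (1500.0, 750.0, 375.0, 187.5)
        assert rbcl.load_ug == 0.5
        psba = gen_blot_table(truth, "PsbA")
        assert tuple(psba.standards["amount_fmol"]) == (125.0, 62.5, 31.25, 15.625)
        assert psba.load_ug == 1.0

    def test_sample_lane_amount_unit_chain(self, truth):
        """8.68 amol/cell at 4.49 pg protein/cell in a 0.5 ug lane ~ 966 fmol."""
        t = copy.copy(truth)
        t.composition.rbcl_amol = 8.68
        t.composition.protein_pg = 4.49
        table = gen_blot_table(t, "RbcL", gain=2.0)
        # independent hand chain: (amol -> mol)/(pg -> g) * g loaded -> fmol
        expected = (8.68e-18 / 4.49e-12) * 0.5e-6 * 1e15
        assert expected == pytest.approx(966.6, abs=0.1)
        sample_signal = table.samples["signal"].iloc[0]
        assert sample_signal / 2.0 == pytest.approx(expected, rel=1e-12)

    def test_zero_gain_breaks_downstream_calibration(self, truth):
        table = gen_blot_table(truth, "RbcL", gain=0.0)
        assert (table.lanes["signal"] == 0).all()
        with pytest.raises(quantify.CalibrationError):
            quantify.fit_standard_curve(table)


class TestAbsorbanceGeneration:
    def test_blank_when_no_chlorophyll(self, truth):
        t = copy.copy(truth)
        t.composition.chla_pg = 0.0
        r = gen_absorbance(t)
        assert r.a664 - r.a750 == pytest.approx(0.0, abs=1e-15)
        assert r.a630 - r.a750 == pytest.approx(0.0, abs=1e-15)

    def test_round_trip_recovers_chla(self, truth):
        r = gen_absorbance(truth)
        conc = quantify.chl_a_concentration(r)
        back = quantify.chl_a_per_cell(conc, r)
        assert back == pytest.approx(truth.composition.chla_pg, rel=1e-12)

    def test_noisy_recovery_within_propagated_error(self, truth):
        """Monte-Carlo: additive absorbance noise propagates linearly through
        the chlorophyll equation; recovery is unbiased within 3 SE."""
        sd = 0.005
        vals = []
        for seed in range(1000):
            r = gen_absorbance(truth, noise_sd=sd, seed=seed)
            vals.append(quantify.chl_a_per_cell(quantify.chl_a_concentration(r), r))
        vals = np.asarray(vals)
        # per-reading sd of the concentration: coefficients (11.47, -0.4, -11.07)
        conc_sd = sd * np.hypot(np.hypot(11.47, 0.4), 11.47 - 0.4)
        cells = truth.cell_density_per_ml * truth.filtered_volume_ml
        pg_sd = conc_sd * 10.0 * 0.45 / cells * 1e6
        se = pg_sd / np.sqrt(len(vals))
        assert abs(vals.mean() - truth.composition.chla_pg) < 3 * se


class TestStudyBundles:
    def test_full_design_counts(self, tmp_path):
        cfg = default_study_config(seed=1, noise=NoiseModel.zero(), n_replicates=3)
        bundle = gen_study(cfg, tmp_path / "s")
        assert len(bundle.runs) == 36  # 2 species x 2 N x 3 lights x 3 reps
        assert len(list((tmp_path / "s").glob("*/frr_dark.csv"))) == 36
        # 3-4 replicates can reach the study's 39 separate runs
        n4 = sum(
            sc.n_replicates
            for sc in default_study_config(n_replicates=4).scenarios
            for _ in synthdata.SPECIES_LIGHTS[sc.species]
        )
        assert len(bundle.runs) <= 39 <= n4

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = default_study_config(seed=9, n_replicates=1)
        gen_study(cfg, tmp_path / "a")
        gen_study(default_study_config(seed=9, n_replicates=1), tmp_path / "b")
        for name in ("manifest.json", "runs.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        run = json.loads((tmp_path / "a" / "manifest.json").read_text())["runs"]
        some_run = sorted(run)[0]
        fa = (tmp_path / "a" / some_run / "frr_dark.csv").read_bytes()
        fb = (tmp_path / "b" / some_run / "frr_dark.csv").read_bytes()
        assert fa == fb

    def test_duplicate_run_ids_rejected(self, tmp_path):
        sc = ScenarioConfig(synthdata.SMALL_DIATOM, "HN", n_replicates=2)
        cfg = StudyConfig(scenarios=[sc, sc], seed=0)
        with pytest.raises(SynthError, match="duplicate"):
            gen_study(cfg, tmp_path / "dup")

    def test_manifest_carries_truth(self, zero_noise_bundle):
        run_id = zero_noise_bundle.runs["run_id"].iloc[0]
        truth = zero_noise_bundle.manifest["runs"][run_id]["truth"]
        assert truth["fm"] > truth["f0"] > 0
        assert "derived" in truth and "turnover_c_per_rbcl_s" in truth["derived"]
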