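"""Synthetic generators: determinism, planted truth, moment checks."""

import numpy as np
import pandas as pd
import pytest

from utrtune import bioprocess, synth


class TestFlowSim:
    def test_determinism(self):
        cfg = synth.FlowSimConfig(n_events=2000, seed=5)
        a = synth.simulate_flow_sample(cfg)
        b = synth.simulate_flow_sample(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_labels_partition_events(self):
        cfg = synth.FlowSimConfig(n_events=10_000, seed=1)
        t = synth.simulate_flow_sample(cfg)
        assert len(t) == 10_000
        counts = t["truth_label"].value_counts()
        assert set(counts.index) <= {"transfected", "untransfected",
                                     "debris", "doublet"}
        assert counts.sum() == len(t)

    def test_configured_fractions(self):
        cfg = synth.FlowSimConfig(n_events=50_000, debris_fraction=0.1,
                                  doublet_fraction=0.05,
                                  transfected_fraction=0.5, seed=2)
        t = synth.simulate_flow_sample(cfg)
        counts = t["truth_label"].value_counts(normalize=True)
        assert counts["debris"] == pytest.approx(0.1, abs=1e-3)
        assert counts["doublet"] == pytest.approx(0.05, abs=1e-3)

    def test_bfp_moments_match_config(self):
        # push the dose far above the autofluorescence floor so the
        # channel is the configured lognormal to within 3 SE
        cfg = synth.FlowSimConfig(n_events=60_000, transfected_fraction=1.0,
                                  debris_fraction=0.0, doublet_fraction=0.0,
                                  channel_noise_cv=0.0,
                                  bfp_log_mean=float(np.log(2e5)), seed=3)
        t = synth.simulate_flow_sample(cfg)
        logs = np.log(t["bfp"])
        se = cfg.bfp_log_sd / np.sqrt(len(t))
        assert abs(logs.mean() - cfg.bfp_log_mean) < 3 * se + 1e-3
        assert abs(logs.std() - cfg.bfp_log_sd) < 0.01

    def test_noise_free_unit_dosage_constant_ratio(self):
        cfg = synth.FlowSimConfig(n_events=500, transfected_fraction=1.0,
                                  debris_fraction=0.0, doublet_fraction=0.0,
                                  channel_noise_cv=0.0, dosage=1.0, seed=4)
        t = synth.simulate_flow_sample(cfg)
        # with noise off, rfp/bfp differs from 1 only through the small
        # autofluorescence floors
        ratio = t["rfp"] / t["bfp"]
        assert np.median(ratio) == pytest.approx(1.0, rel=0.1)

    def test_invalid_fractions_error(self):
        with pytest.raises(ValueError):
            synth.FlowSimConfig(debris_fraction=0.7, doublet_fraction=0.5)
        with pytest.raises(ValueError):
            synth.FlowSimConfig(dosage=-0.1)


class TestQpcrSim:
    def test_planted_ddct_offset(self):
        cts = synth.simulate_qpcr({"A": 0.25}, ct_sd=0.0, seed=0)
        mean = cts.groupby(["sample", "gene"])["ct"].mean()
        # rel 0.25 -> target CT 2 cycles later than the control's
        assert (mean["A", "RFP"] - mean["CMV", "RFP"]) == pytest.approx(2.0)
        assert mean["A", "GAPDH"] == pytest.approx(mean["CMV", "GAPDH"])

    def test_replicates_and_determinism(self):
        a = synth.simulate_qpcr({"A": 0.5}, replicates=3, seed=1)
        b = synth.simulate_qpcr({"A": 0.5}, replicates=3, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert (a.groupby(["sample", "gene"])["ct"].size() == 3).all()

    def test_bad_args(self):
        with pytest.raises(ValueError):
            synth.simulate_qpcr({"A": 0.5}, replicates=1)
        with pytest.raises(ValueError):
            synth.simulate_qpcr({"A": 0.5}, ct_sd=-1.0)
        with pytest.raises(ValueError):
            synth.simulate_qpcr({"A": 0.0})


class TestBatchSim:
    def test_zero_qp_flat_titer(self):
        b = synth.simulate_batch(synth.BatchSimConfig(qp_true=0.0, noise_cv=0.0))
        assert (b["titer"] == 0.0).all()

    def test_constant_vcd_closed_form(self):
        cfg = synth.BatchSimConfig(days=tuple(range(0, 9)), vcd0=5e6,
                                   vcd_max=5.0000001e6, growth_rate=0.0,
                                   qp_true=2.0, noise_cv=0.0)
        b = synth.simulate_batch(cfg)
        # titer(t) = qp * vcd * t * 1e-6
        expected = 2.0 * 5e6 * b["day"] * 1e-6
        assert np.allclose(b["titer"], expected)

    def test_qp_recovery_across_seeds(self):
        errs = []
        for seed in range(20):
            b = synth.simulate_batch(synth.BatchSimConfig(qp_true=2.0,
                                                          noise_cv=0.02,
                                                          seed=seed))
            qp = bioprocess.specific_productivity(b)
            errs.append(abs(qp - 2.0) / 2.0)
        errs = np.array(errs)
        assert np.median(errs) < 0.05
        assert errs.max() < 0.15

    def test_truth_recorded(self):
        b = synth.simulate_batch(synth.BatchSimConfig(seed=0))
        assert b.attrs["truth"]["qp_true"] == 2.0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            synth.BatchSimConfig(vcd0=7e6, vcd_max=6e6)


class TestChromatogramSim:
    def test_single_peak(self):
        c = synth.simulate_chromatogram([1.0], centers=(12.0,), widths=(0.5,))
        assert c.attrs["truth"]["fractions_pct"] == [100.0]

    def test_determinism(self):
        a = synth.simulate_chromatogram((0.05, 0.9, 0.05), noise_sd=0.01, seed=3)
        b = synth.simulate_chromatogram((0.05, 0.9, 0.05), noise_sd=0.01, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_percent_input_normalized(self):
        c = synth.simulate_chromatogram((5, 90, 5))
        assert c.attrs["truth"]["fractions_pct"] == pytest.approx([5, 90, 5])

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_chromatogram((-0.1, 1.1))


class TestGelSim:
    def test_two_lanes_and_windows(self):
        lanes, windows = synth.simulate_gel_lanes(
            [{"fs": 10.0, "2HC": 10.0}, {"fs": 120.0, "2HC": 10.0}], seed=1)
        assert len(lanes) == 2
        assert set(windows) == set(synth.GEL_BAND_POSITIONS)

    def test_determinism(self):
        a, _ = synth.simulate_gel_lanes([{"fs": 10.0}], noise_sd=0.05, seed=2)
        b, _ = synth.simulate_gel_lanes([{"fs": 10.0}], noise_sd=0.05, seed=2)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_unknown_species(self):
        with pytest.raises(ValueError):
            synth.simulate_gel_lanes([{"mystery": 1.0}])


class TestDoseResponseSim:
    def test_noise_free_piecewise_exact(self):
        cfg = synth.DoseResponseSimConfig(noise_sd=0.0, qp_noise_sd=0.0)
        d = synth.simulate_sumf1_dose_response(cfg)
        lv = np.asarray(cfg.sumf1_levels)
        assert np.allclose(d["specific_activity"],
                           4.5 * np.minimum(lv / 0.4, 1.0))
        assert np.allclose(d["qp"], 2.0 - 1.2 * lv)

    def test_breakpoint_outside_range_rejected(self):
        with pytest.raises(ValueError):
            synth.DoseResponseSimConfig(sumf1_levels=(0.5, 0.8), breakpoint=0.4)

    def test_determinism(self):
        a = synth.simulate_sumf1_dose_response(synth.DoseResponseSimConfig(seed=4))
        b = synth.simulate_sumf1_dose_response(synth.DoseResponseSimConfig(seed=4))
        pd.testing.assert_frame_equal(a, b)


class TestAsaAssaySim:
    def test_zero_activity_blank_readings(self):
        assay = synth.simulate_asa_assay(0.0, 0.5)
        a515 = [r[1] for r in assay.readings]
        assert np.allclose(a515, a515[0])

    def test_planted_rate_closed_form(self):
        assay = synth.simulate_asa_assay(4.5, 0.5, std_curve=(0.012, 0.04))
        # rate = 4.5 U/mg * 0.5 mg/mL * 0.1 mL * 1e3 = 225 nmol/min
        t0, a0 = assay.readings[0]
        t1, a1 = assay.readings[1]
        assert (a1 - a0) / (t1 - t0) == pytest.approx(0.012 * 225.0)

    def test_determinism_with_noise(self):
        a = synth.simulate_asa_assay(2.0, 0.5, noise_sd=0.01, seed=6)
        b = synth.simulate_asa_assay(2.0, 0.5, noise_sd=0.01, seed=6)
        assert a.readings == b.readings


def test_write_with_truth_sidecar(tmp_path):
    b = synth.simulate_batch(synth.BatchSimConfig(seed=0))
    path = tmp_path / "batch.csv"
    synth.write_with_truth(b, path)
    assert path.exists()
    import json
    truth = json.loads((tmp_path / "batch.csv.truth.json").read_text())
    assert truth["qp_true"] == 2.0
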