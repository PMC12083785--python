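"""The synthetic study generator: determinism, truth consistency, physiology."""

import numpy as np
import pytest

from apneagram.intervals import contains
from apneagram import synth
from tests.conftest import clean_synth_config


class TestSimulateRr:
    def test_no_events_low_rr_variability(self):
        sim = synth.simulate_rr(clean_synth_config(duration_h=0.5))
        rr = np.diff(sim.times)
        assert rr.std() / rr.mean() < 0.10
        assert sim.events == []

    def test_cvhr_brady_then_tachy(self):
        cfg = clean_synth_config(duration_h=1.0, target_ahi=20.0, seed=3)
        sim = synth.simulate_rr(cfg)
        assert len(sim.events) > 5
        for ev in sim.events:
            t = sim.times
            rr = np.diff(t, prepend=t[0] - 0.85)
            pre = rr[(t >= ev.start - 10) & (t < ev.start)]
            last_third = rr[(t >= ev.end - ev.duration / 3) & (t < ev.end)]
            post = rr[(t > ev.end) & (t <= ev.end + 4.0)]
            assert last_third.mean() > pre.mean()
            assert post.mean() < pre.mean()

    def test_event_count_matches_target(self):
        cfg = clean_synth_config(duration_h=6.0, target_ahi=30.0, seed=5)
        sim = synth.simulate_rr(cfg)
        assert abs(len(sim.events) - 180) <= 2

    def test_events_only_in_sleep_and_spaced(self):
        cfg = synth.SynthConfig(duration_h=4.0, target_ahi=25.0, seed=9,
                                ectopic_rate_per_h=0.0)
        sim = synth.simulate_rr(cfg)
        starts = np.array([e.start for e in sim.events])
        ends = np.array([e.end for e in sim.events])
        assert contains(sim.sleep_blocks, starts).all()
        assert contains(sim.sleep_blocks, ends - 1e-6).all()
        assert (starts[1:] - ends[:-1] >= cfg.min_event_gap_s - 1e-9).all()

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_rr(clean_synth_config(duration_h=1.0, target_ahi=110.0))

    def test_truth_events_satisfy_scoring_rules(self):
        sim = synth.simulate_rr(clean_synth_config(duration_h=2.0, target_ahi=35.0, seed=2))
        for a, b in zip(sim.events, sim.events[1:]):
            assert a.end <= b.start
        for e in sim.events:
            assert e.duration >= 10.0
            assert e.kind in ("apnea", "hypopnea")
            if e.kind == "hypopnea":
                assert e.mechanism == "unknown"


class TestWaveform:
    def test_constant_envelope_constant_amplitude(self):
        times = np.arange(1.0, 30.0, 0.85)
        rec, truth = synth.synthesize_ecg(times, fs=250.0)
        amps = [np.abs(rec.samples[int((t - 0.05) * 250):int((t + 0.05) * 250)]).max()
                for t in times]
        assert np.ptp(amps) / np.mean(amps) < 0.01

    def test_truth_times_reproduced(self):
        times = np.arange(1.0, 20.0, 0.8)
        _, truth = synth.synthesize_ecg(times, fs=400.0)
        np.testing.assert_array_equal(truth, times)

    @pytest.mark.parametrize("width", [0.06, 0.09, 0.12])
    def test_qrs_width_by_threshold_crossing(self, width):
        cfg = synth.SynthConfig(qrs_width_s=width)
        rec, times = synth.synthesize_ecg(np.array([1.0, 2.0, 3.0]), fs=400.0, cfg=cfg)
        measured = np.mean([synth.measure_qrs_width(rec, t) for t in times])
        assert measured == pytest.approx(width, abs=0.010)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            synth.synthesize_ecg(np.array([1.0, 0.5]), fs=250.0)


class TestInjectors:
    def test_zero_artifact_config_identity(self):
        cfg = clean_synth_config()
        rec, _ = synth.synthesize_ecg(np.arange(1.0, 30.0, 0.85), fs=400.0, cfg=cfg)
        out, segs = synth.inject_artifacts(rec, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert segs == []

    def test_ectopics_are_wide_tall_premature(self):
        cfg = synth.SynthConfig(duration_h=1.0, seed=4)
        sim = synth.simulate_rr(cfg)
        out = synth.inject_ectopics(sim, 10.0, np.random.default_rng(1), cfg)
        assert out.ectopic_times.size >= 8
        for t in out.ectopic_times:
            i = int(np.argmin(np.abs(out.times - t)))
            assert out.widths[i] >= 0.22
            assert out.times[i] - out.times[i - 1] < 0.6
            assert out.scales[i] >= 1.5 * np.median(out.scales[max(0, i - 5):i])

    def test_snr_is_respected(self):
        cfg = clean_synth_config(duration_h=0.1, snr_db=15.0)
        rec, _ = synth.synthesize_ecg(np.arange(1.0, 300.0, 0.85), fs=400.0, cfg=cfg)
        out, _ = synth.inject_artifacts(rec, cfg, np.random.default_rng(2))
        noise = out.samples - rec.samples
        snr = 10 * np.log10(np.mean(rec.samples**2) / np.mean(noise**2))
        assert snr == pytest.approx(15.0, abs=0.5)


class TestGenerateStudy:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = synth.SynthConfig(duration_h=0.2, target_ahi=20.0, seed=42,
                                wake_initial_s=0, wake_final_s=0, n_awakenings=0)
        synth.generate_study(cfg, out_dir=tmp_path / "a")
        synth.generate_study(cfg, out_dir=tmp_path / "b")
        for name in ("ecg.dat", "ecg.hea", "truth_events.csv",
                     "truth_hypnogram.csv", "truth_report.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_truth_ahi_consistency(self, noisy_event_study):
        truth = noisy_event_study.truth_report
        assert truth["ahi"] == pytest.approx(
            truth["n_events"] / truth["tst_h"], rel=1e-12
        )
        assert truth["n_events"] == truth["n_apnea"] + truth["n_hypopnea"]

    def test_identity_agreement_on_truth_cohort(self):
        from apneagram.agreement import bias_and_loa

        ahis = [synth.simulate_rr(clean_synth_config(duration_h=0.5, target_ahi=a, seed=s)).ahi
                for s, a in enumerate([0.0, 10.0, 25.0, 50.0])]
        out = bias_and_loa(ahis, ahis)
        assert (out.b, out.lh, out.ll) == (0.0, 0.0, 0.0)
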