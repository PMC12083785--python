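"""Denoising and quality-mask behaviour."""

import numpy as np
import pytest
from scipy import signal

from apneagram.config import PreprocessConfig
from apneagram.intervals import overlap_fraction, total_duration
from apneagram.io import EcgRecord
from apneagram import preprocess as pp
from apneagram.synth import synthesize_ecg


def _sine(freq, fs, dur, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestResample:
    def test_length_arithmetic(self):
        rec = EcgRecord(np.zeros(4000), fs=400.0)
        out = pp.resample_record(rec, 250.0)
        assert out.fs == 250.0
        assert out.samples.size == 2500

    def test_identity_at_target_rate(self):
        rec = EcgRecord(np.arange(100, dtype=float), fs=250.0)
        out = pp.resample_record(rec, 250.0)
        assert out.samples is rec.samples

    def test_sine_preserved(self):
        rec = EcgRecord(_sine(5.0, 400.0, 10.0), fs=400.0)
        out = pp.resample_record(rec, 250.0)
        f, p = signal.periodogram(out.samples, fs=out.fs)
        assert abs(f[np.argmax(p)] - 5.0) < 0.2
        mid = out.samples[200:-200]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)


class TestBaseline:
    def test_wander_suppressed_20db(self):
        fs = 250.0
        ecg, _ = synthesize_ecg(np.arange(1.0, 29.0, 0.8), fs=fs)
        wander = _sine(0.3, fs, ecg.duration, amp=0.3)[: ecg.samples.size]
        rec = EcgRecord(ecg.samples + wander, fs=fs)
        out = pp.remove_baseline(rec)

        def band_power(x):
            f, p = signal.periodogram(x, fs=fs)
            sel = (f > 0.15) & (f < 0.45)
            return np.trapezoid(p[sel], f[sel])

        assert band_power(out.samples) < band_power(rec.samples) / 100.0

    def test_constant_offset_removed(self):
        rec = EcgRecord(np.full(2500, 0.7), fs=250.0)
        out = pp.remove_baseline(rec)
        assert np.max(np.abs(out.samples)) < 1e-6

    def test_zeros_stay_zero(self):
        out = pp.remove_baseline(EcgRecord(np.zeros(2500), fs=250.0))
        assert not np.any(out.samples)

    def test_too_short_record_raises(self):
        with pytest.raises(ValueError):
            pp.remove_baseline(EcgRecord(np.zeros(10), fs=250.0))


class TestPowerline:
    def test_mains_attenuated(self):
        rec = EcgRecord(_sine(50.0, 250.0, 8.0), fs=250.0)
        out = pp.remove_powerline(rec)
        assert np.sqrt(np.mean(out.samples[250:-250] ** 2)) < 0.03 * np.sqrt(0.5)

    def test_passband_untouched(self):
        rec = EcgRecord(_sine(10.0, 250.0, 8.0), fs=250.0)
        out = pp.remove_powerline(rec)
        ratio = np.sqrt(np.mean(out.samples**2) / np.mean(rec.samples**2))
        assert 10 ** (-1 / 20) < ratio <= 1.0 + 1e-9

    def test_zero_in_zero_out(self):
        out = pp.remove_powerline(EcgRecord(np.zeros(1000), fs=250.0))
        assert np.allclose(out.samples, 0.0)


class TestQualityMask:
    def test_clean_ecg_mostly_good(self, clean_study, short_run_config):
        clean = pp.denoise(clean_study.record, short_run_config.preprocess)
        mask = pp.quality_mask(clean, short_run_config.preprocess)
        assert total_duration(mask.good) >= 0.95 * mask.duration

    def test_noise_segment_low_quality(self, clean_study, short_run_config):
        clean = pp.denoise(clean_study.record, short_run_config.preprocess)
        x = clean.samples.copy()
        fs = clean.fs
        s, e = 301.3, 361.3  # deliberately off the window grid
        i0, i1 = int(s * fs), int(e * fs)
        rng = np.random.default_rng(5)
        x[i0:i1] = np.std(x[i0:i1]) * rng.standard_normal(i1 - i0)
        mask = pp.quality_mask(EcgRecord(x, fs=fs), short_run_config.preprocess)
        assert overlap_fraction((s, e), mask.low_quality) >= 0.9

    def test_saturated_segment_low_quality(self, clean_study, short_run_config):
        clean = pp.denoise(clean_study.record, short_run_config.preprocess)
        x = clean.samples.copy()
        fs = clean.fs
        i0, i1 = int(123.7 * fs), int(143.7 * fs)
        x[i0:i1] = 2.0  # rail
        mask = pp.quality_mask(EcgRecord(x, fs=fs), short_run_config.preprocess)
        assert overlap_fraction((123.7, 143.7), mask.low_quality) >= 0.9

    def test_good_and_low_quality_tile_record(self, clean_study, short_run_config):
        clean = pp.denoise(clean_study.record, short_run_config.preprocess)
        mask = pp.quality_mask(clean, short_run_config.preprocess)
        assert total_duration(mask.good) + total_duration(mask.low_quality) == pytest.approx(
            mask.duration, abs=1e-6
        )

    def test_idempotent_on_good_regions(self, clean_study, short_run_config):
        clean = pp.denoise(clean_study.record, short_run_config.preprocess)
        mask = pp.quality_mask(clean, short_run_config.preprocess)
        s, e = max(mask.good, key=lambda iv: iv[1] - iv[0])
        sub = EcgRecord(clean.samples[int(s * clean.fs) : int(e * clean.fs)], fs=clean.fs)
        again = pp.quality_mask(sub, short_run_config.preprocess)
        assert total_duration(again.good) >= 0.95 * sub.duration

    def test_all_noise_record_has_no_good(self, rng):
        rec = EcgRecord(rng.standard_normal(250 * 60), fs=250.0)
        mask = pp.quality_mask(rec)
        assert mask.good == []
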