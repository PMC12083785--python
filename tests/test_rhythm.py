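"""Matching-pursuit beat detection, ectopic screening and the 4 h gate."""

import numpy as np
import pytest

from apneagram.config import RhythmConfig
from apneagram.io import EcgRecord
from apneagram.preprocess import SegmentSet, denoise
from apneagram import rhythm
from apneagram.synth import SynthConfig, synthesize_ecg


def _beat(r, width=0.09, height=1.0, rr=0.85):
    return rhythm.Beat(
        qrs_onset=r - width / 2, r_peak=r, qrs_offset=r + width / 2,
        height=height, width=width, rr_prev=rr,
    )


def _series(specs):
    """Beats from (rr, width, height) triples laid head-to-tail."""
    beats, t = [], 0.0
    for rr, width, height in specs:
        t += rr
        beats.append(_beat(t, width=width, height=height, rr=rr))
    beats[0].rr_prev = None
    return rhythm.BeatSeries(beats)


class TestDictionary:
    def test_atoms_unit_norm(self):
        d = rhythm.build_qrs_dictionary(250.0)
        for atom in d.atoms:
            assert np.linalg.norm(atom.waveform) == pytest.approx(1.0, abs=1e-9)

    def test_width_coverage(self):
        d = rhythm.build_qrs_dictionary(250.0)
        widths = [a.width_s for a in d.atoms]
        assert min(widths) <= 0.04 and max(widths) >= 0.2

    def test_no_duplicate_atoms(self):
        d = rhythm.build_qrs_dictionary(250.0)
        # pairwise peak cross-correlation below 1 for distinct atoms
        assert rhythm.dictionary_coherence(d) < 1.0 - 1e-6

    def test_empty_widths_rejected(self):
        with pytest.raises(ValueError):
            rhythm.build_qrs_dictionary(250.0, widths=())


class TestDetectBeats:
    def test_clean_record_all_beats_found(self, clean_study, short_run_config):
        clean = denoise(clean_study.record, short_run_config.preprocess)
        bs = rhythm.detect_beats(clean, cfg=short_run_config.rhythm)
        truth = clean_study.beats.times
        det = bs.r_times
        matched = np.array([np.min(np.abs(det - t)) <= 0.02 for t in truth])
        spurious = np.array([np.min(np.abs(truth - t)) > 0.02 for t in det])
        assert matched.mean() >= 0.98
        assert spurious.mean() <= 0.02

    def test_all_zero_signal_empty(self):
        bs = rhythm.detect_beats(EcgRecord(np.zeros(2500), fs=250.0))
        assert len(bs) == 0

    def test_single_complex_single_beat(self):
        rec, times = synthesize_ecg(np.array([2.0]), fs=250.0)
        bs = rhythm.detect_beats(rec)
        assert len(bs) == 1
        b = bs.beats[0]
        assert b.qrs_onset < b.r_peak < b.qrs_offset
        assert abs(b.r_peak - 2.0) <= 0.02

    def test_fiducials_ordered(self, clean_study, short_run_config):
        clean = denoise(clean_study.record, short_run_config.preprocess)
        bs = rhythm.detect_beats(clean, cfg=short_run_config.rhythm)
        for b in bs.beats:
            assert b.qrs_onset < b.r_peak < b.qrs_offset


class TestEctopicCriteria:
    def test_wide_qrs_flagged(self):
        bs = _series([(0.85, 0.09, 1.0)] * 3 + [(0.85, 0.22, 1.0)])
        out = rhythm.flag_abnormal_beats(bs)
        assert out.beats[-1].reasons == {"width"}

    def test_short_rr_flagged(self):
        bs = _series([(0.85, 0.09, 1.0)] * 3 + [(0.5, 0.09, 1.0)])
        out = rhythm.flag_abnormal_beats(bs)
        assert out.beats[-1].reasons == {"rr"}

    def test_long_rr_flagged(self):
        bs = _series([(0.85, 0.09, 1.0)] * 3 + [(1.3, 0.09, 1.0)])
        out = rhythm.flag_abnormal_beats(bs)
        assert out.beats[-1].reasons == {"rr"}

    def test_tall_beat_flagged_against_running_mean(self):
        bs = _series([(0.85, 0.09, 1.0)] * 12 + [(0.85, 0.09, 1.6)])
        out = rhythm.flag_abnormal_beats(bs)
        assert out.beats[-1].reasons == {"height"}

    def test_compliant_beats_never_flagged(self):
        # exercises the boundaries: width exactly 200 ms, RR exactly 0.6/1.2 s,
        # height exactly 1.5x the running mean are all compliant
        specs = [(0.85, 0.09, 1.0)] * 12
        specs += [(0.6, 0.2, 1.0), (1.2, 0.09, 1.5), (0.85, 0.1, 1.0)]
        out = rhythm.flag_abnormal_beats(_series(specs))
        assert not any(b.abnormal for b in out.beats)

    def test_height_rule_skipped_without_history(self):
        bs = _series([(0.85, 0.09, 1.0), (0.85, 0.09, 5.0)])
        out = rhythm.flag_abnormal_beats(bs)
        assert "height" not in out.beats[-1].reasons


class TestRegularSegments:
    def _quality(self, dur=1000.0):
        return SegmentSet(good=[(0.0, dur)], low_quality=[], duration=dur)

    def test_no_flags_keeps_quality_segments(self):
        bs = _series([(0.85, 0.09, 1.0)] * 20)
        out = rhythm.regular_segments(rhythm.flag_abnormal_beats(bs), self._quality())
        assert out.intervals == [(0.0, 1000.0)]

    def test_guard_arithmetic(self):
        beats = [_beat(t) for t in np.arange(1.0, 200.0, 0.85)]
        k = np.argmin(np.abs(np.array([b.r_peak for b in beats]) - 100.0))
        beats[k] = _beat(beats[k].r_peak, width=0.25)
        bs = rhythm.flag_abnormal_beats(rhythm.BeatSeries(beats))
        out = rhythm.regular_segments(bs, self._quality(200.0), guard_s=5.0)
        t0 = bs.beats[k].r_peak
        gap = [iv for iv in out.intervals if iv[1] <= t0 - 4.99][-1]
        assert gap[1] == pytest.approx(t0 - 5.0, abs=0.01)

    def test_duration_monotone_in_flags(self):
        durations = []
        for n_bad in (0, 3, 6):
            beats = [_beat(t) for t in np.arange(1.0, 500.0, 0.85)]
            for j in range(n_bad):
                idx = 50 + 100 * j
                beats[idx] = _beat(beats[idx].r_peak, width=0.25)
            bs = rhythm.flag_abnormal_beats(rhythm.BeatSeries(beats))
            seg = rhythm.regular_segments(bs, self._quality(500.0))
            durations.append(seg.total_hours)
        assert durations[0] >= durations[1] >= durations[2]


class TestGate:
    @pytest.mark.parametrize(
        "hours,expected", [(5.0, True), (3.9, False), (4.0, True), (3.99, False)]
    )
    def test_four_hour_gate(self, hours, expected):
        seg = rhythm.AnalyzableSegments(intervals=[(0.0, hours * 3600.0)],
                                        duration=8 * 3600.0)
        verdict = rhythm.enforce_min_duration(seg, min_hours=4.0)
        assert verdict.passed is expected
        if not expected:
            assert "insufficient" in verdict.reason


class TestMorphology:
    def _record_and_beats(self, style):
        cfg = SynthConfig(qrs_style=style)
        times = np.arange(1.0, 80.0, 0.85)
        rec, _ = synthesize_ecg(times, fs=250.0, cfg=cfg)
        beats = [_beat(t) for t in times]
        beats[0].rr_prev = None
        return rec, rhythm.BeatSeries(beats)

    def test_monophasic(self):
        rec, bs = self._record_and_beats("monophasic")
        label, pos, neg = rhythm.classify_qrs_morphology(bs, rec)
        assert label == "monophasic"
        assert (pos > neg).mean() > 0.9

    def test_biphasic(self):
        rec, bs = self._record_and_beats("biphasic")
        label, _, _ = rhythm.classify_qrs_morphology(bs, rec)
        assert label == "biphasic"

    def test_too_few_beats_unknown(self):
        rec, bs = self._record_and_beats("monophasic")
        small = rhythm.BeatSeries(bs.beats[:10])
        label, _, _ = rhythm.classify_qrs_morphology(small, rec)
        assert label == "unknown"
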