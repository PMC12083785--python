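"""Windowed features, clustering and event confirmation/typing."""

import numpy as np
import pytest

from apneagram.config import EventConfig
from apneagram.edr import EdrSet
from apneagram.io import EventAnnotation
from apneagram import resp_events as re_mod


def _edr(duration=600.0, grid_hz=4.0, rwa=None, hrv=None, gaps=None):
    n = int(duration * grid_hz)
    t = np.arange(n) / grid_hz
    rwa = np.ones(n) if rwa is None else rwa
    hrv = np.full(n, 0.85) if hrv is None else hrv
    gap = np.zeros(n, dtype=bool)
    for s, e in gaps or []:
        gap[(t >= s) & (t < e)] = True
    rwa = rwa.copy()
    hrv = hrv.copy()
    rwa[gap] = np.nan
    hrv[gap] = np.nan
    return EdrSet(t=t, hrv=hrv, rwa=rwa, morph=rwa.copy(), gap_mask=gap, grid_hz=grid_hz)


def _event_edr(events, duration=900.0, depth=0.95, noise=0.0, seed=0, osc=0.0):
    """Flat EDR with rectangular amplitude reductions at the given spans."""
    rng = np.random.default_rng(seed)
    n = int(duration * 4)
    t = np.arange(n) / 4.0
    rwa = np.ones(n) + noise * rng.standard_normal(n)
    hrv = 0.85 + 0.02 * np.sin(2 * np.pi * 0.22 * t) + noise * 0.1 * rng.standard_normal(n)
    for s, e in events:
        sel = (t >= s) & (t < e)
        rwa[sel] = 1.0 - depth + osc * np.sin(2 * np.pi * 0.22 * t[sel])
        hrv[sel] *= 1.1
    if osc:
        rwa += 0.08 * np.sin(2 * np.pi * 0.22 * t) * ~np.any(
            [(t >= s) & (t < e) for s, e in events], axis=0
        )
    return EdrSet(t=t, hrv=hrv, rwa=rwa, morph=rwa.copy(),
                  gap_mask=np.zeros(n, dtype=bool), grid_hz=4.0)


class TestWindowFeatures:
    def test_window_count_arithmetic(self):
        edr = _edr(duration=600.0)
        feats = re_mod.window_features(edr)
        assert len(feats) == int((600 - 60) // 10) + 1

    def test_fully_masked_returns_empty(self):
        edr = _edr(duration=300.0, gaps=[(0.0, 300.0)])
        assert len(re_mod.window_features(edr)) == 0

    def test_stationary_record_reduction_near_one(self, rng):
        n = 600 * 4
        rwa = 1.0 + 0.02 * rng.standard_normal(n)
        feats = re_mod.window_features(_edr(duration=600.0, rwa=rwa))
        assert np.all(np.abs(feats.raw[:, 0] - 1.0) < 0.1)

    def test_gap_heavy_windows_excluded(self):
        edr = _edr(duration=600.0, gaps=[(100.0, 140.0)])
        feats = re_mod.window_features(edr)
        for s, e in feats.windows:
            overlap = max(0.0, min(e, 140.0) - max(s, 100.0))
            assert overlap / 60.0 <= 0.25 + 1e-9


class TestClustering:
    def test_separated_clouds_recovered(self, rng):
        z = np.vstack([rng.normal(0, 0.3, (60, 7)), rng.normal(4, 0.3, (25, 7))])
        # abnormal cloud gets the lower reduction ratio in raw feature 0
        raw = z.copy()
        raw[:60, 0] = 1.0
        raw[60:, 0] = 0.4
        feats = re_mod.WindowFeatures(
            windows=np.column_stack([np.arange(85) * 10.0, np.arange(85) * 10.0 + 60]),
            raw=raw, z=(z - z.mean(0)) / z.std(0),
        )
        labels = re_mod.cluster_windows(feats)
        assert labels[60:].all()
        assert not labels[:60].any()

    def test_identical_vectors_all_normal(self):
        feats = re_mod.WindowFeatures(
            windows=np.column_stack([np.arange(20) * 10.0, np.arange(20) * 10.0 + 60]),
            raw=np.ones((20, 7)), z=np.zeros((20, 7)),
        )
        assert not re_mod.cluster_windows(feats).any()

    def test_too_few_windows_all_normal(self, rng):
        z = rng.normal(0, 1, (5, 7))
        feats = re_mod.WindowFeatures(
            windows=np.column_stack([np.arange(5) * 10.0, np.arange(5) * 10.0 + 60]),
            raw=z, z=z,
        )
        assert not re_mod.cluster_windows(feats).any()

    def test_affine_rescaling_invariance(self, rng):
        edr = _event_edr([(200, 230), (500, 540)], noise=0.02)
        f1 = re_mod.window_features(edr)
        edr2 = EdrSet(t=edr.t, hrv=edr.hrv * 3.0 + 1.0, rwa=edr.rwa,
                      morph=edr.morph, gap_mask=edr.gap_mask, grid_hz=4.0)
        f2 = re_mod.window_features(edr2)
        l1 = re_mod.cluster_windows(f1)
        l2 = re_mod.cluster_windows(f2)
        # hrv_mean/hrv_range scale affinely; labels must not change
        assert np.array_equal(l1, l2)


class TestCandidates:
    def _feats(self, labels):
        n = len(labels)
        return re_mod.WindowFeatures(
            windows=np.column_stack([np.arange(n) * 10.0, np.arange(n) * 10.0 + 60]),
            raw=np.zeros((n, 7)), z=np.zeros((n, 7)),
        )

    def test_no_abnormal_windows_no_candidates(self):
        labels = np.zeros(30, dtype=bool)
        assert re_mod.candidate_events(self._feats(labels), labels) == []

    def test_run_of_windows_merges(self):
        labels = np.zeros(30, dtype=bool)
        labels[5:8] = True
        out = re_mod.candidate_events(self._feats(labels), labels)
        assert out == [(50.0, 130.0)]

    def test_candidates_disjoint(self, rng):
        labels = rng.random(50) < 0.4
        out = re_mod.candidate_events(self._feats(labels), labels, dilate_s=30.0)
        assert all(a[1] <= b[0] for a, b in zip(out, out[1:]))


class TestConfirmAndType:
    def test_deep_event_is_apnea(self):
        edr = _event_edr([(400, 420)], depth=0.95, noise=0.01)
        assert re_mod.confirm_and_type(edr, (390.0, 430.0)) == "apnea"

    def test_half_depth_is_hypopnea(self):
        edr = _event_edr([(400, 415)], depth=0.5, noise=0.01)
        assert re_mod.confirm_and_type(edr, (390.0, 425.0)) == "hypopnea"

    def test_short_event_rejected(self):
        edr = _event_edr([(400, 408)], depth=0.5, noise=0.01)
        assert re_mod.confirm_and_type(edr, (390.0, 418.0)) == "reject"

    def test_shallow_event_rejected(self):
        edr = _event_edr([(400, 420)], depth=0.1, noise=0.01)
        assert re_mod.confirm_and_type(edr, (390.0, 430.0)) == "reject"

    def test_masked_flanks_rejected(self):
        edr = _edr(duration=600.0, gaps=[(200.0, 400.0)])
        assert re_mod.confirm_and_type(edr, (290.0, 310.0)) == "reject"

    def test_candidate_split_into_two_events(self):
        edr = _event_edr([(300, 325), (370, 395)], depth=0.95, noise=0.01)
        events = re_mod.refine_candidate(edr, (280.0, 410.0))
        assert len(events) == 2
        assert all(e.duration >= 10.0 for e in events)
        assert events[0].end <= events[1].start

    def test_final_events_disjoint_and_long_enough(self):
        edr = _event_edr([(200, 230), (300, 340), (500, 525)], depth=0.9, noise=0.02)
        events, _, _ = re_mod.detect_events(edr)
        assert all(e.duration >= 10.0 for e in events)
        assert all(a.end <= b.start for a, b in zip(events, events[1:]))


class TestMechanism:
    def test_obstructive_keeps_effort_band(self):
        edr = _event_edr([(400, 430)], depth=0.9, noise=0.005, osc=0.1)
        ev = EventAnnotation(400.0, 430.0, "apnea")
        assert re_mod.type_mechanism(edr, ev) == "obstructive"

    def test_central_suppresses_effort_band(self):
        edr = _event_edr([(400, 430)], depth=0.9, noise=0.005, osc=0.0)
        # flanks carry respiratory oscillation; the event does not
        edr.rwa += 0.08 * np.sin(2 * np.pi * 0.22 * edr.t) * (
            (edr.t < 400) | (edr.t >= 430)
        )
        ev = EventAnnotation(400.0, 430.0, "apnea")
        assert re_mod.type_mechanism(edr, ev) == "central"

    def test_hypopnea_stays_unknown(self):
        edr = _event_edr([(400, 430)], depth=0.5, noise=0.005)
        ev = EventAnnotation(400.0, 430.0, "hypopnea")
        assert re_mod.type_mechanism(edr, ev) == "unknown"
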