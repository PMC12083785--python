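"""Respiratory-event detection from EDR series.

Sliding 60 s windows (10 s step) are summarized by statistical and
morphological respiratory-effort features, z-scored over the record, and
split into two groups by Ward-linkage agglomerative clustering; the group
with the deeper R-wave-amplitude reduction is the abnormal-breathing one
(a silhouette guard declares the record event-free when the two groups are
not really separated). Runs of abnormal windows become candidate
intervals; each candidate is then confirmed against its 60 s flanks on the
RWA series — the amplitude-reduction depth plays the role the airflow
reduction plays in manual scoring: >= 90 % depth for at least 10 s is an
apnea, >= 30 % a hypopnea, anything shallower or shorter is rejected.
Confirmed apneas are typed obstructive/central by whether respiratory-band
(0.15-0.5 Hz) amplitude oscillation — the persisting-effort surrogate —
survives inside the event; hypopneas stay untyped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .config import EventConfig
from .edr import EdrSet
from .intervals import Interval, normalize
from .io import EventAnnotation

FEATURE_NAMES = (
    "rwa_reduction",      # window mean RWA / record median RWA
    "rwa_variance",
    "hrv_mean",
    "hrv_range",
    "cvhr_band_power",    # 0.01-0.04 Hz power of the heart-period series
    "morph_reduction",
    "hrv_rwa_corr",
)


@dataclass
class WindowFeatures:
    windows: np.ndarray        # (n, 2) start/end s
    raw: np.ndarray            # (n, 7) feature values
    z: np.ndarray              # (n, 7) record-standardized features

    def __len__(self) -> int:
        return self.windows.shape[0]


def window_features(edr: EdrSet, cfg: EventConfig | None = None) -> WindowFeatures:
    """Per-window effort features; windows with > 25 % gap are excluded."""
    cfg = cfg or EventConfig()
    fs = edr.grid_hz
    win = int(round(cfg.window_s * fs))
    step = int(round(cfg.step_s * fs))
    n = edr.t.size
    empty = WindowFeatures(np.empty((0, 2)), np.empty((0, 7)), np.empty((0, 7)))
    if n < win:
        return empty
    rwa_med = np.nanmedian(edr.rwa) if np.isfinite(edr.rwa).any() else np.nan
    morph_med = np.nanmedian(np.abs(edr.morph)) if np.isfinite(edr.morph).any() else np.nan
    rows, spans = [], []
    for s in range(0, n - win + 1, step):
        sl = slice(s, s + win)
        gap = edr.gap_mask[sl]
        if gap.mean() > cfg.max_gap_fraction:
            continue
        hrv, rwa, morph = edr.hrv[sl], edr.rwa[sl], edr.morph[sl]
        ok = ~gap
        h, r = hrv[ok], rwa[ok]
        m = morph[ok] if np.isfinite(morph).any() else np.zeros(ok.sum())
        # reduction ratios count masked samples as zero amplitude: inside a
        # deep event the R wave is undetectable, which IS the reduction
        r_full = np.where(ok, np.nan_to_num(rwa), 0.0)
        m_full = np.where(ok, np.nan_to_num(morph), 0.0)
        rows.append([
            np.mean(r_full) / rwa_med if rwa_med else np.nan,
            np.var(r),
            np.mean(h),
            np.ptp(h),
            _band_power(h, fs, 0.01, 0.04),
            (np.mean(np.abs(m_full)) / morph_med) if morph_med and np.isfinite(morph_med) else 1.0,
            _corr(h, r),
        ])
        spans.append((edr.t[s], edr.t[s] + cfg.window_s))
    if not rows:
        return empty
    raw = np.asarray(rows, dtype=float)
    raw[~np.isfinite(raw)] = 0.0
    sd = raw.std(axis=0)
    sd[sd == 0] = 1.0
    z = (raw - raw.mean(axis=0)) / sd
    return WindowFeatures(np.asarray(spans), raw, z)


def _band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    if x.size < 8:
        return 0.0
    f, p = signal.periodogram(x - x.mean(), fs=fs)
    sel = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[sel], f[sel])) if sel.any() else 0.0


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cluster_windows(
    feats: WindowFeatures, cfg: EventConfig | None = None
) -> np.ndarray:
    """Per-window labels: True = abnormal breathing."""
    cfg = cfg or EventConfig()
    n = len(feats)
    labels = np.zeros(n, dtype=bool)
    if n < cfg.min_windows:
        return labels
    z = feats.z
    if np.allclose(z, z[0]):
        return labels
    cl = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(z)
    if len(set(cl)) < 2:
        return labels
    sil = silhouette_score(z, cl)
    if sil < cfg.silhouette_min:
        return labels
    # the cluster with the deeper amplitude reduction is the abnormal one
    m0 = feats.raw[cl == 0, 0].mean()
    m1 = feats.raw[cl == 1, 0].mean()
    abnormal = 0 if m0 < m1 else 1
    labels = cl == abnormal
    # Window abnormality is a continuum (event overlap x depth), while Ward
    # isolates its extreme tail. The normal cluster, however, is tight; any
    # window far outside its own robust spread carries event signature too,
    # so expand the abnormal label by deviation-from-normal. Precision is
    # restored downstream by the depth-based confirmation.
    normal_z = z[~labels]
    c = normal_z.mean(axis=0)
    mad = np.median(np.abs(normal_z - np.median(normal_z, axis=0)), axis=0)
    s = np.maximum(1.4826 * mad, 0.05)
    d = np.sqrt(np.mean(((z - c) / s) ** 2, axis=1))
    return labels | (d > 3.0)


def candidate_events(
    feats: WindowFeatures,
    labels: np.ndarray,
    min_s: float = 10.0,
    dilate_s: float = 0.0,
) -> list[Interval]:
    """Union of abnormal windows, merged into disjoint candidate intervals.

    ``dilate_s`` widens each abnormal span before merging: the pipeline uses
    one window length, so the clustered windows act as region proposals and
    the depth-based confirmation decides the exact event extents. Without
    dilation, neighbouring events that share windows are easily truncated.
    """
    spans = [
        (w[0] - dilate_s, w[1] + dilate_s) for w, ab in zip(feats.windows, labels) if ab
    ]
    spans = [(max(s, 0.0), e) for s, e in spans]
    return [iv for iv in normalize(spans) if iv[1] - iv[0] >= min_s]


# ------------------------------------------------------------ confirmation

def _flank_baseline(edr: EdrSet, interval: Interval, cfg: EventConfig) -> float:
    """Unobstructed-amplitude reference for one candidate.

    The 60 s flank median works for isolated events but is dragged down
    when neighbouring events crowd the flanks, so the reference is the
    larger of the flank median and the 80th percentile over the candidate
    plus flanks — inter-event recoveries keep the upper quantile at the
    unobstructed level even in dense stretches.
    """
    s, e = interval
    pre = (edr.t >= s - cfg.flank_s) & (edr.t < s) & ~edr.gap_mask
    post = (edr.t >= e) & (edr.t < e + cfg.flank_s) & ~edr.gap_mask
    flanks = np.concatenate([edr.rwa[pre], edr.rwa[post]])
    whole_sel = (edr.t >= s - cfg.flank_s) & (edr.t < e + cfg.flank_s) & ~edr.gap_mask
    whole = edr.rwa[whole_sel]
    cands = []
    if flanks.size:
        cands.append(float(np.median(flanks)))
    if whole.size:
        cands.append(float(np.percentile(whole, 80)))
    return max(cands) if cands else np.nan


def _depth_series(edr: EdrSet, cfg: EventConfig) -> np.ndarray:
    k = int(round(cfg.smooth_s * edr.grid_hz))
    k += 1 - k % 2
    rwa = edr.rwa.copy()
    rwa[edr.gap_mask] = np.nan
    sm = ndimage.median_filter(np.nan_to_num(rwa, nan=np.nanmedian(rwa)), size=max(k, 1))
    sm[edr.gap_mask] = np.nan
    return sm


def refine_candidate(
    edr: EdrSet, interval: Interval, cfg: EventConfig | None = None
) -> list[EventAnnotation]:
    """Split one candidate into confirmed, typed events (possibly several).

    Inside the candidate every maximal run of amplitude-reduction depth
    above 30 % (masked gaps up to ``bridge_gap_s`` are bridged) lasting at
    least 10 s becomes one event; its depth median decides apnea vs
    hypopnea, and apneas are typed by the effort-band test.
    """
    cfg = cfg or EventConfig()
    B = _flank_baseline(edr, interval, cfg)
    if not np.isfinite(B) or B <= 0:
        return []
    sm = _depth_series(edr, cfg)
    sel = (edr.t >= interval[0]) & (edr.t < interval[1])
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return []
    depth = 1.0 - sm[idx] / B
    depth = _dropout_as_depth(depth, edr.grid_hz, cfg)
    deep = depth > cfg.depth_hypopnea          # NaN-safe: NaN compares False
    masked = ~np.isfinite(depth)
    deep_b = _bridge(deep, masked, int(round(cfg.bridge_gap_s * edr.grid_hz)))

    events: list[EventAnnotation] = []
    for i0, i1 in _runs(deep_b):
        t0 = edr.t[idx[i0]]
        t1 = edr.t[idx[i1 - 1]] + 1.0 / edr.grid_hz
        if t1 - t0 < cfg.min_event_s:
            continue
        run_depth = depth[i0:i1]
        d = float(np.nanmedian(run_depth))
        if not np.isfinite(d) or d < cfg.depth_hypopnea:
            continue
        kind = "apnea" if d >= cfg.depth_apnea else "hypopnea"
        ev = EventAnnotation(start=float(t0), end=float(t1), kind=kind)
        ev.mechanism = type_mechanism(edr, ev, cfg) if kind == "apnea" else "unknown"
        events.append(ev)
    return events


def confirm_and_type(
    edr: EdrSet, interval: Interval, cfg: EventConfig | None = None
) -> str:
    """Single-interval contract: {'apnea', 'hypopnea', 'reject'}.

    Evaluates the longest qualifying depth run inside the interval.
    """
    events = refine_candidate(edr, interval, cfg)
    if not events:
        return "reject"
    longest = max(events, key=lambda e: e.duration)
    return longest.kind


def type_mechanism(
    edr: EdrSet, event: EventAnnotation, cfg: EventConfig | None = None
) -> str:
    """Obstructive when respiratory-band RWA oscillation survives the event."""
    cfg = cfg or EventConfig()
    if event.kind != "apnea":
        return "unknown"
    lo, hi = cfg.effort_band_hz
    inside = (edr.t >= event.start) & (edr.t < event.end) & ~edr.gap_mask
    if inside.sum() < 4 * edr.grid_hz:
        return "unknown"  # dropout-dominated event: no effort evidence either way
    pre = (edr.t >= event.start - cfg.flank_s) & (edr.t < event.start) & ~edr.gap_mask
    post = (edr.t >= event.end) & (edr.t < event.end + cfg.flank_s) & ~edr.gap_mask
    p_in = _band_power(edr.rwa[inside], edr.grid_hz, lo, hi)
    p_flank = np.mean([
        _band_power(edr.rwa[m], edr.grid_hz, lo, hi) for m in (pre, post) if m.sum() >= 8
    ] or [np.nan])
    if not np.isfinite(p_flank) or p_flank <= 0:
        return "unknown"
    return "obstructive" if p_in >= cfg.effort_power_ratio * p_flank else "central"


def detect_events(edr: EdrSet, cfg: EventConfig | None = None) -> tuple[list[EventAnnotation], WindowFeatures, np.ndarray]:
    """Full stage: features -> clustering -> candidates -> confirmed events."""
    cfg = cfg or EventConfig()
    feats = window_features(edr, cfg)
    labels = cluster_windows(feats, cfg)
    events: list[EventAnnotation] = []
    for iv in candidate_events(feats, labels, cfg.min_event_s, dilate_s=cfg.dilate_s):
        events.extend(refine_candidate(edr, iv, cfg))
    events.sort(key=lambda e: e.start)
    events = _drop_overlaps(events)
    _attach_confidence(events, feats, labels)
    return events, feats, labels


def _attach_confidence(events, feats: WindowFeatures, labels: np.ndarray) -> None:
    if not len(feats) or not labels.any():
        return
    centroid = feats.z[labels].mean(axis=0)
    p = feats.z.shape[1]
    # standardized distance scaled by feature count: a window matching the
    # cluster within ~1 SD per feature maps to confidence ~0.7
    d_all = np.linalg.norm(feats.z - centroid, axis=1) / p
    for ev in events:
        overlap = (feats.windows[:, 0] < ev.end) & (feats.windows[:, 1] > ev.start)
        cover = overlap & labels
        if not cover.any():
            cover = overlap  # event sits between clustered windows: use its span
        if cover.any():
            ev.confidence = float(np.mean(1.0 / (1.0 + d_all[cover])))


def _drop_overlaps(events: list[EventAnnotation]) -> list[EventAnnotation]:
    out: list[EventAnnotation] = []
    for ev in events:
        if out and ev.start < out[-1].end:
            if ev.duration > out[-1].duration:
                out[-1] = ev
            continue
        out.append(ev)
    return out


def _dropout_as_depth(depth: np.ndarray, grid_hz: float, cfg: EventConfig) -> np.ndarray:
    """Score beat-detection dropout inside a candidate as complete reduction.

    During a deep apnea the R wave sinks under the noise floor: no beats are
    detected, the quality mask fires, and the RWA series goes undefined —
    exactly where the reduction is total. A masked run (5-90 s) is scored
    as depth 1 when a defined neighbour on at least one side shows the
    start of a decline (depth >= 0.1): the onset decline is gradual while
    the arousal recovery is abrupt, so only one informative edge can be
    expected. Masked runs bordered by normal-depth samples on both sides
    (electrode artifacts amid normal breathing) stay undefined.
    """
    out = depth.copy()
    near = int(round(8.0 * grid_hz))
    lo_run = int(round(5.0 * grid_hz))
    hi_run = int(round(90.0 * grid_hz))
    finite = np.isfinite(depth)
    for i0, i1 in _runs(~finite):
        if not lo_run <= (i1 - i0) <= hi_run:
            continue
        left = depth[max(0, i0 - near):i0]
        right = depth[i1:i1 + near]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        l_ok = left.size > 0 and left[-1] >= 0.1
        r_ok = right.size > 0 and right[0] >= 0.1
        if l_ok or r_ok:
            out[i0:i1] = 1.0
    return out


def _bridge(deep: np.ndarray, masked: np.ndarray, max_gap: int) -> np.ndarray:
    """Bridge masked gaps <= max_gap samples that are flanked by deep runs."""
    out = deep.copy()
    for i0, i1 in _runs(masked):
        if i1 - i0 <= max_gap and i0 > 0 and i1 < deep.size and deep[i0 - 1] and deep[i1]:
            out[i0:i1] = True
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))
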