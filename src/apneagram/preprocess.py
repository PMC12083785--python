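"""Denoising and signal-quality masking.

The working rate is 250 Hz. Baseline wander is removed by subtracting a
0.2 s running-median estimate; powerline interference by a zero-phase IIR
notch at the mains frequency. Quality is assessed on sliding 5 s windows by
Pearson (non-excess) kurtosis together with flat-line/saturation detection:
noise-like windows (kurtosis below ~5) and impulsive-artifact windows
(above ~80) are rejected, as are windows containing a >=0.5 s run pinned at
a constant value (unhooked or saturated electrode) or with negligible range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal, stats

from .config import PreprocessConfig
from .intervals import Interval, complement, normalize, total_duration
from .io import EcgRecord


@dataclass
class SegmentSet:
    """Tiling of a record into good and low-quality zones."""

    good: list[Interval]
    low_quality: list[Interval]
    duration: float

    def __post_init__(self) -> None:
        self.good = normalize(self.good)
        self.low_quality = normalize(self.low_quality)

    @property
    def good_duration(self) -> float:
        return total_duration(self.good)


def resample_record(rec: EcgRecord, target_fs: float = 250.0) -> EcgRecord:
    """Polyphase resampling to the working rate; identity if already there."""
    if rec.fs == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    n_target = int(round(rec.samples.size * target_fs / rec.fs))
    out = out[:n_target] if out.size >= n_target else np.pad(out, (0, n_target - out.size))
    return EcgRecord(out, fs=target_fs, lead=rec.lead, start_time=rec.start_time)


def remove_baseline(rec: EcgRecord, cfg: PreprocessConfig | None = None) -> EcgRecord:
    """Subtract a running-median baseline estimate (0.2 s window).

    An optional second, wider median stage (0.6 s) can be enabled in the
    configuration for records with strong low-frequency wander.
    """
    cfg = cfg or PreprocessConfig()
    k = _odd_kernel(cfg.baseline_window_s, rec.fs)
    if rec.samples.size < k:
        raise ValueError(
            f"record of {rec.samples.size} samples shorter than "
            f"{cfg.baseline_window_s} s baseline filter window"
        )
    baseline = ndimage.median_filter(rec.samples, size=k, mode="nearest")
    if cfg.baseline_second_stage:
        k2 = _odd_kernel(cfg.baseline_second_window_s, rec.fs)
        baseline = ndimage.median_filter(baseline, size=k2, mode="nearest")
    return EcgRecord(rec.samples - baseline, fs=rec.fs, lead=rec.lead, start_time=rec.start_time)


def remove_powerline(rec: EcgRecord, mains_hz: float = 50.0, q: float = 30.0) -> EcgRecord:
    """Zero-phase second-order IIR notch at the mains frequency."""
    if mains_hz >= rec.fs / 2:
        raise ValueError(f"mains {mains_hz} Hz is above Nyquist for fs={rec.fs}")
    b, a = signal.iirnotch(mains_hz, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.samples)
    return EcgRecord(out, fs=rec.fs, lead=rec.lead, start_time=rec.start_time)


def denoise(rec: EcgRecord, cfg: PreprocessConfig | None = None) -> EcgRecord:
    """Full denoising chain: resample, baseline removal, mains notch."""
    cfg = cfg or PreprocessConfig()
    rec = resample_record(rec, cfg.target_fs)
    rec = remove_baseline(rec, cfg)
    return remove_powerline(rec, cfg.mains_hz, cfg.notch_q)


def quality_mask(rec: EcgRecord, cfg: PreprocessConfig | None = None) -> SegmentSet:
    """Label each part of the record good or low-quality.

    Sliding 5 s windows (1 s stride); a window fails on out-of-band
    kurtosis, negligible amplitude range, or a saturation run. A sample is
    low-quality when any window covering it fails, which keeps the detected
    zones aligned with artifacts regardless of window phase.
    """
    cfg = cfg or PreprocessConfig()
    x, fs = rec.samples, rec.fs
    n = x.size
    win = int(round(cfg.quality_window_s * fs))
    stride = max(1, int(round(cfg.quality_stride_s * fs)))
    if n < win:
        # too short to window: judge the whole record as one window
        bad = _window_fails(x, fs, cfg)
        segs = [(0.0, rec.duration)]
        return SegmentSet(good=[] if bad else segs, low_quality=segs if bad else [],
                          duration=rec.duration)

    starts = np.arange(0, n - win + 1, stride)
    if starts[-1] + win < n:
        starts = np.append(starts, n - win)

    windows = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    with warnings.catch_warnings():
        # constant (saturated) windows trip a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = stats.kurtosis(windows, axis=1, fisher=False, bias=True)
    rng = windows.max(axis=1) - windows.min(axis=1)
    fails = (kurt < cfg.kurtosis_low) | (kurt > cfg.kurtosis_high) | (rng < cfg.flat_range_mv)

    # saturation: any near-constant run of >= saturation_run_s inside the window
    sat_run = int(round(cfg.saturation_run_s * fs))
    const = np.abs(np.diff(x, prepend=x[0])) < 1e-6
    run = _run_lengths(const)
    sat_sample = run >= sat_run
    if sat_sample.any():
        sat_cum = np.concatenate([[0], np.cumsum(sat_sample)])
        fails |= (sat_cum[starts + win] - sat_cum[starts]) > 0

    bad_mask = np.zeros(n, dtype=bool)
    for s in starts[fails]:
        bad_mask[s:s + win] = True

    low = _mask_to_intervals(bad_mask, fs)
    good = complement(low, (0.0, rec.duration))
    return SegmentSet(good=good, low_quality=low, duration=rec.duration)


def _window_fails(x: np.ndarray, fs: float, cfg: PreprocessConfig) -> bool:
    k = float(stats.kurtosis(x, fisher=False, bias=True))
    if not np.isfinite(k) or k < cfg.kurtosis_low or k > cfg.kurtosis_high:
        return True
    return (x.max() - x.min()) < cfg.flat_range_mv


def _run_lengths(flags: np.ndarray) -> np.ndarray:
    """Length of the constant-run each flagged sample belongs to (0 where unflagged)."""
    n = flags.size
    out = np.zeros(n, dtype=int)
    if not flags.any():
        return out
    edges = np.flatnonzero(np.diff(flags.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [n]])
    for s, e in zip(starts, ends):
        if flags[s]:
            out[s:e] = e - s
    return out


def _mask_to_intervals(mask: np.ndarray, fs: float) -> list[Interval]:
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [mask.size]])
    return [(s / fs, e / fs) for s, e in zip(starts, ends) if mask[s]]


def _odd_kernel(window_s: float, fs: float) -> int:
    k = int(round(window_s * fs))
    return k + 1 if k % 2 == 0 else k
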