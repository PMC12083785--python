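"""ECG-derived respiration (EDR) series.

Three surrogate respiration series are rebuilt from the regular-rhythm beat
stream and resampled onto a uniform 4 Hz grid:

* ``hrv`` — the instantaneous heart period (RR tachogram), carrying
  respiratory sinus arrhythmia and the cyclic variation of heart rate;
* ``rwa`` — the R-wave amplitude, modulated by thoracic impedance and
  effort;
* ``morph`` — the signed QRS area, a cheap beat-morphology surrogate.

Values exist only inside analyzable segments; everywhere else the shared
gap mask is set. Interpolation is cubic-spline inside a segment (linear
when a segment holds fewer than four beats) and never extrapolates beyond
the first/last beat of a segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .config import EdrConfig
from .intervals import Interval
from .io import EcgRecord
from .rhythm import AnalyzableSegments, BeatSeries


@dataclass
class EdrSet:
    """Uniformly sampled EDR series sharing one time grid and gap mask."""

    t: np.ndarray
    hrv: np.ndarray
    rwa: np.ndarray
    morph: np.ndarray
    gap_mask: np.ndarray                 # True where no value is defined
    grid_hz: float = 4.0

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("hrv", "rwa", "morph", "gap_mask"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} does not share the time grid")

    @property
    def duration(self) -> float:
        return float(self.t[-1] + 1.0 / self.grid_hz) if self.t.size else 0.0


def _grid(duration: float, grid_hz: float) -> np.ndarray:
    return np.arange(int(np.floor(duration * grid_hz))) / grid_hz


def _interp_series(
    grid: np.ndarray,
    beat_t: np.ndarray,
    values: np.ndarray,
    segments: list[Interval],
) -> tuple[np.ndarray, np.ndarray]:
    out = np.full(grid.size, np.nan)
    mask = np.ones(grid.size, dtype=bool)
    for s, e in segments:
        sel = (beat_t >= s) & (beat_t < e)
        tb, vb = beat_t[sel], values[sel]
        ok = np.isfinite(vb)
        tb, vb = tb[ok], vb[ok]
        if tb.size < 2:
            continue
        gsel = (grid >= max(s, tb[0])) & (grid <= min(e, tb[-1]))
        if not gsel.any():
            continue
        if tb.size >= 4:
            f = CubicSpline(tb, vb, bc_type="natural")
        else:
            f = interp1d(tb, vb, kind="linear")
        out[gsel] = f(grid[gsel])
        mask[gsel] = False
    return out, mask


def extract_hrv(
    bs: BeatSeries,
    seg: AnalyzableSegments,
    grid_hz: float = 4.0,
) -> EdrSet:
    """RR tachogram on the uniform grid (rwa/morph left empty)."""
    return extract_edr(bs, None, seg, grid_hz=grid_hz, series=("hrv",))


def extract_rwa(bs: BeatSeries, seg: AnalyzableSegments, grid_hz: float = 4.0) -> EdrSet:
    return extract_edr(bs, None, seg, grid_hz=grid_hz, series=("rwa",))


def extract_morph(
    bs: BeatSeries, rec: EcgRecord, seg: AnalyzableSegments, grid_hz: float = 4.0
) -> EdrSet:
    return extract_edr(bs, rec, seg, grid_hz=grid_hz, series=("morph",))


def extract_edr(
    bs: BeatSeries,
    rec: EcgRecord | None,
    seg: AnalyzableSegments,
    grid_hz: float | None = None,
    series: tuple[str, ...] = ("hrv", "rwa", "morph"),
    cfg: EdrConfig | None = None,
) -> EdrSet:
    """Build all requested EDR series on one grid; gaps outside segments."""
    cfg = cfg or EdrConfig()
    grid_hz = grid_hz or cfg.grid_hz
    duration = seg.duration
    grid = _grid(duration, grid_hz)
    nan = np.full(grid.size, np.nan)
    hrv, rwa, morph = nan.copy(), nan.copy(), nan.copy()
    mask = np.ones(grid.size, dtype=bool)

    normal = [b for b in bs.beats if not b.abnormal]
    if normal:
        bt = np.array([b.r_peak for b in normal])
        if "hrv" in series:
            rr = np.array([
                b.rr_prev if b.rr_prev is not None else np.nan for b in normal
            ])
            hrv, m = _interp_series(grid, bt, rr, seg.intervals)
            mask &= m
        if "rwa" in series:
            amp = np.abs(np.array([b.height for b in normal]))
            rwa, m = _interp_series(grid, bt, amp, seg.intervals)
            mask &= m
        if "morph" in series:
            if rec is None:
                raise ValueError("morph series requires the waveform record")
            areas = np.array([_qrs_area(rec, b) for b in normal])
            morph, m = _interp_series(grid, bt, areas, seg.intervals)
            mask &= m

    # a sample is usable only where every requested series is defined
    defined = np.ones(grid.size, dtype=bool)
    for name, arr in (("hrv", hrv), ("rwa", rwa), ("morph", morph)):
        if name in series:
            defined &= np.isfinite(arr)
    gap = ~defined
    for arr in (hrv, rwa, morph):
        arr[gap] = np.nan
    return EdrSet(t=grid, hrv=hrv, rwa=rwa, morph=morph, gap_mask=gap, grid_hz=grid_hz)


def _qrs_area(rec: EcgRecord, beat) -> float:
    lo = max(0, int(round(beat.qrs_onset * rec.fs)))
    hi = min(rec.samples.size, int(round(beat.qrs_offset * rec.fs)) + 1)
    if hi - lo < 2:
        return np.nan
    return float(np.trapezoid(rec.samples[lo:hi], dx=1.0 / rec.fs))
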