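"""Beat detection, ectopic flagging and regular-rhythm epoch selection.

QRS complexes are located by greedy matching pursuit over a dedicated
dictionary of unit-norm atoms (Gaussian, first-derivative and Mexican-hat
shapes at QRS-scale widths). Pursuit runs on a 5-30 Hz QRS-emphasis band of
the denoised signal so that P/T waves and baseline residues do not compete
with low-amplitude R waves; fiducials and amplitudes are then measured on
the broadband denoised waveform. The pursuit is correlation-domain: after
each selection the correlation surface is updated through a precomputed
atom-pair Gram table, and the residual energy shrinks by the squared
coefficient, so no residual waveform is ever formed.

Ectopic beats are flagged by the three screening criteria — QRS width over
200 ms, RR interval outside 0.6-1.2 s, or height above 1.5x the mean of the
ten previous complexes — and a guard zone around every flagged beat is
excluded from analysis. Records must retain at least four cumulative hours
of good-quality, regular-rhythm signal to be analyzable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .config import RhythmConfig
from .intervals import Interval, complement, intersect, normalize, total_duration
from .io import EcgRecord
from .preprocess import SegmentSet


@dataclass
class Atom:
    """Unit-norm dictionary atom with its nominal QRS support."""

    waveform: np.ndarray
    width_s: float
    shape: str

    @property
    def half(self) -> int:
        return self.waveform.size // 2


@dataclass
class QrsDictionary:
    atoms: list[Atom]
    fs: float
    gram: np.ndarray = field(repr=False)  # (n, n, 2*Lmax-1) atom cross-correlations

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Beat:
    qrs_onset: float
    r_peak: float
    qrs_offset: float
    height: float          # signed amplitude at the R extremum (mV)
    width: float
    rr_prev: float | None = None
    abnormal: bool = False
    reasons: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (self.qrs_onset < self.r_peak < self.qrs_offset):
            raise ValueError("fiducials must satisfy onset < R < offset")


@dataclass
class BeatSeries:
    beats: list[Beat]
    fs: float | None = None

    def __post_init__(self) -> None:
        times = [b.r_peak for b in self.beats]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def r_times(self) -> np.ndarray:
        return np.array([b.r_peak for b in self.beats])

    @property
    def heights(self) -> np.ndarray:
        return np.array([b.height for b in self.beats])


@dataclass
class AnalyzableSegments:
    """Good-quality AND regular-rhythm time, the substrate for EDR series."""

    intervals: list[Interval]
    duration: float

    def __post_init__(self) -> None:
        self.intervals = normalize(self.intervals)

    @property
    def total_hours(self) -> float:
        return total_duration(self.intervals) / 3600.0


@dataclass
class GateVerdict:
    passed: bool
    total_hours: float
    reason: str = ""


# ------------------------------------------------------------- dictionary

def _atom_shapes(width_s: float, fs: float) -> dict[str, np.ndarray]:
    L = int(round(width_s * fs))
    L += 1 - L % 2  # odd support
    t = np.arange(L) - L // 2
    sigma = max(L / 5.0, 1.0)
    g = np.exp(-0.5 * (t / sigma) ** 2)
    dg = -t * np.exp(-0.5 * (t / sigma) ** 2)
    rk = (1 - (t / sigma) ** 2) * np.exp(-0.5 * (t / sigma) ** 2)
    return {"gauss": g, "dgauss": dg, "ricker": rk}


def build_qrs_dictionary(
    fs: float,
    widths: tuple[float, ...] | None = None,
    shapes: tuple[str, ...] = ("gauss", "dgauss", "ricker"),
) -> QrsDictionary:
    """Build the unit-norm atom dictionary used by the pursuit."""
    widths = tuple(widths) if widths is not None else RhythmConfig().atom_widths_s
    if not widths:
        raise ValueError("widths must be a non-empty list")
    atoms: list[Atom] = []
    for w in widths:
        fams = _atom_shapes(w, fs)
        for name in shapes:
            wf = fams[name]
            wf = wf - wf.mean() if name == "gauss" else wf
            nrm = np.linalg.norm(wf)
            if nrm == 0:
                continue
            atoms.append(Atom(wf / nrm, width_s=w, shape=name))
    Lmax = max(a.waveform.size for a in atoms)
    gram = np.zeros((len(atoms), len(atoms), 2 * Lmax - 1))
    mid = Lmax - 1
    for i, ai in enumerate(atoms):
        for j, aj in enumerate(atoms):
            cc = np.correlate(
                np.pad(ai.waveform, (mid - ai.half, mid - ai.half)), aj.waveform, "same"
            )
            gram[i, j] = cc
    return QrsDictionary(atoms=atoms, fs=fs, gram=gram)


def dictionary_coherence(d: QrsDictionary) -> float:
    """Largest absolute cross-correlation between distinct atoms (any lag)."""
    n = len(d)
    vals = [np.abs(d.gram[i, j]).max() for i in range(n) for j in range(n) if i != j]
    return float(max(vals))


# ---------------------------------------------------------------- pursuit

def detect_beats(
    rec: EcgRecord,
    dictionary: QrsDictionary | None = None,
    cfg: RhythmConfig | None = None,
) -> BeatSeries:
    """Greedy matching pursuit -> refractory pruning -> fiducial refinement."""
    cfg = cfg or RhythmConfig()
    d = dictionary or build_qrs_dictionary(rec.fs, cfg.atom_widths_s)
    if d.fs != rec.fs:
        raise ValueError(f"dictionary built for fs={d.fs}, record has fs={rec.fs}")
    x = rec.samples
    if not np.any(x):
        return BeatSeries([], fs=rec.fs)

    lo, hi = cfg.detect_band_hz
    sos = sp_signal.butter(2, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    det = sp_signal.sosfiltfilt(sos, x)

    cands = _pursue(det, d, cfg)
    if not cands:
        return BeatSeries([], fs=rec.fs)
    cands = _prune(cands, d, cfg)
    beats = _refine(cands, x, d, rec.fs, cfg)
    return BeatSeries(beats, fs=rec.fs)


def _pursue(det: np.ndarray, d: QrsDictionary, cfg: RhythmConfig) -> list[tuple]:
    fs = d.fs
    n = det.size
    win = int(round(cfg.mp_window_s * fs))
    margin = max(a.waveform.size for a in d.atoms)
    n_atoms = len(d)
    Lmax = max(a.waveform.size for a in d.atoms)
    gmid = Lmax - 1
    max_atoms = max(1, int(round(cfg.mp_max_atoms_per_10s * cfg.mp_window_s / 10.0)))

    # FFT plans: atoms padded to the extended-window length
    n_ext_max = win + 2 * margin
    nfft = int(2 ** np.ceil(np.log2(n_ext_max + Lmax)))
    atom_ffts = np.stack(
        [np.conj(np.fft.rfft(a.waveform, nfft)) for a in d.atoms]
    )
    halves = np.array([a.half for a in d.atoms])

    # global noise scale of the correlation surface (median-based, robust to
    # the sparse QRS content of the band-limited signal)
    probe = det[: min(n, int(120 * fs))]
    pf = np.fft.rfft(probe, nfft)
    pc = np.fft.irfft(pf * atom_ffts, nfft, axis=1)[:, : probe.size]
    thr = cfg.mp_accept_sigma * 1.4826 * float(np.median(np.abs(pc)))
    del pf, pc

    out: list[tuple] = []
    n_windows = int(np.ceil(n / win))
    for w in range(n_windows):
        core0, core1 = w * win, min((w + 1) * win, n)
        e0, e1 = max(0, core0 - margin), min(n, core1 + margin)
        seg = det[e0:e1]
        E = float(seg @ seg)
        if E <= 0:
            continue
        E0 = E
        F = np.fft.rfft(seg, nfft)
        cc = np.fft.irfft(F * atom_ffts, nfft, axis=1)
        corr = np.empty((n_atoms, seg.size))
        for a in range(n_atoms):
            corr[a] = np.roll(cc[a], halves[a])[: seg.size]

        for _ in range(max_atoms):
            if E < cfg.mp_residual_frac * E0:
                break
            flat = np.argmax(np.abs(corr))
            a, p = np.unravel_index(flat, corr.shape)
            c = corr[a, p]
            if abs(c) < thr:
                break
            # correlation-domain update via the Gram table
            g = d.gram[a]  # (n_atoms, 2*Lmax-1)
            s0 = p - gmid
            lo_i = max(0, s0)
            hi_i = min(seg.size, s0 + g.shape[1])
            corr[:, lo_i:hi_i] -= c * g[:, lo_i - s0 : hi_i - s0]
            E -= c * c
            t_global = e0 + p
            if core0 <= t_global < core1:
                out.append((t_global, c, a))
    return out


def _prune(cands: list[tuple], d: QrsDictionary, cfg: RhythmConfig) -> list[tuple]:
    import bisect

    fs = d.fs
    refr = cfg.refractory_s * fs
    kept: list[tuple] = []
    kept_pos: list[int] = []  # sorted sample positions of kept beats
    for t, c, a in sorted(cands, key=lambda z: -abs(z[1])):
        i = bisect.bisect_left(kept_pos, t)
        near_left = i > 0 and t - kept_pos[i - 1] < refr
        near_right = i < len(kept_pos) and kept_pos[i] - t < refr
        if not (near_left or near_right):
            kept.append((t, c, a))
            kept_pos.insert(i, t)
    # wide-atom selections must clear a height bar relative to typical narrow
    # selections: rejects smooth T/P-wave residues, keeps tall wide ectopics
    narrow = [abs(c) for _, c, a in kept if d.atoms[a].width_s <= 0.16]
    if narrow:
        bar = 0.5 * float(np.median(narrow))
        kept = [z for z in kept if d.atoms[z[2]].width_s <= 0.16 or abs(z[1]) >= bar]
    return sorted(kept, key=lambda z: z[0])


def _refine(cands, x: np.ndarray, d: QrsDictionary, fs: float, cfg: RhythmConfig) -> list[Beat]:
    search = int(round(0.04 * fs))
    refined: list[tuple[float, float, float]] = []  # (r, height, width)
    for t, c, a in cands:
        lo = max(0, t - search)
        hi = min(x.size, t + search + 1)
        seg = x[lo:hi]
        if seg.size == 0:
            continue
        pk = lo + int(np.argmax(np.abs(seg)))
        refined.append((pk / fs, float(x[pk]), d.atoms[a].width_s))
    # peak refinement can pull two selections inside the refractory window
    # (e.g. a P-wave candidate at the boundary); keep the taller one
    import bisect

    kept: list[tuple[float, float, float]] = []
    kept_r: list[float] = []
    for r, h, w in sorted(refined, key=lambda z: -abs(z[1])):
        i = bisect.bisect_left(kept_r, r)
        near_left = i > 0 and r - kept_r[i - 1] < cfg.refractory_s
        near_right = i < len(kept_r) and kept_r[i] - r < cfg.refractory_s
        if not (near_left or near_right):
            kept.append((r, h, w))
            kept_r.insert(i, r)
    beats: list[Beat] = []
    prev_t = None
    for r, h, w in sorted(kept):
        if beats and r <= beats[-1].r_peak:
            continue
        beats.append(
            Beat(qrs_onset=r - w / 2, r_peak=r, qrs_offset=r + w / 2,
                 height=h, width=w,
                 rr_prev=None if prev_t is None else r - prev_t)
        )
        prev_t = r
    return beats


# ------------------------------------------------------------- screening

def flag_abnormal_beats(bs: BeatSeries, cfg: RhythmConfig | None = None) -> BeatSeries:
    """Apply the three ectopic criteria (width / RR / height) as an OR."""
    cfg = cfg or RhythmConfig()
    heights = np.abs(bs.heights) if len(bs) else np.empty(0)
    flagged: list[Beat] = []
    for i, b in enumerate(bs.beats):
        reasons = set()
        if b.width > cfg.max_width_s:
            reasons.add("width")
        if b.rr_prev is not None and (b.rr_prev > cfg.rr_high_s or b.rr_prev < cfg.rr_low_s):
            reasons.add("rr")
        if i >= cfg.height_lookback:
            ref = heights[i - cfg.height_lookback : i].mean()
            if abs(b.height) > cfg.height_factor * ref:
                reasons.add("height")
        flagged.append(
            Beat(b.qrs_onset, b.r_peak, b.qrs_offset, b.height, b.width,
                 rr_prev=b.rr_prev, abnormal=bool(reasons), reasons=frozenset(reasons))
        )
    return BeatSeries(flagged, fs=bs.fs)


def regular_segments(
    bs: BeatSeries,
    quality: SegmentSet,
    guard_s: float = 5.0,
    guard_reasons: tuple[str, ...] | None = None,
) -> AnalyzableSegments:
    """Good-quality time minus a guard zone around guarded abnormal beats.

    By default every abnormal beat is guarded; restricting
    ``guard_reasons`` (the pipeline guards morphology-aberrant beats only)
    keeps isolated rhythm/height flags from excising signal — such beats
    are still excluded from the EDR stream by their flag.
    """
    span = (0.0, quality.duration)
    guards = [
        (b.r_peak - guard_s, b.r_peak + guard_s)
        for b in bs.beats
        if b.abnormal and (guard_reasons is None or b.reasons & set(guard_reasons))
    ]
    keep = intersect(quality.good, complement(guards, span))
    return AnalyzableSegments(intervals=keep, duration=quality.duration)


def enforce_min_duration(seg: AnalyzableSegments, min_hours: float = 4.0) -> GateVerdict:
    hours = seg.total_hours
    if hours + 1e-9 >= min_hours:
        return GateVerdict(True, hours)
    return GateVerdict(
        False, hours,
        reason=f"insufficient length of exploitable signal ({hours:.2f} h < {min_hours} h)",
    )


def classify_qrs_morphology(
    bs: BeatSeries,
    rec: EcgRecord,
    cfg: RhythmConfig | None = None,
) -> tuple[str, np.ndarray, np.ndarray]:
    """Label the record monophasic or biphasic from per-beat P/N amplitudes.

    For each non-abnormal beat the largest positive (P) and deepest negative
    (N) deflections inside the QRS support are measured; the record is
    biphasic when the median of min(P,N)/max(P,N) reaches 0.5.
    """
    cfg = cfg or RhythmConfig()
    pos, neg = [], []
    for b in bs.beats:
        if b.abnormal:
            continue
        lo = max(0, int(round(b.qrs_onset * rec.fs)))
        hi = min(rec.samples.size, int(round(b.qrs_offset * rec.fs)) + 1)
        seg = rec.samples[lo:hi]
        if seg.size == 0:
            continue
        pos.append(max(seg.max(), 0.0))
        neg.append(max(-seg.min(), 0.0))
    pos_a, neg_a = np.array(pos), np.array(neg)
    if pos_a.size < cfg.morphology_min_beats:
        return "unknown", pos_a, neg_a
    mx = np.maximum(pos_a, neg_a)
    ok = mx > 0
    rho = np.minimum(pos_a[ok], neg_a[ok]) / mx[ok]
    label = "biphasic" if np.median(rho) >= cfg.morphology_ratio else "monophasic"
    return label, pos_a, neg_a
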