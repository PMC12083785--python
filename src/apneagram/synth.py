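"""Synthetic annotated nocturnal-ECG studies.

The generator produces the statistical structure the screening pipeline
assumes, with full ground truth, so every stage is testable without
clinical recordings:

* sinus-rhythm beat stream with respiratory sinus arrhythmia and per-beat
  amplitude modulation by respiration;
* apnea/hypopnea episodes imposing the cyclic-variation-of-heart-rate
  pattern (progressive bradycardia across the event, abrupt tachycardia at
  its end) and a per-event R-wave-amplitude reduction whose depth encodes
  the event class (>= 0.9 for apneas, 0.3-0.9 for hypopneas);
* obstructive events keep (and slightly boost) the respiratory-band
  amplitude oscillation — the surrogate of persisting inspiratory effort —
  while central events suppress it;
* a wake/sleep architecture (30 s epochs) with faster, more variable heart
  rate during wake;
* ectopic beats (wide, tall, premature) and channel artifacts (Gaussian
  noise at a configured SNR, mains interference, baseline wander,
  saturation/detachment segments, noise bursts).

Waveforms are sums of Gaussian PQRST atoms per beat, synthesized at the
acquisition rate (400 Hz by default) so the pipeline's resampling stage is
exercised. Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import Interval, complement, normalize, total_duration
from .io import EcgRecord, EventAnnotation, write_events, write_hypnogram, write_record


@dataclass
class SynthConfig:
    duration_h: float = 8.0
    fs: float = 400.0
    target_ahi: float = 15.0
    frac_hypopnea: float = 0.4
    frac_central: float = 0.1            # fraction of apneas that are central
    event_duration_s: tuple[float, float] = (15.0, 45.0)
    min_event_gap_s: float = 20.0
    apnea_depth: tuple[float, float] = (0.90, 0.98)
    hypopnea_depth: tuple[float, float] = (0.35, 0.85)
    event_edge_s: float = 2.0            # depth ramp at event edges
    # cardiac baseline
    mean_hr: float = 70.0
    wake_hr_delta: float = 15.0
    rsa_depth: float = 0.04              # RR respiratory modulation (fraction)
    rwa_resp_depth: float = 0.08         # R-amplitude respiratory modulation
    resp_rate_hz: float = 0.22
    cvhr_brady: float = 0.20             # RR lengthening at event end (fraction)
    cvhr_tachy: float = 0.10             # RR shortening after event (fraction)
    tachy_s: float = 5.0
    effort_obstructive_gain: float = 1.3
    effort_central_gain: float = 0.1
    rr_jitter: float = 0.015
    wake_jitter_factor: float = 2.0
    amp_jitter_sleep: float = 0.02
    amp_jitter_wake: float = 0.06
    # waveform morphology
    r_amp_mv: float = 1.0
    qrs_width_s: float = 0.09
    qrs_style: str = "monophasic"        # or "biphasic"
    # sleep architecture (seconds, aligned to 30 s epochs)
    wake_initial_s: float = 900.0
    wake_final_s: float = 600.0
    n_awakenings: int = 2
    awakening_s: tuple[float, float] = (60.0, 240.0)
    # artifacts
    snr_db: float | None = 15.0
    mains_amp_mv: float = 0.05
    mains_hz: float = 50.0
    wander_amp_mv: float = 0.15
    wander_hz: float = 0.3
    n_saturation: int = 2
    saturation_s: tuple[float, float] = (15.0, 30.0)
    n_noise_bursts: int = 1
    noise_burst_s: float = 60.0
    ectopic_rate_per_h: float = 3.0
    ectopic_width_s: float = 0.24
    ectopic_height_factor: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.frac_hypopnea, self.frac_central):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.event_duration_s[0] < 10.0:
            raise ValueError("events must last at least 10 s")


@dataclass
class SimulatedBeats:
    """Beat stream plus the ground truth that produced it."""

    times: np.ndarray                    # R-peak times (s)
    scales: np.ndarray                   # per-beat whole-complex scale factor
    widths: np.ndarray                   # per-beat QRS width (s)
    events: list[EventAnnotation]
    hypnogram: list[str]                 # 30 s epochs, {wake, sleep}
    sleep_blocks: list[Interval]
    ectopic_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def tst_h(self) -> float:
        return 30.0 * sum(1 for l in self.hypnogram if l == "sleep") / 3600.0

    @property
    def ahi(self) -> float:
        return len(self.events) / self.tst_h if self.tst_h > 0 else float("nan")


@dataclass
class SynthStudy:
    record: EcgRecord
    beats: SimulatedBeats
    artifact_segments: list[Interval]
    config: SynthConfig

    @property
    def truth_report(self) -> dict:
        ev = self.beats.events
        return {
            "ahi": self.beats.ahi,
            "tst_h": self.beats.tst_h,
            "n_events": len(ev),
            "n_apnea": sum(e.kind == "apnea" for e in ev),
            "n_hypopnea": sum(e.kind == "hypopnea" for e in ev),
            "n_central": sum(e.mechanism == "central" for e in ev),
            "n_obstructive": sum(e.mechanism == "obstructive" for e in ev),
        }


# ----------------------------------------------------------- architecture

def _sleep_architecture(cfg: SynthConfig, rng: np.random.Generator):
    dur = cfg.duration_h * 3600.0
    epoch = 30.0
    wake: list[Interval] = []
    if cfg.wake_initial_s > 0:
        wake.append((0.0, _snap(cfg.wake_initial_s, epoch)))
    if cfg.wake_final_s > 0:
        wake.append((dur - _snap(cfg.wake_final_s, epoch), dur))
    lo = wake[0][1] if wake else 0.0
    hi = wake[-1][0] if len(wake) > 1 else dur
    for _ in range(cfg.n_awakenings):
        w = _snap(rng.uniform(*cfg.awakening_s), epoch)
        start = _snap(rng.uniform(lo + 600, hi - 600 - w), epoch)
        wake.append((start, start + w))
    wake = normalize(wake)
    sleep = complement(wake, (0.0, dur))
    n_ep = int(np.ceil(dur / epoch))
    labels = []
    for i in range(n_ep):
        mid = (i + 0.5) * epoch
        labels.append("wake" if any(s <= mid < e for s, e in wake) else "sleep")
    return sleep, labels


def _snap(x: float, step: float) -> float:
    return round(x / step) * step


def _place_events(cfg: SynthConfig, sleep: list[Interval], rng: np.random.Generator):
    tst = total_duration(sleep)
    n_events = int(round(cfg.target_ahi * tst / 3600.0))
    if n_events == 0:
        return []
    durs = rng.uniform(*cfg.event_duration_s, size=n_events)
    # allocate events to sleep blocks proportionally to block length
    lens = np.array([e - s for s, e in sleep])
    alloc = np.floor(n_events * lens / lens.sum()).astype(int)
    for _ in range(n_events - alloc.sum()):
        alloc[np.argmax(lens / (alloc + 1))] += 1
    events: list[tuple[float, float]] = []
    k = 0
    gap = cfg.min_event_gap_s
    for (s, e), m in zip(sleep, alloc):
        if m == 0:
            continue
        block_durs = durs[k : k + m]
        k += m
        need = block_durs.sum() + (m + 1) * gap
        if need > (e - s):
            raise ValueError(
                f"infeasible event density: {m} events need {need:.0f} s "
                f"in a {e - s:.0f} s sleep block"
            )
        slack = (e - s) - need
        gaps = gap + rng.dirichlet(np.ones(m + 1)) * slack
        t = s
        for d, g in zip(block_durs, gaps):
            t += g
            events.append((t, t + d))
            t += d
    kinds = ["hypopnea"] * int(round(cfg.frac_hypopnea * n_events))
    kinds += ["apnea"] * (n_events - len(kinds))
    rng.shuffle(kinds)
    n_apnea = kinds.count("apnea")
    mechs_pool = ["central"] * int(round(cfg.frac_central * n_apnea))
    mechs_pool += ["obstructive"] * (n_apnea - len(mechs_pool))
    rng.shuffle(mechs_pool)
    out = []
    it = iter(mechs_pool)
    for (s, e), kind in zip(sorted(events), kinds):
        mech = next(it) if kind == "apnea" else "unknown"
        out.append(EventAnnotation(start=s, end=e, kind=kind, mechanism=mech))
    return out


# -------------------------------------------------------------- simulate

def simulate_rr(cfg: SynthConfig) -> SimulatedBeats:
    """Generate the annotated beat stream (times, scales) and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    sleep, hypnogram = _sleep_architecture(cfg, rng)
    events = _place_events(cfg, sleep, rng)
    dur = cfg.duration_h * 3600.0

    depths = np.array([
        rng.uniform(*(cfg.apnea_depth if ev.kind == "apnea" else cfg.hypopnea_depth))
        for ev in events
    ])
    ev_start = np.array([ev.start for ev in events])
    ev_end = np.array([ev.end for ev in events])
    wake_mask_fn = _membership(complement(sleep, (0.0, dur)))

    base_rr = 60.0 / cfg.mean_hr
    wake_rr = 60.0 / (cfg.mean_hr + cfg.wake_hr_delta)
    phase = rng.uniform(0, 2 * np.pi)

    times: list[float] = []
    jitters = rng.standard_normal(int(dur / wake_rr) + 16)
    t, k = 1.0, 0
    while t < dur - 1.0:
        wake = wake_mask_fn(t)
        rr = wake_rr if wake else base_rr
        rr *= 1.0 + cfg.rsa_depth * np.sin(2 * np.pi * cfg.resp_rate_hz * t + phase)
        i = np.searchsorted(ev_start, t, side="right") - 1
        if i >= 0:
            if t < ev_end[i]:
                frac = (t - ev_start[i]) / (ev_end[i] - ev_start[i])
                rr *= 1.0 + cfg.cvhr_brady * frac
            elif t < ev_end[i] + cfg.tachy_s:
                rr *= 1.0 - cfg.cvhr_tachy
        sd = cfg.rr_jitter * (cfg.wake_jitter_factor if wake else 1.0)
        rr *= 1.0 + sd * jitters[k]
        times.append(t)
        t += max(rr, 0.3)
        k += 1
    times_a = np.asarray(times)

    # per-beat amplitude scale: event depth envelope + respiratory effort term
    env = np.ones(times_a.size)
    effort = np.full(times_a.size, cfg.rwa_resp_depth)
    for ev, depth in zip(events, depths):
        g = _trapezoid(times_a, ev.start, ev.end, cfg.event_edge_s)
        env -= depth * g
        if ev.kind == "apnea":
            gain = (cfg.effort_central_gain if ev.mechanism == "central"
                    else cfg.effort_obstructive_gain)
            effort = np.where(g > 0.5, cfg.rwa_resp_depth * gain, effort)
    wake_beats = wake_mask_fn(times_a)
    amp_sd = np.where(wake_beats, cfg.amp_jitter_wake, cfg.amp_jitter_sleep)
    scales = (
        env
        + effort * np.sin(2 * np.pi * cfg.resp_rate_hz * times_a + phase)
        + amp_sd * rng.standard_normal(times_a.size)
    )
    scales = np.maximum(scales, 0.02)
    widths = np.full(times_a.size, cfg.qrs_width_s)
    return SimulatedBeats(times=times_a, scales=scales, widths=widths,
                          events=events, hypnogram=hypnogram, sleep_blocks=sleep)


def _membership(intervals: list[Interval]):
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])

    def inside(t):
        i = np.searchsorted(starts, t, side="right") - 1
        if np.isscalar(t) or np.ndim(t) == 0:
            return bool(i >= 0 and t < ends[i])
        ok = i >= 0
        out = np.zeros(np.shape(t), dtype=bool)
        out[ok] = np.asarray(t)[ok] < ends[i[ok]]
        return out

    return inside


def _trapezoid(t: np.ndarray, s: float, e: float, edge: float) -> np.ndarray:
    up = np.clip((t - s) / edge, 0.0, 1.0)
    down = np.clip((e - t) / edge, 0.0, 1.0)
    return np.minimum(up, down) * ((t >= s) & (t <= e))


# ------------------------------------------------------------- waveforms

# PQRST Gaussian atoms: (relative amplitude, center offset fraction of QRS
# width or absolute seconds, sigma). QRS members scale with the configured
# width; P/T have fixed physiologic timings.
_P_WAVE = (0.12, -0.18, 0.022)
_T_WAVE = (0.30, 0.30, 0.055)


def _qrs_waves(width_s: float, style: str):
    # calibrated so the 5 % threshold-crossing width matches width_s
    sigma_r = width_s / 4.6
    q_amp, s_amp = -0.12, (-0.95 if style == "biphasic" else -0.22)
    return [
        (q_amp, -0.42 * width_s, width_s / 9.0),
        (1.0, 0.0, sigma_r),
        (s_amp, 0.42 * width_s, width_s / 9.0),
    ]


def synthesize_ecg(
    beats: SimulatedBeats | np.ndarray,
    scales: np.ndarray | None = None,
    fs: float | None = None,
    cfg: SynthConfig | None = None,
) -> tuple[EcgRecord, np.ndarray]:
    """Render the beat stream into a waveform; returns (record, truth R times)."""
    cfg = cfg or SynthConfig()
    fs = fs or cfg.fs
    if isinstance(beats, SimulatedBeats):
        times, sc, widths = beats.times, beats.scales, beats.widths
    else:
        times = np.asarray(beats, dtype=float)
        sc = np.ones(times.size) if scales is None else np.asarray(scales, dtype=float)
        widths = np.full(times.size, cfg.qrs_width_s)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    n = int(round((times[-1] + 1.5) * fs)) if times.size else int(fs)
    sig = np.zeros(n)
    uniq_w = np.unique(widths)
    for w in uniq_w:
        sel = widths == w
        waves = [_P_WAVE] + _qrs_waves(w, cfg.qrs_style) + [_T_WAVE]
        for amp, off, sigma in waves:
            _add_gaussians(sig, fs, times[sel] + off,
                           amp * cfg.r_amp_mv * sc[sel], sigma)
    rec = EcgRecord(sig, fs=fs, lead="DII")
    return rec, times.copy()


def _add_gaussians(sig, fs, centers, amps, sigma) -> None:
    half = int(np.ceil(4 * sigma * fs))
    offs = np.arange(-half, half + 1)
    idx = np.round(centers * fs).astype(int)[:, None] + offs[None, :]
    tt = idx / fs - centers[:, None]
    vals = amps[:, None] * np.exp(-0.5 * (tt / sigma) ** 2)
    ok = (idx >= 0) & (idx < sig.size)
    np.add.at(sig, idx[ok], vals[ok])


def measure_qrs_width(
    rec: EcgRecord, r_time: float, frac: float = 0.05, half_s: float = 0.15
) -> float:
    """Threshold-crossing QRS width around one R peak (test oracle).

    The search half-window stays inside the PQ/ST segments so neighbouring
    P and T waves do not enter the measurement.
    """
    i = int(round(r_time * rec.fs))
    half = int(round(half_s * rec.fs))
    lo, hi = max(0, i - half), min(rec.samples.size, i + half + 1)
    seg = np.abs(rec.samples[lo:hi])
    thr = frac * seg.max()
    above = np.flatnonzero(seg >= thr)
    return (above[-1] - above[0]) / rec.fs


# -------------------------------------------------------------- injectors

def inject_ectopics(
    beats: SimulatedBeats,
    rate_per_h: float,
    rng: np.random.Generator,
    cfg: SynthConfig | None = None,
) -> SimulatedBeats:
    """Insert wide, tall, premature beats; returns beats + truth ectopic times."""
    cfg = cfg or SynthConfig()
    n_ect = int(round(rate_per_h * (beats.times[-1] - beats.times[0]) / 3600.0))
    if n_ect == 0:
        return beats
    idx = rng.choice(np.arange(1, beats.times.size - 1), size=n_ect, replace=False)
    idx.sort()
    t_ect = beats.times[idx] + 0.42 * np.diff(beats.times)[idx]
    local = np.array([
        beats.scales[max(0, i - 5) : i + 5].mean() for i in idx
    ])
    times = np.concatenate([beats.times, t_ect])
    scales = np.concatenate([beats.scales, cfg.ectopic_height_factor * local])
    widths = np.concatenate([beats.widths, np.full(n_ect, cfg.ectopic_width_s)])
    order = np.argsort(times)
    return SimulatedBeats(
        times=times[order], scales=scales[order], widths=widths[order],
        events=beats.events, hypnogram=beats.hypnogram,
        sleep_blocks=beats.sleep_blocks, ectopic_times=np.sort(t_ect),
    )


def inject_artifacts(
    rec: EcgRecord,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[EcgRecord, list[Interval]]:
    """Add noise, mains, wander and saturation/burst segments; returns truth zones."""
    x = rec.samples.copy()
    t = rec.t
    if cfg.wander_amp_mv:
        x += cfg.wander_amp_mv * np.sin(2 * np.pi * cfg.wander_hz * t + rng.uniform(0, 7))
    if cfg.mains_amp_mv:
        x += cfg.mains_amp_mv * np.sin(2 * np.pi * cfg.mains_hz * t)
    if cfg.snr_db is not None:
        rms = float(np.sqrt(np.mean(rec.samples**2)))
        x += rms * 10 ** (-cfg.snr_db / 20.0) * rng.standard_normal(x.size)

    segments: list[Interval] = []
    dur = rec.duration

    def _free_slot(length: float) -> Interval | None:
        for _ in range(50):
            s = rng.uniform(60.0, dur - 60.0 - length)
            if all(e0 + 5 < s or s + length + 5 < s0 for s0, e0 in segments):
                return (s, s + length)
        return None

    for k in range(cfg.n_saturation):
        slot = _free_slot(rng.uniform(*cfg.saturation_s))
        if slot is None:
            continue
        s, e = slot
        i0, i1 = int(s * rec.fs), int(e * rec.fs)
        x[i0:i1] = 2.0 if k % 2 == 0 else 0.0  # rail vs detached electrode
        segments.append((s, e))
    for _ in range(cfg.n_noise_bursts):
        slot = _free_slot(cfg.noise_burst_s)
        if slot is None:
            continue
        s, e = slot
        i0, i1 = int(s * rec.fs), int(e * rec.fs)
        x[i0:i1] = np.std(x[i0:i1]) * rng.standard_normal(i1 - i0)
        segments.append((s, e))
    return EcgRecord(x, fs=rec.fs, lead=rec.lead), sorted(segments)


# ----------------------------------------------------------------- study

def generate_study(cfg: SynthConfig, out_dir: str | Path | None = None) -> SynthStudy:
    """Full annotated study; optionally written to disk (WFDB + CSV + JSON)."""
    beats = simulate_rr(cfg)
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    if cfg.ectopic_rate_per_h > 0:
        beats = inject_ectopics(beats, cfg.ectopic_rate_per_h, rng, cfg)
    rec, _ = synthesize_ecg(beats, cfg=cfg)
    rec, artifacts = inject_artifacts(rec, cfg, rng)
    study = SynthStudy(record=rec, beats=beats, artifact_segments=artifacts, config=cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_record(rec, out / "ecg.hea", format="wfdb")
        write_events(beats.events, out / "truth_events.csv")
        write_hypnogram(beats.hypnogram, out / "truth_hypnogram.csv")
        truth = dict(study.truth_report)
        truth["seed"] = cfg.seed
        (out / "truth_report.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
        (out / "synth_config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True) + "\n"
        )
    return study
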