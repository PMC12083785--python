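"""End-to-end screening: waveform in, screening report out.

The seven successive stages: denoising (resample to 250 Hz, baseline
median, mains notch), quality masking, beat detection with ectopic
exclusion and the 4 h analyzability gate, EDR extraction, abnormal-breathing
detection, wake/sleep staging, and AHI + reliability scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import edr as edr_mod
from . import preprocess, resp_events, rhythm, scoring, sleep_staging
from .config import RunConfig
from .intervals import intersect, total_duration
from .io import EcgRecord, EventAnnotation
from .scoring import ScreeningReport


@dataclass
class PipelineResult:
    """Report plus the intermediate products, for inspection and evaluation."""

    report: ScreeningReport
    record: EcgRecord | None = None
    quality: preprocess.SegmentSet | None = None
    beats: rhythm.BeatSeries | None = None
    segments: rhythm.AnalyzableSegments | None = None
    edr: edr_mod.EdrSet | None = None
    events: list[EventAnnotation] = field(default_factory=list)
    hypnogram: sleep_staging.Hypnogram | None = None


def analyze_record(
    rec: EcgRecord,
    cfg: RunConfig | None = None,
    stager: sleep_staging.StagerModel | None = None,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Run the full screening chain on one nocturnal single-lead record."""
    cfg = cfg or RunConfig()

    clean = preprocess.denoise(rec, cfg.preprocess)
    quality = preprocess.quality_mask(clean, cfg.preprocess)

    dictionary = rhythm.build_qrs_dictionary(clean.fs, cfg.rhythm.atom_widths_s)
    beats = rhythm.detect_beats(clean, dictionary, cfg.rhythm)
    beats = rhythm.flag_abnormal_beats(beats, cfg.rhythm)
    segments = rhythm.regular_segments(
        beats, quality, cfg.rhythm.guard_s, cfg.rhythm.guard_reasons
    )
    verdict = rhythm.enforce_min_duration(segments, cfg.rhythm.min_hours)
    morphology, _, _ = rhythm.classify_qrs_morphology(beats, clean, cfg.rhythm)

    if not verdict.passed:
        report = scoring.build_report(
            [], tst_h=0.0, pct_tst_analyzed=0.0, relevance=0.0,
            qrs_morphology=morphology, analyzable_hours=verdict.total_hours,
            gate_passed=False, gate_reason=verdict.reason, cfg=cfg.scoring,
        )
        return PipelineResult(report=report,
                              record=clean if keep_intermediates else None,
                              quality=quality, beats=beats, segments=segments)

    edr = edr_mod.extract_edr(beats, clean, segments, cfg=cfg.edr)
    events, feats, labels = resp_events.detect_events(edr, cfg.events)

    stager = stager or sleep_staging.default_stager(cfg.staging)
    epochs = sleep_staging.epoch_edr(edr, cfg.staging)
    hypnogram = sleep_staging.classify_epochs(epochs, stager, cfg.staging)
    tst_h = sleep_staging.total_sleep_time(hypnogram)

    # events during confirmed wake are discarded; unscored epochs (often the
    # signal dropout inside deep events) do not disqualify an event
    wake_iv = [
        (i * hypnogram.epoch_s, (i + 1) * hypnogram.epoch_s)
        for i, l in enumerate(hypnogram.labels) if l == "wake"
    ]
    events = [e for e in events
              if total_duration(intersect([(e.start, e.end)], wake_iv)) < 0.5 * e.duration]

    sleep_iv = [
        (i * hypnogram.epoch_s, (i + 1) * hypnogram.epoch_s)
        for i, l in enumerate(hypnogram.labels) if l == "sleep"
    ]
    pct_tst = 0.0
    if tst_h > 0:
        analyzed_sleep = total_duration(intersect(segments.intervals, sleep_iv)) / 3600.0
        pct_tst = float(np.clip(100.0 * analyzed_sleep / tst_h, 0.0, 100.0))
    relevance = scoring.relevance_score(events, feats.z if len(feats) else None, labels)

    report = scoring.build_report(
        events, tst_h=tst_h, pct_tst_analyzed=pct_tst,
        relevance=float(np.clip(relevance, 0.0, 100.0)),
        qrs_morphology=morphology, analyzable_hours=segments.total_hours,
        gate_passed=True, cfg=cfg.scoring,
    )
    return PipelineResult(
        report=report, record=clean if keep_intermediates else None,
        quality=quality, beats=beats, segments=segments,
        edr=edr, events=events, hypnogram=hypnogram,
    )
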