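"""Run configuration: every tunable of the pipeline in one serializable object.

Defaults follow the published processing constants where one is stated
(250 Hz working rate, 0.2 s baseline median, 50 Hz band-stop, 5 s quality
windows, 200 ms / 0.6-1.2 s / height ectopic criteria, 4 h analyzability
gate, 30 s sleep epochs, 15 /h screening threshold); the remaining knobs
are this package's own documented choices (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    target_fs: float = 250.0
    baseline_window_s: float = 0.2
    baseline_second_stage: bool = False      # optional extra 0.6 s stage
    baseline_second_window_s: float = 0.6
    mains_hz: float = 50.0
    notch_q: float = 30.0
    quality_window_s: float = 5.0
    quality_stride_s: float = 1.0
    kurtosis_low: float = 3.5                # below: indistinguishable from noise
    kurtosis_high: float = 80.0              # above: impulsive artifact
    flat_range_mv: float = 0.05
    saturation_run_s: float = 0.5


@dataclass
class RhythmConfig:
    atom_widths_s: tuple[float, ...] = (0.04, 0.06, 0.08, 0.10, 0.13, 0.16, 0.20, 0.26, 0.30)
    detect_band_hz: tuple[float, float] = (5.0, 30.0)
    mp_window_s: float = 10.0
    mp_residual_frac: float = 0.005          # stop when residual energy below this
    mp_max_atoms_per_10s: int = 30
    mp_accept_sigma: float = 3.0             # coefficient threshold in noise sigmas
    refractory_s: float = 0.2
    max_width_s: float = 0.2                 # ectopic criterion (a)
    rr_low_s: float = 0.6                    # criterion (b)
    rr_high_s: float = 1.2
    height_factor: float = 1.5               # criterion (c'): > factor x 10-beat mean
    height_lookback: int = 10
    guard_s: float = 5.0
    # flags that excise time (others only drop the beat from the EDR stream):
    # rhythm/height flags fire densely inside deep respiratory events, where
    # amplitude collapse mimics ectopy, so only clear morphology aberrations
    # (wide QRS) remove signal
    guard_reasons: tuple[str, ...] = ("width",)
    min_hours: float = 4.0
    morphology_ratio: float = 0.5            # median min/max wave ratio for biphasic
    morphology_min_beats: int = 50


@dataclass
class EdrConfig:
    grid_hz: float = 4.0


@dataclass
class EventConfig:
    window_s: float = 60.0
    step_s: float = 10.0
    max_gap_fraction: float = 0.25           # window exclusion rule
    min_windows: int = 10
    silhouette_min: float = 0.1
    dilate_s: float = 240.0                  # region-proposal widening of abnormal runs
    flank_s: float = 60.0
    depth_hypopnea: float = 0.3
    depth_apnea: float = 0.9
    min_event_s: float = 10.0
    smooth_s: float = 2.25                   # median smoothing of rwa before depth
    bridge_gap_s: float = 10.0               # masked gap bridged inside one event
    effort_band_hz: tuple[float, float] = (0.15, 0.5)
    effort_power_ratio: float = 0.25


@dataclass
class StagingConfig:
    epoch_s: float = 30.0
    max_gap_fraction: float = 0.5
    model: str = "logistic"                  # or "mlp"
    smooth_epochs: int = 5
    train_seed: int = 2024


@dataclass
class ScoringConfig:
    ahi_threshold: float = 15.0
    pct_tst_grey_below: float = 50.0
    relevance_grey_below: float = 50.0
    relevance_green_at: float = 70.0


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    rhythm: RhythmConfig = field(default_factory=RhythmConfig)
    edr: EdrConfig = field(default_factory=EdrConfig)
    events: EventConfig = field(default_factory=EventConfig)
    staging: StagingConfig = field(default_factory=StagingConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            if dataclasses.is_dataclass(f.type) or f.name in (
                "preprocess", "rhythm", "edr", "events", "staging", "scoring"
            ):
                sub = {
                    "preprocess": PreprocessConfig, "rhythm": RhythmConfig,
                    "edr": EdrConfig, "events": EventConfig,
                    "staging": StagingConfig, "scoring": ScoringConfig,
                }[f.name]
                sd = dict(d[f.name])
                for sf in dataclasses.fields(sub):
                    if sf.name in sd and isinstance(sd[sf.name], list):
                        sd[sf.name] = tuple(sd[sf.name])
                kwargs[f.name] = sub(**sd)
            else:
                kwargs[f.name] = d[f.name]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
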