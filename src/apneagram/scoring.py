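"""AHI, severity, syndrome mechanism and the traffic-light reliability index.

The apnea–hypopnea index is the number of confirmed apneas plus hypopneas
per hour of total sleep time. Severity classes use left-closed bounds:
none < 5 /h <= mild < 15 <= moderate < 30 <= severe. When AHI >= 15 /h the
syndrome is central if central apneas make up more than half of all events,
obstructive otherwise. The reliability index combines the percentage of
sleep time the algorithm could analyze with a relevance score (how much the
detected events resemble the abnormal-breathing cluster); its traffic-light
color is grey (not reportable) when either axis is below 50 %, green when
relevance reaches 70 % with at least half the sleep analyzed, orange
in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScoringConfig
from .io import EventAnnotation


class UndefinedAhiError(ValueError):
    """AHI cannot be formed (no sleep time)."""


@dataclass
class ReliabilityIndex:
    pct_tst_analyzed: float
    relevance: float
    color: str

    def __post_init__(self) -> None:
        for v in (self.pct_tst_analyzed, self.relevance):
            if not 0.0 <= v <= 100.0:
                raise ValueError("reliability inputs must lie in [0, 100]")


@dataclass
class ScreeningReport:
    ahi: float | None
    tst_h: float
    n_apnea: int
    n_hypopnea: int
    n_central: int
    n_obstructive: int
    severity: str
    syndrome: str
    reliability: ReliabilityIndex
    qrs_morphology: str = "unknown"
    analyzable_hours: float = 0.0
    gate_passed: bool = True
    gate_reason: str = ""
    events: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Nocturnal ECG screening report",
            "------------------------------",
            f"AHI: {self.ahi:.1f} /h" if self.ahi is not None else "AHI: not available",
            f"TST: {self.tst_h:.2f} h",
            f"events: {self.n_apnea} apneas ({self.n_central} central, "
            f"{self.n_obstructive} obstructive), {self.n_hypopnea} hypopneas",
            f"severity: {self.severity}   syndrome: {self.syndrome}",
            f"reliability: {self.reliability.color} "
            f"(analyzed {self.reliability.pct_tst_analyzed:.0f}% of TST, "
            f"relevance {self.reliability.relevance:.0f}%)",
            f"QRS morphology: {self.qrs_morphology}",
        ]
        if not self.gate_passed:
            lines.append(f"not analyzable: {self.gate_reason}")
        return "\n".join(lines)


def compute_ahi(events: list[EventAnnotation], tst_h: float) -> float:
    """Apneas + hypopneas per hour of total sleep time."""
    if tst_h <= 0:
        raise UndefinedAhiError(f"total sleep time must be positive, got {tst_h}")
    n = sum(1 for e in events if e.kind in ("apnea", "hypopnea"))
    return n / tst_h


def severity_class(ahi: float) -> str:
    if ahi < 0:
        raise ValueError(f"AHI must be non-negative, got {ahi}")
    if ahi < 5:
        return "none"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def syndrome_mechanism(
    n_central: int, n_apnea: int, n_hypopnea: int, ahi: float
) -> str:
    """CSAHS when central apneas dominate; only defined for AHI >= 15 /h."""
    if ahi < 15:
        return "none"
    total = n_apnea + n_hypopnea
    if total == 0:
        return "none"
    return "CSAHS" if n_central / total > 0.5 else "OSAHS"


def relevance_score(
    events: list[EventAnnotation],
    window_z: np.ndarray | None = None,
    abnormal_labels: np.ndarray | None = None,
) -> float:
    """Percent resemblance of the detected events to the abnormal cluster.

    Mean of per-event confidences (1/(1+d) with d the standardized distance
    to the abnormal-cluster centroid). Event-free records fall back to the
    tightness of the single normal cluster.
    """
    confs = [e.confidence for e in events if e.confidence is not None]
    if confs:
        return 100.0 * float(np.mean(confs))
    if window_z is not None and len(window_z):
        centroid = window_z.mean(axis=0)
        d = np.linalg.norm(window_z - centroid, axis=1) / window_z.shape[1]
        return 100.0 * float(np.mean(1.0 / (1.0 + d)))
    return 0.0


def reliability_color(
    pct_tst: float, relevance: float, cfg: ScoringConfig | None = None
) -> str:
    cfg = cfg or ScoringConfig()
    for v in (pct_tst, relevance):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"reliability inputs must lie in [0, 100], got {v}")
    if relevance < cfg.relevance_grey_below or pct_tst < cfg.pct_tst_grey_below:
        return "grey"
    if relevance < cfg.relevance_green_at:
        return "orange"
    return "green"


def build_report(
    events: list[EventAnnotation],
    tst_h: float,
    pct_tst_analyzed: float,
    relevance: float,
    qrs_morphology: str = "unknown",
    analyzable_hours: float = 0.0,
    gate_passed: bool = True,
    gate_reason: str = "",
    cfg: ScoringConfig | None = None,
) -> ScreeningReport:
    cfg = cfg or ScoringConfig()
    n_apnea = sum(e.kind == "apnea" for e in events)
    n_hyp = sum(e.kind == "hypopnea" for e in events)
    n_cen = sum(e.mechanism == "central" for e in events)
    n_obs = sum(e.mechanism == "obstructive" for e in events)
    if gate_passed and tst_h > 0:
        ahi = compute_ahi(events, tst_h)
        severity = severity_class(ahi)
        syndrome = syndrome_mechanism(n_cen, n_apnea, n_hyp, ahi)
        color = reliability_color(pct_tst_analyzed, relevance, cfg)
    else:
        ahi, severity, syndrome, color = None, "none", "none", "grey"
    rel = ReliabilityIndex(
        pct_tst_analyzed=float(np.clip(pct_tst_analyzed, 0, 100)),
        relevance=float(np.clip(relevance, 0, 100)),
        color=color,
    )
    return ScreeningReport(
        ahi=ahi, tst_h=tst_h, n_apnea=n_apnea, n_hypopnea=n_hyp,
        n_central=n_cen, n_obstructive=n_obs, severity=severity,
        syndrome=syndrome, reliability=rel, qrs_morphology=qrs_morphology,
        analyzable_hours=analyzable_hours, gate_passed=gate_passed,
        gate_reason=gate_reason,
        events=[{
            "start": e.start, "end": e.end, "kind": e.kind,
            "mechanism": e.mechanism, "confidence": e.confidence,
        } for e in events],
    )
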