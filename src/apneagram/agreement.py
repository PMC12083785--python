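"""Agreement and classification statistics for method-vs-reference AHI.

Bland–Altman agreement: with differences d_i = AHI_ref,i − AHI_est,i,

    b  = mean(d),   σ = sample SD of d (N−1),
    lh = b + 1.96 σ,   ll = b − 1.96 σ.

Threshold classification at a fixed AHI cut-off (15 /h by default,
left-closed): Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), Acc = (TP+TN)/N, F1 = 2·PPV·Se/(PPV+Se). A metric whose
denominator vanishes is reported as undefined (None), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AgreementResult:
    b: float          # bias, mean of (ref - est)
    sigma: float      # sample SD of the differences
    lh: float         # upper 95 % limit of agreement
    ll: float         # lower 95 % limit of agreement
    n: int


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def bias_and_loa(ref, est) -> AgreementResult:
    """Bland–Altman bias and 95 % limits of agreement for ref − est."""
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {est.shape}")
    if ref.size < 2:
        raise ValueError("at least two paired measurements are required")
    d = ref - est
    b = float(d.mean())
    sigma = float(d.std(ddof=1))
    return AgreementResult(b=b, sigma=sigma, lh=b + 1.96 * sigma,
                           ll=b - 1.96 * sigma, n=d.size)


def limits_from_bias_sd(b: float, sigma: float) -> tuple[float, float]:
    """(ll, lh) from a printed bias and SD — the closed-form limb of Bland–Altman."""
    return b - 1.96 * sigma, b + 1.96 * sigma


def confusion_at_threshold(ref, est, thr: float = 15.0) -> ConfusionCounts:
    """Tally exams; positive means AHI >= thr on either axis."""
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {est.shape}")
    rp, ep = ref >= thr, est >= thr
    return ConfusionCounts(
        tp=int(np.sum(rp & ep)), fp=int(np.sum(~rp & ep)),
        tn=int(np.sum(~rp & ~ep)), fn=int(np.sum(rp & ~ep)),
    )


def classification_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Se, Sp, PPV, NPV, Acc and F1; undefined metrics are None."""
    if c.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    se = ratio(c.tp, c.tp + c.fn)
    sp = ratio(c.tn, c.tn + c.fp)
    ppv = ratio(c.tp, c.tp + c.fp)
    npv = ratio(c.tn, c.tn + c.fn)
    acc = (c.tp + c.tn) / c.total
    f1 = f1_score(ppv, se)
    return {"Se": se, "Sp": sp, "PPV": ppv, "NPV": npv, "Acc": acc, "F1": f1}


def f1_score(ppv: float | None, se: float | None) -> float | None:
    """Harmonic mean of precision and sensitivity; None when undefined."""
    if ppv is None or se is None or (ppv + se) == 0:
        return None
    return 2.0 * ppv * se / (ppv + se)
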