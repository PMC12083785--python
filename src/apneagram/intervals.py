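"""Half-open interval arithmetic on ``[start, end)`` second pairs.

All pipeline stages exchange time ranges as plain ``(start, end)`` float
tuples in seconds from record start.  The helpers here keep them sorted,
disjoint and clipped, so each stage can reason about durations without
re-deriving set algebra.
"""

from __future__ import annotations

import numpy as np

Interval = tuple[float, float]


def normalize(intervals: list[Interval]) -> list[Interval]:
    """Sort, drop empty, and merge overlapping/touching intervals."""
    ivs = sorted((float(s), float(e)) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_duration(intervals: list[Interval]) -> float:
    return float(sum(e - s for s, e in normalize(intervals)))


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    a, b = normalize(a), normalize(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def complement(intervals: list[Interval], span: Interval) -> list[Interval]:
    """Intervals of ``span`` not covered by ``intervals``."""
    lo, hi = span
    out: list[Interval] = []
    cur = lo
    for s, e in intersect(normalize(intervals), [span]):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if hi > cur:
        out.append((cur, hi))
    return out


def subtract(a: list[Interval], b: list[Interval], span: Interval | None = None) -> list[Interval]:
    if span is None:
        if not a:
            return []
        span = (min(s for s, _ in a), max(e for _, e in a))
    return intersect(a, complement(b, span))


def contains(intervals: list[Interval], t: np.ndarray) -> np.ndarray:
    """Boolean mask: which times fall inside any interval (half-open)."""
    t = np.asarray(t, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    for s, e in intervals:
        mask |= (t >= s) & (t < e)
    return mask


def overlap_fraction(truth: Interval, detected: list[Interval]) -> float:
    """Fraction of ``truth`` covered by the detected interval set."""
    dur = truth[1] - truth[0]
    if dur <= 0:
        return 0.0
    return total_duration(intersect([truth], detected)) / dur
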