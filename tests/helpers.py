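"""Shared test utilities: series builders and brute-force window oracles.

The oracles re-derive the baseline-window definitions with nothing but
date arithmetic and full scans, independently of the package's own
implementation, so agreement is a real check rather than a tautology.
"""

from __future__ import annotations

import statistics
from datetime import date, timedelta

from akilinked import ScrResult

D0 = date(2014, 6, 15)
WIDE_OBS = (D0 - timedelta(days=1000), D0 + timedelta(days=1000))


def mk(day: int, value: float, seq: int = 0, pid: str = "p1") -> ScrResult:
    """A result `day` days after the reference date D0."""
    return ScrResult(pid, D0 + timedelta(days=day), seq, float(value))


def series_from(points) -> list[ScrResult]:
    """Build an ordered series from (day, value) or (day, seq, value) tuples."""
    out = []
    for p in points:
        if len(p) == 2:
            out.append(mk(p[0], p[1]))
        else:
            day, seq, value = p
            out.append(mk(day, value, seq=seq))
    return sorted(out, key=lambda r: (r.test_date, r.seq))


# --- brute-force oracles ---------------------------------------------------

def oracle_short_min(series, i, short_days=7):
    idx = series[i]
    vals = [
        r.value
        for j, r in enumerate(series)
        if j < i and 0 <= (idx.test_date - r.test_date).days <= short_days
    ]
    return min(vals) if vals else None


def oracle_long_median(series, i, lo=8, hi=365):
    idx = series[i]
    vals = [
        r.value
        for j, r in enumerate(series)
        if j < i and lo <= (idx.test_date - r.test_date).days <= hi
    ]
    return float(statistics.median(vals)) if vals else None


def oracle_rise(series, i, window=2):
    idx = series[i]
    vals = [
        r.value
        for j, r in enumerate(series)
        if j < i and 0 <= (idx.test_date - r.test_date).days <= window
    ]
    return idx.value - min(vals) if vals else None
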