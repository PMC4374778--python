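"""Breakpoint-resolution analysis via RO-threshold sweeps.

Tightening the reciprocal-overlap threshold penalises imprecise breakpoints:
a caller whose boundaries wobble loses matches (and hence inherited rate)
faster than one that nails them.  The sweep summarises each tool by the mean
slope of its inherited-rate curve over the threshold grid; a slope near zero
indicates precise breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .family_metrics import QuartetCalls, inherited_rate

DEFAULT_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))  # 0.1 .. 0.9


@dataclass(frozen=True)
class SweepCurve:
    thresholds: tuple[float, ...]
    rates: tuple[float, ...]  # family-averaged inherited rate per threshold

    @property
    def mean_slope(self) -> float:
        return mean_slope(self)


def ro_sweep(
    quartet_callsets: Sequence[QuartetCalls],
    thresholds: Sequence[float] = DEFAULT_GRID,
) -> SweepCurve:
    """Inherited rate averaged over families at each RO threshold.

    Families whose twins called no CNVs are skipped at every threshold (the
    rate is undefined there, not zero).
    """
    thr = tuple(float(t) for t in thresholds)
    if len(thr) < 2:
        raise ValueError("need at least 2 thresholds")
    if any(not 0 < t <= 1 for t in thr):
        raise ValueError("thresholds must lie in (0, 1]")
    if any(b <= a for a, b in zip(thr, thr[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rates = []
    for t in thr:
        fam_rates = [
            r for q in quartet_callsets if (r := inherited_rate(q, t).rate) is not None
        ]
        if not fam_rates:
            raise ValueError("inherited rate undefined for every family")
        rates.append(float(np.mean(fam_rates)))
    return SweepCurve(thresholds=thr, rates=tuple(rates))


def mean_slope(curve: SweepCurve) -> float:
    """Mean of successive finite differences Δrate/Δthreshold; on a uniform
    grid this equals the endpoint slope."""
    if len(curve.thresholds) < 2:
        raise ValueError("a slope needs at least 2 points")
    t = np.asarray(curve.thresholds)
    r = np.asarray(curve.rates)
    return float(np.mean(np.diff(r) / np.diff(t)))
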