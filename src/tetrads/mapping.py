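"""Closed-form tetrad genetics: map distances and crossover interference.

Given PD/TT/NPD tallies for a two-marker interval in ``N = PD + TT + NPD``
tetrads, the Perkins estimator of genetic distance is

    cM = 100 * (TT/2 + 3*NPD) / N,

where the ``3*NPD`` term corrects for the double crossovers that
nonparental ditypes reveal.  Its standard error follows from the
multinomial distribution of (PD, TT, NPD) by the delta method:

    se_cM = 100 * sqrt[ (t(1-t)/4 + 9 d(1-d) - 3 t d) / N ],

with t = TT/N and d = NPD/N (equivalently Var(w)/N for the per-tetrad
crossover score w in {0, 1/2, 3}).

Crossover interference is quantified as the ratio of observed NPDs to the
count expected, at the observed tetratype frequency, from a
no-interference (Poisson chiasma) model:

    E[NPD] = N * 1/2 * [ 1 - f_T - (1 - 3 f_T / 2)^(2/3) ],   f_T = TT/N.

The power term is evaluated on the real cube-root branch,
``cbrt(1 - 3 f_T / 2)**2``, which keeps the expectation defined and
positive for f_T < 3/4 — tetratype frequencies above the Poisson ceiling
of 2/3 do occur in strongly interfering intervals.  A ratio below 1
indicates positive interference.  When NPD = 0 or the bracket is
non-positive the ratio is undefined and reported as "n.d.";
the ratio's standard error takes the observed NPD count as Poisson,
se = ratio / sqrt(NPD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import IntervalCounts, MarkerMap

ND = "n.d."


@dataclass(frozen=True)
class MapEstimate:
    """Map distance and interference summary for one interval."""

    interval: tuple[str, str]
    n: int
    cm: float
    se_cm: float
    f_t: float
    npd_expected: float | None
    interference: float | None
    se_interference: float | None

    @property
    def interference_label(self) -> str:
        if self.interference is None:
            return ND
        return f"{self.interference:.2f}"


@dataclass(frozen=True)
class ChromosomeSummary:
    chromosome: str
    cm: float
    percent_of_reference: float | None = None


def perkins_distance(counts: IntervalCounts) -> tuple[float, float]:
    """Perkins map distance (cM) and its delta-method standard error."""
    n = counts.n
    if n == 0:
        raise ValueError(f"empty interval {counts.interval}")
    t = counts.tt / n
    d = counts.npd / n
    cm = 100.0 * (t / 2.0 + 3.0 * d)
    var = (t * (1.0 - t) / 4.0 + 9.0 * d * (1.0 - d) - 3.0 * t * d) / n
    return cm, 100.0 * float(np.sqrt(var))


def papazian_expected_npd(counts: IntervalCounts) -> float | None:
    """Expected NPD count under no interference at the observed f_T.

    Returns ``None`` (reported as "n.d.") when the expectation is not
    positive, i.e. f_T >= 3/4.
    """
    n = counts.n
    if n == 0:
        raise ValueError(f"empty interval {counts.interval}")
    f_t = counts.tt / n
    bracket = 1.0 - f_t - float(np.cbrt(1.0 - 1.5 * f_t)) ** 2
    expected = n * 0.5 * bracket
    if counts.tt == 0:
        return 0.0
    if expected <= 0.0:
        return None
    return expected


def interference_ratio(counts: IntervalCounts) -> tuple[float, float] | None:
    """Observed/expected NPD ratio with Poisson standard error, or None (n.d.)."""
    if counts.npd == 0:
        return None
    expected = papazian_expected_npd(counts)
    if expected is None or expected == 0.0:
        return None
    ratio = counts.npd / expected
    return ratio, ratio / float(np.sqrt(counts.npd))


def estimate_interval(counts: IntervalCounts) -> MapEstimate:
    cm, se = perkins_distance(counts)
    expected = papazian_expected_npd(counts)
    ratio = interference_ratio(counts)
    return MapEstimate(
        interval=counts.interval,
        n=counts.n,
        cm=cm,
        se_cm=se,
        f_t=counts.tt / counts.n,
        npd_expected=expected,
        interference=None if ratio is None else ratio[0],
        se_interference=None if ratio is None else ratio[1],
    )


def chromosome_cumulative(
    estimates: Sequence[MapEstimate],
    marker_map: MarkerMap,
    chromosome: str,
    rounded: bool = True,
) -> ChromosomeSummary:
    """Cumulative genetic length of one chromosome.

    With ``rounded=True`` (the reporting convention) each interval distance
    is rounded to 1 decimal before summing, so the cumulative value equals
    the sum of the distances as printed.
    """
    by_interval = {e.interval: e for e in estimates}
    total = 0.0
    missing = []
    for interval in marker_map.intervals_on(chromosome):
        est = by_interval.get(interval) or by_interval.get(interval[::-1])
        if est is None:
            missing.append(interval)
            continue
        total += round(est.cm, 1) if rounded else est.cm
    if missing:
        raise ValueError(f"missing interval estimates for {chromosome}: {missing}")
    return ChromosomeSummary(chromosome=chromosome, cm=total)


def percent_of_reference(value: float, reference_value: float) -> float:
    """100 * value / reference; report layers round to integer."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * value / reference_value
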