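"""Statistical tests applied to tetrad summaries.

Two-proportion Z-tests (pooled standard error), Fisher's exact 2x2 test,
Student's t-tests, and an exact binomial test of whether the two converted
markers of double-gene-conversion tetrads are adjacent on the genetic map
more often than a uniform draw of marker pairs predicts.  Also builds the
per-strain gene-conversion summary table.

Standard tests are delegated to scipy/statsmodels; the module fixes the
conventions used throughout (pooled-SE Z, probability-mass-summation
two-sided Fisher, unadjusted p-values by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .model import MarkerMap, Tetrad, gene_conversions


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-SE two-proportion Z statistic and two-sided normal p-value.

    Degenerate pooled proportions (0 or 1) leave no variation to test;
    they return z=0, p=1 with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        warnings.warn("degenerate pooled proportion; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2])
    return float(z), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided by summation of hypergeometric probabilities no larger than
    the observed table's (not by doubling a tail).  Any zero margin fixes
    the table and returns p = 1 with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("zero margin in 2x2 table; returning p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def t_test(
    group1: Sequence[float],
    group2: Sequence[float],
    tails: int = 2,
    paired: bool = False,
    alternative: str | None = None,
) -> tuple[float, float]:
    """Student's t-test between two groups.

    ``tails=2`` is the default two-sided test; ``tails=1`` requires (or
    defaults to) ``alternative='greater'``, testing mean(group1) >
    mean(group2).  ``paired=True`` uses the paired statistic.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if alternative is None:
        alternative = "two-sided" if tails == 2 else "greater"
    if tails == 2 and alternative != "two-sided":
        raise ValueError("tails=2 implies alternative='two-sided'")
    if tails == 1 and alternative not in ("greater", "less"):
        raise ValueError("tails=1 requires alternative 'greater' or 'less'")
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        res = sps.ttest_rel(a, b, alternative=alternative)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        if np.var(a) == 0.0 and np.var(b) == 0.0 and np.mean(a) == np.mean(b):
            # identical constant groups: no variation, define t=0, p at null
            return 0.0, 1.0 if tails == 2 else 0.5
        res = sps.ttest_ind(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AdjacencyResult:
    n_events: int
    observed_adjacent: int
    expected_adjacent: float
    p_adjacent_null: float
    p_value: float


def gc_adjacency_test(
    double_gc_tetrads: Sequence[Tetrad], marker_map: MarkerMap
) -> AdjacencyResult:
    """Are the two converted markers of double-conversion tetrads adjacent
    more often than chance?

    Null model: the two converted markers are a uniform draw from all
    C(M, 2) unordered marker pairs; adjacency means consecutive markers on
    the same chromosome (cross-chromosome pairs are never adjacent).  The
    p-value is a two-sided exact binomial test of the observed adjacent
    count among the events.
    """
    m = len(marker_map.marker_names)
    n_pairs = comb(m, 2)
    adjacent = marker_map.adjacent_pairs()
    p_null = len(adjacent) / n_pairs
    observed = 0
    for tet in double_gc_tetrads:
        converted = gene_conversions(tet, marker_map)
        if len(converted) != 2:
            raise ValueError(
                f"tetrad {tet.tetrad_id!r} has {len(converted)} conversions, expected 2"
            )
        if frozenset(converted) in adjacent:
            observed += 1
    n = len(double_gc_tetrads)
    if n == 0:
        return AdjacencyResult(0, 0, 0.0, p_null, 1.0)
    p = float(sps.binomtest(observed, n, p_null, alternative="two-sided").pvalue)
    return AdjacencyResult(n, observed, n * p_null, p_null, p)


def gc_summary_from_counts(
    counts: pd.DataFrame,
    reference: str,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-strain gene-conversion summary from aggregate counts.

    ``counts`` needs columns ``strain``, ``n_tetrads`` (4-spore-viable
    tetrads analysed), ``with_gc`` (tetrads with >= 1 conversion),
    ``total_gcs``, and optionally ``gcs_chr`` columns giving the
    per-chromosome split of conversions (``pct_chr_*`` passthrough columns
    are kept as-is).  Each strain is compared to ``reference`` with:

    * a two-proportion Z-test on the fraction of tetrads with >= 1
      conversion (``p_freq``),
    * a two-proportion Z-test on conversions per tetrad (``p_rate``), and
    * Fisher's exact test on the converted/unconverted tetrad 2x2
      (``p_fisher``).

    The conversion-rate ratio versus the reference is computed from the
    2-decimal-rounded rates, matching how such tables are conventionally
    presented.  ``adjust=True`` appends Benjamini-Hochberg-adjusted columns
    (off by default: the primary report is unadjusted).
    """
    required = {"strain", "n_tetrads", "with_gc", "total_gcs"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if reference not in set(counts["strain"]):
        raise ValueError(f"reference strain {reference!r} absent from counts")
    ref = counts.set_index("strain").loc[reference]
    ref_rate = round(ref["total_gcs"] / ref["n_tetrads"], 2)

    rows = []
    for _, row in counts.iterrows():
        n = int(row["n_tetrads"])
        with_gc = int(row["with_gc"])
        total = int(row["total_gcs"])
        rate = total / n if n else 0.0
        rec = {
            "strain": row["strain"],
            "n_tetrads": n,
            "with_gc": with_gc,
            "pct_with_gc": 100.0 * with_gc / n if n else 0.0,
            "total_gcs": total,
            "gc_per_tetrad": rate,
            "rate_vs_reference": (round(rate, 2) / ref_rate) if ref_rate else 0.0,
            "without_gc": n - with_gc,
        }
        if row["strain"] == reference or n == 0:
            rec["p_freq"] = rec["p_rate"] = rec["p_fisher"] = np.nan
        else:
            rec["p_freq"] = two_proportion_z(
                with_gc, n, int(ref["with_gc"]), int(ref["n_tetrads"])
            )[1]
            rec["p_rate"] = two_proportion_z(
                total, n, int(ref["total_gcs"]), int(ref["n_tetrads"])
            )[1]
            rec["p_fisher"] = fisher_exact_2x2(
                with_gc, n - with_gc,
                int(ref["with_gc"]), int(ref["n_tetrads"]) - int(ref["with_gc"]),
            )
        for col in counts.columns:
            if col.startswith("pct_chr") or col.startswith("gcs_chr"):
                rec[col] = row[col]
        rows.append(rec)
    out = pd.DataFrame(rows)
    if adjust:
        for col in ("p_freq", "p_rate", "p_fisher"):
            mask = out[col].notna()
            adj = np.full(len(out), np.nan)
            if mask.any():
                adj[mask.to_numpy()] = multipletests(
                    out.loc[mask, col], method="fdr_bh"
                )[1]
            out[col + "_bh"] = adj
    return out


def summarize_gene_conversions(
    tetrads_by_strain: Mapping[str, Sequence[Tetrad]],
    marker_map: MarkerMap,
    reference: str,
    adjust: bool = False,
) -> pd.DataFrame:
    """Gene-conversion summary computed from 4-spore-viable tetrads.

    Tallies conversions per strain (including the per-chromosome split of
    conversion events) and applies the reference-strain comparisons of
    :func:`gc_summary_from_counts`.
    """
    if reference not in tetrads_by_strain:
        raise ValueError(f"reference strain {reference!r} absent")
    chroms = marker_map.chromosomes
    records = []
    for strain, tetrads in tetrads_by_strain.items():
        with_gc = 0
        per_chrom = {c: 0 for c in chroms}
        total = 0
        for tet in tetrads:
            converted = gene_conversions(tet, marker_map)
            if converted:
                with_gc += 1
                total += len(converted)
                for marker in converted:
                    per_chrom[marker_map.chromosome_of(marker)] += 1
        rec = {
            "strain": strain,
            "n_tetrads": len(tetrads),
            "with_gc": with_gc,
            "total_gcs": total,
        }
        for c in chroms:
            rec[f"gcs_chr_{c}"] = per_chrom[c]
            rec[f"pct_chr_{c}"] = 100.0 * per_chrom[c] / total if total else 0.0
        records.append(rec)
    return gc_summary_from_counts(pd.DataFrame(records), reference, adjust=adjust)
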