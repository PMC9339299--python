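"""Tidy report tables: map distances, viability, gene conversion.

Builders accept either raw tetrads or pre-tallied counts, so the same
report code serves simulator output and published count tables.  All
values are kept at full precision here; presentation rounding lives in
:func:`tetrads.io.format_report`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import mapping
from .model import IntervalCounts, MarkerMap, Tetrad, filter_for_mapping, tabulate_interval_counts
from .stats import gc_summary_from_counts, summarize_gene_conversions
from .viability import NDJResult, ViabilityTable, infer_mi_ndj, viability_table


def interval_counts_frame(
    counts_by_strain: Mapping[str, Sequence[IntervalCounts]], marker_map: MarkerMap
) -> pd.DataFrame:
    rows = []
    for strain, counts in counts_by_strain.items():
        for c in counts:
            rows.append(
                {
                    "strain": strain,
                    "interval": "-".join(c.interval),
                    "chromosome": marker_map.chromosome_of(c.interval[0]),
                    "pd": c.pd, "tt": c.tt, "npd": c.npd, "excluded": c.excluded,
                }
            )
    return pd.DataFrame(rows)


def map_report(
    counts: pd.DataFrame, marker_map: MarkerMap, reference: str
) -> pd.DataFrame:
    """Map-distance report, one row per strain x interval.

    ``counts`` needs columns strain, interval ("A-B"), pd, tt, npd.
    Per-interval and per-chromosome percentages are relative to the
    reference strain; the cumulative chromosome distance follows the
    presentation convention of summing interval values rounded to 1
    decimal.  Interference columns are None where undefined (NPD = 0).
    """
    strains = list(dict.fromkeys(counts["strain"]))
    if reference not in strains:
        raise ValueError(f"reference strain {reference!r} absent from counts")
    estimates: dict[str, dict[tuple[str, str], mapping.MapEstimate]] = {}
    for strain in strains:
        sub = counts[counts["strain"] == strain].set_index("interval")
        per = {}
        for a, b in marker_map.intervals:
            key = f"{a}-{b}"
            if key not in sub.index:
                raise ValueError(f"strain {strain!r} missing interval {key}")
            row = sub.loc[key]
            per[(a, b)] = mapping.estimate_interval(
                IntervalCounts(
                    (a, b), int(row["pd"]), int(row["tt"]), int(row["npd"]),
                    int(row.get("excluded", 0) or 0),
                )
            )
        estimates[strain] = per
    chrom_cm = {
        (strain, chrom): mapping.chromosome_cumulative(
            list(per.values()), marker_map, chrom
        ).cm
        for strain, per in estimates.items()
        for chrom in marker_map.chromosomes
    }
    rows = []
    for strain in strains:
        for (a, b), est in estimates[strain].items():
            chrom = marker_map.chromosome_of(a)
            ref_est = estimates[reference][(a, b)]
            rows.append(
                {
                    "strain": strain,
                    "interval": f"{a}-{b}",
                    "chromosome": chrom,
                    "pd": counts.set_index(["strain", "interval"]).loc[(strain, f"{a}-{b}"), "pd"],
                    "tt": counts.set_index(["strain", "interval"]).loc[(strain, f"{a}-{b}"), "tt"],
                    "npd": counts.set_index(["strain", "interval"]).loc[(strain, f"{a}-{b}"), "npd"],
                    "n": est.n,
                    "cm": est.cm,
                    "se_cm": est.se_cm,
                    "pct_wt": mapping.percent_of_reference(est.cm, ref_est.cm),
                    "cm_chrom": chrom_cm[(strain, chrom)],
                    "pct_wt_chrom": mapping.percent_of_reference(
                        chrom_cm[(strain, chrom)], chrom_cm[(reference, chrom)]
                    ),
                    "npd_expected": est.npd_expected,
                    "ratio": est.interference,
                    "se_ratio": est.se_interference,
                }
            )
    return pd.DataFrame(rows)


def map_report_from_tetrads(
    tetrads_by_strain: Mapping[str, Sequence[Tetrad]],
    marker_map: MarkerMap,
    reference: str,
    max_conversions: int = 2,
) -> pd.DataFrame:
    counts = {
        strain: tabulate_interval_counts(
            filter_for_mapping(tets, marker_map, max_conversions), marker_map
        )
        for strain, tets in tetrads_by_strain.items()
    }
    return map_report(interval_counts_frame(counts, marker_map), marker_map, reference)


def viability_report_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Viability report from class counts.

    ``counts`` needs columns strain, c4..c0 and optionally ndj_events /
    ndj_examined and sporulation columns; derived percentages are computed
    here.
    """
    rows = []
    for _, row in counts.iterrows():
        classes = tuple(int(row[f"c{k}"]) for k in (4, 3, 2, 1, 0))
        table = ViabilityTable(
            strain=row["strain"], total=sum(classes), classes=classes
        )
        rec = {"strain": row["strain"]}
        if "sporulation_pct" in counts.columns:
            rec["sporulation_pct"] = row["sporulation_pct"]
        rec.update(
            {
                "pct_viability": table.percent_viability,
                "total_tetrads": table.total,
                "c4": classes[0], "c3": classes[1], "c2": classes[2],
                "c1": classes[3], "c0": classes[4],
            }
        )
        events = row.get("ndj_events")
        examined = row.get("ndj_examined")
        if events is None or pd.isna(events):
            rec["ndj_pct"] = None
            rec["ndj_fraction"] = "n.d."
        else:
            res = NDJResult(row["strain"], int(examined), int(events))
            rec["ndj_pct"] = res.percent
            rec["ndj_fraction"] = f"{res.events}/{res.examined}"
        rows.append(rec)
    return pd.DataFrame(rows)


def viability_report_from_tetrads(
    tetrads_by_strain: Mapping[str, Sequence[Tetrad]]
) -> pd.DataFrame:
    rows = []
    for strain, tets in tetrads_by_strain.items():
        table = viability_table(tets, strain=strain)
        ndj = infer_mi_ndj(tets, strain=strain)
        rows.append(
            {
                "strain": strain,
                "c4": table.classes[0], "c3": table.classes[1],
                "c2": table.classes[2], "c1": table.classes[3],
                "c0": table.classes[4],
                "ndj_events": ndj.events if ndj.examined else None,
                "ndj_examined": ndj.examined if ndj.examined else None,
            }
        )
    return viability_report_from_counts(pd.DataFrame(rows))


def gc_report_from_tetrads(
    tetrads_by_strain: Mapping[str, Sequence[Tetrad]],
    marker_map: MarkerMap,
    reference: str,
    adjust: bool = False,
) -> pd.DataFrame:
    """Gene-conversion report over the 4-spore-viable tetrads of each strain."""
    four_viable = {
        strain: [t for t in tets if t.n_viable == 4]
        for strain, tets in tetrads_by_strain.items()
    }
    return summarize_gene_conversions(four_viable, marker_map, reference, adjust=adjust)


def gc_report_from_counts(
    counts: pd.DataFrame, reference: str, adjust: bool = False
) -> pd.DataFrame:
    return gc_summary_from_counts(counts, reference, adjust=adjust)
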