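"""Bundled reference data: the published tetrad counts of a histone
H2A.Z/H1 meiosis study in *Saccharomyces cerevisiae*.

Four isogenic diploid strains (wild type, *htz1*, *hho1* and the double
mutant) were dissected and scored at 9 heterozygous markers spanning 7
genetic intervals: HIS4-CEN3-MAT-RAD18-HMR on chromosome III and
SPO11-SPO13-THR1-LYS2 on chromosome VIII.  The tables here carry the raw
counts as published — interval PD/TT/NPD tallies, spore-viability class
counts with chromosome III nondisjunction events, and gene-conversion
tallies — plus the study's printed derived values for regression-style
cross-checks.  All downstream numbers (map distances, standard errors,
interference ratios, viability and conversion statistics) are recomputed
from these counts by the package.
"""

from __future__ import annotations

import pandas as pd

from .model import MarkerMap

WILD_TYPE = "wild_type"
STRAINS = (WILD_TYPE, "htz1", "hho1", "htz1_hho1")

#: true wild-type interval distances (cM), used as simulator defaults
WT_INTERVAL_CM: dict[tuple[str, str], float] = {
    ("HIS4", "CEN3"): 28.4,
    ("CEN3", "MAT"): 19.3,
    ("MAT", "RAD18"): 35.0,
    ("RAD18", "HMR"): 20.8,
    ("SPO11", "SPO13"): 41.6,
    ("SPO13", "THR1"): 10.6,
    ("THR1", "LYS2"): 32.4,
}


def reference_marker_map() -> MarkerMap:
    """The 9-marker / 7-interval map of the reference cross.

    The chromosome III centromere is the scored CEN3 marker (index 1);
    CEN8 is not scored and is placed midway through the SPO11-SPO13
    interval (only the simulator's segregation mechanics consume it).
    """
    return MarkerMap.from_pairs(
        [
            ("HIS4", "III"), ("CEN3", "III"), ("MAT", "III"),
            ("RAD18", "III"), ("HMR", "III"),
            ("SPO11", "VIII"), ("SPO13", "VIII"), ("THR1", "VIII"),
            ("LYS2", "VIII"),
        ],
        centromere_index={"III": 1.0, "VIII": 0.5},
    )


# strain, interval, chromosome, PD, TT, NPD,
# published cM, SE, %WT, obs/exp NPD ratio, ratio SE (None where n.d.)
_INTERVAL_ROWS = [
    (WILD_TYPE, "HIS4-CEN3", "III", 230, 251, 4, 28.4, 1.6, 100, 0.14, 0.07),
    (WILD_TYPE, "CEN3-MAT", "III", 320, 165, 4, 19.3, 1.6, 100, 0.43, 0.22),
    (WILD_TYPE, "MAT-RAD18", "III", 176, 305, 6, 35.0, 1.7, 100, 0.11, 0.05),
    (WILD_TYPE, "RAD18-HMR", "III", 306, 179, 4, 20.8, 1.6, 100, 0.36, 0.18),
    (WILD_TYPE, "SPO11-SPO13", "VIII", 166, 301, 17, 41.6, 2.5, 100, 0.33, 0.09),
    (WILD_TYPE, "SPO13-THR1", "VIII", 386, 89, 2, 10.6, 1.2, 100, 0.84, 0.60),
    (WILD_TYPE, "THR1-LYS2", "VIII", 192, 278, 5, 32.4, 1.7, 100, 0.12, 0.06),
    ("htz1", "HIS4-CEN3", "III", 127, 168, 7, 34.8, 2.7, 123, 0.32, 0.13),
    ("htz1", "CEN3-MAT", "III", 181, 125, 2, 22.2, 1.9, 115, 0.22, 0.16),
    ("htz1", "MAT-RAD18", "III", 87, 214, 6, 40.7, 2.5, 116, 0.22, 0.06),
    ("htz1", "RAD18-HMR", "III", 180, 129, 0, 20.9, 1.4, 101, None, None),
    ("htz1", "SPO11-SPO13", "VIII", 114, 176, 14, 42.8, 3.5, 103, 0.57, 0.17),
    ("htz1", "SPO13-THR1", "VIII", 257, 46, 0, 7.6, 1.0, 72, None, None),
    ("htz1", "THR1-LYS2", "VIII", 119, 180, 2, 31.9, 1.9, 98, 0.07, 0.05),
    ("hho1", "HIS4-CEN3", "III", 215, 290, 5, 31.4, 1.6, 111, 0.13, 0.06),
    ("hho1", "CEN3-MAT", "III", 349, 172, 0, 16.5, 1.0, 85, None, None),
    ("hho1", "MAT-RAD18", "III", 186, 312, 15, 39.2, 2.3, 112, 0.30, 0.09),
    ("hho1", "RAD18-HMR", "III", 285, 226, 4, 24.3, 1.5, 117, 0.21, 0.11),
    ("hho1", "SPO11-SPO13", "VIII", 171, 326, 19, 42.6, 2.4, 102, 0.32, 0.08),
    ("hho1", "SPO13-THR1", "VIII", 391, 107, 1, 11.3, 1.1, 107, 0.30, 0.30),
    ("hho1", "THR1-LYS2", "VIII", 247, 242, 7, 28.6, 1.8, 88, 0.29, 0.11),
    ("htz1_hho1", "HIS4-CEN3", "III", 166, 192, 7, 32.1, 2.4, 113, 0.32, 0.13),
    ("htz1_hho1", "CEN3-MAT", "III", 211, 154, 2, 22.6, 1.7, 117, 0.17, 0.12),
    ("htz1_hho1", "MAT-RAD18", "III", 124, 234, 6, 37.1, 2.1, 106, 0.13, 0.06),
    ("htz1_hho1", "RAD18-HMR", "III", 195, 158, 5, 26.3, 2.2, 126, 0.38, 0.18),
    ("htz1_hho1", "SPO11-SPO13", "VIII", 125, 220, 18, 45.2, 3.3, 109, 0.51, 0.14),
    ("htz1_hho1", "SPO13-THR1", "VIII", 286, 69, 0, 9.7, 1.1, 92, None, None),
    ("htz1_hho1", "THR1-LYS2", "VIII", 167, 186, 1, 27.1, 1.5, 84, 0.05, 0.05),
]

#: published cumulative chromosome distances (cM) and percent of wild type
PUBLISHED_CHROMOSOME_CM = {
    (WILD_TYPE, "III"): (103.5, 100), (WILD_TYPE, "VIII"): (84.6, 100),
    ("htz1", "III"): (118.6, 115), ("htz1", "VIII"): (82.24, 97),
    ("hho1", "III"): (111.33, 108), ("hho1", "VIII"): (82.59, 98),
    ("htz1_hho1", "III"): (118.02, 114), ("htz1_hho1", "VIII"): (82.02, 97),
}


def reference_interval_counts(published: bool = False) -> pd.DataFrame:
    """PD/TT/NPD tallies for all 28 strain x interval combinations.

    With ``published=True`` the study's printed derived values (cM, SE,
    percent of wild type, interference ratio and its SE) are included for
    cross-checking recomputations.
    """
    cols = [
        "strain", "interval", "chromosome", "pd", "tt", "npd",
        "published_cm", "published_se", "published_pct_wt",
        "published_ratio", "published_ratio_se",
    ]
    df = pd.DataFrame(_INTERVAL_ROWS, columns=cols)
    if not published:
        df = df[["strain", "interval", "chromosome", "pd", "tt", "npd"]]
    return df


# strain, sporulation % (n cells), viability class counts 4..0,
# NDJ events / 2-spore-viable examined (None = not determined)
_VIABILITY_ROWS = [
    (WILD_TYPE, 50, 6800, 503, 64, 15, 2, 0, 0, 15),
    ("htz1", 48, 6841, 320, 251, 102, 48, 60, 1, 102),
    ("hho1", 56, 6795, 533, 64, 41, 5, 0, None, None),
    ("htz1_hho1", 48, 2601, 415, 284, 127, 35, 8, 1, 127),
]


def reference_viability_counts() -> pd.DataFrame:
    """Sporulation efficiency, viability class counts and NDJ events."""
    return pd.DataFrame(
        _VIABILITY_ROWS,
        columns=[
            "strain", "sporulation_pct", "cells_counted",
            "c4", "c3", "c2", "c1", "c0",
            "ndj_events", "ndj_examined",
        ],
    )


# strain, 4-spore-viable tetrads analysed, tetrads with >=1 conversion,
# total conversions, published per-chromosome split of conversions (%)
_GC_ROWS = [
    (WILD_TYPE, 497, 42, 63, 44, 56),
    ("htz1", 314, 34, 42, 36, 64),
    ("hho1", 530, 64, 91, 45, 55),
    ("htz1_hho1", 396, 68, 150, 75, 25),
]


def reference_gc_counts() -> pd.DataFrame:
    """Gene-conversion tallies per strain (4-spore-viable tetrads only)."""
    return pd.DataFrame(
        _GC_ROWS,
        columns=[
            "strain", "n_tetrads", "with_gc", "total_gcs",
            "pct_chr_III", "pct_chr_VIII",
        ],
    )


#: published per-strain spore viability (%) and NDJ rates (%) for cross-checks
PUBLISHED_VIABILITY_PCT = {WILD_TYPE: 96, "htz1": 73, "hho1": 94, "htz1_hho1": 81}
PUBLISHED_NDJ_PCT = {"htz1": 0.98, "htz1_hho1": 0.79}

#: published gene-conversion statistics for cross-checks
PUBLISHED_GC = pd.DataFrame(
    [
        (WILD_TYPE, 8, None, 0.13, None, 1.0, None),
        ("htz1", 11, 0.26, 0.13, 0.77, 1.0, 0.2675),
        ("hho1", 12, 0.056, 0.17, 0.044, 1.3, 0.0645),
        ("htz1_hho1", 17, 0.0001, 0.38, 0.0001, 2.9, 0.0001),
    ],
    columns=[
        "strain", "pct_with_gc", "p_freq", "gc_per_tetrad", "p_rate",
        "rate_vs_reference", "p_fisher",
    ],
)
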