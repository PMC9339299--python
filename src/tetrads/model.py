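"""Core tetrad data model and segregation/classification logic.

A tetrad is the set of four haploid spores produced by one yeast meiosis.
Each spore is genotyped at a panel of heterozygous markers; the two parental
alleles at every marker are encoded abstractly as ``P`` and ``Q`` (a strain
sheet maps them to concrete alleles such as *HIS4*/*his4*).  Dead spores
carry no genotype.

This module turns raw per-spore genotypes into

* per-marker segregation calls (``2:2`` is Mendelian; ``3:1``/``1:3``/
  ``4:0``/``0:4`` are gene conversions),
* parental-ditype / tetratype / nonparental-ditype (PD/TT/NPD) calls for
  marker intervals,
* spore-viability classes, and
* the filtered tetrad sets used for linkage mapping.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

ALLELE_P = "P"
ALLELE_Q = "Q"
MISSING = "-"
ALLELE_CODES = frozenset({ALLELE_P, ALLELE_Q, MISSING})

#: per-marker segregation patterns (viable-spore P:Q counts)
MENDELIAN = "2:2"
INCOMPLETE = "incomplete"
SEGREGATION_PATTERNS = ("2:2", "3:1", "1:3", "4:0", "0:4", INCOMPLETE)

#: two-marker tetrad classes
PD, TT, NPD, EXCLUDED = "PD", "TT", "NPD", "excluded"

MATING_CODES = frozenset({"a", "alpha", "non", "nd"})


class TetradError(ValueError):
    """Raised for structurally invalid tetrads or map/table mismatches."""


@dataclass(frozen=True)
class Marker:
    name: str
    chromosome: str


@dataclass(frozen=True)
class MarkerMap:
    """Ordered heterozygous markers grouped by chromosome.

    Marker order within a chromosome follows the genetic map and defines
    the set of adjacent-marker intervals (``k`` markers give ``k - 1``
    intervals).  ``centromere_index`` locates the centromere of each
    chromosome in marker-order coordinates: an integer value means the
    centromere coincides with that marker (e.g. *CEN3* scored as a marker),
    a fractional value places it between two markers.  Only the forward
    simulator consumes centromere positions.
    """

    markers: tuple[Marker, ...]
    centromere_index: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(names) != len(set(names)):
            dup = [n for n, c in Counter(names).items() if c > 1]
            raise TetradError(f"duplicate marker names in map: {dup}")
        if not self.markers:
            raise TetradError("marker map is empty")
        for chrom, idx in self.centromere_index.items():
            n = len(self.markers_on(chrom))
            if n == 0:
                raise TetradError(f"centromere given for unknown chromosome {chrom!r}")
            if not (0.0 <= float(idx) <= n - 1):
                raise TetradError(
                    f"centromere index {idx} outside marker range of chromosome {chrom}"
                )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chromosome, None)
        return tuple(seen)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def markers_on(self, chromosome: str) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers if m.chromosome == chromosome)

    def chromosome_of(self, marker: str) -> str:
        for m in self.markers:
            if m.name == marker:
                return m.chromosome
        raise TetradError(f"unknown marker {marker!r}")

    def intervals_on(self, chromosome: str) -> tuple[tuple[str, str], ...]:
        names = self.markers_on(chromosome)
        return tuple(zip(names[:-1], names[1:]))

    @property
    def intervals(self) -> tuple[tuple[str, str], ...]:
        out: list[tuple[str, str]] = []
        for chrom in self.chromosomes:
            out.extend(self.intervals_on(chrom))
        return tuple(out)

    def adjacent_pairs(self) -> frozenset[frozenset[str]]:
        """Unordered adjacent same-chromosome marker pairs."""
        return frozenset(frozenset(iv) for iv in self.intervals)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        centromere_index: Mapping[str, float] | None = None,
    ) -> "MarkerMap":
        return cls(
            tuple(Marker(n, c) for n, c in pairs),
            dict(centromere_index or {}),
        )


@dataclass
class Spore:
    viable: bool
    mating: str = "nd"
    alleles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mating not in MATING_CODES:
            raise TetradError(f"unknown mating code {self.mating!r}")
        for marker, allele in self.alleles.items():
            if allele not in ALLELE_CODES:
                raise TetradError(f"unknown allele code {allele!r} at {marker}")
        if not self.viable:
            bad = [m for m, a in self.alleles.items() if a != MISSING]
            if bad:
                raise TetradError(f"dead spore carries alleles at {bad}")


@dataclass
class Tetrad:
    strain: str
    tetrad_id: str
    spores: tuple[Spore, Spore, Spore, Spore]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise TetradError(
                f"tetrad {self.tetrad_id!r} has {len(self.spores)} spores, expected 4"
            )
        self.spores = tuple(self.spores)  # type: ignore[assignment]

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)

    @property
    def viable_spores(self) -> tuple[Spore, ...]:
        return tuple(s for s in self.spores if s.viable)


@dataclass(frozen=True)
class IntervalCounts:
    """PD/TT/NPD tally for one genetic interval in one strain."""

    interval: tuple[str, str]
    pd: int
    tt: int
    npd: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.pd, self.tt, self.npd, self.excluded) < 0:
            raise ValueError("negative interval counts")

    @property
    def n(self) -> int:
        """Tetrads entering the map-distance estimate (PD + TT + NPD)."""
        return self.pd + self.tt + self.npd

    @property
    def total(self) -> int:
        return self.n + self.excluded


def score_marker_segregation(tetrad: Tetrad, marker: str) -> str:
    """Score the P:Q segregation pattern of one marker in a 4-spore-viable tetrad.

    Returns one of ``2:2``, ``3:1``, ``1:3``, ``4:0``, ``0:4`` or
    ``incomplete`` (any viable spore unscored at the marker).  Non-2:2
    patterns are gene-conversion calls.
    """
    if tetrad.n_viable != 4:
        raise TetradError(
            f"segregation scoring requires 4 viable spores, tetrad "
            f"{tetrad.tetrad_id!r} has {tetrad.n_viable}"
        )
    p = q = 0
    for spore in tetrad.spores:
        allele = spore.alleles.get(marker)
        if allele is None:
            raise TetradError(f"marker {marker!r} absent from tetrad {tetrad.tetrad_id!r}")
        if allele == MISSING:
            return INCOMPLETE
        if allele == ALLELE_P:
            p += 1
        else:
            q += 1
    return f"{p}:{q}"


def gene_conversions(tetrad: Tetrad, marker_map: MarkerMap) -> list[str]:
    """Names of markers showing non-Mendelian (non-2:2) segregation.

    ``incomplete`` markers are not counted as conversions.  Requires a
    4-spore-viable tetrad; callers must filter first.
    """
    if tetrad.n_viable != 4:
        raise TetradError(
            f"gene-conversion counting requires 4 viable spores, tetrad "
            f"{tetrad.tetrad_id!r} has {tetrad.n_viable}"
        )
    converted = []
    for marker in marker_map.marker_names:
        pattern = score_marker_segregation(tetrad, marker)
        if pattern not in (MENDELIAN, INCOMPLETE):
            converted.append(marker)
            if pattern in ("4:0", "0:4"):
                # cannot be distinguished from a genotyping error; kept as a
                # conversion but surfaced for auditing
                logger.warning(
                    "tetrad %s marker %s segregates %s (possible genotyping error)",
                    tetrad.tetrad_id, marker, pattern,
                )
    return converted


def count_gene_conversions(tetrad: Tetrad, marker_map: MarkerMap) -> int:
    return len(gene_conversions(tetrad, marker_map))


def classify_interval(tetrad: Tetrad, marker_a: str, marker_b: str) -> str:
    """Classify a two-marker interval as PD, TT, NPD or ``excluded``.

    A tetrad is excluded from an interval's tally iff it is not
    4-spore-viable or either flanking marker is non-2:2 or incomplete.
    With both markers segregating 2:2, the four two-marker spore genotypes
    are either two distinct parental classes (PD), two distinct recombinant
    classes (NPD), or all four classes (TT).

    The classification is symmetric in marker order and is permitted for
    markers on different chromosomes (used for independence checks).
    """
    if tetrad.n_viable != 4:
        return EXCLUDED
    for marker in (marker_a, marker_b):
        if score_marker_segregation(tetrad, marker) != MENDELIAN:
            return EXCLUDED
    genotypes = {
        (s.alleles[marker_a], s.alleles[marker_b]) for s in tetrad.spores
    }
    if len(genotypes) == 4:
        return TT
    # both markers 2:2 forces exactly 2 or 4 distinct genotypes
    if genotypes == {(ALLELE_P, ALLELE_P), (ALLELE_Q, ALLELE_Q)}:
        return PD
    return NPD


def classify_viability(tetrad: Tetrad) -> int:
    """Number of viable (germinating) spores, 0..4."""
    return tetrad.n_viable


def filter_for_mapping(
    tetrads: Sequence[Tetrad],
    marker_map: MarkerMap,
    max_conversions: int = 2,
) -> list[Tetrad]:
    """Select tetrads usable for linkage mapping.

    Keeps tetrads with exactly 4 viable spores and at most
    ``max_conversions`` gene conversions (default 2, the standard cutoff
    that drops likely false tetrads and aberrant meioses).  Counts removed
    per rule are logged.
    """
    kept: list[Tetrad] = []
    n_dead = n_gc = 0
    for tet in tetrads:
        if tet.n_viable != 4:
            n_dead += 1
        elif count_gene_conversions(tet, marker_map) > max_conversions:
            n_gc += 1
        else:
            kept.append(tet)
    logger.info(
        "filter_for_mapping: %d in, %d kept, %d removed (not 4-spore-viable), "
        "%d removed (> %d gene conversions)",
        len(tetrads), len(kept), n_dead, n_gc, max_conversions,
    )
    return kept


def tabulate_interval_counts(
    tetrads: Sequence[Tetrad], marker_map: MarkerMap
) -> list[IntervalCounts]:
    """PD/TT/NPD tallies for every map interval.

    Exclusion is interval-by-interval: a tetrad with a converted flanking
    marker drops out of that interval only, so PD+TT+NPD totals may differ
    between intervals of the same strain.  For every interval,
    PD+TT+NPD+excluded equals the number of tetrads submitted.
    """
    if not tetrads:
        logger.warning("tabulate_interval_counts: empty tetrad list, all-zero counts")
    out = []
    for a, b in marker_map.intervals:
        tally = Counter(classify_interval(t, a, b) for t in tetrads)
        out.append(
            IntervalCounts(
                interval=(a, b),
                pd=tally[PD],
                tt=tally[TT],
                npd=tally[NPD],
                excluded=tally[EXCLUDED],
            )
        )
    return out
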