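"""Forward simulator of single yeast meioses emitting tetrad tables.

Each chromosome is a line in genetic coordinates (Morgans) on which
chiasmata fall as a point process with mean 2x events per bivalent over a
length of x Morgans — the density under which 1 cM of map equals 1%
recombinant spores for short intervals.  Configured interval distances are
*map* distances, i.e. what the Perkins estimator measures: because the
estimator fully corrects double but not higher-order multiple crossovers,
its expectation over an interval of raw length x falls slightly below
100x cM once x is large.  The simulator therefore calibrates marker
placement, inverting the Perkins expectation under the configured
interference level so that the estimate converges to the configured
distance (the correction is fractions of a cM below ~30 cM and vanishes
under strong interference).

Chiasma interference follows the counting (chi-square) model: underlying
events arrive as a Poisson stream of rate 2(m+1) per Morgan and every
(m+1)-th event matures into a chiasma, started in its stationary phase.
``m = 0`` recovers a Poisson (no-interference) process; larger ``m``
suppresses nearby chiasmata, driving the observed/expected NPD ratio below
one.  Each chiasma joins one chromatid from each homolog, chosen uniformly
and independently (no chromatid interference) — the assumption underlying
both the Perkins and the expected-NPD formulas.

Downstream of crossing over the simulator applies, in order: per-marker
gene conversion (a random spore's allele overwritten, giving 3:1 or 1:3
from 2:2), meiosis-I nondisjunction (both homologs to one pole: two
disomic viable spores — nonmaters when the MAT-bearing chromosome is
involved — and two dead nullisomic spores), meiosis-II precocious
sister-chromatid separation (one disomic and one dead spore, typically a
3-spore-viable tetrad), and independent random spore death.  Dead spores
carry no genotype.

All randomness flows from one seeded generator; the draw order is fixed
(per chromosome: chiasmata, strand choices, centromere orientation, spore
assignment; then conversions per marker; then missegregation per
chromosome; then death per spore), so a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .model import (
    ALLELE_P,
    ALLELE_Q,
    MISSING,
    MarkerMap,
    Spore,
    Tetrad,
)
from .viability import mating_phenotype

_MAT_ALLELE = {ALLELE_P: "a", ALLELE_Q: "alpha"}


def _as_rate_map(value: float | Mapping[str, float], chromosomes: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {c: float(value.get(c, 0.0)) for c in chromosomes}
    else:
        out = {c: float(value) for c in chromosomes}
    for c, r in out.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} for chromosome {c} outside [0, 1]")
    return out


def perkins_expectation(length_morgans: float, m: int) -> float:
    """Expected Perkins distance (Morgans) over a raw interval of the
    chiasma line, under the counting model with parameter ``m``.

    The per-tetrad Perkins score w in {0, 1/2, 3} has E[w | k chiasmata] =
    5/6 + (2/3)(-1/2)^k for k >= 1 under uniform non-sister strand choice,
    so E[w] = sum_j inc_j * P(N >= j) with inc_1 = 1/2 and
    inc_j = -(-1/2)^(j-1); the stationary chiasma-count tail P(N >= j)
    is Poisson for m = 0 and a uniform phase mixture of gamma CDFs for
    the thinned process otherwise.
    """
    x = float(length_morgans)
    if x <= 0.0:
        return 0.0
    if m == 0:
        return 5.0 / 6.0 + (2.0 / 3.0) * np.exp(-3.0 * x) - 1.5 * np.exp(-2.0 * x)
    rate = 2.0 * (m + 1)
    total = 0.0
    for j in range(1, 40):
        shapes = j * (m + 1) - np.arange(m + 1)
        tail = float(np.mean(gamma_dist.cdf(x, a=shapes, scale=1.0 / rate)))
        if tail < 1e-12:
            break
        inc = 0.5 if j == 1 else -((-0.5) ** (j - 1))
        total += inc * tail
    return total


def calibrate_interval_length(target_morgans: float, m: int) -> float:
    """Raw chiasma-line length whose expected Perkins distance equals the
    target map distance (only defined below the 5/6 Morgan ceiling)."""
    d = float(target_morgans)
    if d <= 0.0:
        return 0.0
    if d >= 5.0 / 6.0:
        raise ValueError(
            f"map distance {100 * d:.1f} cM at or above the 83.3 cM Perkins ceiling"
        )
    hi = d
    while perkins_expectation(hi, m) < d:
        hi *= 1.5
        if hi > 50.0:  # pragma: no cover - unreachable below the ceiling
            raise ValueError("calibration failed to bracket")
    return float(brentq(lambda x: perkins_expectation(x, m) - d, d * 0.999, hi))


@dataclass
class SimulationConfig:
    """Parameters of one simulated dissection experiment.

    ``interval_cm`` gives the true genetic distance of every adjacent-marker
    interval; ``interference_m`` is the counting-model parameter (0 = none);
    ``gene_conversion_prob`` is the per-marker per-meiosis conversion
    probability; missegregation rates are per chromosome per meiosis and
    ``spore_death_prob`` is an independent per-spore death probability.
    The seed is mandatory and echoed into the output provenance.
    """

    marker_map: MarkerMap
    interval_cm: Mapping[tuple[str, str], float]
    n_tetrads: int
    seed: int
    interference_m: int = 4
    gene_conversion_prob: float = 0.015
    mi_ndj_prob: float | Mapping[str, float] = 0.0
    mii_pssc_prob: float | Mapping[str, float] = 0.0
    spore_death_prob: float = 0.04
    strain: str = "sim"
    mat_marker: str = "MAT"

    def __post_init__(self) -> None:
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.interference_m < 0 or int(self.interference_m) != self.interference_m:
            raise ValueError("interference_m must be a non-negative integer")
        if not 0.0 <= self.gene_conversion_prob <= 1.0:
            raise ValueError("gene_conversion_prob outside [0, 1]")
        if not 0.0 <= self.spore_death_prob <= 1.0:
            raise ValueError("spore_death_prob outside [0, 1]")
        for interval in self.marker_map.intervals:
            d = self.interval_cm.get(interval, self.interval_cm.get(interval[::-1]))
            if d is None:
                raise ValueError(f"no true distance configured for interval {interval}")
            if d < 0:
                raise ValueError(f"negative distance for interval {interval}")
        self._mi = _as_rate_map(self.mi_ndj_prob, self.marker_map.chromosomes)
        self._mii = _as_rate_map(self.mii_pssc_prob, self.marker_map.chromosomes)
        # calibrated chiasma-line marker coordinates, per chromosome
        self._positions: dict[str, dict[str, float]] = {}
        for chrom in self.marker_map.chromosomes:
            names = self.marker_map.markers_on(chrom)
            pos = {names[0]: 0.0}
            for a, b in zip(names[:-1], names[1:]):
                raw = calibrate_interval_length(
                    self.distance((a, b)) / 100.0, self.interference_m
                )
                pos[b] = pos[a] + raw
            self._positions[chrom] = pos

    def distance(self, interval: tuple[str, str]) -> float:
        d = self.interval_cm.get(interval)
        if d is None:
            d = self.interval_cm[interval[::-1]]
        return float(d)

    def marker_positions(self, chromosome: str) -> dict[str, float]:
        """Calibrated cumulative marker coordinates (Morgans) on the
        chiasma line of one chromosome."""
        return self._positions[chromosome]

    def centromere_position(self, chromosome: str) -> float:
        """Centromere coordinate in Morgans (defaults to the first marker)."""
        idx = float(self.marker_map.centromere_index.get(chromosome, 0.0))
        names = self.marker_map.markers_on(chromosome)
        pos = self.marker_positions(chromosome)
        lo = int(np.floor(idx))
        frac = idx - lo
        if frac == 0.0 or lo + 1 >= len(names):
            return pos[names[lo]]
        return pos[names[lo]] + frac * (pos[names[lo + 1]] - pos[names[lo]])


@dataclass(frozen=True)
class ChromosomeTrace:
    chromosome: str
    #: (position in Morgans, pick within the local P-origin strand pair,
    #:  pick within the local Q-origin strand pair), picks in {0, 1}
    chiasmata: tuple[tuple[float, int, int], ...]
    orientation: int          # which centromere origin goes to the first MI pole
    pole_perms: tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class MeiosisTrace:
    """Everything stochastic about crossing over and assortment in one meiosis."""

    chromosomes: tuple[ChromosomeTrace, ...] = field(default_factory=tuple)


def chiasma_count_model(
    length_morgans: float, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Chiasma positions on a bivalent of the given genetic length.

    ``m = 0``: Poisson process with mean ``2 * length`` chiasmata (two
    spores of four are recombinant per chiasma, so the realized map length
    matches).  ``m > 0``: stationary counting-model renewal — every
    (m+1)-th event of a rate-``2(m+1)`` Poisson stream is a chiasma.
    """
    if length_morgans < 0:
        raise ValueError("genetic length must be non-negative")
    if length_morgans == 0.0:
        return np.empty(0)
    if m == 0:
        k = rng.poisson(2.0 * length_morgans)
        return np.sort(rng.uniform(0.0, length_morgans, size=k))
    rate = 2.0 * (m + 1)
    positions = []
    # stationary phase: intermediate events already accumulated at the origin
    counter = int(rng.integers(0, m + 1))
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= length_morgans:
            break
        counter += 1
        if counter == m + 1:
            positions.append(t)
            counter = 0
    return np.asarray(positions)


def draw_meiosis_trace(config: SimulationConfig, rng: np.random.Generator) -> MeiosisTrace:
    """Draw chiasmata, strand choices and assortment for one meiosis."""
    traces = []
    for chrom in config.marker_map.chromosomes:
        pos = config.marker_positions(chrom)
        length = max(pos.values())
        xs = chiasma_count_model(length, config.interference_m, rng)
        chiasmata = tuple(
            (float(x), int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            for x in xs
        )
        orientation = int(rng.integers(0, 2))
        perm_a = tuple(int(v) for v in rng.permutation(2))
        perm_b = tuple(int(v) for v in rng.permutation(2))
        traces.append(
            ChromosomeTrace(chrom, chiasmata, orientation, (perm_a, perm_b))
        )
    return MeiosisTrace(tuple(traces))


def resolve_tetrad(trace: MeiosisTrace, config: SimulationConfig) -> Tetrad:
    """Propagate alleles through the traced exchanges and segregate.

    Spores 0,1 descend from the first MI pole and 2,3 from the second;
    every spore is viable and fully genotyped (gene conversion,
    missegregation and death are applied by later stages).
    """
    marker_map = config.marker_map
    spore_alleles: list[dict[str, str]] = [{} for _ in range(4)]
    for ct in trace.chromosomes:
        names = marker_map.markers_on(ct.chromosome)
        pos = config.marker_positions(ct.chromosome)
        cen = config.centromere_position(ct.chromosome)
        # chromatids 0,1 replicate homolog P; 2,3 replicate homolog Q
        alleles = [[ALLELE_P] * len(names) for _ in range(2)] + [
            [ALLELE_Q] * len(names) for _ in range(2)
        ]
        cen_origin = [0, 0, 1, 1]
        # origin of each chromatid's sequence at the current position; a
        # chiasma joins one strand of each local origin (never "sisters")
        local_origin = [0, 0, 1, 1]
        for x, pick_p, pick_q in sorted(ct.chiasmata):
            i = [c for c in range(4) if local_origin[c] == 0][pick_p]
            j = [c for c in range(4) if local_origin[c] == 1][pick_q]
            for k, name in enumerate(names):
                if pos[name] > x:
                    alleles[i][k], alleles[j][k] = alleles[j][k], alleles[i][k]
            if cen > x:
                cen_origin[i], cen_origin[j] = cen_origin[j], cen_origin[i]
            local_origin[i], local_origin[j] = 1, 0
        pole_a = [k for k in range(4) if cen_origin[k] == ct.orientation]
        pole_b = [k for k in range(4) if cen_origin[k] != ct.orientation]
        perm_a, perm_b = ct.pole_perms
        assignment = [
            pole_a[perm_a[0]], pole_a[perm_a[1]],
            pole_b[perm_b[0]], pole_b[perm_b[1]],
        ]
        for spore_idx, chromatid in enumerate(assignment):
            for k, name in enumerate(names):
                spore_alleles[spore_idx][name] = alleles[chromatid][k]
    spores = tuple(
        Spore(viable=True, mating=_mating_of(sa, config), alleles=sa)
        for sa in spore_alleles
    )
    return Tetrad(strain=config.strain, tetrad_id="", spores=spores)  # type: ignore[arg-type]


def _mating_of(alleles: Mapping[str, str], config: SimulationConfig) -> str:
    allele = alleles.get(config.mat_marker)
    if allele in (ALLELE_P, ALLELE_Q):
        return mating_phenotype({_MAT_ALLELE[allele]})
    return "nd"


def apply_gene_conversion(
    tetrad: Tetrad, g: float, rng: np.random.Generator, config: SimulationConfig
) -> Tetrad:
    """Convert each marker independently with probability ``g``.

    A conversion overwrites a uniformly chosen spore's allele with the
    other homolog's, turning a 2:2 marker into 3:1 or 1:3 with equal
    probability.  Conversion of the MAT marker updates the spore's mating
    phenotype.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError("conversion probability outside [0, 1]")
    spores = [
        Spore(s.viable, s.mating, dict(s.alleles)) for s in tetrad.spores
    ]
    for marker in config.marker_map.marker_names:
        if rng.random() >= g:
            continue
        target = spores[int(rng.integers(0, 4))]
        current = target.alleles[marker]
        target.alleles[marker] = ALLELE_Q if current == ALLELE_P else ALLELE_P
        if marker == config.mat_marker:
            target.mating = _mating_of(target.alleles, config)
    return replace(tetrad, spores=tuple(spores))


def apply_missegregation_and_death(
    tetrad: Tetrad, config: SimulationConfig, rng: np.random.Generator
) -> Tetrad:
    """Apply MI NDJ, MII precocious sister separation, and random death.

    MI NDJ of a chromosome sends all four chromatids to one MI pole: after
    a normal MII each of that pole's spores carries one chromatid of each
    homolog (disomic, nonmating when the MAT chromosome is involved) and
    the other pole's spores are nullisomic and dead.  MII PSSC leaves one
    spore disomic for two sister chromatids and kills its MII sibling.
    Disomic spores are scored at a marker only when their two chromatids
    agree (heterozygous markers are unscorable and left missing).
    Independent random death is applied last; dead spores are blanked.
    """
    marker_map = config.marker_map
    alleles = [dict(s.alleles) for s in tetrad.spores]
    # extra chromatid carried by a disomic spore, per chromosome
    extra: list[dict[str, dict[str, str]]] = [{} for _ in range(4)]
    dead = [False] * 4
    poles = ((0, 1), (2, 3))
    for chrom in marker_map.chromosomes:
        names = marker_map.markers_on(chrom)
        mi = rng.random() < config._mi[chrom]
        mii = rng.random() < config._mii[chrom]
        if mi:
            keep = poles[int(rng.integers(0, 2))]
            lost = poles[1 - poles.index(keep)]
            partners = list(lost)
            if rng.integers(0, 2):
                partners.reverse()
            for spore_idx, partner in zip(keep, partners):
                extra[spore_idx][chrom] = {n: alleles[partner][n] for n in names}
            for spore_idx in lost:
                dead[spore_idx] = True
        elif mii:
            pole = poles[int(rng.integers(0, 2))]
            receiver = int(rng.integers(0, 2))
            spore_idx, sibling = pole[receiver], pole[1 - receiver]
            extra[spore_idx][chrom] = {n: alleles[sibling][n] for n in names}
            dead[sibling] = True
    if config.spore_death_prob > 0.0:
        for idx in range(4):
            if rng.random() < config.spore_death_prob:
                dead[idx] = True
    spores = []
    for idx in range(4):
        if dead[idx]:
            spores.append(
                Spore(False, "nd", {n: MISSING for n in marker_map.marker_names})
            )
            continue
        own = alleles[idx]
        mat_chrom = None
        if config.mat_marker in marker_map.marker_names:
            mat_chrom = marker_map.chromosome_of(config.mat_marker)
        mat_set = set()
        if mat_chrom is not None and own.get(config.mat_marker) in _MAT_ALLELE:
            mat_set.add(_MAT_ALLELE[own[config.mat_marker]])
        for chrom, second in extra[idx].items():
            for name in marker_map.markers_on(chrom):
                if chrom == mat_chrom and name == config.mat_marker:
                    if second[name] in _MAT_ALLELE:
                        mat_set.add(_MAT_ALLELE[second[name]])
                if own[name] != second[name]:
                    own[name] = MISSING
        mating = mating_phenotype(mat_set) if mat_set else "nd"
        spores.append(Spore(True, mating, own))
    return replace(tetrad, spores=tuple(spores))


def simulate_experiment(config: SimulationConfig) -> list[Tetrad]:
    """Simulate ``n_tetrads`` meioses; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_tetrads))
    out = []
    for i in range(config.n_tetrads):
        trace = draw_meiosis_trace(config, rng)
        tet = resolve_tetrad(trace, config)
        tet = apply_gene_conversion(tet, config.gene_conversion_prob, rng, config)
        tet = apply_missegregation_and_death(tet, config, rng)
        tet = replace(tet, tetrad_id=f"{config.strain}-{i + 1:0{width}d}")
        out.append(tet)
    return out
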