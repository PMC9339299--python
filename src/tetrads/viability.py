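"""Sporulation, spore-viability and meiosis-I nondisjunction summaries.

Spore viability is the fraction of dissected spores that germinate; the
distribution of tetrads over 4-/3-/2-/1-/0-spore-viable classes is itself
diagnostic: meiosis-I nondisjunction (MI NDJ) of a single chromosome
yields 2-spore-viable tetrads, while precocious sister-chromatid
separation enriches the 3-spore-viable class.

MI NDJ of the *MAT*-bearing chromosome (III in S. cerevisiae) is directly
observable: the two surviving spores are disomic for chromosome III, carry
both *MATa* and *MATalpha*, and therefore cannot mate.  The NDJ rate is
reported as double-nonmater tetrads over the 2-spore-viable class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import Tetrad


@dataclass(frozen=True)
class ViabilityTable:
    strain: str
    total: int
    classes: tuple[int, int, int, int, int]  # counts of 4-,3-,2-,1-,0-spore-viable

    def __post_init__(self) -> None:
        if sum(self.classes) != self.total:
            raise ValueError("viability class counts do not sum to total tetrads")

    @property
    def percent_viability(self) -> float:
        """100 * viable spores / dissected spores."""
        if self.total == 0:
            return 0.0
        viable = sum(k * c for k, c in zip((4, 3, 2, 1, 0), self.classes))
        return 100.0 * viable / (4 * self.total)

    @property
    def class_percents(self) -> tuple[float, ...]:
        if self.total == 0:
            return (0.0,) * 5
        return tuple(100.0 * c / self.total for c in self.classes)

    @classmethod
    def from_tetrads(cls, tetrads: Sequence[Tetrad], strain: str = "") -> "ViabilityTable":
        classes = [0, 0, 0, 0, 0]
        for tet in tetrads:
            classes[4 - tet.n_viable] += 1
        if not strain and tetrads:
            strain = tetrads[0].strain
        return cls(strain=strain, total=len(tetrads), classes=tuple(classes))


@dataclass(frozen=True)
class NDJResult:
    strain: str
    examined: int  # 2-spore-viable tetrads with both survivors' mating scored
    events: int    # both viable spores nonmaters

    @property
    def percent(self) -> float:
        return 100.0 * self.events / self.examined if self.examined else 0.0


def sporulation_efficiency(
    dyads: int, triads: int, tetrads: int, unsporulated: int
) -> float:
    """Percent of diploids forming spores (dyads, triads or tetrads)."""
    total = dyads + triads + tetrads + unsporulated
    if total <= 0:
        raise ValueError("no cells counted")
    return 100.0 * (dyads + triads + tetrads) / total


def viability_table(tetrads: Sequence[Tetrad], strain: str = "") -> ViabilityTable:
    return ViabilityTable.from_tetrads(tetrads, strain=strain)


def mating_phenotype(mat_alleles: set[str]) -> str:
    """Mating type from the set of MAT alleles a spore carries.

    A euploid spore carries one allele and mates as it; a spore disomic
    for the MAT-bearing chromosome carries both and is a nonmater.
    Alleles are given as ``{"a"}``, ``{"alpha"}`` or ``{"a", "alpha"}``.
    """
    if not mat_alleles:
        raise ValueError("spore carries no MAT allele (nullisomic spores are dead)")
    if not mat_alleles <= {"a", "alpha"}:
        raise ValueError(f"unknown MAT alleles {mat_alleles}")
    if mat_alleles == {"a", "alpha"}:
        return "non"
    return next(iter(mat_alleles))


def infer_mi_ndj(tetrads: Sequence[Tetrad], strain: str = "") -> NDJResult:
    """MI nondisjunction of the MAT-bearing chromosome from mating phenotypes.

    Counts 2-spore-viable tetrads whose two viable spores are both
    nonmaters.  A tetrad enters the denominator only if both viable spores
    have a scored mating phenotype ("nd" is missing data, never evidence);
    tetrads with 3 or more viable spores never contribute.
    """
    examined = events = 0
    for tet in tetrads:
        if tet.n_viable != 2:
            continue
        matings = [s.mating for s in tet.viable_spores]
        if "nd" in matings:
            continue
        examined += 1
        if matings == ["non", "non"]:
            events += 1
    if not strain and tetrads:
        strain = tetrads[0].strain
    return NDJResult(strain=strain, examined=examined, events=events)
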