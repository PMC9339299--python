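from __future__ import annotations

import pytest
from hypothesis import settings

from tetrads import MarkerMap, Spore, Tetrad
from tetrads.datasets import reference_marker_map

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mmap() -> MarkerMap:
    return reference_marker_map()


@pytest.fixture(scope="session")
def small_map() -> MarkerMap:
    return MarkerMap.from_pairs(
        [("A", "1"), ("B", "1"), ("C", "1"), ("X", "2"), ("Y", "2")]
    )


def build_tetrad(
    alleles_by_spore,
    viable=(True, True, True, True),
    mating=None,
    strain="s",
    tetrad_id="t1",
) -> Tetrad:
    """Construct a tetrad from per-spore allele dicts.

    Dead spores get their alleles blanked automatically.
    """
    mating = mating or ["nd"] * 4
    spores = []
    for alleles, ok, mat in zip(alleles_by_spore, viable, mating):
        if not ok:
            alleles = {m: "-" for m in alleles}
        spores.append(Spore(viable=ok, mating=mat, alleles=dict(alleles)))
    return Tetrad(strain=strain, tetrad_id=tetrad_id, spores=tuple(spores))


@pytest.fixture
def make_tetrad():
    return build_tetrad
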