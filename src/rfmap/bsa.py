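"""In-silico bulked segregant analysis (BSA).

DNA from the two phenotypic extremes of an F2 population is pooled; a
marker shows a pool-level difference only when it is linked to the
trait locus.  The observable for a bulk is modeled as the SET of
parental alleles present at a marker (band presence/absence on a
silver-stained gel), not allele dosage: a plant typed 'A' contributes
the A band, 'B' the B band and 'H' both.  Near a recessive trait locus
the sterile bulk shows only the A band, while the fertile bulk and any
unlinked marker show both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import F2Plant, GenotypeCall, Phenotype

_ALLELES = {
    GenotypeCall.A: frozenset({"A"}),
    GenotypeCall.B: frozenset({"B"}),
    GenotypeCall.H: frozenset({"A", "B"}),
    GenotypeCall.MISSING: frozenset(),
}


@dataclass
class Bulk:
    """A phenotype-defined DNA pool and its per-marker band pattern."""

    phenotype: Phenotype
    members: list[str]
    allele_pattern: dict[str, frozenset[str]]


def _pattern(plants: list[F2Plant], marker_names: list[str]) -> dict[str, frozenset[str]]:
    pattern = {}
    for name in marker_names:
        alleles: set[str] = set()
        for plant in plants:
            alleles |= _ALLELES[plant.call(name)]
        pattern[name] = frozenset(alleles)
    return pattern


def compose_bulks(
    population: list[F2Plant],
    marker_names: list[str],
    n_per_bulk: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[Bulk, Bulk]:
    """Randomly draw a fertile and a sterile bulk of ``n_per_bulk`` plants.

    Selection is reproducible under ``seed``; the allele pattern of each
    bulk is the union of member alleles per marker.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bulks = []
    for phenotype in (Phenotype.FERTILE, Phenotype.STERILE):
        members = [p for p in population if p.phenotype is phenotype]
        if len(members) < n_per_bulk:
            raise ValueError(
                f"only {len(members)} {phenotype.value} plants available, "
                f"need {n_per_bulk} for the bulk"
            )
        idx = rng.choice(len(members), size=n_per_bulk, replace=False)
        chosen = [members[i] for i in sorted(idx)]
        bulks.append(
            Bulk(phenotype, [p.plant_id for p in chosen], _pattern(chosen, marker_names))
        )
    return bulks[0], bulks[1]


def screen_parent_polymorphic(
    marker_names: list[str],
    parent_a_calls: dict[str, GenotypeCall],
    parent_b_calls: dict[str, GenotypeCall],
) -> list[str]:
    """Markers at which the two (inbred, homozygous) parents differ."""
    polymorphic = []
    for name in marker_names:
        a = parent_a_calls.get(name, GenotypeCall.MISSING)
        b = parent_b_calls.get(name, GenotypeCall.MISSING)
        for parent, call in (("A", a), ("B", b)):
            if call is GenotypeCall.H:
                raise ValueError(
                    f"parent {parent} is heterozygous at {name}; parents must be inbred"
                )
        if a is GenotypeCall.MISSING or b is GenotypeCall.MISSING:
            continue
        if a is not b:
            polymorphic.append(name)
    return polymorphic


def screen_bulk_polymorphic(
    marker_names: list[str], fertile: Bulk, sterile: Bulk
) -> list[str]:
    """Markers whose band patterns differ between the two bulks.

    Markers should already be parent-polymorphic; a differing pattern
    flags linkage to the trait locus.
    """
    return [
        name
        for name in marker_names
        if fertile.allele_pattern.get(name, frozenset())
        != sterile.allele_pattern.get(name, frozenset())
    ]
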