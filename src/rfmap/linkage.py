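"""Recessive-class linkage mapping with Kosambi distances.

Only the homozygous-recessive (sterile) F2 class is genotyped: every
restorer-parent marker allele observed there marks a recombinant
chromosome.  For a marker with N1 sterile plants typed 'B' (two
recombinant chromosomes, HO) and N2 typed 'H' (one, HE) among N typed
sterile plants, the recombination fraction is

    c = (N1 + N2/2) / N

and the Kosambi map distance, in centimorgans, is

    d = 25 * ln((1 + 2c) / (1 - 2c)).

'A' calls in sterile plants are non-recombinant by design and missing
calls are excluded from N.  The trait locus is localized to the
physical interval between the nearest markers with c > 0 on either
side of the block of co-segregating (c = 0) markers.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

from .core import F2Plant, GenotypeCall, MarkerDef, Phenotype, validate_panel


@dataclass(frozen=True)
class RecombinantTally:
    """Recombinant counts for one marker over the sterile class."""

    marker: MarkerDef
    n_ho: int  # sterile plants homozygous for the restorer-parent allele
    n_he: int  # sterile plants heterozygous
    n_total: int  # sterile plants with a non-missing call

    def __post_init__(self) -> None:
        if self.n_ho + self.n_he > self.n_total:
            raise ValueError(f"{self.marker.name}: recombinants exceed typed plants")


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    COSEGREGATING = "cosegregating"


@dataclass
class MapEntry:
    marker: MarkerDef
    tally: RecombinantTally
    c: float
    d_cm: float | None  # None when flagged unlinked (c >= 0.5)
    side: Side


@dataclass(frozen=True)
class MappedInterval:
    left_marker: MarkerDef
    right_marker: MarkerDef

    def __post_init__(self) -> None:
        if self.left_marker.position >= self.right_marker.position:
            raise ValueError("interval markers out of physical order")

    @property
    def span_bp(self) -> int:
        return self.right_marker.position - self.left_marker.position

    @property
    def span_kb(self) -> float:
        return round(self.span_bp / 1000, 2)


def tally_recombinants(sterile_plants: list[F2Plant], marker: MarkerDef) -> RecombinantTally:
    """Count HO/HE recombinants at a marker over the sterile class."""
    n_ho = n_he = n_total = 0
    for plant in sterile_plants:
        if plant.phenotype is not Phenotype.STERILE:
            raise ValueError(
                f"plant {plant.plant_id} is fertile; recessive-class mapping "
                "uses sterile plants only"
            )
        call = plant.call(marker.name)
        if call is GenotypeCall.MISSING:
            continue
        n_total += 1
        if call is GenotypeCall.B:
            n_ho += 1
        elif call is GenotypeCall.H:
            n_he += 1
    return RecombinantTally(marker, n_ho, n_he, n_total)


def recombination_fraction(tally: RecombinantTally) -> float:
    """c = (N1 + N2/2) / N over the recessive class."""
    if tally.n_total <= 0:
        raise ValueError(f"{tally.marker.name}: no typed sterile plants")
    return (tally.n_ho + tally.n_he / 2) / tally.n_total


def kosambi_cM(c: float) -> float:
    """Kosambi map distance in centimorgans for recombination fraction c."""
    if not 0 <= c < 0.5:
        raise ValueError(f"recombination fraction {c} outside [0, 0.5)")
    return 25.0 * math.log((1 + 2 * c) / (1 - 2 * c))


def inverse_kosambi(d_cm: float) -> float:
    """Recombination fraction recovered from a Kosambi distance in cM."""
    if d_cm < 0:
        raise ValueError("distance must be non-negative")
    e = math.exp(4 * d_cm / 100)
    return 0.5 * (e - 1) / (e + 1)


def map_from_tallies(tallies: list[RecombinantTally]) -> list[MapEntry]:
    """Build map entries from per-marker tallies, ordered by position.

    Markers with c >= 0.5 are flagged unlinked (``d_cm`` is None).
    Sides are assigned relative to the block of co-segregating markers,
    or to the minimum-c marker (with a warning) when none co-segregates.
    """
    if not tallies:
        raise ValueError("no marker tallies supplied")
    validate_panel(t.marker for t in tallies)
    tallies = sorted(tallies, key=lambda t: t.marker.position)
    entries = []
    for tally in tallies:
        c = recombination_fraction(tally)
        if c >= 0.5:
            warnings.warn(
                f"{tally.marker.name}: c = {c:.3f} >= 0.5, flagged unlinked",
                stacklevel=2,
            )
            entries.append(MapEntry(tally.marker, tally, c, None, Side.RIGHT))
            continue
        entries.append(MapEntry(tally.marker, tally, c, kosambi_cM(c), Side.RIGHT))

    zero = [e for e in entries if e.c == 0]
    if zero:
        lo = min(e.marker.position for e in zero)
        hi = max(e.marker.position for e in zero)
    else:
        best = min(entries, key=lambda e: e.c)
        warnings.warn(
            "no co-segregating marker; sides assigned relative to the "
            f"minimum-c marker {best.marker.name}",
            stacklevel=2,
        )
        lo = hi = best.marker.position
    for entry in entries:
        if entry.c == 0:
            entry.side = Side.COSEGREGATING
        elif entry.marker.position < lo:
            entry.side = Side.LEFT
        elif entry.marker.position > hi:
            entry.side = Side.RIGHT
        else:
            # a recombinant marker physically inside the zero-c block is
            # inconsistent with marker order; report it but keep it out of
            # the flanking search
            entry.side = Side.LEFT if entry.marker.position - lo <= hi - entry.marker.position else Side.RIGHT
            warnings.warn(
                f"{entry.marker.name}: c > 0 but lies inside the "
                "co-segregating block; excluded from interval flanks",
                stacklevel=2,
            )
    return entries


def build_map(sterile_plants: list[F2Plant], panel: list[MarkerDef]) -> list[MapEntry]:
    """Tally recombinants for every panel marker and build the map."""
    if not panel:
        raise ValueError("empty marker panel")
    if not sterile_plants:
        raise ValueError("no sterile plants")
    return map_from_tallies([tally_recombinants(sterile_plants, m) for m in panel])


def locate_interval(entries: list[MapEntry]) -> MappedInterval:
    """Flanking-marker interval around the co-segregating block.

    The left flank is the nearest marker with c > 0 physically left of
    the zero-c block, symmetrically on the right.  Raises when no marker
    co-segregates or when the block touches the panel edge.
    """
    zero = [e for e in entries if e.c == 0]
    if not zero:
        raise ValueError("no co-segregating (c = 0) marker; interval undefined")
    lo = min(e.marker.position for e in zero)
    hi = max(e.marker.position for e in zero)
    left = [e for e in entries if e.c > 0 and e.marker.position < lo]
    right = [e for e in entries if e.c > 0 and e.marker.position > hi]
    if not left:
        raise ValueError("open interval: no recombinant marker left of the block")
    if not right:
        raise ValueError("open interval: no recombinant marker right of the block")
    left_marker = max(left, key=lambda e: e.marker.position).marker
    right_marker = min(right, key=lambda e: e.marker.position).marker
    return MappedInterval(left_marker, right_marker)
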