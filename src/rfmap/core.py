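"""Shared domain types and tabular/FASTA I/O.

The genotype coding follows the convention of F2 marker tables from a
CMS (female, 'A') x restorer (male, 'B') cross: each marker call is one
of 'A' (homozygous female-parent allele), 'B' (homozygous male-parent
allele), 'H' (heterozygous), or '-' (missing).

All genome coordinates are 1-based and inclusive.  Tabular files are
tab-separated with a header line; lines starting with '#' are comments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class GenotypeCall(enum.Enum):
    """A single-marker genotype call in the F2 coding."""

    A = "A"  # homozygous for the CMS/female-parent allele
    H = "H"  # heterozygous
    B = "B"  # homozygous for the restorer/male-parent allele
    MISSING = "-"

    @classmethod
    def from_symbol(cls, symbol: str) -> "GenotypeCall":
        try:
            return _SYMBOL_TO_CALL[symbol]
        except KeyError:
            raise ValueError(
                f"unknown genotype symbol {symbol!r}; expected one of A, B, H, -"
            ) from None

    @property
    def symbol(self) -> str:
        return self.value


_SYMBOL_TO_CALL = {c.value: c for c in GenotypeCall}


class Phenotype(enum.Enum):
    FERTILE = "fertile"
    STERILE = "sterile"

    @classmethod
    def from_label(cls, label: str) -> "Phenotype":
        key = label.strip().lower()
        if key in ("fertile", "f"):
            return cls.FERTILE
        if key in ("sterile", "s"):
            return cls.STERILE
        raise ValueError(f"unknown phenotype label {label!r}")


class MarkerClass(enum.Enum):
    SSR = "SSR"
    INDEL = "InDel"


class LineRole(enum.Enum):
    CMS = "CMS line"
    RESTORER = "Restorer line"
    MAINTAINER = "Maintainer line"

    @classmethod
    def from_label(cls, label: str) -> "LineRole":
        key = label.strip().lower().replace(" line", "")
        for role in cls:
            if role.value.lower().replace(" line", "") == key:
                return role
        raise ValueError(f"unknown line role {label!r}")


@dataclass(frozen=True)
class MarkerDef:
    """A genotyped locus with a 1-based physical position."""

    name: str
    chromosome: str
    position: int
    marker_class: MarkerClass = MarkerClass.SSR

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.name}: position must be >= 1")


@dataclass(frozen=True)
class LineRecord:
    name: str
    role: LineRole


@dataclass
class F2Plant:
    plant_id: str
    phenotype: Phenotype
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def call(self, marker: str) -> GenotypeCall:
        return self.calls.get(marker, GenotypeCall.MISSING)


def validate_panel(markers: Iterable[MarkerDef]) -> list[MarkerDef]:
    """Check marker-name uniqueness and return the panel as a list."""
    panel = list(markers)
    seen: set[str] = set()
    for m in panel:
        if m.name in seen:
            raise ValueError(f"duplicate marker name {m.name!r} in panel")
        seen.add(m.name)
    return panel


# ---------------------------------------------------------------------------
# tabular I/O


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_genotype_table(path: str | Path) -> tuple[list[F2Plant], list[str]]:
    """Read a plant x marker genotype table.

    Expected layout: ``plant_id<TAB>phenotype<TAB><marker1><TAB>...``,
    one row per plant, header row naming the markers.  Returns the
    plants and the marker-name order from the header.
    """
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty genotype table") from None
    cols = header.split("\t")
    if len(cols) < 2:
        raise ValueError(f"{path}: header must name plant_id, phenotype and markers")
    marker_names = cols[2:]

    plants: list[F2Plant] = []
    seen_ids: set[str] = set()
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise ValueError(
                f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
            )
        plant_id = fields[0]
        if plant_id in seen_ids:
            raise ValueError(f"{path}:{lineno}: duplicate plant id {plant_id!r}")
        seen_ids.add(plant_id)
        try:
            phenotype = Phenotype.from_label(fields[1])
            calls = {
                name: GenotypeCall.from_symbol(sym)
                for name, sym in zip(marker_names, fields[2:])
            }
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        plants.append(F2Plant(plant_id, phenotype, calls))
    return plants, marker_names


def write_genotype_table(
    path: str | Path, plants: Iterable[F2Plant], marker_names: list[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("plant_id\tphenotype\t" + "\t".join(marker_names) + "\n")
        for plant in plants:
            syms = [plant.call(m).symbol for m in marker_names]
            fh.write(f"{plant.plant_id}\t{plant.phenotype.value}\t" + "\t".join(syms) + "\n")


def read_marker_table(path: str | Path) -> list[MarkerDef]:
    """Read a marker panel: ``name<TAB>chromosome<TAB>position[<TAB>class]``."""
    rows = iter(_data_lines(path))
    try:
        next(rows)  # header
    except StopIteration:
        raise ValueError(f"{path}: empty marker table") from None
    markers = []
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 fields")
        cls = MarkerClass(fields[3]) if len(fields) > 3 and fields[3] else MarkerClass.SSR
        markers.append(MarkerDef(fields[0], fields[1], int(fields[2].replace(",", "")), cls))
    return validate_panel(markers)


def write_marker_table(path: str | Path, markers: Iterable[MarkerDef]) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchromosome\tposition\tclass\n")
        for m in markers:
            fh.write(f"{m.name}\t{m.chromosome}\t{m.position}\t{m.marker_class.value}\n")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> upper-cased sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
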