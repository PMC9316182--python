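"""Candidate-gene analysis: variant-effect classification and
variant-trait concordance over maintainer/restorer line panels.

A candidate gene inside the mapped interval carries coding variants
that distinguish the CMS line from the restorer line.  Concordance
scoring asks whether independent maintainer lines (which carry no
functional restorer allele) share the CMS-line haplotype at those
sites, and whether independent restorer lines share the restorer-line
haplotype.  A high concordance fraction supports the gene as the
restorer-of-fertility candidate; a single-site restriction of the same
score models a CAPS assay reading one polymorphism.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .core import LineRecord, LineRole


class Consequence(enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP_LOSS = "stop_loss"
    STOP_GAIN = "stop_gain"


#: consequences scored by default: variants that change the protein
DEFAULT_CONSEQUENCES = frozenset({Consequence.MISSENSE, Consequence.STOP_LOSS})


@dataclass(frozen=True)
class VariantSite:
    """A single-nucleotide coding variant, located by CDS offset."""

    gene: str
    cds_offset: int  # 1-based bp within the coding sequence
    ref_allele: str
    alt_allele: str
    consequence: Consequence

    def __post_init__(self) -> None:
        if self.cds_offset < 1:
            raise ValueError("cds_offset must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.cds_offset}"


def classify_variant(
    cds: str, offset: int, ref: str, alt: str
) -> tuple[Consequence, int | None]:
    """Classify a single-nucleotide substitution in a coding sequence.

    ``cds`` is the coding sequence read from the start codon; it may
    extend past the annotated stop so that stop-loss read-through can be
    measured.  Returns the consequence and, for STOP_LOSS, the number of
    extra codons translated up to the next in-frame stop (None when no
    downstream stop exists in the supplied sequence — an unbounded
    extension).
    """
    cds = cds.upper()
    offset0 = offset - 1
    if not 0 <= offset0 < len(cds):
        raise ValueError(f"offset {offset} outside the supplied sequence")
    if cds[offset0] != ref.upper():
        raise ValueError(
            f"reference mismatch at offset {offset}: sequence has "
            f"{cds[offset0]!r}, expected {ref!r}"
        )
    codon_start = (offset0 // 3) * 3
    if codon_start + 3 > len(cds):
        raise ValueError(f"offset {offset} falls in an incomplete codon")
    codon_ref = cds[codon_start : codon_start + 3]
    pos_in_codon = offset0 - codon_start
    codon_alt = codon_ref[:pos_in_codon] + alt.upper() + codon_ref[pos_in_codon + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())

    if aa_ref == aa_alt:
        return Consequence.SYNONYMOUS, None
    if aa_ref == "*":
        # stop codon lost: walk downstream codons to the next in-frame stop
        extension = 0
        pos = codon_start + 3
        while pos + 3 <= len(cds):
            if str(Seq(cds[pos : pos + 3]).translate()) == "*":
                return Consequence.STOP_LOSS, extension
            extension += 1
            pos += 3
        return Consequence.STOP_LOSS, None
    if aa_alt == "*":
        return Consequence.STOP_GAIN, None
    return Consequence.MISSENSE, None


@dataclass
class VariantMatrix:
    """Lines x variant-site allele calls, with class reference haplotypes.

    ``alleles`` is indexed by line name with one column per site label;
    every line is inbred, so calls are single nucleotides.  The CMS and
    restorer reference lines define the two class haplotypes and are
    excluded from scoring.
    """

    lines: list[LineRecord]
    sites: list[VariantSite]
    alleles: pd.DataFrame
    cms_reference: str
    restorer_reference: str

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        missing = set(labels) - set(self.alleles.columns)
        if missing:
            raise ValueError(f"alleles missing site columns: {sorted(missing)}")
        for line in self.lines:
            if line.name not in self.alleles.index:
                raise ValueError(f"no allele calls for line {line.name}")
        for label in labels:
            if self.alleles.at[self.cms_reference, label] == self.alleles.at[
                self.restorer_reference, label
            ]:
                raise ValueError(
                    f"reference lines do not differ at {label}; "
                    "site is uninformative"
                )

    @property
    def scored_lines(self) -> list[LineRecord]:
        return [
            l
            for l in self.lines
            if l.name not in (self.cms_reference, self.restorer_reference)
        ]

    def gene_sites(self, gene: str) -> list[VariantSite]:
        return [s for s in self.sites if s.gene == gene]


@dataclass
class ConcordanceResult:
    gene: str
    sites: list[VariantSite]
    n_concordant: int
    n_lines: int
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_lines

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def concordance_score(
    matrix: VariantMatrix,
    gene: str,
    sites: list[VariantSite] | None = None,
    consequences: frozenset[Consequence] = DEFAULT_CONSEQUENCES,
) -> ConcordanceResult:
    """Score line haplotypes against their class reference at a gene.

    A maintainer line is concordant iff it matches the CMS reference at
    EVERY filtered site; a restorer line iff it matches the restorer
    reference at every filtered site.  Protein-changing sites are used
    by default; synonymous sites are excluded.
    """
    if sites is None:
        sites = matrix.gene_sites(gene)
    used = [s for s in sites if s.consequence in consequences]
    if not used:
        raise ValueError(f"no sites left for {gene} after consequence filtering")

    verdicts: dict[str, bool] = {}
    for line in matrix.scored_lines:
        reference = (
            matrix.restorer_reference
            if line.role is LineRole.RESTORER
            else matrix.cms_reference
        )
        ok = True
        for site in used:
            allele = matrix.alleles.at[line.name, site.label]
            ref_allele = matrix.alleles.at[reference, site.label]
            other = matrix.alleles.at[
                matrix.cms_reference
                if reference == matrix.restorer_reference
                else matrix.restorer_reference,
                site.label,
            ]
            if allele != ref_allele:
                ok = False
                if allele != other:
                    warnings.warn(
                        f"{line.name} at {site.label}: allele {allele!r} matches "
                        "neither reference haplotype",
                        stacklevel=2,
                    )
        verdicts[line.name] = ok
    return ConcordanceResult(gene, used, sum(verdicts.values()), len(verdicts), verdicts)


def caps_accuracy(
    matrix: VariantMatrix, gene: str, site: VariantSite
) -> ConcordanceResult:
    """Single-site concordance, modeling a CAPS assay at one polymorphism."""
    return concordance_score(
        matrix, gene, sites=[site], consequences=frozenset(Consequence)
    )


def genes_in_interval(annotation: pd.DataFrame, interval) -> list[str]:
    """Genes whose 1-based [start, end] span intersects the closed interval.

    ``annotation`` needs columns gene, start, end; ``interval`` is either
    a ``linkage.MappedInterval`` or a (start, end) pair of positions.
    """
    if hasattr(interval, "left_marker"):
        start, end = interval.left_marker.position, interval.right_marker.position
    else:
        start, end = interval
    hits = annotation[(annotation["start"] <= end) & (annotation["end"] >= start)]
    return list(hits["gene"])
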