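"""Synthetic inputs for every pipeline stage, plus packaged fixtures.

The F2 simulator emulates the mapping design: a cross between an
inbred CMS line and an inbred restorer line, F1 selfed, phenotype
determined by a single dominant restorer locus (sterile iff homozygous
for the CMS allele).  Gametes are generated by a no-interference
(Poisson/Haldane) crossover process on a user-supplied genetic map, so
the recombination fraction between two positions d cM apart is
(1 - e^(-2d/100)) / 2.

The remaining generators produce inbred-line variant matrices with a
controlled discordance rate, replicate qPCR Ct tables with planted
group effects, and sequence pairs with planted indels, each of which
has a closed-form expectation the tests check against.  ``load_fixture``
returns typed transcriptions of the published segregation counts,
recombinant tallies, gene annotations and line-variant matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .candidate import Consequence, VariantMatrix, VariantSite
from .core import (
    F2Plant,
    GenotypeCall,
    LineRecord,
    LineRole,
    MarkerClass,
    MarkerDef,
    Phenotype,
)
from .linkage import RecombinantTally
from .segregation import SegregationRecord

FIXTURES = (
    "table2_families",
    "table3_primary",
    "table3_fine",
    "table4_genes",
    "table5_matrix",
)


# ---------------------------------------------------------------------------
# F2 population simulator


@dataclass
class CrossoverModel:
    """Genetic map driving the F2 gamete simulator.

    ``markers`` pairs each marker with its genetic position in cM;
    genetic order must agree with physical order.  The restorer locus
    sits at ``locus_cm`` / ``locus_bp`` and must lie inside the map.
    """

    markers: list[tuple[MarkerDef, float]]
    locus_cm: float
    locus_bp: int

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("empty marker map")
        phys = [m.position for m, _ in self.markers]
        gen = [g for _, g in self.markers]
        order = np.argsort(phys)
        if any(gen[order[i]] > gen[order[i + 1]] for i in range(len(order) - 1)):
            raise ValueError("genetic positions must be non-decreasing with physical")
        if not min(gen) <= self.locus_cm <= max(gen):
            warnings.warn(
                "locus genetic position lies outside the marker map; the "
                "simulated region is extended to cover it",
                stacklevel=2,
            )


@dataclass
class SimulatedPopulation:
    plants: list[F2Plant]
    crossovers: list[tuple[np.ndarray, np.ndarray]]  # per-plant gamete breakpoints, cM
    locus_genotypes: list[GenotypeCall]


_CALL_FROM_DOSE = {0: GenotypeCall.A, 1: GenotypeCall.H, 2: GenotypeCall.B}


def _gamete_alleles(
    positions: np.ndarray, span: tuple[float, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product: allele (0 = CMS, 1 = restorer) per position."""
    length_m = (span[1] - span[0]) / 100.0  # map length in Morgans
    k = rng.poisson(length_m)
    start = rng.integers(0, 2)
    if k == 0:
        return np.full(len(positions), start, dtype=np.int8), np.empty(0)
    points = np.sort(rng.uniform(span[0], span[1], size=k))
    parity = np.searchsorted(points, positions, side="right") % 2
    return ((start + parity) % 2).astype(np.int8), points


def simulate_f2(
    model: CrossoverModel, n: int, seed: int | np.random.Generator = 0
) -> SimulatedPopulation:
    """Simulate ``n`` F2 plants; reproducible under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marker_names = [m.name for m, _ in model.markers]
    gen_pos = np.array([g for _, g in model.markers] + [model.locus_cm])
    span = (min(gen_pos.min(), 0.0), gen_pos.max())

    plants, crossovers, locus_genotypes = [], [], []
    for i in range(n):
        a1, x1 = _gamete_alleles(gen_pos, span, rng)
        a2, x2 = _gamete_alleles(gen_pos, span, rng)
        dose = a1 + a2
        locus_call = _CALL_FROM_DOSE[int(dose[-1])]
        phenotype = (
            Phenotype.STERILE if locus_call is GenotypeCall.A else Phenotype.FERTILE
        )
        calls = {
            name: _CALL_FROM_DOSE[int(d)] for name, d in zip(marker_names, dose[:-1])
        }
        plants.append(F2Plant(f"F2-{i + 1:05d}", phenotype, calls))
        crossovers.append((x1, x2))
        locus_genotypes.append(locus_call)
    return SimulatedPopulation(plants, crossovers, locus_genotypes)


def simulate_sterile_plants(
    model: CrossoverModel,
    n_sterile: int,
    seed: int | np.random.Generator = 0,
    batch: int = 512,
) -> list[F2Plant]:
    """Simulate F2 plants until ``n_sterile`` sterile ones are collected.

    Mirrors the ascertainment of recessive-class mapping, where only
    male-sterile segregants are genotyped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sterile: list[F2Plant] = []
    while len(sterile) < n_sterile:
        pop = simulate_f2(model, batch, rng)
        sterile.extend(p for p in pop.plants if p.phenotype is Phenotype.STERILE)
    return sterile[:n_sterile]


# ---------------------------------------------------------------------------
# variant matrix / Ct table / indel generators

_SIM_REF_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def simulate_variant_matrix(
    n_maintainer: int,
    n_restorer: int,
    n_sites: int = 1,
    discordance: float = 0.0,
    seed: int | np.random.Generator = 0,
    gene: str = "simGene",
) -> VariantMatrix:
    """Inbred-line allele matrix with a controlled discordance rate.

    Each line starts from its class reference haplotype; every site is
    flipped to the other reference allele independently with
    probability ``discordance``.
    """
    if not 0 <= discordance <= 1:
        raise ValueError("discordance must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = []
    for j in range(n_sites):
        cms, res = _SIM_REF_PAIRS[int(rng.integers(len(_SIM_REF_PAIRS)))]
        sites.append(VariantSite(gene, 3 * j + 1, cms, res, Consequence.MISSENSE))

    lines = [LineRecord("CMS_REF", LineRole.CMS), LineRecord("RES_REF", LineRole.RESTORER)]
    rows = {
        "CMS_REF": [s.ref_allele for s in sites],
        "RES_REF": [s.alt_allele for s in sites],
    }
    for role, count, prefix in (
        (LineRole.MAINTAINER, n_maintainer, "M"),
        (LineRole.RESTORER, n_restorer, "R"),
    ):
        for i in range(count):
            name = f"{prefix}{i + 1:02d}"
            lines.append(LineRecord(name, role))
            base = [
                s.ref_allele if role is LineRole.MAINTAINER else s.alt_allele
                for s in sites
            ]
            other = [
                s.alt_allele if role is LineRole.MAINTAINER else s.ref_allele
                for s in sites
            ]
            flips = rng.random(len(sites)) < discordance
            rows[name] = [o if f else b for b, o, f in zip(base, other, flips)]
    alleles = pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.label for s in sites]
    )
    return VariantMatrix(lines, sites, alleles, "CMS_REF", "RES_REF")


def simulate_ct_table(
    effects: dict[tuple[str, str], float],
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
    target: str = "target",
    reference: str = "actin",
    base_target_ct: float = 26.0,
    base_reference_ct: float = 21.0,
) -> pd.DataFrame:
    """Replicate Ct table with planted ddCt ``effects`` per (group, stage).

    A block with effect 0 serves as the calibrator; Gaussian noise of
    sd ``noise_sd`` is added per well.  ``effects`` values of NaN mark
    blocks where the target is not detected (Ct missing).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for (group, stage), effect in effects.items():
        for rep in range(1, n_replicates + 1):
            ref_ct = base_reference_ct + rng.normal(0, noise_sd)
            if np.isnan(effect):
                tgt_ct = np.nan
            else:
                tgt_ct = base_target_ct + effect + rng.normal(0, noise_sd)
            rows.append((group, stage, target, rep, tgt_ct))
            rows.append((group, stage, reference, rep, ref_ct))
    return pd.DataFrame(rows, columns=["group", "stage", "gene", "replicate", "ct"])


def plant_indels(
    length: int = 100_000,
    n_events: int = 50,
    length_range: tuple[int, int] = (5, 30),
    min_spacing: int = 1_000,
    seed: int | np.random.Generator = 0,
):
    """Random sequence pair with planted, well-separated indels.

    Returns (reference, alternate, truth) where truth is a list of
    ``indel_design.IndelCall`` in reference coordinates.  Event
    positions keep ``min_spacing`` bp apart and away from the ends; the
    base preceding each event is forced to differ from the event's last
    base so calls are unambiguous under left alignment.
    """
    from .indel_design import IndelCall, IndelKind  # local import avoids a cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    margin = max(min_spacing, 600)
    if n_events > 0 and (length - 2 * margin) // max(min_spacing, 1) < n_events:
        raise ValueError("sequence too short for the requested events and spacing")
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=length)

    positions = np.sort(
        rng.choice(
            np.arange(margin, length - margin, min_spacing), size=n_events, replace=False
        )
    ) if n_events else np.array([], dtype=int)

    truth: list[IndelCall] = []
    alt_parts: list[str] = []
    cursor = 0
    ref_seq = "".join(bases[ref])
    for pos in positions:  # pos: 1-based anchor of the base preceding the event
        pos = int(pos)
        size = int(rng.integers(length_range[0], length_range[1] + 1))
        kind = IndelKind.INSERTION if rng.random() < 0.5 else IndelKind.DELETION
        if kind is IndelKind.DELETION:
            seq = ref_seq[pos : pos + size]
            if ref_seq[pos - 1] == seq[-1]:  # would left-shift; re-anchor
                pos -= 1
                seq = ref_seq[pos : pos + size]
                while pos >= 1 and ref_seq[pos - 1] == seq[-1]:
                    pos -= 1
                    seq = ref_seq[pos : pos + size]
            alt_parts.append(ref_seq[cursor:pos])
            cursor = pos + size
        else:
            choices = [b for b in "ACGT" if b != ref_seq[pos - 1]]
            seq = "".join(
                str(rng.choice(np.array(list("ACGT")))) for _ in range(size - 1)
            ) + str(rng.choice(np.array(choices)))
            # force last inserted base != preceding ref base (no left shift)
            seq = seq[-1] + seq[:-1] if seq[-1] == ref_seq[pos - 1] else seq
            if seq[-1] == ref_seq[pos - 1]:
                seq = seq[:-1] + choices[0]
            alt_parts.append(ref_seq[cursor:pos] + seq)
            cursor = pos
        truth.append(IndelCall("ref", "alt", pos, kind, seq))
    alt_parts.append(ref_seq[cursor:])
    return ref_seq, "".join(alt_parts), sorted(truth, key=lambda c: c.ref_pos)


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture_path(filename: str):
    return resources.files("rfmap").joinpath("data", filename)


def _read_tsv(filename: str) -> pd.DataFrame:
    with resources.as_file(_fixture_path(filename)) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_fixture(name: str):
    """Load a packaged table transcription by name.

    Available fixtures: table2_families (segregation records),
    table3_primary / table3_fine (recombinant tallies), table4_genes
    (annotation DataFrame), table5_matrix (line-variant matrix).
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    if name == "table2_families":
        df = _read_tsv("table2_families.tsv")
        records = []
        for row in df.itertuples(index=False):
            if row.printed_total != row.n_fertile + row.n_sterile:
                warnings.warn(
                    f"family {row.family}: printed total {row.printed_total} != "
                    f"fertile + sterile = {row.n_fertile + row.n_sterile}; "
                    "using the component sum",
                    stacklevel=2,
                )
            records.append(SegregationRecord(row.family, row.n_fertile, row.n_sterile))
        return records
    if name in ("table3_primary", "table3_fine"):
        df = _read_tsv(f"{name}.tsv").rename(columns={"class": "marker_class"})
        return [
            RecombinantTally(
                MarkerDef(r.marker, r.chromosome, r.position, MarkerClass(r.marker_class)),
                r.n_ho,
                r.n_he,
                r.n_total,
            )
            for r in df.itertuples(index=False)
        ]
    if name == "table4_genes":
        return _read_tsv("table4_genes.tsv")
    # table5_matrix
    sites_df = _read_tsv("table5_sites.tsv")
    sites = [
        VariantSite(
            r.gene, r.cds_offset, r.cms_allele, r.restorer_allele, Consequence(r.consequence)
        )
        for r in sites_df.itertuples(index=False)
    ]
    matrix_df = _read_tsv("table5_matrix.tsv")
    lines = [
        LineRecord(r.line, LineRole.from_label(r.role))
        for r in matrix_df.itertuples(index=False)
    ]
    alleles = matrix_df.set_index("line").drop(columns=["role"])
    return VariantMatrix(lines, sites, alleles, "HZ1A", "HZ1C")
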