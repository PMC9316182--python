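# rfmap

Fine mapping of a single dominant *restorer-of-fertility* (*Rf*) locus from an
F2 population, built as a tested, reusable pipeline. The package targets the
classic "three-line" breeding setting in pepper (*Capsicum annuum*): a
cytoplasmic male-sterile (CMS) line crossed to a restorer line, where a single
dominant nuclear *Rf* gene restores pollen fertility, so the F2 segregates
3 fertile : 1 sterile and the sterile plants form the homozygous-recessive
mapping class.

It is intended for plant geneticists doing marker-based mapping who want the
whole desk-side analysis — from segregation tests to candidate-gene scoring —
scriptable and unit-tested rather than spread over spreadsheets.

## What it computes

- **Segregation tests** (`segregation`): per-family and pooled chi-square
  goodness-of-fit against an expected fertile:sterile ratio (default 3:1),
  χ² = Σ(|O−E|−½)²/E with the Yates continuity correction on by default.
- **Bulked segregant analysis** (`bsa`): composes fertile/sterile DNA bulks
  (default 10 plants each) and flags markers whose pooled band patterns
  differ — the sterile bulk near the locus shows only the CMS-parent band.
- **Recessive-class linkage** (`linkage`): for each marker over N sterile
  plants with N1 homozygous-restorer and N2 heterozygous recombinants, the
  recombination fraction is *c* = (N1 + N2/2)/N and the Kosambi distance is
  *d* = ¼·ln((1+2c)/(1−2c)) Morgans, reported in cM. The locus is localized
  between the nearest recombinant markers flanking the co-segregating block.
- **Candidate genes** (`candidate`): variant-effect classification on coding
  sequence (synonymous / missense / stop-gain / stop-loss with read-through
  length), and variant–trait concordance of maintainer/restorer line panels
  against the CMS and restorer reference haplotypes, including single-site
  CAPS-assay accuracy.
- **Expression** (`expression`): 2^−ΔΔCt relative expression from replicate
  qPCR Ct tables, with Welch t-tests on ΔCt for group comparisons.
- **InDel marker design** (`indel_design`): global alignment of a sequence
  pair, calling of insertions/deletions ≥ 5 bp, and extraction of 500 bp
  flanks as PCR marker candidates.
- **Synthetic data** (`synthetic_data`): an F2 crossover simulator
  (no-interference/Haldane gametes, dominance phenotype), line-matrix, Ct and
  planted-indel generators, plus typed transcriptions of the published
  segregation counts, recombinant tallies, gene annotations and line-variant
  matrix used as fixtures.

## Worked example

The packaged fine-mapping tallies (28 markers over 336 sterile F2 plants) run
through the linkage stage:

```sh
rfmap finemap-fixture table3_fine
```

prints one row per marker and an interval line:

```text
marker      position_bp  n_ho  n_he  n_total  c        d_cM     d_cM_2dp  side
P06g8219    208736376    0     22    336      0.03274  3.27850  3.28      left
P06g8229    208899271    0     43    336      0.06399  6.43409  6.43      left
...
P06g8560    215995331    0     6     336      0.00893  0.89295  0.89      right
# interval  P06gInDel-66  P06gInDel-89  533810 bp  533.81 kb
```

Reading: marker P06g8229 shows 43 heterozygous recombinants among 336 sterile
plants, hence *c* = (0 + 43/2)/336 = 0.064 and a Kosambi distance of 6.43 cM
from the locus. The co-segregating block (c = 0) is flanked by P06gInDel-66
and P06gInDel-89, so the locus maps to the 533.81 kb between them. (The run
also warns that P06g8528 is recombinant yet lies physically inside the
co-segregating block — an order inconsistency in the input that is reported,
not silently dropped.)

Scoring a candidate gene inside that interval over the 13-line
maintainer/restorer panel:

```sh
rfmap concordance Capana06g002968
```

```text
gene    Capana06g002968
sites   20,467
line    P21204  discordant
line    P21238  concordant
...
concordance     11/13   84.62%
```

Each maintainer line is concordant when it carries the CMS-line allele at
every protein-changing site of the gene, each restorer line when it carries
the restorer-line allele; 11 of 13 lines fit, i.e. 84.62% concordance. The
single-site CAPS readout of the stop-loss variant of the neighbouring gene
(`rfmap caps Capana06g002969 318`) scores 12/13 = 92.31%.

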