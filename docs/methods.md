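# Methods

## Mapping design

The pipeline assumes the standard recessive-class design for a dominant
locus: an inbred CMS (female) line crossed to an inbred restorer (male)
line, the F1 selfed, and the F2 phenotyped fertile/sterile. Because the
restorer allele is dominant, sterile F2 plants are homozygous for the
CMS allele at the locus, so every restorer-parent allele observed at a
marker in a sterile plant marks a recombinant chromosome. Genotypes are
coded A (homozygous CMS-parent), B (homozygous restorer-parent), H
(heterozygous), `-` (missing). All genome coordinates are 1-based and
inclusive; missing calls are excluded from every count.

## Segregation tests

Each family is tested against its expected fertile:sterile ratio
(default 3:1) with a 1-df chi-square goodness-of-fit. The Yates
continuity correction, (|O−E|−0.5)²/E, is applied by default and the
(|O−E|−0.5) term is deliberately **not** clamped at zero, so a
near-perfect fit yields a small positive statistic rather than exactly
zero; the uncorrected statistic is available behind a flag. Expected
counts always derive from the component sum fertile+sterile, never from
a separately supplied total — when a printed total disagrees with the
component sum (as in one packaged family record) the loader warns and
the component sum wins. At the default α = 0.05 the corrected test is
conservative; its type-I error on simulated true-3:1 families of n=100
is verified to lie in [0.01, 0.07].

## Bulked segregant analysis

A bulk's observable is the **set** of parental alleles present at a
marker (band presence/absence on a silver-stained gel), not allele
dosage: one plant carrying an allele suffices to produce the band. A
marker is flagged as linked when the two bulk patterns differ. With
bulks of b plants and recombination fraction r to the locus, the
sterile bulk lacks the restorer band with probability (1−r)^(2b), so a
co-located marker is flagged in every replicate and the flagging
probability decays monotonically with distance — both properties are
tested against simulation. Bulk membership is drawn with an explicit
caller-supplied seed; there is no hidden RNG state.

## Recombination fraction and Kosambi distance

Over N typed sterile plants with N1 plants scored B (two recombinant
chromosomes) and N2 scored H (one), the recombination fraction is

    c = (N1 + N2/2) / N.

A calls are non-recombinant by the design and never enter the numerator.
Markers with c ≥ 0.5 are flagged unlinked and get no distance. The map
distance uses Kosambi's function with the **natural** logarithm,

    d = ¼ · ln((1+2c)/(1−2c))  Morgans,  reported as 25·ln(...) cM;

natural log is the only base that reproduces the published distances
recomputed from their tallies (e.g. 3 recombinants/45 → 6.71 cM), which
the fixture tests assert for every tallied marker. The analytic inverse
c = ½(e^{4d/100}−1)/(e^{4d/100}+1) round-trips to 1e−12 and is used as
the property-test oracle.

## Interval localization

Markers are ordered by physical position. The co-segregating block is
the span of all markers with c = 0; the reported interval runs from the
nearest recombinant marker physically left of the block to the nearest
one on the right, with span = right position − left position (no +1 —
the flanking markers themselves are excluded ends). A recombinant
marker that falls physically *inside* the block span contradicts the
assumed marker order; it is excluded from the flank search and
reported with a warning. When no marker co-segregates, map sides are
assigned relative to the minimum-c marker with a warning, but the
interval is considered undefined and localization raises; a block
touching the panel edge raises an open-interval error naming the side.

## Candidate-gene scoring

`classify_variant` substitutes one base in a coding sequence, translates
the affected codon (standard nuclear code) and reports synonymous /
missense / stop-gain / stop-loss; for stop-loss it walks in-frame codons
in the supplied downstream sequence to count the read-through extension,
flagging it unbounded when no stop is found. A brute-force oracle that
translates the entire sequence before and after the substitution checks
the classification on random coding sequences.

Concordance scoring asks whether independent lines share the haplotype
their breeding role predicts: a maintainer line is concordant iff it
matches the CMS reference at **every** scored site of the gene, a
restorer line iff it matches the restorer reference everywhere. Scored
sites are the protein-changing ones (missense and stop-loss) by
default; synonymous sites are excluded. The two reference lines define
the haplotypes and are excluded from the denominator. Full-haplotype
matching is strict: a line matching at one site but not another is
discordant, which is what makes multi-site concordance ≤ the best of
its single sites (a tested property). `caps_accuracy` is the same score
restricted to one site, modeling a CAPS assay that reads a single
polymorphism. Alleles matching neither reference are counted discordant
and reported with a warning rather than dropped.

The packaged line-variant matrix classes the stop-codon site (offset
318 of the fourth gene) as stop-loss, so it is scored by default
alongside missense sites; its single-site readout and the multi-site
scores reproduce the published percentages (61.54 / 38.46 / 84.62 /
92.31) exactly, which the acceptance tests pin.

## Relative expression

ΔCt = mean Ct(target) − mean Ct(reference) per (group, stage) block over
replicates; fold change = 2^−(ΔCt − ΔCt_calibrator). The calibrator is a
required argument, not a default. Undetected expression stays missing
(reported ND), never zero. Group comparison uses a two-sided Welch
(unequal-variance) t-test on per-replicate ΔCt values with tiers *
(p<0.05) and ** (p<0.01); the choice of Welch's test on ΔCt is a
documented assumption of this package — three biological replicates are
too few for distributional diagnostics, and ΔCt is the scale on which
qPCR noise is closest to additive Gaussian. Its null false-positive
rate at n = 3 is verified to sit near the nominal 5%.

## InDel discovery

`align_pair` returns a minimal-edit (Levenshtein) global alignment via
edlib, re-expressed as an edit script relative to the reference.
Minimal-edit alignments systematically fragment long indels: any base
inside a deleted/inserted stretch that coincidentally matches nearby
sequence saves one edit, so a 19 bp deletion is typically reported as
two gaps bridged by a 2 bp chance match. `call_indels` therefore
clusters gap runs separated by fewer than 20 matched bases and realigns
each cluster, padded with up to 30 bp of flanking context, under affine
gap costs (match 1, mismatch −2, open −6, extend −0.1), which restores
one contiguous gap per biological event. Calls are left-aligned within
repeat runs (VCF convention), anchored at the 1-based position of the
last reference base before the event, and filtered at ≥ 5 bp by
default. Marker candidates take 500 bp reference flanks on both sides;
events within one flank of a sequence end are skipped with a warning,
and candidates are named `P<chrom>gInDel-<ordinal>`. The module is
meant for desk-scale windows (≤ ~1 Mb), not whole-genome alignment.

## Synthetic data

The F2 simulator draws, per gamete, a Poisson number of crossovers over
the genetic map span and places them uniformly — the no-interference
(Haldane) model — so the recombination fraction between positions d cM
apart is (1−e^{−2d/100})/2. Phenotype follows dominance at the locus.
Distances are *estimated* in Kosambi units while the generator is
Haldane; at the ≤ 7 cM scale of this design the two map functions
differ by far less than sampling error, and recovery tolerances are set
by the simulation's own standard errors, not by map-function agreement.
The generator does not model segregation distortion, genotyping error,
missing data patterns, or crossover interference, so passing recovery
tests demonstrate estimator correctness under the stated model, not
robustness to those artefacts. The line-matrix generator flips each
site to the opposite reference allele with a given discordance rate
(site-independent, which real linked sites are not); the Ct generator
plants ΔΔCt effects with i.i.d. Gaussian well noise; the indel planter
spaces events ≥ 1 kb apart and anchors them so left alignment is
unambiguous — clustered or repeat-embedded indels in real genomes are
harder than this.

Simulation problem sizes in the tests (500 replicates of 200 sterile
plants for estimator recovery, 200 runs of 336 sterile plants for
interval coverage, 50 events in 100 kb for the caller) were chosen so
each Monte-Carlo band is a few standard errors wide; the 336 matches
the fine-mapping class size of the study design.

## Packaged fixtures

The published segregation counts, recombinant tallies (primary: 12
markers/45 plants; fine: 28 markers/336 plants), interval gene
annotations and the 15-line × 9-site variant matrix ship as
tab-separated data files and load as typed objects. Fine-map tallies
record only heterozygous recombinants, as published; homozygous counts
default to zero there. The one internally inconsistent family total is
preserved as printed and flagged at load time.

## Numerical conventions

Statistics and distances are computed and stored at full double
precision; rounding to 2 decimals happens only at presentation (CLI
display columns, acceptance JSON). Chi-square upper-tail probabilities
come from `scipy.stats.chi2.sf`. Ties in c are all reported in physical
order; no secondary ordering is invented.
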