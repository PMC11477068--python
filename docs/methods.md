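# Methods

## The analysis in brief

The pipeline relates three observables per gene: (1) its 6mA methylation
state and density, from strand-specific single-base modification calls;
(2) its DNA and RNA variant burden; and (3) the six-type classification of
how each DNA variant's genotype appears in RNA. Two regressions tie them
together — a logistic model of the methylation flag on transmit-type
counts, and a linear model of 6mA density on the same counts restricted to
methylated genes — plus t-test contrasts of variant burden across
methylation and imprinting-gene strata.

## Definitions and conventions

* **Coordinates.** Internally everything is 0-based half-open. GFF/GTF and
  VCF (1-based inclusive) and BED (0-based half-open) conventions are
  converted only at the I/O boundary; round-trips are exact.
* **Methylated gene.** A gene with ≥ 1 depth-filtered 6mA site inside its
  body *on its own strand*. The strand rule matters: an antisense site does
  not methylate the gene. Gene-level density is n_6mA / n_A with n_A the
  coding-strand adenines of the body (A's for + genes, plus-strand T's for
  − genes). Gene-body assignment deliberately includes introns: most 6mA
  and most DNA variation sit in introns, and the regression rows are
  defined per gene, not per exon.
* **Depth filter.** Sites with coverage *less than* the cutoff are removed;
  a site exactly at the cutoff survives. Defaults are 30× (autosomes) and
  15× (sex chromosomes); per-sample cutoffs are configurable because real
  samples are sequenced to different depths.
* **Genome density denominator.** Adenines on both strands (plus-strand A
  plus plus-strand T), matching strand-specific site calls; a plus-strand-
  only switch exists for comparison with pipelines that count one strand.
* **On-gene site percentage vs methylated genes.** The count of sites "on
  genes" is positional (any strand, each site once); the methylated-gene
  count is strand-matched. Overlapping same-strand genes each receive a
  shared site (and variant); the generator lays genes out without overlap,
  so the closure tests are exact either way.
* **Variation ratio.** Variants per gene-body base (length includes
  introns). A/T vs C/G classes are split by plus-strand REF base — the only
  strand-unambiguous description of the variant.
* **Methylated variation.** A variant whose position coincides with a 6mA
  site and whose REF base is the site's adenine (REF=A at + sites, REF=T at
  − sites). Positional-only matching is available by flag; a positional
  match with a discordant base is logged as an inconsistent site.
* **RNA 0/0 inference.** Variant callers do not emit hom-ref rows, so
  `X/X_0/0` transmit types need a convention: a DNA variant with no RNA
  call is assigned RNA genotype 0/0 only when the RNA coverage track shows
  ≥ 30× at the site (mirroring the > 30× RNA variant screen); otherwise the
  site is excluded as not assessable. RNA calls at the position with
  different alleles are excluded as allele-discordant. Every DNA variant is
  accounted for in exactly one bucket and the tallies are reported.
* **Cross-sample consistency.** Consistent 6mA sites match on
  (chrom, pos, strand) with coverage taken as the minimum of the samples.
  Consistent transmissions match on the full event
  (chrom, pos, ref, alt, transmit type) — the same transmission observed
  twice, not merely the same locus; a position-only key is available.

## Models and inference

Both fits always offer all six transmit-type covariates and drop, with a
reported reason, columns that are all zero or linearly dependent on
already-kept columns (greedy rank test with the intercept first). In
sparse data the two homozygous-to-non-identical classes are rare, so the
familiar four-term summary table emerges from the dropping rule rather
than from a hand-picked design. Inference is Wald (z for the logistic fit,
t for OLS), matching standard summary-table output; p-values are reported
raw, with a Benjamini–Hochberg helper available but off by default.
Complete separation in the logistic fit is a declared failure naming the
separating covariate when a single covariate explains it — never a silent
huge coefficient. A zero-variance linear response yields the degenerate
but well-defined fit (intercept = the constant, zero slopes, p = 1) with
a warning. Fits are deterministic; permuting row order changes nothing.

The t-test contrasts default to Student's pooled-variance form (Welch by
option). When both groups are constant, equal means report t = 0, p = 1.

## The synthetic study generator

`m6avar.simulate` emulates the full input bundle: a multi-chromosome
genome (default 3 autosomes + chrX), ~2,000 genes of log-normal length
(median ≈ 1.5 kb, ≥ 40% on the minus strand) with exon/intron/UTR
structure, strand-correct 6mA sites, DNA and RNA VCFs, an RNA coverage
track, dbSNP positions, and an imprinting-gene list — all deterministic
given a seed, with ground truth recorded per gene, site and variant.

Key regimes, chosen to match the quantities the analysis is designed to
detect:

* DNA variant rates: 0.21% of gene-body bases in unmethylated genes vs
  0.10% in methylated genes (the observed human-sample regime), 70%
  heterozygous.
* Transmission matrices: methylated genes transmit the DNA genotype
  identically with probability 0.9; unmethylated genes spread 0.4 of the
  mass onto genotype-switching classes. 95% of genes are expressed (RNA
  coverage 31–80×); 95% of DNA variants are dbSNP-consistent.
* Per-gene 6mA density for methylated genes is drawn Uniform(0.01, 0.05)
  per coding adenine — far denser than a human genome, deliberately, so
  that kilobase-scale genes on a megabase-scale genome still carry several
  sites and the methylation flag is recoverable. Site coverage is
  Normal(45, 15) clipped at 1, straddling the depth cutoffs so filtering
  removes a nonzero, known subset; the ground-truth flag is defined on the
  post-filter sites.
* An AGGYR motif instance is planted around 70% of genic sites (reverse-
  complemented for minus-strand sites), skipped when planting would
  overwrite another site's adenine, so the exported context FASTA has a
  recoverable enrichment.

What the generator does **not** emulate: read-level data and sequencing
error (sites and variants are planted, not called), mapping artifacts,
linkage structure, population allele frequencies, gene overlap, and the
absolute genome scale. Passing closure tests therefore demonstrate that
the bookkeeping — strand rules, interval joins, filters, classification,
model fitting — is correct, not that the biological effect sizes of real
samples would be re-estimated.

One consequence of the chosen regimes is worth spelling out: because
unmethylated genes carry ~2.1× more variants, their *absolute* counts of
identity transmissions remain higher even though their identity
*proportion* is lower. A logistic fit on the file-level synthetic study
therefore expresses the stability effect as significant negative
coefficients on the genotype-switching classes (e.g. 0/1_0/0) rather than
positive identity-class coefficients. Recovery of positive planted
identity-class coefficients (magnitudes ≈ 0.12 per event, echoing the
human-sample fits) is exercised by the feature-row simulators, which draw
rows from the regression models themselves.

## Numerical and testing choices

* Replicate seeds for multi-replicate checks derive from
  `numpy.random.SeedSequence`, numpy's mechanism for independent streams;
  raw consecutive small integers measurably distorted Wald-interval
  coverage across replicates.
* Row-simulator recovery runs 20 replicates of n = 5,000 rows; full-study
  checks use 2,000 genes (seconds per study). Module tests use 40–300-gene
  studies against per-base brute-force oracles.
* Rounding to 2 decimals happens only at report boundaries (percentages);
  all internal arithmetic is full precision. Feature-table densities are
  written with full repr precision so write→read round-trips are exact.
* Degenerate inputs are defined, not crashed on: genes with no
  coding-strand adenines report density 0 with a flag; empty modification
  files yield an all-unmethylated run; an undefined A-mutated ratio
  (zero denominator) is reported missing rather than 0; zero-variance
  correlations are reported undefined.

## Known limitations

* The imprinting contrast set is user-supplied; published imprinting-gene
  lists vary slightly in size and the contrasts inherit that choice.
* RNA 0/0 inference depends on the coverage track's resolution; a coarse
  track inflates the insufficient-coverage bucket rather than producing
  wrong genotypes.
* The region-level breakdown resolves a position to one label per gene via
  the precedence UTR > exon > intron; annotations that tag UTRs also as
  exons are handled by that precedence, but exotic feature types beyond
  gene/exon/UTR are ignored.
* Multi-allelic variant sites are excluded rather than decomposed: the
  genotype classes are defined for biallelic sites.
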