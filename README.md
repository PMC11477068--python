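# m6avar

Analysis toolkit for the interplay between **DNA N6-methyladenosine (6mA)
methylation**, **DNA and RNA genetic variants**, and the **DNA-to-RNA
genotype transmission** at variant sites.

6mA is called per strand at single-base resolution from SMRT kinetics
(`ipdSummary`-style modification GFFs). A gene is *methylated* when it
carries at least one depth-filtered 6mA site on its own coding strand, and
its *6mA density* is sites per coding-strand adenine (6mA/A). Given paired
DNA and RNA variant calls for the same individual, every DNA variant site
that is assessable in RNA is classified into one of six **transmit types**
(DNA genotype → RNA genotype):

```
0/1_0/0   0/1_0/1   0/1_1/1   1/1_0/0   1/1_0/1   1/1_1/1
```

where 0 is the reference and 1 the alternate allele. The package then asks
how methylation relates to variation and transmission:

* **Logistic model** — `logit(p_i) = β₀ + Σₙ βₙ x_in`, where `p_i` is the
  probability that gene *i* is methylated and `x_i1..x_i6` are its six
  transmit-type counts.
* **Linear model** — for methylated genes, `y_i = a₀ + Σₙ aₙ x_in + ε`,
  with `y_i` the gene's 6mA density.
* **Group contrasts** — Student's t-tests of per-gene variation ratios
  (variants / gene length) between methylated and unmethylated genes, and
  across the methylation × imprinting-gene 2×2 grid.

All interval work is strand-aware and internally 0-based half-open;
GFF3/GTF, VCF, SMRT modification GFF, FASTA, BED and TSV conversions happen
only at the I/O boundary.

## Layout

| module | role |
|---|---|
| `m6avar.io_formats` | GFF3/GTF, modification GFF/TSV, VCF, FASTA, coverage and feature-table I/O |
| `m6avar.methylome` | depth filtering, genome/chromosome/gene 6mA density, shared-gene and cross-sample consistency, motif-context FASTA export |
| `m6avar.variants` | dbSNP / depth screens, exon–intron–UTR annotation, variation ratios, methylated-variation overlap, A-mutated ratios, t-tests |
| `m6avar.transmission` | transmit-type classification, DNA/RNA pairing with coverage-based 0/0 inference, cross-sample consistent events |
| `m6avar.association` | logistic + linear fits with dropped-term handling, imprinting contrasts |
| `m6avar.simulate` | synthetic study generator with ground truth; feature-row simulators |
| `m6avar.pipeline`, `m6avar.cli` | end-to-end orchestration and the `m6avar` command |

## Worked example

Simulate a study with known truth, run the single-sample pipeline, and fit
the association models:

```bash
m6avar simulate --seed 4 --out-dir sim --n-genes 40
m6avar run-sample \
    --genome sim/genome.fa --annotation sim/annotation.gff3 \
    --modifications sim/modifications.gff --dna-vcf sim/dna.vcf \
    --rna-vcf sim/rna.vcf --rna-coverage sim/rna_coverage.tsv \
    --output-dir run
```

which prints

```
sample sample: 298 filtered 6mA sites, 20 methylated genes, 121 DNA variants
  density.tsv: run/density.tsv
  filtered_sites.bed: run/filtered_sites.bed
  gene_features.tsv: run/gene_features.tsv
  ...
```

298 of 336 simulated 6mA sites survived the depth filter (coverage ≥ 30
autosomal / ≥ 15 on chrX), 20 of the 40 genes carry a same-strand site and
count as methylated, and 121 biallelic SNVs were parsed from the DNA VCF. `gene_features.tsv` is
the per-gene regression design table (methylation flag, 6mA density, six
transmit-type counts, DNA variant count, imprinting flag); the same library
calls are available in Python via `m6avar.pipeline.run_single_sample`.

On a full-size synthetic study (2,000 genes) the unmethylated genes carry a
mean variation ratio of ≈0.21% of gene-body bases against ≈0.10% for
methylated genes, and the two-sample t-test separates the groups at
p ≪ 0.01 — the stability effect the models are built to detect.

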