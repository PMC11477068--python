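"""End-to-end orchestration: single-sample and two-sample analyses.

``run_single_sample`` takes one sample's inputs (genome, annotation, 6mA
calls, DNA VCF, optionally RNA VCF + coverage, dbSNP positions and an
imprinting list) and emits the per-sample report bundle: methylation
summary, per-gene feature table, variation-ratio comparisons, and the
region breakdown. ``run_two_sample`` intersects two samples into
high-confidence consistent sites and transmission events and fits the
logistic and linear association models on the consistent data.

Every number in the reports is recomputable from the emitted TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import association, io_formats, methylome, transmission, variants as var_mod
from .models import DepthThresholds, GeneFeatureRow, MethylSite, RegressionResult, Variant

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """A mandatory input is missing or unusable before computation starts."""


@dataclass
class RunConfig:
    genome: str
    annotation: str
    modifications: str
    dna_vcf: str
    rna_vcf: Optional[str] = None
    rna_coverage: Optional[str] = None
    dbsnp: Optional[str] = None
    imprinted: Optional[str] = None
    output_dir: str = "m6avar_out"
    sample: str = "sample"
    autosome_min_depth: int = 30
    sex_min_depth: int = 15
    sex_chroms: tuple[str, ...] = ("chrX", "chrY", "X", "Y")
    min_rna_depth: int = 30
    rna_min_variant_depth: int = 30
    both_strands_denominator: bool = True
    require_base_concordance: bool = True
    consistency_match_type: bool = True
    motif_flank: int = 10
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) else json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "sex_chroms" in data:
            data["sex_chroms"] = tuple(data["sex_chroms"])
        return cls(**data)

    def validate(self) -> None:
        mandatory = {
            "genome": self.genome, "annotation": self.annotation,
            "modifications": self.modifications, "dna_vcf": self.dna_vcf,
        }
        for name, path in mandatory.items():
            if not path or not os.path.exists(path):
                raise InputError(f"mandatory input '{name}' missing: {path!r}")
        for name, path in (("rna_vcf", self.rna_vcf), ("rna_coverage", self.rna_coverage),
                           ("dbsnp", self.dbsnp), ("imprinted", self.imprinted)):
            if path and not os.path.exists(path):
                raise InputError(f"input '{name}' does not exist: {path!r}")
        if self.autosome_min_depth < 0 or self.sex_min_depth < 0:
            raise InputError("depth thresholds must be non-negative")


@dataclass
class SampleResult:
    """In-memory results of a single-sample run (plus paths of the reports)."""

    config: RunConfig
    genome: dict[str, str]
    genes: list
    filtered_sites: list[MethylSite]
    gene_methylation: list
    methyloci_summary: methylome.MethylociSummary
    dna_variants: list[Variant]
    gene_variation: list
    transmissions: Optional[transmission.JoinResult]
    feature_rows: list[GeneFeatureRow]
    imprinted_ids: set[str] = field(default_factory=set)
    paths: dict[str, str] = field(default_factory=dict)


def _read_imprinted(path: Optional[str]) -> set[str]:
    if not path:
        return set()
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def run_single_sample(config: RunConfig) -> SampleResult:
    config.validate()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)

    genome = io_formats.load_genome(config.genome)
    genes = io_formats.read_annotation(config.annotation)
    raw_sites = io_formats.read_modifications(config.modifications)
    thresholds = DepthThresholds(config.autosome_min_depth, config.sex_min_depth)
    sites = methylome.filter_by_depth(raw_sites, thresholds, set(config.sex_chroms))
    logger.info("depth filter: kept %d of %d sites", len(sites), len(raw_sites))

    gene_meth = methylome.gene_methylation(genes, sites, genome)
    if sites:
        summary = methylome.methyloci_on_gene_summary(sites, genes)
    else:
        logger.warning("no 6mA sites after filtering; all genes unmethylated")
        summary = methylome.MethylociSummary(0, 0, 0.0, 0)
    per_chrom = methylome.per_chromosome_density(sites, genome, config.both_strands_denominator)
    g_density = methylome.genome_density(sites, genome, config.both_strands_denominator)

    dna = io_formats.read_vcf(config.dna_vcf, source="DNA")
    dbsnp = io_formats.read_position_set(config.dbsnp) if config.dbsnp else None
    dna = var_mod.filter_dna_variants(dna, dbsnp)
    dna = var_mod.methylated_variation(dna, sites, config.require_base_concordance)
    gene_var = var_mod.gene_variation(genes, dna)

    # methylated vs unmethylated variation-ratio comparison
    meth_ids = {m.gene_id for m in gene_meth if m.methylated}
    ratios_meth = [v.variation_ratio for v in gene_var if v.gene_id in meth_ids]
    ratios_unmeth = [v.variation_ratio for v in gene_var if v.gene_id not in meth_ids]
    comparison = None
    if len(ratios_meth) >= 2 and len(ratios_unmeth) >= 2:
        comparison = var_mod.group_ratio_comparison(
            ratios_unmeth, ratios_meth, "unmethylated", "methylated"
        )

    # transmission (needs RNA inputs)
    join = None
    transmit_counts: dict[str, dict[str, int]] = {}
    if config.rna_vcf:
        rna = io_formats.read_vcf(config.rna_vcf, source="RNA")
        rna = var_mod.filter_rna_variants(rna, config.rna_min_variant_depth)
        cov = io_formats.read_coverage(config.rna_coverage) if config.rna_coverage else None
        join = transmission.join_dna_rna(dna, rna, cov, config.min_rna_depth)
        transmit_counts = transmission.gene_transmit_counts(join.records, genes)

    imprinted_ids = _read_imprinted(config.imprinted)
    rows = association.build_feature_rows(gene_meth, gene_var, transmit_counts, imprinted_ids)

    paths = _write_sample_reports(
        config, outdir, genome, genes, sites, summary, per_chrom, g_density,
        gene_meth, dna, gene_var, comparison, join, rows,
    )
    return SampleResult(
        config=config, genome=genome, genes=genes, filtered_sites=sites,
        gene_methylation=gene_meth, methyloci_summary=summary,
        dna_variants=dna, gene_variation=gene_var, transmissions=join,
        feature_rows=rows, imprinted_ids=imprinted_ids, paths=paths,
    )


def _write_sample_reports(config, outdir, genome, genes, sites, summary, per_chrom,
                          g_density, gene_meth, dna, gene_var, comparison, join, rows):
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(p("methylation_summary.tsv"), "w") as fh:
        fh.write("sample\tn_methyloci\tn_methyloci_on_genes\tpct_on_genes\tn_methylated_genes\n")
        fh.write(f"{config.sample}\t{summary.n_total}\t{summary.n_on_gene}\t"
                 f"{summary.pct_on_gene:.2f}\t{summary.n_methylated_genes}\n")

    with open(p("density.tsv"), "w") as fh:
        fh.write("chrom\tdensity\n")
        for chrom in sorted(per_chrom):
            fh.write(f"{chrom}\t{per_chrom[chrom]:.6g}\n")
        fh.write(f"genome\t{g_density:.6g}\n")

    with open(p("gene_methylation.tsv"), "w") as fh:
        fh.write("gene_id\tn_6mA\tn_A\tdensity\tmethylated\n")
        for m in sorted(gene_meth, key=lambda m: m.gene_id):
            fh.write(f"{m.gene_id}\t{m.n_6mA}\t{m.n_A}\t{m.density:.6g}\t{int(m.methylated)}\n")

    with open(p("gene_variation.tsv"), "w") as fh:
        fh.write("gene_id\tgene_length\tn_var\tvariation_ratio\tn_AT\tn_CG\tn_methylated_var\n")
        for v in sorted(gene_var, key=lambda v: v.gene_id):
            fh.write(f"{v.gene_id}\t{v.gene_length}\t{v.n_var}\t{v.variation_ratio:.6g}\t"
                     f"{v.n_AT}\t{v.n_CG}\t{v.n_methylated_var}\n")

    with open(p("variation_comparison.tsv"), "w") as fh:
        fh.write("comparison\tn_a\tn_b\tmean_a\tmean_b\tstatistic\tdf\tp_value\n")
        if comparison is not None:
            c = comparison
            fh.write(f"{c.group_a}_vs_{c.group_b}\t{c.n_a}\t{c.n_b}\t{c.mean_a:.6g}\t"
                     f"{c.mean_b:.6g}\t{c.statistic:.6g}\t{c.df:.6g}\t{c.p_value:.6g}\n")

    site_dist = var_mod.site_region_distribution(sites, genes)
    var_dist = var_mod.region_distribution(dna, genes)
    with open(p("region_breakdown.tsv"), "w") as fh:
        fh.write("region\tfraction_6mA\tfraction_dna_variants\n")
        for lab in var_mod.REGION_LABELS:
            fh.write(f"{lab}\t{site_dist[lab]:.6g}\t{var_dist[lab]:.6g}\n")

    io_formats.write_sites_bed(sites, p("filtered_sites.bed"))
    methylome.export_motif_contexts(sites, genome, config.motif_flank, p("motif_contexts.fa"))
    if rows:
        io_formats.write_feature_table(rows, p("gene_features.tsv"))
    if join is not None:
        transmission.write_transmission_tsv(join.records, p("transmissions.tsv"))
        with open(p("transmission_tallies.tsv"), "w") as fh:
            fh.write("bucket\tcount\n")
            for k in sorted(join.tallies):
                fh.write(f"{k}\t{join.tallies[k]}\n")
    return paths


@dataclass
class PairResult:
    consistent_sites: list[MethylSite]
    consistent_records: list
    feature_rows: list[GeneFeatureRow]
    logistic: Optional[RegressionResult]
    linear: Optional[RegressionResult]
    contrasts: Optional[association.ImprintingContrasts]
    paths: dict[str, str] = field(default_factory=dict)


def run_two_sample(
    result_a: SampleResult, result_b: SampleResult, output_dir: Optional[str] = None
) -> PairResult:
    """Cross-sample consistency analysis and the association models.

    High-confidence 6mA sites are those called (post-filter) in both
    samples; high-confidence transmissions are events observed identically
    in both. Feature rows are rebuilt from the consistent data on sample
    A's annotation (both samples must share the chromosome namespace) and
    the logistic and linear models are fitted to them.
    """
    chroms_a = set(result_a.genome)
    chroms_b = set(result_b.genome)
    if chroms_a != chroms_b:
        offenders = sorted(chroms_a ^ chroms_b)
        raise InputError(f"mismatched chromosome namespaces: {offenders}")

    cons_sites = methylome.consistent_sites(result_a.filtered_sites, result_b.filtered_sites)
    if result_a.transmissions is None or result_b.transmissions is None:
        raise InputError("both samples need RNA inputs for the two-sample analysis")
    cons_recs = transmission.consistent_transmissions(
        result_a.transmissions.records,
        result_b.transmissions.records,
        match_type=result_a.config.consistency_match_type,
    )

    genes = result_a.genes
    gene_meth = methylome.gene_methylation(genes, cons_sites, result_a.genome)
    counts = transmission.gene_transmit_counts(cons_recs, genes)
    rows = association.build_feature_rows(
        gene_meth, result_a.gene_variation, counts, result_a.imprinted_ids
    )

    logistic = linear = None
    fit_errors = {}
    try:
        logistic = association.fit_logistic(rows)
    except (ValueError, association.SeparationError) as exc:
        fit_errors["logistic"] = str(exc)
        logger.warning("logistic fit unavailable: %s", exc)
    try:
        linear = association.fit_linear(rows)
    except ValueError as exc:
        fit_errors["linear"] = str(exc)
        logger.warning("linear fit unavailable: %s", exc)
    contrasts = association.imprinting_contrasts(rows) if result_a.imprinted_ids else None

    paths = {}
    if output_dir:
        os.makedirs(output_dir, exist_ok=True)

        def p(name):
            paths[name] = os.path.join(output_dir, name)
            return paths[name]

        io_formats.write_sites_bed(cons_sites, p("consistent_sites.bed"))
        transmission.write_transmission_tsv(cons_recs, p("consistent_transmissions.tsv"))
        if rows:
            io_formats.write_feature_table(rows, p("consistent_gene_features.tsv"))
        if logistic is not None:
            association.write_regression_tsv(logistic, p("logistic_regression.tsv"))
        if linear is not None:
            association.write_regression_tsv(linear, p("linear_regression.tsv"))
        if contrasts is not None:
            association.write_contrasts_tsv(contrasts, p("imprinting_contrasts.tsv"))
        with open(p("consistency_summary.tsv"), "w") as fh:
            fh.write("quantity\tcount\n")
            fh.write(f"consistent_6mA_sites\t{len(cons_sites)}\n")
            fh.write(f"consistent_transmissions\t{len(cons_recs)}\n")
            for name, msg in fit_errors.items():
                fh.write(f"{name}_fit_error\t{msg}\n")

    return PairResult(
        consistent_sites=cons_sites, consistent_records=cons_recs,
        feature_rows=rows, logistic=logistic, linear=linear,
        contrasts=contrasts, paths=paths,
    )
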