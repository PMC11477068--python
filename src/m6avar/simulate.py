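"""Synthetic study generator with known ground truth.

Builds, from a seed and a parameter set, a complete fake study — a small
multi-chromosome genome, gene models with exon/intron/UTR structure on
both strands, strand-correct 6mA sites with planted motif contexts and
per-site coverages straddling the depth cutoffs, DNA variants whose
per-gene rate depends on methylation status, RNA genotypes drawn from a
methylation-dependent transmission matrix, an RNA coverage track, a dbSNP
position list and an imprinting gene list — so that every analysis module
can be tested against recoverable truth without any external data.

Also provides direct feature-row simulators (logistic/linear/null) for
regression parameter-recovery and calibration tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .models import (
    TRANSMIT_TYPES,
    CoverageTrack,
    DepthThresholds,
    GeneFeatureRow,
    GeneModel,
    MethylSite,
    Variant,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "Y": "CT", "R": "AG", "W": "AT", "S": "CG"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _default_t_meth() -> dict:
    # methylated genes favour identity transmission
    return {
        "0/1": {"0/0": 0.05, "0/1": 0.90, "1/1": 0.05},
        "1/1": {"0/0": 0.05, "0/1": 0.05, "1/1": 0.90},
    }


def _default_t_unmeth() -> dict:
    # unmethylated genes spread mass onto genotype-switching classes
    return {
        "0/1": {"0/0": 0.25, "0/1": 0.60, "1/1": 0.15},
        "1/1": {"0/0": 0.20, "0/1": 0.20, "1/1": 0.60},
    }


@dataclass
class SimulationParams:
    """All knobs of the synthetic study; defaults define the study conditions.

    The DNA variation rates (0.21% of gene-body bases for unmethylated
    genes, 0.10% for methylated) and the six-type transmission structure
    are the regimes the analysis is designed to detect; per-gene 6mA
    densities are drawn high enough (1-5% of coding adenines) that a
    methylated gene on a kilobase-scale synthetic genome carries several
    sites. Site coverages are Normal(45, 15) so the depth cutoffs (30
    autosomal / 15 sex-chromosome) remove a nonzero, known subset.
    """

    seed: int = 1
    n_chroms: int = 4  # last one is the sex chromosome
    sex_chrom_name: str = "chrX"
    n_genes: int = 2000
    gene_length_log_mean: float = np.log(1500.0)
    gene_length_log_sigma: float = 0.35
    gene_length_min: int = 600
    gene_length_max: int = 6000
    intergenic_gap_min: int = 200
    intergenic_gap_max: int = 800
    exon_count_min: int = 2
    exon_count_max: int = 4
    minus_strand_fraction: float = 0.45
    p_gene_methylated: float = 0.5
    density_min: float = 0.01  # per coding-strand adenine, methylated genes
    density_max: float = 0.05
    intergenic_site_density: float = 0.005  # per intergenic A/T base
    motif: str = "AGGYR"
    p_motif: float = 0.7  # fraction of genic sites with a planted motif
    coverage_mean: float = 45.0
    coverage_sd: float = 15.0
    depth_thresholds: DepthThresholds = field(default_factory=lambda: DepthThresholds(30, 15))
    dna_variation_ratio_meth: float = 0.0010
    dna_variation_ratio_unmeth: float = 0.0021
    intergenic_variant_rate: float = 0.0010
    p_het: float = 0.7
    t_meth: dict = field(default_factory=_default_t_meth)
    t_unmeth: dict = field(default_factory=_default_t_unmeth)
    p_expressed: float = 0.95
    rna_cov_min: int = 31
    rna_cov_max: int = 80
    rna_only_rate: float = 5e-5  # per expressed gene-body base
    p_imprinted: float = 0.05
    p_in_dbsnp: float = 0.95
    n_dbsnp_decoys: int = 200

    def validate(self) -> None:
        probs = [
            self.minus_strand_fraction, self.p_gene_methylated, self.p_motif,
            self.p_het, self.p_expressed, self.p_imprinted, self.p_in_dbsnp,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for name, rate in (
            ("dna_variation_ratio_meth", self.dna_variation_ratio_meth),
            ("dna_variation_ratio_unmeth", self.dna_variation_ratio_unmeth),
            ("intergenic_variant_rate", self.intergenic_variant_rate),
            ("rna_only_rate", self.rna_only_rate),
        ):
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} implies more than one variant per base")
        for matrix in (self.t_meth, self.t_unmeth):
            for dna_gt, row in matrix.items():
                if dna_gt not in ("0/1", "1/1"):
                    raise ValueError(f"transmission matrix keyed by bad genotype {dna_gt}")
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"transmission row for {dna_gt} does not sum to 1")
        if not (0 < self.density_min <= self.density_max <= 1):
            raise ValueError("bad per-gene density range")


@dataclass
class VariantTruth:
    variant: Variant
    gene_id: Optional[str]
    in_dbsnp: bool
    rna_gt: Optional[str]  # None when the gene is not expressed / intergenic
    transmit_type: Optional[str]


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    length: int
    n_coding_A: int
    methylated_class: bool  # the class the gene was simulated under
    n_sites_planted: int
    n_sites_passing: int
    methylated: bool  # >=1 site surviving the depth filter
    density: float  # passing sites / coding adenines
    n_var: int
    n_var_dbsnp: int
    imprinted: bool
    expressed: bool
    transmit_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth]
    variants: list[VariantTruth]
    t_meth: dict
    t_unmeth: dict


@dataclass
class Study:
    """An in-memory synthetic study bundle."""

    params: SimulationParams
    genome: dict[str, str]
    genes: list[GeneModel]
    sites: list[MethylSite]
    dna_variants: list[Variant]
    rna_variants: list[Variant]
    rna_coverage: CoverageTrack
    dbsnp: set[tuple[str, int]]
    imprinted_ids: set[str]
    truth: GroundTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _gene_structure(rng, start: int, length: int, n_exons: int) -> tuple:
    """Alternating exon/intron blocks plus terminal UTR sub-intervals."""
    n_blocks = 2 * n_exons - 1
    weights = rng.dirichlet(np.ones(n_blocks))
    min_block = 20
    sizes = np.maximum(min_block, np.floor(weights * (length - min_block * n_blocks)).astype(int) + min_block)
    sizes[-1] += length - int(sizes.sum())
    if sizes[-1] < min_block:  # re-balance pathological rounding
        sizes[:] = length // n_blocks
        sizes[-1] += length - int(sizes.sum())
    exons = []
    cursor = start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((cursor, cursor + int(size)))
        cursor += int(size)
    utrs = []
    first, last = exons[0], exons[-1]
    u1 = min((first[1] - first[0]) // 3, int(rng.integers(30, 151)))
    u2 = min((last[1] - last[0]) // 3, int(rng.integers(30, 151)))
    if u1 >= 10:
        utrs.append((first[0], first[0] + u1))
    if u2 >= 10:
        utrs.append((last[1] - u2, last[1]))
    return exons, utrs


def _instantiate_motif(rng, motif: str) -> str:
    return "".join(
        b if b in "ACGT" else _IUPAC[b][int(rng.integers(len(_IUPAC[b])))] for b in motif
    )


def simulate_study(params: Optional[SimulationParams] = None, seed: Optional[int] = None) -> Study:
    """Generate a full synthetic study; deterministic given the seed."""
    params = params or SimulationParams()
    if seed is not None:
        from dataclasses import replace

        params = replace(params, seed=seed)
    params.validate()
    rng = np.random.default_rng(params.seed)

    chrom_names = [f"chr{i + 1}" for i in range(params.n_chroms - 1)] + [params.sex_chrom_name]
    genes_per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    genes_per_chrom[0] += params.n_genes - sum(genes_per_chrom)

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    sites: list[MethylSite] = []
    dna_variants: list[Variant] = []
    rna_variants: list[Variant] = []
    cov_intervals: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_names}
    dbsnp: set[tuple[str, int]] = set()
    imprinted_ids: set[str] = set()
    gene_truths: dict[str, GeneTruth] = {}
    variant_truths: list[VariantTruth] = []

    thr = params.depth_thresholds
    gene_counter = 0

    for chrom, n_genes_here in zip(chrom_names, genes_per_chrom):
        is_sex = chrom == params.sex_chrom_name
        min_cov = thr.sex_min if is_sex else thr.autosome_min

        # -- layout: gene lengths and gaps first, then one sequence draw
        lengths = np.clip(
            np.exp(rng.normal(params.gene_length_log_mean, params.gene_length_log_sigma, n_genes_here)),
            params.gene_length_min, params.gene_length_max,
        ).astype(int)
        gaps = rng.integers(params.intergenic_gap_min, params.intergenic_gap_max + 1,
                            n_genes_here + 1)
        chrom_len = int(lengths.sum() + gaps.sum())
        seq = rng.choice(_BASES, size=chrom_len).copy()

        gene_spans = []
        cursor = int(gaps[0])
        for gi in range(n_genes_here):
            gene_spans.append((cursor, cursor + int(lengths[gi])))
            cursor += int(lengths[gi]) + int(gaps[gi + 1])

        chrom_sites: list[tuple[int, str, int]] = []  # (pos, strand, coverage)
        # positions whose base must stay fixed (site centers): pos -> byte
        locked: dict[int, bytes] = {}

        for start, end in gene_spans:
            gene_id = f"G{gene_counter:05d}"
            gene_counter += 1
            strand = "-" if rng.random() < params.minus_strand_fraction else "+"
            n_exons = int(rng.integers(params.exon_count_min, params.exon_count_max + 1))
            exons, utr_ivs = _gene_structure(rng, start, end - start, n_exons)
            # tag UTRs by transcription direction
            utrs = []
            for s, e in utr_ivs:
                leftmost = s == exons[0][0]
                tag = ("5UTR" if leftmost else "3UTR") if strand == "+" else (
                    "3UTR" if leftmost else "5UTR")
                utrs.append((s, e, tag))
            gene = GeneModel(gene_id, chrom, strand, start, end,
                             exons=tuple(exons), utrs=tuple(sorted(utrs)))
            genes.append(gene)

            coding_byte = b"A" if strand == "+" else b"T"
            coding_pos = start + np.flatnonzero(seq[start:end] == coding_byte)

            methylated_class = rng.random() < params.p_gene_methylated
            site_pos = np.array([], dtype=int)
            if methylated_class and len(coding_pos) > 0:
                density = rng.uniform(params.density_min, params.density_max)
                n_sites = min(len(coding_pos), int(rng.binomial(len(coding_pos), density)))
                if n_sites > 0:
                    site_pos = np.sort(rng.choice(coding_pos, size=n_sites, replace=False))
            for p in site_pos:
                locked[int(p)] = coding_byte

            # plant motif contexts around a fraction of the gene's sites
            for p in site_pos:
                if rng.random() >= params.p_motif:
                    continue
                inst = _instantiate_motif(rng, params.motif)
                if strand == "+":
                    window = range(int(p), int(p) + len(inst))
                    bases = inst
                else:
                    window = range(int(p) - len(inst) + 1, int(p) + 1)
                    bases = "".join(_COMP[b] for b in reversed(inst))
                if window.start < start or window.stop > end:
                    continue
                conflict = any(
                    q in locked and locked[q] != bases[k].encode()
                    for k, q in enumerate(window)
                )
                if conflict:
                    continue
                for k, q in enumerate(window):
                    seq[q] = bases[k].encode()

            n_passing = 0
            for p in site_pos:
                cov = max(1, int(round(rng.normal(params.coverage_mean, params.coverage_sd))))
                chrom_sites.append((int(p), strand, cov))
                if cov >= min_cov:
                    n_passing += 1

            imprinted = rng.random() < params.p_imprinted
            if imprinted:
                imprinted_ids.add(gene_id)
            expressed = rng.random() < params.p_expressed
            if expressed:
                depth = int(rng.integers(params.rna_cov_min, params.rna_cov_max + 1))
                cov_intervals[chrom].append((start, end, depth))

            # -- DNA variants at the methylation-dependent per-bp rate
            rate = (params.dna_variation_ratio_meth if methylated_class
                    else params.dna_variation_ratio_unmeth)
            length = end - start
            n_var = int(rng.binomial(length, rate))
            n_var = min(n_var, length)
            var_pos = np.sort(rng.choice(np.arange(start, end), size=n_var, replace=False)) \
                if n_var else np.array([], dtype=int)
            tmatrix = params.t_meth if methylated_class else params.t_unmeth
            transmit_counts = {t: 0 for t in TRANSMIT_TYPES}
            n_var_dbsnp = 0
            taken = set()
            for p in var_pos:
                p = int(p)
                ref = seq[p].decode()
                alt = _BASES[rng.choice([i for i in range(4) if _BASES[i].decode() != ref])].decode()
                gt = "0/1" if rng.random() < params.p_het else "1/1"
                v = Variant(chrom, p, ref, alt, gt, depth=None, source="DNA")
                dna_variants.append(v)
                taken.add(p)
                in_db = rng.random() < params.p_in_dbsnp
                if in_db:
                    dbsnp.add((chrom, p))
                    n_var_dbsnp += 1
                rna_gt = None
                ttype = None
                if expressed:
                    row = tmatrix[gt]
                    choices = list(row)
                    rna_gt = choices[int(rng.choice(len(choices), p=[row[c] for c in choices]))]
                    if rna_gt != "0/0":
                        rna_variants.append(
                            Variant(chrom, p, ref, alt, rna_gt,
                                    depth=int(rng.integers(params.rna_cov_min, params.rna_cov_max + 1)),
                                    source="RNA")
                        )
                    ttype = f"{gt}_{rna_gt}"
                    if in_db:
                        transmit_counts[ttype] += 1
                variant_truths.append(VariantTruth(v, gene_id, in_db, rna_gt, ttype))

            # -- RNA-only variants (no DNA counterpart) in expressed genes
            if expressed and params.rna_only_rate > 0:
                n_ro = int(rng.binomial(length, params.rna_only_rate))
                for _ in range(n_ro):
                    p = int(rng.integers(start, end))
                    if p in taken or p in locked:
                        continue
                    ref = seq[p].decode()
                    alt = _BASES[rng.choice([i for i in range(4) if _BASES[i].decode() != ref])].decode()
                    gt = "0/1" if rng.random() < params.p_het else "1/1"
                    rna_variants.append(
                        Variant(chrom, p, ref, alt, gt,
                                depth=int(rng.integers(params.rna_cov_min, params.rna_cov_max + 1)),
                                source="RNA")
                    )
                    taken.add(p)

            n_coding_A = int(np.count_nonzero(seq[start:end] == coding_byte))
            gene_truths[gene_id] = GeneTruth(
                gene_id=gene_id, chrom=chrom, strand=strand, length=length,
                n_coding_A=n_coding_A,
                methylated_class=methylated_class,
                n_sites_planted=len(site_pos),
                n_sites_passing=n_passing,
                methylated=n_passing > 0,
                density=n_passing / n_coding_A if n_coding_A else 0.0,
                n_var=n_var, n_var_dbsnp=n_var_dbsnp,
                imprinted=imprinted, expressed=expressed,
                transmit_counts=transmit_counts,
            )

        # -- intergenic 6mA sites and variants
        genic = np.zeros(chrom_len, dtype=bool)
        for start, end in gene_spans:
            genic[start:end] = True
        intergenic_idx = np.flatnonzero(~genic)
        if len(intergenic_idx):
            at_mask = (seq[intergenic_idx] == b"A") | (seq[intergenic_idx] == b"T")
            at_idx = intergenic_idx[at_mask]
            pick = at_idx[rng.random(len(at_idx)) < params.intergenic_site_density]
            for p in pick:
                strand = "+" if seq[p] == b"A" else "-"
                cov = max(1, int(round(rng.normal(params.coverage_mean, params.coverage_sd))))
                chrom_sites.append((int(p), strand, cov))
            vpick = intergenic_idx[rng.random(len(intergenic_idx)) < params.intergenic_variant_rate]
            for p in vpick:
                p = int(p)
                ref = seq[p].decode()
                alt = _BASES[rng.choice([i for i in range(4) if _BASES[i].decode() != ref])].decode()
                gt = "0/1" if rng.random() < params.p_het else "1/1"
                v = Variant(chrom, p, ref, alt, gt, depth=None, source="DNA")
                dna_variants.append(v)
                in_db = rng.random() < params.p_in_dbsnp
                if in_db:
                    dbsnp.add((chrom, p))
                variant_truths.append(VariantTruth(v, None, in_db, None, None))

        for p, strand, cov in chrom_sites:
            sites.append(MethylSite(chrom, p, strand, cov))
        genome[chrom] = seq.tobytes().decode()

    # decoy dbSNP positions (not variant sites)
    taken_positions = {(v.chrom, v.pos) for v in dna_variants}
    for _ in range(params.n_dbsnp_decoys):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        p = int(rng.integers(len(genome[chrom])))
        if (chrom, p) not in taken_positions:
            dbsnp.add((chrom, p))

    sites.sort()
    dna_variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    rna_variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))

    # verify internal consistency: every site sits on its strand's adenine
    for s in sites:
        base = genome[s.chrom][s.pos]
        assert base == ("A" if s.strand == "+" else "T"), "site off adenine"

    truth = GroundTruth(
        genes=gene_truths, variants=variant_truths,
        t_meth=params.t_meth, t_unmeth=params.t_unmeth,
    )
    return Study(
        params=params, genome=genome, genes=genes, sites=sites,
        dna_variants=dna_variants, rna_variants=rna_variants,
        rna_coverage=CoverageTrack(cov_intervals), dbsnp=dbsnp,
        imprinted_ids=imprinted_ids, truth=truth,
    )


# ---------------------------------------------------------------------------
# File bundle
# ---------------------------------------------------------------------------

def write_study(study: Study, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the study as a file bundle; byte-identical across reruns."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "modifications": os.path.join(outdir, "modifications.gff"),
        "dna_vcf": os.path.join(outdir, "dna.vcf"),
        "rna_vcf": os.path.join(outdir, "rna.vcf"),
        "rna_coverage": os.path.join(outdir, "rna_coverage.tsv"),
        "dbsnp": os.path.join(outdir, "dbsnp.tsv"),
        "imprinted": os.path.join(outdir, "imprinted_genes.txt"),
    }
    io_formats.write_fasta(study.genome, paths["genome"])
    io_formats.write_annotation_gff3(study.genes, paths["annotation"])
    io_formats.write_modifications_gff(study.sites, paths["modifications"])
    io_formats.write_vcf(study.dna_variants, study.contig_lengths, paths["dna_vcf"])
    io_formats.write_vcf(study.rna_variants, study.contig_lengths, paths["rna_vcf"])
    io_formats.write_coverage(study.rna_coverage, paths["rna_coverage"])
    with open(paths["dbsnp"], "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in sorted(study.dbsnp):
            fh.write(f"{chrom}\t{pos + 1}\n")
    with open(paths["imprinted"], "w") as fh:
        for gid in sorted(study.imprinted_ids):
            fh.write(gid + "\n")
    return paths


def truth_report(study: Study, outdir: Optional[str] = None) -> dict[str, pd.DataFrame]:
    """Flat per-gene and per-variant truth tables (for recovery tests)."""
    gene_rows = []
    for gt in study.truth.genes.values():
        row = {
            "gene_id": gt.gene_id, "chrom": gt.chrom, "strand": gt.strand,
            "length": gt.length, "n_coding_A": gt.n_coding_A,
            "methylated_class": int(gt.methylated_class),
            "n_sites_planted": gt.n_sites_planted,
            "n_sites_passing": gt.n_sites_passing,
            "methylated": int(gt.methylated), "density": gt.density,
            "n_var": gt.n_var, "n_var_dbsnp": gt.n_var_dbsnp,
            "imprinted": int(gt.imprinted), "expressed": int(gt.expressed),
        }
        row.update({t: gt.transmit_counts.get(t, 0) for t in TRANSMIT_TYPES})
        gene_rows.append(row)
    genes_df = pd.DataFrame(gene_rows).sort_values("gene_id").reset_index(drop=True)
    var_rows = [
        {
            "chrom": vt.variant.chrom, "pos": vt.variant.pos + 1,
            "ref": vt.variant.ref, "alt": vt.variant.alt,
            "dna_gt": vt.variant.genotype, "gene_id": vt.gene_id or ".",
            "in_dbsnp": int(vt.in_dbsnp), "rna_gt": vt.rna_gt or ".",
            "transmit_type": vt.transmit_type or ".",
        }
        for vt in study.truth.variants
    ]
    variants_df = pd.DataFrame(var_rows).sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)
    out = {"genes": genes_df, "variants": variants_df}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        genes_df.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
        variants_df.to_csv(os.path.join(outdir, "truth_variants.tsv"), sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# Direct feature-row simulators (regression recovery / calibration)
# ---------------------------------------------------------------------------

#: Poisson means for transmit-type counts in the row simulators. The two
#: homozygous-to-non-identical classes are left at 0: they are rare in
#: practice, and their all-zero columns exercise the dropped-term path,
#: yielding the familiar four-term summary table.
DEFAULT_X_MEANS = {
    "0/1_0/0": 0.5,
    "0/1_0/1": 3.0,
    "0/1_1/1": 0.4,
    "1/1_0/0": 0.0,
    "1/1_0/1": 0.0,
    "1/1_1/1": 2.0,
}

DEFAULT_LOGISTIC_BETA = {"0/1_0/1": 0.12, "1/1_1/1": 0.13}
DEFAULT_LINEAR_SLOPES = {"0/1_0/0": 4.7e-4}


def _draw_x(rng, n: int, x_means: dict) -> np.ndarray:
    return np.column_stack([rng.poisson(x_means.get(t, 0.0), size=n) for t in TRANSMIT_TYPES])


def _rows_from_arrays(x: np.ndarray, y_density: np.ndarray, methylated: np.ndarray,
                      n_var: Optional[np.ndarray] = None,
                      imprinted: Optional[np.ndarray] = None) -> list[GeneFeatureRow]:
    rows = []
    for i in range(x.shape[0]):
        rows.append(
            GeneFeatureRow(
                gene_id=f"S{i:05d}",
                y_density=float(y_density[i]),
                methylated=bool(methylated[i]),
                x={t: int(x[i, j]) for j, t in enumerate(TRANSMIT_TYPES)},
                n_var_dna=int(n_var[i]) if n_var is not None else 0,
                imprinted=bool(imprinted[i]) if imprinted is not None else False,
            )
        )
    return rows


def simulate_logistic_rows(
    n: int = 5000,
    intercept: float = -0.5,
    beta: Optional[dict[str, float]] = None,
    x_means: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> list[GeneFeatureRow]:
    """Rows drawn from the logistic model itself, for parameter recovery.

    Effect sizes default to magnitudes on the order of the fitted
    human-sample coefficients (~0.12 per transmitted event for the two
    identity classes).
    """
    beta = DEFAULT_LOGISTIC_BETA if beta is None else beta
    x_means = DEFAULT_X_MEANS if x_means is None else x_means
    rng = np.random.default_rng(seed)
    x = _draw_x(rng, n, x_means)
    bvec = np.array([beta.get(t, 0.0) for t in TRANSMIT_TYPES])
    eta = intercept + x @ bvec
    p = 1.0 / (1.0 + np.exp(-eta))
    methylated = rng.random(n) < p
    y_density = np.where(methylated, rng.uniform(0.001, 0.05, size=n), 0.0)
    return _rows_from_arrays(x, y_density, methylated)


def simulate_linear_rows(
    n: int = 5000,
    intercept: float = 1.3e-4,
    slopes: Optional[dict[str, float]] = None,
    sigma: float = 2.0e-4,
    x_means: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> list[GeneFeatureRow]:
    """Methylated-gene rows from the linear density model, for recovery."""
    slopes = DEFAULT_LINEAR_SLOPES if slopes is None else slopes
    x_means = dict(DEFAULT_X_MEANS, **{"0/1_0/0": 1.0}) if x_means is None else x_means
    rng = np.random.default_rng(seed)
    x = _draw_x(rng, n, x_means)
    avec = np.array([slopes.get(t, 0.0) for t in TRANSMIT_TYPES])
    y = intercept + x @ avec + rng.normal(0.0, sigma, size=n)
    return _rows_from_arrays(x, y, np.ones(n, dtype=bool))


def simulate_null_rows(
    n: int = 600,
    p_methylated: float = 0.5,
    p_imprinted: float = 0.1,
    n_var_mean: float = 3.0,
    seed: int = 0,
) -> list[GeneFeatureRow]:
    """Rows where variant counts are independent of everything (null model).

    Used to check that the imprinting contrasts are calibrated: at the
    null, each t-test should reject at about its nominal rate.
    """
    rng = np.random.default_rng(seed)
    methylated = rng.random(n) < p_methylated
    imprinted = rng.random(n) < p_imprinted
    n_var = rng.poisson(n_var_mean, size=n)
    x = np.zeros((n, len(TRANSMIT_TYPES)), dtype=int)
    y_density = np.where(methylated, 0.01, 0.0)
    return _rows_from_arrays(x, y_density, methylated, n_var=n_var, imprinted=imprinted)
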