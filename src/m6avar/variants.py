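"""Variant filtering, gene/region annotation and variation-ratio statistics.

Covers the DNA-side post-calling screen (dbSNP position consistency), the
RNA-side depth screen (> 30X), assignment of variants to genes and to
exon/intron/UTR regions, per-gene variation ratios with the A/T vs C/G
partition, the methylated-variation overlap with 6mA sites, per-gene
A-mutated ratios at modified vs unmodified adenines, and the two-group
t-test used to compare ratio distributions.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .methylome import SiteIndex, coding_adenine_count
from .models import ComparisonResult, GeneModel, GeneVariation, MethylSite, Variant, merge_intervals

logger = logging.getLogger(__name__)

REGION_LABELS = ("UTR", "exon", "intron", "intergenic")
#: higher wins when a position carries several annotations within one gene
_PRECEDENCE = {"UTR": 3, "exon": 2, "intron": 1, "intergenic": 0}


# ---------------------------------------------------------------------------
# Post-calling filters
# ---------------------------------------------------------------------------

def filter_dna_variants(
    variants: Iterable[Variant], dbsnp: Optional[set[tuple[str, int]]]
) -> list[Variant]:
    """Keep DNA variants whose (chrom, pos) is a known dbSNP position.

    ``dbsnp`` holds 0-based positions. When no dbSNP set is supplied the
    input passes through unchanged with a logged notice.
    """
    variants = list(variants)
    if dbsnp is None:
        logger.info("filter_dna_variants: no dbSNP positions supplied; passing through")
        return variants
    kept = [v for v in variants if (v.chrom, v.pos) in dbsnp]
    logger.info("filter_dna_variants: kept %d of %d", len(kept), len(variants))
    return kept


def filter_rna_variants(variants: Iterable[Variant], min_depth: int = 30) -> list[Variant]:
    """Keep RNA variants with depth strictly greater than ``min_depth``.

    The cutoff is exclusive (depth must exceed 30X at the default);
    variants without a depth field are dropped with a warning.
    """
    kept = []
    n_missing = 0
    n_in = 0
    for v in variants:
        n_in += 1
        if v.depth is None:
            n_missing += 1
            logger.debug("variant %s:%d has no depth; dropped", v.chrom, v.pos + 1)
            continue
        if v.depth > min_depth:
            kept.append(v)
    logger.info(
        "filter_rna_variants: kept %d of %d (%d without depth)", len(kept), n_in, n_missing
    )
    return kept


# ---------------------------------------------------------------------------
# Gene / region annotation
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval tree over gene bodies for point queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            self._trees[g.chrom].addi(g.start, g.end, g)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: g.gene_id)


def region_label_in_gene(gene: GeneModel, pos: int) -> str:
    """Label a position inside a gene body: UTR beats exon beats intron."""
    if not gene.contains(pos):
        raise ValueError(f"position {pos} outside gene {gene.gene_id}")
    for s, e, _tag in gene.utrs:
        if s <= pos < e:
            return "UTR"
    for s, e in gene.exons:
        if s <= pos < e:
            return "exon"
    return "intron"


def annotate_regions(
    variants: Sequence[Variant], genes: Sequence[GeneModel]
) -> list[list[tuple[Optional[str], str]]]:
    """Per-variant (gene_id, region label) assignments, aligned with input.

    A variant inside several genes gets one entry per gene; a variant
    outside every gene body gets the single entry ``(None, "intergenic")``.
    """
    index = GeneIndex(genes)
    out = []
    for v in variants:
        hits = index.overlapping(v.chrom, v.pos)
        if not hits:
            out.append([(None, "intergenic")])
        else:
            out.append([(g.gene_id, region_label_in_gene(g, v.pos)) for g in hits])
    return out


def best_region_label(assignments: list[tuple[Optional[str], str]]) -> str:
    """Collapse multi-gene assignments to the highest-precedence label."""
    return max((lab for _g, lab in assignments), key=_PRECEDENCE.__getitem__)


def region_distribution(
    variants: Sequence[Variant], genes: Sequence[GeneModel]
) -> dict[str, float]:
    """Fraction of variants per region label (one label per variant).

    Labels follow the in-gene precedence UTR > exon > intron and sum to 1
    including the intergenic class.
    """
    if not variants:
        return {lab: 0.0 for lab in REGION_LABELS}
    counts = {lab: 0 for lab in REGION_LABELS}
    for assignment in annotate_regions(variants, genes):
        counts[best_region_label(assignment)] += 1
    n = len(variants)
    return {lab: counts[lab] / n for lab in REGION_LABELS}


def site_region_distribution(
    sites: Sequence[MethylSite], genes: Sequence[GeneModel]
) -> dict[str, float]:
    """Same as :func:`region_distribution` but for 6mA sites (same-strand genes)."""
    if not sites:
        return {lab: 0.0 for lab in REGION_LABELS}
    index = GeneIndex(genes)
    counts = {lab: 0 for lab in REGION_LABELS}
    for s in sites:
        hits = [g for g in index.overlapping(s.chrom, s.pos) if g.strand == s.strand]
        if not hits:
            counts["intergenic"] += 1
        else:
            counts[max((region_label_in_gene(g, s.pos) for g in hits), key=_PRECEDENCE.__getitem__)] += 1
    n = len(sites)
    return {lab: counts[lab] / n for lab in REGION_LABELS}


def gene_region_lengths(gene: GeneModel) -> dict[str, int]:
    """Disjoint region lengths (bp) under the UTR > exon > intron precedence."""
    utr = merge_intervals([(s, e) for s, e, _ in gene.utrs])
    exon = merge_intervals(gene.exons)
    utr_bp = sum(e - s for s, e in utr)
    exon_minus_utr = _subtract(exon, utr)
    exon_bp = sum(e - s for s, e in exon_minus_utr)
    intron_bp = gene.length - utr_bp - exon_bp
    return {"UTR": utr_bp, "exon": exon_bp, "intron": intron_bp}


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval subtraction a \\ b for merged, sorted half-open intervals."""
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# Per-gene variation
# ---------------------------------------------------------------------------

def gene_variation(
    genes: Sequence[GeneModel], variants: Sequence[Variant]
) -> list[GeneVariation]:
    """Per-gene variant counts and the variation ratio n_var / gene length.

    The denominator is the full gene-body length (introns included). The
    A/T vs C/G split is by plus-strand REF base; ``n_methylated_var``
    counts variants whose ``m6a_overlap`` flag was set by
    :func:`methylated_variation`. Genes with no variants are still emitted
    (ratio 0) — they are the regression negatives. Variants in overlapping
    genes contribute to each gene's row.
    """
    index = GeneIndex(genes)
    per_gene: dict[str, list[Variant]] = defaultdict(list)
    for v in variants:
        for g in index.overlapping(v.chrom, v.pos):
            per_gene[g.gene_id].append(v)
    out = []
    for g in genes:
        vs = per_gene.get(g.gene_id, [])
        n_at = sum(1 for v in vs if v.ref in "AT")
        n_meth = sum(1 for v in vs if v.m6a_overlap)
        out.append(
            GeneVariation(
                gene_id=g.gene_id,
                gene_length=g.length,
                n_var=len(vs),
                variation_ratio=len(vs) / g.length,
                n_AT=n_at,
                n_CG=len(vs) - n_at,
                n_methylated_var=n_meth,
            )
        )
    return out


def gene_region_variation(
    genes: Sequence[GeneModel], variants: Sequence[Variant]
) -> dict[str, dict[str, tuple[int, int, float]]]:
    """Region-level variation per gene: region -> (length, n_var, ratio).

    Mirrors the gene-level definition with each region's merged length as
    the denominator; a region of length 0 reports ratio 0.
    """
    index = GeneIndex(genes)
    counts: dict[str, dict[str, int]] = {
        g.gene_id: {"UTR": 0, "exon": 0, "intron": 0} for g in genes
    }
    for v in variants:
        for g in index.overlapping(v.chrom, v.pos):
            counts[g.gene_id][region_label_in_gene(g, v.pos)] += 1
    out = {}
    for g in genes:
        lengths = gene_region_lengths(g)
        out[g.gene_id] = {
            lab: (lengths[lab], counts[g.gene_id][lab],
                  counts[g.gene_id][lab] / lengths[lab] if lengths[lab] else 0.0)
            for lab in ("UTR", "exon", "intron")
        }
    return out


# ---------------------------------------------------------------------------
# Methylated variation and A-mutated ratios
# ---------------------------------------------------------------------------

def methylated_variation(
    variants: Sequence[Variant],
    sites: Sequence[MethylSite],
    require_base_concordance: bool = True,
) -> list[Variant]:
    """Flag variants that coincide with a 6mA site (methylated variation).

    With base concordance (default) the variant's REF base must be the
    adenine of the site's strand: REF=A for a plus-strand site, REF=T for
    a minus-strand site (VCF REF is the plus-strand base). A positional
    match with a discordant REF base is logged as an inconsistent site.
    Returns flagged copies; the input is not mutated.
    """
    by_pos: dict[tuple[str, int], list[MethylSite]] = defaultdict(list)
    for s in sites:
        by_pos[(s.chrom, s.pos)].append(s)
    out = []
    n_flagged = n_discordant = 0
    for v in variants:
        hits = by_pos.get((v.chrom, v.pos), ())
        flagged = False
        for s in hits:
            expected_ref = "A" if s.strand == "+" else "T"
            if not require_base_concordance or v.ref == expected_ref:
                flagged = True
            else:
                n_discordant += 1
                logger.warning(
                    "inconsistent site: variant REF=%s at %s:%d overlaps %s-strand 6mA",
                    v.ref, v.chrom, v.pos + 1, s.strand,
                )
        n_flagged += flagged
        out.append(replace(v, m6a_overlap=flagged))
    logger.info(
        "methylated_variation: flagged %d of %d variants (%d discordant overlaps)",
        n_flagged, len(out), n_discordant,
    )
    return out


def a_mutated_ratio(
    gene: GeneModel,
    sites: Sequence[MethylSite],
    variants: Sequence[Variant],
    genome: Mapping[str, str],
) -> tuple[Optional[float], Optional[float]]:
    """A-mutated ratios (mutated-A / A) at modified vs unmodified adenines.

    ``ratio_modified`` is the fraction of the gene's same-strand 6mA sites
    carrying a (base-concordant) variant; ``ratio_unmodified`` is the
    fraction of the gene's unmodified coding-strand adenines carrying a
    variant. A zero denominator makes that ratio undefined (None).
    """
    site_index = SiteIndex(sites)
    site_pos = set(site_index.positions(gene.chrom, gene.strand, gene.start, gene.end))
    n_a = coding_adenine_count(gene, genome)
    coding_ref = "A" if gene.strand == "+" else "T"

    n_mut_modified = 0
    n_mut_unmodified = 0
    for v in variants:
        if v.chrom != gene.chrom or not gene.contains(v.pos):
            continue
        if v.ref != coding_ref:
            continue
        if v.pos in site_pos:
            n_mut_modified += 1
        else:
            n_mut_unmodified += 1

    n_modified = len(site_pos)
    n_unmodified = n_a - n_modified
    ratio_mod = n_mut_modified / n_modified if n_modified else None
    ratio_unmod = n_mut_unmodified / n_unmodified if n_unmodified > 0 else None
    return ratio_mod, ratio_unmod


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def group_ratio_comparison(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    name_a: str = "a",
    name_b: str = "b",
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided two-sample t-test on two groups of per-gene ratios.

    Student's (pooled-variance) test by default; ``equal_var=False`` gives
    Welch. Degenerate case: when both groups have zero variance, the test
    reports t=0, p=1 for equal means and p=0 otherwise.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = float(len(a) + len(b) - 2)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return ComparisonResult(
        group_a=name_a, group_b=name_b,
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        statistic=stat, df=df, p_value=p,
    )
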