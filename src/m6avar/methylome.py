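"""Depth filtering of 6mA site calls and all methylation summaries.

A "methylated gene" is strand-aware throughout: a site contributes to a
gene only when it lies in the gene body *and* its strand equals the gene's
strand, because 6mA on the coding strand is what marks the gene as
modified. 6mA density is always sites / adenines, where the adenine count
is taken on the relevant strand (coding strand for genes; both strands for
genome and chromosome densities, since site calls are strand-specific).
"""

from __future__ import annotations

import bisect
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .models import DepthThresholds, GeneMethylation, GeneModel, MethylSite

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Depth filtering
# ---------------------------------------------------------------------------

def filter_by_depth(
    sites: Iterable[MethylSite],
    thresholds: DepthThresholds,
    sex_chroms: set[str] = frozenset(),
) -> list[MethylSite]:
    """Drop sites whose coverage is *less than* the per-class threshold.

    Boundary values are kept: a site with coverage exactly at the cutoff
    survives. Autosomes use ``thresholds.autosome_min``, chromosomes named
    in ``sex_chroms`` use ``thresholds.sex_min``. Output is sorted by
    (chrom, pos, strand), so the operation is deterministic and idempotent.
    """
    kept = [
        s
        for s in sites
        if s.coverage >= (thresholds.sex_min if s.chrom in sex_chroms else thresholds.autosome_min)
    ]
    kept.sort()
    return kept


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------

def _adenine_positions(seq: str, both_strands: bool) -> int:
    n = seq.count("A")
    if both_strands:
        n += seq.count("T")  # adenines on the minus strand
    return n


def genome_density(
    sites: Sequence[MethylSite],
    genome: Mapping[str, str],
    both_strands: bool = True,
) -> float:
    """Genome-wide 6mA density: sites / adenine positions.

    With ``both_strands`` (default) the denominator counts A plus T on the
    plus-strand sequence, i.e. adenines on both strands, matching the
    strand-specific site calls. Raises on a genome with no adenines.
    """
    n_a = sum(_adenine_positions(seq, both_strands) for seq in genome.values())
    if n_a == 0:
        raise ValueError("genome contains no adenine positions")
    return len(sites) / n_a


def per_chromosome_density(
    sites: Sequence[MethylSite],
    genome: Mapping[str, str],
    both_strands: bool = True,
) -> dict[str, float]:
    """6mA density per chromosome; chromosomes with no sites report 0."""
    counts: dict[str, int] = defaultdict(int)
    for s in sites:
        counts[s.chrom] += 1
    out = {}
    for chrom, seq in genome.items():
        n_a = _adenine_positions(seq, both_strands)
        out[chrom] = counts.get(chrom, 0) / n_a if n_a else 0.0
    return out


def density_correlation(
    per_chrom_a: Mapping[str, float], per_chrom_b: Mapping[str, float]
) -> Optional[float]:
    """Pearson r of two per-chromosome density maps over shared chromosomes.

    Returns None (undefined) when either vector has zero variance; raises
    if fewer than 3 chromosomes are shared.
    """
    shared = sorted(set(per_chrom_a) & set(per_chrom_b))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared chromosomes, have {len(shared)}")
    a = [per_chrom_a[c] for c in shared]
    b = [per_chrom_b[c] for c in shared]
    if len(set(a)) == 1 or len(set(b)) == 1:
        logger.warning("density_correlation: zero variance, correlation undefined")
        return None
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# Per-gene methylation
# ---------------------------------------------------------------------------

class SiteIndex:
    """Sorted per-(chrom, strand) site positions for fast interval counting."""

    def __init__(self, sites: Iterable[MethylSite]):
        by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for s in sites:
            by_key[(s.chrom, s.strand)].append(s.pos)
            by_chrom[s.chrom].append(s.pos)
        self._by_key = {k: sorted(v) for k, v in by_key.items()}
        self._by_chrom = {k: sorted(v) for k, v in by_chrom.items()}

    def count(self, chrom: str, strand: str, start: int, end: int) -> int:
        pos = self._by_key.get((chrom, strand), ())
        return bisect.bisect_left(pos, end) - bisect.bisect_left(pos, start)

    def count_any_strand(self, chrom: str, start: int, end: int) -> int:
        pos = self._by_chrom.get(chrom, ())
        return bisect.bisect_left(pos, end) - bisect.bisect_left(pos, start)

    def positions(self, chrom: str, strand: str, start: int, end: int) -> list[int]:
        pos = self._by_key.get((chrom, strand), ())
        lo = bisect.bisect_left(pos, start)
        hi = bisect.bisect_left(pos, end)
        return list(pos[lo:hi])


def coding_adenine_count(gene: GeneModel, genome: Mapping[str, str]) -> int:
    """Adenines on the gene's coding strand within the gene body.

    For a minus-strand gene these are the T's of the plus-strand sequence.
    """
    if gene.chrom not in genome:
        raise KeyError(f"no sequence for chromosome {gene.chrom} (gene {gene.gene_id})")
    seq = genome[gene.chrom][gene.start : gene.end]
    return seq.count("A") if gene.strand == "+" else seq.count("T")


def gene_methylation(
    genes: Sequence[GeneModel],
    sites: Sequence[MethylSite],
    genome: Mapping[str, str],
) -> list[GeneMethylation]:
    """Per-gene 6mA count, coding-strand adenine count and density.

    Sites must already be depth-filtered. A site falling in two overlapping
    same-strand genes counts in both. A gene with zero coding-strand
    adenines reports density 0 with ``zero_adenine=True`` and a warning.
    """
    index = SiteIndex(sites)
    out = []
    for g in genes:
        n_sites = index.count(g.chrom, g.strand, g.start, g.end)
        n_a = coding_adenine_count(g, genome)
        if n_a == 0:
            if n_sites:
                raise ValueError(
                    f"gene {g.gene_id}: {n_sites} 6mA sites but no coding-strand adenines"
                )
            logger.warning("gene %s has no coding-strand adenines; density reported as 0", g.gene_id)
            out.append(GeneMethylation(g.gene_id, 0, 0, 0.0, False, zero_adenine=True))
            continue
        out.append(
            GeneMethylation(
                gene_id=g.gene_id,
                n_6mA=n_sites,
                n_A=n_a,
                density=n_sites / n_a,
                methylated=n_sites > 0,
            )
        )
    return out


@dataclass
class MethylociSummary:
    n_total: int
    n_on_gene: int
    pct_on_gene: float  # 2-decimal percentage
    n_methylated_genes: int


def methyloci_on_gene_summary(
    sites: Sequence[MethylSite], genes: Sequence[GeneModel]
) -> MethylociSummary:
    """Counts of sites on genes and of strand-methylated genes.

    ``n_on_gene`` counts sites whose position lies in at least one gene
    body regardless of strand (each site once); ``n_methylated_genes``
    counts genes with at least one same-strand site. Raises when there are
    no sites at all.
    """
    if not sites:
        raise ValueError("no 6mA sites: on-gene percentage undefined")
    from .models import merge_intervals

    bodies: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in genes:
        bodies[g.chrom].append((g.start, g.end))
    merged = {c: merge_intervals(iv) for c, iv in bodies.items()}
    starts = {c: [s for s, _ in iv] for c, iv in merged.items()}

    def on_gene(site: MethylSite) -> bool:
        iv = merged.get(site.chrom)
        if not iv:
            return False
        i = bisect.bisect_right(starts[site.chrom], site.pos) - 1
        return i >= 0 and iv[i][0] <= site.pos < iv[i][1]

    n_on = sum(1 for s in sites if on_gene(s))
    index = SiteIndex(sites)
    n_meth = sum(1 for g in genes if index.count(g.chrom, g.strand, g.start, g.end) > 0)
    pct = round(100.0 * n_on / len(sites), 2)
    return MethylociSummary(len(sites), n_on, pct, n_meth)


# ---------------------------------------------------------------------------
# Cross-sample summaries
# ---------------------------------------------------------------------------

@dataclass
class SharedGeneReport:
    """Intersection counts and per-sample shared percentages.

    ``intersections`` maps a frozenset of sample names (size >= 2) to the
    number of gene ids present in *all* of those samples; ``set_sizes``
    holds each sample's own count. Percentages are 2-decimal and ``None``
    (undefined) for an empty sample.
    """

    set_sizes: dict[str, int]
    intersections: dict[frozenset, int]

    def pct_shared(self, sample: str, group: Iterable[str]) -> Optional[float]:
        group = frozenset(group)
        if sample not in group:
            raise ValueError(f"{sample} not in group {sorted(group)}")
        if self.set_sizes[sample] == 0:
            return None
        return round(100.0 * self.intersections[group] / self.set_sizes[sample], 2)


def shared_gene_summary(gene_sets: Mapping[str, set[str]]) -> SharedGeneReport:
    """Overlap report over >=2 per-sample methylated-gene sets."""
    names = sorted(gene_sets)
    if len(names) < 2:
        raise ValueError("need at least two samples")
    from itertools import combinations

    inter: dict[frozenset, int] = {}
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            common = set.intersection(*(set(gene_sets[n]) for n in combo))
            inter[frozenset(combo)] = len(common)
    sizes = {n: len(gene_sets[n]) for n in names}
    for n in names:
        if sizes[n] == 0:
            logger.warning("sample %s has no methylated genes; percentages undefined", n)
    return SharedGeneReport(set_sizes=sizes, intersections=inter)


def consistent_sites(
    sites_a: Iterable[MethylSite], sites_b: Iterable[MethylSite]
) -> list[MethylSite]:
    """Sites called in both samples at the same (chrom, pos, strand).

    Coverage of a consistent site is the minimum of the two samples'
    coverages (the conservative shared depth).
    """
    b_by_key = {s.key: s for s in sites_b}
    out = []
    for a in sites_a:
        b = b_by_key.get(a.key)
        if b is not None:
            out.append(
                MethylSite(a.chrom, a.pos, a.strand, min(a.coverage, b.coverage), a.score)
            )
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Motif context export
# ---------------------------------------------------------------------------

def export_motif_contexts(
    sites: Sequence[MethylSite],
    genome: Mapping[str, str],
    flank: int,
    path: Optional[str] = None,
) -> list[tuple[str, str]]:
    """Reference windows of length 2*flank+1 centered on each site.

    Minus-strand windows are reverse-complemented so the methylated adenine
    is always the center base and always 'A'; sites closer than ``flank``
    to a contig end are skipped with a warning. Returns (name, sequence)
    records and optionally writes them as FASTA (input for motif discovery
    tools such as MEME).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    records = []
    n_skipped = 0
    for s in sorted(sites):
        seq = genome.get(s.chrom)
        if seq is None:
            raise KeyError(f"no sequence for chromosome {s.chrom}")
        lo, hi = s.pos - flank, s.pos + flank + 1
        if lo < 0 or hi > len(seq):
            n_skipped += 1
            continue
        window = seq[lo:hi]
        if s.strand == "-":
            window = revcomp(window)
        records.append((f"{s.chrom}:{s.pos + 1}:{s.strand}", window))
    if n_skipped:
        logger.warning("export_motif_contexts: skipped %d sites near contig ends", n_skipped)
    if path is not None:
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n{seq}\n")
    return records
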