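"""Core domain types shared across the pipeline.

Coordinate convention: **all in-memory coordinates are 0-based, half-open**.
Conversion to/from the 1-based inclusive conventions of GFF/GTF/VCF happens
only inside :mod:`m6avar.io_formats` (and the simulator's writers). A
``MethylSite.pos`` of 149 therefore corresponds to position 150 in a
modifications GFF.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

STRANDS = ("+", "-")

#: DNA genotype classes that can appear in a parsed VCF record. 0/0 never
#: appears as a record; it is only ever inferred for RNA from coverage.
DNA_GENOTYPES = ("0/1", "1/1")
RNA_GENOTYPES = ("0/0", "0/1", "1/1")

#: The six DNA->RNA genotype transmission classes, in canonical order.
TRANSMIT_TYPES = (
    "0/1_0/0",
    "0/1_0/1",
    "0/1_1/1",
    "1/1_0/0",
    "1/1_0/1",
    "1/1_1/1",
)


@dataclass(frozen=True, order=True)
class MethylSite:
    """A single called 6mA locus (one adenine on one strand)."""

    chrom: str
    pos: int  # 0-based
    strand: str
    coverage: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.coverage < 0:
            raise ValueError(f"negative coverage {self.coverage}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exon and UTR sub-intervals; introns are derived.

    ``start``/``end`` and every sub-interval are 0-based half-open. Exons are
    stored merged and sorted; UTR intervals carry a tag (``5UTR``/``3UTR`` or
    plain ``UTR`` when the annotation does not distinguish).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    utrs: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad gene body [{self.start},{self.end})")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene body")
        for s, e, _tag in self.utrs:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: UTR [{s},{e}) outside gene body")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gene body minus (merged) exons and UTRs."""
        blocks = sorted([(s, e) for s, e in self.exons] + [(s, e) for s, e, _ in self.utrs])
        out = []
        cursor = self.start
        for s, e in merge_intervals(blocks):
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.end:
            out.append((cursor, self.end))
        return tuple(out)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted list."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class Variant:
    """A biallelic SNV with a genotype class and molecule source."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotype: str  # "0/1" or "1/1"
    depth: Optional[int] = None
    source: str = "DNA"  # "DNA" or "RNA"
    m6a_overlap: bool = False  # set by variants.methylated_variation

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.genotype not in DNA_GENOTYPES:
            raise ValueError(f"genotype must be 0/1 or 1/1, got {self.genotype!r}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def allele_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class CoverageTrack:
    """Per-base read depth stored as sorted non-overlapping intervals.

    Used to decide whether an RNA genotype of 0/0 (no variant call) is
    supported by enough RNA evidence at a DNA-variant site.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, int]]]):
        # intervals: chrom -> [(start, end, depth)], 0-based half-open
        self._starts: dict[str, list[int]] = {}
        self._ivs: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            for (s1, e1, d1), (s2, _e2, _d2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping coverage intervals on {chrom}")
            for s, e, d in ivs:
                if d < 0 or s >= e:
                    raise ValueError(f"bad coverage interval ({s},{e},{d}) on {chrom}")
            self._ivs[chrom] = list(ivs)
            self._starts[chrom] = [s for s, _, _ in ivs]

    def depth(self, chrom: str, pos: int) -> int:
        ivs = self._ivs.get(chrom)
        if not ivs:
            return 0
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i >= 0:
            s, e, d = ivs[i]
            if s <= pos < e:
                return d
        return 0

    def chroms(self) -> list[str]:
        return sorted(self._ivs)

    def intervals(self, chrom: str) -> list[tuple[int, int, int]]:
        return list(self._ivs.get(chrom, []))


@dataclass(frozen=True)
class TransmissionRecord:
    """A DNA variant site paired with its RNA genotype."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    dna_gt: str
    rna_gt: str
    transmit_type: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        expected = f"{self.dna_gt}_{self.rna_gt}"
        if self.transmit_type != expected:
            raise ValueError(f"transmit_type {self.transmit_type!r} != {expected!r}")
        if self.transmit_type not in TRANSMIT_TYPES:
            raise ValueError(f"unknown transmit type {self.transmit_type!r}")

    @property
    def event_key(self) -> tuple[str, int, str, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt, self.transmit_type)


@dataclass
class GeneMethylation:
    """Per-gene methylation summary (same-strand sites over coding-strand A)."""

    gene_id: str
    n_6mA: int
    n_A: int
    density: float
    methylated: bool
    zero_adenine: bool = False  # density undefined, reported as 0

    def __post_init__(self) -> None:
        if not self.zero_adenine and self.n_6mA > self.n_A:
            raise ValueError(f"{self.gene_id}: n_6mA {self.n_6mA} > n_A {self.n_A}")
        if self.methylated != (self.n_6mA > 0):
            raise ValueError(f"{self.gene_id}: methylated flag inconsistent")


@dataclass
class GeneVariation:
    """Per-gene variant burden; ratio is count over gene-body length."""

    gene_id: str
    gene_length: int
    n_var: int
    variation_ratio: float
    n_AT: int
    n_CG: int
    n_methylated_var: int

    def __post_init__(self) -> None:
        if self.n_AT + self.n_CG != self.n_var:
            raise ValueError(f"{self.gene_id}: A/T + C/G partition != total")
        if self.n_methylated_var > self.n_AT:
            raise ValueError(f"{self.gene_id}: methylated variants exceed A/T variants")


@dataclass
class GeneFeatureRow:
    """One regression design row: methylation response plus transmit-type counts."""

    gene_id: str
    y_density: float
    methylated: bool
    x: dict[str, int] = field(default_factory=dict)  # transmit type -> count
    n_var_dna: int = 0
    imprinted: bool = False

    def __post_init__(self) -> None:
        for t in TRANSMIT_TYPES:
            self.x.setdefault(t, 0)
        extra = set(self.x) - set(TRANSMIT_TYPES)
        if extra:
            raise ValueError(f"{self.gene_id}: unknown transmit types {sorted(extra)}")
        if any(v < 0 for v in self.x.values()):
            raise ValueError(f"{self.gene_id}: negative transmit count")

    def x_vector(self) -> list[int]:
        return [self.x[t] for t in TRANSMIT_TYPES]


@dataclass(frozen=True)
class DepthThresholds:
    """Minimum 6mA site coverage kept, by chromosome class."""

    autosome_min: int
    sex_min: int

    def __post_init__(self) -> None:
        if self.autosome_min < 0 or self.sex_min < 0:
            raise ValueError("depth thresholds must be non-negative")


@dataclass
class TermEstimate:
    name: str
    coefficient: float
    std_error: float
    statistic: float
    p_value: float


@dataclass
class RegressionResult:
    """Summary-table style fit result for the logistic or linear model."""

    model: str  # "logistic" or "linear"
    terms: list[TermEstimate]
    n_obs: int
    dropped_terms: list[tuple[str, str]]  # (name, reason)
    residual_summary: float  # deviance (logistic) or residual variance (linear)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]


@dataclass
class ComparisonResult:
    """Two-sample t-test summary."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    df: float
    p_value: float
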