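"""DNA-to-RNA genotype transmission: pairing, classification, aggregation.

At every DNA variant site the RNA genotype is established one of three
ways: an RNA variant call at the same position and alleles supplies it
directly; absent a call, sufficient RNA coverage implies the reference
genotype 0/0; absent both, the site is not assessable in RNA and is
excluded. Each assessable site is classified into one of the six transmit
types (DNA genotype underscore RNA genotype), e.g. ``0/1_0/1``.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .models import (
    DNA_GENOTYPES,
    RNA_GENOTYPES,
    TRANSMIT_TYPES,
    CoverageTrack,
    GeneModel,
    TransmissionRecord,
    Variant,
)
from .variants import GeneIndex

logger = logging.getLogger(__name__)


def classify_transmit(dna_gt: str, rna_gt: str) -> str:
    """Classify a (DNA genotype, RNA genotype) pair into a transmit type.

    DNA must be 0/1 or 1/1 — a 0/0 DNA genotype is not a variant site and
    lies outside the six classes (RNA-only variants are handled upstream).
    Phased separators are normalized (``0|1`` -> ``0/1``).
    """
    dna_gt = dna_gt.replace("|", "/")
    rna_gt = rna_gt.replace("|", "/")
    if dna_gt == "0/0":
        raise ValueError("DNA genotype 0/0 is outside the six transmit types")
    if dna_gt not in DNA_GENOTYPES:
        raise ValueError(f"bad DNA genotype {dna_gt!r}")
    if rna_gt not in RNA_GENOTYPES:
        raise ValueError(f"bad RNA genotype {rna_gt!r}")
    return f"{dna_gt}_{rna_gt}"


@dataclass
class JoinResult:
    """Outcome of pairing DNA variants with RNA evidence.

    Every DNA variant lands in exactly one bucket (classified record,
    allele-discordant, or insufficient RNA coverage); RNA variants with no
    DNA counterpart are returned unclassified in ``rna_only``.
    """

    records: list[TransmissionRecord]
    rna_only: list[Variant]
    tallies: dict[str, int] = field(default_factory=dict)


def join_dna_rna(
    dna: Sequence[Variant],
    rna: Sequence[Variant],
    rna_cov: Optional[CoverageTrack] = None,
    min_rna_depth: int = 30,
) -> JoinResult:
    """Pair filtered DNA and RNA variants into transmission records.

    For each DNA variant: a same-position, same-allele RNA call supplies
    the RNA genotype; otherwise RNA coverage >= ``min_rna_depth`` at the
    site implies 0/0; otherwise the site is excluded as not assessable.
    An RNA call at the position with different alleles excludes the site
    as allele-discordant. Without a coverage track no 0/0 can be inferred.
    """
    rna_by_pos: dict[tuple[str, int], list[Variant]] = defaultdict(list)
    for v in rna:
        rna_by_pos[v.site_key].append(v)

    records: list[TransmissionRecord] = []
    tallies: Counter = Counter(
        {"rna_call": 0, "inferred_ref": 0, "allele_discordant": 0,
         "insufficient_coverage": 0}
    )
    dna_site_keys = set()
    for v in dna:
        dna_site_keys.add(v.site_key)
        rna_here = rna_by_pos.get(v.site_key, ())
        match = [r for r in rna_here if (r.ref, r.alt) == (v.ref, v.alt)]
        if match:
            rna_gt = match[0].genotype
            tallies["rna_call"] += 1
        elif rna_here:
            tallies["allele_discordant"] += 1
            logger.warning(
                "allele-discordant RNA call at %s:%d (DNA %s>%s)",
                v.chrom, v.pos + 1, v.ref, v.alt,
            )
            continue
        elif rna_cov is not None and rna_cov.depth(v.chrom, v.pos) >= min_rna_depth:
            rna_gt = "0/0"
            tallies["inferred_ref"] += 1
        else:
            tallies["insufficient_coverage"] += 1
            continue
        records.append(
            TransmissionRecord(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                dna_gt=v.genotype, rna_gt=rna_gt,
                transmit_type=classify_transmit(v.genotype, rna_gt),
            )
        )

    rna_only = [v for v in rna if v.site_key not in dna_site_keys]
    tallies["rna_only"] = len(rna_only)
    tallies["classified"] = len(records)
    logger.info("join_dna_rna: %s", dict(tallies))
    return JoinResult(records=records, rna_only=rna_only, tallies=dict(tallies))


def consistent_transmissions(
    recs_a: Iterable[TransmissionRecord],
    recs_b: Iterable[TransmissionRecord],
    match_type: bool = True,
) -> list[TransmissionRecord]:
    """Transmission events detected in both samples.

    The default key is the full event — (chrom, pos, ref, alt,
    transmit_type) — i.e. the same transmission observed twice, not merely
    the same locus; ``match_type=False`` relaxes to the allele key.
    """
    if match_type:
        keys_b = {r.event_key for r in recs_b}
        out = [r for r in recs_a if r.event_key in keys_b]
    else:
        keys_b = {(r.chrom, r.pos, r.ref, r.alt) for r in recs_b}
        out = [r for r in recs_a if (r.chrom, r.pos, r.ref, r.alt) in keys_b]
    out.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return out


def assign_genes(
    records: Sequence[TransmissionRecord], genes: Sequence[GeneModel]
) -> list[TransmissionRecord]:
    """Attach gene ids to records by gene-body position (one copy per gene)."""
    index = GeneIndex(genes)
    out = []
    for r in records:
        hits = index.overlapping(r.chrom, r.pos)
        if not hits:
            out.append(r)
        else:
            for g in hits:
                out.append(
                    TransmissionRecord(
                        chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                        dna_gt=r.dna_gt, rna_gt=r.rna_gt,
                        transmit_type=r.transmit_type, gene_id=g.gene_id,
                    )
                )
    return out


def gene_transmit_counts(
    records: Sequence[TransmissionRecord], genes: Sequence[GeneModel]
) -> dict[str, dict[str, int]]:
    """Per-gene counts of each of the six transmit types.

    Records are assigned by gene-body position; genes with no records emit
    all-zero rows (the logistic regression's negative class needs them).
    """
    index = GeneIndex(genes)
    counts = {g.gene_id: {t: 0 for t in TRANSMIT_TYPES} for g in genes}
    for r in records:
        for g in index.overlapping(r.chrom, r.pos):
            counts[g.gene_id][r.transmit_type] += 1
    return counts


def write_transmission_tsv(
    records: Sequence[TransmissionRecord], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tdna_gt\trna_gt\ttransmit_type\tgene_id\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt, r.gene_id or "")):
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.ref}\t{r.alt}\t{r.dna_gt}\t{r.rna_gt}\t"
                f"{r.transmit_type}\t{r.gene_id or '.'}\n"
            )
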