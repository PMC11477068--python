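"""Readers and writers for every external format the pipeline touches.

All parsers normalize to the package's internal convention (0-based,
half-open; see :mod:`m6avar.models`) and convert back on write:

* GFF3 / GTF gene annotation  -> :class:`GeneModel`
* SMRT ``ipdSummary``-style modifications GFF, or a flat TSV dialect
  (``chrom  pos  strand  coverage [score]``) -> :class:`MethylSite`
* single-sample VCF v4.x -> :class:`Variant` (biallelic SNVs only)
* BED-graph-like coverage TSV (0-based half-open) -> :class:`CoverageTrack`
* per-gene feature table TSV <-> :class:`GeneFeatureRow`

Parsers are total: malformed records are rejected with a logged warning and
a tally, never an unhandled crash.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter
from typing import Iterable, Optional, Sequence

from cyvcf2 import VCF
from pyfaidx import Fasta

from .models import (
    TRANSMIT_TYPES,
    CoverageTrack,
    GeneFeatureRow,
    GeneModel,
    MethylSite,
    Variant,
    merge_intervals,
)

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Structurally invalid gene annotation (e.g. exon outside its gene)."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an upper-cased chrom -> sequence dict."""
    fa = Fasta(str(path), rebuild=False, build_index=True)
    genome = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    return genome


def write_fasta(genome: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 / GTF)
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')

_UTR_TAGS = {
    "five_prime_utr": "5UTR",
    "5utr": "5UTR",
    "three_prime_utr": "3UTR",
    "3utr": "3UTR",
    "utr": "UTR",
}


def _parse_attributes(raw: str) -> dict[str, str]:
    """Parse column 9 of either dialect into a flat dict.

    GTF uses ``key "value";`` pairs, GFF3 uses ``key=value`` pairs; the
    dialect is auto-detected per record from the attribute syntax.
    """
    raw = raw.strip().rstrip(";")
    if "=" in raw and '"' not in raw.split("=", 1)[0]:
        out = {}
        for part in raw.split(";"):
            part = part.strip()
            if not part or "=" not in part:
                continue
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
        return out
    return {m.group(1): m.group(2) for m in _GTF_ATTR.finditer(raw)}


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 or GTF annotation into :class:`GeneModel` objects.

    Both dialects are normalized identically: 1-based inclusive intervals
    become 0-based half-open, exons are merged per gene, and UTR records
    keep a 5'/3' tag when the feature type distinguishes them. Records
    without a strand are rejected with a warning; an exon or UTR falling
    outside its gene body raises :class:`AnnotationError` naming the gene.
    """
    genes: dict[str, dict] = {}
    # sub-features seen before (or without) their gene record
    pending_exons: list[tuple[str, int, int]] = []
    pending_utrs: list[tuple[str, int, int, str]] = []
    # transcript id -> gene id, to resolve exon Parent chains in real GFF3
    tx_to_gene: dict[str, str] = {}
    tallies: Counter = Counter()

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                tallies["malformed"] += 1
                logger.warning("%s:%d: expected 9 columns, got %d", path, lineno, len(fields))
                continue
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            ftype_l = ftype.lower()
            if ftype_l not in {"gene", "exon", "mrna", "transcript"} and ftype_l not in _UTR_TAGS:
                tallies["skipped_type"] += 1
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError:
                tallies["malformed"] += 1
                logger.warning("%s:%d: non-numeric coordinates", path, lineno)
                continue
            attrs = _parse_attributes(attr_s)
            if ftype_l == "gene":
                gid = attrs.get("gene_id") or attrs.get("ID")
                if gid is None:
                    tallies["no_gene_id"] += 1
                    logger.warning("%s:%d: gene record without gene_id/ID", path, lineno)
                    continue
                if strand not in ("+", "-"):
                    tallies["no_strand"] += 1
                    logger.warning("%s:%d: gene %s has no strand; rejected", path, lineno, gid)
                    continue
                genes[gid] = {"chrom": chrom, "strand": strand, "start": start, "end": end,
                              "exons": [], "utrs": []}
            elif ftype_l in ("mrna", "transcript"):
                tid = attrs.get("transcript_id") or attrs.get("ID")
                gid = attrs.get("gene_id") or attrs.get("Parent")
                if tid and gid:
                    tx_to_gene[tid] = gid
            else:
                gid = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID")
                if gid is None:
                    tallies["orphan"] += 1
                    logger.warning("%s:%d: %s without a parent gene id; skipped", path, lineno, ftype)
                    continue
                gid = gid.split(",")[0]
                if ftype_l == "exon":
                    pending_exons.append((gid, start, end))
                else:
                    pending_utrs.append((gid, start, end, _UTR_TAGS[ftype_l]))

    def resolve(gid: str) -> Optional[str]:
        seen = set()
        while gid not in genes:
            if gid in seen or gid not in tx_to_gene:
                return None
            seen.add(gid)
            gid = tx_to_gene[gid]
        return gid

    for gid, start, end in pending_exons:
        owner = resolve(gid)
        if owner is None:
            tallies["orphan"] += 1
            logger.warning("exon parent %r not found in annotation; skipped", gid)
            continue
        g = genes[owner]
        if start < g["start"] or end > g["end"]:
            raise AnnotationError(
                f"exon [{start + 1},{end}] outside body of gene {owner}"
            )
        g["exons"].append((start, end))
    for gid, start, end, tag in pending_utrs:
        owner = resolve(gid)
        if owner is None:
            tallies["orphan"] += 1
            logger.warning("UTR parent %r not found in annotation; skipped", gid)
            continue
        g = genes[owner]
        if start < g["start"] or end > g["end"]:
            raise AnnotationError(
                f"UTR [{start + 1},{end}] outside body of gene {owner}"
            )
        g["utrs"].append((start, end, tag))

    if tallies:
        logger.info("read_annotation(%s): rejected/skipped records: %s", path, dict(tallies))
    out = []
    for gid in sorted(genes):
        g = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=tuple(merge_intervals(g["exons"])),
                utrs=tuple(sorted(g["utrs"])),
            )
        )
    return out


def write_annotation_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write genes to canonical GFF3 (sorted, merged exons) for round-trips."""
    tag_to_type = {"5UTR": "five_prime_UTR", "3UTR": "three_prime_UTR", "UTR": "UTR"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tm6avar\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tm6avar\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
            for s, e, tag in g.utrs:
                fh.write(
                    f"{g.chrom}\tm6avar\t{tag_to_type[tag]}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


def write_annotation_gtf(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write the same annotation in the GTF dialect (dialect-equivalence tests)."""
    tag_to_type = {"5UTR": "five_prime_utr", "3UTR": "three_prime_utr", "UTR": "UTR"}
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attr = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tm6avar\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attr}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tm6avar\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attr}\n")
            for s, e, tag in g.utrs:
                fh.write(
                    f"{g.chrom}\tm6avar\t{tag_to_type[tag]}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attr}\n"
                )


# ---------------------------------------------------------------------------
# 6mA modification calls
# ---------------------------------------------------------------------------

def read_modifications(path: str | os.PathLike) -> list[MethylSite]:
    """Read 6mA site calls from a modifications GFF or flat TSV.

    The GFF dialect is the one ``ipdSummary`` emits: feature type ``m6A``
    (or ``modified_base`` carrying an m6A tag), start == end at the
    methylated adenine, strand in column 7, ``coverage=N`` in column 9.
    The TSV dialect has a header ``chrom pos strand coverage [score]`` with
    1-based positions. The dialect is sniffed from the first data line.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    is_gff = len(first.rstrip("\n").split("\t")) >= 8
    return _read_modifications_gff(path) if is_gff else _read_modifications_tsv(path)


def _read_modifications_gff(path) -> list[MethylSite]:
    sites = []
    tallies: Counter = Counter()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                tallies["malformed"] += 1
                logger.warning("%s:%d: short modification record", path, lineno)
                continue
            chrom, _src, ftype, start_s, end_s, score_s, strand = fields[:7]
            attr_s = fields[8] if len(fields) > 8 else ""
            if ftype != "m6A" and not (ftype == "modified_base" and "m6A" in attr_s):
                tallies[f"skipped_{ftype}"] += 1
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                tallies["malformed"] += 1
                logger.warning("%s:%d: non-numeric coordinates", path, lineno)
                continue
            if start != end:
                tallies["multi_base"] += 1
                logger.warning("%s:%d: modification with start != end rejected", path, lineno)
                continue
            if strand not in ("+", "-"):
                tallies["no_strand"] += 1
                logger.warning("%s:%d: modification without strand rejected", path, lineno)
                continue
            attrs = _parse_attributes(attr_s)
            if "coverage" not in attrs:
                tallies["no_coverage"] += 1
                logger.warning("%s:%d: modification without coverage rejected", path, lineno)
                continue
            score = None if score_s in (".", "") else float(score_s)
            sites.append(
                MethylSite(chrom=chrom, pos=start - 1, strand=strand,
                           coverage=int(float(attrs["coverage"])), score=score)
            )
    if tallies:
        logger.info("read_modifications(%s): rejected/skipped: %s", path, dict(tallies))
    return sites


def _read_modifications_tsv(path) -> list[MethylSite]:
    sites = []
    tallies: Counter = Counter()
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = [f.lower() for f in fields]
                continue
            row = dict(zip(header, fields))
            try:
                sites.append(
                    MethylSite(
                        chrom=row["chrom"],
                        pos=int(row["pos"]) - 1,
                        strand=row["strand"],
                        coverage=int(row["coverage"]),
                        score=float(row["score"]) if row.get("score") not in (None, "", ".") else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                tallies["malformed"] += 1
                logger.warning("%s:%d: rejected TSV modification record (%s)", path, lineno, exc)
    if tallies:
        logger.info("read_modifications(%s): rejected: %s", path, dict(tallies))
    return sites


def write_modifications_gff(sites: Iterable[MethylSite], path: str | os.PathLike) -> None:
    """Write sites in the ipdSummary-like modifications GFF dialect."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in sorted(sites):
            score = "." if s.score is None else f"{s.score:g}"
            fh.write(
                f"{s.chrom}\tkinModCall\tm6A\t{s.pos + 1}\t{s.pos + 1}\t{score}\t{s.strand}\t.\t"
                f"coverage={s.coverage}\n"
            )


def write_sites_bed(sites: Iterable[MethylSite], path: str | os.PathLike) -> None:
    """BED6 export (0-based half-open) of site positions; score = coverage."""
    with open(path, "w") as fh:
        for s in sorted(sites):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t.\t{s.coverage}\t{s.strand}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, source: str = "DNA") -> list[Variant]:
    """Read a single-sample VCF, keeping only biallelic SNVs called 0/1 or 1/1.

    Multi-allelic records, indels, hom-ref and missing-genotype rows are
    excluded and tallied in the log. Genotype phasing is ignored (``0|1``
    counts as ``0/1``).
    """
    if source not in ("DNA", "RNA"):
        raise ValueError(f"source must be DNA or RNA, got {source!r}")
    tallies: Counter = Counter()
    out: list[Variant] = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            if len(v.ALT) != 1:
                tallies["multiallelic"] += 1
                continue
            ref, alt = v.REF.upper(), v.ALT[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                tallies["not_snv"] += 1
                continue
            try:
                gt_type = v.gt_types[0]
            except (IndexError, TypeError):
                tallies["bad_genotype"] += 1
                logger.warning("%s: malformed genotype at %s:%d", path, v.CHROM, v.POS)
                continue
            if gt_type == 1:
                genotype = "0/1"
            elif gt_type == 3:
                genotype = "1/1"
            elif gt_type == 0:
                tallies["hom_ref"] += 1
                continue
            else:
                tallies["missing_gt"] += 1
                continue
            depth = None
            try:
                fmt_dp = v.format("DP")
                if fmt_dp is not None and int(fmt_dp[0][0]) >= 0:
                    depth = int(fmt_dp[0][0])
            except (KeyError, IndexError, TypeError, ValueError):
                pass
            if depth is None:
                info_dp = v.INFO.get("DP")
                if info_dp is not None:
                    depth = int(info_dp)
            out.append(
                Variant(chrom=v.CHROM, pos=v.POS - 1, ref=ref, alt=alt,
                        genotype=genotype, depth=depth, source=source)
            )
            tallies["kept"] += 1
    finally:
        vcf.close()
    logger.info("read_vcf(%s, %s): %s", path, source, dict(tallies))
    return out


def write_vcf(
    variants: Sequence[Variant],
    contig_lengths: dict[str, int],
    path: str | os.PathLike,
    sample: str = "sample",
) -> None:
    """Write a minimal single-sample VCF v4.2 with GT and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(contig_lengths):
            fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            dp = "." if v.depth is None else str(v.depth)
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:DP\t"
                f"{v.genotype}:{dp}\n"
            )


def write_flagged_vcf(
    variants: Sequence[Variant], contig_lengths: dict[str, int], path: str | os.PathLike
) -> None:
    """VCF export carrying the 6mA-overlap flag as INFO tag M6A_OVERLAP=1."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(contig_lengths):
            fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
        fh.write('##INFO=<ID=M6A_OVERLAP,Number=0,Type=Flag,Description="Variant at a 6mA site">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            info = "M6A_OVERLAP" if v.m6a_overlap else "."
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{v.genotype}\n"
            )


def read_position_set(path: str | os.PathLike) -> set[tuple[str, int]]:
    """Read a dbSNP-style position list as 0-based (chrom, pos) pairs.

    Accepts either a VCF (positions of all records) or a two-column TSV
    ``chrom  pos`` with 1-based positions; the dialect is sniffed from the
    first line.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        out = set()
        vcf = VCF(str(path))
        try:
            for v in vcf:
                out.add((v.CHROM, v.POS - 1))
        finally:
            vcf.close()
        return out
    out = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                out.add((fields[0], int(fields[1]) - 1))
            except (IndexError, ValueError):
                logger.warning("%s: malformed position line %r skipped", path, line.strip())
    return out


# ---------------------------------------------------------------------------
# Coverage track
# ---------------------------------------------------------------------------

def read_coverage(path: str | os.PathLike) -> CoverageTrack:
    """Read a BED-graph-like TSV (chrom, start, end, depth; 0-based half-open)."""
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, depth = line.rstrip("\n").split("\t")[:4]
            per_chrom.setdefault(chrom, []).append((int(start), int(end), int(depth)))
    return CoverageTrack(per_chrom)


def write_coverage(track: CoverageTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for s, e, d in track.intervals(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = (
    ["gene_id", "methylated", "y_density"]
    + list(TRANSMIT_TYPES)
    + ["n_var_dna", "imprinted"]
)


def write_feature_table(rows: Sequence[GeneFeatureRow], path: str | os.PathLike) -> None:
    """Write the per-gene regression design table as TSV.

    Densities are written with full precision (repr), genes sorted by id.
    Raises on an empty collection or duplicate gene ids.
    """
    if not rows:
        raise ValueError("refusing to write an empty feature table")
    ids = [r.gene_id for r in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene_id in feature table: {dup}")
    with open(path, "w") as fh:
        fh.write("\t".join(_FEATURE_COLUMNS) + "\n")
        for r in sorted(rows, key=lambda r: r.gene_id):
            vals = [r.gene_id, str(int(r.methylated)), repr(float(r.y_density))]
            vals += [str(r.x[t]) for t in TRANSMIT_TYPES]
            vals += [str(r.n_var_dna), str(int(r.imprinted))]
            fh.write("\t".join(vals) + "\n")


def read_feature_table(path: str | os.PathLike) -> list[GeneFeatureRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _FEATURE_COLUMNS:
            raise ValueError(f"unexpected feature-table header in {path}")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(
                GeneFeatureRow(
                    gene_id=f["gene_id"],
                    methylated=bool(int(f["methylated"])),
                    y_density=float(f["y_density"]),
                    x={t: int(f[t]) for t in TRANSMIT_TYPES},
                    n_var_dna=int(f["n_var_dna"]),
                    imprinted=bool(int(f["imprinted"])),
                )
            )
    return rows
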