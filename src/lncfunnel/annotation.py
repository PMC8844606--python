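"""Genome annotation model and strand-aware unique-exon isolation.

The central genomic operation of the pipeline lives here: lncRNA exons are
retained only if they share no base with any protein-coding exon *on the same
strand*, so that read counts over the retained ("unique") exons are
unambiguously attributable to the lncRNA rather than to an overlapping mRNA.

Coordinate convention
---------------------
All in-memory coordinates are 0-based half-open ``[start, end)``.  GTF input
and output are 1-based closed and are converted at the I/O boundary; BED
output is 0-based half-open and needs no shift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the offending line."""


class AnnotationError(ValueError):
    """Raised when annotation content violates a structural invariant."""


@dataclass(frozen=True)
class Exon:
    """One exon, 0-based half-open, strand always '+' or '-'."""

    exon_id: str
    contig: str
    start: int
    end: int
    strand: str
    transcript_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"exon {self.exon_id}: start {self.start} must be < end {self.end} "
                "(0-based half-open)"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"exon {self.exon_id}: strand {self.strand!r} is not '+' or '-'"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[Exon] = field(default_factory=list)

    @property
    def length(self) -> int:
        """Spliced transcript length: sum of exon spans (bp)."""
        return sum(e.span for e in self.exons)

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        contigs = {e.contig for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(contigs) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons span multiple contigs/strands"
            )
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons {a.exon_id} and "
                    f"{b.exon_id} overlap"
                )


@dataclass
class Gene:
    gene_id: str
    biotype: str
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    contigs: dict[str, int] = field(default_factory=dict)

    def transcript_class(self, transcript_id: str) -> str:
        """Resolve a transcript to {'lncRNA', 'protein_coding', 'other'}.

        A transcript counts as lncRNA if *either* its own biotype or its
        gene's biotype is ``lncRNA``; likewise for ``protein_coding`` (checked
        second, so a lncRNA transcript of a protein-coding gene is lncRNA).
        """
        t = self.transcripts[transcript_id]
        g = self.genes[t.gene_id]
        if "lncRNA" in (t.biotype, g.biotype):
            return "lncRNA"
        if "protein_coding" in (t.biotype, g.biotype):
            return "protein_coding"
        return "other"

    def validate(self) -> None:
        for t in self.transcripts.values():
            t.validate()
            if t.gene_id not in self.genes:
                raise AnnotationError(
                    f"transcript {t.transcript_id}: unknown gene {t.gene_id}"
                )


@dataclass
class BiotypePartition:
    """Disjoint, exhaustive partition of transcript IDs by resolved biotype."""

    lncRNA: list[str]
    protein_coding: list[str]
    other: list[str]


# Accept both Gencode (gene_type) and Ensembl (gene_biotype) attribute keys.
_GENE_TYPE_KEYS = ("gene_type", "gene_biotype")
_TX_TYPE_KEYS = ("transcript_type", "transcript_biotype")

_ATTR_RE = re.compile(r'(\S+)\s+(?:"([^"]*)"|([^;\s]+))\s*;')


def _parse_attributes(attr_string: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for m in _ATTR_RE.finditer(attr_string):
        attrs[m.group(1)] = m.group(2) if m.group(2) is not None else m.group(3)
    if not attrs and attr_string.strip():
        raise GtfParseError(f"line {lineno}: cannot parse attribute string {attr_string!r}")
    return attrs


def _first(attrs: dict[str, str], keys: Iterable[str]) -> str | None:
    for k in keys:
        if k in attrs:
            return attrs[k]
    return None


def parse_gtf(path) -> GenomeAnnotation:
    """Parse a GTF file into a :class:`GenomeAnnotation`.

    Transcript biotype is resolved from the transcript-level attribute,
    falling back to the gene-level attribute.  Coordinates are converted from
    1-based closed to 0-based half-open.  Exons with strand ``.`` are
    rejected: the same-strand subtraction rule is undefined without strand.
    """
    ann = GenomeAnnotation()
    tx_biotype: dict[str, str | None] = {}
    tx_gene: dict[str, str] = {}
    gene_biotype: dict[str, str | None] = {}
    exons: dict[str, list[Exon]] = {}
    exon_counter: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GtfParseError(
                    f"line {lineno}: end {end1} < start {start1}"
                )
            attrs = _parse_attributes(attr_s, lineno)
            gid = attrs.get("gene_id")
            if feature in ("gene", "transcript", "exon") and gid is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")

            if feature == "gene":
                gene_biotype.setdefault(gid, _first(attrs, _GENE_TYPE_KEYS))
            elif feature in ("transcript", "exon"):
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
                tx_gene[tid] = gid
                gb = _first(attrs, _GENE_TYPE_KEYS)
                if gb is not None:
                    gene_biotype.setdefault(gid, gb)
                tb = _first(attrs, _TX_TYPE_KEYS)
                if tb is not None:
                    tx_biotype.setdefault(tid, tb)
                else:
                    tx_biotype.setdefault(tid, None)
                if feature == "exon":
                    if strand not in ("+", "-"):
                        raise GtfParseError(
                            f"line {lineno}: exon strand {strand!r} is not '+' or '-' "
                            "(the same-strand overlap rule requires a defined strand)"
                        )
                    n = exon_counter.get(tid, 0) + 1
                    exon_counter[tid] = n
                    eid = attrs.get("exon_id", f"{tid}.exon{n}")
                    exons.setdefault(tid, []).append(
                        Exon(eid, contig, start1 - 1, end1, strand, tid)
                    )
            ann.contigs[contig] = max(ann.contigs.get(contig, 0), end1)

    for gid in sorted(set(tx_gene.values()) | set(gene_biotype)):
        ann.genes[gid] = Gene(gid, gene_biotype.get(gid) or "unknown")
    for tid in sorted(tx_gene):
        gid = tx_gene[tid]
        biotype = tx_biotype.get(tid) or gene_biotype.get(gid) or "unknown"
        t = Transcript(tid, gid, biotype, sorted(exons.get(tid, []), key=lambda e: e.start))
        if not t.exons:
            # transcript line without exon lines: keep as zero-exon record only
            # if it never appears downstream; reject to keep invariants simple
            raise GtfParseError(f"transcript {tid} has no exon lines")
        ann.transcripts[tid] = t
        ann.genes[gid].transcript_ids.append(tid)
    ann.validate()
    return ann


def write_gtf(ann: GenomeAnnotation, path) -> None:
    """Write the annotation back to GTF (1-based closed), deterministically."""
    with open(path, "w") as fh:
        for gid in sorted(ann.genes):
            g = ann.genes[gid]
            tids = sorted(g.transcript_ids)
            if not tids:
                continue
            g_start = min(ann.transcripts[t].start for t in tids)
            g_end = max(ann.transcripts[t].end for t in tids)
            contig = ann.transcripts[tids[0]].contig
            strand = ann.transcripts[tids[0]].strand
            fh.write(
                f"{contig}\tlncfunnel\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; gene_type "{g.biotype}";\n'
            )
            for tid in tids:
                t = ann.transcripts[tid]
                fh.write(
                    f"{t.contig}\tlncfunnel\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f'{t.strand}\t.\tgene_id "{gid}"; transcript_id "{tid}"; '
                    f'gene_type "{g.biotype}"; transcript_type "{t.biotype}";\n'
                )
                for e in t.exons:
                    fh.write(
                        f"{e.contig}\tlncfunnel\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f'{e.strand}\t.\tgene_id "{gid}"; transcript_id "{tid}"; '
                        f'gene_type "{g.biotype}"; transcript_type "{t.biotype}"; '
                        f'exon_id "{e.exon_id}";\n'
                    )


def classify_biotypes(ann: GenomeAnnotation) -> BiotypePartition:
    """Partition transcript IDs into lncRNA / protein_coding / other."""
    part = BiotypePartition([], [], [])
    for tid in sorted(ann.transcripts):
        cls = ann.transcript_class(tid)
        if cls == "lncRNA":
            part.lncRNA.append(tid)
        elif cls == "protein_coding":
            part.protein_coding.append(tid)
        else:
            part.other.append(tid)
    return part


def unique_lncrna_exons(ann: GenomeAnnotation) -> dict[str, list[Exon]]:
    """Retain, per lncRNA transcript, exons with zero same-strand overlap with
    any protein-coding exon.

    Antisense (opposite-strand) overlap does not exclude.  A partial overlap
    of even one base excludes the whole exon — no trimming — because the
    unique-exon count layer is defined over existing annotated exons.
    A transcript may map to an empty list.
    """
    part = classify_biotypes(ann)
    coding_trees: dict[tuple[str, str], IntervalTree] = {}
    for tid in part.protein_coding:
        for e in ann.transcripts[tid].exons:
            key = (e.contig, e.strand)
            coding_trees.setdefault(key, IntervalTree()).addi(e.start, e.end)

    retained: dict[str, list[Exon]] = {}
    for tid in part.lncRNA:
        tree = coding_trees.get((ann.transcripts[tid].contig, ann.transcripts[tid].strand))
        kept = []
        for e in ann.transcripts[tid].exons:
            if tree is None or not tree.overlap(e.start, e.end):
                kept.append(e)
        retained[tid] = kept
    return retained


def write_bed(unique_exons: dict[str, list[Exon]], path) -> None:
    """Write retained exons as BED6 (0-based half-open) for inspection."""
    rows = []
    for tid in sorted(unique_exons):
        for e in unique_exons[tid]:
            rows.append((e.contig, e.start, e.end, e.exon_id, 0, e.strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
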