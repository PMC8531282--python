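"""Genomic feature records and GTF round-trip.

Coordinates are 1-based inclusive throughout, matching GTF. An
:class:`AnnotationSet` holds transcripts of all RNA classes (mRNA,
lncRNA, circRNA, miRNA) plus the span of every gene, which is what the
cis-target windowing needs.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils

from .core import SchemaError

BIOTYPES = ("mRNA", "lncRNA", "circRNA", "miRNA")


@dataclass(frozen=True)
class Interval:
    """A named, stranded genomic span (1-based inclusive)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SchemaError(f"{self.id}: start {self.start} > end {self.end}")


@dataclass
class TranscriptRecord:
    """One transcript with its exon structure.

    ``length`` is the mature (spliced) length: the sum of exon lengths.
    circRNAs carry the id of the gene they back-splice from in
    ``host_gene_id``.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    host_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise SchemaError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if self.start > self.end:
            raise SchemaError(f"{self.transcript_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise SchemaError(
                    f"{self.transcript_id}: exon ({s},{e}) outside transcript span"
                )
            if prev_end is not None and s <= prev_end:
                raise SchemaError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if self.biotype == "circRNA" and not self.host_gene_id:
            raise SchemaError(f"{self.transcript_id}: circRNA without host gene")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def interval(self) -> Interval:
        return Interval(self.transcript_id, self.chrom, self.start, self.end, self.strand)


class AnnotationSet:
    """Transcripts keyed by id plus gene spans keyed by gene id."""

    def __init__(
        self,
        transcripts: Iterable[TranscriptRecord] = (),
        genes: Iterable[Interval] = (),
    ) -> None:
        self.transcripts: dict[str, TranscriptRecord] = {}
        self.genes: dict[str, Interval] = {}
        for g in genes:
            self.genes[g.id] = g
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptRecord) -> None:
        if t.transcript_id in self.transcripts:
            raise SchemaError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t

    def by_biotype(self, biotype: str) -> list[TranscriptRecord]:
        return [t for t in self.transcripts.values() if t.biotype == biotype]

    def gene_intervals(self) -> list[Interval]:
        return list(self.genes.values())

    def transcript_intervals(self, biotype: str) -> list[Interval]:
        return [t.interval() for t in self.by_biotype(biotype)]

    def __len__(self) -> int:
        return len(self.transcripts)

    # -- GTF round trip ---------------------------------------------------

    def to_gtf(self, path: str | Path) -> None:
        """Write transcripts and exons as GTF 2.2, genes as 'gene' features."""
        lines: list[str] = []

        def attrs(**kv: str) -> str:
            return " ".join(f'{k} "{v}";' for k, v in kv.items() if v is not None)

        by_gene: dict[str, list[str]] = {}
        for tid, t in self.transcripts.items():
            by_gene.setdefault(t.gene_id, []).append(tid)

        def emit_transcript(tid: str) -> None:
            t = self.transcripts[tid]
            common = dict(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                biotype=t.biotype,
                host_gene_id=t.host_gene_id,
            )
            lines.append(
                "\t".join(
                    [
                        t.chrom,
                        "cernaforge",
                        "transcript",
                        str(t.start),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        attrs(**common),
                    ]
                )
            )
            for s, e in t.exons:
                lines.append(
                    "\t".join(
                        [
                            t.chrom,
                            "cernaforge",
                            "exon",
                            str(s),
                            str(e),
                            ".",
                            t.strand,
                            ".",
                            attrs(**common),
                        ]
                    )
                )

        # conventional interleaved order: each gene line directly followed by
        # the transcripts it hosts, then gene-less transcripts
        emitted: set[str] = set()
        for gid in sorted(self.genes):
            g = self.genes[gid]
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        "cernaforge",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs(gene_id=g.id),
                    ]
                )
            )
            for tid in sorted(by_gene.get(gid, [])):
                emit_transcript(tid)
                emitted.add(tid)
        for tid in sorted(self.transcripts):
            if tid not in emitted:
                emit_transcript(tid)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gtf(cls, path: str | Path) -> "AnnotationSet":
        """Parse a GTF with gene/transcript/exon features via gffutils."""
        with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
            db = gffutils.create_db(
                str(path),
                dbfn=tmp.name,
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
                disable_infer_genes=True,
                disable_infer_transcripts=True,
            )
            ann = cls()
            for f in db.features_of_type("gene"):
                gid = f.attributes["gene_id"][0]
                ann.genes[gid] = Interval(gid, f.seqid, f.start, f.end, f.strand)
            exons: dict[str, list[tuple[int, int]]] = {}
            for f in db.features_of_type("exon"):
                tid = f.attributes["transcript_id"][0]
                exons.setdefault(tid, []).append((f.start, f.end))
            for f in db.features_of_type("transcript"):
                tid = f.attributes["transcript_id"][0]
                host = f.attributes.get("host_gene_id", [None])[0]
                ann.add(
                    TranscriptRecord(
                        transcript_id=tid,
                        gene_id=f.attributes["gene_id"][0],
                        biotype=f.attributes.get("biotype", ["mRNA"])[0],
                        chrom=f.seqid,
                        strand=f.strand,
                        start=f.start,
                        end=f.end,
                        exons=sorted(exons.get(tid, [])),
                        host_gene_id=host,
                    )
                )
        return ann


def iter_sorted(records: dict[str, TranscriptRecord]) -> Iterator[TranscriptRecord]:
    for tid in sorted(records):
        yield records[tid]
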