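"""Core domain types: intervals, exons, transcripts, loci, 5'-end evidence.

Internal convention: all coordinates are 0-based half-open on the contig.
Coordinates printed in GFF3 or quoted from literature are 1-based inclusive
and converted at I/O time (:func:`GenomicInterval.from_one_based`).

Minus-strand loci are normalised to a plus-strand working copy at load time
(see :func:`spliceatlas.io.normalize_locus`), so every downstream rule is
written once for the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

STRANDS = ("+", "-")
EVIDENCE_SOURCES = ("RACE", "RNASeq", "RefSeq")
TRANSCRIPT_SOURCES = EVIDENCE_SOURCES + ("cloned", "synthetic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"require 0 <= start <= end, got [{self.start}, {self.end})")

    @classmethod
    def from_one_based(cls, contig: str, start: int, end: int, strand: str = "+") -> "GenomicInterval":
        """Build from 1-based inclusive boundaries as printed in GFF3 or text."""
        return cls(contig, start - 1, end, strand)

    def to_one_based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersection_length(self, other: "GenomicInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def interval_length(iv: GenomicInterval) -> int:
    """Number of bases covered by the interval.

    For coordinates quoted 1-based inclusive, construct the interval with
    :func:`GenomicInterval.from_one_based`; a degenerate 1-based interval
    with start == end then has length 1.
    """
    return iv.length


@dataclass(frozen=True)
class ExonRecord:
    interval: GenomicInterval
    ordinal: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError("exon ordinal must be >= 1")


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon intervals on one contig with an optional genomic CDS span.

    ``cds`` is the genomic [start, end) span of the coding sequence (the
    union of CDS features / BED12 thick region); it must begin and end inside
    exons of the transcript.
    """

    id: str
    exons: tuple[ExonRecord, ...]
    cds: Optional[tuple[int, int]] = None
    source: str = "synthetic"
    retention_isoform: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        if self.source not in TRANSCRIPT_SOURCES:
            raise ValueError(f"unknown transcript source {self.source!r}")
        ivs = [e.interval for e in self.exons]
        contigs = {iv.contig for iv in ivs}
        strands = {iv.strand for iv in ivs}
        if len(contigs) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id}: exons span multiple contigs/strands")
        ordinals = [e.ordinal for e in self.exons]
        if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
            raise ValueError(f"transcript {self.id}: exon ordinals must strictly increase")
        for a, b in zip(ivs, ivs[1:]):
            if self.strand == "+":
                if b.start < a.end:
                    raise ValueError(f"transcript {self.id}: exons overlap or are unsorted")
                if b.start == a.end and not self.retention_isoform:
                    raise ValueError(f"transcript {self.id}: zero-length intron")
            else:
                if a.start < b.end:
                    raise ValueError(f"transcript {self.id}: exons overlap or are unsorted")
        if self.cds is not None:
            s, e = self.cds
            if not s < e:
                raise ValueError(f"transcript {self.id}: empty CDS span")

    @property
    def contig(self) -> str:
        return self.exons[0].interval.contig

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed nucleotide."""
        first = self.exons[0].interval
        return first.start if self.strand == "+" else first.end - 1

    @property
    def span(self) -> GenomicInterval:
        starts = [e.interval.start for e in self.exons]
        ends = [e.interval.end for e in self.exons]
        return GenomicInterval(self.contig, min(starts), max(ends), self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(e.interval.length for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        ivs = [e.interval for e in self.exons]
        if self.strand == "-":
            ivs = ivs[::-1]
        for a, b in zip(ivs, ivs[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.contig, a.end, b.start, self.strand))
        return out

    def junctions_spliced(self) -> list[int]:
        """Spliced coordinates of exon-exon junctions (start of each exon > 1)."""
        out, acc = [], 0
        for e in self.exons[:-1]:
            acc += e.interval.length
            out.append(acc)
        return out

    def genomic_to_spliced(self, g: int) -> Optional[int]:
        """0-based offset of genomic position g in the spliced transcript.

        Returns None when g is intronic or outside the transcript. Total
        function; inverse of :meth:`spliced_to_genomic` on its image.
        """
        acc = 0
        for e in self.exons:
            iv = e.interval
            if iv.contains(g):
                return acc + (g - iv.start if self.strand == "+" else iv.end - 1 - g)
            acc += iv.length
        return None

    def spliced_to_genomic(self, s: int) -> int:
        if s < 0:
            raise IndexError("negative spliced coordinate")
        acc = 0
        for e in self.exons:
            iv = e.interval
            if s < acc + iv.length:
                off = s - acc
                return iv.start + off if self.strand == "+" else iv.end - 1 - off
            acc += iv.length
        raise IndexError(f"spliced coordinate {s} beyond transcript {self.id}")

    def cds_spliced_span(self) -> Optional[tuple[int, int]]:
        """CDS span in spliced coordinates [start, end), stop codon included."""
        if self.cds is None:
            return None
        s, e = self.cds
        if self.strand == "+":
            a, b = self.genomic_to_spliced(s), self.genomic_to_spliced(e - 1)
        else:
            a, b = self.genomic_to_spliced(e - 1), self.genomic_to_spliced(s)
        if a is None or b is None:
            raise ValueError(f"transcript {self.id}: CDS boundary is not exonic")
        return a, b + 1


@dataclass(frozen=True)
class FivePrimeEvidence:
    """One mapped transcript 5' end with provenance."""

    position: int
    strand: str = "+"
    source: str = "RNASeq"
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(f"evidence source must be one of {EVIDENCE_SOURCES}")


@dataclass
class GeneLocus:
    """A contig with one reference gene model, alternatives, and 5'-end evidence."""

    contig_id: str
    sequence: str
    reference: TranscriptModel
    alternatives: list[TranscriptModel] = field(default_factory=list)
    evidence: list[FivePrimeEvidence] = field(default_factory=list)
    origin_strand: str = "+"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for t in [self.reference, *self.alternatives]:
            sp = t.span
            if sp.start < 0 or sp.end > n:
                raise ValueError(f"transcript {t.id} outside contig bounds")
        if self.reference.cds is None:
            raise ValueError("reference transcript must carry a CDS")
        for ev in self.evidence:
            if not (0 <= ev.position < n):
                raise ValueError(f"evidence position {ev.position} outside contig")

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [self.reference, *self.alternatives]


def spliced_sequence(locus: GeneLocus, t: TranscriptModel) -> str:
    """Concatenated exon sequence in transcription order (mRNA sense)."""
    ivs = [e.interval for e in t.exons]
    if t.strand == "+":
        return "".join(locus.sequence[iv.start:iv.end] for iv in ivs)
    return "".join(
        str(Seq(locus.sequence[iv.start:iv.end]).reverse_complement()) for iv in ivs
    )


def make_transcript(
    tid: str,
    contig: str,
    exon_intervals: Sequence[tuple[int, int]],
    strand: str = "+",
    cds: Optional[tuple[int, int]] = None,
    source: str = "synthetic",
    labels: Optional[Sequence[str]] = None,
    retention_isoform: bool = False,
) -> TranscriptModel:
    """Convenience constructor: exon (start, end) pairs in transcription order."""
    exons = tuple(
        ExonRecord(
            GenomicInterval(contig, s, e, strand),
            ordinal=i + 1,
            label=labels[i] if labels else "",
        )
        for i, (s, e) in enumerate(exon_intervals)
    )
    return TranscriptModel(tid, exons, cds=cds, source=source, retention_isoform=retention_isoform)
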