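"""Readers and writers for GFF3, BED12, BED6 evidence, and FASTA.

GFF3 is parsed with :mod:`gffutils` (in-memory sqlite db). All external
coordinates are 1-based inclusive (GFF3) or 0-based half-open (BED) and are
converted to the internal 0-based half-open convention at the boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from .models import (
    ExonRecord,
    FivePrimeEvidence,
    GeneLocus,
    GenomicInterval,
    TranscriptModel,
    make_transcript,
)


class InputError(ValueError):
    """Malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# FASTA


def read_contig(fasta_path: str | Path, contig: str) -> str:
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    if contig not in fa:
        raise InputError(f"contig {contig!r} not found in {fasta_path}")
    return str(fa[contig][:])


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _transcript_from_gff(db: gffutils.FeatureDB, mrna) -> Optional[TranscriptModel]:
    exons = list(db.children(mrna, featuretype="exon"))
    if not exons:
        warnings.warn(f"mRNA {mrna.id} has no exons; skipped")
        return None
    strand = mrna.strand if mrna.strand in "+-" else "+"
    pairs = sorted(
        (
            (
                GenomicInterval(mrna.seqid, e.start - 1, e.end, strand),
                e.attributes.get("label", [""])[0],
            )
            for e in exons
        ),
        key=lambda p: p[0].start,
        reverse=(strand == "-"),
    )
    cds_feats = list(db.children(mrna, featuretype="CDS"))
    cds = None
    if cds_feats:
        cds = (min(c.start for c in cds_feats) - 1, max(c.end for c in cds_feats))
    source = mrna.attributes.get("source_tag", ["synthetic"])[0]
    retention = mrna.attributes.get("retention_isoform", ["0"])[0] == "1"
    recs = tuple(
        ExonRecord(iv, ordinal=i + 1, label=label) for i, (iv, label) in enumerate(pairs)
    )
    return TranscriptModel(mrna.id, recs, cds=cds, source=source, retention_isoform=retention)


def read_gene_models(
    gff3_path: str | Path,
    fasta_path: str | Path,
    evidence_path: str | Path | None = None,
    reference_id: str | None = None,
) -> GeneLocus:
    """Load a locus from GFF3 + FASTA (+ optional BED6 evidence).

    The reference transcript is the mRNA named by ``reference_id``, else the
    one carrying a ``reference=1`` attribute, else the transcript with the
    longest CDS. Minus-strand loci are normalised to a plus-strand working
    copy (mirror coordinates, reverse-complemented contig).
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", force=True
    )
    transcripts: list[TranscriptModel] = []
    flagged_ref: Optional[str] = None
    for mrna in db.features_of_type("mRNA"):
        t = _transcript_from_gff(db, mrna)
        if t is None:
            continue
        transcripts.append(t)
        if mrna.attributes.get("reference", ["0"])[0] == "1":
            flagged_ref = t.id
    if not transcripts:
        raise InputError(f"no usable mRNA features in {gff3_path}")

    contigs = {t.contig for t in transcripts}
    if len(contigs) > 1:
        raise InputError(f"transcripts span multiple contigs: {sorted(contigs)}")
    contig = contigs.pop()
    sequence = read_contig(fasta_path, contig)
    for t in transcripts:
        if t.span.end > len(sequence) or t.span.start < 0:
            raise InputError(f"transcript {t.id} has exons outside contig {contig}")

    ref_id = reference_id or flagged_ref
    if ref_id is not None:
        matches = [t for t in transcripts if t.id == ref_id]
        if not matches:
            raise InputError(f"reference transcript {ref_id!r} not found")
        reference = matches[0]
    else:
        coding = [t for t in transcripts if t.cds is not None]
        if not coding:
            raise InputError("no transcript with a CDS; cannot pick a reference")
        reference = max(coding, key=lambda t: (t.cds[1] - t.cds[0], t.spliced_length))
    alternatives = [t for t in transcripts if t.id != reference.id]

    evidence = read_evidence_bed(evidence_path) if evidence_path else []
    locus = GeneLocus(contig, sequence, reference, alternatives, evidence)
    if reference.strand == "-":
        locus = normalize_locus(locus)
    return locus


def write_gene_models(locus: GeneLocus, gff3_path: str | Path, gene_id: str = "gene1") -> None:
    """Emit the locus transcripts as a GFF3 gene/mRNA/exon/CDS hierarchy."""
    lines = ["##gff-version 3"]
    span = GenomicInterval(
        locus.contig_id,
        min(t.span.start for t in locus.transcripts),
        max(t.span.end for t in locus.transcripts),
        locus.reference.strand,
    )
    s1, e1 = span.to_one_based()
    strand = locus.reference.strand
    lines.append(
        f"{locus.contig_id}\tspliceatlas\tgene\t{s1}\t{e1}\t.\t{strand}\t.\tID={gene_id}"
    )
    for t in locus.transcripts:
        ts, te = t.span.to_one_based()
        attrs = f"ID={t.id};Parent={gene_id};source_tag={t.source}"
        if t.id == locus.reference.id:
            attrs += ";reference=1"
        if t.retention_isoform:
            attrs += ";retention_isoform=1"
        lines.append(f"{locus.contig_id}\tspliceatlas\tmRNA\t{ts}\t{te}\t.\t{t.strand}\t.\t{attrs}")
        for e in t.exons:
            es, ee = e.interval.to_one_based()
            label = f";label={e.label}" if e.label else ""
            lines.append(
                f"{locus.contig_id}\tspliceatlas\texon\t{es}\t{ee}\t.\t{t.strand}\t.\t"
                f"ID={t.id}.exon{e.ordinal};Parent={t.id}{label}"
            )
        if t.cds is not None:
            cs, ce = t.cds
            for e in t.exons:
                iv = e.interval
                lo, hi = max(iv.start, cs), min(iv.end, ce)
                if lo < hi:
                    c = GenomicInterval(locus.contig_id, lo, hi, t.strand).to_one_based()
                    lines.append(
                        f"{locus.contig_id}\tspliceatlas\tCDS\t{c[0]}\t{c[1]}\t.\t{t.strand}\t0\t"
                        f"ID={t.id}.cds;Parent={t.id}"
                    )
    Path(gff3_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed12_transcripts(bed_path: str | Path, source: str = "RNASeq") -> list[TranscriptModel]:
    """Read transcript models from BED12; thickStart/thickEnd define the CDS."""
    out = []
    for ln, raw in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        f = raw.split("\t")
        if len(f) < 12:
            raise InputError(f"{bed_path}:{ln}: BED12 requires 12 columns")
        contig, chrom_start = f[0], int(f[1])
        name, strand = f[3], f[5]
        thick_s, thick_e = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise InputError(f"{bed_path}:{ln}: block count mismatch")
        ivs = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
        if strand == "-":
            ivs = ivs[::-1]
        cds = (thick_s, thick_e) if thick_e > thick_s else None
        out.append(make_transcript(name, contig, ivs, strand=strand, cds=cds, source=source))
    return out


def read_evidence_bed(bed_path: str | Path) -> list[FivePrimeEvidence]:
    """BED6 5'-end evidence; the name field carries the source tag.

    The 5' end is the interval start on '+' and end-1 on '-'. Name may be
    "SOURCE" or "SOURCE:transcript_id".
    """
    out = []
    for ln, raw in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        f = raw.split("\t")
        if len(f) < 6:
            raise InputError(f"{bed_path}:{ln}: BED6 requires 6 columns")
        start, end, name, strand = int(f[1]), int(f[2]), f[3], f[5]
        src, _, tid = name.partition(":")
        pos = start if strand == "+" else end - 1
        out.append(FivePrimeEvidence(pos, strand=strand, source=src, transcript_id=tid or None))
    return out


def write_evidence_bed(evidence: list[FivePrimeEvidence], bed_path: str | Path, contig: str) -> None:
    lines = []
    for ev in evidence:
        name = ev.source if ev.transcript_id is None else f"{ev.source}:{ev.transcript_id}"
        lines.append(f"{contig}\t{ev.position}\t{ev.position + 1}\t{name}\t0\t{ev.strand}")
    Path(bed_path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Strand normalisation


def _mirror_transcript(t: TranscriptModel, n: int) -> TranscriptModel:
    ivs = [
        (n - e.interval.end, n - e.interval.start) for e in t.exons
    ]  # transcription order is preserved: 5'-most exon stays first
    labels = [e.label for e in t.exons]
    cds = None
    if t.cds is not None:
        cds = (n - t.cds[1], n - t.cds[0])
    return make_transcript(
        t.id, t.contig, ivs, strand="+", cds=cds, source=t.source,
        labels=labels, retention_isoform=t.retention_isoform,
    )


def normalize_locus(locus: GeneLocus) -> GeneLocus:
    """Return a plus-strand working copy of a minus-strand locus.

    Coordinates are mirrored (x -> n - 1 - x for positions, intervals flip),
    the contig is reverse-complemented, and ``origin_strand`` records the
    original orientation so reports can translate back.
    """
    if locus.reference.strand == "+":
        return locus
    n = len(locus.sequence)
    seq = str(Seq(locus.sequence).reverse_complement())
    ref = _mirror_transcript(locus.reference, n)
    alts = [_mirror_transcript(t, n) for t in locus.alternatives]
    ev = [
        FivePrimeEvidence(n - 1 - e.position, "+", e.source, e.transcript_id)
        for e in locus.evidence
    ]
    return GeneLocus(locus.contig_id, seq, ref, alts, ev, origin_strand="-")


def denormalize_position(pos: int, locus: GeneLocus) -> int:
    """Map a working-copy position back to original-strand coordinates."""
    if locus.origin_strand == "+":
        return pos
    return len(locus.sequence) - 1 - pos
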