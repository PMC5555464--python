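"""Per-locus isoform-complexity report tying all analysis stages together.

``annotate`` runs the full pipeline — TSS calling and clustering, promoter
shape/TATA/exonic annotation, first-exon classification, transcript diffing,
and coding-consequence calling — and returns a :class:`LocusReport` whose
summary counts equal the lengths of the underlying tables. The report
serialises deterministically to JSON (schema below) and to a set of TSVs.

All thresholds are configuration, never hard-coded, and are echoed in the
report header for provenance. NAGNAG nomenclature used throughout: the
proximal (upstream) AG yields the longer mRNA, the distal AG the shorter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as sio
from .consequences import (
    CodingConsequence,
    consequence_of_event,
    consequence_of_first_exon,
    find_orf_and_translate,
)
from .events import KIND_RETENTION, diff_transcripts, pair_mutually_exclusive
from .first_exons import (
    CLASS_CANONICAL,
    CLASS_EXTENSION,
    CLASS_ME_FIRST,
    assign_me_first_labels,
    classify_first_exon,
)
from .models import GeneLocus
from .tss import analyze_promoters

SCHEMA_VERSION = 1


@dataclass
class Thresholds:
    """Analysis thresholds with their literature-derived defaults."""

    separation_nt: int = 500  # TSS clusters further apart belong to distinct promoters
    sharp_width_nt: int = 62  # average TSS scatter of focused promoters
    canonical_tol_nt: int = 62  # first-exon starts within this of the reference are canonical
    nmd_distance_nt: int = 50  # PTC distance upstream of the last junction
    tata_window: tuple[int, int] = (-40, -20)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tata_window"] = list(self.tata_window)
        return d


@dataclass
class LocusReport:
    locus_id: str
    thresholds: Thresholds
    tss_clusters: list[dict] = field(default_factory=list)
    first_exons: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    consequences: list[dict] = field(default_factory=list)
    me_pairs: list[dict] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "locus_id": self.locus_id,
            "thresholds": self.thresholds.as_dict(),
            "nagnag_nomenclature": "proximal AG = upstream AG (longer mRNA)",
            "tss_clusters": self.tss_clusters,
            "first_exons": self.first_exons,
            "events": self.events,
            "consequences": self.consequences,
            "me_pairs": self.me_pairs,
            "summary": self.summary,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n")
        for name in ("tss_clusters", "first_exons", "events", "consequences"):
            rows = getattr(self, name)
            df = pd.DataFrame(rows)
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        if self.proteins:
            sio.write_fasta(outdir / "proteins.fa", self.proteins)
        # events also as GFF3, one feature per event
        lines = ["##gff-version 3"]
        for ev in self.events:
            lines.append(
                "\t".join(
                    [
                        self.locus_id,
                        "spliceatlas",
                        ev["kind"],
                        str(ev["start"] + 1),
                        str(max(ev["end"], ev["start"] + 1)),
                        ".",
                        "+",
                        ".",
                        f"transcript={ev['transcript_id']};delta_nt={ev['delta_nt']};"
                        f"ref_exons={','.join(map(str, ev['ref_exons']))}",
                    ]
                )
            )
        (outdir / "events.gff3").write_text("\n".join(lines) + "\n")


def _consequence_row(c: CodingConsequence, event_id: Optional[str]) -> dict:
    row = {
        "transcript_id": c.transcript_id,
        "event_id": event_id,
        "category": c.category,
        "deleted_residues": c.deleted_residues,
        "inserted_residues": c.inserted_residues,
        "substitutions": ";".join(f"{r}>{a}" for r, a in c.substituted_residues),
        "ptc_spliced_position": c.ptc_spliced_position,
        "nmd_candidate": c.nmd_candidate,
    }
    if c.truncation is not None:
        row.update(
            unique_n=c.truncation.unique_n,
            missing_n=c.truncation.missing_n,
            shared_suffix=c.truncation.shared_suffix,
        )
    return row


def annotate(locus: GeneLocus, thresholds: Thresholds | None = None) -> LocusReport:
    """Run the full annotation pipeline on a loaded locus."""
    th = thresholds or Thresholds()
    report = LocusReport(locus_id=locus.contig_id, thresholds=th)
    ref = locus.reference

    clusters = analyze_promoters(
        locus, th.separation_nt, th.sharp_width_nt, th.tata_window
    )
    for cl in clusters:
        report.tss_clusters.append(
            {
                "representative": cl.representative,
                "n_members": len(cl),
                "width": cl.width,
                "shape": cl.shape,
                "tata": cl.tata,
                "tata_position": cl.tata_position,
                "exonic": cl.exonic,
                "member_sources": ",".join(m.source for m in cl.members),
            }
        )

    calls = assign_me_first_labels(
        [classify_first_exon(t, ref, th.canonical_tol_nt) for t in locus.alternatives]
    )
    for c in calls:
        report.first_exons.append(
            {
                "transcript_id": c.transcript_id,
                "class": c.call_class,
                "anchor_exon": c.anchor_exon,
                "retained_nt": c.retained_nt,
                "label": c.label,
            }
        )

    nagnag_sites = set()
    n_retentions = 0
    for t, call in zip(locus.alternatives, calls):
        events = diff_transcripts(t, ref, locus, th.canonical_tol_nt, call)
        for k, ev in enumerate(events):
            event_id = f"{t.id}.ev{k + 1}"
            report.events.append(
                {
                    "event_id": event_id,
                    "transcript_id": t.id,
                    "kind": ev.kind,
                    "ref_exons": list(ev.ref_exons),
                    "delta_nt": ev.delta_nt,
                    "start": ev.coords.start,
                    "end": ev.coords.end,
                    "nagnag": ev.nagnag is not None,
                }
            )
            if ev.nagnag is not None:
                nagnag_sites.add(ev.nagnag.acceptor)
            if ev.kind == KIND_RETENTION:
                n_retentions += 1
            cons = consequence_of_event(locus, ref, t, ev, th.nmd_distance_nt)
            report.consequences.append(_consequence_row(cons, event_id))
        if call.call_class != CLASS_CANONICAL:
            cons = consequence_of_first_exon(locus, ref, t, call)
            report.consequences.append(_consequence_row(cons, None))

    for pair in pair_mutually_exclusive(locus.transcripts, ref):
        report.me_pairs.append(
            {
                "a": pair.a_label,
                "b": pair.b_label,
                "a_span": [pair.a_span.start, pair.a_span.end],
                "b_span": [pair.b_span.start, pair.b_span.end],
                "flanking_ref_exons": list(pair.slot),
            }
        )

    for t in locus.transcripts:
        iso = find_orf_and_translate(locus, t)
        if iso is not None:
            report.proteins[t.id] = iso.sequence

    report.summary = {
        "n_PAPs": len(report.tss_clusters),
        "n_ME_first_exons": sum(
            1 for c in calls if c.call_class == CLASS_ME_FIRST
        ),
        "n_extensions": sum(1 for c in calls if c.call_class == CLASS_EXTENSION),
        "n_NAGNAG": len(nagnag_sites),
        "n_retentions": n_retentions,
        "n_isoforms": len(locus.transcripts),
        "n_events": len(report.events),
    }
    return report


def load_locus(
    fasta: str | Path,
    gff3: str | Path | None = None,
    bed12: str | Path | None = None,
    evidence: str | Path | None = None,
    reference_id: str | None = None,
) -> GeneLocus:
    """Load a locus from GFF3 or BED12 transcript models plus a FASTA contig."""
    if (gff3 is None) == (bed12 is None):
        raise sio.InputError("provide exactly one of gff3 or bed12")
    if gff3 is not None:
        return sio.read_gene_models(gff3, fasta, evidence, reference_id)
    transcripts = sio.read_bed12_transcripts(bed12)
    if not transcripts:
        raise sio.InputError(f"no transcripts in {bed12}")
    contig = transcripts[0].contig
    sequence = sio.read_contig(fasta, contig)
    if reference_id:
        ref = next((t for t in transcripts if t.id == reference_id), None)
        if ref is None:
            raise sio.InputError(f"reference transcript {reference_id!r} not found")
    else:
        coding = [t for t in transcripts if t.cds is not None]
        if not coding:
            raise sio.InputError("no BED12 transcript has a thick (CDS) region")
        ref = max(coding, key=lambda t: (t.cds[1] - t.cds[0], t.spliced_length))
    alts = [t for t in transcripts if t.id != ref.id]
    ev = sio.read_evidence_bed(evidence) if evidence else []
    locus = GeneLocus(contig, sequence, ref, alts, ev)
    if ref.strand == "-":
        locus = sio.normalize_locus(locus)
    return locus
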