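"""Putative TSS calling and promoter (PAP) clustering.

A mapped 5' end is accepted as a putative TSS according to its context in
the reference gene model: ends at or inside annotated first exons and ends
inside introns are accepted; ends inside internal exons are accepted unless
they fall exactly on an ATG, in which case they are rejected as likely
truncated cDNAs. Accepted TSSs are clustered by single-linkage with a gap
threshold (default 500 nt: two promoters are considered distinct when their
TSS groups are separated by more than 500 bp). Cluster shape is sharp when
the TSS scatter is at most 62 nt (the average scatter reported for focused
promoters), else broad.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import GeneLocus

DEFAULT_SEPARATION_NT = 500
DEFAULT_SHARP_WIDTH_NT = 62
DEFAULT_TATA_WINDOW = (-40, -20)

TATA_CONSENSUS = re.compile("TATA[AT]A[AT][AG]")

STATUS_ACCEPTED = "accepted"
STATUS_REJECTED = "rejected_truncation_suspect"
STATUS_CANONICAL = "canonical"

CTX_ANNOTATED = "annotated_start"
CTX_INTRONIC = "intronic"
CTX_INTERNAL = "internal_exonic"
CTX_INTERNAL_ATG = "internal_exonic_at_ATG"


@dataclass(frozen=True)
class CandidateTss:
    position: int
    source: str
    status: str
    context: str

    def __post_init__(self) -> None:
        if (self.status == STATUS_REJECTED) != (self.context == CTX_INTERNAL_ATG):
            raise ValueError("rejected_truncation_suspect iff internal_exonic_at_ATG")


@dataclass
class TssCluster:
    members: list[CandidateTss]
    representative: int = field(init=False)
    width: int = field(init=False)
    shape: str = "sharp"
    tata: bool = False
    tata_position: Optional[int] = None
    exonic: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty TSS cluster")
        self.members = sorted(self.members, key=lambda c: c.position)
        positions = [m.position for m in self.members]
        self.representative = positions[0]  # 5'-most member (plus-strand copy)
        self.width = positions[-1] - positions[0]

    def __len__(self) -> int:
        return len(self.members)


def _annotated_starts(locus: GeneLocus) -> list[int]:
    return [t.tss for t in locus.transcripts]


def call_candidate_tss(locus: GeneLocus) -> list[CandidateTss]:
    """Classify each 5'-end evidence position against the gene models.

    Contexts: ``annotated_start`` — exactly at a transcript start or inside a
    first exon (TSS scatter around an annotated promoter); ``intronic`` —
    inside a reference intron or outside annotated exons (a novel putative
    TSS); ``internal_exonic`` — strictly inside an internal exon (accepted;
    internal promoters do occur); ``internal_exonic_at_ATG`` — inside an
    internal exon exactly at an ATG, rejected as a truncation suspect.
    """
    starts = set(_annotated_starts(locus))
    first_exons = [t.exons[0].interval for t in locus.transcripts]
    internal = [e.interval for t in locus.transcripts for e in t.exons[1:]]
    out = []
    for ev in locus.evidence:
        pos = ev.position
        if pos in starts or any(iv.contains(pos) for iv in first_exons):
            ctx = CTX_ANNOTATED
            status = STATUS_CANONICAL if pos in starts else STATUS_ACCEPTED
        elif any(iv.contains(pos) for iv in internal):
            if locus.sequence[pos : pos + 3] == "ATG":
                ctx, status = CTX_INTERNAL_ATG, STATUS_REJECTED
            else:
                ctx, status = CTX_INTERNAL, STATUS_ACCEPTED
        else:
            ctx, status = CTX_INTRONIC, STATUS_ACCEPTED
        out.append(CandidateTss(pos, ev.source, status, ctx))
    return out


def cluster_tss(
    candidates: Iterable[CandidateTss],
    separation_threshold: int = DEFAULT_SEPARATION_NT,
) -> list[TssCluster]:
    """Single-linkage 1-D clustering of accepted TSS candidates.

    A gap strictly greater than the threshold between consecutive sorted
    positions starts a new cluster; a gap of exactly the threshold merges.
    The partition is independent of input order, and the number of clusters
    is non-increasing in the threshold.
    """
    accepted = sorted(
        (c for c in candidates if c.status != STATUS_REJECTED),
        key=lambda c: c.position,
    )
    if not accepted:
        return []
    groups: list[list[CandidateTss]] = [[accepted[0]]]
    for c in accepted[1:]:
        if c.position - groups[-1][-1].position > separation_threshold:
            groups.append([c])
        else:
            groups[-1].append(c)
    return [TssCluster(g) for g in groups]


def classify_shape(cluster: TssCluster, sharp_width_max: int = DEFAULT_SHARP_WIDTH_NT) -> str:
    """Sharp iff the TSS scatter (cluster width) is at most the cutoff."""
    return "sharp" if cluster.width <= sharp_width_max else "broad"


def scan_tata(
    locus: GeneLocus,
    cluster: TssCluster,
    window: tuple[int, int] = DEFAULT_TATA_WINDOW,
) -> tuple[bool, Optional[int]]:
    """Scan the sense strand for a TATA box upstream of the representative TSS.

    The consensus is TATAWAWR (W in {A,T}, R in {A,G}); a hit is reported
    when the motif *starts* within ``window`` (offsets relative to the
    representative TSS, inclusive). The leftmost match is returned as a
    genomic position. Windows truncated by the contig edge are scanned as-is.
    """
    rep = cluster.representative
    lo = max(0, rep + window[0])
    hi = max(0, rep + window[1])
    for start in range(lo, hi + 1):
        if TATA_CONSENSUS.fullmatch(locus.sequence[start : start + 8]):
            return True, start
    return False, None


def flag_exonic_tss(
    cluster: TssCluster,
    locus: GeneLocus,
    min_start_distance: int = DEFAULT_SEPARATION_NT,
) -> bool:
    """True for an internal-exonic promoter candidate.

    The representative must lie strictly inside an internal or coding exon of
    some annotated transcript and be more than ``min_start_distance`` nt away
    from every annotated transcript start (the same threshold that separates
    distinct promoters); closer candidates merge with that start's promoter.
    """
    rep = cluster.representative
    inside = False
    for t in locus.transcripts:
        cds = t.cds
        for e in t.exons:
            iv = e.interval
            strictly_inside = iv.start < rep < iv.end - 1
            coding = cds is not None and cds[0] <= rep < cds[1]
            if strictly_inside and (e.ordinal > 1 or coding):
                inside = True
    if not inside:
        return False
    return all(abs(rep - s) > min_start_distance for s in _annotated_starts(locus))


def analyze_promoters(
    locus: GeneLocus,
    separation_threshold: int = DEFAULT_SEPARATION_NT,
    sharp_width_max: int = DEFAULT_SHARP_WIDTH_NT,
    tata_window: tuple[int, int] = DEFAULT_TATA_WINDOW,
) -> list[TssCluster]:
    """Full promoter analysis: call, cluster, and annotate shape/TATA/exonic."""
    cands = call_candidate_tss(locus)
    clusters = cluster_tss(cands, separation_threshold)
    for cl in clusters:
        cl.shape = classify_shape(cl, sharp_width_max)
        cl.tata, cl.tata_position = scan_tata(locus, cl, tata_window)
        cl.exonic = flag_exonic_tss(cl, locus, separation_threshold)
    return clusters
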