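"""Structural diff between an alternative transcript and the reference.

``diff_transcripts`` enumerates the splice events distinguishing two exon
chains: skipped exons (one event per contiguous run), alternative donors and
acceptors (signed nt deltas), mutually exclusive exon swaps, intron
retention (partial at the donor edge or full, exon-bridging), and cryptic
donors inside the 5'-UTR. First-exon differences are factored out first (see
:mod:`spliceatlas.first_exons`); the diff runs on the shared suffix of the
two structures, and the per-event ``delta_nt`` values sum to the spliced
length difference over the compared region.

Event-typing conventions (boundary shifts):

* acceptor-side differences are always ``alt_acceptor`` (NAGNAG shifts are
  plus/minus 3-nt alt_acceptor events);
* donor shifts into the exon (negative delta) are ``alt_donor``;
* donor extensions into the intron (positive delta) are
  ``cryptic_donor_utr`` when the extension lies entirely in the 5'-UTR,
  otherwise partial ``intron_retention``.

``detect_nagnag`` tests the intron-terminal hexamer ending one base before
an exon's first nucleotide against the NAGNAG consensus; the upstream
("proximal") AG yields the longer mRNA, the downstream ("distal") AG the
shorter one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .first_exons import (
    CLASS_CANONICAL,
    CLASS_EXTENSION,
    CLASS_ME_FIRST,
    CLASS_RETAINING,
    FirstExonCall,
    classify_first_exon,
)
from .models import GeneLocus, GenomicInterval, TranscriptModel

KIND_SKIPPED = "skipped_exon"
KIND_ALT_DONOR = "alt_donor"
KIND_ALT_ACCEPTOR = "alt_acceptor"
KIND_ME_PAIR = "mutually_exclusive_pair"
KIND_RETENTION = "intron_retention"
KIND_CRYPTIC_UTR = "cryptic_donor_utr"


@dataclass(frozen=True)
class NagnagSite:
    """A tandem 3' splice acceptor: two AGs 3 nt apart at an intron end."""

    acceptor: int  # exon first base when the distal AG is used
    proximal_ag: int  # upstream AG (genomic start); usage yields the longer mRNA
    distal_ag: int  # downstream AG
    hexamer: str

    def __post_init__(self) -> None:
        if self.distal_ag - self.proximal_ag != 3:
            raise ValueError("tandem AGs must be 3 nt apart")


@dataclass(frozen=True)
class SpliceEvent:
    kind: str
    ref_exons: tuple[int, ...]
    delta_nt: int
    coords: GenomicInterval
    alt_exon_span: Optional[GenomicInterval] = None
    subsumed_exons: tuple[int, ...] = ()
    nagnag: Optional[NagnagSite] = None


def detect_nagnag(locus: GeneLocus, acceptor_position: int) -> Optional[NagnagSite]:
    """Return the NAGNAG site whose distal AG ends at ``acceptor_position`` - 1.

    ``acceptor_position`` is the first exonic base of the (shorter) exon. The
    6 nt ending just before it must match NAGNAG (N = any base). Acceptors
    within 6 nt of the contig start cannot be tested and yield None.
    """
    if acceptor_position < 6:
        return None
    hexamer = locus.sequence[acceptor_position - 6 : acceptor_position]
    if hexamer[1:3] == "AG" and hexamer[4:6] == "AG":
        return NagnagSite(
            acceptor=acceptor_position,
            proximal_ag=acceptor_position - 5,
            distal_ag=acceptor_position - 2,
            hexamer=hexamer,
        )
    return None


def is_nagnag_shift(locus: GeneLocus, event: SpliceEvent) -> Optional[NagnagSite]:
    """Classify a 3-nt acceptor shift as NAGNAG-mediated if the motif exists."""
    if event.kind != KIND_ALT_ACCEPTOR or abs(event.delta_nt) != 3:
        return None
    return detect_nagnag(locus, event.coords.end)


def _alignment(alt: TranscriptModel, ref: TranscriptModel, call: FirstExonCall):
    """(alt index, ref index, suppress-first-acceptor) to start the diff at."""
    if call.call_class == CLASS_CANONICAL:
        return 0, 0, True
    if call.call_class == CLASS_ME_FIRST:
        return 1, call.anchor_exon - 1, False
    if call.call_class in (CLASS_EXTENSION, CLASS_RETAINING):
        return 1, call.anchor_exon, False
    return None


def diff_transcripts(
    alt: TranscriptModel,
    ref: TranscriptModel,
    locus: Optional[GeneLocus] = None,
    canonical_tol: int = 62,
    first_exon_call: Optional[FirstExonCall] = None,
) -> list[SpliceEvent]:
    """Enumerate splice events of ``alt`` relative to ``ref``.

    Events are returned sorted 5' to 3'. When a ``locus`` is given, 3-nt
    acceptor shifts are annotated with their NAGNAG site if present and
    donor extensions are typed against the reference 5'-UTR.
    """
    if alt.contig != ref.contig or alt.strand != ref.strand:
        raise ValueError("transcripts must share contig and strand")
    call = first_exon_call or classify_first_exon(alt, ref, canonical_tol)
    align = _alignment(alt, ref, call)
    if align is None:
        warnings.warn(f"{alt.id}: no structural overlap with {ref.id}; empty diff")
        return []
    j0, i0, suppress_acc = align
    A = list(alt.exons[j0:])
    R = list(ref.exons[i0:])
    if not A or not R:
        return []

    cds_start = ref.cds[0] if ref.cds else None
    contig = alt.contig
    events: list[SpliceEvent] = []
    balanced = True
    suppressed_delta = 0
    i = j = 0
    first_pair = True

    def span(*ivs: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(contig, min(v.start for v in ivs), max(v.end for v in ivs))

    while i < len(R) and j < len(A):
        r, a = R[i].interval, A[j].interval
        if a.end <= r.start:
            # novel alt exon upstream of the next reference exon
            nxt = A[j + 1].interval if j + 1 < len(A) else None
            if nxt is not None and r.end <= nxt.start:
                events.append(
                    SpliceEvent(
                        KIND_ME_PAIR,
                        ref_exons=(R[i].ordinal,),
                        delta_nt=a.length - r.length,
                        coords=span(a, r),
                        alt_exon_span=a,
                    )
                )
                i += 1
                j += 1
            else:
                warnings.warn(f"{alt.id}: novel internal exon {a.start}-{a.end} with no replaced reference exon")
                balanced = False
                j += 1
            first_pair = False
            continue
        if r.end <= a.start:
            run = [R[i]]
            i += 1
            while i < len(R) and R[i].interval.end <= a.start:
                run.append(R[i])
                i += 1
            a_is_novel = not (i < len(R) and a.overlaps(R[i].interval))
            if a_is_novel and len(run) == 1:
                events.append(
                    SpliceEvent(
                        KIND_ME_PAIR,
                        ref_exons=(run[0].ordinal,),
                        delta_nt=a.length - run[0].interval.length,
                        coords=span(a, run[0].interval),
                        alt_exon_span=a,
                    )
                )
                j += 1
                first_pair = False
                continue
            events.append(
                SpliceEvent(
                    KIND_SKIPPED,
                    ref_exons=tuple(e.ordinal for e in run),
                    delta_nt=-sum(e.interval.length for e in run),
                    coords=span(*(e.interval for e in run)),
                )
            )
            continue

        # overlap: group every reference exon the alt exon touches
        group = [R[i]]
        i += 1
        while i < len(R) and R[i].interval.start < a.end:
            group.append(R[i])
            i += 1
        if len(group) > 1:
            retained_ivs = [
                GenomicInterval(contig, p.interval.end, q.interval.start)
                for p, q in zip(group, group[1:])
            ]
            events.append(
                SpliceEvent(
                    KIND_RETENTION,
                    ref_exons=tuple(e.ordinal for e in group),
                    delta_nt=sum(iv.length for iv in retained_ivs),
                    coords=span(*retained_ivs),
                    alt_exon_span=a,
                    subsumed_exons=tuple(e.ordinal for e in group[1:-1]),
                )
            )
        first_r, last_r = group[0].interval, group[-1].interval
        acc_d = first_r.start - a.start
        if acc_d != 0:
            if first_pair and suppress_acc:
                suppressed_delta = acc_d
            else:
                events.append(
                    SpliceEvent(
                        KIND_ALT_ACCEPTOR,
                        ref_exons=(group[0].ordinal,),
                        delta_nt=acc_d,
                        coords=GenomicInterval(
                            contig, min(first_r.start, a.start), max(first_r.start, a.start)
                        ),
                    )
                )
        don_d = a.end - last_r.end
        if don_d != 0:
            alt_has_junction = j + 1 < len(A)
            ref_has_junction = i < len(R)
            if alt_has_junction and ref_has_junction:
                coords = GenomicInterval(contig, min(a.end, last_r.end), max(a.end, last_r.end))
                if don_d < 0:
                    kind = KIND_ALT_DONOR
                elif cds_start is not None and a.end <= cds_start:
                    kind = KIND_CRYPTIC_UTR
                else:
                    kind = KIND_RETENTION
                events.append(
                    SpliceEvent(kind, ref_exons=(group[-1].ordinal,), delta_nt=don_d, coords=coords)
                )
            else:
                # at least one transcript ends here: a 3'-terminus difference,
                # not a splice event
                balanced = False
        j += 1
        first_pair = False

    if i < len(R) or j < len(A):
        warnings.warn(f"{alt.id}: transcript ends before {ref.id if i < len(R) else alt.id} tail; no events emitted for the tail")
        balanced = False

    events.sort(key=lambda e: (e.coords.start, e.coords.end))

    if locus is not None:
        events = [
            SpliceEvent(
                e.kind, e.ref_exons, e.delta_nt, e.coords, e.alt_exon_span,
                e.subsumed_exons, is_nagnag_shift(locus, e),
            )
            for e in events
        ]

    if balanced:
        len_a = sum(e.interval.length for e in A)
        len_r = sum(e.interval.length for e in R)
        total = sum(e.delta_nt for e in events)
        if total + suppressed_delta != len_a - len_r:
            raise AssertionError(
                f"{alt.id}: event deltas ({total}) do not balance spliced-length "
                f"difference ({len_a - len_r}, suppressed {suppressed_delta})"
            )
    return events


@dataclass(frozen=True)
class MePair:
    """A mutually exclusive internal exon pair across a transcript set."""

    a_label: str
    b_label: str
    a_span: GenomicInterval
    b_span: GenomicInterval
    slot: tuple[int, int]  # flanking reference exon ordinals


def _ref_ordinal_of(iv: GenomicInterval, ref: TranscriptModel) -> Optional[int]:
    hits = [e.ordinal for e in ref.exons if e.interval.overlaps(iv)]
    return hits[0] if hits else None


def pair_mutually_exclusive(
    transcripts: list[TranscriptModel], ref: TranscriptModel
) -> list[MePair]:
    """Find mutually exclusive internal exon pairs across a transcript set.

    Reports pairs (a, b) of internal exons occupying disjoint genomic
    intervals between the same flanking reference exons, where no transcript
    contains both and each appears in at least one transcript.
    """
    info: dict[tuple[int, int], dict] = {}
    per_transcript: dict[str, set[tuple[int, int]]] = {}
    for t in transcripts:
        keys = set()
        for idx in range(1, len(t.exons) - 1):
            iv = t.exons[idx].interval
            prev_ord = _ref_ordinal_of(t.exons[idx - 1].interval, ref)
            next_ord = _ref_ordinal_of(t.exons[idx + 1].interval, ref)
            if prev_ord is None or next_ord is None:
                continue
            key = (iv.start, iv.end)
            keys.add(key)
            rec = info.setdefault(key, {"slots": set(), "label": t.exons[idx].label, "iv": iv})
            rec["slots"].add((prev_ord, next_ord))
            if t.exons[idx].label:
                rec["label"] = t.exons[idx].label
        per_transcript[t.id] = keys

    # overlapping candidate exons (e.g. boundary-shift variants of the same
    # exon) are one locus for pairing purposes: group by overlap
    keys = sorted(info)
    group_of: dict[tuple[int, int], int] = {}
    groups: list[list[tuple[int, int]]] = []
    for key in keys:
        placed = False
        for gi, members in enumerate(groups):
            if any(info[key]["iv"].overlaps(info[m]["iv"]) for m in members):
                members.append(key)
                group_of[key] = gi
                placed = True
                break
        if not placed:
            group_of[key] = len(groups)
            groups.append([key])

    def group_label(members: list[tuple[int, int]]) -> str:
        for m in members:
            if info[m]["label"]:
                return info[m]["label"]
        k = members[0]
        return f"{k[0]}-{k[1]}"

    def group_span(members: list[tuple[int, int]]) -> GenomicInterval:
        ivs = [info[m]["iv"] for m in members]
        return GenomicInterval(ivs[0].contig, min(v.start for v in ivs), max(v.end for v in ivs))

    pairs = []
    for x in range(len(groups)):
        for y in range(x + 1, len(groups)):
            ga, gb = groups[x], groups[y]
            slots_a = set().union(*(info[m]["slots"] for m in ga))
            slots_b = set().union(*(info[m]["slots"] for m in gb))
            if not (slots_a & slots_b):
                continue
            if any(
                info[a]["iv"].overlaps(info[b]["iv"]) for a in ga for b in gb
            ):
                continue
            if any(
                (s & set(ga)) and (s & set(gb)) for s in per_transcript.values()
            ):
                continue
            pairs.append(
                MePair(
                    group_label(ga),
                    group_label(gb),
                    group_span(ga),
                    group_span(gb),
                    sorted(slots_a & slots_b)[0],
                )
            )
    return pairs
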