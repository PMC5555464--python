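"""Protein-level consequences of splice events and alternative first exons.

Each event's effect on the encoded protein is computed by translating both
transcripts and aligning the proteins by common prefix and suffix:

* events outside the CDS leave the protein identical (``silent_utr``);
* in-frame excisions (delta divisible by 3) delete ``|delta|/3`` residues;
  a cut that is not codon-aligned creates one chimeric junction codon,
  reported as a substitution when the translated residue actually changes;
* frame-disrupting deltas produce a downstream premature termination codon
  (PTC); the transcript is an NMD candidate when the PTC lies more than
  50 nt upstream of the last exon-exon junction (standard rule, advisory);
* alternative first exons that drop the annotated start codon yield
  N-terminally truncated isoforms, summarised by the longest common suffix:
  ``len(alt) = len(ref) - missing_n + unique_n``.

Deleted runs are reported with leftmost placement when the placement is
ambiguous in repeat context; junction substitutions are aligned at the right
edge of the changed run (so a run G,K,Y -> D reads as deletion of G and K
and substitution of Y by D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .events import SpliceEvent
from .first_exons import FirstExonCall
from .models import GeneLocus, TranscriptModel, spliced_sequence

DEFAULT_NMD_DISTANCE_NT = 50

CAT_SILENT_UTR = "silent_utr"
CAT_INFRAME_DEL = "inframe_deletion"
CAT_INFRAME_DEL_SUB = "inframe_deletion_with_substitution"
CAT_INFRAME_INS = "inframe_insertion"
CAT_INFRAME_SUB = "inframe_substitution"
CAT_FRAMESHIFT = "frameshift_ptc"
CAT_NTERM_TRUNC = "n_terminal_truncation"
CAT_NON_CODING = "non_coding"


@dataclass(frozen=True)
class ProteinIsoform:
    transcript_id: str
    sequence: str
    orf_span: tuple[int, int]  # spliced coords, start codon through stop inclusive

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("protein sequence must not contain a stop symbol")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TruncationStats:
    unique_n: int
    missing_n: int
    shared_suffix: int
    unrelated_c_termini: bool = False


@dataclass(frozen=True)
class CodingConsequence:
    category: str
    transcript_id: str
    event: Optional[SpliceEvent] = None
    first_exon: Optional[FirstExonCall] = None
    deleted_residues: int = 0
    inserted_residues: int = 0
    substituted_residues: tuple[tuple[str, str], ...] = ()
    ptc_spliced_position: Optional[int] = None
    nmd_candidate: bool = False
    truncation: Optional[TruncationStats] = None


# ---------------------------------------------------------------------------
# translation


def _translate_to_stop(mrna: str, start: int) -> tuple[str, Optional[int]]:
    """Translate from ``start`` to the first in-frame stop.

    Returns (protein, spliced position of the stop codon's first base), or
    (protein-to-end, None) when no stop is reached.
    """
    coding = mrna[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    prot = str(Seq(coding).translate())
    stop_idx = prot.find("*")
    if stop_idx == -1:
        return prot, None
    return prot[:stop_idx], start + 3 * stop_idx


def find_orf_and_translate(locus: GeneLocus, t: TranscriptModel) -> Optional[ProteinIsoform]:
    """Translate the annotated CDS, or the first AUG to the first stop.

    Returns None (a non-coding call) when no AUG or no in-frame stop exists.
    The standard nuclear genetic code is used throughout; no Kozak scoring.
    """
    mrna = spliced_sequence(locus, t)
    if len(mrna) < 6:
        raise ValueError(f"transcript {t.id} too short to translate")
    if t.cds is not None:
        a, b = t.cds_spliced_span()
        if (b - a) % 3 != 0:
            raise ValueError(f"transcript {t.id}: CDS length not divisible by 3")
        prot, stop = _translate_to_stop(mrna, a)
        if stop != b - 3:
            warnings.warn(f"transcript {t.id}: annotated CDS has an unexpected stop; truncated")
        return ProteinIsoform(t.id, prot, (a, (stop + 3) if stop is not None else b))
    start = mrna.find("ATG")
    if start == -1:
        return None
    prot, stop = _translate_to_stop(mrna, start)
    if stop is None:
        return None
    return ProteinIsoform(t.id, prot, (start, stop + 3))


def _alt_protein_from_ref_start(
    locus: GeneLocus, ref: TranscriptModel, alt: TranscriptModel
) -> tuple[Optional[str], Optional[int], Optional[int]]:
    """Translate ``alt`` from the reference start codon mapped into it.

    Returns (protein, orf spliced start, stop spliced position). Falls back
    to the first-AUG policy when the reference start codon is not exonic in
    ``alt``.
    """
    mrna = spliced_sequence(locus, alt)
    if alt.cds is not None:
        iso = find_orf_and_translate(locus, alt)
        return (iso.sequence, iso.orf_span[0], iso.orf_span[1] - 3) if iso else (None, None, None)
    start = alt.genomic_to_spliced(ref.cds[0]) if ref.cds else None
    if start is None:
        start = mrna.find("ATG")
        if start == -1:
            return None, None, None
    prot, stop = _translate_to_stop(mrna, start)
    return prot, start, stop


# ---------------------------------------------------------------------------
# prefix/suffix protein alignment


def _prefix_suffix(ref_p: str, alt_p: str) -> tuple[int, int]:
    n = min(len(ref_p), len(alt_p))
    p = 0
    while p < n and ref_p[p] == alt_p[p]:
        p += 1
    s = 0
    while s < n - p and ref_p[-1 - s] == alt_p[-1 - s]:
        s += 1
    return p, s


def consequence_of_event(
    locus: GeneLocus,
    ref: TranscriptModel,
    alt: TranscriptModel,
    event: SpliceEvent,
    nmd_distance: int = DEFAULT_NMD_DISTANCE_NT,
) -> CodingConsequence:
    """Protein-level effect of one splice event of ``alt`` vs ``ref``.

    The event must come from ``diff_transcripts(alt, ref)``; the comparison
    translates both full transcripts, so the result reflects the event in
    the context of the whole isoform.
    """
    ref_iso = find_orf_and_translate(locus, ref)
    if ref_iso is None:
        raise ValueError(f"reference {ref.id} is not translatable")
    sp = alt.span
    if not (sp.start <= event.coords.start and event.coords.end <= max(sp.end, ref.span.end)):
        raise ValueError(f"event {event.kind} at {event.coords.start} outside transcript bounds")
    alt_p, alt_start, alt_stop = _alt_protein_from_ref_start(locus, ref, alt)
    if alt_p is None:
        return CodingConsequence(CAT_NON_CODING, alt.id, event=event)
    ref_p = ref_iso.sequence

    if alt_p == ref_p:
        return CodingConsequence(CAT_SILENT_UTR, alt.id, event=event)

    if event.delta_nt % 3 != 0:
        nmd = False
        junctions = alt.junctions_spliced()
        if alt_stop is not None and junctions:
            nmd = (junctions[-1] - alt_stop) > nmd_distance
        return CodingConsequence(
            CAT_FRAMESHIFT, alt.id, event=event,
            ptc_spliced_position=alt_stop, nmd_candidate=nmd,
        )

    p, s = _prefix_suffix(ref_p, alt_p)
    mid_r = ref_p[p : len(ref_p) - s]
    mid_a = alt_p[p : len(alt_p) - s]
    if len(mid_r) > len(mid_a):
        deleted = len(mid_r) - len(mid_a)
        subs = tuple(
            (r, a) for r, a in zip(mid_r[deleted:], mid_a) if r != a
        )
        cat = CAT_INFRAME_DEL_SUB if subs else CAT_INFRAME_DEL
        return CodingConsequence(
            cat, alt.id, event=event, deleted_residues=deleted, substituted_residues=subs
        )
    if len(mid_a) > len(mid_r):
        inserted = len(mid_a) - len(mid_r)
        subs = tuple((r, a) for r, a in zip(mid_r, mid_a[inserted:]) if r != a)
        return CodingConsequence(
            CAT_INFRAME_INS, alt.id, event=event,
            inserted_residues=inserted, substituted_residues=subs,
        )
    subs = tuple((r, a) for r, a in zip(mid_r, mid_a) if r != a)
    return CodingConsequence(CAT_INFRAME_SUB, alt.id, event=event, substituted_residues=subs)


def consequence_of_first_exon(
    locus: GeneLocus,
    ref: TranscriptModel,
    alt: TranscriptModel,
    call: FirstExonCall,
) -> CodingConsequence:
    """Protein-level effect of an alternative first exon.

    A first exon that preserves the reference ORF is ``silent_utr``; one that
    replaces the N-terminus is summarised by the truncation identity.
    """
    ref_iso = find_orf_and_translate(locus, ref)
    if ref_iso is None:
        raise ValueError(f"reference {ref.id} is not translatable")
    alt_iso = find_orf_and_translate(locus, alt)
    if alt_iso is None:
        return CodingConsequence(CAT_NON_CODING, alt.id, first_exon=call)
    if alt_iso.sequence == ref_iso.sequence:
        return CodingConsequence(CAT_SILENT_UTR, alt.id, first_exon=call)
    stats = nterm_truncation_stats(ref_iso.sequence, alt_iso.sequence)
    return CodingConsequence(CAT_NTERM_TRUNC, alt.id, first_exon=call, truncation=stats)


# ---------------------------------------------------------------------------
# N-terminal truncation bookkeeping


def nterm_truncation_stats(ref_protein: str, alt_protein: str) -> TruncationStats:
    """Compare two proteins by their longest common suffix.

    ``shared_suffix`` is the length of the longest common suffix;
    ``unique_n = len(alt) - shared_suffix`` counts novel N-terminal residues
    of the alternative isoform and ``missing_n = len(ref) - shared_suffix``
    the reference N-terminal residues it lacks, so that
    ``len(alt) = len(ref) - missing_n + unique_n`` holds by construction.
    """
    if not ref_protein or not alt_protein:
        raise ValueError("both proteins must be non-empty")
    s = 0
    n = min(len(ref_protein), len(alt_protein))
    while s < n and ref_protein[-1 - s] == alt_protein[-1 - s]:
        s += 1
    stats = TruncationStats(
        unique_n=len(alt_protein) - s,
        missing_n=len(ref_protein) - s,
        shared_suffix=s,
        unrelated_c_termini=(s == 0),
    )
    assert len(alt_protein) == len(ref_protein) - stats.missing_n + stats.unique_n
    return stats


def predicted_isoform_length(ref_len: int, missing_n: int, unique_n: int) -> int:
    """Length of an N-terminally modified isoform: ref_len - missing_n + unique_n."""
    if missing_n > ref_len:
        raise ValueError("missing_n cannot exceed the reference length")
    return ref_len - missing_n + unique_n
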