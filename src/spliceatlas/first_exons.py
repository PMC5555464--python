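"""Taxonomy of alternative first exons against a reference gene model.

Classes:

* ``canonical`` — starts within the TSS-scatter tolerance of the reference
  first-exon start (default 62 nt).
* ``mutually_exclusive_first`` — lies entirely within a reference intron
  (zero overlap with any reference exon) and its donor joins a downstream
  reference acceptor.
* ``five_prime_extension`` — starts in a reference intron (or overlaps one
  reference exon) and shares the 3' (donor) boundary of reference exon N;
  labelled "NL".
* ``intron_retaining_first`` — runs uninterrupted through at least one
  reference intron into the next exon; ``retained_nt`` counts the intronic
  nucleotides it includes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .models import TranscriptModel

CLASS_CANONICAL = "canonical"
CLASS_ME_FIRST = "mutually_exclusive_first"
CLASS_EXTENSION = "five_prime_extension"
CLASS_RETAINING = "intron_retaining_first"
CLASS_UNRESOLVABLE = "unresolvable"

DEFAULT_CANONICAL_TOL_NT = 62


@dataclass(frozen=True)
class FirstExonCall:
    transcript_id: str
    call_class: str
    anchor_exon: int
    retained_nt: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if (self.retained_nt > 0) != (self.call_class == CLASS_RETAINING):
            raise ValueError("retained_nt > 0 iff intron_retaining_first")


def classify_first_exon(
    alt: TranscriptModel,
    ref: TranscriptModel,
    canonical_tol: int = DEFAULT_CANONICAL_TOL_NT,
) -> FirstExonCall:
    """Classify the first exon of ``alt`` against ``ref`` (plus-strand copy).

    A mutually exclusive first exon must not overlap any reference exon by
    even one nucleotide; any overlap with a shared donor reclassifies it as a
    5' extension. Classification only inspects the first exon and the splice
    acceptor of the second, so it is invariant to downstream exons.
    """
    fe = alt.exons[0].interval
    ref_first = ref.exons[0].interval
    if abs(fe.start - ref_first.start) <= canonical_tol:
        return FirstExonCall(alt.id, CLASS_CANONICAL, anchor_exon=1, label=ref.exons[0].label or "1")

    overlapped = [e for e in ref.exons if fe.overlaps(e.interval)]
    introns = ref.introns()

    if len(overlapped) >= 2:
        retained = sum(fe.intersection_length(iv) for iv in introns)
        anchor = max(e.ordinal for e in overlapped)
        return FirstExonCall(alt.id, CLASS_RETAINING, anchor_exon=anchor, retained_nt=retained)

    if len(overlapped) == 1:
        e = overlapped[0]
        if fe.end == e.interval.end:
            return FirstExonCall(alt.id, CLASS_EXTENSION, anchor_exon=e.ordinal, label=f"{e.ordinal}L")
        warnings.warn(
            f"first exon of {alt.id} overlaps reference exon {e.ordinal} "
            "without sharing its donor; unresolvable"
        )
        return FirstExonCall(alt.id, CLASS_UNRESOLVABLE, anchor_exon=e.ordinal)

    # no overlap with any reference exon: mutually exclusive first exon if the
    # transcript splices onto a downstream reference acceptor
    if len(alt.exons) >= 2:
        second = alt.exons[1].interval
        for e in ref.exons:
            if e.interval.start == second.start:
                return FirstExonCall(alt.id, CLASS_ME_FIRST, anchor_exon=e.ordinal)
    warnings.warn(
        f"first exon of {alt.id} overlaps no reference feature and splices to "
        "no reference acceptor; unresolvable"
    )
    return FirstExonCall(alt.id, CLASS_UNRESOLVABLE, anchor_exon=1)


def assign_me_first_labels(calls: list[FirstExonCall]) -> list[FirstExonCall]:
    """Assign "1B"-style letters to mutually exclusive first exons, in order."""
    out = []
    letter = ord("B")
    for c in calls:
        if c.call_class == CLASS_ME_FIRST and not c.label:
            c = FirstExonCall(c.transcript_id, c.call_class, c.anchor_exon, c.retained_nt, f"1{chr(letter)}")
            letter += 1
        out.append(c)
    return out
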