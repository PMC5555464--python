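"""Seeded generator of toy gene loci with ground-truth annotations.

A :class:`LocusSpec` declares a reference gene architecture (exon count,
length ranges, where the CDS starts) plus a list of planted features — every
structural class the pipeline detects: NAGNAG tandem acceptors, alternative
donors/acceptors with configurable offsets, skipped exons, mutually
exclusive internal exon pairs, partial and full (exon-bridging) intron
retentions, mutually exclusive first exons, 5'-extension first exons, a
cryptic 5'-UTR donor, and 5'-end tag clusters with optional TATA box.

``generate_locus`` emits a :class:`~spliceatlas.models.GeneLocus` together
with a :class:`TruthSet` naming every expected first-exon call, splice
event, coding consequence, and TSS cluster. Generation is deterministic
under a fixed seed; every intron begins GT and ends AG; planted coding
offsets are engineered at the codon level (exon boundaries are phase 0
unless a feature requires otherwise) and the generator back-checks each
planted consequence by direct translation before returning.

Background sequence is uniform random. To keep planted truth exact the
generator scrubs confounders: no ATG substring in introns or UTRs except
planted start codons, no NAGNAG hexamer at non-planted acceptors, and no
TATA consensus inside scanned promoter windows except the planted box.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio.Seq import Seq

from . import io as sio
from .models import FivePrimeEvidence, GeneLocus, TranscriptModel, make_transcript

STOP_CODONS = {"TAA", "TAG", "TGA"}
CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
# codon by terminal dinucleotide, for plants that must end in a splice AG
AG_CODONS = {"K": "AAG", "E": "GAG", "Q": "CAG"}
PLAIN_CODONS = {"K": "AAA", "E": "GAA", "Q": "CAA"}


# ---------------------------------------------------------------------------
# planted features


@dataclass(frozen=True)
class Nagnag:
    """Tandem acceptor at ``exon``: reference uses the proximal AG (keeps one
    extra codon), the alternative isoform the distal AG (-3 nt)."""

    exon: int


@dataclass(frozen=True)
class AltDonor:
    """Donor shift at ``exon`` by ``offset`` nt (negative = into the exon)."""

    exon: int
    offset: int = -21


@dataclass(frozen=True)
class AltAcceptor:
    """Acceptor shift at ``exon`` by ``offset`` nt (negative = nt excluded)."""

    exon: int
    offset: int = -15


@dataclass(frozen=True)
class DonorShiftWithSubstitution:
    """A -6 nt donor shift across a codon boundary: deletes two residues
    (G, K) and substitutes the junction residue (Y -> D)."""

    exon: int


@dataclass(frozen=True)
class SkippedExons:
    exons: tuple[int, ...]


@dataclass(frozen=True)
class PartialRetention:
    """Alternative isoform retains the first ``retained`` nt of ``intron``
    (donor-edge partial retention); retained % 3 != 0 so a planted stop
    creates a PTC."""

    intron: int
    retained: int = 38


@dataclass(frozen=True)
class FullRetention:
    """One alternative exon bridges reference exons ``first_exon`` through
    ``last_exon``, retaining the introns between them (optionally forced to
    total ``retained_total`` nt)."""

    first_exon: int
    last_exon: int
    retained_total: Optional[int] = None


@dataclass(frozen=True)
class MutuallyExclusive:
    """Reference exon ``exon`` is swapped for a planted partner exon of
    ``partner_length`` nt (multiple of 3) in the downstream intron."""

    exon: int
    partner_length: int = 60


@dataclass(frozen=True)
class MeFirstExon:
    """A mutually exclusive first exon inside ``intron``, spliced to the
    next reference exon; when the reference start codon lies upstream the
    exon carries its own ATG and ``n_unique`` novel codons."""

    intron: int
    length: int = 120
    n_unique: int = 8


@dataclass(frozen=True)
class FivePrimeExtension:
    """A first exon 5'-extending reference exon ``exon`` by ``extension`` nt
    into the upstream intron (shares the exon's donor)."""

    exon: int
    extension: int = 90
    n_unique: int = 8


@dataclass(frozen=True)
class CrypticDonorUtr:
    """The first (untranslated) exon splices from a cryptic donor ``offset``
    nt inside intron 1; the coding region is unaffected."""

    offset: int = 132


@dataclass(frozen=True)
class TssClusterSpec:
    """One intended TSS cluster; offsets are genomic, relative to the
    reference transcript start."""

    offsets: tuple[int, ...]


Feature = Union[
    Nagnag,
    AltDonor,
    AltAcceptor,
    DonorShiftWithSubstitution,
    SkippedExons,
    PartialRetention,
    FullRetention,
    MutuallyExclusive,
    MeFirstExon,
    FivePrimeExtension,
    CrypticDonorUtr,
]


@dataclass
class LocusSpec:
    seed: int = 0
    n_exons: int = 10
    exon_length: tuple[int, int] = (90, 150)
    intron_length: tuple[int, int] = (250, 450)
    cds_start_exon: int = 2
    utr5_in_start_exon: int = 60
    utr3_in_last_exon: int = 60
    features: tuple[Feature, ...] = ()
    tss_clusters: tuple[TssClusterSpec, ...] = ()
    tata: bool = False
    tss_jitter: int = 0
    upstream_pad: int = 300
    downstream_pad: int = 200
    exon_length_overrides: dict[int, int] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check planted features are mutually compatible; raise naming the
        violated constraint otherwise."""
        n, c = self.n_exons, self.cds_start_exon
        if not (1 <= c < n):
            raise ValueError(f"cds_start_exon {c} must lie in [1, n_exons)")
        if self.utr5_in_start_exon % 3 != 0:
            raise ValueError("utr5_in_start_exon must be a multiple of 3")
        acceptor_claims: dict[int, Feature] = {}
        donor_claims: dict[int, Feature] = {}
        exon_claims: dict[int, Feature] = {}
        intron_claims: dict[int, Feature] = {}

        def claim(table: dict, key: int, f: Feature, what: str) -> None:
            if key in table:
                raise ValueError(
                    f"incompatible features: {f} and {table[key]} both claim {what} {key}"
                )
            table[key] = f

        for f in self.features:
            if isinstance(f, Nagnag):
                if not (c < f.exon < n):
                    raise ValueError(f"{f}: NAGNAG exon must be coding-internal")
                claim(acceptor_claims, f.exon, f, "acceptor of exon")
            elif isinstance(f, AltAcceptor):
                if not (c < f.exon < n):
                    raise ValueError(f"{f}: acceptor-shift exon must be coding-internal")
                if f.offset >= 0 or f.offset % 3 != 0 or f.offset < -30:
                    raise ValueError(f"{f}: offset must be in {{-3,...,-30}}, multiple of 3")
                claim(acceptor_claims, f.exon, f, "acceptor of exon")
            elif isinstance(f, AltDonor):
                if not (c < f.exon < n - 1):
                    raise ValueError(f"{f}: donor-shift exon must be coding-internal")
                if f.offset >= 0 or f.offset % 3 != 0 or f.offset < -30:
                    raise ValueError(f"{f}: offset must be negative, multiple of 3, >= -30")
                claim(donor_claims, f.exon, f, "donor of exon")
            elif isinstance(f, DonorShiftWithSubstitution):
                if not (c < f.exon < n - 1):
                    raise ValueError(f"{f}: exon must be coding-internal")
                claim(donor_claims, f.exon, f, "donor of exon")
                claim(acceptor_claims, f.exon + 1, f, "acceptor of exon")
            elif isinstance(f, SkippedExons):
                if not f.exons or list(f.exons) != sorted(f.exons):
                    raise ValueError(f"{f}: exons must be sorted and non-empty")
                for e in f.exons:
                    if not (c < e < n):
                        raise ValueError(f"{f}: skipped exons must be coding-internal")
                    claim(exon_claims, e, f, "exon")
            elif isinstance(f, PartialRetention):
                if not (c <= f.intron < n):
                    raise ValueError(f"{f}: retention intron must be within the CDS")
                if f.retained % 3 == 0 or f.retained < 9:
                    raise ValueError(f"{f}: retained must be >= 9 and not a multiple of 3")
                claim(intron_claims, f.intron, f, "intron")
            elif isinstance(f, FullRetention):
                if not (c < f.first_exon < f.last_exon < n):
                    raise ValueError(f"{f}: bridged exons must be coding-internal, ordered")
                total_introns = f.last_exon - f.first_exon
                if f.retained_total is not None and f.retained_total < 12 * total_introns:
                    raise ValueError(f"{f}: retained_total too small for {total_introns} introns")
                for k in range(f.first_exon, f.last_exon):
                    claim(intron_claims, k, f, "intron")
                for e in range(f.first_exon, f.last_exon + 1):
                    claim(exon_claims, e, f, "exon")
            elif isinstance(f, MutuallyExclusive):
                if not (c < f.exon < n - 1):
                    raise ValueError(f"{f}: swapped exon must be coding-internal")
                if f.partner_length % 3 != 0 or f.partner_length < 9:
                    raise ValueError(f"{f}: partner_length must be >= 9, multiple of 3")
                claim(exon_claims, f.exon, f, "exon")
                claim(intron_claims, f.exon, f, "intron")
                # a swapped exon's boundaries must stay pristine or the
                # planted frame and flanking splice sites break
                claim(acceptor_claims, f.exon, f, "acceptor of exon")
                claim(donor_claims, f.exon, f, "donor of exon")
            elif isinstance(f, MeFirstExon):
                if not (1 <= f.intron < n - 1):
                    raise ValueError(f"{f}: intron index out of range")
                if f.n_unique < 2 or f.length < 3 * f.n_unique + 6:
                    raise ValueError(f"{f}: exon too short for {f.n_unique} planted codons")
                claim(intron_claims, f.intron, f, "intron")
            elif isinstance(f, FivePrimeExtension):
                if not (2 <= f.exon < n):
                    raise ValueError(f"{f}: extended exon must have an upstream intron")
                if f.n_unique < 2 or f.extension < 3 * f.n_unique + 6:
                    raise ValueError(f"{f}: extension too short for {f.n_unique} planted codons")
                claim(intron_claims, f.exon - 1, f, "intron")
            elif isinstance(f, CrypticDonorUtr):
                if c < 2:
                    raise ValueError(f"{f}: needs an untranslated first exon (cds_start_exon >= 2)")
                if f.offset < 12:
                    raise ValueError(f"{f}: offset must be >= 12")
                claim(intron_claims, 1, f, "intron")
            else:
                raise ValueError(f"unknown feature {f!r}")
        # a DonorShiftWithSubstitution moves the two exons off phase 0;
        # features that rely on codon-aligned boundaries cannot target them
        phase_shifted = set()
        for f in self.features:
            if isinstance(f, DonorShiftWithSubstitution):
                phase_shifted.update((f.exon, f.exon + 1))
        if phase_shifted:
            for f in self.features:
                needs_phase0: tuple[int, ...] = ()
                if isinstance(f, SkippedExons):
                    needs_phase0 = f.exons
                elif isinstance(f, MutuallyExclusive):
                    needs_phase0 = (f.exon,)
                elif isinstance(f, MeFirstExon):
                    needs_phase0 = (f.intron + 1,)
                elif isinstance(f, FivePrimeExtension):
                    needs_phase0 = (f.exon,)
                elif isinstance(f, (Nagnag, AltAcceptor)):
                    needs_phase0 = (f.exon,)
                elif isinstance(f, AltDonor):
                    needs_phase0 = (f.exon,)
                bad = phase_shifted.intersection(needs_phase0) - (
                    {f.exon, f.exon + 1} if isinstance(f, DonorShiftWithSubstitution) else set()
                )
                if bad:
                    raise ValueError(
                        f"incompatible features: {f} needs phase-0 boundaries on "
                        f"exon(s) {sorted(bad)} shifted by a DonorShiftWithSubstitution"
                    )
        # TSS clusters must be pairwise separated by more than the promoter
        # threshold so the declared grouping is the true partition
        flat = []
        for ci, cl in enumerate(self.tss_clusters):
            if not cl.offsets:
                raise ValueError("empty TSS cluster spec")
            flat.append((min(cl.offsets), max(cl.offsets), ci))
        flat.sort()
        for (_, hi, a), (lo, _, b) in zip(flat, flat[1:]):
            if lo - hi <= 500 + 2 * self.tss_jitter:
                raise ValueError(
                    f"TSS clusters {a} and {b} are not separated by more than 500 nt"
                )


# ---------------------------------------------------------------------------
# truth set


@dataclass
class TruthSet:
    """Ground-truth annotations for a generated locus (JSON-serialisable)."""

    reference_id: str
    ref_protein_length: int
    first_exon_calls: dict[str, dict] = field(default_factory=dict)
    events: dict[str, list[dict]] = field(default_factory=dict)
    consequences: dict[str, dict] = field(default_factory=dict)
    tss_clusters: list[dict] = field(default_factory=list)
    nagnag_acceptors: list[int] = field(default_factory=list)
    me_pairs: list[list[str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# generation machinery


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _scrub_atg(chars: list[str]) -> None:
    for i in range(len(chars) - 2):
        if chars[i] == "A" and chars[i + 1] == "T" and chars[i + 2] == "G":
            chars[i + 1] = "C"


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(CODONS), size=n)
    return "".join(CODONS[i] for i in idx)


def _plant_orf(
    rng: np.random.Generator, n_unique: int, avoid_last_aa: str, splice_ag_end: bool
) -> str:
    """ATG + (n_unique - 1) codons; the final codon's residue avoids
    ``avoid_last_aa`` (and ends in AG when it must double as an intron end)."""
    table = AG_CODONS if splice_ag_end else PLAIN_CODONS
    choices = [aa for aa in table if aa != avoid_last_aa]
    last = table[choices[int(rng.integers(0, len(choices)))]]
    middle = _rand_codons(rng, n_unique - 2)
    if splice_ag_end:
        # the penultimate codon must not recreate a NAGNAG hexamer at the
        # reference acceptor this plant abuts
        middle = middle[:-3] + "GAA" if n_unique >= 3 else middle
        if n_unique == 2:
            return "ATG" + last
    return "ATG" + middle + last


def _translate(nt: str) -> str:
    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


class _Builder:
    """Assembles one locus from a validated spec."""

    def __init__(self, spec: LocusSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.n = spec.n_exons
        self.c = spec.cds_start_exon

    # -- layout --------------------------------------------------------
    def _draw_len(self, lo: int, hi: int) -> int:
        v = int(self.rng.integers(lo, hi + 1))
        return v - v % 3

    def layout(self) -> None:
        sp, n, c = self.spec, self.n, self.c
        self.L = {k: self._draw_len(*sp.exon_length) for k in range(1, n + 1)}
        for k, v in sp.exon_length_overrides.items():
            self.L[k] = v - v % 3
        self.L[c] += sp.utr5_in_start_exon
        self.cds_in_last = self.L[n]
        self.L[n] += sp.utr3_in_last_exon
        # donor-substitution features need a phase-1 donor on exon k
        for f in sp.features:
            if isinstance(f, DonorShiftWithSubstitution):
                self.L[f.exon] += 1
                self.L[f.exon + 1] += 2
        self.I = {
            k: int(self.rng.integers(*sp.intron_length)) for k in range(1, n)
        }
        for f in sp.features:
            if isinstance(f, MeFirstExon):
                self.I[f.intron] = max(self.I[f.intron], 20 + f.length + 12)
            elif isinstance(f, MutuallyExclusive):
                self.I[f.exon] = max(self.I[f.exon], 30 + f.partner_length + 12)
            elif isinstance(f, PartialRetention):
                self.I[f.intron] = max(self.I[f.intron], f.retained + 12)
            elif isinstance(f, CrypticDonorUtr):
                self.I[1] = max(self.I[1], f.offset + 12)
            elif isinstance(f, FivePrimeExtension):
                self.I[f.exon - 1] = max(self.I[f.exon - 1], f.extension + 12)
            elif isinstance(f, FullRetention):
                cnt = f.last_exon - f.first_exon
                total = f.retained_total or sum(
                    self.I[k] for k in range(f.first_exon, f.last_exon)
                )
                if f.retained_total is None and total % 3 == 0:
                    total += 1  # keep the retention frame-disrupting
                base = total // cnt
                for i, k in enumerate(range(f.first_exon, f.last_exon)):
                    self.I[k] = base + (total - base * cnt if i == 0 else 0)
        # extension + ME-first sharing an intron with other plants is checked
        # at validate() via exclusive claims, so offsets cannot collide here
        self.estart, self.eend = {}, {}
        pos = sp.upstream_pad
        for k in range(1, n + 1):
            self.estart[k] = pos
            pos += self.L[k]
            self.eend[k] = pos
            if k < n:
                pos += self.I[k]
        self.contig_len = pos + sp.downstream_pad
        # CDS bookkeeping
        self.cds_nt_in_exon = {}
        for k in range(1, n + 1):
            if k < c:
                self.cds_nt_in_exon[k] = 0
            elif k == c:
                self.cds_nt_in_exon[k] = self.L[k] - sp.utr5_in_start_exon
            elif k < n:
                self.cds_nt_in_exon[k] = self.L[k]
            else:
                self.cds_nt_in_exon[k] = self.cds_in_last
        self.cds_total = sum(self.cds_nt_in_exon.values())
        assert self.cds_total % 3 == 0
        self.cds_gstart = self.estart[c] + sp.utr5_in_start_exon
        self.cds_gend = self.estart[n] + self.cds_in_last

    def cds_offset_at_exon_start(self, k: int) -> int:
        return sum(self.cds_nt_in_exon[j] for j in range(1, k))

    # -- sequence ------------------------------------------------------
    def sequences(self) -> None:
        rng, sp, n, c = self.rng, self.spec, self.n, self.c
        # coding sequence first: ATG + random codons + TAA, then codon plants
        n_codons = self.cds_total // 3
        cds = list("ATG" + _rand_codons(rng, n_codons - 2) + "TAA")
        ref_prot_design = _translate("".join(cds))[:-1]

        def put_cds(offset: int, s: str) -> None:
            cds[offset : offset + len(s)] = list(s)

        for f in sp.features:
            if isinstance(f, Nagnag):
                put_cds(self.cds_offset_at_exon_start(f.exon), "CAG")
            elif isinstance(f, AltAcceptor):
                # the shifted intron must still end in AG: the two exonic
                # bases just before the alternative acceptor
                put_cds(self.cds_offset_at_exon_start(f.exon) - f.offset - 2, "AG")
            elif isinstance(f, AltDonor):
                off = self.cds_offset_at_exon_start(f.exon) + self.cds_nt_in_exon[f.exon] + f.offset
                put_cds(off, "GT")
            elif isinstance(f, DonorShiftWithSubstitution):
                end = self.cds_offset_at_exon_start(f.exon) + self.cds_nt_in_exon[f.exon]
                put_cds(end - 7, "GGTAAAT")
                put_cds(end, "AC")
        # re-assert stop-free frame after raw plants
        for i in range(0, self.cds_total - 3, 3):
            codon = "".join(cds[i : i + 3])
            if codon in STOP_CODONS:
                cds[i] = "C"
        self.ref_protein = _translate("".join(cds))[:-1]
        assert "*" not in self.ref_protein and len(self.ref_protein) == n_codons - 1
        cds = "".join(cds)

        # exon sequences
        self.exon_seq: dict[int, list[str]] = {}
        for k in range(1, n + 1):
            if k < c:
                chars = _rand_seq(rng, self.L[k])
                _scrub_atg(chars)
                chars[0] = "C"
                chars[-1] = "C"
                self.exon_seq[k] = chars
            elif k == c:
                utr = _rand_seq(rng, sp.utr5_in_start_exon)
                _scrub_atg(utr)
                if utr:
                    utr[0] = "C"
                    utr[-1] = "C"
                body = cds[: self.cds_nt_in_exon[k]]
                self.exon_seq[k] = utr + list(body)
            elif k < n:
                off = self.cds_offset_at_exon_start(k)
                self.exon_seq[k] = list(cds[off : off + self.cds_nt_in_exon[k]])
            else:
                off = self.cds_offset_at_exon_start(k)
                utr3 = _rand_seq(rng, sp.utr3_in_last_exon)
                _scrub_atg(utr3)
                if utr3:
                    utr3[0] = "C"
                self.exon_seq[k] = list(cds[off:]) + utr3

        # intron sequences: GT ... AG, ATG-scrubbed, NAGNAG-scrubbed
        self.intron_seq: dict[int, list[str]] = {}
        for k in range(1, n):
            chars = _rand_seq(rng, self.I[k])
            _scrub_atg(chars)
            chars[0], chars[1] = "G", "T"
            chars[-2], chars[-1] = "A", "G"
            chars[-5], chars[-4] = "T", "T"
            self.intron_seq[k] = chars

    # -- feature plants and alternative transcripts ---------------------
    def build_alternatives(self) -> None:
        rng, sp, n, c = self.rng, self.spec, self.n, self.c
        E = {k: (self.estart[k], self.eend[k]) for k in range(1, n + 1)}
        self.alts: list[TranscriptModel] = []
        self.truth_first: dict[str, dict] = {}
        self.truth_events: dict[str, list[dict]] = {}
        self.truth_cons: dict[str, dict] = {}
        self.nagnag_sites: list[int] = []
        self.me_labels: dict[int, tuple[str, str]] = {}
        self.exon_labels = {k: str(k) for k in range(1, n + 1)}
        contig = "locus1"

        def base_exons(skip: set[int] | None = None) -> list[tuple[int, int]]:
            return [E[k] for k in range(1, n + 1) if not skip or k not in skip]

        def add(tid: str, exons, first: dict, events: list[dict], cons: dict, **kw) -> None:
            labels = kw.pop("labels", None)
            self.alts.append(
                make_transcript(tid, contig, exons, source="synthetic", labels=labels, **kw)
            )
            self.truth_first[tid] = first
            self.truth_events[tid] = events
            self.truth_cons[tid] = cons

        canonical = {"class": "canonical", "anchor": 1, "retained_nt": 0}
        for f in sp.features:
            if isinstance(f, Nagnag):
                k = f.exon
                tid = f"alt_nagnag_e{k}"
                exons = base_exons()
                exons[k - 1] = (E[k][0] + 3, E[k][1])
                self.nagnag_sites.append(E[k][0] + 3)
                add(
                    tid, exons, canonical,
                    [{"kind": "alt_acceptor", "ref_exons": [k], "delta_nt": -3, "nagnag": True}],
                    {"category": "inframe_deletion", "deleted": 1, "inserted": 0, "n_subs": 0},
                )
            elif isinstance(f, AltAcceptor):
                k = f.exon
                tid = f"alt_acceptor_e{k}"
                exons = base_exons()
                exons[k - 1] = (E[k][0] - f.offset, E[k][1])
                add(
                    tid, exons, canonical,
                    [{"kind": "alt_acceptor", "ref_exons": [k], "delta_nt": f.offset}],
                    {"category": "inframe_deletion", "deleted": -f.offset // 3, "inserted": 0, "n_subs": 0},
                )
            elif isinstance(f, AltDonor):
                k = f.exon
                tid = f"alt_donor_e{k}"
                exons = base_exons()
                exons[k - 1] = (E[k][0], E[k][1] + f.offset)
                add(
                    tid, exons, canonical,
                    [{"kind": "alt_donor", "ref_exons": [k], "delta_nt": f.offset}],
                    {"category": "inframe_deletion", "deleted": -f.offset // 3, "inserted": 0, "n_subs": 0},
                )
            elif isinstance(f, DonorShiftWithSubstitution):
                k = f.exon
                tid = f"alt_donor_subst_e{k}"
                exons = base_exons()
                exons[k - 1] = (E[k][0], E[k][1] - 6)
                add(
                    tid, exons, canonical,
                    [{"kind": "alt_donor", "ref_exons": [k], "delta_nt": -6}],
                    {
                        "category": "inframe_deletion_with_substitution",
                        "deleted": 2, "inserted": 0, "n_subs": 1,
                        "substitutions": [["Y", "D"]],
                    },
                )
            elif isinstance(f, SkippedExons):
                tid = "alt_skip_" + "_".join(map(str, f.exons))
                deleted_nt = sum(self.L[e] for e in f.exons)
                add(
                    tid, base_exons(set(f.exons)), canonical,
                    [{"kind": "skipped_exon", "ref_exons": list(f.exons), "delta_nt": -deleted_nt}],
                    {"category": "inframe_deletion", "deleted": deleted_nt // 3, "inserted": 0, "n_subs": 0},
                )
            elif isinstance(f, PartialRetention):
                k, r = f.intron, f.retained
                tid = f"alt_retention_i{k}"
                seqI = self.intron_seq[k]
                seqI[r], seqI[r + 1] = "G", "T"  # donor of the shortened intron
                seqI[3], seqI[4], seqI[5] = "T", "A", "A"  # in-frame PTC
                exons = base_exons()
                exons[k - 1] = (E[k][0], E[k][1] + r)
                ptc = sum(self.L[j] for j in range(1, k + 1)) + 3
                last_junction = (
                    sum(self.L[j] for j in range(1, n)) + r
                )  # alt spliced position of the last junction
                add(
                    tid, exons, canonical,
                    [{"kind": "intron_retention", "ref_exons": [k], "delta_nt": r}],
                    {
                        "category": "frameshift_ptc",
                        "nmd_candidate": (last_junction - ptc) > 50,
                    },
                )
            elif isinstance(f, FullRetention):
                a, b = f.first_exon, f.last_exon
                tid = f"alt_retention_e{a}_{b}"
                retained = sum(self.I[k] for k in range(a, b))
                seqI = self.intron_seq[a]
                seqI[3], seqI[4], seqI[5] = "T", "A", "A"
                exons = [E[k] for k in range(1, a)] + [(E[a][0], E[b][1])] + [
                    E[k] for k in range(b + 1, n + 1)
                ]
                ptc = sum(self.L[j] for j in range(1, a + 1)) + 3
                last_junction = sum(self.L[j] for j in range(1, n)) + retained
                add(
                    tid, exons, canonical,
                    [{
                        "kind": "intron_retention",
                        "ref_exons": list(range(a, b + 1)),
                        "delta_nt": retained,
                    }],
                    {
                        "category": "frameshift_ptc",
                        "nmd_candidate": (last_junction - ptc) > 50,
                    },
                )
            elif isinstance(f, MutuallyExclusive):
                k, P = f.exon, f.partner_length
                tid = f"alt_me_e{k}"
                seqI = self.intron_seq[k]
                p_off = 30
                # partner exon carved inside intron k with its own AG/GT flanks
                m = self.cds_nt_in_exon[k] // 3
                q = P // 3
                exon_aas = self.ref_protein[
                    self.cds_offset_at_exon_start(k) // 3 :
                ][:m]
                partner = list(_rand_codons(rng, q))
                # force every aligned residue pair (and the prefix boundary)
                # to differ so the planted category and counts are exact:
                # the swap reads as deletion/insertion of |m - q| residues
                # plus min(m, q) substitutions
                for i in range(q):
                    avoid = set()
                    if i == 0:
                        avoid.add(exon_aas[0])
                    if q <= m:
                        avoid.add(exon_aas[m - q + i])
                    elif i >= q - m:
                        avoid.add(exon_aas[i - (q - m)])
                    codon = "".join(partner[3 * i : 3 * i + 3])
                    if _translate(codon) in avoid:
                        pick = int(rng.integers(0, len(CODONS)))
                        for step in range(len(CODONS)):
                            cand = CODONS[(pick + step) % len(CODONS)]
                            if _translate(cand) not in avoid:
                                codon = cand
                                break
                        partner[3 * i : 3 * i + 3] = list(codon)
                seqI[p_off - 2 : p_off] = ["A", "G"]
                seqI[p_off : p_off + P] = partner
                seqI[p_off + P : p_off + P + 2] = ["G", "T"]
                p_start = self.eend[k] + p_off
                exons = base_exons()
                exons[k - 1] = (p_start, p_start + P)
                self.exon_labels[k] = f"{k}a"
                self.me_labels[k] = (f"{k}a", f"{k}b")
                labels = [
                    f"{k}b" if j == k - 1 else self.exon_labels.get(j + 1, "")
                    for j in range(n)
                ]
                deleted = max(0, m - q)
                inserted = max(0, q - m)
                add(
                    tid, exons, canonical,
                    [{
                        "kind": "mutually_exclusive_pair",
                        "ref_exons": [k],
                        "delta_nt": P - self.cds_nt_in_exon[k],
                    }],
                    {
                        "category": (
                            "inframe_deletion_with_substitution" if m > q
                            else "inframe_insertion" if q > m
                            else "inframe_substitution"
                        ),
                        "deleted": deleted, "inserted": inserted, "n_subs": min(m, q),
                    },
                    labels=labels,
                )
            elif isinstance(f, MeFirstExon):
                k = f.intron
                tid = f"alt_me_first_i{k}"
                seqI = self.intron_seq[k]
                fe_off = 20
                fe = (self.eend[k] + fe_off, self.eend[k] + fe_off + f.length)
                seqI[fe_off + f.length], seqI[fe_off + f.length + 1] = "G", "T"
                exons = [fe] + [E[j] for j in range(k + 1, n + 1)]
                first = {"class": "mutually_exclusive_first", "anchor": k + 1, "retained_nt": 0}
                if k >= c:
                    missing = self.cds_offset_at_exon_start(k + 1) // 3
                    orf = self._planted_orf(f.n_unique, missing, splice_ag_end=False)
                    seqI[fe_off + f.length - len(orf) : fe_off + f.length] = list(orf)
                    cons = self._trunc_cons(f.n_unique, missing)
                else:
                    cons = {"category": "silent_utr"}
                add(tid, exons, first, [], cons)
            elif isinstance(f, FivePrimeExtension):
                k = f.exon
                tid = f"alt_ext_e{k}"
                seqI = self.intron_seq[k - 1]
                fe = (self.estart[k] - f.extension, E[k][1])
                exons = [fe] + [E[j] for j in range(k + 1, n + 1)]
                first = {"class": "five_prime_extension", "anchor": k, "retained_nt": 0}
                if k > c:
                    missing = self.cds_offset_at_exon_start(k) // 3
                    orf = self._planted_orf(f.n_unique, missing, splice_ag_end=True)
                    seqI[len(seqI) - len(orf) :] = list(orf)
                    cons = self._trunc_cons(f.n_unique, missing)
                else:
                    cons = {"category": "silent_utr"}
                add(tid, exons, first, [], cons)
            elif isinstance(f, CrypticDonorUtr):
                tid = "alt_cryptic_donor_e1"
                seqI = self.intron_seq[1]
                seqI[f.offset], seqI[f.offset + 1] = "G", "T"
                exons = base_exons()
                exons[0] = (E[1][0], E[1][1] + f.offset)
                add(
                    tid, exons, canonical,
                    [{"kind": "cryptic_donor_utr", "ref_exons": [1], "delta_nt": f.offset}],
                    {"category": "silent_utr"},
                )

    def _planted_orf(self, n_unique: int, missing: int, splice_ag_end: bool) -> str:
        avoid = self.ref_protein[missing - 1]
        return _plant_orf(self.rng, n_unique, avoid, splice_ag_end)

    def _trunc_cons(self, n_unique: int, missing: int) -> dict:
        shared = len(self.ref_protein) - missing
        return {
            "category": "n_terminal_truncation",
            "truncation": {
                "unique_n": n_unique,
                "missing_n": missing,
                "shared_suffix": shared,
            },
            "predicted_length": len(self.ref_protein) - missing + n_unique,
        }

    # -- promoter evidence ----------------------------------------------
    def build_evidence(self) -> None:
        sp, rng = self.spec, self.rng
        self.evidence: list[FivePrimeEvidence] = []
        self.truth_tss: list[dict] = []
        sources = ["RACE", "RNASeq", "RefSeq"]
        tss0 = self.estart[1]
        self.tata_pos: Optional[int] = None
        for ci, cl in enumerate(sp.tss_clusters):
            positions = []
            for i, off in enumerate(cl.offsets):
                pos = tss0 + off
                if sp.tss_jitter:
                    pos += int(rng.integers(-sp.tss_jitter, sp.tss_jitter + 1))
                positions.append(pos)
                self.evidence.append(
                    FivePrimeEvidence(pos, "+", sources[i % len(sources)])
                )
            width = max(positions) - min(positions)
            self.truth_tss.append(
                {
                    "size": len(positions),
                    "width": width,
                    "shape": "sharp" if width <= 62 else "broad",
                    "tata": bool(sp.tata and ci == 0),
                }
            )
            if sp.tata and ci == 0:
                self.tata_pos = min(positions) - 30

    # -- assembly and confounder scrubbing -------------------------------
    def assemble(self) -> GeneLocus:
        sp, n = self.spec, self.n
        parts = []
        pad0 = _rand_seq(self.rng, sp.upstream_pad)
        _scrub_atg(pad0)
        parts.append(pad0)
        for k in range(1, n + 1):
            parts.append(self.exon_seq[k])
            if k < n:
                parts.append(self.intron_seq[k])
        pad1 = _rand_seq(self.rng, sp.downstream_pad)
        parts.append(pad1)
        chars = [ch for p in parts for ch in p]

        # TATA handling: plant the box, then remove accidental consensus
        # matches from every scanned window outside protected regions
        protected = [(self.cds_gstart, self.cds_gend)]
        if self.tata_pos is not None:
            chars[self.tata_pos : self.tata_pos + 8] = list("TATAAAAG")
            protected.append((self.tata_pos, self.tata_pos + 8))

        def is_protected(i: int) -> bool:
            return any(a <= i < b for a, b in protected)

        import re

        tata_re = re.compile("TATA[AT]A[AT][AG]")
        # remove accidental consensus matches from every scanned window
        # (conservatively: a window around each evidence position, not only
        # the representative); mutating a motif base to C can never create a
        # new match, so the rescan loop terminates
        for ev in self.evidence:
            lo = max(0, ev.position - 40)
            hi = max(0, ev.position - 20)
            changed = True
            while changed:
                changed = False
                window = "".join(chars[lo : hi + 8])
                for m in tata_re.finditer(window):
                    g = lo + m.start()
                    if self.tata_pos is not None and g == self.tata_pos:
                        continue
                    for off in range(8):
                        if not is_protected(g + off):
                            chars[g + off] = "C"
                            changed = True
                            break
                    if changed:
                        break

        sequence = "".join(chars)
        contig = "locus1"
        ref = make_transcript(
            "ref",
            contig,
            [(self.estart[k], self.eend[k]) for k in range(1, n + 1)],
            cds=(self.cds_gstart, self.cds_gend),
            source="synthetic",
            labels=[self.exon_labels[k] for k in range(1, n + 1)],
        )
        return GeneLocus(contig, sequence, ref, self.alts, self.evidence)


def generate_locus(spec: LocusSpec) -> tuple[GeneLocus, TruthSet]:
    """Generate a locus and its truth set; deterministic in ``spec.seed``."""
    spec.validate()
    b = _Builder(spec)
    b.layout()
    b.sequences()
    b.build_alternatives()
    b.build_evidence()
    locus = b.assemble()
    truth = TruthSet(
        reference_id="ref",
        ref_protein_length=len(b.ref_protein),
        first_exon_calls=b.truth_first,
        events=b.truth_events,
        consequences=b.truth_cons,
        tss_clusters=b.truth_tss,
        nagnag_acceptors=b.nagnag_sites,
        me_pairs=[list(v) for v in b.me_labels.values()],
    )
    _back_check(locus, truth)
    return locus, truth


def _back_check(locus: GeneLocus, truth: TruthSet) -> None:
    """Verify planted coding consequences by direct translation."""
    from .models import spliced_sequence

    ref_mrna = spliced_sequence(locus, locus.reference)
    a, bnd = locus.reference.cds_spliced_span()
    prot = _translate(ref_mrna[a:bnd])
    if not prot.endswith("*") or "*" in prot[:-1]:
        raise AssertionError("generated reference ORF is malformed")
    if len(prot) - 1 != truth.ref_protein_length:
        raise AssertionError("reference protein length does not match design")
    for t in locus.alternatives:
        mrna = spliced_sequence(locus, t)
        start = t.genomic_to_spliced(locus.reference.cds[0])
        if start is None:
            start = mrna.find("ATG")
        body = mrna[start:]
        p = _translate(body)
        stop = p.find("*")
        cons = truth.consequences[t.id]
        if cons["category"] == "frameshift_ptc" and stop == -1:
            raise AssertionError(f"{t.id}: planted PTC missing")
        if cons["category"] in ("silent_utr",) and p[:stop] != prot[:-1]:
            raise AssertionError(f"{t.id}: planted silent event changed the protein")


# ---------------------------------------------------------------------------
# presets and random specs


def preset_auts2a_like(seed: int = 0) -> LocusSpec:
    """A 19-exon locus with the headline architecture of a large, promoter-
    rich vertebrate gene: an untranslated first exon, five mutually
    exclusive first exons, six 5'-extension first exons, NAGNAG tandem
    acceptors at exons 3/8/15, a -21 nt donor at exon 9, a 38-nt partial
    retention of intron 15 and a 745-nt full retention bridging exons 12-14,
    a cryptic +132 nt 5'-UTR donor, and two TSS clusters (one sharp with a
    TATA box, one broad)."""
    return LocusSpec(
        seed=seed,
        n_exons=19,
        cds_start_exon=2,
        exon_length_overrides={1: 1200},
        features=(
            MeFirstExon(intron=2),
            MeFirstExon(intron=3),
            MeFirstExon(intron=4),
            MeFirstExon(intron=5),
            MeFirstExon(intron=6),
            FivePrimeExtension(exon=8),
            FivePrimeExtension(exon=9),
            FivePrimeExtension(exon=10),
            FivePrimeExtension(exon=11),
            FivePrimeExtension(exon=15),
            FivePrimeExtension(exon=17),
            Nagnag(exon=3),
            Nagnag(exon=8),
            Nagnag(exon=15),
            AltDonor(exon=9, offset=-21),
            PartialRetention(intron=15, retained=38),
            FullRetention(first_exon=12, last_exon=14, retained_total=745),
            CrypticDonorUtr(offset=132),
        ),
        tss_clusters=(
            TssClusterSpec(offsets=(0, 10, 25, 40, 58)),
            TssClusterSpec(offsets=(700, 800, 900, 1000)),
        ),
        tata=True,
    )


def random_spec(seed: int) -> LocusSpec:
    """Draw a random compatible feature set (used for round-trip testing)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 13))
    c = 2
    free_acceptors = set(range(c + 1, n))
    free_donors = set(range(c + 1, n - 1))
    free_exons = set(range(c + 1, n))
    free_introns = set(range(1, n - 1))
    used_phase: set[int] = set()  # exons whose phase-0 boundary another feature relies on
    shifted: set[int] = set()  # exons moved off phase 0 by a donor substitution
    features: list[Feature] = []

    def take(pool: set[int]) -> Optional[int]:
        avail = sorted(pool)
        if not avail:
            return None
        k = avail[int(rng.integers(0, len(avail)))]
        return k

    kinds = list(range(9))
    rng.shuffle(kinds)
    n_feat = int(rng.integers(2, 6))
    for kind in kinds[:n_feat]:
        if kind == 0:  # NAGNAG
            k = take((free_acceptors & free_exons) - shifted)
            if k is None:
                continue
            free_acceptors.discard(k)
            used_phase.add(k)
            features.append(Nagnag(exon=k))
        elif kind == 1:  # alt donor
            k = take(free_donors - shifted)
            if k is None:
                continue
            free_donors.discard(k)
            used_phase.add(k)
            features.append(AltDonor(exon=k, offset=int(rng.choice([-21, -9, -12]))))
        elif kind == 2:  # alt acceptor
            k = take(free_acceptors - shifted)
            if k is None:
                continue
            free_acceptors.discard(k)
            used_phase.add(k)
            features.append(AltAcceptor(exon=k, offset=int(rng.choice([-15, -9]))))
        elif kind == 3:  # donor shift with substitution
            k = take(
                {
                    x
                    for x in free_donors
                    if x + 1 in free_acceptors
                    and x not in used_phase
                    and x + 1 not in used_phase
                }
            )
            if k is None:
                continue
            free_donors.discard(k)
            free_acceptors.discard(k + 1)
            shifted.update((k, k + 1))
            features.append(DonorShiftWithSubstitution(exon=k))
        elif kind == 4:  # skipped run
            k = take(
                {x for x in free_exons - shifted if x + 1 in free_exons - shifted and x + 1 < n}
            )
            if k is not None and bool(rng.integers(0, 2)):
                free_exons -= {k, k + 1}
                used_phase.update((k, k + 1))
                features.append(SkippedExons(exons=(k, k + 1)))
            else:
                k = take(free_exons - shifted)
                if k is None:
                    continue
                free_exons.discard(k)
                used_phase.add(k)
                features.append(SkippedExons(exons=(k,)))
        elif kind == 5:  # partial retention
            k = take({x for x in free_introns if x >= c})
            if k is None:
                continue
            free_introns.discard(k)
            r = int(rng.choice([38, 106, 25]))
            features.append(PartialRetention(intron=k, retained=r))
        elif kind == 6:  # mutually exclusive internal pair
            k = take(
                {
                    x
                    for x in free_exons - shifted
                    if x < n - 1
                    and x in free_introns
                    and x in free_acceptors
                    and x in free_donors
                }
            )
            if k is None:
                continue
            free_exons.discard(k)
            free_introns.discard(k)
            free_acceptors.discard(k)
            free_donors.discard(k)
            used_phase.add(k)
            features.append(MutuallyExclusive(exon=k, partner_length=int(rng.choice([30, 60, 90]))))
        elif kind == 7:  # mutually exclusive first exon
            k = take({x for x in free_introns if x < n - 1 and x + 1 not in shifted})
            if k is None:
                continue
            free_introns.discard(k)
            used_phase.add(k + 1)
            features.append(MeFirstExon(intron=k))
        elif kind == 8:  # 5' extension first exon
            k = take(
                {
                    x
                    for x in (free_exons | {c}) - shifted
                    if x >= 2 and (x - 1) in free_introns
                }
            )
            if k is None:
                continue
            free_introns.discard(k - 1)
            used_phase.add(k)
            features.append(FivePrimeExtension(exon=k))
    offsets = tuple(sorted(int(x) for x in rng.integers(-260, -200, size=int(rng.integers(2, 6)))))
    return LocusSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_exons=n,
        cds_start_exon=c,
        features=tuple(features),
        tss_clusters=(TssClusterSpec(offsets=offsets),),
        tata=bool(rng.integers(0, 2)),
    )


# ---------------------------------------------------------------------------
# on-disk output


def write_locus_dir(locus: GeneLocus, truth: TruthSet, outdir: str | Path) -> None:
    """Emit locus.fa, models.gff3, evidence.bed, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_fasta(outdir / "locus.fa", {locus.contig_id: locus.sequence})
    sio.write_gene_models(locus, outdir / "models.gff3")
    sio.write_evidence_bed(locus.evidence, outdir / "evidence.bed", locus.contig_id)
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
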