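"""Splice-event diffing and NAGNAG detection."""

import itertools
import re

import pytest

from spliceatlas import (
    detect_nagnag,
    diff_transcripts,
    generate_locus,
    make_transcript,
    pair_mutually_exclusive,
    random_spec,
)
from spliceatlas.events import (
    KIND_ALT_ACCEPTOR,
    KIND_ALT_DONOR,
    KIND_CRYPTIC_UTR,
    KIND_ME_PAIR,
    KIND_RETENTION,
    KIND_SKIPPED,
)
from conftest import build_locus

REF_EXONS = [(200 * k, 200 * k + 100) for k in range(1, 9)]
REF = make_transcript("ref", "c", REF_EXONS, cds=(230, 1550))


def _alt(exons, tid="alt"):
    return make_transcript(tid, "c", exons)


class TestDiff:
    def test_identical_structures_give_empty_diff(self):
        assert diff_transcripts(REF, REF) == []

    def test_single_skipped_exon(self):
        alt = _alt(REF_EXONS[:5] + REF_EXONS[6:])
        (ev,) = diff_transcripts(alt, REF)
        assert ev.kind == KIND_SKIPPED
        assert ev.ref_exons == (6,)
        assert ev.delta_nt == -100

    def test_adjacent_skipped_exons_are_one_event(self):
        # two exons spliced out together: one event, two ordinals
        alt = _alt(REF_EXONS[:5] + REF_EXONS[7:])
        (ev,) = diff_transcripts(alt, REF)
        assert ev.kind == KIND_SKIPPED
        assert ev.ref_exons == (6, 7)
        assert ev.delta_nt == -200

    def test_donor_shift_into_exon(self):
        alt = _alt(REF_EXONS[:3] + [(800, 879)] + REF_EXONS[4:])
        (ev,) = diff_transcripts(alt, REF)
        assert ev.kind == KIND_ALT_DONOR
        assert ev.ref_exons == (4,)
        assert ev.delta_nt == -21

    def test_acceptor_shift(self):
        alt = _alt(REF_EXONS[:2] + [(603, 700)] + REF_EXONS[3:])
        (ev,) = diff_transcripts(alt, REF)
        assert ev.kind == KIND_ALT_ACCEPTOR
        assert ev.delta_nt == -3

    def test_donor_extension_in_utr_is_cryptic_donor(self):
        # CDS starts in exon 2; exon 1's donor moves 132 nt into intron 1
        ref = make_transcript(
            "ref", "c", [(200, 300), (600, 700), (900, 1000)], cds=(630, 980)
        )
        alt = _alt([(200, 432), (600, 700), (900, 1000)])
        (ev,) = diff_transcripts(alt, ref)
        assert ev.kind == KIND_CRYPTIC_UTR
        assert ev.delta_nt == 132

    def test_donor_extension_in_cds_is_partial_retention(self):
        alt = _alt(REF_EXONS[:3] + [(800, 938)] + REF_EXONS[4:])
        (ev,) = diff_transcripts(alt, REF)
        assert ev.kind == KIND_RETENTION
        assert ev.delta_nt == 38

    def test_exon_bridging_retention_records_subsumed_exons(self):
        # one exon spans exons 4-6, retaining introns 4 and 5 (100 nt each)
        alt = _alt(REF_EXONS[:3] + [(800, 1300)] + REF_EXONS[6:])
        (ev,) = diff_transcripts(alt, REF)
        assert ev.kind == KIND_RETENTION
        assert ev.ref_exons == (4, 5, 6)
        assert ev.subsumed_exons == (5,)
        assert ev.delta_nt == 200

    def test_mutually_exclusive_swap(self):
        # exon 5 replaced by a disjoint exon in intron 5
        alt = _alt(REF_EXONS[:4] + [(1120, 1180)] + REF_EXONS[5:])
        (ev,) = diff_transcripts(alt, REF)
        assert ev.kind == KIND_ME_PAIR
        assert ev.ref_exons == (5,)
        assert ev.delta_nt == -40

    def test_events_sorted_5prime_to_3prime_and_deltas_balance(self):
        # -3 acceptor on exon 3, -21 donor on exon 4, skipped exon 6
        alt = _alt(REF_EXONS[:2] + [(603, 700), (800, 879)] + REF_EXONS[4:5] + REF_EXONS[6:])
        events = diff_transcripts(alt, REF)
        assert [e.kind for e in events] == [KIND_ALT_ACCEPTOR, KIND_ALT_DONOR, KIND_SKIPPED]
        assert [e.coords.start for e in events] == sorted(e.coords.start for e in events)
        assert sum(e.delta_nt for e in events) == alt.spliced_length - REF.spliced_length

    def test_diff_invariant_under_genomic_offset(self):
        shift = 5000
        ref2 = make_transcript(
            "ref", "c", [(s + shift, e + shift) for s, e in REF_EXONS],
            cds=(230 + shift, 1550 + shift),
        )
        alt = _alt(REF_EXONS[:5] + REF_EXONS[6:])
        alt2 = _alt([(s + shift, e + shift) for s, e in (REF_EXONS[:5] + REF_EXONS[6:])])
        ev1 = diff_transcripts(alt, REF)
        ev2 = diff_transcripts(alt2, ref2)
        assert [(e.kind, e.ref_exons, e.delta_nt) for e in ev1] == [
            (e.kind, e.ref_exons, e.delta_nt) for e in ev2
        ]

    @pytest.mark.parametrize("seed", range(30))
    def test_simulated_events_recovered_exactly(self, seed):
        locus, truth = generate_locus(random_spec(seed))
        for t in locus.alternatives:
            events = diff_transcripts(t, locus.reference, locus)
            got = [
                {"kind": e.kind, "ref_exons": list(e.ref_exons), "delta_nt": e.delta_nt}
                for e in events
            ]
            want = [
                {k: v for k, v in ev.items() if k != "nagnag"}
                for ev in truth.events[t.id]
            ]
            assert got == want
            # conservation over the compared region holds for every diff
            # (asserted internally by diff_transcripts; re-check totals here)
            assert sum(e.delta_nt for e in events) == sum(
                ev["delta_nt"] for ev in truth.events[t.id]
            )


class TestNagnag:
    def test_intron_ending_in_tandem_ag(self):
        seq = "A" * 94 + "TTCAGCAG" + "C" * 98  # exon starts at 102
        locus = build_locus([(0, 50), (102, 150)], sequence=seq, cds=(0, 50))
        site = detect_nagnag(locus, 102)
        assert site is not None
        assert site.distal_ag - site.proximal_ag == 3
        assert site.hexamer == "CAGCAG"

    def test_plain_acceptor_is_not_nagnag(self):
        seq = "A" * 94 + "TTTTCAGC" + "C" * 98
        locus = build_locus([(0, 50), (103, 150)], sequence=seq, cds=(0, 50))
        assert detect_nagnag(locus, 101) is None

    def test_acceptor_too_close_to_contig_start(self):
        locus = build_locus([(0, 20), (40, 60)], sequence="A" * 110, cds=(0, 20))
        assert detect_nagnag(locus, 3) is None

    def test_all_4096_hexamers_against_brute_force_oracle(self):
        pattern = re.compile(".AG.AG")
        for hexamer in map("".join, itertools.product("ACGT", repeat=6)):
            seq = "C" * 50 + hexamer + "G" * 60
            locus = build_locus([(0, 30), (56, 100)], sequence=seq, cds=(0, 30))
            got = detect_nagnag(locus, 56)
            assert (got is not None) == bool(pattern.fullmatch(hexamer))


class TestMePairs:
    def test_planted_pair_recovered(self):
        ref = make_transcript(
            "ref", "c", REF_EXONS, cds=(230, 1550),
            labels=["1", "2", "3", "4", "5a", "6", "7", "8"],
        )
        alt = make_transcript(
            "i1b", "c", REF_EXONS[:4] + [(1120, 1180)] + REF_EXONS[5:],
            labels=["1", "2", "3", "4", "5b", "6", "7", "8"],
        )
        pairs = pair_mutually_exclusive([ref, alt], ref)
        assert [(p.a_label, p.b_label) for p in pairs] == [("5a", "5b")]

    def test_all_shared_internal_exons_give_no_pairs(self):
        alt = _alt(REF_EXONS[1:])  # different first exon, same internals
        assert pair_mutually_exclusive([REF, alt], REF) == []

    def test_boundary_variant_of_partner_does_not_create_extra_pair(self):
        # a donor-shifted variant of exon 5b overlaps 5b: still one pair
        ref = make_transcript(
            "ref", "c", REF_EXONS, cds=(230, 1550),
            labels=["1", "2", "3", "4", "5a", "6", "7", "8"],
        )
        alt1 = make_transcript(
            "i1b", "c", REF_EXONS[:4] + [(1120, 1180)] + REF_EXONS[5:],
            labels=["", "", "", "", "5b", "", "", ""],
        )
        alt2 = make_transcript(
            "i1c", "c", REF_EXONS[:4] + [(1120, 1159)] + REF_EXONS[5:],
        )
        pairs = pair_mutually_exclusive([ref, alt1, alt2], ref)
        assert [(p.a_label, p.b_label) for p in pairs] == [("5a", "5b")]

    def test_two_planted_pairs_no_false_pairs(self):
        locus, truth = generate_locus(random_spec(5))
        pairs = pair_mutually_exclusive(locus.transcripts, locus.reference)
        got = sorted(tuple(sorted((p.a_label, p.b_label))) for p in pairs)
        want = sorted(tuple(sorted(p)) for p in truth.me_pairs)
        assert got == want
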