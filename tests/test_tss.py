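"""Putative TSS calling, promoter clustering, shape, TATA, exonic flags."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceatlas import FivePrimeEvidence, cluster_tss, classify_shape, scan_tata
from spliceatlas.tss import (
    CTX_ANNOTATED,
    CTX_INTERNAL,
    CTX_INTERNAL_ATG,
    CTX_INTRONIC,
    STATUS_REJECTED,
    CandidateTss,
    TssCluster,
    call_candidate_tss,
    flag_exonic_tss,
)
from conftest import build_locus


def _cands(positions):
    return [CandidateTss(p, "RACE", "accepted", CTX_INTRONIC) for p in positions]


def _locus_with_evidence(positions, sequence=None):
    # reference: exon1 600-800, exon2 (coding) 1400-1700, exon3 2500-2700
    return build_locus(
        [(600, 800), (1400, 1700), (2500, 2700)],
        sequence=sequence,
        cds=(1450, 2600),
        evidence=[FivePrimeEvidence(p, "+", "RNASeq") for p in positions],
    )


class TestCandidateCalling:
    def test_annotated_start_is_canonical(self):
        locus = _locus_with_evidence([600])
        (c,) = call_candidate_tss(locus)
        assert c.context == CTX_ANNOTATED and c.status == "canonical"

    def test_intronic_start_accepted_as_putative_tss(self):
        locus = _locus_with_evidence([1000])
        (c,) = call_candidate_tss(locus)
        assert c.context == CTX_INTRONIC and c.status == "accepted"

    def test_internal_exonic_start_accepted_unless_at_atg(self):
        seq = list("C" * 3000)
        seq[1500:1503] = "ATG"
        locus = _locus_with_evidence([1500, 1600], sequence="".join(seq))
        at_atg, plain = call_candidate_tss(locus)
        assert at_atg.context == CTX_INTERNAL_ATG and at_atg.status == STATUS_REJECTED
        assert plain.context == CTX_INTERNAL and plain.status == "accepted"
        # the rejected truncation suspect never enters a cluster
        clusters = cluster_tss([at_atg, plain])
        assert sum(len(c) for c in clusters) == 1


class TestClustering:
    def test_two_groups_separated_by_593(self):
        # five 5' ends in one group, two in the other, nearest gap 593 nt
        positions = [1000, 1010, 1025, 1040, 1058, 1651, 1655]
        clusters = cluster_tss(_cands(positions), separation_threshold=500)
        assert sorted(len(c) for c in clusters) == [2, 5]
        assert len(clusters) == 2

    def test_single_position_single_cluster_width_zero(self):
        (c,) = cluster_tss(_cands([42]))
        assert len(c) == 1 and c.width == 0

    def test_boundary_gap_exactly_at_threshold_merges(self):
        assert len(cluster_tss(_cands([0, 500]), 500)) == 1
        assert len(cluster_tss(_cands([0, 501]), 500)) == 2

    def test_empty_input(self):
        assert cluster_tss([]) == []

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.integers(0, 5000), min_size=1, max_size=20),
        st.integers(1, 1000),
    )
    def test_partition_against_pairwise_gap_oracle(self, positions, threshold):
        cands = _cands(positions)
        clusters = cluster_tss(cands, threshold)
        # oracle: exhaustively split the sorted positions at gaps > threshold
        ps = sorted(positions)
        oracle, cur = [], [ps[0]]
        for a, b in zip(ps, ps[1:]):
            if b - a > threshold:
                oracle.append(cur)
                cur = []
            cur.append(b)
        oracle.append(cur)
        assert [sorted(m.position for m in c.members) for c in clusters] == oracle
        # partition property: every candidate in exactly one cluster
        assert sorted(m.position for c in clusters for m in c.members) == ps

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 3000), min_size=2, max_size=10, unique=True), st.data())
    def test_order_invariance(self, positions, data):
        perm = data.draw(st.permutations(positions))
        a = [[m.position for m in c.members] for c in cluster_tss(_cands(positions))]
        b = [[m.position for m in c.members] for c in cluster_tss(_cands(perm))]
        assert a == b

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 5000), min_size=1, max_size=15),
        st.integers(1, 800),
        st.integers(0, 500),
    )
    def test_cluster_count_monotone_in_threshold(self, positions, t_low, bump):
        lo = cluster_tss(_cands(positions), t_low)
        hi = cluster_tss(_cands(positions), t_low + bump)
        assert len(lo) >= len(hi)


class TestShape:
    @pytest.mark.parametrize("width,expected", [(58, "sharp"), (300, "broad"), (0, "sharp"), (62, "sharp"), (63, "broad")])
    def test_width_cutoff(self, width, expected):
        cl = TssCluster(_cands([100, 100 + width]))
        assert classify_shape(cl) == expected


class TestTata:
    def test_planted_consensus_found(self):
        seq = list("C" * 3000)
        rep = 600
        seq[rep - 30 : rep - 22] = "TATAAAAG"
        locus = _locus_with_evidence([rep], sequence="".join(seq))
        hit, pos = scan_tata(locus, TssCluster(_cands([rep])))
        assert hit and pos == rep - 30

    def test_all_c_window_has_no_box(self):
        locus = _locus_with_evidence([600], sequence="C" * 3000)
        hit, pos = scan_tata(locus, TssCluster(_cands([600])))
        assert not hit and pos is None

    def test_scan_matches_brute_force_over_random_sequence(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        locus = _locus_with_evidence([], sequence=seq)
        pattern = re.compile("TATA[AT]A[AT][AG]")
        for rep in range(100, 2000, 37):
            hit, pos = scan_tata(locus, TssCluster(_cands([rep])))
            oracle = [
                s for s in range(rep - 40, rep - 19) if pattern.fullmatch(seq[s : s + 8])
            ]
            assert hit == bool(oracle)
            if oracle:
                assert pos == oracle[0]

    def test_every_consensus_8mer_accepted_and_others_rejected(self):
        # exhaustive check of the motif matcher against a brute-force oracle
        pattern = re.compile("TATA[AT]A[AT][AG]")
        matcher = __import__("spliceatlas.tss", fromlist=["TATA_CONSENSUS"]).TATA_CONSENSUS
        for mer in map("".join, itertools.product("ACGT", repeat=4)):
            word = "TATA" + mer
            assert bool(matcher.fullmatch(word)) == bool(pattern.fullmatch(word))


class TestExonicFlag:
    def test_tss_inside_coding_exon_far_from_starts(self):
        # inside coding exon 2, >500 nt from every annotated start
        locus = _locus_with_evidence([1500])
        cl = TssCluster(_cands([1500]))
        assert flag_exonic_tss(cl, locus) is True

    def test_tss_close_to_annotated_start_merges_with_its_promoter(self):
        # only 100 nt downstream of the exon-2-proximal annotated start of an
        # alternative transcript: merges with that promoter
        locus = build_locus(
            [(600, 800), (1400, 1700), (2500, 2700)],
            cds=(1450, 2600),
            alternatives=[("alt2L", [(1400, 1700), (2500, 2700)])],
        )
        cl = TssCluster(_cands([1500]))
        assert flag_exonic_tss(cl, locus) is False

    def test_annotated_first_exon_start_not_exonic(self):
        locus = _locus_with_evidence([600])
        assert flag_exonic_tss(TssCluster(_cands([600])), locus) is False
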