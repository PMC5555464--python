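"""ORF translation, event consequences, and N-terminal truncation bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceatlas import (
    LocusSpec,
    consequence_of_event,
    diff_transcripts,
    find_orf_and_translate,
    generate_locus,
    make_transcript,
    nterm_truncation_stats,
    predicted_isoform_length,
)
from spliceatlas.consequences import (
    CAT_FRAMESHIFT,
    CAT_INFRAME_DEL,
    CAT_INFRAME_DEL_SUB,
    CAT_SILENT_UTR,
)
from spliceatlas.simulate import (
    AltAcceptor,
    AltDonor,
    CrypticDonorUtr,
    DonorShiftWithSubstitution,
    Nagnag,
    PartialRetention,
)
from conftest import build_locus

# independent translation oracle: the standard genetic code in TCAG order
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(nt: str) -> str:
    prot = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa = CODON_TABLE[nt[i : i + 3].replace("U", "T")]
        if aa == "*":
            break
        prot.append(aa)
    return "".join(prot)


class TestTranslation:
    def test_minimal_orf(self):
        locus = build_locus([(0, 6)], sequence="ATGTAA" + "C" * 44, cds=(0, 6))
        iso = find_orf_and_translate(locus, locus.reference)
        assert iso.sequence == "M" and iso.length == 1

    def test_complete_2529_nt_orf_translates_to_842_residues(self):
        rng = np.random.default_rng(3)
        safe = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
        body = "".join(rng.choice(safe, size=841))
        mrna = "ATG" + body + "TAA"
        assert len(mrna) == 2529
        locus = build_locus([(0, 2529)], sequence=mrna + "A" * 50, cds=(0, 2529))
        iso = find_orf_and_translate(locus, locus.reference)
        assert iso.length == 842

    def test_random_orfs_match_codon_table_oracle(self):
        rng = np.random.default_rng(17)
        codons = list(CODON_TABLE)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            body = "".join(rng.choice(codons, size=n))
            mrna = "ATG" + body + "TAA"
            locus = build_locus([(0, len(mrna))], sequence=mrna + "C" * 30, cds=(0, 6))
            # no CDS annotation on the transcript: first-AUG policy
            t = make_transcript("t", "chr", [(0, len(mrna))])
            iso = find_orf_and_translate(locus, t)
            assert iso is not None  # the appended TAA guarantees a stop
            assert iso.sequence == "M" + oracle_translate(body)

    def test_no_start_codon_is_noncoding(self):
        t = make_transcript("t", "chr", [(0, 12)])
        locus = build_locus([(0, 12)], sequence="CCCCCCCCCCCC" + "C" * 38, cds=(0, 12))
        assert find_orf_and_translate(locus, t) is None


def _single_feature_consequence(feature, seed=0, n_exons=6):
    spec = LocusSpec(seed=seed, n_exons=n_exons, features=(feature,))
    locus, truth = generate_locus(spec)
    (alt,) = locus.alternatives
    (event,) = diff_transcripts(alt, locus.reference, locus)
    return locus, alt, event, consequence_of_event(locus, locus.reference, alt, event)


class TestEventConsequences:
    def test_nagnag_shift_deletes_one_residue(self):
        _, _, event, cons = _single_feature_consequence(Nagnag(exon=3))
        assert event.delta_nt == -3 and event.nagnag is not None
        assert cons.category == CAT_INFRAME_DEL
        assert cons.deleted_residues == 1

    def test_21_nt_donor_shift_deletes_seven_residues(self):
        _, _, event, cons = _single_feature_consequence(AltDonor(exon=3, offset=-21))
        assert cons.category == CAT_INFRAME_DEL
        assert cons.deleted_residues == 7

    def test_15_nt_acceptor_shift_deletes_five_residues(self):
        _, _, event, cons = _single_feature_consequence(AltAcceptor(exon=3, offset=-15))
        assert cons.category == CAT_INFRAME_DEL
        assert cons.deleted_residues == 5

    def test_off_frame_6_nt_donor_shift_deletes_two_and_substitutes_one(self):
        _, _, event, cons = _single_feature_consequence(DonorShiftWithSubstitution(exon=3))
        assert event.delta_nt == -6
        assert cons.category == CAT_INFRAME_DEL_SUB
        assert cons.deleted_residues == 2
        assert cons.substituted_residues == (("Y", "D"),)

    def test_106_nt_retention_causes_frameshift_ptc(self):
        _, alt, event, cons = _single_feature_consequence(
            PartialRetention(intron=3, retained=106)
        )
        assert event.delta_nt == 106
        assert cons.category == CAT_FRAMESHIFT
        assert cons.ptc_spliced_position is not None
        # PTC far upstream of the last junction: NMD candidate
        assert cons.nmd_candidate is True

    def test_utr_event_leaves_protein_bit_identical(self):
        locus, alt, event, cons = _single_feature_consequence(CrypticDonorUtr(offset=132))
        assert cons.category == CAT_SILENT_UTR
        ref_iso = find_orf_and_translate(locus, locus.reference)
        from spliceatlas.models import spliced_sequence

        mrna = spliced_sequence(locus, alt)
        start = alt.genomic_to_spliced(locus.reference.cds[0])
        alt_prot = oracle_translate(mrna[start + 3 :])
        assert "M" + alt_prot == ref_iso.sequence

    def test_frameshift_iff_delta_not_multiple_of_three(self):
        for feature, frameshift in [
            (PartialRetention(intron=3, retained=38), True),
            (AltDonor(exon=3, offset=-21), False),
        ]:
            _, _, event, cons = _single_feature_consequence(feature)
            assert (cons.category == CAT_FRAMESHIFT) is frameshift
            assert (event.delta_nt % 3 != 0) is frameshift


class TestTruncationStats:
    def _proteins(self, unique_n, missing_n, shared):
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        suffix = "".join(rng.choice(aas, size=shared))
        ref = "".join(rng.choice(aas, size=missing_n)) + suffix
        alt_head = "".join(rng.choice(aas, size=unique_n))
        # boundary residues must differ or the common suffix grows
        while alt_head and alt_head[-1] == ref[missing_n - 1]:
            alt_head = alt_head[:-1] + ("A" if ref[missing_n - 1] != "A" else "C")
        return ref, alt_head + suffix

    @pytest.mark.parametrize(
        "unique_n,missing_n,shared,alt_len",
        [(16, 166, 1112, 1128), (32, 227, 1051, 1083)],
    )
    def test_known_truncation_triples(self, unique_n, missing_n, shared, alt_len):
        ref, alt = self._proteins(unique_n, missing_n, shared)
        assert len(ref) == 1278 and len(alt) == alt_len
        stats = nterm_truncation_stats(ref, alt)
        assert (stats.unique_n, stats.missing_n, stats.shared_suffix) == (
            unique_n,
            missing_n,
            shared,
        )
        assert predicted_isoform_length(len(ref), stats.missing_n, stats.unique_n) == alt_len

    def test_identical_proteins(self):
        stats = nterm_truncation_stats("MAGICPEPTIDE", "MAGICPEPTIDE")
        assert (stats.unique_n, stats.missing_n, stats.shared_suffix) == (0, 0, 12)

    def test_unrelated_c_termini_flagged(self):
        stats = nterm_truncation_stats("AAAA", "CCC")
        assert stats.unrelated_c_termini and stats.shared_suffix == 0

    @settings(max_examples=200, deadline=None)
    @given(st.text("ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80),
           st.text("ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    def test_identity_holds_for_all_pairs_and_matches_brute_force(self, ref, alt):
        stats = nterm_truncation_stats(ref, alt)
        assert len(alt) == len(ref) - stats.missing_n + stats.unique_n
        # brute-force longest common suffix
        s = 0
        while s < min(len(ref), len(alt)) and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]:
            s += 1
        assert stats.shared_suffix == s

    @pytest.mark.parametrize(
        "ref_len,missing,unique,expected",
        [(1278, 166, 16, 1128), (1278, 227, 32, 1083), (500, 0, 0, 500)],
    )
    def test_predicted_isoform_length(self, ref_len, missing, unique, expected):
        assert predicted_isoform_length(ref_len, missing, unique) == expected

    def test_missing_cannot_exceed_reference(self):
        with pytest.raises(ValueError):
            predicted_isoform_length(100, 101, 0)
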