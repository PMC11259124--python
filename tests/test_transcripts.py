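import warnings

import numpy as np
import pytest

from ptvburden import (
    Consequence,
    TranscriptModel,
    VariantRecord,
    apply_and_translate,
    classify_consequence,
    project_position,
    project_to_cds,
    simulate_transcript,
)
from ptvburden.simulate import mirror_transcript, mirror_variant
from ptvburden.transcripts import _edit_to_transcript, _shift3, parse_hgvs_c
from ptvburden.variants import normalize, revcomp

from _oracles import (
    random_cds_edits,
    edited_spliced_sequence,
    genomic_to_spliced_map,
    oracle_exonic_ptv,
    translate_codon_by_codon,
)


# -- coordinate projection ---------------------------------------------------


class TestProjection:
    def test_cds_offset(self, toy_single_exon):
        v = VariantRecord(contig="chrT", pos=104, ref="A", alt="T")
        assert str(project_to_cds(toy_single_exon, v)) == "4"

    def test_donor_offset(self, toy_two_exon):
        assert str(project_position(toy_two_exon, 111)) == "9+2"

    def test_acceptor_offset(self, toy_two_exon):
        assert str(project_position(toy_two_exon, 208)) == "10-2"

    def test_utr_positions(self, toy_with_utr):
        assert str(project_position(toy_with_utr, 101)) == "-6"
        assert str(project_position(toy_with_utr, 122)) == "*1"

    def test_outside_span(self, toy_single_exon):
        v = VariantRecord(contig="chrT", pos=5, ref="N", alt="A")
        assert project_to_cds(toy_single_exon, v).kind == "outside"

    def test_exonic_positions_match_bruteforce_map(self):
        """g2t agrees with an exhaustive scan over all spliced positions."""
        for seed in (1, 2, 3):
            for strand in ("+", "-"):
                t = simulate_transcript(seed, n_exons=4, strand=strand)
                oracle = genomic_to_spliced_map(t.exons, t.strand)
                for g, tp in oracle.items():
                    assert t.g2t(g) == tp
                    assert t.t2g(tp) == g


# -- apply and translate -----------------------------------------------------


class TestApplyAndTranslate:
    def test_forced_stop(self, toy_single_exon):
        v = VariantRecord(contig="chrT", pos=104, ref="A", alt="T")  # AAA -> TAA
        res = apply_and_translate(toy_single_exon, v)
        assert res.peptide == "M*"

    def test_frameshift_matches_independent_retranslation(self, toy_with_utr):
        v = VariantRecord(contig="chrT", pos=109, ref="GA", alt="G")  # del c.4
        res = apply_and_translate(toy_with_utr, v)
        edited = "ATG" + "AAGGGCCCTGA" + "TTAACCCGG"
        assert res.peptide == translate_codon_by_codon(edited)

    def test_identity_edit_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord(contig="chrT", pos=104, ref="A", alt="A")


# -- classification ----------------------------------------------------------


class TestClassification:
    def test_stop_gain(self, toy_single_exon):
        call = classify_consequence(
            toy_single_exon, VariantRecord(contig="chrT", pos=104, ref="A", alt="T")
        )
        assert call.consequence is Consequence.stop_gain
        assert call.is_ptv
        assert call.hgvs_p == "p.Lys2Ter"

    def test_frameshift_vs_inframe_deletion(self, toy_with_utr):
        fs = classify_consequence(
            toy_with_utr, VariantRecord(contig="chrT", pos=109, ref="GAA", alt="G")
        )
        assert fs.consequence is Consequence.frameshift and fs.is_ptv
        inframe = classify_consequence(
            toy_with_utr, VariantRecord(contig="chrT", pos=109, ref="GAAA", alt="G")
        )
        assert inframe.consequence is Consequence.inframe_indel and not inframe.is_ptv

    def test_canonical_splice_donor_and_acceptor(self, toy_two_exon):
        donor = classify_consequence(
            toy_two_exon, VariantRecord(contig="chrT", pos=111, ref="T", alt="G")
        )
        assert donor.consequence is Consequence.canonical_splice
        assert donor.hgvs_c == "c.9+2T>G"
        assert donor.hgvs_p == "p.?"
        acceptor = classify_consequence(
            toy_two_exon, VariantRecord(contig="chrT", pos=209, ref="G", alt="A")
        )
        assert acceptor.consequence is Consequence.canonical_splice
        assert acceptor.hgvs_c == "c.10-1G>A"

    def test_deep_intronic_not_ptv(self, toy_two_exon):
        call = classify_consequence(
            toy_two_exon, VariantRecord(contig="chrT", pos=150, ref="N", alt="A")
        )
        assert call.consequence is Consequence.intronic and not call.is_ptv

    def test_synonymous_and_missense(self, toy_with_utr):
        syn = classify_consequence(  # AAA -> AAG, both Lys
            toy_with_utr, VariantRecord(contig="chrT", pos=112, ref="A", alt="G")
        )
        assert syn.consequence is Consequence.synonymous
        mis = classify_consequence(  # AAA -> ACA (Lys2Thr)
            toy_with_utr, VariantRecord(contig="chrT", pos=111, ref="A", alt="C")
        )
        assert mis.consequence is Consequence.missense
        assert mis.hgvs_p == "p.Lys2Thr"




class TestOracleAgreement:
    def test_classifier_agrees_with_translation_oracle(self, rng):
        """Consequence class matches brute-force edit-and-retranslate on
        >=1,000 random coding edits across several synthetic transcripts."""
        total = 0
        for seed, strand in [(5, "+"), (6, "+"), (7, "-"), (8, "-")]:
            t = simulate_transcript(seed, n_exons=4, exon_length=(60, 150), strand=strand)
            tx_map = genomic_to_spliced_map(t.exons, t.strand)
            ref_read = t.sequence[t.tx_cds_start - 1 :]
            for v in random_cds_edits(t, rng, 260):
                e = normalize(v)
                edited_spliced = edited_spliced_sequence(
                    t.sequence, tx_map, t.strand, e.start, e.ref or "", e.alt or "", revcomp
                ) if e.kind.value != "insertion" else None
                if edited_spliced is None:
                    # insertion: place inserted bases after the anchor's spliced pos
                    tpos = (
                        tx_map[e.end] if t.strand == "+" else tx_map[e.start]
                    )
                    ins = e.alt if t.strand == "+" else revcomp(e.alt)
                    edited_spliced = t.sequence[:tpos] + ins + t.sequence[tpos:]
                edited_read = edited_spliced[t.tx_cds_start - 1 :]
                want_ptv, want_class = oracle_exonic_ptv(
                    ref_read, edited_read, e.length_change
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    call = classify_consequence(t, v)
                assert call.is_ptv == want_ptv, (v.token, call.consequence, want_class)
                if want_class in ("frameshift", "stop_gain"):
                    assert call.consequence.value == want_class, v.token
                total += 1
        assert total >= 1000


class TestInvariants:
    def test_strand_symmetry(self, rng):
        """Mirrored variants on the reverse-complement transcript get the
        same consequence class."""
        t = simulate_transcript(13, n_exons=4)
        tm = mirror_transcript(t)
        for v in random_cds_edits(t, rng, 150):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c1 = classify_consequence(t, v)
                c2 = classify_consequence(tm, mirror_variant(t, v))
            assert c1.consequence == c2.consequence, v.token

    def test_inframe_indels_never_frameshift(self, rng):
        """Indels of length 0 mod 3 fully inside the CDS are never frameshift."""
        t = simulate_transcript(17, n_exons=3, exon_length=(80, 150))
        seq = t.contig_sequence
        checked = 0
        for _ in range(400):
            g = int(rng.integers(t.cds_start + 12, t.cds_end - 24))
            if any(t.g2t(x) is None for x in range(g, g + 10)):
                continue
            if rng.random() < 0.5:
                v = VariantRecord(contig=t.contig, pos=g, ref=seq[g - 1 : g + 3], alt=seq[g - 1])
            else:
                ins = "".join(rng.choice(list("ACGT"), size=3))
                v = VariantRecord(contig=t.contig, pos=g, ref=seq[g - 1], alt=seq[g - 1] + ins)
            call = classify_consequence(t, v)
            assert call.consequence is not Consequence.frameshift
            checked += 1
        assert checked > 100

    def test_hgvs_c_roundtrip(self, rng):
        """Parsing an emitted exonic c. name recovers the 3'-shifted edit."""
        t = simulate_transcript(19, n_exons=3, exon_length=(80, 150))
        for v in random_cds_edits(t, rng, 200):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                call = classify_consequence(t, v)
            expect = _shift3(t.sequence, _edit_to_transcript(t, normalize(v)))
            got = parse_hgvs_c(t, call.hgvs_c)
            assert (got.kind, got.start, got.end, got.ref, got.alt) == (
                expect.kind, expect.start, expect.end, expect.ref, expect.alt
            ), (v.token, call.hgvs_c)


class TestHgvsNames:
    def test_insertion_in_repeat_is_dup(self):
        """An insertion identical to the preceding base is written dup."""
        t = TranscriptModel(
            id="T", contig="c", strand="+", exons=((101, 112),),
            cds_start=101, cds_end=112, sequence="ATGAAACCCTAG",
        )
        v = VariantRecord(contig="c", pos=104, ref="A", alt="AA")
        call = classify_consequence(t, v)
        assert call.hgvs_c == "c.6dup"

    def test_fster_index_counts_from_first_changed_residue(self, toy_with_utr):
        """fsTer index = 1 + complete new-frame codons before the new stop,
        verified by independent re-translation."""
        v = VariantRecord(contig="chrT", pos=109, ref="GA", alt="G")  # del c.4
        call = classify_consequence(toy_with_utr, v)
        edited = "ATG" + "AAGGGCCCTGA" + "TTAACCCGG"
        pep = translate_codon_by_codon(edited)
        ref_pep = translate_codon_by_codon("ATGAAAGGGCCCTGA")
        first_changed = next(
            i for i, (a, b) in enumerate(zip(ref_pep, pep)) if a != b
        )
        k = pep.index("*") - first_changed + 1
        assert call.consequence is Consequence.frameshift
        assert call.hgvs_p.endswith(f"fsTer{k}")

    def test_frameshift_without_downstream_stop_warns(self, toy_single_exon):
        v = VariantRecord(contig="chrT", pos=104, ref="AA", alt="A")
        with pytest.warns(UserWarning, match="no downstream stop"):
            call = classify_consequence(toy_single_exon, v)
        assert call.hgvs_p.endswith("fsTer?")


class TestModelValidation:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            TranscriptModel(
                id="X", contig="c", strand="+", exons=((101, 120), (110, 130)),
                cds_start=101, cds_end=120, sequence="A" * 41,
            )

    def test_cds_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            TranscriptModel(
                id="X", contig="c", strand="+", exons=((101, 110),),
                cds_start=101, cds_end=110, sequence="ATGAAATAGG",
            )
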