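"""Re-alignment, pileup calling, origin assignment, coding annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudolink.refbuild import AnchorRegions, ReconstructedRef, build_recon_ref
from pseudolink.seq import random_seq, revcomp
from pseudolink.smallvar import (BOTH, GENE_ONLY, PSEUDO_ONLY, FilterThresholds,
                                 SmallVariantCall, align_to_recon, assign_origin,
                                 call_small_variants, cds_sequence,
                                 classify_consequence, first_affected_codon,
                                 genome_to_cdna, left_align, pileup, right_align)


@pytest.fixture(scope="module")
def recon(rng):
    return ReconstructedRef("recon1", random_seq(rng, 4000),
                            [(0, 4000, 0, 4000, "+")])


def _reads_from(recon, spans, mutate=None, barcode=(1, 1, 1)):
    """Raw (id, mate, barcode, seq) tuples cut from the recon sequence."""
    out = []
    for i, (s, e) in enumerate(spans):
        seq = recon.sequence[s:e]
        if mutate:
            seq = mutate(i, s, seq)
        out.append((f"r{i}", 1, barcode, seq))
    return out


class TestAlignToRecon:
    def test_exact_read_zero_edits(self, recon):
        (a,) = align_to_recon(_reads_from(recon, [(100, 200)]), recon)
        assert a.edit_distance == 0 and a.start == 100 and a.cigar == "100="

    def test_duplication_read_single_insertion(self, recon):
        def dup(i, s, seq):
            return seq[:50] + seq[49] + seq[50:99]
        (a,) = align_to_recon(_reads_from(recon, [(100, 200)], mutate=dup), recon)
        assert a.edit_distance == 1
        assert sum(n for n, op in
                   __import__("pseudolink.align", fromlist=["parse_cigar"])
                   .parse_cigar(a.cigar) if op == "I") == 1

    def test_random_read_dropped(self, recon, rng):
        got = align_to_recon([("rx", 1, (1, 1, 1), random_seq(rng, 100))], recon)
        assert got == []


class TestPileup:
    def test_single_read_depth_profile(self, recon):
        al = align_to_recon(_reads_from(recon, [(500, 600)]), recon)
        pile = pileup(al, recon)
        assert pile.depth(550) == 1
        assert pile.depth(499) == 0 and pile.depth(600) == 0

    def test_counts_match_bruteforce(self, recon, rng):
        spans = [(int(p), int(p) + 100)
                 for p in rng.integers(0, 3900, size=50)]
        al = align_to_recon(_reads_from(recon, spans), recon)
        pile = pileup(al, recon)
        brute = np.zeros(4000, dtype=int)
        for s, e in spans:
            brute[s:e] += 1
        for pos in rng.integers(0, 4000, size=200):
            assert pile.depth(int(pos)) == brute[int(pos)]

    def test_insertion_registered_at_anchor_only(self, recon):
        def dup(i, s, seq):
            return seq[:50] + "AAAA" + seq[50:96]
        al = align_to_recon(_reads_from(recon, [(1000, 1100)], mutate=dup), recon)
        pile = pileup(al, recon)
        keys = list(pile.ins)
        assert len(keys) == 1
        anchor, ins_seq = keys[0]
        # anchored at the last unchanged base (left-shift may move it back
        # through any run of reference A's)
        assert len(ins_seq) == 4
        assert 1040 <= anchor <= 1049

    def test_column_view(self, recon):
        al = align_to_recon(_reads_from(recon, [(200, 300), (250, 350)]), recon)
        pile = pileup(al, recon)
        col = pile.column(260)
        assert col.depth == 2
        assert col.base_counts == {recon.sequence[260]: 2}


class TestCallSmallVariants:
    def test_reference_only_pileup_no_calls(self, recon):
        spans = [(i * 100, i * 100 + 100) for i in range(30)]
        al = align_to_recon(_reads_from(recon, spans), recon)
        assert call_small_variants(pileup(al, recon), recon) == []

    def test_balanced_het_duplication_called(self, recon):
        # 30 reads over one window, 15 with a 1bp duplication, both strands
        spans = [(1000, 1100)] * 30
        def mutate(i, s, seq):
            if i < 15:
                seq = seq[:50] + seq[49] + seq[50:99]
            return seq if i % 2 == 0 else revcomp(seq)
        al = align_to_recon(_reads_from(recon, spans, mutate=mutate), recon)
        calls = [c for c in call_small_variants(pileup(al, recon), recon)
                 if c.is_pass]
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "INS" and c.genotype == "het"
        assert abs(c.alt_fraction - 0.5) < 0.01
        # both strands support the event
        assert c.alt_count == 15

    def test_two_alt_reads_fail_min_alt(self, recon):
        spans = [(2000, 2100)] * 30
        def mutate(i, s, seq):
            if i < 2:
                seq = seq[:50] + seq[49] + seq[50:99]
            return seq
        al = align_to_recon(_reads_from(recon, spans, mutate=mutate), recon)
        calls = call_small_variants(pileup(al, recon), recon)
        assert all(not c.is_pass for c in calls)
        assert any(c.filter_status == "MIN_ALT" for c in calls)

    def test_low_af_fails_allele_fraction(self, recon):
        spans = [(3000, 3100)] * 40
        def mutate(i, s, seq):
            if i < 4:
                seq = seq[:50] + seq[49] + seq[50:99]
            return seq
        al = align_to_recon(_reads_from(recon, spans, mutate=mutate), recon)
        calls = call_small_variants(pileup(al, recon), recon)
        assert any(c.filter_status == "ALLELE_FRACTION" for c in calls)

    def test_inconsistent_thresholds_rejected(self, recon):
        with pytest.raises(ValueError):
            call_small_variants(pileup([], recon), recon,
                                FilterThresholds(het_low=0.9, het_high=0.2))

    def test_foreign_subtraction_restores_native_af(self, recon):
        # 20 native reads (10 alt) plus 20 foreign reads dilute AF to 0.25;
        # subtracting the known-foreign pileup restores 0.5
        spans = [(1000, 1100)] * 40
        def mutate(i, s, seq):
            if i < 10:
                seq = seq[:50] + seq[49] + seq[50:99]
            return seq
        reads = _reads_from(recon, spans, mutate=mutate)
        reads = [(rid, m, (2, 2, 2) if i >= 20 else (1, 1, 1), seq)
                 for i, (rid, m, _bc, seq) in enumerate(reads)]
        al = align_to_recon(reads, recon)
        pile = pileup(al, recon)
        foreign = pileup([r for r in al if tuple(r.barcode) == (2, 2, 2)], recon)
        (call,) = [c for c in call_small_variants(pile, recon, foreign=foreign)
                   if c.is_pass]
        assert call.depth == 20 and abs(call.alt_fraction - 0.5) < 0.01


class TestNormalization:
    def test_left_align_duplication(self):
        seq = "GGGTTTACACACGGG"
        # insertion of "AC" after the last AC of the run shifts to the
        # leftmost equivalent anchor (the T before the AC run)
        pos, ref, alt = left_align(11, seq[11], seq[11] + "AC", seq)
        assert (pos, ref, alt) == (5, "T", "TAC")

    def test_right_align_duplication(self):
        seq = "GGGTTTACACACGGG"
        pos, ref, alt = right_align(5, "T", "TAC", seq)
        assert (pos, ref, alt) == (11, "C", "CAC")

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(5, 90), st.integers(1, 4), st.integers(0, 4))
    def test_shift_preserves_edited_sequence(self, pos, ins_len, seed):
        seq = random_seq(np.random.default_rng(seed), 100)
        ins = seq[pos - ins_len + 1 : pos + 1]
        lp, lref, lalt = left_align(pos, seq[pos], seq[pos] + ins, seq)
        rp, rref, ralt = right_align(lp, lref, lalt, seq)
        def apply(p, ref, alt):
            return seq[:p] + alt + seq[p + len(ref):]
        assert apply(lp, lref, lalt) == apply(pos, seq[pos], seq[pos] + ins)
        assert apply(rp, rref, ralt) == apply(pos, seq[pos], seq[pos] + ins)


@pytest.fixture(scope="module")
def recons(locus_default):
    _, ref, ann, _ = locus_default
    anchors = AnchorRegions.from_annotation(ann)
    return (build_recon_ref(ref, ann, anchors, 1),
            build_recon_ref(ref, ann, anchors, 2), ann)


class TestOriginAssignment:

    def _call(self, recon_name, pos, ref_a, alt_a, status="PASS"):
        return SmallVariantCall(
            recon_name=recon_name, recon_pos=pos, ref=ref_a, alt=alt_a,
            depth=20, alt_count=10, alt_fraction=0.5, genotype="het",
            filter_status=status, kind="INS" if len(alt_a) > 1 else "SNV")

    def test_empty_inputs(self, recons):
        r1, r2, ann = recons
        assert assign_origin([], [], r1, r2, ann) == []

    def test_paralogous_pair_labelled_both(self, recons, locus_default):
        r1, r2, ann = recons
        _, ref, _, _ = locus_default
        g = 27500  # inside the homologous gene segment (recon1 == locus)
        p = ann.paralogous_position(g)
        # recon2 is gene-forward: its coordinate for locus p reflects
        from pseudolink.refbuild import locus_to_recon
        c1 = self._call("recon1", g, ref[g], ref[g] + "AAAA")
        c2 = self._call("recon2", locus_to_recon(r2, p), ref[g], ref[g] + "AAAA")
        merged = assign_origin([c1], [c2], r1, r2, ann)
        assert len(merged) == 1 and merged[0].origin == BOTH
        assert merged[0].paralog is c2

    def test_single_sided_calls(self, recons, locus_default):
        r1, r2, ann = recons
        _, ref, _, _ = locus_default
        c1 = self._call("recon1", 27500, ref[27500], ref[27500] + "T")
        from pseudolink.refbuild import locus_to_recon
        p = ann.paralogous_position(30000)
        c2 = self._call("recon2", locus_to_recon(r2, p), ref[30000], ref[30000] + "G")
        merged = assign_origin([c1], [c2], r1, r2, ann)
        origins = {(c.recon_name, c.origin) for c in merged}
        assert origins == {("recon1", GENE_ONLY), ("recon2", PSEUDO_ONLY)}

    def test_failing_calls_excluded(self, recons, locus_default):
        r1, r2, ann = recons
        _, ref, _, _ = locus_default
        c1 = self._call("recon1", 27500, ref[27500], ref[27500] + "T", "MIN_ALT")
        assert assign_origin([c1], [], r1, r2, ann) == []


class TestCodingAnnotation:
    def test_first_cds_base(self, locus_default):
        _, _, _, t = locus_default
        assert genome_to_cdna(t.cds_start, t) == (1, 0, "cds")

    def test_intronic_offsets_against_enumeration(self, locus_default):
        _, _, _, t = locus_default
        # brute-force nearest-exon-edge map over intron 3
        exon3_end, exon4_start = t.exons[2][1], t.exons[3][0]
        for pos in range(exon3_end, exon4_start):
            c, off, region = genome_to_cdna(pos, t)
            assert region == "intron"
            d_left = pos - (exon3_end - 1)
            d_right = exon4_start - pos
            if d_left <= d_right:
                assert (c, off) == (518, d_left)
            else:
                assert (c, off) == (519, -d_right)

    def test_flank_position_rejected(self, locus_default):
        _, _, _, t = locus_default
        with pytest.raises(ValueError):
            genome_to_cdna(10, t)

    @pytest.mark.parametrize("p,codon", [(1167, 390), (700, 234), (519, 174),
                                         (3, 2), (1, 1)])
    def test_first_affected_codon_values(self, p, codon):
        assert first_affected_codon(p) == codon

    def test_first_affected_codon_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            first_affected_codon(0)

    def test_frameshift_vs_translation_oracle_1000_cds(self):
        # independent oracle: right-align the duplication on the cDNA,
        # rebuild the mutant transcript, find the first changed nucleotide
        # codon; biopython translation confirms the frame is broken
        rng = np.random.default_rng(777)
        bases = "ACGT"
        for trial in range(1000):
            n_codons = int(rng.integers(30, 200))
            cds = "ATG" + "".join(
                c for _ in range(n_codons - 2)
                for c in [bases[rng.integers(4)] + bases[rng.integers(4)]
                          + bases[rng.integers(4)]]
                if c not in ("TAA", "TAG", "TGA")) + "TAA"
            L = (len(cds) // 3) * 3
            cds = cds[:L]
            ins_len = int(rng.choice([1, 2, 4]))
            p = int(rng.integers(ins_len, len(cds) - ins_len - 3))
            ins = cds[p - ins_len : p]
            rp, rref, ralt = right_align(p - 1, cds[p - 1], cds[p - 1] + ins, cds)
            fac = first_affected_codon(rp + 1)
            mutant = cds[: rp + 1] + ralt[1:] + cds[rp + 1 :]
            first_diff = next(i for i in range(len(cds))
                              if mutant[i] != cds[i])
            assert fac == first_diff // 3 + 1
            if trial % 100 == 0:  # spot-check the frameshift at protein level
                prot = Seq(cds).translate()
                prot_m = Seq(mutant[: (len(mutant) // 3) * 3]).translate()
                assert str(prot) != str(prot_m)

    def test_consequences_on_synthetic_transcript(self, locus_default):
        _, ref, ann, t = locus_default
        gene_seq = ref[ann.gene.start : ann.gene.start + 40000]

        def mk(kind, gene_frame_pos, ref_a, alt_a):
            return SmallVariantCall(
                recon_name="recon1", recon_pos=gene_frame_pos, ref=ref_a,
                alt=alt_a, depth=20, alt_count=10, alt_fraction=0.5,
                genotype="het", filter_status="PASS", kind=kind,
                gene_frame_pos=gene_frame_pos)

        g700 = ann.locus_pos(7681)  # c.700
        c = mk("INS", g700, ref[g700], ref[g700] + "T")
        a = classify_consequence(c, t, ann, gene_seq)
        assert a.consequence == "frameshift" and a.first_affected_codon is not None

        c = mk("INS", g700, ref[g700], ref[g700] + "TTT")
        a = classify_consequence(c, t, ann, gene_seq)
        assert a.consequence == "inframe_indel"

        # 4bp duplication whose 3' representation ends at the acceptor
        g519 = ann.locus_pos(7500)
        dup = ref[g519 - 3 : g519 + 1]
        c = mk("INS", g519, ref[g519], ref[g519] + dup)
        a = classify_consequence(c, t, ann, gene_seq)
        assert a.consequence == "frameshift" and a.splice_region
        assert a.first_affected_codon == first_affected_codon(
            genome_to_cdna(7500 + (0 if a.cdna == "c.519" else 0), t)[0])

        # deep intronic SNV
        gi = ann.locus_pos(6000)
        c = mk("SNV", gi, ref[gi], "A" if ref[gi] != "A" else "C")
        a = classify_consequence(c, t, ann, gene_seq)
        assert a.consequence == "intronic" and not a.splice_region

    def test_snv_synonymous_vs_missense(self, locus_default):
        _, ref, ann, t = locus_default
        gene_seq = ref[ann.gene.start : ann.gene.start + 40000]
        cds = cds_sequence(gene_seq, t)
        # find a position where a synonymous change exists (codon 3rd base)
        from pseudolink.smallvar import _translate
        for ci in range(5, 100):
            codon = cds[ci * 3 : ci * 3 + 3]
            for b in "ACGT":
                if b != codon[2] and _translate(codon[:2] + b) == _translate(codon):
                    gl = __import__("pseudolink.locus", fromlist=["x"]) \
                        .cdna_to_gene_local(t, ci * 3 + 3)
                    call = SmallVariantCall(
                        recon_name="recon1", recon_pos=0, ref=codon[2], alt=b,
                        depth=20, alt_count=10, alt_fraction=0.5,
                        genotype="het", filter_status="PASS", kind="SNV",
                        gene_frame_pos=ann.locus_pos(gl))
                    a = classify_consequence(call, t, ann, gene_seq)
                    assert a.consequence == "synonymous"
                    return
        pytest.fail("no synonymous site found in the first 100 codons")
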