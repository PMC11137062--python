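"""Local assembly, breakpoints, N-gap exclusion, junction logic, tracing."""

import numpy as np
import pytest

from pseudolink.cnv import (MUT, REF1, REF2, REFUTED, SUPPORTING, UNINFORMATIVE,
                            BreakpointCandidate, Contig, align_contigs,
                            assemble_local, assign_cnv_copy, build_junction_refs,
                            call_cnv, classify_junction_read, filter_ngap,
                            find_breakpoints, select_junction_reads,
                            trace_fragments)
from pseudolink.linked import AlignedRead, FragmentRecord
from pseudolink.locus import Interval
from pseudolink.refbuild import AnchorRegions
from pseudolink.seq import random_seq, revcomp


def tiling_reads(seq, step=10, read_len=100, start=0, end=None, prefix="t"):
    """Error-free single-end tiling reads as (id, seq, barcode) tuples."""
    end = len(seq) if end is None else end
    out = []
    i = start
    n = 0
    while i + read_len <= end:
        out.append((f"{prefix}{n}/1", seq[i : i + read_len], (1, 1, 1)))
        i += step
        n += 1
    return out


def paired_reads(seq, positions, insert, read_len=100, prefix="p"):
    """Proper read pairs (mate1 forward, mate2 reverse) at given starts."""
    out = []
    for n, s in enumerate(positions):
        out.append((f"{prefix}{n}/1", seq[s : s + read_len], (2, 2, 2)))
        out.append((f"{prefix}{n}/2",
                    revcomp(seq[s + insert - read_len : s + insert]), (2, 2, 2)))
    return out


class TestAssembler:
    def test_identity_on_clean_nonrepetitive_input(self, rng):
        source = random_seq(rng, 5000)
        reads = tiling_reads(source, step=3)  # ~depth 33
        # terminal k-mers must clear the solidity cutoff too
        reads += [("e0/1", source[:100], (1, 1, 1)),
                  ("e1/1", source[-100:], (1, 1, 1)),
                  ("e2/1", source[-100:], (1, 1, 1))]
        contigs = assemble_local(reads, barcode_bridge=False)
        contigs = [c for c in contigs if len(c.sequence) > 200]
        assert len(contigs) == 1
        got = contigs[0].sequence
        assert got == source or got == revcomp(source)

    def test_member_reads_and_barcodes_recorded(self, rng):
        source = random_seq(rng, 2000)
        reads = tiling_reads(source, step=5)
        (contig,) = [c for c in assemble_local(reads, barcode_bridge=False)
                     if len(c.sequence) > 200]
        assert len(contig.member_read_ids) >= 0.9 * len(reads)
        assert contig.barcodes == {(1, 1, 1)}

    def test_invalid_parameters(self, rng):
        reads = tiling_reads(random_seq(rng, 500))
        with pytest.raises(ValueError):
            assemble_local([], k=31)
        with pytest.raises(ValueError):
            assemble_local(reads, k=101)
        with pytest.raises(ValueError):
            assemble_local(reads, k=30)

    def test_coverage_hole_scaffolded_with_n_run(self, rng):
        source = random_seq(rng, 5000)
        reads = tiling_reads(source, step=4, end=2000) \
            + tiling_reads(source, step=4, start=2300, prefix="u")
        # pairs bridging the hole: mate1 ends before it, mate2 after it
        reads += paired_reads(source, [1850, 1870, 1890, 1860], insert=600)
        contigs = assemble_local(reads, scaffold=True, insert_mean=600,
                                 barcode_bridge=False)
        scaf = [c for c in contigs if "N" in c.sequence]
        assert len(scaf) == 1
        runs = scaf[0].n_runs()
        assert len(runs) == 1
        s, e = runs[0]
        assert 100 <= e - s <= 500  # insert-estimated gap, true hole is 300

    def test_no_contig_crosses_a_repeat_copy_unambiguously(self, locus_default):
        # two identical 879bp repeats force graph branches: without
        # barcode bridging no contig joins a repeat's two distinct flanks
        _, ref, ann, _ = locus_default
        r1, r2 = ann.repeats_gene
        window = ref[r1.start - 2000 : r2.end + 2000]
        reads = tiling_reads(window, step=4)
        contigs = assemble_local(reads, barcode_bridge=False)
        up1 = window[1900 : 2000]                     # just before repeat 1
        into_inner = window[2000 + 879 : 2000 + 979]  # just after repeat 1
        r2_off = r2.start - (r1.start - 2000)
        up2 = window[r2_off - 100 : r2_off]           # just before repeat 2
        for c in contigs:
            s = c.sequence
            for probe_pair in ((up1, up2),):
                a, b = probe_pair
                both = (a in s or revcomp(a) in s) and (b in s or revcomp(b) in s)
                assert not both


class TestAlignContigs:
    def test_short_contig_discarded(self, rng):
        locus = random_seq(rng, 3000)
        c = Contig("c", locus[100:599], ["r1"])
        assert align_contigs([c], locus, min_contig=500) == []

    def test_exact_substring_single_full_identity_block(self, rng):
        locus = random_seq(rng, 5000)
        c = Contig("c", locus[1000:2500], ["r1"])
        (b,) = align_contigs([c], locus)
        assert (b.contig_start, b.contig_end) == (0, 1500)
        assert (b.locus_start, b.locus_end) == (1000, 2500)
        assert b.identity == 100.0

    def test_chimeric_contig_two_blocks_with_locus_gap(self, rng):
        locus = random_seq(rng, 20000)
        c = Contig("c", locus[1000:2000] + locus[14000:15000], ["r1"])
        blocks = sorted(align_contigs([c], locus), key=lambda b: b.contig_start)
        assert len(blocks) == 2
        gap = blocks[1].locus_start - blocks[0].locus_end
        # chance single-base matches at the junction can nibble a few bp
        assert abs(gap - 12000) <= 10

    def test_low_identity_block_dropped(self, rng):
        locus = random_seq(rng, 3000)
        noisy = "".join(b if rng.random() > 0.10 else "ACGT"[int(rng.integers(4))]
                        for b in locus[500:1500])
        c = Contig("c", noisy, ["r1"])
        blocks = align_contigs([c], locus, min_identity=95.0)
        assert all(b.identity >= 95.0 for b in blocks)


class TestFindBreakpoints:
    def _block(self, cid, cs, ce, ls, le, strand="+"):
        from pseudolink.cnv import AlignmentBlock
        return AlignmentBlock(cid, cs, ce, ls, le, strand, 100.0)

    def test_single_block_no_candidates(self):
        assert find_breakpoints([self._block("c", 0, 1000, 0, 1000)]) == []

    def test_deletion_gap_detected(self):
        blocks = [self._block("c", 0, 1000, 5000, 6000),
                  self._block("c", 1000, 2000, 19400, 20400)]
        (cand,) = find_breakpoints(blocks, join_tolerance=50)
        assert cand.kind == "deletion"
        assert cand.implied_gap == 13400
        assert (cand.left_locus_anchor, cand.right_locus_anchor) == (6000, 19400)

    def test_small_gap_within_tolerance_ignored(self):
        blocks = [self._block("c", 0, 1000, 5000, 6000),
                  self._block("c", 1000, 2000, 6005, 7005)]
        assert find_breakpoints(blocks, join_tolerance=10) == []

    def test_strand_flip_is_rearrangement(self):
        blocks = [self._block("c", 0, 1000, 5000, 6000),
                  self._block("c", 1000, 2000, 8000, 9000, "-")]
        (cand,) = find_breakpoints(blocks)
        assert cand.kind == "rearrangement"


class TestNgapFilter:
    def _cand(self, cid, pos):
        return BreakpointCandidate(cid, pos, 0, 300, 300, "deletion")

    def test_contig_without_n_unchanged(self):
        c = Contig("c", "ACGT" * 300, ["r"])
        cands = [self._cand("c", 600)]
        assert filter_ngap([c], cands) == cands
        assert not cands[0].caused_by_ngap

    def test_breakpoint_at_n_run_flagged_and_excluded(self):
        c = Contig("c", "A" * 500 + "N" * 200 + "C" * 500, ["r"])
        cands = [self._cand("c", 510)]
        assert filter_ngap([c], cands) == []
        assert cands[0].caused_by_ngap

    def test_breakpoint_far_from_n_retained(self):
        c = Contig("c", "A" * 500 + "N" * 200 + "C" * 1500, ["r"])
        cands = [self._cand("c", 1700)]
        assert filter_ngap([c], cands, window=50) == cands


@pytest.fixture(scope="module")
def junction_refs(locus_default):
    _, ref, ann, _ = locus_default
    return ref, ann, build_junction_refs(ref, list(ann.repeats_gene), flank=500)


class TestJunctionRefs:
    def test_three_contexts_share_identical_core(self, junction_refs):
        ref, ann, refs = junction_refs
        core = lambda s: s[refs.flank : refs.flank + refs.repeat_length]
        assert core(refs.ref1_context) == core(refs.ref2_context) \
            == core(refs.mut_junction)
        assert refs.repeat_length == 879

    def test_mut_junction_is_spliced_deletion_allele(self, junction_refs):
        ref, ann, refs = junction_refs
        r1, r2 = ann.repeats_gene
        expected = ref[r1.start - 500 : r1.end] + ref[r2.end : r2.end + 500]
        assert refs.mut_junction == expected

    def test_flank_shorter_than_read_rejected(self, junction_refs):
        ref, ann, _ = junction_refs
        with pytest.raises(ValueError):
            build_junction_refs(ref, list(ann.repeats_gene), flank=50,
                                read_length=100)


class TestClassifyJunctionRead:
    def test_core_read_three_way_tie(self, junction_refs):
        _, _, refs = junction_refs
        read = refs.mut_junction[refs.flank + 300 : refs.flank + 400]
        assert classify_junction_read(read, refs) == {MUT, REF1, REF2}

    def test_read_into_downstream_flank_mut_or_ref2(self, junction_refs):
        _, _, refs = junction_refs
        j = refs.flank + refs.repeat_length
        read = refs.mut_junction[j - 50 : j + 50]
        assert classify_junction_read(read, refs) == {MUT, REF2}

    def test_read_from_upstream_flank_mut_or_ref1(self, junction_refs):
        _, _, refs = junction_refs
        read = refs.mut_junction[refs.flank - 50 : refs.flank + 50]
        assert classify_junction_read(read, refs) == {MUT, REF1}

    def test_reverse_complement_reads_classify_identically(self, junction_refs):
        _, _, refs = junction_refs
        j = refs.flank + refs.repeat_length
        read = refs.mut_junction[j - 50 : j + 50]
        assert classify_junction_read(revcomp(read), refs) == {MUT, REF2}

    def test_unalignable_read_raises(self, junction_refs, rng):
        _, _, refs = junction_refs
        with pytest.raises(ValueError):
            classify_junction_read(random_seq(rng, 100), refs)


def _fragment(name, barcode, members):
    return FragmentRecord(barcode=barcode, ref_name="locus",
                          start=min(m[2] for m in members),
                          end=max(m[3] for m in members), members=members)


def _aread(rid, mate, bc, start, mapq=60):
    return AlignedRead(read_id=rid, mate=mate, barcode=bc, ref_name="locus",
                       start=start, end=start + 100, strand="+", cigar="100=",
                       seq="A" * 100, mapq=mapq, edit_distance=0, score=100)


class TestTracing:
    DEL = (26479, 39000)

    def _fixture(self):
        """5 fragments carrying a junction read; 3 with in-deletion reads."""
        jr = []
        frags = []
        for i in range(5):
            bc = (10 + i, 1, 1)
            members = [(f"j{i}", 1, 25700, 25800),     # junction read
                       (f"a{i}", 1, 24000, 24100),
                       (f"b{i}", 1, 40000, 40100)]
            if i < 3:
                members.append((f"d{i}", 1, 30000, 30100))  # inside deletion
            frags.append(_fragment(f"f{i}", bc, members))
            jr.append(_aread(f"j{i}", 1, bc, 25700))
        return jr, frags

    def test_three_refuted_two_supporting(self):
        jr, frags = self._fixture()
        ev = trace_fragments(jr, frags, self.DEL)
        verdicts = sorted(e.verdict for e in ev)
        assert verdicts.count(REFUTED) == 3 and verdicts.count(SUPPORTING) == 2

    def test_single_in_deletion_read_refutes_at_min_one(self):
        jr, frags = self._fixture()
        ev = {e.fragment.name: e for e in trace_fragments(jr, frags, self.DEL,
                                                          refute_min=1)}
        assert ev["10_1_1"].verdict == REFUTED
        assert ev["10_1_1"].reads_in_deletion == 1

    def test_span_not_reaching_interval_uninformative(self):
        bc = (99, 1, 1)
        frag = _fragment("f", bc, [("j", 1, 25700, 25800), ("a", 1, 24000, 24100)])
        jr = [_aread("j", 1, bc, 25700)]
        (e,) = trace_fragments(jr, [frag], self.DEL)
        assert e.verdict == UNINFORMATIVE

    def test_alt_placement_counts_as_in_deletion(self):
        bc = (99, 1, 1)
        members = [("j", 1, 25700, 25800), ("x", 1, 96000, 96100),
                   ("b", 1, 40000, 40100)]
        frag = _fragment("f", bc, members)
        jr = [_aread("j", 1, bc, 25700)]
        x = _aread("x", 1, bc, 96000, mapq=0)
        x.tie_alts = [(30000, "+")]
        reads_by_id = {("j", 1): jr[0], ("x", 1): x,
                       ("b", 1): _aread("b", 1, bc, 40000)}
        (e,) = trace_fragments(jr, [frag], self.DEL, reads_by_id=reads_by_id)
        assert e.verdict == REFUTED

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            trace_fragments([], [], (100, 100))


class TestCnvCall:
    def _evidence(self, n_sup, n_ref):
        ev = []
        for i in range(n_sup):
            f = _fragment(f"s{i}", (i + 1, 1, 1), [("r", 1, 25000, 40000)])
            ev.append(type("E", (), {"fragment": f, "reads_in_deletion": 0,
                                     "verdict": SUPPORTING})())
        for i in range(n_ref):
            f = _fragment(f"x{i}", (i + 50, 1, 1), [("r", 1, 25000, 40000)])
            ev.append(type("E", (), {"fragment": f, "reads_in_deletion": 3,
                                     "verdict": REFUTED})())
        return ev

    CAND = BreakpointCandidate("c", 1000, 26479, 39000, 12521, "deletion")

    def test_two_supporters_make_candidate(self):
        call = call_cnv(self._evidence(2, 3), self.CAND, min_support=2)
        assert call.status == "CANDIDATE" and len(call.supporting) == 2

    def test_zero_or_one_supporter_no_call(self):
        assert call_cnv(self._evidence(0, 3), self.CAND).status == "NO_CALL"
        assert call_cnv(self._evidence(1, 3), self.CAND).status == "NO_CALL"

    def test_copy_assignment_by_exclusive_anchor_majority(self):
        anchors = AnchorRegions(Interval(10000, 24500), Interval(109500, 119500))
        ev = self._evidence(2, 0)
        reads = {}
        for i, e in enumerate(ev):
            rid = f"anch{i}"
            e.fragment.members.append((rid, 1, 20000, 20100))
            reads[(rid, 1)] = _aread(rid, 1, e.fragment.barcode, 20000)
            reads[("r", 1)] = _aread("r", 1, e.fragment.barcode, 25000, mapq=0)
        call = call_cnv(ev, self.CAND, min_support=2)
        assign_cnv_copy(call, ev, anchors, reads)
        assert call.copy == "GENE"

    def test_unanchored_supporters_unassigned(self):
        anchors = AnchorRegions(Interval(10000, 24500), Interval(109500, 119500))
        ev = self._evidence(2, 0)
        reads = {("r", 1): _aread("r", 1, (1, 1, 1), 25000, mapq=0)}
        call = call_cnv(ev, self.CAND, min_support=2)
        assign_cnv_copy(call, ev, anchors, reads)
        assert call.copy == "UNASSIGNED"
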