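"""Small-variant calling on reconstructed references.

Extracted co-barcoded reads are re-aligned to the copy-specific
reconstructed references, piled up, and called with hard filters sized
for ~20x depth.  Calls from the two references are lifted back to locus
coordinates and compared at paralogous positions to label each variant
GENE_ONLY, PSEUDO_ONLY, or BOTH.  Coding consequences (frameshift /
in-frame / missense / synonymous, splice-region proximity) and the first
affected codon of a frameshift are annotated against the transcript
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .align import ReferenceIndex, align_read, parse_cigar, refine_alignment
from .linked import AlignedRead
from .locus import LocusAnnotation, TranscriptModel
from .refbuild import ReconstructedRef, lift_to_locus
from .seq import revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"

GENE_ONLY = "GENE_ONLY"
PSEUDO_ONLY = "PSEUDO_ONLY"
BOTH = "BOTH"


@dataclass
class FilterThresholds:
    """Hard filters for pileup calls, sized for ~20x mean depth."""

    min_depth: int = 8
    min_alt_reads: int = 3
    het_low: float = 0.2
    het_high: float = 0.8
    hom_threshold: float = 0.8
    strand_bias_p: float = 0.001
    min_end_distance: int = 5

    def validate(self) -> None:
        if not (0.0 < self.het_low < self.het_high <= 1.0):
            raise ValueError("het window must satisfy 0 < low < high <= 1")
        if not 0.0 < self.hom_threshold <= 1.0:
            raise ValueError("hom threshold must be in (0, 1]")
        if min(self.min_depth, self.min_alt_reads) <= 0:
            raise ValueError("count thresholds must be positive")


def align_to_recon(reads, recon: ReconstructedRef, k_seed: int = 17,
                   band: int = 12, index: ReferenceIndex | None = None) -> list:
    """Re-align extracted reads to a reconstructed reference.

    ``reads`` may be AlignedRead objects (their stored sequence is used)
    or (read_id, mate, barcode, seq) tuples.  Reads with no exact seed
    match stay unaligned and are dropped.
    """
    if index is None:
        index = ReferenceIndex(recon.name, recon.sequence, k=k_seed)
    out = []
    for r in reads:
        if isinstance(r, AlignedRead):
            # stored sequence is reference-forward; restore read orientation
            seq = revcomp(r.seq) if r.strand == "-" else r.seq
            rid, mate, bc = r.read_id, r.mate, r.barcode
        else:
            rid, mate, bc, seq = r
        raw = align_read(seq, index, band=band)
        if raw is None:
            continue
        raw = refine_alignment(raw, recon.sequence)
        out.append(AlignedRead.from_raw(raw, rid, mate, bc, recon.name))
    return out


@dataclass
class PileupColumn:
    ref_name: str
    position: int
    depth: int
    base_counts: dict
    ins_counts: dict
    del_counts: dict
    strand_counts: dict        # base -> (fwd, rev)


class Pileup:
    """Per-position counts over one reconstructed reference.

    Insertions are keyed to the last unchanged base; deletions to their
    first deleted base.  ``end_window`` tracks how many supporting bases
    sat within that many bp of a read end (read-end artifacts).
    """

    def __init__(self, ref_name: str, length: int, end_window: int = 5):
        self.ref_name = ref_name
        self.length = length
        self.end_window = end_window
        self.base = np.zeros((2, 4, length), dtype=np.int32)   # strand, base, pos
        self.near_end = np.zeros((4, length), dtype=np.int32)
        self.ins: dict = {}    # (anchor_pos, seq) -> [fwd, rev, well_positioned]
        self.dels: dict = {}   # (first_del_pos, length) -> [fwd, rev, well_positioned]

    def add_read(self, read: AlignedRead) -> None:
        s = 0 if read.strand == "+" else 1
        codes = np.frombuffer(read.seq.encode().translate(_TRANS), dtype=np.uint8)
        codes = np.minimum(codes, 3).astype(np.intp)  # non-ACGT guarded
        L = len(read.seq)
        w = self.end_window
        r, q = read.start, 0
        for n, op in parse_cigar(read.cigar):
            if op in "=XM":
                rr = np.arange(r, r + n)
                qq = np.arange(q, q + n)
                np.add.at(self.base[s], (codes[qq], rr), 1)
                near = (qq < w) | (qq >= L - w)
                if near.any():
                    np.add.at(self.near_end, (codes[qq[near]], rr[near]), 1)
                r += n
                q += n
            elif op == "S":
                q += n
            elif op == "I":
                if r > 0:
                    key = (r - 1, read.seq[q : q + n])
                    rec = self.ins.setdefault(key, [0, 0, 0])
                    rec[s] += 1
                    if q >= w and q + n <= L - w:
                        rec[2] += 1
                q += n
            elif op == "D":
                key = (r, n)
                rec = self.dels.setdefault(key, [0, 0, 0])
                rec[s] += 1
                if q >= w and q <= L - w:
                    rec[2] += 1
                r += n

    def depth(self, pos: int) -> int:
        return int(self.base[:, :, pos].sum())

    def column(self, pos: int) -> PileupColumn:
        bc = {}
        sc = {}
        for b in range(4):
            f, r = int(self.base[0, b, pos]), int(self.base[1, b, pos])
            if f + r:
                bc[_BASE[b]] = f + r
                sc[_BASE[b]] = (f, r)
        return PileupColumn(
            ref_name=self.ref_name, position=pos, depth=self.depth(pos),
            base_counts=bc,
            ins_counts={seq: sum(v[:2]) for (p, seq), v in self.ins.items() if p == pos},
            del_counts={n: sum(v[:2]) for (p, n), v in self.dels.items() if p == pos},
            strand_counts=sc,
        )


_TRANS = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))


def pileup(alignments: list, recon: ReconstructedRef, end_window: int = 5) -> Pileup:
    """Pile all alignments onto the reconstructed reference."""
    p = Pileup(recon.name, len(recon.sequence), end_window=end_window)
    for a in alignments:
        p.add_read(a)
    return p


@dataclass
class SmallVariantCall:
    recon_name: str
    recon_pos: int             # anchor position on the recon (0-based)
    ref: str
    alt: str
    depth: int
    alt_count: int
    alt_fraction: float
    genotype: str              # het | hom
    filter_status: str         # PASS or the first failing filter
    kind: str                  # SNV | INS | DEL
    locus_pos: int | None = None
    locus_strand: str | None = None
    gene_frame_pos: int | None = None
    origin: str | None = None
    annotation: object | None = None
    paralog: object | None = None
    event_key: tuple | None = None   # raw pileup event, pre-normalization

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"


def left_align(pos: int, ref: str, alt: str, seq: str):
    """Left-align an anchored indel representation against ``seq``."""
    changed = True
    while changed:
        changed = False
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        elif (len(ref) == 1 or len(alt) == 1) and len(ref) != len(alt) \
                and ref[-1] == alt[-1] and pos > 0:
            b = seq[pos - 1]
            ref, alt = b + ref[:-1], b + alt[:-1]
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _evaluate(depth, alt_count, af, ref_fr, alt_fr, well_positioned, t: FilterThresholds):
    if depth < t.min_depth:
        return "MIN_DEPTH"
    if alt_count < t.min_alt_reads:
        return "MIN_ALT"
    if af < t.het_low:
        return "ALLELE_FRACTION"
    if min(alt_fr) == 0 and sum(alt_fr) >= 4:
        p = fisher_exact([list(ref_fr), list(alt_fr)])[1]
        if p < t.strand_bias_p:
            return "STRAND_BIAS"
    if well_positioned == 0:
        return "END_DISTANCE"
    return "PASS"


def call_small_variants(pile: Pileup, recon: ReconstructedRef,
                        thresholds: FilterThresholds | None = None,
                        foreign: Pileup | None = None) -> list:
    """Emit pileup variants; failing events carry the failing filter name.

    ``foreign``, when given, is a pileup of the reads whose barcodes are
    anchored exclusively to the opposite copy: known cross-copy
    contamination.  Its counts are subtracted before filter evaluation,
    so depth, allele fraction and genotype describe the copy-native
    molecules only (the discovery pileup still sees every read).
    """
    t = thresholds or FilterThresholds()
    t.validate()
    seq = recon.sequence
    calls = []

    def native(pos, alt_count, key):
        depth = pile.depth(pos)
        if foreign is None:
            return depth, alt_count
        fd = foreign.depth(pos)
        if key[0] == "SNV":
            fa = int(foreign.base[:, _CODE[key[2]], pos].sum())
        elif key[0] == "INS":
            fa = sum(foreign.ins.get((key[1], key[2]), [0, 0, 0])[:2])
        else:
            fa = sum(foreign.dels.get((key[1], key[2]), [0, 0, 0])[:2])
        return max(0, depth - fd), max(0, alt_count - fa)

    def emit(pos, ref_a, alt_a, kind, key, alt_count, alt_fr, well, anchor):
        depth_n, alt_n = native(anchor, alt_count, key)
        af = alt_n / depth_n if depth_n else 0.0
        rb = int(refcode[anchor])
        ref_fr = (int(pile.base[0, rb, anchor]), int(pile.base[1, rb, anchor]))
        status = _evaluate(depth_n, alt_n, af, ref_fr, alt_fr,
                           min(well, alt_n), t)
        calls.append(SmallVariantCall(
            recon_name=recon.name, recon_pos=pos, ref=ref_a, alt=alt_a,
            depth=depth_n, alt_count=alt_n, alt_fraction=af,
            genotype="hom" if af >= t.hom_threshold else "het",
            filter_status=status, kind=kind, event_key=key))

    total = pile.base.sum(axis=0)  # (4, L)
    refcode = np.frombuffer(seq.encode().translate(_TRANS), dtype=np.uint8)
    cand = np.argwhere(total >= 2)
    for b, pos in cand:
        b, pos = int(b), int(pos)
        if b == refcode[pos]:
            continue
        alt_count = int(total[b, pos])
        alt_fr = (int(pile.base[0, b, pos]), int(pile.base[1, b, pos]))
        well = alt_count - int(pile.near_end[b, pos])
        emit(pos, seq[pos], _BASE[b], "SNV", ("SNV", pos, _BASE[b]),
             alt_count, alt_fr, well, pos)

    for (anchor, ins_seq), (f, r, well) in sorted(pile.ins.items()):
        if f + r < 2:
            continue
        pos, ref_a, alt_a = left_align(anchor, seq[anchor], seq[anchor] + ins_seq, seq)
        emit(pos, ref_a, alt_a, "INS", ("INS", anchor, ins_seq),
             f + r, (f, r), well, anchor)

    for (first_del, n), (f, r, well) in sorted(pile.dels.items()):
        if f + r < 2 or first_del == 0:
            continue
        anchor = first_del - 1
        pos, ref_a, alt_a = left_align(anchor, seq[anchor : first_del + n],
                                       seq[anchor], seq)
        emit(pos, ref_a, alt_a, "DEL", ("DEL", first_del, n),
             f + r, (f, r), well, anchor)

    # merge duplicate representations after normalization
    merged: dict = {}
    for c in calls:
        key = (c.recon_pos, c.ref, c.alt)
        if key not in merged or (c.is_pass and not merged[key].is_pass):
            merged[key] = c
    return sorted(merged.values(), key=lambda c: (c.recon_pos, c.ref, c.alt))


def lift_call(call: SmallVariantCall, recon: ReconstructedRef,
              ann: LocusAnnotation) -> SmallVariantCall:
    """Fill locus position/strand and the gene-frame paralog coordinate."""
    pos, strand = lift_to_locus(recon, call.recon_pos)
    call.locus_pos, call.locus_strand = pos, strand
    if strand == "-" and ann.pseudogene.contains(pos):
        call.gene_frame_pos = ann.paralogous_position(pos)
    else:
        call.gene_frame_pos = pos
    return call


def assign_origin(calls1: list, calls2: list, recon1: ReconstructedRef,
                  recon2: ReconstructedRef, ann: LocusAnnotation,
                  tolerance: int = 2) -> list:
    """Label lifted PASS calls GENE_ONLY / PSEUDO_ONLY / BOTH.

    Both reconstructed references read gene-forward, so a paralogous pair
    shares its normalized alleles; positions must agree within
    ``tolerance`` bp in the gene frame (identical repeat context makes
    exact coordinates unstable).
    """
    for c in calls1:
        lift_call(c, recon1, ann)
    for c in calls2:
        lift_call(c, recon2, ann)
    pass2 = [c for c in calls2 if c.is_pass]
    used = set()
    for c1 in calls1:
        if not c1.is_pass:
            continue
        for j, c2 in enumerate(pass2):
            if j in used:
                continue
            if (c1.ref, c1.alt) == (c2.ref, c2.alt) and \
                    abs(c1.gene_frame_pos - c2.gene_frame_pos) <= tolerance:
                c1.origin = c2.origin = BOTH
                c1.paralog = c2
                used.add(j)
                break
        else:
            c1.origin = GENE_ONLY
    for j, c2 in enumerate(pass2):
        if j not in used:
            c2.origin = PSEUDO_ONLY
    merged = [c for c in calls1 if c.is_pass]
    merged += [c for j, c in enumerate(pass2) if j not in used]
    return sorted(merged, key=lambda c: (c.gene_frame_pos, c.ref, c.alt))


def _read_supports(read: AlignedRead, key: tuple) -> bool:
    kind, pos, what = key
    if not (read.start <= pos < read.end + 1):
        return False
    r, q = read.start, 0
    for n, op in parse_cigar(read.cigar):
        if op in "=XM":
            if kind == "SNV" and r <= pos < r + n:
                return read.seq[q + (pos - r)] == what
            r += n
            q += n
        elif op == "S":
            q += n
        elif op == "I":
            if kind == "INS" and r - 1 == pos and read.seq[q : q + n] == what:
                return True
            q += n
        else:
            if kind == "DEL" and r == pos and n == what:
                return True
            r += n
    return False


def alt_support_barcodes(call: SmallVariantCall, alignments: list) -> set:
    """Barcodes of reads that carry the call's alternate allele."""
    if call.event_key is None:
        return set()
    pos = call.event_key[1]
    out = set()
    for r in alignments:
        if r.start - 1 <= pos <= r.end and _read_supports(r, call.event_key):
            out.add(tuple(r.barcode))
    return out


def refine_origin_with_barcodes(merged: list, aligned1: list, aligned2: list,
                                raw_barcodes1: set, raw_barcodes2: set) -> list:
    """Validate origin labels with copy-anchored fragment support.

    Read extraction casts a wide net (anchor regions plus extension), so
    reads of opposite-copy fragments shadow each call on the other
    reconstructed reference.  The co-barcoding signal resolves it: an
    allele is native to a copy only if at least one read carrying it
    belongs to a fragment anchored *exclusively* in that copy's own
    non-homologous region (a molecule long enough to span both copies
    anchors in both regions and says nothing about which copy carries the
    allele).  Labels are rewritten accordingly; when neither side has
    anchored support the positional label stands.
    """
    only1 = raw_barcodes1 - raw_barcodes2
    only2 = raw_barcodes2 - raw_barcodes1
    for c in merged:
        calls = [c] + ([c.paralog] if c.paralog is not None else [])
        support = set()
        for cc in calls:
            support |= alt_support_barcodes(cc, aligned1 if cc.recon_name == "recon1"
                                            else aligned2)
        gene_native = bool(support & only1)
        pseudo_native = bool(support & only2)
        if gene_native and pseudo_native:
            c.origin = BOTH
        elif gene_native:
            c.origin = GENE_ONLY
        elif pseudo_native:
            c.origin = PSEUDO_ONLY
    return merged


# ---------------------------------------------------------------------------
# transcript annotation


@dataclass
class CodingAnnotation:
    cdna: str                  # c.HGVS-lite position of the event anchor
    consequence: str           # frameshift | inframe_indel | missense | synonymous | intronic | noncoding
    first_affected_codon: int | None = None
    splice_region: bool = False


def _coding_exons(transcript: TranscriptModel):
    out = []
    n = 0
    for s, e in transcript.exons:
        cs, ce = max(s, transcript.cds_start), min(e, transcript.cds_end)
        if cs < ce:
            out.append((cs, ce, n + 1))  # gene-local start/end, cDNA of first base
            n += ce - cs
    return out, n


def genome_to_cdna(pos: int, transcript: TranscriptModel) -> tuple[int, int, str]:
    """(cDNA position, offset, region) of a gene-local position.

    Region is one of ``cds`` (offset 0), ``intron`` (nearest-exon-edge
    offset: 3 bases before an acceptor whose first base is c.X gives
    (X, -3, 'intron')), ``utr5`` (c.-n) or ``utr3`` (c.*n).  Positions
    outside the transcript span raise.
    """
    span = (transcript.exons[0][0], transcript.exons[-1][1])
    if not span[0] <= pos < span[1]:
        raise ValueError(f"position {pos} outside transcript span {span}")
    exons, total = _coding_exons(transcript)
    for cs, ce, c0 in exons:
        if cs <= pos < ce:
            return c0 + (pos - cs), 0, "cds"
    for s, e in transcript.exons:
        if s <= pos < e:  # exonic but non-coding: count exonic bases to CDS
            if pos < transcript.cds_start:
                n = _exonic_between(transcript, pos - 1, transcript.cds_start)
                return n, 0, "utr5"
            n = _exonic_between(transcript, transcript.cds_end - 1, pos + 1)
            return n, 0, "utr3"
    # intronic: anchor to the nearest coding-exon edge
    best = None
    for cs, ce, c0 in exons:
        if pos < cs:
            cand = (cs - pos, c0, -(cs - pos))
        elif pos >= ce:
            cand = (pos - ce + 1, c0 + (ce - cs) - 1, pos - ce + 1)
        else:
            continue
        if best is None or cand[0] < best[0]:
            best = cand
    return best[1], best[2], "intron"


def _exonic_between(transcript: TranscriptModel, a: int, b: int) -> int:
    """Number of exonic bases strictly between gene-local positions a < b."""
    n = 0
    for s, e in transcript.exons:
        n += max(0, min(e, b) - max(s, a + 1))
    return n


def format_cdna(cdna: int, offset: int, region: str = "cds") -> str:
    if region == "utr5":
        return f"c.-{cdna}"
    if region == "utr3":
        return f"c.*{cdna}"
    if offset == 0:
        return f"c.{cdna}"
    return f"c.{cdna}{offset:+d}"


def first_affected_codon(p: int) -> int:
    """1-based index of the first codon altered by a frameshift insertion
    whose last unchanged cDNA position is ``p``."""
    if p < 1:
        raise ValueError("cDNA positions are 1-based")
    return p // 3 + 1


def cds_sequence(reference_gene_local: str, transcript: TranscriptModel) -> str:
    parts = []
    for s, e in transcript.exons:
        cs, ce = max(s, transcript.cds_start), min(e, transcript.cds_end)
        if cs < ce:
            parts.append(reference_gene_local[cs:ce])
    return "".join(parts)


def right_align(pos: int, ref: str, alt: str, seq: str):
    """3'-most equivalent representation of an anchored indel (HGVS rule)."""
    if len(alt) > len(ref) == 1:  # insertion
        ins = alt[1:]
        while pos + 1 < len(seq) and ins[0] == seq[pos + 1]:
            pos += 1
            ins = ins[1:] + seq[pos]
        return pos, seq[pos], seq[pos] + ins
    if len(ref) > len(alt) == 1:  # deletion
        dele = ref[1:]
        while pos + len(dele) + 1 < len(seq) and dele[0] == seq[pos + 1 + len(dele)]:
            pos += 1
            dele = dele[1:] + seq[pos + len(dele)]
        return pos, seq[pos] + dele, seq[pos]
    return pos, ref, alt


def classify_consequence(call: SmallVariantCall, transcript: TranscriptModel,
                         ann: LocusAnnotation,
                         gene_sequence: str | None = None) -> CodingAnnotation:
    """Coding consequence of a lifted, normalized call.

    The call anchor is interpreted in the gene frame; indels are shifted
    to their 3'-most representation first (an insertion left-aligned into
    an intron can still duplicate exonic bases — the splice-acceptor
    duplication case).  Indels whose net length is not a multiple of 3
    inside the CDS are frameshifts with their first affected codon;
    events within 3 bp of an exon boundary are flagged splice_region.
    """
    gl = ann.gene_local(call.gene_frame_pos)
    net = len(call.alt) - len(call.ref)
    ref_a, alt_a = call.ref, call.alt
    gl_left = gl
    if net != 0 and gene_sequence is not None:
        gl, ref_a, alt_a = right_align(gl, call.ref, call.alt, gene_sequence)
    cdna, offset, region = genome_to_cdna(gl, transcript)
    in_cds = region == "cds"

    def near_boundary(p):
        return any(min(abs(p - s), abs(p - (e - 1))) <= 3 for s, e in transcript.exons)

    splice = near_boundary(gl) or near_boundary(gl_left) or near_boundary(gl + max(0, -net))

    if net == 0:
        if not in_cds:
            cons = "intronic" if region == "intron" else "noncoding"
            return CodingAnnotation(format_cdna(cdna, offset, region), cons,
                                    splice_region=splice)
        if gene_sequence is not None and len(call.ref) == 1:
            codon_i = (cdna - 1) // 3
            cds = cds_sequence(gene_sequence, transcript)
            codon = cds[codon_i * 3 : codon_i * 3 + 3]
            off_in = (cdna - 1) % 3
            alt_codon = codon[:off_in] + call.alt + codon[off_in + 1 :]
            cons = "synonymous" if _translate(codon) == _translate(alt_codon) else "missense"
        else:
            cons = "missense"
        return CodingAnnotation(format_cdna(cdna, offset, region), cons,
                                splice_region=splice)

    exons, total = _coding_exons(transcript)
    if net > 0:
        # after 3'-shifting, inserted bases are exonic iff the anchor is a
        # coding base other than the last one
        affects_cds = in_cds and cdna < total
    else:
        del_start, del_len = gl + 1, -net
        affects_cds = any(cs < del_start + del_len and del_start < ce
                          for cs, ce, _ in exons)
    if not affects_cds:
        cons = "intronic" if region in ("intron",) else "noncoding"
        return CodingAnnotation(format_cdna(cdna, offset, region), cons,
                                splice_region=splice)
    if abs(net) % 3 == 0:
        return CodingAnnotation(format_cdna(cdna, offset, region), "inframe_indel",
                                splice_region=splice)
    fac = first_affected_codon(cdna) if in_cds else None
    return CodingAnnotation(format_cdna(cdna, offset, region), "frameshift",
                            first_affected_codon=fac, splice_region=splice)


_CODONS = {}


def _translate(codon: str) -> str:
    global _CODONS
    if not _CODONS:
        bases = "TCAG"
        aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
               "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
        _CODONS = {a + b + c: aas[i * 16 + j * 4 + k]
                   for i, a in enumerate(bases) for j, b in enumerate(bases)
                   for k, c in enumerate(bases)}
    return _CODONS.get(codon.upper(), "X")


def annotate_calls(calls: list, transcript: TranscriptModel, ann: LocusAnnotation,
                   gene_sequence: str) -> list:
    """Attach CodingAnnotation to calls whose anchor lies in the transcript."""
    span0 = ann.locus_pos(transcript.exons[0][0])
    span1 = ann.locus_pos(transcript.exons[-1][1])
    for c in calls:
        if c.gene_frame_pos is not None and span0 <= c.gene_frame_pos < span1:
            c.annotation = classify_consequence(c, transcript, ann, gene_sequence)
    return calls
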