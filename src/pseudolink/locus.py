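"""Synthetic gene/pseudogene locus model.

Builds a diploid test locus that reproduces the architecture that makes
gene/pseudogene pairs hard to genotype with short reads: a ~23 kb functional
gene with 10 exons, a highly homologous pseudogene 31 kb downstream in
opposite orientation carrying exons 3-10, a 35.5 kb homologous segment,
and two identical 879 bp repeats (one in intron 3, one downstream of the
last exon) whose recombination deletes exons 4-10.

All coordinates are 0-based half-open; 1-based conventions appear only at
VCF/BED/HGVS emission boundaries.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .seq import random_seq, revcomp, write_fasta

GENE = "GENE"
PSEUDO = "PSEUDO"
BOTH = "BOTH"

SNV = "SNV"
DUP_INS = "DUP_INS"
SMALL_DEL = "SMALL_DEL"
RECOMB_DEL = "RECOMB_DEL"

STOP_CODONS = frozenset(["TAA", "TAG", "TGA"])

#: Default gene-local exon intervals (0-based, half-open).  Chosen so that
#: the cumulative CDS places the first base of exon 4 at c.519 (the
#: splice-acceptor duplication context), c.700 inside exon 4 and c.1167
#: inside exon 7, with a total CDS of 2001 bases (667 codons).
DEFAULT_EXONS = (
    (1000, 1200),
    (3000, 3180),
    (5000, 5188),
    (7500, 7700),
    (9000, 9200),
    (10800, 11000),
    (12500, 12700),
    (14200, 14400),
    (16000, 16200),
    (18000, 18600),
)


@dataclass
class LocusSpec:
    """Parameters of the synthetic locus.

    Lengths are in bp.  ``homology_start`` is the gene-local start of the
    segment copied into the pseudogene; because the homologous segment
    (35.5 kb) is longer than the gene (23 kb) it necessarily extends past
    the gene end into the spacer.
    """

    gene_length: int = 23000
    n_exons: int = 10
    exon_intervals: tuple = DEFAULT_EXONS
    cds_start: int = 1050
    cds_end: int = 18283
    spacer_length: int = 31000
    pseudogene_exon_range: tuple = (3, 10)
    pseudogene_orientation: str = "reverse"
    homology_start: int = 4500
    homology_length: int = 35500
    repeat_length: int = 879
    repeat1_position: int = 5600
    repeat2_position: int = 19000
    psv_count: int = 0
    flank_length: int = 20000
    seed: int = 0

    def validate(self) -> None:
        ex = list(self.exon_intervals)
        if len(ex) != self.n_exons:
            raise ValueError("n_exons does not match exon_intervals")
        for (s, e), (s2, e2) in zip(ex, ex[1:]):
            if not (s < e <= s2 < e2):
                raise ValueError("exons must be sorted and non-overlapping")
        if ex[0][0] < 0 or ex[-1][1] > self.gene_length:
            raise ValueError("exons outside [0, gene_length)")
        intron3 = (ex[2][1], ex[3][0])
        r1 = (self.repeat1_position, self.repeat1_position + self.repeat_length)
        if not (intron3[0] <= r1[0] and r1[1] <= intron3[1]):
            raise ValueError("repeat 1 must lie inside intron 3")
        r2 = (self.repeat2_position, self.repeat2_position + self.repeat_length)
        if not (ex[-1][1] <= r2[0] and r2[1] <= self.gene_length):
            raise ValueError("repeat 2 must lie between the last exon and the gene end")
        if self.homology_length and not (
            0 <= self.homology_start <= ex[2][0]
            and self.homology_start + self.homology_length
            <= self.gene_length + self.spacer_length
        ):
            raise ValueError("homologous segment must cover exon 3 and fit the gene+spacer")
        if self.homology_length and self.homology_start + self.homology_length < r2[1]:
            raise ValueError("homologous segment must contain both repeat copies")


@dataclass
class TranscriptModel:
    """Exon/CDS model in gene-local coordinates (gene always '+')."""

    exons: tuple
    cds_start: int
    cds_end: int
    strand: str = "+"

    def coding_length(self) -> int:
        n = 0
        for s, e in self.exons:
            n += max(0, min(e, self.cds_end) - max(s, self.cds_start))
        return n

    def validate(self) -> None:
        n = self.coding_length()
        if n <= 0 or n % 3 != 0:
            raise ValueError(f"CDS length {n} is not a positive multiple of 3")


@dataclass
class Interval:
    start: int
    end: int

    def __iter__(self):
        yield self.start
        yield self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self):
        return self.end - self.start


@dataclass
class LocusAnnotation:
    """Every named interval of the built locus, in locus coordinates."""

    length: int
    gene: Interval
    exons: list                  # locus-coordinate exon intervals (gene copy)
    repeats_gene: list           # [MER67B-like copy 1, copy 2] on the gene copy
    homology_gene: Interval      # gene-side homologous segment
    pseudogene: Interval         # == pseudo-side homologous segment
    repeats_pseudo: list         # repeat copies inside the pseudogene (locus coords)
    anchor1: Interval            # gene-specific (non-homologous) region
    anchor2: Interval            # pseudogene-specific region
    pseudogene_orientation: str = "reverse"
    flank_length: int = 0

    def gene_local(self, locus_pos: int) -> int:
        return locus_pos - self.gene.start

    def locus_pos(self, gene_local: int) -> int:
        return gene_local + self.gene.start

    def in_homology(self, pos: int) -> bool:
        return self.homology_gene.contains(pos) or self.pseudogene.contains(pos)

    def paralogous_position(self, pos: int) -> int:
        """Map a locus position in one homologous copy to the other copy.

        An involution: gene-side positions map to the pseudogene and back.
        """
        hg, hp = self.homology_gene, self.pseudogene
        if hg.contains(pos):
            i = pos - hg.start
            if self.pseudogene_orientation == "reverse":
                return hp.start + (len(hp) - 1 - i)
            return hp.start + i
        if hp.contains(pos):
            i = pos - hp.start
            if self.pseudogene_orientation == "reverse":
                return hg.start + (len(hg) - 1 - i)
            return hg.start + i
        raise ValueError(f"position {pos} is outside both homologous copies")

    def named_intervals(self):
        for i, ex in enumerate(self.exons, 1):
            yield f"exon{i}", ex
        yield "MER67B_1", self.repeats_gene[0]
        yield "MER67B_2", self.repeats_gene[1]
        yield "MER67B_P1", self.repeats_pseudo[0]
        yield "MER67B_P2", self.repeats_pseudo[1]
        yield "homology", self.homology_gene
        yield "pseudogene", self.pseudogene
        yield "anchor1", self.anchor1
        yield "anchor2", self.anchor2

    def to_bed(self, path, ref_name: str = "locus") -> None:
        with open(path, "w") as fh:
            for name, iv in self.named_intervals():
                fh.write(f"{ref_name}\t{iv.start}\t{iv.end}\t{name}\n")


def default_transcript(spec: LocusSpec) -> TranscriptModel:
    t = TranscriptModel(tuple(spec.exon_intervals), spec.cds_start, spec.cds_end)
    t.validate()
    return t


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence: starts ATG, ends TAA, no internal stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_seq(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def build_locus(spec: LocusSpec) -> tuple[str, LocusAnnotation]:
    """Generate the locus reference sequence and its annotation.

    Layout: left flank | gene | spacer | pseudogene | right flank.  The
    pseudogene is a copy of the gene-side homologous segment (exons 3-10
    plus flanks including both repeats), reverse-complemented when the
    orientation is ``reverse``.  With ``homology_length == 0`` the
    pseudogene is omitted entirely.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    F = spec.flank_length
    # without a pseudogene there is nothing downstream: flank|gene|flank
    core_len = spec.gene_length + (spec.spacer_length if spec.homology_length else 0)

    core = np.frombuffer(random_seq(rng, core_len).encode(), dtype="S1").copy()

    # overwrite the concatenated coding sequence with a valid CDS
    transcript = default_transcript(spec)
    cds = _random_cds(rng, transcript.coding_length() // 3)
    k = 0
    for s, e in spec.exon_intervals:
        cs, ce = max(s, spec.cds_start), min(e, spec.cds_end)
        if cs < ce:
            core[cs:ce] = np.frombuffer(cds[k : k + ce - cs].encode(), dtype="S1")
            k += ce - cs
    # the two repeat copies are exactly identical
    r1, r2 = spec.repeat1_position, spec.repeat2_position
    core[r2 : r2 + spec.repeat_length] = core[r1 : r1 + spec.repeat_length]
    core_seq = core.tobytes().decode()

    hom_seg = core_seq[spec.homology_start : spec.homology_start + spec.homology_length]
    if spec.homology_length:
        pseudo = revcomp(hom_seg) if spec.pseudogene_orientation == "reverse" else hom_seg
        if spec.psv_count:
            arr = np.frombuffer(pseudo.encode(), dtype="S1").copy()
            pos = rng.choice(len(arr), size=spec.psv_count, replace=False)
            for p in pos:
                old = arr[p]
                choices = [b for b in (b"A", b"C", b"G", b"T") if b != old]
                arr[p] = choices[rng.integers(3)]
            pseudo = arr.tobytes().decode()
    else:
        pseudo = ""

    left = random_seq(rng, F)
    right = random_seq(rng, F)
    seq = left + core_seq + pseudo + right

    pseudo_start = F + core_len
    pseudo_end = pseudo_start + len(pseudo)
    gene = Interval(F, F + spec.gene_length)
    exons = [Interval(F + s, F + e) for s, e in spec.exon_intervals]
    rep_g = [
        Interval(F + r1, F + r1 + spec.repeat_length),
        Interval(F + r2, F + r2 + spec.repeat_length),
    ]
    hom_g = Interval(F + spec.homology_start, F + spec.homology_start + spec.homology_length)
    hom_p = Interval(pseudo_start, pseudo_end)

    ann = LocusAnnotation(
        length=len(seq),
        gene=gene,
        exons=exons,
        repeats_gene=rep_g,
        homology_gene=hom_g,
        pseudogene=hom_p,
        repeats_pseudo=[],
        anchor1=Interval(max(0, F - 10000), hom_g.start),
        anchor2=Interval(pseudo_end, min(len(seq), pseudo_end + 10000)),
        pseudogene_orientation=spec.pseudogene_orientation,
        flank_length=F,
    )
    if spec.homology_length:
        reps = []
        for r in rep_g:
            a = ann.paralogous_position(r.start)
            b = ann.paralogous_position(r.end - 1)
            reps.append(Interval(min(a, b), max(a, b) + 1))
        reps.sort(key=lambda iv: iv.start)
        ann.repeats_pseudo = reps
    return seq, ann


# ---------------------------------------------------------------------------
# haplotypes and variants


@dataclass
class VariantSpec:
    """A variant to plant on a haplotype.

    ``position`` is interpreted according to ``coord_system``:
    ``gene_local`` (default), ``locus``, or ``cdna`` (then ``position`` is
    the cDNA base and ``cdna_offset`` the intronic offset, e.g. c.519-3 is
    position 519, offset -3).  For SNV, ``sequence`` is the alternate
    base.  For DUP_INS, the insertion is anchored immediately after
    ``position`` (the last unchanged base); if ``sequence`` is None the
    ``length`` bases ending at ``position`` are duplicated.  RECOMB_DEL
    takes no position: it deletes between the two repeat copies of the
    target copy, retaining exactly one repeat at the junction.
    """

    kind: str
    target_copy: str = GENE
    haplotype_index: int = 0
    position: int | None = None
    coord_system: str = "gene_local"
    cdna_offset: int = 0
    sequence: str | None = None
    length: int = 0


class CoordMap:
    """Piecewise monotone map haplotype position -> reference position.

    Pieces are ``(hap_start, length, ref_start)`` with ``ref_start is
    None`` for inserted sequence.
    """

    def __init__(self, pieces=None, ref_length: int = 0):
        self.pieces = list(pieces) if pieces is not None else [(0, ref_length, 0)]

    def hap_length(self) -> int:
        hs, ln, _ = self.pieces[-1]
        return hs + ln

    def hap_to_ref(self, pos: int):
        for hs, ln, rs in self.pieces:
            if hs <= pos < hs + ln:
                return None if rs is None else rs + (pos - hs)
        raise IndexError(f"haplotype position {pos} out of range")

    def ref_to_hap(self, ref_pos: int):
        """Haplotype position of a reference base, or None if deleted."""
        for hs, ln, rs in self.pieces:
            if rs is not None and rs <= ref_pos < rs + ln:
                return hs + (ref_pos - rs)
        return None

    def _normalize(self):
        out = []
        for p in self.pieces:
            if p[1] <= 0:
                continue
            if out:
                hs, ln, rs = out[-1]
                hs2, ln2, rs2 = p
                if hs + ln == hs2 and (
                    (rs is None and rs2 is None)
                    or (rs is not None and rs2 is not None and rs + ln == rs2)
                ):
                    out[-1] = (hs, ln + ln2, rs)
                    continue
            out.append(p)
        self.pieces = out

    def insert(self, hap_after: int, length: int) -> None:
        """Insert ``length`` unmapped bases after haplotype pos ``hap_after``."""
        cut = hap_after + 1
        new = []
        for hs, ln, rs in self.pieces:
            if hs + ln <= cut:
                new.append((hs, ln, rs))
            elif hs >= cut:
                new.append((hs + length, ln, rs))
            else:
                lead = cut - hs
                new.append((hs, lead, rs))
                new.append((cut + length, ln - lead, None if rs is None else rs + lead))
        new.append((cut, length, None))
        new.sort()
        self.pieces = new
        self._normalize()

    def delete(self, hap_start: int, length: int) -> None:
        """Remove haplotype interval [hap_start, hap_start+length)."""
        cut_end = hap_start + length
        new = []
        for hs, ln, rs in self.pieces:
            lo, hi = max(hs, hap_start), min(hs + ln, cut_end)
            if lo >= hi:  # untouched
                new.append((hs - length if hs >= cut_end else hs, ln, rs))
                continue
            if hs < hap_start:
                new.append((hs, hap_start - hs, rs))
            if hs + ln > cut_end:
                off = cut_end - hs
                new.append((hap_start, hs + ln - cut_end, None if rs is None else rs + off))
        new.sort()
        self.pieces = new
        self._normalize()


@dataclass
class Haplotype:
    """One allele of the locus: sequence plus map back to the reference."""

    sequence: str
    coord_map: CoordMap
    applied_variants: list = field(default_factory=list)

    @classmethod
    def from_reference(cls, reference: str) -> "Haplotype":
        return cls(reference, CoordMap(ref_length=len(reference)))

    def __len__(self):
        return len(self.sequence)


def cdna_to_gene_local(transcript: TranscriptModel, cdna_pos: int, offset: int = 0) -> int:
    """Gene-local position of c.<cdna_pos> (with optional intronic offset)."""
    if cdna_pos < 1:
        raise ValueError("cDNA positions are 1-based")
    n = 0
    for s, e in transcript.exons:
        cs, ce = max(s, transcript.cds_start), min(e, transcript.cds_end)
        if cs >= ce:
            continue
        if n + (ce - cs) >= cdna_pos:
            return cs + (cdna_pos - n - 1) + offset
        n += ce - cs
    raise ValueError(f"c.{cdna_pos} beyond CDS of length {n}")


def _resolve_edits(variant: VariantSpec, annotation: LocusAnnotation,
                   transcript: TranscriptModel, reference: str):
    """Expand one VariantSpec into concrete reference-coordinate edits.

    Each edit is ``('sub', pos, alt)``, ``('ins', after_pos, seq)`` or
    ``('del', start, length)``.
    """
    if variant.kind == RECOMB_DEL:
        if variant.target_copy == BOTH:
            raise ValueError("RECOMB_DEL targets a single copy")
        reps = (annotation.repeats_gene if variant.target_copy == GENE
                else annotation.repeats_pseudo)
        if len(reps) != 2:
            raise ValueError(f"{variant.target_copy} copy lacks two repeat copies")
        return [("del", reps[0].start, reps[1].start - reps[0].start)]

    if variant.position is None:
        raise ValueError(f"{variant.kind} requires a position")
    if variant.coord_system == "cdna":
        gl = cdna_to_gene_local(transcript, variant.position, variant.cdna_offset)
        pos = annotation.locus_pos(gl)
    elif variant.coord_system == "gene_local":
        pos = annotation.locus_pos(variant.position)
    elif variant.coord_system == "locus":
        pos = variant.position
    else:
        raise ValueError(f"unknown coord_system {variant.coord_system!r}")

    if variant.target_copy == BOTH and not annotation.homology_gene.contains(pos):
        raise ValueError("a BOTH variant must lie inside the homologous region")

    edits = []
    if variant.kind == SNV:
        alt = variant.sequence
        if not alt or len(alt) != 1:
            raise ValueError("SNV needs a single alternate base")
        edits.append(("sub", pos, alt))
        if variant.target_copy == BOTH:
            edits.append(("sub", annotation.paralogous_position(pos), revcomp(alt)))
    elif variant.kind == DUP_INS:
        ins = variant.sequence
        if ins is None:
            if variant.length <= 0:
                raise ValueError("duplication needs sequence or length")
            ins = reference[pos - variant.length + 1 : pos + 1]
        edits.append(("ins", pos, ins))
        if variant.target_copy == BOTH:
            # "after pos" in gene orientation = "before paralog(pos)" forward
            edits.append(("ins", annotation.paralogous_position(pos) - 1, revcomp(ins)))
    elif variant.kind == SMALL_DEL:
        if variant.length <= 0:
            raise ValueError("deletion needs a positive length")
        edits.append(("del", pos, variant.length))
        if variant.target_copy == BOTH:
            last = annotation.paralogous_position(pos + variant.length - 1)
            edits.append(("del", last, variant.length))
    else:
        raise ValueError(f"unknown variant kind {variant.kind!r}")

    if variant.target_copy == PSEUDO and variant.coord_system != "locus":
        # position was given in gene coordinates: move edits to the pseudogene
        moved = []
        for e in edits:
            if e[0] == "sub":
                moved.append(("sub", annotation.paralogous_position(e[1]), revcomp(e[2])))
            elif e[0] == "ins":
                moved.append(("ins", annotation.paralogous_position(e[1]) - 1, revcomp(e[2])))
            else:
                last = annotation.paralogous_position(e[1] + e[2] - 1)
                moved.append(("del", last, e[2]))
        edits = moved
    return edits


def apply_variants(haplotype: Haplotype, variants: list, annotation: LocusAnnotation,
                   transcript: TranscriptModel, reference: str) -> Haplotype:
    """Return a new haplotype with the variants applied.

    Edits are resolved to reference coordinates, checked for overlap, and
    spliced in right-to-left so earlier coordinates stay valid; the
    coordinate map is updated alongside.
    """
    edits = []
    for v in variants:
        edits.extend(_resolve_edits(v, annotation, transcript, reference))
    spans = []
    for e in edits:
        if e[0] == "sub":
            spans.append((e[1], e[1] + 1))
        elif e[0] == "ins":
            spans.append((e[1], e[1] + 1))
        else:
            spans.append((e[1], e[1] + e[2]))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("conflicting overlapping edits")

    hap = Haplotype(haplotype.sequence, CoordMap(list(haplotype.coord_map.pieces)),
                    list(haplotype.applied_variants) + list(copy.deepcopy(variants)))
    for e in sorted(edits, key=lambda x: -x[1]):
        if e[0] == "sub":
            hp = hap.coord_map.ref_to_hap(e[1])
            if hp is None:
                raise ValueError(f"edit position {e[1]} was deleted")
            hap.sequence = hap.sequence[:hp] + e[2] + hap.sequence[hp + 1 :]
        elif e[0] == "ins":
            hp = hap.coord_map.ref_to_hap(e[1])
            if hp is None:
                raise ValueError(f"edit position {e[1]} was deleted")
            hap.sequence = hap.sequence[: hp + 1] + e[2] + hap.sequence[hp + 1 :]
            hap.coord_map.insert(hp, len(e[2]))
        else:
            hp = hap.coord_map.ref_to_hap(e[1])
            if hp is None:
                raise ValueError(f"edit position {e[1]} was deleted")
            hap.sequence = hap.sequence[:hp] + hap.sequence[hp + e[2] :]
            hap.coord_map.delete(hp, e[2])
    return hap


def truth_table(variants: list, transcript: TranscriptModel,
                annotation: LocusAnnotation, reference: str) -> list:
    """Expected-call rows for a set of planted variants.

    Small variants yield one row per affected copy with the locus
    coordinate of the edit on that copy; a RECOMB_DEL yields one CNV row
    with the deleted interval.  Genotype is het when the variant sits on
    one haplotype of the diploid.
    """
    rows = []
    by_key: dict = {}
    for v in variants:
        by_key.setdefault(
            (v.kind, v.target_copy, v.position, v.coord_system, v.cdna_offset,
             v.sequence, v.length), []
        ).append(v)
    for key, vs in by_key.items():
        v = vs[0]
        genotype = "hom" if len({x.haplotype_index for x in vs}) > 1 else "het"
        if v.kind == RECOMB_DEL:
            reps = (annotation.repeats_gene if v.target_copy == GENE
                    else annotation.repeats_pseudo)
            rows.append({
                "type": "CNV", "kind": RECOMB_DEL,
                "interval": (reps[0].start, reps[1].start),
                "origin": f"{v.target_copy}_ONLY", "genotype": genotype,
            })
            continue
        edits = _resolve_edits(v, annotation, transcript, reference)
        origin = {GENE: "GENE_ONLY", PSEUDO: "PSEUDO_ONLY", BOTH: "BOTH"}[v.target_copy]
        for e in edits:
            if e[0] == "sub":
                ref_a, alt_a = reference[e[1]], e[2]
                pos = e[1]
            elif e[0] == "ins":
                ref_a = reference[e[1]]
                alt_a = ref_a + e[2]
                pos = e[1]
            else:
                pos = e[1] - 1
                ref_a = reference[pos : pos + e[2] + 1]
                alt_a = reference[pos]
            rows.append({
                "type": "SMALL", "kind": v.kind, "locus_pos": pos,
                "ref": ref_a, "alt": alt_a, "genotype": genotype,
                "origin": origin,
            })
    return rows


def write_truth_tsv(rows: list, path) -> None:
    cols = ["type", "kind", "locus_pos", "interval", "ref", "alt", "genotype", "origin"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, ".")) for c in cols) + "\n")


def write_truth_vcf(rows: list, path, ref_name: str = "locus") -> None:
    """Minimal VCF of the planted truth (1-based positions at emission)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Copy of origin">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(rows, key=lambda x: x.get("locus_pos", x.get("interval", (0,))[0])):
            if r["type"] == "CNV":
                s, e = r["interval"]
                fh.write(f"{ref_name}\t{s + 1}\t.\tN\t<DEL>\t.\t.\t"
                         f"SVTYPE=DEL;END={e};ORIGIN={r['origin']}\n")
            else:
                fh.write(f"{ref_name}\t{r['locus_pos'] + 1}\t.\t{r['ref']}\t{r['alt']}\t.\t.\t"
                         f"ORIGIN={r['origin']}\n")


def write_locus_fasta(path, reference: str, name: str = "locus") -> None:
    write_fasta(path, [(name, reference)])
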