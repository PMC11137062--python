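"""Reconstructed references and co-barcoded read extraction.

The gene and the pseudogene each have a unique (non-homologous) anchor
region.  Barcodes of confidently-mapped reads in the anchor region (plus
a 50 kb extension) identify the long molecules belonging to that copy;
*all* reads sharing those barcodes — including mapq-0 multimappers from
the homologous segment — are then extracted and re-aligned to a
copy-specific reconstructed reference.  Positions on the reconstructed
references are lifted back to locus coordinates through a strand-aware
segment map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .locus import Interval, LocusAnnotation
from .seq import revcomp

log = logging.getLogger(__name__)


@dataclass
class AnchorRegions:
    """Copy-specific anchor regions.

    ``extension`` (50 kb) widens the *reconstructed reference* span;
    barcode collection itself uses the non-homologous regions proper plus
    ``collect_extension`` (default 0 — reads of the opposite copy's
    fragments would otherwise seed the wrong barcode set).
    """

    region1: Interval            # gene-specific
    region2: Interval            # pseudogene-specific
    extension: int = 50000
    collect_extension: int = 0

    @classmethod
    def from_annotation(cls, ann: LocusAnnotation, extension: int = 50000,
                        collect_extension: int = 0) -> "AnchorRegions":
        return cls(region1=Interval(*ann.anchor1), region2=Interval(*ann.anchor2),
                   extension=extension, collect_extension=collect_extension)

    def validate(self, ann: LocusAnnotation) -> None:
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        for r in (self.region1, self.region2):
            if len(r) <= 0:
                raise ValueError("empty anchor interval")
            if r.overlaps(*ann.homology_gene) or r.overlaps(*ann.pseudogene):
                raise ValueError("anchor regions must be disjoint from the homology")


@dataclass
class ReconstructedRef:
    """Copy-specific reference with a strand-aware map back to the locus.

    ``segment_map`` rows are (recon_start, recon_end, locus_start,
    locus_end, strand); rows tile [0, len) exactly once.
    """

    name: str
    sequence: str
    segment_map: list = field(default_factory=list)

    def validate(self) -> None:
        pos = 0
        for rs, re, ls, le, strand in self.segment_map:
            if rs != pos or re - rs != le - ls or strand not in "+-":
                raise ValueError("segment map must tile the recon without overlap")
            pos = re
        if pos != len(self.sequence):
            raise ValueError("segment map does not cover the full recon length")


def _extended(region: Interval, extension: int, length: int) -> Interval:
    return Interval(max(0, region.start - extension), min(length, region.end + extension))


def collect_anchor_barcodes(reads: list, anchors: AnchorRegions, side: int,
                            mapq_min: int = 20, locus_length: int | None = None,
                            extension: int | None = None) -> set:
    """Barcodes of confidently mapped reads in one anchor region.

    Only reads with mapping quality >= ``mapq_min`` count (the anchor must
    be copy-specific evidence); unresolved barcodes are excluded.  The
    region may be widened by ``extension`` (defaults to the anchors'
    ``collect_extension``).
    """
    region = anchors.region1 if side == 1 else anchors.region2
    if len(region) <= 0:
        raise ValueError("empty anchor interval")
    L = locus_length if locus_length is not None else max((r.end for r in reads), default=0)
    if extension is None:
        extension = anchors.collect_extension
    ext = _extended(region, extension, L)
    out = set()
    for r in reads:
        if r.mapq >= mapq_min and r.overlaps(*ext) and tuple(r.barcode) != (0, 0, 0):
            out.add(tuple(r.barcode))
    return out


def fetch_cobarcoded_reads(all_reads: list, barcode_set: set) -> list:
    """Every read (any mapping quality) whose barcode is in the set."""
    sub = [r for r in all_reads if tuple(r.barcode) in barcode_set]
    log.info("fetched %d co-barcoded reads for %d barcodes", len(sub), len(barcode_set))
    return sub


def build_recon_ref(locus_seq: str, ann: LocusAnnotation, anchors: AnchorRegions,
                    side: int) -> ReconstructedRef:
    """Build the gene-side (recon1) or pseudogene-side (recon2) reference.

    recon1 spans anchor1 minus the extension through the end of the
    gene-side homologous segment, forward.  recon2 spans from there
    through anchor2 plus the extension and is emitted in the pseudogene's
    transcriptional orientation (reverse-complemented for a reverse-
    oriented pseudogene), so both references read gene-forward.
    Out-of-bounds requests are clamped.
    """
    L = len(locus_seq)
    if side == 1:
        start = max(0, anchors.region1.start - anchors.extension)
        end = ann.homology_gene.end
        if anchors.region1.start - anchors.extension < 0:
            log.info("recon1 extension clamped to locus start")
        seq = locus_seq[start:end]
        segs = [(0, end - start, start, end, "+")]
        recon = ReconstructedRef("recon1", seq, segs)
    elif side == 2:
        start = ann.homology_gene.end
        end = min(L, anchors.region2.end + anchors.extension)
        if anchors.region2.end + anchors.extension > L:
            log.info("recon2 extension clamped to locus end")
        sub = locus_seq[start:end]
        if ann.pseudogene_orientation == "reverse":
            recon = ReconstructedRef("recon2", revcomp(sub),
                                     [(0, end - start, start, end, "-")])
        else:
            recon = ReconstructedRef("recon2", sub, [(0, end - start, start, end, "+")])
    else:
        raise ValueError("side must be 1 or 2")
    recon.validate()
    return recon


def lift_to_locus(recon: ReconstructedRef, pos: int) -> tuple[int, str]:
    """Locus position and strand of a reconstructed-reference position.

    On reverse-strand segments positions reflect within the segment;
    allele strings must be reverse-complemented by the caller when the
    returned strand is '-'.
    """
    for rs, re, ls, le, strand in recon.segment_map:
        if rs <= pos < re:
            if strand == "+":
                return ls + (pos - rs), "+"
            return le - 1 - (pos - rs), "-"
    raise IndexError(f"position {pos} outside all segments of {recon.name}")


def locus_to_recon(recon: ReconstructedRef, locus_pos: int) -> int:
    """Inverse of :func:`lift_to_locus`."""
    for rs, re, ls, le, strand in recon.segment_map:
        if ls <= locus_pos < le:
            if strand == "+":
                return rs + (locus_pos - ls)
            return rs + (le - 1 - locus_pos)
    raise IndexError(f"locus position {locus_pos} outside {recon.name}")


def multimap_diagnostic(aligned_reads: list, truth_intervals: dict,
                        ann: LocusAnnotation) -> float:
    """Fraction of homology-origin reads whose best alignment is tied.

    ``truth_intervals`` maps (read_id, mate) to the read's true locus
    interval (valid on unmutated haplotypes).  This quantifies why routine
    analysis fails: with identical paralogs every read from the homologous
    region multimaps (mapq 0).
    """
    n = tied = 0
    for r in aligned_reads:
        iv = truth_intervals.get((r.read_id, r.mate))
        if iv is None:
            continue
        s, e = iv
        inside = (ann.homology_gene.start <= s and e <= ann.homology_gene.end) or (
            ann.pseudogene.start <= s and e <= ann.pseudogene.end)
        if not inside:
            continue
        n += 1
        if r.tie_alts or r.mapq == 0:
            tied += 1
    return tied / n if n else 0.0


def write_segment_map_tsv(recon: ReconstructedRef, path) -> None:
    with open(path, "w") as fh:
        fh.write("recon_start\trecon_end\tlocus_start\tlocus_end\tstrand\n")
        for row in recon.segment_map:
            fh.write("\t".join(map(str, row)) + "\n")


def write_barcode_list(barcodes: set, path) -> None:
    with open(path, "w") as fh:
        for b in sorted(barcodes):
            fh.write("_".join(map(str, b)) + "\n")
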