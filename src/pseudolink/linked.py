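"""Barcode parsing, aligned-read records, and fragment reconstruction.

Co-barcoded reads that align close together on the reference are grouped
back into FragmentRecords — the in-silico reconstruction of the long DNA
molecules that stLFR beads capture.  One barcode may carry several
molecules (published average ≈1.5 fragments per barcode), so reads from
one barcode separated by more than ``max_gap`` start a new record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .align import RawAlignment, cigar_blocks, parse_cigar

UNRESOLVED = (0, 0, 0)


def parse_barcode(read_name: str) -> tuple:
    """Barcode triple from a '#b1_b2_b3'-suffixed read name.

    A trailing '/1' or '/2' mate suffix is ignored; (0,0,0) is the
    unresolved sentinel.
    """
    if read_name.count("#") != 1:
        raise ValueError(f"read {read_name!r}: missing or ambiguous barcode suffix")
    suffix = read_name.split("#", 1)[1]
    if "/" in suffix:
        suffix = suffix.split("/", 1)[0]
    parts = suffix.split("_")
    if len(parts) != 3:
        raise ValueError(f"read {read_name!r}: malformed barcode suffix {suffix!r}")
    try:
        triple = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise ValueError(f"read {read_name!r}: malformed barcode suffix {suffix!r}") from exc
    if triple != UNRESOLVED and min(triple) < 1:
        raise ValueError(f"read {read_name!r}: barcode components must be >= 1")
    return triple


def is_unresolved(barcode: tuple) -> bool:
    return tuple(barcode) == UNRESOLVED


@dataclass
class AlignedRead:
    """One aligned mate with its barcode and alignment geometry."""

    read_id: str
    mate: int
    barcode: tuple
    ref_name: str
    start: int
    end: int
    strand: str
    cigar: str                 # extended cigar (=, X, I, D)
    seq: str                   # reference-forward oriented
    mapq: int
    edit_distance: int
    score: int
    tie_alts: list = field(default_factory=list)

    @property
    def blocks(self):
        return cigar_blocks(self.start, self.cigar)

    @classmethod
    def from_raw(cls, raw: RawAlignment, read_id: str, mate: int, barcode: tuple,
                 ref_name: str) -> "AlignedRead":
        return cls(
            read_id=read_id, mate=mate, barcode=barcode, ref_name=ref_name,
            start=raw.ref_start, end=raw.ref_end, strand=raw.strand,
            cigar=raw.cigar, seq=raw.seq, mapq=raw.mapq,
            edit_distance=raw.edit_distance, score=raw.score,
            tie_alts=list(raw.tie_alts),
        )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class FragmentRecord:
    """A reconstructed long molecule: barcode, span, member reads."""

    barcode: tuple
    ref_name: str
    start: int
    end: int
    members: list              # (read_id, mate, start, end)

    @property
    def read_count(self) -> int:
        return len(self.members)

    @property
    def name(self) -> str:
        return "_".join(map(str, self.barcode))


def group_by_barcode(reads: list) -> tuple[dict, int]:
    """Partition resolved reads by barcode; unresolved excluded and counted."""
    groups: dict[tuple, list] = {}
    unresolved = 0
    for r in reads:
        if is_unresolved(r.barcode):
            unresolved += 1
        else:
            groups.setdefault(tuple(r.barcode), []).append(r)
    return groups, unresolved


def infer_fragments(grouped: dict, max_gap: int = 20000) -> list:
    """Cluster each barcode's reads into fragment records.

    Within one barcode and reference, position-sorted reads separated by
    more than ``max_gap`` (previous end to next start) open a new record.
    The 20 kb default sits below the gene-to-pseudogene spacing, so one
    barcode carrying molecules from both copies yields separate records.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    out = []
    for barcode in sorted(grouped):
        by_ref: dict[str, list] = {}
        for r in grouped[barcode]:
            by_ref.setdefault(r.ref_name, []).append(r)
        for ref_name in sorted(by_ref):
            reads = sorted(by_ref[ref_name], key=lambda r: (r.start, r.end, r.read_id))
            cur: list = []
            cur_end = None
            for r in reads:
                if cur and r.start - cur_end > max_gap:
                    out.append(_make_record(barcode, ref_name, cur))
                    cur = []
                cur.append(r)
                cur_end = max(cur_end, r.end) if cur_end is not None and len(cur) > 1 else r.end
            if cur:
                out.append(_make_record(barcode, ref_name, cur))
    return out


def _make_record(barcode, ref_name, reads) -> FragmentRecord:
    return FragmentRecord(
        barcode=barcode, ref_name=ref_name,
        start=min(r.start for r in reads), end=max(r.end for r in reads),
        members=[(r.read_id, r.mate, r.start, r.end) for r in reads],
    )


class _Clusters:
    """Sorted, merge-on-insert interval set for one barcode's reads."""

    def __init__(self, merge_gap: int):
        self.merge_gap = merge_gap
        self.ivs: list = []

    def add(self, start: int, end: int) -> None:
        new = [start, end]
        out = []
        for iv in self.ivs:
            if iv[0] - self.merge_gap <= new[1] and new[0] - self.merge_gap <= iv[1]:
                new = [min(new[0], iv[0]), max(new[1], iv[1])]
            else:
                out.append(iv)
        out.append(new)
        out.sort()
        self.ivs = out

    def dist(self, start: int, end: int) -> float:
        if not self.ivs:
            return float("inf")
        best = float("inf")
        for s, e in self.ivs:
            if start < e and s < end:
                return 0.0
            best = min(best, abs(start - e), abs(s - end))
        return best


def resolve_ambiguous_placements(grouped: dict, index, merge_gap: int = 20000) -> None:
    """Barcode-guided rescue of multimapping reads (in place).

    Uniquely mapped reads of a barcode seed position clusters; ambiguous
    reads are then attached greedily, most-confident first, to whichever
    tied placement lies closest to the growing clusters — the co-barcoding
    signal that routine mapq-0 handling throws away.  Barcodes with no
    uniquely mapped read are left at their primary placements (with
    identical paralogs their copy of origin is genuinely unidentifiable;
    the placements are at least mutually consistent).
    """
    from .align import relocate

    for barcode, reads in grouped.items():
        clusters = _Clusters(merge_gap)
        pending = []
        for i, r in enumerate(reads):
            if r.tie_alts:
                pending.append(i)
            else:
                clusters.add(r.start, r.end)
        if not clusters.ivs or not pending:
            continue
        while pending:
            best = None
            for i in pending:
                r = reads[i]
                rl = r.end - r.start
                for cand in [(r.start, r.strand)] + list(r.tie_alts):
                    d = clusters.dist(cand[0], cand[0] + rl)
                    if best is None or d < best[0]:
                        best = (d, i, cand)
            d, i, cand = best
            r = reads[i]
            if (cand[0], cand[1]) != (r.start, r.strand):
                raw = RawAlignment(
                    ref_start=r.start, ref_end=r.end, strand=r.strand,
                    cigar=r.cigar, edit_distance=r.edit_distance,
                    score=r.score, seq=r.seq, tie_alts=list(r.tie_alts),
                )
                new = relocate(raw, index, cand[0], cand[1])
                reads[i] = AlignedRead.from_raw(new, r.read_id, r.mate, r.barcode,
                                                r.ref_name)
            clusters.add(reads[i].start, reads[i].end)
            pending.remove(i)

        _parsimony_repair(reads, index, merge_gap)


def _parsimony_repair(reads: list, index, merge_gap: int, max_rounds: int = 4) -> None:
    """Bridge split clusters of one barcode via tied alternate placements.

    All tied placements score equally, so when a barcode's reads fall in
    clusters separated by more than the fragment gap, the single-molecule
    explanation is preferred.  The repair is minimal: for each inter-
    cluster gap it moves the smallest chain of ambiguous reads whose
    alternate placements step across the gap in hops of at most
    ``merge_gap``; if no such chain exists the split stands.
    """
    from .align import relocate

    for _ in range(max_rounds):
        clusters = _Clusters(merge_gap)
        for r in reads:
            clusters.add(r.start, r.end)
        if len(clusters.ivs) <= 1:
            return
        moved = False
        for (_s1, e1), (s2, _e2) in zip(clusters.ivs, clusters.ivs[1:]):
            # candidate stepping stones strictly inside the gap
            stones = []
            for i, r in enumerate(reads):
                for a, st in r.tie_alts:
                    if e1 < a and a + (r.end - r.start) < s2:
                        stones.append((a, i, st))
            stones.sort()
            chain = []
            used: set = set()
            cur = e1
            while cur + merge_gap < s2:
                # farthest stone reachable from the covered prefix
                best = None
                for a, i, st in stones:
                    if a <= cur + merge_gap and i not in used:
                        if best is None or a > best[0]:
                            best = (a, i, st)
                if best is None or best[0] <= cur:
                    chain = []
                    break
                chain.append(best)
                used.add(best[1])
                cur = best[0] + (reads[best[1]].end - reads[best[1]].start)
            for a, i, st in chain:
                r = reads[i]
                raw = RawAlignment(
                    ref_start=r.start, ref_end=r.end, strand=r.strand,
                    cigar=r.cigar, edit_distance=r.edit_distance,
                    score=r.score, seq=r.seq, tie_alts=list(r.tie_alts))
                reads[i] = AlignedRead.from_raw(
                    relocate(raw, index, a, st), r.read_id, r.mate,
                    r.barcode, r.ref_name)
                moved = True
        if not moved:
            return


def fragments_to_bed(fragments: list, path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.ref_name}\t{f.start}\t{f.end}\t{f.name}\t{f.read_count}\n")


# ---------------------------------------------------------------------------
# SAM round trip (barcode carried in the BX tag when writing)

_SAM_OPS = {"=": "M", "X": "M", "M": "M", "I": "I", "D": "D", "S": "S"}


def _sam_cigar(cigar: str) -> str:
    out = []
    for n, op in parse_cigar(cigar):
        op = _SAM_OPS[op]
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return "".join(f"{n}{op}" for n, op in out)


def write_sam(reads: list, ref_name: str, ref_length: int, path) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": ref_name, "LN": ref_length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in sorted(reads, key=lambda x: (x.start, x.read_id, x.mate)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{r.read_id}/{r.mate}"
            a.query_sequence = r.seq
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = _sam_cigar(r.cigar)
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            a.set_tag("BX", "_".join(map(str, r.barcode)), "Z")
            a.set_tag("NM", r.edit_distance, "i")
            out.write(a)


def read_sam(path) -> list:
    """Read alignments back; barcode from the BX tag, else the read name."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            name = a.query_name
            mate = 1
            if name.endswith(("/1", "/2")):
                mate = int(name[-1])
                name = name[:-2]
            if a.has_tag("BX"):
                barcode = tuple(int(x) for x in a.get_tag("BX").split("_"))
            else:
                barcode = parse_barcode(a.query_name)
            cigar = a.cigarstring.replace("M", "=")  # lossy: treated as match
            out.append(AlignedRead(
                read_id=name, mate=mate, barcode=barcode,
                ref_name=a.reference_name, start=a.reference_start,
                end=a.reference_end, strand="-" if a.is_reverse else "+",
                cigar=cigar, seq=a.query_sequence, mapq=a.mapping_quality,
                edit_distance=a.get_tag("NM") if a.has_tag("NM") else 0,
                score=len(a.query_sequence or "") - (a.get_tag("NM") if a.has_tag("NM") else 0),
            ))
    return out
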