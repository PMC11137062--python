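"""Seed-and-extend read alignment kernel.

Exact k-mer seeding against an indexed reference followed by banded
edit-distance extension (edlib).  The kernel reports every tied best
location, which is what makes the gene/pseudogene multimapping problem
visible downstream: with zero paralogous sequence variants, a read from
the homologous region matches both copies exactly and gets mapping
quality 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .seq import revcomp

_CIG = re.compile(r"(\d+)([=XIDMS])")


@dataclass
class RawAlignment:
    ref_start: int
    ref_end: int
    strand: str               # strand of the read relative to the reference
    cigar: str                # edlib extended cigar (=, X, I, D)
    edit_distance: int
    score: int                # read length minus edit distance
    seq: str                  # read sequence in reference-forward orientation
    tie_alts: list = field(default_factory=list)  # other best (start, strand)

    @property
    def mapq(self) -> int:
        return 0 if self.tie_alts else 60


def parse_cigar(cigar: str):
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


def cigar_blocks(ref_start: int, cigar: str):
    """Reference-consuming blocks as (ref_start, ref_end, read_offset)."""
    blocks = []
    r, q = ref_start, 0
    bs, qs = r, q
    open_block = False
    for n, op in parse_cigar(cigar):
        if op in "=XM":
            if not open_block:
                bs, qs = r, q
                open_block = True
            r += n
            q += n
        else:
            if open_block:
                blocks.append((bs, r, qs))
                open_block = False
            if op in "IS":
                q += n
            else:  # D
                r += n
    if open_block:
        blocks.append((bs, r, qs))
    return blocks


def _runs_from_bools(mismatch) -> list:
    """Run-length encode a boolean mismatch vector into =/X cigar runs."""
    out = []
    for m in mismatch:
        op = "X" if m else "="
        if out and out[-1][1] == op:
            out[-1][0] += 1
        else:
            out.append([1, op])
    return [(n, op) for n, op in out]


def condense_gaps(cigar: str, seq: str, ref: str, ref_start: int,
                  max_sep: int = 20, pad: int = 5) -> str:
    """Merge nearby split gaps into one contiguous indel when cost allows.

    Unit-cost alignment has no gap-open penalty, so a single biological
    insertion is often reported as several scattered small gaps whose
    placement varies between reads.  For each cluster of gaps separated by
    at most ``max_sep`` read bases, the window is re-aligned with exactly
    one contiguous gap; the representation is adopted when its unit cost
    does not exceed the original, making supporting reads agree on one
    canonical event.
    """
    runs = parse_cigar(cigar)
    if sum(1 for _n, op in runs if op in "ID") < 2:
        return cigar
    # per-base walk: list of (op, q, r)
    cells = []
    q = r = 0
    for n, op in runs:
        for _ in range(n):
            cells.append((op, q, r))
            if op in "=XM":
                q += 1
                r += 1
            elif op in "IS":
                q += 1
            else:
                r += 1
    q_end, r_end = q, r
    # gap clusters by read position
    gaps = [(i, c) for i, c in enumerate(cells) if c[0] in "ID"]
    clusters = [[gaps[0]]]
    for g in gaps[1:]:
        if g[1][1] - clusters[-1][-1][1][1] <= max_sep:
            clusters[-1].append(g)
        else:
            clusters.append([g])
    new_cells = list(cells)
    for cl in clusters:
        if len(cl) < 2:
            continue
        first_i, last_i = cl[0][0], cl[-1][0]
        # widen to matched context, staying inside the alignment
        lo = first_i
        while lo > 0 and (first_i - lo < pad or cells[lo - 1][0] not in "=XM"):
            lo -= 1
        hi = last_i + 1
        while hi < len(cells) and (hi - last_i - 1 < pad or cells[hi][0] not in "=XM"):
            hi += 1
        if lo == 0 or hi == len(cells):
            continue  # cluster touches an alignment end; leave to trimming
        q0, r0 = cells[lo][1], cells[lo][2]
        q1 = cells[hi][1]
        r1 = cells[hi][2]
        sub_q = seq[q0:q1]
        sub_r = ref[ref_start + r0 : ref_start + r1]
        net = len(sub_q) - len(sub_r)
        old_cost = sum(1 for c in cells[lo:hi] if c[0] in "XID")
        rep = _single_gap_align(sub_q, sub_r, net)
        if rep is None or rep[0] > old_cost:
            continue
        _cost, k, runs_new = rep
        new_cells[lo:hi] = [("?",)] * (hi - lo)  # placeholder, rebuilt below
        new_cells[lo] = ("REPL", runs_new)
    if all(c[0] != "REPL" for c in new_cells):
        return cigar
    # rebuild cigar
    out = []

    def push(n, op):
        if n <= 0:
            return
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))

    for c in new_cells:
        if c[0] == "?":
            continue
        if c[0] == "REPL":
            for n, op in c[1]:
                push(n, op)
        else:
            push(1, c[0])
    return "".join(f"{n}{op}" for n, op in out)


def _single_gap_align(sub_q: str, sub_r: str, net: int):
    """Best alignment of two strings with exactly one contiguous gap.

    Returns (cost, gap_position, cigar runs) or None.
    """
    import numpy as np

    a = np.frombuffer(sub_q.encode(), dtype=np.uint8)
    b = np.frombuffer(sub_r.encode(), dtype=np.uint8)
    if net == 0:
        mm = a != b
        return int(mm.sum()), 0, _runs_from_bools(mm)
    if net > 0:  # one insertion of length net in the read
        m = len(b)
        best = None
        for k in range(m + 1):
            mm_pre = a[:k] != b[:k]
            mm_suf = a[k + net :] != b[k:]
            cost = int(mm_pre.sum() + mm_suf.sum())
            if best is None or cost < best[0]:
                best = (cost, k, mm_pre, mm_suf)
        cost, k, mm_pre, mm_suf = best
        runs = _runs_from_bools(mm_pre) + [(net, "I")] + _runs_from_bools(mm_suf)
        return cost + net, k, runs
    # one deletion of length -net from the reference
    d = -net
    n = len(a)
    best = None
    for k in range(n + 1):
        mm_pre = a[:k] != b[:k]
        mm_suf = a[k:] != b[k + d :]
        cost = int(mm_pre.sum() + mm_suf.sum())
        if best is None or cost < best[0]:
            best = (cost, k, mm_pre, mm_suf)
    cost, k, mm_pre, mm_suf = best
    runs = _runs_from_bools(mm_pre) + [(d, "D")] + _runs_from_bools(mm_suf)
    return cost + d, k, runs


def trim_noisy_ends(ref_start: int, cigar: str, min_anchor: int = 8,
                    max_edit_bases: int = 2):
    """Soft-clip alignment ends that are dense in edits.

    Reads that only partially belong to the reference (e.g. crossing a
    homology boundary) align with a short garbage tail within the
    edit-distance band; everything outside the first ``min_anchor``-long
    exact run is clipped when it carries more than ``max_edit_bases``
    edited bases.  Returns (new_ref_start, new_cigar).
    """
    runs = parse_cigar(cigar)

    def scan(rs):
        acc = []
        for idx, (n, op) in enumerate(rs):
            if op == "=" and n >= min_anchor:
                return idx, acc
            acc.append((n, op))
        return len(rs), acc

    # head
    idx, acc = scan(runs)
    edit = sum(n for n, op in acc if op in "XID")
    if idx < len(runs) and edit > max_edit_bases:
        clip_q = sum(n for n, op in acc if op in "=XMIS")
        clip_r = sum(n for n, op in acc if op in "=XMD")
        runs = ([(clip_q, "S")] if clip_q else []) + runs[idx:]
        ref_start += clip_r
    # tail
    rev = runs[::-1]
    idx, acc = scan(rev)
    edit = sum(n for n, op in acc if op in "XID")
    if idx < len(rev) and edit > max_edit_bases:
        clip_q = sum(n for n, op in acc if op in "=XMIS")
        runs = rev[idx:][::-1] + ([(clip_q, "S")] if clip_q else [])
    return ref_start, "".join(f"{n}{op}" for n, op in runs)


class ReferenceIndex:
    """Exact k-mer index of one reference sequence."""

    def __init__(self, name: str, seq: str, k: int = 17):
        if k < 8:
            raise ValueError("k too small for confident seeding")
        self.name = name
        self.seq = seq
        self.k = k
        idx: dict[str, list] = {}
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i : i + k], []).append(i)
        self.index = idx

    def seed_candidates(self, seq: str, n_seeds: int = 3):
        """Candidate alignment start positions from spaced exact seeds."""
        k, L = self.k, len(seq)
        if L < k:
            raise ValueError(f"read shorter than seed length {k}")
        offsets = sorted({0, (L - k) // 2, L - k})[:n_seeds]
        cands: list[int] = []
        for off in offsets:
            for pos in self.index.get(seq[off : off + k], ()):
                cands.append(pos - off)
        # cluster within a small diagonal tolerance
        cands.sort()
        merged = []
        for c in cands:
            if not merged or c - merged[-1] > 30:
                merged.append(c)
        return merged


def align_read(seq: str, index: ReferenceIndex, band: int = 12,
               max_candidates: int = 8, tie_sep: int = 50) -> RawAlignment | None:
    """Best gapped alignment of a read against the indexed reference.

    Both strands are tried; all locations within the edit-distance band
    that tie the best score are recorded as alternates.  Returns None when
    no seed matches or the best alignment exceeds the band.
    """
    ref = index.seq
    pad = band + 2
    hits = []  # (dist, ref_start, ref_end, strand, oriented_seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for cand in index.seed_candidates(s)[: max_candidates]:
            lo = max(0, cand - pad)
            hi = min(len(ref), cand + len(s) + pad)
            res = edlib.align(s, ref[lo:hi], mode="HW", task="locations", k=band)
            if res["editDistance"] < 0:
                continue
            for st, en in res["locations"]:
                hits.append((res["editDistance"], lo + st, lo + en + 1, strand, s))
    if not hits:
        return None
    best = min(h[0] for h in hits)
    # dedupe tied locations that are essentially the same placement
    placements = []
    for h in sorted(h for h in hits if h[0] == best):
        if all(abs(h[1] - p[1]) > tie_sep or h[3] != p[3] for p in placements):
            placements.append(h)
    dist, rs, re_, strand, s = placements[0]
    res = edlib.align(s, ref[rs:re_], mode="NW", task="path")
    return RawAlignment(
        ref_start=rs, ref_end=re_, strand=strand,
        cigar=res["cigar"], edit_distance=dist, score=len(s) - dist, seq=s,
        tie_alts=[(p[1], p[3]) for p in placements[1:]],
    )


def refine_alignment(raw: RawAlignment, ref: str) -> RawAlignment:
    """Canonicalize an alignment: condense split gaps, trim noisy ends."""
    from dataclasses import replace as _replace

    cig = condense_gaps(raw.cigar, raw.seq, ref, raw.ref_start)
    rs, cig = trim_noisy_ends(raw.ref_start, cig)
    runs = parse_cigar(cig)
    ref_len = sum(n for n, op in runs if op in "=XMD")
    ed = sum(n for n, op in runs if op in "XID")
    return _replace(raw, ref_start=rs, ref_end=rs + ref_len, cigar=cig,
                    edit_distance=ed, score=len(raw.seq) - ed)


def relocate(aln: RawAlignment, index: ReferenceIndex, alt_start: int,
             alt_strand: str) -> RawAlignment:
    """Re-anchor an alignment at one of its tied alternate placements."""
    ref = index.seq
    s = aln.seq if alt_strand == aln.strand else revcomp(aln.seq)
    pad = aln.edit_distance + 2
    lo = max(0, alt_start - pad)
    hi = min(len(ref), alt_start + len(s) + pad)
    res = edlib.align(s, ref[lo:hi], mode="HW", task="path")
    st, en = res["locations"][0]
    alts = [(aln.ref_start, aln.strand)] + [
        a for a in aln.tie_alts if not (abs(a[0] - alt_start) <= 50 and a[1] == alt_strand)
    ]
    return RawAlignment(
        ref_start=lo + st, ref_end=lo + en + 1, strand=alt_strand,
        cigar=res["cigar"], edit_distance=res["editDistance"],
        score=len(s) - res["editDistance"], seq=s, tie_alts=alts,
    )
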