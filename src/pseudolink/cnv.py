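"""Recombination-deletion detection by local de novo assembly.

Co-barcoded reads extracted for the locus are assembled with a k-mer de
Bruijn assembler (optionally scaffolding across coverage holes with
N-runs, emulating linked-read scaffolders).  Contigs are aligned back to
the locus; adjacent alignment blocks whose locus projections leave a gap
expose breakpoint candidates.  Candidates at N-runs are assembly
artifacts and are excluded.  Reads passing through a surviving junction
are classified against three contexts sharing the identical repeat core
(repeat copy 1, repeat copy 2, and the deletion junction), and the long
fragments carrying them are traced: a fragment with reads inside the
putative deletion region refutes the deletion on that molecule; a
fragment spanning the region with none supports it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .locus import LocusAnnotation
from .seq import revcomp

SUPPORTING = "SUPPORTING"
REFUTED = "REFUTED"
UNINFORMATIVE = "UNINFORMATIVE"

MUT = "MUT"
REF1 = "REF1"
REF2 = "REF2"


@dataclass
class Contig:
    id: str
    sequence: str
    member_read_ids: list
    barcodes: set = field(default_factory=set)

    def __post_init__(self):
        if self.sequence != self.sequence.strip("N"):
            raise ValueError("contig must not have leading/trailing N")

    def n_runs(self):
        return [(m.start(), m.end()) for m in re.finditer(r"N+", self.sequence)]


@dataclass
class AlignmentBlock:
    contig_id: str
    contig_start: int
    contig_end: int
    locus_start: int
    locus_end: int
    strand: str
    identity: float


@dataclass
class BreakpointCandidate:
    contig_id: str
    contig_pos: int
    left_locus_anchor: int      # locus end of the left block
    right_locus_anchor: int     # locus start of the right block
    implied_gap: int
    kind: str                   # deletion | rearrangement
    caused_by_ngap: bool = False


@dataclass
class JunctionRefs:
    """The three discriminating contexts sharing one repeat core."""

    ref1_context: str
    ref2_context: str
    mut_junction: str
    flank: int
    repeat_length: int

    def contexts(self):
        return {REF1: self.ref1_context, REF2: self.ref2_context,
                MUT: self.mut_junction}


@dataclass
class FragmentEvidence:
    fragment: object            # linked.FragmentRecord
    reads_in_deletion: int
    verdict: str


@dataclass
class CnvCall:
    interval: tuple
    copy: str                   # GENE | PSEUDO | UNASSIGNED
    supporting: list            # fragment names
    refuted: list
    status: str                 # CANDIDATE | NO_CALL
    candidate: BreakpointCandidate | None = None


# ---------------------------------------------------------------------------
# assembly


def _read_items(reads):
    for r in reads:
        if hasattr(r, "seq"):
            yield f"{r.read_id}/{r.mate}", r.seq, tuple(getattr(r, "barcode", ()))
        else:
            rid, seq = r[0], r[1]
            bc = tuple(r[2]) if len(r) > 2 else ()
            yield rid, seq, bc


def assemble_local(reads, k: int = 31, min_kmer_count: int = 2,
                   scaffold: bool = False, insert_mean: int = 400,
                   min_link_pairs: int = 3, tip_length: int | None = None,
                   barcode_bridge: bool = True, bridge_min_links: int = 2) -> list:
    """de Bruijn assembly of a read set into unitigs (optionally scaffolds).

    k-mers below ``min_kmer_count`` are dropped (sequencing-error
    removal), short dead-end tips are clipped, and unambiguous paths are
    condensed.  With ``scaffold`` set, unitigs linked by at least
    ``min_link_pairs`` read pairs are joined by an N-run sized from the
    insert estimate — reproducing the N-gap phenomenon of linked-read
    scaffolders over coverage holes.

    A repeat longer than both k and the insert collapses to one unitig
    with several entries and exits, and a deletion whose junction lies
    inside the repeat adds no novel k-mer — it is invisible to the graph.
    With ``barcode_bridge`` set, entry/exit pairs of such repeat unitigs
    are resolved with co-barcoding: an entry X is joined through the
    repeat to an exit Y when at least ``bridge_min_links`` barcodes have
    reads on both X and Y but on no competing exit (the long-fragment
    information that short-read assemblers lack).
    """
    items = list(_read_items(reads))
    if not items:
        raise ValueError("empty read set")
    read_len = max(len(s) for _, s, _ in items)
    if k >= read_len:
        raise ValueError("k must be smaller than the read length")
    if k % 2 == 0:
        raise ValueError("k must be odd")

    counts: dict[str, int] = {}
    for _, s, _ in items:
        for seq in (s, revcomp(s)):
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                counts[km] = counts.get(km, 0) + 1
    solid = {km for km, c in counts.items() if c >= min_kmer_count and "N" not in km}

    _prune_low_coverage_branches(solid, counts, k)
    unitigs = _build_unitigs(solid, k)
    for _ in range(2):  # error bubbles can nest once in high-coverage repeats
        popped = _pop_bubbles(unitigs, solid, k, counts)
        if not popped:
            break
        solid -= popped
        unitigs = _build_unitigs(solid, k)
    if tip_length is None:
        tip_length = 2 * k
    unitigs = _clip_tips(unitigs, solid, k, tip_length)

    # canonical dedupe (each unitig also exists reverse-complemented)
    seen = {}
    for u in unitigs:
        key = min(u, revcomp(u))
        seen.setdefault(key, u)
    unitigs = sorted(seen.values(), key=lambda u: (-len(u), u))

    # read membership via k-mer lookup
    km2u: dict[str, tuple] = {}
    for ui, u in enumerate(unitigs):
        for i in range(len(u) - k + 1):
            km2u[u[i : i + k]] = (ui, i, "+")
        rc = revcomp(u)
        for i in range(len(rc) - k + 1):
            km2u.setdefault(rc[i : i + k], (ui, i, "-"))
    members: dict[int, list] = {i: [] for i in range(len(unitigs))}
    barcodes: dict[int, set] = {i: set() for i in range(len(unitigs))}
    placements: dict[str, tuple] = {}
    for rid, s, bc in items:
        # placement frame: the contig orientation in which the read is forward
        hit = None
        for i in (0, len(s) // 2, len(s) - k):
            if i < 0:
                break
            p = km2u.get(s[i : i + k])
            if p is not None:
                ui, off, orient = p
                hit = (ui, off - i, orient)
                break
        if hit is None:
            continue
        ui, off, orient = hit
        members[ui].append(rid)
        if bc:
            barcodes[ui].add(bc)
        placements[rid] = (ui, off, orient)

    contigs = [Contig(f"contig_{i}", u, members[i], barcodes[i])
               for i, u in enumerate(unitigs)]
    if barcode_bridge:
        read_bc = {rid: bc for rid, _s, bc in items if bc}
        contigs += _barcode_bridge(unitigs, solid, k, placements, read_bc,
                                   members, barcodes, bridge_min_links)
    if scaffold and len(contigs) > 1:
        contigs = _scaffold(contigs, placements, items, insert_mean,
                            min_link_pairs, read_len)
    return contigs


def _barcode_bridge(unitigs, solid, k, placements, read_bc, members, barcodes,
                    min_links, hood_bp: int = 3000):
    """Resolve multi-entry/multi-exit repeat unitigs with barcode linkage.

    Evidence for joining entry X through repeat R to exit Y: barcodes
    whose reads fall in X's upstream neighborhood and Y's downstream
    neighborhood (graph-BFS up to ``hood_bp`` away from R) while avoiding
    every competing entry/exit neighborhood — i.e. long fragments that
    traverse the repeat via this path and no other.
    """
    first = {}
    last = {}
    for ui, u in enumerate(unitigs):
        for orient in "+-":
            s = u if orient == "+" else revcomp(u)
            first.setdefault(s[:k], (ui, orient))
            last.setdefault(s[-k:], (ui, orient))

    def out_edges(ui, orient):
        s = unitigs[ui] if orient == "+" else revcomp(unitigs[ui])
        return [first[x] for x in _succ(s[-k:], solid) if x in first]

    def neighborhood(ui, orient, avoid):
        """Unitigs reachable from (ui, orient) moving away, within hood_bp."""
        seen_u = {ui}
        frontier = [(ui, orient, 0)]
        while frontier:
            cu, co, dist = frontier.pop()
            for nu, no in out_edges(cu, co):
                nd = dist + len(unitigs[nu])
                if nu in seen_u or nu == avoid or nd > hood_bp:
                    continue
                seen_u.add(nu)
                frontier.append((nu, no, nd))
        return seen_u

    bc_units: dict = {}
    for rid, (ui, _off, _or) in placements.items():
        bc = read_bc.get(rid)
        if bc:
            bc_units.setdefault(bc, set()).add(ui)

    flip = {"+": "-", "-": "+"}
    out = []
    seen = set()
    for ri, r in enumerate(unitigs):
        for orient in "+-":
            rs = r if orient == "+" else revcomp(r)
            entries = [last[p] for p in _pred(rs[:k], solid) if p in last]
            exits = [first[s] for s in _succ(rs[-k:], solid) if s in first]
            entries = [e for e in entries if e[0] != ri]
            exits = [e for e in exits if e[0] != ri]
            if len(entries) < 2 or len(exits) < 2:
                continue
            # neighborhoods point away from the repeat
            hood_in = {(xi, xo): neighborhood(xi, flip[xo], ri) for xi, xo in entries}
            hood_out = {(yi, yo): neighborhood(yi, yo, ri) for yi, yo in exits}
            for xi, xo in entries:
                for yi, yo in exits:
                    if xi == yi:
                        continue
                    want_x = hood_in[(xi, xo)]
                    want_y = hood_out[(yi, yo)]
                    if want_x & want_y:
                        continue  # the two sides reach each other: no junction
                    avoid = set()
                    for e, h in hood_in.items():
                        if e != (xi, xo):
                            avoid |= h
                    for e, h in hood_out.items():
                        if e != (yi, yo):
                            avoid |= h
                    avoid -= want_x | want_y | {ri}
                    support = [bc for bc, units in bc_units.items()
                               if units & want_x and units & want_y
                               and not (units & avoid)]
                    if len(support) < min_links:
                        continue
                    xs = unitigs[xi] if xo == "+" else revcomp(unitigs[xi])
                    ys = unitigs[yi] if yo == "+" else revcomp(unitigs[yi])
                    seq = xs + rs[k - 1 :] + ys[k - 1 :]
                    key = min(seq, revcomp(seq))
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(Contig(
                        f"bridge_{len(out)}", seq,
                        members[xi] + members[ri] + members[yi],
                        barcodes[xi] | barcodes[ri] | barcodes[yi]))
    return out


def _succ(km, solid):
    t = km[1:]
    return [t + b for b in "ACGT" if t + b in solid]


def _pred(km, solid):
    t = km[:-1]
    return [b + t for b in "ACGT" if b + t in solid]


def _build_unitigs(solid: set, k: int) -> list:
    starts = []
    for km in solid:
        p = _pred(km, solid)
        if len(p) != 1 or len(_succ(p[0], solid)) != 1:
            starts.append(km)
    visited = set()
    unitigs = []
    for start in sorted(starts):
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            s = _succ(cur, solid)
            if len(s) != 1:
                break
            nxt = s[0]
            if len(_pred(nxt, solid)) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    # isolated cycles
    for km in sorted(solid - visited):
        if km in visited:
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            s = _succ(cur, solid)
            if len(s) != 1 or s[0] in visited:
                break
            cur = s[0]
            path.append(cur)
            visited.add(cur)
        unitigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    return unitigs


def _prune_low_coverage_branches(solid: set, counts: dict, k: int,
                                 max_count: int = 3, ratio: int = 10,
                                 rounds: int = 3) -> None:
    """Drop rare k-mers branching off much deeper paths (in place).

    A sequencing error duplicated by chance reaches the solidity cutoff
    inside high-coverage sequence (the repeat copies stack four-fold), and
    its branch fragments the repeat path.  A k-mer seen <= ``max_count``
    times next to a k-mer seen ``ratio`` times more often is such an
    error; genuine low-coverage sequence has low-coverage neighbors.
    """
    for _ in range(rounds):
        drop = []
        for km in solid:
            c = counts.get(km, 0)
            if c > max_count:
                continue
            for nb in _succ(km, solid) + _pred(km, solid):
                if counts.get(nb, 0) >= ratio * c:
                    drop.append(km)
                    break
        if not drop:
            return
        for km in drop:
            solid.discard(km)


def _pop_bubbles(unitigs: list, solid: set, k: int, counts: dict,
                 max_len: int = 93, min_ratio: float = 3.0) -> set:
    """k-mers of low-coverage bubble branches (e.g. duplicated errors).

    Two short unitigs with identical predecessor and successor sets are
    alternative paths between the same graph points; the branch whose
    mean k-mer count is ``min_ratio`` times lower is an error path (a
    sequencing error repeated by chance — likely in high-coverage
    repeats) and its private k-mers are returned for removal.
    """
    groups: dict = {}
    for u in unitigs:
        if len(u) > max_len:
            continue
        key = (tuple(sorted(_pred(u[:k], solid))), tuple(sorted(_succ(u[-k:], solid))))
        if not key[0] or not key[1]:
            continue
        groups.setdefault(key, []).append(u)
    drop: set = set()
    for twins in groups.values():
        if len(twins) < 2:
            continue
        def mean_count(u):
            kms = [u[i : i + k] for i in range(len(u) - k + 1)]
            return sum(counts.get(km, 0) for km in kms) / len(kms)
        twins.sort(key=mean_count, reverse=True)
        top = mean_count(twins[0])
        for u in twins[1:]:
            if top >= min_ratio * mean_count(u):
                drop.update(u[i : i + k] for i in range(len(u) - k + 1))
                drop.update(revcomp(u)[i : i + k] for i in range(len(u) - k + 1))
    return drop


def _clip_tips(unitigs: list, solid: set, k: int, tip_length: int) -> list:
    out = []
    for u in unitigs:
        if len(u) >= tip_length + k:
            out.append(u)
            continue
        first, last = u[:k], u[-k:]
        dead_start = len(_pred(first, solid)) == 0
        dead_end = len(_succ(last, solid)) == 0
        branch_start = len(_pred(first, solid)) > 1
        branch_end = len(_succ(last, solid)) > 1
        if (dead_start and branch_end) or (dead_end and branch_start):
            continue  # a short tip hanging off a branch: clip
        out.append(u)
    return out if out else unitigs


def _scaffold(contigs, placements, items, insert_mean, min_link_pairs, read_len):
    """Join contigs linked by read pairs, bridging with N-runs."""
    by_pair: dict[str, dict] = {}
    for rid, s, _bc in items:
        if "/" not in rid:
            continue
        base, mate = rid.rsplit("/", 1)
        if rid in placements:
            by_pair.setdefault(base, {})[mate] = (placements[rid], len(s))
    links: dict[tuple, list] = {}
    for base, mates in by_pair.items():
        if "1" not in mates or "2" not in mates:
            continue
        (u1, o1, or1), l1 = mates["1"]
        (u2, o2, or2), l2 = mates["2"]
        if u1 == u2:
            continue
        lenA, lenB = len(contigs[u1].sequence), len(contigs[u2].sequence)
        # molecule-forward geometry: mate1 is molecule-forward, mate2 reversed
        a_mol = or1
        o1_mf = o1
        b_mol = "-" if or2 == "+" else "+"
        o2_mf = lenB - (o2 + l2)
        gap = int(insert_mean - (lenA - o1_mf) - (o2_mf + l2))
        links.setdefault(((u1, a_mol), (u2, b_mol)), []).append(gap)

    chosen = {}
    for (a, b), gaps in sorted(links.items(), key=lambda kv: -len(kv[1])):
        if len(gaps) < min_link_pairs:
            continue
        if a in chosen or any(v[0] == b for v in chosen.values()):
            continue
        chosen[a] = (b, max(1, int(np.median(gaps))))

    def oriented(ui, orient):
        s = contigs[ui].sequence
        return s if orient == "+" else revcomp(s)

    incoming = {v[0] for v in chosen.values()}
    used = set()
    out = []
    for a in sorted(chosen, key=lambda x: x[0]):
        if a in incoming or a[0] in used:
            continue
        seq_parts = [oriented(*a)]
        ids = list(contigs[a[0]].member_read_ids)
        bcs = set(contigs[a[0]].barcodes)
        used.add(a[0])
        cur = a
        while cur in chosen:
            nxt, gap = chosen[cur]
            if nxt[0] in used:
                break
            seq_parts.append("N" * gap)
            seq_parts.append(oriented(*nxt))
            ids += contigs[nxt[0]].member_read_ids
            bcs |= contigs[nxt[0]].barcodes
            used.add(nxt[0])
            cur = nxt
        out.append(Contig(f"scaffold_{len(out)}", "".join(seq_parts), ids, bcs))
    for i, c in enumerate(contigs):
        if i not in used:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# contig-to-locus alignment and breakpoints


def align_contigs(contigs: list, locus_seq: str, min_contig: int = 500,
                  min_identity: float = 95.0, k: int = 31,
                  sample_step: int = 16) -> list:
    """Decompose each contig into high-identity locus alignment blocks.

    Contigs shorter than ``min_contig`` are discarded.  Exact k-mer
    anchors are clustered by diagonal into blocks; overlapping blocks are
    trimmed on the contig so the reported blocks tile each contig's
    aligned portion in contig order.
    """
    index: dict[str, list] = {}
    for i in range(len(locus_seq) - k + 1):
        index.setdefault(locus_seq[i : i + k], []).append(i)

    out = []
    for contig in contigs:
        if len(contig.sequence) < min_contig:
            continue
        raw_blocks = []
        for strand in "+-":
            s = contig.sequence if strand == "+" else revcomp(contig.sequence)
            matches: dict[int, list] = {}  # diagonal-bucket -> [(cpos, lpos)]
            offs = list(range(0, len(s) - k + 1, sample_step))
            if offs and offs[-1] != len(s) - k:
                offs.append(len(s) - k)
            for c in offs:
                km = s[c : c + k]
                if "N" in km:
                    continue
                for p in index.get(km, ()):
                    matches.setdefault((p - c) // 50, []).append((c, p))
            clusters: dict[int, list] = {}
            for bucket in sorted(matches):
                tgt = bucket
                for nb in (bucket - 1,):
                    if nb in clusters and any(
                            abs((p - c) - (p2 - c2)) <= 50
                            for (c, p) in matches[bucket][:1]
                            for (c2, p2) in clusters[nb][-1:]):
                        tgt = nb
                clusters.setdefault(tgt, []).extend(matches[bucket])
            for pts in clusters.values():
                pts.sort()
                runs = [[pts[0]]]
                for c, p in pts[1:]:
                    pc, pp = runs[-1][-1]
                    if c - pc <= 4 * sample_step and abs((p - pp) - (c - pc)) <= 50:
                        runs[-1].append((c, p))
                    else:
                        runs.append([(c, p)])
                for run in runs:
                    cs, ls = run[0]
                    ce, le = run[-1][0] + k, run[-1][1] + k
                    if strand == "+":
                        raw_blocks.append((cs, ce, ls, le, "+"))
                    else:
                        L = len(contig.sequence)
                        raw_blocks.append((L - ce, L - cs, ls, le, "-"))
        # greedy selection by block length with contig-overlap trimming;
        # a pure-strand chain is preferred over a mixed one of equal
        # coverage (a homology junction aligns whole to either copy, and a
        # chimeric gene-forward/pseudogene-reverse mixture is an artifact)
        def select(blocks):
            blocks = sorted(blocks, key=lambda b: (-(b[1] - b[0]), b[0], b[4]))
            kept: list = []
            for cs, ce, ls, le, strand in blocks:
                for kcs, kce, *_ in kept:
                    if cs < kce and kcs < ce:
                        if cs < kcs:  # trim right side of this block
                            cut = ce - kcs
                            ce -= cut
                            if strand == "+":
                                le -= cut
                            else:
                                ls += cut
                        else:  # trim left side
                            cut = kce - cs
                            cs += cut
                            if strand == "+":
                                ls += cut
                            else:
                                le -= cut
                if ce - cs < k:
                    continue
                kept.append((cs, ce, ls, le, strand))
            return sorted(kept)

        def coverage(kept):
            return sum(ce - cs for cs, ce, *_ in kept)

        options = []
        for strand in "+-":
            pure = select([b for b in raw_blocks if b[4] == strand])
            options.append((coverage(pure), strand == "-", pure))
        mixed = select(raw_blocks)
        best_pure = max(options, key=lambda o: (o[0], -o[1]))
        if best_pure[0] >= coverage(mixed) - 2 * k:
            kept = best_pure[2]
        else:
            kept = mixed
        # exact-match extension of block edges (k-mer anchors stop short
        # of breakpoints by up to a sample step)
        ext = []
        cseq = contig.sequence
        for i, (cs, ce, ls, le, strand) in enumerate(kept):
            lo_lim = kept[i - 1][1] if i else 0
            hi_lim = kept[i + 1][0] if i + 1 < len(kept) else len(cseq)
            if strand == "+":
                while cs > lo_lim and ls > 0 and cseq[cs - 1] == locus_seq[ls - 1]:
                    cs -= 1
                    ls -= 1
                while ce < hi_lim and le < len(locus_seq) and cseq[ce] == locus_seq[le]:
                    ce += 1
                    le += 1
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
                while cs > lo_lim and le < len(locus_seq) and \
                        comp[cseq[cs - 1]] == locus_seq[le]:
                    cs -= 1
                    le += 1
                while ce < hi_lim and ls > 0 and comp[cseq[ce]] == locus_seq[ls - 1]:
                    ce += 1
                    ls -= 1
            ext.append((cs, ce, ls, le, strand))
        kept = ext
        for cs, ce, ls, le, strand in kept:
            sub = contig.sequence[cs:ce]
            if strand == "-":
                sub = revcomp(sub)
            res = edlib.align(sub, locus_seq[ls:le], mode="NW", task="distance")
            ident = 100.0 * (1.0 - res["editDistance"] / max(1, ce - cs))
            if ident >= min_identity:
                out.append(AlignmentBlock(contig.id, cs, ce, ls, le, strand, ident))
    return out


def find_breakpoints(blocks: list, join_tolerance: int = 50) -> list:
    """Breakpoint candidates from adjacent blocks of each contig.

    Same-strand adjacent blocks whose locus projections leave a gap
    larger than ``join_tolerance`` imply a deletion-type candidate;
    strand flips or locus reordering yield rearrangement candidates.
    """
    by_contig: dict[str, list] = {}
    for b in blocks:
        by_contig.setdefault(b.contig_id, []).append(b)
    out = []
    for cid in sorted(by_contig):
        bs = sorted(by_contig[cid], key=lambda b: b.contig_start)
        for a, b in zip(bs, bs[1:]):
            if a.strand == b.strand == "+":
                gap = b.locus_start - a.locus_end
                left, right = a.locus_end, b.locus_start
            elif a.strand == b.strand == "-":
                gap = a.locus_start - b.locus_end
                left, right = b.locus_end, a.locus_start
            else:
                out.append(BreakpointCandidate(cid, a.contig_end, a.locus_end,
                                               b.locus_start, 0, "rearrangement"))
                continue
            if gap > join_tolerance:
                out.append(BreakpointCandidate(cid, a.contig_end, left, right,
                                               gap, "deletion"))
            elif gap < -join_tolerance:
                out.append(BreakpointCandidate(cid, a.contig_end, left, right,
                                               0, "rearrangement"))
    return out


def filter_ngap(contigs: list, candidates: list, window: int = 50) -> list:
    """Flag candidates whose contig breakpoint sits near an N-run.

    Flagged candidates are removed from the returned list (they are
    assembly artifacts, not deletion evidence) but the flag is set on the
    input objects so reports can show them.
    """
    runs = {c.id: c.n_runs() for c in contigs}
    kept = []
    for cand in candidates:
        near = any(s - window <= cand.contig_pos <= e + window
                   for s, e in runs.get(cand.contig_id, ()))
        cand.caused_by_ngap = near
        if not near:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# junction classification and fragment tracing


def build_junction_refs(locus_seq: str, repeats: list, flank: int = 500,
                        read_length: int = 100) -> JunctionRefs:
    """The three contexts for one copy's repeat pair.

    ``repeats`` are the two repeat intervals of that copy (locus
    coordinates, ascending).  The deletion junction is upstream flank of
    repeat 1 + the repeat + downstream flank of repeat 2.
    """
    if len(repeats) != 2:
        raise ValueError("need exactly two repeat copies")
    if flank < read_length:
        raise ValueError("flank must be at least one read length")
    r1, r2 = sorted(repeats, key=lambda r: r.start)
    core1 = locus_seq[r1.start : r1.end]
    core2 = locus_seq[r2.start : r2.end]
    if core1 != core2:
        raise ValueError("repeat cores differ between the two copies")
    ref1 = locus_seq[r1.start - flank : r1.end + flank]
    ref2 = locus_seq[r2.start - flank : r2.end + flank]
    mut = locus_seq[r1.start - flank : r1.start] + core1 + \
        locus_seq[r2.end : r2.end + flank]
    return JunctionRefs(ref1, ref2, mut, flank, len(core1))


def classify_junction_read(seq: str, refs: JunctionRefs, band: int = 10) -> set:
    """Contexts achieving the read's best alignment score.

    A read wholly inside the repeat core ties all three ways; reads
    crossing into a flank resolve to {MUT, REF1} or {MUT, REF2}; only a
    read bridging flank-to-flank is unambiguous.
    """
    best: dict[str, int] = {}
    for name, ctx in refs.contexts().items():
        d = None
        for s in (seq, revcomp(seq)):
            res = edlib.align(s, ctx, mode="HW", task="distance", k=band)
            if res["editDistance"] >= 0:
                d = res["editDistance"] if d is None else min(d, res["editDistance"])
        if d is not None:
            best[name] = d
    if not best:
        raise ValueError("read aligns to none of the junction contexts")
    m = min(best.values())
    return {name for name, d in best.items() if d == m}


def select_junction_reads(reads: list, refs: JunctionRefs, band: int = 10) -> list:
    """Reads whose best placement on the deletion junction overlaps the core."""
    out = []
    core_start, core_end = refs.flank, refs.flank + refs.repeat_length
    for r in reads:
        d = None
        loc = None
        for s in (r.seq, revcomp(r.seq)):
            res = edlib.align(s, refs.mut_junction, mode="HW", task="locations", k=band)
            if res["editDistance"] >= 0 and (d is None or res["editDistance"] < d):
                d = res["editDistance"]
                loc = res["locations"][0]
        if d is None:
            continue
        s, e = loc[0], loc[1] + 1
        if s < core_end and core_start < e:
            out.append(r)
    return out


def trace_fragments(junction_reads: list, fragments: list, deletion_interval: tuple,
                    refute_min: int = 1, reads_by_id: dict | None = None) -> list:
    """Per-fragment verdicts from the deletion-region read distribution.

    A fragment carrying a junction read SUPPORTS the deletion if none of
    its co-barcoded reads lie strictly inside the deletion interval, is
    REFUTED by >= ``refute_min`` in-deletion reads, and is UNINFORMATIVE
    when its span does not reach the interval.  When ``reads_by_id`` is
    given, a member read also counts as in-deletion if any of its tied
    alternate placements falls inside — with identical paralogs a
    multimapper placed on the wrong copy must still refute.
    """
    ds, de = deletion_interval
    if de <= ds:
        raise ValueError("empty deletion interval")
    jr = {(r.read_id, r.mate) for r in junction_reads}

    def in_del(rid, mate, s, e):
        if ds <= s and e <= de:
            return True
        if reads_by_id is not None:
            r = reads_by_id.get((rid, mate))
            if r is not None:
                rl = e - s
                return any(ds <= a and a + rl <= de for a, _st in r.tie_alts)
        return False

    out = []
    for f in fragments:
        if not any((rid, mate) in jr for rid, mate, _s, _e in f.members):
            continue
        inside = sum(1 for rid, m, s, e in f.members if in_del(rid, m, s, e))
        if not (f.start < de and ds < f.end):
            verdict = UNINFORMATIVE
        elif inside >= refute_min:
            verdict = REFUTED
        elif inside == 0:
            verdict = SUPPORTING
        else:
            verdict = UNINFORMATIVE
        out.append(FragmentEvidence(f, inside, verdict))
    return out


def call_cnv(evidence: list, candidate: BreakpointCandidate,
             min_support: int = 2) -> CnvCall:
    """CANDIDATE iff enough fragments support the deletion junction."""
    supporting = [e.fragment.name for e in evidence if e.verdict == SUPPORTING]
    refuted = [e.fragment.name for e in evidence if e.verdict == REFUTED]
    status = "CANDIDATE" if len(supporting) >= min_support else "NO_CALL"
    return CnvCall(
        interval=(candidate.left_locus_anchor, candidate.right_locus_anchor),
        copy="UNASSIGNED", supporting=supporting, refuted=refuted,
        status=status, candidate=candidate)


def assign_cnv_copy(call: CnvCall, evidence: list, anchors, reads_by_id: dict,
                    mapq_min: int = 20) -> CnvCall:
    """Assign the deletion to a copy via anchor-region reads of supporters.

    Each supporting fragment votes for the copy whose anchor region holds
    at least one of its uniquely mapped reads; fragments anchored in both
    regions (molecules long enough to span both copies) or in neither are
    uninformative.  The call is assigned to the copy with the informative
    majority; a tie or no informative supporter leaves it UNASSIGNED.
    """
    if call.status != "CANDIDATE":
        return call
    sup = {e.fragment.name: e.fragment for e in evidence if e.verdict == SUPPORTING}

    def frag_hits(frag, region):
        for rid, mate, _s, _e in frag.members:
            r = reads_by_id.get((rid, mate))
            if r is not None and r.mapq >= mapq_min and r.overlaps(*region):
                return True
        return False

    g = p = 0
    for f in sup.values():
        in1, in2 = frag_hits(f, anchors.region1), frag_hits(f, anchors.region2)
        if in1 and not in2:
            g += 1
        elif in2 and not in1:
            p += 1
    if g > p:
        call.copy = "GENE"
    elif p > g:
        call.copy = "PSEUDO"
    else:
        call.copy = "UNASSIGNED"
    return call


def tracing_interval(candidate: BreakpointCandidate, ann: LocusAnnotation) -> tuple:
    """Inner inter-repeat interval of the copy matching a candidate.

    Reads inside the repeats are uninformative (identical copies), so the
    traced deletion region excludes them.
    """
    for reps in (ann.repeats_gene, ann.repeats_pseudo):
        if len(reps) != 2:
            continue
        inner = (reps[0].end, reps[1].start)
        lo = min(candidate.left_locus_anchor, candidate.right_locus_anchor)
        hi = max(candidate.left_locus_anchor, candidate.right_locus_anchor)
        if lo < inner[1] and inner[0] < hi and \
                abs(lo - inner[0]) < 2 * len(reps[0]) + 1000:
            return inner
    return (min(candidate.left_locus_anchor, candidate.right_locus_anchor),
            max(candidate.left_locus_anchor, candidate.right_locus_anchor))
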