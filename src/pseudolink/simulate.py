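"""stLFR co-barcoded read simulation.

Long high-molecular-weight fragments are drawn from the diploid
haplotypes, fragments share bead barcodes according to a zero-truncated
Poisson bead-multiplicity model, and each fragment sheds a sparse set of
100 bp read pairs (transposon insertion is per-bp, so longer fragments
get proportionally more pairs).  Presets P1-P4 carry the published
per-sample library statistics (mean fragment length, fragments per
barcode, read pairs per fragment, depth).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .seq import revcomp


@dataclass
class SimParams:
    target_depth: float = 20.0
    read_length: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    mean_fragment_length: float = 39287.7
    fragment_length_cv: float = 0.6
    fragments_per_barcode_mean: float = 1.47
    reads_per_fragment_mean: float = 21.57
    base_error_rate: float = 0.001
    n_barcodes_per_axis: int = 1536
    unresolved_barcode_rate: float = 0.05
    min_fragment_length: int = 1000
    genome_length: float = 3.1e9
    seed: int = 0

    def validate(self) -> None:
        for r in (self.base_error_rate, self.unresolved_barcode_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if min(self.mean_fragment_length, self.read_length, self.insert_mean) <= 0:
            raise ValueError("lengths must be positive")


#: Per-sample library statistics: depth, mean fragment length (bp),
#: fragments per barcode, read pairs per fragment.
PRESETS = {
    "P1": (20.3, 39287.7, 1.47, 21.57),
    "P2": (20.89, 22413.1, 1.70, 12.89),
    "P3": (19.98, 35401.7, 1.59, 15.13),
    "P4": (22.47, 48481.3, 1.47, 25.78),
}


def make_preset(name: str) -> SimParams:
    """SimParams for one of the published samples (default = P1)."""
    if name == "default":
        name = "P1"
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    depth, flen, fpb, rpf = PRESETS[name]
    p = SimParams(
        target_depth=depth,
        mean_fragment_length=flen,
        fragments_per_barcode_mean=fpb,
        reads_per_fragment_mean=rpf,
    )
    p.validate()
    return p


@dataclass
class SimFragment:
    fragment_id: int
    haplotype_index: int
    start: int
    length: int
    barcode: tuple | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimReadPair:
    pair_id: int
    fragment_id: int
    barcode: tuple
    haplotype_index: int
    seq1: str
    seq2: str
    qual: str
    m1_start: int  # haplotype coordinates, mate 1 forward
    m1_end: int
    m2_start: int  # mate 2 reverse strand
    m2_end: int


def _lognormal_lengths(rng, n, mean, cv):
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def draw_fragments(haplotypes: list, params: SimParams,
                   rng: np.random.Generator) -> list:
    """Draw long fragments so realized locus depth matches target_depth.

    The fragment count is set so that expected read bases divided by the
    single-copy locus length (the WGS depth convention) equals
    ``target_depth``; haplotypes are chosen uniformly, starts uniform,
    lengths lognormal with the configured mean.
    """
    if params.target_depth < 0:
        raise ValueError("target_depth must be >= 0")
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    locus_len = sum(len(h) for h in haplotypes) / len(haplotypes)
    n_frag = int(round(params.target_depth * locus_len
                       / (params.reads_per_fragment_mean * 2 * params.read_length)))
    if n_frag == 0:
        return []
    lengths = _lognormal_lengths(rng, n_frag, params.mean_fragment_length,
                                 params.fragment_length_cv)
    lengths = np.maximum(lengths, params.min_fragment_length).astype(int)
    hap_idx = rng.integers(0, len(haplotypes), size=n_frag)
    out = []
    for i in range(n_frag):
        h = int(hap_idx[i])
        hl = len(haplotypes[h])
        ln = int(min(lengths[i], hl))
        start = int(rng.integers(0, hl - ln + 1))
        out.append(SimFragment(i, h, start, ln))
    return out


def _zt_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean."""
    if mean < 1.0:
        raise ValueError("fragments per barcode must be >= 1")
    if mean == 1.0:
        return 0.0
    return brentq(lambda lam: lam / -np.expm1(-lam) - mean, 1e-9, 50.0)


def assign_barcodes(fragments: list, params: SimParams,
                    rng: np.random.Generator, locus_fraction: float = 1.0) -> list:
    """Assign a barcode triple to every fragment.

    Bead multiplicity (molecules per bead) is zero-truncated Poisson with
    mean ``fragments_per_barcode_mean``; which fragments share a bead is
    random (beads capture molecules independently of genomic position).
    ``locus_fraction`` is the probability that a co-bead molecule falls in
    the simulated window: at 1.0 every bead slot is a visible fragment
    (whole-genome behaviour); for a small locus inside a large genome it
    thins bead sharing to the locally observable rate.
    """
    n = len(fragments)
    if n == 0:
        return fragments
    lam = _zt_poisson_lambda(params.fragments_per_barcode_mean)
    if lam == 0.0:
        mult = np.ones(n, dtype=int)
    else:
        mult = []
        total = 0
        while total < n:
            batch = rng.poisson(lam, size=max(16, n))
            batch = batch[batch > 0]
            if locus_fraction < 1.0:
                batch = rng.binomial(batch, locus_fraction)
                batch = batch[batch > 0]
            mult.extend(batch.tolist())
            total += int(batch.sum())
        mult = np.asarray(mult, dtype=int)
    # number of beads actually consumed
    cum = np.cumsum(mult)
    n_bead = int(np.searchsorted(cum, n) + 1)
    space = params.n_barcodes_per_axis ** 3
    if n_bead > space:
        raise ValueError("barcode space smaller than required distinct barcodes")
    codes: set = set()
    while len(codes) < n_bead:
        triples = rng.integers(1, params.n_barcodes_per_axis + 1, size=(n_bead, 3))
        codes.update(map(tuple, triples.tolist()))
    codes = sorted(codes)[:n_bead]
    rng.shuffle(codes := list(codes))
    order = rng.permutation(n)
    j = 0
    for b in range(n_bead):
        for _ in range(int(mult[b])):
            if j >= n:
                break
            fragments[int(order[j])].barcode = tuple(int(x) for x in codes[b])
            j += 1
    return fragments


def sample_reads(fragment: SimFragment, haplotype_seq: str, params: SimParams,
                 rng: np.random.Generator, pair_id_start: int = 0) -> list:
    """Sample paired 100 bp reads from one fragment.

    Pair count is Poisson with mean proportional to fragment length;
    insert starts are uniform; sequencing errors are i.i.d. substitutions.
    """
    rl = params.read_length
    if fragment.length < rl:
        raise ValueError("fragment shorter than a read")
    mean_pairs = params.reads_per_fragment_mean * fragment.length / params.mean_fragment_length
    n_pairs = int(rng.poisson(mean_pairs))
    out = []
    for i in range(n_pairs):
        insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        insert = max(rl, min(insert, fragment.length))
        start = int(rng.integers(0, fragment.length - insert + 1))
        fs = fragment.start + start
        m1 = haplotype_seq[fs : fs + rl]
        m2 = revcomp(haplotype_seq[fs + insert - rl : fs + insert])
        if params.base_error_rate > 0:
            m1 = _add_errors(m1, params.base_error_rate, rng)
            m2 = _add_errors(m2, params.base_error_rate, rng)
        out.append(SimReadPair(
            pair_id=pair_id_start + i,
            fragment_id=fragment.fragment_id,
            barcode=fragment.barcode or (0, 0, 0),
            haplotype_index=fragment.haplotype_index,
            seq1=m1, seq2=m2, qual="I" * rl,
            m1_start=fs, m1_end=fs + rl,
            m2_start=fs + insert - rl, m2_end=fs + insert,
        ))
    return out


_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = _OTHER.get(s[p], "ACG")[rng.integers(3)]
    return "".join(s)


def simulate_library(haplotypes: list, params: SimParams,
                     rng: np.random.Generator | None = None):
    """Full library simulation: returns (fragments, read_pairs).

    Read pairs carry the fragment barcode except for a
    ``unresolved_barcode_rate`` share, whose barcode is the (0,0,0)
    sentinel.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fragments = draw_fragments(haplotypes, params, rng)
    locus_len = sum(len(h) for h in haplotypes) / len(haplotypes)
    assign_barcodes(fragments, params, rng,
                    locus_fraction=min(1.0, locus_len / params.genome_length))
    pairs = []
    for f in fragments:
        pairs.extend(sample_reads(f, haplotypes[f.haplotype_index], params, rng,
                                  pair_id_start=len(pairs)))
    if params.unresolved_barcode_rate > 0 and pairs:
        lost = rng.random(len(pairs)) < params.unresolved_barcode_rate
        for p, flag in zip(pairs, lost):
            if flag:
                p.barcode = (0, 0, 0)
    return fragments, pairs


def read_name(pair: SimReadPair) -> str:
    b1, b2, b3 = pair.barcode
    return f"sim:{pair.pair_id}#{b1}_{b2}_{b3}"


def write_fastq(read_pairs: list, path1, path2) -> None:
    """Write mates to two FASTQ files, matched order, sorted by pair id."""
    pairs = sorted(read_pairs, key=lambda p: p.pair_id)
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            name = read_name(p)
            f1.write(f"@{name}/1\n{p.seq1}\n+\n{p.qual}\n")
            f2.write(f"@{name}/2\n{p.seq2}\n+\n{p.qual}\n")


def write_truth_tsv(read_pairs: list, fragments: list, path) -> None:
    """Per-mate truth: haplotype, haplotype interval, fragment, barcode."""
    frag = {f.fragment_id: f for f in fragments}
    with open(path, "w") as fh:
        fh.write("pair_id\tmate\thaplotype\tstart\tend\tfragment_id\tbarcode\n")
        for p in sorted(read_pairs, key=lambda x: x.pair_id):
            f = frag[p.fragment_id]
            bc = "_".join(map(str, f.barcode or (0, 0, 0)))
            fh.write(f"{p.pair_id}\t1\t{p.haplotype_index}\t{p.m1_start}\t{p.m1_end}\t"
                     f"{p.fragment_id}\t{bc}\n")
            fh.write(f"{p.pair_id}\t2\t{p.haplotype_index}\t{p.m2_start}\t{p.m2_end}\t"
                     f"{p.fragment_id}\t{bc}\n")


def true_locus_span(fragment: SimFragment, haplotype) -> tuple:
    """Project a fragment's haplotype span onto locus coordinates."""
    cm = haplotype.coord_map
    lo = None
    for p in range(fragment.start, fragment.end):
        lo = cm.hap_to_ref(p)
        if lo is not None:
            break
    hi = None
    for p in range(fragment.end - 1, fragment.start - 1, -1):
        hi = cm.hap_to_ref(p)
        if hi is not None:
            break
    if lo is None or hi is None:
        return (0, 0)
    return (lo, hi + 1)
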