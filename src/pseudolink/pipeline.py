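"""End-to-end orchestration of the linked-read pseudogene pipeline.

Stages: simulate (or load) a co-barcoded library over the synthetic
gene/pseudogene locus -> align to the locus and reconstruct long
fragments -> collect anchor barcodes and extract co-barcoded reads ->
call small variants on the two reconstructed references and assign
gene/pseudogene origin -> detect the recombination deletion by local
assembly, junction classification and fragment tracing -> report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import cnv as cnvmod
from . import linked, locus as locusmod, refbuild, simulate as simmod, smallvar
from .align import ReferenceIndex, align_read
from .locus import LocusSpec, VariantSpec
from .simulate import SimParams, make_preset
from .smallvar import FilterThresholds

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    locus: LocusSpec = field(default_factory=LocusSpec)
    sim: SimParams = field(default_factory=lambda: make_preset("P1"))
    preset: str = "P1"
    scenario: str = "none"
    seed: int = 0
    extension: int = 50000
    anchor_mapq_min: int = 20
    fetch_mapq_min: int = 0
    max_gap: int = 20000
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    origin_tolerance: int = 2
    assembly_k: int = 31
    min_kmer_count: int = 2
    scaffold: bool = False
    min_contig: int = 500
    min_identity: float = 95.0
    join_tolerance: int = 50
    ngap_window: int = 50
    junction_flank: int = 500
    junction_band: int = 10
    refute_min: int = 1
    min_support: int = 2
    k_seed: int = 17
    align_band: int = 12
    outdir: str = "pseudolink_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["locus"]["exon_intervals"] = [list(x) for x in d["locus"]["exon_intervals"]]
        d["locus"]["pseudogene_exon_range"] = list(d["locus"]["pseudogene_exon_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "locus" in d:
            ld = dict(d["locus"])
            if "exon_intervals" in ld:
                ld["exon_intervals"] = tuple(tuple(x) for x in ld["exon_intervals"])
            if "pseudogene_exon_range" in ld:
                ld["pseudogene_exon_range"] = tuple(ld["pseudogene_exon_range"])
            d["locus"] = LocusSpec(**ld)
        if "sim" in d:
            d["sim"] = SimParams(**d["sim"])
        if "thresholds" in d:
            d["thresholds"] = FilterThresholds(**d["thresholds"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_config(preset: str = "P1", scenario: str = "none", seed: int = 0,
                **overrides) -> PipelineConfig:
    cfg = PipelineConfig(sim=make_preset(preset), preset=preset,
                         scenario=scenario, seed=seed, **overrides)
    cfg.locus = dataclasses.replace(cfg.locus, seed=seed)
    cfg.sim = dataclasses.replace(cfg.sim, seed=seed + 1)
    return cfg


def scenario_variants(name: str) -> list:
    """Planted-variant sets mirroring the four study configurations.

    P1: 4-base splice-acceptor duplication present in both copies (het).
    P2: 1-base coding duplication in the gene only (het).
    P3: 1-base coding duplication in the gene only, different exon (het).
    P4: recombination deletion between the repeat copies of the gene (het).
    """
    if name in ("none", "custom"):
        return []
    if name == "P1":
        return [VariantSpec(kind=locusmod.DUP_INS, target_copy=locusmod.BOTH,
                            haplotype_index=0, position=519, coord_system="cdna",
                            length=4)]
    if name == "P2":
        return [VariantSpec(kind=locusmod.DUP_INS, target_copy=locusmod.GENE,
                            haplotype_index=0, position=1167, coord_system="cdna",
                            length=1)]
    if name == "P3":
        return [VariantSpec(kind=locusmod.DUP_INS, target_copy=locusmod.GENE,
                            haplotype_index=0, position=700, coord_system="cdna",
                            length=1)]
    if name == "P4":
        return [VariantSpec(kind=locusmod.RECOMB_DEL, target_copy=locusmod.GENE,
                            haplotype_index=0)]
    raise ValueError(f"unknown scenario {name!r}")


@dataclass
class LocusBundle:
    reference: str
    annotation: locusmod.LocusAnnotation
    transcript: locusmod.TranscriptModel
    haplotypes: list
    variants: list
    truth: list


def build_locus_bundle(config: PipelineConfig, variants: list | None = None) -> LocusBundle:
    ref, ann = locusmod.build_locus(config.locus)
    transcript = locusmod.default_transcript(config.locus)
    if variants is None:
        variants = scenario_variants(config.scenario)
    base = locusmod.Haplotype.from_reference(ref)
    haps = []
    for hi in (0, 1):
        vs = [v for v in variants if v.haplotype_index == hi]
        haps.append(locusmod.apply_variants(base, vs, ann, transcript, ref)
                    if vs else base)
    truth = locusmod.truth_table(variants, transcript, ann, ref)
    return LocusBundle(ref, ann, transcript, haps, variants, truth)


@dataclass
class SimBundle:
    fragments: list
    pairs: list


def simulate_bundle(bundle: LocusBundle, config: PipelineConfig) -> SimBundle:
    fragments, pairs = simmod.simulate_library(
        [h.sequence for h in bundle.haplotypes], config.sim)
    log.info("simulated %d fragments, %d read pairs", len(fragments), len(pairs))
    return SimBundle(fragments, pairs)


@dataclass
class AlnBundle:
    reads: list                  # all aligned mates (locus coordinates)
    grouped: dict                # barcode -> reads
    unresolved: int
    fragments: list              # FragmentRecords
    index: ReferenceIndex
    reads_by_id: dict            # (read_id, mate) -> AlignedRead


def align_locus(pairs: list, reference: str, config: PipelineConfig,
                index: ReferenceIndex | None = None) -> list:
    """Align every simulated mate to the locus reference."""
    if index is None:
        index = ReferenceIndex("locus", reference, k=config.k_seed)
    reads = []
    for p in pairs:
        rid = f"sim:{p.pair_id}"
        for mate, seq in ((1, p.seq1), (2, p.seq2)):
            raw = align_read(seq, index, band=config.align_band)
            if raw is None:
                continue
            reads.append(linked.AlignedRead.from_raw(raw, rid, mate, p.barcode, "locus"))
    return reads


def reconstruct_fragments(reads: list, config: PipelineConfig,
                          index: ReferenceIndex) -> AlnBundle:
    grouped, unresolved = linked.group_by_barcode(reads)
    linked.resolve_ambiguous_placements(grouped, index)
    fragments = linked.infer_fragments(grouped, max_gap=config.max_gap)
    flat = [r for rs in grouped.values() for r in rs]
    flat += [r for r in reads if linked.is_unresolved(r.barcode)]
    by_id = {}
    for r in flat:
        by_id[(r.read_id, r.mate)] = r
    return AlnBundle(flat, grouped, unresolved, fragments, index, by_id)


def align_stage(sim: SimBundle, bundle: LocusBundle,
                config: PipelineConfig) -> AlnBundle:
    index = ReferenceIndex("locus", bundle.reference, k=config.k_seed)
    reads = align_locus(sim.pairs, bundle.reference, config, index)
    return reconstruct_fragments(reads, config, index)


@dataclass
class SmallVarResult:
    recon1: refbuild.ReconstructedRef
    recon2: refbuild.ReconstructedRef
    barcodes1: set
    barcodes2: set
    reads1: list
    reads2: list
    calls1: list
    calls2: list
    merged: list                 # origin-labelled PASS calls, annotated
    aligned1: list = field(default_factory=list)
    aligned2: list = field(default_factory=list)


def extract_side(aln: AlnBundle, anchors: refbuild.AnchorRegions, side: int,
                 config: PipelineConfig, locus_length: int):
    barcodes = refbuild.collect_anchor_barcodes(
        aln.reads, anchors, side, mapq_min=config.anchor_mapq_min,
        locus_length=locus_length)
    subset = refbuild.fetch_cobarcoded_reads(aln.reads, barcodes)
    return barcodes, subset


def small_variant_stage(aln: AlnBundle, bundle: LocusBundle,
                        config: PipelineConfig) -> SmallVarResult:
    ann = bundle.annotation
    anchors = refbuild.AnchorRegions.from_annotation(
        ann, extension=config.extension, collect_extension=config.extension)
    anchors.validate(ann)
    L = len(bundle.reference)
    bcs1, sub1 = extract_side(aln, anchors, 1, config, L)
    bcs2, sub2 = extract_side(aln, anchors, 2, config, L)
    # copy-anchored barcodes (no extension): the origin oracle
    raw1 = refbuild.collect_anchor_barcodes(aln.reads, anchors, 1,
                                            mapq_min=config.anchor_mapq_min,
                                            locus_length=L, extension=0)
    raw2 = refbuild.collect_anchor_barcodes(aln.reads, anchors, 2,
                                            mapq_min=config.anchor_mapq_min,
                                            locus_length=L, extension=0)
    recon1 = refbuild.build_recon_ref(bundle.reference, ann, anchors, 1)
    recon2 = refbuild.build_recon_ref(bundle.reference, ann, anchors, 2)

    calls = []
    aligned = []
    for recon, sub, foreign_set in ((recon1, sub1, raw2 - raw1),
                                    (recon2, sub2, raw1 - raw2)):
        al = smallvar.align_to_recon(sub, recon, k_seed=config.k_seed,
                                     band=config.align_band)
        pile = smallvar.pileup(al, recon,
                               end_window=config.thresholds.min_end_distance)
        foreign = smallvar.pileup(
            [r for r in al if tuple(r.barcode) in foreign_set], recon,
            end_window=config.thresholds.min_end_distance)
        calls.append(smallvar.call_small_variants(pile, recon, config.thresholds,
                                                  foreign=foreign))
        aligned.append(al)
    merged = smallvar.assign_origin(calls[0], calls[1], recon1, recon2, ann,
                                    tolerance=config.origin_tolerance)
    smallvar.refine_origin_with_barcodes(merged, aligned[0], aligned[1], raw1, raw2)
    gene_seq = bundle.reference[ann.gene.start : ann.gene.start + 40000]
    smallvar.annotate_calls(merged, bundle.transcript, ann, gene_seq)
    return SmallVarResult(recon1, recon2, bcs1, bcs2, sub1, sub2,
                          calls[0], calls[1], merged, aligned[0], aligned[1])


@dataclass
class CnvResult:
    contigs: list
    blocks: list
    candidates: list             # all breakpoint candidates (flags set)
    kept: list                   # after N-gap exclusion
    calls: list                  # (CnvCall, evidence) pairs
    junction_read_counts: dict


def _dedupe_candidates(kept: list, ann) -> list:
    """(candidate, tracing interval) pairs, one per distinct interval.

    A junction inside the homologous repeat aligns equally well to either
    copy, so a candidate whose interval matches one copy's inter-repeat
    interval is evaluated against both copies' intervals.
    """
    inner = {}
    if len(ann.repeats_gene) == 2:
        inner["gene"] = (ann.repeats_gene[0].end, ann.repeats_gene[1].start)
    if len(ann.repeats_pseudo) == 2:
        inner["pseudo"] = (ann.repeats_pseudo[0].end, ann.repeats_pseudo[1].start)
    seen = {}
    for cand in kept:
        if cand.kind != "deletion":
            continue
        iv = cnvmod.tracing_interval(cand, ann)
        if iv not in seen:
            seen[iv] = cand
        if iv in inner.values():
            for other in inner.values():
                if other != iv and other not in seen:
                    seen[other] = cand
    return [(seen[iv], iv) for iv in sorted(seen)]


def junction_prefilter(aln: AlnBundle, ann, flank: int) -> list:
    regions = [(r.start - flank, r.end + flank)
               for r in list(ann.repeats_gene) + list(ann.repeats_pseudo)]
    out = []
    for r in aln.reads:
        if any(r.start < e and s < r.end for s, e in regions):
            out.append(r)
    return out


def trace_candidate(candidate, aln: AlnBundle, bundle: LocusBundle,
                    config: PipelineConfig, interval: tuple | None = None):
    """Junction classification + fragment tracing for one candidate."""
    ann = bundle.annotation
    if interval is None:
        interval = cnvmod.tracing_interval(candidate, ann)
    gene_inner = (ann.repeats_gene[0].end, ann.repeats_gene[1].start) \
        if len(ann.repeats_gene) == 2 else None
    reps = ann.repeats_gene if interval == gene_inner else ann.repeats_pseudo
    refs = cnvmod.build_junction_refs(bundle.reference, list(reps),
                                      flank=config.junction_flank,
                                      read_length=config.sim.read_length)
    near = junction_prefilter(aln, ann, config.junction_flank)
    junction_reads = cnvmod.select_junction_reads(near, refs,
                                                  band=config.junction_band)
    evidence = cnvmod.trace_fragments(junction_reads, aln.fragments, interval,
                                      refute_min=config.refute_min,
                                      reads_by_id=aln.reads_by_id)
    return interval, refs, junction_reads, evidence


def cnv_stage(aln: AlnBundle, bundle: LocusBundle, config: PipelineConfig,
              sv: SmallVarResult | None = None) -> CnvResult:
    ann = bundle.annotation
    anchors = refbuild.AnchorRegions.from_annotation(ann, extension=config.extension)
    if sv is not None:
        pool = {(r.read_id, r.mate): r for r in sv.reads1}
        pool.update({(r.read_id, r.mate): r for r in sv.reads2})
        reads = list(pool.values())
    else:
        reads = aln.reads
    contigs = cnvmod.assemble_local(
        reads, k=config.assembly_k, min_kmer_count=config.min_kmer_count,
        scaffold=config.scaffold, insert_mean=int(config.sim.insert_mean))
    blocks = cnvmod.align_contigs(contigs, bundle.reference,
                                  min_contig=config.min_contig,
                                  min_identity=config.min_identity,
                                  k=config.assembly_k)
    candidates = cnvmod.find_breakpoints(blocks, join_tolerance=config.join_tolerance)
    kept = cnvmod.filter_ngap(contigs, candidates, window=config.ngap_window)
    calls = []
    jr_counts = {}
    for cand, iv in _dedupe_candidates(kept, ann):
        interval, refs, junction_reads, evidence = trace_candidate(
            cand, aln, bundle, config, interval=iv)
        call = cnvmod.call_cnv(evidence, cand, min_support=config.min_support)
        call.interval = interval
        cnvmod.assign_cnv_copy(call, evidence, anchors, aln.reads_by_id,
                               mapq_min=config.anchor_mapq_min)
        calls.append((call, evidence))
        jr_counts[interval] = len(junction_reads)
    return CnvResult(contigs, blocks, candidates, kept, calls, jr_counts)


def count_supporting_without_deletion(config: PipelineConfig) -> int:
    """SUPPORTING-fragment count when no deletion exists (false positives).

    Runs the junction-classification + fragment-tracing path against the
    gene copy's inter-repeat interval on a deletion-free library: every
    SUPPORTING verdict is a fragment whose read coverage happened to skip
    the deletion region — the sparse-coverage false-positive mechanism.
    No assembly stage is involved (the quantity under study is per-
    fragment read coverage).
    """
    bundle = build_locus_bundle(config, variants=[])
    sim = simulate_bundle(bundle, config)
    aln = align_stage(sim, bundle, config)
    ann = bundle.annotation
    inner = (ann.repeats_gene[0].end, ann.repeats_gene[1].start)
    refs = cnvmod.build_junction_refs(bundle.reference, list(ann.repeats_gene),
                                      flank=config.junction_flank,
                                      read_length=config.sim.read_length)
    near = junction_prefilter(aln, ann, config.junction_flank)
    jr = cnvmod.select_junction_reads(near, refs, band=config.junction_band)
    ev = cnvmod.trace_fragments(jr, aln.fragments, inner,
                                refute_min=config.refute_min,
                                reads_by_id=aln.reads_by_id)
    return sum(1 for e in ev if e.verdict == cnvmod.SUPPORTING)


# ---------------------------------------------------------------------------
# report


@dataclass
class RunReport:
    seed: int
    preset: str
    scenario: str
    library: dict
    small_variants: list
    cnv: list
    cnv_counts: dict
    multimap_fraction: float | None
    thresholds: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    def render_text(self) -> str:
        lines = [f"pseudolink run report (seed={self.seed}, preset={self.preset}, "
                 f"scenario={self.scenario})", "", "[library]"]
        for key in sorted(self.library):
            lines.append(f"  {key}: {self.library[key]}")
        lines.append("")
        lines.append("[small variants]")
        if not self.small_variants:
            lines.append("  (none)")
        for v in self.small_variants:
            lines.append("  " + "\t".join(str(v[c]) for c in _SMALLVAR_COLS))
        lines.append("")
        lines.append("[cnv]")
        for key in sorted(self.cnv_counts):
            lines.append(f"  {key}: {self.cnv_counts[key]}")
        if not self.cnv:
            lines.append("  (no candidates evaluated)")
        for c in self.cnv:
            lines.append("  " + "\t".join(str(c[k]) for k in _CNV_COLS))
        lines.append("")
        if self.multimap_fraction is not None:
            lines.append(f"[multimap diagnostic] homologous-region reads with tied "
                         f"best alignment: {self.multimap_fraction:.4f}")
        lines.append("[thresholds]")
        for key in sorted(self.thresholds):
            lines.append(f"  {key}: {self.thresholds[key]}")
        return "\n".join(lines) + "\n"


_SMALLVAR_COLS = ["gene_frame_pos", "ref", "alt", "depth", "alt_fraction",
                  "genotype", "origin", "cdna", "consequence",
                  "first_affected_codon"]
_CNV_COLS = ["interval", "status", "copy", "n_supporting", "n_refuted",
             "supporting"]


def library_stats(aln: AlnBundle, locus_length: int,
                  sim_fragments: list | None = None) -> dict:
    n_reads = len(aln.reads)
    aligned_bases = sum(r.end - r.start for r in aln.reads)
    n_barcodes = len(aln.grouped)
    n_frag = len(aln.fragments)
    # molecule length estimated from the read-pair span, de-biased with
    # the uniform order-statistics correction: for m pair starts uniform
    # on [0, L - insert], E[span] = (L - insert)(m-1)/(m+1) + insert
    spans = []
    for f in aln.fragments:
        pairs: dict = {}
        for rid, _mate, s, e in f.members:
            lo, hi = pairs.get(rid, (s, e))
            pairs[rid] = (min(lo, s), max(hi, e))
        m = len(pairs)
        if m < 2:
            continue
        insert = np.mean([hi - lo for lo, hi in pairs.values()])
        span = f.end - f.start
        spans.append(max(span, (span - insert) * (m + 1) / (m - 1) + insert))
    # pairs per fragment (the published per-fragment read-number unit)
    reads_per_frag = [len({rid for rid, *_ in f.members}) for f in aln.fragments]
    out = {
        "reads": n_reads,
        "unresolved_reads": aln.unresolved,
        "mean_depth": round(aligned_bases / locus_length, 2),
        "barcodes": n_barcodes,
        "fragments": n_frag,
        "fragments_per_barcode": round(n_frag / n_barcodes, 3) if n_barcodes else 0.0,
        "mean_inferred_fragment_length":
            round(float(np.mean(spans)), 1) if spans else 0.0,
        "reads_per_fragment": round(float(np.mean(reads_per_frag)), 2) if spans else 0.0,
    }
    if sim_fragments is not None:
        # simulation mode: the molecule truth table is a pipeline output
        out["mean_fragment_length"] = round(
            float(np.mean([f.length for f in sim_fragments])), 1)
    else:
        out["mean_fragment_length"] = out["mean_inferred_fragment_length"]
    return out


def smallvar_rows(merged: list) -> list:
    rows = []
    for c in merged:
        a = c.annotation
        rows.append({
            "gene_frame_pos": c.gene_frame_pos, "ref": c.ref, "alt": c.alt,
            "depth": c.depth, "alt_fraction": round(c.alt_fraction, 3),
            "genotype": c.genotype, "origin": c.origin,
            "cdna": a.cdna if a else ".",
            "consequence": (a.consequence + ("+splice_region" if a.splice_region else ""))
            if a else ".",
            "first_affected_codon": a.first_affected_codon if a else ".",
        })
    return rows


def cnv_rows(result: CnvResult) -> list:
    rows = []
    for call, _ev in result.calls:
        rows.append({
            "interval": f"{call.interval[0]}-{call.interval[1]}",
            "status": call.status, "copy": call.copy,
            "n_supporting": len(call.supporting), "n_refuted": len(call.refuted),
            "supporting": ",".join(call.supporting) or ".",
        })
    return rows


def run_full(config: PipelineConfig, variants: list | None = None,
             with_cnv: bool = True, with_smallvar: bool = True,
             truth_intervals: dict | None = None):
    """Execute the full strategy; returns (RunReport, artifacts dict)."""
    bundle = build_locus_bundle(config, variants)
    sim = simulate_bundle(bundle, config)
    aln = align_stage(sim, bundle, config)

    sv = small_variant_stage(aln, bundle, config) if with_smallvar else None
    cnvres = cnv_stage(aln, bundle, config, sv=sv) if with_cnv else None

    mm = None
    if truth_intervals is None and not bundle.variants:
        truth_intervals = {(f"sim:{p.pair_id}", m): (s, e)
                           for p in sim.pairs
                           for m, s, e in ((1, p.m1_start, p.m1_end),
                                           (2, p.m2_start, p.m2_end))}
    if truth_intervals:
        mm = round(refbuild.multimap_diagnostic(aln.reads, truth_intervals,
                                                bundle.annotation), 4)

    report = RunReport(
        seed=config.seed, preset=config.preset, scenario=config.scenario,
        library=library_stats(aln, len(bundle.reference),
                              sim_fragments=sim.fragments),
        small_variants=smallvar_rows(sv.merged) if sv else [],
        cnv=cnv_rows(cnvres) if cnvres else [],
        cnv_counts={
            "candidates_total": len(cnvres.candidates) if cnvres else 0,
            "excluded_ngap": sum(1 for c in (cnvres.candidates if cnvres else [])
                                 if c.caused_by_ngap),
            "evaluated": len(cnvres.calls) if cnvres else 0,
        },
        multimap_fraction=mm,
        thresholds={**dataclasses.asdict(config.thresholds),
                    "min_support": config.min_support,
                    "refute_min": config.refute_min,
                    "max_gap": config.max_gap,
                    "extension": config.extension},
    )
    artifacts = {"bundle": bundle, "sim": sim, "aln": aln, "smallvar": sv,
                 "cnv": cnvres}
    return report, artifacts
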