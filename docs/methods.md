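# Methods

`pseudolink` implements a linked-read (stLFR-style) strategy for calling
variants in a functional gene that shares a long, near-identical homologous
region with a pseudogene, and for detecting the recurrent exon deletion
caused by recombination between two identical repeats. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not show.

## The problem

A ~23 kb gene with 10 exons has a pseudogene 31 kb downstream in opposite
orientation that carries copies of exons 3–10 inside a 35.5 kb homologous
segment. Two identical 879 bp repeats — one in intron 3, one downstream of
exon 10 — mediate a recurrent recombination deletion of exons 4–10. With
zero paralogous sequence variants (PSVs), a 100 bp read from the homologous
region matches both copies exactly: routine short-read analysis assigns it
mapping quality 0 and calls nothing there. The deletion junction is equally
invisible: because the junction sequence *is* the repeat, the deletion
allele contains no base that does not also exist in the reference, and no
single read (or read pair, at ~400 bp inserts) can span the 879 bp repeat.

The information that rescues both problems is co-barcoding: all short reads
from one long DNA molecule (tens of kb) share a barcode triple, so a
molecule can be re-assembled in silico from its reads, and a molecule's
unique anchor region determines which copy its homologous-region reads came
from.

## Synthetic locus

`locus.LocusSpec` builds a 129.5 kb reference:

    flank (20 kb) | gene (23 kb) | spacer (31 kb) | pseudogene (35.5 kb) | flank (20 kb)

The homologous segment is gene-local [4500, 40000): it must extend past the
gene end because 35.5 kb > 23 kb, leaving a 14 kb locus-unique stretch of
spacer between homology end and pseudogene start. The pseudogene is the
exact reverse complement of that segment (`psv_count` plants fixed
differences when > 0; the default 0 is the hardest case). Both repeat
copies are exactly identical by construction. Exon coordinates were chosen
so that the cumulative CDS places exon 4's first base at c.519, c.700 in
exon 4, and c.1167 in exon 7 — the three published frameshift duplications
fall at their printed cDNA coordinates. The CDS (2001 nt) starts ATG, ends
TAA and contains no internal stop; all non-coding sequence is i.i.d.
uniform ACGT from the seed. The deletion spans repeat1→repeat2 = 13.4 kb,
covering exons 4–10.

Variants are planted through `VariantSpec` (SNV, duplication/insertion,
small deletion, recombination deletion) with a coordinate map per
haplotype for exact truth emission. A variant targeted at BOTH copies is
placed at paralogous positions with reverse-complemented alleles.

## Library simulation

`simulate.SimParams` carries the per-sample presets (P1–P4): mean fragment
length 39.3/22.4/35.4/48.5 kb, fragments per barcode 1.47/1.70/1.59/1.47,
read pairs per fragment 21.6/12.9/15.1/25.8, depth ≈20×, 100 bp paired-end.
Model choices where only means are published:

- fragment lengths are lognormal with CV 0.6 (heavy right tail typical of
  HMW DNA), truncated at 1 kb;
- the fragment count is set so that expected read bases / locus length =
  `target_depth` (the WGS convention; realized pileup depth ≈ 20×);
- read-pair count per fragment is Poisson, proportional to fragment length
  (transposon insertion is per-bp);
- inserts are Normal(400, 50); sequencing errors are substitutions only at
  rate 0.001; 5% of pairs lose their barcode (the (0,0,0) sentinel);
- bead multiplicity is zero-truncated Poisson matching the
  fragments-per-barcode mean, **thinned by locus_length/genome_length**
  (default 3.1 Gb): a bead's other molecules land anywhere in the genome,
  so two molecules of one bead co-occur in a 130 kb window with
  probability ~4×10⁻⁵. Simulating full sharing inside the window would
  create local barcode collisions that never occur in real data and that
  corrupt fragment reconstruction. `assign_barcodes(locus_fraction=1.0)`
  recovers the full genome-wide sharing model.

## Fragment reconstruction and multimapper rescue

Reads are aligned to the locus by exact 17-mer seeding plus banded
edit-distance extension (edlib); all tied best placements are recorded and
mapping quality 0 marks ties. Within each barcode, reads within
`max_gap = 20 kb` (safely below the 31 kb gene–pseudogene spacing) are
clustered into FragmentRecords. Ambiguous reads are placed by co-barcoding:
uniquely mapped reads seed clusters, ambiguous reads attach greedily to the
nearest tied placement, and a parsimony repair bridges split clusters
through tied alternates (all tied placements score identically, so the
single-molecule explanation wins). Molecules that lie entirely within the
homologous region have no unique read at all; their copy of origin is
mathematically unidentifiable at zero PSVs and they are left at a
consistent (gene-side) placement. Deletion tracing therefore also consults
tied alternate placements (below), so no verdict depends on an arbitrary
tie choice.

## Small variants on reconstructed references

Barcodes are collected from reads with mapping quality ≥20 in each copy's
non-homologous anchor region; all co-barcoded reads (including mapq-0
multimappers) are then extracted and re-aligned to a copy-specific
reconstructed reference: recon1 = locus start through the end of the
gene-side homology; recon2 = the remainder, reverse-complemented so both
references read gene-forward. Positions lift back to locus coordinates
through a strand-aware segment map. For extraction the anchor regions are
widened by 50 kb (`extension`); for *origin evidence* the raw regions are
used (a molecule anchored via the extension may belong to either copy).

Alignments to the recons are canonicalized: split gaps are condensed into
one contiguous indel when the unit cost allows (edit distance has no
gap-open penalty, so a 4 bp duplication is otherwise scattered into 1–2 bp
gaps whose placement varies between reads), and read ends carrying more
than 2 edited bases before the first 8 bp exact run are soft-clipped
(reads half-crossing a homology boundary otherwise align with an in-band
garbage tail).

Calling is by pileup with hard filters sized for ~20× depth: `min_depth`
8, `min_alt_reads` 3, het allele fraction in [0.2, 0.8], hom ≥ 0.8,
strand-bias Fisher p ≥ 0.001, and at least one supporting read with the
event ≥5 bp from both read ends. Cross-copy contamination is subtracted
before filter evaluation: reads whose barcode is anchored *exclusively* in
the opposite copy's raw region form a "foreign" pileup whose counts are
removed, so depth and allele fraction describe copy-native molecules.
Indels are left-aligned; origin assignment compares normalized alleles at
paralogous positions within ±2 bp in the gene frame (identical repeat
context makes exact coordinates unstable), then validates each label with
barcode-native support: an allele is native to a copy only when an
alt-carrying read belongs to a molecule anchored exclusively in that
copy's own region. This resolves BOTH vs GENE_ONLY vs PSEUDO_ONLY even
when the opposite recon's pileup shadow passes or fails the filters by
luck.

Coding annotation shifts indels to their 3'-most representation (HGVS
rule) before classification; a frame-shifting insertion whose last
unchanged cDNA base is p alters codon ⌊p/3⌋+1 first. For the three
published duplications (p = 1167, 700, 519) that gives codons 390, 234
and 174. Events within 3 bp of an exon boundary carry a splice-region
flag (the c.519-3 acceptor duplication case).

## Deletion detection

A de Bruijn assembler (k = 31, k-mers below count 2 dropped) assembles the
extracted reads. Two error-removal passes matter at this locus: k-mers seen
≤3 times adjacent to k-mers seen ≥10× more often are pruned (the four
repeat copies stack ~56× coverage, so coincident sequencing errors reach
the solidity cutoff and fragment the repeat path), and short equal-endpoint
"bubble" twins lose their low-coverage branch. Tips shorter than 2k are
clipped. An optional scaffold pass joins unitigs linked by ≥3 read pairs
with an N-run sized from the insert estimate — reproducing the N-gap
behaviour of linked-read scaffolders over coverage holes.

The deletion junction adds no novel k-mer, so the graph alone cannot emit
a junction contig. `assemble_local` therefore resolves multi-entry/
multi-exit repeat unitigs with barcode linkage: entry X joins through the
repeat to exit Y when ≥2 barcodes have reads in X's and Y's graph
neighborhoods (BFS ≤3 kb away from the repeat) and in no competing
context. Contigs ≥500 bp are decomposed into ≥95%-identity locus blocks
(k-mer anchor chains, strand-consistent selection — a homology junction
contig aligns whole to either copy, and a mixed gene-forward/
pseudogene-reverse chimera is an artifact — with exact-match edge
extension). Adjacent blocks whose locus projections leave a gap >50 bp are
deletion-type breakpoint candidates; candidates within 50 bp of an N-run
are flagged `caused_by_ngap` and excluded.

Each surviving candidate is vetted by fragment tracing against the
inter-repeat interval of *both* copies (the junction is copy-ambiguous).
Reads overlapping the repeat neighborhoods are classified against three
contexts sharing the identical repeat core (repeat 1 with native flanks,
repeat 2, and the deletion junction); reads inside the core tie three
ways, flank-crossing reads resolve to {MUT, REF1} or {MUT, REF2}. For
every fragment holding such a read, co-barcoded reads strictly inside the
deletion interval (by placement or by any tied alternate) refute the
deletion on that molecule (`refute_min` 1); a fragment spanning the
interval with none supports it. A candidate with ≥2 supporting fragments
(`min_support`, following the two-supporter published call) is reported;
the copy is assigned by exclusive-anchor majority vote of the supporters.
Tracing intervals exclude the repeats themselves (reads there carry no
signal).

False positives are expected and intended to be visible: a molecule whose
sparse reads happen to skip the deletion interval supports a deletion that
is not there. At 12.9 pairs per 22 kb fragment the interval (12.5 kb)
holds ~7 expected pairs, so P(skip) ≈ e⁻⁷ per covering molecule — small
per molecule but non-negligible over hundreds. Doubling reads per fragment
at constant depth roughly squares that probability, which is the
monotonicity the acceptance suite measures; downstream wet-lab validation
of candidates remains out of scope.

## Problem sizes in the test suite

The acceptance suite simulates the 129.5 kb locus at ~20× (≈13 000 read
pairs, ≈600 molecules per library): origin disambiguation runs 10 seeds per
scenario, deletion recovery 10 seeds, and the false-positive comparison
2×20 seeds — each library takes a few seconds end to end. Larger loci and
deeper libraries scale linearly and were not needed to exercise any code
path.

## What the benchmark does and does not show

The generator reproduces the locus architecture and the published library
statistics, but not: PCR duplicates (published duplicate rates are not
modeled), quality-score profiles, indel sequencing errors, chimeric
fragments, bead size variation, GC bias, or the true human sequence
(including the real repeat family content and real PSV structure, which
makes the real problem slightly *easier* than the zero-PSV default here).
Passing tests demonstrate that the strategy's logic — barcode collection,
multimapper rescue, copy-aware calling, junction tracing — behaves as
designed under idealized noise; they do not certify performance on real
libraries. The hard filters stand in for an external caller's
unpublished filter set and are deliberately configurable.

## Known limitations

- Molecules wholly inside the homologous region are unassignable and are
  silently shared between both reconstructed references; with real PSVs
  they would often be assignable.
- Copy assignment of a deletion needs supporting molecules to reach a
  copy-specific anchor region; a deletion in a (hypothetical) homology
  much longer than the fragment length would stay UNASSIGNED.
- Only deletion-type candidates are traced; duplications and inversions
  are reported as rearrangement breakpoints without tracing.
- The assembler's barcode bridging requires the repeat to condense into a
  single unitig; heavily diverged repeat copies (not the case here) would
  need a different traversal.
- At 20× with ~13 pairs per fragment the false-positive rate of deletion
  candidates is visible (2–3 spurious supporters appear in a minority of
  runs); the method is a screening strategy whose candidates need
  orthogonal confirmation.
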