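# Methods

This note documents the models, conventions and numerical choices behind
`csatk`, in the order data flows through the pipeline.

## Coordinates, formats, determinism

All coordinates are 0-based half-open; intervals are emitted as BED, tables
as TSV. FASTQ is Phred+33 only — Phred+64 input is rejected rather than
auto-detected, so a file always decodes the same way. Every writer is
byte-stable, every random draw flows from a single global seed through
named child streams (`numpy` `SeedSequence` spawn keys derived from stage
and clone names), so any stage can be rerun in isolation and a whole run is
reproducible byte for byte. Runs of fewer than 10 consecutive Ns are treated
as ambiguous bases, not structural gaps (`gap_min_run = 10`); scaffolding
gaps are never emitted shorter than that.

## The simulator: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:

- **Diploid region.** Haplotype A is drawn base-by-base with
  P(G) = P(C) = GC/2 (default GC 0.57, the high-GC regime of an avian MHC);
  per-base sampling rather than rejection keeps generation linear and gives
  a realized GC within ~0.1 % at 60 kb. Haplotype B is derived by Bernoulli
  substitutions (default 8×10⁻⁴/bp) and Bernoulli indels of 1–5 bp (default
  10⁻⁴/bp); the variant list is recorded and re-applying it to haplotype A
  must reproduce haplotype B exactly (tested). Larger structural variants
  (copy-number differences between haplotypes) are deliberately out of the
  generator's scope.
- **Clones.** Insert lengths follow a triangular distribution
  (28 kb / 39 kb / 47 kb), the source haplotype is uniform, and every
  target site is spanned by a configurable number of clones. The first
  clone of each site is centred on the site; this guarantees that clones of
  adjacent sites overlap whenever site spacing is below about half the
  insert length, which is the connectivity regime the merge tier needs. The
  remaining clones are placed uniformly among legal starts. The paper-style
  inter-clone overlap length is therefore an emergent property of spacing
  and insert length, not an asserted constant.
- **Reads.** Inward-facing 2×100 bp pairs; insert sizes
  Normal(mean, sd) truncated to [read length, clone length] with library
  classes 500 bp / 2 kb / 5 kb (sd = 10 % of the mean); pair count is
  exactly `coverage × length / (2 × read_len)`. Uniform per-base
  substitution errors (default 10⁻³); a configurable fraction of pairs is
  re-emitted verbatim (PCR duplicates) and a configurable fraction is given
  a sub-read-length insert so the 3' ends run into adapter. Large-insert
  libraries are drawn from the pooled clone mixture, with per-clone counts
  proportional to length. Qualities are a constant Q40: instrument-specific
  quality profiles and indel sequencing errors are not modelled, so passing
  tests demonstrate the pipeline's logic under its stated assumptions, not
  robustness to real instrument noise.

## Reagent design

One target site (500–1000 bp) per 30-kb window, preferring exon over intron
over intergenic annotation; within a class, candidates are tried leftmost
first at a 100-bp stride (the window-position convention is ours; nothing
upstream pins it down). Uniqueness is an exact k-mer criterion — every
31-mer of the site occurs exactly once in the genome counting both
strands — which is deterministic and strictly more conservative than a
heuristic alignment screen; k is a parameter. Homology arms are 50-nt
windows with G+C count < 35 (strict) on each arm and |GC(F) − GC(R)| < 2
(strict, i.e. ≤ 1), chosen to minimise the summed distance to the screening
primers, ties to the leftmost F arm; the implementation reduces the search
to the closest window per GC class and is tested against a brute-force
search over all window pairs. Oligos are arm + 25-nt marker primer (75 nt);
the R arm is reverse-complemented into its oligo; only the F oligo is
5'-phosphorylated, and the output table carries that flag.

## Read filtering

Six rules in fixed order: (1) trim 2 nt / 3 nt from the 5'/3' ends;
(2) drop reads whose 3' end overlaps an adapter by an exact seed of ≥ 10 nt
or that are shorter than 30 nt post-trim (the minimum length is a
parameter; no upstream value exists for "small"); (3) drop reads with
> 40 % of bases strictly below Q7; (4) drop reads with > 10 % N; (5) drop
exact PCR-duplicate pairs — identical ordered (read1, read2) post-trim
sequences, qualities ignored; (6) drop reads sharing an exact substring of
≥ 30 bp with a contaminant reference on either strand (implemented as a
30-mer index; a printed ">30 bp" cannot be distinguished from ≥ 30 by a
30-mer seed without extension, so the threshold is explicit and
configurable). A pair is dropped when either mate fails, attributed to the
first failing rule; the report must balance exactly (input = surviving +
Σ dropped) and is asserted on every run. Because deduplication runs after
trimming, pairs that become identical only post-trim collapse — this order
sensitivity is tested, not accidental.

## Per-clone assembly

A deliberately minimal de Bruijn assembler, suited to clone-sized inputs:
canonical k-mers (lexicographic min of k-mer and reverse complement) with
count ≥ 2, maximal unbranched paths walked from sorted seeds (deterministic),
no bubble popping, tip clipping or gap filling. Scaffolding places
large-insert mates by the unique k-mer at the read midpoint (the single
placement convention used toolkit-wide, also for depth tracks and mate-pair
validation), joins contig ends supported by ≥ 3 uniquely-placed concordant
pairs, refuses end re-use and cycles, and writes the mean implied gap as Ns
(clamped below at `gap_min_run`). The k-sweep runs the whole
contigs+scaffolds build per k and keeps the assembly with the largest
scaffold N50, ties to the larger k. Defaults k ∈ {21, 31, 41}: the sweep
must stay below the read length (95 nt post-trim), and on clone-sized
non-repetitive inputs the N50 criterion is insensitive within that range.
External assemblies can be substituted downstream; the merge tier only
needs FASTA.

## Overlap detection and merging

`find_overlap` anchors shared 16-mers, takes the best-supported diagonal
(histogram of offsets, 50-bp bins with neighbour pooling, median offset),
aligns the implied overlapping segments globally with edlib, trims end
gaps, and scores identity = matches / (matches + mismatches + indel_bases)
with any column containing N excluded. Both orientations of the second
sequence are tried. Defaults: `min_overlap` 500 bp, `min_identity` 0.97 —
chosen so the observed ~1 variant/kb between haplotypes passes while
repeat-induced spurious overlaps fail; both are flags. Difference *events*
are canonicalised independently of the aligner's gap placement: difference
columns separated by ≤ 5 matching columns form a cluster, cluster alleles
are trimmed by their common prefix/suffix, equal-length remainders become
per-position SNPs and length-changing remainders a single indel event. (The
5-column merge window matches the maximum simulated indel length; two true
variants closer than that are counted as one event — a documented, rare
collapse at the simulated densities.)

Layouts are connected components of the overlap graph: offsets and
orientations propagate breadth-first from the longest scaffold; an edge
whose implied placement contradicts an earlier one by more than
`offset_tol` = 100 bp (absorbing indel drift) or flips an orientation is
dropped with a warning, splitting rather than force-joining. A multiple
alignment would serve the same purpose for dovetail tilings; pairwise
anchored overlap with offset propagation is equivalent there and fully
deterministic, which is why it is the design here. Merging projects members
onto layout coordinates and, in every interval covered by more than one
scaffold, copies the contributor with the fewest N bases in that interval —
the smaller-gap rule — with ties to the longer scaffold, then the
lexicographically smaller id. Provenance tiles the output exactly: every
merged base is attributable to one input clone, making the implicit
haplotype choice in merged regions explicit rather than silent. The same
procedure runs per site (second-class) and across sites (super-scaffolds).

## Haplotype separation

Exactly two haplotypes are assumed (one diploid individual). Each overlap
is labelled same/different by variant density: ≤ 0.2 variants/kb ⇒ same
(same-haplotype pairs differ only by residual assembly error, ~0 in
simulation; different-haplotype pairs sit near the planted ~1/kb). Labels
propagate as a graph two-coloring seeded from the clone with the most total
overlap; a non-two-colorable component (which would indicate >2 haplotypes
or a chimeric clone) is reported as a conflict with its clones unassigned,
never as a third label. Separated regions are defined on doubly-covered
layout intervals — intervals covered by clones of both groups — with SNP
and indel counts deduplicated by projected position; the report states this
definition in its header columns (counts on merged coordinates, one count
per position).

## Evaluation

`global_identity` is an anchor–chain–extend block aligner: unique 32-mers
shared by query and target (better-supported orientation wins), clustered
into collinear chains (band 300 bp), each block globally aligned with
edlib. Identity is Σ matches / Σ (matches + mismatches + indel_bases) over
all blocks — stated explicitly because "percent identity" is not a single
formula across aligners; numbers produced here are interpretable only
against this definition. Blocks extend to the sequence ends only across
short (≤ band) unanchored tails; longer unanchored stretches — e.g. an
unrelated insertion — are reported as uncovered rather than force-aligned.
N-runs of ≥ 10 are also reported uncovered. Differences are classified in
fixed priority: `gap` (within 50 bp of an N-gap in either assembly),
`homopolymer_indel` (an indel inside a run of ≥ 4 identical bases — the
classic short-read error mode in runs of Gs), `low_coverage` (query depth
< 5 at the site, depth from mapping the clone's own filtered reads by the
toolkit-wide unique-anchor convention; unavailable depth is noted, not
guessed), else `insertion`/`normal`.

Mate-pair validation maps large-insert pairs by unique anchors; concordant
means same scaffold, inward orientation, span within mean ± 3 sd. Pairs
bridging two scaffolds are aggregated by (scaffold end, scaffold end); a
join is proposed at ≥ 3 pairs agreeing on orientation and implied offset
(within 3 sd of the library). Windowed GC uses non-overlapping windows
(default 500 bp), GC over non-N bases, trailing partial window excluded,
all-N windows skipped and counted. The gene-set merge clusters models by
single-linkage on > 100 bp genomic overlap (strict), keeps one
representative per cluster by source precedence homology > RNA-seq >
de novo, and keeps a de-novo-only cluster only with align rate > 30 % and
≥ 2 exons.

## Pipeline and problem sizes

The driver chains simulate → filter → assemble → merge → haplotype →
evaluate, records a manifest (stage list, parameter hash, SHA-256 per
output) and attributes any failure to its stage. Stage outputs are always
rewritten; the parameter hash in the manifest is what tests compare, which
proved sufficient without an on-disk cache. The default configuration — a
60-kb region, 3 sites × 3 clones, error-free 100× reads — is the package's
reference problem size: large enough that clones tile and both haplotypes
appear at every site, small enough that a full run takes about a minute
and a half on one CPU. The acceptance script uses the same defaults plus a
20-replicate haplotype sweep on 30-kb regions with 6 clones of 20–25 kb
(pairwise overlaps ≥ 10 kb by construction, ≥ 0.5 variants/kb).

## Known limitations

- The assembler is not SOAPdenovo: no error correction, bubble/tip
  handling, or gap closing; it is adequate for clone-scale, moderate-error
  inputs and is not meant for genome-scale data.
- Sequencing errors are substitution-only and uniform; quality strings are
  flat.
- `find_overlap` assumes a single dominant diagonal per pair; two scaffolds
  sharing two distant repeats could anchor on the wrong diagonal (rejected
  by the identity gate rather than resolved).
- Haplotype separation needs overlaps long enough to carry variants at the
  region's density; below ~5 kb × 0.5 variants/kb the same/different
  relation degrades toward "same".
- Gene-model merging operates on provided models; no gene prediction is
  performed.
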