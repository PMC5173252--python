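# csatk — clone-based sequence-and-assembly toolkit

Highly polymorphic, GC- and repeat-rich genomic regions — the avian major
histocompatibility complex (MHC) is the motivating case — assemble poorly in
whole-genome shotgun projects: the two haplotypes of a diploid individual
interfere with each other and genome-wide repeats tangle the assembly graph.
A clone-based sequence-and-assembly (CSA) strategy sidesteps both problems:
fosmid clones (~28–47 kb inserts) covering the region are fished out of
pooled libraries by recombineering, each clone is short-read sequenced and
assembled **separately** (a single clone carries a single haplotype and far
fewer repeats), and the per-clone scaffolds are merged hierarchically —
first-class (per clone) → second-class (per recombination site) →
super-scaffolds — by overlap. Overlapping clones from opposite chromosomes
then let the two haplotypes be separated directly from assembled sequence.

`csatk` implements the computational side of this strategy end to end, plus
a seeded simulator of the study conditions so the whole pipeline is testable
without any external data:

| module | what it does |
|---|---|
| `csatk.core_io` | domain types; FASTA/FASTQ (Phred+33)/BED/TSV readers and writers; N-gap tracking |
| `csatk.simulate` | two-haplotype regions, triangular (28/39/47 kb) clone inserts, 2×100 bp paired reads at configurable coverage, PCR duplicates, adapter/vector contamination |
| `csatk.target_cassette` | target-site picking (one unique 500–1000 bp site per 30-kb window, exon > intron > intergenic) and recombineering cassette design: 50-nt homology arms (G+C < 35 nt, F/R difference < 2 nt) + 25-nt marker primers = 75-nt oligos, forward oligo 5'-phosphorylated |
| `csatk.read_filter` | the six cleaning rules: end-trimming (2 nt / 3 nt), adapter/short reads, >40 % bases below Q7, >10 % N, PCR-duplicate pairs, ≥30 bp vector/bacterial contamination — pair-aware, with a balanced accounting report |
| `csatk.mini_assembly` | per-clone de Bruijn assembly (canonical k-mers, count threshold), mate-pair scaffolding with N-gaps, and a k-sweep keeping the assembly with the longest scaffold N50 |
| `csatk.csa_merge` | overlap detection (k-mer anchoring + edit-distance extension, both strands), offset-consistent tiling layouts, and hierarchical merging where regions covered by more than one clone take the contributor with the smaller gap |
| `csatk.haplotypes` | variant calling between overlapping clones (SNPs; indels as single left-aligned events) and haplotype partitioning by graph two-coloring |
| `csatk.evaluate` | block identity between two assemblies with difference classification (gap / homopolymer indel / low coverage / insertion / normal), mate-pair concordance and inter-scaffold linkage, windowed GC, and the 3-criteria gene-model merge |

The statistic at the core of the merge tier is plain but load-bearing:
an overlap between scaffolds *a* and *b* is accepted when its aligned length
is ≥ 500 bp and its identity over non-N columns,

    identity = matches / (matches + mismatches + indel_bases),

is ≥ 0.97 — permissive enough for the ~1 variant/kb seen between haplotypes,
strict enough to reject repeat-induced false overlaps. Haplotype separation
thresholds the same quantity per overlap: ≤ 0.2 variants/kb ⇒ same
haplotype, else different, propagated as a two-coloring.

## Worked example

```bash
csa run --seed 1 --out csa_out
```

simulates a 60-kb two-haplotype region (GC 0.57, SNP rate 8×10⁻⁴, indel
rate 10⁻⁴), places 3 clones on each of 3 target sites, sequences each clone
error-free at 100×, then filters, assembles, merges, haplotypes and
evaluates. It prints the run summary:

```json
{
  "best_identity_to_truth": 0.9998999849977497,
  "haplotype_assignment": {
    "s00_c0": 2, "s00_c1": 1, "s00_c2": 1,
    "s01_c0": 2, "s01_c1": 1, "s01_c2": 2,
    "s02_c0": 2, "s02_c1": 1, "s02_c2": 1
  },
  "n_clones": 9,
  "n_second_class": 3,
  "n_superscaffolds": 1
}
```

One super-scaffold covers the region at 99.99 % identity to the true
haplotype; the nine clones split into the two haplotype groups exactly as
simulated (labels 1/2 are arbitrary). `csa_out/` holds the per-stage
outputs: clone scaffolds, second-class and super-scaffold FASTA, provenance
BED (which clone contributed every merged base), haplotype assignment and
separated-region TSVs, the per-rule filtering report, and a manifest with
the SHA-256 of every file — rerunning with the same seed reproduces each
byte.

The same stages are available individually (`csa simulate`, `csa
design-sites`, `csa design-cassettes`, `csa filter`, `csa assemble`, `csa
merge`, `csa haplotype`, `csa evaluate`, `csa gc`, `csa merge-genes`), and
as library functions.

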