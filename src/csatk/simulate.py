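"""Seeded simulator of two-haplotype regions, fosmid-like clone inserts and paired reads.

The generator reproduces the statistical structure the CSA pipeline assumes:
a diploid region with configurable SNP/indel density between the two
haplotypes, high GC content, clone inserts drawn from a triangular length
distribution (28/39/47 kb by default, matching fosmid insert sizes), 2x100 bp
inward-facing read pairs from small- (500 bp) and large-insert (2 kb / 5 kb)
libraries, uniform sequencing error, PCR duplicates, and adapter/vector
contamination.  Everything is deterministic given the single global seed;
per-stage child streams are derived from it so stages can be rerun in
isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from csatk.core_io import SeqRecord, revcomp, write_fasta, write_fastq_pairs

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALT = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def stage_rng(seed: int, *key: str | int) -> np.random.Generator:
    """Child RNG for a named stage, derived deterministically from the global seed."""
    spawn_key = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the sequencing design the toolkit targets: fosmid inserts
    of 28-47 kb peaking at 39 kb, 2x100 bp reads, ~250-fold per-clone
    coverage, a 500 bp small-insert library plus 2 kb and 5 kb large-insert
    libraries, GC around 57%.
    """

    region_len: int = 60_000
    gc_target: float = 0.57
    snp_rate: float = 8e-4
    indel_rate: float = 1e-4
    clone_len_min: int = 28_000
    clone_len_mode: int = 39_000
    clone_len_max: int = 47_000
    clones_per_site: int = 3
    read_len: int = 100
    insert_stats: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {500: (500.0, 50.0), 2000: (2000.0, 200.0), 5000: (5000.0, 500.0)}
    )
    coverage: float = 250.0
    seq_error_rate: float = 1e-3
    duplicate_frac: float = 0.05
    adapter_frac: float = 0.0
    adapter_seq: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
    vector_seq: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_target", "snp_rate", "indel_rate", "seq_error_rate",
                     "duplicate_frac", "adapter_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not self.clone_len_min <= self.clone_len_mode <= self.clone_len_max:
            raise ValueError("clone length min <= mode <= max violated")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class SimVariant:
    """A planted inter-haplotype difference, positioned on haplotype A."""

    pos: int
    type: str  # "SNP" | "indel"
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class CloneMeta:
    clone_id: str
    site_id: str
    haplotype: str  # "A" | "B"
    start: int  # on the source haplotype
    end: int
    flank: int = 0  # vector flank length on each side of the insert


@dataclass
class SimTruth:
    """Ground truth of a simulated region: both haplotypes, the planted
    variants, and the clone table."""

    hapA: SeqRecord
    hapB: SeqRecord
    variants: list[SimVariant]
    clones: list[CloneMeta] = field(default_factory=list)
    config: Optional[SimConfig] = None

    def map_a_to_b(self, pos: int) -> int:
        """Project a haplotype-A coordinate onto haplotype B through the
        planted indels."""
        shift = 0
        for v in self.variants:
            if v.pos >= pos:
                break
            if v.type == "indel":
                shift += len(v.allele_b) - len(v.allele_a)
        return pos + shift


def apply_variants(seq: str, variants: Sequence[SimVariant]) -> str:
    """Apply a planted-variant list to a haplotype-A sequence (oracle for
    hapB construction, reused by the round-trip invariant test)."""
    out = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        out.append(seq[cursor : v.pos])
        out.append(v.allele_b)
        cursor = v.pos + len(v.allele_a)
    out.append(seq[cursor:])
    return "".join(out)


def random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with per-base GC probability ``gc`` (linear time, no
    rejection)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode()


def simulate_region(config: SimConfig) -> SimTruth:
    """Draw haplotype A at the target GC, derive haplotype B by planting
    Bernoulli SNPs and short (1-5 bp) indels, and record the truth."""
    if config.region_len < 1000:
        raise ValueError("region_len < 1000: too small to place clones")
    rng = stage_rng(config.seed, "region")
    hap_a = random_seq(rng, config.region_len, config.gc_target)

    u = rng.random(config.region_len)
    variants: list[SimVariant] = []
    blocked_until = 0  # skip positions consumed by an earlier deletion
    for pos in range(config.region_len):
        if pos < blocked_until:
            continue
        if u[pos] < config.snp_rate:
            ref = hap_a[pos]
            alt = _ALT[ref][rng.integers(3)]
            variants.append(SimVariant(pos, "SNP", ref, alt))
        elif u[pos] < config.snp_rate + config.indel_rate:
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5 and pos + length <= config.region_len:
                variants.append(SimVariant(pos, "indel", hap_a[pos : pos + length], ""))
                blocked_until = pos + length
            else:
                ins = random_seq(rng, length, config.gc_target)
                variants.append(SimVariant(pos, "indel", "", ins))
    hap_b = apply_variants(hap_a, variants)
    return SimTruth(
        hapA=SeqRecord(id="hapA", seq=hap_a),
        hapB=SeqRecord(id="hapB", seq=hap_b),
        variants=variants,
        config=config,
    )


def make_target_sites(region_len: int, n_sites: int, size: int = 600) -> list[tuple[int, int]]:
    """Evenly spaced target-site intervals (haplotype-A coordinates)."""
    sites = []
    for i in range(n_sites):
        center = int((i + 0.5) * region_len / n_sites)
        sites.append((center - size // 2, center + size - size // 2))
    return sites


def simulate_clones(
    truth: SimTruth, config: SimConfig, target_sites: Sequence[tuple[int, int]]
) -> list[tuple[SeqRecord, CloneMeta]]:
    """Place clone inserts so every target site is spanned by
    ``clones_per_site`` clones.

    Insert lengths follow a triangular (min, mode, max) distribution and the
    source haplotype is chosen uniformly.  The first clone of each site is
    centred on the site, which guarantees that clones of adjacent sites
    overlap whenever site spacing is below half the insert length; remaining
    clones are placed uniformly among the legal starts.  When
    ``config.vector_seq`` is set, each insert is flanked by the vector on
    both sides (reads near the insert ends then contain vector sequence).
    """
    rng = stage_rng(config.seed, "clones")
    haps = {"A": truth.hapA.seq, "B": truth.hapB.seq}
    out: list[tuple[SeqRecord, CloneMeta]] = []
    for si, (s_start, s_end) in enumerate(target_sites):
        if s_end - s_start > config.clone_len_max:
            raise ValueError(f"site {si} ({s_end - s_start} bp) exceeds max clone length")
        site_id = f"s{si:02d}"
        for j in range(config.clones_per_site):
            hap = "A" if rng.random() < 0.5 else "B"
            hseq = haps[hap]
            h_start = s_start if hap == "A" else truth.map_a_to_b(s_start)
            h_end = s_end if hap == "A" else truth.map_a_to_b(s_end)
            length = int(rng.triangular(config.clone_len_min, config.clone_len_mode,
                                        config.clone_len_max))
            length = min(length, len(hseq))
            lo = max(0, h_end - length)
            hi = min(h_start, len(hseq) - length)
            if hi < lo:
                raise ValueError(f"site {site_id} not coverable by a {length} bp clone")
            if j == 0:
                center = (h_start + h_end) // 2
                start = int(np.clip(center - length // 2, lo, hi))
            else:
                start = int(rng.integers(lo, hi + 1))
            insert = hseq[start : start + length]
            flank = len(config.vector_seq)
            seq = config.vector_seq + insert + config.vector_seq if flank else insert
            clone_id = f"{site_id}_c{j}"
            meta = CloneMeta(clone_id, site_id, hap, start, start + length, flank)
            out.append((SeqRecord(id=clone_id, seq=seq), meta))
            truth.clones.append(meta)
    return out


def _plant_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return read
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    positions = rng.choice(len(read), size=n_err, replace=False)
    chars = list(read)
    for p in positions:
        if chars[p] in _ALT:
            chars[p] = _ALT[chars[p]][rng.integers(3)]
    return "".join(chars)


def simulate_reads(
    clone: SeqRecord,
    config: SimConfig,
    library_class: int,
    coverage: Optional[float] = None,
    insert_stats: Optional[tuple[float, float]] = None,
) -> tuple[list[tuple[SeqRecord, SeqRecord]], pd.DataFrame]:
    """Inward-facing 2 x ``read_len`` pairs from one template.

    Insert sizes are Normal(mean, sd) truncated to [read_len, template
    length]; the pair count is ``coverage * len / (2 * read_len)``; a
    ``duplicate_frac`` fraction of pairs is re-emitted verbatim (PCR
    duplicates) and an ``adapter_frac`` fraction is given a sub-read-length
    insert so the 3' end runs into adapter.  Returns the pairs plus a
    per-pair origin table (pair_id, start, end, is_duplicate, has_adapter).
    """
    mean, sd = insert_stats if insert_stats is not None else config.insert_stats[library_class]
    rl = config.read_len
    if rl > mean:
        raise ValueError(f"read_len {rl} exceeds insert mean {mean}")
    if len(clone.seq) <= mean:
        raise ValueError(f"clone {clone.id} shorter than insert mean {mean}")
    cov = coverage if coverage is not None else config.coverage
    rng = stage_rng(config.seed, "reads", clone.id, library_class)
    tpl = clone.seq
    n_pairs = int(round(cov * len(tpl) / (2 * rl)))
    inserts = np.clip(np.rint(rng.normal(mean, sd, size=n_pairs)), rl, len(tpl)).astype(int)
    n_adapter = int(round(config.adapter_frac * n_pairs))
    if n_adapter:
        short = rng.integers(max(30, rl // 2), rl, size=n_adapter)
        inserts[rng.choice(n_pairs, size=n_adapter, replace=False)] = short
    starts = (rng.random(n_pairs) * (len(tpl) - inserts + 1)).astype(int)
    q40 = [40] * rl

    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    rows = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        frag = tpl[s : s + ins]
        if ins < rl:  # adapter read-through
            tail = config.adapter_seq * (rl // len(config.adapter_seq) + 1)
            r1 = frag + tail[: rl - ins]
            r2 = revcomp(frag) + tail[: rl - ins]
            has_adapter = True
        else:
            r1 = frag[:rl]
            r2 = revcomp(frag[-rl:])
            has_adapter = False
        r1 = _plant_errors(r1, rng, config.seq_error_rate)
        r2 = _plant_errors(r2, rng, config.seq_error_rate)
        pid = f"{clone.id}:{library_class}:{i}"
        pairs.append((SeqRecord(id=pid + "/1", seq=r1, qual=q40),
                      SeqRecord(id=pid + "/2", seq=r2, qual=q40)))
        rows.append((pid, clone.id, library_class, s, s + ins, False, has_adapter))

    n_dup = int(round(config.duplicate_frac * n_pairs))
    if n_dup:
        dup_idx = rng.choice(n_pairs, size=n_dup, replace=False)
        for i in sorted(dup_idx):
            r1, r2 = pairs[i]
            pid = f"{clone.id}:{library_class}:{i}:dup"
            pairs.append((SeqRecord(id=pid + "/1", seq=r1.seq, qual=q40),
                          SeqRecord(id=pid + "/2", seq=r2.seq, qual=q40)))
            rows.append((pid, clone.id, library_class, int(starts[i]),
                         int(starts[i] + inserts[i]), True, False))
    origins = pd.DataFrame(
        rows, columns=["pair_id", "clone_id", "library", "start", "end",
                       "is_duplicate", "has_adapter"]
    )
    return pairs, origins


def simulate_pool_reads(
    clones: Sequence[SeqRecord],
    config: SimConfig,
    library_class: int,
    coverage: float,
) -> tuple[list[tuple[SeqRecord, SeqRecord]], pd.DataFrame]:
    """Large-insert pairs drawn from the pooled clone mixture, coverage split
    across clones in proportion to length (one library over all clones, as in
    a mixed-DNA large-insert prep)."""
    mean, _sd = config.insert_stats[library_class]
    all_pairs: list[tuple[SeqRecord, SeqRecord]] = []
    tables = []
    for clone in clones:
        if len(clone.seq) <= mean:  # too short for this library prep
            continue
        pairs, origins = simulate_reads(clone, config, library_class, coverage=coverage)
        all_pairs.extend(pairs)
        tables.append(origins)
    origins = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return all_pairs, origins


def write_simulation(
    outdir: str | Path,
    truth: SimTruth,
    clones: Sequence[tuple[SeqRecord, CloneMeta]],
) -> None:
    """Write haplotypes, clone FASTA and TSV truth tables for a simulated region."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([truth.hapA, truth.hapB], outdir / "haplotypes.fasta")
    write_fasta([rec for rec, _ in clones], outdir / "clones.fasta")
    pd.DataFrame(
        [(v.pos, v.type, v.allele_a, v.allele_b) for v in truth.variants],
        columns=["pos", "type", "allele_a", "allele_b"],
    ).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m.clone_id, m.site_id, m.haplotype, m.start, m.end, m.flank)
         for _, m in clones],
        columns=["clone_id", "site_id", "haplotype", "start", "end", "flank"],
    ).to_csv(outdir / "clones.tsv", sep="\t", index=False)
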