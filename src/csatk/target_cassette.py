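"""Target-site selection and recombineering cassette design.

A target site is a 500-1000 bp stretch chosen once per 30-kb window of a
draft genome, preferring annotated exon over intron over intergenic sequence,
and required to be k-mer unique so the downstream recombination screen pulls
out a single locus.  For each site a selection cassette is designed: two
50-nt homology arms close to the screening primers (each with fewer than 35
G+C, arms differing by fewer than 2 G+C) joined to 25-nt marker-amplification
primers to form a pair of 75-nt oligos; the forward oligo is 5'-phosphorylated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from csatk.core_io import AnnotationInterval, SeqRecord, revcomp

logger = logging.getLogger(__name__)

ARM_LEN = 50
MARKER_PRIMER_LEN = 25
OLIGO_LEN = ARM_LEN + MARKER_PRIMER_LEN
MAX_ARM_GC = 35      # strict: a 50-mer with 35 G+C is excluded
MAX_GC_DIFF = 2      # strict: |GC(F) - GC(R)| must be < 2, i.e. <= 1


@dataclass
class TargetSite:
    seq_id: str
    start: int
    end: int
    priority_class: str  # exon | intron | intergenic
    unique: bool
    site_id: str = ""
    screening_primer_f: Optional[tuple[int, int]] = None
    screening_primer_r: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        size = self.end - self.start
        if not 500 <= size <= 1000:
            raise ValueError(f"target site size {size} outside [500, 1000]")


@dataclass
class Cassette:
    site_id: str
    f_arm: str
    r_arm: str
    f_oligo: str
    r_oligo: str
    marker_primer_f: str
    marker_primer_r: str
    f_phosphorylated: bool = True

    def __post_init__(self) -> None:
        if len(self.f_arm) != ARM_LEN or len(self.r_arm) != ARM_LEN:
            raise ValueError("homology arms must be exactly 50 nt")
        if len(self.f_oligo) != OLIGO_LEN or len(self.r_oligo) != OLIGO_LEN:
            raise ValueError("oligos must be exactly 75 nt")
        gc_f, gc_r = gc_count(self.f_arm), gc_count(self.r_arm)
        if gc_f >= MAX_ARM_GC or gc_r >= MAX_ARM_GC:
            raise ValueError(f"arm G+C count must be < {MAX_ARM_GC} (got {gc_f}, {gc_r})")
        if abs(gc_f - gc_r) >= MAX_GC_DIFF:
            raise ValueError(f"arm G+C difference must be < {MAX_GC_DIFF}")


def gc_count(seq: str) -> int:
    """Number of G or C bases (the 'G+C nt' unit of the arm criteria)."""
    return seq.count("G") + seq.count("C")


def _kmer_counts(genome: Sequence[SeqRecord], k: int) -> Counter:
    """Counts of canonical k-mers over both strands of the genome."""
    counts: Counter = Counter()
    for rec in genome:
        fwd = rec.seq
        rc = revcomp(fwd)
        n = len(fwd)
        counts.update(
            min(fwd[i : i + k], rc[n - k - i : n - i]) for i in range(n - k + 1)
        )
    return counts


def is_unique(site_seq: str, genome: Sequence[SeqRecord], k: int = 31,
              _counts: Optional[Counter] = None) -> bool:
    """True iff every k-mer of the site occurs exactly once in the genome
    counting both strands (a conservative, deterministic uniqueness screen)."""
    if len(site_seq) < k:
        raise ValueError(f"site shorter than k={k}")
    counts = _counts if _counts is not None else _kmer_counts(genome, k)
    rc = revcomp(site_seq)
    n = len(site_seq)
    for i in range(n - k + 1):
        canon = min(site_seq[i : i + k], rc[n - k - i : n - i])
        if counts[canon] != 1:
            return False
    return True


def _window_class_regions(
    window: tuple[int, int],
    annotations: Sequence[AnnotationInterval],
    seq_id: str,
) -> dict[str, list[tuple[int, int]]]:
    """Candidate source regions per priority class, clipped to the window.
    Intergenic is the window complement of all annotated spans."""
    w_start, w_end = window
    regions: dict[str, list[tuple[int, int]]] = {"exon": [], "intron": []}
    covered: list[tuple[int, int]] = []
    for iv in annotations:
        if iv.seq_id != seq_id or iv.end <= w_start or iv.start >= w_end:
            continue
        clipped = (max(iv.start, w_start), min(iv.end, w_end))
        if iv.kind in regions:
            regions[iv.kind].append(clipped)
        covered.append(clipped)
    covered.sort()
    intergenic = []
    cursor = w_start
    for s, e in covered:
        if s > cursor:
            intergenic.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < w_end:
        intergenic.append((cursor, w_end))
    regions["intergenic"] = intergenic
    for v in regions.values():
        v.sort()
    return regions


def pick_target_sites(
    genome: Sequence[SeqRecord],
    annotations: Sequence[AnnotationInterval],
    spacing: int = 30_000,
    size_range: tuple[int, int] = (500, 1000),
    k: int = 31,
    candidate_stride: int = 100,
) -> list[TargetSite]:
    """One target site per ``spacing`` window per scaffold.

    Within a window the highest-priority class (exon > intron > intergenic)
    holding a candidate of legal size wins; candidates failing the uniqueness
    screen are skipped in favour of the next candidate by priority, then
    leftmost position.  A window with no legal unique candidate is omitted
    with a warning.
    """
    min_size, max_size = size_range
    counts = _kmer_counts(genome, k)
    sites: list[TargetSite] = []
    for rec in genome:
        n_windows = max(1, -(-len(rec.seq) // spacing))
        for w in range(n_windows):
            window = (w * spacing, min((w + 1) * spacing, len(rec.seq)))
            if window[1] - window[0] < min_size:
                continue
            regions = _window_class_regions(window, annotations, rec.id)
            chosen = None
            for cls in ("exon", "intron", "intergenic"):
                for r_start, r_end in regions[cls]:
                    if r_end - r_start < min_size:
                        continue
                    pos = r_start
                    while pos + min_size <= r_end and chosen is None:
                        size = min(max_size, r_end - pos)
                        cand = rec.seq[pos : pos + size]
                        if "N" not in cand and is_unique(cand, genome, k, _counts=counts):
                            chosen = TargetSite(
                                seq_id=rec.id, start=pos, end=pos + size,
                                priority_class=cls, unique=True,
                                site_id=f"{rec.id}:w{w}",
                            )
                        pos += candidate_stride
                    if chosen:
                        break
                if chosen:
                    break
            if chosen:
                sites.append(chosen)
            else:
                logger.warning("no legal unique target site in %s window %d", rec.id, w)
    return sites


@dataclass
class ArmSelection:
    """Result of homology-arm search: either a located arm pair, or a
    'no-arm' outcome with per-criterion failure counts."""

    found: bool
    f_start: int = -1
    r_start: int = -1
    f_arm: str = ""
    r_arm: str = ""
    gc_f: int = -1
    gc_r: int = -1
    failure_counts: dict[str, int] = field(default_factory=dict)

    @property
    def failed_criterion(self) -> str:
        if self.found or not self.failure_counts:
            return ""
        return max(self.failure_counts, key=self.failure_counts.get)


def _window_gc(region_seq: str, arm_len: int) -> np.ndarray:
    """G+C count of every ``arm_len`` window (sliding, step 1) via cumsum."""
    is_gc = np.frombuffer(region_seq.encode(), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    cs = np.concatenate([[0], np.cumsum(is_gc)])
    return (cs[arm_len:] - cs[:-arm_len]).astype(int)


def select_homology_arms(
    region_seq: str,
    primer_f_pos: tuple[int, int],
    primer_r_pos: tuple[int, int],
    arm_len: int = ARM_LEN,
) -> ArmSelection:
    """Choose the F/R 50-nt arm pair closest to the screening primers.

    The F arm lies wholly upstream of the forward primer, the R arm wholly
    downstream of the reverse primer.  Among windows with G+C count < 35 the
    pair with |GC(F) - GC(R)| < 2 minimising the summed distance to the
    primers wins; ties break to the leftmost F arm.
    """
    gc = _window_gc(region_seq, arm_len)
    f_limit = primer_f_pos[0] - arm_len  # last legal F start
    r_first = primer_r_pos[1]            # first legal R start
    fails = {"no_f_window": 0, "no_r_window": 0, "gc_count": 0, "gc_diff": 0}
    if f_limit < 0:
        fails["no_f_window"] = 1
        return ArmSelection(found=False, failure_counts=fails)
    if r_first > len(region_seq) - arm_len:
        fails["no_r_window"] = 1
        return ArmSelection(found=False, failure_counts=fails)

    # best (closest-to-primer) window per GC class, on each side
    best_f: dict[int, int] = {}
    for s in range(f_limit, -1, -1):  # descending start: first hit per class is closest
        g = int(gc[s])
        if g >= MAX_ARM_GC:
            fails["gc_count"] += 1
            continue
        if g not in best_f:
            best_f[g] = s
    best_r: dict[int, int] = {}
    for s in range(r_first, len(region_seq) - arm_len + 1):
        g = int(gc[s])
        if g >= MAX_ARM_GC:
            fails["gc_count"] += 1
            continue
        if g not in best_r:
            best_r[g] = s

    best: Optional[tuple[int, int, int, int]] = None  # (dist, f_start, r_start)
    for gf, fs in best_f.items():
        for gr, rs in best_r.items():
            if abs(gf - gr) >= MAX_GC_DIFF:
                fails["gc_diff"] += 1
                continue
            dist = (primer_f_pos[0] - (fs + arm_len)) + (rs - primer_r_pos[1])
            key = (dist, fs, rs)
            if best is None or key < best:
                best = key
    if best is None:
        return ArmSelection(found=False, failure_counts=fails)
    _, fs, rs = best
    return ArmSelection(
        found=True, f_start=fs, r_start=rs,
        f_arm=region_seq[fs : fs + arm_len], r_arm=region_seq[rs : rs + arm_len],
        gc_f=int(gc[fs]), gc_r=int(gc[rs]),
    )


def build_cassette(
    site: TargetSite, arms: ArmSelection, marker_primers: tuple[str, str]
) -> Cassette:
    """Assemble the 75-nt oligo pair: F oligo = F arm + marker primer; R
    oligo = reverse-complemented R arm + marker primer.  Only the F oligo is
    5'-phosphorylated."""
    if not arms.found:
        raise ValueError(f"site {site.site_id}: no homology arms selected")
    mp_f, mp_r = marker_primers
    if len(mp_f) != MARKER_PRIMER_LEN or len(mp_r) != MARKER_PRIMER_LEN:
        raise ValueError("marker primers must be exactly 25 nt")
    return Cassette(
        site_id=site.site_id,
        f_arm=arms.f_arm,
        r_arm=arms.r_arm,
        f_oligo=arms.f_arm + mp_f,
        r_oligo=revcomp(arms.r_arm) + mp_r,
        marker_primer_f=mp_f,
        marker_primer_r=mp_r,
    )


def cassettes_to_table(cassettes: Sequence[Cassette]) -> pd.DataFrame:
    """TSV-ready cassette table; the modification column carries 5'-PO4 on
    the forward oligo only (reverse oligos are unmodified)."""
    rows = []
    for c in cassettes:
        rows.append((c.site_id, c.f_arm, c.r_arm, c.f_oligo, c.r_oligo,
                     gc_count(c.f_arm), gc_count(c.r_arm),
                     "5'-PO4" if c.f_phosphorylated else "", ""))
    return pd.DataFrame(rows, columns=[
        "site_id", "f_arm", "r_arm", "f_oligo", "r_oligo",
        "gc_f", "gc_r", "f_modification", "r_modification",
    ])
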