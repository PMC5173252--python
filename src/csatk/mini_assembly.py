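"""A minimal per-clone assembler: de Bruijn contigs, mate-pair scaffolding
with N-gaps, and k-sweep model selection by scaffold N50.

This is a deliberately simple assembler for clone-sized (tens of kb)
problems: maximal unbranched de Bruijn paths over canonical k-mers with a
count threshold, scaffolding by uniquely-anchored large-insert pairs, and a
sweep over k keeping the assembly with the longest scaffold N50 (ties go to
the larger k).  There is no bubble popping, tip clipping beyond the count
threshold, error correction or gap filling; externally assembled scaffolds
can be supplied downstream instead.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from csatk.core_io import GAP_MIN_RUN, GapInterval, SeqRecord, find_gaps, revcomp

logger = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    k_min: int = 21
    k_max: int = 41
    k_step: int = 10          # even step keeps k odd
    kmer_min_count: int = 2
    min_contig_len: int = 100
    scaffold_min_links: int = 3
    anchor_k: int = 31        # read-placement k-mer for scaffolding
    gap_min_run: int = GAP_MIN_RUN
    insert_stats: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {2000: (2000.0, 200.0), 5000: (5000.0, 500.0)}
    )

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError("k_min > k_max")
        if self.k_min % 2 == 0 or self.k_max % 2 == 0 or self.k_step % 2 != 0:
            raise ValueError("k values must stay odd (odd k_min/k_max, even k_step)")

    @property
    def k_values(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1, self.k_step))


@dataclass
class CloneScaffold:
    """The assembled sequence of one clone: the longest scaffold of its
    assembly, with tracked N-gap intervals and sweep provenance."""

    clone_id: str
    site_id: str
    seq: str
    gaps: list[GapInterval]
    k_used: int
    stats: dict
    scaffolds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gaps != find_gaps(self.seq):
            raise ValueError("gap list inconsistent with sequence")


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that pieces of length >= L hold at least half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    running = 0
    for x in sorted(lengths, reverse=True):
        running += x
        if 2 * running >= total:
            return x
    raise AssertionError("unreachable")


def _canon_kmers(seq: str, k: int):
    rc = revcomp(seq)
    n = len(seq)
    return (min(seq[i : i + k], rc[n - k - i : n - i]) for i in range(n - k + 1))


def count_kmers(reads: Sequence[str], k: int) -> Counter:
    """Canonical (strand-collapsed) k-mer counts over a read set."""
    counts: Counter = Counter()
    for r in reads:
        if len(r) >= k:
            counts.update(_canon_kmers(r, k))
    return counts


def _canon(s: str) -> str:
    return min(s, revcomp(s))


def _successors(node: str, kmers: set[str]) -> list[str]:
    suf = node[1:]
    return [suf + b for b in "ACGT" if _canon(suf + b) in kmers]


def _predecessors(node: str, kmers: set[str]) -> list[str]:
    pre = node[:-1]
    return [b + pre for b in "ACGT" if _canon(b + pre) in kmers]


def _extend_forward(start: str, k: int, kmers: set[str], visited: set[str]) -> str:
    """Walk a maximal unbranched path rightward from an oriented seed
    (a k-mer or a longer stub whose last k-mer is the walk front)."""
    contig = start
    node = start[-k:]
    while True:
        nxt = _successors(node, kmers)
        if len(nxt) != 1:
            break
        node2 = nxt[0]
        if len(_predecessors(node2, kmers)) != 1:
            break
        c = _canon(node2)
        if c in visited:
            break
        visited.add(c)
        contig += node2[-1]
        node = node2
    return contig


def assemble_contigs(
    reads: Sequence[str], k: int, kmer_min_count: int = 2, min_contig_len: int = 100
) -> list[str]:
    """Maximal unbranched de Bruijn paths over canonical k-mers with count
    >= ``kmer_min_count``; contigs shorter than ``min_contig_len`` dropped.
    Deterministic: seeds are taken in sorted k-mer order."""
    if not reads:
        return []
    if any(len(r) <= k for r in reads if r):
        shortest = min(len(r) for r in reads)
        if shortest <= k:
            logger.warning("k=%d not below every read length (min %d)", k, shortest)
    counts = count_kmers(reads, k)
    kmers = {km for km, c in counts.items() if c >= kmer_min_count}
    if not kmers:
        logger.warning("no k-mer reaches count %d at k=%d", kmer_min_count, k)
        return []
    visited: set[str] = set()
    contigs = []
    for seed in sorted(kmers):
        if seed in visited:
            continue
        visited.add(seed)
        contig = _extend_forward(seed, k, kmers, visited)
        contig = _extend_forward(revcomp(contig), k, kmers, visited)
        contigs.append(min(contig, revcomp(contig)))
    return [c for c in contigs if len(c) >= min_contig_len]


class _AnchorIndex:
    """Unique canonical k-mer -> (contig, position, window-is-forward) map
    used for exact-anchor read placement (the one mapping convention used
    toolkit-wide)."""

    def __init__(self, contigs: Sequence[str], k: int):
        self.k = k
        index: dict[str, Optional[tuple[int, int, bool]]] = {}
        for ci, seq in enumerate(contigs):
            rc = revcomp(seq)
            n = len(seq)
            for i in range(n - k + 1):
                fwd = seq[i : i + k]
                canon = min(fwd, rc[n - k - i : n - i])
                if canon in index:
                    index[canon] = None  # repeated: unusable
                else:
                    index[canon] = (ci, i, fwd == canon)
        self.index = {km: v for km, v in index.items() if v is not None}

    def place_read(self, read: str) -> Optional[tuple[int, int, int]]:
        """Place by the k-mer at the read midpoint; returns (contig, read
        start on contig, strand) or None when unanchored/ambiguous."""
        k = self.k
        if len(read) < k:
            return None
        mid = (len(read) - k) // 2
        km = read[mid : mid + k]
        canon = _canon(km)
        hit = self.index.get(canon)
        if hit is None:
            return None
        ci, pos, window_is_canon = hit
        read_is_canon = km == canon
        if read_is_canon == window_is_canon:  # read forward on contig
            return ci, pos - mid, 1
        return ci, pos - (len(read) - k - mid), -1


def _mate_tail(place: tuple[int, int, int], read_len: int, contig_len: int) -> tuple[str, int]:
    """(contig end the fragment exits through, distance from read to that end)."""
    _, p, s = place
    if s == 1:
        return "R", contig_len - p
    return "L", p + read_len


def scaffold_contigs(
    contigs: Sequence[str],
    pairs_by_lib: dict[int, Sequence[tuple[SeqRecord, SeqRecord]]],
    insert_stats: dict[int, tuple[float, float]],
    scaffold_min_links: int = 3,
    anchor_k: int = 31,
    gap_min_run: int = GAP_MIN_RUN,
) -> list[str]:
    """Join contigs supported by >= ``scaffold_min_links`` uniquely-placed
    large-insert pairs agreeing on relative order/orientation; the joint gap
    is the mean implied gap over links, clamped below by ``gap_min_run`` Ns.
    Contradictory links (would close a cycle or re-use a contig end) are
    discarded and logged."""
    if not contigs:
        return []
    index = _AnchorIndex(contigs, anchor_k)
    links: dict[tuple, list[float]] = defaultdict(list)
    for lib, pairs in pairs_by_lib.items():
        mean, _sd = insert_stats[lib]
        for r1, r2 in pairs:
            p1 = index.place_read(r1.seq)
            p2 = index.place_read(r2.seq)
            if p1 is None or p2 is None or p1[0] == p2[0]:
                continue
            e1, t1 = _mate_tail(p1, len(r1.seq), len(contigs[p1[0]]))
            e2, t2 = _mate_tail(p2, len(r2.seq), len(contigs[p2[0]]))
            gap = mean - t1 - t2
            key = ((p1[0], e1), (p2[0], e2))
            if key[0] > key[1]:
                key = (key[1], key[0])
            links[key].append(gap)

    # accept links by support, refusing end re-use and cycles
    used_ends: set[tuple[int, str]] = set()
    parent = list(range(len(contigs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    joins: list[tuple[tuple[int, str], tuple[int, str], int]] = []
    for key, gaps in sorted(links.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        (c1, e1), (c2, e2) = key
        if len(gaps) < scaffold_min_links:
            continue
        if (c1, e1) in used_ends or (c2, e2) in used_ends:
            logger.info("link %s discarded: contig end already joined", key)
            continue
        if find(c1) == find(c2):
            logger.info("link %s discarded: would close a cycle", key)
            continue
        used_ends.update([(c1, e1), (c2, e2)])
        parent[find(c1)] = find(c2)
        gap_len = max(int(round(sum(gaps) / len(gaps))), gap_min_run)
        joins.append(((c1, e1), (c2, e2), gap_len))

    # build chains: each joined end appears in at most one join and cycles
    # were refused, so components are simple paths
    neigh: dict[tuple[int, str], tuple[tuple[int, str], int]] = {}
    joined_ends: dict[int, set[str]] = defaultdict(set)
    for a, b, g in joins:
        neigh[a] = (b, g)
        neigh[b] = (a, g)
        joined_ends[a[0]].add(a[1])
        joined_ends[b[0]].add(b[1])

    emitted: set[int] = set()
    scaffolds = []
    for ci in range(len(contigs)):
        if ci in emitted or len(joined_ends[ci]) == 2:
            continue  # start only at chain termini (or singletons)
        # orient the terminus so its joined end (if any) faces right
        flipped = "L" in joined_ends[ci]
        parts = []
        cur = ci
        while True:
            emitted.add(cur)
            parts.append(revcomp(contigs[cur]) if flipped else contigs[cur])
            exit_end = "L" if flipped else "R"
            step = neigh.get((cur, exit_end))
            if step is None or step[0][0] in emitted:
                break
            (nxt, enter_end), gap = step
            parts.append("N" * gap)
            cur, flipped = nxt, enter_end == "R"
        scaffolds.append("".join(parts))
    return scaffolds


def ksweep_assemble(
    reads: Sequence[tuple[SeqRecord, SeqRecord]],
    params: AssemblyParams,
    large_pairs_by_lib: Optional[dict[int, Sequence[tuple[SeqRecord, SeqRecord]]]] = None,
    clone_id: str = "",
    site_id: str = "",
) -> CloneScaffold:
    """Assemble at every k in the sweep and keep the assembly with the
    longest scaffold N50 (tie -> larger k).  The clone scaffold is the
    longest scaffold of the winning assembly."""
    flat = [r.seq for pair in reads for r in pair]
    read_len = min((len(s) for s in flat), default=0)
    valid_k = [k for k in params.k_values if k < read_len]
    if not valid_k:
        raise ValueError(
            f"no k in {params.k_values} is below the read length ({read_len})")
    diagnostics = {}
    best: Optional[tuple[int, int, list[str]]] = None  # (n50, k, scaffolds)
    for k in valid_k:
        contigs = assemble_contigs(flat, k, params.kmer_min_count, params.min_contig_len)
        if not contigs:
            diagnostics[k] = "no contigs"
            continue
        if large_pairs_by_lib:
            scaffolds = scaffold_contigs(
                contigs, large_pairs_by_lib, params.insert_stats,
                params.scaffold_min_links, params.anchor_k, params.gap_min_run)
        else:
            scaffolds = list(contigs)
        score = n50([len(s) for s in scaffolds])
        diagnostics[k] = f"{len(scaffolds)} scaffolds, N50={score}"
        if best is None or (score, k) >= (best[0], best[1]):
            best = (score, k, scaffolds)
    if best is None:
        raise ValueError(f"assembly failed at every k; diagnostics: {diagnostics}")
    score, k_used, scaffolds = best
    longest = max(scaffolds, key=len)
    return CloneScaffold(
        clone_id=clone_id,
        site_id=site_id,
        seq=longest,
        gaps=find_gaps(longest),
        k_used=k_used,
        stats={
            "n_contigs": len(scaffolds),
            "scaffold_n50": score,
            "total_len": sum(len(s) for s in scaffolds),
            "longest_len": len(longest),
            "per_k": diagnostics,
        },
        scaffolds=scaffolds,
    )
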