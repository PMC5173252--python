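"""Haplotype separation from overlapping clones.

Clones sampled from a diploid individual carry one of two parental
haplotypes.  Where two clones overlap, the variant density of the overlap
tells them apart: same-haplotype pairs differ only by residual assembly
error, different-haplotype pairs at the region's inter-haplotype density.
Thresholding the density gives a same/different relation; propagating it as
a graph two-coloring partitions the clones into the two haplotype groups,
with non-two-colorable components surfacing as conflicts rather than extra
labels (exactly two haplotypes are assumed — one diploid individual).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from csatk.csa_merge import Layout, OverlapEdge

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Variant:
    """One difference between two overlapping clone scaffolds, positioned on
    the first scaffold.  An indel is one contiguous gap run counted as a
    single event (gaps are left-aligned upstream so equivalent alignments
    count identically)."""

    pos: int
    type: str  # "SNP" | "indel"
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.type == "SNP":
            if len(self.allele_a) != 1 or len(self.allele_b) != 1 or (
                    self.allele_a == self.allele_b):
                raise ValueError("SNP alleles must be single, differing bases")
        elif self.type != "indel":
            raise ValueError(f"invalid variant type {self.type!r}")


@dataclass
class HaplotypePartition:
    assignment: dict[str, int | str]  # clone_id -> 1 | 2 | "unassigned"
    separated_regions: list[tuple[int, int, int, int]] = field(default_factory=list)
    conflicts: list[tuple[str, str, str]] = field(default_factory=list)

    def groups(self) -> tuple[set[str], set[str]]:
        g1 = {c for c, l in self.assignment.items() if l == 1}
        g2 = {c for c, l in self.assignment.items() if l == 2}
        return g1, g2


def call_clone_variants(edge: OverlapEdge) -> list[Variant]:
    """Variant list of one overlap: SNPs at non-N mismatch columns, one
    event per maximal gap run, positions on scaffold a."""
    return [Variant(pos, vtype, a, b) for pos, vtype, a, b in edge.variants]


def variant_density(edge: OverlapEdge) -> float:
    """Variants per kb of aligned overlap."""
    if edge.aligned_len <= 0:
        return 0.0
    return len(edge.variants) / (edge.aligned_len / 1000.0)


def partition_clones(
    clones: Sequence[str],
    edges: Sequence[OverlapEdge],
    same_threshold: float = 0.2,
) -> HaplotypePartition:
    """Two-color the clone graph under the same/different relation.

    A pair is "same" when its overlap carries at most ``same_threshold``
    variants per kb, else "different".  Labels propagate breadth-first from
    the clone with the most total overlap in each component; a component
    that cannot be two-colored is reported in ``conflicts`` and its clones
    left unassigned.
    """
    relation: dict[str, list[tuple[str, bool]]] = defaultdict(list)
    total_overlap: dict[str, int] = defaultdict(int)
    for e in edges:
        same = variant_density(e) <= same_threshold
        relation[e.id_a].append((e.id_b, same))
        relation[e.id_b].append((e.id_a, same))
        total_overlap[e.id_a] += e.aligned_len
        total_overlap[e.id_b] += e.aligned_len

    assignment: dict[str, int | str] = {}
    conflicts: list[tuple[str, str, str]] = []
    remaining = set(clones)
    while remaining:
        seed = max(sorted(remaining), key=lambda c: total_overlap.get(c, 0))
        labels: dict[str, int] = {seed: 1}
        queue = [seed]
        component = {seed}
        consistent = True
        while queue:
            u = queue.pop(0)
            for v, same in sorted(relation.get(u, [])):
                want = labels[u] if same else 3 - labels[u]
                if v in labels:
                    if labels[v] != want:
                        conflicts.append((seed, u, v))
                        consistent = False
                    continue
                labels[v] = want
                component.add(v)
                queue.append(v)
        for c in component:
            assignment[c] = labels[c] if consistent else UNASSIGNED
        remaining -= component
    return HaplotypePartition(assignment=assignment, conflicts=conflicts)


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return sorted(out)


def summarize_separated_regions(
    partition: HaplotypePartition,
    layouts: Sequence[Layout],
    scaffold_lens: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Intervals covered by clones of both haplotype groups, with SNP and
    indel counts from the cross-group overlaps.

    Counts are defined on doubly-covered layout intervals; a variant seen in
    several clone pairs at the same projected position is counted once.
    Returns one row per separated interval plus layout/span/count columns.
    """
    rows = []
    for li, layout in enumerate(layouts):
        placement = {sid: (off, ori) for sid, off, ori in layout.members}
        lens: dict[str, int] = dict(scaffold_lens or {})
        for e in layout.edges:
            lens.setdefault(e.id_a, e.len_a)
            lens.setdefault(e.id_b, e.len_b)
        cover: dict[int, list[tuple[int, int]]] = {1: [], 2: []}
        for sid, (off, _ori) in placement.items():
            label = partition.assignment.get(sid)
            if label in (1, 2) and sid in lens:
                cover[label].append((off, off + lens[sid]))
        doubly = _intersect(_union(cover[1]), _union(cover[2]))
        if not doubly:
            continue
        # project cross-group variants into layout coordinates
        seen: dict[tuple[int, int], set[tuple[int, str]]] = defaultdict(set)
        for e in layout.edges:
            la = partition.assignment.get(e.id_a)
            lb = partition.assignment.get(e.id_b)
            if {la, lb} != {1, 2}:
                continue
            off_a, ori_a = placement[e.id_a]
            for pos, vtype, _aa, _ab in e.variants:
                if ori_a == 1:
                    lpos = off_a + pos
                else:
                    lpos = off_a + lens[e.id_a] - pos - 1
                for idx, (s, end) in enumerate(doubly):
                    if s <= lpos < end:
                        seen[(li, idx)].add((lpos, vtype))
                        break
        for idx, (s, end) in enumerate(doubly):
            variants = seen.get((li, idx), set())
            n_snp = sum(1 for _p, t in variants if t == "SNP")
            n_indel = sum(1 for _p, t in variants if t == "indel")
            rows.append((li, s, end, end - s, n_snp, n_indel))
            partition.separated_regions.append((s, end, n_snp, n_indel))
    return pd.DataFrame(
        rows, columns=["layout", "start", "end", "span", "snps", "indels"])
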