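"""The CSA core: overlap detection among clone scaffolds, tiling layout, and
hierarchical merging (first -> second -> super class) with the
gap-minimising conflict rule.

Overlaps are found by shared-k-mer anchoring plus edit-distance extension
(both orientations of the second sequence are tried); connected components
of the overlap graph become layouts by propagating offsets from the longest
scaffold; merged consensus copies, in every interval covered by more than
one scaffold, the contributor with the fewest N bases there ("the assembly
with a smaller gap was kept"), with full per-base provenance.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import edlib

from csatk.core_io import GapInterval, SeqRecord, find_gaps, revcomp

logger = logging.getLogger(__name__)

_CIG = re.compile(r"(\d+)([=XIDM])")


@dataclass
class MergeParams:
    min_overlap: int = 500
    min_identity: float = 0.97  # tolerates inter-haplotype variant density
    offset_tol: int = 100       # absorbs indel-induced coordinate drift
    anchor_k: int = 16


@dataclass
class OverlapEdge:
    """Pairwise overlap evidence; b coordinates are on the plus strand of b,
    ``orientation`` records whether b was reverse-complemented to match."""

    id_a: str
    id_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # "same" | "reverse"
    aligned_len: int
    identity: float
    variants: list[tuple[int, str, str, str]] = field(default_factory=list)
    len_a: int = 0
    len_b: int = 0

    def swapped(self) -> "OverlapEdge":
        """The same overlap seen from b's side (coordinate roles exchanged)."""
        return replace(
            self, id_a=self.id_b, id_b=self.id_a,
            a_start=self.b_start, a_end=self.b_end,
            b_start=self.a_start, b_end=self.a_end,
            len_a=self.len_b, len_b=self.len_a,
            variants=[],
        )


@dataclass
class Layout:
    """An ordered, oriented tiling: (scaffold_id, offset, orientation) with
    offset in layout coordinates and orientation +1/-1."""

    members: list[tuple[str, int, int]]
    edges: list[OverlapEdge] = field(default_factory=list)


@dataclass
class MergedScaffold:
    id: str
    seq: str
    cls: str  # first | second | super
    provenance: list[tuple[int, int, str]]
    gaps: list[GapInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cls not in {"first", "second", "super"}:
            raise ValueError(f"invalid class {self.cls!r}")
        cursor = 0
        for s, e, _src in self.provenance:
            if s != cursor or e <= s:
                raise ValueError("provenance does not tile the sequence")
            cursor = e
        if cursor != len(self.seq):
            raise ValueError("provenance does not cover the full sequence")


def _alignment_strings(sa: str, sb: str) -> Optional[tuple[str, str]]:
    """Global edit-distance alignment of two segments as gapped strings."""
    res = edlib.align(sa, sb, task="path", mode="NW")
    cigar = res.get("cigar")
    if cigar is None:
        return None
    out_a, out_b = [], []
    ia = ib = 0
    for m in _CIG.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in "=XM":
            out_a.append(sa[ia : ia + n])
            out_b.append(sb[ib : ib + n])
            ia += n
            ib += n
        elif op == "D":  # gap in query sa
            out_a.append("-" * n)
            out_b.append(sb[ib : ib + n])
            ib += n
        else:  # "I": gap in target sb
            out_a.append(sa[ia : ia + n])
            out_b.append("-" * n)
            ia += n
    return "".join(out_a), "".join(out_b)


def _trim_end_gaps(aln_a: str, aln_b: str) -> tuple[str, str, int, int, int, int]:
    """Strip leading/trailing gap columns; returns trimmed strings plus the
    number of a-bases and b-bases trimmed at (left_a, left_b, right_a, right_b)."""
    start, end = 0, len(aln_a)
    while start < end and (aln_a[start] == "-" or aln_b[start] == "-"):
        start += 1
    while end > start and (aln_a[end - 1] == "-" or aln_b[end - 1] == "-"):
        end -= 1
    la = sum(1 for c in aln_a[:start] if c != "-")
    lb = sum(1 for c in aln_b[:start] if c != "-")
    ra = sum(1 for c in aln_a[end:] if c != "-")
    rb = sum(1 for c in aln_b[end:] if c != "-")
    return aln_a[start:end], aln_b[start:end], la, lb, ra, rb


def _left_align_gaps(aln_a: str, aln_b: str) -> tuple[str, str]:
    """Shift gap runs leftward where sequence-equivalent, so equivalent
    alignments give identical indel positions and counts."""
    a = list(aln_a)
    b = list(aln_b)

    def shift(g: list[str], s: list[str]) -> None:
        # g holds the gaps, s the bases spanning them
        i = 0
        n = len(g)
        while i < n:
            if g[i] == "-":
                j = i
                while j < n and g[j] == "-":
                    j += 1
                # try to move run [i,j) left
                while i > 0 and g[i - 1] != "-" and s[i - 1] == s[j - 1] and s[i - 1] != "-":
                    g[i - 1], g[j - 1] = g[j - 1], g[i - 1]
                    i -= 1
                    j -= 1
                i = j
            else:
                i += 1

    shift(a, b)
    shift(b, a)
    return "".join(a), "".join(b)


def _alignment_events(
    aln_a: str,
    aln_b: str,
    a_offset: int = 0,
    b_offset: int = 0,
    merge_gap: int = 5,
) -> tuple[int, int, int, list[tuple[int, int, str, str, str]]]:
    """Column walk of one gapped alignment.

    Returns (matches, mismatches, indel_bases, events) where identity tallies
    are per alignment column with N-containing columns excluded, and events
    are canonicalised differences (pos_a, pos_b, type, allele_a, allele_b):
    difference columns separated by at most ``merge_gap`` matching columns
    form one cluster, the cluster alleles are trimmed by their common
    prefix/suffix, equal-length remainders become per-position SNPs and
    length-changing remainders one indel event — so the same underlying
    difference always yields the same event list regardless of how the
    aligner placed its gaps."""
    matches = mismatches = indel_bases = 0
    n = len(aln_a)
    # per-column: 'M' match, 'D' difference, 'n' N-excluded
    classes = []
    for ca, cb in zip(aln_a, aln_b):
        if ca == "-" or cb == "-":
            other = cb if ca == "-" else ca
            if other == "N":
                classes.append("n")
            else:
                classes.append("D")
                indel_bases += 1
        elif ca == "N" or cb == "N":
            classes.append("n")
        elif ca == cb:
            classes.append("M")
            matches += 1
        else:
            classes.append("D")
            mismatches += 1

    # cluster difference columns, merging across short match stretches
    clusters: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if classes[i] != "D":
            i += 1
            continue
        j = i + 1
        last_diff = i
        while j < n:
            if classes[j] == "D":
                last_diff = j
                j += 1
            elif classes[j] in "Mn" and j - last_diff <= merge_gap:
                j += 1
            else:
                break
        clusters.append((i, last_diff + 1))
        i = last_diff + 1

    # absolute a/b positions at the start of every column
    pos_a = [0] * (n + 1)
    pos_b = [0] * (n + 1)
    pa, pb = a_offset, b_offset
    for idx in range(n):
        pos_a[idx], pos_b[idx] = pa, pb
        if aln_a[idx] != "-":
            pa += 1
        if aln_b[idx] != "-":
            pb += 1
    pos_a[n], pos_b[n] = pa, pb

    events: list[tuple[int, int, str, str, str]] = []
    for s, e in clusters:
        ma = aln_a[s:e].replace("-", "")
        mb = aln_b[s:e].replace("-", "")
        if "N" in ma or "N" in mb:
            continue
        p = 0
        while p < min(len(ma), len(mb)) and ma[p] == mb[p]:
            p += 1
        q = 0
        while q < min(len(ma), len(mb)) - p and ma[len(ma) - 1 - q] == mb[len(mb) - 1 - q]:
            q += 1
        ca = ma[p : len(ma) - q]
        cb = mb[p : len(mb) - q]
        if len(ca) == len(cb):
            for k in range(len(ca)):
                if ca[k] != cb[k]:
                    events.append((pos_a[s] + p + k, pos_b[s] + p + k,
                                   "SNP", ca[k], cb[k]))
        else:
            events.append((pos_a[s] + p, pos_b[s] + p, "indel", ca, cb))
    return matches, mismatches, indel_bases, events


def _anchor_offset(a: str, b: str, k: int) -> Optional[tuple[int, int]]:
    """Most-supported diagonal (a_pos - b_pos) from shared k-mers; returns
    (offset, support) or None."""
    positions: dict[str, int] = {}
    multi: set[str] = set()
    for i in range(len(a) - k + 1):
        km = a[i : i + k]
        if "N" in km:
            continue
        if km in positions:
            multi.add(km)
        else:
            positions[km] = i
    offsets: Counter = Counter()
    raw: dict[int, list[int]] = defaultdict(list)
    for j in range(len(b) - k + 1):
        km = b[j : j + k]
        if km in multi or km not in positions:
            continue
        d = positions[km] - j
        offsets[d // 50] += 1
        raw[d // 50].append(d)
    if not offsets:
        return None
    # pool each bin with its right neighbour so diagonals straddling a bin
    # boundary are not split
    best_bin, best_n = None, 0
    for bin_id in offsets:
        n = offsets[bin_id] + offsets.get(bin_id + 1, 0)
        if n > best_n or (n == best_n and (best_bin is None or bin_id < best_bin)):
            best_bin, best_n = bin_id, n
    ds = sorted(raw[best_bin] + raw.get(best_bin + 1, []))
    return ds[len(ds) // 2], best_n


def find_overlap(
    a: SeqRecord,
    b: SeqRecord,
    min_overlap: int = 500,
    min_identity: float = 0.97,
    anchor_k: int = 16,
) -> Optional[OverlapEdge]:
    """Detect a dovetail or containment overlap between two scaffolds.

    Tries b as-is and reverse-complemented; the highest-identity candidate
    with aligned length >= ``min_overlap`` and identity >= ``min_identity``
    (over non-N columns) wins.  Returns None when no such overlap exists.
    """
    best: Optional[OverlapEdge] = None
    for orientation in ("same", "reverse"):
        bseq = b.seq if orientation == "same" else revcomp(b.seq)
        anc = _anchor_offset(a.seq, bseq, anchor_k)
        if anc is None:
            continue
        d, support = anc
        if support * anchor_k < min_overlap // 4:
            continue
        a0, b0 = max(0, d), max(0, -d)
        a1 = min(len(a.seq), d + len(bseq))
        b1 = min(len(bseq), len(a.seq) - d)
        if a1 - a0 < min_overlap // 2 or b1 - b0 < min_overlap // 2:
            continue
        aligned = _alignment_strings(a.seq[a0:a1], bseq[b0:b1])
        if aligned is None:
            continue
        aln_a, aln_b, la, lb, ra, rb = _trim_end_gaps(*aligned)
        aln_a, aln_b = _left_align_gaps(aln_a, aln_b)
        a_start, a_end = a0 + la, a1 - ra
        bo_start, bo_end = b0 + lb, b1 - rb
        matches, mismatches, indel_bases, events = _alignment_events(
            aln_a, aln_b, a_start)
        variants = [(pa, vtype, va, vb) for pa, _pb, vtype, va, vb in events]
        denom = matches + mismatches + indel_bases
        if denom == 0:
            continue
        identity = matches / denom
        aligned_len = a_end - a_start
        if orientation == "same":
            b_start, b_end = bo_start, bo_end
        else:
            b_start, b_end = len(b.seq) - bo_end, len(b.seq) - bo_start
        if aligned_len < min_overlap or identity < min_identity:
            continue
        edge = OverlapEdge(
            id_a=a.id, id_b=b.id, a_start=a_start, a_end=a_end,
            b_start=b_start, b_end=b_end, orientation=orientation,
            aligned_len=aligned_len, identity=identity, variants=variants,
            len_a=len(a.seq), len_b=len(b.seq),
        )
        if best is None or (edge.identity, edge.aligned_len) > (best.identity, best.aligned_len):
            best = edge
    return best


def all_pairs_overlaps(
    records: Sequence[SeqRecord], params: MergeParams
) -> list[OverlapEdge]:
    edges = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            e = find_overlap(records[i], records[j], params.min_overlap,
                             params.min_identity, params.anchor_k)
            if e is not None:
                edges.append(e)
    return edges


def _oriented_b(edge: OverlapEdge) -> tuple[int, int]:
    """b-side region of the edge in b's *edge-matched* orientation frame."""
    if edge.orientation == "same":
        return edge.b_start, edge.b_end
    return edge.len_b - edge.b_end, edge.len_b - edge.b_start


def build_layout(
    scaffolds: Sequence[SeqRecord],
    edges: Sequence[OverlapEdge],
    offset_tol: int = 100,
) -> list[Layout]:
    """Connected components of the overlap graph as offset-consistent tilings.

    Offsets and orientations propagate by breadth-first traversal from the
    longest scaffold of each component; an edge whose implied placement
    contradicts an earlier one by more than ``offset_tol`` (or flips an
    assigned orientation) is dropped with a warning, leaving components
    split rather than force-joined.
    """
    by_id = {r.id: r for r in scaffolds}
    adj: dict[str, list[OverlapEdge]] = defaultdict(list)
    for e in edges:
        adj[e.id_a].append(e)
        adj[e.id_b].append(e.swapped())

    placed: dict[str, tuple[int, int]] = {}
    layouts: list[Layout] = []
    order = sorted(by_id.values(), key=lambda r: (-len(r.seq), r.id))
    for root in order:
        if root.id in placed:
            continue
        placed[root.id] = (0, 1)
        members = {root.id}
        used_edges: list[OverlapEdge] = []
        used_pairs: set[frozenset[str]] = set()
        queue = [root.id]
        while queue:
            uid = queue.pop(0)
            off_u, ori_u = placed[uid]
            for e in sorted(adj[uid], key=lambda e: e.id_b):
                vid = e.id_b
                bo_start, bo_end = _oriented_b(e)
                ori_edge = 1 if e.orientation == "same" else -1
                if ori_u == 1:
                    ori_v = ori_edge
                    off_v = off_u + e.a_start - bo_start
                else:
                    ori_v = -ori_edge
                    off_v = off_u + (e.len_a - e.a_end) - (e.len_b - bo_end)
                if vid in placed:
                    exp_off, exp_ori = placed[vid]
                    if exp_ori != ori_v or abs(exp_off - off_v) > offset_tol:
                        logger.warning(
                            "dropping inconsistent overlap %s-%s "
                            "(offset %d vs %d, orientation %d vs %d)",
                            uid, vid, off_v, exp_off, ori_v, exp_ori)
                        continue
                    pair = frozenset((uid, vid))
                    if vid in members and pair not in used_pairs:
                        used_edges.append(e)
                        used_pairs.add(pair)
                    continue
                placed[vid] = (off_v, ori_v)
                members.add(vid)
                used_edges.append(e)
                used_pairs.add(frozenset((uid, vid)))
                queue.append(vid)
        min_off = min(placed[m][0] for m in members)
        layout_members = sorted(
            ((m, placed[m][0] - min_off, placed[m][1]) for m in members),
            key=lambda t: (t[1], t[0]),
        )
        layouts.append(Layout(members=layout_members, edges=used_edges))
    return layouts


def merge_layout(
    layout: Layout,
    scaffolds: Sequence[SeqRecord],
    cls: str = "second",
    merged_id: str = "merged",
) -> MergedScaffold:
    """Coordinate-projected consensus of one layout.

    In every interval covered by more than one member, the contributor with
    the fewest N bases in that interval is copied; ties go to the longer
    scaffold, then the lexicographically smaller id.  Provenance records
    every choice and tiles the output exactly.
    """
    by_id = {r.id: r for r in scaffolds}
    oriented: dict[str, str] = {}
    spans: list[tuple[int, int, str]] = []
    for sid, off, ori in layout.members:
        seq = by_id[sid].seq
        oriented[sid] = seq if ori == 1 else revcomp(seq)
        spans.append((off, off + len(seq), sid))
    total = max(e for _s, e, _i in spans)
    cuts = sorted({0, total, *(s for s, _e, _i in spans), *(e for _s, e, _i in spans)})

    out: list[str] = []
    provenance: list[tuple[int, int, str]] = []
    cursor = 0
    for x, y in zip(cuts, cuts[1:]):
        covering = [(s, e, sid) for s, e, sid in spans if s <= x and e >= y]
        if not covering:
            continue  # disjoint members in one layout cannot happen (connected)

        def rank(span: tuple[int, int, str]):
            s, _e, sid = span
            piece = oriented[sid][x - s : y - s]
            return (piece.count("N"), -len(oriented[sid]), sid)

        s, _e, sid = min(covering, key=rank)
        piece = oriented[sid][x - s : y - s]
        out.append(piece)
        seg_start = cursor
        cursor += len(piece)
        if provenance and provenance[-1][2] == sid:
            provenance[-1] = (provenance[-1][0], cursor, sid)
        else:
            provenance.append((seg_start, cursor, sid))
    seq = "".join(out)
    return MergedScaffold(id=merged_id, seq=seq, cls=cls,
                          provenance=provenance, gaps=find_gaps(seq))


def merge_site_clones(
    clone_scaffolds_by_site: dict[str, Sequence[SeqRecord]],
    params: Optional[MergeParams] = None,
) -> tuple[list[MergedScaffold], dict[str, list[Layout]]]:
    """Per recombination site: overlap -> layout -> merge, yielding one or
    more second-class scaffolds per site (plus the layouts, for haplotype
    analysis)."""
    params = params or MergeParams()
    merged: list[MergedScaffold] = []
    layouts_by_site: dict[str, list[Layout]] = {}
    for site_id in sorted(clone_scaffolds_by_site):
        records = list(clone_scaffolds_by_site[site_id])
        edges = all_pairs_overlaps(records, params)
        layouts = build_layout(records, edges, params.offset_tol)
        layouts_by_site[site_id] = layouts
        for i, layout in enumerate(layouts):
            merged.append(
                merge_layout(layout, records, cls="second",
                             merged_id=f"{site_id}_sc{i}")
            )
    return merged, layouts_by_site


def build_superscaffolds(
    second_class: Sequence[MergedScaffold],
    params: Optional[MergeParams] = None,
) -> tuple[list[MergedScaffold], list[Layout]]:
    """Merge second-class scaffolds across sites into super-scaffolds; groups
    with no bridging overlap stay separate."""
    params = params or MergeParams()
    records = [SeqRecord(id=m.id, seq=m.seq) for m in second_class]
    edges = all_pairs_overlaps(records, params)
    layouts = build_layout(records, edges, params.offset_tol)
    supers = []
    for i, layout in enumerate(layouts):
        supers.append(
            merge_layout(layout, records, cls="super", merged_id=f"SC{i + 1}")
        )
    return supers, layouts
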