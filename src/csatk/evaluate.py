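"""Assembly assessment: block identity between two assemblies, difference
classification, mate-pair concordance and inter-scaffold linkage, GC
windows, and the three-criteria gene-model merge.

Identity is defined explicitly — sum(matches) / sum(matches + mismatches +
indel_bases) over anchored, chained, gap-extended alignment blocks, with
columns containing N excluded — so a reported percentage is interpretable
on its own terms rather than tied to any particular aligner's convention.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from csatk.core_io import GAP_MIN_RUN, SeqRecord, find_gaps, revcomp
from csatk.csa_merge import (_alignment_events, _alignment_strings,
                             _left_align_gaps, _trim_end_gaps)
from csatk.mini_assembly import _AnchorIndex

logger = logging.getLogger(__name__)

CATEGORIES = ("normal", "gap", "low_coverage", "homopolymer_indel", "insertion")


@dataclass
class Difference:
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    type: str  # "SNP" | "indel"
    allele_q: str = ""
    allele_t: str = ""
    category: str = ""


@dataclass
class IdentityReport:
    blocks: list[tuple[int, int, int, int, int, int, int]]
    identity: float
    uncovered_query: list[tuple[int, int]]
    uncovered_target: list[tuple[int, int]]
    differences: list[Difference]
    orientation: str = "same"
    notes: list[str] = field(default_factory=list)


def _walk(aln_q: str, aln_t: str, q0: int, t0: int):
    """Identity tallies plus differences carrying both coordinate systems
    (shared canonical event extraction; N columns excluded)."""
    matches, mismatches, indel_bases, events = _alignment_events(
        aln_q, aln_t, q0, t0)
    diffs = [
        Difference(pq, pq + len(aq), pt, pt + len(at),
                   vtype, aq, at)
        for pq, pt, vtype, aq, at in events
    ]
    return matches, mismatches, indel_bases, diffs


def _anchors(query: str, target: str, k: int) -> list[tuple[int, int]]:
    """(q_pos, t_pos) for k-mers unique in both sequences."""
    qpos: dict[str, int] = {}
    qmulti: set[str] = set()
    for i in range(len(query) - k + 1):
        km = query[i : i + k]
        if "N" in km:
            continue
        if km in qpos:
            qmulti.add(km)
        else:
            qpos[km] = i
    tseen: dict[str, int] = {}
    tmulti: set[str] = set()
    for j in range(len(target) - k + 1):
        km = target[j : j + k]
        if km in qpos and km not in qmulti:
            if km in tseen:
                tmulti.add(km)
            else:
                tseen[km] = j
    return sorted(
        (qpos[km], j) for km, j in tseen.items() if km not in tmulti
    )


def _complement_intervals(covered: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    cursor = 0
    for s, e in sorted(covered):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return out


def global_identity(
    query: SeqRecord,
    target: SeqRecord,
    anchor_k: int = 32,
    band: int = 300,
    gap_min_run: int = GAP_MIN_RUN,
) -> IdentityReport:
    """K-mer anchored, chained, gap-extended block alignment of two assemblies.

    Anchors on the better-supported orientation are clustered by diagonal,
    chained into blocks, and each block is globally aligned; identity is
    sum(matches) / sum(matches + mismatches + indel_bases) over all blocks.
    Unanchored stretches are reported as uncovered, as are N-runs of
    ``gap_min_run`` or more.  No anchors at all gives identity 0 with both
    sequences fully uncovered.
    """
    if not query.seq or not target.seq:
        raise ValueError("both sequences must be non-empty")
    fwd = _anchors(query.seq, target.seq, anchor_k)
    rc_t = revcomp(target.seq)
    rev = _anchors(query.seq, rc_t, anchor_k)
    if len(rev) > len(fwd):
        orientation, anchors, tseq = "reverse", rev, rc_t
    else:
        orientation, anchors, tseq = "same", fwd, target.seq
    if not anchors:
        return IdentityReport(
            blocks=[], identity=0.0,
            uncovered_query=[(0, len(query.seq))],
            uncovered_target=[(0, len(target.seq))],
            differences=[], orientation=orientation,
            notes=["no anchors shared between the sequences"],
        )
    # chain anchors: same diagonal cluster, collinear, small jumps allowed
    clusters: list[list[tuple[int, int]]] = []
    for qp, tp in anchors:
        placedc = None
        for cl in clusters:
            lq, lt = cl[-1]
            if qp >= lq and tp >= lt and abs((qp - tp) - (lq - lt)) <= band:
                placedc = cl
                break
        if placedc is not None:
            placedc.append((qp, tp))
        else:
            clusters.append([(qp, tp)])
    clusters.sort(key=lambda cl: -(cl[-1][0] + anchor_k - cl[0][0]))

    blocks = []
    differences: list[Difference] = []
    total_m = total_mm = total_ind = 0
    covered_q: list[tuple[int, int]] = []
    covered_t: list[tuple[int, int]] = []
    for cl in clusters:
        q0, t0 = cl[0]
        q1 = cl[-1][0] + anchor_k
        t1 = cl[-1][1] + anchor_k
        if any(s < q1 and q0 < e for s, e in covered_q):
            continue  # secondary cluster over already-aligned query span
        # extend a block to the sequence ends only when the unanchored tail
        # is short (within the chain band); a long unanchored stretch stays
        # uncovered rather than being force-aligned
        ext_left = min(q0, t0) if min(q0, t0) <= band else 0
        tail = min(len(query.seq) - q1, len(tseq) - t1)
        ext_right = tail if tail <= band else 0
        q0e, t0e = q0 - ext_left, t0 - ext_left
        q1e, t1e = q1 + ext_right, t1 + ext_right
        aligned = _alignment_strings(query.seq[q0e:q1e], tseq[t0e:t1e])
        if aligned is None:
            continue
        aln_q, aln_t, lq, lt, rq, rt = _trim_end_gaps(*aligned)
        aln_q, aln_t = _left_align_gaps(aln_q, aln_t)
        bq0, bt0 = q0e + lq, t0e + lt
        m, mm, ind, diffs = _walk(aln_q, aln_t, bq0, bt0)
        bq1, bt1 = q1e - rq, t1e - rt
        total_m += m
        total_mm += mm
        total_ind += ind
        differences.extend(diffs)
        covered_q.append((bq0, bq1))
        covered_t.append((bt0, bt1))
        blocks.append((bq0, bq1, bt0, bt1, m, mm, ind))
    denom = total_m + total_mm + total_ind
    identity = total_m / denom if denom else 0.0
    uncov_q = _complement_intervals(covered_q, len(query.seq))
    uncov_t = _complement_intervals(covered_t, len(tseq))
    uncov_q.extend((g.start, g.end) for g in find_gaps(query.seq, gap_min_run))
    uncov_t.extend((g.start, g.end) for g in find_gaps(tseq, gap_min_run))
    if orientation == "reverse":
        uncov_t = sorted((len(tseq) - e, len(tseq) - s) for s, e in uncov_t)
    return IdentityReport(
        blocks=sorted(blocks), identity=identity,
        uncovered_query=sorted(set(uncov_q)),
        uncovered_target=sorted(set(uncov_t)),
        differences=sorted(differences, key=lambda d: d.q_start),
        orientation=orientation,
    )


def _near_gap(pos: int, seq: str, flank: int, gap_min_run: int) -> bool:
    lo, hi = max(0, pos - flank), min(len(seq), pos + flank + 1)
    return any(g.start < hi and g.end > lo for g in find_gaps(seq, gap_min_run))


def _in_homopolymer(pos: int, seq: str, min_run: int) -> bool:
    lo = max(0, pos - min_run)
    hi = min(len(seq), pos + min_run)
    window = seq[lo:hi]
    run = 1
    for i in range(1, len(window)):
        if window[i] == window[i - 1] and window[i] != "N":
            run += 1
            if run >= min_run:
                return True
        else:
            run = 1
    return False


def classify_differences(
    report: IdentityReport,
    query: SeqRecord,
    target: SeqRecord,
    query_depth: Optional[np.ndarray] = None,
    homopolymer_min_run: int = 4,
    gap_flank: int = 50,
    low_cov: int = 5,
    gap_min_run: int = GAP_MIN_RUN,
) -> IdentityReport:
    """Label each difference: ``gap`` when within ``gap_flank`` of an N-gap
    of either assembly, ``homopolymer_indel`` for an indel inside a run of
    >= ``homopolymer_min_run`` identical bases, ``low_coverage`` when query
    read depth at the site is below ``low_cov``, else ``insertion`` (indel)
    or ``normal`` (substitution)."""
    if query_depth is None:
        note = "no depth track: low_coverage category unavailable"
        if note not in report.notes:
            report.notes.append(note)
    for d in report.differences:
        if _near_gap(d.q_start, query.seq, gap_flank, gap_min_run) or _near_gap(
                d.t_start, target.seq, gap_flank, gap_min_run):
            d.category = "gap"
        elif d.type == "indel" and (
            _in_homopolymer(d.q_start, query.seq, homopolymer_min_run)
            or _in_homopolymer(d.t_start, target.seq, homopolymer_min_run)
        ):
            d.category = "homopolymer_indel"
        elif query_depth is not None and query_depth[
                min(d.q_start, len(query_depth) - 1)] < low_cov:
            d.category = "low_coverage"
        elif d.type == "indel":
            d.category = "insertion"
        else:
            d.category = "normal"
    return report


def read_depth(
    reads: Sequence[SeqRecord], scaffold: SeqRecord, anchor_k: int = 31
) -> np.ndarray:
    """Per-base depth from unique k-mer anchored read placement (the same
    placement convention used for scaffolding and mate-pair mapping)."""
    index = _AnchorIndex([scaffold.seq], anchor_k)
    depth = np.zeros(len(scaffold.seq), dtype=np.int32)
    for r in reads:
        placed = index.place_read(r.seq)
        if placed is None:
            continue
        _ci, start, _strand = placed
        lo = max(0, start)
        hi = min(len(depth), start + len(r.seq))
        if lo < hi:
            depth[lo:hi] += 1
    return depth


@dataclass
class LinkProposal:
    scaffold_a: str
    scaffold_b: str
    support_count: int
    implied_gap: int
    end_a: str = "R"
    end_b: str = "L"


@dataclass
class MatePairSupport:
    concordant: int
    discordant: int
    unmapped: int
    links: list[LinkProposal] = field(default_factory=list)
    link_min_support: int = 3

    @property
    def proposed_joins(self) -> list[LinkProposal]:
        return [l for l in self.links if l.support_count >= self.link_min_support]


def map_matepairs(
    pairs_by_lib: dict[int, Sequence[tuple[SeqRecord, SeqRecord]]],
    scaffolds: Sequence[SeqRecord],
    insert_stats: dict[int, tuple[float, float]],
    link_min_support: int = 3,
    anchor_k: int = 31,
) -> MatePairSupport:
    """Map large-insert pairs to scaffolds by unique exact k-mer anchoring.

    Concordant: both mates on one scaffold, inward-facing, span within
    mean +- 3 sd of the library insert.  Pairs bridging two scaffolds are
    collected as links; a join is proposed when at least
    ``link_min_support`` pairs agree on orientation and implied offset
    (within 3 sd)."""
    seqs = [s.seq for s in scaffolds]
    ids = [s.id for s in scaffolds]
    index = _AnchorIndex(seqs, anchor_k)
    concordant = discordant = unmapped = 0
    bridge: dict[tuple, list[float]] = defaultdict(list)
    sd_by_key: dict[tuple, float] = {}
    for lib, pairs in pairs_by_lib.items():
        mean, sd = insert_stats[lib]
        for r1, r2 in pairs:
            p1 = index.place_read(r1.seq)
            p2 = index.place_read(r2.seq)
            if p1 is None or p2 is None:
                unmapped += 1
                continue
            if p1[0] == p2[0]:
                c, s1 = p1[0], p1[2]
                # inward: forward mate upstream of reverse mate
                if p1[2] != p2[2]:
                    fwd, rev = (p1, p2) if p1[2] == 1 else (p2, p1)
                    fwd_read, rev_read = (r1, r2) if p1[2] == 1 else (r2, r1)
                    span = (rev[1] + len(rev_read.seq)) - fwd[1]
                    if fwd[1] <= rev[1] and abs(span - mean) <= 3 * sd:
                        concordant += 1
                        continue
                discordant += 1
                continue
            # inter-scaffold pair: record through which end each fragment exits
            ends = []
            for p, r in ((p1, r1), (p2, r2)):
                ci, pos, strand = p
                if strand == 1:
                    ends.append((ci, "R", len(seqs[ci]) - pos))
                else:
                    ends.append((ci, "L", pos + len(r.seq)))
            (c1, e1, t1), (c2, e2, t2) = ends
            key = ((c1, e1), (c2, e2))
            if key[0] > key[1]:
                key = (key[1], key[0])
            bridge[key].append(mean - t1 - t2)
            sd_by_key[key] = max(sd_by_key.get(key, 0.0), sd)
    links = []
    for key, gaps in sorted(bridge.items()):
        (c1, e1), (c2, e2) = key
        sd = sd_by_key[key]
        gaps = sorted(gaps)
        med = gaps[len(gaps) // 2]
        agreeing = [g for g in gaps if abs(g - med) <= 3 * sd]
        links.append(LinkProposal(
            scaffold_a=ids[c1], scaffold_b=ids[c2],
            support_count=len(agreeing), implied_gap=int(round(med)),
            end_a=e1, end_b=e2,
        ))
    return MatePairSupport(
        concordant=concordant, discordant=discordant, unmapped=unmapped,
        links=links, link_min_support=link_min_support,
    )


@dataclass
class GCProfile:
    per_window: list[Optional[float]]  # None where a window is all N
    mean: float
    skipped: int

    @property
    def values(self) -> list[float]:
        return [v for v in self.per_window if v is not None]


def gc_windows(seq: str, window: int = 500) -> GCProfile:
    """Non-overlapping window GC over non-N bases; the trailing partial
    window is excluded; all-N windows are skipped (and counted)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    per: list[Optional[float]] = []
    skipped = 0
    for i in range(0, len(seq) - window + 1, window):
        w = seq[i : i + window]
        denom = window - w.count("N")
        if denom == 0:
            per.append(None)
            skipped += 1
        else:
            per.append((w.count("G") + w.count("C")) / denom)
    vals = [v for v in per if v is not None]
    mean = float(np.mean(vals)) if vals else float("nan")
    return GCProfile(per_window=per, mean=mean, skipped=skipped)


@dataclass(frozen=True)
class GeneModel:
    id: str
    seq_id: str
    start: int
    end: int
    n_exons: int
    source: str  # homology | rnaseq | denovo
    align_rate: float = 0.0  # fraction of the model aligned to a known protein

    def __post_init__(self) -> None:
        if self.source not in {"homology", "rnaseq", "denovo"}:
            raise ValueError(f"invalid source {self.source!r}")


_SOURCE_RANK = {"homology": 0, "rnaseq": 1, "denovo": 2}


def merge_gene_models(
    models: Sequence[GeneModel],
    min_overlap: int = 100,
    min_align_rate: float = 0.30,
    min_exons: int = 2,
) -> list[GeneModel]:
    """Three-criteria non-redundant gene set.

    1) single-linkage clustering of models overlapping by strictly more
    than ``min_overlap`` bp on the same sequence; 2) one representative per
    cluster by source precedence (homology > RNA-seq > de novo); 3) a
    cluster containing only de-novo models survives only when its
    representative has align_rate > ``min_align_rate`` and at least
    ``min_exons`` exons."""
    parent = {m.id: m.id for m in models}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ms = sorted(models, key=lambda m: (m.seq_id, m.start, m.id))
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            a, b = ms[i], ms[j]
            if a.seq_id != b.seq_id or b.start >= a.end:
                break
            if min(a.end, b.end) - max(a.start, b.start) > min_overlap:
                parent[find(a.id)] = find(b.id)
    clusters: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        clusters[find(m.id)].append(m)
    out = []
    for members in clusters.values():
        rep = min(members, key=lambda m: (_SOURCE_RANK[m.source],
                                          -(m.end - m.start), m.id))
        if all(m.source == "denovo" for m in members):
            if rep.align_rate > min_align_rate and rep.n_exons >= min_exons:
                out.append(rep)
        else:
            out.append(rep)
    return sorted(out, key=lambda m: (m.seq_id, m.start, m.id))
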