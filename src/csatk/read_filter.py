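"""Pair-aware read filtering: the six-rule cleaning pipeline with accounting.

Rules, applied in order: (1) fixed end-trimming (2 nt at 5', 3 nt at 3');
(2) adapter-bearing or too-short reads; (3) reads with more than 40% of
bases below Q7; (4) reads with more than 10% N; (5) PCR duplicates (exact
ordered pair of post-trim sequences); (6) vector/bacterial contamination
(an exact shared substring of >= 30 nt with any contaminant reference,
either strand).  A pair is dropped when either mate fails a read-level
rule; the report reconciles every pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from csatk.core_io import SeqRecord, revcomp

RULES = ("trim", "adapter_or_short", "low_quality", "too_many_n", "duplicate", "contaminant")


@dataclass
class FilterParams:
    trim5: int = 2
    trim3: int = 3
    min_len_after_trim: int = 30  # 'small size' is not pinned down upstream; exposed here
    adapter_seqs: list[str] = field(default_factory=list)
    adapter_min_seed: int = 10
    low_q_threshold: int = 7     # strictly below Q7 counts as low quality
    low_q_frac: float = 0.40     # strictly more than 40% low-quality bases fails
    n_frac: float = 0.10         # strictly more than 10% N fails
    contam_refs: list[SeqRecord] = field(default_factory=list)
    contam_min_match: int = 30   # a shared exact substring of >= this length fails

    def __post_init__(self) -> None:
        for name in ("low_q_frac", "n_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("trim5", "trim3", "min_len_after_trim", "low_q_threshold",
                     "contam_min_match", "adapter_min_seed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterReport:
    input_pairs: int = 0
    surviving_pairs: int = 0
    dropped_by_rule: dict[str, int] = field(default_factory=dict)
    bases_removed_by_trimming: int = 0

    def check_balance(self) -> None:
        total = self.surviving_pairs + sum(self.dropped_by_rule.values())
        if total != self.input_pairs:
            raise AssertionError(
                f"report does not balance: {self.input_pairs} input != "
                f"{self.surviving_pairs} surviving + {sum(self.dropped_by_rule.values())} dropped"
            )


def trim_read(read: SeqRecord, trim5: int, trim3: int) -> SeqRecord:
    """Shorten sequence and qualities identically; a read too short to trim
    is emptied (and will be removed by the length rule)."""
    if len(read.seq) <= trim5 + trim3:
        return replace(read, seq="", qual=[] if read.qual is not None else None)
    end = len(read.seq) - trim3 if trim3 else len(read.seq)
    qual = read.qual[trim5:end] if read.qual is not None else None
    return replace(read, seq=read.seq[trim5:end], qual=qual)


def has_adapter_or_short(read: SeqRecord, params: FilterParams) -> bool:
    """True if the read is shorter than the post-trim minimum, or its 3' end
    matches an adapter with an exact overlap of >= ``adapter_min_seed`` nt."""
    if len(read.seq) < params.min_len_after_trim:
        return True
    for adapter in params.adapter_seqs:
        max_ov = min(len(read.seq), len(adapter))
        for ov in range(max_ov, params.adapter_min_seed - 1, -1):
            if read.seq.endswith(adapter[:ov]):
                return True
    return False


def low_quality(read: SeqRecord, params: FilterParams) -> bool:
    """True iff strictly more than ``low_q_frac`` of bases are below the
    quality threshold."""
    if read.qual is None:
        raise ValueError(f"read {read.id}: qualities required for the quality rule")
    if not read.qual:
        return False
    n_low = sum(1 for q in read.qual if q < params.low_q_threshold)
    return n_low / len(read.qual) > params.low_q_frac


def too_many_n(read: SeqRecord, params: FilterParams) -> bool:
    """True iff the N fraction strictly exceeds ``n_frac`` (vacuously false
    for empty reads)."""
    if not read.seq:
        return False
    return read.seq.count("N") / len(read.seq) > params.n_frac


def dedup_pairs(
    pairs: Sequence[tuple[SeqRecord, SeqRecord]]
) -> tuple[list[tuple[SeqRecord, SeqRecord]], int]:
    """Keep the first pair of each identical (read1.seq, read2.seq) ordered
    tuple; qualities are ignored.  Returns (kept, n_removed)."""
    seen: set[tuple[str, str]] = set()
    kept = []
    removed = 0
    for r1, r2 in pairs:
        key = (r1.seq, r2.seq)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append((r1, r2))
    return kept, removed


class _ContaminantIndex:
    """Exact-substring screen: a read is contaminated iff it shares a k-mer
    (k = contam_min_match) with any reference, either strand."""

    def __init__(self, refs: Sequence[SeqRecord], k: int):
        self.k = k
        self.kmers: set[str] = set()
        for ref in refs:
            for s in (ref.seq, revcomp(ref.seq)):
                self.kmers.update(s[i : i + k] for i in range(len(s) - k + 1))

    def hits(self, seq: str) -> bool:
        k = self.k
        return any(seq[i : i + k] in self.kmers for i in range(len(seq) - k + 1))


def is_contaminant(read: SeqRecord, params: FilterParams,
                   _index: Optional[_ContaminantIndex] = None) -> bool:
    """True iff the read shares an exact substring of length >=
    ``contam_min_match`` with a contaminant reference on either strand."""
    if not params.contam_refs:
        return False
    index = _index or _ContaminantIndex(params.contam_refs, params.contam_min_match)
    return index.hits(read.seq)


def filter_pipeline(
    pairs: Sequence[tuple[SeqRecord, SeqRecord]], params: FilterParams
) -> tuple[list[tuple[SeqRecord, SeqRecord]], FilterReport]:
    """Apply the six rules in order; a pair is dropped when either mate
    fails, attributed to the first rule that fails it."""
    report = FilterReport(input_pairs=len(pairs),
                          dropped_by_rule={r: 0 for r in RULES[1:]})
    trimmed: list[tuple[SeqRecord, SeqRecord]] = []
    for r1, r2 in pairs:
        t1 = trim_read(r1, params.trim5, params.trim3)
        t2 = trim_read(r2, params.trim5, params.trim3)
        report.bases_removed_by_trimming += (len(r1.seq) - len(t1.seq)) + (
            len(r2.seq) - len(t2.seq))
        trimmed.append((t1, t2))

    survivors: list[tuple[SeqRecord, SeqRecord]] = []
    for t1, t2 in trimmed:
        if has_adapter_or_short(t1, params) or has_adapter_or_short(t2, params):
            report.dropped_by_rule["adapter_or_short"] += 1
        elif low_quality(t1, params) or low_quality(t2, params):
            report.dropped_by_rule["low_quality"] += 1
        elif too_many_n(t1, params) or too_many_n(t2, params):
            report.dropped_by_rule["too_many_n"] += 1
        else:
            survivors.append((t1, t2))

    survivors, n_dup = dedup_pairs(survivors)
    report.dropped_by_rule["duplicate"] = n_dup

    if params.contam_refs:
        index = _ContaminantIndex(params.contam_refs, params.contam_min_match)
        clean = []
        for t1, t2 in survivors:
            if index.hits(t1.seq) or index.hits(t2.seq):
                report.dropped_by_rule["contaminant"] += 1
            else:
                clean.append((t1, t2))
        survivors = clean

    report.surviving_pairs = len(survivors)
    report.check_balance()
    return survivors, report
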