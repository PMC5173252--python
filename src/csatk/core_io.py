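"""Shared domain types and readers/writers for the standard formats the toolkit touches.

Coordinates are 0-based half-open everywhere; intervals are emitted as BED.
FASTQ is Phred+33 only; Phred+64 input is rejected rather than auto-detected,
so a given file always decodes the same way.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: N-runs shorter than this are ambiguous bases, not structural gaps.
GAP_MIN_RUN = 10


class ParseError(ValueError):
    """Raised for malformed sequence files; the message names the offending line."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """An identified nucleotide sequence with optional per-base Phred qualities.

    ``seq`` is uppercase over {A,C,G,T,N}; ``qual``, when present, holds one
    Phred integer (0-60) per base.
    """

    id: str
    seq: str
    description: str = ""
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AnnotationInterval:
    """A labelled genomic interval (exon/intron/intergenic/gene/other)."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in {"exon", "intron", "intergenic", "gene", "other"}:
            raise ValueError(f"invalid kind {self.kind!r}")


@dataclass(frozen=True)
class GapInterval:
    """A maximal run of Ns treated as a structural (scaffolding) gap."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gap [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def coerce_seq(raw: str, context: str = "") -> tuple[str, int]:
    """Uppercase ``raw`` and replace non-ACGTN characters by N.

    Returns the coerced sequence and the number of replacements (logged when
    non-zero).
    """
    seq = raw.upper()
    n_bad = len(_NON_ACGTN.findall(seq))
    if n_bad:
        seq = _NON_ACGTN.sub("N", seq)
        logger.info("%s: replaced %d non-ACGTN characters with N", context or "sequence", n_bad)
    return seq, n_bad


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, in file order.

    Sequences are uppercased; non-ACGTN characters become N (count logged).
    Raises :class:`ParseError` naming the line for an empty file, a file not
    starting with a header, or a duplicate id.
    """
    text = Path(path).read_text()
    first_content = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        raise ParseError(f"{path}: empty FASTA file (line 1)")
    if not first_content[1].lstrip().startswith(">"):
        raise ParseError(
            f"{path}: line {first_content[0]}: expected FASTA header starting with '>'"
        )
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq, _ = coerce_seq(str(rec.seq), context=f"{path}:{rec.id}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (byte-stable)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _read_fastq(path: str | Path) -> list[SeqRecord]:
    records = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            qual = rec.letter_annotations["phred_quality"]
            if qual and max(qual) > 60:
                raise ParseError(
                    f"{path}: record {idx} ({rec.id}): quality above Q60 — "
                    "Phred+64 input is not accepted"
                )
            seq, _ = coerce_seq(str(rec.seq), context=f"{path}:{rec.id}")
            records.append(SeqRecord(id=rec.id, seq=seq, qual=list(qual)))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: record {len(records)}: {exc}") from exc
    return records


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[SeqRecord, SeqRecord]]:
    """Read two mate FASTQ files (Phred+33) into an ordered list of pairs.

    Mate i of file 1 is paired with mate i of file 2; a record-count mismatch
    is an error identifying the first unmatched index.
    """
    r1 = _read_fastq(path1)
    r2 = _read_fastq(path2)
    if len(r1) != len(r2):
        raise ParseError(
            f"mate files differ in record count ({len(r1)} vs {len(r2)}); "
            f"first unmatched record index {min(len(r1), len(r2))}"
        )
    return list(zip(r1, r2))


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as Phred+33 FASTQ; records must carry qualities."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id} has no qualities")
            qline = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")


def write_fastq_pairs(
    pairs: Iterable[tuple[SeqRecord, SeqRecord]], path1: str | Path, path2: str | Path
) -> None:
    pairs = list(pairs)
    write_fastq((p[0] for p in pairs), path1)
    write_fastq((p[1] for p in pairs), path2)


_N_RUN = re.compile(r"N+")


def find_gaps(seq: str, gap_min_run: int = GAP_MIN_RUN) -> list[GapInterval]:
    """Maximal N-runs of length >= ``gap_min_run``, sorted and non-overlapping."""
    return [
        GapInterval(m.start(), m.end())
        for m in _N_RUN.finditer(seq)
        if m.end() - m.start() >= gap_min_run
    ]


def write_bed(intervals: Iterable[AnnotationInterval], path: str | Path) -> None:
    """Emit intervals as 6-column BED (0-based half-open, matching our coordinates)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.label or iv.kind
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[AnnotationInterval]:
    """Read a BED file into AnnotationIntervals; the name column maps to ``kind``
    when it is a recognised class, else to ``label``."""
    kinds = {"exon", "intron", "intergenic", "gene"}
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            kind = name if name in kinds else "other"
            label = "" if name in kinds else name
            out.append(
                AnnotationInterval(
                    seq_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand,
                    kind=kind,
                    label=label,
                )
            )
    return out
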