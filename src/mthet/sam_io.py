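"""Minimal SAM text reader/writer and CIGAR arithmetic.

The heteroplasmy caller consumes a restricted alignment dialect: mapped,
Phred+33-encoded records over a linear amplicon reference.  Coordinates are
1-based leftmost (as in SAM); reference spans are half-open intervals.
Unmapped, secondary and supplementary records are skipped and counted rather
than parsed.  Hard clips are accepted but consume neither query nor
reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_OPS = frozenset("MIDSH=X")
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MD=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_LAST = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: op in {M, I, D, S, H, =, X}, length >= 1."""

    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in VALID_OPS:
            raise ValueError(f"unsupported CIGAR op {self.op!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR length must be >= 1, got {self.length}")


def parse_cigar(text: str) -> tuple[CigarOp, ...]:
    """Parse a CIGAR string into CigarOp tuples; '*' is rejected."""
    if text == "*":
        raise ValueError("missing CIGAR ('*')")
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {text!r}")
        ops.append(CigarOp(m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text) or not ops:
        raise ValueError(f"malformed CIGAR {text!r}")
    return tuple(ops)


def cigar_text(cigar: Sequence[CigarOp]) -> str:
    return "".join(f"{c.length}{c.op}" for c in cigar)


@dataclass
class AlignedRead:
    """One mapped read.

    ``position`` is the 1-based leftmost reference coordinate.  ``qualities``
    are integer Phred scores, one per base.  Pairing, orientation and the
    duplicate mark live in the SAM ``flag``.
    """

    name: str
    reference_name: str
    position: int
    cigar: tuple[CigarOp, ...]
    bases: str
    qualities: tuple[int, ...]
    flag: int = 0
    mapq: int = 60

    # -- flag accessors -------------------------------------------------
    @property
    def is_paired_complete(self) -> bool:
        """Both mates present: paired and mate mapped."""
        return bool(self.flag & FLAG_PAIRED) and not (self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @is_duplicate.setter
    def is_duplicate(self, value: bool) -> None:
        if value:
            self.flag |= FLAG_DUPLICATE
        else:
            self.flag &= ~FLAG_DUPLICATE

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    def query_length(self) -> int:
        return sum(c.length for c in self.cigar if c.op in QUERY_OPS)

    def validate(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        qlen = self.query_length()
        if qlen != len(self.bases) or qlen != len(self.qualities):
            raise ValueError(
                f"read {self.name!r}: query-consuming CIGAR length {qlen} does not "
                f"match {len(self.bases)} bases / {len(self.qualities)} qualities"
            )

    def mean_quality(self) -> float:
        if not self.qualities:
            raise ValueError("read has no qualities")
        return sum(self.qualities) / len(self.qualities)


def reference_span(read: AlignedRead) -> tuple[int, int]:
    """Half-open 1-based reference interval covered by the alignment."""
    ref_len = sum(c.length for c in read.cigar if c.op in REF_OPS)
    if ref_len == 0:
        raise ValueError(f"read {read.name!r}: no reference footprint")
    return read.position, read.position + ref_len


@dataclass
class ParsedSam:
    """parse_sam output: reads plus header lines and skip accounting."""

    reads: list[AlignedRead]
    header: list[str] = field(default_factory=list)
    n_skipped_unmapped: int = 0
    n_skipped_secondary: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_unmapped + self.n_skipped_secondary


def _decode_quals(qual: str) -> tuple[int, ...]:
    return tuple(ord(c) - 33 for c in qual)


def _encode_quals(quals: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def parse_sam(lines: Iterable[str]) -> ParsedSam:
    """Parse SAM text lines into AlignedReads.

    Header lines ('@...') are retained verbatim.  Unmapped records and records
    with '*' CIGAR are skipped and counted, as are secondary/supplementary
    alignments.  Malformed records raise ValueError naming the line number.
    """
    result = ParsedSam(reads=[])
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("@"):
            result.header.append(line)
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ValueError(f"line {lineno}: SAM record has {len(fields)} fields, need >= 11")
        try:
            flag = int(fields[1])
            pos = int(fields[3])
            mapq = int(fields[4])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric flag/position/mapq") from exc
        if flag & FLAG_UNMAPPED or fields[5] == "*" or pos == 0:
            result.n_skipped_unmapped += 1
            continue
        if flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            result.n_skipped_secondary += 1
            continue
        try:
            cigar = parse_cigar(fields[5])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        read = AlignedRead(
            name=fields[0],
            reference_name=fields[2],
            position=pos,
            cigar=cigar,
            bases=fields[9],
            qualities=_decode_quals(fields[10]),
            flag=flag,
            mapq=mapq,
        )
        try:
            read.validate()
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        result.reads.append(read)
    return result


def write_sam(reads: Iterable[AlignedRead], header: Sequence[str] | None = None) -> list[str]:
    """Serialize reads to SAM text lines (Phred+33).

    Reads violating the query-length invariant are refused.  The round trip
    ``parse_sam(write_sam(reads))`` reproduces every field exactly.
    """
    lines = list(header) if header is not None else []
    for read in reads:
        read.validate()
        lines.append(
            "\t".join(
                (
                    read.name,
                    str(read.flag),
                    read.reference_name,
                    str(read.position),
                    str(read.mapq),
                    cigar_text(read.cigar),
                    "=" if read.flag & FLAG_PAIRED else "*",
                    "0",
                    "0",
                    read.bases,
                    _encode_quals(read.qualities),
                )
            )
        )
    return lines


def default_header(reference_name: str, reference_length: int) -> list[str]:
    return [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{reference_name}\tLN:{reference_length}",
    ]


def read_sam_file(path: str) -> ParsedSam:
    with open(path) as fh:
        return parse_sam(fh)


def write_sam_file(path: str, reads: Iterable[AlignedRead], header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in write_sam(reads, header):
            fh.write(line + "\n")
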