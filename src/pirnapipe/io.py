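"""Reading/writing small-RNA sequencing formats and library preprocessing.

The preprocessing contract mirrors a typical TruSeq small-RNA workflow:
3' adapter clipping by exact prefix match, then a strict "more than 10 bp"
length filter (insert length >= 11 nt). Coordinates are 0-based half-open
throughout; the 5'/3' ends of an interval depend on its strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")

#: Illumina TruSeq small-RNA 3' adapter.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Strict reading of "more than 10 bp": keep inserts of at least 11 nt.
MIN_INSERT_LENGTH = 11

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised when a FASTQ file is truncated or internally inconsistent."""


class BedParseError(ValueError):
    """Raised for malformed BED records."""


class ConfigError(ValueError):
    """Raised for invalid preprocessing parameters."""


@dataclass(frozen=True)
class RawRead:
    """A sequenced read before adapter removal."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FastqParseError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise FastqParseError(f"read {self.id!r}: invalid bases {bad}")


@dataclass(frozen=True)
class CleanRead:
    """An adapter-clipped insert with its library label."""

    id: str
    sequence: str
    library: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval on a named reference."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BedParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise BedParseError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5'-most base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Coordinate of the 3'-most base (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def read_fastq(path: str | os.PathLike) -> Iterator[RawRead]:
    """Stream RawReads from a 4-line FASTQ file in file order.

    Raises FastqParseError (with an approximate line number) on truncated
    records or sequence/quality length mismatches.
    """
    with open(path) as handle:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield RawRead(title.split()[0], seq.upper(), qual)
                n += 1
        except ValueError as err:
            raise FastqParseError(
                f"{path}: malformed FASTQ near line {4 * n + 1}: {err}"
            ) from err


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> int:
    """Write (id, sequence) pairs as FASTQ with constant quality 'I'.

    Returns the number of records written.
    """
    n = 0
    with open(path, "w") as out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def clip_adapter(
    sequence: str,
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
    min_overlap: int = 5,
) -> Optional[str]:
    """Remove a 3' adapter by exact prefix match; None when no match.

    Scans for the leftmost position i where the read beyond i matches a
    prefix of the adapter: either a full-length adapter occurrence (or a
    read-suffix/adapter-prefix overlap of >= min_overlap nt), or a shorter
    terminal overlap where the read ends inside the adapter. Returns the
    insert ``sequence[:i]``. Reads without any adapter evidence return
    None; the caller decides whether to drop or keep them.
    """
    if min_overlap < 1:
        raise ConfigError("min_overlap must be >= 1")
    if len(adapter) < min_overlap:
        raise ConfigError(
            f"adapter ({len(adapter)} nt) shorter than min_overlap {min_overlap}"
        )
    n = len(sequence)
    for i in range(n):
        ov = min(n - i, len(adapter))
        if sequence[i : i + ov] == adapter[:ov]:
            if ov >= min_overlap or i + ov == n:
                return sequence[:i]
    return None


def length_filter(
    reads: Iterable[CleanRead], min_length: int = MIN_INSERT_LENGTH
) -> tuple[list[CleanRead], int]:
    """Keep reads of length >= min_length; return (kept, n_discarded)."""
    kept: list[CleanRead] = []
    dropped = 0
    for read in reads:
        if read.length >= min_length:
            kept.append(read)
        else:
            dropped += 1
    return kept, dropped


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED6 intervals verbatim (0-based half-open, input order kept)."""
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand, name)
            except (ValueError, BedParseError) as err:
                raise BedParseError(f"{path}:{lineno}: {err}") from err
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA as ordered (name, sequence) pairs, upper-cased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | os.PathLike, wrap: int = 70
) -> None:
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                out.write(seq[i : i + wrap] + "\n")
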