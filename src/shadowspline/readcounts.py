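"""Read-count tables: FASTQ tallying, TSV round-trip I/O and ranking.

A sequencing sample (one FASTQ file of equal-length short reads) is reduced
to a table mapping each distinct read sequence to its multiplicity.  All
downstream shadow counting and error-rate estimation consumes this table;
base qualities play no role in the method and are discarded.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["ReadCountTable", "count_reads", "write_counts", "read_counts", "rank_sequences"]

_ALPHABET = frozenset("ACGTN")

PathLike = Union[str, Path]


@dataclass
class ReadCountTable:
    """Distinct sequence -> multiplicity for one sample.

    Parameters
    ----------
    entries : dict
        Maps each distinct read sequence (A/C/G/T/N, fixed length) to the
        number of reads with exactly that sequence (>= 1).
    read_length : int
        Common length of every sequence key, in bases.
    total_reads : int
        Number of reads in the sample; equals ``sum(entries.values())``.
    """

    entries: dict[str, int]
    read_length: int
    total_reads: int = field(default=0)

    def __post_init__(self) -> None:
        if self.total_reads == 0:
            self.total_reads = sum(self.entries.values())
        self.validate()

    def validate(self) -> None:
        if not self.entries:
            raise ValueError("read-count table is empty")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        total = 0
        for seq, count in self.entries.items():
            if len(seq) != self.read_length:
                raise ValueError(
                    f"sequence {seq!r} has length {len(seq)}, expected {self.read_length}"
                )
            if not isinstance(count, int) or count < 1:
                raise ValueError(f"count for {seq!r} must be a positive integer, got {count!r}")
            total += count
        if total != self.total_reads:
            raise ValueError(f"total_reads={self.total_reads} but counts sum to {total}")

    def __len__(self) -> int:
        return len(self.entries)


def _open_maybe_gzip(source: Union[PathLike, IO]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _iter_fastq(handle: IO[str]) -> Iterator[tuple[int, str]]:
    """Yield (record_index, uppercase sequence) for each FASTQ record."""
    try:
        for idx, (_title, seq, _qual) in enumerate(FastqGeneralIterator(handle)):
            yield idx, seq.upper()
    except ValueError as exc:  # malformed record: re-raise with context
        raise ValueError(f"malformed FASTQ record: {exc}") from exc


def count_reads(source: Union[PathLike, IO]) -> ReadCountTable:
    """Tally a FASTQ sample (optionally gzip-compressed) into a count table.

    Every read must have the same length; base qualities are ignored.
    Reads containing ``N`` are retained (they may later be counted as
    shadows but are never eligible as error-free anchors).

    Raises
    ------
    ValueError
        On an empty file, a malformed record, a read whose length differs
        from the first read's (the offending record index is reported), or
        characters outside A/C/G/T/N.
    """
    entries: dict[str, int] = {}
    read_length = -1
    n_records = 0
    handle = _open_maybe_gzip(source)
    try:
        for idx, seq in _iter_fastq(handle):
            if read_length < 0:
                read_length = len(seq)
                if read_length == 0:
                    raise ValueError("record 0 has an empty sequence")
            elif len(seq) != read_length:
                raise ValueError(
                    f"record {idx} has read length {len(seq)}, expected {read_length}"
                )
            if not _ALPHABET.issuperset(seq):
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"record {idx} contains invalid symbols {bad}")
            entries[seq] = entries.get(seq, 0) + 1
            n_records += 1
    finally:
        if not hasattr(source, "read"):
            handle.close()
    if n_records == 0:
        raise ValueError("FASTQ input contains no records")
    return ReadCountTable(entries=entries, read_length=read_length, total_reads=n_records)


def write_counts(table: ReadCountTable, path: PathLike) -> None:
    """Write a count table as 2-column TSV (``sequence\\tcount``) with header."""
    with open(path, "wt") as out:
        out.write("sequence\tcount\n")
        for seq, count in rank_sequences(table):
            out.write(f"{seq}\t{count}\n")


def read_counts(path: PathLike) -> ReadCountTable:
    """Read a 2-column TSV count file; a ``sequence\\tcount`` header is optional.

    Raises
    ------
    ValueError
        On duplicate sequence rows, non-integer counts or ragged rows.
    """
    entries: dict[str, int] = {}
    read_length = -1
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            seq, count_str = fields
            if lineno == 1 and (seq, count_str) == ("sequence", "count"):
                continue
            seq = seq.upper()
            try:
                count = int(count_str)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer count {count_str!r}") from None
            if seq in entries:
                raise ValueError(f"line {lineno}: duplicate sequence {seq!r}")
            if read_length < 0:
                read_length = len(seq)
            entries[seq] = count
    if not entries:
        raise ValueError(f"{path}: no count rows")
    return ReadCountTable(entries=entries, read_length=read_length)


def rank_sequences(table: ReadCountTable) -> list[tuple[str, int]]:
    """Rank sequences by count, descending; ties broken lexicographically.

    The deterministic tie-break makes the top-N error-free selection
    reproducible across runs and platforms.
    """
    return sorted(table.entries.items(), key=lambda item: (-item[1], item[0]))
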