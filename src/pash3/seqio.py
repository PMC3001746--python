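"""FASTA/FASTQ readers, SAM writing, and small tabular formats.

Coordinates are 0-based half-open everywhere inside the package; the single
conversion to SAM's 1-based POS happens in :func:`write_sam`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_fasta",
    "read_fastq",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "write_sam",
    "read_bed",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class SequenceRecord:
    """A named sequence with optional per-base qualities."""

    name: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ParseError("sequence record with empty name")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.name!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )


def read_fasta(path: PathLike) -> Iterator[SequenceRecord]:
    """Lazily yield records from a FASTA file.

    Multi-line sequences are joined; lowercase is folded to uppercase; the
    record name is the header token before the first whitespace.  A sequence
    line before any header raises :class:`ParseError` with its line number.
    """
    name: Optional[str] = None
    chunks: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield SequenceRecord(name, "".join(chunks).upper())
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                name = header.split()[0]
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence line before any '>' header"
                    )
                chunks.append(line.strip())
    if name is not None:
        yield SequenceRecord(name, "".join(chunks).upper())


def read_fastq(path: PathLike) -> Iterator[SequenceRecord]:
    """Lazily yield 4-line FASTQ records (qualities retained, unused by
    mapping).  Truncated records or length mismatches raise ParseError."""
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {title.split()[0]!r}: sequence/quality "
                        "length mismatch"
                    )
                yield SequenceRecord(title.split()[0], seq.upper(), qual)
        except ValueError as exc:  # Biopython's own format errors
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: {exc}") from exc


def read_sequences(path: PathLike) -> Iterator[SequenceRecord]:
    """Dispatch on content: FASTQ if the file starts with '@', else FASTA."""
    with open(path) as handle:
        first = handle.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[SequenceRecord], out: IO[str], width: int = 70) -> None:
    for rec in records:
        out.write(f">{rec.name}\n")
        for i in range(0, len(rec.seq), width):
            out.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], out: IO[str]) -> None:
    for rec in records:
        qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
        out.write(f"@{rec.name}\n{rec.seq}\n+\n{qual}\n")


def write_sam(
    references: Sequence[tuple[str, int]],
    mappings: Iterable["ReadMapping"],
    reads: Sequence[SequenceRecord],
    out: IO[str],
    program_args: str = "",
) -> None:
    """Emit SAM text: @HD/@SQ/@PG header, one record per read in input order.

    ``mappings`` holds the primary mapping per mapped read (see
    :meth:`pash3.mapper.MappingResult.primary_mappings`); reads without one
    are written unmapped (flag 4, POS 0, CIGAR '*').
    """
    ref_lengths = dict(references)
    out.write("@HD\tVN:1.6\tSO:unknown\n")
    for name, length in references:
        out.write(f"@SQ\tSN:{name}\tLN:{length}\n")
    out.write(f"@PG\tID:pash3\tPN:pash3\tVN:0.1.0\tCL:{program_args}\n")

    by_read: dict[int, "ReadMapping"] = {}
    for m in mappings:
        if m.ref_name not in ref_lengths:
            raise ValueError(f"mapping for read {m.read_name!r} references "
                             f"unknown sequence {m.ref_name!r}")
        by_read.setdefault(m.read_id, m)

    for read_id, rec in enumerate(reads):
        m = by_read.get(read_id)
        if m is None:
            out.write(
                f"{rec.name}\t4\t*\t0\t0\t*\t*\t0\t0\t{rec.seq}\t"
                f"{rec.qual or '*'}\n"
            )
            continue
        flag = 16 if m.strand == "-" else 0
        qual = rec.qual or "*"
        if m.strand == "-" and rec.qual:
            qual = rec.qual[::-1]
        out.write(
            f"{m.read_name}\t{flag}\t{m.ref_name}\t{m.pos + 1}\t{m.mapq}\t"
            f"{m.cigar}\t*\t0\t0\t{m.seq}\t{qual}\tNM:i:{m.nm}\tAS:i:{m.score}\n"
        )


def read_bed(path: PathLike) -> list[tuple[str, int, int]]:
    """Minimal BED3 reader: (chrom, start, end) per non-comment line."""
    regions = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line with <3 fields")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions
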