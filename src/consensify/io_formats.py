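"""Readers and writers for the file dialects the tool touches.

The central input is the paired ``.pos`` / ``.counts`` table dialect produced
by per-site base counting of reads mapped to a reference (angsd
``-doCounts``-style): the ``.pos`` file carries ``chr``, ``pos`` (1-based) and
``totDepth`` columns, the line-paired ``.counts`` file carries the per-base
read support ``totA totC totG totT``. Sites with zero coverage are simply
absent from the files. Both files may be plain text or gzip; gzip is detected
from the magic bytes, never from the file name.

Scaffold names and lengths come from a standard ``samtools faidx``-style
index. Pseudohaploid output sequences are written as FASTA with one record
per reference scaffold.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from Bio import SeqIO

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
N_CODE = 4
ALPHABET = set("ACGTN")

_COUNTS_HEADER = ("totA", "totC", "totG", "totT")


class CountsFormatError(ValueError):
    """Raised when a pos/counts pair (or fai file) violates its dialect."""


@dataclass(frozen=True)
class SiteCounts:
    """Read support at one reference position.

    ``counts`` is ordered (A, C, G, T); ``depth`` is their sum. ``position``
    is 1-based, matching the pos-file dialect.
    """

    scaffold: str
    position: int
    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if len(self.counts) != 4 or any(c < 0 for c in self.counts):
            raise ValueError(f"counts must be 4 non-negative integers, got {self.counts!r}")

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ScaffoldIndex:
    """Ordered (name, length) pairs of the reference scaffolds."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scaffold names in index")
        for name, length in self.entries:
            if length < 1:
                raise ValueError(f"scaffold {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def length_of(self, name: str) -> int:
        for n, ln in self.entries:
            if n == name:
                return ln
        raise KeyError(name)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _open_text(source: str | os.PathLike | IO) -> IO[str]:
    """Open ``source`` for text reading, transparently decoding gzip.

    Accepts a path or an already-open (text or binary) stream. Gzip is
    recognised by its two magic bytes.
    """
    if isinstance(source, (str, os.PathLike)):
        raw: IO[bytes] = open(source, "rb")
        return _wrap_binary(raw)
    if isinstance(source, io.TextIOBase):
        return source
    if hasattr(source, "read"):
        probe = source.read(0)
        if isinstance(probe, bytes):
            return _wrap_binary(source)
        return source  # text-mode duck
    raise TypeError(f"cannot read from {source!r}")


def _wrap_binary(raw: IO[bytes]) -> IO[str]:
    head = raw.peek(2)[:2] if hasattr(raw, "peek") else None
    if head is None:
        buffered = io.BufferedReader(raw)  # type: ignore[arg-type]
        head = buffered.peek(2)[:2]
        raw = buffered
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(raw, "rb"))  # type: ignore[arg-type]
    return io.TextIOWrapper(raw)


def read_counts(
    pos_source: str | os.PathLike | IO,
    counts_source: str | os.PathLike | IO,
    *,
    counts_header: bool = True,
) -> Iterator[SiteCounts]:
    """Yield one :class:`SiteCounts` per paired line of a pos/counts pair.

    The two files are line-paired: line *i* of the counts body describes the
    position named on line *i* of the pos body. The pos header line is
    optional and auto-detected; the counts header is required unless
    ``counts_header=False``. ``totDepth`` in the pos file must equal the sum
    of the four counts, otherwise a :class:`CountsFormatError` names the
    offending line.
    """
    pos_fh = _open_text(pos_source)
    counts_fh = _open_text(counts_source)

    pos_lines = (ln for ln in pos_fh if ln.strip())
    counts_lines = (ln for ln in counts_fh if ln.strip())

    if counts_header:
        try:
            header = next(counts_lines)
        except StopIteration:
            raise CountsFormatError("counts file is empty (expected a header line)")
        cols = tuple(header.split())
        if cols != _COUNTS_HEADER:
            raise CountsFormatError(
                f"counts header must be {' '.join(_COUNTS_HEADER)!r}, got {header.strip()!r}"
            )

    first_pos = next(pos_lines, None)
    if first_pos is not None:
        fields = first_pos.split()
        if len(fields) < 3:
            raise CountsFormatError(f"pos line 1 has {len(fields)} fields, expected >= 3")
        try:
            int(fields[1])
            has_header = False
        except ValueError:
            has_header = True
        if not has_header:
            pos_lines = _chain_first(first_pos, pos_lines)

    lineno = 0
    for pos_line in pos_lines:
        lineno += 1
        counts_line = next(counts_lines, None)
        if counts_line is None:
            raise CountsFormatError(
                f"pos/counts line-count mismatch: counts file ended before pos line {lineno}"
            )
        yield _parse_pair(pos_line, counts_line, lineno)
    trailing = next(counts_lines, None)
    if trailing is not None:
        raise CountsFormatError(
            f"pos/counts line-count mismatch: counts file has extra data after line {lineno}"
        )


def _chain_first(first: str, rest: Iterator[str]) -> Iterator[str]:
    yield first
    yield from rest


def _parse_pair(pos_line: str, counts_line: str, lineno: int) -> SiteCounts:
    pfields = pos_line.split()
    if len(pfields) < 3:
        raise CountsFormatError(f"pos line {lineno}: expected chr, pos, totDepth")
    scaffold = pfields[0]
    try:
        position = int(pfields[1])
        tot_depth = int(pfields[2])
    except ValueError as exc:
        raise CountsFormatError(f"pos line {lineno}: non-integer field ({exc})") from None
    cfields = counts_line.split()
    if len(cfields) != 4:
        raise CountsFormatError(f"counts line {lineno}: expected 4 columns, got {len(cfields)}")
    try:
        counts = tuple(int(c) for c in cfields)
    except ValueError:
        raise CountsFormatError(f"counts line {lineno}: non-integer count in {cfields!r}") from None
    if any(c < 0 for c in counts):
        raise CountsFormatError(f"counts line {lineno}: negative count in {counts!r}")
    if sum(counts) != tot_depth:
        raise CountsFormatError(
            f"line {lineno}: pos totDepth {tot_depth} != counts sum {sum(counts)}"
        )
    try:
        return SiteCounts(scaffold, position, counts)  # type: ignore[arg-type]
    except ValueError as exc:
        raise CountsFormatError(f"line {lineno}: {exc}") from None


def write_counts(
    sites: Iterable[SiteCounts],
    pos_sink: str | os.PathLike | IO[str],
    counts_sink: str | os.PathLike | IO[str],
    *,
    pos_header: bool = True,
) -> None:
    """Write a SiteCounts stream back to the paired pos/counts dialect."""
    own_pos = isinstance(pos_sink, (str, os.PathLike))
    own_counts = isinstance(counts_sink, (str, os.PathLike))
    pos_fh = open(pos_sink, "w") if own_pos else pos_sink
    counts_fh = open(counts_sink, "w") if own_counts else counts_sink
    try:
        if pos_header:
            pos_fh.write("chr\tpos\ttotDepth\n")
        counts_fh.write("\t".join(_COUNTS_HEADER) + "\n")
        for site in sites:
            pos_fh.write(f"{site.scaffold}\t{site.position}\t{site.depth}\n")
            counts_fh.write("\t".join(str(c) for c in site.counts) + "\n")
    finally:
        if own_pos:
            pos_fh.close()
        if own_counts:
            counts_fh.close()


def read_fasta_index(index_source: str | os.PathLike | IO) -> ScaffoldIndex:
    """Parse a faidx-style index; only name and length columns are consumed."""
    fh = _open_text(index_source)
    entries: list[tuple[str, int]] = []
    for lineno, line in enumerate(fh, start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 2:
            raise CountsFormatError(f"fai line {lineno}: expected at least name and length")
        try:
            length = int(fields[1])
        except ValueError:
            raise CountsFormatError(f"fai line {lineno}: non-integer length {fields[1]!r}") from None
        entries.append((fields[0], length))
    try:
        return ScaffoldIndex(tuple(entries))
    except ValueError as exc:
        raise CountsFormatError(str(exc)) from None


def write_fasta(
    sequences: Mapping[str, str],
    sink: str | os.PathLike | IO[str],
    line_width: int = 60,
) -> None:
    """Write scaffold -> base-string mappings as FASTA.

    Headers match the reference scaffold names. Bases must be A/C/G/T/N.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "w") if own else sink
    try:
        for name, seq in sequences.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"scaffold {name!r}: illegal characters {sorted(bad)}")
            fh.write(f">{name}\n")
            for start in range(0, len(seq), line_width):
                fh.write(seq[start : start + line_width] + "\n")
    finally:
        if own:
            fh.close()


def read_fasta(source: str | os.PathLike | IO[str]) -> dict[str, str]:
    """Read a FASTA file into an ordered scaffold -> sequence mapping."""
    fh = _open_text(source)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
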