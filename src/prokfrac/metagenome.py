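"""Total metagenome base counts, from read files or a sizes table.

The denominator of the prokaryotic fraction is the total number of bases
sequenced.  It can be counted directly from FASTA/FASTQ files (gzipped or
not; format auto-detected from content) or supplied per sample via a
two-column TSV, in bases or megabases (the SRA "mbases" convention,
10^6 bases).  Files are counted verbatim: quality lines are never
counted, and N characters count as bases.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, List, TextIO, Tuple, Union

from Bio import SeqIO

from .errors import SequenceFileError, TableFormatError
from .profile import PathSource, _open_for_read

SIZES_HEADER = ("sample", "size")
MEGABASE = 1_000_000


@dataclass(frozen=True)
class MetagenomeSize:
    """Total bases for one sample and how the number was obtained."""

    sample_id: str
    bases: int
    source: str  # "counted" or "table"

    def __post_init__(self) -> None:
        if self.bases <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: metagenome size must be > 0 bases"
            )
        if self.source not in ("counted", "table"):
            raise ValueError(f"unknown size source {self.source!r}")


def _open_maybe_gzip(path: PathSource) -> TextIO:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "r", encoding="ascii")


def _detect_format(handle: TextIO, path: PathSource) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise SequenceFileError(
        f"{os.fspath(path)}: not FASTA or FASTQ (first character {first!r})"
    )


def count_bases(read_files: Union[PathSource, Iterable[PathSource]]) -> int:
    """Sum sequence lengths over one or more FASTA/FASTQ(.gz) files.

    Paired files are simply summed.  A truncated or corrupt record raises
    :class:`SequenceFileError` naming the file and record index.
    """
    if isinstance(read_files, (str, os.PathLike)):
        read_files = [read_files]
    total = 0
    for path in read_files:
        handle = _open_maybe_gzip(path)
        try:
            fmt = _detect_format(handle, path)
            parser = SeqIO.parse(handle, fmt)
            index = 0
            while True:
                try:
                    record = next(parser)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise SequenceFileError(
                        f"{os.fspath(path)}: corrupt {fmt} record at index "
                        f"{index}: {exc}"
                    ) from exc
                total += len(record.seq)
                index += 1
        finally:
            handle.close()
    return total


def read_sizes_table(
    source: Union[PathSource, TextIO], units: str = "bases"
) -> List[MetagenomeSize]:
    """Read a per-sample sizes TSV with header ``sample<TAB>size``.

    ``units`` is ``"bases"`` or ``"megabases"``; megabase values are
    multiplied by 10^6 (decimal, not binary).  Non-positive sizes raise
    :class:`TableFormatError` with the line number.
    """
    if units not in ("bases", "megabases"):
        raise ValueError(f"units must be 'bases' or 'megabases', got {units!r}")
    handle, should_close = _open_for_read(source)
    try:
        header = tuple(handle.readline().rstrip("\n").split("\t"))
        if header != SIZES_HEADER:
            raise TableFormatError(
                f"line 1: expected header {SIZES_HEADER}, got {header}"
            )
        sizes: List[MetagenomeSize] = []
        seen = set()
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise TableFormatError(
                    f"line {lineno}: expected 2 columns, got {len(fields)}"
                )
            sample, size_text = fields
            if sample in seen:
                raise TableFormatError(
                    f"line {lineno}: duplicate sample {sample!r}"
                )
            seen.add(sample)
            try:
                size = float(size_text)
            except ValueError:
                raise TableFormatError(
                    f"line {lineno}: size {size_text!r} is not a number"
                ) from None
            if size <= 0:
                raise TableFormatError(
                    f"line {lineno}: size must be > 0, got {size_text}"
                )
            bases = int(round(size * MEGABASE)) if units == "megabases" else int(
                round(size)
            )
            sizes.append(MetagenomeSize(sample_id=sample, bases=bases, source="table"))
        return sizes
    finally:
        if should_close:
            handle.close()


def write_sizes_table(
    sizes: Iterable[MetagenomeSize], dest: Union[PathSource, TextIO]
) -> None:
    from .profile import _open_for_write

    handle, should_close = _open_for_write(dest)
    try:
        handle.write("\t".join(SIZES_HEADER) + "\n")
        for s in sizes:
            handle.write(f"{s.sample_id}\t{s.bases}\n")
    finally:
        if should_close:
            handle.close()
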