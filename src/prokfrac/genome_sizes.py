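"""Taxon genome-length model: completeness/contamination correction and
rank-averaged genome sizes.

A recovered genome's observed length underestimates the true length when
the bin is incomplete and overestimates it when contaminated.  The
corrected size is ``genome_size / completeness * (1 + contamination)``
with completeness and contamination as decimal fractions.

Sizes are propagated up the taxonomy by unweighted averaging of the rank
immediately below: a genus size is the mean of its species' adjusted
sizes, a family size the mean of its genus sizes, and so on through
order, class, phylum and domain.  The root fallback continues the same
recursion one level further (mean of domain sizes) so that coverage left
entirely unclassified still receives a size.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, TextIO, Tuple, Union

from .errors import TableFormatError, TaxonNotFoundError
from .profile import (
    PathSource,
    TaxonomyPath,
    _open_for_read,
    _open_for_write,
    parse_taxonomy,
    ROOT_TOKEN,
)

GENOME_METADATA_HEADER = (
    "accession", "taxonomy", "genome_size_bp", "completeness", "contamination",
)
TAXON_LENGTH_HEADER = ("taxon", "genome_size_bp")


def adjusted_genome_size(
    genome_size: float, completeness: float, contamination: float
) -> float:
    """Correct an observed genome size for bin completeness and contamination.

    Parameters are validated: ``genome_size > 0``, ``0 < completeness <= 1``
    and ``contamination >= 0`` (both as decimal fractions, not percent).
    Contamination above 1.0 is accepted — pathological bins can exceed
    100% duplication — but triggers a warning.
    """
    if genome_size <= 0:
        raise ValueError(f"genome_size must be > 0, got {genome_size}")
    if not (0 < completeness <= 1):
        raise ValueError(
            f"completeness must be in (0, 1], got {completeness} "
            "(fractions, not percent)"
        )
    if contamination < 0:
        raise ValueError(f"contamination must be >= 0, got {contamination}")
    if contamination > 1.0:
        warnings.warn(
            f"contamination {contamination} exceeds 1.0; check that the value "
            "is a fraction, not a percentage",
            stacklevel=2,
        )
    return genome_size / completeness * (1 + contamination)


@dataclass(frozen=True)
class GenomeRecord:
    """One reference genome or MAG with quality estimates and species taxonomy."""

    accession: str
    taxonomy: TaxonomyPath
    genome_size: int
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if self.taxonomy.depth != 7:
            raise ValueError(
                f"genome {self.accession!r}: taxonomy must be species-level "
                f"(7 ranks), got depth {self.taxonomy.depth}"
            )
        # reuse the validation; result discarded
        adjusted_genome_size(self.genome_size, self.completeness, self.contamination)

    @property
    def adjusted_size(self) -> float:
        return adjusted_genome_size(
            self.genome_size, self.completeness, self.contamination
        )


@dataclass
class TaxonLengthTable:
    """Rank-qualified taxon → mean adjusted genome size (bp).

    ``sizes`` maps full :class:`TaxonomyPath` keys at every rank to their
    mean size; ``root_size`` is the fallback for root-level coverage.
    """

    sizes: Dict[TaxonomyPath, float] = field(default_factory=dict)
    root_size: float = 0.0

    def lookup(self, path: TaxonomyPath) -> float:
        if path.is_root:
            if self.root_size <= 0:
                raise TaxonNotFoundError("no root-level size available in table")
            return self.root_size
        try:
            return self.sizes[path]
        except KeyError:
            raise TaxonNotFoundError(
                f"taxon {path} absent from taxon-length table"
            ) from None


def lookup_size(table: TaxonLengthTable, path: TaxonomyPath) -> float:
    """Size at the path's deepest rank; root path returns the root fallback.

    A missing taxon is a hard :class:`TaxonNotFoundError` — there is no
    silent fallback to a parent rank, so profile/table version mismatches
    surface loudly.
    """
    return table.lookup(path)


def _mean(values: Sequence[float]) -> float:
    # fsum keeps the bottom-up means exact for integer-valued sizes
    return math.fsum(values) / len(values)


def build_taxon_length_table(records: Sequence[GenomeRecord]) -> TaxonLengthTable:
    """Aggregate genome records into per-rank mean genome sizes.

    Species size is the mean adjusted size of that species' records (one
    record per species in the usual representative-genome case).  Each
    higher rank is the *unweighted* mean of the sizes one rank below it —
    a family with a 10-species genus and a 1-species genus weights the two
    genera equally.  The root fallback is the mean of domain sizes.
    """
    if not records:
        raise ValueError("cannot build a taxon-length table from zero records")
    by_species: Dict[TaxonomyPath, List[float]] = {}
    for record in records:
        by_species.setdefault(record.taxonomy, []).append(record.adjusted_size)
    sizes: Dict[TaxonomyPath, float] = {
        path: _mean(vals) for path, vals in by_species.items()
    }
    # average upward one rank at a time: genus <- species, ..., domain <- phylum
    for depth in range(6, 0, -1):
        children: Dict[TaxonomyPath, List[float]] = {}
        for path, size in sizes.items():
            if path.depth == depth + 1:
                children.setdefault(path.truncate(depth), []).append(size)
        for parent, vals in children.items():
            sizes[parent] = _mean(vals)
    domain_sizes = [s for p, s in sizes.items() if p.depth == 1]
    return TaxonLengthTable(sizes=sizes, root_size=_mean(domain_sizes))


def write_taxon_lengths(
    table: TaxonLengthTable, dest: Union[PathSource, TextIO]
) -> None:
    """Serialize a table as a two-column TSV (taxon path, size in bp).

    Sizes are written with full float precision so a round trip preserves
    every lookup result bit-for-bit.
    """
    handle, should_close = _open_for_write(dest)
    try:
        handle.write("\t".join(TAXON_LENGTH_HEADER) + "\n")
        handle.write(f"{ROOT_TOKEN}\t{table.root_size!r}\n")
        for path in sorted(table.sizes, key=lambda p: (p.depth, str(p))):
            handle.write(f"{path}\t{table.sizes[path]!r}\n")
    finally:
        if should_close:
            handle.close()


def read_taxon_lengths(source: Union[PathSource, TextIO]) -> TaxonLengthTable:
    """Read a taxon-length TSV written by :func:`write_taxon_lengths`.

    A ``Root`` row sets the root fallback; if absent, the fallback is the
    mean of the domain-level rows.  Non-positive sizes raise
    :class:`TableFormatError` with the line number.
    """
    handle, should_close = _open_for_read(source)
    try:
        header = tuple(handle.readline().rstrip("\n").split("\t"))
        if header != TAXON_LENGTH_HEADER:
            raise TableFormatError(
                f"line 1: expected header {TAXON_LENGTH_HEADER}, got {header}"
            )
        sizes: Dict[TaxonomyPath, float] = {}
        root_size = None
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise TableFormatError(
                    f"line {lineno}: expected 2 columns, got {len(fields)}"
                )
            taxon_text, size_text = fields
            try:
                size = float(size_text)
            except ValueError:
                raise TableFormatError(
                    f"line {lineno}: size {size_text!r} is not a number"
                ) from None
            if size <= 0:
                raise TableFormatError(
                    f"line {lineno}: genome size must be > 0, got {size_text}"
                )
            path = parse_taxonomy(taxon_text)
            if path.is_root:
                root_size = size
            else:
                sizes[path] = size
        if root_size is None:
            domain_sizes = [s for p, s in sizes.items() if p.depth == 1]
            if not domain_sizes:
                raise TableFormatError(
                    "table has neither a Root row nor domain-level rows"
                )
            root_size = _mean(domain_sizes)
        return TaxonLengthTable(sizes=sizes, root_size=root_size)
    finally:
        if should_close:
            handle.close()


def _parse_fraction(text: str, column: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise TableFormatError(
            f"line {lineno}: {column} {text!r} is not a number"
        ) from None
    if value > 1:
        warnings.warn(
            f"line {lineno}: {column} {value} > 1; interpreting as a "
            "percentage and dividing by 100",
            stacklevel=3,
        )
        value /= 100.0
    return value


def read_genome_metadata(source: Union[PathSource, TextIO]) -> List[GenomeRecord]:
    """Read genome metadata TSV: accession, taxonomy, size, completeness, contamination.

    Completeness and contamination are decimal fractions; values above 1
    are taken as percentages and divided by 100, with a warning.
    """
    handle, should_close = _open_for_read(source)
    try:
        header = tuple(handle.readline().rstrip("\n").split("\t"))
        if header != GENOME_METADATA_HEADER:
            raise TableFormatError(
                f"line 1: expected header {GENOME_METADATA_HEADER}, got {header}"
            )
        records: List[GenomeRecord] = []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise TableFormatError(
                    f"line {lineno}: expected 5 columns, got {len(fields)}"
                )
            accession, taxonomy_text, size_text, comp_text, cont_text = fields
            try:
                genome_size = int(size_text)
            except ValueError:
                raise TableFormatError(
                    f"line {lineno}: genome_size_bp {size_text!r} is not an integer"
                ) from None
            if genome_size <= 0:
                raise TableFormatError(
                    f"line {lineno}: genome_size_bp must be > 0, got {size_text}"
                )
            completeness = _parse_fraction(comp_text, "completeness", lineno)
            contamination = _parse_fraction(cont_text, "contamination", lineno)
            records.append(
                GenomeRecord(
                    accession=accession,
                    taxonomy=parse_taxonomy(taxonomy_text),
                    genome_size=genome_size,
                    completeness=completeness,
                    contamination=contamination,
                )
            )
        return records
    finally:
        if should_close:
            handle.close()


def write_genome_metadata(
    records: Sequence[GenomeRecord], dest: Union[PathSource, TextIO]
) -> None:
    handle, should_close = _open_for_write(dest)
    try:
        handle.write("\t".join(GENOME_METADATA_HEADER) + "\n")
        for r in records:
            handle.write(
                f"{r.accession}\t{r.taxonomy}\t{r.genome_size}\t"
                f"{r.completeness!r}\t{r.contamination!r}\n"
            )
    finally:
        if should_close:
            handle.close()
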