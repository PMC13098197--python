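"""Condensed community profiles and GTDB-style taxonomy strings.

A *condensed profile* is a sparse community profile: each row assigns a
per-base read coverage to a taxon at whatever rank the underlying reads
could be resolved to.  Coverage stored at a genus-level node represents
reads that were classified to the genus but not to any species within it;
it is **not** the cumulative coverage of the genus' descendants.

Taxonomy strings follow the seven-rank Genome Taxonomy Database (GTDB)
convention — ``d__``, ``p__``, ``c__``, ``o__``, ``f__``, ``g__``, ``s__``
prefixes joined by ``"; "``, optionally led by a literal ``Root`` token.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, List, Sequence, TextIO, Tuple, Union

from .errors import ProfileFormatError, TaxonomyParseError

RANK_LEVELS: Tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
RANK_PREFIXES: Tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

ROOT_TOKEN = "Root"
#: Pseudo-rank returned by :func:`deepest_rank` for the empty (root) path.
ROOT_RANK = "root"

CONDENSED_HEADER = ("sample", "coverage", "taxonomy")

PathSource = Union[str, os.PathLike]


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered domain→species rank path; the empty path is root level.

    ``ranks`` is a tuple of ``(rank_level, name)`` pairs.  Ranks must start
    at domain and descend without gaps, so a species-level path always has
    all seven levels.
    """

    ranks: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for i, (level, name) in enumerate(self.ranks):
            if i >= len(RANK_LEVELS) or level != RANK_LEVELS[i]:
                raise TaxonomyParseError(
                    f"rank {level!r} at position {i} breaks domain→species order"
                )
            if not name:
                raise TaxonomyParseError(f"empty taxon name at rank {level!r}")
            if "\t" in name or ";" in name or "\n" in name:
                raise TaxonomyParseError(
                    f"taxon name {name!r} contains a forbidden character"
                )

    @property
    def depth(self) -> int:
        return len(self.ranks)

    @property
    def is_root(self) -> bool:
        return not self.ranks

    def deepest_rank(self) -> str:
        """The last rank level of the path, or ``"root"`` for the empty path."""
        return self.ranks[-1][0] if self.ranks else ROOT_RANK

    def truncate(self, depth: int) -> "TaxonomyPath":
        """The ancestor path keeping only the first ``depth`` ranks."""
        return TaxonomyPath(self.ranks[:depth])

    def __str__(self) -> str:
        if not self.ranks:
            return ROOT_TOKEN
        tokens = [ROOT_TOKEN] + [
            RANK_PREFIXES[i] + name for i, (_, name) in enumerate(self.ranks)
        ]
        return "; ".join(tokens)


def parse_taxonomy(text: str) -> TaxonomyPath:
    """Parse a semicolon-delimited GTDB taxonomy string into a rank path.

    The string may optionally begin with a ``Root`` token; ``"Root"`` alone
    denotes the empty (root-level) path.  Prefixes are validated against
    rank order, so a gap or out-of-order rank raises
    :class:`TaxonomyParseError` naming the offending token.
    """
    if not text.strip():
        raise TaxonomyParseError("empty taxonomy string")
    tokens = [t.strip() for t in text.split(";")]
    if tokens and tokens[0] == ROOT_TOKEN:
        tokens = tokens[1:]
    ranks = []
    for i, token in enumerate(tokens):
        if i >= len(RANK_PREFIXES):
            raise TaxonomyParseError(f"token {token!r} exceeds the species rank")
        prefix = RANK_PREFIXES[i]
        if not token.startswith(prefix):
            raise TaxonomyParseError(
                f"token {token!r} at position {i}: expected prefix {prefix!r} "
                f"({RANK_LEVELS[i]} rank)"
            )
        name = token[len(prefix):]
        if not name:
            raise TaxonomyParseError(f"token {token!r} has an empty taxon name")
        ranks.append((RANK_LEVELS[i], name))
    return TaxonomyPath(tuple(ranks))


def deepest_rank(path: TaxonomyPath) -> str:
    """Rank level of a path's last node (``"root"`` for the empty path)."""
    return path.deepest_rank()


@dataclass(frozen=True)
class ProfileEntry:
    """Coverage assigned at one taxonomy node (not cumulative over children)."""

    taxonomy: TaxonomyPath
    coverage: float

    def __post_init__(self) -> None:
        if not (self.coverage >= 0):
            raise ProfileFormatError(
                f"coverage must be >= 0, got {self.coverage!r} for {self.taxonomy}"
            )


@dataclass(frozen=True)
class CondensedProfile:
    """One sample's community profile: a set of per-taxon coverages."""

    sample_id: str
    entries: Tuple[ProfileEntry, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for entry in self.entries:
            if entry.taxonomy in seen:
                raise ProfileFormatError(
                    f"duplicate taxonomy {entry.taxonomy} in sample "
                    f"{self.sample_id!r}"
                )
            seen.add(entry.taxonomy)

    @property
    def total_coverage(self) -> float:
        return sum(e.coverage for e in self.entries)


def _open_for_read(source) -> Tuple[TextIO, bool]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _open_for_write(dest) -> Tuple[TextIO, bool]:
    if isinstance(dest, (str, os.PathLike)):
        return open(dest, "w", encoding="utf-8", newline="\n"), True
    return dest, False


def read_condensed(source: Union[PathSource, TextIO]) -> List[CondensedProfile]:
    """Read a condensed-profile TSV into one :class:`CondensedProfile` per sample.

    Expects a header row ``sample<TAB>coverage<TAB>taxonomy``.  Rows are
    grouped by sample preserving input order.  Malformed rows raise
    :class:`ProfileFormatError` carrying the 1-based line number.
    """
    handle, should_close = _open_for_read(source)
    try:
        header_line = handle.readline()
        header = tuple(header_line.rstrip("\n").split("\t"))
        if header != CONDENSED_HEADER:
            raise ProfileFormatError(
                f"line 1: expected header {CONDENSED_HEADER}, got {header}"
            )
        order: List[str] = []
        grouped: dict = {}
        seen: set = set()
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ProfileFormatError(
                    f"line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            sample, coverage_text, taxonomy_text = fields
            try:
                coverage = float(coverage_text)
            except ValueError:
                raise ProfileFormatError(
                    f"line {lineno}: coverage {coverage_text!r} is not a number"
                ) from None
            if coverage < 0:
                raise ProfileFormatError(
                    f"line {lineno}: negative coverage {coverage_text}"
                )
            try:
                taxonomy = parse_taxonomy(taxonomy_text)
            except TaxonomyParseError as exc:
                raise ProfileFormatError(f"line {lineno}: {exc}") from exc
            key = (sample, taxonomy)
            if key in seen:
                raise ProfileFormatError(
                    f"line {lineno}: duplicate (sample, taxonomy) row for "
                    f"sample {sample!r}, taxonomy {taxonomy}"
                )
            seen.add(key)
            if sample not in grouped:
                grouped[sample] = []
                order.append(sample)
            grouped[sample].append(ProfileEntry(taxonomy, coverage))
        return [CondensedProfile(s, tuple(grouped[s])) for s in order]
    finally:
        if should_close:
            handle.close()


def write_condensed(
    profiles: Sequence[CondensedProfile],
    dest: Union[PathSource, TextIO],
    precision: int = 2,
) -> None:
    """Write profiles as a canonical three-column TSV.

    Coverage is formatted with ``precision`` decimal places (default 2);
    full precision is retained in memory, only serialization rounds.
    """
    handle, should_close = _open_for_write(dest)
    try:
        handle.write("\t".join(CONDENSED_HEADER) + "\n")
        for profile in profiles:
            for entry in profile.entries:
                handle.write(
                    f"{profile.sample_id}\t{entry.coverage:.{precision}f}\t"
                    f"{entry.taxonomy}\n"
                )
    finally:
        if should_close:
            handle.close()
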