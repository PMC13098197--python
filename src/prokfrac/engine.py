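"""Prokaryotic-fraction computation.

The estimator rests on a Lander–Waterman-style identity: the number of
metagenome bases deriving from a taxon is its per-base read coverage times
its genome size.  Summing over every taxon in the community profile gives
the bacterial/archaeal base count; dividing by the metagenome's total base
count and capping at 100% gives the reported prokaryotic fraction.

The same per-taxon sizes, weighted by coverage, yield the community's
average microbial genome size.  A perturbation analysis of the most
abundant rank-unresolved lineages flags simple communities whose estimate
hinges on uncertain genome sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, TextIO, Tuple, Union

from .genome_sizes import TaxonLengthTable
from .profile import CondensedProfile, PathSource, _open_for_write

#: A perturbed-minus-baseline raw fraction must stay within this many
#: percentage points for every probed lineage, else a warning is raised.
WARNING_THRESHOLD_PERCENT = 2.0
#: Number of most-abundant rank-unresolved lineages probed by the warning.
WARNING_TOP_N = 3

SPF_OUTPUT_COLUMNS = (
    "sample",
    "bacterial_archaeal_bases",
    "metagenome_size",
    "read_fraction",
    "average_bacterial_archaeal_genome_size",
    "warning",
)


@dataclass(frozen=True)
class PerturbationDelta:
    """Raw-fraction shift (percentage points) from resizing one lineage."""

    taxonomy: str
    coverage: float
    delta_doubled: float
    delta_halved: float

    @property
    def max_abs_delta(self) -> float:
        return max(abs(self.delta_doubled), abs(self.delta_halved))


@dataclass(frozen=True)
class SPFResult:
    """Per-sample prokaryotic-fraction estimate and its derived quantities."""

    sample_id: str
    microbial_bases: float
    metagenome_bases: float
    raw_fraction: float
    reported_fraction: float
    average_genome_size: float
    warning: bool
    warning_detail: Tuple[PerturbationDelta, ...] = ()


def microbial_bases(profile: CondensedProfile, table: TaxonLengthTable) -> float:
    """Sum of coverage × genome size over all profile entries, in bp.

    Entries at non-species ranks use their rank's mean size from the
    table; an unresolvable taxon propagates a lookup error.
    """
    return math.fsum(
        entry.coverage * table.lookup(entry.taxonomy) for entry in profile.entries
    )


def average_genome_size(
    profile: CondensedProfile, table: TaxonLengthTable
) -> float:
    """Coverage-weighted mean genome size over all entries (all ranks)."""
    if not profile.entries:
        raise ValueError("average genome size is undefined for an empty profile")
    total_coverage = math.fsum(e.coverage for e in profile.entries)
    if total_coverage <= 0:
        raise ValueError("average genome size is undefined at zero total coverage")
    weighted = math.fsum(
        entry.coverage * table.lookup(entry.taxonomy) for entry in profile.entries
    )
    return weighted / total_coverage


def novelty_warning(
    profile: CondensedProfile,
    table: TaxonLengthTable,
    metagenome_bases_count: float,
) -> Tuple[bool, Tuple[PerturbationDelta, ...]]:
    """Flag simple communities dominated by rank-unresolved lineages.

    The three most abundant lineages not classified to species level
    (root-level entries included) are probed one at a time: the raw,
    uncapped fraction is recomputed with that lineage's genome size
    doubled and halved, everything else fixed.  A warning is raised if
    any probe moves the raw fraction by more than 2 percentage points.
    Ties in abundance are broken by taxonomy string for determinism.
    """
    if metagenome_bases_count <= 0:
        raise ValueError(
            f"metagenome_bases must be > 0, got {metagenome_bases_count}"
        )
    baseline_raw = (
        microbial_bases(profile, table) / metagenome_bases_count * 100.0
    )
    candidates = sorted(
        (e for e in profile.entries if e.taxonomy.depth < 7),
        key=lambda e: (-e.coverage, str(e.taxonomy)),
    )[:WARNING_TOP_N]
    details = []
    for candidate in candidates:
        perturbed = {}
        for factor in (2.0, 0.5):
            total = math.fsum(
                entry.coverage
                * table.lookup(entry.taxonomy)
                * (factor if entry is candidate else 1.0)
                for entry in profile.entries
            )
            perturbed[factor] = total / metagenome_bases_count * 100.0
        details.append(
            PerturbationDelta(
                taxonomy=str(candidate.taxonomy),
                coverage=candidate.coverage,
                delta_doubled=perturbed[2.0] - baseline_raw,
                delta_halved=perturbed[0.5] - baseline_raw,
            )
        )
    warn = any(d.max_abs_delta > WARNING_THRESHOLD_PERCENT for d in details)
    return warn, tuple(details)


def compute_spf(
    profile: CondensedProfile,
    table: TaxonLengthTable,
    metagenome_bases_count: float,
) -> SPFResult:
    """Estimate the prokaryotic fraction of one sample's metagenome.

    ``raw_fraction`` is microbial bases over metagenome bases × 100 and
    may exceed 100 when genome sizes are overestimated or the metagenome
    base count understates the sequencing effort; ``reported_fraction``
    caps it at 100 since larger fractions are impossible.
    """
    if metagenome_bases_count <= 0:
        raise ValueError(
            f"metagenome_bases must be > 0, got {metagenome_bases_count}"
        )
    bases = microbial_bases(profile, table)
    raw = bases / metagenome_bases_count * 100.0
    reported = min(raw, 100.0)
    if profile.entries and profile.total_coverage > 0:
        ags = average_genome_size(profile, table)
    else:
        ags = 0.0
    warn, detail = novelty_warning(profile, table, metagenome_bases_count)
    return SPFResult(
        sample_id=profile.sample_id,
        microbial_bases=bases,
        metagenome_bases=metagenome_bases_count,
        raw_fraction=raw,
        reported_fraction=reported,
        average_genome_size=ags,
        warning=warn,
        warning_detail=detail,
    )


def write_spf_results(
    results: Sequence[SPFResult],
    dest: Union[PathSource, TextIO],
    emit_raw: bool = False,
) -> None:
    """Write one TSV row per sample; fractions use 2 decimal places."""
    handle, should_close = _open_for_write(dest)
    try:
        columns = SPF_OUTPUT_COLUMNS + (("raw_read_fraction",) if emit_raw else ())
        handle.write("\t".join(columns) + "\n")
        for r in results:
            row = [
                r.sample_id,
                f"{r.microbial_bases:.2f}",
                f"{r.metagenome_bases:.0f}",
                f"{r.reported_fraction:.2f}",
                f"{r.average_genome_size:.2f}",
                str(r.warning),
            ]
            if emit_raw:
                row.append(f"{r.raw_fraction:.2f}")
            handle.write("\t".join(row) + "\n")
    finally:
        if should_close:
            handle.close()
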