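"""Metrics derived from a prokaryotic-fraction estimate.

Domain-adjusted mapping rate (DAMR)
    Read-mapping rates against a genome catalog understate recovery
    success when much of a metagenome is non-microbial.  DAMR divides the
    mapped-read percentage by the prokaryotic fraction: mapping 45% of
    reads in a community that is 50% microbial means the catalog captures
    90% of the microbial portion.  Where the fraction estimate falls below
    the mapping rate — an artifact of one or the other — DAMR is rounded
    down to 100%.

Fungi : microbial cell ratios
    In a community of bacteria and fungi only, with equal lysis
    efficiency and equal genome copies per cell, read counts satisfy
    ``r_m = c_m * g_m * s`` and ``r_f = c_f * g_f * s`` (cells × genome
    size × reads-per-position), and the microbial read share is
    ``SPF = r_m / (r_m + r_f)``.  Eliminating ``s`` gives
    ``c_f / c_m = (1 - SPF) * g_m / (SPF * g_f)``.  The default fungal
    genome size of 37.5 Mbp is an Ascomycota-wide average (mean over
    genera of per-genus median sizes); every assumption is an overridable
    parameter, not a hard-coded truth.
"""

from __future__ import annotations

#: Default average fungal genome size in bp (Ascomycota genus-median mean).
DEFAULT_FUNGAL_GENOME_SIZE = 37_500_000.0


def damr(mapped_fraction: float, spf: float) -> float:
    """Domain-adjusted mapping rate, in percent.

    Both operands are percentages in [0, 100].  Returns
    ``min(mapped_fraction / spf * 100, 100)``.
    """
    if not (0 <= mapped_fraction <= 100):
        raise ValueError(
            f"mapped_fraction must be a percentage in [0, 100], got {mapped_fraction}"
        )
    if not (0 < spf <= 100):
        raise ValueError(
            f"spf must be a percentage in (0, 100], got {spf} "
            "(a zero fraction leaves DAMR undefined)"
        )
    return min(mapped_fraction / spf * 100.0, 100.0)


def fungal_cell_ratio(
    spf: float, gm: float, gf: float = DEFAULT_FUNGAL_GENOME_SIZE
) -> float:
    """Fungal-to-microbial cell count ratio ``c_f / c_m``.

    ``spf`` is the microbial read share as a fraction in (0, 1]; ``gm``
    and ``gf`` are the average microbial and fungal genome sizes in bp.
    ``spf == 1`` (no fungal reads) returns 0.
    """
    if not (0 < spf <= 1):
        raise ValueError(
            f"spf must be a fraction in (0, 1], got {spf}"
            + (" (zero microbial reads imply an infinite ratio)" if spf == 0 else "")
        )
    if gm <= 0 or gf <= 0:
        raise ValueError(f"genome sizes must be > 0, got gm={gm}, gf={gf}")
    return (1.0 - spf) * gm / (spf * gf)


def microbial_cell_ratio(
    spf: float, gm: float, gf: float = DEFAULT_FUNGAL_GENOME_SIZE
) -> float:
    """Microbial-to-fungal cell count ratio ``c_m / c_f`` (reciprocal form).

    Requires ``spf`` strictly inside (0, 1): at ``spf == 1`` there are no
    fungal cells and the ratio diverges.
    """
    if not (0 < spf < 1):
        raise ValueError(
            f"spf must be a fraction in (0, 1), got {spf}"
            + (" (no fungal reads imply an infinite ratio)" if spf == 1 else "")
        )
    if gm <= 0 or gf <= 0:
        raise ValueError(f"genome sizes must be > 0, got gm={gm}, gf={gf}")
    return spf * gf / ((1.0 - spf) * gm)
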