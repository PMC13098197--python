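"""Independent brute-force oracles and random-fixture generators.

These deliberately avoid the implementation's code paths: the taxonomy
tree oracle recurses top-down with statistics.mean, whereas the package
aggregates bottom-up with fsum.
"""

from __future__ import annotations

import statistics
from typing import Dict, List, Tuple

import numpy as np

from prokfrac import GenomeRecord, TaxonomyPath

_BRANCHING = (2, 3, 3, 3, 3, 3, 4)  # per-level fan-out for random trees


def random_records(rng: np.random.Generator, max_species: int = 100) -> List[GenomeRecord]:
    """Random species-level genome records on a random nested taxonomy tree."""
    n = int(rng.integers(1, max_species + 1))
    records = []
    for i in range(n):
        indices = ""
        ranks = []
        from prokfrac.profile import RANK_LEVELS

        for level, branch in zip(RANK_LEVELS, _BRANCHING):
            indices += f".{int(rng.integers(0, branch))}"
            ranks.append((level, f"T{indices}"))
        records.append(
            GenomeRecord(
                accession=f"R{i:04d}",
                taxonomy=TaxonomyPath(tuple(ranks)),
                genome_size=int(rng.integers(1_000_000, 10_000_000)),
                completeness=float(rng.uniform(0.5, 1.0)),
                contamination=float(rng.uniform(0.0, 0.3)),
            )
        )
    return records


def brute_force_sizes(
    records: List[GenomeRecord],
) -> Tuple[Dict[TaxonomyPath, float], float]:
    """Top-down recursive mean-of-children oracle; returns (sizes, root size)."""
    by_species: Dict[TaxonomyPath, List[float]] = {}
    for r in records:
        adjusted = r.genome_size / r.completeness * (1 + r.contamination)
        by_species.setdefault(r.taxonomy, []).append(adjusted)
    species_paths = list(by_species)
    result: Dict[TaxonomyPath, float] = {}

    def compute(path: TaxonomyPath) -> float:
        if path.depth == 7:
            value = statistics.mean(by_species[path])
        else:
            kids = sorted(
                {
                    p.truncate(path.depth + 1)
                    for p in species_paths
                    if p.ranks[: path.depth] == path.ranks
                },
                key=str,
            )
            value = statistics.mean(compute(k) for k in kids)
        if path.depth > 0:
            result[path] = value
        return value

    root = compute(TaxonomyPath())
    return result, root
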