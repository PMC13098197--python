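"""Synthetic communities with known ground-truth prokaryotic fractions.

Real benchmarking of a read-fraction estimator simulates reads; this
package consumes community profiles, not reads, so the generator here
builds the downstream objects directly: a condensed profile, the genome
records to build a taxon-length table from, and a stated metagenome size,
all mutually consistent with a designed prokaryotic fraction.

Novel species — community members missing from the reference at species
rank — are emulated by the exact mechanism that matters to the estimator:
their profile entry is truncated to genus rank and their genome record is
withheld from the table-building set, so their genome size must be
imputed from congeners via the genus mean.  ``within_genus_size_cv``
controls how much congener sizes scatter around the withheld species'
size, emulating real inter-strain genome-size variance.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .engine import compute_spf
from .genome_sizes import GenomeRecord, build_taxon_length_table
from .metagenome import MetagenomeSize
from .profile import CondensedProfile, ProfileEntry, TaxonomyPath, RANK_LEVELS


@dataclass(frozen=True)
class SyntheticTruth:
    """Exact ground truth backing one synthetic community.

    ``species`` lists (taxonomy, true genome size bp, cell abundance);
    ``s`` is the reads-per-position sequencing depth factor, so coverage
    is abundance × s; ``novelty_map`` records which species' profile
    entries were truncated to genus rank.
    """

    species: Tuple[Tuple[TaxonomyPath, int, float], ...]
    s: float
    nonmicrobial_bases: float
    metagenome_bases: int
    microbial_bases: float
    true_fraction: float
    novelty_map: Dict[str, str]


def expected_coverage(n_reads: float, read_length: float, genome_size: float) -> float:
    """Fold coverage of a genome: reads × read length / genome size.

    Sequencing a 1 Mbp genome to 1,000,000 reads of 150 bp covers each
    position 150 times on average.
    """
    if n_reads <= 0 or read_length <= 0:
        raise ValueError("n_reads and read_length must be > 0")
    if genome_size <= 0:
        raise ValueError(f"genome_size must be > 0, got {genome_size}")
    return n_reads * read_length / genome_size


def _lineage(genus_index: int) -> Tuple[Tuple[str, str], ...]:
    # deterministic nested grouping: families pair genera, orders pair
    # families, and so on up to a single bacterial domain
    names = (
        "Bacteria",
        f"Phy{genus_index // 16 + 1}",
        f"Cls{genus_index // 8 + 1}",
        f"Ord{genus_index // 4 + 1}",
        f"Fam{genus_index // 2 + 1}",
        f"Genus{genus_index + 1}",
    )
    return tuple(zip(RANK_LEVELS[:6], names))


def _species_path(genus_index: int, species_index: int) -> TaxonomyPath:
    lineage = _lineage(genus_index)
    name = f"Genus{genus_index + 1} sp{species_index + 1:03d}"
    return TaxonomyPath(lineage + (("species", name),))


def _round_to_multiple(value: float, multiple: int) -> int:
    return max(multiple, int(round(value / multiple)) * multiple)


def simulate_community(
    n_species: int,
    abundance_model: str = "lognormal",
    novelty_fraction: float = 0.0,
    spike_fraction: float = 0.0,
    seed: int = 0,
    s: float = 1.0,
    species_per_genus: int = 2,
    within_genus_size_cv: float = 0.0,
) -> Tuple[CondensedProfile, List[GenomeRecord], MetagenomeSize, SyntheticTruth]:
    """Build one self-consistent synthetic community.

    ``abundance_model`` is ``"lognormal"`` (long-tailed, lognormal(0, 1),
    the realistic default) or ``"uniform"`` (equal abundances, the
    worst-case simple community).  ``novelty_fraction`` of species are
    truncated to genus rank in the profile and withheld from the genome
    records; at least one congener must remain per genus to impute the
    genus size, otherwise a ``ValueError`` is raised.  ``spike_fraction``
    of the metagenome is non-microbial, so the designed fraction is
    ``100 × (1 − spike_fraction)``.

    Genome sizes are drawn per genus in 2–8 Mbp and shared by congeners
    up to a lognormal factor with coefficient of variation
    ``within_genus_size_cv``.  Completeness/contamination of the emitted
    records are chosen so the adjusted sizes equal the true sizes exactly.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not (0 <= novelty_fraction <= 1):
        raise ValueError(f"novelty_fraction must be in [0, 1], got {novelty_fraction}")
    if not (0 <= spike_fraction < 1):
        raise ValueError(f"spike_fraction must be in [0, 1), got {spike_fraction}")
    if abundance_model not in ("uniform", "lognormal"):
        raise ValueError(f"unknown abundance_model {abundance_model!r}")
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    rng = np.random.default_rng(seed)

    # assign species to genera in blocks of species_per_genus
    genus_of = [i // species_per_genus for i in range(n_species)]
    n_genera = genus_of[-1] + 1
    genus_members: Dict[int, List[int]] = {}
    for i, g in enumerate(genus_of):
        genus_members.setdefault(g, []).append(i)

    # true genome sizes: genus base size, multiplied by within-genus noise;
    # multiples of 4 bp so completeness in {1, 1/2, 1/4} divides exactly
    genus_base = [
        _round_to_multiple(rng.uniform(2e6, 8e6), 4) for _ in range(n_genera)
    ]
    if within_genus_size_cv > 0:
        sigma = math.sqrt(math.log1p(within_genus_size_cv**2))
        mu = -(sigma**2) / 2.0
        noise = rng.lognormal(mu, sigma, size=n_species)
    else:
        noise = np.ones(n_species)
    true_sizes = [
        _round_to_multiple(genus_base[genus_of[i]] * noise[i], 4)
        for i in range(n_species)
    ]

    if abundance_model == "uniform":
        abundances = np.ones(n_species)
    else:
        abundances = rng.lognormal(0.0, 1.0, size=n_species)
    coverages = [float(a * s) for a in abundances]

    # choose novel species: at most (genus size - 1) per genus so a
    # congener always remains to estimate the genus mean from
    n_novel = int(round(novelty_fraction * n_species))
    capacity = sum(len(m) - 1 for m in genus_members.values())
    if n_novel > capacity:
        raise ValueError(
            f"cannot withhold {n_novel} species: only {capacity} have a "
            "congener left to estimate their genus genome size from"
        )
    novel: set = set()
    eligible = [g for g in range(n_genera) if len(genus_members[g]) > 1]
    # round-robin over genera (shuffled) so novelty spreads evenly
    order = list(rng.permutation(eligible))
    while len(novel) < n_novel:
        for g in order:
            if len(novel) >= n_novel:
                break
            remaining = [i for i in genus_members[g] if i not in novel]
            if len(remaining) > 1:
                novel.add(int(rng.choice(remaining)))

    species_paths = [
        _species_path(genus_of[i], i - genus_of[i] * species_per_genus)
        for i in range(n_species)
    ]

    # profile: novel species collapse to their genus path; coverages of
    # entries collapsing to the same node are summed
    entry_order: List[TaxonomyPath] = []
    entry_cov: Dict[TaxonomyPath, float] = {}
    novelty_map: Dict[str, str] = {}
    for i in range(n_species):
        if i in novel:
            path = species_paths[i].truncate(6)
            novelty_map[str(species_paths[i])] = str(path)
        else:
            path = species_paths[i]
        if path not in entry_cov:
            entry_cov[path] = 0.0
            entry_order.append(path)
        entry_cov[path] += coverages[i]
    sample_id = f"sim_seed{seed}"
    profile = CondensedProfile(
        sample_id,
        tuple(ProfileEntry(p, entry_cov[p]) for p in entry_order),
    )

    # genome records for non-novel species; completeness in {1, 1/2, 1/4}
    # and zero contamination keep size / completeness exactly the true size
    completeness_choices = np.array([1.0, 0.5, 0.25])
    records = []
    for i in range(n_species):
        if i in novel:
            continue
        comp = float(rng.choice(completeness_choices))
        records.append(
            GenomeRecord(
                accession=f"SYN{i + 1:04d}",
                taxonomy=species_paths[i],
                genome_size=int(true_sizes[i] * comp),
                completeness=comp,
                contamination=0.0,
            )
        )

    microbial = math.fsum(
        coverages[i] * true_sizes[i] for i in range(n_species)
    )
    metagenome_bases = int(round(microbial / (1.0 - spike_fraction)))
    # same operation order as the estimator so self-consistency is exact
    true_fraction = microbial / metagenome_bases * 100.0
    truth = SyntheticTruth(
        species=tuple(
            (species_paths[i], true_sizes[i], float(abundances[i]))
            for i in range(n_species)
        ),
        s=s,
        nonmicrobial_bases=metagenome_bases - microbial,
        metagenome_bases=metagenome_bases,
        microbial_bases=microbial,
        true_fraction=true_fraction,
        novelty_map=novelty_map,
    )
    size = MetagenomeSize(sample_id=sample_id, bases=metagenome_bases, source="table")
    return profile, records, size, truth


def recovery_error(
    n_reps: int,
    novelty_fraction: float,
    size_noise_cv: float,
    seed: int = 0,
    n_species: int = 10,
    spike_fraction: float = 0.25,
) -> float:
    """Mean absolute error (percentage points) of the estimator vs truth.

    Each replicate simulates a community, builds the taxon-length table
    from the non-withheld records, runs the estimator, and compares the
    reported fraction with the designed one.  With ``size_noise_cv`` 0
    congeners share the withheld species' exact size, so genus-mean
    imputation is perfect and the error is zero; positive noise makes the
    imputed sizes scatter and the error grow.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if size_noise_cv < 0:
        raise ValueError(f"size_noise_cv must be >= 0, got {size_noise_cv}")
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_reps):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        profile, records, size, truth = simulate_community(
            n_species=n_species,
            abundance_model="lognormal",
            novelty_fraction=novelty_fraction,
            spike_fraction=spike_fraction,
            seed=sub_seed,
            within_genus_size_cv=size_noise_cv,
        )
        table = build_taxon_length_table(records)
        result = compute_spf(profile, table, size.bases)
        errors.append(abs(result.reported_fraction - truth.true_fraction))
    return math.fsum(errors) / len(errors)
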