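"""Prokaryotic-fraction arithmetic, the cap, and the perturbation warning."""

import math

import numpy as np
import pytest

from prokfrac import (
    CondensedProfile,
    ProfileEntry,
    TaxonLengthTable,
    average_genome_size,
    compute_spf,
    microbial_bases,
    novelty_warning,
    parse_taxonomy,
)


def _species_path(i):
    return parse_taxonomy(
        f"Root; d__Bacteria; p__P{i}; c__C{i}; o__O{i}; f__F{i}; g__G{i}; "
        f"s__G{i} sp{i}"
    )


def _table_for(entries_sizes):
    """Table mapping each path (and nothing else) to a fixed size."""
    sizes = {path: size for path, size in entries_sizes}
    return TaxonLengthTable(sizes=sizes, root_size=4_000_000.0)


def _profile(pairs, sample="S1"):
    return CondensedProfile(
        sample, tuple(ProfileEntry(path, cov) for path, cov in pairs)
    )


def test_microbial_bases_single_species():
    path = _species_path(1)
    profile = _profile([(path, 10.0)])
    table = _table_for([(path, 4_000_000.0)])
    assert microbial_bases(profile, table) == 40_000_000.0


def test_microbial_bases_empty_profile_is_zero():
    assert microbial_bases(_profile([]), _table_for([])) == 0.0


def test_microbial_bases_matches_resummation_oracle():
    rng = np.random.default_rng(11)
    paths = [_species_path(i) for i in range(20)]
    covs = rng.uniform(0, 50, size=20)
    sizes = rng.uniform(1e6, 8e6, size=20)
    profile = _profile(list(zip(paths, covs)))
    table = _table_for(list(zip(paths, sizes)))
    oracle = sum(float(c) * float(s) for c, s in zip(covs, sizes))
    assert microbial_bases(profile, table) == pytest.approx(oracle, rel=1e-12)


def test_compute_spf_half_and_cap():
    path = _species_path(1)
    profile = _profile([(path, 10.0)])
    table = _table_for([(path, 4_000_000.0)])
    half = compute_spf(profile, table, 80_000_000)
    assert half.raw_fraction == 50.0
    assert half.reported_fraction == 50.0
    capped = compute_spf(profile, table, 20_000_000)
    assert capped.raw_fraction == 200.0
    assert capped.reported_fraction == 100.0


def test_compute_spf_rejects_nonpositive_metagenome():
    path = _species_path(1)
    profile = _profile([(path, 1.0)])
    table = _table_for([(path, 4e6)])
    with pytest.raises(ValueError):
        compute_spf(profile, table, 0)


@pytest.mark.parametrize(
    "pairs, expected",
    [
        ([(1.0, 2_000_000.0), (1.0, 4_000_000.0)], 3_000_000.0),
        ([(1.0, 2_000_000.0), (3.0, 4_000_000.0)], 3_500_000.0),
        ([(7.3, 5_000_000.0)], 5_000_000.0),
    ],
)
def test_average_genome_size(pairs, expected):
    paths = [_species_path(i) for i in range(len(pairs))]
    profile = _profile([(p, c) for p, (c, _) in zip(paths, pairs)])
    table = _table_for([(p, s) for p, (_, s) in zip(paths, pairs)])
    assert average_genome_size(profile, table) == pytest.approx(expected)


def test_average_genome_size_undefined_cases():
    with pytest.raises(ValueError):
        average_genome_size(_profile([]), _table_for([]))
    path = _species_path(1)
    with pytest.raises(ValueError):
        average_genome_size(
            _profile([(path, 0.0)]), _table_for([(path, 4e6)])
        )


def test_linearity_of_raw_fraction_in_coverage():
    """Scaling every coverage by k scales the raw fraction by exactly k."""
    paths = [_species_path(i) for i in range(5)]
    sizes = [2e6, 3e6, 4e6, 5e6, 6e6]
    table = _table_for(list(zip(paths, sizes)))
    base = compute_spf(
        _profile([(p, 1.0) for p in paths]), table, 1_000_000_000
    )
    for k in (0.5, 2.0, 4.0):
        scaled = compute_spf(
            _profile([(p, k) for p in paths]), table, 1_000_000_000
        )
        assert scaled.raw_fraction == pytest.approx(k * base.raw_fraction, rel=1e-12)


def test_average_genome_size_scale_invariant_and_bounded():
    paths = [_species_path(i) for i in range(4)]
    sizes = [2e6, 3e6, 5e6, 8e6]
    covs = [0.5, 2.0, 1.0, 0.25]
    table = _table_for(list(zip(paths, sizes)))
    ags = average_genome_size(_profile(list(zip(paths, covs))), table)
    scaled = average_genome_size(
        _profile([(p, 7.0 * c) for p, c in zip(paths, covs)]), table
    )
    assert scaled == pytest.approx(ags, rel=1e-12)
    assert min(sizes) <= ags <= max(sizes)


def test_self_consistent_fixture_recovers_designed_fraction():
    paths = [_species_path(i) for i in range(8)]
    rng = np.random.default_rng(2)
    sizes = rng.uniform(2e6, 8e6, size=8)
    covs = rng.lognormal(0, 1, size=8)
    table = _table_for(list(zip(paths, sizes)))
    profile = _profile(list(zip(paths, covs)))
    bases = microbial_bases(profile, table)
    for f in (0.1, 0.5, 0.75, 1.0):
        result = compute_spf(profile, table, bases / f)
        assert result.reported_fraction == pytest.approx(100 * f, rel=1e-6)


def test_no_warning_when_profile_is_fully_species_level():
    paths = [_species_path(i) for i in range(3)]
    table = _table_for([(p, 4e6) for p in paths])
    warn, detail = novelty_warning(
        _profile([(p, 1.0) for p in paths]), table, 100_000_000
    )
    assert warn is False
    assert detail == ()


def test_single_dominant_genus_triggers_warning():
    genus = _species_path(1).truncate(6)
    table = TaxonLengthTable(sizes={genus: 4_000_000.0}, root_size=4e6)
    profile = _profile([(genus, 10.0)])
    # raw fraction 50%; doubling the genus size gives 100% (delta 50)
    warn, detail = novelty_warning(profile, table, 80_000_000)
    assert warn is True
    assert detail[0].delta_doubled == pytest.approx(50.0)
    assert detail[0].delta_halved == pytest.approx(-25.0)


def test_complex_community_with_minor_unresolved_entry_does_not_warn():
    species = [_species_path(i) for i in range(100)]
    genus = _species_path(999).truncate(6)
    sizes = [(p, 4_000_000.0) for p in species] + [(genus, 4_000_000.0)]
    table = _table_for(sizes)
    # 100 species each contributing 0.9% raw, one genus entry at 1.0% raw
    cov_for_percent = lambda pct, mg: pct / 100 * mg / 4_000_000.0
    mg = 1_000_000_000
    profile = _profile(
        [(p, cov_for_percent(0.9, mg)) for p in species]
        + [(genus, cov_for_percent(1.0, mg))]
    )
    warn, detail = novelty_warning(profile, table, mg)
    assert warn is False
    assert len(detail) == 1  # only the genus entry is a candidate
    assert detail[0].delta_doubled == pytest.approx(1.0)


def test_root_level_entries_are_warning_candidates():
    root = parse_taxonomy("Root")
    table = TaxonLengthTable(sizes={}, root_size=4_000_000.0)
    profile = _profile([(root, 10.0)])
    warn, detail = novelty_warning(profile, table, 80_000_000)
    assert warn is True
    assert detail[0].taxonomy == "Root"


def test_warning_probes_at_most_three_candidates_by_abundance():
    genera = [_species_path(i).truncate(6) for i in range(5)]
    table = _table_for([(g, 4e6) for g in genera])
    profile = _profile([(g, float(10 - i)) for i, g in enumerate(genera)])
    _, detail = novelty_warning(profile, table, 1_000_000_000)
    assert len(detail) == 3
    assert [d.coverage for d in detail] == [10.0, 9.0, 8.0]


def test_added_species_coverage_never_creates_a_warning():
    """With candidates fixed and the denominator growing in proportion,
    extra species-level coverage cannot flip a false warning to true."""
    genus = _species_path(1).truncate(6)
    species = _species_path(2)
    table = _table_for([(genus, 4e6), (species, 4e6)])
    mg = 10_000_000_000
    base_profile = _profile([(genus, 1.0)])
    warn_before, _ = novelty_warning(base_profile, table, mg)
    assert warn_before is False
    grown = _profile([(genus, 1.0), (species, 100.0)])
    warn_after, _ = novelty_warning(grown, table, mg * 2)
    assert warn_after is False
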