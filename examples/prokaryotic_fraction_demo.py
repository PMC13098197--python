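"""Estimate the prokaryotic fraction of a small hand-built community.

Builds a three-taxon community profile (two species plus one lineage only
resolved to genus rank), a genome-length table from four reference
genomes, and computes the prokaryotic fraction of a 100 Mbp metagenome.
"""

from prokfrac import (
    CondensedProfile,
    GenomeRecord,
    ProfileEntry,
    build_taxon_length_table,
    compute_spf,
    parse_taxonomy,
)

LINEAGE = "Root; d__Bacteria; p__Bacillota; c__Bacilli; o__Lactobacillales; f__Lactobacillaceae; g__Lactobacillus"

# four reference genomes; the second is 95% complete and 5% contaminated,
# so its observed 3.8 Mbp is corrected to 4.2 Mbp
records = [
    GenomeRecord("G001", parse_taxonomy(f"{LINEAGE}; s__Lactobacillus sp001"),
                 2_000_000, 1.0, 0.0),
    GenomeRecord("G002", parse_taxonomy(f"{LINEAGE}; s__Lactobacillus sp002"),
                 3_800_000, 0.95, 0.05),
    GenomeRecord("G003", parse_taxonomy(
        "Root; d__Bacteria; p__Bacteroidota; c__Bacteroidia; o__Bacteroidales; "
        "f__Bacteroidaceae; g__Bacteroides; s__Bacteroides sp003"),
        5_000_000, 1.0, 0.0),
    GenomeRecord("G004", parse_taxonomy(
        "Root; d__Archaea; p__Methanobacteriota; c__Methanobacteria; "
        "o__Methanobacteriales; f__Methanobacteriaceae; g__Methanobrevibacter; "
        "s__Methanobrevibacter sp004"),
        1_800_000, 0.9, 0.0),
]
table = build_taxon_length_table(records)

# coverage at the genus node means reads classified to Lactobacillus but
# to no species within it; its size is the genus mean (3.1 Mbp here)
profile = CondensedProfile("demo", (
    ProfileEntry(parse_taxonomy(f"{LINEAGE}; s__Lactobacillus sp001"), 5.0),
    ProfileEntry(records[2].taxonomy, 8.0),
    ProfileEntry(parse_taxonomy(LINEAGE), 2.0),
))

result = compute_spf(profile, table, metagenome_bases_count=100_000_000)

print(f"microbial bases        : {result.microbial_bases:,.0f} bp")
print(f"metagenome bases       : {result.metagenome_bases:,.0f} bp")
print(f"prokaryotic fraction   : {result.reported_fraction:.2f} %")
print(f"average genome size    : {result.average_genome_size:,.0f} bp")
print(f"warning                : {result.warning}")
for d in result.warning_detail:
    print(f"  probe {d.taxonomy}: x2 -> {d.delta_doubled:+.2f} pp, "
          f"x0.5 -> {d.delta_halved:+.2f} pp")
print()
print("The fraction is the coverage-weighted microbial base count over the")
print("metagenome size; the probes show how far the estimate would move if a")
print("rank-unresolved lineage's genome size were doubled or halved.")
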