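"""Derived metrics: domain-adjusted mapping rate and cell ratios.

DAMR asks: of the *microbial* portion of a metagenome, how much does a
genome catalog capture?  The cell-ratio conversion turns a microbial read
share into relative fungal/bacterial cell counts under a fixed average
fungal genome size.
"""

from prokfrac import damr, fungal_cell_ratio, microbial_cell_ratio

# 45% of reads map to the MAG catalog, but only 50% of the metagenome is
# microbial: the catalog captures 90% of what it could
print(f"DAMR(mapped=45%, fraction=50%) = {damr(45, 50):.1f} %")
# estimate above the fraction estimate: rounded down to 100%
print(f"DAMR(mapped=60%, fraction=50%) = {damr(60, 50):.1f} %")
print()

# a soil-like community: 69% of reads microbial, 4 Mbp average microbial
# genomes, 37.5 Mbp average fungal genomes
spf, gm = 0.69, 4_000_000
cf_cm = fungal_cell_ratio(spf, gm)
cm_cf = microbial_cell_ratio(spf, gm)
print(f"fungal:microbial cells at 69% microbial reads = {cf_cm:.4f}")
print(f"microbial:fungal cells                        = {cm_cf:.2f}")
print()
print("Because fungal genomes are ~10x larger, a 31% fungal read share")
print("corresponds to only ~1 fungal cell per ~21 microbial cells.")
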