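# Methods

## The estimator

For a sample with community-profile entries (taxonomy *i*, coverage
*c<sub>i</sub>*) and a stated metagenome size *B* (bases), the package
computes

* microbial bases  m = Σ<sub>i</sub> c<sub>i</sub> · g(taxonomy<sub>i</sub>)
* raw fraction  = m / B × 100
* reported fraction = min(raw, 100)

Coverage here is *fold coverage*: the mean number of reads overlapping
each genomic position, as estimated upstream by a marker-gene profiler.
The coverage stored at a non-species node is the coverage of reads
classified to that node and no deeper — it is not cumulative over
descendants — so the sum runs over all entries at all ranks.

Assumptions: coverage estimates are unbiased per lineage; one genome
size per species is representative; sequencing effort is uniform across
community members (the same Lander–Waterman constant cancels).  Raw
fractions above 100% occur in practice when genome sizes are
overestimated or the stated metagenome size undercounts the data; the
reported value is capped because larger fractions are impossible, while
the raw value remains available (`SPFResult.raw_fraction`,
`--emit-raw`) since it is the honest quantity for benchmarking.

## Genome sizes

A recovered genome's observed length is corrected for bin quality:

    adjusted = genome_size / completeness × (1 + contamination)

with completeness ∈ (0, 1] and contamination ≥ 0 as decimal fractions
(inputs above 1 in metadata files are interpreted as percentages and
rescaled, with a warning; contamination above 1.0 is accepted but
warned about, since pathological bins can exceed 100% duplication).

Sizes propagate up the seven-rank taxonomy by **unweighted** means of
the rank immediately below: species → mean of its records' adjusted
sizes, genus → mean of species sizes, then family, order, class, phylum,
domain, each the mean of the sizes one rank down.  Unweighted means keep
a species-rich genus from dominating its family's estimate.  The root
fallback (coverage left entirely unclassified) continues the same
recursion one step further, the mean of domain sizes.  Lookups of taxa
absent from the table are hard errors rather than silent parent
fallbacks, so profile/table version mismatches surface loudly.

If several records share a species (e.g. a user-supplemented MAG set),
their adjusted sizes are averaged; with one representative genome per
species this reduces to using that genome's adjusted size.

## Average genome size and the reliability warning

The average microbial genome size is the coverage-weighted mean
Σ g<sub>i</sub>c<sub>i</sub> / Σ c<sub>i</sub> over all entries.  It is
scale-invariant in coverage and bounded by the smallest and largest
per-taxon sizes.

Simple communities dominated by lineages without species-level
references are the estimator's known weak spot: one uncertain genome
size can move the result a lot.  The warning rule probes the three most
abundant entries whose deepest rank is above species (root-level entries
included; ties broken by taxonomy string).  Each probe doubles, then
halves, that lineage's size — one lineage at a time, others fixed — and
recomputes the **raw** fraction.  If any probe shifts it by more than
2 percentage points, the warning fires.  The raw (uncapped) fraction is
used deliberately: a capped value near 100% would mask the perturbation
entirely.  Absolute percentage points, not relative change, define the
threshold, since the quantity itself is a percentage.

## Derived metrics

* **DAMR** = min(mapped% / fraction% × 100, 100).  Inputs are
  percentages in [0, 100]; a zero fraction leaves the metric undefined
  and is rejected.  Values above 100 indicate artifacts in mapping or in
  the fraction estimate and are rounded down.
* **Cell ratios.**  With read counts r<sub>m</sub> =
  c<sub>m</sub>g<sub>m</sub>s and r<sub>f</sub> =
  c<sub>f</sub>g<sub>f</sub>s and SPF = r<sub>m</sub>/(r<sub>m</sub>+r<sub>f</sub>),
  eliminating the depth factor s gives c<sub>f</sub>/c<sub>m</sub> =
  (1 − SPF)·g<sub>m</sub>/(SPF·g<sub>f</sub>); the reciprocal is
  exposed separately so neither direction need be inferred.  The
  conversion assumes a two-kingdom community, equal lysis efficiency and
  equal genome copies per cell; the average fungal genome size defaults
  to 37.5 Mbp (an Ascomycota-wide mean of per-genus median sizes) and
  every one of these assumptions is an overridable parameter.

## Metagenome sizes

The denominator can be supplied per sample (TSV, in bases or decimal
megabases — 10⁶, the SRA convention, not 2²⁰) or counted from
FASTA/FASTQ files, gzipped or plain, format auto-detected from content.
Files are counted verbatim: no quality filtering, quality lines never
counted, N characters counted as bases.

## The synthetic-community generator

`simulate_community` builds the estimator's inputs directly — profile,
genome records, stated metagenome size — mutually consistent with a
designed fraction, replacing read-level simulation (the package consumes
profiles, not reads, so simulating reads would only test the upstream
profiler).  Design choices:

* **Abundances**: lognormal(0, 1) by default, echoing long-tailed
  marine-style community compositions; `uniform` (equal abundances)
  retained as the worst-case simple community.  Coverage = abundance ×
  s, with the depth factor s defaulting to 1.
* **Genome sizes**: one base size per genus, uniform in 2–8 Mbp (the
  typical prokaryotic range), shared by congeners up to a lognormal
  factor with coefficient of variation `within_genus_size_cv`
  (default 0).  Sizes are rounded to multiples of 4 bp and record
  completeness is drawn from {1, ½, ¼} with zero contamination, so the
  quality-adjusted sizes equal the true sizes *exactly* in floating
  point — self-consistency tests can then assert exact recovery rather
  than approximate.
* **Novelty**: a `novelty_fraction` share of species have their profile
  entry truncated to genus rank and their genome record withheld, which
  is precisely the mechanism by which real novel lineages force the
  estimator onto rank-mean sizes.  At least one congener must remain
  per genus (default two species per genus), otherwise the genus size
  would be unobtainable and a `ValueError` is raised.
* **Spike**: the stated metagenome size is microbial bases /
  (1 − spike_fraction), so the designed fraction is 100 × (1 − spike).
  The ground-truth fraction is computed with the same operation order
  as the estimator, making the zero-noise recovery error exactly 0.

`recovery_error` averages |reported − designed| over seeded replicates
(default 10 species, spike 0.25 — a non-degenerate fraction of 75% kept
safely below the cap so capping never masks errors).

What the generator does **not** emulate: read-level noise, coverage
estimation error from the upstream profiler, taxonomic
misclassification, and real inter-strain genome-size variance (the
mapping from `within_genus_size_cv` to real variance is a free
parameter).  Passing tests therefore demonstrate correctness of the
arithmetic, the size model and the novelty mechanism, not field accuracy
of upstream coverage estimates.

## Numerical choices

* All sums use `math.fsum` (exactly rounded), so results are independent
  of entry order and self-consistency fixtures recover designed
  fractions exactly.
* Fractions are computed and held in double precision; rounding to two
  decimals happens only at serialization.  Coverage is likewise written
  at two decimals while full precision is retained in memory; the
  taxon-length table is written at full float precision so a round trip
  preserves every lookup bit-for-bit.
* Duplicate (sample, taxonomy) rows in profiles are errors, not summed —
  silent aggregation hides upstream bugs.
* Warning candidate ties are broken lexicographically by taxonomy string
  for determinism.
* Problem sizes in the test suite (≤ 100 species per tree, 100
  replicates per sweep) keep each oracle comparison well-conditioned
  and the whole suite in a few seconds.

## Known limitations

* The estimate inherits any bias of the upstream coverage estimates; the
  package cannot detect coverage that is systematically wrong.
* Root-level coverage is included in the microbial sum using the
  domain-mean fallback size; whether fully unclassified reads are truly
  prokaryotic is unknowable from the profile alone.
* The cell-ratio conversion is only as good as its two-kingdom and
  equal-lysis assumptions; in communities with abundant non-fungal
  eukaryotes it overstates fungal cells.
* No converters from other profilers' formats are included; any profile
  that provides lineage-wise fold coverage can be reformatted to the
  condensed TSV by the user.
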