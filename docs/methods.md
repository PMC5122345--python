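# Methods

## Coordinate conventions

All intervals are 0-based half-open (the BED convention). GTF input
(1-based closed) is converted at the parser boundary; nothing else in
the package ever sees 1-based coordinates. Chromosome names are
compared as exact strings — no "chr" prefix normalization — because
silent aliasing produces miscounts that are hard to detect downstream.

The center of a peak [start, end) is `floor((start + end − 1) / 2)`,
the midpoint base of the closed base span; for even-width peaks this
rounds down, a deterministic choice matching integer division. When a
narrowPeak summit is recorded, every distance-based operation accepts a
`summit` mode that uses `start + summit_offset` instead.

## Peak annotation

**Features.** Each gene contributes a promoter (strand-aware window
TSS −2000/+500 bp by default; the window is a configuration knob
because published category percentages depend directly on it), 5'/3'
UTRs (exonic sequence outside the coding bounds, strand-aware), coding
exon remainder, and introns (gaps between consecutive exons).
Overlapping genes contribute features independently. An enhancer
category exists only when the user supplies enhancer intervals; the
package refuses to invent an enhancer definition.

**Classification.** A peak is assigned the highest-priority category
whose interval contains its center (promoter > enhancer > 5'UTR >
3'UTR > exon > intron, else intergenic). Center-based containment —
rather than any-overlap — forces the single-category partition that a
percentage distribution requires, and matches the center-to-center
convention of the co-localization stage. The indexed implementation
(one interval tree per category per chromosome) is checked against a
brute-force containment oracle in the test suite.

**Nearest gene.** Distance is |peak center − TSS|; the TSS is the
biologically standard anchor, and ties break to the lexicographically
smallest gene_id so results are deterministic. The reported distance is
signed, positive downstream of the TSS in the gene's orientation.
Peaks on gene-free chromosomes get no assignment but are still
classified (intergenic).

**Position profiles.** For each offset in [−half_window, +half_window]
at a constant step, the profile counts (gene, peak) pairs where the
peak interval covers the position TSS (or TES) + offset in the gene's
orientation, pooled across genes; a per-gene variant would weight all
genes equally regardless of peak density and is not what a pooled
metagene figure shows. Counts are rescaled so the maximum position
reads 100; an all-zero profile stays zero rather than dividing by zero.

## Co-localization density (HMd)

Each query peak is assigned to its **single nearest anchor** center on
the same chromosome (queries on anchor-free chromosomes get distance ∞
and are never binned). Counting each query once — rather than once per
anchor within range — keeps Y bounded by the number of queries and
makes the mass-conservation identity

    Σ_i HMd_i · ΔX_i(kb) · M / 100 = Y_last

exact, which the suite fuzz-tests to 1e-9 relative error. The
alternative (per-anchor multiplicity) is deliberately not implemented;
nearest-assignment is the documented semantics.

Y and X are cumulative with an implicit (X_0, Y_0) = (0, 0); the
density differencing then yields per-annulus values. X is converted
bp → kb inside `hmd_density` so the stated unit — query peaks per 100
anchor peaks per kb — is honored literally: X = (50, 100) bp,
Y = (2, 5), M = 10 gives HMd = (400, 600).

## Cohort statistics

The qPCR standard curve is an ordinary least-squares fit of Ct on
log10(quantity) over ≥3 serial dilutions; quantification inverts it as
`10^((Ct − intercept)/slope)`. Expression is GOI quantity divided by
GAPDH quantity.

Dichotomization splits at the sample median (upper two quartiles =
high): strictly above the median → high, ties at the median → low, so
distinct values at even n split n/2 : n/2. Published cohorts sometimes
report unequal high/low splits produced by opaque software cutoffs; an
explicit numeric cutoff parameter reproduces those without guessing the
rule.

Categorical covariates use the Pearson χ² on the 2×2 table without
continuity correction by default (a Yates flag exists); a zero margin
raises rather than returning an undefined statistic. Continuous
covariates use the two-sided Mann–Whitney U: exact null enumeration
when both groups have ≤8 patients, the tie-corrected normal
approximation otherwise. The boundary (8) is where the exact and
asymptotic branches agree to well under the decision threshold on
typical data, which the suite checks directly.

## Synthetic data

The generators are pure functions of a `SimulationConfig` including its
seed; the four generators draw from independently spawned RNG streams
of the one seed, so e.g. changing the cohort size never perturbs the
genome.

**Genome.** Genes are placed uniformly without overlap on toy
chromosomes (`chrS1` …, 10 Mb by default — toy names prevent
conflation with real assemblies), 5–20 kb long, 1–8 exons, random
strand, 80% coding. A minimum inter-gene gap of 3 kb (≥ the promoter
window) keeps one gene's promoter clear of its neighbour's body, which
is what makes planted feature categories exactly recoverable.

**Feature-weighted peaks.** Each peak's category is drawn from the
configured weights (defaults: intergenic 0.55, intron 0.25, exon 0.09,
promoter 0.06, 3'UTR 0.03, 5'UTR 0.02 — the "majority intergenic, ~6%
promoter" shape of genome-wide binding data), its center placed
uniformly inside a random interval of that category. Pools for
lower-priority categories exclude promoter windows, and the intergenic
pool is the complement of gene bodies and promoters, so classification
recovers the planted label for every peak.

**Co-localized queries.** A query is uniform background with the
configured probability (default 0.2), otherwise a uniformly chosen
anchor center plus a two-sided exponential (Laplace) offset, scale
300 bp by default. The Laplace kernel was chosen because its |offset|
is exponential — median = scale·ln 2 — making the expected HMd curve
analytically checkable.

**Cohort.** GOI expression is log-normal (σ = 0.5 in log10) with a
planted mean shift of `effect_size`·σ in the phenotype-positive half of
the cohort; GAPDH is phenotype-independent (σ = 0.05). Ct values are
back-computed through a known 100%-efficiency curve
(Ct = −3.32·log10(q) + 40) so the benchmarks exercise quantification →
normalization → dichotomization → testing end to end.

## Benchmark study conditions

The property benchmarks run at sizes chosen so each effect is resolved
well above its sampling noise:

- *Oracle equivalence*: 100 random genomes, ≤50 genes and ≤200 peaks
  each, indexed paths vs exhaustive scans.
- *Null flatness*: 200 anchors and 5000 queries drawn independently and
  uniformly on 10 Mb; the regression of HMd on bin midpoint should be
  non-significant (α = 0.01) in ≥18 of 20 seeds.
- *Planted decay*: 2000 anchors on 10 Mb, 20 000 queries (Laplace
  300 bp, 20% background). The anchor density matters here: the
  background's nearest-anchor distances are exponential with rate
  2M/L, so with only 200 anchors the outer 1-kb annuli differ by well
  under one SD of their Poisson noise and strict monotonicity of HMd
  would be a coin flip; at 2000 anchors the adjacent-bin gap is ≈5 SD
  and the non-increasing shape is a well-posed property (expected in
  ≥19 of 20 seeds, with first-bin HMd >10× the last).
- *Feature recovery*: 5000 peaks, recovery within ±2 percentage points
  per category (≈3 SD of the binomial noise at p = 0.55).
- *Cohort calibration*: 1000 null cohorts of n = 60 (rejection rate in
  [0.035, 0.065] at α = 0.05) and 1000 shifted cohorts (power > 0.9 at
  a 1-SD shift).

## What the synthetic benchmarks do and do not show

They establish that the implementation is correct and calibrated: the
indexed data structures agree with brute force, the density statistic
conserves mass and recovers a planted kernel, and the tests reject at
their nominal rate under the null. They do not emulate real genomes:
no overlapping or nested genes, no alternative transcripts, no
chromatin-accessibility structure in peak placement, no qPCR efficiency
drift or technical replicates, and peak widths independent of signal.
Percentages and densities from real data will differ accordingly;
conclusions about any specific dataset require that dataset.

## Known limitations

- One transcript per gene: the gene model has a single exon chain and
  single coding region.
- The enhancer category is purely user-supplied intervals.
- No significance testing of co-localization (the density curve is
  descriptive), and no survival machinery — remission duration is
  treated as a binary covariate.
- The nearest-anchor multiplicity choice means HMd values are not
  comparable with pipelines that count a query once per anchor in
  range.
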