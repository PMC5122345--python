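# chipcoloc

Downstream analysis of ChIP-seq peak calls for regulatory-genomics
studies of histone-mark scaffolding — typified by asking where a
chromatin factor such as WDR5 binds relative to genes, and how tightly
its binding sites co-localize with the active-promoter mark H3K4me3.
The package consumes called peaks (BED / narrowPeak) and gene models
(BED12 / minimal GTF); it does not align reads or call peaks.

It provides four analysis stages plus a synthetic-data generator, so
every stage is testable end to end without external downloads:

1. **Peak annotation** — assign each peak to its nearest gene by
   |peak center − TSS|, and classify it into exactly one regulatory
   category (promoter, 5'UTR, 3'UTR, exon, intron, intergenic, and
   optionally enhancer when an enhancer BED is supplied) by the
   feature containing the peak center, with a fixed priority order.
2. **Distributions and metagene profiles** — per-category peak
   percentages, and percent-of-max counts of peaks covering each
   position around the TSS or TES, pooled over genes, strand-oriented.
3. **Co-localization density (HMd)** — map a query peak set onto an
   anchor peak set at center-to-center distances, count queries
   cumulatively within the threshold ladder
   X = 50, 100, 200, 500 bp, 1, 2, 3, 4, 5 kb, and compute the
   per-annulus density

   ```
   HMd_i = (Y_i − Y_{i−1}) · 100 / ((X_i − X_{i−1})_kb · M)
   ```

   where Y_i is the cumulative query count within X_i, M the number of
   anchor peaks, and (X_0, Y_0) = (0, 0) — query peaks per 100 anchor
   peaks per kb. The identity Σ_i HMd_i · ΔX_i(kb) · M / 100 = Y_last
   holds exactly.
4. **Cohort statistics** — qPCR standard-curve quantification
   (Ct = slope·log10(q) + intercept), GOI/GAPDH normalization,
   high/low dichotomization at the sample median (upper vs lower
   quartile pair, or an explicit cutoff), Pearson χ² for categorical
   covariates and the two-sided Mann–Whitney U for continuous ones.

## Worked example

```python
import chipcoloc as cc

cfg = cc.SimulationConfig(seed=42, n_genes=50, n_query_peaks=5000)
genes = cc.simulate_genome(cfg)
peaks = cc.simulate_peaks_by_feature(genes, cfg)

dist = cc.feature_distribution(peaks, genes)
for cat, pct in dist.percentages.items():
    print(f"{cat:<11} {dist.counts[cat]:>5} {pct:6.2f}%")
```

```
promoter      297   5.94%
5utr           93   1.86%
3utr          148   2.96%
exon          411   8.22%
intron       1245  24.90%
intergenic   2806  56.12%
```

The generator planted the peaks with weights 0.06 promoter / 0.55
intergenic / ..., and classification recovers those percentages to
within sampling noise — the same "majority intergenic, ~6% promoter"
shape seen in genome-wide binding profiles.

```python
anchors = [p for p in peaks if p.name.startswith("promoter")]
qcfg = cc.SimulationConfig(seed=43, n_query_peaks=10_000,
                           decay_scale=300.0, background_fraction=0.2)
queries = cc.simulate_colocalized(anchors, qcfg)
prof = cc.colocalization_profile(anchors, queries)
for x, y, inc, h in zip(prof.X, prof.Y, prof.increments, prof.hmd):
    print(f"{x:>5} {y:>6} {inc:>5} {h:9.1f}")
```

```
   50   2484  2484   16727.3
  100   4053  1569   10565.7
  200   6004  1951    6569.0
  500   7526  1522    1708.2
 1000   7913   387     260.6
 2000   8019   106      35.7
 3000   8036    17       5.7
 4000   8060    24       8.1
 5000   8081    21       7.1
```

Columns are the distance threshold (bp), cumulative query count,
per-annulus increment, and HMd. The density collapses by three orders
of magnitude from the first annulus to the outermost — the signature of
genuine co-localization (here, planted with a 300 bp Laplace kernel
over a 20% uniform background).

## Command line

Each analysis is also a subcommand of `chipcoloc`:

```sh
chipcoloc simulate peaks --seed 5 --out-dir sim/
chipcoloc annotate   --peaks sim/peaks.bed --genes sim/genome.bed12
chipcoloc distribution --peaks sim/peaks.bed --genes sim/genome.bed12
chipcoloc profile    --peaks sim/peaks.bed --genes sim/genome.bed12 --anchor tss --window 5000 --step 50
chipcoloc coloc      --anchors wdr5.bed --queries h3k4me3.bed --plot hmd.png
chipcoloc cohort     --table cohort.tsv --cutoff median
```

## Documentation

`docs/methods.md` describes the models, parameter defaults, numerical
conventions, and the limits of what the synthetic benchmarks show.
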