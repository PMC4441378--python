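# nicheevo

Tools for asking how climatic niches evolve across a complex of closely
related lineages: do sister clades occupy interchangeable environments
(niche conservatism), or has cladogenesis been accompanied by shifts into
distinct climatic space (niche divergence)?

The package implements, as a reusable and tested pipeline, the workflow
used to study the six mitochondrial clades of a Mediterranean gecko
species complex from satellite-derived environmental layers:

1. **Bioclim-style predictors** (`nicheevo.biovars`). Five monthly
   variable stacks — Middle Infra-Red (MIR), daytime and night-time land
   surface temperature (DTLST/NTLST), NDVI and EVI; 60 layers in all —
   are condensed into 30 temporal summaries (X1–X30): annual mean (BIO1),
   seasonality (BIO4 = SD of the monthly values × 100), extreme months
   (BIO5/BIO6), annual range (BIO7) and warmest/coldest consecutive
   quarter means (BIO10/BIO11), plus mean diurnal range (BIO2) and
   isothermality (BIO3) for the day/night temperature pair.
2. **Environmental ordination** (`nicheevo.env_space`). Correlation-matrix
   PCA with Kaiser retention (eigenvalue > 1), plus great-circle
   background buffers (default 100 km) delimiting the environment
   available to each clade.
3. **Envelope SDMs** (`nicheevo.envelope`). Bioclim boxcar envelopes on
   the retained PC scores: suitability is the per-axis percentile score
   s = 1 − 2|F(x) − 0.5|, aggregated by the minimum across axes, zero
   outside the training box.
4. **Realized-niche overlap** (`nicheevo.overlap`). Occupancy-corrected
   kernel density grids (r × r = 100 × 100 by default) on the first two
   PCs of the pooled-background ordination; Schoener's
   D = 1 − ½ Σ|z₁ − z₂|; niche equivalency (pool-and-resplit) and
   background similarity (random draws from the other clade's
   background) randomization tests with two-sided add-one p-values.
5. **Ancestral climatic tolerances** (`nicheevo.ancestral`). Predicted
   niche occupancy (PNO) profiles — suitability mass binned into 100
   categories per PC — sampled 1000 times and reconstructed on a
   calibrated ultrametric tree under Brownian motion by generalized
   least squares, giving per-node tolerance means with 80% central
   density intervals.

A synthetic-data module (`nicheevo.synthetic`) generates the full study
system — spatially autocorrelated seasonal rasters, clade occurrences
with controllable niche structure (identical / nested / disjoint), and
the six-clade reference tree with divergence times 5.88, 4.82, 4.32,
4.14 and 2.47 Ma — so the entire pipeline runs and is testable without
any satellite downloads.

## Worked example

```python
import nicheevo as ne
from nicheevo import pipeline, synthetic

stacks = ne.generate_monthly_stacks(extent=(-5, 7.5, 33, 45.5), resolution=0.25, seed=2)
occ = ne.generate_clade_occurrences(stacks, synthetic.reference_scenario(stacks, seed=3))
tree = ne.build_reference_tree()

cfg = pipeline.PipelineConfig(output_dir="demo_out", n_reps=100, n_samples=1000, seed=0)
result = pipeline.run_pipeline(cfg, stacks=stacks, occurrences=occ, trees=[tree])

eig = result.pca.eigenvalues
print("retained PCs:", result.pca.retained_count)
print("PC1+PC2 variance: {:.1f}%".format(100 * eig[:2].sum() / eig.sum()))
print(result.overlap_table.head(5).to_string(index=False))
```

prints

```
retained PCs: 5
PC1+PC2 variance: 79.9%
 pair      D class  equivalency_p  similarity_p_2to1  similarity_p_1to2
 I-II 0.1678  none         0.0198             0.0198             0.1584
I-III 0.0451  none         0.0198             0.0198             0.0198
 I-IV 0.7670  high         0.6337             0.3960             0.1386
  I-V 0.0000  none         0.0198             0.2376             0.0198
 I-VI 0.1481  none         0.0198             0.2772             0.1386
```

Reading the table: clades I and IV were generated with adjacent niche
centres, and the pipeline recovers that — high overlap (D = 0.77) and an
equivalency test that cannot tell their records apart (p = 0.63). Most
other pairs occupy distinct environmental space: low D and equivalency
rejected at the saturating two-sided p-value 2/101 ≈ 0.02, the most
extreme value attainable with 100 permutations. The similarity columns
report, per direction, whether the observed overlap differs from overlaps
with random draws out of the other clade's 100-km background.
`result.ancestral.table` holds the per-node tolerance means and 80%
intervals per PC; `demo_out/` contains the overlap table, PCA loadings,
suitability rasters and node-tolerance CSVs.

The same stages are scriptable from a shell:

```sh
nicheevo make-synthetic --out demo --seed 4
nicheevo run-all --config demo/config.yml
```

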