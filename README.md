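# planktos

Downstream analysis of abundant and rare microbial-eukaryote
subcommunities from rarefied OTU tables, built for disturbance–recovery
time series such as the succession of lake plankton after a
cyanobacterial bloom. The package takes an OTU × sample count table plus
sample metadata (successional period, water-layer depth, environmental
variables) and answers, with tested and reproducible code, the questions
a community ecologist asks of such data:

- **Who is rare?** Every OTU is placed in one of six per-sample
  relative-abundance categories — always abundant (AAT, ≥ 1% in all
  samples), conditionally abundant (CAT), always rare (ART, < 0.01% in
  all samples), conditionally rare (CRT), moderate (MT), and
  conditionally rare-and-abundant (CRAT) — and rolled up into the
  abundant (AT = AAT ∪ CAT) and rare (RT = ART ∪ CRT) subcommunities.
- **How diverse, and how completely sampled?** Richness, Shannon (nats),
  Gini–Simpson 1 − Σp², Pielou evenness, Chao1 and ACE per sample; a
  truncated Preston log-normal fit to the pooled species-abundance
  distribution estimates the fraction of total richness the sequencing
  recovered; a time × depth two-way ANOVA tests each index.
- **How does the community turn over?** Bray–Curtis dissimilarity
  BC = 1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ), its Baselga partition into
  balanced-variation and abundance-gradient components, time-lag
  regression of dissimilarity on elapsed time, NMDS ordination, ANOSIM
  and SIMPER, Levins' niche breadth B = 1/ΣP², and the
  abundance–occupancy relationship.
- **Which taxa mark each period?** IndVal indicator analysis:
  stat = √(A·B) from specificity A and fidelity B, screened at
  stat > 0.7 and permutation P < 0.05 (999 permutations).
- **Is assembly neutral?** The Sloan neutral community model predicts an
  OTU's occurrence frequency from its mean relative abundance p as
  freq(p) = 1 − BetaCDF(d; Nm·p, Nm(1−p)), with detection limit
  d = 1/N; the single parameter Nm (metacommunity size × immigration)
  is fitted by bounded nonlinear least squares and R² measures how much
  of the occupancy–abundance relationship drift and dispersal explain.
- **Who co-occurs with whom?** A correlation network over OTUs passing a
  prevalence filter (> 6 samples, > 20 reads), with edges at Spearman
  |r| > 0.8 and P < 0.01; node and graph topology, Louvain modules
  benchmarked against 1000 Erdős–Rényi G(n, m) null graphs, keystone
  taxa (degree > 100, betweenness < 5000), Zi–Pi role classification
  (module hubs, connectors), and module–environment association counts.

A first-class synthetic-data module generates OTU tables with known
ground truth — neutral occupancy–abundance structure, three-period
directional succession with planted indicator OTUs, and planted
correlated OTU modules tied to latent environmental drivers — so every
stage of the pipeline is testable end to end without sequence data.

## Worked example

```python
import planktos as pk

sim = pk.simulate_succession(seed=42)          # 2000 OTUs, 18 samples
table, meta = sim.table, sim.meta
observed = table.select_otus(table.counts.index[table.counts.sum(axis=1) > 0])

rel = pk.relative_abundance(observed)
classes = pk.classify_otus(rel)
print(pk.class_proportions(classes).round(2))

dist = pk.bray_curtis_matrix(observed)
res = pk.anosim(dist, meta.period.astype(str), n_perm=999, seed=0)
print(f"ANOSIM by period: R = {res.statistic:.3f}, P = {res.p_value:.3f}")

lag = pk.time_lag_regression(dist, meta.date_index)
print(f"time-lag slope = {lag.slope:.4f} (R^2 = {lag.r_squared:.3f})")

fit = pk.ncm_fit(observed)
rare = classes.index[classes["rollup"] == "RT"]
print(f"NCM: Nm = {fit.nm:.0f}, R^2 = {fit.r_squared:.3f} "
      f"(rare subcommunity R^2 = {fit.r_squared_for(rare):.3f})")
```

prints

```
        n_otus    pct
rollup
AT          40   4.49
RT         805  90.35
MT          30   3.37
CRAT        16   1.80
ANOSIM by period: R = 1.000, P = 0.001
time-lag slope = 0.0661 (R^2 = 0.651)
NCM: Nm = 724, R^2 = 0.655 (rare subcommunity R^2 = 0.526)
```

Read: ~90% of observed OTUs are rare and ~4% abundant (the long-tailed
SAD); the three successional periods are perfectly separated (R = 1 at
the permutation floor P = 0.001); dissimilarity grows with time lag
(positive slope, directional succession); and the neutral model
explains only part of the occupancy–abundance structure here — as it
should, since this data set was generated *with* deterministic
period-to-period turnover on top of neutral sampling.

The same stages run from the shell:

```bash
planktos simulate --kind succession --seed 1 -o data/
planktos all --counts data/counts.tsv --metadata data/metadata.tsv -o out/
```

Each run writes its result tables (TSV/JSON/GraphML) plus a
`manifest.json` recording input checksums, seeds and thresholds, so
identical configurations reproduce identical outputs.

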