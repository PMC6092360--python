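# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions a user
auditing results should know about.

## Data model and rarefaction

The canonical layout is OTUs-as-rows × samples-as-columns, integer read
counts, validated on construction (unique ids, non-negative integers,
≥ 2 samples, positive column totals). Readers accept the transposed
layout via a flag. I/O is plain TSV (UTF-8, `#` comments ignored);
taxonomy strings are semicolon-delimited, at most seven ranks.

Rarefaction to a common depth draws each sample's subsample **without
replacement** (multivariate hypergeometric), so expected post-rarefaction
counts are `depth × count/total` and no OTU can gain reads. The random
stream for sample *j* is derived from `(seed, j)`, making results
independent of sample order on disk. OTUs left with zero reads
everywhere can be re-filtered explicitly (`drop_empty_otus=True`, count
logged) — the choice is left to the user because observed-OTU totals
depend on it. Whole-dataset singleton removal (total ≤ 1 read) is an
optional pre-rarefaction filter, the usual guard against sequencing
error OTUs.

## Abundance classes

Six categories from per-sample relative abundances with
`abundant_cut = 1%` and `rare_cut = 0.01%`. Boundary handling: "abundant"
comparisons use ≥, "rare" use strict <, so the moderate band owns
`[rare_cut, abundant_cut)` for both the per-OTU minimum and maximum. An
OTU at exactly 1% in some samples with min ≥ 0.01% is CAT. Relative
abundance is computed per sample on the rarefied table (not pooled),
because "in all/some samples" is a per-sample statement. Venn presence
is `count > 0` after rarefaction, with no extra abundance floor.

## Alpha diversity and coverage

Shannon uses natural logarithms; Simpson is reported as 1 − Σp²
(Gini–Simpson); Pielou = H/ln S, defined as 1 for S = 1 (flagged
convention). Chao1 is the classic S + F1²/(2F2) (bias-corrected variant
switchable); ACE uses the standard 10-individual rare/abundant split and
is reported as NaN when every rare taxon is a singleton (the estimator
is undefined there). The Preston fit bins pooled abundances into
doubling octaves with the standard half-split of counts lying exactly on
an octave boundary, fits a Gaussian to the occupied octaves by least
squares (truncation at the veil line is implicit: hidden octaves
contribute no points) and extrapolates total richness as the area
S0·width·√(2π). It needs ≥ 3 occupied octaves and, like all veil-line
methods, underestimates total richness when the mode itself is hidden.
The two-way ANOVA uses type-II sums of squares, which reduces to the
classical balanced decomposition for balanced designs and stays sensible
under mild imbalance; empty design cells are an error.

## Beta diversity

Bray–Curtis is computed on raw counts (scale-invariant when totals are
equal, i.e. after rarefaction). The Baselga partition uses
A = Σmin, B, C (unique abundance of each sample):
total = (B+C)/(2A+B+C), balanced = min(B,C)/(A+min(B,C)),
gradient = total − balanced; additivity holds to 1e-12. The component
names follow the balanced-variation / abundance-gradient algebra; users
mapping them onto "turnover" and "richness" labels should note that
balanced variation is the replacement-like component.

Time-lag analysis regresses all n(n−1)/2 pairwise dissimilarities on
|date difference| measured in sampling-event units (calendar lags can be
supplied instead; a √lag option covers the classic variant). Slope
significance is the OLS t test. Because pairs share samples they are not
independent; simulations with no turnover show the test rejects at
roughly 6–7% instead of the nominal 5%. The test is kept because it is
the field's convention for time-lag plots; treat borderline P-values
with care. NMDS (Kruskal stress-1, SMACOF with random restarts) is a
plotting export, not an inferential surface.

Levins' niche breadth B_j = 1/Σᵢ P²ᵢⱼ row-normalizes each OTU's profile
over samples; B runs from 1 (one sample) to n (uniform). The
abundance–occupancy relationship is an OLS fit of occupancy on log10
mean relative abundance, with a Spearman correlation alongside.

## Permutation tests

All permutation p-values use the add-one estimator
p = (1 + #{perm ≥ obs})/(1 + n_perm) with ties counted as ≥, so the
floor at 999 permutations is 1/1000. ANOSIM ranks all pairwise
distances with midranks and reports R = (r̄_between − r̄_within)/(M/2),
M = n(n−1)/2; an exhaustive mode enumerates every label permutation for
small n and returns the exact tail probability. SIMPER averages
|xᵢ−yᵢ|/Σ(x+y) over between-group pairs; per-pair contributions
reassemble that pair's Bray–Curtis exactly, and percentages are of the
mean between-group dissimilarity. Mantel correlates upper triangles
under simultaneous row/column permutation; for Spearman the entries are
rank-transformed once, which is exact because permutation only permutes
them. Environmental distances are |differences| of log(x+1)-transformed
values (natural log; log10 switchable) except pH, which is used raw;
the design factors period and depth are coded ordinally 1–3. Samples
with missing values are dropped pairwise and logged.

IndVal uses group-mean specificity A (so unequal group sizes do not
bias toward large groups), occurrence fidelity B, stat = √(A·B) for the
argmax group, and a permutation p for that best-group statistic. Strict
indicators are records with stat > 0.7 and p < 0.05; no group
combinations are considered (single-period indicators only).

## Neutral community model

freq(p) = 1 − BetaCDF(d; Nm·p, Nm(1−p)). p is the mean relative
abundance **including zeros** (the metacommunity mean); observed
frequency is occupancy; N is the rarefied depth and d = 1/N (one read)
by default, both configurable. Nm is optimized over log Nm ∈ [0, ln 1e7]
by a bounded scalar search plus three deterministic multistarts —
the SSE in log Nm is well-behaved but this guards against plateaus at
the bounds. R² = 1 − SSE/SStot is **not clamped**: negative values mean
the neutral curve explains occupancy worse than its mean, which is
diagnostic information. The 95% envelope uses Wilson binomial intervals
around the predicted frequency at n = number of samples; OTUs are
partitioned above/within/below. Subcommunity fits default to post-hoc
restriction: Nm and the curve come from the full community, and
`NcmFit.r_squared_for(otu_ids)` scores a subset against that curve
(fitting a subcommunity-only table is also possible by passing the
subset table to `ncm_fit`).

Parameter recovery: on Dirichlet-multinomial data (1000 OTUs, 18
samples, depth 10,000, Nm = 500) the median |N̂m − Nm|/Nm over 50
replicates is ~12%, with a small upward bias from the extra multinomial
read-sampling layer that the fitted model does not represent.

## Co-occurrence networks

Prevalence filter: occupancy > 6 samples AND total reads > 20, both
strict. Edges: Spearman |r| strictly > 0.8 and p strictly < 0.01 by the
t approximation t = r√((n−2)/(1−r²)), signs kept as attributes; at
n = 18 the |r| rule already implies the p rule, and the screen logs how
many pairs the p filter removed (expected 0). No multiple-testing
correction by default, matching the raw-P screening convention for
these networks; a Benjamini–Hochberg flag is the modern alternative.
Constant profiles are skipped (undefined correlation); degree-zero
nodes are dropped from the reported network with a logged count.

Topology is computed on the unsigned simple graph: degree, unnormalized
betweenness, closeness, eigenvector centrality; average clustering;
average shortest path over the largest connected component; modularity
from seeded Louvain (resolution 1.0, modules labeled by descending
size, "major" above 40 nodes); power-law R² from log–log OLS on the
positive-count degree histogram. Erdős–Rényi nulls are uniform G(n, m)
graphs with exactly the observed node and edge counts; each metric's
null mean, sd, z-score and the real value's empirical percentile are
reported. Keystones are nodes with degree > 100 and raw betweenness
< 5000 (raw, since thresholds of that magnitude imply unnormalized path
counts). Zi–Pi: z is the within-module degree standardized within the
module (0 where the sd is 0), P = 1 − Σ(k_is/k_i)²; roles use the
usual 2.5 / 0.62 thresholds. Module–environment association counts, per
module and variable, the member OTUs passing the same Spearman screen
against the variable.

## Synthetic data: what it emulates, what it does not

Defaults mirror a bloom-succession survey: 18 samples = 3 periods × 3
depths × 2 dates; 10,000 reads per sample (a desk-scale stand-in for
deep amplicon sequencing — all statistics are computed the same way at
any depth); log-normal SAD with σ = 3 on the log scale, chosen so that
roughly 2–4% of observed OTUs classify abundant and ~90% rare, echoing
the strongly long-tailed communities these analyses target.

- **Neutral tables**: metacommunity proportions from the log-normal
  SAD; each sample is Dirichlet(Nm·p) (the diffusion-limit neutral
  kernel) followed by multinomial read sampling. Default Nm = 1000.
  Exact birth–death forward simulation is out of scope.
- **Succession**: period metacommunities drift apart by a per-OTU
  log-abundance random walk with step sd `turnover_rate` (default
  0.75, strong bloom-like turnover); each period has 20 planted
  indicator OTUs pinned at `indicator_effect` (10×) the period's mean
  OTU weight inside their period and suppressed by the same factor
  outside, which makes the planted signal detectable by construction.
- **Modular counts**: module members load (loading 2.0, noise sd 0.5)
  on a per-module latent factor per sample; designated environmental
  variables are exponentiated noisy copies of those latents (noise sd
  0.3). Background OTUs are deliberately abundant and stable (base
  N(2.0, 0.5), independent noise sd 1.0) so they absorb each sample's
  total: without that, compositional renormalization couples every OTU
  to the dominant module and scrambles OTU–environment correlations.
  The modular generator defaults to 150 OTUs (4 × 25 members + 50
  background) because planted blocks must carry a visible read share.

Deliberately not emulated: sequence-level error, chimeras, taxonomy;
phylogenetic structure; overdispersion beyond the Dirichlet kernel;
seasonal forcing beyond the three-period design. Passing tests on these
generators show the *statistics* behave correctly under their stated
models — they do not certify that real communities satisfy those models.
At n = 18 samples, individual latent draws occasionally leave one
environmental variable without super-threshold correlations; the planted
association tests therefore check concentration of hits on the driving
module at fixed seeds rather than a hit minimum for every seed.

## Problem sizes used in the automated checks

The test suite and acceptance script run at desk scale by design:
survey-sized tables (2305 OTUs × 18 samples) are used only for
bookkeeping identities (rarefaction totals, share percentages);
statistical recovery suites use 300–1000 OTUs, depths 2000–10,000, 200
replicates for power/type-I rates, 500 null simulations at 199
permutations for calibration, and 1000 Erdős–Rényi nulls for network
benchmarks. These sizes were chosen so the whole suite completes in a
few minutes while leaving binomial noise on estimated rates well inside
the asserted bands.

## Known limitations

- The time-lag t test's mild anti-conservatism (above) is inherent to
  regressing dependent pairwise dissimilarities; a restricted
  permutation test would be exact but is not the convention the
  pipeline mirrors.
- Spearman co-occurrence on compositional data inherits the usual
  compositionality caveats; SparCC-style inference is deliberately out
  of scope.
- Chao1/ACE standard errors are not reported; the Preston fit reports
  no confidence interval on extrapolated richness.
- The BIOM format is not read; TSV is the interchange surface.
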