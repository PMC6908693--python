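# Methods

## Quantification chain

Targeted analytes form a fixed six-compound panel: one hydroxy acid and
one epoxy-alcohol per fatty-acid precursor — HHTrE/EHHDE (HTrA, C16:3),
HEPE/EHETE (EPA, C20:5), HDoHE/EHDPE (DHA, C22:6). Each sample carries a
single internal-standard peak area `a_S` (1 µg of 16-hydroxyhexadecanoic
acid), so the absolute amount of analyte x is `ng_x = a_x · 1000 / a_S` —
linear and homogeneous in the analyte area. Normalizations: ng/L divides
by filtered volume (0.5–2 L); fg per diatom cell multiplies ng/L by 10⁶
and divides by total diatom density (cells/L); fg per ng carbon uses the
diatom biovolume power law `pg C per cell = c1 · V^c2` with defaults
c1 = 0.288, c2 = 0.811 (config-exposed, since conversions differ between
labs). Weeks with zero or missing diatom counts yield *missing* fg/cell
values, not zeros — the ratio is undefined and such weeks must drop out
of downstream statistics rather than bias them.

Per-cell production groups follow fixed bounds: [0, 100) fg/cell = low,
[100, 300) = medium, ≥ 300 = high. The interval edges are assigned
upward (100 → medium, 300 → high) so that "above 300" reads literally.

## Log scale

All density-dependence and transcript fits run on the **natural-log
scale**. The slope, R², F and degrees of freedom of a log-log regression
are invariant under the choice of log base; the intercept is not, and the
planted intercepts (10.75 for `ln(fg/cell)` on `ln(cells/L)`; 21.33 for
the transcript relation) are meaningful only on the ln scale — at
10⁶ cells/L the per-cell law gives exp(10.75 − 0.46 · ln 10⁶) ≈ 81
fg/cell, rising to ≈ 1400 fg/cell at sparse winter densities, which is
the physically sensible range for this assay and is what populates all
three production groups. Zeros are excluded from log fits with a logged
warning (targeted quantities are strictly positive when detected).

## Regression machinery

`fit_simple` is ordinary least squares with adjusted
R² = 1 − (1 − R²)(N − 1)/(N − 2), F on (1, N − 2) df and a two-tailed p.
The outlier screen fits a preliminary OLS and drops observations whose
internally studentized residual magnitude exceeds 1.96 (the two-tailed
95% normal bound); a numerically perfect fit drops nothing. The screen is
residual-based — applying it to x or y alone was the open alternative;
residuals are what the 95%-interval criterion naturally refers to, and
the dropped labels are always reported. Multi-predictor models first
remove predictors with VIF > 10 (VIF_k = 1/(1 − R²_k) from regressing
predictor k on the rest; perfect collinearity → +inf, dropped first),
then backward-eliminate the least significant predictor until every
survivor has p ≤ 0.05. Ties break by larger p, then alphabetical label.
Residual diagnostics (Shapiro–Wilk, Breusch–Pagan) are reported but never
gate a fit. No autocorrelation correction is applied: the design treats
weekly samples as independent points, which is the main caveat when
reading the p-values.

## Community statistics

Bray–Curtis runs on raw counts, Jaccard on presence/absence binarized at
> 0; a pair of all-zero samples is defined as identical (d = 0). ANOSIM
ranks all off-diagonal dissimilarities with midranks on ties and forms
R = (mean between-group rank − mean within-group rank)/(M/2). The
permutation engine **enumerates every distinct relabelling** whenever
there are no more of them than the requested permutation count — the
reported p is then exact (observed assignment included, so p > 0) —
and otherwise samples relabellings with the (1 + hits)/(N + 1)
estimator. Balancing pads each group to the largest group's size with
synthetic samples equal to the group's taxon-wise mean; padded labels are
flagged, participate in distances, and are excluded from SIMPER. For the
presence/absence test the matrix is binarized *before* padding, so pad
rows are fractional presence profiles rather than forced 0/1 vectors.
SIMPER attributes |x_ij − x_ik| / Σ_s(x_sj + x_sk) to taxon i per
between-group pair, so per-pair contributions sum exactly to that pair's
Bray–Curtis value. nMDS is SMACOF-style stress majorization with isotonic
regression of configuration distances on dissimilarity ranks, best of 20
random restarts (seeded), 300 iterations, tolerance 1e-6, reporting
Kruskal stress-1.

## Co-variation network

Water-mass windows are maximal runs of ≥ 3 consecutive sampled weeks
whose salinity spread is ≤ 2 × tolerance (default 0.15 PSU, wide enough
that a ±0.12 PSU plateau qualifies); candidates are taken greedily
longest-first and never overlap. Within each window, Spearman ρ between
every taxon pair uses midranks; the significance gate defaults to the
t-approximation with df = n − 2 because an exact permutation test cannot
reach p < 0.05 from a 3-week window at all (best two-tailed p = 1/3), yet
short windows are part of the design; every edge from a window shorter
than 5 weeks is flagged `low_support`. An exact enumeration p over all n!
orderings is available for n ≤ 9 and is the oracle used in tests. Kept
edges satisfy |ρ| ≥ 0.7 and p < 0.05; a pair significant in several
windows merges into one edge that keeps the strongest period's ρ and sign
(averaging ρ could silently break the inclusion rule) while its chemical
annotation averages over all source periods.

Modules come from modularity maximization on the positive-edge subgraph
(negative-edge modularity is ill-defined; negative edges stay in the
graph for degree tallies and annotation): several seeded Louvain restarts
plus greedy agglomeration, keeping the best-Q partition, which matches
exhaustive-partition search on all small graphs we test. Module labels
are ordered by size then smallest node id, so they are deterministic
given a seed.

Each edge is annotated with the mean fg/cell of the HTrA-, EPA- and
DHA-derived classes over its source window's weeks (missing weeks
skipped). The null model reshuffles the intra-module edge annotations
across modules — each reshuffle is a permutation, so the annotation
multiset is conserved exactly — pools the values landing in each module
over 1000 reshuffles (seeded), and subsamples back to the module's edge
count. An F-test at α = 0.05 picks the pooled-variance t-test
(df = n1 + n2 − 2) or Welch's test; all tests are two-tailed. Whether the
original procedure compared against one reshuffle or a pooled null is
unknowable from its description; the pooled-subsample design is this
package's defined stand-in.

## Synthetic data: what it emulates and what it does not

The generator plants, with known parameters recorded in `truth`:

- **Community** (53 taxa × 52 weeks): taxa split round-robin into 3
  guilds; each guild shares a Gaussian-in-time bloom envelope (floor
  0.0015 of peak, width n_weeks/(7·n_modules)) multiplied by per-taxon
  lognormal noise, giving strong within-guild rank co-variation, weak
  between-guild co-variation, and a ≥ 100-fold range in total weekly
  density. Counts below a 250 cells/L detection limit are recorded as
  absent, as a settling-chamber count would be, so presence/absence
  varies seasonally.
- **Oxylipins**: per week, per-class fg/cell follows
  ln(class fg/cell) = [10.75 + ln f_class] − 0.46 · ln(total cells/L) + ε,
  ε ~ N(0, noise_sd). Class fractions f default to EPA 0.7668,
  DHA 0.2196, HTrA 0.0136 (the observed precursor ordering); each class
  splits 0.7/0.3 into its hydroxy acid and epoxy-alcohol. The peak-area
  model is the exact algebraic inverse of the quantification chain, so
  noise-free peaks quantify back to planted values to machine precision.
  noise_sd defaults to 0.38, set a priori from
  noise = |b| · sd(ln D) · sqrt((1 − R²)/R²) with the generator's
  sd(ln D) ≈ 2 and the target adjusted R² ≈ 0.855 — the midpoint of the
  0.84–0.87 band the field fits occupy.
- **Environment**: declared salinity windows (defaults: a 7-week plateau
  at 38.0 ± 0.06 PSU and three 3-week plateaus at 37.5 ± 0.12,
  37.7 ± 0.05, 38.2 ± 0.01 PSU) sit on a reflecting random walk capped at
  37.2 PSU with a minimum step of 0.35 PSU, so no spurious plateau can
  form outside a window and every declared window is recovered exactly at
  the default tolerance. Temperature and chl-a are seasonal curves plus
  noise.
- **Stations** (146 rows = stations × size classes): metagenome abundance
  G lognormal (sd(ln G) = 2.3); normalized LOX = exp(21.33 − 0.7 ln G + ε)
  with ε-sd 1.97 targeting R² ≈ 0.4; raw transcript counts are emitted so
  that LOX/total reproduces the normalized value exactly.

Not emulated: counting error of microscopy, LC-MS drift or batch effects,
station geography, autocorrelated residuals, or sudden one-week density
spikes (off by default). Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under clean conditions —
not that field data of this kind are free of the confounders above.

## Problem sizes and seeds

Recovery checks refit the planted slopes at the survey sizes (38 weekly
points after exclusions; 146 station rows) across 100 generator seeds and
require the 95% CI to cover the planted value in ≥ 90 of them. The
ANOSIM engine's type-I error is checked on 1000 structureless 12-sample
designs (924 exact relabellings each). Every stochastic component — the
generator, permutation engines, Louvain restarts, null reshuffles — takes
an explicit integer seed and is reproducible byte-for-byte.

## Known limitations

- ANOSIM R values on synthetic data (~0.3 for the Bray–Curtis grouping
  test) are smaller than a strongly structured field community would
  give; the generator's grouping signal is purely density-mediated. The
  presence/absence (Jaccard) test is correspondingly near-null, which is
  the qualitatively expected contrast.
- Modularity maximization is heuristic for large graphs; optimality is
  verified exhaustively only up to 8 nodes.
- The per-litre fit's slope (1 + b on planted data) is reported from the
  same weeks as the per-cell fit; it is not an independent measurement.
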