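# oxynet

Density-dependent oxylipin production in natural diatom communities:
a tested analysis pipeline for targeted-oxylipin quantification,
community statistics, log-log density regressions, global transcript
normalization, and chemically annotated co-occurrence networks.

## The problem

Marine diatoms synthesize lipoxygenase (LOX)-derived oxylipins — here the
non-volatile linear oxygenated fatty acids (LOFAs): hydroxy acids and
epoxy-alcohols derived from the precursors HTrA (C16:3), EPA (C20:5) and
DHA (C22:6). Field surveys that pair weekly phytoplankton counts with
targeted LC-MS oxylipin panels ask: does per-cell oxylipin production
depend on diatom density, and do oxylipin classes structure diatom–diatom
co-variation? This package implements the full analysis chain for such a
survey, plus a synthetic-data generator that plants every relationship
with known parameters, so each statistical stage is testable without any
field data.

## The models and statistics at its core

- **Quantification.** Against a 1 µg internal standard,
  `ng_x = a_x × 1000 / a_S` per analyte from chromatogram peak areas;
  normalized to ng/L by filtered volume, to fg per diatom cell by total
  diatom density (1 ng = 10⁶ fg), and to fg per ng diatom carbon via the
  diatom biovolume power law `pg C = 0.288 · V^0.811`.
- **Density dependence.** OLS on log-transformed data:
  `ln(fg/cell) = a + b · ln(cells/L)` with planted defaults a = 10.75,
  b = −0.46 (≈ 81 fg/cell at 10⁶ cells/L), 95%-interval outlier screening
  on studentized residuals, VIF screening (> 10) and backward elimination
  at α = 0.05 for multi-predictor models.
- **Community tests.** Bray–Curtis / Jaccard dissimilarity, balanced
  one-way ANOSIM (group-mean padding; exact relabelling enumeration when
  the design is small enough, Monte Carlo otherwise), SIMPER
  decomposition, and non-metric MDS minimizing Kruskal stress-1.
- **Global transcript check.** LOX transcript abundance normalized by
  total diatom transcripts, regressed on diatom metagenome abundance:
  planted `ln(LOX/total) = 21.33 − 0.7 · ln(G)`.
- **Co-variation network.** Water-mass windows from salinity persistence;
  within-window Spearman correlations kept at |ρ| ≥ 0.7, p < 0.05 as
  signed edges; modularity maximization on the positive subgraph; edges
  annotated with mean per-cell production of each precursor class;
  module-wise enrichment tested against nulls that reshuffle annotations
  across modules, with an F-test choosing pooled vs Welch t-tests.

## Worked example

```bash
python analysis/01_simulate.py --seed 1      # synthetic year + station table
python analysis/02_quantify.py               # peak areas -> profiles
python analysis/03_density_regressions.py    # log-log fits
python analysis/04_community_groups.py       # ANOSIM / SIMPER / nMDS
python analysis/05_tara_fit.py               # global transcript regression
python analysis/06_network.py                # annotated network + null tests
```

Representative output (seed 1):

```
per-cell: y = -0.417x + 10.26; adj-R2 = 0.868; F = 318.0; df = 47; N = 49
ANOSIM Bray-Curtis: Global-R = 0.33, p = 0.0001
ANOSIM Jaccard (presence/absence): Global-R = 0.00, p = 0.4237
nMDS stress = 0.070
pooled: y = -0.612x + 17.34; adj-R2 = 0.33; F = 71.3; df = 144; N = 146
574 edges over 53/53 connected nodes; 3 modules, Q = 0.379
  EPA-derived module-1: t = 6.30, df = 315, p = 1.02e-09 (enriched, n = 180)
```

Reading: the fitted per-cell slope (−0.417 here; −0.46 planted) says each
e-fold increase in diatom density lowers per-cell oxylipin output by
~40%; the Bray–Curtis ANOSIM separates the low/medium/high production
groups while the presence/absence test does not, i.e. the grouping is
driven by abundance, not by which taxa are present; the network recovers
the three planted guilds as modules and the null tests flag modules whose
edges carry non-random oxylipin annotations.

The same stages are scriptable through the `oxynet` CLI
(`oxynet synth | quantify | multivar | tara | network | run`).

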