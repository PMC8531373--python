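# Methods

This note records the statistical model behind `cranionet`, the
numerical choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Data model

A *specimen* is one individual's Martin-system measurements in mm with
a provenance flag per value: `observed`, `estimated` (reconstructed by
the source; printed in parentheses in the CSV dialect) or `missing`.
A *population sample* is a per-measurement summary `(n, mean, sd)`;
`sd` is absent when `n = 1`.  Sample SDs use the n−1 denominator, the
convention under which the small-sample SDs of published tables
(n = 2–6) are interpretable.  A plausibility guard rejects values
outside (0, 300) mm.

Estimated values take part in aggregation and every downstream
computation by default — summary tables fold reconstructed values into
their means, and excluding them would discard most of a fragmentary
cranium — but `aggregate_specimens(..., include_estimated=False)` and
the CLI's `include_estimated` flag provide the exclusion path.

The packaged focal-site fixture transcribes the 13-measurement battery
for seven early-Holocene sites (five single female crania and two
summary samples).  One source cell carries a stray minus sign on a
breadth measurement; a negative breadth being physically impossible,
it is transcribed positive and flagged `estimated`.  The fixture is
restricted to the analysis battery because the remaining rows of the
source table cannot be transcribed unambiguously from the available
text.

### Regression imputation

Basion–bregma height (M17) is the battery measurement most often
destroyed postmortem.  The packaged imputer is the published female
regression on auricular–basion height, `M17 = 1.05 × ABH + 14.26` (mm),
applied only to M17; the full-precision value is kept internally and
rounded to whole mm only for display.  At ABH = 112 mm it yields
131.86 → 132.

## Standardization and Q-mode correlation distance

For battery code `c`, sample mean `m_c`:

    z_c = (m_c − g_c) / s_c

where `g_c` is the **unweighted** mean of the comparative samples'
means (each population counts once, since census sizes of skeletal
series are arbitrary) and `s_c` is the SD of one designated reference
sample — a hunter-gatherer series large enough to estimate dispersion
(the Jomon sample plays this role in the motivating analysis).  Focal
ancient samples are standardized against this reference but excluded
from the grand mean, which is defined by the comparative panel alone.

The similarity between samples `a` and `b` is the Pearson correlation
`r` computed *across* the 13 standardized values (Q-mode, i.e. objects
correlated over variables, with within-profile centering — the
conventional reading of a Q-mode correlation coefficient, as opposed to
an uncentred cosine).  The distance is `1 − r ∈ [0, 2]`; values above 1
(negative correlation) are kept as-is because the network construction
tolerates them.  Completeness is enforced — a sample missing any
battery code is rejected rather than silently pairwise-deleted; the
imputer above is the sanctioned fill-in.

Degenerate profiles (zero variance across the battery, e.g. a sample
exactly at the grand mean) have no defined correlation and raise a
specific error naming the sample.

## NeighborNet

### Circular ordering

Taxa begin as singleton clusters.  Each iteration:

1. Among cluster pairs, minimize the neighbor-joining criterion
   `Q(A,B) = (m−2)·d(A,B) − R_A − R_B`, with `d(·,·)` average linkage,
   `R_A = Σ_C d(A,C)` and `m` the number of clusters.
2. Within the chosen pair, minimize the same criterion over node pairs
   `x ∈ A, y ∈ B` in the refined collection where A and B are broken
   into singleton nodes (so `m̂ = m − 2 + |A| + |B|`).
3. Link the cluster paths at `x`–`y`.  Clusters are kept to ≤ 2 active
   nodes: a path `x–y–z` is replaced by two nodes `u, v` with the
   equal-thirds reduction

       d(u,w) = 2/3 d(x,w) + 1/3 d(y,w)
       d(v,w) = 1/3 d(y,w) + 2/3 d(z,w)
       d(u,v) = (d(x,y) + d(x,z) + d(y,z)) / 3

   (applied twice when two 2-node clusters join).

When ≤ 3 active nodes remain they close into a cycle and the reductions
are expanded in reverse, each reduced pair re-inflating to its three
original nodes with orientation preserved.  **Tie-breaking:** both
selection steps scan candidates in ascending node-index order and keep
the first strict minimum, making the construction fully deterministic;
the output cycle is normalized to start at the first taxon and run
toward its lower-indexed neighbour.  Orderings are unique only up to
rotation/reflection, so tests compare split sets, not raw cycles.

### Split weights

The n(n−1)/2 interval splits of the ordering define 0/1 split metrics
`δ_s` over taxon pairs.  Weights solve `min ‖d − Σ_s w_s δ_s‖` by
non-negative least squares (scipy's active-set NNLS; the full design
matrix is explicit, which is adequate up to the ~80-taxon panels this
package targets).  An unconstrained least-squares option exists for
diagnostics.  Splits with weight ≤ 1e-8 are dropped — the NNLS
active set makes true zeros exact, so this threshold only clears float
dust; trivial (singleton) splits are retained since they carry the
terminal edge lengths of a drawn network.  The residual norm reported
by the results object is the Euclidean distance between observed and
reconstructed pairwise distances.

On exactly additive (tree) input the positive non-trivial splits are
provably the tree's bipartitions; the test suite verifies this against
an independent neighbor-joining implementation (scikit-bio's) and
against brute-force least-squares topology selection on quartets.

### Output

TAXA + SPLITS NEXUS blocks in the SplitsTree-4 dialect: 1-based CYCLE
indices, one row per split listing its weight and the members of the
side containing taxon 1, rows ordered by weight descending then
lexicographically.  Network layout/drawing is out of scope.

## PCA

Eigendecomposition of the covariance matrix of the fit-set standardized
profiles.  The inputs are already z-scored by the reference SDs, so no
second per-variable rescaling is applied (a correlation-matrix PCA
would erase the reference-SD weighting).  Centering is on the fit-set
means — the fit set defines the axes, and held-out (ancient) samples
are projected as supplementary points: `score = Lᵀ(z − center)`,
leaving the model untouched.

Numerical choices: components with eigenvalues clipped at zero beyond
the matrix rank are not reported; the eigenvector sign indeterminacy is
fixed by flipping any column with negative loading sum, which renders
PC1 — whose loadings are all positive on size-structured data — the
overall-size axis scoring large crania positively; retention rules use
strict inequalities (`eigenvalue > 1`, `contribution > p%`).  A fit set
smaller than the 13 variables triggers a rank-deficiency warning and
returns min(rank, 13) components.

## Synthetic two-layer world

The generator emulates the statistical shape of a worldwide female
craniometric database: population mean profiles with

    μ_p = s_p · (base_mean + sign_c · λ · σ ⊙ contrast)

where `s_p` is a per-population multiplicative size factor
~ U(0.88, 1.05), `sign_c = ±1` for the two layers, `λ` the contrast
scale in within-population SD units, `σ` the within-population SDs and
`contrast` the layer-1 direction (+1 on M1/M45/M46, −1 on M48/M55: a
longer vault, broader face, lower facial/nasal heights).  Individuals
are iid Normal(μ_p, σ) per measurement; missingness, when enabled, is
completely at random.  A reference population is drawn from the
uncontrasted base mean at size factor 1 and donates its SDs to the
standardization.

Defaults (the study conditions of every seeded property below): 16
populations per layer, 30 individuals per population, base means and
SDs at the magnitude of published female tables (M1 ≈ 180 ± 6 mm,
M54 ≈ 26 ± 1.5 mm), `λ = 1`, no missingness, reference n = 30.  A
1-SD between-layer difference is the conventional size of regional
craniometric contrasts, and it keeps overall size the dominant variance
component (population-limit eigenvalues ≈ 18 vs ≈ 4.4), matching the
strong PC1 dominance of real worldwide panels.  The panel is half the
scale of the motivating 67-population database; at that full scale the
same recovery properties hold but 100-replicate network suites become
disproportionately slow on one CPU, so the packaged checks use the
32-population panel.

What the generator does **not** model: cross-measurement covariance
beyond the shared size factor (real measurements correlate through
integrated growth), admixture or drift through time, informative
missingness, and sexual dimorphism.  Passing the recovery tests
therefore shows the *pipeline* is correct and well-calibrated for
cluster structure of realistic magnitude — not that real population
history is this simple.

## Scope and limitations

- The worldwide comparative database behind the motivating analysis is
  not redistributable; the PCA retention check against its published
  summary (five eigenvalues > 1, cumulative contribution 85.64%) can
  only run when a user supplies that table, and is reported as failing
  otherwise rather than being silently skipped.
- NNLS scales as O(n⁴)-ish in taxa through the explicit design matrix;
  beyond ~100 taxa an iterative solver would be needed.
- Distances `1 − r` are not metrics (triangle inequality can fail);
  NeighborNet does not require metricity, but tree-based methods
  downstream of the PHYLIP export may.
- The NJ oracle and the PCA cross-check (scikit-learn) are independent
  implementations used in tests only; the analysis path itself is
  self-contained.
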