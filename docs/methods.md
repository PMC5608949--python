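# Methods

This note documents the models and procedures implemented in `fluidmap`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Preprocessing

The chain runs in a fixed order; each stage's rule and rationale:

**Run-day filter and rescaling.** Mass-spectrometry intensities drift by
acquisition day, so every value is divided by the median of its feature on
its run day. Medians over fewer than 3 values are unreliable: a feature
with fewer than 3 measured values on more than half of the run days is
removed first (both inequalities strict). After rescaling, each
(feature, run day) group has median exactly 1.

**PQN.** Urine and saliva concentrations are dominated by per-sample
dilution (hydration state, stimulation). Probabilistic quotient
normalization computes a reference pseudo-sample as the per-feature mean
over samples, using only features with no missing entries; each sample's
dilution factor is the median of its quotients against the reference, and
the sample's whole fluid block is divided by it. Dividing by the median
quotient makes each sample's median quotient against the defining
reference exactly 1 (the identity the tests assert). The fluids to
normalize are configurable (default urine and saliva; plasma is
osmotically regulated and left alone). Creatinine scaling is deliberately
not offered — PQN is the more robust choice for untargeted panels.

**Log2 and outliers.** All intensities are log2-transformed. Outlier
exclusion runs per fluid on the features with no missing values: features
are robustly centered/scaled (median, scaled MAD), projected onto
principal components retaining ≥ 99% of variance, and samples scored by a
Mahalanobis-type distance with per-component robust location/scale; a
sample is excluded if its score exceeds the median score by more than
4 robust SDs. This is a documented re-implementation of the
robust-PCA-score family of outlier detectors, validated by planted-outlier
recovery (a sample at 10 SD on every axis is flagged; a homogeneous
Gaussian cloud yields < 2% flags), not a bit-compatible port of any
particular implementation.

**Missingness filter.** Features with strictly more than 20% missing
values (over retained samples) are dropped: correlations estimated on
heavily imputed features would inherit the imputation model's covariance.

**Censored-normal imputation.** Missingness in this platform is mostly
left-censoring at a detection limit. Per (feature, run day) with more than
10 observed values, a left-censored normal is fitted by maximum likelihood
on the log2 *raw* (pre-normalization) values — observed x₁..x_k plus m
values known only to lie at or below the censor point c — maximizing
Σ log φ((x−μ)/σ)/σ + m·log Φ((c−μ)/σ) (Nelder–Mead on (μ, log σ)).
Missing entries are drawn from the fitted normal truncated to (−∞, c].
c is taken as the minimum observed value of that (feature, run day): the
platform's detection limit is not recorded, and the smallest observed
value is its sharpest available upper bound. Draws are mapped into the
normalized log2 space by subtracting the log2 run-day median and log2
dilution factor of the target cell. Groups at or below 10 observed values
are left for PMM (too little data for a stable two-parameter fit).

**Predictive mean matching.** Residual missing values: each incomplete
feature is regressed on its 10 most-correlated complete features; a
missing entry receives one of the 5 observed values of that feature with
the closest predicted mean, drawn uniformly. K = 10 predictors and
5 donors follow common PMM practice; both are configurable. Features with
fewer than 10 observed values fall back to their marginal empirical
distribution (logged). Imputation never alters observed values, and PMM
draws are always observed values of the same feature.

**RNG discipline.** One master seed; per-(feature, run day) substreams are
derived by a stable hash of the labels, so feature or sample order never
changes the draws attached to a given cell.

## Network inference

**Estimator.** The sample correlation matrix of the network variables plus
appended covariates is shrunk toward the identity with the analytic
(Ledoit–Wolf / Schäfer–Strimmer) intensity λ* = Σ Var̂(r_ij) / Σ r_ij²
(clipped to [0, 1]), inverted, and partial correlations read off the
precision matrix: pcor(i,j) = −Ω_ij/√(Ω_ii Ω_jj). Covariates (age, gender,
BMI) are conditioned on by inclusion — their rows/columns are removed from
the output and never count as nodes. λ* → 1 on data with no true
correlation is correct behavior (the identity is then the true target) and
yields zero partial correlations, with a warning.

**Pearson side.** Pearson correlations are computed on
covariate-residualized data and tested with the exact t-test on
n − 2 − c degrees of freedom, which is identical to the partial
correlation given the covariates (cross-checked against an independent
implementation in the tests).

**Partial-correlation p-values.** Under the null the partial correlation
follows f₀(r) ∝ (1−r²)^((κ−3)/2), where κ is an effective degree of
freedom; shrinkage narrows the null, so κ must be estimated from the data.
The default fit maximizes the likelihood of the two-component mixture
η₀·f₀(r; κ) + (1−η₀)·U(−1,1) over the observed off-diagonal partial
correlations, so genuinely connected pairs are absorbed by the uniform
component and κ is estimated on the null bulk. κ is bounded below by
n − 1 − (number of conditioned variables) — exact for the unshrunk null,
and shrinkage can only narrow the distribution — which keeps the fit from
degenerating on very small panels where non-null pairs dominate.
Two-sided p-values are Beta tail probabilities of r² under f₀. A pure
single-component κ fit and a Fisher-z test (effective df κ−3) are
selectable by config; the Fisher-z fallback also engages automatically if
the fitted κ ≤ 3.

**Edges.** An edge is drawn iff *both* p-values beat α / C(p, 2) with
p the number of network variables only. Calibration: on null data with
forced λ = 0.5 the fraction of partial p-values below 0.05 is 0.049
(asserted at ±0.02 in the tests); with analytic shrinkage on pure-null
data λ* reaches 1 and the test is degenerate-conservative by design.

## Hierarchical map

**Eigenmetabolites.** Per fluid-resolved sub-pathway, members are z-scored
and the first principal-component score vector is the pathway
representative; explained variance = leading eigenvalue / trace of the
member correlation matrix. The sign is fixed so the eigenmetabolite
correlates non-negatively with the mean of the z-scored members, making
results deterministic and orientation-interpretable. Single-member
pathways are kept (representative = the z-scored member, EV = 1). For an
m-member single-factor pathway with loading a, EV → (1+(m−1)a²)/m, the
closed form the tests check.

**Levels.** The metabolite GGM includes structurally unidentified
metabolites (they carry real correlation information); pathway levels
exclude them (no pathway assignment is possible). The super-pathway
network is produced *only* by collapsing the sub-pathway GGM — broad
groups like "Lipid" are too heterogeneous for a first principal component
to represent, so super-pathway eigenmetabolites are deliberately not
offered. Intra-super-pathway sub-pathway edges would be self-loops and are
dropped; collapsed edges carry the member-edge count but no correlation
statistics.

## Module identification

Scoring is ordinary least squares of the module representative on
[1, P, covariates] with the two-sided t-test p-value of the P
coefficient; score = −log10 p, capped at 300 (p-value underflow). A
single-node module's score is its univariate association. Binary
phenotypes are coded 0/1 and used as a regressor (no logistic variant: P
is on the right-hand side of the model).

The greedy step adds the neighbor v* maximizing score(M ∪ {v}), accepted
iff the new score strictly exceeds both score(M) and the single-node score
of every member of M ∪ {v*}; ties break to the lexicographically smallest
node id, making runs deterministic. Optima from all seeds are merged by
connected components of the overlap graph into pairwise-disjoint maximal
modules and rescored; a merged module that fails significance after
rescoring is dropped, not decomposed back into its optima. Reporting
requires p < α/n_nodes (node-level Bonferroni) and strict dominance over
the best member. Because the dominance inequality is strict, single-node
modules are never reported.

Known limitation (by construction of the mean-z representative): members
with opposing effect directions cancel; such modules are invisible to this
scoring. On networks of ~10 nodes the node-level Bonferroni threshold is
lenient enough that greedy selection admits a false module in ~10% of
phenotype permutations; at cohort scale (~150 nodes) the permutation null
is clean (99/100).

## Synthetic data generator

Log2-scale latent model per feature j of pathway g, sample i:
z_ij = a·f_gi + β_j·P_i + √(1−a²−β_j²)·e_ij with pathway factor
f_g ~ N(0,1) (configured cross-fluid pathway pairs share a factor
component: cor(f_A, f_B) = g²), standardized phenotype P, iid noise e, and
a variance budget enforced (a² + β² < 1). Raw intensity =
2^(z+μ_j) × run-day offset × per-sample dilution (lognormal, per fluid);
values below the feature's censor quantile go missing, for a configurable
fraction of features (real panels have many fully observed metabolites —
which PQN's reference and the outlier scan rely on). A configurable
fraction of features loses its pathway annotation ("unknowns"). Ground
truth (factors, dilution, censor points, planted effects) is returned
alongside.

What the generator does *not* emulate: heavy-tailed or skewed marginal
intensity distributions, correlated missingness beyond left-censoring,
nonlinear metabolite relationships, covariate-phenotype confounding, and
real pathway catalogues. Passing tests therefore demonstrate correctness
of the algorithms under the stated model, not robustness to every
real-data pathology.

**Named study conditions.**
- `make_cohort_config`: three fluids with feature counts in the
  ratio of a full cohort panel (335/473/189 at scale 1; default scale 0.15
  for desk-scale runs), 8 super-pathways, many-to-one sub→super mapping,
  cross-fluid coupling of matching plasma/urine pathways, 4 run days
  (log2 offset SD 0.5), urine/saliva dilution (log2 SD 0.7/0.5),
  censoring of 40% of features at their 10% quantile, 20% unknowns,
  n = 906 samples.
- `sparse_phenotype_config`: a 12-node three-fluid panel (4-member
  pathways, loading 0.45) with four plasma members carrying 0.094 SD
  effects at n = 906 — sized by a design-stage power calculation so the
  population single-node z (≈2.8) sits just below the node-level
  Bonferroni threshold (≈2.9) while the module-mean z (≈4.5) clears it;
  measured recovery of the planted module is ~85%.
- `pqn_recovery_config`: 140 urine features (70 two-member pathways,
  loading 0.5) at n = 200, log2 dilution SD 1.5 (urine swings roughly
  ten-fold with hydration), censoring of half the features at their 10%
  quantile (5% missingness overall). Dilution recovery requires the
  dilution spread to dominate biological variation and enough complete,
  weakly correlated features for the median quotient; under these
  conditions recovery is r > 0.99.

## Numerical choices

- Strict inequalities throughout the filter rules ("more than 20%", "more
  than 10", "more than half", and both clauses of the greedy acceptance).
- Censored-normal MLE: Nelder–Mead on (μ, log σ), 2000 iterations,
  fallback to PMM on non-convergence or σ̂ < 1e−8 (logged).
- Null-density fit: deterministic coarse grid (5 η₀ × 40 log κ values)
  then Nelder–Mead refinement; κ capped at 1e9.
- Score cap 300; deterministic lexicographic tie-breaks in the greedy
  search; all serialization lexicographically ordered so outputs diff
  cleanly.
- Degenerate inputs error early and name the offender: constant columns,
  zero-variance pathway members, non-positive intensities (cell named),
  rank-deficient scoring designs, sub-pathways mapped to two
  super-pathways.
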