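# Methods

This note records the statistical model, the defaults and the numerical
choices behind `symptomnet`, and what the simulation-based tests do and do
not establish.

## Data model and preprocessing

The pipeline expects a rectangular table of N subjects × P variables with
a schema declaring, per column, its type (continuous / ordinal / binary),
admissible range, marginal summary and expected missingness. Missing
cells are permitted; a column enters the analysis only if its missing
fraction is *strictly* below 15% (the screening rule is a strict
inequality, so a column with exactly 15% missing is dropped).

**Imputation.** Remaining holes are filled by a single chained-equations
pass: missing cells are initialized with the column median (continuous) or
mode (ordinal/binary), then the columns containing missing values are
revisited in schema order for 10 sweeps. Continuous columns are imputed by
ordinary least squares on all other columns plus a Gaussian residual draw
(scale from the residual mean square; draws clipped to the declared
range); ordinal and binary columns by predictive mean matching with 5
donors nearest in the linear predictor, which guarantees valid category
values. One completed dataset is produced per call: imputation
uncertainty is propagated by the subsample-rerun loop (which re-imputes
every time), not by pooled multiple imputation. A column constant among
its observed values is filled with that constant and logged as a warning.

**Nonparanormal transform.** Each column's values are replaced by
Φ⁻¹(r/(n+1)) where r is the mid-rank (average ranks for ties), then
rescaled to unit sample variance (1/n convention, matching the likelihood
below). Only rank information survives, so any strictly increasing
distortion of a tie-free column leaves every downstream result — the
transformed matrix, the fitted network, all centralities — bit-identical.
A constant column is an error naming the column.

## Ridge Gaussian graphical model

The precision matrix is estimated by maximizing the Gaussian
log-likelihood with a Frobenius penalty toward a target T,

log det Ω − tr(SΩ) − (λ/2)‖Ω − T‖²_F,

whose maximizer has the exact spectral closed form
Ω̂ = U diag(1/(√(λ + d²/4) + d/2)) Uᵀ with S − λT = U diag(d) Uᵀ. This
estimator exists and is positive definite for every λ > 0, including the
rank-deficient n < p case. S uses the maximum-likelihood 1/n convention,
so the transformed data's unit variances give S a unit diagonal exactly.

* **Target.** T = αI with α = p/trace(S) (≈ I on unit-variance input):
  rotation-equivariant, and it defines the large-λ limit. Configurable.
* **Penalty selection.** Leave-one-out cross-validation: for each λ on a
  25-point log-spaced grid in [10⁻³, 10] and each held-out row, the model
  is refitted on the remaining rows (re-centered on their own mean) and
  scored by the held-out Gaussian negative log-likelihood; ties break
  toward the smaller λ. The fixed-λ default for reruns is 0.125. λ is
  selected once on the full data and held fixed across stability reruns —
  one network model, many data perturbations.
* **Partial correlations.** ρ̂_ij = −ω̂_ij/√(ω̂_ii ω̂_jj), diagonal set
  to 0 by convention.

## Local-FDR edge selection

The p(p−1)/2 statistics z_ij = atanh(ρ̂_ij) are modelled as a two-group
mixture on the variance-stabilized Fisher scale.

* **Empirical null.** N(0, σ₀²), with σ₀ fitted by truncated maximum
  likelihood on the central statistics (|z| ≤ 75th percentile of |z|), so
  genuine edges in the tails do not inflate the null. When the central
  window carries no shape information — a truncated normal with σ ≫
  window width is indistinguishable from uniform, and the bounded
  likelihood search then runs to its upper boundary — σ₀ falls back to
  central matching: the value that makes the null mass of the window equal
  the observed inside fraction. Without this fallback the degenerate case
  (possible under a global null with heavily discretized variables)
  declares everything significant; with it, the null calibration is
  stable across seeds.
* **Null proportion.** η₀ = min(1, inside fraction ÷ null window mass).
* **Marginal density.** Gaussian kernel density estimate with Silverman
  bandwidth (configurable through the fit object).
* **lfdr.** min(1, η₀ φ(z; 0, σ₀)/f(z)), monotonized to be non-increasing
  in |z| by a running minimum outward from 0, so retention thresholds give
  nested edge sets. An edge is retained when 1 − lfdr ≥ 0.80; retained
  edges carry the sign and magnitude of their partial correlation. An
  exactly zero saturated matrix short-circuits to an empty network.

## Stability and centrality

Each of B reruns (reference configuration B = 1000; the analysis scripts
and acceptance checks use B = 200, which already yields selection-
frequency standard errors below 0.04) draws ⌊0.75·N⌋ rows without
replacement — 161 of 215 at the study size — re-imputes, re-transforms,
re-fits at the fixed λ and re-sparsifies. Reported per pair: selection
frequency (fraction of reruns retaining the pair) and the median
saturated partial correlation over *all* reruns (unconditional on
retention). Per-rerun seeds derive from the base seed and the rerun
counter, so reports are byte-reproducible.

The final reported edge set is the full-data sparsified network;
stability metrics annotate it.

Centralities on the retained-edge graph:

* **Degree**: incident retained edges, split by partial-correlation sign.
* **Eigenvector**: power iteration on A + σI (σ = max absolute row sum;
  shares eigenvectors with A but is never oscillatory on bipartite
  components), absolute |ρ̂| weights by default, scaled so the maximum
  node scores 1; isolated nodes and nodes outside the spectrally dominant
  component score 0. A signed-adjacency mode exists as an option; with
  several components this centrality can legitimately assign 0 to
  connected nodes, which is a property of the definition, not a bug.
* **Betweenness**: unweighted shortest-path betweenness (Brandes, each
  unordered pair counted once, fractional credit for tied paths); a
  1/|ρ̂|-distance weighted mode is available but not default.

Layout uses the classic Fruchterman–Reingold spring embedder (repulsion
k²/d, attraction d²/k, linear cooling from 0.1 over 200 iterations,
k = √(1/n)), deterministic given its seed.

## Synthetic data

The generator emulates the study conditions: 20 variables with the
published marginal means/SDs, prevalences, instrument ranges and
per-variable missingness (education 14.4%, single status 4.7%, apathy
scale 0.9%, quality of life 1.4%, others complete), over N = 215
subjects, on top of a known sparse precision matrix (26 edges by default,
partial-correlation magnitudes 0.15–0.40 — the magnitude range is the
package's own choice of a realistic span for questionnaire networks; the
edge count matches the scale of the reported network).

Latent rows are N(0, Ω⁻¹); each column is mapped through Φ and the
declared inverse marginal CDF — truncated normal for continuous scores,
thresholding at cumulative category probabilities for ordinal/binary ones
(never rounding), so the latent copula is exact. Bounded integer scores
published only as mean [SD] get a discretized-normal marginal matched to
those moments. Missingness is injected MCAR at the declared rates; the
real missingness mechanism is uncharacterized, and MCAR matches the
screening rule's spirit.

Support generation: the requested number of pairs receives magnitudes
uniform in the requested band with random signs (unit diagonal, so the
precision entry is minus the partial correlation). If the matrix is not
comfortably positive definite (min eigenvalue ≤ 0.05), off-diagonals are
shrunk multiplicatively by 0.9 — which preserves the support exactly —
and if shrinkage would push any magnitude more than 0.02 outside the
band, the support is redrawn rather than silently collapsing strengths;
100 failed attempts raise.

**What the simulations do not show.** The generator reproduces marginals
and a Gaussian-copula dependence structure, not the real instruments'
item-level structure, informative missingness, rater effects, or the
two-form discrepancy construction behind the awareness score. Passing
recovery tests therefore validate the statistical machinery under the
stated model, not the clinical conclusions of any particular dataset.

## Verification problem sizes

The acceptance checks run at the study scale: estimator algebra against
an independent numerical optimizer (50 random instances, p ≤ 5), LOOCV
against a naive double loop, partial correlations against
regression-residual correlations, null calibration and edge recovery at
n = 215/p = 20 over 50 simulations, stability separation over 20
replicate experiments of 200 reruns each, and full-pipeline determinism
at B = 200. The acceptance script reports replicate means at slightly
smaller counts (25) to keep a single run fast; both counts give
Monte-Carlo errors well inside the asserted margins.

## Known limitations

* The chained-equations scheme uses linear models throughout; strongly
  nonlinear conditional relations are only captured through the rank
  transform downstream, not in imputation.
* η₀ is capped at 1 and estimated from a fixed 75th-percentile window;
  with very dense true graphs (most pairs non-null) the empirical null is
  biased toward absorbing signal, making edge selection conservative.
* Eigenvector centrality on disconnected retained graphs scores
  non-dominant components 0 (see above); compare degree and betweenness
  when components matter.
* LOOCV refits n times per grid point; at n in the thousands a k-fold
  variant (not provided) would be preferable.
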