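# Methods

This note documents the models, the numerical choices, and the open design
decisions behind `medomics`, and states what the synthetic-data generators
do and do not emulate.

## Preprocessing

Exposure harmonization divides cord-blood total-mercury concentrations by
1.7, the cord:maternal whole-blood partition ratio, so cohorts that only
measured cord blood are comparable to those with maternal samples.
Exposure and continuous outcome are then scaled to mean 0, SD 1 *within
each cohort* (n−1 denominator throughout), which removes cohort-level
location/scale differences from both ends of the mediation path. Omics
features are replaced by their **internally studentized** residuals from
`feature ~ covariates` — e_i/(s·√(1−h_ii)) — then re-projected orthogonal
to the covariate design and z-scored. The extra projection exists because
studentization is not a linear projection: without it, features would
retain O(leverage-spread) correlation with the covariates. A consequence is
that the operation is exactly idempotent only on constant-leverage
(balanced) designs; on general designs a second application changes values
by at most the leverage spread, which is negligible at n ≫ p but is a
documented approximation. Features missing in <5% of samples are
mean-imputed before residualization; more-missing or zero-residual-variance
features are dropped with a logged warning. Categorical covariates are
dummy-coded against the lexicographically first level. An optional
`log_exposure` flag covers right-skewed exposures; it is off by default
because the scaling conventions downstream are defined on the raw scale.

## Total effect and sensitivity analyses

γ is the OLS coefficient of exposure with Wald CIs using t critical values
(small-sample correct). Forward covariate selection follows the 10%
change-in-estimate rule: at each step the candidate producing the largest
relative change in γ is added if |Δγ|/|γ| > 0.10 (ties break
lexicographically; when γ ≈ 0 the absolute change is used and logged).
Fixed-effects meta-analysis is inverse-variance pooling with Cochran's
Q = Σ w_i(b_i − pooled)² on χ²(groups−1). The robustness value is computed
from the partial Cohen's f = q·|t|/√df as RV = ½(√(f⁴+4f²) − f²), reported
for q = 1 (full nullification): the minimum partial R² an unmeasured
confounder needs with both exposure and outcome residuals to drive the
estimate to zero.

## Screening

The sure-independence-screening budget is ⌈2n/ln n⌉ rounded up to the
nearest multiple of five and divided across layers with a per-layer
ceiling; natural log is used (at n = 420 and five layers this yields 140
total, 28 per layer). Features are ranked within each layer by |α·β| —
α from `feature ~ exposure + covariates`, β from
`outcome ~ feature + exposure + covariates` (computed via
Frisch–Waugh–Lovell partialling, which is exact) — with the absolute value
taken so that negative mediation paths rank as highly as positive ones.
Ranking is deterministic; ties break by feature id.

## High-dimensional mediation

All three modes compute per-feature α by OLS and β from a penalized
outcome model in which exposure and covariates are unpenalized. The
penalty family is **lasso with an unpenalized OLS refit** of the selected
set; the refit debiases β and yields conventional SEs, preserving the
select-then-debias structure of MCP-based mediation procedures with a
simpler, well-tested optimizer. Unpenalized terms are profiled out exactly
by partialling them from the outcome and every feature before the lasso
(for quadratic loss this is equivalent to leaving them unpenalized in the
joint problem). The base penalty is chosen by 10-fold CV at the 1-SE rule
(fold assignment seeded). Per-feature p-values are joint-significance
(max of the α and β marginal p-values) with Benjamini–Hochberg correction
across the selected set; the **reported mediator set** (`significant`) is
the penalized selection pruned at FDR < 0.05, while `selected` records the
raw penalized support.

Intermediate integration multiplies the penalty by a per-layer factor
(group-lasso-type shrinkage, implemented by column scaling), tuned by
coordinate-wise search over the 5-point log grid {¼, ½, 1, 2, 4} against
10-fold CV error — the full grid is 5^L and becomes impractical beyond two
layers, and the coordinate search with two sweeps is deterministic and
testable. β SEs come from a nonparametric pairs bootstrap (B = 200 by
default; B < 50 warns) refitting the penalized model at the chosen penalty
on each resample, re-partialling within each resample. With all
multipliers forced to 1 the procedure runs the identical code path as
early integration, so the two modes coincide by construction. Late
integration applies the early procedure per layer with no cross-layer
conditioning, so correlated proxies of one latent mediator can be selected
in several layers at once.

Distribution-of-the-product CIs treat α̂ and β̂ as independent normals
(they come from different regressions on the same data; a correlation
input exists and defaults to 0 via independence). The CDF of A·B is
integrated by adaptive quadrature over A with breakpoints at the sign
change of A and at the CDF's fastest transition (critical when one SE is
tiny), then inverted by Brent's method; the implementation matches a
10^7-draw Monte-Carlo oracle within 0.005·(se_a|b| + se_b|a| + se_a·se_b)
per endpoint across the tested (a, b, se) grid.

## Latent-factor mediation

PCA keeps the smallest leading component set whose cumulative explained
variance *exceeds* the threshold (default 80%). The joint/individual
decomposition X_i = J_i + A_i + E_i centers each layer and scales it to
unit Frobenius norm (so wide layers cannot dominate the joint structure),
then alternates truncated SVDs: joint from the concatenated (X − A),
individual from each layer's residual projected orthogonal to the joint
score space. The residual objective is non-increasing and iteration stops
at a 1e-6 relative change or 100 iterations. Component signs are fixed by
making the largest-|loading| feature positive.

Rank selection ("permutation", 100 permutations, 95th percentile, seeded):
the joint rank counts observed singular values of the concatenated matrix
exceeding the null obtained by permuting sample order independently within
each layer (destroys cross-layer alignment, preserves within-layer
structure). Individual ranks are derived from each layer's **total**
within-layer signal rank — observed singular values against a null that
permutes every feature column independently — minus the joint rank,
clamped at zero. This uses the model identity
rank(layer signal) = r_J + r_i and deliberately avoids testing the
joint-fit residual, where the subtraction of an *estimated* joint
component leaves a rank-one leakage term that inflates false positives
(measured at ~9% per layer versus ~3% for this rule, with planted
individual factors still detected). The caveat: a layer on which the true
joint component has (near-)zero loading would have its individual rank
under-counted; with Frobenius-normalized layers and a genuinely joint
factor this does not arise.

Component mediation standardizes the scores and reuses the penalized
early-integration machinery — all components enter one outcome model
jointly, consistent with the high-dimensional procedure, rather than being
tested marginally (the open alternative). Two percent-mediated columns are
reported: `pct_te` = 100·αβ/γ per component, and `pct_te_scaled`, the
component's share of the summed indirect effect across FDR-significant
components (sums to 100%), which is the natural reading of "scaled"
component-level mediation summaries. Feature–component Pearson
correlations (with t-distribution p-values) are exported for every
applicable pair; features from other layers are flagged not-applicable for
layer-individual components, and constant features are flagged with
undefined r.

## Latent-cluster quasi-mediation

The generative model is X → L → (Z, Y): cluster membership L is
multinomial-logistic in the exposure; features are independent normals
given L with cluster-specific means and a **shared per-feature variance**
(diagonal covariance — the only tractable choice at omics dimensionality,
floored at 1e-6 to avoid collapse); in supervised fits the outcome is
normal with a cluster-specific mean. K = 2 clusters per layer by default
and no variable selection inside the cluster model. Covariates act only
through the upstream residualization/scaling; the cluster model itself
takes none.

EM details: initialization by seeded k-means (responsibilities softened to
0.95/0.05), five restarts keeping the best final log-likelihood; the
logistic M-step is a weighted multinomial fit on K-fold expanded samples,
warm-started from the previous iteration so each M-step ascends and the
observed-data log-likelihood is non-decreasing (asserted at 1e-8
tolerance); convergence at 1e-6 relative change or 500 iterations; an
empty cluster triggers re-initialization (up to 5 extra restarts) before
failing with diagnostics. Labels are anchored by ordering clusters on
outcome mean (supervised) or first-feature mean (unsupervised), with the
reference cluster's log-odds and outcome effect fixed at 0.

Parallel integration fits one cluster variable per layer jointly: layers
are conditionally independent given their clusters, the outcome is
additive in per-layer cluster effects (no cross-layer interactions — the
open alternative), and the E-step enumerates all K^m configurations (m >
10 layers at K = 2 is refused in favor of serial mode). With one layer the
code delegates to the early fit, so the reduction is bit-for-bit. Serial
integration chains single-layer fits, passing the non-reference-cluster
posterior inclusion probabilities of each fit as the next fit's exposure;
only the final fit is supervised. Cluster omics profiles are PIP-weighted
feature means, recomputed from the data (they equal the fitted means at
convergence) for auditability.

## Synthetic data

The generators emulate the *statistical* structure of a multi-cohort,
five-layer pediatric exposome study at desk scale: a continuous exposure
with cohort mean shifts, exchangeable block correlation within layers
(single ρ per block), sparse exposure→mediator→outcome paths plus a direct
effect ("mediation" mode), shared and layer-individual factors with the
exposure and outcome loading on a joint factor ("latent_factor"), and
exposure-dependent binary clusters shifting both features and outcome
("latent_cluster"). Default layer widths 500/300/100/36/177 preserve the
real layers' relative size ordering (≈4×10^5 CpGs down to 36 proteins)
while keeping full pipelines fast; the default n = 420 matches the
motivating study's analysis sample. All randomness flows from a single
seed and two calls with one spec are bitwise identical.

What the generators do **not** emulate: assay-specific marginals
(beta-value distributions, intensity effects), probe-level QC artifacts,
batch structure, non-linear or interactive effects, and missingness
mechanisms. Passing recovery tests therefore demonstrates correctness of
the estimators under the assumed generative structure, not robustness to
real-data pathologies.

## Problem sizes used in the automated checks

The test suite and acceptance script run planted-truth simulations at
n = 150–2000 with 20–140 features per layer and 25–100 replicates per
stochastic check — sizes chosen so each check's Monte-Carlo error is well
inside its decision margin while the whole battery stays fast on one CPU.
Stated thresholds (e.g. ≥80% rank recovery, ≥95% assignment accuracy,
±0.25 log-odds recovery) are properties of the estimators at those study
conditions, verified empirically.

## Known limitations

- The lasso+refit penalty family approximates, but does not replicate, MCP
  or empirical-Bayes penalty tuning in the cited tools; `penalty` is
  exposed for future families.
- Post-selection OLS SEs ignore selection uncertainty (standard in this
  literature; the bootstrap in intermediate mode partially accounts for
  it).
- The distribution-of-product CI assumes independent α̂, β̂.
- The cluster model's diagonal covariance ignores residual within-cluster
  feature correlation; strongly block-correlated layers can inflate
  cluster-separation confidence.
- Binary outcomes are accepted by the data model but the cluster and
  factor outcome models are implemented and tested for continuous
  outcomes.
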