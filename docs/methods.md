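# Methods

This note records the statistical models, parameter defaults, numerical
conventions and deliberate design choices behind `amlsig`, and what the
synthetic cohorts can and cannot certify about real data.

## Synthetic cohorts

The generator (`amlsig.simulate`) emulates the inputs of a small-trial
correlative study:

- **Counts.** Negative-binomial with log-linear means,
  log₂ μ_gj = b_g + β·PB_j·1[g confounded] ± δ·σ_g·1[g signature]·1[j responder].
  Baselines b_g ~ U(2, 9) (log₂ scale), dispersion 0.1 by default
  (biological replication in human cohorts; 0 gives Poisson).
- **Blast confounding** enters as a continuous covariate loading
  (β, default 1.5 log₂ units at PB = 1) on a designated gene block
  (default 30% of the universe), not as an explicit cell-type mixture:
  it is the simplest structure the PC-removal stage must detect. Blast
  fractions default to Beta(1.3, 3.5) draws — median ≈ 0.25 with a long
  right tail, matching the spread seen in relapsed/refractory AML blood.
  Healthy-donor-like samples are emulated by blast fraction 0.
- **Response classes.** Default cohort n = 32 with a 17/32 responder
  fraction. The signature effect δ is a *standardized* shift: it is
  multiplied by each gene's delta-method log₂-scale noise SD
  σ_g = √(1/μ_g + φ)/ln 2, so δ = 1.5 means Cohen's d ≈ 1.5 per signature
  gene regardless of expression level. Default 10 signature genes with
  random effect directions.
- **Gene sets.** Curated collections are redundant — the same expression
  program is reported by many overlapping sets — so the generator plants,
  per effect direction, one pure signature set plus several partial
  variants (≈70% of the direction's genes plus random padding) among
  uniform random sets. A set mixing up- and down-shifted genes would
  cancel in any rank-walk statistic, which is why direction matters.
- **Mutations.** Per planted gene, the mutation probability interpolates
  between its two class rates along the sample's continuous response
  probability (the "SRSF2"-like driver rises from 0.05 to 0.55); null
  genes mutate at class-independent rates; one gene has expected count 1
  to exercise the ≥3-recurrence filter.

What passing tests on these cohorts do **not** show: robustness to
cell-type mixtures more complex than a single continuous loading, to
batch effects, to count matrices quantified with different pipelines, or
to label noise beyond the simulated non-evaluable fraction.

## Preprocessing

Library-size normalization is median-of-ratios against a geometric-mean
reference over genes positive in every sample; size factors are rescaled
to geometric mean 1, which preserves the counts scale and makes the
operation idempotent. The variance-stabilizing transform is the shifted
log, log₂(x + c) with prior count c = 1: the downstream stages are
rank-based (gene-set scores, Blom) or PC/variance-based, and need only a
monotone variance-flattening map, not a dispersion-trend parametric
transform. The Blom transform uses the classical 3/8 offset,
Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties; an all-tied vector
maps to zeros with a warning.

## Blast correction

PCA is taken by SVD of the gene-centered matrix with samples as
observations. R² is the squared Pearson correlation between each PC's
per-sample score and the blast fraction (equal to simple-regression R²);
a zero-variance PC scores 0. The removal count is the knee — maximum
perpendicular distance to the first–last chord — of the cumulative sorted
R²×POV curve, anchored at 0 so a single dominant PC is detectable. When
the blast covariate is constant, or the curve is flat (distance < 1e−12),
nothing is removed and the input is returned with a warning: silently
removing a PC absent evidence of confounding would destroy signal.

A documented hazard of the weighted-POV rule: a very-high-variance PC with
negligible blast correlation (e.g., a strong disease-class axis) can
out-rank genuinely blast-linked PCs and be removed, especially when the
class and blast variables are correlated in the draw. This is intrinsic
to the method, not to this implementation; it is why the correction is
toggleable in the pipeline and why its report lists per-PC R², POV and
the removal decision for inspection.

## Gene-set scores and consensus clustering

The per-sample score is a rank-weighted KS walk over the sample's
descending expression ranking: hit steps proportional to the linearly
decaying rank weight (n − r + 1) normalized over in-set genes, miss steps
uniform over the complement; the score is max(walk) + min(walk)
(max-deviation form, range [−1, 1]). It is invariant to monotone
transforms of a sample's values. This is a deliberate surrogate for the
ECDF-kernel formulation of gene-set variation analysis: scores are used
downstream only as clustering inputs, and the contract (rank-based,
direction-signed, set-size normalized) is what the tests pin down.

Consensus clustering follows the Monti resampling scheme: default 1000
resamples at subsample fraction 0.8, hierarchical clustering with
Euclidean distance and average linkage inside each resample (the
conventional defaults; the in-resample algorithm is configurable since no
single choice is canonical), consensus = co-cluster count / co-sample
count, final labels by average-linkage clustering of 1 − consensus cut at
k = 2. Label reassignment names the cluster holding the majority of raw
bone-marrow responders as the consensus responder class; ties break
toward the cluster with higher mean item consensus among raw responders
(logged).

## Moderated t and preranked GSEA

Per gene, pooled two-group residual variance s² with d = n₁ + n₂ − 2
degrees of freedom is shrunk to s²ₚₒₛₜ = (d₀s₀² + d s²)/(d₀ + d). The
prior (d₀, s₀²) is fitted by moment matching on z = log s² across genes:
the excess of var(z) over trigamma(d/2) identifies trigamma(d₀/2)
(inverted by Newton iteration), and the mean of z identifies s₀².
Non-positive excess variance yields d₀ = ∞ (complete shrinkage, normal
reference distribution); `prior_df=0` recovers the ordinary t exactly.
p-values use d₀ + d degrees of freedom; genes constant in both groups are
reported as t = 0, p = 1. The GSEA ranking metric is the signed
significance score log₂FC × −log₁₀ p.

Preranked GSEA uses weight exponent 1 (hit increments ∝ |score|, uniform
miss decrements), enrichment score = running-sum value of maximum
magnitude. Exact magnitude ties between the positive and negative
extremes are resolved by first occurrence. Significance is by gene-label
permutation — sample permutation does not exist for a preranked list —
with each observed score referred to its same-sign permutation tail,
which keeps null p-values uniform; BH adjustment runs across analyzed
sets. The leading edge is the in-set genes at or before the peak
(positive scores) or at or after the trough (negative). The feature pool
is the union of leading edges over sets with adjusted p below α = 0.05,
intersected with the external cohort's gene universe, ranked by |signed
score| and truncated at the knee of the decay curve; a knee-less
(near-linear) curve keeps the whole pool.

## Nested boosted signature

The split plan is frozen up front: 100 stratified 80/20 train/hold-out
partitions (stratification keeps both classes in every 6–7-sample
hold-out, a deliberate refinement of plain random splitting at n = 32),
serialized and reused by every stage, with hold-outs untouched until
final evaluation. Feature selection runs two rounds of boosted fits on
random stratified 80/20 sub-splits of each inner set (20 per inner set by
default), ordering genes by mean total split gain with absent features
counting 0.

Selection-round boosters are pinned to a randomized-subspace stump
configuration: depth-1 trees, η = 0.1, `colsample_bytree` = 0.15, 300
rounds, early stopping against the sub-split's validation portion. The
rationale: with a few dozen samples and hundreds of candidates, greedy
deep trees let one strong gene absorb all gain and mask its equally
informative peers, making gain a poor ranking statistic; shallow additive
trees over random feature subspaces spread gain across every marginally
informative gene. This configuration was validated on synthetic cohorts
for recovery of planted signature genes. Tuned hyperparameters apply to
the final ensemble only, not to the selection rounds — ranking stability
is worth more there than per-dataset fit.

Tuning maximizes mean ROC AUC over repeated stratified CV (5 × 4); ties
break toward smaller depth, then lower learning rate. The final ensemble
fits cv_folds × cv_repeats models per outer pair (2000 at defaults),
each recording CV-fold and hold-out metrics; the model-count invariant is
enforced. Prediction pools each sample's per-model probabilities into a
Gaussian KDE (Silverman bandwidth, 1001-point grid on [0, 1]); the mode
calls a responder iff it exceeds 0.5 — a boundary mode of exactly 0.5 is
a non-responder.

Reduced plans used in tests cut the outer-split count and round-1 reps
(10 outer splits, 5 reps); round 2 operates on 50 genes and keeps its
full 20 reps, which is cheap there and stabilizes the final ranking.

## Mutation association

The recurrence filter keeps genes mutated at least 3 times (idempotent by
construction). Elastic-net selection (mixing 0.5 by default) picks the
penalty by the one-standard-error rule on the cross-validated error path,
falling back to the CV-minimum penalty if everything is zeroed (logged).
Boosted selection ranks genes by total gain of a squared-error boosted
regression and cuts at the knee of the gain curve (a fixed top-k override
exists, since no principled count is canonical). The union of both
selections enters one joint OLS fit with intercept; duplicated indicator
columns are dropped with a warning. The group test reports the Pearson
χ² (df = 1) both with and without Yates continuity correction.

## Exact 2×2 inference

All conditional quantities are computed from log-space central
hypergeometric weights log C(r₁, k) + log C(n − r₁, c₁ − k) + k·log ψ,
normalized by logsumexp — stable across the ψ range explored. The
two-sided Fisher p sums probabilities ≤ the observed one, with a 1 + 1e−7
relative tolerance guarding floating-point ties (the common convention).
The CMLE solves E[A | margins, ψ] = a by Brent root-finding on log ψ over
[−50, 50] (xtol 1e−12); a at the support minimum/maximum gives ψ̂ = 0/∞.
Confidence limits invert the one-sided exact tails at α/2 per side with
the same boundary conventions; at these tolerances the returned limits
satisfy the defining tail equations to ~1e−10, which can differ in the
second decimal from implementations using looser root-finders. Standard
(not mid-) p-values are used throughout. The crude odds ratio ad/bc is
reported alongside for transparency.

## Pipeline

Stages run in the order: normalize → VST → blast-correct (toggleable) →
gene-set scores → consensus cluster → moderated t + GSEA → feature pool →
Blom → nested ensemble → predict → mutation association (toggleable) →
exact 2×2 statistics. One global seed is expanded through
`numpy.random.SeedSequence.spawn` into independent per-stage seeds (all
< 2³¹), recorded in the run manifest together with package version and
per-stage summaries; reruns with the same configuration are byte-identical.
TSV is the interchange default, with MTX for sparse matrices, GMT for gene
sets, and long-form TSV for mutations.

## Known limitations

- The weighted-POV correction can remove a class axis when class and
  blast fraction are correlated in the cohort (see above).
- At n = 32, two-round gain selection operates near the information
  limit: in a typical draw with per-gene d = 1.5, one or two of ten
  planted genes fall below the top noise order statistics of ~500
  background genes, so perfect recovery is not attainable by any marginal
  ranking.
- Permutation p-values are floored at 1/(1 + same-sign permutations);
  significance thresholds must respect the chosen permutation count.
- The ensemble reuses cohort samples across outer pairs; hold-out metrics
  are honest per pair but not independent across pairs, and training-set
  recall is expected to be optimistic.
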