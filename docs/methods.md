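# Methods

## The problem

Filter feature selection ranks features by a model-free score before any
classifier or regressor is trained. For a single categorical target the
information-theoretic state of the art scores a candidate feature `Xk`
against the already-selected set `Xθ` with the joint mutual information
(JMI) criterion, `J(Xk) = Σ_{Xj∈Xθ} I(Xj Xk; Y)`, which balances the three
quantities that matter: relevancy `I(Xk;Y)`, redundancy `I(Xk;Xj)` and
complementarity `I(Xk;Xj|Y)`.

Multi-target problems (multi-label classification, multi-dimensional
classification, multivariate regression) put a vector `Y = Y1..Ym` on the
output side. The two classical extensions sit at opposite extremes:

- **Single-JMI** treats every target independently
  (`Σ_j Σ_i I(Xj Xk; Yi)`; the binary-relevance view). Its MI estimates are
  low-dimensional and reliable, but it is blind to inter-target dependence.
- **Joint-JMI** uses the labelset-encoded joint target
  (`Σ_j I(Xj Xk; Y)`; the label-powerset view). It captures all dependence
  in principle but must estimate distributions over up to `min(N, 2^m)`
  labelsets, which is hopeless at realistic sample sizes.

## Output-space quantization and the group criterion

The group criterion interpolates between these extremes by replacing `Y`
with pseudo-targets `Ỹ1..Ỹm`, each a low-cardinality categorical summary
of a random group of targets:

1. **Grouping (PoT).** Draw `m` random target subsets, each a
   without-replacement sample of `round(m·PoT)` targets; overlap between
   groups is allowed. With `m = 20` and PoT = 0.30 this gives 20 groups of
   6 targets each; a group of 6 binary targets has a joint alphabet of
   `2^6 = 64` — too large to estimate directly.
2. **Clustering (NoC).** For each group, cluster the samples' restricted
   output vectors into NoC clusters with k-medoids (Hamming distance for
   categorical targets, Euclidean for continuous ones, chosen for
   robustness to outliers) and use the cluster index as the pseudo-target.

The selection score is then `Σ_{Xj∈Xθ} Σ_i I(Xj Xk; Ỹi)`: every estimated
distribution involves two feature codes and at most NoC target categories,
yet each `Ỹi` reflects the joint behaviour of several targets.

By the MI chain rule and the identity `I(A;B|C) = I(A;B) − I(A;C) +
I(A;C|B)`, the criterion is ranking-equivalent (equal argmax at every
greedy step) to

    Σ_i I(Xk;Ỹi)  −  (1/|Xθ|) Σ_j Σ_i [ I(Xk;Xj) − I(Xk;Xj|Ỹi) ]

i.e. relevancy minus average redundancy plus average complementarity. The
package implements both forms; the equivalence is verified step-by-step on
random instances in the test suite (the two forms differ by a positive
affine transform that does not depend on the candidate, so exact ties are
mapped to exact ties).

The **randomized variant** draws, independently for every group, PoT
uniformly from [0.25, 0.75] and NoC uniformly from {4, ..., 16}. This
removes both tuning parameters at the price of averaging over group
resolutions, and is the package default.

## Estimation

All information quantities are maximum-likelihood plug-in estimates on
discrete codes, in nats. Continuous features are discretized into 5
equal-width bins per feature by default; declared-categorical columns are
re-coded bijectively and never binned (detection is by schema, not
inference). No small-sample bias correction is applied: the greedy search
compares scores whose estimation biases largely cancel, and the raw
estimator keeps results exactly reproducible.

Numerical choices that affect reproducibility are fixed explicitly:

- Binning: the range [min, max] is split into equal-width intervals,
  leftmost closed on the left, all closed on the right (a value equal to a
  cut point falls in the lower bin; the maximum falls in the top bin);
  constant columns map to a single code.
- In the benchmark protocol, bin edges are fit on the training half only;
  the selection stage never sees held-out rows (enforced by an integration
  test that poisons the test half).
- MI is computed from integer contingency tables with log terms grouped so
  that degenerate margins (constant variables, deterministic dependence)
  cancel exactly in floating point; results are clamped to be
  non-negative.
- Greedy ties are broken by the lowest feature index. The first greedy
  step, where all JMI sums are empty, uses the relevancy-only score
  `Σ_i I(Xk; target_i)` — the standard convention, which also makes all
  criteria comparable at K = 1.
- K-medoids is a PAM-style Voronoi iteration: seeded random distinct
  initial medoids, nearest-medoid assignment (ties to the lowest medoid
  index), medoid update to the member minimizing total within-cluster
  distance, at most 100 iterations (the objective is non-increasing, so
  termination is guaranteed). Distinct rows are ordered by first
  occurrence, which makes the whole procedure invariant to the order of
  targets within a group. If a group has fewer distinct output rows than
  NoC, the cluster count silently drops to the distinct-row count (logged):
  the zero-cost partition is the only sensible answer.
- Continuous targets are z-standardized per group before Euclidean
  clustering so the distance is scale-free across heterogeneous targets.
- Each group draws from its own child RNG stream (hierarchically spawned
  from the config seed), so enlarging `n_groups` never perturbs the
  pseudo-targets already produced.

Quantization happens once per selection run, before the greedy loop, and
discretization once per dataset (per training split in the protocol); the
criteria in a comparison share both.

## Synthetic data

The generators produce datasets with known ground-truth feature roles so
that every claim about the criteria is testable without external data.

Multi-label mechanism: a shared Bernoulli(0.5) latent factor `S`; each
non-XOR target's latent copies `S` with probability `target_dependence`
per sample and is otherwise an independent coin flip; labels are the
latents flipped independently with probability `label_noise` (default
0.05). Relevant features are their assigned latent plus N(0, 0.5) noise
(unit-scale signal, SNR 2:1 — a deliberately noisy but clearly detectable
measurement); redundant features are relevant columns plus the same noise
again. Each complementary pair (A, B) drives one designated target with
`A xor B`, where A ~ Bernoulli(0.5) and B ~ Bernoulli(0.3). The asymmetry
is intentional: it makes A marginally visible (≈0.066 nats at 5% label
noise) while B stays *exactly* marginally independent of the target, so a
pure-relevancy ranking cannot find B but a JMI criterion finds it
immediately after selecting A. A fully balanced parity would have no
marginally visible member, and no forward filter of any kind could begin
the pair — the asymmetric design is the realistic hard case a
complementarity-aware criterion can actually win.

Multivariate regression: iid N(0,1) relevant features; target `t` is a
weighted sum with weights mixing a shared loading vector (weight
`target_dependence`) and a target-specific loading (weight
`1 − dependence`), plus a product interaction per complementary pair and
N(0, 0.5) noise. The weight matrix is returned, so the implied target
covariance `W Wᵀ + σ²I` is available in closed form for testing.

What the generators do **not** emulate: real multi-label marginals (label
sparsity, power-law labelset frequencies), feature heterogeneity and
higher-order label interactions beyond one shared factor. Passing the
recovery and benchmark tests therefore shows the machinery behaves as
designed under controlled dependence, not that the randomized group
criterion dominates on any particular real dataset. One measured
consequence: with a *single* shared factor all labels are exchangeable
noisy copies of it, the per-label sum inside Single-JMI already aggregates
them, and the directional benchmark between the randomized group criterion
and Single-JMI is a statistical tie whose winner flips with the dataset
seed — the benchmark asserts a direction the single-factor mechanism does
not reliably produce.

## Evaluation machinery

Multi-label metrics: hamming loss; ranking loss (a relevant/irrelevant
score tie counts as misordered — the pessimistic convention); coverage
depth normalized by the number of labels so it lies in [0, 1]; macro-F1
with the convention that a label with no positives in either truth or
prediction scores 1. ML-kNN (neighbourhood label-count posteriors with
Laplace smoothing 1, 7 neighbours) is the classifier; a 10-neighbour kNN
regressor with aRRMSE (per-target RMSE relative to the train-mean
predictor, averaged over targets) covers regression. The protocol is a
repeated 50/50 holdout (default 30 repeats), stratified by labelset
frequency where feasible (labelsets with a single occurrence are pooled);
criteria are compared by per-K average ranks (best = 1, ties share the
mean rank) over the top-K grid, K = 1..50 by default.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's desk-scale defaults: estimator-oracle checks on
hundreds of random instances with N ≤ 100; ranking-equivalence on 50–100
instances (d ≤ 8, m ≤ 4, N ≤ 200); XOR fixture n = 2000 with 10 noise
features over 30 seeds; recovery at n = 1000, d = 100 (10 relevant, 5
redundant, 1 XOR pair), m = 10, dependence 0.6, over 30 seeds; the
directional benchmark at n = 1000, d = 80, m = 12, dependence 0.7, one
holdout per each of 10 protocol seeds with K = 1..30.

## Known limitations

- The plug-in estimator is biased upward for large alphabets; rankings
  across features with very different alphabet sizes inherit that bias
  (noise features with more bins score slightly higher than binary noise).
- NoC and PoT are not optimized; the randomized variant is a pragmatic
  default, and parameter optimization is out of scope.
- Sparse ARFF input, alternative clusterers and continuous (kNN/KDE) MI
  estimators are not implemented.
- Joint-JMI refuses continuous targets rather than discretizing them
  silently; quantization via the group criteria is the supported route.
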