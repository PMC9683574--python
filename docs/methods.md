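# Methods

This note documents the model, the estimators, the synthetic benchmark and
the numerical choices behind `shapaal`, in enough detail to audit or extend
any of them.

## Problem setting and training objective

We classify univariate time series x ∈ R^T with labels y ∈ {1..C} from a
fixed training split of N instances, with N small (tens to low hundreds).
The classifier h_θ is trained by empirical risk minimization with the
cross-entropy loss over softmax outputs. When N is small the empirical
distribution is far from the data distribution, so two corrections are
applied: input-space augmentation by controlled Gaussian perturbation, and
Shapley-based removal of non-contributing training samples.

## Perturbation model

Training inputs are replaced by x + δ with δ i.i.d. per entry from
α·N(μ, σ²); μ and σ² are the scalar mean and variance pooled over *all*
N·T entries of the raw training matrix. Defaults:

* α = 0.020 — dimensionless noise scale; small enough to keep a high
  signal-to-noise ratio, large enough to populate the neighborhood of each
  training point. α = 0 reduces the entire pipeline bit-for-bit to its
  unperturbed counterpart (zero noise is added as an exact zero matrix and
  no RNG state is shared with the trainer).
* Resampling policy `per_instance_once` (default): one δ per training
  instance for the whole fit. `per_instance_per_epoch` redraws δ on the raw
  inputs every epoch and re-normalizes; it is exposed as an option because
  the resampling cadence is a genuinely open design choice.

Order of operations is perturb **then** z-normalize. The same perturbed
signal x + δ feeds both the convolutional path and the shortcut of every
residual block — there is no second noise source inside the network. Test
inputs are never perturbed. The worst-case (adversarial max over δ) version
of the objective is intentionally not implemented; sampled Gaussian noise is
the supported surrogate.

RNG: numpy's PCG64 (`default_rng`), seeded explicitly everywhere; every API
that draws randomness takes a seed.

## Normalization

z-normalization uses scalar statistics pooled over all entries of the
training matrix — not per-series or per-timestamp vectors — because only a
pooled scalar pair transfers cleanly from the training to the test split.
The standard deviation uses the population (divide-by-N) convention, fixed
so tests are bit-stable. Below a std floor of 1e-12 normalization raises
instead of dividing. Test data is normalized exclusively with its paired
training statistics (enforced by a name-pairing check); per-series
normalization is deliberately not offered as a default path.

## Network

Input reshape T → T×1 single-channel plane (so the 2-D convolution view of
the architecture is realized with k×1 kernels on univariate input), then
χ residual blocks, global average pooling, dense softmax head.

Each block: conv(k=8) → batch-norm → ReLU → conv(k=5) → BN → ReLU →
conv(k=3) → BN, summed with the shortcut (identity when channel counts
match, else 1×1 conv + BN), followed by an output ReLU. Kernel lengths are
clipped to T. This is the community time-series residual block; filter
count defaults to 64 per block and is fully configurable (the scaled-down
studies in the test suite use 6–8 filters).

Depth χ ∈ [2, 10] is chosen per dataset by a documented complexity proxy:
score = C · log(#distinct instances after exact deduplication), mapped
affinely from the (C=2, 20 instances) … (C=3, 200 instances) regime onto
[2, 10] and clamped. It is deterministic, duplication-invariant and
monotone in the score, and an explicit `n_blocks` overrides it. It is a
stand-in for distribution-aware elastic depth estimation, declared as a
proxy, not claimed equivalent.

Batch size: 2 when N ≤ 10, else min(ceil(N/10), 16). Learning rate fixed at
10⁻³, no schedule. The optimizer is Adam at that fixed rate (the rate is
the Keras-default convention this architecture family is normally trained
with); plain SGD is available via `optimizer="sgd"`. Epochs default to 500
with best-training-loss checkpoint restore; the scaled-down studies use
30–100 epochs. Training is plain numpy, single-threaded, and repeated runs
with the same seed produce bit-identical parameters; a non-finite loss
raises a divergence error carrying the epoch index.

## Sample valuation

Definition: the game v maps coalitions ψ of training-sample indices to a
real payoff with v(∅) = 0; every value function is shifted by its
empty-coalition evaluation so this normalization holds by construction.
The marginal contribution of sample n to ψ is Δ_v(n, ψ) = v(ψ∪{n}) − v(ψ),
and φ_v(n) is the factorial-weighted sum over coalitions, equivalently the
average of Δ over all N! orderings.

Two routes to φ are shipped, deliberately:

1. **Game-theoretic data valuation** (`retrain_value_fn` + exact or
   Monte-Carlo estimators): v_raw(ψ) is the accuracy on an evaluation set
   of a surrogate retrained on ψ; v_raw(∅) is the majority-class baseline.
   The default surrogate is 1-NN on Euclidean distance with the full
   distance matrix precomputed, which makes coalition evaluations cheap
   enough for permutation sampling at N ≈ 60 in seconds. When the
   evaluation set *is* the training set (declared with
   `allow_train_reuse=True`, and the pipeline's default when no held-out
   valuation split exists — the test split must never leak into valuation),
   the self-match is excluded, i.e. leave-self-out 1-NN; without this the
   trivial self-neighbor would make every sample look helpful. The full
   residual network is available as the expensive surrogate.
2. **Model attribution** (`model_attribution_values`): the practical
   shortcut — per-sample aggregation of input-feature attributions of the
   fitted augmented model, computed by integrated gradients of the
   true-class logit against a seeded background set (default
   min(N, 50) training instances, 8 midpoint path steps). By completeness
   the per-sample sum of attributions approximates
   logit_c(x) − mean_b logit_c(b). Aggregation to one scalar is the signed
   sum over time steps (sign-preserving, so the φ ≤ 0 rule stays
   meaningful); mean and true-minus-max-other are exposed as options.

Exact estimators: the subset-weight formula (cap N ≤ 12) and full
permutation enumeration (cap N ≤ 8) cross-check each other to 1e-9 and
satisfy efficiency to 1e-9 and the null-player axiom to 1e-12; above the
caps a feasibility error directs callers to the Monte-Carlo estimator,
which samples permutations, scans each left-to-right with one incremental
evaluation per prefix, and reports per-player standard errors (ddof=1).
Coalition evaluations are memoized per game on the sorted index tuple.

On sign behavior: the retrain game yields genuinely signed values (a sample
whose presence lowers held-out accuracy gets φ < 0), so the φ ≤ 0 discard
rule is directly meaningful. The attribution shortcut ranks mislabeled
samples below clean ones (verified on synthetic ground truth) but its
values are offset by the background baseline and, at desk scale where the
reference model can overfit every training point, typically stay positive;
quantitative discard studies in this package therefore use the retrain
game (`valuation="retrain_mc"`), while the attribution path remains the
architectural default and the documented practical shortcut.

## Subset selection and re-learning

Discard every sample with φ(n) ≤ 0. The boundary includes exact zeros: a
zero-valued player is a null player and contributes nothing. A strict-<
variant is available behind `threshold_rule="lt"`. If the rule would
discard everything, a guard keeps the single highest-valued sample per
class and flags the run loudly — an empty training set is never produced.

Re-learning always builds a fresh, re-initialized model of the same
architecture (no warm start from the augmented model) and draws fresh
perturbation noise (seeded) for the retained subset. The four ablation
variants are: M (plain fit), M_Shapley (subset selected from a valuation
that uses the unperturbed base model M as its reference), M_aug (perturbed
fit on all data), M_ShapAAL (full pipeline). All four are evaluated on the
identical clean test split under the identical training statistics.

## Metrics

* accuracy — exact-match fraction.
* MPCE — mean of per-class error rates over the C classes; classes absent
  from the truth vector are excluded with the denominator adjusted. The
  per-instance weighted form (each instance contributes its own class's
  error rate, i.e. classes weighted by frequency) is available behind
  `form="per_instance"`; the per-class mean is the default because it is
  the standard definition of the metric and the two coincide on balanced
  test sets, where default MPCE = 1 − accuracy exactly.
* learning gain (acc − acc_base)/acc_base, differential benchmark gain
  (acc − benchmark)/benchmark, training-insufficiency factor
  N_train/N_test.
* mode over seeds: accuracies rounded to 4 decimals, most frequent value,
  ties broken toward the larger value (reproducible and stated).

## Synthetic benchmark

Class templates are analytically simple so that a nearest-template oracle
classifier exists: sinusoids with class-specific frequency (c+1 cycles) and
staggered phase, or localized Gaussian bumps with class-specific centers.
Each instance is its class template plus i.i.d. N(0, noise_sd²) noise.
Defaults — N_train = 60, N_test = 120, T = 96, C = 2, noise_sd = 0.5 — sit
in the middle of the small-sample regime the method targets, with the test
split twice the training split (insufficiency factor 0.5). Mislabeling
flips exactly ⌊ρ·N_train⌋ training labels to a uniformly chosen wrong
class and records the flipped indices; test labels are never flipped.

Mislabeling is the synthetic stand-in for "negatively contributing"
samples: it gives exact ground truth for the discard rule's precision
(`enrichment_score`, whose random-discard baseline is ρ). What the
generator does **not** emulate: real ECG morphology, autocorrelated or
heteroscedastic noise, class imbalance, concept drift, variable lengths.
Passing synthetic studies therefore demonstrate the mechanics and the
qualitative ordering of the variants, not performance on any real archive
dataset; the CLI reads real UCR-dialect splits for that.

## Study sizes and determinism

The bundled studies run the reduced network (χ = 2, 6–8 filters, 30–100
epochs) on the default synthetic sizes; these are the package's chosen
desk-scale study conditions and are stated alongside every reported number
(`scripts/acceptance.py` records the problem size next to each value).
Exact Shapley checks use random games with N ∈ {3..8}; Monte-Carlo
calibration uses 6-player games at 5000 permutations; the discard study
uses ρ = 0.2, 10 generator seeds, 150 permutations; the ablation trend uses
10 training seeds with the mode aggregation.

Everything is deterministic given seeds: data generation, parameter
initialization, batch shuffling, noise draws, permutation sampling and
background selection all flow through explicitly seeded PCG64 generators,
and repeated runs produce byte-identical reports and manifest digests.

## Known limitations

* The depth heuristic is a proxy; it is not the elastic depth-estimation
  algorithm it stands in for.
* The attribution path's absolute sign depends on the background baseline
  and reference-model confidence (see above); its discard decisions at
  desk scale are conservative.
* Exact enumeration is capped (N ≤ 12 / N ≤ 8); beyond it only Monte-Carlo
  estimates with standard errors are available.
* The retrain game with the 1-NN surrogate values samples for a different
  learner than the network that is finally trained; this is the standard
  cheap-surrogate compromise of retrain-based data valuation.
* Multivariate or variable-length series and missing values are out of
  scope.
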