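# shapaal

Shapley-attributed augmented learning for small-sample time-series
classification.

## The problem

Sensor time-series classification tasks (ECG change detection, power-demand
identification, accelerometer surface typing, ...) routinely come with very
small fixed training splits — N between 20 and 200 labelled series of length
T up to a few hundred — while the test split is often larger than the
training split. Under that training-data insufficiency, empirical risk
minimization overfits: the empirical distribution is a poor stand-in for the
data distribution, and a handful of unhelpful or mislabeled training samples
can dominate what the model learns.

`shapaal` implements a three-stage remedy:

1. **Learn (augmentation).** Train a residual-network classifier whose
   training inputs are additively perturbed, x → x + δ, with
   δ ~ α·N(μ, σ²), where μ and σ² are the mean and variance of the training
   matrix itself and α (default 0.020) keeps the signal-to-noise ratio high.
   Because the perturbed input also feeds each residual block's shortcut,
   the identity connection becomes a *perturbation connection*:
   H(x+δ) = F(x) + x + δ. Perturbation happens before z-normalization, and
   the test split is always clean and normalized with the *training*
   statistics.
2. **Unlearn (valuation + discard).** Treat the N training samples as
   players in a transferable-utility game v: 2^N → R, v(∅) = 0, and compute
   each sample's Shapley value

   φ_v(n) = Σ_{ψ ⊆ N\{n}} |ψ|! (N−|ψ|−1)! / N! · [v(ψ∪{n}) − v(ψ)],

   the unique allocation satisfying efficiency (Σφ = v(N)), symmetry, null
   player and linearity. Samples with φ(n) ≤ 0 are null-or-harmful players
   and are discarded, leaving N_effective samples.
3. **Re-learn.** Train a fresh model of the same architecture on the
   perturbed retained subset and classify with it.

The network stacks χ ∈ [2, 10] residual blocks (chosen from the training-set
distribution), each with three convolution→batch-norm→ReLU stages of kernel
lengths 8/5/3, ends in global average pooling and a dense softmax trained
with cross-entropy, uses the batch-size rule
`2 if N ≤ 10 else min(ceil(N/10), 16)` and a fixed learning rate 10⁻³.

Shapley estimators provided: exact enumeration (two independent formulas
that cross-check each other), seeded Monte-Carlo permutation sampling with
standard errors, a retrain-based value function (held-out accuracy of a
surrogate, 1-NN by default, retrained per coalition), and a gradient-based
per-sample attribution of the fitted augmented model against a background
sample set. Evaluation metrics include test accuracy, mean per-class error
(MPCE), learning gain, training-insufficiency factor, differential benchmark
gain, and mode-over-seeds aggregation.

A seeded synthetic generator produces UCR-dialect datasets with known class
templates, Gaussian noise and a controllable fraction of flipped training
labels, so the discard rule can be validated against exact ground truth.

## Worked example

```python
import shapaal

spec = shapaal.SyntheticSpec(n_train=60, n_test=120, length_t=96,
                             mislabel_fraction=0.2, seed=3)
train, test, truth = shapaal.generate(spec)

cfg = shapaal.PipelineConfig(
    valuation="retrain_mc", n_permutations=150,
    model=shapaal.ResNetConfig(n_blocks=2, epochs=100, filters_per_block=8),
    seed=5,
)
model, ablation, metrics = shapaal.run_shapaal(train, test, cfg)
print(metrics)
print("discarded:", ablation.n_discarded,
      "enrichment:", shapaal.enrichment_score(ablation, truth))
```

prints

```
{'test_accuracy': 0.9916666666666667, 'mpce': 0.00847457627118644,
 'n_effective': 44, 'n_discarded': 16}
discarded: 16 enrichment: 0.6875
```

With 20% of the 60 training labels flipped, the null-player rule discarded
16 samples of which 68.75% were genuinely mislabeled (a random discard would
hit 20%), and the re-learned model classifies 99.2% of the 120 clean test
series correctly with an MPCE of 0.008.

The same study from the shell:

```bash
shapaal run --synthetic --mislabel-fraction 0.2 --seed 5 \
    --estimator retrain_mc --n-blocks 2 --epochs 100 --filters 8 \
    --out runs/demo
shapaal ablation --synthetic --mislabel-fraction 0.2 --seeds 1..10 \
    --variants M,M_ShapAAL --estimator retrain_mc \
    --n-blocks 2 --epochs 100 --filters 8 --out runs/study
```

Every run writes a `manifest.json` (config, seeds, version fingerprint,
output digests); re-running the same manifest reproduces the outputs byte
for byte.

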