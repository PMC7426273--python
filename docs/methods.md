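# Methods

## Problem setting

A classifier is trained sequentially on an ordered series of *contexts*
(tasks or episodes); during each context only that context's data are
available.  Three scenarios differ in what is asked at test time:

- **Task-IL** — task identity is given; the softmax is *multi-headed*
  (only the queried task's output units are active).
- **Domain-IL** — task identity is withheld but the output space is shared;
  all output units are always active.
- **Class-IL** — the output space spans all classes seen so far; the
  softmax is *single-headed* (all units of seen classes active).

"Active" is implemented exactly: the softmax normalizes over active units
only and inactive classes receive probability exactly 0.  Performance is
the average test accuracy over all contexts (Task-IL/Class-IL) or
transformations (Domain-IL) seen so far, evaluated after each context.

## Models and losses

The base network is a fully connected ReLU classifier (optionally preceded
by a frozen convolutional feature extractor) with one linear output unit
per class.  The generator is a symmetric VAE with a 100-unit Gaussian
latent layer by default (σ is parameterized as exp(log σ) with log σ
clamped to [−10, 10]).  The replay-through-feedback model adds a softmax
classification head to the final hidden layer of the VAE encoder; the
classification path never touches the decoder, so inference is unaffected
by the generative parameters (asserted in the tests by a zero-gradient
check).

Per-sample loss terms (all implemented in `bireplay.objectives`):

- classification: −log p(Y=y|x) over the active units;
- distillation: −T² Σ_c ỹ_c log p^T(Y=c|x) with soft targets ỹ produced by
  the frozen previous model at the same temperature (default T=2);
- latent: the KL divergence between the encoder posterior
  N(μ^(x), σ^(x)²I) and the prior.  With the standard-normal prior and with
  hard-labelled data under the Gaussian-mixture prior the KL is closed-form;
  with soft-labelled data it is estimated with a single reparameterized
  sample per datapoint.  A sign convention is enforced so every latent term
  is the *nonnegative* KL (single-sample estimates may dip below zero, but
  their expectation may not — both facts are tested against Monte-Carlo and
  quadrature oracles);
- reconstruction: summed binary cross-entropy over pixels (decoder output
  squashed to (0,1) by a logistic), or, for internal replay, the summed
  squared error between the frozen conv features of the input and the
  decoded feature vector;
- current/replay weighting: L_total = (1/N) L_current + (1 − 1/N) L_replay
  with N the number of contexts seen so far, so replay has weight 0 on the
  first context.

Mini-batch losses are means over samples.  One noise draw ε per datapoint
per iteration is shared between the reconstruction and latent terms.

## Replay generation

During context K, replayed samples are produced by *frozen copies* of the
generator and classifier stored at the end of context K−1 — never by the
live model (each batch carries a source-version tag asserted in tests).
Latents come from the standard normal, or, with conditional replay, from
the mode of an intended class drawn uniformly over seen classes; decoding
optionally applies the intended class's (or task's) gating mask; generated
inputs are then labelled by a feedforward pass through the frozen
classifier — hard argmax labels, or soft targets when distilling.  Which
output units are active during labelling follows the scenario: the intended
task's classes (Task-IL), all classes up to the previous context
(Class-IL), or all classes (Domain-IL).  During *training* on replayed
samples the active set follows the output-layer regime instead: Class-IL is
single-headed, so all classes seen so far are active and the replay targets
place zero mass on the current classes.  Conflating these two active sets
removes most of replay's protective effect; the distinction is covered by
the acceptance tests.

Learning without forgetting uses the same machinery but replays the
*current* inputs, soft-labelled by the frozen previous model.  The separate
generator of standard generative replay is itself trained with replay,
using the same 1/N weighting.

## Regularization baselines

- **SI**: per-parameter contributions ω_i accumulate (θ_after − θ_before)·(−g_i)
  every iteration, with g the gradient of the *full* training loss; at each
  context boundary Ω_i += ω_i / (Δ_i² + ξ) with damping ξ = 0.1, and the
  penalty is Σ Ω_i (θ_i − θ̂_i)² added with strength λ (often called c).
- **EWC**: the diagonal Fisher information
  F_ii = mean_x Σ_c p(c|x) (∂ log p(c|x)/∂θ_i)² is computed at the
  post-context parameters (exact per-sample loop; a subsample of the
  context's data can be configured for small runs, the full set is the
  default).  The per-context penalty carries a ½ factor; the *online*
  variant keeps a γ-decayed running Fisher sum (γ = 1 by default) and omits
  the ½ — the factor-of-two relationship between the two variants for a
  single consolidated context is asserted in the tests.
- **XdG**: a random X% of every hidden classifier layer is fully inhibited
  per task; valid only under Task-IL since the mask must be selected at
  test time.

Gated-unit counts are round-half-up of X/100 × width.  The optimizer
(ADAM, β₁=0.9, β₂=0.999) is re-instantiated at each context boundary;
cross-context moment carry-over is not modelled.

## Architectures and reference hyperparameters

For the published benchmark configurations: two hidden layers of 400 units
(split handwritten digits; 2000 for the 100-permutation and natural-image
protocols), latent dimension 100, 2000 iterations per context (5000 for
natural images), learning rate 1e-3 (1e-4 for the larger protocols), batch
128 (256), replay batch equal to the current batch.  The natural-image
feature extractor has five 3×3 conv layers (stride 1,2,2,2,2; channels
16–32–64–128–256; batch-norm + ReLU, no pooling), yielding exactly
256×2×2 = 1024 features on 32×32 RGB input — this identity is asserted
analytically in the tests.  Its mirror-image transposed-convolution stack
(4×4 kernels, stride 2, then a 3×3 stride-1 output layer) handles
pixel-level decoding of natural images.  The decoded *hidden* vector of
internal replay passes through a final ReLU so it shares the nonnegative
support of the post-ReLU conv features (a package choice; the source
configuration leaves this unspecified).  Channel-standardized natural-image
inputs are affinely remapped to [0,1] before the pixel-level binary
cross-entropy (another package choice: standardized values fall outside the
unit interval).

## Synthetic data generator

`generate_synthetic_set` emulates the statistical role the image benchmarks
play in the protocols: each class c has a fixed spatial template
0.5 + s·U_c (U_c a seeded standard-normal pattern, s = `class_separation`,
default 0.25) and images are the template plus pixel noise of standard
deviation `noise_sd` (default 0.1), clipped to [0,1].  Defaults are 8×8
grayscale, 100 training / 50 test images per class — small enough to train
in seconds, separable enough that joint training reaches perfect accuracy
(so any loss of accuracy in sequential training is attributable to
forgetting, not capacity).  What the generator does *not* emulate: object
structure, within-class style variation beyond isotropic noise, or
natural-image statistics.  Passing tests on this data therefore validate
the training logic, loss algebra and the qualitative orderings between
strategies, not full-scale benchmark accuracy; the reference
hyperparameters above are provided for real-data runs.

## Desk-scale experiment sizes

The qualitative replay experiments in the test suite use a 3-context,
2-classes-per-context Class-IL protocol on the synthetic data, networks
with two hidden layers of 100 units, latent dimension 16, 500 iterations
per context, current batch 128, and 5 seeded repetitions per
configuration.  Under these conditions: naive sequential training collapses
to the most recent context (earlier-context accuracy near zero), generative
replay retains all contexts, joint training bounds both from above,
shrinking the replay batch from 128 to 1 costs little, and the
reinitialize-before-each-context control (which must relearn everything
from replay alone) is significantly worse than continued training — the
orderings reported for the full-scale benchmarks.

## Generator-evaluation metrics

Samples generated at the hidden level cannot be embedded by an
image-pretrained scoring network, so all three measures use a task-matched
embedding classifier sharing the frozen conv stack of the trained models;
pixel-level samples enter at the bottom, hidden-level samples after the
conv layers, and features are tapped before the softmax head.

- modified IS = exp(mean KL(p(·|x_g) ‖ p̄)), bounded in [1, C]; both bounds
  are attained by constructed inputs in the tests.
- modified FID = ‖μ_r − μ_g‖² + Tr(Σ_r + Σ_g − 2(Σ_r Σ_g)^{1/2}); the
  matrix square root is computed from the eigendecomposition of the
  symmetrized product Σ_r^{1/2} Σ_g Σ_r^{1/2}, clipping tiny negative
  eigenvalues to zero (verified against a general-purpose matrix square
  root in the tests).
- precision–recall curves: pooled real+generated feature vectors are
  k-means-clustered (k = 20, seeded, repeated 10 times and averaged);
  α(λ) = Σ_ω min(λP(ω), Q(ω)), β(λ) = Σ_ω min(P(ω), Q(ω)/λ) over
  Λ = {tan(iπ/(2(m+1)))}.  The grid resolution m defaults to 999 (the
  defining construction leaves m open; 999 gives a smooth curve at
  negligible cost).

## Numerical choices and determinism

All computation runs in float64 on the package's own reverse-mode autodiff
engine; gradients of every operation are verified against central finite
differences.  Pixel probabilities are clipped to [1e−7, 1−1e−7] inside
logs; softmax and log-sum-exp computations subtract a per-row maximum.
Every stochastic component (initialization, data order, ε draws, prior and
replay sampling, mask creation, Fisher subsampling) draws from an
independent child generator spawned from the run seed, so toggling one
component does not shift another's stream; a run manifest plus seed
reproduces accuracy matrices bit-for-bit.  SEM over a single repetition is
reported as 0 with a warning rather than raising.

## Known limitations

- The engine is CPU/numpy: full-scale benchmark replication is possible but
  slow; the package's tested regime is the desk scale described above.
- SI importance is tracked for the main model's parameters (for
  replay-through-feedback that includes the whole merged network), not for
  a separate generator's.
- Task-free (boundary-free) continual learning, stored-data rehearsal
  beyond the LwF special case, and sequence replay are out of scope.
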