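# bireplay

Continual learning with **brain-inspired generative replay**: train a
classifier on a sequence of tasks or episodes *without storing past data*,
interleaving each new task's examples with samples produced by a learned
generative model of previous observations.

Artificial neural networks forget catastrophically: fine-tuning on new
classes destroys performance on old ones, and in the **class-incremental**
setting (the network must eventually separate *all* classes, though it only
ever observes a few at a time) regularization-based defences fail outright.
`bireplay` implements generative replay and its brain-inspired refinements
for researchers studying continual learning and for computational
neuroscientists modelling memory replay:

- **Replay-through-feedback (RtF)** — the generator is merged into the
  classifier: a symmetric VAE whose encoder doubles as the feedforward
  classification path, with a softmax head on the encoder's final hidden
  layer.
- **Conditional replay** — the standard-normal latent prior is replaced by a
  trainable Gaussian mixture with one mode per class,
  p<sub>χ</sub>(z) = Σ<sub>c</sub> p(Y=c) N(z; μ<sup>c</sup>, σ<sup>c2</sup>I),
  so specific classes can be generated on demand.
- **Gating based on internal context** — per class (or per task), a random
  X% of each hidden decoder layer is fully inhibited during the generative
  backward pass.
- **Internal replay** — hidden (post-convolutional) representations are
  generated and matched (squared error) instead of pixels, with a frozen
  pre-trained convolutional feature extractor.
- **Distillation** — replayed inputs carry temperature-softened soft targets
  from the previous model, trained with the T²-scaled cross-entropy.

All compared baselines are included under the same training engine: SI
(synaptic intelligence), EWC and online EWC (diagonal-Fisher penalties),
XdG (context-dependent gating of the classifier), LwF (learning without
forgetting), naive fine-tuning (None) and joint training (upper bound).
Per-sample losses follow the variational objective
L = L<sup>recon</sup> + D<sub>KL</sub>(q<sub>ϕ</sub>(·|x) ‖ p(·)), with the
current/replay weighting
L<sub>total</sub> = (1/N) L<sub>current</sub> + (1 − 1/N) L<sub>replay</sub>
for N tasks seen so far.  Generator quality is evaluated with
embedding-swapped metrics (modified Inception Score, modified Fréchet
distance, clustered precision–recall curves) so that pixel-level and
hidden-level samples share one embedding space.

Everything runs on a small self-contained numpy tensor engine with
reverse-mode automatic differentiation (`bireplay._autodiff`, `bireplay.nn`)
— no deep-learning framework is required.

## Worked example

Three episodes of two classes each, class-incremental, on the built-in
synthetic image generator:

```python
from bireplay import (SyntheticConfig, generate_synthetic_set,
                      build_split_protocol, ContinualLearner)

train, test = generate_synthetic_set(
    SyntheticConfig(n_classes=6, images_per_class_train=100,
                    images_per_class_test=50, image_size=8, seed=0))
protocol = build_split_protocol(train, test, 3, 2, scenario="class_il")

naive = ContinualLearner(protocol, method="none", hidden_layers=(100, 100),
                         iters=500, batch_size=128).fit(seed=0)
replay = ContinualLearner(protocol, method="gr", hidden_layers=(100, 100),
                          latent_dim=16, iters=500, batch_size=128).fit(seed=0)
print(naive.summary())
print(replay.summary())
```

The naive run prints

```
average accuracy over contexts seen so far:
  after context 1: 1.0000
  after context 2: 0.5000
  after context 3: 0.3333
final average accuracy: 0.3333
```

— catastrophic forgetting: after the third episode the network classifies
only the two most recent classes, so the average over all six classes falls
to chance-per-context (1/3).  The generative-replay run prints

```
average accuracy over contexts seen so far:
  after context 1: 1.0000
  after context 2: 1.0000
  after context 3: 1.0000
final average accuracy: 1.0000
```

— replaying generated samples of earlier classes preserves them without
storing a single image.  `res.accuracy_frame()` gives the full
accuracy-after-each-context matrix, `res.loss_frame()` the per-iteration
loss terms, and `res.generate_replay_samples(n)` draws what would be
replayed next.

The same runs are available from the shell:

```bash
bireplay train --method gr --contexts 3 --classes 6 --iters 500 \
               --batch 128 --seed 0 1 2 --out runs/gr
bireplay train --method bir --sweep ablation --iters 200 --out runs/ablation
```

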