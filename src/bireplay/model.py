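"""High-level modelling interface.

:class:`ContinualLearner` is constructed from a task protocol plus strategy
options; :meth:`ContinualLearner.fit` trains the network sequentially
through all contexts and returns a :class:`ContinualResults` object
carrying the accuracy trace, per-iteration loss diagnostics, the trained
model(s) and convenience methods (``summary``, ``plot``,
``generate_replay_samples``).

Example
-------
>>> from bireplay import SyntheticConfig, generate_synthetic_set
>>> from bireplay import build_split_protocol, ContinualLearner
>>> train, test = generate_synthetic_set(SyntheticConfig(n_classes=6))
>>> protocol = build_split_protocol(train, test, 3, 2, scenario="class_il")
>>> res = ContinualLearner(protocol, method="gr", hidden_layers=(100, 100),
...                        latent_dim=20, iters=200, batch_size=64).fit(seed=0)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datasets import TaskProtocol
from .networks import ConvStack
from .strategies import StrategyConfig, TrainOutput, generate_replay, train_sequence

__all__ = ["ContinualLearner", "ContinualResults"]


class ContinualLearner:
    """A continual-learning model specification bound to a task protocol.

    Parameters
    ----------
    protocol
        The ordered sequence of contexts to learn (split / permuted /
        synthetic), including the scenario it is run under.
    method
        '+'-joined strategy, e.g. ``"none"``, ``"joint"``, ``"gr"``,
        ``"bir"``, ``"bir+si"``, ``"ewc"``, ``"lwf"``, ``"xdg"``.
    conv_stack
        Optional frozen convolutional feature extractor (natural-image
        mode / internal replay).
    **options
        Any :class:`~bireplay.strategies.StrategyConfig` field
        (``iters``, ``batch_size``, ``hidden_layers``, ``reg_strength``,
        toggles ``rtf``/``conditional``/``gating``/``internal``/``distill``,
        ...).
    """

    def __init__(self, protocol: TaskProtocol, method: str = "bir",
                 conv_stack: ConvStack | None = None, **options):
        scenario = options.pop("scenario", protocol.scenario)
        self.config = StrategyConfig(method=method, scenario=scenario, **options)
        self.config.validate(has_conv=conv_stack is not None)
        self.protocol = protocol
        self.conv_stack = conv_stack

    def fit(self, seed: int = 0, verbose: bool = False) -> "ContinualResults":
        out = train_sequence(self.protocol, dataclasses.replace(self.config),
                             conv_stack=self.conv_stack, seed=seed, verbose=verbose)
        return ContinualResults(self, out)


class ContinualResults:
    """Results of sequentially fitting a :class:`ContinualLearner`.

    Attributes
    ----------
    accuracy_matrix : ndarray (n_contexts, n_contexts)
        ``[i, j]`` = test accuracy on context j+1 after finishing training
        on context i+1 (NaN above the diagonal).
    avg_accuracy : ndarray (n_contexts,)
        After each context, the mean test accuracy over all contexts so far
        (the paper-style headline trace).
    losses : list of dict
        Per-iteration loss-term values.
    """

    def __init__(self, learner: ContinualLearner, out: TrainOutput):
        self.learner = learner
        self.protocol = learner.protocol
        self.config = out.config
        self.seed = out.seed
        self.accuracy_matrix = out.accuracy_matrix
        self.avg_accuracy = out.avg_accuracy
        self.losses = out.losses
        self.model = out.model
        self.generator = out.generator if out.generator is not None else out.model
        self.prior = out.prior
        self.dec_masks = out.dec_masks
        self.xdg_masks = out.xdg_masks

    @property
    def final_average_accuracy(self) -> float:
        return float(self.avg_accuracy[-1])

    def accuracy_frame(self) -> pd.DataFrame:
        n = self.protocol.n_contexts
        return pd.DataFrame(
            self.accuracy_matrix,
            index=[f"after_ctx_{i}" for i in range(1, n + 1)],
            columns=[f"ctx_{j}" for j in range(1, n + 1)],
        )

    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.losses)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Continual learning results",
            "=" * 60,
            f"method:          {cfg.method} (scenario: {cfg.scenario})",
            f"contexts:        {self.protocol.n_contexts} "
            f"({self.protocol.kind} protocol, {self.protocol.n_classes_total} classes)",
            f"iters/context:   {cfg.iters}  batch: {cfg.batch_size}"
            + (f"  replay batch: {cfg.replay_batch_size or cfg.batch_size}"
               if cfg.base in ("gr", "bir", "lwf") else ""),
            f"seed:            {self.seed}",
            "-" * 60,
            "average accuracy over contexts seen so far:",
        ]
        for i, acc in enumerate(self.avg_accuracy, 1):
            lines.append(f"  after context {i}: {acc:.4f}")
        lines.append("-" * 60)
        lines.append(f"final average accuracy: {self.final_average_accuracy:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Average-accuracy trace after each context."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, len(self.avg_accuracy) + 1)
        ax.plot(x, self.avg_accuracy, marker="o", label=self.config.method)
        ax.set_xlabel("contexts trained")
        ax.set_ylabel("average accuracy (contexts so far)")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax

    def generate_replay_samples(self, n: int = 16, seed: int = 0):
        """Draw a replay batch from the final trained generator, labelled by
        the final model (what would be replayed by a hypothetical next
        context)."""
        toggles = self.config.resolved_toggles(has_conv=self.learner.conv_stack is not None)
        level = "hidden" if toggles["internal"] else "pixel"
        gate_by = "task" if self.config.scenario == "domain_il" else "class"
        rng = np.random.default_rng(seed)
        return generate_replay(
            self.generator, self.model, self.prior, n, self.protocol,
            self.protocol.n_contexts + 1, self.config, rng,
            masks=self.dec_masks, gate_by=gate_by, level=level,
            distill=toggles["distill"],
        )
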