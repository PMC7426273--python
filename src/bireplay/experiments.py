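"""Experiment orchestration: seeded repetitions, aggregation, and the
standard sweeps (addition/ablation of the replay modifications, replay
mini-batch size, generator size), with machine-readable outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    SyntheticConfig,
    TaskProtocol,
    build_permuted_protocol,
    build_split_protocol,
    generate_synthetic_set,
)
from .model import ContinualLearner, ContinualResults
from .strategies import StrategyConfig

__all__ = [
    "RunManifest",
    "run_experiment",
    "aggregate",
    "ablation_manifests",
    "replay_size_manifests",
    "generator_size_manifests",
    "build_protocol_from_spec",
]

_TOGGLES = ("rtf", "conditional", "gating", "internal", "distill")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: strategy configuration, a
    protocol description, and the seeds of the repetitions."""

    config: StrategyConfig
    protocol_spec: dict
    seeds: list[int] = field(default_factory=lambda: [0])
    label: str = ""
    out_dir: str | None = None

    def to_json(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "label": self.label or self.config.method,
            "config": cfg,
            "protocol": self.protocol_spec,
            "seeds": list(self.seeds),
        }


def build_protocol_from_spec(spec: dict) -> TaskProtocol:
    """Instantiate a protocol from its JSON-style description.

    Supported kinds: "synthetic_split" and "synthetic_permuted" (generated
    on the fly from a SyntheticConfig); real-data protocols are built
    directly through the datasets API."""
    kind = spec["kind"]
    syn = SyntheticConfig(**spec.get("synthetic", {}))
    train, test = generate_synthetic_set(syn)
    if kind == "synthetic_split":
        return build_split_protocol(
            train, test, spec["n_contexts"], spec["classes_per_context"],
            scenario=spec.get("scenario", "class_il"),
        )
    if kind == "synthetic_permuted":
        return build_permuted_protocol(
            train, test, spec["n_contexts"], pad_to=spec.get("pad_to"),
            seed=spec.get("permutation_seed", 0),
            scenario=spec.get("scenario", "domain_il"),
        )
    raise ValueError(f"unknown protocol kind {kind!r}")


def aggregate(traces: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of the mean (sd/sqrt(n)) per checkpoint.

    A single trace yields SEM 0 (with a warning): undefined statistically,
    but single-seed smoke runs should not crash."""
    arrs = [np.asarray(t, dtype=np.float64) for t in traces]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("all traces must have the same shape")
    stacked = np.stack(arrs)
    mean = stacked.mean(axis=0)
    if len(arrs) == 1:
        warnings.warn("SEM reported as 0 for a single repetition", stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = stacked.std(axis=0, ddof=1) / np.sqrt(len(arrs))
    return mean, sem


def run_experiment(manifest: RunManifest, conv_stack=None,
                   verbose: bool = False) -> dict:
    """Execute all seeded repetitions of a manifest.

    Returns {"results": per-seed ContinualResults, "mean": ..., "sem": ...}
    over the average-accuracy trace, and writes the manifest, per-seed
    accuracy CSVs and a JSONL loss log when an output directory is set."""
    protocol = build_protocol_from_spec(manifest.protocol_spec)
    learner = ContinualLearner(protocol, method=manifest.config.method,
                               conv_stack=conv_stack,
                               **{k: v for k, v in dataclasses.asdict(manifest.config).items()
                                  if k != "method"})
    results: list[ContinualResults] = []
    for seed in manifest.seeds:
        results.append(learner.fit(seed=seed, verbose=verbose))
    mean, sem = aggregate([r.avg_accuracy for r in results])
    bundle = {"results": results, "mean": mean, "sem": sem,
              "label": manifest.label or manifest.config.method}
    if manifest.out_dir:
        out = Path(manifest.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest.to_json(), fh, indent=2)
        for r in results:
            r.accuracy_frame().to_csv(out / f"accuracy_seed{r.seed}.csv")
            with open(out / f"losses_seed{r.seed}.jsonl", "w") as fh:
                for recd in r.losses:
                    fh.write(json.dumps(recd) + "\n")
        pd.DataFrame({"after_context": np.arange(1, len(mean) + 1),
                      "mean": mean, "sem": sem}).to_csv(
            out / "avg_accuracy_aggregate.csv", index=False)
    return bundle


def _with_toggles(config: StrategyConfig, method: str, **toggles) -> StrategyConfig:
    return dataclasses.replace(config, method=method, **toggles)


def ablation_manifests(base: RunManifest, has_conv: bool = False) -> list[RunManifest]:
    """The addition/ablation design: standard generative replay, GR with
    each modification added in isolation ('+'), brain-inspired replay, and
    BI-R with each modification removed ('-')."""
    manifests = []
    applicable = [t for t in _TOGGLES if t != "internal" or has_conv]

    def mk(label, method, **toggles):
        cfg = _with_toggles(base.config, method, **toggles)
        manifests.append(dataclasses.replace(base, config=cfg, label=label))

    mk("GR", "gr")
    for t in applicable:
        mk(f"GR+{t}", "gr", **{t: True})
    mk("BI-R", "bir")
    for t in applicable:
        mk(f"BI-R-{t}", "bir", **{t: False})
    return manifests


def replay_size_manifests(base: RunManifest, sizes=(1, 2, 4, 8, 16, 32, 64, 128)) -> list[RunManifest]:
    """Replay-quantity sweep: vary the replay mini-batch size while keeping
    the current-task mini-batch size fixed."""
    out = []
    for s in sizes:
        cfg = dataclasses.replace(base.config, replay_batch_size=int(s))
        out.append(dataclasses.replace(base, config=cfg, label=f"replay{s}"))
    return out


def generator_size_manifests(base: RunManifest, widths=(10, 100, 1000)) -> list[RunManifest]:
    """Generator-quality sweep: vary the width of the VAE hidden layers."""
    out = []
    for w in widths:
        cfg = dataclasses.replace(base.config, vae_hidden_layers=(int(w), int(w)))
        out.append(dataclasses.replace(base, config=cfg, label=f"vae{w}"))
    return out
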