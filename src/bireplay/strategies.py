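"""Sequential training engines for continual learning.

Implements the replay family (standard generative replay, brain-inspired
replay with each modification toggleable, learning-without-forgetting), the
regularization family (synaptic intelligence, elastic weight consolidation
and its online variant), context-dependent gating of the classifier (XdG),
and the naive (None) and joint-training baselines, together with
replay-batch generation from frozen post-task model copies.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from . import objectives as obj
from .datasets import TaskProtocol
from .networks import (
    Classifier,
    ConvStack,
    GatingMaskSet,
    GenerativePrior,
    RtfModel,
    VAE,
    classify,
    extract_features,
    make_masks,
    sample_prior,
)
from .nn import Adam, Module

__all__ = [
    "StrategyConfig",
    "ImportanceState",
    "ReplayBatch",
    "TrainOutput",
    "replay_active_set",
    "generate_replay",
    "train_sequence",
    "si_accumulate",
    "si_consolidate",
    "si_penalty",
    "ewc_penalty",
    "fisher_diagonal",
    "lwf_targets",
    "evaluate_protocol",
]

_REPLAY_BASES = {"none", "joint", "gr", "bir", "lwf", "xdg"}
_REGULARIZERS = {"si", "ewc", "online_ewc"}


@dataclass
class StrategyConfig:
    """Full configuration of a sequential training run.

    ``method`` is a '+'-joined combination of one base strategy
    (none / joint / gr / bir / lwf / xdg) and optionally one regularizer
    (si / ewc / online_ewc); a regularizer alone (e.g. ``"si"``) means
    regularized fine-tuning without replay.  The five replay modifications
    (rtf, conditional, gating, internal, distill) default to all-on for
    ``bir`` and all-off for ``gr`` and can be toggled individually.
    """

    method: str = "bir"
    scenario: str = "class_il"
    # replay-modification toggles (None = resolved from the method name)
    rtf: bool | None = None
    conditional: bool | None = None
    gating: bool | None = None
    internal: bool | None = None
    distill: bool | None = None
    # regularization hyperparameters
    reg_strength: float = 1.0  # lambda (called c for SI)
    si_xi: float = 0.1
    ewc_gamma: float = 1.0
    # distillation / gating
    temperature: float = 2.0
    gate_percent: float = 80.0
    xdg_percent: float = 80.0
    # optimization
    batch_size: int = 128
    replay_batch_size: int | None = None  # defaults to batch_size
    iters: int = 2000
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    # architecture
    hidden_layers: tuple[int, ...] = (400, 400)
    vae_hidden_layers: tuple[int, ...] | None = None
    latent_dim: int = 100
    # controls
    fisher_subsample: int | None = None
    reinit_each_task: bool = False
    reset_optimizer_per_task: bool = True
    eval_batch: int = 512

    def tokens(self) -> list[str]:
        return [t.strip().lower() for t in self.method.split("+") if t.strip()]

    @property
    def base(self) -> str:
        bases = [t for t in self.tokens() if t in _REPLAY_BASES]
        regs = [t for t in self.tokens() if t in _REGULARIZERS]
        unknown = [t for t in self.tokens() if t not in _REPLAY_BASES | _REGULARIZERS]
        if unknown:
            raise ValueError(f"unknown method token(s): {unknown}")
        if len(bases) > 1 or len(regs) > 1:
            raise ValueError(f"at most one base strategy and one regularizer: {self.method}")
        if not bases and not regs:
            raise ValueError("empty method")
        return bases[0] if bases else "none"

    @property
    def regularizer(self) -> str | None:
        regs = [t for t in self.tokens() if t in _REGULARIZERS]
        return regs[0] if regs else None

    def resolved_toggles(self, has_conv: bool) -> dict[str, bool]:
        base = self.base
        if base == "bir":
            defaults = dict(rtf=True, conditional=True, gating=True,
                            internal=has_conv, distill=True)
        else:
            defaults = dict(rtf=False, conditional=False, gating=False,
                            internal=False, distill=False)
        out = {}
        for key, default in defaults.items():
            val = getattr(self, key)
            out[key] = default if val is None else bool(val)
        return out

    def validate(self, has_conv: bool) -> None:
        base = self.base  # raises on malformed method strings
        if self.scenario not in ("task_il", "domain_il", "class_il"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if base == "xdg" and self.scenario != "task_il":
            raise ValueError("XdG requires task identity at test time (task_il only)")
        tog = self.resolved_toggles(has_conv)
        if tog["internal"] and not has_conv:
            raise ValueError("internal replay requires a (frozen) conv feature extractor")
        if base not in ("gr", "bir") and any(
            tog[k] for k in ("rtf", "conditional", "gating", "internal")
        ):
            raise ValueError("replay modifications apply only to gr/bir methods")


@dataclass
class ReplayBatch:
    """Inputs generated by the frozen post-previous-task models.

    ``level`` is "pixel" (inputs shaped like images) or "hidden" (decoded
    feature vectors).  Targets are hard class ids and, when distillation is
    on, additionally soft probability vectors.  ``source_version`` records
    which post-task snapshot produced the batch (always the previous one)."""

    inputs: np.ndarray
    level: str
    hard: np.ndarray
    soft: obj.SoftTarget | None
    intended_contexts: np.ndarray | None
    intended_classes: np.ndarray | None
    active_sets: list[tuple[np.ndarray, tuple[int, ...]]]  # (sample idx, active ids)
    source_version: int


@dataclass
class TrainOutput:
    accuracy_matrix: np.ndarray  # (n_contexts, n_contexts), NaN above diagonal
    avg_accuracy: np.ndarray  # after each context, mean over contexts so far
    losses: list[dict]
    model: Module
    generator: Module | None
    prior: GenerativePrior | None
    config: StrategyConfig
    seed: int
    dec_masks: GatingMaskSet | None = None
    xdg_masks: GatingMaskSet | None = None


# ---------------------------------------------------------------------------
# active sets

def replay_active_set(protocol: TaskProtocol, current_context: int,
                      intended_context: int | None = None,
                      scenario: str | None = None) -> tuple[int, ...]:
    """Output units active when labelling/learning a replayed sample.

    task_il: the classes of the context intended to be replayed;
    class_il: all classes of contexts up to the previously learned one;
    domain_il: all classes."""
    scenario = scenario or protocol.scenario
    if scenario == "domain_il":
        return tuple(range(protocol.n_classes_total))
    if scenario == "task_il":
        if intended_context is None:
            raise ValueError("task_il replay requires an intended context")
        return protocol.contexts[intended_context - 1].class_ids
    if current_context < 2:
        raise ValueError("replay is undefined during the first context")
    return protocol.classes_seen(current_context - 1)


def _current_active_set(protocol: TaskProtocol, context_id: int, scenario: str) -> tuple[int, ...]:
    if scenario == "task_il":
        return protocol.contexts[context_id - 1].class_ids
    if scenario == "domain_il":
        return tuple(range(protocol.n_classes_total))
    return protocol.classes_seen(context_id)  # single-headed: all seen so far


# ---------------------------------------------------------------------------
# SI / EWC importance bookkeeping

@dataclass
class ImportanceState:
    """Per-parameter importance bookkeeping for SI and (online) EWC."""

    xi: float = 0.1
    gamma: float = 1.0
    omega: dict = field(default_factory=dict)  # running SI contributions
    start: dict = field(default_factory=dict)  # theta at task start
    anchors: dict = field(default_factory=dict)  # theta-hat^(K-1)
    Omega: dict = field(default_factory=dict)  # consolidated SI importance
    fishers: list = field(default_factory=list)  # per-task diagonal Fisher
    fisher_anchors: list = field(default_factory=list)  # per-task theta-hat^(k)
    f_tilde: dict = field(default_factory=dict)  # running Fisher sum
    n_consolidated: int = 0

    def begin_task(self, named_params) -> None:
        for name, p in named_params:
            if not p.requires_grad:
                continue
            self.start[name] = p.data.copy()
            self.omega.setdefault(name, np.zeros_like(p.data))


def si_accumulate(state: ImportanceState, name: str, theta_before: np.ndarray,
                  theta_after: np.ndarray, grad: np.ndarray) -> None:
    """Add one training step's contribution: omega_i += delta_theta_i * (-g_i)."""
    state.omega[name] = state.omega.get(name, 0.0) + (theta_after - theta_before) * (-grad)


def si_consolidate(state: ImportanceState, named_params) -> None:
    """End of task: Omega_i += omega_i / (Delta_i^2 + xi); reset omega and
    update the anchors to the post-task parameters."""
    for name, p in named_params:
        if not p.requires_grad:
            continue
        delta = p.data - state.start[name]
        contrib = state.omega[name] / (delta**2 + state.xi)
        state.Omega[name] = state.Omega.get(name, 0.0) + contrib
        state.omega[name] = np.zeros_like(p.data)
        state.anchors[name] = p.data.copy()
    state.n_consolidated += 1


def si_penalty(named_params, state: ImportanceState) -> Tensor:
    """sum_i Omega_i (theta_i - theta-hat_i)^2 as a differentiable scalar."""
    if state.n_consolidated < 1:
        raise RuntimeError("SI penalty requested before any task was consolidated")
    total = Tensor(0.0)
    for name, p in named_params:
        if not p.requires_grad or name not in state.Omega:
            continue
        diff = p - Tensor(state.anchors[name])
        total = total + (Tensor(state.Omega[name]) * diff * diff).sum()
    return total


def fisher_diagonal(model, images: np.ndarray, active, subsample: int | None = None,
                    rng: np.random.Generator | None = None,
                    from_hidden: bool = False) -> dict[str, np.ndarray]:
    """Diagonal of the Fisher information at the current parameters:
    F_ii = mean_x sum_c p(c|x) (d log p(c|x) / d theta_i)^2."""
    if len(images) == 0:
        raise ValueError("Fisher estimation needs a non-empty data set")
    if subsample is not None and subsample < len(images):
        rng = rng or np.random.default_rng()
        idx = rng.choice(len(images), size=subsample, replace=False)
        images = images[idx]
    act = sorted(set(int(a) for a in active))
    named = [(n, p) for n, p in model.named_parameters() if p.requires_grad]
    fisher = {n: np.zeros_like(p.data) for n, p in named}
    for i in range(len(images)):
        x = images[i : i + 1]
        logits = model.logits(x, from_hidden=from_hidden)
        logp, _ = obj.log_softmax_active(logits, act)
        probs = np.exp(logp.data[0])
        for j in range(len(act)):
            model.zero_grad()
            logp_j = logp[0, j]
            logp_j.backward()
            for n, p in named:
                if p.grad is not None:
                    fisher[n] += probs[j] * p.grad**2
    model.zero_grad()
    for n in fisher:
        fisher[n] /= len(images)
    return fisher


def ewc_consolidate(state: ImportanceState, named_params, fisher: dict) -> None:
    anchors = {n: p.data.copy() for n, p in named_params if p.requires_grad}
    state.fishers.append(fisher)
    state.fisher_anchors.append(anchors)
    for n, f in fisher.items():
        state.f_tilde[n] = state.gamma * state.f_tilde.get(n, 0.0) + f
    state.anchors = anchors
    state.n_consolidated += 1


def ewc_penalty(named_params, state: ImportanceState, mode: str = "ewc") -> Tensor:
    """EWC: sum over previous tasks of 1/2 sum_i F_ii^(k) (theta_i - theta-hat_i^(k))^2;
    online EWC: sum_i F~_ii (theta_i - theta-hat_i^(K-1))^2 (no 1/2 factor)."""
    if state.n_consolidated < 1:
        raise RuntimeError("EWC penalty requested before any task was consolidated")
    total = Tensor(0.0)
    params = {n: p for n, p in named_params if p.requires_grad}
    if mode == "ewc":
        for fisher, anchors in zip(state.fishers, state.fisher_anchors):
            for n, f in fisher.items():
                diff = params[n] - Tensor(anchors[n])
                total = total + (Tensor(f) * diff * diff).sum() * 0.5
    elif mode == "online":
        for n, f in state.f_tilde.items():
            diff = params[n] - Tensor(state.anchors[n])
            total = total + (Tensor(f) * diff * diff).sum()
    else:
        raise ValueError("mode must be 'ewc' or 'online'")
    return total


# ---------------------------------------------------------------------------
# replay generation

def _label_by_model(model, inputs, groups, protocol, current_context, scenario,
                    distill: bool, T: float, from_hidden: bool):
    """Label generated inputs with the frozen main model, per active set."""
    n = len(inputs)
    n_classes = protocol.n_classes_total
    hard = np.zeros(n, dtype=np.int64)
    soft_full = np.zeros((n, n_classes)) if distill else None
    active_sets = []
    logits = model.logits(inputs, from_hidden=from_hidden).data
    for intended_ctx, idx in groups:
        act = replay_active_set(protocol, current_context,
                                intended_context=intended_ctx, scenario=scenario)
        sub = logits[np.asarray(idx)][:, list(act)]
        hard[idx] = np.asarray(act)[np.argmax(sub, axis=1)]
        if distill:
            st = obj.soft_targets_from_logits(logits[np.asarray(idx)], act, T=T)
            soft_full[idx] = st.probs
        active_sets.append((np.asarray(idx), tuple(act)))
    return hard, soft_full, active_sets


def lwf_targets(model_prev, x, active, T: float = 2.0) -> obj.SoftTarget:
    """Soft targets for current-task inputs from the frozen previous model
    (the replayed 'samples' of learning-without-forgetting)."""
    return obj.soft_targets(model_prev, x, active, T=T)


def generate_replay(frozen_gen, frozen_main, prior: GenerativePrior | None,
                    n: int, protocol: TaskProtocol, current_context: int,
                    config: StrategyConfig, rng: np.random.Generator,
                    masks: GatingMaskSet | None = None, gate_by: str = "class",
                    level: str = "pixel", distill: bool | None = None) -> ReplayBatch:
    """Draw a batch of samples from the frozen generator and label them with
    the frozen main model (hard argmax, or soft targets when distilling)."""
    if current_context < 2:
        raise RuntimeError("replay can only be generated from the second context on")
    if distill is None:
        distill = config.resolved_toggles(has_conv=True)["distill"]
    scenario = config.scenario
    seen_classes = protocol.classes_seen(current_context - 1)
    # intended contexts (task_il): uniform over previous contexts, per sample
    if scenario == "task_il":
        intended_ctx = rng.integers(1, current_context, size=n)
    else:
        intended_ctx = None

    if prior is not None:
        intended_cls = np.empty(n, dtype=np.int64)
        if scenario == "task_il":
            for k in np.unique(intended_ctx):
                sel = np.nonzero(intended_ctx == k)[0]
                pool = [c for c in protocol.contexts[k - 1].class_ids if c in prior.seen]
                intended_cls[sel] = rng.choice(pool, size=len(sel))
        else:
            intended_cls = rng.choice(sorted(set(seen_classes) & prior.seen), size=n)
        mu = prior.mu.data[intended_cls]
        sigma = np.exp(np.clip(prior.log_sigma.data[intended_cls], -10, 10))
        z = mu + sigma * rng.standard_normal((n, prior.latent_dim))
    else:
        intended_cls = None
        z, _ = sample_prior(None, rng, n=n, latent_dim=frozen_gen.latent_dim)

    mask_arrays = None
    if masks is not None:
        if gate_by == "class":
            ids = intended_cls if intended_cls is not None else rng.choice(
                list(seen_classes), size=n
            )
        else:  # per-task masks
            ids = intended_ctx if intended_ctx is not None else rng.integers(
                1, current_context, size=n
            )
        mask_arrays = masks.batch(ids)

    out = frozen_gen.decode(z, masks=mask_arrays, level=level).data
    if level == "pixel":
        out = out.reshape((n,) + tuple(frozen_gen.input_shape))

    if scenario == "task_il":
        groups = [(int(k), np.nonzero(intended_ctx == k)[0])
                  for k in np.unique(intended_ctx)]
    else:
        groups = [(None, np.arange(n))]
    hard, soft_full, active_sets = _label_by_model(
        frozen_main, out, groups, protocol, current_context, scenario,
        distill=distill, T=config.temperature,
        from_hidden=(level == "hidden"),
    )
    soft = None
    if soft_full is not None:
        soft = obj.SoftTarget(probs=soft_full, temperature=config.temperature,
                              active=tuple(sorted({c for _, a in active_sets for c in a})))
    return ReplayBatch(
        inputs=out, level=level, hard=hard, soft=soft,
        intended_contexts=intended_ctx, intended_classes=intended_cls,
        active_sets=active_sets, source_version=current_context - 1,
    )


# ---------------------------------------------------------------------------
# evaluation

def evaluate_protocol(model, protocol: TaskProtocol, through_context: int,
                      scenario: str, xdg_masks: GatingMaskSet | None = None,
                      eval_batch: int = 512) -> np.ndarray:
    """Test accuracy on each context 1..through_context (row of the
    accuracy matrix)."""
    accs = np.zeros(through_context)
    for j in range(1, through_context + 1):
        xs, ys = protocol.test_data(j)
        if scenario == "task_il":
            active = protocol.contexts[j - 1].class_ids
        elif scenario == "domain_il":
            active = tuple(range(protocol.n_classes_total))
        else:
            active = protocol.classes_seen(through_context)
        masks = xdg_masks.keep(j) if xdg_masks is not None else None
        correct = 0
        for a in range(0, len(xs), eval_batch):
            batch = xs[a : a + eval_batch]
            probs = classify(model, batch, active, masks=masks)
            correct += int((np.argmax(probs, axis=1) == ys[a : a + eval_batch]).sum())
        accs[j - 1] = correct / len(xs)
    return accs


# ---------------------------------------------------------------------------
# the training engine

class _Trainer:
    def __init__(self, protocol: TaskProtocol, config: StrategyConfig,
                 conv_stack: ConvStack | None = None, seed: int = 0,
                 verbose: bool = False):
        config.validate(has_conv=conv_stack is not None)
        self.protocol = protocol
        self.config = config
        self.conv = conv_stack
        self.seed = int(seed)
        self.verbose = verbose
        self.scenario = config.scenario
        self.toggles = config.resolved_toggles(has_conv=conv_stack is not None)
        ss = np.random.SeedSequence(self.seed)
        (self.rng_init, self.rng_order, self.rng_eps, self.rng_prior,
         self.rng_mask, self.rng_replay, self.rng_fisher) = (
            np.random.default_rng(s) for s in ss.spawn(7)
        )
        self.level = "hidden" if self.toggles["internal"] else "pixel"
        self.gate_by = "task" if self.scenario == "domain_il" else "class"
        self._build()

    # -- construction ----------------------------------------------------
    def _build(self):
        cfg, protocol = self.config, self.protocol
        shape = protocol.image_shape
        n_classes = protocol.n_classes_total
        self.base = cfg.base
        self.regularizer = cfg.regularizer
        uses_generator = self.base in ("gr", "bir")
        vae_hidden = cfg.vae_hidden_layers or cfg.hidden_layers
        self.generator = None
        self.prior = None
        if uses_generator and self.toggles["rtf"]:
            self.model = RtfModel(shape, list(cfg.hidden_layers), n_classes,
                                  latent_dim=cfg.latent_dim, conv=self.conv,
                                  deconv=(self.conv is not None and not self.toggles["internal"]),
                                  internal=self.toggles["internal"], rng=self.rng_init)
            self.generator = self.model
        else:
            self.model = Classifier(shape, list(cfg.hidden_layers), n_classes,
                                    conv=self.conv, rng=self.rng_init)
            if uses_generator:
                self.generator = VAE(shape, list(vae_hidden), latent_dim=cfg.latent_dim,
                                     conv=self.conv,
                                     deconv=(self.conv is not None and not self.toggles["internal"]),
                                     internal=self.toggles["internal"], rng=self.rng_init)
        if uses_generator and self.toggles["conditional"]:
            self.prior = GenerativePrior(n_classes, cfg.latent_dim)
        self.dec_masks = None
        if uses_generator and self.toggles["gating"]:
            ids = (range(1, protocol.n_contexts + 1) if self.gate_by == "task"
                   else range(n_classes))
            self.dec_masks = make_masks(
                protocol.n_contexts, self.generator.dec_widths, cfg.gate_percent,
                seed=int(self.rng_mask.integers(2**31)), context_ids=ids,
            )
        self.xdg_masks = None
        if self.base == "xdg":
            self.xdg_masks = make_masks(
                protocol.n_contexts, list(cfg.hidden_layers), cfg.xdg_percent,
                seed=int(self.rng_mask.integers(2**31)),
            )
        self._make_optimizers()
        self.importance = ImportanceState(xi=cfg.si_xi, gamma=cfg.ewc_gamma)
        self.frozen_main = None
        self.frozen_gen = None
        self.frozen_prior = None
        self.losses: list[dict] = []
        # affine remap for pixel-level BCE on channel-standardized inputs
        if protocol.train_set.standardized and self.level == "pixel" and uses_generator:
            imgs = protocol.train_set.images
            self._pix_lo, self._pix_hi = float(imgs.min()), float(imgs.max())
        else:
            self._pix_lo, self._pix_hi = 0.0, 1.0

    def _trainable(self, module) -> list:
        return [p for p in module.parameters() if p.requires_grad]

    def _make_optimizers(self):
        cfg = self.config
        params = self._trainable(self.model)
        if self.prior is not None and self.generator is self.model:
            params = params + self._trainable(self.prior)
        self.opt = Adam(params, lr=cfg.lr, betas=cfg.betas)
        self.gen_opt = None
        if self.generator is not None and self.generator is not self.model:
            gen_params = self._trainable(self.generator)
            if self.prior is not None:
                gen_params = gen_params + self._trainable(self.prior)
            self.gen_opt = Adam(gen_params, lr=cfg.lr, betas=cfg.betas)

    def _reinit(self):
        """Reinitialization control: rebuild networks from scratch (masks,
        importance state and frozen copies are kept)."""
        cfg, protocol = self.config, self.protocol
        shape, n_classes = protocol.image_shape, protocol.n_classes_total
        vae_hidden = cfg.vae_hidden_layers or cfg.hidden_layers
        seen = None
        if isinstance(self.model, RtfModel):
            self.model = RtfModel(shape, list(cfg.hidden_layers), n_classes,
                                  latent_dim=cfg.latent_dim, conv=self.conv,
                                  deconv=(self.conv is not None and not self.toggles["internal"]),
                                  internal=self.toggles["internal"], rng=self.rng_init)
            self.generator = self.model
        else:
            self.model = Classifier(shape, list(cfg.hidden_layers), n_classes,
                                    conv=self.conv, rng=self.rng_init)
            if self.generator is not None:
                self.generator = VAE(shape, list(vae_hidden), latent_dim=cfg.latent_dim,
                                     conv=self.conv,
                                     deconv=(self.conv is not None and not self.toggles["internal"]),
                                     internal=self.toggles["internal"], rng=self.rng_init)
        if self.prior is not None:
            seen = set(self.prior.seen)
            self.prior = GenerativePrior(n_classes, cfg.latent_dim)
            self.prior.seen = seen
        self._make_optimizers()

    # -- loss helpers ----------------------------------------------------
    def _pixels01(self, x: np.ndarray) -> np.ndarray:
        if self._pix_lo == 0.0 and self._pix_hi == 1.0:
            return x
        return (x - self._pix_lo) / (self._pix_hi - self._pix_lo)

    def _gen_loss(self, generator, x, y_hard, soft, eps, level: str,
                  from_hidden: bool, mask_ids=None) -> Tensor:
        """Per-batch mean VAE loss (reconstruction + latent term)."""
        masks = None
        if self.dec_masks is not None and mask_ids is not None:
            masks = self.dec_masks.batch(mask_ids)
        x_hat, mu, log_sigma = generator.reconstruct(
            x, eps, masks=masks, from_hidden=from_hidden, level=level
        )
        if level == "hidden":
            target = x if from_hidden else extract_features(generator.conv, x)
            recon = obj.recon_loss_internal(np.asarray(target).reshape(len(eps), -1), x_hat)
        else:
            x01 = self._pixels01(np.asarray(x).reshape(len(eps), -1))
            recon = obj.recon_loss_pixel(x01, x_hat)
        if self.prior is not None:
            if soft is not None:
                latent = obj.latent_loss_gmm_soft(mu, log_sigma, soft, self.prior, eps)
            else:
                latent = obj.latent_loss_gmm_hard(mu, log_sigma, y_hard, self.prior)
        else:
            latent = obj.latent_loss_standard(mu, log_sigma)
        return (recon + latent).mean()

    def _grouped_class_loss(self, logits: Tensor, y: np.ndarray, groups) -> Tensor:
        """Mean classification loss where the active set differs per group."""
        total = Tensor(0.0)
        n = len(y)
        for active, idx in groups:
            sub = logits[np.asarray(idx)]
            total = total + obj.class_loss(sub, active, y[idx]).sum()
        return total * (1.0 / n)

    def _replay_main_loss(self, logits: Tensor, rb: ReplayBatch, K: int) -> Tensor:
        """Classification or distillation loss on a replay batch.

        The softmax active set follows the output-layer regime of the
        scenario: single-headed Class-IL keeps *all* classes seen so far
        active (the targets put zero mass on the current classes), Task-IL
        uses the replayed task's head, Domain-IL all units.  Only the
        *labelling* of the batch was restricted to previously seen classes.
        """
        if self.scenario == "class_il":
            act_of = lambda _labelling_act: self.protocol.classes_seen(K)
        elif self.scenario == "domain_il":
            act_of = lambda _labelling_act: tuple(range(self.protocol.n_classes_total))
        else:  # task_il: multi-headed, use the replayed task's own head
            act_of = lambda labelling_act: labelling_act
        if rb.soft is not None:
            total = Tensor(0.0)
            for idx, act in rb.active_sets:
                st = obj.SoftTarget(rb.soft.probs[idx], rb.soft.temperature, act_of(act))
                total = total + obj.distill_loss(logits[idx], st).sum()
            return total * (1.0 / len(rb.hard))
        groups = [(act_of(act), idx) for idx, act in rb.active_sets]
        return self._grouped_class_loss(logits, rb.hard, groups)

    # -- the main loop ---------------------------------------------------
    def run(self) -> TrainOutput:
        cfg, protocol = self.config, self.protocol
        n_ctx = protocol.n_contexts
        acc_matrix = np.full((n_ctx, n_ctx), np.nan)
        avg_acc = np.zeros(n_ctx)
        joint_pool = None
        reg_named = lambda: self.model.named_parameters()

        for K in range(1, n_ctx + 1):
            ctx = protocol.contexts[K - 1]
            X_cur, y_cur = protocol.train_data(K)
            active_cur = _current_active_set(protocol, K, self.scenario)
            if self.prior is not None:
                self.prior.mark_seen(ctx.class_ids)
            uses_replay = self.base in ("gr", "bir", "lwf") and K >= 2
            weights = obj.LossWeights(K if self.base in ("gr", "bir", "lwf") else 1)
            if self.base == "joint":
                joint_pool = (
                    (X_cur, y_cur, np.full(len(y_cur), K)) if joint_pool is None else (
                        np.concatenate([joint_pool[0], X_cur]),
                        np.concatenate([joint_pool[1], y_cur]),
                        np.concatenate([joint_pool[2], np.full(len(y_cur), K)]),
                    )
                )
            if cfg.reinit_each_task and K >= 2:
                self._reinit()  # frozen copies were made at the end of K-1
            elif cfg.reset_optimizer_per_task and K >= 2:
                self._make_optimizers()
            if self.regularizer == "si":
                self.importance.begin_task(reg_named())

            for t in range(cfg.iters):
                rec = self._train_iteration(K, t, X_cur, y_cur, active_cur,
                                            uses_replay, weights, joint_pool)
                self.losses.append(rec)

            # post-task bookkeeping: frozen copies, importance consolidation
            self._end_of_task(K, X_cur, active_cur)
            accs = evaluate_protocol(self.model, protocol, K, self.scenario,
                                     xdg_masks=self.xdg_masks, eval_batch=cfg.eval_batch)
            acc_matrix[K - 1, :K] = accs
            avg_acc[K - 1] = accs.mean()
            if self.verbose:
                print(f"context {K}/{n_ctx}: per-context acc {np.round(accs, 3)} "
                      f"(avg {avg_acc[K - 1]:.3f})")

        return TrainOutput(acc_matrix, avg_acc, self.losses, self.model,
                           None if self.generator is self.model else self.generator,
                           self.prior, cfg, self.seed,
                           dec_masks=self.dec_masks, xdg_masks=self.xdg_masks)

    def _train_iteration(self, K, t, X_cur, y_cur, active_cur, uses_replay,
                         weights, joint_pool) -> dict:
        cfg = self.config
        rec = {"context": K, "iter": t}

        # ---- current-task mini-batch
        if self.base == "joint":
            Xp, yp, ctx_of = joint_pool
            idx = self.rng_order.integers(0, len(Xp), cfg.batch_size)
            xb, yb, cb = Xp[idx], yp[idx], ctx_of[idx]
        else:
            idx = self.rng_order.integers(0, len(X_cur), cfg.batch_size)
            xb, yb = X_cur[idx], y_cur[idx]

        masks_cls = self.xdg_masks.keep(K) if self.xdg_masks is not None else None
        logits = self.model.logits(xb, masks=masks_cls)
        if self.base == "joint" and self.scenario == "task_il":
            groups = [(self.protocol.contexts[k - 1].class_ids, np.nonzero(cb == k)[0])
                      for k in np.unique(cb)]
            l_class = self._grouped_class_loss(logits, yb, groups)
        else:
            l_class = obj.class_loss(logits, active_cur, yb).mean()
        l_current = l_class
        if self.generator is not None:
            eps = self.rng_eps.standard_normal((len(yb), cfg.latent_dim))
            mask_ids = yb if self.gate_by == "class" else np.full(len(yb), K)
            l_gen_cur = self._gen_loss(self.generator, xb, yb, None, eps,
                                       self.level, from_hidden=False, mask_ids=mask_ids)
            if self.generator is self.model:
                l_current = l_current + l_gen_cur
        else:
            l_gen_cur = None

        # ---- replay mini-batch
        l_replay = None
        l_gen_replay = None
        rb = None
        if uses_replay:
            n_rep = cfg.replay_batch_size or cfg.batch_size
            if self.base == "lwf":
                ridx = self.rng_order.integers(0, len(X_cur), n_rep)
                xr = X_cur[ridx]
                if self.scenario == "task_il":
                    intended = self.rng_replay.integers(1, K, size=n_rep)
                    groups = [(int(k), np.nonzero(intended == k)[0])
                              for k in np.unique(intended)]
                else:
                    groups = [(None, np.arange(n_rep))]
                hard, soft_full, active_sets = _label_by_model(
                    self.frozen_main, xr, groups, self.protocol, K, self.scenario,
                    distill=True, T=cfg.temperature, from_hidden=False,
                )
                soft = obj.SoftTarget(soft_full, cfg.temperature,
                                      tuple(sorted({c for _, a in active_sets for c in a})))
                rb = ReplayBatch(xr, "pixel", hard, soft, None, None, active_sets, K - 1)
            else:
                rb = generate_replay(
                    self.frozen_gen, self.frozen_main, self.frozen_prior,
                    n_rep, self.protocol, K, cfg, self.rng_replay,
                    masks=self.dec_masks, gate_by=self.gate_by, level=self.level,
                    distill=self.toggles["distill"],
                )
            r_logits = self.model.logits(rb.inputs, from_hidden=(rb.level == "hidden"))
            l_replay = self._replay_main_loss(r_logits, rb, K)
            if self.generator is not None:
                epsr = self.rng_eps.standard_normal((len(rb.hard), cfg.latent_dim))
                rep_mask_ids = (rb.hard if self.gate_by == "class"
                                else rb.intended_contexts)
                if rep_mask_ids is None:
                    rep_mask_ids = self.rng_replay.integers(1, K, size=len(rb.hard))
                l_gen_replay = self._gen_loss(
                    self.generator, rb.inputs, rb.hard, rb.soft, epsr,
                    self.level, from_hidden=(rb.level == "hidden"),
                    mask_ids=rep_mask_ids,
                )
                if self.generator is self.model:
                    l_replay = l_replay + l_gen_replay

        # ---- total loss for the main model
        l_total = obj.combine(l_current, l_replay if l_replay is not None else 0.0, weights)
        penalty_val = 0.0
        if self.regularizer is not None and self.importance.n_consolidated >= 1:
            named = self.model.named_parameters()
            if self.regularizer == "si":
                pen = si_penalty(named, self.importance)
            else:
                pen = ewc_penalty(named, self.importance,
                                  mode="online" if self.regularizer == "online_ewc" else "ewc")
            l_total = l_total + pen * cfg.reg_strength
            penalty_val = pen.item()

        si_track = self.regularizer == "si"
        if si_track:
            before = {n: p.data.copy() for n, p in self.model.named_parameters()
                      if p.requires_grad}
        self.opt.zero_grad()
        if self.prior is not None:
            self.prior.zero_grad()
        l_total.backward()
        if si_track:
            grads = {n: (p.grad.copy() if p.grad is not None else np.zeros_like(p.data))
                     for n, p in self.model.named_parameters() if p.requires_grad}
        self.opt.step()
        if si_track:
            for n, p in self.model.named_parameters():
                if p.requires_grad:
                    si_accumulate(self.importance, n, before[n], p.data, grads[n])

        # ---- separate generator step (standard GR family)
        if self.gen_opt is not None:
            lg = obj.combine(l_gen_cur, l_gen_replay if l_gen_replay is not None else 0.0,
                             weights)
            self.gen_opt.zero_grad()
            lg.backward()
            self.gen_opt.step()
            rec["loss_generator"] = lg.item()

        rec["loss_total"] = l_total.item()
        rec["loss_current"] = l_current.item() if isinstance(l_current, Tensor) else float(l_current)
        if l_replay is not None:
            rec["loss_replay"] = l_replay.item()
        if rb is not None:
            rec["replay_source"] = rb.source_version
        if self.regularizer is not None and self.importance.n_consolidated >= 1:
            rec["penalty"] = penalty_val
        return rec

    def _end_of_task(self, K, X_cur, active_cur):
        cfg = self.config
        # frozen post-task snapshots (never the live model)
        if self.base in ("gr", "bir", "lwf"):
            self.frozen_main = self.model.copy()
            for p in self.frozen_main.parameters():
                p.requires_grad = False
            self.frozen_main.eval()
            if self.generator is not None:
                if self.generator is self.model:
                    self.frozen_gen = self.frozen_main
                else:
                    self.frozen_gen = self.generator.copy()
                    for p in self.frozen_gen.parameters():
                        p.requires_grad = False
                    self.frozen_gen.eval()
            if self.prior is not None:
                self.frozen_prior = _copy.deepcopy(self.prior)
                for p in self.frozen_prior.parameters():
                    p.requires_grad = False
        if self.regularizer == "si":
            si_consolidate(self.importance, self.model.named_parameters())
        elif self.regularizer in ("ewc", "online_ewc"):
            fisher = fisher_diagonal(self.model, X_cur, active_cur,
                                     subsample=cfg.fisher_subsample, rng=self.rng_fisher)
            ewc_consolidate(self.importance, self.model.named_parameters(), fisher)


def train_sequence(protocol: TaskProtocol, config: StrategyConfig,
                   conv_stack: ConvStack | None = None, seed: int = 0,
                   verbose: bool = False) -> TrainOutput:
    """Sequentially train on every context of the protocol under the given
    strategy; returns the trained model(s) and the accuracy trace."""
    return _Trainer(protocol, config, conv_stack=conv_stack, seed=seed,
                    verbose=verbose).run()
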