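"""Per-sample loss terms and the current/replay loss weighting.

All functions are batched: model outputs are tensors of shape
(batch, n_classes) or (batch, latent_dim) and each loss returns a
per-sample tensor of shape (batch,); training code takes the mean over the
mini-batch.  Sign conventions follow the KL-divergence definition of the
variational objective, so every latent regularization term is nonnegative
in expectation and minimizing it is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .networks import LOG_SIGMA_CLAMP, GenerativePrior

__all__ = [
    "SoftTarget",
    "LossWeights",
    "log_softmax_active",
    "class_loss",
    "soft_targets",
    "soft_targets_from_logits",
    "distill_loss",
    "latent_loss_standard",
    "latent_loss_gmm_hard",
    "latent_loss_gmm_soft",
    "recon_loss_pixel",
    "recon_loss_internal",
    "combine",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class SoftTarget:
    """Temperature-softened probability vectors over the full class set.

    Rows are zero outside the active set used at creation and sum to one
    over it."""

    probs: np.ndarray  # (batch, n_classes)
    temperature: float
    active: tuple[int, ...]


@dataclass
class LossWeights:
    """Current/replay weighting: 1/N for current data, 1 - 1/N for replay,
    with N the number of tasks/episodes seen so far."""

    n_tasks_so_far: int

    def __post_init__(self):
        if self.n_tasks_so_far < 1:
            raise ValueError("n_tasks_so_far must be >= 1")

    @property
    def current(self) -> float:
        return 1.0 / self.n_tasks_so_far

    @property
    def replay(self) -> float:
        return 1.0 - 1.0 / self.n_tasks_so_far


def _active_array(active) -> np.ndarray:
    arr = np.asarray(sorted(set(int(a) for a in active)), dtype=int)
    if arr.size == 0:
        raise ValueError("active set must be non-empty")
    return arr


def log_softmax_active(logits: Tensor, active, T: float = 1.0) -> tuple[Tensor, np.ndarray]:
    """Log-probabilities over the active output units at temperature T.

    Returns (log-prob tensor of shape (batch, n_active), active id array)."""
    act = _active_array(active)
    sub = logits[:, act] * (1.0 / T)
    m = sub.data.max(axis=1, keepdims=True)  # constant shift for stability
    shifted = sub - Tensor(m)
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    return shifted - lse, act


def class_loss(logits: Tensor, active, y) -> Tensor:
    """Per-sample multi-class cross-entropy -log p(Y=y|x) over the active
    units.  Raises if any label is outside the active set (which would mean
    it has probability exactly zero)."""
    logp, act = log_softmax_active(logits, active)
    y = np.asarray(y, dtype=int)
    pos = np.searchsorted(act, y)
    if np.any(pos >= len(act)) or np.any(act[np.minimum(pos, len(act) - 1)] != y):
        bad = y[(pos >= len(act)) | (act[np.minimum(pos, len(act) - 1)] != y)]
        raise ValueError(f"labels {sorted(set(bad.tolist()))} are not in the active set")
    return -logp[np.arange(len(y)), pos]


def soft_targets_from_logits(logits: np.ndarray, active, T: float = 2.0) -> SoftTarget:
    """Temperature-softened softmax of given logits, restricted to the
    active units (zeros elsewhere)."""
    act = _active_array(active)
    sub = np.asarray(logits)[:, act] / T
    sub = sub - sub.max(axis=1, keepdims=True)
    e = np.exp(sub)
    p = e / e.sum(axis=1, keepdims=True)
    full = np.zeros_like(np.asarray(logits, dtype=np.float64))
    full[:, act] = p
    return SoftTarget(probs=full, temperature=T, active=tuple(act.tolist()))


def soft_targets(model_prev, x, active, T: float = 2.0, from_hidden: bool = False) -> SoftTarget:
    """Soft targets produced by a frozen previous-model copy."""
    logits = model_prev.logits(x, from_hidden=from_hidden).data
    return soft_targets_from_logits(logits, active, T=T)


def distill_loss(logits: Tensor, target: SoftTarget, T: float | None = None) -> Tensor:
    """Per-sample distillation loss: -T^2 * sum_c  y~_c log p^T(Y=c|x),
    with the current model's probabilities softened at the same temperature
    (and over the same active set) used to create the target."""
    T = target.temperature if T is None else T
    if T != target.temperature:
        raise ValueError(
            f"temperature mismatch: targets made at T={target.temperature}, got T={T}"
        )
    logp, act = log_softmax_active(logits, target.active, T=T)
    if tuple(act.tolist()) != tuple(target.active):
        raise ValueError("active-set mismatch between prediction and soft target")
    w = Tensor(target.probs[:, act])
    return (w * logp).sum(axis=1) * (-T * T)


def latent_loss_standard(mu: Tensor, log_sigma: Tensor) -> Tensor:
    """Per-sample KL( N(mu, sigma^2 I) || N(0, I) )
    = -1/2 sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2)."""
    s2 = (log_sigma * 2.0).exp()
    return (1.0 + log_sigma * 2.0 - mu * mu - s2).sum(axis=1) * (-0.5)


def _mode_params(prior: GenerativePrior, y: np.ndarray) -> tuple[Tensor, Tensor]:
    missing = set(int(c) for c in np.unique(y)) - prior.seen
    if missing:
        raise RuntimeError(f"classes {sorted(missing)} have no initialized prior mode")
    mu_y = prior.mu[y]
    ls_y = prior.log_sigma[y].clamp(-LOG_SIGMA_CLAMP, LOG_SIGMA_CLAMP)
    return mu_y, ls_y


def latent_loss_gmm_hard(mu: Tensor, log_sigma: Tensor, y, prior: GenerativePrior) -> Tensor:
    """Per-sample KL between the posterior and the prior mode of class y
    (closed form), used for hard-labelled data under the mixture prior."""
    y = np.asarray(y, dtype=int)
    mu_y, ls_y = _mode_params(prior, y)
    s2_x = (log_sigma * 2.0).exp()
    s2_y = (ls_y * 2.0).exp()
    diff = mu - mu_y
    inner = 1.0 + log_sigma * 2.0 - ls_y * 2.0 - (diff * diff + s2_x) / s2_y
    return inner.sum(axis=1) * (-0.5)


def latent_loss_gmm_soft(mu: Tensor, log_sigma: Tensor, target: SoftTarget | np.ndarray,
                         prior: GenerativePrior, eps: np.ndarray) -> Tensor:
    """Single-sample estimate of the latent loss for soft-labelled data:

    -H-term - log sum_c y~_c N(z | mu_c, sigma_c^2 I),  z = mu + sigma*eps,

    where the H-term is 1/2 sum_j (1 + log 2 pi + log sigma_j^2).  Its
    expectation over eps equals the KL-style latent regularizer being
    minimized (nonnegative in expectation; single draws may be negative)."""
    probs = target.probs if isinstance(target, SoftTarget) else np.asarray(target)
    support = np.unique(np.nonzero(probs > 0)[1])
    missing = set(int(c) for c in support) - prior.seen
    if missing:
        raise RuntimeError(f"soft-target mass on classes without prior modes: {sorted(missing)}")
    d = mu.shape[1]
    z = mu + log_sigma.exp() * Tensor(np.asarray(eps, dtype=np.float64))
    # mixture-component log densities via broadcasting: (batch, 1, d) vs (1, C, d)
    z3 = z.reshape(z.shape[0], 1, d)
    mu_c = prior.mu.reshape(1, prior.n_classes, d)
    ls_c = prior.log_sigma.clamp(-LOG_SIGMA_CLAMP, LOG_SIGMA_CLAMP).reshape(1, prior.n_classes, d)
    diff = z3 - mu_c
    log_n = (ls_c * 2.0 + _LOG_2PI + diff * diff * (ls_c * -2.0).exp()).sum(axis=2) * (-0.5)
    log_w = np.where(probs > 0, np.log(np.clip(probs, 1e-300, None)), -np.inf)
    terms = log_n + Tensor(log_w)
    m = np.max(np.where(np.isfinite(terms.data), terms.data, -np.inf), axis=1, keepdims=True)
    # exp(-inf - m) underflows to 0 exactly, so zero-weight components drop out
    shifted = terms - Tensor(m)
    log_mix = Tensor(m.reshape(-1)) + shifted.exp().sum(axis=1).log()
    neg_h = (1.0 + _LOG_2PI + log_sigma * 2.0).sum(axis=1) * (-0.5)
    return neg_h - log_mix


def recon_loss_pixel(x, x_hat: Tensor) -> Tensor:
    """Per-sample binary cross-entropy between original pixels in [0,1] and
    decoded pixels in (0,1): -sum_p [x log x^ + (1-x) log(1-x^)]."""
    x = np.asarray(x, dtype=np.float64).reshape(x_hat.shape[0], -1)
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("pixel targets must lie in [0, 1]")
    xh = x_hat.clamp(1e-7, 1.0 - 1e-7)
    xt = Tensor(x)
    return -(xt * xh.log() + (1.0 - xt) * (1.0 - xh).log()).sum(axis=1)


def recon_loss_internal(h, h_hat: Tensor) -> Tensor:
    """Per-sample squared error between hidden activations and the decoded
    hidden activations: sum_i (h_i - h^_i)^2."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape != h_hat.shape:
        raise ValueError(f"hidden-vector shape mismatch: {h.shape} vs {h_hat.shape}")
    diff = h_hat - Tensor(h)
    return (diff * diff).sum(axis=1)


def combine(current_loss, replay_loss, weights: LossWeights):
    """Total loss: (1/N) * current + (1 - 1/N) * replay; on the first task
    the replay term has weight exactly zero."""
    if weights.replay == 0.0:
        return current_loss * weights.current if isinstance(current_loss, Tensor) \
            else weights.current * current_loss
    return current_loss * weights.current + replay_loss * weights.replay
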