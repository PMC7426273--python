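"""Embedding-swapped measures of generated-sample quality and diversity.

The usual Inception-based scores cannot embed samples generated at the
hidden (post-convolutional) level, so all three measures here use a
task-matched embedding classifier that shares the frozen convolutional
layers of the incrementally trained models: pixel-level samples go through
the full stack, hidden-level samples are injected after the conv layers.

* modified Inception Score: exp of the mean KL between per-sample class
  distributions and their average; bounded between 1 and C (the number of
  classes of the embedding head);
* modified Frechet distance between Gaussian fits to real and generated
  feature vectors;
* precision--recall curves from k-means cluster histograms of the pooled
  feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .datasets import LabeledImageSet
from .networks import Classifier, ConvStack
from .nn import Adam
from . import objectives as obj

__all__ = [
    "EmbeddingNetwork",
    "PRCurve",
    "modified_is",
    "modified_fid",
    "pr_curve",
    "embed",
    "train_embedding_network",
]


class EmbeddingNetwork(Classifier):
    """Classifier used as the common embedding space for generator metrics.

    Features are tapped from the penultimate layer (the final hidden layer,
    before the softmax head); hidden-level samples enter after the conv
    stack."""

    def embed(self, samples, level: str = "pixel") -> tuple[np.ndarray, np.ndarray]:
        return embed(self, samples, level=level)


def embed(net, samples, level: str = "pixel") -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors (penultimate layer) and softmax class distributions.

    level="hidden" injects flattened feature-level samples after the conv
    stack; their length must match the conv-stack output."""
    samples = np.asarray(samples, dtype=np.float64)
    from_hidden = level == "hidden"
    if from_hidden:
        flat = samples.reshape(len(samples), -1)
        if flat.shape[1] != net.n_features_in:
            raise ValueError(
                f"hidden-level samples of length {flat.shape[1]} do not match the "
                f"conv-stack output length {net.n_features_in}"
            )
    hid = net.hidden(samples, from_hidden=from_hidden)
    logits = net.head(hid).data
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    return hid.data, probs


def modified_is(cond_probs: np.ndarray) -> float:
    """exp( mean_g KL( p(.|x_g) || p(.) ) ) with p(.) the mean row.

    Bounded between 1 and the number of classes C; 1 when all rows are
    identical, C when each class is predicted deterministically for an
    equal share of the samples."""
    p = np.asarray(cond_probs, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("cond_probs must be (n_samples, n_classes)")
    if np.any(p < -1e-12) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each row of cond_probs must be a probability distribution")
    marginal = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(marginal)), 0.0)
    return float(np.exp(terms.sum(axis=1).mean()))


def _cov(x: np.ndarray) -> np.ndarray:
    return np.cov(x, rowvar=False).reshape(x.shape[1], x.shape[1])


def modified_fid(feats_real: np.ndarray, feats_gen: np.ndarray) -> float:
    """|| mu_r - mu_g ||^2 + Tr( S_r + S_g - 2 (S_r S_g)^{1/2} ).

    The trace of the matrix square root is computed from the eigenvalues of
    the symmetrized product S_r^{1/2} S_g S_r^{1/2}, clipping tiny negative
    eigenvalues to zero."""
    fr = np.asarray(feats_real, dtype=np.float64)
    fg = np.asarray(feats_gen, dtype=np.float64)
    if fr.ndim != 2 or fg.ndim != 2 or fr.shape[1] != fg.shape[1]:
        raise ValueError("feature sets must be 2-d with equal dimension")
    if len(fr) < 2 or len(fg) < 2:
        raise ValueError("need at least two feature vectors per side")
    mu_r, mu_g = fr.mean(axis=0), fg.mean(axis=0)
    s_r, s_g = _cov(fr), _cov(fg)
    # sqrt(S_r) via eigendecomposition (S_r is symmetric PSD)
    w, v = np.linalg.eigh(s_r)
    sqrt_r = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    middle = sqrt_r @ s_g @ sqrt_r
    ev = np.linalg.eigvalsh((middle + middle.T) / 2.0)
    tr_sqrt = np.sqrt(np.clip(ev, 0.0, None)).sum()
    return float(((mu_r - mu_g) ** 2).sum() + np.trace(s_r) + np.trace(s_g) - 2.0 * tr_sqrt)


@dataclass
class PRCurve:
    """Precision-recall curve over a lambda grid (averaged over clustering
    repeats); alpha = precision, beta = recall, both in [0, 1]."""

    lambdas: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray

    def as_points(self) -> np.ndarray:
        return np.column_stack([self.alphas, self.betas])


def _pr_from_histograms(P: np.ndarray, Q: np.ndarray, lambdas: np.ndarray):
    alphas = np.array([np.minimum(lam * P, Q).sum() for lam in lambdas])
    betas = np.array([np.minimum(P, Q / lam).sum() for lam in lambdas])
    return alphas, betas


def pr_curve(feats_real: np.ndarray, feats_gen: np.ndarray, k: int = 20,
             m: int = 999, repeats: int = 10, seed: int = 0) -> PRCurve:
    """Cluster the pooled real+generated feature vectors into k groups with
    k-means, form the per-side cluster histograms P and Q, and evaluate

        alpha(lam) = sum_w min(lam P(w), Q(w)),
        beta(lam)  = sum_w min(P(w), Q(w)/lam)

    over the grid  Lambda = { tan(i/(m+1) * pi/2) : i = 1..m }, averaging
    the curves over seeded clustering repeats."""
    fr = np.asarray(feats_real, dtype=np.float64)
    fg = np.asarray(feats_gen, dtype=np.float64)
    if len(fr) == 0 or len(fg) == 0:
        raise ValueError("both feature sets must be non-empty")
    if k > len(fr) + len(fg):
        raise ValueError("more clusters than feature vectors")
    pooled = np.concatenate([fr, fg])
    lambdas = np.tan(np.arange(1, m + 1) / (m + 1) * np.pi / 2.0)
    alphas = np.zeros(m)
    betas = np.zeros(m)
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(pooled)
        P = np.bincount(labels[: len(fr)], minlength=k) / len(fr)
        Q = np.bincount(labels[len(fr) :], minlength=k) / len(fg)
        a, b = _pr_from_histograms(P, Q, lambdas)
        alphas += a
        betas += b
    return PRCurve(lambdas, alphas / repeats, betas / repeats)


def train_embedding_network(train: LabeledImageSet, hidden_layers=(2000, 2000),
                            conv: ConvStack | None = None, epochs: int = 20,
                            batch_size: int = 256, lr: float = 1e-4,
                            seed: int = 0) -> EmbeddingNetwork:
    """Train the embedding classifier offline on the full class set
    (plain cross-entropy over all classes)."""
    rng = np.random.default_rng(seed)
    net = EmbeddingNetwork(train.image_shape, list(hidden_layers), train.n_classes,
                           conv=conv, rng=rng)
    active = tuple(range(train.n_classes))
    optimizer = Adam([p for p in net.parameters() if p.requires_grad], lr=lr)
    n = len(train)
    for _ in range(epochs):
        order = rng.permutation(n)
        for a in range(0, n, batch_size):
            idx = order[a : a + batch_size]
            logits = net.logits(train.images[idx])
            loss = obj.class_loss(logits, active, train.labels[idx]).mean()
            net.zero_grad()
            loss.backward()
            optimizer.step()
    net.eval()
    return net
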