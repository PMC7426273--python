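"""Model architectures for incremental training with generative feedback.

The package's models are:

* :class:`Classifier` — the base feedforward network (optional frozen
  convolutional stack, fully connected ReLU hidden layers, linear output
  with one unit per class; softmax normalization over the *active* units
  happens in :func:`classify`);
* :class:`VAE` — a symmetric variational autoencoder used as a separate
  generator for standard generative replay, with a 100-unit (configurable)
  Gaussian latent layer;
* :class:`RtfModel` — the replay-through-feedback model: a VAE whose
  encoder doubles as the classifier's feedforward path, with a softmax
  classification head on the encoder's final hidden layer;
* :class:`GenerativePrior` — a trainable Gaussian-mixture latent prior with
  one mode per class (conditional replay);
* :class:`GatingMaskSet` — per-context random gating masks that fully
  inhibit a fraction of hidden units (context-dependent gating).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .nn import MLP, BatchNorm2d, Conv2d, ConvTranspose2d, Linear, Module, Parameter

__all__ = [
    "ConvStack",
    "DeconvStack",
    "cifar_conv_plan",
    "Classifier",
    "VAE",
    "RtfModel",
    "GenerativePrior",
    "GatingMaskSet",
    "make_masks",
    "classify",
    "sample_prior",
    "extract_features",
    "save_model",
    "load_model_arrays",
]

LOG_SIGMA_CLAMP = 10.0  # numerical safety bound on log(sigma)


# ---------------------------------------------------------------------------
# convolutional feature extractor

def cifar_conv_plan() -> dict:
    """Five-layer conv plan used for 32x32 RGB natural images: 3x3 kernels,
    padding 1, stride 1 then 2,2,2,2, channels 16-32-64-128-256, batch-norm
    and ReLU in every layer, no pooling.  On 32x32 input it returns
    256 x 2 x 2 = 1024 features."""
    return {
        "channels": (16, 32, 64, 128, 256),
        "strides": (1, 2, 2, 2, 2),
        "kernel": 3,
        "padding": 1,
        "batchnorm": True,
    }


class ConvStack(Module):
    """Stack of Conv2d (+ optional BatchNorm2d) + ReLU layers."""

    def __init__(self, in_channels: int = 3, channels=(16, 32, 64, 128, 256),
                 strides=(1, 2, 2, 2, 2), kernel: int = 3, padding: int = 1,
                 batchnorm: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.convs = []
        self.bns = []
        prev = in_channels
        for c, s in zip(channels, strides):
            self.convs.append(Conv2d(prev, c, kernel=kernel, stride=s, padding=padding, rng=rng))
            self.bns.append(BatchNorm2d(c) if batchnorm else None)
            prev = c
        self.bns = [b for b in self.bns]  # keep None placeholders
        self.channels = tuple(channels)
        self.strides = tuple(strides)
        self.kernel = kernel
        self.padding = padding
        self.batchnorm = batchnorm
        self.in_channels = in_channels
        self.frozen = False

    def parameters(self):
        params = []
        for conv in self.convs:
            params.extend([conv.weight, conv.bias])
        for bn in self.bns:
            if bn is not None:
                params.extend([bn.gamma, bn.beta])
        return params

    def named_parameters(self, prefix: str = ""):
        out = []
        for i, conv in enumerate(self.convs):
            out.append((f"{prefix}convs.{i}.weight", conv.weight))
            out.append((f"{prefix}convs.{i}.bias", conv.bias))
        for i, bn in enumerate(self.bns):
            if bn is not None:
                out.append((f"{prefix}bns.{i}.gamma", bn.gamma))
                out.append((f"{prefix}bns.{i}.beta", bn.beta))
        return out

    def out_spatial(self, h: int) -> int:
        for conv in self.convs:
            h = conv.output_size(h)
            if h <= 0:
                raise ValueError("input spatial size incompatible with conv stride plan")
        return h

    def n_features(self, h: int) -> int:
        return self.channels[-1] * self.out_spatial(h) ** 2

    def freeze(self) -> None:
        """Freeze weights and put normalization layers in inference mode."""
        for p in self.parameters():
            p.requires_grad = False
        self.eval()
        self.frozen = True

    def train(self):
        if self.frozen:
            return  # normalization layers stay in inference mode once frozen
        super().train()
        for bn in self.bns:
            if bn is not None:
                bn.train()
        for c in self.convs:
            c.train()

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, bn in zip(self.convs, self.bns):
            h = conv(h)
            if bn is not None:
                h = bn(h)
            h = h.relu()
        return h

    def features(self, x) -> Tensor:
        """Flattened feature vector h(x); shape (batch, n_features)."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        h = self(x)
        return h.reshape(h.shape[0], -1)


def extract_features(conv: ConvStack, x: np.ndarray) -> np.ndarray:
    """Run inputs through a (frozen) conv stack, returning the flattened
    post-ReLU feature vectors as a plain array."""
    was_training = conv.training
    conv.eval()
    out = conv.features(x).data
    if was_training and not conv.frozen:
        conv.train()
    return out


class DeconvStack(Module):
    """Mirror of :class:`ConvStack` for pixel-level decoding: transposed
    convolutions upsampling back to the input resolution; the final layer
    has no normalization or nonlinearity."""

    def __init__(self, in_channels: int, out_channels: int = 3,
                 channels=(128, 64, 32, 16), rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.deconvs = []
        self.bns = []
        prev = in_channels
        for c in channels:
            self.deconvs.append(ConvTranspose2d(prev, c, kernel=4, stride=2, padding=1, rng=rng))
            self.bns.append(BatchNorm2d(c))
            prev = c
        self.final = ConvTranspose2d(prev, out_channels, kernel=3, stride=1, padding=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for deconv, bn in zip(self.deconvs, self.bns):
            h = bn(deconv(h))
            h = h.relu()
        return self.final(h)


# ---------------------------------------------------------------------------
# classifier

class Classifier(Module):
    """Base network: optional conv stack, fully connected ReLU hidden
    layers, linear output layer with one unit per class."""

    def __init__(self, input_shape: tuple[int, int, int], hidden_layers: list[int],
                 n_classes: int, conv: ConvStack | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.input_shape = tuple(input_shape)
        self.conv = conv
        c, h, w = input_shape
        n_in = conv.n_features(h) if conv is not None else c * h * w
        self.n_features_in = n_in
        self.mlp = MLP([n_in] + list(hidden_layers), rng=rng, final_activation="relu")
        last = hidden_layers[-1] if hidden_layers else n_in
        self.head = Linear(last, n_classes, rng=rng)
        self.n_classes = n_classes
        self.hidden_widths = list(hidden_layers)

    def _embed(self, x, from_hidden: bool = False) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if from_hidden:
            return t.reshape(t.shape[0], -1)
        if self.conv is not None:
            return self.conv.features(t)
        return t.reshape(t.shape[0], -1)

    def hidden(self, x, masks=None, from_hidden: bool = False) -> Tensor:
        """Final hidden-layer activations (post-ReLU), optionally gated."""
        return self._mlp_forward(self._embed(x, from_hidden), masks)

    def _mlp_forward(self, feats: Tensor, masks) -> Tensor:
        h = feats
        for i, layer in enumerate(self.mlp.layers):
            h = layer(h)
            h = h.relu()
            if masks is not None and i < len(masks) and masks[i] is not None:
                h = h * Tensor(np.asarray(masks[i], dtype=np.float64))
        return h

    def logits(self, x, masks=None, from_hidden: bool = False) -> Tensor:
        return self.head(self.hidden(x, masks=masks, from_hidden=from_hidden))


# ---------------------------------------------------------------------------
# gating masks

@dataclass
class GatingMaskSet:
    """Per-context, per-hidden-layer binary keep-masks.

    ``masks[context_id][layer]`` is a float {0,1} vector of the layer's
    width with exactly ``round(X/100 * width)`` zeros (gated units)."""

    masks: dict[int, list[np.ndarray]]
    gate_fraction: float
    seed: int
    layer_widths: list[int]

    def keep(self, context_id: int) -> list[np.ndarray]:
        if context_id not in self.masks:
            raise KeyError(f"no gating mask for context {context_id}")
        return self.masks[context_id]

    def batch(self, context_ids) -> list[np.ndarray]:
        """Stack per-sample masks: list over layers of (batch, width)."""
        ids = np.asarray(context_ids, dtype=int)
        return [
            np.stack([self.keep(int(c))[layer] for c in ids])
            for layer in range(len(self.layer_widths))
        ]


def make_masks(n_contexts: int, layer_widths: list[int], X: float, seed: int,
               context_ids=None) -> GatingMaskSet:
    """Draw random gating masks: per context and hidden layer, exactly
    round(X/100 * width) units are gated (activation forced to 0)."""
    if not 0 <= X <= 100:
        raise ValueError("gate percentage X must be in [0, 100]")
    if context_ids is None:
        context_ids = range(1, n_contexts + 1)
    context_ids = list(context_ids)
    rng = np.random.default_rng(seed)
    masks: dict[int, list[np.ndarray]] = {}
    for cid in context_ids:
        layer_masks = []
        for width in layer_widths:
            n_gated = int(np.floor(X / 100.0 * width + 0.5))  # round half up
            keep = np.ones(width)
            gated = rng.choice(width, size=n_gated, replace=False)
            keep[gated] = 0.0
            layer_masks.append(keep)
        masks[cid] = layer_masks
    return GatingMaskSet(masks, gate_fraction=X, seed=seed, layer_widths=list(layer_widths))


# ---------------------------------------------------------------------------
# Gaussian-mixture latent prior

class GenerativePrior(Module):
    """Trainable per-class modes N(mu_c, sigma_c^2 I) over the latent space.

    Modes are initialized at the standard normal (mu=0, sigma=1) when a
    class is first seen; the class prior is uniform over seen classes."""

    def __init__(self, n_classes: int, latent_dim: int):
        super().__init__()
        self.mu = Parameter(np.zeros((n_classes, latent_dim)))
        self.log_sigma = Parameter(np.zeros((n_classes, latent_dim)))
        self.n_classes = n_classes
        self.latent_dim = latent_dim
        self.seen: set[int] = set()

    def mark_seen(self, class_ids) -> None:
        self.seen.update(int(c) for c in class_ids)

    def mode(self, class_id: int) -> tuple[np.ndarray, np.ndarray]:
        if class_id not in self.seen:
            raise RuntimeError(f"class {class_id} has no initialized prior mode")
        sigma = np.exp(np.clip(self.log_sigma.data[class_id], -LOG_SIGMA_CLAMP, LOG_SIGMA_CLAMP))
        return self.mu.data[class_id], sigma

    def sample(self, rng: np.random.Generator, class_id: int | None = None,
               n: int = 1, classes_allowed=None) -> tuple[np.ndarray, np.ndarray]:
        """Draw latent vectors; returns (z, intended class per sample)."""
        if class_id is not None:
            classes = np.full(n, int(class_id))
            if class_id not in self.seen:
                raise RuntimeError(f"class {class_id} has no initialized prior mode")
        else:
            pool = sorted(self.seen if classes_allowed is None
                          else (self.seen & set(int(c) for c in classes_allowed)))
            if not pool:
                raise RuntimeError("no seen classes to sample the prior from")
            classes = rng.choice(pool, size=n)
        mu = self.mu.data[classes]
        sigma = np.exp(np.clip(self.log_sigma.data[classes], -LOG_SIGMA_CLAMP, LOG_SIGMA_CLAMP))
        z = mu + sigma * rng.standard_normal((n, self.latent_dim))
        return z, classes


def sample_prior(prior: GenerativePrior | None, rng: np.random.Generator,
                 class_id: int | None = None, n: int = 1, latent_dim: int | None = None,
                 classes_allowed=None) -> tuple[np.ndarray, np.ndarray | None]:
    """Sample latents from the Gaussian-mixture prior, or from the standard
    normal when no mixture prior is used (`prior` is None)."""
    if prior is None:
        if latent_dim is None:
            raise ValueError("latent_dim required for the standard-normal prior")
        return rng.standard_normal((n, latent_dim)), None
    return prior.sample(rng, class_id=class_id, n=n, classes_allowed=classes_allowed)


# ---------------------------------------------------------------------------
# VAE and replay-through-feedback model

class VAE(Module):
    """Symmetric VAE generator.

    Encoder: (frozen conv stack ->) fully connected ReLU layers -> Gaussian
    latent layer (mean and log-sd heads).  Decoder: fully connected ReLU
    layers -> either a sigmoid pixel head ("pixel" level), a ReLU feature
    head ("hidden" level), or a transposed-convolution stack when decoding
    natural images at pixel level.
    """

    def __init__(self, input_shape: tuple[int, int, int], hidden_layers: list[int],
                 latent_dim: int = 100, conv: ConvStack | None = None,
                 deconv: bool = False, internal: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.input_shape = tuple(input_shape)
        self.conv = conv
        self.internal = internal
        c, h, w = input_shape
        if conv is not None:
            n_in = conv.n_features(h)
            self._conv_out_shape = (conv.channels[-1], conv.out_spatial(h), conv.out_spatial(h))
        else:
            n_in = c * h * w
            self._conv_out_shape = None
        self.n_features_in = n_in
        self.latent_dim = latent_dim
        sizes = [n_in] + list(hidden_layers)
        self.enc_mlp = MLP(sizes, rng=rng, final_activation="relu")
        last = sizes[-1]
        self.mu_head = Linear(last, latent_dim, rng=rng)
        self.log_sigma_head = Linear(last, latent_dim, rng=rng)
        dec_sizes = [latent_dim] + list(reversed(hidden_layers))
        self.dec_mlp = MLP(dec_sizes, rng=rng, final_activation="relu")
        dec_last = dec_sizes[-1]
        self.dec_widths = dec_sizes[1:]
        if internal:
            # decoded hidden activations share the nonnegative support of the
            # post-ReLU conv features
            self.out_head = Linear(dec_last, n_in, rng=rng)
            self.deconv = None
        elif deconv and conv is not None:
            self.out_head = Linear(dec_last, n_in, rng=rng)
            self.deconv = DeconvStack(self._conv_out_shape[0], out_channels=c, rng=rng)
        else:
            self.out_head = Linear(dec_last, c * h * w, rng=rng)
            self.deconv = None

    # -- encoder ---------------------------------------------------------
    def _embed(self, x, from_hidden: bool = False) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if from_hidden or self.conv is None:
            return t.reshape(t.shape[0], -1)
        return self.conv.features(t)

    def encoder_hidden(self, x, from_hidden: bool = False) -> Tensor:
        return self.enc_mlp(self._embed(x, from_hidden))

    def encode(self, x, from_hidden: bool = False) -> tuple[Tensor, Tensor, Tensor]:
        """Posterior parameters: returns (mu, log_sigma, final hidden)."""
        hid = self.encoder_hidden(x, from_hidden)
        mu = self.mu_head(hid)
        log_sigma = self.log_sigma_head(hid).clamp(-LOG_SIGMA_CLAMP, LOG_SIGMA_CLAMP)
        return mu, log_sigma, hid

    @staticmethod
    def reparameterize(mu: Tensor, log_sigma: Tensor, eps: np.ndarray) -> Tensor:
        """z = mu + sigma * eps (reparameterization trick)."""
        return mu + log_sigma.exp() * Tensor(np.asarray(eps, dtype=np.float64))

    # -- decoder ---------------------------------------------------------
    def decode(self, z, masks: list[np.ndarray] | None = None,
               level: str = "pixel") -> Tensor:
        """Decode latents; gated decoder units contribute exactly zero.

        level="pixel" returns values in (0,1) (sigmoid squashing) unless a
        deconv stack handles the upsampling; level="hidden" returns the
        decoded feature vector (ReLU support)."""
        t = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))
        h = t
        for i, layer in enumerate(self.dec_mlp.layers):
            h = layer(h)
            h = h.relu()
            if masks is not None and i < len(masks) and masks[i] is not None:
                h = h * Tensor(np.asarray(masks[i], dtype=np.float64))
        out = self.out_head(h)
        if level == "hidden" or self.internal:
            return out.relu()
        if self.deconv is not None:
            cc, hh, ww = self._conv_out_shape
            img = self.deconv(out.relu().reshape(out.shape[0], cc, hh, ww))
            return img.reshape(img.shape[0], -1).sigmoid()
        return out.sigmoid()

    def reconstruct(self, x, eps: np.ndarray, masks=None, from_hidden: bool = False,
                    level: str = "pixel") -> tuple[Tensor, Tensor, Tensor]:
        """Full pass: encode, reparameterize with the given noise, decode."""
        mu, log_sigma, _ = self.encode(x, from_hidden=from_hidden)
        z = self.reparameterize(mu, log_sigma, eps)
        return self.decode(z, masks=masks, level=level), mu, log_sigma


class RtfModel(VAE):
    """Replay-through-feedback model: a symmetric VAE with a softmax
    classification head added to the final hidden layer of the encoder.

    Classification uses only the feedforward (encoder) path; gating applies
    only to decoder layers, so inference is unaffected by the generative
    parameters."""

    def __init__(self, input_shape, hidden_layers, n_classes: int,
                 latent_dim: int = 100, conv: ConvStack | None = None,
                 deconv: bool = False, internal: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__(input_shape, hidden_layers, latent_dim=latent_dim,
                         conv=conv, deconv=deconv, internal=internal, rng=rng)
        last = ([self.n_features_in] + list(hidden_layers))[-1]
        self.head = Linear(last, n_classes, rng=rng)
        self.n_classes = n_classes
        self.hidden_widths = list(hidden_layers)

    def logits(self, x, masks=None, from_hidden: bool = False) -> Tensor:
        # `masks` kept for interface parity with Classifier (XdG applies to
        # the classifier path; unused for the RtF encoder by default)
        hid = self.encoder_hidden(x, from_hidden=from_hidden)
        return self.head(hid)


# ---------------------------------------------------------------------------
# inference

def classify(model, x, active, masks=None, from_hidden: bool = False) -> np.ndarray:
    """Class probabilities with softmax normalization restricted to the
    active output units; inactive classes get probability exactly 0."""
    active = sorted(set(int(a) for a in active))
    if not active:
        raise ValueError("active set must be non-empty")
    logits = model.logits(x, masks=masks, from_hidden=from_hidden).data
    sub = logits[:, active]
    sub = sub - sub.max(axis=1, keepdims=True)
    e = np.exp(sub)
    probs_active = e / e.sum(axis=1, keepdims=True)
    probs = np.zeros_like(logits)
    probs[:, active] = probs_active
    return probs


# ---------------------------------------------------------------------------
# serialization

def save_model(model: Module, path, manifest: dict | None = None) -> None:
    """Save parameters to NPZ with a JSON architecture manifest alongside."""
    state = model.state_dict()
    np.savez(path, **state)
    if manifest is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def load_model_arrays(path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
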