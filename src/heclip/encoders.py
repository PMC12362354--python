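"""Image and spot encoders mapping both modalities into a shared embedding space.

The image path is a convolutional backbone whose pooled features pass through
a projection head

    h1  = GELU(W1 z + b1)
    h2  = Dropout(W2 h1 + b2)
    out = LayerNorm(h1 + h2)

and the spot path is a single linear map from the gene panel dimension d to
d_o followed by an identical projection head. Both produce batch x d_o
embeddings, which the contrastive loss and the retrieval stage consume.

The working backbone is ``tiny_cnn`` — three stride-2 conv blocks and a
global average pool — sized so the whole pipeline trains on one CPU core in
minutes. A ``resnet50`` backbone name is reserved for the full-scale
architecture; it requires a GPU deep-learning runtime with pretrained
weights and is not available here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .types import EmbeddingMatrix

_TINY_CNN_CHANNELS = (16, 32, 64)


@dataclass
class ImageEncoderConfig:
    backbone: str = "tiny_cnn"
    pretrained: bool = False
    feature_dim: int | None = None  # derived from the backbone when None
    d_o: int = 256
    dropout_rate: float = 0.1
    layernorm_eps: float = 1e-5
    l2_normalize: bool = False
    freeze_backbone: bool = False

    def __post_init__(self) -> None:
        if self.backbone not in ("tiny_cnn", "resnet50"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone == "resnet50":
            raise NotImplementedError(
                "the resnet50 backbone requires a deep-learning runtime with "
                "pretrained weights; use backbone='tiny_cnn'"
            )
        if self.feature_dim is None:
            self.feature_dim = _TINY_CNN_CHANNELS[-1]


class ProjectionHead(nn.Module):
    """Linear -> GELU, Linear -> Dropout, residual add, LayerNorm."""

    def __init__(self, d_in: int, d_o: int, dropout_rate: float, eps: float, rng: np.random.Generator):
        self.lin1 = nn.Linear(d_in, d_o, rng)
        self.act = nn.GELU()
        self.lin2 = nn.Linear(d_o, d_o, rng)
        self.drop = nn.Dropout(dropout_rate, rng)
        self.norm = nn.LayerNorm(d_o, eps=eps)

    def forward(self, z: np.ndarray) -> np.ndarray:
        h1 = self.act.forward(self.lin1.forward(z))
        h2 = self.drop.forward(self.lin2.forward(h1))
        return self.norm.forward(h1 + h2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.norm.backward(gout)
        g_h1 = g + self.lin2.backward(self.drop.backward(g))
        return self.lin1.backward(self.act.backward(g_h1))


class ImageEncoder(nn.Module):
    """Backbone features, global-average-pooled, projected to d_o."""

    def __init__(self, config: ImageEncoderConfig, rng: np.random.Generator):
        self.config = config
        layers: list[nn.Module] = []
        c_prev = 3
        for c in _TINY_CNN_CHANNELS:
            layers.append(nn.Conv2d(c_prev, c, kernel=3, stride=2, padding=1, rng=rng))
            layers.append(nn.ReLU())
            c_prev = c
        layers.append(nn.GlobalAvgPool())
        self.backbone = nn.Sequential(layers)
        self.head = ProjectionHead(
            config.feature_dim, config.d_o, config.dropout_rate, config.layernorm_eps, rng
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.head.backward(gout)
        if self.config.freeze_backbone:
            return g
        return self.backbone.backward(g)


class SpotEncoder(nn.Module):
    """Shallow linear embed (d -> d_o) followed by a projection head."""

    def __init__(self, d: int, config: ImageEncoderConfig, rng: np.random.Generator):
        self.d = d
        self.embed = nn.Linear(d, config.d_o, rng)
        self.head = ProjectionHead(config.d_o, config.d_o, config.dropout_rate, config.layernorm_eps, rng)

    def pre_projection(self, expression: np.ndarray) -> np.ndarray:
        """The linear embedding before the projection head (exactly linear in
        the input when the bias is zero; exposed for diagnostics)."""
        return np.asarray(expression, dtype=nn.DTYPE) @ self.embed.W.value + self.embed.b.value

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.embed.forward(x))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.embed.backward(self.head.backward(gout))


@dataclass
class HeclipModel:
    """Both encoders plus the config needed to rebuild them."""

    image_encoder: ImageEncoder
    spot_encoder: SpotEncoder
    config: ImageEncoderConfig
    n_genes: int

    def set_training(self, flag: bool) -> None:
        self.image_encoder.set_training(flag)
        self.spot_encoder.set_training(flag)

    def named_params(self):
        yield from self.image_encoder.named_params("image.")
        yield from self.spot_encoder.named_params("spot.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        image = {k[len("image."):]: v for k, v in state.items() if k.startswith("image.")}
        spot = {k[len("spot."):]: v for k, v in state.items() if k.startswith("spot.")}
        self.image_encoder.load_state_dict(image)
        self.spot_encoder.load_state_dict(spot)


def build_model(n_genes: int, config: ImageEncoderConfig | None = None, seed: int = 0) -> HeclipModel:
    """Construct a fresh model with reproducible initialization."""
    config = config or ImageEncoderConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    image_encoder = ImageEncoder(config, rng)
    spot_encoder = SpotEncoder(n_genes, config, rng)
    return HeclipModel(image_encoder, spot_encoder, config, n_genes)


def preprocess_patches(patches: np.ndarray) -> np.ndarray:
    """uint8 H&E patches -> float32 in [0, 1], NHWC."""
    patches = np.asarray(patches)
    if patches.ndim == 3:
        patches = patches[None]
    if patches.ndim != 4 or patches.shape[3] != 3:
        raise ValueError("patches must be (n, H, W, 3)")
    if np.issubdtype(patches.dtype, np.floating) and not np.all(np.isfinite(patches)):
        raise ValueError("patch pixels contain NaN/inf")
    return (patches.astype(nn.DTYPE) / 255.0) if patches.dtype == np.uint8 else patches.astype(nn.DTYPE)


def _maybe_normalize(values: np.ndarray, config: ImageEncoderConfig) -> tuple[np.ndarray, bool]:
    if not config.l2_normalize:
        return values, False
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return values / norms, True


def encode_images(model: HeclipModel, patches: np.ndarray, training: bool = False) -> EmbeddingMatrix:
    """Embed a batch of RGB patches; deterministic in evaluation mode."""
    x = preprocess_patches(patches)
    if x.shape[0] == 0:
        raise ValueError("empty patch batch")
    model.image_encoder.set_training(training)
    values = model.image_encoder.forward(x)
    values, normed = _maybe_normalize(values, model.config)
    return EmbeddingMatrix(values, "image", normalized=normed)


def encode_spots(model: HeclipModel, expression: np.ndarray, training: bool = False) -> EmbeddingMatrix:
    """Embed a batch of expression vectors (batch x d)."""
    x = np.asarray(expression, dtype=nn.DTYPE)
    if x.ndim == 1:
        x = x[None]
    if x.shape[1] != model.spot_encoder.d:
        raise ValueError(f"expression width {x.shape[1]} != trained gene panel size {model.spot_encoder.d}")
    model.spot_encoder.set_training(training)
    values = model.spot_encoder.forward(x)
    values, normed = _maybe_normalize(values, model.config)
    return EmbeddingMatrix(values, "spot", normalized=normed)
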