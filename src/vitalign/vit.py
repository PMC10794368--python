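"""Compact Vision Transformer with an expose-everything forward pass.

The forward pass returns logits, the full stack of post-softmax attention
maps (one ``(B, H, N, N)`` tensor per block) and the pre-head class-token
features. The classification head grows as new classes arrive, preserving
the rows of previously learned classes bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import tensor as T
from .errors import ConfigurationError, DimensionError
from .tensor import Tensor


@dataclass(frozen=True)
class ViTConfig:
    """Architecture hyperparameters for the backbone.

    The defaults are a desk-scale configuration: 32x32 inputs, 8x8 patches
    (16 patches + class token), 4 blocks of 4 heads at embedding width 96.
    """

    image_size: int = 32
    patch_size: int = 8
    channels: int = 3
    embed_dim: int = 96
    depth: int = 4
    heads: int = 4
    mlp_ratio: float = 2.0
    dropout_rate: float = 0.0
    # attention projections need a larger init than the 0.02 used elsewhere:
    # at desk scale, std 0.02 leaves every attention row exactly uniform and
    # the maps carry no routing structure to align
    qkv_init_std: float = 0.15

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} not divisible by patch_size "
                f"{self.patch_size}")
        if self.embed_dim % self.heads != 0:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} not divisible by heads {self.heads}")
        if self.head_dim <= 0:
            raise ConfigurationError("head_dim must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def seq_len(self) -> int:
        return self.n_patches + 1  # class token prepended

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * self.channels


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples clipped to two standard deviations."""
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


def scaled_dot_product_attention(q: Tensor, k: Tensor, v: Tensor,
                                 d: int) -> tuple[Tensor, Tensor]:
    """Return ``(Z, A)``: the value-weighted output and row-stochastic weights.

    ``A = softmax(q k^T / sqrt(d))`` along the key axis; ``Z = A v``.
    """
    if d <= 0:
        raise ConfigurationError(f"head dimension must be positive, got {d}")
    if q.shape != k.shape or q.shape != v.shape:
        raise DimensionError(
            f"Q/K/V shapes differ: {q.shape} vs {k.shape} vs {v.shape}")
    scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) \
        * (1.0 / np.sqrt(d))
    attn = T.softmax(scores, axis=-1)
    return attn @ v, attn


class ViTModel:
    """Backbone + growing linear head, parameters stored as a flat dict."""

    def __init__(self, config: ViTConfig, n_classes: int, seed: int = 0):
        if n_classes < 1:
            raise ConfigurationError("need at least one class")
        self.config = config
        self.k_classes = n_classes
        self.rng = np.random.default_rng(seed)
        self._seed = seed
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- parameters -----------------------------------------------------------

    def _param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self) -> None:
        cfg, rng = self.config, self.rng
        D, Hd = cfg.embed_dim, int(cfg.embed_dim * cfg.mlp_ratio)
        self._param("patch_embed.weight", trunc_normal(rng, (cfg.patch_dim, D)))
        self._param("patch_embed.bias", np.zeros(D))
        self._param("cls_token", trunc_normal(rng, (1, 1, D)))
        self._param("pos_embed", trunc_normal(rng, (1, cfg.seq_len, D)))
        for i in range(cfg.depth):
            p = f"blocks.{i}."
            self._param(p + "ln1.gamma", np.ones(D))
            self._param(p + "ln1.beta", np.zeros(D))
            self._param(p + "qkv.weight",
                        trunc_normal(rng, (D, 3 * D), std=cfg.qkv_init_std))
            self._param(p + "qkv.bias", np.zeros(3 * D))
            self._param(p + "proj.weight", trunc_normal(rng, (D, D)))
            self._param(p + "proj.bias", np.zeros(D))
            self._param(p + "ln2.gamma", np.ones(D))
            self._param(p + "ln2.beta", np.zeros(D))
            self._param(p + "mlp.fc1.weight", trunc_normal(rng, (D, Hd)))
            self._param(p + "mlp.fc1.bias", np.zeros(Hd))
            self._param(p + "mlp.fc2.weight", trunc_normal(rng, (Hd, D)))
            self._param(p + "mlp.fc2.bias", np.zeros(D))
        self._param("norm.gamma", np.ones(D))
        self._param("norm.beta", np.zeros(D))
        self._param("head.weight", trunc_normal(rng, (D, self.k_classes)))
        self._param("head.bias", np.zeros(self.k_classes))

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def head_parameter_names(self) -> list[str]:
        return ["head.weight", "head.bias"]

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def checksum(self) -> float:
        """Cheap change detector over all parameters."""
        return float(sum(np.abs(p.data).sum() for p in self.params.values()))

    # -- forward --------------------------------------------------------------

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        cfg = self.config
        b, c, h, w = images.shape
        p = cfg.patch_size
        x = images.reshape(b, c, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 3, 5, 1)  # B, gh, gw, p, p, C
        return x.reshape(b, cfg.n_patches, cfg.patch_dim)

    def forward(self, images: np.ndarray, train: bool = False
                ) -> tuple[Tensor, list[Tensor], Tensor]:
        """Run the backbone; returns (logits, attention stack, features)."""
        cfg = self.config
        images = np.asarray(images, dtype=np.float64)
        expected = (cfg.channels, cfg.image_size, cfg.image_size)
        if images.ndim != 4 or images.shape[1:] != expected:
            raise DimensionError(
                f"expected image batch of shape (B, {expected[0]}, "
                f"{expected[1]}, {expected[2]}), got {images.shape}")
        drop = cfg.dropout_rate if train else 0.0
        rng = self.rng

        x = Tensor(self._patchify(images)) @ self.params["patch_embed.weight"] \
            + self.params["patch_embed.bias"]
        b = images.shape[0]
        cls = Tensor(np.zeros((b, 1, cfg.embed_dim))) + self.params["cls_token"]
        x = T.concat([cls, x], axis=1) + self.params["pos_embed"]
        x = T.dropout(x, drop, rng)

        attn_stack: list[Tensor] = []
        n, h, d = cfg.seq_len, cfg.heads, cfg.head_dim
        for i in range(cfg.depth):
            p = f"blocks.{i}."
            y = T.layer_norm(x, self.params[p + "ln1.gamma"],
                             self.params[p + "ln1.beta"])
            qkv = y @ self.params[p + "qkv.weight"] + self.params[p + "qkv.bias"]
            qkv = qkv.reshape(b, n, 3, h, d).transpose(2, 0, 3, 1, 4)
            z, attn = scaled_dot_product_attention(qkv[0], qkv[1], qkv[2], d)
            attn_stack.append(attn)
            z = z.transpose(0, 2, 1, 3).reshape(b, n, cfg.embed_dim)
            z = z @ self.params[p + "proj.weight"] + self.params[p + "proj.bias"]
            x = x + T.dropout(z, drop, rng)

            y = T.layer_norm(x, self.params[p + "ln2.gamma"],
                             self.params[p + "ln2.beta"])
            y = (y @ self.params[p + "mlp.fc1.weight"]
                 + self.params[p + "mlp.fc1.bias"]).gelu()
            y = T.dropout(y, drop, rng)
            y = y @ self.params[p + "mlp.fc2.weight"] + self.params[p + "mlp.fc2.bias"]
            x = x + T.dropout(y, drop, rng)

        x = T.layer_norm(x, self.params["norm.gamma"], self.params["norm.beta"])
        features = x[:, 0, :]
        logits = features @ self.params["head.weight"] + self.params["head.bias"]
        return logits, attn_stack, features

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class indices, computed without building a graph."""
        out = []
        with T.no_grad():
            for lo in range(0, len(images), batch_size):
                logits, _, _ = self.forward(images[lo:lo + batch_size])
                out.append(np.argmax(logits.data, axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=int)

    # -- head growth ----------------------------------------------------------

    def expand_head(self, new_class_count: int) -> "ViTModel":
        """Grow the head to ``new_class_count`` outputs in place.

        Existing rows are preserved bit-identically; new rows are drawn from
        the model's seeded initializer. Returns ``self`` for chaining.
        """
        if new_class_count <= self.k_classes:
            raise ConfigurationError(
                f"new_class_count must exceed current {self.k_classes}, "
                f"got {new_class_count}")
        extra = new_class_count - self.k_classes
        w = self.params["head.weight"].data
        new_w = np.concatenate(
            [w, trunc_normal(self.rng, (self.config.embed_dim, extra))], axis=1)
        new_b = np.concatenate([self.params["head.bias"].data, np.zeros(extra)])
        self._param("head.weight", new_w)
        self._param("head.bias", new_b)
        self.k_classes = new_class_count
        return self

    # -- snapshot -------------------------------------------------------------

    def snapshot(self) -> "ModelSnapshot":
        return ModelSnapshot.of(self)

    # -- serialization --------------------------------------------------------

    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "k_classes": self.k_classes,
                "seed": self._seed}
        arrays = {k.replace(".", "__"): p.data for k, p in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ViTModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(ViTConfig(**meta["config"]), meta["k_classes"],
                        seed=meta["seed"])
            for key in z.files:
                if key == "__meta__":
                    continue
                model._param(key.replace("__", "."), z[key].copy())
        return model


@dataclass
class ModelSnapshot:
    """Frozen deep copy of a model at the end of a stage.

    The snapshot's forward never builds an autodiff graph, so it can only
    serve as a reference distribution, never be trained.
    """

    model: ViTModel = field(repr=False)
    k_classes: int = 0

    @classmethod
    def of(cls, model: ViTModel) -> "ModelSnapshot":
        frozen = ViTModel.__new__(ViTModel)
        frozen.config = model.config
        frozen.k_classes = model.k_classes
        frozen._seed = model._seed
        frozen.rng = np.random.default_rng(0)  # never consumed (no dropout)
        frozen.params = {k: Tensor(p.data.copy())
                         for k, p in model.params.items()}
        return cls(model=frozen, k_classes=model.k_classes)

    def forward(self, images: np.ndarray) -> tuple[Tensor, list[Tensor], Tensor]:
        with T.no_grad():
            return self.model.forward(images, train=False)

    def checksum(self) -> float:
        return self.model.checksum()
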