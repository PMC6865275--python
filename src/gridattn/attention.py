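"""Soft attention over the grid feature map and the tissue classifier.

The model scores every grid cell with F learnable 3-D convolutional
filters of size k x d x d applied to U (zero padding of 0 in depth and
(d-1)/2 in height/width, so the attention map keeps the grid's spatial
extent).  Because the kernel spans the full feature depth k with no
depth padding, this 3-D convolution is computed as a 2-D convolution
with k input channels and F output channels.

Each filter's score map is normalized with a softmax over the r*c grid
positions, giving a per-head attention map alpha_f that is nonnegative
and sums to one — the weights of an affine combination of the cell
feature vectors.  The F attended k-vectors are concatenated into the
tissue representation z (length F*k), regularized with dropout
(p = 0.5) and mapped by a single fully connected layer to the four
class logits.  Training uses only the softmax cross-entropy against the
tissue-level label; gradients flow through the attention maps into the
backbone, so the network discovers diagnostic regions without any
lesion annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .backbone import Backbone, GridTensor, extract_features, make_backbone
from .classes import CLASS_ORDER, N_CLASSES
from .nn import BatchNorm2d, Conv2d, Dropout, Linear, cross_entropy, softmax
from .preprocessing import GridShape

__all__ = [
    "AttentionConfig",
    "AttentionMap",
    "compute_attention_logits",
    "normalize_attention",
    "attend",
    "classify",
    "AttentionModel",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Attention-module hyperparameters.

    ``n_filters`` attention heads, spatial kernel ``d`` (odd; padding
    (d-1)/2 keeps the r x c extent; the depth dimension spans all k
    features with no padding), dropout probability on z.
    """

    n_filters: int = 64
    kernel: int = 3
    dropout_p: float = 0.5

    def __post_init__(self):
        if self.n_filters < 1:
            raise ValueError("need at least one attention filter")
        if self.kernel % 2 != 1:
            raise ValueError("attention kernel size must be odd")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass
class AttentionMap:
    """Per-head weights over grid cells; each head sums to one."""

    alpha: np.ndarray  # (F, r, c), nonnegative

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=np.float32)
        if a.ndim != 3:
            raise ValueError("alpha must be (F, r, c)")
        if (a < -1e-7).any():
            raise ValueError("attention weights must be nonnegative")
        sums = a.sum(axis=(1, 2))
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("each attention head must sum to 1")
        self.alpha = a

    @property
    def n_heads(self) -> int:
        return self.alpha.shape[0]


def compute_attention_logits(U: GridTensor | np.ndarray, filter_weights: np.ndarray,
                             bias: np.ndarray | None = None) -> np.ndarray:
    """Raw attention scores: F filters of size k x d x d convolved over U.

    ``filter_weights`` has shape (F, k, d, d); zero padding of (d-1)/2
    is applied in height/width and none in depth, so the result is
    (F, r, c).
    """
    u = U.values if isinstance(U, GridTensor) else np.asarray(U, dtype=np.float32)
    f, k, d, d2 = filter_weights.shape
    if d != d2 or d % 2 != 1:
        raise ValueError("attention filters must be square with odd size")
    if k != u.shape[2]:
        raise ValueError(f"filter depth {k} does not match feature dim {u.shape[2]}")
    conv = Conv2d(k, f, d, pad=(d - 1) // 2, bias=bias is not None)
    conv.weight.value = np.asarray(filter_weights, dtype=np.float32)
    if bias is not None:
        conv.bias.value = np.asarray(bias, dtype=np.float32)
    x = u.transpose(2, 0, 1)[None]  # (1, k, r, c)
    return conv.forward(x)[0]


def normalize_attention(logits: np.ndarray) -> AttentionMap:
    """Softmax each head's scores over the r*c grid positions."""
    logits = np.asarray(logits, dtype=np.float32)
    f = logits.shape[0]
    flat = logits.reshape(f, -1)
    return AttentionMap(alpha=softmax(flat, axis=1).reshape(logits.shape))


def attend(U: GridTensor | np.ndarray, alpha: AttentionMap | np.ndarray) -> np.ndarray:
    """Affine combination per head, concatenated: z of length F*k."""
    u = U.values if isinstance(U, GridTensor) else np.asarray(U, dtype=np.float32)
    a = alpha.alpha if isinstance(alpha, AttentionMap) else np.asarray(alpha, dtype=np.float32)
    if a.shape[1:] != u.shape[:2]:
        raise ValueError("attention map and grid shapes disagree")
    z = np.einsum("frc,rck->fk", a, u, optimize=True)
    return z.reshape(-1)


def classify(z: np.ndarray, fc_weight: np.ndarray, fc_bias: np.ndarray,
             dropout_p: float = 0.5, mode: str = "eval",
             rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Dropout (training only) then the linear 4-class head.

    Returns ``(probabilities, logits)``; probabilities are the softmax
    of the logits and sum to one.
    """
    z = np.asarray(z, dtype=np.float32)
    if mode == "train" and dropout_p > 0:
        rng = rng or np.random.default_rng(0)
        mask = (rng.random(z.shape) >= dropout_p) / (1.0 - dropout_p)
        z = z * mask
    logits = fc_weight @ z + fc_bias
    return softmax(logits), logits


class AttentionModel:
    """Backbone + attention module + classifier, trainable end to end.

    The attention convolution, dropout and fully connected head live
    here; the backbone is pluggable.  ``forward`` accepts any grid
    shape — nothing in the module depends on fixed r, c.
    """

    def __init__(self, backbone: Backbone | None = None,
                 config: AttentionConfig = AttentionConfig(), seed: int = 0):
        self.backbone = backbone or make_backbone("tiny", seed=seed)
        self.config = config
        rng = np.random.default_rng(seed + 1)
        k = self.backbone.feature_dim
        self.att_conv = Conv2d(k, config.n_filters, config.kernel,
                               pad=(config.kernel - 1) // 2, rng=rng, name="attention.conv")
        self.dropout = Dropout(config.dropout_p, rng=np.random.default_rng(seed + 2))
        self.fc = Linear(config.n_filters * k, N_CLASSES, rng=rng, name="classifier.fc")
        self._cache = None

    # ------------------------------------------------------------------ params
    def params(self):
        return self.backbone.params() + self.att_conv.params() + self.fc.params()

    def trainable_params(self):
        return [p for p in self.params() if p.trainable]

    # ----------------------------------------------------------------- forward
    def forward_features(self, U: GridTensor, train: bool = False):
        """Attention + head on a precomputed grid tensor."""
        f = self.config.n_filters
        x = U.values.transpose(2, 0, 1)[None]
        logits = self.att_conv.forward(x, train=train)[0]  # (F, r, c)
        alpha = softmax(logits.reshape(f, -1), axis=1).reshape(logits.shape)
        z = np.einsum("frc,rck->fk", alpha, U.values, optimize=True)
        zflat = z.reshape(1, -1)
        zd = self.dropout.forward(zflat, train=train)
        cls_logits = self.fc.forward(zd, train=train)[0]
        self._cache = (U, alpha, z)
        return softmax(cls_logits), cls_logits, AttentionMap(alpha=alpha.copy())

    def forward(self, cells: np.ndarray, grid: GridShape, train: bool = False):
        """Normalized cells -> (class probabilities, attention map).

        Composition of feature extraction, attention scoring, softmax
        normalization, affine combination, dropout and the linear head.
        """
        U = extract_features(cells, self.backbone, grid, train=train)
        probs, _, amap = self.forward_features(U, train=train)
        return probs, amap

    def forward_from_prefix(self, prefix: np.ndarray, grid: GridShape, train: bool = False):
        """Like ``forward`` but starting from cached frozen-prefix activations."""
        feats = self.backbone.suffix_forward(prefix, train=train)
        U = GridTensor(values=feats.reshape(grid.r, grid.c, -1).astype(np.float32),
                       shape=grid, k=feats.shape[1])
        return self.forward_features(U, train=train)

    # ---------------------------------------------------------------- backward
    def backward(self, cls_logits: np.ndarray, label: int,
                 through_backbone: bool = True) -> float:
        """Cross-entropy loss + gradient accumulation for the last forward."""
        U, alpha, z = self._cache
        loss, dlogits = cross_entropy(cls_logits, label)
        dzd = self.fc.backward(dlogits[None, :])
        dz = self.dropout.backward(dzd).reshape(self.config.n_filters, -1)
        # affine combination: direct path to U and path through alpha
        dalpha = np.einsum("fk,rck->frc", dz, U.values, optimize=True)
        dU = np.einsum("frc,fk->rck", alpha, dz, optimize=True)
        # softmax backward per head over grid positions
        inner = (dalpha * alpha).sum(axis=(1, 2), keepdims=True)
        dscore = alpha * (dalpha - inner)
        dx = self.att_conv.backward(dscore[None])[0]  # (k, r, c)
        dU += dx.transpose(1, 2, 0)
        if through_backbone:
            self.backbone.suffix_backward(dU.reshape(-1, U.k))
        return loss

    def loss_and_grad(self, cells: np.ndarray, grid: GridShape, label: int) -> float:
        """One training forward/backward on a single tissue."""
        U = extract_features(cells, self.backbone, grid, train=True)
        _, cls_logits, _ = self.forward_features(U, train=True)
        return self.backward(cls_logits, label)

    # ------------------------------------------------------------- persistence
    def _batchnorms(self):
        def walk(layer):
            if isinstance(layer, BatchNorm2d):
                yield layer
            for child in layer.children():
                yield from walk(child)
        for _, block in [("stem", self.backbone.stem)] + self.backbone.blocks:
            yield from walk(block)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for bn in self._batchnorms():
            state[f"{bn.weight.name}.running_mean"] = bn.running_mean.copy()
            state[f"{bn.weight.name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for bn in self._batchnorms():
            bn.running_mean[...] = state[f"{bn.weight.name}.running_mean"]
            bn.running_var[...] = state[f"{bn.weight.name}.running_var"]

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        meta = dict(config=vars(self.config) | {},
                    backbone=type(self.backbone).__name__,
                    feature_dim=self.backbone.feature_dim,
                    classes=list(CLASS_ORDER))
        if extra:
            meta.update(extra)
        np.savez(path, __meta__=json.dumps({k: v for k, v in meta.items()}),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, backbone: Backbone | None = None) -> "AttentionModel":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg = AttentionConfig(n_filters=meta["config"]["n_filters"],
                              kernel=meta["config"]["kernel"],
                              dropout_p=meta["config"]["dropout_p"])
        if backbone is None:
            name = "resnet18" if meta["backbone"] == "ResNet18Backbone" else "tiny"
            kwargs = {} if name == "resnet18" else {"feature_dim": meta["feature_dim"]}
            backbone = make_backbone(name, **kwargs)
        model = cls(backbone=backbone, config=cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model
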