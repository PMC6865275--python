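"""Per-cell feature extraction: the grid feature map U.

A shared convolutional backbone maps every normalized grid cell to a
k-vector; stacking the vectors in row-major grid order yields the
r x c x k tensor U that the attention module consumes.  Extraction is
cell-local, so any grid shape works without reconfiguration.

Two backbones are provided behind one contract:

* :class:`TinyCNN` — a three-block CNN (k = 16 by default) whose stem is
  a parameter-free 8x average pool, small enough to train end to end on
  a CPU in minutes.  This is the default everywhere at desk scale.
* :class:`ResNet18Backbone` — the ResNet-18 layout (k = 512, final fully
  connected layer removed, global average pooling) for paper-scale
  work.  Pretrained weights can be loaded from a checkpoint when
  available; they are not required.

The freeze policy mirrors the training recipe: every residual/conv
block except the last is frozen as a regularizer, and batch
normalization in frozen blocks runs in inference mode so its statistics
cannot drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    MaxPool2d,
    ReLU,
    Sequential,
)
from .preprocessing import GridShape

__all__ = [
    "GridTensor",
    "Backbone",
    "TinyCNN",
    "ResNet18Backbone",
    "BasicBlock",
    "extract_features",
    "apply_freeze_policy",
    "make_backbone",
]


@dataclass
class GridTensor:
    """The r x c x k grid feature map U."""

    values: np.ndarray  # (r, c, k) float32
    shape: GridShape
    k: int

    def __post_init__(self):
        if self.values.shape != (self.shape.r, self.shape.c, self.k):
            raise ValueError("GridTensor values do not match (r, c, k)")
        if not np.isfinite(self.values).all():
            raise ValueError("GridTensor contains non-finite entries")


class BasicBlock(Layer):
    """Residual block: conv-BN-ReLU-conv-BN + identity/projection skip."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "block"):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, bias=False,
                            rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(out_ch, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, pad=1, bias=False,
                            rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_ch, name=f"{name}.bn2")
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, pad=0,
                                    bias=False, rng=rng, name=f"{name}.down")
            self.down_bn = BatchNorm2d(out_ch, name=f"{name}.down_bn")
        else:
            self.down_conv = self.down_bn = None

    def params(self):
        ps = (self.conv1.params() + self.bn1.params()
              + self.conv2.params() + self.bn2.params())
        if self.down_conv is not None:
            ps += self.down_conv.params() + self.down_bn.params()
        return ps

    def children(self):
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]
        if self.down_conv is not None:
            subs += [self.down_conv, self.down_bn]
        return subs

    def forward(self, x, train=False):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.down_conv is not None:
            sc = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            sc = x
        return self.relu2.forward(out + sc, train)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dsc = d
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(dmain)))
        if self.down_conv is not None:
            dsc = self.down_conv.backward(self.down_bn.backward(dsc))
        return dmain + dsc


class Backbone:
    """Contract: shared-weight map from normalized cells to k-vectors.

    Subclasses define ``stem`` (a Layer, possibly parameter-free) and
    ``blocks`` (ordered ``(name, Layer)`` pairs); a global average pool
    reduces the final activation to the k-vector.  ``frozen`` marks the
    stem/blocks whose parameters must not train.
    """

    feature_dim: int
    stem: Layer
    blocks: list[tuple[str, Layer]]

    def __init__(self):
        self._frozen: set[str] = set()

    # -- freeze bookkeeping -------------------------------------------------
    def freeze(self, names) -> None:
        self._frozen |= set(names)
        for name, layer in [("stem", self.stem)] + self.blocks:
            for p in layer.params():
                if name in self._frozen:
                    p.trainable = False

    def unfreeze_all(self) -> None:
        self._frozen.clear()
        for p in self.params():
            p.trainable = True

    def is_frozen(self, name: str) -> bool:
        return name in self._frozen

    def params(self):
        return self.stem.params() + [p for _, l in self.blocks for p in l.params()]

    def trainable_params(self):
        return [p for p in self.params() if p.trainable]

    # -- forward / backward -------------------------------------------------
    def _stage_train_flag(self, name: str, train: bool) -> bool:
        # frozen blocks run batch norm in inference mode even during training
        return train and name not in self._frozen

    def _first_trainable_index(self) -> int:
        for i, (name, _) in enumerate(self.blocks):
            if name not in self._frozen:
                return i
        return len(self.blocks)

    def frozen_prefix(self, cells: np.ndarray) -> np.ndarray:
        """Run the stem and all leading frozen blocks (no caching needed)."""
        x = self._to_nchw(cells)
        x = self.stem.forward(x, train=False)
        for name, layer in self.blocks[: self._first_trainable_index()]:
            x = layer.forward(x, train=False)
        return x

    def suffix_forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Run the remaining (trainable) blocks plus global average pooling."""
        self._gap = GlobalAvgPool()
        self._suffix = self.blocks[self._first_trainable_index():]
        for name, layer in self._suffix:
            x = layer.forward(x, train=self._stage_train_flag(name, train))
        return self._gap.forward(x, train=train)

    def suffix_backward(self, dfeat: np.ndarray) -> None:
        d = self._gap.backward(dfeat)
        for _, layer in reversed(self._suffix):
            d = layer.backward(d)

    def features(self, cells: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, 3) normalized cells -> (N, k) feature matrix."""
        return self.suffix_forward(self.frozen_prefix(cells), train=train)

    @staticmethod
    def _to_nchw(cells: np.ndarray) -> np.ndarray:
        cells = np.asarray(cells, dtype=np.float32)
        if cells.ndim != 4 or cells.shape[-1] != 3:
            raise ValueError("expected cells of shape (N, H, W, 3)")
        return np.ascontiguousarray(cells.transpose(0, 3, 1, 2))


class TinyCNN(Backbone):
    """Three-block CPU-scale backbone; stem is a fixed 8x average pool."""

    def __init__(self, feature_dim: int = 16, seed: int = 0, stem_pool: int = 8):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        self.stem = AvgPool2d(stem_pool)
        self.blocks = [
            ("block1", Sequential(Conv2d(3, 8, 3, pad=1, rng=rng, name="b1.conv"),
                                  BatchNorm2d(8, name="b1.bn"), ReLU(), AvgPool2d(2))),
            ("block2", Sequential(Conv2d(8, 16, 3, pad=1, rng=rng, name="b2.conv"),
                                  BatchNorm2d(16, name="b2.bn"), ReLU(), AvgPool2d(2))),
            ("block3", Sequential(Conv2d(16, feature_dim, 3, pad=1, rng=rng, name="b3.conv"),
                                  BatchNorm2d(feature_dim, name="b3.bn"), ReLU())),
        ]


class ResNet18Backbone(Backbone):
    """ResNet-18 layout with the classification layer removed (k = 512).

    The eight residual blocks are exposed individually so the freeze
    policy ("all residual blocks except the last one") applies verbatim.
    """

    def __init__(self, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.feature_dim = 512
        self.stem = Sequential(Conv2d(3, 64, 7, stride=2, pad=3, bias=False,
                                      rng=rng, name="stem.conv"),
                               BatchNorm2d(64, name="stem.bn"), ReLU(),
                               MaxPool2d(3, 2, pad=1))
        chans = [64, 64, 128, 256, 512]
        self.blocks = []
        for stage in range(4):
            in_ch, out_ch = chans[stage], chans[stage + 1]
            stride = 1 if stage == 0 else 2
            self.blocks.append((f"layer{stage + 1}.0",
                                BasicBlock(in_ch, out_ch, stride, rng,
                                           name=f"layer{stage + 1}.0")))
            self.blocks.append((f"layer{stage + 1}.1",
                                BasicBlock(out_ch, out_ch, 1, rng,
                                           name=f"layer{stage + 1}.1")))


def make_backbone(name: str = "tiny", seed: int = 0, **kwargs) -> Backbone:
    if name == "tiny":
        return TinyCNN(seed=seed, **kwargs)
    if name == "resnet18":
        return ResNet18Backbone(seed=seed, **kwargs)
    raise ValueError(f"unknown backbone {name!r}")


def apply_freeze_policy(backbone: Backbone, freeze_all_but_last: bool = True) -> Backbone:
    """Freeze the stem and every block except the last one.

    Acts in place and returns the backbone.  With the policy disabled,
    everything stays trainable.  A backbone without block structure gets
    a warning and no change.
    """
    if not freeze_all_but_last:
        backbone.unfreeze_all()
        return backbone
    if not getattr(backbone, "blocks", None):
        warnings.warn("backbone exposes no block structure; freeze policy is a no-op",
                      stacklevel=2)
        return backbone
    names = ["stem"] + [n for n, _ in backbone.blocks[:-1]]
    backbone.freeze(names)
    return backbone


def extract_features(cells: np.ndarray, backbone: Backbone,
                     grid: GridShape, train: bool = False) -> GridTensor:
    """Build U by applying the shared backbone to every cell of the grid.

    ``cells`` are the normalized row-major cells from tiling; the output
    is ``U[i, j, :] = backbone(cell at row i, col j)``.
    """
    cells = np.asarray(cells, dtype=np.float32)
    if cells.shape[0] != grid.r * grid.c:
        raise ValueError(f"got {cells.shape[0]} cells for a {grid.r}x{grid.c} grid")
    feats = backbone.features(cells, train=train)
    k = feats.shape[1]
    return GridTensor(values=feats.reshape(grid.r, grid.c, k).astype(np.float32),
                      shape=grid, k=k)
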