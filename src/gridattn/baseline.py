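"""Sliding-window baseline: ROI-crop classifier + heuristic aggregation.

The conventional approach to whole-slide classification trains a
cropped-image classifier on 224 x 224 patches cut from
pathologist-annotated lesion bounding boxes (normal patches come from
lesion-free tissue), slides it densely over each test tissue, and
aggregates the per-window predictions with a thresholded counting
heuristic: a window "votes" for a class when its probability exceeds
that class's confidence threshold, and the tissue receives the
highest-risk class whose vote count reaches its minimum, else normal.
Thresholds and minimum counts are chosen by exhaustive grid search on
the validation set (maximizing mean F1; ties prefer lower thresholds).

Unlike the attention model, this path cannot run without lesion box
annotations — requesting a crop set without any raises
:class:`MissingAnnotationsError`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .backbone import Backbone, make_backbone
from .classes import CLASS_ORDER, NORMAL, class_index
from .evaluation import confusion_matrix, mean_metrics, one_vs_rest_metrics
from .nn import Adam, Linear, softmax, zero_grads
from .preprocessing import ChannelStats, compute_normalization_stats, normalize_cells

__all__ = [
    "MissingAnnotationsError",
    "WindowGrid",
    "HeuristicConfig",
    "CropClassifier",
    "make_crop_set",
    "train_crop_classifier",
    "classify_windows",
    "aggregate",
    "grid_search_heuristic",
]

CROP_PX = 224


class MissingAnnotationsError(ValueError):
    """The sliding-window baseline needs lesion bounding boxes to train."""


@dataclass
class WindowGrid:
    """Per-window class probabilities over one tissue."""

    probs: np.ndarray  # (n_windows, 4), rows sum to 1
    coords: np.ndarray  # (n_windows, 4) boxes (x_min, y_min, x_max, y_max)

    def __post_init__(self):
        if len(self.probs) != len(self.coords):
            raise ValueError("probs and coords disagree")


@dataclass(frozen=True)
class HeuristicConfig:
    """Aggregation rule: per-class confidence thresholds and vote minimums."""

    thresholds: dict = field(default_factory=lambda: {c: 0.5 for c in CLASS_ORDER[1:]})
    min_counts: dict = field(default_factory=lambda: {c: 1 for c in CLASS_ORDER[1:]})

    def __post_init__(self):
        for cls, t in self.thresholds.items():
            class_index(cls)
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold for {cls} outside [0, 1]")
        for cls, m in self.min_counts.items():
            class_index(cls)
            if m < 0:
                raise ValueError("minimum counts must be >= 0")


def make_crop_set(tissues, crop_px: int = CROP_PX, crops_per_box: int = 3,
                  crops_per_normal: int = 3, seed: int = 0):
    """Build the labeled crop dataset for the baseline classifier.

    ``tissues`` carry pixels, a label and lesion boxes.  Crops inside a
    lesion box take the box's class (crop centers stay inside the box);
    lesion-free tissues contribute normal crops from their central
    region.  Boxes narrower than ``crop_px`` in either dimension are
    skipped with a warning.  Raises :class:`MissingAnnotationsError`
    when no tissue has any box annotation (the attention model has no
    such requirement).
    """
    if all(not t.lesion_boxes for t in tissues):
        raise MissingAnnotationsError(
            "no lesion bounding boxes available; the sliding-window baseline "
            "cannot be trained without ROI annotations")
    rng = np.random.default_rng(seed)
    crops, labels = [], []

    def sample_crop(img, x0, y0, x1, y1):
        """Crop of crop_px whose center lies inside [x0,x1) x [y0,y1)."""
        h, w = img.shape[:2]
        cx = int(rng.integers(x0, x1))
        cy = int(rng.integers(y0, y1))
        left = int(np.clip(cx - crop_px // 2, 0, w - crop_px))
        top = int(np.clip(cy - crop_px // 2, 0, h - crop_px))
        return img[top : top + crop_px, left : left + crop_px]

    for t in tissues:
        img = t.pixels
        h, w = img.shape[:2]
        if h < crop_px or w < crop_px:
            warnings.warn(f"tissue {getattr(t, 'source_id', '?')} smaller than a crop; skipped",
                          stacklevel=2)
            continue
        if not t.lesion_boxes:
            for _ in range(crops_per_normal):
                crops.append(sample_crop(img, int(0.3 * w), int(0.3 * h),
                                         int(0.7 * w), int(0.7 * h)))
                labels.append(NORMAL)
            continue
        for cls, x0, y0, x1, y1 in t.lesion_boxes:
            if x1 - x0 < crop_px or y1 - y0 < crop_px:
                warnings.warn(f"lesion box {(x0, y0, x1, y1)} smaller than {crop_px} px; "
                              "skipped", stacklevel=2)
                continue
            # keep centers far enough inside the box that crops stay lesion-pure
            m = crop_px // 2
            for _ in range(crops_per_box):
                crops.append(sample_crop(img, x0 + m, y0 + m, x1 - m, y1 - m))
                labels.append(cls)
    return np.stack(crops), np.asarray(labels)


def _augment_crops(crops: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard crop augmentation: color jitter, random flips, rotations."""
    out = np.empty_like(crops)
    for i, crop in enumerate(crops):
        c = crop.astype(np.float32)
        c = c * rng.uniform(0.9, 1.1) + rng.uniform(-10, 10)  # contrast + brightness
        c = np.clip(c, 0, 255)
        if rng.random() < 0.5:
            c = c[:, ::-1]
        if rng.random() < 0.5:
            c = c[::-1, :]
        c = np.rot90(c, k=int(rng.integers(4)), axes=(0, 1))
        out[i] = c.astype(crops.dtype)
    return out


class CropClassifier:
    """Backbone + linear head predicting the class of a 224-px window."""

    def __init__(self, backbone: Backbone | None = None, seed: int = 0):
        self.backbone = backbone or make_backbone("tiny", seed=seed)
        self.fc = Linear(self.backbone.feature_dim, len(CLASS_ORDER),
                         rng=np.random.default_rng(seed + 1), name="crop.fc")
        self.stats: ChannelStats | None = None

    def params(self):
        return self.backbone.params() + self.fc.params()

    def predict_proba(self, crops: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 224, 224, 3) crops (uint8 or normalized) -> (N, 4) probabilities."""
        x = np.asarray(crops)
        if x.dtype == np.uint8:
            if self.stats is None:
                raise ValueError("classifier has no channel stats; train it first")
            x = normalize_cells(x.astype(np.float32) / 255.0, self.stats)
        logits = self.fc.forward(self.backbone.features(x, train=train), train=train)
        return softmax(logits, axis=1)


def train_crop_classifier(crops: np.ndarray, labels: np.ndarray,
                          epochs: int = 100, batch_size: int = 16, lr: float = 1e-3,
                          weight_decay: float = 1e-4, lr_step: int = 50,
                          lr_gamma: float = 0.1, seed: int = 0,
                          backbone: Backbone | None = None,
                          augment: bool = True) -> CropClassifier:
    """Train the cropped-image classifier with cross-entropy.

    MSRA-initialized backbone (nothing frozen), L2 weight decay and a
    step learning-rate decay (x ``lr_gamma`` every ``lr_step`` epochs).
    Every class present in ``labels`` must have at least one crop.
    """
    present = set(labels.tolist())
    if len(present) < 2:
        raise ValueError("crop training needs at least two classes")
    clf = CropClassifier(backbone=backbone, seed=seed)
    clf.stats = compute_normalization_stats(iter(crops))
    y = np.asarray([class_index(l) for l in labels])
    x_norm_base = crops
    params = clf.params()
    opt = Adam(params, lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    n = len(crops)
    for epoch in range(epochs):
        opt.lr = lr * (lr_gamma ** (epoch // lr_step))
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = x_norm_base[idx]
            if augment:
                batch = _augment_crops(batch, rng)
            xb = normalize_cells(batch.astype(np.float32) / 255.0, clf.stats)
            zero_grads(params)
            feats = clf.backbone.features(xb, train=True)
            logits = clf.fc.forward(feats, train=True)
            probs = softmax(logits, axis=1)
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            dlogits /= len(idx)
            dfeat = clf.fc.backward(dlogits.astype(np.float32))
            clf.backbone.suffix_backward(dfeat)
            opt.step()
    return clf


def classify_windows(tissue: np.ndarray, classifier: CropClassifier,
                     window_px: int = CROP_PX, stride: int | None = None,
                     batch: int = 64) -> WindowGrid:
    """Dense sliding-window inference over one tissue image.

    Windows tile the tissue at ``stride`` (default: the window size,
    non-overlapping); the last row/column is clamped inside the tissue.
    A tissue smaller than the window yields one centered, white-padded
    window.  Each window is classified independently of its neighbors.
    """
    img = np.asarray(tissue)
    h, w = img.shape[:2]
    stride = stride or window_px
    if h < window_px or w < window_px:
        pad = np.full((max(h, window_px), max(w, window_px), 3), 250, dtype=img.dtype)
        top = (pad.shape[0] - h) // 2
        left = (pad.shape[1] - w) // 2
        pad[top : top + h, left : left + w] = img
        img, (h, w) = pad, pad.shape[:2]

    def starts(extent):
        s = list(range(0, extent - window_px + 1, stride))
        if s[-1] != extent - window_px:
            s.append(extent - window_px)
        return s

    coords = [(x, y, x + window_px, y + window_px)
              for y in starts(h) for x in starts(w)]
    probs = np.empty((len(coords), len(CLASS_ORDER)), dtype=np.float64)
    for start in range(0, len(coords), batch):
        chunk = coords[start : start + batch]
        stackd = np.stack([img[y0:y1, x0:x1] for x0, y0, x1, y1 in chunk])
        probs[start : start + len(chunk)] = classifier.predict_proba(stackd)
    return WindowGrid(probs=probs, coords=np.asarray(coords))


def aggregate(window_grid: WindowGrid, heuristic: HeuristicConfig) -> str:
    """Tissue class from window votes by the count-threshold priority rule.

    Count, per abnormal class, the windows whose probability for that
    class exceeds its threshold; predict the highest-risk class whose
    count reaches its minimum; otherwise normal.  Permutation-invariant
    over windows.
    """
    if len(window_grid.probs) == 0:
        raise ValueError("empty window grid")
    for cls in reversed(CLASS_ORDER[1:]):  # highest risk first
        i = class_index(cls)
        count = int((window_grid.probs[:, i] > heuristic.thresholds[cls]).sum())
        if count >= max(heuristic.min_counts[cls], 1):
            return cls
    return NORMAL


def grid_search_heuristic(window_grids: list[WindowGrid], labels,
                          threshold_grid=(0.3, 0.5, 0.7, 0.9),
                          count_grid=(1, 2, 4)) -> HeuristicConfig:
    """Exhaustive search for the aggregation rule on the validation set.

    Scores every combination of per-class thresholds and minimum counts
    by the unweighted mean F1 of the aggregated predictions against the
    validation labels; ties keep the earlier (lower-threshold)
    combination.  Deterministic.
    """
    if not threshold_grid or not count_grid:
        raise ValueError("empty search grids")
    labels = list(labels)
    abnormal = CLASS_ORDER[1:]
    best_cfg, best_score = None, -np.inf
    for thresholds in itertools.product(sorted(threshold_grid), repeat=len(abnormal)):
        for counts in itertools.product(sorted(count_grid), repeat=len(abnormal)):
            cfg = HeuristicConfig(thresholds=dict(zip(abnormal, thresholds)),
                                  min_counts=dict(zip(abnormal, counts)))
            preds = [aggregate(g, cfg) for g in window_grids]
            cm = confusion_matrix(labels, preds)
            score = mean_metrics({c: one_vs_rest_metrics(cm, c) for c in CLASS_ORDER})["f1"]
            if score > best_score:
                best_score, best_cfg = score, cfg
    return best_cfg
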