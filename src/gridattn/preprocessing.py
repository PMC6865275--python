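"""Slide preprocessing: background removal, tissue separation, labelling,
grid tiling and channel normalization.

Whole-slide scans contain large near-white glass regions and often
several disjoint tissue pieces.  Preprocessing removes the background,
cuts each connected tissue component into its own subimage (keeping
slide provenance so that splits never separate same-slide tissues),
assigns each tissue the highest-risk class among its lesions, tiles it
into a grid of 492-px cells resized to 224 px, and standardizes pixel
values by the per-channel mean/SD pooled over the training tissues.

Conventions used repo-wide: 0-based half-open boxes ``(x_min, y_min,
x_max, y_max)``, row-major grid order, images as ``(H, W, 3)`` arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .classes import CLASS_ORDER, highest_risk

__all__ = [
    "GridShape",
    "ChannelStats",
    "TissueCrop",
    "DEFAULT_CELL_PX",
    "DEFAULT_OUT_PX",
    "segment_tissues",
    "assign_label",
    "tile_grid",
    "compute_normalization_stats",
    "normalize_cells",
    "split_by_slide",
    "load_image",
    "boxes_to_grid_mask",
]

DEFAULT_CELL_PX = 492
DEFAULT_OUT_PX = 224

#: A pixel is glass background when every channel reaches this value.
BACKGROUND_THRESHOLD = 240
#: Connected components below this fraction of the slide are debris.
MIN_COMPONENT_FRAC = 1e-3


@dataclass(frozen=True)
class GridShape:
    r: int
    c: int

    def __post_init__(self):
        if self.r < 1 or self.c < 1:
            raise ValueError("grid must have at least one row and one column")


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel pixel mean/SD on the [0, 1] scale, train-set pooled."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.sd):
            raise ValueError("channel SDs must be positive")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"mean": list(self.mean), "sd": list(self.sd)}))

    @classmethod
    def load(cls, path: str | Path) -> "ChannelStats":
        d = json.loads(Path(path).read_text())
        return cls(mean=tuple(d["mean"]), sd=tuple(d["sd"]))


@dataclass
class TissueCrop:
    """A single-tissue subimage cut from a slide, with provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max) in slide coords
    slide_id: str = "slide_0"


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as (H, W, 3) uint8."""
    return np.asarray(Image.open(path).convert("RGB"))


def segment_tissues(slide_image: np.ndarray, slide_id: str = "slide_0",
                    background_threshold: int = BACKGROUND_THRESHOLD,
                    min_component_frac: float = MIN_COMPONENT_FRAC) -> list[TissueCrop]:
    """Cut one crop per connected tissue component of a slide image.

    A pixel is tissue when any channel falls below ``background_threshold``;
    8-connected components smaller than ``min_component_frac`` of the
    slide area are discarded as debris.  Crops are the tight bounding
    boxes of their components, ordered left to right, and keep the slide
    id so train/test splits can keep same-slide tissues together.
    An image with no tissue yields an empty list.
    """
    img = np.asarray(slide_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    tissue = (img < background_threshold).any(axis=2)
    labels, n = ndimage.label(tissue, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    min_area = min_component_frac * img.shape[0] * img.shape[1]
    crops = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        ys, xs = sl
        component = labels[ys, xs]
        if np.count_nonzero(component) < min_area:
            continue
        crops.append(TissueCrop(pixels=img[ys, xs].copy(),
                                bbox=(xs.start, ys.start, xs.stop, ys.stop),
                                slide_id=slide_id))
    crops.sort(key=lambda c: c.bbox[0])
    return crops


def assign_label(lesion_classes, class_order=CLASS_ORDER) -> str:
    """Tissue label under the highest-risk rule.

    The most clinically severe class among the lesions wins; a tissue
    with no lesions is normal.  Raises on unknown class names.
    """
    del class_order  # the risk order is fixed repo-wide
    return highest_risk(lesion_classes)


def tile_grid(pixels: np.ndarray, cell_px: int = DEFAULT_CELL_PX,
              out_px: int | None = DEFAULT_OUT_PX) -> tuple[GridShape, np.ndarray]:
    """Tile a tissue into its grid of cells.

    The image is padded with white to the next multiple of ``cell_px``
    in each dimension (no tissue pixel is discarded), split into
    ``r = ceil(H / cell_px)`` by ``c = ceil(W / cell_px)`` cells in
    row-major order, and each cell is bilinearly resized to
    ``out_px`` (pass ``out_px=None`` to keep raw cells, e.g. for the
    lossless-reassembly check).

    Returns ``(GridShape, cells)`` with ``cells`` of shape
    ``(r*c, out_px, out_px, 3)`` as float32 on the [0, 1] scale.
    """
    img = np.asarray(pixels)
    if img.size == 0:
        raise ValueError("empty tissue image")
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    h, w = img.shape[:2]
    r = -(-h // cell_px)
    c = -(-w // cell_px)
    padded = np.ones((r * cell_px, c * cell_px, 3), dtype=np.float32)  # white
    padded[:h, :w] = img
    cells = (padded.reshape(r, cell_px, c, cell_px, 3)
             .transpose(0, 2, 1, 3, 4)
             .reshape(r * c, cell_px, cell_px, 3))
    if out_px is not None and out_px != cell_px:
        resized = np.empty((r * c, out_px, out_px, 3), dtype=np.float32)
        for i, cell in enumerate(cells):
            resized[i] = _sk_resize(cell, (out_px, out_px), order=1,
                                    anti_aliasing=False, preserve_range=True)
        cells = resized
    return GridShape(r, c), np.ascontiguousarray(cells, dtype=np.float32)


def compute_normalization_stats(images) -> ChannelStats:
    """Per-channel mean/SD pooled over all pixels of the training tissues.

    ``images`` is an iterable of (H, W, 3) arrays or image paths; sizes
    may differ (pooling is over pixels, not per image).  uint8 input is
    rescaled to [0, 1] first.  A degenerate SD is floored at 1e-6 with
    a warning so constant channels do not break normalization.
    """
    n = 0
    s = np.zeros(3, dtype=np.float64)
    ss = np.zeros(3, dtype=np.float64)
    for img in images:
        if isinstance(img, (str, Path)):
            img = load_image(img)
        x = np.asarray(img)
        if x.dtype == np.uint8:
            x = x.astype(np.float64) / 255.0
        x = x.reshape(-1, 3).astype(np.float64)
        n += x.shape[0]
        s += x.sum(axis=0)
        ss += (x * x).sum(axis=0)
    if n == 0:
        raise ValueError("no training tissues provided")
    mean = s / n
    var = np.maximum(ss / n - mean**2, 0.0)
    sd = np.sqrt(var)
    if (sd < 1e-6).any():
        warnings.warn("degenerate channel SD floored at 1e-6", stacklevel=2)
        sd = np.maximum(sd, 1e-6)
    return ChannelStats(mean=tuple(mean.tolist()), sd=tuple(sd.tolist()))


def normalize_cells(cells: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Standardize cells per channel: ``(x - mean) / sd``."""
    mean = np.asarray(stats.mean, dtype=np.float32)
    sd = np.asarray(stats.sd, dtype=np.float32)
    return (np.asarray(cells, dtype=np.float32) - mean) / sd


def split_by_slide(manifest: pd.DataFrame, test_frac: float = 1 / 3,
                   val_frac: float = 0.198, seed: int = 0):
    """Slide-grouped train/validation/test split of a manifest.

    All tissues cut from the same slide land in the same subset (no
    leakage of near-duplicate tissue between sets).  ``val_frac`` is the
    fraction of the non-test slides reserved for validation; the study
    held out one-third of images for testing and 19.8% of the training
    slides for validation.
    """
    rng = np.random.default_rng(seed)
    slides = manifest["slide_id"].unique()
    slides = slides[rng.permutation(len(slides))]
    n_test = int(round(test_frac * len(slides)))
    test_slides = set(slides[:n_test])
    rest = slides[n_test:]
    n_val = int(round(val_frac * len(rest)))
    val_slides = set(rest[:n_val])
    part = manifest["slide_id"].map(
        lambda s: "test" if s in test_slides else ("val" if s in val_slides else "train"))
    return (manifest[part == "train"].reset_index(drop=True),
            manifest[part == "val"].reset_index(drop=True),
            manifest[part == "test"].reset_index(drop=True))


def boxes_to_grid_mask(boxes, image_hw: tuple[int, int], grid: GridShape,
                       cell_px: int = DEFAULT_CELL_PX, classes=None,
                       min_overlap: float = 0.5) -> np.ndarray:
    """Rasterize pixel lesion boxes to a boolean (r, c) grid-cell mask.

    A cell is positive when lesion boxes (optionally restricted to
    ``classes``) cover at least ``min_overlap`` of its tissue-visible
    area.  Used to score attention maps against planted lesions.
    """
    h, w = image_hw
    cover = np.zeros((grid.r * cell_px, grid.c * cell_px), dtype=np.float32)
    for cls, x0, y0, x1, y1 in boxes:
        if classes is not None and cls not in classes:
            continue
        cover[y0:y1, x0:x1] = 1.0
    mask = np.zeros((grid.r, grid.c), dtype=bool)
    for i in range(grid.r):
        for j in range(grid.c):
            cell = cover[i * cell_px : (i + 1) * cell_px, j * cell_px : (j + 1) * cell_px]
            # overlap measured against the part of the cell inside the image
            vis_h = max(min((i + 1) * cell_px, h) - i * cell_px, 0)
            vis_w = max(min((j + 1) * cell_px, w) - j * cell_px, 0)
            if vis_h * vis_w > 0 and cell[:vis_h, :vis_w].mean() >= min_overlap:
                mask[i, j] = True
    return mask
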