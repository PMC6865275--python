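"""Whole-tissue prediction and attention-map visualization.

The trained model returns, for each tissue, class probabilities and F
attention maps over the grid.  For display, a head's map is divided by
its maximum (so the brightest cell is 1), upsampled to tissue pixel
dimensions and optionally overlaid on the image.  The head shown for a
class is the one whose attended features carry the largest classifier
weight mass toward that class's logit.  The enrichment ratio quantifies
whether attention concentrates on planted lesions: attention mass
inside the lesion cells divided by the lesions' share of grid cells
(uniform attention scores exactly 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attention import AttentionMap, AttentionModel
from .classes import CLASS_ORDER
from .preprocessing import (
    ChannelStats,
    DEFAULT_CELL_PX,
    DEFAULT_OUT_PX,
    load_image,
    normalize_cells,
    tile_grid,
)

__all__ = [
    "AttentionRender",
    "predict",
    "render_attention",
    "attention_enrichment",
    "select_class_head",
    "write_predictions",
    "save_overlay",
]


@dataclass
class AttentionRender:
    """A max-normalized attention map at tissue pixel resolution."""

    values: np.ndarray  # (H, W) in [0, 1]; max is 1 unless the map is all-zero
    head: int = 0

    def __post_init__(self):
        v = self.values
        if v.min() < 0 or v.max() > 1 + 1e-6:
            raise ValueError("rendered attention must lie in [0, 1]")


def predict(image, model: AttentionModel, stats: ChannelStats,
            cell_px: int = DEFAULT_CELL_PX, out_px: int = DEFAULT_OUT_PX):
    """Classify one tissue image.

    Returns ``(class_name, probabilities, AttentionMap)``.  The class is
    the argmax of the probabilities; exact ties resolve to the
    lowest-risk class (deterministic and clinically conservative).
    Evaluation mode throughout — repeated calls are identical.
    """
    img = load_image(image) if isinstance(image, (str, Path)) else np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("predict expects an (H, W, 3) RGB tissue image")
    grid, cells = tile_grid(img, cell_px=cell_px, out_px=out_px)
    probs, amap = model.forward(normalize_cells(cells, stats), grid, train=False)
    return CLASS_ORDER[int(np.argmax(probs))], probs, amap


def render_attention(alpha_head: np.ndarray, tissue_hw: tuple[int, int],
                     cell_px: int = DEFAULT_CELL_PX, head: int = 0,
                     interpolation: str = "nearest") -> AttentionRender:
    """Max-normalize one head's map and upsample it to tissue pixels.

    The map is divided by its maximum (an all-zero map stays zero, with
    a warning), expanded to the padded grid extent and cropped to the
    tissue size, so each grid cell's weight paints its source pixels.
    """
    a = np.asarray(alpha_head, dtype=np.float32)
    if a.ndim != 2:
        raise ValueError("expected one (r, c) attention head")
    peak = float(a.max())
    if peak > 0:
        a = a / peak
    else:
        warnings.warn("all-zero attention map; rendering zeros", stacklevel=2)
    h, w = tissue_hw
    if interpolation == "nearest":
        up = np.repeat(np.repeat(a, cell_px, axis=0), cell_px, axis=1)
    elif interpolation == "bilinear":
        from skimage.transform import resize
        up = resize(a, (a.shape[0] * cell_px, a.shape[1] * cell_px), order=1,
                    anti_aliasing=False, preserve_range=True)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return AttentionRender(values=np.clip(up[:h, :w], 0.0, 1.0), head=head)


def attention_enrichment(alpha_head: np.ndarray, grid_mask: np.ndarray) -> float:
    """Attention mass inside the mask relative to the mask's area share.

    ``grid_mask`` is a boolean (r, c) lesion mask at grid resolution
    with at least one positive cell.  1.0 means no enrichment (uniform
    attention); larger values mean the head concentrates on the lesion.
    """
    a = np.asarray(alpha_head, dtype=np.float64)
    m = np.asarray(grid_mask, dtype=bool)
    if a.shape != m.shape:
        raise ValueError("attention head and mask shapes disagree")
    if not m.any():
        raise ValueError("empty lesion mask")
    mass = a[m].sum() / a.sum()
    area_frac = m.mean()
    return float(mass / area_frac)


def select_class_head(model: AttentionModel, cls: str) -> int:
    """Head contributing most classifier-weight mass to a class logit.

    The classifier sees z as F concatenated k-blocks; the selected head
    maximizes the L1 norm of its block in the class's weight row.  The
    choice is invariant to rescaling all weights by a positive constant.
    """
    row = model.fc.weight.value[CLASS_ORDER.index(cls)]
    k = model.backbone.feature_dim
    blocks = np.abs(row).reshape(model.config.n_filters, k).sum(axis=1)
    if blocks.max() == 0:
        warnings.warn("classifier weights are all zero (untrained model?)", stacklevel=2)
    return int(np.argmax(blocks))


def write_predictions(samples, model: AttentionModel, stats: ChannelStats,
                      out_csv: str | Path, cell_px: int = DEFAULT_CELL_PX,
                      out_px: int = DEFAULT_OUT_PX) -> pd.DataFrame:
    """Predict a list of ``(tissue_id, image)`` pairs and write a CSV.

    Columns: tissue_id, predicted class and the four class
    probabilities.
    """
    rows = []
    for tissue_id, image in samples:
        cls, probs, _ = predict(image, model, stats, cell_px, out_px)
        rows.append({"tissue_id": tissue_id, "prediction": cls,
                     **{f"p_{c}": float(p) for c, p in zip(CLASS_ORDER, probs)}})
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df


def save_overlay(image: np.ndarray, render: AttentionRender, path: str | Path,
                 alpha: float = 0.5, cmap: str = "inferno") -> None:
    """Write a heatmap overlay PNG of a rendered attention map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6 * image.shape[0] / max(image.shape[1], 1)))
    ax.imshow(image)
    ax.imshow(render.values, cmap=cmap, alpha=alpha, vmin=0.0, vmax=1.0)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
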