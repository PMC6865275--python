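"""Synthetic high-resolution tissue images with planted, labelled lesions.

Real inputs to the classifier are single-tissue subimages cut from
hematoxylin-eosin whole-slide scans.  This module emulates them with
procedural textures so that every downstream stage (preprocessing,
feature extraction, attention training, the sliding-window baseline and
the evaluation statistics) can be exercised end to end without clinical
data.

A synthetic tissue is an elliptical tissue region on a near-white
background (all channels >= 240, as slide glass scans).  The tissue
carries the normal-class texture; zero or more rectangular lesions with
soft (blended) edges carry the texture of their own class.  The tissue
label follows the highest-risk rule over its lesions.  Textures are
band-limited Gaussian noise around class-specific base colors with
class-specific granularity, so simple texture statistics separate the
four classes — the learning task is solvable by construction, while
remaining far easier than real histology.

Everything is deterministic given the seed carried by each
:class:`SyntheticSpec`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .classes import (
    ADENOCARCINOMA,
    BE_NO_DYSPLASIA,
    BE_WITH_DYSPLASIA,
    CLASS_ORDER,
    NORMAL,
    class_index,
    highest_risk,
)

__all__ = [
    "Lesion",
    "SyntheticSpec",
    "TissueImage",
    "STUDY_CLASS_MIX",
    "STUDY_CLASS_COUNTS",
    "DESK_SIZE",
    "generate_tissue_image",
    "generate_slide_image",
    "sample_dataset_specs",
    "write_dataset",
    "generate_dataset",
    "sample_tissue_size",
]

#: Class frequencies of the 379-image study data set (195/80/46/58).
STUDY_CLASS_COUNTS = {NORMAL: 195, BE_NO_DYSPLASIA: 80, BE_WITH_DYSPLASIA: 46, ADENOCARCINOMA: 58}
STUDY_CLASS_MIX = tuple(STUDY_CLASS_COUNTS[c] / 379 for c in CLASS_ORDER)

#: Desk-scale tissue size: height x width for a 3 x 4 grid of 492-px cells.
DESK_SIZE = (1476, 1968)

# Base color (RGB), noise amplitude, and smoothing scale per class.  The
# colors mimic increasing hematoxylin uptake with increasing cellularity
# (normal squamous mucosa stains lightly; adenocarcinoma is dense and
# dark) and are deliberately well separated.
_TEXTURES = {
    NORMAL: dict(base=(226, 178, 192), amp=14.0, smooth=8.0),
    BE_NO_DYSPLASIA: dict(base=(186, 152, 212), amp=18.0, smooth=3.0),
    BE_WITH_DYSPLASIA: dict(base=(152, 118, 180), amp=22.0, smooth=5.0, blobs=True),
    ADENOCARCINOMA: dict(base=(112, 74, 134), amp=26.0, smooth=1.0),
}

_WHITE_FLOOR = 240  # background pixels stay at or above this in every channel
_TISSUE_CEIL = 235  # tissue pixels stay strictly below the background floor


@dataclass(frozen=True)
class Lesion:
    """A rectangular lesion: class plus 0-based half-open pixel box."""

    cls: str
    box: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max)
    texture_params: dict = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic tissue image (cheap to hold; render on demand)."""

    image_width: int
    image_height: int
    seed: int
    background_texture_class: str = NORMAL
    lesions: list[Lesion] = field(default_factory=list)
    class_mix: tuple[float, ...] | None = None
    tissue_id: str = "tissue_0"
    slide_id: str = "slide_0"

    def __post_init__(self):
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        class_index(self.background_texture_class)
        for les in self.lesions:
            x0, y0, x1, y1 = les.box
            class_index(les.cls)
            if not (0 <= x0 < x1 <= self.image_width and 0 <= y0 < y1 <= self.image_height):
                raise ValueError(f"lesion box {les.box} outside image "
                                 f"{self.image_width}x{self.image_height}")
        if self.class_mix is not None:
            mix = np.asarray(self.class_mix, dtype=float)
            if mix.shape != (len(CLASS_ORDER),) or not np.isclose(mix.sum(), 1.0):
                raise ValueError("class_mix must have 4 probabilities summing to 1")

    @property
    def label(self) -> str:
        return highest_risk(les.cls for les in self.lesions)


@dataclass
class TissueImage:
    """One rendered RGB tissue subimage with its label and lesion boxes."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: str
    lesion_boxes: list[tuple[str, int, int, int, int]]
    source_id: str = "tissue_0"
    slide_id: str = "slide_0"

    def lesion_mask(self) -> np.ndarray:
        """Boolean (H, W) union of all lesion boxes."""
        h, w = self.pixels.shape[:2]
        m = np.zeros((h, w), dtype=bool)
        for _, x0, y0, x1, y1 in self.lesion_boxes:
            m[y0:y1, x0:x1] = True
        return m


def _smooth_field(h: int, w: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise.

    For large smoothing scales the field is synthesized at reduced
    resolution and bilinearly upsampled — visually equivalent and an
    order of magnitude faster on multi-megapixel tissues.
    """
    factor = max(int(sigma // 2), 1)
    hs, ws = -(-h // factor), -(-w // factor)
    noise = ndimage.gaussian_filter(
        rng.standard_normal((hs, ws)).astype(np.float32), sigma / factor)
    if factor > 1:
        noise = np.kron(noise, np.ones((factor, factor), dtype=np.float32))[:h, :w]
    return noise / max(noise.std(), 1e-6)


def _class_texture(cls: str, h: int, w: int, rng: np.random.Generator,
                   overrides: dict | None = None) -> np.ndarray:
    params = dict(_TEXTURES[cls])
    if overrides:
        params.update(overrides)
    base = np.asarray(params["base"], dtype=np.float32)
    if params["smooth"] > 0:
        noise = _smooth_field(h, w, params["smooth"], rng)
    else:
        noise = rng.standard_normal((h, w)).astype(np.float32)
    tex = base[None, None, :] + params["amp"] * noise[:, :, None]
    if params.get("blobs"):
        blob_field = _smooth_field(h, w, 12.0, rng)
        tex[blob_field > 1.0] -= 35.0
    return np.clip(tex, 0, _TISSUE_CEIL)


def _tissue_support(h: int, w: int) -> np.ndarray:
    yy, xx = np.ogrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((xx - cx) / (0.46 * w)) ** 2 + ((yy - cy) / (0.46 * h)) ** 2 <= 1.0


def generate_tissue_image(spec: SyntheticSpec) -> TissueImage:
    """Render one tissue image from its spec (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    canvas = np.full((h, w, 3), 250.0, dtype=np.float32)  # glass background
    support = _tissue_support(h, w)
    background = _class_texture(spec.background_texture_class, h, w, rng)
    canvas[support] = background[support]
    for les in spec.lesions:
        x0, y0, x1, y1 = les.box
        # work in a local window (box + blend margin) for speed
        m = 20
        wx0, wy0 = max(x0 - m, 0), max(y0 - m, 0)
        wx1, wy1 = min(x1 + m, w), min(y1 + m, h)
        soft = np.zeros((wy1 - wy0, wx1 - wx0), dtype=np.float32)
        soft[y0 - wy0 : y1 - wy0, x0 - wx0 : x1 - wx0] = 1.0
        soft = ndimage.gaussian_filter(soft, 6.0)
        soft *= support[wy0:wy1, wx0:wx1]  # lesions never bleed onto the glass
        tex = _class_texture(les.cls, wy1 - wy0, wx1 - wx0, rng, les.texture_params)
        window = canvas[wy0:wy1, wx0:wx1]
        canvas[wy0:wy1, wx0:wx1] = (window * (1.0 - soft[:, :, None])
                                    + tex * soft[:, :, None])
    boxes = [(les.cls, *les.box) for les in spec.lesions]
    return TissueImage(pixels=np.clip(canvas, 0, 255).astype(np.uint8),
                       label=spec.label, lesion_boxes=boxes,
                       source_id=spec.tissue_id, slide_id=spec.slide_id)


def generate_slide_image(specs: list[SyntheticSpec], gap: int = 64,
                         seed: int = 0) -> tuple[np.ndarray, list[TissueImage]]:
    """Compose several tissues side by side on one white slide canvas.

    Used to exercise background removal / tissue separation; returns the
    slide array and the individual rendered tissues in left-to-right
    order.
    """
    del seed  # kept for interface stability; the canvas is plain glass
    tissues = [generate_tissue_image(s) for s in specs]
    h = max(t.pixels.shape[0] for t in tissues) + 2 * gap
    w = sum(t.pixels.shape[1] for t in tissues) + gap * (len(tissues) + 1)
    slide = np.full((h, w, 3), 250, dtype=np.uint8)
    x = gap
    for t in tissues:
        th, tw = t.pixels.shape[:2]
        slide[gap : gap + th, x : x + tw] = t.pixels
        x += tw + gap
    return slide, tissues


def sample_tissue_size(rng: np.random.Generator, scale: str = "desk") -> tuple[int, int]:
    """Draw a (height, width) tissue size.

    ``desk`` is the fixed CPU-friendly default (3 x 4 grid of 492-px
    cells).  ``paper`` draws log-normal sizes matched to the study's
    tissue dimensions: width median 4500 px (IQR 3000-6500), height
    median 5500 px (IQR 4000-7500).
    """
    if scale == "desk":
        return DESK_SIZE
    if scale == "paper":
        # sigma from IQR: log(q75/q25) = 2 * 0.6745 * sigma
        w = int(np.exp(rng.normal(np.log(4500), np.log(6500 / 3000) / (2 * 0.6745))))
        h = int(np.exp(rng.normal(np.log(5500), np.log(7500 / 4000) / (2 * 0.6745))))
        return max(h, 1000), max(w, 1000)
    raise ValueError(f"unknown scale {scale!r}")


def _place_lesions(rng: np.random.Generator, h: int, w: int, cls: str) -> list[Lesion]:
    """Plant 1-2 lesions of ``cls`` (plus, sometimes, one of lower risk)."""
    lesions: list[Lesion] = []
    classes = [cls] * int(rng.integers(1, 3))
    if class_index(cls) >= 2 and rng.random() < 0.3:
        classes.append(CLASS_ORDER[int(rng.integers(1, class_index(cls)))])
    for c in classes:
        lw = int((0.25 + 0.2 * rng.random()) * w)
        lh = int((0.25 + 0.2 * rng.random()) * h)
        # keep the box inside the rectangle inscribed in the tissue ellipse
        x0 = int(0.2 * w + rng.random() * (0.6 * w - lw)) if 0.6 * w > lw else int(0.2 * w)
        y0 = int(0.2 * h + rng.random() * (0.6 * h - lh)) if 0.6 * h > lh else int(0.2 * h)
        lesions.append(Lesion(c, (x0, y0, min(x0 + lw, w), min(y0 + lh, h))))
    return lesions


def sample_dataset_specs(n: int, class_mix=STUDY_CLASS_MIX, scale: str = "desk",
                         seed: int = 0) -> list[SyntheticSpec]:
    """Draw ``n`` tissue specs with the given class mix.

    Tissues are grouped into pseudo-slides of 1-3 tissues (the study's
    whole-slide images covered several tissue pieces), so that splits
    can keep same-slide tissues together.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (len(CLASS_ORDER),) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must have 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    specs: list[SyntheticSpec] = []
    slide, left_in_slide = 0, 0
    for i in range(n):
        if left_in_slide == 0:
            slide += 1
            left_in_slide = int(rng.integers(1, 4))
        left_in_slide -= 1
        cls = CLASS_ORDER[int(rng.choice(len(CLASS_ORDER), p=mix))]
        h, w = sample_tissue_size(rng, scale)
        lesions = [] if cls == NORMAL else _place_lesions(rng, h, w, cls)
        specs.append(SyntheticSpec(
            image_width=w, image_height=h, seed=int(rng.integers(0, 2**31 - 1)),
            lesions=lesions, tissue_id=f"tissue_{i:04d}", slide_id=f"slide_{slide:04d}"))
    return specs


def write_dataset(specs: list[SyntheticSpec], out_dir: str | Path) -> tuple[Path, Path]:
    """Render all specs to PNG and write manifest + lesion-box CSVs.

    Returns ``(manifest_path, boxes_path)``.  The manifest has columns
    ``image_path, tissue_id, slide_id, label``; the box file has
    ``image_path, class, x_min, y_min, x_max, y_max`` (0-based,
    half-open).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    manifest_rows, box_rows = [], []
    for spec in specs:
        tissue = generate_tissue_image(spec)
        path = out / "images" / f"{spec.tissue_id}.png"
        Image.fromarray(tissue.pixels).save(path)
        manifest_rows.append(dict(image_path=str(path), tissue_id=spec.tissue_id,
                                  slide_id=spec.slide_id, label=tissue.label))
        for cls, x0, y0, x1, y1 in tissue.lesion_boxes:
            box_rows.append(dict(image_path=str(path), **{"class": cls},
                                 x_min=x0, y_min=y0, x_max=x1, y_max=y1))
    manifest_path = out / "manifest.csv"
    boxes_path = out / "boxes.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(box_rows, columns=["image_path", "class", "x_min", "y_min",
                                    "x_max", "y_max"]).to_csv(boxes_path, index=False)
    return manifest_path, boxes_path


def generate_dataset(n: int, out_dir: str | Path, class_mix=STUDY_CLASS_MIX,
                     scale: str = "desk", seed: int = 0) -> tuple[Path, Path]:
    """Sample ``n`` tissue specs and write the rendered dataset to disk."""
    return write_dataset(sample_dataset_specs(n, class_mix, scale, seed), out_dir)


def spec_from_tissue(tissue: TissueImage, seed: int = 0) -> SyntheticSpec:
    """Rebuild a spec-like description (for round-trip label checks)."""
    h, w = tissue.pixels.shape[:2]
    lesions = [Lesion(cls, (x0, y0, x1, y1)) for cls, x0, y0, x1, y1 in tissue.lesion_boxes]
    return SyntheticSpec(image_width=w, image_height=h, seed=seed, lesions=lesions,
                         tissue_id=tissue.source_id, slide_id=tissue.slide_id)
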