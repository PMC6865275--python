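"""Desk-scale synthetic study: the full pipeline on generated tissues.

This module wires the pieces together the way the clinical study runs:
generate a labelled dataset (study class mix, 3 x 4-cell tissues of
1476 x 1968 px), train the attention model end to end from tissue-level
labels only, classify the held-out tissues, score them with the
evaluation statistics, quantify attention localization on planted
adenocarcinoma lesions, and (optionally) train and run the
sliding-window baseline for the paired comparison.

Default problem sizes — 200 training / 40 validation / 60 test tissues,
30 epochs, a 16-feature tiny backbone with 8 attention heads — are
chosen so the whole study runs on one CPU in minutes.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attention import AttentionConfig, AttentionModel
from .backbone import make_backbone
from .baseline import (
    aggregate,
    classify_windows,
    grid_search_heuristic,
    make_crop_set,
    train_crop_classifier,
)
from .classes import ADENOCARCINOMA, CLASS_ORDER
from .evaluation import confusion_matrix, mcnemar_bowker, metrics_report
from .inference import attention_enrichment, predict, select_class_head
from .preprocessing import (
    boxes_to_grid_mask,
    compute_normalization_stats,
    load_image,
    tile_grid,
)
from .synthetic import TissueImage, sample_dataset_specs, write_dataset
from .training import TrainConfig, initialize_weights, train

__all__ = ["StudyResult", "run_synthetic_study"]


@dataclass
class StudyResult:
    """Everything the synthetic study measures."""

    test_accuracy: float
    mean_metrics: dict[str, float]
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray
    metrics_table: pd.DataFrame
    adenocarcinoma_enrichment: float
    n_train: int
    n_test: int
    baseline: dict = field(default_factory=dict)
    predictions: pd.DataFrame | None = None


def _load_boxes(boxes_path: Path) -> pd.DataFrame:
    return pd.read_csv(boxes_path)


def _tissues_from(manifest: pd.DataFrame, boxes: pd.DataFrame):
    """Lazily yield TissueImage objects from a written dataset."""
    for row in manifest.itertuples():
        b = boxes[boxes.image_path == row.image_path]
        lesions = [(r["class"], int(r.x_min), int(r.y_min), int(r.x_max), int(r.y_max))
                   for _, r in b.iterrows()]
        yield TissueImage(pixels=load_image(row.image_path), label=row.label,
                          lesion_boxes=lesions, source_id=row.tissue_id,
                          slide_id=row.slide_id)


def run_synthetic_study(seed: int = 1, n_train: int = 200, n_val: int = 40,
                        n_test: int = 60, epochs: int = 30, n_filters: int = 8,
                        feature_dim: int = 16, bootstrap_B: int = 1000,
                        with_baseline: bool = False, baseline_epochs: int = 15,
                        work_dir: str | Path | None = None,
                        progress: bool = False) -> StudyResult:
    """Run the full synthetic end-to-end study; see the module docstring.

    All randomness (dataset, initialization, training order, dropout,
    bootstrap) derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    tmp_ctx = None
    if work_dir is None:
        tmp_ctx = tempfile.TemporaryDirectory(prefix="gridattn_study_")
        work_dir = tmp_ctx.name
    work_dir = Path(work_dir)

    try:
        # --- data ----------------------------------------------------------
        parts = {}
        for name, n, s in (("train", n_train, seeds[0]), ("val", n_val, seeds[1]),
                           ("test", n_test, seeds[2])):
            m_path, b_path = write_dataset(
                sample_dataset_specs(n, scale="desk", seed=int(s)), work_dir / name)
            parts[name] = (pd.read_csv(m_path), _load_boxes(b_path))

        train_manifest, _ = parts["train"]
        samples = [(p, l) for p, l in zip(train_manifest.image_path, train_manifest.label)]
        val_manifest, _ = parts["val"]
        val_samples = [(p, l) for p, l in zip(val_manifest.image_path, val_manifest.label)]

        stats = compute_normalization_stats(p for p, _ in samples)

        # --- attention model ----------------------------------------------
        model = AttentionModel(
            backbone=make_backbone("tiny", feature_dim=feature_dim, seed=int(seeds[3])),
            config=AttentionConfig(n_filters=n_filters), seed=int(seeds[3]))
        initialize_weights(model, seed=int(seeds[3]))
        cfg = TrainConfig(total_epochs=epochs, cycle_length=min(50, epochs),
                          augment=False, seed=int(seeds[4]))
        model, _ = train(samples, model, cfg, val_samples=val_samples, stats=stats,
                         progress=progress)

        # --- test-set evaluation ------------------------------------------
        test_manifest, test_boxes = parts["test"]
        preds, enrich = [], []
        head = select_class_head(model, ADENOCARCINOMA)
        for tissue in _tissues_from(test_manifest, test_boxes):
            cls, probs, amap = predict(tissue.pixels, model, stats)
            preds.append(dict(tissue_id=tissue.source_id, label=tissue.label,
                              prediction=cls,
                              **{f"p_{c}": float(p) for c, p in zip(CLASS_ORDER, probs)}))
            eac_boxes = [b for b in tissue.lesion_boxes if b[0] == ADENOCARCINOMA]
            if eac_boxes:
                grid, _ = tile_grid(tissue.pixels, out_px=None)
                mask = boxes_to_grid_mask(eac_boxes, tissue.pixels.shape[:2], grid,
                                          classes={ADENOCARCINOMA})
                if mask.any():
                    enrich.append(attention_enrichment(amap.alpha[head], mask))
        pred_df = pd.DataFrame(preds)

        report = metrics_report(pred_df.label, pred_df.prediction,
                                B=bootstrap_B, seed=int(seeds[5]))
        cm = confusion_matrix(pred_df.label, pred_df.prediction)
        result = StudyResult(
            test_accuracy=float((pred_df.label == pred_df.prediction).mean()),
            mean_metrics={m: report.point("mean", m)
                          for m in ("accuracy", "recall", "precision", "specificity", "f1")},
            per_class_accuracy={c: report.point(c, "accuracy") for c in CLASS_ORDER},
            confusion=cm,
            metrics_table=report.table,
            adenocarcinoma_enrichment=float(np.mean(enrich)) if enrich else float("nan"),
            n_train=len(samples), n_test=len(pred_df),
            predictions=pred_df,
        )

        # --- sliding-window baseline --------------------------------------
        if with_baseline:
            train_tissues = list(_tissues_from(*parts["train"]))
            crops, labels = make_crop_set(train_tissues, seed=int(seeds[3]))
            del train_tissues
            clf = train_crop_classifier(crops, labels, epochs=baseline_epochs,
                                        seed=int(seeds[3]))
            val_t = list(_tissues_from(*parts["val"]))
            heur = grid_search_heuristic(
                [classify_windows(t.pixels, clf) for t in val_t],
                [t.label for t in val_t])
            del val_t
            base_preds = [aggregate(classify_windows(t.pixels, clf), heur)
                          for t in _tissues_from(test_manifest, test_boxes)]
            base_acc = float(np.mean(np.asarray(base_preds) == pred_df.label.values))
            base_report = metrics_report(pred_df.label, base_preds,
                                         B=bootstrap_B, seed=int(seeds[5]))
            stat, df_, p = mcnemar_bowker(pred_df.prediction, base_preds)
            result.baseline = dict(
                predictions=base_preds, test_accuracy=base_acc,
                mean_accuracy=base_report.point("mean", "accuracy"),
                mean_f1=base_report.point("mean", "f1"),
                mcnemar=dict(statistic=stat, df=df_, p=p))
        return result
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()
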