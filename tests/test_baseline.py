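"""Sliding-window baseline: crop set, window inference, aggregation."""

import numpy as np
import pytest

from gridattn.backbone import make_backbone
from gridattn.baseline import (
    HeuristicConfig,
    MissingAnnotationsError,
    WindowGrid,
    aggregate,
    classify_windows,
    grid_search_heuristic,
    make_crop_set,
    train_crop_classifier,
)
from gridattn.classes import ADENOCARCINOMA, BE_NO_DYSPLASIA, CLASS_ORDER, NORMAL
from gridattn.synthetic import Lesion, SyntheticSpec, generate_tissue_image


def _tissue(seed, lesions=()):
    spec = SyntheticSpec(image_width=984, image_height=492, seed=seed,
                         lesions=list(lesions))
    return generate_tissue_image(spec)


@pytest.fixture(scope="module")
def lesioned_tissues():
    box = Lesion(ADENOCARCINOMA, (450, 100, 900, 400))
    box2 = Lesion(BE_NO_DYSPLASIA, (100, 100, 550, 400))
    return [_tissue(1, [box]), _tissue(2, [box2]), _tissue(3), _tissue(4)]


class TestMakeCropSet:
    def test_no_annotations_raises_loudly(self):
        with pytest.raises(MissingAnnotationsError, match="without ROI annotations"):
            make_crop_set([_tissue(1), _tissue(2)])

    def test_small_box_skipped_with_warning(self):
        t = _tissue(5, [Lesion(ADENOCARCINOMA, (450, 150, 600, 280))])  # < 224 px
        with pytest.warns(UserWarning, match="smaller than 224"):
            crops, labels = make_crop_set([t, _tissue(6)])
        assert set(labels) == {NORMAL}

    def test_crop_labels_and_shapes(self, lesioned_tissues):
        crops, labels = make_crop_set(lesioned_tissues, seed=0)
        assert crops.shape[1:] == (224, 224, 3)
        assert set(labels) == {NORMAL, ADENOCARCINOMA, BE_NO_DYSPLASIA}

    def test_fixed_seed_identical(self, lesioned_tissues):
        c1, l1 = make_crop_set(lesioned_tissues, seed=9)
        c2, l2 = make_crop_set(lesioned_tissues, seed=9)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(l1, l2)

    def test_lesion_crops_carry_lesion_texture(self, lesioned_tissues):
        """Crops labelled adenocarcinoma are darker than normal crops
        (their centers lie inside the planted lesion)."""
        crops, labels = make_crop_set(lesioned_tissues, seed=0)
        eac = crops[labels == ADENOCARCINOMA].mean()
        normal = crops[labels == NORMAL].mean()
        assert eac < normal - 20


class TestCropClassifier:
    def test_training_reduces_loss_and_probs_sum_to_one(self, lesioned_tissues):
        crops, labels = make_crop_set(lesioned_tissues, seed=0)
        clf = train_crop_classifier(crops, labels, epochs=30, batch_size=4, seed=0,
                                    backbone=make_backbone("tiny", feature_dim=8))
        probs = clf.predict_proba(crops)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        # separable crop classes should be mostly learned within a few epochs
        from gridattn.classes import class_index
        acc = (probs.argmax(axis=1) == [class_index(l) for l in labels]).mean()
        assert acc > 0.6

    def test_single_class_rejected(self):
        crops = np.zeros((4, 224, 224, 3), np.uint8)
        with pytest.raises(ValueError, match="two classes"):
            train_crop_classifier(crops, np.array([NORMAL] * 4), epochs=1)


@pytest.fixture(scope="module")
def clf(lesioned_tissues):
    crops, labels = make_crop_set(lesioned_tissues, seed=0)
    return train_crop_classifier(crops, labels, epochs=2, seed=0,
                                 backbone=make_backbone("tiny", feature_dim=8))


class TestClassifyWindows:
    def test_window_counts(self, clf):
        tissue = np.full((448, 448, 3), 180, np.uint8)
        grid = classify_windows(tissue, clf, stride=224)
        assert len(grid.coords) == 4  # 2 x 2

    def test_smaller_stride_yields_more_windows(self, clf):
        tissue = np.full((448, 448, 3), 180, np.uint8)
        n224 = len(classify_windows(tissue, clf, stride=224).coords)
        n112 = len(classify_windows(tissue, clf, stride=112).coords)
        assert n112 >= n224

    def test_tiny_tissue_gets_single_centered_window(self, clf):
        grid = classify_windows(np.full((100, 80, 3), 150, np.uint8), clf)
        assert len(grid.coords) == 1

    def test_windows_classified_independently(self, clf):
        """Perturbing one window's pixels leaves other windows' predictions
        untouched."""
        rng = np.random.default_rng(0)
        tissue = (rng.random((448, 448, 3)) * 200).astype(np.uint8)
        g1 = classify_windows(tissue, clf, stride=224)
        tissue2 = tissue.copy()
        tissue2[:224, :224] = 30  # hit only window 0
        g2 = classify_windows(tissue2, clf, stride=224)
        np.testing.assert_allclose(g1.probs[1:], g2.probs[1:], atol=1e-6)


class TestAggregate:
    def _grid(self, probs):
        probs = np.asarray(probs, float)
        coords = np.tile([0, 0, 224, 224], (len(probs), 1))
        return WindowGrid(probs=probs, coords=coords)

    def test_all_confidently_normal(self):
        grid = self._grid([[0.97, 0.01, 0.01, 0.01]] * 5)
        assert aggregate(grid, HeuristicConfig()) == NORMAL

    def test_single_confident_eac_window_overrides_majority(self):
        rows = [[0.97, 0.01, 0.01, 0.01]] * 9 + [[0.05, 0.05, 0.1, 0.8]]
        cfg = HeuristicConfig(thresholds={c: 0.5 for c in CLASS_ORDER[1:]},
                              min_counts={c: 1 for c in CLASS_ORDER[1:]})
        assert aggregate(self._grid(rows), cfg) == ADENOCARCINOMA

    def test_raising_threshold_never_increases_votes(self):
        probs = np.random.default_rng(2).dirichlet(np.ones(4), size=30)
        for cls in CLASS_ORDER[1:]:
            i = CLASS_ORDER.index(cls)
            counts = [(probs[:, i] > t).sum() for t in (0.2, 0.5, 0.8)]
            assert counts == sorted(counts, reverse=True)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(4), size=12)
        cfg = HeuristicConfig()
        p1 = aggregate(self._grid(probs), cfg)
        p2 = aggregate(self._grid(probs[rng.permutation(12)]), cfg)
        assert p1 == p2


class TestGridSearch:
    def _val_data(self):
        rng = np.random.default_rng(0)
        grids, labels = [], []
        for i in range(12):
            cls = CLASS_ORDER[i % 4]
            probs = np.full((6, 4), 0.05)
            probs[:, 0] = 0.85
            if cls != NORMAL:
                idx = CLASS_ORDER.index(cls)
                probs[:2, :] = 0.05
                probs[:2, idx] = 0.85
            probs /= probs.sum(axis=1, keepdims=True)
            coords = np.tile([0, 0, 224, 224], (6, 1))
            grids.append(WindowGrid(probs=probs, coords=coords))
            labels.append(cls)
        return grids, labels

    def test_singleton_grids_return_that_config(self):
        grids, labels = self._val_data()
        cfg = grid_search_heuristic(grids, labels, threshold_grid=(0.5,), count_grid=(1,))
        assert all(t == 0.5 for t in cfg.thresholds.values())
        assert all(m == 1 for m in cfg.min_counts.values())

    def test_chosen_config_is_exhaustive_optimum(self):
        from gridattn.evaluation import confusion_matrix, mean_metrics, one_vs_rest_metrics
        grids, labels = self._val_data()
        tg, cg = (0.3, 0.7), (1, 3)
        best = grid_search_heuristic(grids, labels, threshold_grid=tg, count_grid=cg)

        def score(cfg):
            preds = [aggregate(g, cfg) for g in grids]
            cm = confusion_matrix(labels, preds)
            return mean_metrics({c: one_vs_rest_metrics(cm, c) for c in CLASS_ORDER})["f1"]

        import itertools
        abnormal = CLASS_ORDER[1:]
        best_score = score(best)
        for th in itertools.product(tg, repeat=3):
            for ct in itertools.product(cg, repeat=3):
                cfg = HeuristicConfig(thresholds=dict(zip(abnormal, th)),
                                      min_counts=dict(zip(abnormal, ct)))
                assert score(cfg) <= best_score + 1e-12

    def test_deterministic(self):
        grids, labels = self._val_data()
        c1 = grid_search_heuristic(grids, labels, threshold_grid=(0.3, 0.7), count_grid=(1, 2))
        c2 = grid_search_heuristic(grids, labels, threshold_grid=(0.3, 0.7), count_grid=(1, 2))
        assert c1 == c2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_heuristic([], [], threshold_grid=(), count_grid=(1,))
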