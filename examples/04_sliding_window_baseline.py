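"""The annotation-hungry baseline: crop classifier + heuristic aggregation.

The sliding-window approach needs lesion bounding boxes to build its
crop training set — the very annotations the attention model does
without.  This script trains the crop classifier on box-derived crops,
tunes the aggregation heuristic (confidence thresholds and minimum vote
counts per class) by grid search on a validation split, and compares
tissue-level predictions with the truth.
"""

import numpy as np

from gridattn.baseline import (
    aggregate,
    classify_windows,
    grid_search_heuristic,
    make_crop_set,
    train_crop_classifier,
)
from gridattn.evaluation import confusion_matrix
from gridattn.synthetic import generate_tissue_image, sample_dataset_specs

train_tissues = [generate_tissue_image(s) for s in sample_dataset_specs(24, seed=3)]
val_tissues = [generate_tissue_image(s) for s in sample_dataset_specs(12, seed=4)]
test_tissues = [generate_tissue_image(s) for s in sample_dataset_specs(12, seed=5)]

crops, labels = make_crop_set(train_tissues, seed=0)
print(f"crop set: {len(crops)} crops, classes {sorted(set(labels))}")
clf = train_crop_classifier(crops, labels, epochs=12, seed=0)

val_grids = [classify_windows(t.pixels, clf) for t in val_tissues]
heuristic = grid_search_heuristic(val_grids, [t.label for t in val_tissues])
print("tuned thresholds:", heuristic.thresholds)
print("tuned minimum vote counts:", heuristic.min_counts)

truth = [t.label for t in test_tissues]
preds = [aggregate(classify_windows(t.pixels, clf), heuristic) for t in test_tissues]
print("\nconfusion matrix (rows = truth):")
print(confusion_matrix(truth, preds))
print(f"tissue-level accuracy: {np.mean(np.array(truth) == np.array(preds)):.2f}")
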