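"""Generate a small synthetic tissue dataset and inspect its manifest.

Each image is a procedural stand-in for a single-tissue subimage of a
hematoxylin-eosin whole-slide scan: an elliptical tissue on near-white
glass, with zero or more rectangular lesions whose texture encodes
their class.  The tissue label is the highest-risk class among its
lesions (normal when there are none), and the class mix follows the
study's 51.5/21.1/12.1/15.3% distribution.
"""

import pandas as pd

from gridattn.synthetic import generate_dataset

manifest_path, boxes_path = generate_dataset(n=24, out_dir="scratch/example_dataset",
                                             seed=7)
manifest = pd.read_csv(manifest_path)
boxes = pd.read_csv(boxes_path)

print(manifest.head())
print("\nclass counts:")
print(manifest.label.value_counts())
print(f"\n{len(boxes)} lesion boxes written to {boxes_path}")
print("Tissues with no boxes are normal; multi-lesion tissues take the "
      "most severe lesion class.")
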