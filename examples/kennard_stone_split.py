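"""Partition a dataset with the Kennard-Stone max-min algorithm.

Kennard-Stone picks training compounds that span descriptor space evenly:
it seeds with the two most distant points and then repeatedly adds the
candidate farthest from everything already selected.  The test set ends up
inside the convex span of the training set, which is what an external
validation wants.
"""

import numpy as np

from skinperm import SynthConfig, assign_split, generate_dataset

ds = generate_dataset(SynthConfig(n=60, seed=2))
labeled, result = assign_split(ds, n_train=30)

print("first ten selections:", result.selection_order[:10])
train = labeled.subset("train")
test = labeled.subset("test")
print(f"train/test sizes: {len(train)}/{len(test)}")

# every test point should be close to some training point
X_tr = train.descriptor_matrix()
X_te = test.descriptor_matrix()
d = np.linalg.norm(X_te[:, None, :] - X_tr[None, :, :], axis=-1).min(axis=1)
print(f"max distance from a test point to the training set: {d.max():.3f}")
print("Small values mean the training set covers the test chemistry.")
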