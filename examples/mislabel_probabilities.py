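"""Estimate per-cell mislabelling probabilities on planted outliers.

Three well-separated Gaussian cell types in 10-D component space; a few
cells are deliberately relabelled to the wrong type.  After three adaptive
resampling iterations their mislabelling probability eps should be near 1
while correctly labelled cells stay near 0.
"""

import numpy as np

from relabeler import CellAnnotation, adasample
from relabeler.preprocess import ReducedMatrix

rng = np.random.default_rng(0)
centers = rng.normal(0, 1, size=(3, 10)) * 12.0
scores = np.concatenate([rng.normal(c, 1.0, size=(50, 10)) for c in centers])
cell_ids = [f"cell{i}" for i in range(150)]
labels = [f"type{j}" for j in range(3) for _ in range(50)]

reduced = ReducedMatrix(scores=scores, selected_pcs=10,
                        explained_ratios=np.full(10, 0.1), d=10,
                        cell_ids=cell_ids)
truth = CellAnnotation(labels, cell_ids)

# plant 3 outliers: relabel one cell of each type to the next type
noisy_labels = list(labels)
planted = [0, 50, 100]
for i, j in zip(planted, (1, 2, 0)):
    noisy_labels[i] = f"type{j}"
noisy = CellAnnotation(noisy_labels, cell_ids, label_set=truth.label_set)

eps = adasample(reduced, noisy, "svm", L=3, rng=np.random.default_rng(1))
clean = np.setdiff1d(np.arange(150), planted)
print(f"median eps, planted outliers: {np.median(eps[planted]):.3f}")
print(f"median eps, clean cells:      {np.median(eps[clean]):.3f}")
# eps is one minus the classifier's probability for the assigned type, so
# the wide gap between the two medians is what flags the planted cells.
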