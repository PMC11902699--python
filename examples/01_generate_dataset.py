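"""Generate a synthetic multitask benchmark and inspect its task structure.

The high-congruence ("ku-like") benchmark emulates windowed activity data:
18 fine-grained activity blobs in feature space, coarse-grained into three
3-class tasks (activity type, intensity band, stress effect). Because the
coarse-grainings largely agree, the task label columns are highly correlated —
the regime in which a single reference task can drive query selection.
"""

import numpy as np

import mtal

dataset = mtal.ku_like(n=3000, seed=0)
print(f"samples: {dataset.n_samples}, features: {dataset.n_features}, tasks: {dataset.n_tasks}")
for t in dataset.tasks:
    print(f"  task {t.name!r}: {t.n_classes} classes, weight {t.weight}")

R = mtal.pairwise_association(dataset.labels)
combined = mtal.combined_correlation(matrix=R)
print("\npairwise |correlation| between task label columns:")
print(np.round(R, 3))
print("combined correlation per task:", np.round(combined, 2))
print("reference task (max combined correlation):", mtal.reference_task(matrix=R))

# The combined correlation sums each task's correlations with all others; the
# task that "agrees most" with the rest is the best single proxy for querying.
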