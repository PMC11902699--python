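"""Clustered Stratified Sampling: class-balanced query batches.

Greedy least-confidence selection piles queries onto whichever classes the
current model confuses. CSS clusters the unlabeled pool (k = classes of the
reference task) and takes an equal quota of the most informative samples from
each cluster, keeping the labeled pool closer to class-uniform.
"""

import numpy as np

import mtal

dataset = mtal.ku_like(n=3000, seed=2)
pool = mtal.split_seed(dataset, n_seed=3, seed=2)
ref = mtal.reference_task(dataset.labels[dataset.train_indices])

model = mtal.fit(
    mtal.ModelConfig(epochs=50, seed=0),
    dataset.features[pool.labeled], dataset.labels[pool.labeled], dataset.tasks,
)
probs = mtal.predict_proba(model, dataset.features[pool.unlabeled])
U = mtal.score_pool(probs, "least_confidence")

k = mtal.choose_cluster_count(dataset.tasks, "one_sided", reference=ref)
assignment = mtal.cluster_pool(dataset.features[pool.unlabeled], k, seed=0)
css_batch = mtal.stratified_select(assignment, U.scores[:, ref], pool, b=30)
greedy_batch = mtal.select_one_sided(U, ref, pool, b=30)

def class_counts(batch):
    return np.bincount(dataset.labels[batch.indices, ref], minlength=k)

print(f"reference task {ref}, k = {k} clusters, batch of 30")
print("greedy LC batch class counts:   ", class_counts(greedy_batch))
print("CSS batch class counts:         ", class_counts(css_batch))
per_cluster = np.bincount([p["cluster_id"] for p in css_batch.provenance], minlength=k)
print("CSS picks per cluster (quotas): ", per_cluster)

# CSS spreads the batch evenly over feature-space clusters; because clusters
# align with classes on this benchmark, the batch covers all classes.
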