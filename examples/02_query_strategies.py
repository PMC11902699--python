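"""Score an unlabeled pool and compare the three query strategies.

Trains the multitask model on a tiny 3-sample seed, scores the unlabeled pool
with each informativeness measure, and shows which samples one-sided,
alternating and rank-combination selection would query next.
"""

import numpy as np

import mtal

dataset = mtal.ku_like(n=600, seed=1)
pool = mtal.split_seed(dataset, n_seed=3, seed=1)
print(f"seed pool: {pool.n_labeled} labeled / {pool.n_unlabeled} unlabeled")

model = mtal.fit(
    mtal.ModelConfig(epochs=50, seed=0),
    dataset.features[pool.labeled], dataset.labels[pool.labeled], dataset.tasks,
)
probs = mtal.predict_proba(model, dataset.features[pool.unlabeled])

for measure in ("least_confidence", "margin", "entropy"):
    U = mtal.score_pool(probs, measure)
    print(f"{measure:>16}: score range [{U.scores.min():.3f}, {U.scores.max():.3f}]")

U_lc = mtal.score_pool(probs, "least_confidence")
U_ent = mtal.score_pool(probs, "entropy")
ref = mtal.reference_task(dataset.labels[dataset.train_indices])

one_sided = mtal.select_one_sided(U_lc, ref, pool, b=5)
alternating = mtal.select_alternating(U_lc, iteration=1, pool=pool, b=5)
rc = mtal.select_rank_combination(U_ent, pool, b=5)

print(f"\none-sided (reference task {ref}):", one_sided.indices.tolist())
print("alternating (iteration 1 -> task 1):", alternating.indices.tolist())
print("rank combination (smallest rank sums):", rc.indices.tolist())
print("  RC rank sums:", [round(p["rank_sum"], 1) for p in rc.provenance])

# One-sided focuses on samples the model finds hardest for the reference task;
# RC sums per-task entropy ranks so its picks are uncertain for *all* tasks.
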