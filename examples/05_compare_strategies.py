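"""Strategy-comparison grid: plain vs CSS variants at several budgets.

Runs each query strategy with and without clustered stratified sampling on a
reduced benchmark and tabulates mean +/- sd average accuracy over repeats.
(Desk-scale settings; increase n, budgets and repeats for smoother numbers.)
"""

import mtal

dataset = mtal.ku_like(n=1000, seed=4)
table = mtal.compare_strategies(
    dataset,
    strategies=["random", "one_sided", "rank_combination"],
    budgets=[60, 120],
    repeats=3,
    master_seed=4,
    css_flags=(False, True),
    base_config=mtal.RunConfig(budget=120, batch_size=20, model=mtal.ModelConfig(epochs=60)),
)
print(mtal.format_table(table))

# Each row is one (strategy, CSS) arm read at a budget checkpoint; the same
# per-repeat seeds are reused across arms, so rows are directly comparable.
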