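"""The two-stage optimal-parameter-range search, demonstrated with mock trainers.

Stage 1 picks the convolutional depth with the best grid-mean recognition
rate; stage 2 repeats the per-combination search N times at that depth and
pools the per-iteration best combos into per-family [min, max] ranges.  A
deterministic pseudo-accuracy trainer stands in for real training so the
combinatorics run in seconds; pass a real trainer callable for actual runs.
"""

from respiradar import (
    ParamGrid,
    count_combos,
    search_optimal_depth,
    search_optimal_range,
    summarize_search,
)

grid = ParamGrid()
print("combination counts:",
      {d: count_combos(grid, d) for d in grid.depths})

# stage 1: injected per-depth mean accuracies (87.4% / 90.7% / 92.6%)
means = {1: 0.874, 2: 0.907, 3: 0.926}
depth_result = search_optimal_depth(grid, trainer=lambda c: means[c.depth],
                                    subsample=100, seed=0)
print(summarize_search(depth_result)["depth_means"].to_string(index=False))
print(f"optimal depth: {depth_result.d_opt}\n")


# stage 2: a combo-dependent pseudo-accuracy, subsampled grid, 5 iterations
def pseudo_trainer(combo, iteration=0):
    h = hash((combo.conv_layers, combo.dense_neurons, iteration))
    return 0.85 + (h % 1000) / 10_000.0


range_result = search_optimal_range(grid, depth_result.d_opt, pseudo_trainer,
                                    n_iterations=5, subsample=400, seed=0)
tables = summarize_search(range_result)
print(tables["iteration_bests"].to_string(index=False))
print()
print(tables["optimal_ranges"].to_string(index=False))
print("\nThe ranges pool kernel sizes/counts across all conv layers of the "
      "per-iteration best combos.")
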