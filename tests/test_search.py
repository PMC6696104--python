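import itertools
import warnings

import numpy as np
import pytest

from respiradar import (
    ParamCombo,
    ParamGrid,
    combo_from_index,
    combo_to_index,
    count_combos,
    enumerate_combos,
    extract_parameter_ranges,
    search_optimal_depth,
    search_optimal_range,
    summarize_search,
)

SMALL_GRID = ParamGrid(depths=(1, 2), kernel_sizes=(3, 5), kernel_counts=(4,),
                       dense_counts=(8, 16))

# the four published per-iteration best combinations (iterations 1, 2, 8, 10)
# of the 10-iteration range search, with their sequence numbers
PUBLISHED_BESTS = [
    (942110, ParamCombo(((21, 256), (25, 128), (29, 64)), (2048, 1024))),
    (898926, ParamCombo(((21, 128), (21, 256), (29, 128)), (2048, 1024))),
    (937339, ParamCombo(((21, 256), (21, 64), (29, 256)), (1024, 2048))),
    (1098106, ParamCombo(((25, 128), (21, 128), (29, 64)), (1024, 1024))),
]


class TestEnumeration:
    def test_default_grid_cardinalities(self):
        grid = ParamGrid()
        assert count_combos(grid, 1) == 800
        assert count_combos(grid, 2) == 40_000
        assert count_combos(grid, 3) == 2_000_000

    def test_small_grid_matches_bruteforce_product(self):
        # independent oracle: itertools product in lexicographic order
        grid = SMALL_GRID
        pairs = list(itertools.product(grid.kernel_sizes, grid.kernel_counts))
        expected = [
            ParamCombo(conv_layers=(p1, p2), dense_neurons=(d1, d2))
            for p1 in pairs for p2 in pairs
            for d1 in grid.dense_counts for d2 in grid.dense_counts
        ]
        got = list(enumerate_combos(grid, 2))
        assert len(got) == 16 == count_combos(grid, 2)
        assert got == expected

    def test_index_roundtrip(self):
        grid = SMALL_GRID
        for i in range(count_combos(grid, 2)):
            combo = combo_from_index(grid, 2, i)
            assert combo_to_index(grid, combo) == i

    def test_published_sequence_numbers(self):
        grid = ParamGrid()
        for seq, combo in PUBLISHED_BESTS:
            assert combo_to_index(grid, combo) == seq
            assert combo_from_index(grid, 3, seq) == combo

    def test_subsample_draws_without_replacement(self):
        grid = ParamGrid()
        combos = list(enumerate_combos(grid, 1, subsample=50, seed=3))
        assert len(combos) == 50
        idx = [combo_to_index(grid, c) for c in combos]
        assert len(set(idx)) == 50
        assert idx == sorted(idx)
        again = list(enumerate_combos(grid, 1, subsample=50, seed=3))
        assert combos == again

    def test_subsample_too_large_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_combos(SMALL_GRID, 1, subsample=100))


def _pseudo_accuracy(combo: ParamCombo) -> float:
    """Deterministic combo-dependent mock accuracy."""
    h = hash((combo.conv_layers, combo.dense_neurons))
    return 0.5 + (h % 1000) / 2000.0


class TestDepthSearch:
    def test_reported_depth_means_pick_depth_3(self):
        # grid-mean accuracies 87.4% / 90.7% / 92.6% at depths 1/2/3
        means = {1: 0.874, 2: 0.907, 3: 0.926}
        grid = ParamGrid(depths=(1, 2, 3), kernel_sizes=(3, 5),
                         kernel_counts=(4,), dense_counts=(8, 16))
        result = search_optimal_depth(grid,
                                      trainer=lambda combo: means[combo.depth])
        assert result.d_opt == 3
        for d, m in means.items():
            assert result.per_depth[d].mean_accuracy == pytest.approx(m)

    def test_constant_trainer_ties_break_to_shallowest(self):
        result = search_optimal_depth(SMALL_GRID, trainer=lambda c: 0.5)
        assert result.d_opt == 1

    def test_mean_matches_bruteforce(self):
        result = search_optimal_depth(SMALL_GRID, trainer=_pseudo_accuracy)
        for depth in SMALL_GRID.depths:
            expected = np.mean([_pseudo_accuracy(c)
                                for c in enumerate_combos(SMALL_GRID, depth)])
            assert result.per_depth[depth].mean_accuracy == pytest.approx(expected)
            assert result.per_depth[depth].combo_count == count_combos(
                SMALL_GRID, depth)

    def test_trainer_failures_excluded_with_warning(self):
        def flaky(combo):
            if combo.dense_neurons == (8, 8):
                raise RuntimeError("boom")
            return 0.7

        with pytest.warns(UserWarning, match="trainer failed"):
            result = search_optimal_depth(SMALL_GRID, trainer=flaky)
        r = result.per_depth[1]
        assert r.n_failed == 2          # (8,8) appears twice at depth 1
        assert r.n_evaluated == 8 - 2
        assert r.mean_accuracy == pytest.approx(0.7)


class TestRangeSearch:
    def test_single_iteration_degenerate_ranges(self):
        target = ParamCombo(((5, 4), (3, 4)), (16, 16))

        def trainer(combo, iteration=0):
            return 0.99 if combo == target else 0.5

        result = search_optimal_range(SMALL_GRID, 2, trainer, n_iterations=1)
        assert result.iterations[0].combo == target
        assert result.ks_range == (3, 5)    # pooled over the two conv layers
        assert result.kc_range == (4, 4)
        assert result.dlnc_range == (16, 16)

    def test_published_bests_give_published_ranges(self):
        combos = [c for _, c in PUBLISHED_BESTS]
        ks, kc, dlnc = extract_parameter_ranges(combos)
        assert ks == (21, 29)
        assert kc == (64, 256)
        assert dlnc == (1024, 2048)

    def test_end_to_end_injected_iteration_bests(self):
        # a grid restricted to the published optimum neighbourhood; the mock
        # trainer makes each iteration's best equal one published combo
        grid = ParamGrid(depths=(3,), kernel_sizes=(21, 25, 29),
                         kernel_counts=(64, 128, 256),
                         dense_counts=(1024, 2048))
        targets = {t + 1: c for t, (_, c) in enumerate(
            [b for b in PUBLISHED_BESTS if b[1].dense_neurons != (1024, 1024)])}
        # (1024, 1024) is outside this reduced grid; use the three that fit

        def trainer(combo, iteration=1):
            return 0.95 if combo == targets[iteration] else _pseudo_accuracy(combo) * 0.5

        result = search_optimal_range(grid, 3, trainer,
                                      n_iterations=len(targets))
        assert [b.combo for b in result.iterations] == list(targets.values())
        assert result.ks_range == (21, 29)
        assert result.kc_range == (64, 256)
        assert result.dlnc_range == (1024, 2048)

    def test_ranges_monotone_in_iterations(self):
        combos = [c for _, c in PUBLISHED_BESTS]
        prev = None
        for k in range(1, len(combos) + 1):
            ks, kc, dl = extract_parameter_ranges(combos[:k])
            if prev is not None:
                for new, old in zip((ks, kc, dl), prev):
                    assert new[0] <= old[0] and new[1] >= old[1]
            prev = (ks, kc, dl)

    def test_ranges_subset_of_grid(self):
        grid = SMALL_GRID
        result = search_optimal_range(grid, 2, _pseudo_accuracy, n_iterations=3)
        assert result.ks_range[0] in grid.kernel_sizes
        assert result.ks_range[1] in grid.kernel_sizes
        assert result.kc_range[0] in grid.kernel_counts
        assert result.dlnc_range[0] in grid.dense_counts


class TestSummaries:
    def test_depth_summary_table(self):
        result = search_optimal_depth(SMALL_GRID, trainer=_pseudo_accuracy)
        tables = summarize_search(result)
        df = tables["depth_means"]
        assert list(df["depth"]) == [1, 2]
        assert df["is_optimal"].sum() == 1

    def test_range_summary_tables(self):
        result = search_optimal_range(SMALL_GRID, 2, _pseudo_accuracy,
                                      n_iterations=4)
        tables = summarize_search(result)
        assert len(tables["iteration_bests"]) == 4
        assert list(tables["optimal_ranges"]["parameter"]) == ["KS", "KC", "DLNC"]

    def test_unknown_result_type_rejected(self):
        with pytest.raises(TypeError):
            summarize_search(object())
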