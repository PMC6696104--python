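"""Two-stage hyperparameter range search over the CNN parameter grid.

Stage 1 picks the convolutional-layer depth whose grid-mean recognition rate
is highest; stage 2 repeats the per-combination search N times at that depth
and reports, per parameter family, the [min, max] range spanned by the N
per-iteration best combinations.

Combinations are enumerated in a fixed lexicographic mixed-radix order
(layers most significant, per-layer pair index = ks_index * |KC| + kc_index,
then the two dense widths), so every combination has a stable integer
sequence number; enumeration is lazy and a seeded uniform subsample is
supported for grids too large to train exhaustively.
"""

from __future__ import annotations

import inspect
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ParamCombo

__all__ = [
    "ParamGrid",
    "DepthResult",
    "DepthSearchResult",
    "IterationBest",
    "RangeSearchResult",
    "count_combos",
    "combo_from_index",
    "combo_to_index",
    "enumerate_combos",
    "search_optimal_depth",
    "search_optimal_range",
    "extract_parameter_ranges",
    "summarize_search",
]

Trainer = Callable[..., float]


@dataclass(frozen=True)
class ParamGrid:
    """The searched value sets (defaults reproduce the experiment grid)."""

    depths: tuple[int, ...] = (1, 2, 3)
    kernel_sizes: tuple[int, ...] = (5, 9, 13, 17, 21, 25, 29, 33, 37, 41)
    kernel_counts: tuple[int, ...] = (32, 64, 128, 256, 512)
    dense_counts: tuple[int, ...] = (256, 512, 1024, 2048)

    def __post_init__(self) -> None:
        for name in ("depths", "kernel_sizes", "kernel_counts", "dense_counts"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(int(v) != v or v < 1 for v in vals):
                raise ValueError(f"{name} must hold positive integers")


def count_combos(grid: ParamGrid, depth: int) -> int:
    """Number of combinations at a depth: (|KS|*|KC|)^depth * |DLNC|^2."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    pairs = len(grid.kernel_sizes) * len(grid.kernel_counts)
    return pairs ** depth * len(grid.dense_counts) ** 2


def combo_from_index(grid: ParamGrid, depth: int, index: int) -> ParamCombo:
    """Decode a sequence number into its combination (lexicographic order)."""
    total = count_combos(grid, depth)
    if not (0 <= index < total):
        raise ValueError(f"index {index} outside [0, {total})")
    nk, nc, nd = len(grid.kernel_sizes), len(grid.kernel_counts), len(grid.dense_counts)
    d2 = index % nd
    index //= nd
    d1 = index % nd
    index //= nd
    layers: list[tuple[int, int]] = []
    for _ in range(depth):
        pair = index % (nk * nc)
        index //= nk * nc
        layers.append((grid.kernel_sizes[pair // nc], grid.kernel_counts[pair % nc]))
    layers.reverse()  # first conv layer is most significant
    return ParamCombo(conv_layers=tuple(layers),
                      dense_neurons=(grid.dense_counts[d1], grid.dense_counts[d2]))


def combo_to_index(grid: ParamGrid, combo: ParamCombo) -> int:
    """Sequence number of a combination under the grid's enumeration order."""
    nk, nc, nd = len(grid.kernel_sizes), len(grid.kernel_counts), len(grid.dense_counts)
    idx = 0
    for ks, kc in combo.conv_layers:
        idx = idx * (nk * nc) + grid.kernel_sizes.index(ks) * nc \
            + grid.kernel_counts.index(kc)
    d1, d2 = combo.dense_neurons
    return (idx * nd + grid.dense_counts.index(d1)) * nd + grid.dense_counts.index(d2)


def enumerate_combos(
    grid: ParamGrid,
    depth: int,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> Iterator[ParamCombo]:
    """Lazily enumerate combinations at a depth in sequence-number order.

    With ``subsample``, a seeded uniform draw of that many distinct sequence
    numbers is enumerated instead (still in ascending order).
    """
    total = count_combos(grid, depth)
    if subsample is None:
        indices: Iterable[int] = range(total)
    else:
        if subsample > total:
            raise ValueError(f"subsample {subsample} exceeds {total} combinations")
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(total, size=subsample, replace=False))
    for i in indices:
        yield combo_from_index(grid, depth, int(i))


@dataclass
class DepthResult:
    depth: int
    mean_accuracy: float
    accuracies: list[Optional[float]]
    combo_count: int          # full-grid cardinality z at this depth
    n_evaluated: int
    n_failed: int


@dataclass
class DepthSearchResult:
    per_depth: dict[int, DepthResult]
    d_opt: int


@dataclass
class IterationBest:
    iteration: int
    combo: ParamCombo
    accuracy: float
    sequence_no: int


@dataclass
class RangeSearchResult:
    iterations: list[IterationBest]
    ks_range: tuple[int, int]
    kc_range: tuple[int, int]
    dlnc_range: tuple[int, int]
    d_opt: int


def _call_trainer(trainer: Trainer, combo: ParamCombo,
                  iteration: Optional[int], accepts_iteration: bool) -> float:
    if accepts_iteration and iteration is not None:
        return trainer(combo, iteration=iteration)
    return trainer(combo)


def _accepts_iteration(trainer: Trainer) -> bool:
    try:
        sig = inspect.signature(trainer)
    except (TypeError, ValueError):
        return False
    return any(
        p.name == "iteration" or p.kind is inspect.Parameter.VAR_KEYWORD
        for p in sig.parameters.values()
    )


def search_optimal_depth(
    grid: ParamGrid,
    trainer: Trainer,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> DepthSearchResult:
    """Stage 1: evaluate every (or a subsampled) combination per depth.

    The optimal depth maximizes the mean accuracy over evaluated combos; ties
    break to the smallest depth.  A trainer failure on a combo is recorded as
    missing, excluded from the mean, and warned about.
    """
    per_depth: dict[int, DepthResult] = {}
    for depth in sorted(grid.depths):
        accs: list[Optional[float]] = []
        n_failed = 0
        for combo in enumerate_combos(grid, depth, subsample=subsample,
                                      seed=seed + depth):
            try:
                acc = float(trainer(combo))
            except Exception as exc:  # noqa: BLE001 - combo-level isolation
                warnings.warn(f"trainer failed on {combo}: {exc}", stacklevel=2)
                accs.append(None)
                n_failed += 1
                continue
            accs.append(acc)
        ok = [a for a in accs if a is not None]
        mean = float(np.mean(ok)) if ok else float("nan")
        per_depth[depth] = DepthResult(
            depth=depth, mean_accuracy=mean, accuracies=accs,
            combo_count=count_combos(grid, depth),
            n_evaluated=len(ok), n_failed=n_failed,
        )
    d_opt, best = None, -math.inf
    for depth in sorted(per_depth):
        m = per_depth[depth].mean_accuracy
        if not math.isnan(m) and m > best:
            d_opt, best = depth, m
    if d_opt is None:
        raise RuntimeError("no depth produced any successful evaluation")
    return DepthSearchResult(per_depth=per_depth, d_opt=d_opt)


def extract_parameter_ranges(
    combos: Sequence[ParamCombo],
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """[min, max] per parameter family over a set of best combinations.

    Kernel sizes and kernel counts are pooled across all convolutional
    layers; dense widths are pooled over both dense layers.
    """
    if len(combos) == 0:
        raise ValueError("no combinations to extract ranges from")
    ks = [k for c in combos for k, _ in c.conv_layers]
    kc = [k for c in combos for _, k in c.conv_layers]
    dl = [d for c in combos for d in c.dense_neurons]
    return (min(ks), max(ks)), (min(kc), max(kc)), (min(dl), max(dl))


def search_optimal_range(
    grid: ParamGrid,
    d_opt: int,
    trainer: Trainer,
    n_iterations: int = 10,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> RangeSearchResult:
    """Stage 2: N repeated searches at the fixed depth.

    Each iteration records the argmax-accuracy combination (ties break to the
    first in enumeration order); the final ranges are the per-family
    [min, max] over the N recorded combos.  The trainer may accept an
    ``iteration`` keyword to model run-to-run stochasticity.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    accepts_iter = _accepts_iteration(trainer)
    bests: list[IterationBest] = []
    for t in range(1, n_iterations + 1):
        best_combo, best_acc = None, -math.inf
        for combo in enumerate_combos(grid, d_opt, subsample=subsample,
                                      seed=seed + t):
            try:
                acc = float(_call_trainer(trainer, combo, t, accepts_iter))
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"trainer failed on {combo}: {exc}", stacklevel=2)
                continue
            if acc > best_acc:
                best_combo, best_acc = combo, acc
        if best_combo is None:
            raise RuntimeError(f"iteration {t}: every evaluation failed")
        bests.append(IterationBest(
            iteration=t, combo=best_combo, accuracy=best_acc,
            sequence_no=combo_to_index(grid, best_combo)))
    ks_r, kc_r, dl_r = extract_parameter_ranges([b.combo for b in bests])
    return RangeSearchResult(iterations=bests, ks_range=ks_r, kc_range=kc_r,
                             dlnc_range=dl_r, d_opt=d_opt)


def summarize_search(result) -> dict[str, pd.DataFrame]:
    """Tabular report of a search result (per-depth means or per-iteration bests)."""
    if isinstance(result, DepthSearchResult):
        rows = [
            {
                "depth": r.depth,
                "mean_accuracy": r.mean_accuracy,
                "combo_count": r.combo_count,
                "n_evaluated": r.n_evaluated,
                "n_failed": r.n_failed,
                "is_optimal": r.depth == result.d_opt,
            }
            for r in result.per_depth.values()
        ]
        return {"depth_means": pd.DataFrame(rows).sort_values("depth",
                                                              ignore_index=True)}
    if isinstance(result, RangeSearchResult):
        it_rows = [
            {
                "iteration": b.iteration,
                "sequence_no": b.sequence_no,
                "accuracy": b.accuracy,
                "conv_layers": "; ".join(
                    f"KS:{ks},KC:{kc}" for ks, kc in b.combo.conv_layers),
                "dense": f"{b.combo.dense_neurons[0]}/{b.combo.dense_neurons[1]}",
            }
            for b in result.iterations
        ]
        rng_rows = [
            {"parameter": "KS", "min": result.ks_range[0], "max": result.ks_range[1]},
            {"parameter": "KC", "min": result.kc_range[0], "max": result.kc_range[1]},
            {"parameter": "DLNC", "min": result.dlnc_range[0],
             "max": result.dlnc_range[1]},
        ]
        return {"iteration_bests": pd.DataFrame(it_rows),
                "optimal_ranges": pd.DataFrame(rng_rows)}
    raise TypeError(f"unsupported result type: {type(result)!r}")
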