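"""Raw radar streams to labeled training windows.

Pipeline: scalar Kalman smoothing of the target range-bin series, distance-
gated bin selection, 10-s sliding-window extraction with time-shift
augmentation, and seeded class-stratified train/test splitting.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np

from .datatypes import (
    DEFAULT_BIN_SPACING_CM,
    FRAME_RATE_HZ,
    N_RANGE_BINS,
    KalmanParams,
    PatternClass,
    RadarFrame,
    RespirationTrace,
    SplitSpec,
    WindowSample,
    WindowSpec,
)

__all__ = [
    "kalman_filter",
    "extract_respiration",
    "window_series",
    "split_dataset",
]


def kalman_filter(
    signal: Sequence[float],
    params: KalmanParams = KalmanParams(),
    init_estimate: Optional[float] = None,
    init_variance: Optional[float] = None,
) -> np.ndarray:
    """Scalar random-walk Kalman filter.

    Per measurement m: predict ``P += q``; update ``K = P/(P+r)``,
    ``x += K*(m - x)``, ``P *= (1-K)``.  Defaults initialise from the data
    (x0 = first measurement, P0 = r + q) to avoid a startup transient on
    arbitrary signal offsets.  Returns the per-step posterior estimates,
    same length as the input.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    est = float(x[0]) if init_estimate is None else float(init_estimate)
    var = (params.r + params.q) if init_variance is None else float(init_variance)
    q, r = params.q, params.r
    out = np.empty_like(x)
    for i in range(x.size):
        var += q
        gain = var / (var + r)
        est += gain * (x[i] - est)
        var *= 1.0 - gain
        out[i] = est
    return out


def extract_respiration(
    frames: Iterable[RadarFrame],
    distance_cm: float = 20.0,
    tolerance_bins: int = 3,
    kalman: KalmanParams = KalmanParams(),
    bin_spacing_cm: float = DEFAULT_BIN_SPACING_CM,
    fs: float = FRAME_RATE_HZ,
    return_bin: bool = False,
):
    """Select the respiration-carrying range bin and return its filtered series.

    Within ``tolerance_bins`` of the bin implied by the sensor-to-thorax
    distance, the bin with maximal temporal variance is selected (ties break
    to the lowest index); its time series is Kalman-filtered.  With
    ``return_bin`` the selected bin index is returned alongside the trace.
    """
    frame_list = list(frames)
    if not frame_list:
        raise ValueError("empty radar frame stream")
    target = int(round(distance_cm / bin_spacing_cm))
    if not (0 <= target < N_RANGE_BINS):
        raise ValueError(
            f"distance {distance_cm} cm maps to bin {target}, outside "
            f"[0, {N_RANGE_BINS - 1}]"
        )
    arr = np.stack([f.bins for f in frame_list])  # (n_frames, 660)
    lo = max(0, target - tolerance_bins)
    hi = min(N_RANGE_BINS - 1, target + tolerance_bins)
    variances = arr[:, lo:hi + 1].var(axis=0)
    best = lo + int(np.argmax(variances))  # argmax returns first max: lowest index
    filtered = kalman_filter(arr[:, best], params=kalman)
    trace = RespirationTrace(filtered, fs=fs, label=None)
    return (trace, best) if return_bin else trace


def window_series(
    trace: RespirationTrace,
    spec: WindowSpec = WindowSpec(),
    label: Optional[PatternClass] = None,
    max_windows: Optional[int] = None,
) -> list[WindowSample]:
    """Cut a trace into time-shifted windows (offsets 0, S, 2S, ...).

    Yields ``floor((T - L)/S) + 1`` windows; when ``max_windows`` caps the
    count, a uniform-stride subselection over the candidate offsets is used.
    Every window inherits the trace's (or the explicit) label — one pattern
    per window.
    """
    T = len(trace)
    L, S = spec.window_len, spec.shift
    if T < L:
        raise ValueError(f"trace of {T} samples is shorter than the "
                         f"{L}-sample window")
    lab = label if label is not None else trace.label
    if lab is None:
        raise ValueError("no label: trace is unlabeled and none was given")
    n_avail = (T - L) // S + 1
    starts = np.arange(n_avail) * S
    if max_windows is not None:
        if max_windows < 1:
            raise ValueError("max_windows must be >= 1")
        if max_windows < n_avail:
            sel = (np.arange(max_windows) * n_avail) // max_windows
            starts = starts[sel]
    sid = trace.subject_id or "trace"
    return [
        WindowSample(values=trace.samples[s:s + L].copy(), label=lab,
                     source_id=f"{sid}:{lab.value}:{int(s)}")
        for s in starts
    ]


def split_dataset(
    samples: Sequence[WindowSample],
    spec: SplitSpec = SplitSpec(),
) -> tuple[list[WindowSample], list[WindowSample]]:
    """Seeded train/test partition, class-stratified by default.

    Stratified: each class contributes ``round(train_fraction * n_class)``
    members to train, remainder to test; a class with fewer than 2 members
    goes entirely to train with a warning.  The partition is disjoint and
    exhaustive, and identical seeds give identical partitions.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        by_class: dict[PatternClass, list[int]] = {}
        for i, s in enumerate(samples):
            by_class.setdefault(s.label, []).append(i)
        for cls in sorted(by_class, key=lambda c: c.value):
            idx = np.array(by_class[cls])
            if idx.size < 2:
                warnings.warn(
                    f"class {cls.value} has {idx.size} sample(s); "
                    "assigning all to train", stacklevel=2)
                train_idx.extend(idx.tolist())
                continue
            rng.shuffle(idx)
            n_train = round(spec.train_fraction * idx.size)
            train_idx.extend(idx[:n_train].tolist())
            test_idx.extend(idx[n_train:].tolist())
    else:
        idx = rng.permutation(len(samples))
        n_train = round(spec.train_fraction * len(samples))
        train_idx = idx[:n_train].tolist()
        test_idx = idx[n_train:].tolist()
    train_idx = list(np.array(train_idx)[rng.permutation(len(train_idx))]) \
        if train_idx else []
    test_idx = list(np.array(test_idx)[rng.permutation(len(test_idx))]) \
        if test_idx else []
    return [samples[i] for i in train_idx], [samples[i] for i in test_idx]
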