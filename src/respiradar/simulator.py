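"""Synthetic respiration-signal and radar-stream generator.

Emulates the acquisition protocol end to end so every downstream stage is
testable without human recordings: asymmetric raised-cosine breath cycles,
five pattern classes (eupnea, bradypnea, tachypnea, apnea, motion), embedding
into 660-bin radar frame streams at 25 fps, and the 10-subject x 5-pattern x
50-window collection design (2500 windows total).

All randomness is driven by explicit integer seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_BIN_SPACING_CM,
    FRAME_RATE_HZ,
    N_RANGE_BINS,
    BreathParams,
    PatternClass,
    RadarFrame,
    RespirationTrace,
    WindowSample,
    WindowSpec,
)

__all__ = [
    "simulate_breath_cycle",
    "simulate_pattern",
    "embed_in_radar_frames",
    "generate_dataset",
    "SubjectProfile",
]

#: default additive Gaussian noise, as displacement s.d. (5% of eupnea amplitude)
DEFAULT_NOISE_SD = 0.05

#: per-cycle breathing-rate jitter, as a fraction of the nominal rate
RATE_JITTER_FRAC = 0.10

#: motion transients per 10-s block: 1-3, each 3-8x the breathing amplitude
MOTION_TRANSIENTS_PER_10S = (1, 3)
MOTION_AMPLITUDE_RANGE = (3.0, 8.0)
MOTION_DECAY_RANGE_S = (0.5, 2.0)


def simulate_breath_cycle(params: BreathParams) -> np.ndarray:
    """One breath cycle as an asymmetric raised cosine.

    The cycle has ``round(fs * 60 / rate)`` samples: a half-cosine rise over
    the inspiration fraction 1/(1+e) of the cycle (e = expiration share of
    the 1:e inspiration:expiration ratio) peaking at the inspiration end,
    then a half-cosine fall over the remainder.  Trough is 0, peak is
    ``params.amplitude``, and the waveform continues smoothly into the next
    cycle (the implicit next sample is again 0).
    """
    n = int(round(params.fs * 60.0 / params.rate))
    if n < 2:
        raise ValueError(
            f"rate {params.rate}/min at fs {params.fs} Hz leaves fewer than 2 "
            "samples per cycle"
        )
    n_insp = math.ceil(n / (1.0 + params.ie_ratio))
    n_insp = min(max(n_insp, 1), n - 1)
    n_exp = n - n_insp
    i = np.arange(n, dtype=float)
    y = np.empty(n, dtype=float)
    a = params.amplitude
    y[:n_insp] = 0.5 * a * (1.0 - np.cos(np.pi * i[:n_insp] / n_insp))
    y[n_insp:] = 0.5 * a * (1.0 + np.cos(np.pi * (i[n_insp:] - n_insp) / n_exp))
    return y


def _rhythmic_samples(
    n_total: int,
    params: BreathParams,
    cls: PatternClass,
    rng: np.random.Generator,
) -> np.ndarray:
    """Concatenated breath cycles with per-cycle rate jitter inside the band."""
    chunks: list[np.ndarray] = []
    n = 0
    while n < n_total:
        rate = params.rate * (1.0 + rng.uniform(-RATE_JITTER_FRAC, RATE_JITTER_FRAC))
        rate = cls.clip_rate(rate)
        cyc = simulate_breath_cycle(
            BreathParams(rate=rate, amplitude=params.amplitude,
                         ie_ratio=params.ie_ratio, fs=params.fs)
        )
        chunks.append(cyc)
        n += cyc.size
    return np.concatenate(chunks)[:n_total]


def simulate_pattern(
    cls: PatternClass,
    duration_s: float,
    params: Optional[BreathParams] = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    subject_id: Optional[str] = None,
) -> RespirationTrace:
    """Simulate one labeled respiration trace of ``duration_s`` seconds.

    Rhythmic classes concatenate jittered breath cycles confined to the class
    rate band.  Apnea uses the same cycle shape with amplitude suppressed by
    the class factor (<= 0.10 of the eupnea baseline; default 0.05).  Motion
    superimposes 1-3 step-and-decay transients per 10 s, each 3-8x the
    breathing amplitude with random sign.  Gaussian noise with s.d.
    ``noise_sd`` is added throughout.
    """
    if duration_s < 0:
        raise ValueError(f"duration_s must be >= 0, got {duration_s}")
    if cls is PatternClass.APNEA and duration_s < 10.0:
        raise ValueError("apnea is defined as >= 10 s of suppressed flow; "
                         f"got duration {duration_s} s")
    if params is None:
        params = BreathParams()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    fs = params.fs
    n_total = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    if n_total == 0:
        return RespirationTrace(np.empty(0), fs=fs, label=cls,
                                subject_id=subject_id, seed=seed)

    eff = BreathParams(
        rate=cls.clip_rate(params.rate),
        amplitude=params.amplitude * cls.amplitude_factor,
        ie_ratio=params.ie_ratio,
        fs=fs,
    )
    base = _rhythmic_samples(n_total, eff, cls, rng)

    if cls is PatternClass.MOTION:
        t = np.arange(n_total) / fs
        n_blocks = max(1, math.ceil(duration_s / 10.0))
        for b in range(n_blocks):
            lo_t, hi_t = 10.0 * b, min(10.0 * (b + 1), duration_s)
            k = int(rng.integers(MOTION_TRANSIENTS_PER_10S[0],
                                 MOTION_TRANSIENTS_PER_10S[1] + 1))
            for _ in range(k):
                t0 = rng.uniform(lo_t, hi_t)
                amp = rng.uniform(*MOTION_AMPLITUDE_RANGE) * params.amplitude
                amp *= rng.choice([-1.0, 1.0])
                tau = rng.uniform(*MOTION_DECAY_RANGE_S)
                mask = t >= t0
                base[mask] += amp * np.exp(-(t[mask] - t0) / tau)

    base += rng.normal(0.0, noise_sd, n_total)
    return RespirationTrace(base, fs=fs, label=cls, subject_id=subject_id, seed=seed)


def embed_in_radar_frames(
    trace: RespirationTrace,
    distance_cm: float = 20.0,
    clutter_sd: float = 0.01,
    seed: int = 0,
    bin_spacing_cm: float = DEFAULT_BIN_SPACING_CM,
) -> list[RadarFrame]:
    """Embed a displacement trace into a stream of 660-bin radar frames.

    The bin nearest ``distance_cm`` carries the trace; its two neighbours
    carry a half-amplitude copy (finite range resolution); every bin carries
    i.i.d. Gaussian clutter with s.d. ``clutter_sd``.  One frame is emitted
    per trace sample with timestamps stepping by 1/fs.
    """
    target = int(round(distance_cm / bin_spacing_cm))
    if not (0 <= target < N_RANGE_BINS):
        raise ValueError(
            f"distance {distance_cm} cm maps to bin {target}, outside "
            f"[0, {N_RANGE_BINS - 1}] at {bin_spacing_cm} cm/bin"
        )
    n = len(trace)
    rng = np.random.default_rng(seed)
    bins = rng.normal(0.0, clutter_sd, (n, N_RANGE_BINS)) if clutter_sd > 0 \
        else np.zeros((n, N_RANGE_BINS))
    bins[:, target] += trace.samples
    for nb in (target - 1, target + 1):
        if 0 <= nb < N_RANGE_BINS:
            bins[:, nb] += 0.5 * trace.samples
    dt = 1.0 / trace.fs
    return [RadarFrame(frame_no=i, timestamp=i * dt, bins=bins[i]) for i in range(n)]


def target_bin_index(distance_cm: float,
                     bin_spacing_cm: float = DEFAULT_BIN_SPACING_CM) -> int:
    """Range-bin index corresponding to a sensor-to-thorax distance."""
    return int(round(distance_cm / bin_spacing_cm))


class SubjectProfile:
    """Per-subject breathing parameters drawn from seeded distributions.

    Mimics inter-subject variability: a global amplitude scale U(0.8, 1.2),
    an expiration share U(1.5, 2.0), and nominal rates drawn inside each
    class band (bradypnea U(7, 11), eupnea U(13, 19), tachypnea U(22, 40)
    breaths/min).  Apnea and motion reuse the subject's eupnea rate.
    """

    RATE_RANGES = {
        PatternClass.EUPNEA: (13.0, 19.0),
        PatternClass.BRADYPNEA: (7.0, 11.0),
        PatternClass.TACHYPNEA: (22.0, 40.0),
    }

    def __init__(self, subject_id: str, rng: np.random.Generator):
        self.subject_id = subject_id
        self.amplitude = float(rng.uniform(0.8, 1.2))
        self.ie_ratio = float(rng.uniform(1.5, 2.0))
        self.rates = {
            cls: float(rng.uniform(*band)) for cls, band in self.RATE_RANGES.items()
        }
        eup = self.rates[PatternClass.EUPNEA]
        self.rates[PatternClass.APNEA] = eup
        self.rates[PatternClass.MOTION] = eup

    def params_for(self, cls: PatternClass) -> BreathParams:
        return BreathParams(rate=self.rates[cls], amplitude=self.amplitude,
                            ie_ratio=self.ie_ratio)


def generate_dataset(
    n_subjects: int = 10,
    per_pattern: int = 50,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    window_spec: Optional[WindowSpec] = None,
    via_radar: bool = False,
    distance_cm: float = 20.0,
    clutter_sd: float = 0.01,
) -> tuple[list[WindowSample], pd.DataFrame]:
    """Generate the full labeled window collection.

    For each of ``n_subjects`` subjects and each of the five classes, one
    trace long enough for exactly ``per_pattern`` sliding windows is
    simulated (optionally routed through radar-frame embedding and
    target-bin extraction when ``via_radar``), then windowed.  Returns
    ``n_subjects * 5 * per_pattern`` windows plus per-subject metadata.
    """
    from .preprocess import extract_respiration, window_series

    if n_subjects < 1 or per_pattern < 1:
        raise ValueError("n_subjects and per_pattern must be >= 1")
    spec = window_spec or WindowSpec()
    need = spec.window_len + (per_pattern - 1) * spec.shift
    duration_s = need / spec.fs

    rng = np.random.default_rng(seed)
    windows: list[WindowSample] = []
    meta_rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        profile = SubjectProfile(sid, rng)
        for cls in PatternClass:
            trace_seed = int(rng.integers(0, 2**31 - 1))
            params = profile.params_for(cls)
            trace = simulate_pattern(cls, duration_s, params=params,
                                     noise_sd=noise_sd, seed=trace_seed,
                                     subject_id=sid)
            if via_radar:
                embed_seed = int(rng.integers(0, 2**31 - 1))
                frames = embed_in_radar_frames(trace, distance_cm=distance_cm,
                                               clutter_sd=clutter_sd,
                                               seed=embed_seed)
                extracted = extract_respiration(frames, distance_cm=distance_cm)
                trace = RespirationTrace(extracted.samples, fs=trace.fs,
                                         label=cls, subject_id=sid,
                                         seed=trace_seed)
            windows.extend(
                window_series(trace, spec=spec, label=cls,
                              max_windows=per_pattern)
            )
            meta_rows.append({
                "subject": sid,
                "pattern": cls.value,
                "rate_bpm": params.rate,
                "amplitude": params.amplitude,
                "ie_ratio": params.ie_ratio,
                "noise_sd": noise_sd,
                "trace_seed": trace_seed,
                "n_windows": per_pattern,
            })
    return windows, pd.DataFrame(meta_rows)
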