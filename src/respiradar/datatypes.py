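"""Shared data containers for radar respiration signals.

The acquisition geometry mirrors an impulse UWB radar staring at a lying
subject: each frame is one amplitude sweep over 660 discrete range bins at
25 frames per second, and chest displacement modulates the bin at the
subject's distance.  Pattern windows are 10-s (250-sample) displacement
vectors labeled with one of five respiration classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

#: frames (samples) per second produced by the radar
FRAME_RATE_HZ: float = 25.0
#: range bins stored per frame
N_RANGE_BINS: int = 660
#: default range-bin spacing; 660 bins x 3 cm ~ 19.8 m of range coverage
DEFAULT_BIN_SPACING_CM: float = 3.0
#: default window length: 10 s at 25 Hz
WINDOW_LEN: int = 250


class PatternClass(Enum):
    """The five respiration signal classes.

    The three rhythmic classes are defined by breaths/min bands (eupnea owns
    the closed interval [12, 20]; bradypnea strictly below; tachypnea strictly
    above).  Apnea is a >=90% amplitude reduction sustained >=10 s; motion is
    a body-movement artifact with large aperiodic transients.
    """

    EUPNEA = "eupnea"
    BRADYPNEA = "bradypnea"
    TACHYPNEA = "tachypnea"
    APNEA = "apnea"
    MOTION = "motion"

    @property
    def rate_band(self) -> Optional[tuple[float, float]]:
        """Breaths/min band for rhythmic classes, ``None`` otherwise."""
        return _RATE_BANDS[self]

    @property
    def amplitude_factor(self) -> float:
        """Displacement amplitude relative to the eupnea baseline."""
        return _AMPLITUDE_FACTORS[self]

    def clip_rate(self, rate: float) -> float:
        """Clip a breaths/min value into this class's band (identity if none)."""
        band = self.rate_band
        if band is None:
            return rate
        lo, hi = band
        return float(min(max(rate, lo), hi))


# Eupnea owns [12, 20] inclusive; the open neighbours are realised by nudging
# clipped rates off the shared boundary by one machine-noticeable step.
_RATE_BANDS = {
    PatternClass.EUPNEA: (12.0, 20.0),
    PatternClass.BRADYPNEA: (1.0, 12.0 - 1e-6),
    PatternClass.TACHYPNEA: (20.0 + 1e-6, 60.0),
    PatternClass.APNEA: None,
    PatternClass.MOTION: None,
}

_AMPLITUDE_FACTORS = {
    PatternClass.EUPNEA: 1.0,
    PatternClass.BRADYPNEA: 0.7,   # lowered depth of inhalation/exhalation
    PatternClass.TACHYPNEA: 0.5,   # shallow breathing
    PatternClass.APNEA: 0.05,      # >=95% flow reduction (bound is <=0.10)
    PatternClass.MOTION: 1.0,      # breathing baseline under the transients
}

#: fixed label ordering used for confusion matrices and model outputs
CLASS_ORDER: tuple[PatternClass, ...] = (
    PatternClass.EUPNEA,
    PatternClass.BRADYPNEA,
    PatternClass.TACHYPNEA,
    PatternClass.APNEA,
    PatternClass.MOTION,
)

CLASS_INDEX: dict[PatternClass, int] = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class BreathParams:
    """One subject's breathing parameters.

    ``ie_ratio`` is the expiration share e of the inspiration:expiration
    ratio 1:e, physiologically in [1.5, 2.0].
    """

    rate: float = 16.0                 # breaths/min
    amplitude: float = 1.0             # displacement, arbitrary units
    ie_ratio: float = 1.75
    fs: float = FRAME_RATE_HZ          # Hz

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not (1.5 <= self.ie_ratio <= 2.0):
            raise ValueError(
                f"ie_ratio (expiration share) must be in [1.5, 2.0], got {self.ie_ratio}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")


@dataclass
class RespirationTrace:
    """A 1-D chest-displacement signal sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float = FRAME_RATE_HZ
    label: Optional[PatternClass] = None
    subject_id: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class RadarFrame:
    """One radar sweep: 660 range-bin amplitudes with frame index and time."""

    frame_no: int
    timestamp: float
    bins: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_RANGE_BINS,):
            raise ValueError(
                f"a radar frame carries exactly {N_RANGE_BINS} bins, got {self.bins.shape}"
            )


@dataclass
class WindowSample:
    """A fixed-length (default 250-sample) labeled window — the training unit."""

    values: np.ndarray
    label: PatternClass
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("window values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")


@dataclass(frozen=True)
class KalmanParams:
    """Scalar random-walk Kalman filter noise parameters (defaults 0.01/0.1)."""

    q: float = 0.01   # process-noise variance
    r: float = 0.1    # measurement-noise variance

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError(f"process noise q must be > 0, got {self.q}")
        if self.r < 0:
            raise ValueError(f"measurement noise r must be >= 0, got {self.r}")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window extraction: 250-sample windows shifted by 12 samples.

    The nominal 0.5-s shift at 25 Hz is 12.5 samples; windows must align to
    sample boundaries, so the default integer shift is 12 samples (0.48 s).
    """

    window_len: int = WINDOW_LEN
    shift: int = 12
    fs: float = FRAME_RATE_HZ

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if not (0 < self.shift <= self.window_len):
            raise ValueError(
                f"shift must satisfy 0 < shift <= window_len, got {self.shift}"
            )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: seeded shuffle, 6:4 by default, class-stratified."""

    train_fraction: float = 0.6
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")
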