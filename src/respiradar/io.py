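"""Readers and writers for the on-disk formats.

Radar record files are plain CSV, one row per frame: frame number, timestamp
in seconds, then 660 range-bin amplitudes.  Window datasets are CSV with a
``label`` column followed by the window's sample values; a JSON sidecar
carries generator metadata.  Numeric text uses 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    N_RANGE_BINS,
    KalmanParams,
    PatternClass,
    RadarFrame,
    SplitSpec,
    WindowSample,
    WindowSpec,
)
from .model import ParamCombo, TrainConfig, TrainedModel
from .search import ParamGrid

__all__ = [
    "read_radar_records",
    "write_radar_records",
    "read_windows",
    "write_windows",
    "save_model",
    "load_model",
    "RunConfig",
    "load_config",
    "save_config",
    "FormatError",
]

_FMT = "%.6g"


class FormatError(ValueError):
    """A malformed on-disk record (message names the offending line)."""


def write_radar_records(frames: Sequence[RadarFrame],
                        path: Union[str, Path]) -> None:
    """Write a frame stream: frame_no, timestamp, 660 amplitudes per row."""
    path = Path(path)
    with path.open("w") as fh:
        for f in frames:
            vals = ",".join(_FMT % v for v in f.bins)
            fh.write(f"{f.frame_no},{_FMT % f.timestamp},{vals}\n")


def read_radar_records(path: Union[str, Path]) -> list[RadarFrame]:
    """Read and validate a radar record file.

    Raises :class:`FormatError` naming the 1-based line number of any row
    whose column count is not 2 + 660 or whose fields do not parse.
    """
    path = Path(path)
    frames: list[RadarFrame] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2 + N_RANGE_BINS:
                raise FormatError(
                    f"{path}:{lineno}: expected {2 + N_RANGE_BINS} columns "
                    f"(frame_no, timestamp, {N_RANGE_BINS} bins), got {len(parts)}")
            try:
                frame_no = int(parts[0])
                timestamp = float(parts[1])
                bins = np.array(parts[2:], dtype=float)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable field: {exc}") \
                    from exc
            frames.append(RadarFrame(frame_no=frame_no, timestamp=timestamp,
                                     bins=bins))
    return frames


def write_windows(samples: Sequence[WindowSample], path: Union[str, Path],
                  metadata: Optional[pd.DataFrame] = None) -> None:
    """Write a labeled window dataset as CSV (label, source_id, v0..vN).

    ``metadata`` (subject/seed/generator parameters) goes to a CSV sidecar
    ``<path>.meta.csv``.
    """
    path = Path(path)
    if len(samples) == 0:
        raise ValueError("no windows to write")
    n = samples[0].values.size
    cols = ",".join(f"v{i}" for i in range(n))
    with path.open("w") as fh:
        fh.write(f"label,source_id,{cols}\n")
        for s in samples:
            if s.values.size != n:
                raise ValueError("windows of mixed lengths")
            vals = ",".join(_FMT % v for v in s.values)
            fh.write(f"{s.label.value},{s.source_id},{vals}\n")
    if metadata is not None:
        metadata.to_csv(path.with_suffix(path.suffix + ".meta.csv"), index=False)


def read_windows(path: Union[str, Path]) -> list[WindowSample]:
    """Read a labeled window CSV written by :func:`write_windows`."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    value_cols = [c for c in df.columns if c.startswith("v")]
    samples = []
    for _, row in df.iterrows():
        try:
            label = PatternClass(row["label"])
        except ValueError as exc:
            raise FormatError(f"{path}: unknown label {row['label']!r}") from exc
        samples.append(WindowSample(
            values=row[value_cols].to_numpy(dtype=float),
            label=label,
            source_id=str(row.get("source_id", "")),
        ))
    return samples


# ------------------------------------------------------------ model storage

def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Serialize a trained model (weights + architecture + config) to one .npz."""
    meta = {
        "conv_layers": [list(p) for p in model.architecture.conv_layers],
        "dense_neurons": list(model.architecture.dense_neurons),
        "dropout_keep": model.architecture.dropout_keep,
        "config": dataclasses.asdict(model.config),
        "classes": [c.value for c in model.classes],
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    np.savez(path, meta=json.dumps(meta),
             history=model.history.to_json(orient="records"), **arrays)


def load_model(path: Union[str, Path]) -> TrainedModel:
    from io import StringIO

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        hist_json = str(data["history"])
        history = pd.read_json(StringIO(hist_json), orient="records") \
            if hist_json != "[]" else pd.DataFrame()
        weights = [data[f"w{i}"] for i in range(len(
            [k for k in data.files if k.startswith("w")]))]
    combo = ParamCombo(
        conv_layers=tuple(tuple(p) for p in meta["conv_layers"]),
        dense_neurons=tuple(meta["dense_neurons"]),
        dropout_keep=meta["dropout_keep"],
    )
    cfg = TrainConfig(**meta["config"])
    classes = tuple(PatternClass(v) for v in meta["classes"])
    return TrainedModel(architecture=combo, config=cfg, weights=weights,
                        history=history, classes=classes)


# ---------------------------------------------------------------- run config

@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one run; written beside every output."""

    seed: int = 0
    grid: ParamGrid = dataclasses.field(default_factory=ParamGrid)
    window: WindowSpec = dataclasses.field(default_factory=WindowSpec)
    kalman: KalmanParams = dataclasses.field(default_factory=KalmanParams)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            # grid keys mirror the parameter-table symbols
            "grid": {
                "CLD": list(self.grid.depths),
                "KS": list(self.grid.kernel_sizes),
                "KC": list(self.grid.kernel_counts),
                "DLNC": list(self.grid.dense_counts),
            },
            "window": dataclasses.asdict(self.window),
            "kalman": dataclasses.asdict(self.kalman),
            "train": dataclasses.asdict(self.train),
            "split": dataclasses.asdict(self.split),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        grid = d.get("grid", {})
        kwargs = {}
        if grid:
            kwargs["grid"] = ParamGrid(
                depths=tuple(grid.get("CLD", (1, 2, 3))),
                kernel_sizes=tuple(grid.get("KS", ParamGrid().kernel_sizes)),
                kernel_counts=tuple(grid.get("KC", ParamGrid().kernel_counts)),
                dense_counts=tuple(grid.get("DLNC", ParamGrid().dense_counts)),
            )
        if "window" in d:
            kwargs["window"] = WindowSpec(**d["window"])
        if "kalman" in d:
            kwargs["kalman"] = KalmanParams(**d["kalman"])
        if "train" in d:
            kwargs["train"] = TrainConfig(**d["train"])
        if "split" in d:
            kwargs["split"] = SplitSpec(**d["split"])
        return cls(seed=d.get("seed", 0), **kwargs)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: Union[str, Path]) -> RunConfig:
    with Path(path).open() as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})
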