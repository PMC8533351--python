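"""Uniformly sampled time-series traces and ROI definitions.

:class:`TimeSeriesTrace` is the common currency of the pipeline: every stage
(simulation, ROI extraction, calibration, kinetics) consumes and produces one.
Units are carried as a declared label, not inferred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesTrace", "RoiSpec", "read_roi_json", "write_roi_json"]


@dataclass
class TimeSeriesTrace:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        One sample per frame.
    sampling_rate : float
        Frames per second (Hz). Must be positive.
    start_time : float, default 0
        Time of the first sample, in seconds.
    units : str, default "RLU"
        Unit label, e.g. ``"RLU"`` (counts per frame), ``"cps"``
        (counts per second), ``"uM"``, ``"per_s"``, ``"au"``.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    units: str = "RLU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be 1-D with at least 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return self.start_time + np.arange(self.values.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate

    def slice_time(self, t0: float, t1: float) -> "TimeSeriesTrace":
        """Sub-trace covering frames whose start time lies in [t0, t1)."""
        t = self.times
        mask = (t >= t0) & (t < t1)
        if mask.sum() < 2:
            raise ValueError(f"window [{t0}, {t1}) contains fewer than 2 frames")
        return TimeSeriesTrace(
            self.values[mask], self.sampling_rate, start_time=float(t[mask][0]), units=self.units
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values, "units": self.units})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeriesTrace":
        """Read the shared trace dialect: columns time_s, value, units."""
        df = pd.read_csv(path)
        missing = {"time_s", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("trace CSV must contain at least 2 rows")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace CSV is not uniformly sampled")
        units = str(df["units"].iloc[0]) if "units" in df.columns else "RLU"
        return cls(df["value"].to_numpy(dtype=float), 1.0 / float(steps[0]),
                   start_time=float(t[0]), units=units)


_ROI_LABELS = {"ventricle", "atrium", "custom"} | {f"background_{i}" for i in range(1, 7)}


@dataclass
class RoiSpec:
    """Polygonal region of interest in 0-based pixel coordinates.

    Vertices are (row, col) pairs, row-major. ``reduction`` selects whether
    :func:`~cardiolum.calibration.extract_trace` sums or averages the pixels
    inside the polygon (sum for luminescence budgets, mean for SNR inputs).
    """

    label: str
    polygon: np.ndarray  # (n, 2) float array of (row, col) vertices
    reduction: str = "sum"

    def __post_init__(self) -> None:
        if self.label not in _ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}")
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centres fall inside the polygon."""
        from matplotlib.path import Path as MplPath

        rows, cols = shape
        if self.polygon[:, 0].min() < -0.5 or self.polygon[:, 1].min() < -0.5 \
                or self.polygon[:, 0].max() > rows - 0.5 or self.polygon[:, 1].max() > cols - 0.5:
            raise ValueError("polygon extends outside image bounds")
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        pts = np.column_stack([rr.ravel(), cc.ravel()])
        inside = MplPath(self.polygon).contains_points(pts)
        return inside.reshape(shape)


def write_roi_json(rois: Sequence[RoiSpec], path: str | Path) -> None:
    payload = [
        {"label": r.label, "polygon": r.polygon.tolist(), "reduction": r.reduction}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi_json(path: str | Path) -> list[RoiSpec]:
    payload = json.loads(Path(path).read_text())
    return [RoiSpec(d["label"], np.asarray(d["polygon"]), d.get("reduction", "sum"))
            for d in payload]
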