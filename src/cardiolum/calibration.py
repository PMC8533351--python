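"""Aequorin luminescence budget and signal-to-noise calibration.

Raw luminescence has no meaning in terms of Ca²⁺ until it is normalised by
the photoprotein still available: aequorin is consumed with every photon, so
the same Ca²⁺ level emits less light late in a recording. The classic
consumption-corrected signal is

    L / Lmax,

where ``L`` is the instantaneous luminescence rate (counts/s) and ``Lmax``
the emittable counts remaining. ``Lmax`` is anchored by recording until the
pool is exhausted — in practice by detergent (Triton) lysis at the end, which
releases all residual counts — so that

    Ltotal  = sum of background-subtracted counts over the whole experiment
    Lconsumed[t] = cumulative counts up to and including frame t
    Lmax[t] = Ltotal - Lconsumed[t-1]   (pool available entering frame t).

L/Lmax is monotone in free Ca²⁺ and independent of both the amount of
functional aequorin and the acquisition frequency, which is what makes it a
calibratable Ca²⁺ proxy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trace import TimeSeriesTrace, RoiSpec

__all__ = [
    "LumCalibration",
    "SnrTrace",
    "extract_trace",
    "compute_snr",
    "calibrate",
    "summarize_ratio",
]

logger = logging.getLogger(__name__)


def extract_trace(stack, roi: RoiSpec, sampling_rate: float | None = None,
                  start_time: float = 0.0) -> TimeSeriesTrace:
    """Reduce an image stack to a per-frame scalar over one ROI.

    Parameters
    ----------
    stack : path or ndarray
        Multi-page TIFF path or an (n_frames, rows, cols) array.
    roi : RoiSpec
        Pixel membership uses the pixel-centre inclusion test. The ROI's
        ``reduction`` decides sum (luminescence budgets) vs mean (SNR inputs).
    sampling_rate : float
        Required when the source carries no rate metadata (plain TIFF).
    """
    if not isinstance(stack, np.ndarray):
        import tifffile

        stack = tifffile.imread(stack)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, rows, cols)")
    if sampling_rate is None:
        raise ValueError("sampling_rate is required for TIFF/array input")

    mask = roi.mask(stack.shape[1:])
    if not mask.any():
        raise ValueError(f"empty mask for ROI {roi.label!r}")
    pixels = stack[:, mask].astype(float)
    values = pixels.sum(axis=1) if roi.reduction == "sum" else pixels.mean(axis=1)
    return TimeSeriesTrace(values, sampling_rate, start_time=start_time, units="RLU")


@dataclass
class SnrTrace:
    """Per-frame signal-to-noise ratio against a panel of background ROIs."""

    snr: np.ndarray                # masked (NaN) where background SD is zero
    background_mean: np.ndarray
    background_sd: np.ndarray
    sampling_rate: float

    @property
    def summary_mean(self) -> float:
        return float(np.nanmean(self.snr))

    @property
    def summary_max(self) -> float:
        return float(np.nanmax(self.snr))


def compute_snr(signal: TimeSeriesTrace,
                backgrounds: Sequence[TimeSeriesTrace]) -> SnrTrace:
    """SNR = (Signal − Background) / SD(Background), framewise.

    ``Background`` is the across-ROI mean of the background ROI means at each
    frame and ``SD`` their sample standard deviation (n−1): the spread of the
    background panel at that frame, not a temporal statistic. Traces must be
    mean-reduced so that differently shaped ROIs remain comparable.
    """
    if len(backgrounds) < 2:
        raise ValueError("need at least 2 background ROIs")
    n = len(signal)
    for b in backgrounds:
        if len(b) != n or b.sampling_rate != signal.sampling_rate:
            raise ValueError("all traces must share length and sampling rate")
    bg = np.vstack([b.values for b in backgrounds])
    bg_mean = bg.mean(axis=0)
    bg_sd = bg.std(axis=0, ddof=1)
    snr = np.full(n, np.nan)
    ok = bg_sd > 0
    if not ok.all():
        logger.warning("background SD is zero at %d frames; SNR masked there",
                       int((~ok).sum()))
    snr[ok] = (signal.values[ok] - bg_mean[ok]) / bg_sd[ok]
    return SnrTrace(snr, bg_mean, bg_sd, signal.sampling_rate)


@dataclass
class LumCalibration:
    """Per-frame aequorin luminescence budget.

    All budget quantities are in background-subtracted counts (RLU) except
    ``L`` (counts/s) and ``ratio`` (1/s). ``ratio`` is NaN where the
    remaining pool is below the noise floor.
    """

    raw_counts: np.ndarray    # background-subtracted counts per frame
    L: np.ndarray             # counts/s
    Ltotal: float
    Lconsumed: np.ndarray     # cumulative, inclusive of the current frame
    Lmax: np.ndarray          # counts remaining entering each frame
    ratio: np.ndarray         # L / Lmax, 1/s, NaN below the Lmax floor
    sampling_rate: float
    start_time: float
    triton_index: int | None

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.raw_counts.size) / self.sampling_rate

    @property
    def masked(self) -> np.ndarray:
        return np.isnan(self.ratio)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.raw_counts.size),
            "time_s": self.times,
            "raw_counts": self.raw_counts,
            "L_cps": self.L,
            "Lconsumed": self.Lconsumed,
            "Lmax": self.Lmax,
            "ratio_per_s": self.ratio,
            "masked_flag": self.masked.astype(int),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def calibrate(trace: TimeSeriesTrace, background: TimeSeriesTrace | float = 0.0,
              triton_index: int | None = None,
              subtract_background: bool = True,
              mask_floor: float | None = None) -> LumCalibration:
    """Transform a raw luminescence trace into the aequorin budget.

    ``raw_counts[t] = max(signal[t] − background[t], 0)`` (photon counts
    cannot be negative); ``L = raw_counts * sampling_rate``;
    ``Ltotal = Σ raw_counts`` including any Triton frames;
    ``Lmax[t] = Ltotal − Lconsumed[t−1]``; ``ratio = L / Lmax`` masked where
    the remaining pool drops below the noise floor, by default
    ``max(0.1% of Ltotal, 10 counts)`` (override with ``mask_floor``, e.g. 0
    for idealised noise-free data).

    A recording without a Triton segment underestimates the remaining pool
    (Lmax is then only the counts left in the recording), so a warning is
    issued when ``triton_index`` is None.
    """
    sig = trace.values.astype(float)
    if isinstance(background, TimeSeriesTrace):
        if len(background) != len(trace):
            raise ValueError("background trace length mismatch")
        bg = background.values.astype(float)
    else:
        bg = float(background)

    if subtract_background:
        residual = sig - bg
        n_clipped = int((residual < 0).sum())
        raw = np.maximum(residual, 0.0)
        if n_clipped > 0.5 * raw.size:
            warnings.warn(
                f"{n_clipped}/{raw.size} frames fell below background and were "
                "clipped to 0; background may be overestimated", stacklevel=2)
    else:
        raw = np.maximum(sig, 0.0)

    ltotal = float(raw.sum())
    if ltotal == 0:
        raise ValueError("no luminescence: total background-subtracted counts are zero")
    if triton_index is None:
        warnings.warn(
            "no Triton segment: Lmax reflects only counts remaining in the "
            "recording and underestimates the true pool", stacklevel=2)

    lconsumed = np.cumsum(raw)
    lmax = ltotal - np.concatenate([[0.0], lconsumed[:-1]])
    L = raw * trace.sampling_rate
    floor = max(1e-3 * ltotal, 10.0) if mask_floor is None else mask_floor
    ratio = np.full(raw.size, np.nan)
    ok = lmax >= floor if floor > 0 else lmax > 0
    ratio[ok] = L[ok] / lmax[ok]

    return LumCalibration(
        raw_counts=raw, L=L, Ltotal=ltotal, Lconsumed=lconsumed, Lmax=lmax,
        ratio=ratio, sampling_rate=trace.sampling_rate,
        start_time=trace.start_time, triton_index=triton_index,
    )


def summarize_ratio(cal: LumCalibration, window: tuple[float, float] | None = None) -> float:
    """Arithmetic mean of L/Lmax over a time window, skipping masked frames.

    This is the "time-averaged Ca²⁺ level" readout used with slow (1–2 Hz)
    acquisitions; windows before and after a drug give its fold effect.
    """
    t = cal.times
    if window is None:
        sel = np.ones(t.size, dtype=bool)
    else:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window end must exceed start")
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1.0 / cal.sampling_rate + 1e-9:
            raise ValueError("window extends outside the recording")
        sel = (t >= t0) & (t < t1)
    vals = cal.ratio[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("window is fully masked or empty")
    return float(vals.mean())
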