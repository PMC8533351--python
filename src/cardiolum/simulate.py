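"""Forward simulator of aequorin cardioluminescence in a beating larval heart.

The model chain is:

1. A beat clock: atrial beats on a regular grid at ``atrial_rate`` bpm,
   thinned to ventricular beats by the conduction rule (every beat, or every
   Nth beat for an N:1 atrioventricular block).
2. A free-Ca²⁺ trace: diastolic level plus a difference-of-exponentials
   transient (unit peak) at each ventricular beat, on a fine time grid.
3. A consumption law: aequorin is irreversibly consumed at fractional rate
   ``lambda(t) = lambda_max * Ca^n / (Kd^n + Ca^n)`` with Hill coefficient
   ``n = 3`` by default, reflecting the three Ca²⁺ ions that trigger the
   photoprotein. The remaining pool decays as ``A' = -lambda * A``.
4. Photon detection: expected detected counts in a camera frame are
   ``detect_eff * (A(frame start) - A(frame end))`` plus background; observed
   counts are Poisson draws with optional Gaussian read noise.
5. Optional detergent (Triton) lysis at ``triton_time``: the consumption rate
   steps to a large release constant so the residual pool is emitted, which
   anchors the Lmax budget downstream.

Everything is seeded and reproducible; ground truth (Ca, lambda, pool, beat
times) is returned alongside the synthetic recording so downstream estimators
can be validated against it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .trace import TimeSeriesTrace, RoiSpec, write_roi_json

__all__ = [
    "SimConfig",
    "DrugEvent",
    "GroundTruth",
    "LuminescenceSim",
    "GeometryTrace",
    "beat_kernel",
    "kernel_peak_time",
    "simulate_ca_trace",
    "simulate_luminescence",
    "render_image_stack",
    "simulate_geometry",
    "simulate_gcamp",
]

#: consumption rate (1/s) substituted after detergent lysis, fast enough to
#: empty the pool within a few seconds of recording
TRITON_RELEASE_RATE = 2.0

#: acquisition frequencies used in practice (Hz); any positive rate is allowed
STANDARD_ACQ_FREQS = (1.0, 2.0, 9.0, 12.0, 17.0, 25.0)


@dataclass(frozen=True)
class DrugEvent:
    """A pharmacological perturbation of the Ca²⁺ transients.

    From ``time`` onward the transient amplitude is multiplied by a factor
    ramping exponentially from 1 to ``ca_scale`` with time constant
    ``ramp_tau`` (drugs reach the larval heart by diffusion, so effects are
    gradual). If ``scale_diastolic`` is set the diastolic level ramps too.
    """

    time: float
    ca_scale: float
    ramp_tau: float
    scale_diastolic: bool = False

    def __post_init__(self) -> None:
        if self.time < 0 or self.ca_scale <= 0 or self.ramp_tau <= 0:
            raise ValueError("drug event needs time >= 0, ca_scale > 0, ramp_tau > 0")

    def multiplier(self, t: np.ndarray) -> np.ndarray:
        m = np.ones_like(t, dtype=float)
        after = t >= self.time
        m[after] = 1.0 + (self.ca_scale - 1.0) * (1.0 - np.exp(-(t[after] - self.time) / self.ramp_tau))
        return m


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic cardioluminescence recording.

    Defaults describe a 3–4 dpf larva: heart rate ~180 bpm, diastolic Ca²⁺
    0.1 µM rising ~1 µM per beat, transient rise ~30 ms and decay ~150 ms,
    aequorin half-consumption around 5 µM with a maximal fractional rate of
    1 s⁻¹, and a photon budget large enough that single transients are
    resolvable at 9–25 Hz.
    """

    duration: float = 60.0            # s
    acq_freq: float = 9.0             # Hz
    atrial_rate: float = 180.0        # bpm
    conduction_ratio: int = 1         # ventricle fires every Nth atrial beat
    ca_diastolic: float = 0.1         # µM
    ca_amplitude: float = 1.0         # µM, transient peak above diastole
    tau_rise: float = 0.03            # s
    tau_decay: float = 0.15           # s
    hill_n: float = 3.0               # aequorin cooperativity
    kd: float = 5.0                   # µM
    lambda_max: float = 1.0           # 1/s
    pool0: float = 1.0e6              # emittable photons at t=0
    detect_eff: float = 1.0           # fraction of emitted photons detected
    bg_rate: float = 50.0             # background counts/s per ROI
    read_noise_sd: float = 0.0        # counts per frame
    triton_time: float | None = None  # s
    drug_event: DrugEvent | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.drug_event, Mapping):
            self.drug_event = DrugEvent(**self.drug_event)
        positive = {
            "duration": self.duration, "acq_freq": self.acq_freq,
            "atrial_rate": self.atrial_rate, "ca_diastolic": self.ca_diastolic,
            "ca_amplitude": self.ca_amplitude, "tau_rise": self.tau_rise,
            "tau_decay": self.tau_decay, "kd": self.kd,
            "lambda_max": self.lambda_max, "pool0": self.pool0,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not (0 < self.detect_eff <= 1):
            raise ValueError("detect_eff must be in (0, 1]")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if int(self.conduction_ratio) != self.conduction_ratio or self.conduction_ratio < 1:
            raise ValueError("conduction_ratio must be an integer >= 1")
        self.conduction_ratio = int(self.conduction_ratio)
        if self.bg_rate < 0 or self.read_noise_sd < 0:
            raise ValueError("noise rates must be non-negative")
        if self.triton_time is not None and not (0 <= self.triton_time < self.duration):
            raise ValueError("triton_time must lie inside [0, duration)")

    # --- derived grid geometry -------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.acq_freq))

    @property
    def substeps_per_frame(self) -> int:
        """Fine integration substeps per camera frame.

        At least 20 per frame and never coarser than 1 ms, so the pool-decay
        integration error stays below 0.1%.
        """
        frame_dt = 1.0 / self.acq_freq
        return max(20, int(math.ceil(frame_dt / 1e-3)))

    @property
    def fine_dt(self) -> float:
        return 1.0 / (self.acq_freq * self.substeps_per_frame)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent state of a simulated recording, on the fine time grid."""

    ca_trace: TimeSeriesTrace        # µM
    lambda_trace: TimeSeriesTrace    # 1/s, Ca-driven Hill rate (no Triton step)
    pool_trace: TimeSeriesTrace      # photons remaining (Triton included)
    beat_times_atrium: np.ndarray
    beat_times_ventricle: np.ndarray
    config: SimConfig

    def lambda_effective(self) -> np.ndarray:
        """Consumption rate actually applied to the pool (Triton step included)."""
        lam = self.lambda_trace.values.copy()
        tt = self.config.triton_time
        if tt is not None:
            lam[self.lambda_trace.times >= tt] = TRITON_RELEASE_RATE
        return lam


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the maximum of the raw difference-of-exponentials kernel."""
    return tau_rise * math.log1p(tau_decay / tau_rise)


def beat_kernel(u: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak transient shape ``(1 - exp(-u/tau_r)) * exp(-u/tau_d)`` for u >= 0."""
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    u = np.asarray(u, dtype=float)
    g = np.zeros_like(u)
    pos = u >= 0
    up = u[pos]
    g[pos] = (1.0 - np.exp(-up / tau_rise)) * np.exp(-up / tau_decay)
    upk = kernel_peak_time(tau_rise, tau_decay)
    peak = (1.0 - math.exp(-upk / tau_rise)) * math.exp(-upk / tau_decay)
    return g / peak


def _beat_times(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    period = 60.0 / config.atrial_rate
    n_atrial = int(math.floor(config.duration / period - 1e-12)) + 1
    atrial = np.arange(n_atrial) * period
    ventricular = atrial[:: config.conduction_ratio]
    return atrial, ventricular


def _kernel_sum(t: np.ndarray, beat_times: np.ndarray, tau_rise: float,
                tau_decay: float) -> np.ndarray:
    """Superposition of unit-peak kernels at the given beat times."""
    out = np.zeros_like(t, dtype=float)
    # kernels are negligible after ~12 decay constants; restrict the window
    horizon = 12.0 * tau_decay + 5.0 * tau_rise
    for tb in beat_times:
        i0 = np.searchsorted(t, tb)
        i1 = np.searchsorted(t, tb + horizon)
        out[i0:i1] += beat_kernel(t[i0:i1] - tb, tau_rise, tau_decay)
    return out


def simulate_ca_trace(config: SimConfig) -> GroundTruth:
    """Generate the ground-truth Ca²⁺, consumption-rate, and pool traces.

    The Ca²⁺ trace is ``ca_diastolic + ca_amplitude * sum_k g(t - t_k)`` on a
    fine grid aligned with the camera frames; ventricular beat times are the
    atrial grid thinned by the conduction ratio; a drug event scales the
    transient amplitude (and optionally the diastolic level) along an
    exponential ramp.
    """
    atrial, ventricular = _beat_times(config)
    n_fine = config.n_frames * config.substeps_per_frame + 1
    t = np.arange(n_fine) * config.fine_dt

    kern = _kernel_sum(t, ventricular, config.tau_rise, config.tau_decay)
    amp = np.full_like(t, config.ca_amplitude)
    dia = np.full_like(t, config.ca_diastolic)
    if config.drug_event is not None:
        m = config.drug_event.multiplier(t)
        amp = amp * m
        if config.drug_event.scale_diastolic:
            dia = dia * m
    ca = dia + amp * kern

    lam = config.lambda_max * ca ** config.hill_n / (config.kd ** config.hill_n + ca ** config.hill_n)

    lam_eff = lam.copy()
    if config.triton_time is not None:
        lam_eff[t >= config.triton_time] = TRITON_RELEASE_RATE
    # A(t) = pool0 * exp(-integral of lambda); left-endpoint rule on the fine grid
    decrement = np.concatenate([[0.0], np.cumsum(lam_eff[:-1] * config.fine_dt)])
    pool = config.pool0 * np.exp(-decrement)

    rate = 1.0 / config.fine_dt
    return GroundTruth(
        ca_trace=TimeSeriesTrace(ca, rate, units="uM"),
        lambda_trace=TimeSeriesTrace(lam, rate, units="per_s"),
        pool_trace=TimeSeriesTrace(pool, rate, units="photons"),
        beat_times_atrium=atrial,
        beat_times_ventricle=ventricular,
        config=config,
    )


@dataclass
class LuminescenceSim:
    """A synthetic photon-count recording plus its bookkeeping."""

    trace: TimeSeriesTrace           # observed counts per frame (RLU)
    expected: np.ndarray             # noise-free expected counts per frame
    signal_expected: np.ndarray      # expected counts net of background
    pool_at_frames: np.ndarray       # pool at frame boundaries, length n_frames+1
    triton_index: int | None


def simulate_luminescence(gt: GroundTruth, config: SimConfig | None = None,
                          rng: np.random.Generator | None = None,
                          noise: bool = True) -> LuminescenceSim:
    """Turn a ground-truth pool trajectory into per-frame detected counts.

    Expected detected counts in frame k are
    ``detect_eff * (A(t_k) - A(t_{k+1})) + bg_rate / acq_freq``; observed
    counts are Poisson with that mean, plus optional Gaussian read noise,
    clamped at zero. With ``noise=False`` the expected counts are returned
    verbatim (useful for validating estimators against the exact budget).
    """
    config = config or gt.config
    if config.detect_eff * config.pool0 < 100:
        raise ValueError(
            "detect_eff * pool0 < 100: the recording would be essentially empty"
        )
    sub = config.substeps_per_frame
    pool = gt.pool_trace.values
    if pool.size != config.n_frames * sub + 1:
        raise ValueError("ground-truth fine grid does not cover the configured frames")
    edges = pool[::sub]
    signal = config.detect_eff * (edges[:-1] - edges[1:])
    expected = signal + config.bg_rate / config.acq_freq

    if noise:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        observed = rng.poisson(expected).astype(float)
        if config.read_noise_sd > 0:
            observed = observed + rng.normal(0.0, config.read_noise_sd, observed.size)
        observed = np.maximum(observed, 0.0)
    else:
        observed = expected.copy()

    triton_index = None
    if config.triton_time is not None:
        triton_index = int(config.triton_time * config.acq_freq)

    return LuminescenceSim(
        trace=TimeSeriesTrace(observed, config.acq_freq, units="RLU"),
        expected=expected,
        signal_expected=signal,
        pool_at_frames=edges,
        triton_index=triton_index,
    )


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _ellipse_polygon(center: tuple[float, float], semi_axes: tuple[float, float],
                     n_vertices: int = 32) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r0, c0 = center
    a, b = semi_axes
    return np.column_stack([r0 + a * np.sin(th), c0 + b * np.cos(th)])


def default_rois(shape: tuple[int, int] = (128, 128)) -> list[RoiSpec]:
    """Ventricle + atrium ellipses and six equal-size background squares."""
    rows, cols = shape
    sr, sc = rows / 128.0, cols / 128.0
    vent = RoiSpec("ventricle",
                   _ellipse_polygon((64 * sr, 48 * sc), (20 * sr, 14 * sc)), "sum")
    atr = RoiSpec("atrium",
                  _ellipse_polygon((64 * sr, 92 * sc), (13 * sr, 10 * sc)), "sum")
    # background squares matched in pixel area to the ventricle ROI
    vent_area = int(vent.mask(shape).sum())
    half = max(2, int(round(math.sqrt(vent_area) / 2)))
    centers = [(14, 14), (14, 64), (14, 114), (114, 14), (114, 64), (114, 114)]
    bgs = []
    for i, (r, c) in enumerate(centers, start=1):
        r, c = r * sr, c * sc
        poly = np.array([[r - half, c - half], [r - half, c + half],
                         [r + half, c + half], [r + half, c - half]])
        poly[:, 0] = np.clip(poly[:, 0], 0, rows - 1)
        poly[:, 1] = np.clip(poly[:, 1], 0, cols - 1)
        bgs.append(RoiSpec(f"background_{i}", poly, "mean"))
    return [vent, atr] + bgs


def render_image_stack(chamber_counts: Mapping[str, np.ndarray], config: SimConfig,
                       *, shape: tuple[int, int] = (128, 128),
                       beat_times: np.ndarray | None = None,
                       pulsation_fs: float = 0.0,
                       out_tiff: str | Path | None = None,
                       out_roi: str | Path | None = None,
                       rng: np.random.Generator | None = None) -> tuple[np.ndarray, list[RoiSpec]]:
    """Render per-chamber photon counts into a 16-bit image stack.

    Each chamber's expected per-frame counts are spread uniformly over its
    ellipse mask and drawn Poisson per pixel; a uniform per-pixel background
    (``bg_rate`` per ROI-sized area per second) is added everywhere. With
    ``pulsation_fs > 0`` the ventricle ellipse shrinks by that fractional
    shortening at each systole, synchronised to ``beat_times``.

    Returns the stack (uint16) and the ROI set used; optionally writes a
    multi-page TIFF and the ROI JSON.
    """
    rois = default_rois(shape)
    roi_by_label = {r.label: r for r in rois}
    n_frames = None
    for label, counts in chamber_counts.items():
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError(f"negative frame counts for chamber {label!r}")
        n_frames = counts.size if n_frames is None else n_frames
        if counts.size != n_frames:
            raise ValueError("chamber traces differ in length")
    if n_frames is None:
        raise ValueError("no chamber traces supplied")

    rng = rng if rng is not None else np.random.default_rng([config.seed, 0xC0FFEE])
    vent_mask0 = roi_by_label["ventricle"].mask(shape)
    bg_per_pixel = (config.bg_rate / config.acq_freq) / max(int(vent_mask0.sum()), 1)

    frame_times = np.arange(n_frames) / config.acq_freq
    if pulsation_fs > 0 and beat_times is not None and len(beat_times):
        kern = _kernel_sum(frame_times, np.asarray(beat_times), config.tau_rise, config.tau_decay)
        kern = np.clip(kern, 0.0, 1.0)
    else:
        kern = np.zeros(n_frames)

    stack = rng.poisson(bg_per_pixel, size=(n_frames, *shape)).astype(np.int64)

    # static chamber masks; ventricle recomputed per frame only when pulsating
    masks: dict[str, np.ndarray] = {}
    for label in chamber_counts:
        if label not in roi_by_label:
            raise ValueError(f"no ROI geometry for chamber {label!r}")
        masks[label] = roi_by_label[label].mask(shape)

    vent_center = (shape[0] / 128.0 * 64, shape[1] / 128.0 * 48)
    vent_axes = (shape[0] / 128.0 * 20, shape[1] / 128.0 * 14)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")

    for k in range(n_frames):
        for label, counts in chamber_counts.items():
            if label == "ventricle" and kern[k] > 0:
                scale = 1.0 - pulsation_fs * kern[k]
                a, b = vent_axes[0] * scale, vent_axes[1] * scale
                mask = ((rr - vent_center[0]) / a) ** 2 + ((cc - vent_center[1]) / b) ** 2 <= 1.0
            else:
                mask = masks[label]
            npix = int(mask.sum())
            if npix == 0:
                raise ValueError(f"empty mask for chamber {label!r}")
            mean = np.asarray(chamber_counts[label])[k] / npix
            stack[k][mask] += rng.poisson(mean, size=npix)

    n_sat = int((stack > 65535).sum())
    if n_sat:
        warnings.warn(f"{n_sat} saturated pixels clamped at 65535", stacklevel=2)
    stack16 = np.clip(stack, 0, 65535).astype(np.uint16)

    if out_tiff is not None:
        import tifffile

        tifffile.imwrite(out_tiff, stack16, photometric="minisblack")
    if out_roi is not None:
        write_roi_json(rois, out_roi)
    return stack16, rois


# ---------------------------------------------------------------------------
# ventricle geometry
# ---------------------------------------------------------------------------

@dataclass
class GeometryTrace:
    """Per-frame ventricle diameters and cavity area, with phase labels."""

    times: np.ndarray
    major_um: np.ndarray
    minor_um: np.ndarray
    area_um2: np.ndarray
    phase: np.ndarray  # '' / 'ED' / 'ES'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.times.size),
            "time_s": self.times,
            "major_um": self.major_um,
            "minor_um": self.minor_um,
            "area_um2": self.area_um2,
            "phase": self.phase,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GeometryTrace":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(
            times=df["time_s"].to_numpy(float),
            major_um=df["major_um"].to_numpy(float),
            minor_um=df["minor_um"].to_numpy(float),
            area_um2=df["area_um2"].to_numpy(float),
            phase=df["phase"].astype(str).to_numpy(),
        )


def simulate_geometry(config: SimConfig, fs_major: float, fs_minor: float,
                      dd_major: float, dd_minor: float) -> GeometryTrace:
    """Ventricle diameter series oscillating between diastole and systole.

    Diameters follow ``D(t) = D_d * (1 - FS * K(t))`` where K is the unit-peak
    beat kernel at the ventricular beat times; the cavity area is the ellipse
    area ``(pi/4) * major * minor``. Frames nearest each kernel extremum are
    labelled end-diastole / end-systole and evaluated exactly at the extremum,
    the way an operator picks the most contracted / most relaxed frame.
    """
    for name, v in ("fs_major", fs_major), ("fs_minor", fs_minor):
        if not (0 < v < 1):
            raise ValueError(f"{name} must lie in (0, 1)")
    if dd_major <= 0 or dd_minor <= 0:
        raise ValueError("diastolic diameters must be positive")

    _, ventricular = _beat_times(config)
    n = config.n_frames
    t = np.arange(n) / config.acq_freq
    kern = np.clip(_kernel_sum(t, ventricular, config.tau_rise, config.tau_decay), 0.0, 1.0)

    phase = np.full(n, "", dtype=object)
    u_pk = kernel_peak_time(config.tau_rise, config.tau_decay)
    for tb in ventricular:
        i_es = int(round((tb + u_pk) * config.acq_freq))
        i_ed = int(round(tb * config.acq_freq)) - 1
        if 0 <= i_es < n:
            kern[i_es] = 1.0
            phase[i_es] = "ES"
        if 0 <= i_ed < n and phase[i_ed] == "":
            kern[i_ed] = 0.0
            phase[i_ed] = "ED"
    if not (phase == "ED").any():  # recording starts mid-beat: label frame 0
        kern[0] = 0.0
        phase[0] = "ED"

    major = dd_major * (1.0 - fs_major * kern)
    minor = dd_minor * (1.0 - fs_minor * kern)
    area = (np.pi / 4.0) * major * minor
    return GeometryTrace(t, major, minor, area, phase.astype(str))


def simulate_gcamp(config: SimConfig, f0: float, bleach_tau: float = math.inf,
                   amp: float | None = None, noise_sd: float = 0.0,
                   sampling_rate: float = 200.0,
                   rng: np.random.Generator | None = None) -> TimeSeriesTrace:
    """Fluorescent (GCaMP-style) counterpart of the Ca²⁺ trace.

    ``F(t) = (f0 + amp * sum_k g(t - t_k)) * exp(-t / bleach_tau) + noise``,
    sampled at 200 Hz by default. Unlike aequorin, fluorescence is not
    consumed, but it photobleaches.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    amp = f0 * 0.5 if amp is None else amp
    _, ventricular = _beat_times(config)
    n = int(round(config.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    f = (f0 + amp * _kernel_sum(t, ventricular, config.tau_rise, config.tau_decay))
    if math.isfinite(bleach_tau):
        f = f * np.exp(-t / bleach_tau)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        f = f + rng.normal(0.0, noise_sd, n)
    return TimeSeriesTrace(f, sampling_rate, units="au")


def ground_truth_to_csv(gt: GroundTruth, lum: LuminescenceSim, path: str | Path) -> None:
    """Write frame-level ground truth: time, Ca²⁺, lambda, pool, counts."""
    sub = gt.config.substeps_per_frame
    t = gt.ca_trace.times[::sub][:-1]
    pd.DataFrame({
        "time_s": t,
        "ca_uM": gt.ca_trace.values[::sub][:-1],
        "lambda_per_s": gt.lambda_trace.values[::sub][:-1],
        "pool": lum.pool_at_frames[:-1],
        "counts": lum.trace.values,
    }).to_csv(path, index=False)
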