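# cardiolum

Quantitative analysis of **aequorin cardioluminescence** in the beating heart
of larval zebrafish, together with a seeded forward simulator that makes
every analysis stage verifiable against known ground truth.

## The problem

Aequorin is a Ca²⁺-activated photoprotein: each molecule emits one photon
when Ca²⁺ binds (three ions are required, giving a steep, roughly cubic
Ca²⁺-response) and is then irreversibly consumed. Raw luminescence from a
beating heart therefore has no direct meaning in terms of Ca²⁺ — the same
Ca²⁺ level emits less light late in a recording, simply because less
functional aequorin remains. The classic remedy is the
**consumption-corrected ratio**

```
L / Lmax
```

where `L` is the instantaneous luminescence rate (counts/s) and `Lmax` the
emittable counts still available. `Lmax` is anchored by lysing the
preparation with Triton X-100 at the end of the recording, which releases
the residual photon budget:

```
Ltotal       = Σ background-subtracted counts over the whole experiment
Lconsumed[t] = Σ counts up to and including frame t
Lmax[t]      = Ltotal − Lconsumed[t−1]
```

`L/Lmax` is monotone in free Ca²⁺, independent of the amount of functional
aequorin, and independent of the image acquisition frequency — unlike the
signal-to-noise ratio, which falls as frames get shorter. The package also
quantifies beat-to-beat Ca²⁺ transient kinetics (peak amplitude, 10–90% rise,
90–10% decay), heart rate and atrioventricular conduction ratio, ΔF/F₀
normalisation for fluorescent (GCaMP-type) biosensors, and ventricular
hemodynamics from 2-D geometry via the ellipsoid-of-revolution model

```
V = (π/6)·D_major·D_minor²,   SV = EDV − ESV,   EF = SV/EDV,   CO = SV·HR
FS = (D_dia − D_sys)/D_dia,   FAC = (A_dia − A_sys)/A_dia
```

It is intended for experimentalists analysing luminescence/fluorescence
image stacks or pre-extracted ROI traces of the larval heart, and for method
development where a fully known ground truth is needed.

## Modules

| module | contents |
|---|---|
| `cardiolum.simulate` | beat clock with N:1 conduction block, Ca²⁺ transients, Hill-saturating aequorin consumption, Poisson photon detection, 16-bit image rendering, ventricle geometry, GCaMP traces |
| `cardiolum.calibration` | ROI extraction (pixel-centre polygon test), per-frame SNR against a six-ROI background panel, the `L/Lmax` budget |
| `cardiolum.kinetics` | EWMA smoothing, ΔF/F₀, beat detection and transient kinetics, heart rate, AV ratio |
| `cardiolum.hemodynamics` | FS/FAC/volumes/SV/CO/EF per larva, two-group fold-change reports with Student's t |
| `cardiolum.cli` | `cardiolum simulate / analyze-lum / analyze-fluo / hemodynamics / report` |

## Worked example

Simulate a 30-s ventricular recording at 9 Hz (180 bpm, Triton lysis at
25 s), calibrate the budget, and extract beat metrics:

```python
import numpy as np
from cardiolum import (SimConfig, simulate_ca_trace, simulate_luminescence,
                       calibrate, detect_beats, summarize_ratio, TimeSeriesTrace)

cfg = SimConfig(duration=30.0, acq_freq=9.0, atrial_rate=180.0,
                ca_amplitude=2.0, kd=2.0, pool0=2e6, triton_time=25.0, seed=42)
gt = simulate_ca_trace(cfg)
lum = simulate_luminescence(gt, cfg)
cal = calibrate(lum.trace, cfg.bg_rate / cfg.acq_freq,
                triton_index=lum.triton_index)
ratio = TimeSeriesTrace(cal.ratio, cfg.acq_freq, units="per_s")
beats = detect_beats(ratio.slice_time(0.0, 20.0))
```

This prints (values from the seeded run above):

```
total counts (Ltotal):   1999619
heart rate:              180.0 bpm
mean L/Lmax (0-20 s):    0.2664 1/s
systolic / diastolic:    0.5083 / 0.0476 1/s
transient rise / decay:  90 / 180 ms
```

`Ltotal` is within 0.02% of the simulated photon budget (2×10⁶; the
difference is Poisson noise and background clipping), the heart rate matches
the 180 bpm beat clock, and the systolic/diastolic `L/Lmax` levels bracket
the mean. The same workflow runs from the shell:

```bash
cardiolum simulate --config sim.yaml --out-dir run1
cardiolum analyze-lum run1/stack.tiff --rois run1/rois.json --rate 9 \
    --triton-time 25 --out-dir run1/analysis
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, and known limitations.
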