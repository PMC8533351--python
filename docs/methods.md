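# Methods

## Forward model of aequorin cardioluminescence

The simulator produces a recording whose latent state is fully known, so
every downstream estimator can be validated quantitatively.

**Beat clock.** Atrial beats lie on a regular grid at `atrial_rate` (bpm).
Ventricular beats are that grid thinned by the conduction rule: every beat in
normal rhythm, every Nth beat for an N:1 atrioventricular block (a 2:1 block
halves the ventricular rate, giving an AV rate ratio of 0.5).

**Ca²⁺ transient.** Free Ca²⁺ is

```
Ca(t) = ca_diastolic + ca_amplitude · Σ_k g(t − t_k)
g(u)  = (1 − e^(−u/τ_rise)) · e^(−u/τ_decay),  u ≥ 0, rescaled to unit peak
```

on a fine grid with step `1/(20·acq_freq)`, capped at 1 ms, so the pool
integration error stays below 0.1%. The difference-of-exponentials kernel is
the standard minimal description of a cardiac Ca²⁺ transient (fast upstroke,
slower mono-exponential relaxation); its peak lies at
`u* = τ_rise·ln(1 + τ_decay/τ_rise)`. A drug event multiplies the transient
amplitude (optionally the diastolic level) by a factor ramping exponentially
from 1 to `ca_scale` with time constant `ramp_tau`, emulating diffusion-
limited drug action on an embedded larva.

**Consumption law.** Aequorin is consumed at the fractional rate

```
λ(t) = λ_max · Ca(t)^n / (Kd^n + Ca(t)^n),  n = 3 by default
```

a Hill saturation reflecting the three Ca²⁺ ions that trigger the
photoprotein; `Kd` is the half-saturating Ca²⁺ of the consumption rate. The
remaining pool decays as `A' = −λA`, integrated by the exact exponential
step `A(t+δ) = A(t)·e^(−λ(t)δ)` on the fine grid. Detergent (Triton) lysis
replaces λ with a release constant of 2 s⁻¹ from `triton_time` onward — fast
enough that a ≥5 s tail empties the pool to <10⁻⁴ of its value, while still
producing the recognisable release transient.

**Detection.** Expected detected counts in camera frame k are
`detect_eff·(A(t_k) − A(t_{k+1})) + bg_rate/acq_freq`; observed counts are
Poisson with that mean plus optional Gaussian read noise, clamped at zero.
Camera EM gain and binning are not modelled separately; they are absorbed
into `detect_eff` and `read_noise_sd`. Image rendering spreads each
chamber's counts uniformly over its ellipse mask with per-pixel Poisson
draws, plus a uniform per-pixel background normalised so that a
ventricle-sized area accrues `bg_rate` counts/s; 16-bit output saturates at
65535 with a warning.

**Defaults.** No published absolute Ca²⁺ concentrations or aequorin pool
sizes exist for the larval heart, so the defaults are free parameters chosen
once at physiologically plausible values and documented here: diastolic
Ca²⁺ 0.1 µM, transient amplitude 1–2 µM, τ_rise 30 ms, τ_decay 150 ms
(≈180 bpm resting rhythm at 26–28 °C), Kd 2–5 µM, λ_max ≤ 1 s⁻¹, pool
10⁵–10⁷ photons, background 50 counts/s per ROI. Acquisition frequencies
follow the instrument's discrete set (1, 2, 9, 12, 17, 25 Hz), though any
positive rate is accepted.

## What the simulator does and does not emulate

It reproduces beat-periodic transients driving stochastic photon emission
from a depleting pool, conduction block, drug ramps, camera background and
read noise, and chamber geometry with systolic pulsation. It does **not**
model optics (no point-spread function), motion artifacts from overlapping
chambers, EM-CCD gain-register statistics, spatial Ca²⁺ gradients or
microdomains, or reconstitution chemistry. Tests passing on synthetic data
therefore validate the estimators' arithmetic and statistical behaviour, not
robustness to optical crosstalk or motion — on real recordings those effects
add systematic error the suite cannot see.

## Luminescence budget (L/Lmax)

Background is subtracted before any budget sum (negative residuals clipped
at 0, since photon counts cannot be negative; a flag disables subtraction).
With `raw[t]` the clipped counts of frame t:

```
Ltotal       = Σ raw          (Triton frames included)
Lconsumed[t] = Σ_{0..t} raw   (inclusive of frame t)
Lmax[t]      = Ltotal − Lconsumed[t−1]
L[t]         = raw[t] · acq_freq
ratio[t]     = L[t] / Lmax[t]
```

The off-by-one convention makes `Lmax[t]` the pool available *entering*
frame t, so a fully consumed pool ends with `ratio·Δ = 1` rather than 0/0,
and the budget identity `Lmax[t] + Lconsumed[t−1] = Ltotal` holds at every
frame. `ratio` is reported in s⁻¹ and masked (NaN) where the remaining pool
falls below `max(0.1%·Ltotal, 10 counts)`, because SNR collapses near pool
exhaustion; the floor is overridable for idealised data. Without a Triton
segment `Lmax` underestimates the true remaining pool and a warning is
issued.

On noise-free data the per-frame identity
`ratio·Δ = 1 − exp(−∫_frame λ dt)` holds, so
`λ̂ = −ln(1 − ratio/f)·f` recovers the frame-averaged consumption rate; this
is how the simulator closes the loop on the estimator.

Two regimes matter in practice. At high rates (9–25 Hz) individual
transients are resolved and per-beat kinetics are meaningful; at 1–2 Hz each
frame integrates several beats and the mean ratio reports time-averaged
Ca²⁺. The mean ratio is invariant to acquisition frequency only while the
per-frame consumed fraction is small (`λΔ ≲ 0.1`): at larger fractions the
concavity of `1 − e^(−λΔ)` compresses high-λ frames. Real recordings sit
deep inside the small-fraction regime; the frequency-invariance tests use a
consumption scale (λ_max = 0.25 s⁻¹ with ~0.05 s⁻¹ time-average) chosen to
match it.

## SNR

`SNR[t] = (signal[t] − B̄[t]) / SD[t]`, where B̄ and SD are the mean and
sample standard deviation (n−1) across the panel of six background-ROI
means *at that frame* — a per-frame statistic, not a temporal one. All SNR
inputs are mean-reduced so differently shaped ROIs remain comparable. At a
fixed photon budget the per-frame signal scales as 1/f while the SD of
background means scales as 1/√f, so mean SNR falls as 1/√f with acquisition
frequency — the trade-off against the frequency-invariant ratio.

## Transient kinetics

ΔF/F₀ uses `F₀ = min` of the (optionally EWMA-smoothed) recording. The EWMA
factor 0.7 is taken as the weight of the *current* sample
(`s[t] = 0.7·x[t] + 0.3·s[t−1]`, DC gain 1); the opposite convention is
available by flag since the definition is ambiguous in common usage.

Beat detection: peaks are local maxima with prominence above 30% of the
5–95 percentile span; the minimum inter-peak distance is 30% of the beat
period estimated from the autocorrelation (single-pass fallback with a
warning on aperiodic traces). Peak times/values are refined by a three-point
parabola — exact when the true peak falls on the grid, and removing most of
the 1/f quantisation otherwise. The per-beat baseline is the *last*
occurrence of the minimum between peaks (just before the upstroke), averaged
over a ~10 ms window behind it at high sampling rates to suppress the
downward order-statistic bias of a noisy minimum. Rise (10→90%) and decay
(90→10%) times are linearly interpolated crossings of levels set between
baseline and peak; unresolved crossings give NaN for that beat rather than a
biased number.

Amplitude convention: peak − preceding minimum for luminescence-ratio traces
(no bleaching trend, so a local baseline is appropriate); peak − global
minimum for ΔF/F₀ traces, where F₀ anchors every amplitude.

Heart rate: a Theil–Sen fit (median of pairwise slopes) of refined peak
times against an integer beat index. The simpler median inter-peak interval
is robust to a missed beat but inherits the grid's phase-dependent peak-time
error — on a noise-free 180 bpm train sampled at 25 Hz it reads ~178.8 bpm —
whereas the pairwise-slope median averages that error out (±0.01 bpm) while
missed beats merely advance the index by more than one. The plain
beat-count/duration rate is reported alongside. The systolic/diastolic
levels are means of per-beat extrema (not envelope percentiles).

## Hemodynamics

Diameters and areas are averaged over the first three valid end-diastole /
end-systole pairs *before* forming any ratio or volume (pairs whose systole
exceeds diastole are flagged and excluded). Volumes use the
ellipsoid-of-revolution formula with 1 pL = 10⁶ µm³; CO is reported in
nL/min (`SV(pL)·HR/1000`); EF = SV/EDV. Group comparisons report the fold
change of group means and a two-tailed Student's t — paired for
within-larva designs, pooled-variance unpaired otherwise; from published
summary statistics only the unpaired t is computable (a paired t needs the
within-subject correlation), while the fold change of means is defined
either way. Printed-table matching uses round-half-away-from-zero at 2
decimal places. A packaged CSV transcribes the published propranolol and
terfenadine group statistics so the fold-change report is reproducible
without the original recordings; a handful of published fold-change and EF
cells differ from the ratio of the printed group means at 2 d.p. (per-larva
averaging in the source), and only the self-consistent cells are used for
exact matching.

## Numerical and design notes

- Pixel membership of ROI polygons uses the pixel-centre inclusion test,
  0-based row-major coordinates; sums for luminescence budgets, means for
  SNR inputs.
- Fine-grid/frame alignment is exact by construction (integer substeps per
  frame), so frame edges never interpolate the pool.
- `simulate_luminescence` refuses configurations with an expected total
  detected budget below 100 counts (the recording would be empty).
- Geometry frames labelled end-diastole/end-systole are evaluated exactly at
  the kernel extrema, the way an operator picks the most relaxed/contracted
  frame; this makes the FS/FAC round trip exact to machine precision.
- All randomness flows from `SimConfig.seed` through
  `numpy.random.default_rng`; identical config + seed gives bit-identical
  outputs.
- Problem sizes in the test suite and acceptance script (4–60 s recordings,
  10⁵–5×10⁶-photon pools, 100-seed ensembles) were chosen as the smallest
  sizes at which Monte-Carlo variability is clearly below the tolerances
  being checked.

## Known limitations

- No absolute Ca²⁺ calibration: L/Lmax is reported in s⁻¹ and compared as
  ratios/fold changes only; converting to molar Ca²⁺ would require the
  photoprotein's rate-vs-pCa calibration for the exact substrate analogue
  used.
- The budget assumes all residual counts are captured (Triton segment
  recorded to exhaustion); truncated recordings bias Lmax low.
- Beat detection assumes a dominantly periodic trace; highly irregular
  rhythms fall back to single-pass detection and deserve manual review.
- The atrium is often too dim for luminescence beat detection in practice;
  the AV ratio is therefore optional in the hemodynamics record.
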