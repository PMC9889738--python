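# Methods

This note records the models behind the simulator, the parameters that
matter, the numerical conventions, and what the synthetic conditions do and
do not say about real tissue.

## Forward optics

The SLM is conjugated to the rear pupil of the focusing objective, so the
focal field is the centred 2-D DFT of the pupil field. For even grid size
`n` the transform is `F[u,v] = (1/n) Σ E[x,y] exp(−2πj((u−c)(x−c)+(v−c)(y−c))/n)`
with `c = n//2`; it conserves energy exactly (Parseval). The focal pixel
pitch is fixed by the calibration identity

```
pitch = λ · d / (2 · NA · n)    [μm]
```

(`d` = pupil diameter in pixels), which places the ideal Airy FWHM at
`0.514·λ/NA` — 3.03 μm at λ = 0.589 μm, NA = 0.1. Defaults: `n = 256`,
`d = 128` (≥2× oversampling of the speckle grain), pitch = 1.4725 μm.
Experimental systems typically underfill the pupil and report slightly
larger spots (~3.6 μm in comparable hardware); we model the ideal filled
pupil and assert only the < 4 μm envelope.

Segments tile the square bounding the pupil disk with cell size `d // N`
pixels; a segment is active iff its cell centre lies within `N/2` cells of
the grid centre (inscribed circle — the area covered by the incident beam).
For N = 32 this gives exactly M = 812 ≈ (π/4)·N² active segments. Pupil
pixels outside active cells (and outside the disk) contribute static light.
An enlarged stimulation focus is available two ways: `pupil_scale < 1`
(underfilled pupil, FWHM × 1/scale) or a larger/shaped detection aperture.

Because the focal field is affine in the per-segment phasors
`exp(j b_i)`, per-segment responses `E_i` at the detection pixels are
precomputed once (direct DFT kernel for screens, matrix columns for
transmission matrices) and each of the thousands of dither patterns costs a
small real matrix product. The linearity identity is exact to machine
precision and is tested against direct propagation.

## Scattering media

Two interchangeable forms, chosen because they are the two standard models
with known statistics:

* **Transmission matrix** — independent circular-Gaussian entries,
  `E|T|² = 1`. Gives fully developed speckle (exponential intensities,
  contrast 1) and exact enhancement theory to test against.
* **Phase screen** — `exp(j·g)` on the pupil grid; `g` is a Gaussian random
  field built by Gaussian-filtering white noise, normalised to RMS
  `strength` (radians), with autocorrelation half-width
  `correlation_length` (pixels). Defaults `strength = 2π`,
  `correlation_length = 2` make a fully scrambling screen; milder settings
  stand in for thinner tissue. No quantitative mapping from μm of tissue to
  screen parameters is attempted — none is available.

**Decorrelation.** Living media change over seconds; a correction decays
with the field autocorrelation. Matrix form: complex Ornstein–Uhlenbeck
interpolation toward fresh draws, `T' = T√(1−α) + √α·T_fresh`,
`α = 1 − exp(−2Δt/τ)`, giving `⟨T'T*⟩/⟨|T|²⟩ = exp(−Δt/τ)` exactly. Screen
form: a Brownian phase walk `g' = g + √(2Δt/τ)·w` with `w` a fresh unit-RMS
correlated field — this keeps the screen pure phase and gives exactly
`⟨e^{j(g'−g)}⟩ = e^{−Δt/τ}`. Both updates compose, so evolution can be
applied in chunks (the run loop refreshes every 16 patterns while the clock
advances per pattern; the statistics are unchanged, only the time grid is
coarser). τ is qualitative: focus lifetimes of tens of seconds in living
tissue suggest τ in the 10–60 s range, but no calibrated value exists.

## The correction algorithm

Planning: active segments are split into two near-equal halves
(checkerboard parity by default, seeded random split optional). With
`H = max(H₁, H₂)`, each half's record has `T = 4H` samples and its segments
get the distinct integer DFT bins `[T/4, T/4 + H) ⊂ [T/4, T/2)` — the
lowest modulation frequency is half the highest, so no segment sits in the
sparsely sampled low bins. Budget: `2T = 4M` patterns (3248 for M = 812,
under the 3500 envelope for a 1024-segment device).

Dithering: segment *i* toggles base ↔ base+π following
`s_i(t) = sgn(cos(2π k_i t/T))` (ties → +1; at t = 0 all segments sit at
base). Demodulation computes `c_i = Σ_t I(t)·e^{−2πj k_i t/T}` and removes
the waveform's own reference phase `ψ_i = arg Σ_t s_i(t) e^{−2πj k_i t/T}`
(computed from the actual waveform, so any convention change is absorbed).
For a binary dither the cross term with the reference makes
`Re(c_i e^{−jψ_i}) ∝ cos(φ_i)`: the extracted phase is 0 or π up to noise,
and binarization yields the decision bit. Segments with no signal stay at
base. A continuous phase-ramp dither mode (`mode="ramp"`) recovers the full
medium phase `arg(E_i E_ref*)` before binarization; it is used for
validation only (a binary device cannot display it).

Procedure: first half dithered against the static second half; decisions
applied; second half dithered against the corrected first half; the
combined mask is the result (one iteration by default — the scheme's speed
is the point; an `iterations` parameter allows refinement, and re-running
with `initial_mask` set to a previous result implements the continuous
working mode on a drifting medium).

### Known imperfections, quantified

The square wave carries odd harmonics, and with bins packed into
`[T/4, T/2)` two effects land back inside the band:

* aliased third harmonics of bins ≥ 5T/12, at 1/3 amplitude, on top of
  exactly one other segment's bin;
* pairwise intermodulation products `s_i·s_j` whose sum frequencies alias
  onto in-band bins (order √H pairs per bin, incoherently summed).

Both exist in the hardware this emulates and are accepted, not filtered.
Their net cost is bounded in the test suite by comparison with a greedy
coordinate-flip oracle that sees the exact responses: the one-iteration
correction reaches ≥ 70% of the greedy intensity at M = 812 (measured
0.77–0.83 across seeds), and mean corrected PBR grows linearly in M with
slope ≈ 0.27 (binary-phase ideal 1/π ≈ 0.318).

A second, purely statistical effect dominates the run-to-run spread: the
first half's reference is the undithered second half, whose field at a
single-pixel target is one speckle amplitude — Rayleigh distributed. The
demodulation SNR scales with that amplitude, so a weak draw (no rare event:
P ≈ 10–15% for a substantially weakened reference) corrupts part of the
first-half decisions; the second half, referenced to the corrected first
half, usually recovers most of the loss. Across 60 media the corrected PBR
at M = 812 spans roughly 110–260 with ensemble mean ≈ 200. A physical
system integrating several speckle modes on its detector (a multimode-fibre
face rather than a single camera pixel) concentrates the reference norm and
softens this tail; the simulator exposes the aperture as a parameter but
the headline metrics use the single-pixel pinhole.

## Focus metrics

Pipeline order is fixed: dark-offset subtraction (camera offset 200 counts,
clamped at zero; simulator renders are offset-free and skip it), tenfold
bicubic interpolation, then metrics. Interpolation is cubic-convolution
resampling (bounded overshoot, the `interp2`/ImageJ semantics), pixel-centre
aligned so positions map back exactly; it is not a cubic spline. PBR = peak
over a disk of radius 3× the nominal FWHM around the target ÷ mean over the
rest of the frame, making the background insensitive to the focus itself.
FWHM is measured on the horizontal and vertical section profiles through
the peak (half level referenced to the background mean, linear
interpolation at the crossings); the headline value is the mean of the two.
Focus position is the interpolated peak; position error is its Euclidean
distance to the target. Decorrelation traces sample the detected intensity
of a frozen mask at 10 frames/s through an evolving medium, normalised to
t = 0.

## Calcium readout

The optogenetics readout is emulated, not claimed: disk neurons with
baseline fluorescence F₀ = 1000 counts respond to the light delivered to
their soma through a sigmoid `A(I) = A_max / (1 + e^{−(I−I_th)/s})` — an
explicit modelling choice that reproduces threshold behaviour (speckle
below threshold, focus above; defaults `A_max = 0.8`, sized so strong/weak
responses sit in the tens-of-percent ΔF/F regime). Each 200 ms stimulus
(5 s period, 9 stimuli, 10 frames/s, 3 s pre-stimulus baseline) adds a
transient `(1 − e^{−t/τ_r})·e^{−t/τ_d}` (τ_r = 0.2 s, τ_d = 1.5 s, slow
indicator kinetics), normalised to unit peak so the generator amplitude is
recoverable. Movies carry Poisson shot noise and the 200-count dark offset.
Analysis mirrors the experimental recipe: circular ROI mean minus blank-ROI
mean, ΔF/F = (F − F₀)/F₀ with a fixed pre-stimulus baseline window (the
sliding-baseline variant of some pipelines is not implemented), and
per-stimulus peak responses with mean ± SE. Round-trip recovery of the
generator amplitude is within 10% at default noise.

What passing these tests does **not** show: real neurons are not disks, real
dose–response curves are not a two-parameter sigmoid, expression levels
vary, and no claim about neural circuits follows from the generator
recovering its own parameters. The generator exists to make the
focus-vs-speckle contrast demonstrable and the analysis code testable.

## Problem sizes and numerical choices

* Headline runs: 256² grid, 128-px pupil, N = 32 (M = 812), single-pixel
  aperture, noiseless detector — one correction ≈ 0.5 s, so the acceptance
  suites (10 screens + 5 matrices) complete in seconds.
* Matrix media use 4096 output modes (64² rendered image) — enough
  background for a stable PBR denominator.
* Binarization intervals are half-open ([0, π/2), [π/2, 3π/2), [3π/2, 2π))
  to avoid double assignment at boundaries; ties in the square wave go to +1.
* No-signal convention: |c_i| below 1e−12 of the record's total magnitude
  keeps the segment at its base phase.
* Detector noise (Poisson at a configurable photon budget + Gaussian read
  noise) is off by default; all headline metrics assume noiseless feedback.
* All randomness is seeded; media record their seed, and manifests record
  every seed plus a config hash, so noiseless runs reproduce bit-exactly.

## Limitations

Thin-screen and matrix models ignore multi-slice propagation, polarization
and absorption; τ is not calibrated to any tissue; the enlarged-focus modes
change the envelope but not the per-mode statistics of a real low-NA
system; and the measured 3.6 μm experimental spot size (pupil underfilling)
is represented only by the ideal-pupil ≤ 4 μm envelope.
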