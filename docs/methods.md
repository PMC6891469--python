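# Methods

## Imaging model

The sample is a thin complex transmission function f(x, y) = |f| e^{jφ}. An
LED at position (x, y, −z) relative to the field center illuminates it with
a plane wave of direction sines (−x, −y)/√(x²+y²+z²); the corresponding
sub-aperture of the object spectrum is centered at (sinθx, sinθy)/λ
(cycles/μm — all spatial frequencies in this package are cycles per micron;
factors of 2π exist only inside FFTs). The plane-wave-per-patch
approximation evaluates the wave vector at the center of the imaged patch,
which is accurate for patches small compared to the standoff (here
~110 μm versus 93 mm). The objective is an ideal hard-edged circular pupil
of radius NA/λ: pixels whose center lies strictly inside the cutoff are 1,
all others 0, with no apodization or aberration.

The forward simulation keeps the object on a high-resolution (HR) grid at
pitch p_cam/(M·u) — camera pixel p_cam = 3.45 μm, magnification M = 2,
integer upsampling u — and produces each low-resolution (LR) image by
cropping the LR-sized window of the HR spectrum at the (grid-snapped)
illumination frequency, masking it with the pupil, and inverse-transforming.
Because the pupil-filtered field is band-limited below the LR Nyquist
frequency, this spectral cropping is exact band-limited (coherent) sampling;
area-integrating pixel sampling is deliberately not modeled. The same
windowing, with the same scale convention (a unit-amplitude object gives
unit LR intensity), is used by the reconstruction, so forward and inverse
models are consistent by construction.

Sub-aperture centers snap to the nearest HR frequency-grid pixel
(round(f/dk)); sub-pixel shift refinement is out of scope. The sign
convention — the LED at +x captures the sub-aperture at −fx — is fixed once
and shared by simulator and reconstructor; a global flip would be equally
self-consistent.

## Camera and acquisition model

Per image, in order: ideal intensity × brightness factor c_i ×
exposure_ms × duty_cycle → expected photoelectrons via `photon_budget`
(default 500 e⁻ per unit intensity per ms) → Poisson shot noise → additive
Gaussian read noise → gain → clip to the ADC range → integer codes.
Defaults pair a 10⁵ e⁻ full well with 316 e⁻ RMS read noise, i.e. a 50 dB
dynamic range (20·log₁₀), quantized to 10 bits. The photon budget is chosen
so a unit-intensity bright-field pixel at the 100 ms base exposure sits at
~half full well — bright-field images well exposed, outer dark-field images
read-noise-limited unless their exposure is raised, which is exactly what
the ring-wise exposure schedule does (rings 0–3: 100 ms, 4–8: 150 ms,
9–14: 450 ms, 15: 700 ms; per-ring PWM duty cycles default to 1 and are free
parameters). Saturated pixels (pre-clip value above full scale) are flagged
and excluded from amplitude replacement and from the annealing cost — a
clipped sample carries no radiometric information.

Brightness factors c_i are i.i.d. lognormal with median 1 and log-scale
σ = 0.2 by default, one scalar per acquisition, absorbing LED manufacturing
spread, angular falloff and response nonlinearity into a single
multiplicative error — the error mode the annealing correction targets.

Normalization divides each raw image by gain · photon_budget ·
exposure_ms · duty_cycle, putting the whole stack on one radiometric scale;
on noiseless unit-factor data it reproduces the ideal intensity exactly.

## Reconstruction

Standard alternating projections: initialize the HR spectrum from the
band-limited upsampled square root of the on-axis image (zero phase; stack
mean as fallback); per sub-iteration extract the sub-aperture → replace the
amplitude with √measured keeping the model phase (zero-model pixels get
phase 0) → write the masked transform back, touching only pixels inside the
shifted pupil. Update order is center-out (ascending illumination
frequency, then angle), the usual low-frequency-first choice. The
upsampling factor defaults to the smallest integer whose HR pitch meets
Nyquist for the synthetic aperture NA_obj + NA_ill,radial, grown if needed
until every shifted pupil fits on the grid.

Convergence is tracked as the mean relative L2 difference between measured
and model amplitudes per sweep; iteration stops when its relative change
falls below rel_tol = 10⁻³ or at max_sweeps = 10. These are declared
defaults — the method has no canonical stopping rule — and 10 sweeps is
past the knee of the cost trace on all the synthetic cases here. No
explicit regularization, pupil recovery or LED-position refinement is
performed.

## Simulated-annealing intensity correction

Each image's factor is refined every time the image is visited, before its
amplitude replacement: `proposals_per_visit` = 3 multiplicative proposals
c′ = c·exp(ε), ε ~ U(−w, w) with w = 0.1, accepted by the Metropolis rule;
the best accepted value is kept and the measurement is divided by it. One
temperature is shared by all images. Because a sensible initial temperature
depends on the cost scale, the first sweep runs greedily (downhill only)
while recording |ΔE| of every proposal; the initial temperature is then the
median of those samples, multiplied by 0.9 after each subsequent sweep and
floored at 10⁻¹². The cost compares amplitudes, Σ(√(I/c) − |model|)²,
matching the geometry of the projection it feeds.

The forward model is invariant to one global brightness rescale, so factors
are identifiable only up to gauge: the on-axis factor is pinned to 1 (its
image is never annealed) and all recovered factors are relative to it;
evaluations compare gauge-fixed ratios.

## Synthetic samples and what they do (not) show

Bar charts are unit-background amplitude objects with opaque bars of width
period/2 — hard-edged, no anti-aliasing, each edge rounded independently to
a pixel boundary so the mean period survives rasterization. Phase objects
are transparent (amplitude 1) with band-limited Gaussian-noise phase min–max
scaled to [0, max_phase]. These capture the two canonical bench tests
(resolution target, unstained tissue) but not real-sample structure:
no halftones, no absorption–phase coupling, no thickness effects, no
partial coherence. Passing tests therefore demonstrate the *algorithmic*
chain — geometry, radiometry, phase retrieval, factor correction — not
photorealism. The simulation and reconstruction also share the same
discretized coherent model (the usual synthetic-data caveat), which is why
geometry quantities, oracle equivalences and noise are tested independently.

## Standard experiment sizes

The benchmark experiments use a 64×64-pixel camera patch (110.4 μm square in
object space), LED rings 0–9 (361 images, radial illumination NA ≈ 0.32,
synthetic NA ≈ 0.42), upsampling factor 3 (192×192 HR grid, 0.575 μm pitch)
and a chart with elements at 6.6, 4.4, 2.19 and 1.6 μm periods — the
coarsest above the bare objective's 6.33 μm coherent cutoff, the rest below
it, the finest near the synthetic-aperture limit λ/NA_syn ≈ 1.5 μm. These
sizes exercise a >3× resolution gain while a full benchmark run stays in
the seconds range.

## Resolvability criterion

The published judgment of chart resolvability is visual; this package
operationalizes it: an intensity profile is taken perpendicular to the bars
through the element center, 1.5× the element extent long, bilinearly
interpolated; the element resolves if at least n_bars extrema of bar
polarity each reach Michelson contrast (max−min)/(max+min) ≥ 0.2 against
both adjacent opposite extrema. The default 0.2 sits below the classical
Rayleigh two-point contrast (≈0.26) and above noise-induced undulations;
it is configurable and every reported experiment states the value used.

## Numerical choices and degenerate inputs

- Exposure rings: the published grouping has a one-ring gap (the "five
  rings" after the central 7×7 block end at 17×17, but the next group is
  described around a 19×19 block); the default map assigns that ring to
  the 450 ms group, and the map is user-configurable.
- Zero-amplitude model pixels take phase 0 in amplitude replacement.
- A fully saturated image contributes nothing to cost or update (logged).
- Non-finite cost aborts reconstruction with a diagnostic rather than
  continuing on NaNs.
- All randomness (factors, noise, annealing) flows from explicit integer
  seeds; identical seeds give identical outputs, including across the CLI
  pipeline stages, which derive one sub-seed per stage from the global seed.

## Known limitations

Single multiplicative factor per image (no per-pixel flat-field error); no
pupil aberrations or aberration recovery; no LED-position self-calibration
beyond the static offset/roll terms in the geometry; coherent monochromatic
model only; decimation-free spectral sampling assumes a band-limited sensor
(no pixel-aperture MTF); annealing optimizes each factor independently and
can trade global convergence speed for robustness on heavily saturated
stacks.
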