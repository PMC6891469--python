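# fpmkit

Fourier ptychography microscopy (FPM) on simple hardware: a forward
simulator of LED-array acquisition with an industrial-camera noise model, the
alternating-projection reconstruction, and a simulated-annealing correction
for per-image illumination inconsistency.

## The problem

A microscope's resolution and field of view trade off against each other. FPM
sidesteps the trade-off computationally: the sample is illuminated
sequentially by each LED of a programmable array, and each tilted plane wave
shifts a different circular window (sub-aperture) of the object's Fourier
spectrum through the low-NA objective. Stitching the windows back together in
Fourier space recovers a complex (amplitude + phase) image whose resolution
corresponds to the *synthetic* aperture

    NA_syn = NA_objective + NA_illumination,

far beyond the objective's own diffraction limit. The stitching is an
alternating-projection phase retrieval: for LED (m, n) with illumination
frequency (k_m, k_n), the model low-resolution field is

    ψ(k) = Ψ(k) · P(k − k_m, k − k_n),        I_l e^{jφ_l} = F⁻¹[ψ],

its amplitude is replaced by the measured √I_m while the phase φ_l is kept,
and F[√I_m e^{jφ_l}] · P is written back into the same window of the
high-resolution spectrum Ψ. Sweeping all LEDs and iterating to
self-consistency yields the final image.

Doing this with an *industrial* camera (≈50 dB dynamic range, 10-bit, high
read noise) instead of an sCMOS poses two extra problems that this package
models and solves:

1. **Dynamic range** — dark-field images (LEDs beyond the objective NA) are
   orders of magnitude dimmer than bright-field ones. The acquisition plan
   uses ring-wise exposure times (100/150/450/700 ms from the array center
   outward) plus per-LED PWM duty cycles, and the stack is radiometrically
   renormalized before reconstruction.
2. **Inconsistent illumination** — each image is scaled by an unknown
   brightness factor c_i (LED manufacturing spread, angular falloff, sensor
   nonlinearity). Uncorrected, these factors leave ripples in the
   reconstruction background. A simulated-annealing step embedded in the
   reconstruction loop refines each c_i (Metropolis acceptance of
   multiplicative log-space proposals under a geometric cooling schedule),
   with the on-axis factor pinned to 1 as the gauge.

## Worked example

The default platform is a 31×31 LED array (2.5 mm pitch, 633 nm) 93 mm below
the sample, a telecentric 2×/NA 0.1 objective and a 3.45 μm-pixel camera:

```python
from fpmkit import OpticalSystem, LEDArrayGeometry, illumination_na, overlap_ratio
print(f"axial illumination NA: {illumination_na(LEDArrayGeometry()):.3f}")
print(f"adjacent sub-aperture overlap: {overlap_ratio(OpticalSystem(), LEDArrayGeometry()):.3f}")
```

```
axial illumination NA: 0.374
adjacent sub-aperture overlap: 0.829
```

The array's edge LEDs give illumination NA ≈ 0.37 along the axes, and
adjacent sub-apertures overlap by ≈83% in Fourier space — comfortably above
what alternating-projection phase retrieval needs to converge.

The end-to-end resolution experiment images a bar chart with elements at
6.6, 4.4, 2.19 and 1.6 μm periods over LED rings 0–9, with lognormal
(σ = 0.2) per-LED brightness factors and the full camera noise model, then
reconstructs with the SA-embedded algorithm:

```python
from fpmkit.experiments import resolution_benchmark, factor_recovery_benchmark

r = resolution_benchmark(seed=1)
print(f"images: {r['n_images']}")
print(f"reconstruction resolves down to: {r['smallest_resolved_um']} um")
print(f"raw on-axis LR image resolves down to: {r['raw_smallest_resolved_um']} um")

f = factor_recovery_benchmark(seed=1)   # same acquisition, no camera noise
print(f"median factor error: {f['median_factor_error']:.4f}")
print(f"RMSE  SA: {f['rmse_sa']:.4f}   conventional: {f['rmse_conventional']:.4f}")
print(f"ripple SA: {f['ripple_sa']:.4f}   conventional: {f['ripple_conventional']:.4f}")
```

```
images: 361
reconstruction resolves down to: 2.19 um
raw on-axis LR image resolves down to: 6.6 um
median factor error: 0.0318
RMSE  SA: 0.0424   conventional: 0.0456
ripple SA: 0.0046   conventional: 0.0137
```

The raw low-resolution image resolves only the 6.6 μm element (the bare
objective's coherent cutoff is λ/NA = 6.33 μm), while the reconstruction
resolves the 2.19 μm bars — a 3× resolution gain. On noise-free data the
annealing recovers the per-image brightness factors to ~3% median error and
cuts the background ripple (std/mean over a blank region) by ~3× relative to
the conventional reconstruction.

A `fpm` command line wraps the same machinery:

```
fpm pipeline --config run.yaml --out results/
```

runs simulate → reconstruct → evaluate from one YAML config and writes the
stack, amplitude/phase TIFFs, a convergence trace, recovered-factor CSV and
a metrics summary.

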