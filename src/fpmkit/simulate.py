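"""Coherent forward simulator with an industrial-camera noise model.

For each LED the sample is illuminated by a tilted plane wave; the camera
records |F⁻¹[Ψ(k) · P(k − k_led)]|², the intensity of the pupil-filtered,
spectrum-shifted object field, sampled at the camera pitch.  The object is
held on a fine (high-resolution) grid and the low-resolution image is
obtained by spectral cropping — ideal band-limited sampling, consistent
with the coherent model.

On top of the ideal intensity the camera model applies, in order: the
per-image brightness factor c_i (LED manufacturing spread and angular
falloff), exposure × duty-cycle scaling, conversion to expected
photoelectrons, Poisson shot noise, Gaussian read noise, gain to digital
codes, clipping to the ADC range, and quantization.  Saturated pixels are
flagged; they carry no radiometric information and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .samples import ComplexField
from .system import IlluminationPlan, LEDArrayGeometry, OpticalSystem, pupil_mask, wave_vector

__all__ = [
    "CameraModel",
    "LRStack",
    "simulate_lr_intensity",
    "draw_factors",
    "simulate_stack",
    "normalize_stack",
]


@dataclass(frozen=True)
class CameraModel:
    """Radiometric model of the sensor.

    ``photon_budget`` is the expected number of photoelectrons produced by
    unit ideal intensity in one (exposure_ms × duty_cycle) unit.  The default
    pairing of a 1e5 e⁻ full well with 316 e⁻ RMS read noise realizes a
    50 dB dynamic range (20·log10(full_well/read_noise)); 10-bit codes.
    Set ``shot_noise=False`` and ``read_noise_e=0`` and ``quantize=False``
    for an ideal noiseless camera (codes stay floating point).
    """

    photon_budget: float = 500.0
    full_well_e: float = 1.0e5
    read_noise_e: float = 316.0
    bit_depth: int = 10
    shot_noise: bool = True
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be > 0")
        if self.read_noise_e < 0:
            raise ValueError("read_noise_e must be >= 0")
        if self.full_well_e <= 0:
            raise ValueError("full_well_e must be > 0")

    @property
    def code_max(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def gain(self) -> float:
        """Digital codes per photoelectron."""
        return self.code_max / self.full_well_e


@dataclass
class LRStack:
    """Ordered low-resolution intensity images with per-image metadata.

    ``images`` is (n_images, rows, cols); digital codes when raw, floats on
    the ideal-intensity scale after :func:`normalize_stack`.  ``metadata``
    holds one dict per image: led_index, exposure_ms, duty_cycle.
    """

    images: np.ndarray
    metadata: list[dict[str, Any]]
    sat_masks: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError(f"images must be 3-D, got shape {self.images.shape}")
        if len(self.metadata) != self.images.shape[0]:
            raise ValueError(
                f"{len(self.metadata)} metadata entries for "
                f"{self.images.shape[0]} images"
            )
        self.sat_masks = np.asarray(self.sat_masks, dtype=bool)
        if self.sat_masks.shape != self.images.shape:
            raise ValueError("sat_masks shape must match images")

    def __len__(self) -> int:
        return self.images.shape[0]

    def onaxis_position(self) -> int | None:
        for i, md in enumerate(self.metadata):
            if tuple(md["led_index"]) == (0, 0):
                return i
        return None


def _lr_window(spec: np.ndarray, lr_shape: tuple[int, int], f_led, dk: float) -> np.ndarray:
    """Crop the LR-sized window of a centered HR spectrum at +f_led."""
    n_hr = spec.shape[0]
    n_lr = lr_shape[0]
    cy, cx = n_hr // 2, n_hr // 2
    sy = int(round(f_led[1] / dk))
    sx = int(round(f_led[0] / dk))
    r0, c0 = cy + sy - n_lr // 2, cx + sx - n_lr // 2
    if r0 < 0 or c0 < 0 or r0 + n_lr > n_hr or c0 + n_lr > n_hr:
        raise ValueError(
            f"sub-aperture window at shift ({sx}, {sy}) px exceeds the "
            f"{n_hr}x{n_hr} spectrum grid"
        )
    return spec[r0 : r0 + n_lr, c0 : c0 + n_lr]


def simulate_lr_intensity(
    obj: ComplexField,
    sys: OpticalSystem,
    f_led: tuple[float, float],
    lr_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Ideal low-resolution intensity of ``obj`` under one tilted plane wave.

    The object spectrum is shifted by the illumination frequency (the
    window at +f_led is cropped), masked by the objective pupil, and
    inverse-transformed on the camera grid.  The object pitch must be the
    camera object-space pitch divided by an integer upsampling factor.
    """
    if lr_shape is None:
        lr_shape = sys.sensor_shape
    n_hr = obj.shape[0]
    n_lr = lr_shape[0]
    ratio = obj.pixel_pitch_um * n_hr / (sys.object_pixel_um * n_lr)
    if not np.isclose(ratio, round(ratio)) or round(ratio) < 1:
        raise ValueError(
            "object field does not cover an integer upsampling of the "
            f"requested {n_lr}x{n_lr} camera patch "
            f"(object {n_hr} px at {obj.pixel_pitch_um} um, camera pitch "
            f"{sys.object_pixel_um} um)"
        )
    dk = 1.0 / (n_hr * obj.pixel_pitch_um)
    spec = np.fft.fftshift(np.fft.fft2(obj.data))
    win = _lr_window(spec, lr_shape, f_led, dk)
    pupil = pupil_mask(sys, lr_shape, dk)
    lr_field = np.fft.ifft2(np.fft.ifftshift(win * pupil.weights)) * (n_lr / n_hr) ** 2
    return np.abs(lr_field) ** 2


def draw_factors(
    plan: IlluminationPlan, sigma: float, seed: int | None = 0
) -> np.ndarray:
    """Per-image brightness factors c_i, i.i.d. lognormal with median 1.

    ``sigma`` is the log-scale spread; sigma = 0 gives all ones.  Models
    LED-to-LED luminous-intensity differences and angular falloff as one
    multiplicative scalar per acquisition.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return np.exp(sigma * rng.standard_normal(len(plan)))


def simulate_stack(
    obj: ComplexField,
    sys: OpticalSystem,
    geom: LEDArrayGeometry,
    plan: IlluminationPlan,
    factors: np.ndarray | None = None,
    cam: CameraModel | None = None,
    seed: int | None = 0,
    lr_shape: tuple[int, int] | None = None,
) -> LRStack:
    """Render the full acquisition: one camera frame per plan entry.

    Pipeline per image: ideal intensity × c_i × exposure_ms × duty_cycle
    → expected photoelectrons (photon_budget) → Poisson shot noise →
    Gaussian read noise → gain → clip to the ADC range → integer codes.
    ``sat_masks`` flags pixels whose pre-clip value exceeded full scale.
    """
    if cam is None:
        cam = CameraModel()
    if lr_shape is None:
        lr_shape = sys.sensor_shape
    if factors is None:
        factors = np.ones(len(plan))
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (len(plan),):
        raise ValueError(f"need {len(plan)} factors, got shape {factors.shape}")
    if np.any(factors <= 0):
        raise ValueError("all intensity factors must be > 0")

    rng = np.random.default_rng(seed)
    images = np.empty((len(plan), *lr_shape))
    sat = np.empty((len(plan), *lr_shape), dtype=bool)
    metadata = []
    for i, entry in enumerate(plan):
        f_led = wave_vector(*entry.led_index, geom, sys)
        ideal = simulate_lr_intensity(obj, sys, f_led, lr_shape)
        electrons = ideal * factors[i] * entry.exposure_ms * entry.duty_cycle * cam.photon_budget
        if cam.shot_noise:
            electrons = rng.poisson(electrons).astype(float)
        if cam.read_noise_e > 0:
            electrons = electrons + cam.read_noise_e * rng.standard_normal(lr_shape)
        codes = electrons * cam.gain
        sat[i] = codes > cam.code_max
        codes = np.clip(codes, 0.0, cam.code_max)
        if cam.quantize:
            codes = np.round(codes)
        images[i] = codes
        metadata.append(
            {
                "led_index": entry.led_index,
                "exposure_ms": entry.exposure_ms,
                "duty_cycle": entry.duty_cycle,
            }
        )
    if cam.quantize:
        images = images.astype(np.uint16)
    return LRStack(images=images, metadata=metadata, sat_masks=sat, normalized=False)


def normalize_stack(stack: LRStack, cam: CameraModel | None = None) -> LRStack:
    """Map raw codes back to a single radiometric (ideal-intensity) scale.

    Each image is divided by its exposure_ms × duty_cycle; when the camera
    model is supplied the gain and photon budget are also inverted, so a
    noiseless unit-factor acquisition reproduces the ideal intensity
    exactly.  Saturated-pixel masks are carried forward unchanged.
    """
    if cam is None:
        cam = CameraModel()
    if stack.normalized:
        raise ValueError("stack is already normalized")
    out = np.empty(stack.images.shape)
    for i, md in enumerate(stack.metadata):
        if "exposure_ms" not in md or "duty_cycle" not in md:
            raise ValueError(f"image {i} missing exposure/duty metadata")
        scale = md["exposure_ms"] * md["duty_cycle"] * cam.photon_budget * cam.gain
        out[i] = stack.images[i] / scale
    return LRStack(
        images=out,
        metadata=[dict(md) for md in stack.metadata],
        sat_masks=stack.sat_masks.copy(),
        normalized=True,
    )
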