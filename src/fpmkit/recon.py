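"""Alternating-projection Fourier-ptychographic reconstruction.

The recovered object lives as a high-resolution (HR) complex spectrum on a
grid ``upsampling_factor`` times finer in real space than the camera.  Each
sub-iteration enforces one measurement: the sub-aperture of the HR spectrum
centered at the LED's illumination frequency is extracted through the pupil,
inverse-transformed to a model low-resolution (LR) field, its amplitude is
replaced by the square root of the measured intensity (the phase is kept),
and the result is transformed back and written into the same sub-aperture.
Sweeping all LEDs low-frequency-first and repeating until self-consistency
stitches the synthetic aperture: final resolution corresponds to
NA_objective + NA_illumination.

When a simulated-annealing configuration is supplied, each image's
brightness factor is refined just before its amplitude replacement and the
measured intensity is divided by it (see :mod:`fpmkit.sa`).

Scaling convention: the HR spectrum is the centered (fftshifted) DFT of the
HR field; extracting an LR window and inverse-transforming multiplies by
(n_lr/n_hr)² so a unit-amplitude object yields unit LR intensity, matching
the forward simulator exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .samples import ComplexField
from .sa import SAConfig, SAState, sa_refine_factor
from .simulate import LRStack
from .system import (
    LEDArrayGeometry,
    OpticalSystem,
    PupilMask,
    illumination_na,
    pupil_mask,
    wave_vector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HRSpectrum",
    "ReconConfig",
    "ReconResult",
    "auto_upsampling_factor",
    "initialize_spectrum",
    "extract_subaperture",
    "amplitude_replace",
    "update_spectrum",
    "reconstruct",
]


@dataclass
class HRSpectrum:
    """Centered high-resolution spectrum with its frequency spacing.

    ``dk`` (cycles/μm) equals 1/(n_lr · LR pixel pitch); the HR grid has
    the same dk but upsampling_factor times more samples per axis, i.e. a
    wider frequency support, hence finer real-space pitch.
    """

    data: np.ndarray
    dk: float
    lr_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"spectrum must be square, got {self.data.shape}")
        if self.data.shape[0] % self.lr_shape[0] != 0:
            raise ValueError(
                f"HR side {self.data.shape[0]} is not a multiple of LR side "
                f"{self.lr_shape[0]}"
            )

    @property
    def upsampling_factor(self) -> int:
        return self.data.shape[0] // self.lr_shape[0]

    def copy(self) -> "HRSpectrum":
        return HRSpectrum(self.data.copy(), self.dk, self.lr_shape)


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction controls.

    upsampling_factor=None picks the smallest integer whose HR pitch
    satisfies Nyquist for the synthetic aperture NA_obj + NA_ill (and whose
    grid contains every shifted pupil).  The convergence metric is the mean
    over images of the relative L2 difference between measured and model
    amplitudes; iteration stops when its relative change drops below
    ``rel_tol`` or after ``max_sweeps``.
    """

    upsampling_factor: int | None = None
    max_sweeps: int = 10
    rel_tol: float = 1e-3
    update_order: Literal["center_out_spiral", "raster"] = "center_out_spiral"
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.upsampling_factor is not None and self.upsampling_factor < 2:
            raise ValueError("upsampling_factor must be >= 2 (or None for auto)")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.update_order not in ("center_out_spiral", "raster"):
            raise ValueError(f"unknown update_order {self.update_order!r}")


@dataclass
class ReconResult:
    """Output of :func:`reconstruct`."""

    hr_field: ComplexField
    hr_spectrum: HRSpectrum
    factors: np.ndarray
    trace: list[float]
    sweeps_run: int
    config: ReconConfig
    sa_config: SAConfig | None = None


def auto_upsampling_factor(
    sys: OpticalSystem, geom: LEDArrayGeometry, max_ring: int | None = None
) -> int:
    """Smallest integer upsampling meeting synthetic-aperture Nyquist.

    HR pitch must be ≤ λ / (2·(NA_obj + NA_ill,radial)); the radial
    illumination NA (corner LED of the used rings) bounds the largest
    spectral shift.
    """
    if max_ring is not None and max_ring < geom.half_extent:
        geom_used = LEDArrayGeometry(
            half_extent=max_ring,
            pitch_mm=geom.pitch_mm,
            standoff_mm=geom.standoff_mm,
            offset_mm=geom.offset_mm,
            roll_deg=geom.roll_deg,
        )
    else:
        geom_used = geom
    na_syn = sys.objective_na + illumination_na(geom_used, "radial")
    target_pitch = sys.wavelength_um / (2.0 * na_syn)
    factor = max(2, math.ceil(sys.object_pixel_um / target_pitch))
    return factor


def _window_origin(
    n_hr: int, n_lr: int, f_led: tuple[float, float], dk: float
) -> tuple[int, int]:
    """Top-left (row, col) of the LR window at +f_led; raises if outside."""
    cy = cx = n_hr // 2
    sy = int(round(f_led[1] / dk))
    sx = int(round(f_led[0] / dk))
    r0, c0 = cy + sy - n_lr // 2, cx + sx - n_lr // 2
    if r0 < 0 or c0 < 0 or r0 + n_lr > n_hr or c0 + n_lr > n_hr:
        raise ValueError(
            f"shifted pupil at ({sx}, {sy}) px exceeds the {n_hr}x{n_hr} HR grid; "
            "increase upsampling_factor"
        )
    return r0, c0


def initialize_spectrum(stack: LRStack, upsampling_factor: int, lr_pitch_um: float) -> HRSpectrum:
    """Initial HR spectrum: band-limited upsampling of the on-axis amplitude.

    The square root of the normalized on-axis intensity (zero phase) is
    transformed on the LR grid and embedded in the center of the HR grid.
    Falls back to the stack mean image if no on-axis acquisition exists.
    """
    if not stack.normalized:
        raise ValueError("stack must be normalized before reconstruction")
    n_lr = stack.images.shape[1]
    pos = stack.onaxis_position()
    if pos is not None:
        img = stack.images[pos]
    else:
        logger.warning("no on-axis image in stack; initializing from the stack mean")
        img = stack.images.mean(axis=0)
    amp = np.sqrt(np.clip(img, 0.0, None))
    lr_spec = np.fft.fftshift(np.fft.fft2(amp))
    n_hr = n_lr * upsampling_factor
    data = np.zeros((n_hr, n_hr), dtype=complex)
    r0 = n_hr // 2 - n_lr // 2
    # embed with the (n_hr/n_lr)^2 scale so HR ifft reproduces the amplitude
    data[r0 : r0 + n_lr, r0 : r0 + n_lr] = lr_spec * (n_hr / n_lr) ** 2
    dk = 1.0 / (n_lr * lr_pitch_um)
    return HRSpectrum(data=data, dk=dk, lr_shape=(n_lr, n_lr))


def extract_subaperture(
    spec: HRSpectrum, f_led: tuple[float, float], P: PupilMask
) -> np.ndarray:
    """Model LR complex field seen through the pupil at one illumination.

    Crops the LR-sized window of the HR spectrum centered at the nearest
    grid pixel to f_led/dk, masks it with the pupil, and inverse-transforms.
    """
    n_hr = spec.data.shape[0]
    n_lr = spec.lr_shape[0]
    r0, c0 = _window_origin(n_hr, n_lr, f_led, spec.dk)
    win = spec.data[r0 : r0 + n_lr, c0 : c0 + n_lr] * P.weights
    return np.fft.ifft2(np.fft.ifftshift(win)) * (n_lr / n_hr) ** 2


def amplitude_replace(
    model_lr: np.ndarray,
    measured_intensity: np.ndarray,
    sat_mask: np.ndarray | None = None,
) -> np.ndarray:
    """The phase-retrieval projection: measured amplitude, model phase.

    Returns √I_meas · exp(j·arg(model)).  Where the model is exactly zero
    the phase is taken as 0.  Saturated pixels keep the model value — a
    clipped measurement carries no usable amplitude.
    """
    if model_lr.shape != measured_intensity.shape:
        raise ValueError("model and measured shapes differ")
    if np.any(measured_intensity < 0):
        raise ValueError("measured intensity must be >= 0")
    mag = np.abs(model_lr)
    phase_factor = np.where(mag > 0, model_lr / np.where(mag > 0, mag, 1.0), 1.0)
    out = np.sqrt(measured_intensity) * phase_factor
    if sat_mask is not None:
        out = np.where(sat_mask, model_lr, out)
    return out


def update_spectrum(
    spec: HRSpectrum,
    updated_lr: np.ndarray,
    f_led: tuple[float, float],
    P: PupilMask,
) -> HRSpectrum:
    """Write the transformed updated LR field back into its sub-aperture.

    Only pixels inside the shifted pupil support change; the rest of the
    spectrum is untouched.  Modifies ``spec`` in place and returns it.
    """
    n_hr = spec.data.shape[0]
    n_lr = spec.lr_shape[0]
    r0, c0 = _window_origin(n_hr, n_lr, f_led, spec.dk)
    new_win = np.fft.fftshift(np.fft.fft2(updated_lr)) * (n_hr / n_lr) ** 2
    sl = (slice(r0, r0 + n_lr), slice(c0, c0 + n_lr))
    spec.data[sl] = spec.data[sl] * (1.0 - P.weights) + new_win * P.weights
    return spec


def _sweep_order(stack: LRStack, f_leds: list[tuple[float, float]], order: str) -> list[int]:
    idx = list(range(len(stack)))
    if order == "raster":
        return idx
    # center-out spiral: ascending illumination frequency, then angle
    def key(i: int):
        fx, fy = f_leds[i]
        return (round(math.hypot(fx, fy), 12), math.atan2(fy, fx))

    return sorted(idx, key=key)


def reconstruct(
    stack: LRStack,
    sys: OpticalSystem,
    geom: LEDArrayGeometry,
    cfg: ReconConfig | None = None,
    sa: SAConfig | None = None,
) -> ReconResult:
    """Run the full alternating-projection reconstruction on a normalized stack.

    Sweeps all images in ``cfg.update_order``; each sub-iteration extracts
    the sub-aperture, optionally refines the image's brightness factor by
    simulated annealing, replaces the amplitude with the (factor-corrected)
    measurement, and writes the spectrum window back.  Stops at
    ``max_sweeps`` or when the data-fidelity cost stalls (rel_tol).

    Returns the HR complex field, final spectrum, recovered per-image
    factors (all 1 when SA is disabled), and the per-sweep cost trace.
    """
    if cfg is None:
        cfg = ReconConfig()
    if not stack.normalized:
        raise ValueError("reconstruct requires a normalized stack (see normalize_stack)")
    n_lr = stack.images.shape[1]
    lr_pitch = sys.object_pixel_um
    f_leds = [
        wave_vector(*md["led_index"], geom, sys) for md in stack.metadata
    ]

    factor = cfg.upsampling_factor
    if factor is None:
        max_ring = max(
            max(abs(md["led_index"][0]), abs(md["led_index"][1]))
            for md in stack.metadata
        )
        factor = auto_upsampling_factor(sys, geom, max_ring=max_ring)
    # grow until every shifted pupil (window) fits on the HR grid
    dk = 1.0 / (n_lr * lr_pitch)
    max_shift = max(
        max(abs(round(fx / dk)), abs(round(fy / dk))) for fx, fy in f_leds
    )
    while factor * n_lr // 2 < max_shift + n_lr // 2:
        factor += 1
    logger.info("upsampling factor %d (HR pitch %.4g um)", factor, lr_pitch / factor)

    spec = initialize_spectrum(stack, factor, lr_pitch)
    P = pupil_mask(sys, (n_lr, n_lr), spec.dk)
    order = _sweep_order(stack, f_leds, cfg.update_order)

    factors = np.ones(len(stack))
    onaxis = stack.onaxis_position()
    sa_state = SAState.from_config(sa, seed=sa.seed if sa.seed is not None else cfg.seed) if sa is not None else None

    trace: list[float] = []
    sweeps_run = 0
    for sweep in range(cfg.max_sweeps):
        num = 0.0
        den = 0.0
        for i in order:
            measured = stack.images[i]
            sat = stack.sat_masks[i]
            sat_mask = sat if sat.any() else None
            model_lr = extract_subaperture(spec, f_leds[i], P)
            if sa_state is not None and i != onaxis:
                factors[i] = sa_refine_factor(
                    factors[i], measured, model_lr, sat_mask, sa_state
                )
            corrected = measured / factors[i]
            # data-fidelity residual between measured and model amplitudes
            amp_meas = np.sqrt(np.clip(corrected, 0.0, None))
            amp_model = np.abs(model_lr)
            if sat_mask is not None:
                resid = amp_meas[~sat_mask] - amp_model[~sat_mask]
                num += float(np.sum(resid**2))
                den += float(np.sum(amp_meas[~sat_mask] ** 2))
            else:
                num += float(np.sum((amp_meas - amp_model) ** 2))
                den += float(np.sum(amp_meas**2))
            updated = amplitude_replace(model_lr, np.clip(corrected, 0.0, None), sat_mask)
            update_spectrum(spec, updated, f_leds[i], P)
        cost = math.sqrt(num / den) if den else 0.0  # NaN den propagates
        if not math.isfinite(cost):
            raise RuntimeError(
                f"reconstruction diverged at sweep {sweep}: cost={cost}, "
                f"|spectrum|max={np.abs(spec.data).max():.3g}"
            )
        trace.append(cost)
        sweeps_run = sweep + 1
        if sa_state is not None:
            sa_state.end_sweep()
        if sweep > 0 and trace[-2] > 0:
            if abs(trace[-2] - trace[-1]) / trace[-2] < cfg.rel_tol:
                break

    hr = np.fft.ifft2(np.fft.ifftshift(spec.data))
    hr_field = ComplexField(
        data=hr,
        pixel_pitch_um=lr_pitch / factor,
        meta={"upsampling_factor": factor, "sweeps_run": sweeps_run},
    )
    return ReconResult(
        hr_field=hr_field,
        hr_spectrum=spec,
        factors=factors,
        trace=trace,
        sweeps_run=sweeps_run,
        config=cfg,
        sa_config=sa,
    )
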