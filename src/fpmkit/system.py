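"""Geometric and Fourier-optics description of an LED-array microscope.

The platform is a programmable LED matrix a fixed standoff below the sample,
a low-NA objective, and a camera.  Each LED illuminates the sample with a
tilted plane wave; the objective passes a circular pupil of radius NA/λ in
frequency space, so each acquisition samples one shifted sub-aperture of the
object spectrum.  This module computes LED positions, illumination wave
vectors, pupil masks, illumination NA, sub-aperture overlap, and the
ring-wise exposure schedule used to stretch the camera's dynamic range.

Units: lengths in the units named on each field (μm for optics, mm for the
LED array), spatial frequencies in cycles/μm everywhere.  Factors of 2π live
only inside the Fourier transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "OpticalSystem",
    "LEDArrayGeometry",
    "PlanEntry",
    "IlluminationPlan",
    "PupilMask",
    "DEFAULT_EXPOSURE_MAP",
    "led_position",
    "wave_vector",
    "illumination_na",
    "pupil_mask",
    "overlap_ratio",
    "exposure_for_led",
    "make_plan",
]


#: Ring-wise exposure schedule (ms), as ``(last_ring, exposure_ms)`` pairs.
#: Ring r = max(|m|, |n|).  Central 7×7 block (rings 0–3) at 100 ms, the five
#: rings around it at 150 ms, the next six at 450 ms, the outermost at 700 ms.
DEFAULT_EXPOSURE_MAP: tuple[tuple[int, float], ...] = (
    (3, 100.0),
    (8, 150.0),
    (14, 450.0),
    (15, 700.0),
)


@dataclass(frozen=True)
class OpticalSystem:
    """Imaging-side parameters: wavelength, objective, camera.

    Parameters
    ----------
    wavelength_um : float
        Illumination wavelength in μm (quasi-monochromatic LED line).
    objective_na : float
        Objective numerical aperture, in (0, 1).
    magnification : float
        Objective magnification (> 0).
    camera_pixel_um : float
        Camera pixel pitch in μm.
    bit_depth : int
        ADC bit depth (≥ 8).
    dynamic_range_db : float
        Sensor dynamic range in dB (full well over read noise).
    sensor_shape : tuple of int
        (rows, cols) of the sensor or the patch being simulated.
    """

    wavelength_um: float = 0.633
    objective_na: float = 0.1
    magnification: float = 2.0
    camera_pixel_um: float = 3.45
    bit_depth: int = 10
    dynamic_range_db: float = 50.0
    sensor_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not (0.0 < self.objective_na < 1.0):
            raise ValueError(f"objective_na must be in (0, 1), got {self.objective_na}")
        if self.wavelength_um <= 0:
            raise ValueError(f"wavelength_um must be > 0, got {self.wavelength_um}")
        if self.magnification <= 0:
            raise ValueError(f"magnification must be > 0, got {self.magnification}")
        if self.camera_pixel_um <= 0:
            raise ValueError(f"camera_pixel_um must be > 0, got {self.camera_pixel_um}")
        if self.bit_depth < 8:
            raise ValueError(f"bit_depth must be >= 8, got {self.bit_depth}")
        if self.dynamic_range_db < 0:
            raise ValueError("dynamic_range_db must be >= 0")

    @property
    def object_pixel_um(self) -> float:
        """Object-space pixel pitch (camera pixel demagnified), μm."""
        return self.camera_pixel_um / self.magnification

    @property
    def pupil_cutoff(self) -> float:
        """Coherent pupil cutoff frequency NA/λ, cycles/μm."""
        return self.objective_na / self.wavelength_um


@dataclass(frozen=True)
class LEDArrayGeometry:
    """LED matrix geometry relative to the sample.

    The array is indexed by integer (m, n) with |m|,|n| ≤ ``half_extent``;
    the (0, 0) LED is nominally on the optical axis.  ``offset_mm`` and
    ``roll_deg`` describe residual misalignment after physical alignment.
    """

    half_extent: int = 15
    pitch_mm: float = 2.5
    standoff_mm: float = 93.0
    offset_mm: tuple[float, float] = (0.0, 0.0)
    roll_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.half_extent < 0:
            raise ValueError(f"half_extent must be >= 0, got {self.half_extent}")
        if self.pitch_mm <= 0:
            raise ValueError(f"pitch_mm must be > 0, got {self.pitch_mm}")
        if self.standoff_mm <= 0:
            raise ValueError(f"standoff_mm must be > 0, got {self.standoff_mm}")

    @property
    def n_leds(self) -> int:
        return (2 * self.half_extent + 1) ** 2

    def indices(self) -> Iterable[tuple[int, int]]:
        """All (m, n) index pairs, row-major."""
        r = range(-self.half_extent, self.half_extent + 1)
        return ((m, n) for n in r for m in r)


@dataclass(frozen=True)
class PlanEntry:
    """One acquisition: which LED, for how long, at what PWM duty cycle."""

    led_index: tuple[int, int]
    exposure_ms: float
    duty_cycle: float = 1.0

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError(f"exposure_ms must be > 0, got {self.exposure_ms}")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError(f"duty_cycle must be in (0, 1], got {self.duty_cycle}")

    @property
    def ring(self) -> int:
        m, n = self.led_index
        return max(abs(m), abs(n))


@dataclass(frozen=True)
class IlluminationPlan:
    """Ordered LED firing sequence with per-image exposure and duty cycle."""

    entries: tuple[PlanEntry, ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.led_index in seen:
                raise ValueError(f"duplicate LED index {e.led_index} in plan")
            seen.add(e.led_index)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def onaxis_position(self) -> int | None:
        """Index of the (0, 0) entry in the plan, or None if absent."""
        for i, e in enumerate(self.entries):
            if e.led_index == (0, 0):
                return i
        return None


@dataclass(frozen=True)
class PupilMask:
    """Binary circular pupil on a centered frequency grid.

    ``weights`` is 1 where the frequency-grid pixel center lies strictly
    inside the cutoff radius, 0 outside (hard disk, no apodization).
    ``dk`` is the grid spacing in cycles/μm; the grid center is at index
    ``shape // 2`` (fftshift convention).
    """

    weights: np.ndarray
    dk: float
    cutoff: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape  # type: ignore[return-value]


def led_position(
    m: int, n: int, geom: LEDArrayGeometry
) -> tuple[float, float, float]:
    """LED center in sample-centered coordinates (x, y, z), mm.

    The nominal in-plane position (m, n)·pitch is rotated by the array roll
    angle and shifted by the lateral offset; z is the standoff.
    """
    h = geom.half_extent
    if abs(m) > h or abs(n) > h:
        raise ValueError(
            f"LED index ({m}, {n}) outside array of half extent {h}"
        )
    c, s = math.cos(math.radians(geom.roll_deg)), math.sin(math.radians(geom.roll_deg))
    x0, y0 = m * geom.pitch_mm, n * geom.pitch_mm
    x = c * x0 - s * y0 + geom.offset_mm[0]
    y = s * x0 + c * y0 + geom.offset_mm[1]
    return (x, y, geom.standoff_mm)


def wave_vector(
    m: int, n: int, geom: LEDArrayGeometry, sys: OpticalSystem
) -> tuple[float, float]:
    """Illumination spatial frequency (fx, fy) for LED (m, n), cycles/μm.

    A plane wave from an LED at (x, y, −z) relative to the field center has
    direction sines (sinθx, sinθy) = (−x, −y)/√(x²+y²+z²); the corresponding
    sub-aperture of the object spectrum is centered at (sinθx, sinθy)/λ.
    The plane-wave-per-patch approximation evaluates this at the center of
    the imaged field.
    """
    x, y, z = led_position(m, n, geom)
    r = math.sqrt(x * x + y * y + z * z)
    lam = sys.wavelength_um
    return (-x / r / lam, -y / r / lam)


def illumination_na(
    geom: LEDArrayGeometry, mode: Literal["axial", "radial"] = "axial"
) -> float:
    """Maximum illumination NA (direction sine) over the array.

    mode="axial": maximum over LEDs on the array axes (m = 0 or n = 0) —
    the number usually quoted for a square array.  mode="radial": maximum
    over all LEDs, attained at a corner.
    """
    if mode not in ("axial", "radial"):
        raise ValueError(f"mode must be 'axial' or 'radial', got {mode!r}")
    best = 0.0
    for m, n in geom.indices():
        if mode == "axial" and m != 0 and n != 0:
            continue
        x, y, z = led_position(m, n, geom)
        best = max(best, math.hypot(x, y) / math.sqrt(x * x + y * y + z * z))
    return best


def pupil_mask(
    sys: OpticalSystem, grid_shape: tuple[int, int], dk: float
) -> PupilMask:
    """Binary circular pupil of radius NA/λ on a (rows, cols) frequency grid."""
    if dk <= 0:
        raise ValueError(f"dk must be > 0, got {dk}")
    rows, cols = grid_shape
    cutoff = sys.pupil_cutoff
    half = min(rows // 2, cols // 2) * dk
    if half < cutoff:
        raise ValueError(
            f"frequency grid half-width {half:.4g} cycles/um cannot contain "
            f"the pupil of cutoff {cutoff:.4g} cycles/um"
        )
    ky = (np.arange(rows) - rows // 2) * dk
    kx = (np.arange(cols) - cols // 2) * dk
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    weights = (k2 < cutoff**2).astype(float)
    return PupilMask(weights=weights, dk=dk, cutoff=cutoff)


def _disk_overlap_fraction(d: float, r: float) -> float:
    """Area fraction shared by two disks of radius r at center distance d."""
    if d >= 2.0 * r:
        return 0.0
    if d <= 0.0:
        return 1.0
    h = d / (2.0 * r)
    lens = 2.0 * r * r * math.acos(h) - (d / 2.0) * math.sqrt(4.0 * r * r - d * d)
    return lens / (math.pi * r * r)


def overlap_ratio(sys: OpticalSystem, geom: LEDArrayGeometry) -> float:
    """Fourier-domain overlap of adjacent sub-apertures at the array center.

    The fractional area one pupil disk shares with its nearest neighbor's
    disk, for the wave-vector step between LED (0,0) and (1,0).  Sufficient
    overlap (tens of percent) is what lets alternating-projection phase
    retrieval converge.
    """
    if geom.half_extent == 0:
        return 1.0
    f0 = wave_vector(0, 0, geom, sys)
    f1 = wave_vector(1, 0, geom, sys)
    step = math.hypot(f1[0] - f0[0], f1[1] - f0[1])
    return _disk_overlap_fraction(step, sys.pupil_cutoff)


def exposure_for_led(
    m: int,
    n: int,
    ring_map: Sequence[tuple[int, float]] = DEFAULT_EXPOSURE_MAP,
) -> float:
    """Exposure time (ms) for LED (m, n) under a ring→exposure schedule.

    ``ring_map`` is a sequence of (last_ring, exposure_ms) breakpoints in
    increasing ring order; the LED's ring max(|m|, |n|) selects the first
    breakpoint at or beyond it.
    """
    ring = max(abs(m), abs(n))
    for last_ring, exposure_ms in ring_map:
        if ring <= last_ring:
            return float(exposure_ms)
    raise ValueError(
        f"ring {ring} for LED ({m}, {n}) not covered by exposure map "
        f"(max ring {ring_map[-1][0]})"
    )


def _center_out_order(
    indices: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    # low rings (low spatial frequencies) first, then by angle within a ring
    def key(idx: tuple[int, int]):
        m, n = idx
        return (max(abs(m), abs(n)), m * m + n * n, math.atan2(n, m))

    return sorted(indices, key=key)


def make_plan(
    geom: LEDArrayGeometry,
    max_ring: int | None = None,
    exposure_map: Sequence[tuple[int, float]] = DEFAULT_EXPOSURE_MAP,
    duty_cycle: float | dict[int, float] = 1.0,
    order: Literal["center_out", "raster"] = "center_out",
) -> IlluminationPlan:
    """Build the firing sequence for the array out to ``max_ring``.

    Exposures come from the ring map; duty cycle is a scalar or a
    per-ring dict (defaults to 1.0, i.e. continuous drive).
    """
    if max_ring is None:
        max_ring = geom.half_extent
    if max_ring > geom.half_extent:
        raise ValueError(
            f"max_ring {max_ring} exceeds array half extent {geom.half_extent}"
        )
    indices = [
        (m, n) for (m, n) in geom.indices() if max(abs(m), abs(n)) <= max_ring
    ]
    if order == "center_out":
        indices = _center_out_order(indices)
    elif order != "raster":
        raise ValueError(f"unknown order {order!r}")
    entries = []
    for m, n in indices:
        ring = max(abs(m), abs(n))
        duty = duty_cycle[ring] if isinstance(duty_cycle, dict) else duty_cycle
        entries.append(
            PlanEntry(
                led_index=(m, n),
                exposure_ms=exposure_for_led(m, n, exposure_map),
                duty_cycle=duty,
            )
        )
    return IlluminationPlan(entries=tuple(entries))
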