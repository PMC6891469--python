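"""Synthetic ground-truth objects: bar resolution charts and phase objects.

Objects are thin complex transmission functions f(x, y) = |f| exp(jφ) sampled
on a square, even-sided grid (FFT-friendly).  Two families emulate the usual
bench tests: opaque-bar resolution elements in the style of a USAF-1951
chart, and smooth transparent phase objects standing in for unstained
biological tissue.

Bar edges are hard (no anti-aliasing): each edge position in μm is rounded
to the nearest pixel boundary independently, so the mean period is preserved
even when the period is a non-integer number of pixels.  Resolvability in
downstream experiments is then limited by the imaging model, not the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = ["ComplexField", "bar_target", "usaf_like_target", "phase_object"]


@dataclass
class ComplexField:
    """A sampled 2-D complex transmission or reconstructed field.

    Attributes
    ----------
    data : complex ndarray, square with even side
    pixel_pitch_um : object-space sampling pitch, μm
    meta : free-form metadata (generator parameters, chart layout)
    """

    data: np.ndarray
    pixel_pitch_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"field must be square 2-D, got shape {self.data.shape}")
        if self.data.shape[0] % 2 != 0:
            raise ValueError(f"field side must be even, got {self.data.shape[0]}")
        if self.pixel_pitch_um <= 0:
            raise ValueError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    @property
    def extent_um(self) -> float:
        return self.shape[0] * self.pixel_pitch_um


def _paint_bars(
    amp: np.ndarray,
    period_um: float,
    n_bars: int,
    orientation: str,
    pitch_um: float,
    center_xy_um: tuple[float, float],
    bar_length_um: float,
    bar_level: float,
) -> None:
    """Paint n_bars of width period/2, spaced by period, into ``amp`` in place.

    Edges are rounded to pixel boundaries individually, preserving the mean
    period.  ``orientation`` is the direction along which intensity varies:
    'vertical' bars vary along x (columns), 'horizontal' bars along y.
    """
    width = period_um / 2.0
    extent = n_bars * period_um - width  # first bar start to last bar end
    cx, cy = center_xy_um
    along0 = (cx if orientation == "vertical" else cy) - extent / 2.0
    across_c = cy if orientation == "vertical" else cx
    a0 = int(round((across_c - bar_length_um / 2.0) / pitch_um))
    a1 = int(round((across_c + bar_length_um / 2.0) / pitch_um))
    n = amp.shape[0]
    a0, a1 = max(a0, 0), min(a1, n)
    for i in range(n_bars):
        lo = int(round((along0 + i * period_um) / pitch_um))
        hi = int(round((along0 + i * period_um + width) / pitch_um))
        lo, hi = max(lo, 0), min(hi, n)
        if orientation == "vertical":
            amp[a0:a1, lo:hi] = bar_level
        else:
            amp[lo:hi, a0:a1] = bar_level


def bar_target(
    period_um: float,
    n_bars: int,
    orientation: Literal["horizontal", "vertical"] = "vertical",
    shape: tuple[int, int] = (128, 128),
    pitch_um: float = 0.8625,
    bar_level: float = 0.0,
) -> ComplexField:
    """A single bar element: ``n_bars`` bars of width period/2 at spacing period.

    Background amplitude is 1; bars have amplitude ``bar_level`` (0 = opaque
    chrome, values > 1 give bright bars).  Phase is identically zero.  One
    line pair per period: a chart element of P pairs/mm has
    period_um = 1000 / P.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if n_bars < 1:
        raise ValueError("n_bars must be >= 1")
    if period_um < 2.0 * pitch_um:
        raise ValueError(
            f"period {period_um} um is below the grid Nyquist period "
            f"{2.0 * pitch_um} um"
        )
    n = shape[0]
    amp = np.ones(shape, dtype=float)
    center = (n * pitch_um / 2.0, n * pitch_um / 2.0)
    bar_length = n_bars * period_um  # square-ish element, USAF style
    _paint_bars(amp, period_um, n_bars, orientation, pitch_um, center, bar_length, bar_level)
    meta = {
        "generator": "bar_target",
        "elements": [
            {
                "period_um": period_um,
                "n_bars": n_bars,
                "orientation": orientation,
                "center_xy_um": list(center),
                "extent_um": n_bars * period_um - period_um / 2.0,
            }
        ],
    }
    return ComplexField(data=amp.astype(complex), pixel_pitch_um=pitch_um, meta=meta)


def usaf_like_target(
    elements: Sequence[tuple[float, str, tuple[float, float]]],
    shape: tuple[int, int] = (128, 128),
    pitch_um: float = 0.8625,
    n_bars: int = 3,
    bar_level: float = 0.0,
) -> ComplexField:
    """Compose several bar elements into one chart.

    ``elements`` is a sequence of (period_um, orientation, (cx_um, cy_um)).
    Element bounding boxes must not overlap; positions and periods are
    recorded in the returned field's metadata (sorted coarsest first) so
    evaluation code can extract profiles automatically.
    """
    n = shape[0]
    amp = np.ones(shape, dtype=float)
    boxes = []
    meta_elems = []
    for period_um, orientation, center in elements:
        if period_um < 2.0 * pitch_um:
            raise ValueError(
                f"element period {period_um} um below grid Nyquist {2 * pitch_um} um"
            )
        extent = n_bars * period_um - period_um / 2.0
        length = n_bars * period_um
        cx, cy = center
        if orientation == "vertical":
            box = (cx - extent / 2, cx + extent / 2, cy - length / 2, cy + length / 2)
        else:
            box = (cx - length / 2, cx + length / 2, cy - extent / 2, cy + extent / 2)
        if not (0 <= box[0] and box[1] <= n * pitch_um and 0 <= box[2] and box[3] <= n * pitch_um):
            raise ValueError(f"element of period {period_um} um does not fit in the field")
        for other in boxes:
            if box[0] < other[1] and other[0] < box[1] and box[2] < other[3] and other[2] < box[3]:
                raise ValueError(
                    f"element of period {period_um} um overlaps another element"
                )
        boxes.append(box)
        _paint_bars(amp, period_um, n_bars, orientation, pitch_um, center, length, bar_level)
        meta_elems.append(
            {
                "period_um": period_um,
                "n_bars": n_bars,
                "orientation": orientation,
                "center_xy_um": [cx, cy],
                "extent_um": extent,
            }
        )
    meta_elems.sort(key=lambda e: -e["period_um"])
    meta = {"generator": "usaf_like_target", "elements": meta_elems}
    return ComplexField(data=amp.astype(complex), pixel_pitch_um=pitch_um, meta=meta)


def phase_object(
    feature_scale_um: float,
    max_phase_rad: float,
    shape: tuple[int, int] = (128, 128),
    pitch_um: float = 0.8625,
    seed: int | None = 0,
) -> ComplexField:
    """Transparent object with smooth random phase in [0, max_phase_rad].

    Band-limited Gaussian noise (white noise smoothed at feature_scale_um)
    is min–max scaled to the requested phase range; amplitude is 1
    everywhere, emulating an unstained, non-absorbing sample.
    """
    if not (0.0 < max_phase_rad <= np.pi):
        raise ValueError(f"max_phase_rad must be in (0, pi], got {max_phase_rad}")
    if feature_scale_um <= pitch_um:
        raise ValueError("feature_scale_um must exceed the pixel pitch")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=feature_scale_um / pitch_um, mode="wrap")
    lo, hi = smooth.min(), smooth.max()
    phase = (smooth - lo) / (hi - lo) * max_phase_rad
    meta = {
        "generator": "phase_object",
        "feature_scale_um": feature_scale_um,
        "max_phase_rad": max_phase_rad,
        "seed": seed,
    }
    return ComplexField(data=np.exp(1j * phase), pixel_pitch_um=pitch_um, meta=meta)
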