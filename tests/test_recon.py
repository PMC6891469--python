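"""Alternating-projection reconstruction: projections, sweeps, consistency."""

import numpy as np
import pytest

from fpmkit.recon import (
    ReconConfig,
    amplitude_replace,
    auto_upsampling_factor,
    extract_subaperture,
    initialize_spectrum,
    reconstruct,
    update_spectrum,
)
from fpmkit.recon import HRSpectrum, _window_origin
from fpmkit.samples import ComplexField, phase_object
from fpmkit.simulate import CameraModel, LRStack, normalize_stack, simulate_stack
from fpmkit.system import (
    LEDArrayGeometry,
    OpticalSystem,
    make_plan,
    pupil_mask,
    wave_vector,
)

NOISELESS = CameraModel(shot_noise=False, read_noise_e=0.0, quantize=False)


def _uniform_stack(value=4.0, n_lr=16):
    imgs = np.full((1, n_lr, n_lr), value)
    md = [{"led_index": (0, 0), "exposure_ms": 100.0, "duty_cycle": 1.0}]
    return LRStack(imgs, md, np.zeros_like(imgs, dtype=bool), normalized=True)


def _smooth_object(n, pitch, seed=1):
    ph = phase_object(12.0, 1.0, shape=(n, n), pitch_um=pitch, seed=seed)
    am = phase_object(15.0, 1.0, shape=(n, n), pitch_um=pitch, seed=seed + 1)
    return ComplexField((0.6 + 0.4 * am.phase) * np.exp(1j * ph.phase), pitch)


def _noiseless_acquisition(geom, max_ring, lr, factor, seed=1):
    sys = OpticalSystem(sensor_shape=(lr, lr))
    obj = _smooth_object(lr * factor, sys.object_pixel_um / factor, seed)
    plan = make_plan(geom, max_ring=max_ring)
    stack = simulate_stack(obj, sys, geom, plan, None, NOISELESS, seed=0,
                           lr_shape=(lr, lr))
    return sys, obj, normalize_stack(stack, NOISELESS)


class TestInitializeSpectrum:
    def test_uniform_image_gives_flat_sqrt_field(self):
        spec = initialize_spectrum(_uniform_stack(4.0), 2, 1.725)
        field = np.fft.ifft2(np.fft.ifftshift(spec.data))
        assert np.allclose(field, 2.0, atol=1e-10)

    def test_hr_grid_sizing(self):
        spec = initialize_spectrum(_uniform_stack(n_lr=16), 3, 1.725)
        assert spec.data.shape == (48, 48)
        assert spec.upsampling_factor == 3

    def test_deterministic(self):
        a = initialize_spectrum(_uniform_stack(), 2, 1.725)
        b = initialize_spectrum(_uniform_stack(), 2, 1.725)
        assert np.array_equal(a.data, b.data)

    def test_missing_onaxis_falls_back_to_mean(self):
        imgs = np.stack([np.full((8, 8), 1.0), np.full((8, 8), 9.0)])
        md = [
            {"led_index": (1, 0), "exposure_ms": 100.0, "duty_cycle": 1.0},
            {"led_index": (0, 1), "exposure_ms": 100.0, "duty_cycle": 1.0},
        ]
        stack = LRStack(imgs, md, np.zeros_like(imgs, dtype=bool), normalized=True)
        spec = initialize_spectrum(stack, 2, 1.725)
        field = np.fft.ifft2(np.fft.ifftshift(spec.data))
        assert np.allclose(field, np.sqrt(5.0), atol=1e-10)  # mean image is 5

    def test_unnormalized_stack_rejected(self):
        stack = _uniform_stack()
        stack.normalized = False
        with pytest.raises(ValueError, match="normalized"):
            initialize_spectrum(stack, 2, 1.725)


class TestWindowIndexing:
    def test_window_origin_matches_hand_computed_indices(self, optics):
        # toy 3-LED geometry: ring-1 wave vector ~0.04246 cycles/um maps to
        # round(0.04246/0.03623) = 1 px on a 16-px LR grid at 1.725 um
        geom = LEDArrayGeometry()
        n_lr, factor = 16, 2
        dk = 1.0 / (n_lr * optics.object_pixel_um)
        # sign convention: LED at +x illuminates the sub-aperture at -fx
        for (m, n), (er, ec) in {(0, 0): (8, 8), (1, 0): (8, 7), (0, -1): (9, 8)}.items():
            f = wave_vector(m, n, geom, optics)
            assert _window_origin(n_lr * factor, n_lr, f, dk) == (er, ec)

    def test_out_of_grid_pupil_raises(self, optics):
        spec = HRSpectrum(np.zeros((32, 32), dtype=complex), 0.03623, (16, 16))
        P = pupil_mask(optics, (16, 16), spec.dk)
        with pytest.raises(ValueError, match="exceeds"):
            extract_subaperture(spec, (20 * spec.dk, 0.0), P)


class TestProjections:
    def _spec_and_pupil(self, seed=0):
        optics = OpticalSystem()
        n_lr, factor = 16, 2
        dk = 1.0 / (n_lr * optics.object_pixel_um)
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        return HRSpectrum(data, dk, (n_lr, n_lr)), pupil_mask(optics, (16, 16), dk), optics

    def test_extract_then_writeback_is_identity(self):
        spec, P, _ = self._spec_and_pupil()
        f = (2 * spec.dk, -1 * spec.dk)
        before = spec.data.copy()
        lr = extract_subaperture(spec, f, P)
        update_spectrum(spec, lr, f, P)
        assert np.allclose(spec.data, before, atol=1e-10)

    def test_update_changes_only_pupil_support(self):
        spec, P, _ = self._spec_and_pupil()
        f = (3 * spec.dk, 0.0)
        before = spec.data.copy()
        update_spectrum(spec, np.ones((16, 16), dtype=complex), f, P)
        changed = spec.data != before
        r0, c0 = _window_origin(32, 16, f, spec.dk)
        support = np.zeros((32, 32), dtype=bool)
        support[r0 : r0 + 16, c0 : c0 + 16] = P.weights > 0
        assert not changed[~support].any()

    def test_double_update_idempotent(self):
        spec, P, _ = self._spec_and_pupil()
        f = (1 * spec.dk, 2 * spec.dk)
        measured = np.abs(extract_subaperture(spec, f, P)) ** 2 * 1.3
        for _ in range(2):
            lr = extract_subaperture(spec, f, P)
            update_spectrum(spec, amplitude_replace(lr, measured), f, P)
            snapshot = spec.data.copy()
        assert np.allclose(spec.data, snapshot, atol=1e-10)

    def test_extraction_is_a_contraction(self):
        spec, P, _ = self._spec_and_pupil()
        n_lr, n_hr = 16, 32
        lr = extract_subaperture(spec, (0.0, 0.0), P)
        win_energy = np.sum(np.abs(np.fft.fft2(lr) / (n_lr / n_hr) ** 2) ** 2)
        assert win_energy <= np.sum(np.abs(spec.data) ** 2) + 1e-9


class TestAmplitudeReplace:
    def test_consistent_measurement_is_fixed_point(self):
        rng = np.random.default_rng(0)
        model = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        out = amplitude_replace(model, np.abs(model) ** 2)
        assert np.allclose(out, model, atol=1e-12)

    def test_amplitude_equals_sqrt_measured(self):
        rng = np.random.default_rng(1)
        model = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        measured = rng.random((8, 8))
        out = amplitude_replace(model, measured)
        assert np.allclose(np.abs(out), np.sqrt(measured), atol=1e-12)

    def test_zero_model_gets_zero_phase(self):
        out = amplitude_replace(np.zeros((4, 4), dtype=complex), np.full((4, 4), 4.0))
        assert np.allclose(out, 2.0)

    def test_saturated_pixels_keep_model(self):
        model = np.full((4, 4), 1 + 1j)
        sat = np.zeros((4, 4), dtype=bool)
        sat[0, 0] = True
        out = amplitude_replace(model, np.full((4, 4), 9.0), sat)
        assert out[0, 0] == 1 + 1j
        assert np.allclose(np.abs(out[~sat]), 3.0)

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            amplitude_replace(np.ones((2, 2), dtype=complex), np.full((2, 2), -1.0))


def _naive_one_sweep(stack, sys, geom, factor):
    """Straight-line re-implementation of initialization plus one raster
    sweep, using nothing but numpy FFTs (no shared helpers)."""
    n_lr = stack.images.shape[1]
    n_hr = n_lr * factor
    pitch = sys.object_pixel_um
    dk = 1.0 / (n_lr * pitch)
    onaxis = next(
        i for i, md in enumerate(stack.metadata) if tuple(md["led_index"]) == (0, 0)
    )
    lr_spec = np.fft.fftshift(np.fft.fft2(np.sqrt(stack.images[onaxis])))
    S = np.zeros((n_hr, n_hr), dtype=complex)
    r = n_hr // 2 - n_lr // 2
    S[r : r + n_lr, r : r + n_lr] = lr_spec * (n_hr / n_lr) ** 2
    k = (np.arange(n_lr) - n_lr // 2) * dk
    P = (k[:, None] ** 2 + k[None, :] ** 2 < (sys.objective_na / sys.wavelength_um) ** 2).astype(float)
    for img, md in zip(stack.images, stack.metadata):
        m, n = md["led_index"]
        x, y = m * geom.pitch_mm, n * geom.pitch_mm
        rr = np.sqrt(x * x + y * y + geom.standoff_mm**2)
        fx, fy = -x / rr / sys.wavelength_um, -y / rr / sys.wavelength_um
        sx, sy = round(fx / dk), round(fy / dk)
        r0, c0 = n_hr // 2 + sy - n_lr // 2, n_hr // 2 + sx - n_lr // 2
        sl = (slice(r0, r0 + n_lr), slice(c0, c0 + n_lr))
        win = S[sl] * P
        lr = np.fft.ifft2(np.fft.ifftshift(win)) * (n_lr / n_hr) ** 2
        upd = np.sqrt(img) * np.exp(1j * np.angle(lr))
        new = np.fft.fftshift(np.fft.fft2(upd)) * (n_hr / n_lr) ** 2
        S[sl] = S[sl] * (1.0 - P) + new * P
    return S


class TestReconstruct:
    def test_one_sweep_matches_straight_line_reimplementation(self, geom):
        sys, obj, norm = _noiseless_acquisition(geom, max_ring=1, lr=16, factor=2)
        cfg = ReconConfig(upsampling_factor=2, max_sweeps=1, update_order="raster")
        result = reconstruct(norm, sys, geom, cfg, sa=None)
        expected = _naive_one_sweep(norm, sys, geom, 2)
        scale = np.abs(expected).max()
        assert np.allclose(result.hr_spectrum.data, expected, atol=1e-9 * scale)

    def test_noiseless_consistency_recovers_object(self, geom):
        # 9x9 LEDs, 64x64 patch, smooth object: forward then inverse should
        # agree to well under 1% complex RMSE after gauge alignment
        from fpmkit.evaluate import rmse_complex

        sys, obj, norm = _noiseless_acquisition(geom, max_ring=4, lr=64, factor=2)
        result = reconstruct(norm, sys, geom, ReconConfig(max_sweeps=10), sa=None)
        assert rmse_complex(result.hr_field, obj) < 1e-2

    def test_trace_decreases_on_noiseless_data(self, geom):
        sys, obj, norm = _noiseless_acquisition(geom, max_ring=2, lr=32, factor=2)
        result = reconstruct(norm, sys, geom, ReconConfig(max_sweeps=6), sa=None)
        assert all(np.isfinite(result.trace))
        assert result.trace[-1] <= result.trace[0]

    def test_support_property_untouched_outside_all_pupils(self, geom):
        sys, obj, norm = _noiseless_acquisition(geom, max_ring=1, lr=16, factor=4)
        cfg = ReconConfig(upsampling_factor=4, max_sweeps=3)
        result = reconstruct(norm, sys, geom, cfg, sa=None)
        # corners of the 64x64 HR grid lie far outside every shifted pupil
        # (initialization there is zero)
        spec = result.hr_spectrum.data
        assert np.all(spec[:8, :8] == 0)
        assert np.all(spec[-8:, -8:] == 0)

    def test_single_led_gives_no_synthetic_aperture(self, geom):
        sys, obj, norm = _noiseless_acquisition(geom, max_ring=0, lr=16, factor=2)
        result = reconstruct(norm, sys, geom, ReconConfig(upsampling_factor=2), sa=None)
        spec = result.hr_spectrum.data
        dk = result.hr_spectrum.dk
        k = (np.arange(32) - 16) * dk
        outside = k[:, None] ** 2 + k[None, :] ** 2 >= sys.pupil_cutoff**2
        init = initialize_spectrum(norm, 2, sys.object_pixel_um)
        assert np.allclose(spec[outside], init.data[outside], atol=1e-12)

    def test_auto_upsampling_respects_synthetic_na(self, geom, optics):
        # rings 0-9: synthetic NA ~0.424 -> HR pitch <= 0.746 um -> factor 3
        assert auto_upsampling_factor(optics, geom, max_ring=9) == 3

    def test_non_finite_input_raises_diagnostic(self, geom):
        sys, obj, norm = _noiseless_acquisition(geom, max_ring=0, lr=16, factor=2)
        norm.images[0, 0, 0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            reconstruct(norm, sys, geom, ReconConfig(max_sweeps=2), sa=None)

    def test_unnormalized_stack_rejected(self, geom):
        sys, obj, norm = _noiseless_acquisition(geom, max_ring=0, lr=16, factor=2)
        norm.normalized = False
        with pytest.raises(ValueError, match="normalize"):
            reconstruct(norm, sys, geom)
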