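"""Talbot relations, gratings, free-space propagation."""

import math

import numpy as np
import pytest
import scipy.fft as fft

from darkfield import (
    SystemGeometry,
    Wavefield,
    apply_analyzer_grating,
    apply_phase_grating,
    apply_source_blur,
    autocorrelation_length,
    make_grid,
    plane_wave,
    propagate,
    talbot_distance,
    wavelength_from_energy,
)


class TestTalbotRelations:
    @pytest.mark.parametrize(
        "energy, expected_nm",
        [(27.7, 0.044759), (64.5, 0.019223), (1.23984193, 1.0)],
    )
    def test_wavelength_from_energy(self, energy, expected_nm):
        assert wavelength_from_energy(energy) * 1e9 == pytest.approx(expected_nm, abs=5e-6)

    def test_wavelength_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            wavelength_from_energy(0.0)

    @pytest.mark.parametrize(
        "energy, expected_cm", [(27.7, 4.47), (64.5, 10.4)]
    )
    def test_first_talbot_distance_matches_instrument_settings(self, energy, expected_cm):
        d = talbot_distance(2.000e-6, wavelength_from_energy(energy), 1)
        assert round(d * 100, 2 if expected_cm < 10 else 1) == expected_cm

    def test_even_order_rejected(self):
        with pytest.raises(ValueError):
            talbot_distance(2e-6, 4.5e-11, 2)

    def test_distance_linear_in_order(self):
        lam = wavelength_from_energy(27.7)
        assert talbot_distance(2e-6, lam, 3) == pytest.approx(
            3 * talbot_distance(2e-6, lam, 1), rel=1e-12
        )

    @pytest.mark.parametrize("energy", [27.7, 64.5])
    def test_autocorrelation_length_one_micron_at_first_order(self, energy):
        """d_auto = lambda d / p2 = m p2 / 2 at the Talbot distance: energy
        invariant, about 1 um for p2 = 2 um."""
        lam = wavelength_from_energy(energy)
        d = talbot_distance(2e-6, lam, 1)
        assert autocorrelation_length(lam, d, 2e-6) == pytest.approx(1e-6, rel=1e-9)

    def test_autocorrelation_linear_in_distance(self):
        assert autocorrelation_length(4.5e-11, 0.08, 2e-6) == pytest.approx(
            2 * autocorrelation_length(4.5e-11, 0.04, 2e-6), rel=1e-12
        )


class TestSystemGeometry:
    def test_distance_defaults_to_talbot(self):
        g = SystemGeometry(design_energy_kev=27.7)
        assert g.distance == pytest.approx(
            talbot_distance(g.p2, g.wavelength, 1), rel=1e-12
        )
        assert g.autocorrelation_length == pytest.approx(1e-6, rel=1e-9)

    def test_distance_override(self):
        g = SystemGeometry(distance_d=0.05)
        assert g.distance == 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fine_sampling": 4},
            {"talbot_order": 2},
            {"p1": 5.0e-6},
            {"guard_periods": 4},
            {"pixel_pitch": 100.1e-6},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SystemGeometry(**kwargs)

    def test_grid_covers_field_of_view_plus_guard(self):
        g = SystemGeometry(field_of_view=(2, 2), fine_sampling=8)
        grid = make_grid(g)
        assert grid.fov_nx == 2 * g.samples_per_pixel
        assert grid.guard_x * grid.spacing >= 32 * g.p2
        assert grid.nx >= grid.fov_nx + 2 * 32 * g.fine_sampling


def _small_grid():
    g = SystemGeometry(field_of_view=(1, 1), fine_sampling=8, pixel_pitch=96e-6)
    return g, make_grid(g)


class TestGratings:
    def test_phase_grating_preserves_magnitude(self):
        g, grid = _small_grid()
        psi = apply_phase_grating(plane_wave(grid), g.p1)
        np.testing.assert_allclose(np.abs(psi.amplitude), 1.0, rtol=1e-12)

    def test_zero_phase_shift_is_identity(self):
        g, grid = _small_grid()
        field = plane_wave(grid)
        out = apply_phase_grating(field, g.p1, phase_shift=0.0)
        np.testing.assert_array_equal(out.amplitude, field.amplitude)

    def test_analyzer_transparent_bars_no_effect(self):
        g, grid = _small_grid()
        field = plane_wave(grid)
        out = apply_analyzer_grating(field, g.p2, 0.3e-6, bar_transmission=1.0)
        np.testing.assert_allclose(out, field.intensity, rtol=1e-12)

    def test_analyzer_half_duty_passes_half(self):
        # an exact whole number of p2 periods across the grid
        field = Wavefield(np.ones((4, 1024), dtype=complex), 0.25e-6)
        out = apply_analyzer_grating(field, 2e-6, 0.0, duty_cycle=0.5)
        assert out.mean() == pytest.approx(0.5, abs=1e-9)

    def test_analyzer_periodic_in_step(self):
        g, grid = _small_grid()
        field = plane_wave(grid)
        a = apply_analyzer_grating(field, g.p2, 0.7e-6)
        b = apply_analyzer_grating(field, g.p2, 0.7e-6 + g.p2)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestPropagation:
    def test_zero_distance_identity(self):
        _, grid = _small_grid()
        field = plane_wave(grid)
        out = propagate(field, 0.0, 4.5e-11)
        np.testing.assert_array_equal(out.amplitude, field.amplitude)

    def test_plane_wave_invariant(self):
        _, grid = _small_grid()
        out = propagate(plane_wave(grid), 0.05, 4.5e-11)
        np.testing.assert_allclose(np.abs(out.amplitude), 1.0, atol=1e-10)

    def test_energy_conserved(self):
        g, grid = _small_grid()
        rng = np.random.default_rng(0)
        amp = np.exp(1j * rng.uniform(0, 2 * np.pi, (grid.ny, grid.nx)))
        field = Wavefield(amp, grid.spacing)
        out = propagate(field, 0.12, 4.5e-11)
        assert out.total_intensity() == pytest.approx(field.total_intensity(), rel=1e-10)

    def test_self_image_period_is_half_grating_pitch(self):
        """A pi grating at the first fractional Talbot distance forms an
        intensity fringe of period p1/2."""
        g, grid = _small_grid()
        lam = g.wavelength
        psi = apply_phase_grating(plane_wave(grid), g.p1)
        psi = propagate(psi, talbot_distance(g.p1 / 2, lam, 1), lam)
        profile = psi.intensity[0]
        spectrum = np.abs(fft.rfft(profile - profile.mean()))
        freqs = fft.rfftfreq(profile.size, d=grid.spacing)
        dominant = freqs[np.argmax(spectrum)]
        assert dominant == pytest.approx(2.0 / g.p1, rel=0.02)

    def test_talbot_revival_of_sinusoidal_phase_grating(self):
        """Any periodic field self-images after the full Talbot length
        2 p^2 / lambda (grid chosen commensurate with the period)."""
        lam = 4.476e-11
        p = 4e-6
        spacing = 0.25e-6
        x = np.arange(1024) * spacing  # 64 whole periods
        amp = np.exp(0.7j * np.sin(2 * np.pi * x / p))[np.newaxis, :] * np.ones((4, 1))
        field = Wavefield(amp, spacing)
        out = propagate(field, 2 * p * p / lam, lam)
        # global phase factored out before comparison
        phase = np.vdot(out.amplitude, field.amplitude)
        phase /= abs(phase)
        np.testing.assert_allclose(out.amplitude * phase, field.amplitude, atol=1e-7)


class TestSourceBlur:
    def test_zero_width_identity(self):
        _, grid = _small_grid()
        field = plane_wave(grid)
        out = apply_source_blur(field, 0.0)
        np.testing.assert_array_equal(out.amplitude, field.amplitude)

    def test_uniform_field_unchanged(self):
        _, grid = _small_grid()
        out = apply_source_blur(plane_wave(grid), 1e-6)
        np.testing.assert_allclose(out.amplitude, 1.0, atol=1e-12)

    def test_sinusoid_damped_by_gaussian_transform(self):
        """First harmonic of a period-p2 sinusoid is damped by
        exp(-2 pi^2 sigma^2 / p2^2)."""
        p2 = 2e-6
        sigma = 0.6e-6
        spacing = 0.25e-6
        x = np.arange(1024) * spacing  # 128 whole periods
        eps = 0.01
        amp = (1.0 + eps * np.cos(2 * np.pi * x / p2))[np.newaxis, :] * np.ones((4, 1))
        out = apply_source_blur(Wavefield(amp, spacing), sigma)
        carrier = np.exp(-2j * np.pi * x / p2)
        h_in = np.abs((amp[0] * carrier).mean())
        h_out = np.abs((out.amplitude[0] * carrier).mean())
        expected = math.exp(-2 * math.pi**2 * sigma**2 / p2**2)
        assert h_out / h_in == pytest.approx(expected, rel=1e-6)
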