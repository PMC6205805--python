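"""Monochromatic wave optics for a symmetric Talbot grating interferometer.

The interferometer is modelled in the projection / paraxial regime: a unit
plane wave traverses the object and the pi-phase grating G1, propagates in
free space to the absorption grating G2 (angular-spectrum propagator), and
the transmitted intensity is recorded while G2 is stepped laterally.

Everything here is strictly deterministic; units are SI (metres, radians)
throughout.  Gratings vary along the last array axis (x); the first axis (y)
carries the two-dimensional phantom statistics and may have length one for a
fast quasi-1-D computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as _fft

__all__ = [
    "HC_KEV_NM",
    "SystemGeometry",
    "SimulationGrid",
    "Wavefield",
    "wavelength_from_energy",
    "talbot_distance",
    "autocorrelation_length",
    "make_grid",
    "plane_wave",
    "apply_phase_grating",
    "propagate",
    "apply_source_blur",
    "apply_analyzer_grating",
]

#: Planck constant times speed of light, in keV * nm.
HC_KEV_NM = 1.23984193


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength (m) for a photon energy in keV, lambda = hc/E."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_NM / energy_kev * 1e-9


def talbot_distance(p2: float, wavelength: float, m: int = 1) -> float:
    """First (or m-th odd) fractional Talbot distance of a pi-phase grating.

    For a pi-shifting phase grating of pitch ``p1 = 2*p2`` the self-image of
    period ``p1/2`` appears at ``d = m * p1**2 / (8*lambda) = m * p2**2 /
    (2*lambda)`` for odd ``m``.  ``p2`` is the fringe / analyzer pitch.
    """
    if p2 <= 0 or wavelength <= 0:
        raise ValueError("p2 and wavelength must be positive")
    m = int(m)
    if m < 1 or m % 2 == 0:
        raise ValueError(f"Talbot order m must be an odd positive integer, got {m}")
    return m * p2 * p2 / (2.0 * wavelength)


def autocorrelation_length(wavelength: float, distance_d: float, p2: float) -> float:
    """Autocorrelation length d_auto = lambda * d / p2.

    This is the structural length scale the interferometer is most sensitive
    to; at the m-th Talbot distance it reduces to m * p2 / 2.
    """
    if wavelength <= 0 or distance_d <= 0 or p2 <= 0:
        raise ValueError("all arguments must be positive")
    return wavelength * distance_d / p2


@dataclass(frozen=True)
class SystemGeometry:
    """Geometry of the grating interferometer and the detector sampling.

    Parameters
    ----------
    p1, p2 : float
        Pitches of the phase grating G1 and the analyzer grating G2 (m).
        ``p1`` must be within 5% of ``2*p2``.  The default G1 pitch is the
        plane-wave equivalent ``2*p2`` = 4.000 um, whose self-image period
        matches the analyzer exactly; the physical pitch of a diverging-beam
        instrument (e.g. 3.901 um, magnified onto the analyzer in reality)
        may be set explicitly, at the price of a moire between self-image
        and analyzer.
    design_energy_kev : float
        Photon energy of the monochromatic design wave (keV).
    talbot_order : int
        Odd fractional Talbot order m of the G1-G2 spacing.
    pixel_pitch : float
        Detector pixel size (m); must be commensurate with the fine grid.
    field_of_view : (int, int)
        Detector field of view in pixels, (nx, ny).
    fine_sampling : int
        Fine wave samples per ``p2`` period (>= 8).
    distance_d : float or None
        G1-to-G2 distance (m).  ``None`` resolves to the Talbot distance.
    guard_periods : int
        Periodic guard band on each side of the field of view, in units of
        ``p2`` periods (>= 32); cropped away before pixel binning.
    g1_duty, g2_duty : float
        Duty cycles of the rectangular grating profiles.
    g1_phase : float
        Phase shift imparted by the G1 lamellae (radians), pi by design.
    g2_bar_transmission : float
        Intensity transmission of the G2 bars (0 = ideal absorber).
    """

    p1: float = 4.000e-6
    p2: float = 2.000e-6
    design_energy_kev: float = 27.7
    talbot_order: int = 1
    pixel_pitch: float = 100e-6
    field_of_view: tuple[int, int] = (5, 5)
    fine_sampling: int = 16
    distance_d: float | None = None
    guard_periods: int = 32
    g1_duty: float = 0.5
    g2_duty: float = 0.5
    g1_phase: float = math.pi
    g2_bar_transmission: float = 0.0

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0:
            raise ValueError("grating pitches must be positive")
        if abs(self.p1 - 2.0 * self.p2) > 0.05 * 2.0 * self.p2:
            raise ValueError(
                f"p1 = {self.p1} must be within 5% of 2*p2 = {2 * self.p2}"
            )
        m = int(self.talbot_order)
        if m < 1 or m % 2 == 0:
            raise ValueError(f"talbot_order must be odd and >= 1, got {m}")
        if self.fine_sampling < 8:
            raise ValueError(
                f"fine_sampling must be >= 8 samples per p2 period, "
                f"got {self.fine_sampling}"
            )
        if self.guard_periods < 32:
            raise ValueError("guard_periods must be >= 32")
        nx, ny = self.field_of_view
        if nx < 1 or ny < 1:
            raise ValueError("field_of_view must be at least 1x1 pixels")
        ratio = self.pixel_pitch / self.grid_spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "pixel_pitch must be an integer multiple of the fine grid "
                f"spacing p2/fine_sampling (ratio {ratio})"
            )
        if not 0.0 <= self.g2_bar_transmission <= 1.0:
            raise ValueError("g2_bar_transmission must lie in [0, 1]")

    # -- derived quantities -------------------------------------------------

    @property
    def wavelength(self) -> float:
        return wavelength_from_energy(self.design_energy_kev)

    @property
    def distance(self) -> float:
        """Resolved G1-to-G2 distance (explicit override or Talbot distance)."""
        if self.distance_d is not None:
            return self.distance_d
        return talbot_distance(self.p2, self.wavelength, self.talbot_order)

    @property
    def grid_spacing(self) -> float:
        return self.p2 / self.fine_sampling

    @property
    def autocorrelation_length(self) -> float:
        return autocorrelation_length(self.wavelength, self.distance, self.p2)

    @property
    def samples_per_pixel(self) -> int:
        return int(round(self.pixel_pitch / self.grid_spacing))

    def with_field_of_view(self, nx: int, ny: int) -> "SystemGeometry":
        return replace(self, field_of_view=(int(nx), int(ny)))


@dataclass(frozen=True)
class SimulationGrid:
    """Padded fine sampling grid of one acquisition.

    ``nx, ny`` include the periodic guard bands; ``crop_x, crop_y`` index the
    central field-of-view region.
    """

    nx: int
    ny: int
    spacing: float
    guard_x: int
    guard_y: int
    fov_nx: int
    fov_ny: int

    @property
    def crop_x(self) -> slice:
        return slice(self.guard_x, self.guard_x + self.fov_nx)

    @property
    def crop_y(self) -> slice:
        return slice(self.guard_y, self.guard_y + self.fov_ny)

    @property
    def extent_x(self) -> float:
        return self.nx * self.spacing

    @property
    def extent_y(self) -> float:
        return self.ny * self.spacing

    def x_coords(self) -> np.ndarray:
        return np.arange(self.nx) * self.spacing

    def y_coords(self) -> np.ndarray:
        return np.arange(self.ny) * self.spacing


def make_grid(geometry: SystemGeometry) -> SimulationGrid:
    """Build the padded fine grid for ``geometry``.

    The guard band is at least ``guard_periods * p2`` on each side and is
    widened so that the padded length is an FFT-friendly size.
    """
    spp = geometry.samples_per_pixel
    fov_nx = spp * geometry.field_of_view[0]
    fov_ny = spp * geometry.field_of_view[1]
    guard = int(math.ceil(geometry.guard_periods * geometry.p2 / geometry.grid_spacing))

    def _pad(n_fov: int) -> tuple[int, int]:
        n = _fft.next_fast_len(n_fov + 2 * guard, real=False)
        return n, (n - n_fov) // 2

    nx, gx = _pad(fov_nx)
    ny, gy = _pad(fov_ny)
    return SimulationGrid(
        nx=nx, ny=ny, spacing=geometry.grid_spacing,
        guard_x=gx, guard_y=gy, fov_nx=fov_nx, fov_ny=fov_ny,
    )


@dataclass
class Wavefield:
    """Complex scalar amplitude on the fine transverse grid (y, x order)."""

    amplitude: np.ndarray
    grid_spacing: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.complex128)
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude must be a 2-D array (y, x)")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    def total_intensity(self) -> float:
        return float(np.sum(self.intensity))


def plane_wave(grid: SimulationGrid) -> Wavefield:
    """Unit-amplitude plane wave psi_0 = 1 on the padded grid."""
    return Wavefield(np.ones((grid.ny, grid.nx), dtype=np.complex128), grid.spacing)


def _pulse_train(x: np.ndarray, period: float, duty: float, shift: float = 0.0) -> np.ndarray:
    """Rectangular pulse train: 1 inside the open fraction of each period.

    A relative epsilon snaps samples landing (up to rounding) exactly on an
    edge, so commensurate grids classify edges consistently at every step.
    """
    frac = np.mod((x - shift) / period + 1e-9, 1.0)
    return (frac < duty).astype(np.float64)


def apply_phase_grating(
    field: Wavefield,
    p1: float,
    duty_cycle: float = 0.5,
    phase_shift: float = math.pi,
) -> Wavefield:
    """Multiply by the G1 phase profile exp(i * phase_shift * Pi(x)).

    A pure phase element: the amplitude magnitude is unchanged.
    """
    x = np.arange(field.amplitude.shape[1]) * field.grid_spacing
    train = _pulse_train(x, p1, duty_cycle)
    factor = np.exp(1j * phase_shift * train)
    return Wavefield(field.amplitude * factor[np.newaxis, :], field.grid_spacing)


def propagate(field: Wavefield, distance: float, wavelength: float) -> Wavefield:
    """Free-space propagation by the angular-spectrum (Fresnel) propagator.

    The spectrum is multiplied by ``exp(-i * pi * d * lambda * (u^2 + v^2))``
    under periodic boundary conditions; total intensity is conserved.
    """
    if distance < 0:
        raise ValueError("propagation distance must be >= 0")
    if distance == 0:
        return Wavefield(field.amplitude.copy(), field.grid_spacing)
    ny, nx = field.amplitude.shape
    u = _fft.fftfreq(nx, d=field.grid_spacing)
    v = _fft.fftfreq(ny, d=field.grid_spacing)
    chirp_u = np.exp(-1j * math.pi * distance * wavelength * u * u)
    chirp_v = np.exp(-1j * math.pi * distance * wavelength * v * v)
    spectrum = _fft.fft2(field.amplitude)
    spectrum *= chirp_u[np.newaxis, :]
    spectrum *= chirp_v[:, np.newaxis]
    return Wavefield(_fft.ifft2(spectrum), field.grid_spacing)


def apply_source_blur(field: Wavefield, aperture_width: float) -> Wavefield:
    """Convolve the complex amplitude with a Gaussian of std ``aperture_width``.

    Models the finite G0 source apertures; acts on the amplitude (not the
    intensity), as a Fourier-domain multiplication by the Gaussian transform
    ``exp(-2 * pi^2 * sigma^2 * f^2)``.  Width 0 is the identity.
    """
    if aperture_width < 0:
        raise ValueError("aperture_width must be >= 0")
    if aperture_width == 0:
        return Wavefield(field.amplitude.copy(), field.grid_spacing)
    ny, nx = field.amplitude.shape
    u = _fft.fftfreq(nx, d=field.grid_spacing)
    v = _fft.fftfreq(ny, d=field.grid_spacing)
    s2 = 2.0 * math.pi**2 * aperture_width**2
    gu = np.exp(-s2 * u * u)
    gv = np.exp(-s2 * v * v)
    spectrum = _fft.fft2(field.amplitude)
    spectrum *= gu[np.newaxis, :]
    spectrum *= gv[:, np.newaxis]
    return Wavefield(_fft.ifft2(spectrum), field.grid_spacing)


def apply_analyzer_grating(
    field: Wavefield,
    p2: float,
    step_position: float,
    duty_cycle: float = 0.5,
    bar_transmission: float = 0.0,
) -> np.ndarray:
    """Intensity behind the stepped absorption grating G2.

    Returns ``|psi|^2`` multiplied by the shifted rectangular transmission
    train: open slits transmit 1, bars transmit ``bar_transmission``.
    """
    if not 0.0 <= bar_transmission <= 1.0:
        raise ValueError("bar_transmission must lie in [0, 1]")
    x = np.arange(field.amplitude.shape[1]) * field.grid_spacing
    train = _pulse_train(x, p2, duty_cycle, shift=step_position)
    transmission = bar_transmission + (1.0 - bar_transmission) * train
    return field.intensity * transmission[np.newaxis, :]
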