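"""Phase-stepping acquisition and Fourier retrieval of the GI images.

The analyzer grating G2 is stepped through one fringe period while frames
are recorded; per pixel, the stepping curve is analysed by a discrete
Fourier transform.  The mean (a0), first-harmonic amplitude (a1) and phase
(phi) give the transmission, differential-phase and dark-field images:

    transmission = a0_obj / a0_ref
    dark_field   = v_obj / v_ref        with visibility v = 2 * a1 / a0
    diff. phase  = wrap(phi_obj - phi_ref)  in (-pi, pi]

The expensive wave propagation is independent of the G2 step, so one
propagated field is reused for the whole stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import optics as _optics
from .detector import DetectorModel, add_noise, apply_system_blur, bin_to_pixels, scale_exposure
from .optics import SimulationGrid, SystemGeometry, Wavefield
from .phantom import (
    MaterialOptics,
    SpherePack,
    object_transmission,
    project_air_path,
    project_chord_sum,
)

__all__ = [
    "PhaseStepStack",
    "GIImages",
    "FringeComponents",
    "propagate_to_analyzer",
    "step_and_detect",
    "acquire_stack",
    "fourier_retrieve",
    "visibility",
    "compute_gi_images",
]


@dataclass
class PhaseStepStack:
    """Ordered phase-stepping frames over exactly one G2 period."""

    frames: np.ndarray  # (n_steps, ny_pix, nx_pix)
    step_positions: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.step_positions = np.asarray(self.step_positions, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_steps, ny, nx) array")
        n = self.frames.shape[0]
        if n < 3:
            raise ValueError(f"phase stepping needs at least 3 steps, got {n}")
        if self.step_positions.shape != (n,):
            raise ValueError("one step position per frame is required")
        expected = np.arange(n) * self.period / n
        if not np.allclose(self.step_positions, expected, atol=1e-12 * self.period):
            raise ValueError("step positions must uniformly span one period [0, p2)")

    @property
    def n_steps(self) -> int:
        return self.frames.shape[0]


@dataclass
class GIImages:
    """Per-pixel transmission, differential phase and dark-field images."""

    transmission: np.ndarray
    differential_phase: np.ndarray
    dark_field: np.ndarray
    reference_visibility: np.ndarray
    object_visibility: np.ndarray

    @property
    def mean_dark_field(self) -> float:
        """Plain arithmetic mean of pixel dark-field values over the field of view."""
        return float(self.dark_field.mean())


class FringeComponents(NamedTuple):
    a0: np.ndarray
    a1: np.ndarray
    phi: np.ndarray


def propagate_to_analyzer(
    geometry: SystemGeometry,
    pack: SpherePack | None = None,
    tissue: MaterialOptics | None = None,
    air: MaterialOptics | None = None,
    grid: SimulationGrid | None = None,
    projection: str = "additive",
) -> Wavefield:
    """Unit plane wave -> object -> G1 -> free space to the G2 plane.

    With ``pack`` None the undisturbed reference field is returned.  This is
    the step-independent (and expensive) part of an acquisition.
    ``projection`` selects the phantom projection semantics: ``"additive"``
    (each sphere an independent scatterer, the lung-study default) or
    ``"union"`` (exact merged air path).
    """
    if grid is None:
        grid = _optics.make_grid(geometry)
    psi = _optics.plane_wave(grid)
    if pack is not None:
        if tissue is None or air is None:
            raise ValueError("tissue and air optical constants are required with a phantom")
        if projection == "additive":
            projected = project_chord_sum(pack, grid.spacing, (grid.ny, grid.nx))
        elif projection == "union":
            projected = project_air_path(pack, grid.spacing, (grid.ny, grid.nx))
        else:
            raise ValueError(f"unknown projection {projection!r}")
        psi = Wavefield(
            psi.amplitude * object_transmission(projected, tissue, air, geometry.wavelength),
            grid.spacing,
        )
    psi = _optics.apply_phase_grating(psi, geometry.p1, geometry.g1_duty, geometry.g1_phase)
    return _optics.propagate(psi, geometry.distance, geometry.wavelength)


def step_and_detect(
    psi: Wavefield,
    geometry: SystemGeometry,
    detector: DetectorModel,
    grid: SimulationGrid | None = None,
    n_steps: int = 8,
    noise_seed: int = 0,
    reference_mean: float | None = None,
    source_aperture: float = 0.0,
) -> PhaseStepStack:
    """Step G2 over one period and run the detector chain per frame."""
    if n_steps < 3:
        raise ValueError(f"phase stepping needs at least 3 steps, got {n_steps}")
    if grid is None:
        grid = _optics.make_grid(geometry)
    if source_aperture > 0:
        psi = _optics.apply_source_blur(psi, source_aperture)
    steps = np.arange(n_steps) * geometry.p2 / n_steps
    frames = []
    ref_mean = reference_mean
    raw_frames = []
    for step in steps:
        fine = _optics.apply_analyzer_grating(
            psi, geometry.p2, step, geometry.g2_duty, geometry.g2_bar_transmission
        )
        fine = fine[grid.crop_y, grid.crop_x]
        raw_frames.append(bin_to_pixels(fine, geometry.pixel_pitch, grid.spacing, step))
    if ref_mean is None:
        ref_mean = float(np.mean([im.values.mean() for im in raw_frames]))
    for k, image in enumerate(raw_frames):
        image = scale_exposure(image, detector.eak, detector.exposure_calibration, ref_mean)
        image = apply_system_blur(image, detector)
        image = add_noise(image, detector, seed=noise_seed + k)
        frames.append(image.values)
    return PhaseStepStack(np.stack(frames), steps, geometry.p2)


def acquire_stack(
    geometry: SystemGeometry,
    pack: SpherePack | None,
    detector: DetectorModel,
    tissue: MaterialOptics | None = None,
    air: MaterialOptics | None = None,
    n_steps: int = 8,
    seed: int = 0,
    reference_mean: float | None = None,
    projection: str = "additive",
) -> PhaseStepStack:
    """Full acquisition: propagation plus stepped detection.

    ``pack=None`` produces the reference stack.  ``reference_mean`` carries
    the exposure normalization of a previously acquired reference stack; by
    default the stack is normalized to its own mean raw intensity.
    """
    grid = _optics.make_grid(geometry)
    psi = propagate_to_analyzer(geometry, pack, tissue, air, grid=grid,
                                projection=projection)
    return step_and_detect(
        psi, geometry, detector, grid=grid, n_steps=n_steps,
        noise_seed=seed, reference_mean=reference_mean,
    )


def fourier_retrieve(stack: PhaseStepStack) -> FringeComponents:
    """Per-pixel DFT of the stepping curve: mean, first harmonic, phase.

    For frames I_k = a0 * (1 + v * cos(2*pi*k/N + phi)) this returns exactly
    (a0, a0*v/2, phi); visibility is ``2 * a1 / a0``.
    """
    spectrum = np.fft.rfft(stack.frames, axis=0)
    n = stack.n_steps
    a0 = spectrum[0].real / n
    if np.any(a0 == 0):
        raise ValueError("degenerate pixel with zero mean intensity")
    a1 = np.abs(spectrum[1]) / n
    phi = np.angle(spectrum[1])
    return FringeComponents(a0=a0, a1=a1, phi=phi)


def visibility(stack: PhaseStepStack) -> np.ndarray:
    a0, a1, _ = fourier_retrieve(stack)
    return 2.0 * a1 / a0


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    wrapped = np.mod(phi + math.pi, 2.0 * math.pi) - math.pi
    return np.where(wrapped == -math.pi, math.pi, wrapped)


def compute_gi_images(
    object_stack: PhaseStepStack,
    reference_stack: PhaseStepStack,
) -> GIImages:
    """Transmission, differential-phase and dark-field images from two stacks."""
    if object_stack.frames.shape != reference_stack.frames.shape:
        raise ValueError("object and reference stacks must share shape and step grid")
    if not np.allclose(object_stack.step_positions, reference_stack.step_positions):
        raise ValueError("object and reference stacks must share the step grid")
    a0_o, a1_o, phi_o = fourier_retrieve(object_stack)
    a0_r, a1_r, phi_r = fourier_retrieve(reference_stack)
    v_ref = 2.0 * a1_r / a0_r
    if np.any(v_ref == 0):
        raise ValueError("reference visibility vanishes: no carrier fringe")
    v_obj = 2.0 * a1_o / a0_o
    return GIImages(
        transmission=a0_o / a0_r,
        differential_phase=_wrap_phase(phi_o - phi_r),
        dark_field=v_obj / v_ref,
        reference_visibility=v_ref,
        object_visibility=v_obj,
    )
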