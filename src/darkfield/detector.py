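"""Detector chain: pixel integration, exposure scaling, blur and noise.

The fine-grid intensity behind G2 is integrated over each pixel footprint,
scaled to realistic pixel values through a linear exposure calibration
(pixel value per unit entrance air kerma, EAK), blurred by the presampling
MTF and a Gaussian focal-spot kernel, and finally corrupted by noise whose
texture follows a measured noise power spectrum (NPS) and whose magnitude
follows Poisson scaling (sigma = sqrt(intensity)).

The default detector is ideal: MTF identically 1, flat NPS, zero focal-spot
blur and noise disabled.  Measured MTF/NPS curves are opt-in and are loaded
from two-column text files (spatial frequency in cycles/mm, value); no
estimation from raw edge or flat-field images is performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft as _fft

__all__ = [
    "DetectorCurve",
    "DetectorModel",
    "PixelImage",
    "load_mtf",
    "load_nps",
    "bin_to_pixels",
    "scale_exposure",
    "apply_system_blur",
    "add_noise",
]


@dataclass(frozen=True)
class DetectorCurve:
    """Tabulated radially-symmetric curve vs spatial frequency.

    Frequencies are stored in cycles/m; evaluation interpolates linearly and
    clamps beyond the last tabulated point.
    """

    frequencies: np.ndarray
    values: np.ndarray
    kind: str = "mtf"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if f.ndim != 1 or f.shape != v.shape or f.size < 2:
            raise ValueError("curve needs two same-length 1-D columns with >= 2 rows")
        if f[0] < 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency axis must be non-negative and strictly increasing")
        if np.any(v < 0):
            raise ValueError("curve values must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)
        if self.kind == "mtf":
            if f[0] != 0:
                raise ValueError("an MTF curve must be tabulated from frequency 0")
            if v[0] <= 0:
                raise ValueError("MTF at zero frequency must be positive")
            if v[0] != 1.0:  # normalize so MTF(0) = 1
                object.__setattr__(self, "values", v / v[0])

    @classmethod
    def from_file(cls, path, kind: str = "mtf") -> "DetectorCurve":
        """Load a two-column text file (frequency in cycles/mm, value)."""
        table = np.atleast_2d(np.loadtxt(path))
        if table.size == 0 or table.shape[1] < 2:
            raise ValueError(f"{path}: expected a two-column frequency/value table")
        return cls(frequencies=table[:, 0] * 1e3, values=table[:, 1], kind=kind)

    def __call__(self, frequency: np.ndarray) -> np.ndarray:
        return np.interp(np.abs(frequency), self.frequencies, self.values)


def load_mtf(path) -> DetectorCurve:
    return DetectorCurve.from_file(path, kind="mtf")


def load_nps(path) -> DetectorCurve:
    return DetectorCurve.from_file(path, kind="nps")


@dataclass(frozen=True)
class DetectorModel:
    """Detector response model; defaults describe an ideal noiseless detector."""

    pixel_pitch: float = 100e-6
    mtf: DetectorCurve | None = None
    nps: DetectorCurve | None = None
    exposure_calibration: float = 1.0  # pixel value per mGy EAK
    focal_spot_sigma: float = 0.0
    noise_enabled: bool = False
    eak: float = 1e3  # entrance air kerma per frame, mGy

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.exposure_calibration <= 0:
            raise ValueError("exposure_calibration must be positive")
        if self.focal_spot_sigma < 0:
            raise ValueError("focal_spot_sigma must be >= 0")
        if self.eak < 0:
            raise ValueError("eak must be >= 0")

    @property
    def is_ideal_blur(self) -> bool:
        return self.mtf is None and self.focal_spot_sigma == 0.0

    @classmethod
    def ideal(cls, pixel_pitch: float = 100e-6) -> "DetectorModel":
        return cls(pixel_pitch=pixel_pitch)


@dataclass
class PixelImage:
    """2-D image at detector pixel pitch, tagged with its G2 step position."""

    values: np.ndarray
    step_position: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")


def bin_to_pixels(
    intensity: np.ndarray,
    pixel_pitch: float,
    grid_spacing: float,
    step_position: float = 0.0,
) -> PixelImage:
    """Sum fine samples within each pixel footprint (intensity conserving)."""
    ratio = pixel_pitch / grid_spacing
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"pixel_pitch must be an integer multiple of grid_spacing (ratio {ratio})"
        )
    ny, nx = intensity.shape
    if ny % k or nx % k:
        raise ValueError("intensity shape must be divisible by samples per pixel")
    binned = intensity.reshape(ny // k, k, nx // k, k).sum(axis=(1, 3))
    return PixelImage(binned, step_position)


def scale_exposure(
    image: PixelImage,
    eak: float,
    calibration: float,
    reference_mean: float = 1.0,
) -> PixelImage:
    """Linear pixel-value scaling S_PV = calibration * EAK.

    ``reference_mean`` is the mean raw pixel intensity of the no-object
    reference acquisition; dividing by it normalizes the scaling to the
    integrated intensity of the reference wave.
    """
    if eak < 0:
        raise ValueError("eak must be >= 0")
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    factor = calibration * eak / reference_mean
    return PixelImage(image.values * factor, image.step_position)


def apply_system_blur(image: PixelImage, model: DetectorModel) -> PixelImage:
    """Fourier-domain MTF and focal-spot blur; preserves the image mean."""
    if model.is_ideal_blur:
        return PixelImage(image.values.copy(), image.step_position)
    if model.mtf is not None and not math.isclose(float(model.mtf(0.0)), 1.0):
        raise ValueError("MTF must equal 1 at zero frequency")
    ny, nx = image.values.shape
    u = _fft.fftfreq(nx, d=model.pixel_pitch)
    v = _fft.fftfreq(ny, d=model.pixel_pitch)
    f = np.hypot(u[np.newaxis, :], v[:, np.newaxis])
    filt = np.ones_like(f)
    if model.mtf is not None:
        filt = filt * model.mtf(f)
    if model.focal_spot_sigma > 0:
        filt = filt * np.exp(-2.0 * math.pi**2 * model.focal_spot_sigma**2 * f * f)
    blurred = _fft.ifft2(_fft.fft2(image.values) * filt).real
    return PixelImage(blurred, image.step_position)


def add_noise(image: PixelImage, model: DetectorModel, seed: int) -> PixelImage:
    """Add NPS-textured, Poisson-scaled noise (bit-identical pass-through when off).

    A unit-variance Gaussian field R is filtered in Fourier space by the
    square root of the NPS, rescaled to unit empirical standard deviation,
    multiplied pointwise by sqrt(intensity), and added.
    """
    if not model.noise_enabled:
        return image
    values = image.values
    if values.min() < 0:
        raise ValueError("pixel values must be non-negative before adding noise")
    rng = np.random.default_rng(seed)
    r = rng.standard_normal(values.shape)
    if model.nps is not None:
        ny, nx = values.shape
        u = _fft.fftfreq(nx, d=model.pixel_pitch)
        v = _fft.fftfreq(ny, d=model.pixel_pitch)
        f = np.hypot(u[np.newaxis, :], v[:, np.newaxis])
        r = _fft.ifft2(_fft.fft2(r) * np.sqrt(model.nps(f))).real
    sigma_n = r.std()
    if sigma_n == 0:
        raise ValueError("degenerate NPS: filtered noise field has zero variance")
    noisy = values + (r / sigma_n) * np.sqrt(values)
    return PixelImage(noisy, image.step_position)
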