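"""Thickness-series experiments and the linear diffusion coefficient.

At fixed interferometer geometry the dark-field signal of a statistically
homogeneous scatterer decays exponentially with traversed thickness t:

    -log(df) = (2 * pi**2 * d**2 / p2**2) * epsilon * t

where epsilon is the material's linear diffusion coefficient.  This module
orchestrates simulated thickness series (fresh random sphere pack per
repetition), fits epsilon by least squares through the origin, and provides
the forward prediction and the single-ROI inversion of the same relation.

Internally everything is SI (epsilon in 1/m); printed reports use the
conventional 1/mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .detector import DetectorModel
from .optics import SystemGeometry, make_grid
from .phantom import MaterialOptics, generate_sphere_pack
from .retrieval import compute_gi_images, propagate_to_analyzer, step_and_detect

__all__ = [
    "ThicknessSeries",
    "DiffusionFitResult",
    "ComparisonResult",
    "slope_factor",
    "run_thickness_series",
    "fit_epsilon",
    "predict_df",
    "epsilon_from_roi",
    "murine_human_comparison",
]


def slope_factor(geometry: SystemGeometry) -> float:
    """Dimensionless prefactor 2 * pi**2 * d**2 / p2**2 of the decay law."""
    return 2.0 * math.pi**2 * geometry.distance**2 / geometry.p2**2


@dataclass
class ThicknessSeries:
    """Mean field-of-view dark-field signal versus slab thickness.

    ``df_samples`` holds the individual repetition values, shape
    (n_thicknesses, n_repetitions); thicknesses are in metres.
    """

    thicknesses: np.ndarray
    mean_df: np.ndarray
    std_df: np.ndarray
    n_repetitions: int
    sphere_diameter: float
    preset_name: str = "custom"
    df_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.thicknesses = np.asarray(self.thicknesses, dtype=np.float64)
        self.mean_df = np.asarray(self.mean_df, dtype=np.float64)
        self.std_df = np.asarray(self.std_df, dtype=np.float64)
        if self.thicknesses.ndim != 1 or self.thicknesses.size == 0:
            raise ValueError("thicknesses must be a non-empty 1-D array")
        if np.any(np.diff(self.thicknesses) <= 0):
            raise ValueError("thicknesses must be strictly increasing")
        if self.mean_df.shape != self.thicknesses.shape or self.std_df.shape != self.thicknesses.shape:
            raise ValueError("mean_df and std_df must match thicknesses")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @property
    def df_at_max_thickness(self) -> float:
        return float(self.mean_df[-1])


@dataclass
class DiffusionFitResult:
    """Fitted linear diffusion coefficient and its diagnostics (SI units)."""

    epsilon: float  # 1/m
    epsilon_se: float  # 1/m
    r_squared: float
    slope_factor: float
    intercept: float | None = None  # free-intercept diagnostic fit
    intercept_se: float | None = None
    sphere_diameter: float | None = None
    preset_name: str = "custom"

    @property
    def epsilon_per_mm(self) -> float:
        """epsilon in the conventional 1/mm."""
        return self.epsilon * 1e-3

    @property
    def epsilon_se_per_mm(self) -> float:
        return self.epsilon_se * 1e-3

    def summary(self) -> str:
        lines = [
            "Linear diffusion coefficient fit (-log df = 2 pi^2 d^2/p2^2 * eps * t)",
            f"  preset            : {self.preset_name}",
        ]
        if self.sphere_diameter is not None:
            lines.append(f"  sphere diameter   : {self.sphere_diameter * 1e6:.0f} um")
        lines += [
            f"  epsilon           : {self.epsilon_per_mm:.3e} 1/mm",
            f"  std. error        : {self.epsilon_se_per_mm:.1e} 1/mm",
            f"  r-squared         : {self.r_squared:.5f}",
            f"  slope factor      : {self.slope_factor:.4e}",
        ]
        if self.intercept is not None:
            lines.append(
                f"  intercept (diag.) : {self.intercept:.3e} +/- {self.intercept_se:.1e}"
            )
        return "\n".join(lines)


def run_thickness_series(
    geometry: SystemGeometry,
    detector: DetectorModel,
    tissue: MaterialOptics,
    air: MaterialOptics,
    sphere_diameter: float,
    thicknesses,
    volume_fraction: float = 0.56,
    n_repetitions: int = 10,
    base_seed: int = 0,
    n_steps: int = 8,
    preset_name: str = "custom",
    projection: str = "additive",
) -> ThicknessSeries:
    """Simulate the mean dark-field signal for a list of slab thicknesses.

    For every (thickness, repetition) cell a fresh sphere pack is generated
    with seed ``base_seed + cell_index`` (cells enumerated thickness-major,
    so series are reproducible and extensible); the reference acquisition is
    computed once and shared.  The per-run value is the arithmetic mean of
    the pixel dark-field values over the whole field of view.
    """
    thicknesses = np.asarray(thicknesses, dtype=np.float64)
    if thicknesses.size == 0:
        raise ValueError("thicknesses must be non-empty")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    grid = make_grid(geometry)
    psi_ref = propagate_to_analyzer(geometry, None, grid=grid)
    # raw (pre-scaling) mean pixel intensity of the reference acquisition;
    # both stacks are exposure-normalized against it
    raw_ref = step_and_detect(
        psi_ref, geometry, detector, grid=grid, n_steps=n_steps,
        noise_seed=base_seed + 990_000, reference_mean=1.0,
    )
    raw_ref_mean = float(raw_ref.frames.mean()) / (
        detector.exposure_calibration * detector.eak
    )
    ref_stack = step_and_detect(
        psi_ref, geometry, detector, grid=grid, n_steps=n_steps,
        noise_seed=base_seed + 990_000, reference_mean=raw_ref_mean,
    )
    samples = np.empty((thicknesses.size, n_repetitions), dtype=np.float64)
    for it, t in enumerate(thicknesses):
        for rep in range(n_repetitions):
            seed = base_seed + it * n_repetitions + rep
            pack = generate_sphere_pack(
                geometry, sphere_diameter, float(t), volume_fraction,
                seed=seed, grid=grid,
            )
            psi = propagate_to_analyzer(geometry, pack, tissue, air, grid=grid,
                                        projection=projection)
            stack = step_and_detect(
                psi, geometry, detector, grid=grid, n_steps=n_steps,
                noise_seed=seed + 500_000, reference_mean=raw_ref_mean,
            )
            gi = compute_gi_images(stack, ref_stack)
            samples[it, rep] = gi.mean_dark_field
    return ThicknessSeries(
        thicknesses=thicknesses,
        mean_df=samples.mean(axis=1),
        std_df=samples.std(axis=1, ddof=1) if n_repetitions > 1 else np.zeros(thicknesses.size),
        n_repetitions=n_repetitions,
        sphere_diameter=sphere_diameter,
        preset_name=preset_name,
        df_samples=samples,
    )


def fit_epsilon(
    series: ThicknessSeries,
    geometry: SystemGeometry,
    weighting: str = "unweighted",
) -> DiffusionFitResult:
    """Zero-intercept regression of -log(mean df) on thickness.

    The default is ordinary (unweighted) least squares through the origin,
    the convention of standard curve-fitting packages.  With
    ``weighting="inverse_variance"`` points are weighted by the inverse
    variance propagated from the repetition scatter (sigma_y = std_df /
    mean_df); this falls back to unweighted when repetition scatter is
    unavailable.  A free-intercept fit is reported as a diagnostic
    alongside.
    """
    if series.thicknesses.size < 2:
        raise ValueError("at least two thicknesses are required to fit epsilon")
    if np.any(series.mean_df <= 0):
        raise ValueError("dark-field signal saturated: mean df must be positive")
    # df marginally above 1 (noise) is kept unclipped so averages stay unbiased
    t = series.thicknesses
    y = -np.log(series.mean_df)
    if weighting not in ("unweighted", "inverse_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    sigma_y = series.std_df / series.mean_df
    use_weights = (
        weighting == "inverse_variance"
        and series.n_repetitions > 1
        and np.all(sigma_y > 0)
    )
    if use_weights:
        weights = 1.0 / sigma_y**2
    else:
        weights = np.ones_like(y)
    origin_fit = sm.WLS(y, t[:, np.newaxis], weights=weights).fit()
    slope = float(origin_fit.params[0])
    slope_se = float(origin_fit.bse[0])
    factor = slope_factor(geometry)
    if t.size > 2:  # free-intercept diagnostic needs a residual dof
        diag = sm.WLS(y, sm.add_constant(t), weights=weights).fit()
        intercept, intercept_se = float(diag.params[0]), float(diag.bse[0])
    else:
        intercept = intercept_se = None
    return DiffusionFitResult(
        epsilon=slope / factor,
        epsilon_se=slope_se / factor,
        r_squared=float(origin_fit.rsquared),
        slope_factor=factor,
        intercept=intercept,
        intercept_se=intercept_se,
        sphere_diameter=series.sphere_diameter,
        preset_name=series.preset_name,
    )


def predict_df(epsilon: float, thickness: float, geometry: SystemGeometry) -> float:
    """Forward model df = exp(-(2 pi^2 d^2 / p2^2) * epsilon * t) (SI units)."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    return math.exp(-slope_factor(geometry) * epsilon * thickness)


def epsilon_from_roi(df_value: float, thickness: float, geometry: SystemGeometry) -> float:
    """Single-point inversion: epsilon (1/m) from one ROI df at known thickness."""
    if not 0.0 < df_value <= 1.0:
        raise ValueError(f"df must lie in (0, 1], got {df_value}")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    return -math.log(df_value) / (slope_factor(geometry) * thickness)


@dataclass
class ComparisonResult:
    """Murine-versus-human comparison of the fitted diffusion coefficients."""

    epsilon_ratio: float
    murine_df_at_max: float
    human_df_at_max: float
    relative_thickness: np.ndarray
    murine_df: np.ndarray
    human_df: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "relative_thickness": self.relative_thickness,
                "murine_df": self.murine_df,
                "human_df": self.human_df,
            }
        )


def murine_human_comparison(
    murine: DiffusionFitResult,
    human: DiffusionFitResult,
    murine_series: ThicknessSeries,
    human_series: ThicknessSeries,
) -> ComparisonResult:
    """Ratio of diffusion coefficients and df versus relative thickness t/t_max."""
    if human.epsilon <= 0:
        raise ValueError("human epsilon must be positive to form a ratio")
    rel = np.concatenate(
        [[0.0], murine_series.thicknesses / murine_series.thicknesses[-1]]
    )
    rel_h = np.concatenate(
        [[0.0], human_series.thicknesses / human_series.thicknesses[-1]]
    )
    if not np.allclose(rel, rel_h, atol=1e-9):
        raise ValueError("series must share the same relative-thickness grid")
    return ComparisonResult(
        epsilon_ratio=murine.epsilon / human.epsilon,
        murine_df_at_max=murine_series.df_at_max_thickness,
        human_df_at_max=human_series.df_at_max_thickness,
        relative_thickness=rel,
        murine_df=np.concatenate([[1.0], murine_series.mean_df]),
        human_df=np.concatenate([[1.0], human_series.mean_df]),
    )
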