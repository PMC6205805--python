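"""Export of stacks, GI images and series tables (TIFF + CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .retrieval import GIImages, PhaseStepStack

__all__ = ["save_stack", "save_gi_images", "plot_thickness_series"]


def save_stack(stack: PhaseStepStack, path, metadata: dict | None = None) -> None:
    """Write the phase-stepping frames as a 32-bit float TIFF stack."""
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        metadata={"step_positions_m": list(map(float, stack.step_positions)),
                  **(metadata or {})},
    )


def save_gi_images(gi: GIImages, out_dir, prefix: str = "gi",
                   config: dict | None = None) -> dict:
    """Write transmission/differential-phase/dark-field TIFFs plus a CSV summary.

    Returns the paths written.  The summary CSV carries per-image mean and
    standard deviation and embeds ``config`` as a JSON comment header.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images = {
        "transmission": gi.transmission,
        "differential_phase": gi.differential_phase,
        "dark_field": gi.dark_field,
    }
    paths = {}
    for name, image in images.items():
        path = out / f"{prefix}_{name}.tif"
        tifffile.imwrite(path, image.astype(np.float32))
        paths[name] = path
    summary = pd.DataFrame(
        {
            "image": list(images),
            "mean": [float(im.mean()) for im in images.values()],
            "std": [float(im.std()) for im in images.values()],
        }
    )
    csv_path = out / f"{prefix}_summary.csv"
    with open(csv_path, "w") as fh:
        if config is not None:
            fh.write(f"# config: {json.dumps(config, sort_keys=True)}\n")
        summary.to_csv(fh, index=False)
    paths["summary"] = csv_path
    return paths


def plot_thickness_series(series_list, fits=None, path=None):
    """Plot mean dark field vs thickness with the fitted exponential decay.

    ``series_list`` is one ThicknessSeries or a list of them; ``fits`` the
    matching DiffusionFitResult(s) (optional).  Returns the matplotlib
    figure; saves it to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(series_list, (list, tuple)):
        series_list = [series_list]
    if fits is not None and not isinstance(fits, (list, tuple)):
        fits = [fits]
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, series in enumerate(series_list):
        t_mm = series.thicknesses * 1e3
        label = f"{series.preset_name}, S = {series.sphere_diameter * 1e6:.0f} um"
        ax.errorbar(t_mm, series.mean_df, yerr=series.std_df, fmt="o", label=label)
        if fits is not None and i < len(fits):
            fit = fits[i]
            tt = np.linspace(0, series.thicknesses[-1], 200)
            ax.plot(tt * 1e3, np.exp(-fit.slope_factor * fit.epsilon * tt), "-",
                    color=ax.lines[-1].get_color())
    ax.set_xlabel("slab thickness t [mm]")
    ax.set_ylabel("mean dark field  v_obj / v_ref")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
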