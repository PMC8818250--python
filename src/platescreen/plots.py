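"""QC and results figures: plate heatmaps, column plots, volcanoes, mixture fits.

All functions render straight to a file (PDF by default) through the Agg
backend, so they are safe in headless batch runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .mixture import MixtureFit, lgr_cutoff
from .normalization import DegeneratePlateError
from .plate_io import ColonyGrid, SchemaError, row_label

PLOT_KINDS = ("scatter", "histogram", "heatmap", "volcano",
              "mixture_components", "mixture_fit")


def plate_heatmap(grid: ColonyGrid, out, cmap: str = "RdBu_r") -> Path:
    """Plate heatmap: red above the plate median, blue below.

    The colour scale is symmetric in log space around the median, so a
    colony at twice the median and one at half saturate equally.
    """
    med = float(np.nanmedian(grid.sizes))
    if not med > 0:
        raise DegeneratePlateError(f"plate {grid.plate}: median {med}; cannot plot")
    with np.errstate(divide="ignore"):
        ratio = np.log2(np.maximum(grid.sizes, med * 1e-3) / med)
    finite = ratio[np.isfinite(ratio)]
    vmax = max(float(np.abs(finite).max()) if finite.size else 1.0, 0.1)
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(ratio, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    step = max(1, grid.format.rows // 16)
    ax.set_yticks(range(0, grid.format.rows, step))
    ax.set_yticklabels([row_label(r + 1) for r in range(0, grid.format.rows, step)])
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_title(f"{grid.condition_label or 'plate'} {grid.plate}")
    fig.colorbar(im, ax=ax, label="log2(size / plate median)")
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out


def column_plot(
    table: pd.DataFrame,
    x: str,
    out,
    y: str | None = None,
    kind: str = "scatter",
    bins: int = 30,
    lgr_guide: float | None = None,
    q_guide: float | None = None,
) -> Path:
    """Scatter, histogram or volcano plot of result-table columns.

    A volcano plots an LGR column against a -ln(p) or -ln(q) column, with
    optional guide lines at ``lgr_guide`` (vertical) and -ln(``q_guide``)
    (horizontal).
    """
    if kind not in ("scatter", "histogram", "volcano"):
        raise ValueError(f"unsupported plot kind {kind!r}")
    for col in filter(None, [x, y]):
        if col not in table.columns:
            raise SchemaError(
                f"column {col!r} not in table (have: {', '.join(table.columns)})"
            )
    fig, ax = plt.subplots(figsize=(7, 5))
    if kind == "histogram":
        ax.hist(pd.to_numeric(table[x], errors="coerce").dropna(), bins=bins,
                color="steelblue", edgecolor="white")
        ax.set_ylabel("count")
    else:
        if y is None:
            raise ValueError(f"{kind} plot requires a y column")
        xv = pd.to_numeric(table[x], errors="coerce")
        yv = pd.to_numeric(table[y], errors="coerce")
        ax.scatter(xv, yv, s=6, alpha=0.5, color="steelblue", linewidths=0)
        ax.set_ylabel(y)
        if kind == "volcano":
            if lgr_guide is not None:
                ax.axvline(lgr_guide, color="red", linestyle="--", linewidth=1)
            if q_guide is not None:
                ax.axhline(-np.log(q_guide), color="black", linestyle="--", linewidth=1)
    ax.set_xlabel(x)
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out


def mixture_plots(
    fit: MixtureFit,
    values: Sequence[float],
    component_out,
    fit_out,
    bins: int = 60,
) -> tuple[Path, Path]:
    """Component plot (two weighted densities) and fit plot (mixture over histogram).

    Both draw the q(x) = 0.5 cut-off as a vertical line.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    cutoff = lgr_cutoff(fit, x).root
    lo = min(x.min(), fit.mean_1 - 4 * fit.sd_1)
    hi = max(x.max(), fit.mean_2 + 4 * fit.sd_2)
    grid = np.linspace(lo, hi, 512)
    d1 = fit.weight_1 * stats.norm.pdf(grid, fit.mean_1, fit.sd_1)
    d2 = fit.weight_2 * stats.norm.pdf(grid, fit.mean_2, fit.sd_2)

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(grid, d1, color="steelblue", label="component 1 (central peak)")
    ax.plot(grid, d2, color="firebrick", label="component 2 (hit peak)")
    ax.axvline(cutoff, color="black", linestyle="--", linewidth=1,
               label=f"q = 0.5 cut-off ({cutoff:.3f})")
    ax.set_xlabel("mean LGR")
    ax.set_ylabel("weighted density")
    ax.legend()
    component_out = Path(component_out)
    fig.savefig(component_out)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.hist(x, bins=bins, density=True, color="lightgray", edgecolor="white")
    ax.plot(grid, d1 + d2, color="black", label="mixture fit")
    ax.axvline(cutoff, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel("mean LGR")
    ax.set_ylabel("density")
    ax.legend()
    fit_out = Path(fit_out)
    fig.savefig(fit_out)
    plt.close(fig)
    return component_out, fit_out
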