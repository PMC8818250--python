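"""Colony-size normalization, spatial smoothing and control-dead flagging.

Plate-level growth differences (nutrition, humidity, incubation order) are
removed by dividing every colony by the plate median, or by the median of
designated within-plate control colonies. Within-plate spatial trends —
colonies at the plate periphery grow larger because they face less
competition for nutrients — are corrected by a multiplicative row/column
median adjustment. Positions where the *control* colony failed to grow are
flagged so downstream statistics can exclude them while still reporting
their normalized sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .plate_io import CONTROL_ID, ColonyGrid, KeyMap

logger = logging.getLogger(__name__)

NORMALIZATION_MODES = ("plate_median", "control_median", "none")


class DegeneratePlateError(ValueError):
    """The plate has no usable sizes (all zero/missing, or median zero)."""


class InsufficientControlsError(ValueError):
    """Fewer than the required number of live control colonies on a plate."""


@dataclass
class NormalizationOptions:
    """Tunable knobs of the normalization stage.

    mode
        ``plate_median`` divides by the plate median, ``control_median`` by
        the median of live ``Control``-keyed colonies, ``none`` leaves raw
        sizes (for screens where most colonies are affected and the median
        is no longer a neutral reference).
    smooth
        apply the row/column spatial correction after normalization.
    size_floor_epsilon
        lower bound applied to normalized sizes before logarithms, in
        plate-median units; bounds a dead colony's LGR at ln(1/epsilon).
    control_dead_threshold
        normalized control size below which the position is flagged
        control-dead (strict ``<``); the flag excludes the position from
        aggregation and testing, not from reporting.
    """

    mode: str = "plate_median"
    smooth: bool = False
    size_floor_epsilon: float = 0.01
    control_dead_threshold: float = 0.30

    def __post_init__(self) -> None:
        if self.mode not in NORMALIZATION_MODES:
            raise ValueError(
                f"mode must be one of {NORMALIZATION_MODES}, got {self.mode!r}"
            )
        if self.size_floor_epsilon <= 0:
            raise ValueError("size_floor_epsilon must be positive")
        if not 0 <= self.control_dead_threshold <= 1:
            raise ValueError("control_dead_threshold must lie in [0, 1]")
        if self.size_floor_epsilon >= self.control_dead_threshold > 0:
            raise ValueError(
                "size_floor_epsilon must be smaller than control_dead_threshold"
            )


@dataclass
class NormalizedGrid:
    """A plate of normalized colony sizes plus the divisor that produced it."""

    grid: ColonyGrid
    reference_median: float
    smoothed: bool = False
    mode: str = "plate_median"

    @property
    def sizes(self) -> np.ndarray:
        return self.grid.sizes


def plate_median_normalize(grid: ColonyGrid) -> NormalizedGrid:
    """Divide every colony size by the plate median of non-missing sizes."""
    sizes = grid.sizes
    if not np.isfinite(sizes).any():
        raise DegeneratePlateError(f"plate {grid.plate}: all sizes missing")
    med = float(np.nanmedian(sizes))
    if not med > 0:
        raise DegeneratePlateError(
            f"plate {grid.plate}: plate median is {med}; cannot normalize"
        )
    return NormalizedGrid(
        grid=replace(grid, sizes=sizes / med),
        reference_median=med,
        smoothed=False,
        mode="plate_median",
    )


def control_median_normalize(
    grid: ColonyGrid, key: KeyMap, min_live_controls: int = 3
) -> NormalizedGrid:
    """Divide every colony size by the median of live control colonies.

    Control positions are those the key file labels ``Control`` on this
    plate; at least ``min_live_controls`` of them must have nonzero size to
    anchor a median.
    """
    positions = key.control_positions(grid.plate)
    control_sizes = np.array(
        [grid.sizes[r - 1, c - 1] for r, c in positions], dtype=float
    )
    live = control_sizes[np.isfinite(control_sizes) & (control_sizes > 0)]
    if live.size < min_live_controls:
        raise InsufficientControlsError(
            f"plate {grid.plate}: {live.size} live {CONTROL_ID!r} colonies; "
            f"need at least {min_live_controls} for control-median normalization"
        )
    med = float(np.median(live))
    return NormalizedGrid(
        grid=replace(grid, sizes=grid.sizes / med),
        reference_median=med,
        smoothed=False,
        mode="control_median",
    )


def no_normalize(grid: ColonyGrid) -> NormalizedGrid:
    """Pass raw sizes through unchanged (reference divisor 1)."""
    return NormalizedGrid(
        grid=replace(grid, sizes=grid.sizes.copy()),
        reference_median=1.0,
        smoothed=False,
        mode="none",
    )


def spatial_smooth(ngrid: NormalizedGrid) -> NormalizedGrid:
    """Remove systematic row/column growth trends from a normalized plate.

    Each cell is divided by the product of its row factor (row median over
    plate median) and column factor; the result is re-divided by its own
    median so the plate median returns to 1. A purely multiplicative
    row x column bias is inverted exactly; a whole-missing row or column
    contributes a factor of 1.
    """
    s = ngrid.sizes
    gmed = float(np.nanmedian(s))
    if not gmed > 0:
        raise DegeneratePlateError(
            f"plate {ngrid.grid.plate}: median {gmed}; cannot smooth"
        )
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        row_med = np.nanmedian(s, axis=1)
        col_med = np.nanmedian(s, axis=0)
    f_row = row_med / gmed
    f_col = col_med / gmed
    for name, f in (("row", f_row), ("column", f_col)):
        bad = ~np.isfinite(f) | (f <= 0)
        if bad.any():
            logger.warning(
                "plate %d: %d empty/degenerate %ss during smoothing; factor set to 1",
                ngrid.grid.plate, int(bad.sum()), name,
            )
            f[bad] = 1.0
    corrected = s / np.outer(f_row, f_col)
    corrected = corrected / float(np.nanmedian(corrected))
    return NormalizedGrid(
        grid=replace(ngrid.grid, sizes=corrected),
        reference_median=ngrid.reference_median,
        smoothed=True,
        mode=ngrid.mode,
    )


def floor_sizes(ngrid: NormalizedGrid, epsilon: float = 0.01) -> NormalizedGrid:
    """Raise normalized sizes below ``epsilon`` to ``epsilon`` (NaN passes through)."""
    if epsilon <= 0:
        raise ValueError("size floor must be positive")
    return NormalizedGrid(
        grid=replace(ngrid.grid, sizes=np.maximum(ngrid.sizes, epsilon)),
        reference_median=ngrid.reference_median,
        smoothed=ngrid.smoothed,
        mode=ngrid.mode,
    )


def flag_control_dead(control_norm_size, threshold: float = 0.30):
    """True where the normalized control size falls strictly below ``threshold``.

    Works elementwise on arrays; NaN compares False (missing positions are
    handled by the aggregation step, not by this flag).
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(control_norm_size) < threshold
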