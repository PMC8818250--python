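"""Log-growth-ratio statistics for plate-paired colony screens.

The central quantity is the log growth ratio (LGR) of a colony,

    LGR = ln(control size / experimental size),

computed position-by-position between an experimental plate and its paired
control plate after normalization; positive values mean a growth defect in
the experimental condition. If colony sizes are lognormal, LGRs are normal,
which motivates taking the logarithm per colony *before* averaging over
replicates. Per strain, replicate control vs experimental sizes are
compared with a two-sided pooled-variance Student's t-test; p-values are
adjusted across the whole screen with the Benjamini–Hochberg step-up, and
mean LGRs are standardized into Z-scores over all strains in the run.
Screens run against two independent controls are merged by averaging the
two mean LGRs and taking the maximum of the two p- and q-values, which
demands concordance of both controls rather than pooled significance.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import (
    MEAN_COLUMNS,
    MERGE_COLUMNS,
    REPLICATE_COLUMNS,
    ColonyGrid,
    KeyMap,
)
from .normalization import (
    NormalizationOptions,
    NormalizedGrid,
    control_median_normalize,
    flag_control_dead,
    floor_sizes,
    no_normalize,
    plate_median_normalize,
    spatial_smooth,
)

logger = logging.getLogger(__name__)


class PairingError(ValueError):
    """Experimental and control plate sets cannot be paired one-to-one."""


def colony_lgr(control_norm, experiment_norm):
    """ln(control / experimental) normalized colony size; positive = defect."""
    c = np.asarray(control_norm, dtype=float)
    e = np.asarray(experiment_norm, dtype=float)
    if np.any(c <= 0) or np.any(e <= 0):
        raise ValueError(
            "colony_lgr requires positive (floored) normalized sizes; "
            "apply the size floor before taking logarithms"
        )
    out = np.log(c / e)
    return float(out) if out.ndim == 0 else out


def replicate_p_value(
    control_norms: Sequence[float], experiment_norms: Sequence[float]
) -> float:
    """Two-sided pooled-variance Student's t-test p for one strain's replicates.

    Returns NaN (missing) when either side has fewer than two observations,
    or when the pooled variance is zero with unequal means; returns 1.0 for
    identical constant samples.
    """
    a = np.asarray(control_norms, dtype=float)
    b = np.asarray(experiment_norms, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        return float("nan")
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled == 0:
        return 1.0 if a.mean() == b.mean() else float("nan")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(t), n1 + n2 - 2))


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    q for the i-th smallest p is min over j >= i of p_(j) * m / j, capped at
    1, mapped back to input order. ``m`` defaults to the number of supplied
    p-values; pass the full family size when some tests are missing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def neg_log(v):
    """-ln(v) for v in (0, 1]; the volcano-plot transform of p and q."""
    arr = np.asarray(v, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("values must lie in (0, 1]")
    out = -np.log(arr)
    return float(out) if out.ndim == 0 else out


def z_scores(mean_lgrs) -> np.ndarray:
    """Standardize mean LGRs over the whole run (sample sd, NaN passthrough)."""
    x = np.asarray(mean_lgrs, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("z-scores require at least 2 non-missing values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("z-scores undefined: zero variance across mean LGRs")
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# the single-control engine


def _normalize_plate(
    grid: ColonyGrid, key: KeyMap, opts: NormalizationOptions
) -> NormalizedGrid:
    if opts.mode == "plate_median":
        ngrid = plate_median_normalize(grid)
    elif opts.mode == "control_median":
        ngrid = control_median_normalize(grid, key)
    else:
        ngrid = no_normalize(grid)
    if opts.smooth:
        ngrid = spatial_smooth(ngrid)
    return ngrid


def calculate_lgrs(
    experiment: Sequence[ColonyGrid],
    control: Sequence[ColonyGrid],
    key: KeyMap,
    opts: NormalizationOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the single-control engine: normalized sizes -> LGRs -> strain stats.

    Plates are paired by order; the strain layout must be identical on the
    experimental and control plates. Returns the replicates table (one row
    per keyed colony) and the mean table (one row per strain per plate, with
    mean LGR, pooled-t p, BH q, -ln transforms and run-wide Z-score).
    Positions flagged control-dead are reported in the replicates table but
    excluded from aggregation and testing.
    """
    opts = opts or NormalizationOptions()
    if len(experiment) != len(control):
        raise PairingError(
            f"{len(experiment)} experimental plates cannot be paired with "
            f"{len(control)} control plates"
        )
    rows: list[tuple] = []
    n_missing = 0
    for exp_grid, ctl_grid in zip(experiment, control):
        if exp_grid.format != ctl_grid.format:
            raise PairingError("experimental and control plates differ in array format")
        if exp_grid.plate != ctl_grid.plate:
            raise PairingError(
                f"plate numbering mismatch: experimental plate {exp_grid.plate} "
                f"paired with control plate {ctl_grid.plate}"
            )
        n_exp = floor_sizes(
            _normalize_plate(exp_grid, key, opts), opts.size_floor_epsilon
        )
        n_ctl_raw = _normalize_plate(ctl_grid, key, opts)
        dead = flag_control_dead(n_ctl_raw.sizes, opts.control_dead_threshold)
        n_ctl = floor_sizes(n_ctl_raw, opts.size_floor_epsilon)
        plate = exp_grid.plate
        for row, col in key.positions_on_plate(plate):
            sid = key.id_at(plate, row, col)
            c = n_ctl.sizes[row - 1, col - 1]
            e = n_exp.sizes[row - 1, col - 1]
            if not (np.isfinite(c) and np.isfinite(e)):
                n_missing += 1
                continue
            excluded = bool(dead[row - 1, col - 1])
            rows.append((plate, row, col, sid, c, e, float(np.log(c / e)), excluded))
    if n_missing:
        logger.warning("%d keyed positions missing from the colony data", n_missing)
    replicates = pd.DataFrame(rows, columns=REPLICATE_COLUMNS)
    mean = _aggregate_strains(replicates)
    logger.info(
        "calculate_lgrs: %d plates, %d replicate records (%d excluded), %d strain rows",
        len(experiment), len(replicates), int(replicates["excluded"].sum()), len(mean),
    )
    return replicates, mean


def _aggregate_strains(replicates: pd.DataFrame) -> pd.DataFrame:
    if replicates.empty:
        return pd.DataFrame(columns=MEAN_COLUMNS)
    keys = ["Plate", "ID"]
    first_pos = (
        replicates.sort_values(["Plate", "Row", "Column"])
        .groupby(keys, sort=True)[["Row", "Column"]]
        .first()
    )
    n_total = replicates.groupby(keys, sort=True).size().rename("n_reps")
    inc = replicates.loc[~replicates["excluded"]]
    g = inc.groupby(keys, sort=True)
    agg = g.agg(
        n_inc=("LGR", "size"),
        mean_LGR=("LGR", "mean"),
        control_mean_norm=("control_norm", "mean"),
        experiment_mean_norm=("experiment_norm", "mean"),
        m1=("control_norm", "mean"),
        m2=("experiment_norm", "mean"),
        v1=("control_norm", "var"),
        v2=("experiment_norm", "var"),
    )
    out = pd.concat([first_pos, n_total], axis=1).join(agg)
    out["n_inc"] = out["n_inc"].fillna(0).astype(int)

    # pooled-variance two-sample t on control vs experimental replicate sizes
    n = out["n_inc"].to_numpy(dtype=float)
    v1 = out["v1"].to_numpy(dtype=float)
    v2 = out["v2"].to_numpy(dtype=float)
    m1 = out["m1"].to_numpy(dtype=float)
    m2 = out["m2"].to_numpy(dtype=float)
    p = np.full(len(out), np.nan)
    testable = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(testable, (v1 + v2) / 2.0, np.nan)  # equal n per side
        se = np.sqrt(pooled * (2.0 / np.maximum(n, 1)))
        tstat = (m1 - m2) / se
        df = 2 * n - 2
        p_t = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
    p[testable & (pooled > 0)] = p_t[testable & (pooled > 0)]
    p[testable & (pooled == 0) & (m1 == m2)] = 1.0
    out["p_value"] = p

    q = np.full(len(out), np.nan)
    has_p = np.isfinite(p)
    if has_p.any():
        q[has_p] = bh_adjust(p[has_p], m=int(has_p.sum()))
    out["q_value"] = q
    with np.errstate(invalid="ignore"):
        out["neg_lnP"] = -np.log(out["p_value"])
        out["neg_lnQ"] = -np.log(out["q_value"])

    mean_lgr = out["mean_LGR"].to_numpy(dtype=float)
    finite = np.isfinite(mean_lgr)
    z = np.full(len(out), np.nan)
    if finite.sum() >= 2:
        sd = mean_lgr[finite].std(ddof=1)
        if sd == 0:
            logger.warning("all mean LGRs identical; Z-scores set to 0")
            z[finite] = 0.0
        else:
            z[finite] = (mean_lgr[finite] - mean_lgr[finite].mean()) / sd
    out["zscore"] = z
    out["excluded"] = out["n_inc"] == 0
    out = out.reset_index()
    return out.loc[:, MEAN_COLUMNS]


# ---------------------------------------------------------------------------
# two-control merging and hit calling


def combine_two_controls(mean1: pd.DataFrame, mean2: pd.DataFrame) -> pd.DataFrame:
    """Join two single-control mean tables into a merge table.

    avg_LGR is the mean of the two per-control mean LGRs (missing unless both
    are present), max_p/max_q the maxima of the per-control values, and
    zscore_merged is recomputed by standardizing avg_LGR over the merged run.
    """
    cols = ["Plate", "ID", "mean_LGR", "zscore", "p_value", "q_value", "excluded"]
    a = mean1.loc[:, cols].rename(
        columns={"mean_LGR": "mean_LGR_c1", "zscore": "zscore_c1",
                 "p_value": "p_c1", "q_value": "q_c1", "excluded": "excluded_c1"}
    )
    b = mean2.loc[:, cols].rename(
        columns={"mean_LGR": "mean_LGR_c2", "zscore": "zscore_c2",
                 "p_value": "p_c2", "q_value": "q_c2", "excluded": "excluded_c2"}
    )
    merged = pd.merge(a, b, on=["Plate", "ID"], how="outer", sort=True)
    only1 = merged["mean_LGR_c2"].isna() & merged["mean_LGR_c1"].notna()
    only2 = merged["mean_LGR_c1"].isna() & merged["mean_LGR_c2"].notna()
    if only1.any() or only2.any():
        logger.warning(
            "merge: %d strains present only in control 1, %d only in control 2",
            int(only1.sum()), int(only2.sum()),
        )
    for side in ("c1", "c2"):
        col = merged[f"excluded_{side}"]
        excl = np.where(col.isna(), True, col).astype(bool)
        merged.loc[excl, f"mean_LGR_{side}"] = np.nan
    merged["avg_LGR"] = (merged["mean_LGR_c1"] + merged["mean_LGR_c2"]) / 2.0
    merged["max_p"] = np.maximum(merged["p_c1"], merged["p_c2"])
    merged["max_q"] = np.maximum(merged["q_c1"], merged["q_c2"])
    with np.errstate(invalid="ignore"):
        merged["neg_ln_maxP"] = -np.log(merged["max_p"])
        merged["neg_ln_maxQ"] = -np.log(merged["max_q"])
    avg = merged["avg_LGR"].to_numpy(dtype=float)
    finite = np.isfinite(avg)
    z = np.full(len(merged), np.nan)
    if finite.sum() >= 2:
        sd = avg[finite].std(ddof=1)
        if sd == 0:
            logger.warning("all avg LGRs identical; merged Z-scores set to 0")
            z[finite] = 0.0
        else:
            z[finite] = (avg[finite] - avg[finite].mean()) / sd
    merged["zscore_merged"] = z
    return merged.loc[:, MERGE_COLUMNS]


HIT_RULES = ("lgr_threshold", "zscore_threshold", "mixture_q")


def call_hits(
    table: pd.DataFrame,
    rule: str = "lgr_threshold",
    threshold: float = 0.4,
    column: str | None = None,
) -> pd.DataFrame:
    """Flag hits with an inclusive (>=) threshold on the rule's column.

    Default columns: avg_LGR (merge) or mean_LGR (mean) for the LGR rule,
    zscore_merged or zscore for the Z rule, and a mixture ``q`` column for
    the mixture rule. Missing values are never hits.
    """
    if rule not in HIT_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {HIT_RULES}")
    if column is None:
        candidates = {
            "lgr_threshold": ["avg_LGR", "mean_LGR"],
            "zscore_threshold": ["zscore_merged", "zscore"],
            "mixture_q": ["q", "mixture_q"],
        }[rule]
        column = next((c for c in candidates if c in table.columns), None)
        if column is None:
            raise ValueError(
                f"no suitable column for rule {rule!r}; expected one of {candidates}"
            )
    if column not in table.columns:
        raise ValueError(f"column {column!r} not present in table")
    out = table.copy()
    vals = pd.to_numeric(out[column], errors="coerce")
    out["is_hit"] = (vals >= threshold).fillna(False)
    out.attrs["hit_rule"] = rule
    out.attrs["hit_threshold"] = threshold
    out.attrs["hit_column"] = column
    return out
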