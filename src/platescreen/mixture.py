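"""Two-component normal mixture model for data-driven hit thresholds.

A screen with many growth defects has a bimodal mean-LGR distribution: a
central peak of unaffected strains near zero (component 1) and a "hit peak"
of growth defects at higher LGRs (component 2). Fitting

    f(x) = w1 N(x; mu1, sd1^2) + w2 N(x; mu2, sd2^2),   w1 + w2 = 1

by expectation–maximization yields, for each observed LGR x, the posterior
probability q(x) of membership in the hit component. q(x) = 0.5 — the point
where an LGR is equally likely to come from either component — defines the
hit cut-off, replacing a fixed empirical threshold with one derived from
the data's own distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateDataError(ValueError):
    """The values carry no variance; a mixture cannot be fit."""


class ConvergenceError(RuntimeError):
    """No EM restart converged; the best partial fit is attached as ``.fit``."""

    def __init__(self, message: str, fit: "MixtureFit"):
        super().__init__(message)
        self.fit = fit


@dataclass
class MixtureFit:
    """Parameters of a fitted two-component normal mixture.

    Components are ordered so component 2 is the higher-mean hit peak.
    ``ll_trace`` records the log-likelihood after every EM iteration of the
    winning restart (nondecreasing by the EM guarantee).
    """

    weight_1: float
    weight_2: float
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    seed: int
    ll_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        assert abs(self.weight_1 + self.weight_2 - 1.0) < 1e-9
        assert self.mean_1 <= self.mean_2
        assert self.sd_1 > 0 and self.sd_2 > 0


def _log_density(x: np.ndarray, w, mu, var) -> np.ndarray:
    """(n, 2) array of log(w_k) + log N(x; mu_k, var_k)."""
    x = x[:, None]
    return (
        np.log(w)[None, :]
        - 0.5 * (_LOG_2PI + np.log(var))[None, :]
        - 0.5 * (x - mu[None, :]) ** 2 / var[None, :]
    )


def _em_once(x, w, mu, var, tol, max_iter, var_floor):
    n = x.size
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logd = _log_density(x, w, mu, var)
        norm = logsumexp(logd, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logd - norm[:, None])
        trace.append(ll)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = resp.T @ x / nk
        var = np.maximum((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk, var_floor)
    return w, mu, var, trace[-1], it, converged, trace


def em_fit(
    values,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    var_floor: float = 1e-6,
) -> MixtureFit:
    """Fit the two-component mixture by EM, best of several restarts.

    The first restart anchors component 1 at the data median with a
    MAD-based scale (screens are mostly null, so the central peak dominates)
    and component 2 at the 90th percentile with weights (0.9, 0.1); further
    restarts perturb both means by seeded Gaussian noise of 0.5 scale units.
    Convergence is an absolute log-likelihood improvement below ``tol``.
    Variances are floored at ``var_floor`` to prevent component collapse.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError(f"mixture fit needs at least 20 finite values, got {x.size}")
    if x.min() == x.max():
        raise DegenerateDataError("all values identical; mixture fit is degenerate")
    rng = np.random.default_rng(seed)
    med = float(np.median(x))
    mad_scale = 1.4826 * float(np.median(np.abs(x - med)))
    scale = mad_scale if mad_scale > 0 else float(np.std(x))
    q90 = float(np.quantile(x, 0.9))

    best = None
    for r in range(max(1, restarts)):
        m1, m2 = med, q90
        if r > 0:
            m1 += rng.normal(0.0, 0.5 * scale)
            m2 += rng.normal(0.0, 0.5 * scale)
        w, mu, var, ll, n_it, conv, trace = _em_once(
            x,
            np.array([0.9, 0.1]),
            np.array([m1, m2]),
            np.array([scale**2, scale**2]),
            tol,
            max_iter,
            var_floor,
        )
        if best is None or ll > best[3]:
            best = (w, mu, var, ll, n_it, conv, trace)
    w, mu, var, ll, n_it, conv, trace = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], np.sqrt(var[order])
    fit = MixtureFit(
        weight_1=float(w[0]), weight_2=float(w[1]),
        mean_1=float(mu[0]), mean_2=float(mu[1]),
        sd_1=float(sd[0]), sd_2=float(sd[1]),
        log_likelihood=ll, n_iterations=n_it, converged=conv,
        seed=seed, ll_trace=trace,
    )
    if not conv:
        raise ConvergenceError(
            f"no EM restart converged within {max_iter} iterations", fit
        )
    return fit


def posterior_q(fit: MixtureFit, x):
    """q(x): posterior probability that LGR x belongs to the hit component."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    w = np.array([fit.weight_1, fit.weight_2])
    mu = np.array([fit.mean_1, fit.mean_2])
    var = np.array([fit.sd_1**2, fit.sd_2**2])
    logd = _log_density(arr, w, mu, var)
    # logistic form: exact 0.5 when the weighted densities tie
    q = expit(logd[:, 1] - logd[:, 0])
    q = np.where(np.isfinite(arr), q, np.nan)
    return float(q[0]) if np.ndim(x) == 0 else q


@dataclass(frozen=True)
class Cutoff:
    """The q(x) = 0.5 hit cut-off.

    ``root`` is the continuous solution of q(x) = 0.5 between the component
    means (bisection to 1e-8); ``observed`` is the smallest observed LGR
    above mean_1 whose posterior reaches 0.5, or None if no value does.
    """

    root: float
    observed: float | None


def lgr_cutoff(fit: MixtureFit, values) -> Cutoff:
    """Locate the q(x) = 0.5 threshold for a fitted mixture."""
    g = lambda t: posterior_q(fit, t) - 0.5
    lo, hi = fit.mean_1, fit.mean_2
    # widen the bracket if the posterior has not crossed 0.5 at either mean
    lo_ext = fit.mean_1 - 10.0 * fit.sd_1
    hi_ext = fit.mean_2 + 10.0 * fit.sd_2
    if g(lo) >= 0:
        lo = lo_ext
    if g(hi) <= 0:
        hi = hi_ext
    if g(lo) < 0 and g(hi) > 0:
        root = float(brentq(g, lo, hi, xtol=1e-8))
    else:
        # no sign change at the extended endpoints: scan for the first crossing
        grid = np.linspace(lo_ext, hi_ext, 4097)
        sign = np.sign(posterior_q(fit, grid) - 0.5)
        crossings = np.nonzero(np.diff(sign) > 0)[0]
        if crossings.size == 0:
            warnings.warn("posterior never crosses 0.5; returning the midpoint")
            return Cutoff(root=float((fit.mean_1 + fit.mean_2) / 2.0), observed=None)
        i = crossings[0]
        root = float(brentq(g, grid[i], grid[i + 1], xtol=1e-8))

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    above = x[(x > fit.mean_1) & (posterior_q(fit, x) >= 0.5)]
    if above.size == 0:
        warnings.warn("no observed value reaches q(x) >= 0.5; hit set is empty")
        return Cutoff(root=root, observed=None)
    return Cutoff(root=root, observed=float(above.min()))


def classify(
    fit: MixtureFit, mean_table: pd.DataFrame, column: str = "mean_LGR"
) -> pd.DataFrame:
    """Annotate a mean/merge table with q(x) and the inclusive q >= 0.5 hit flag."""
    if column not in mean_table.columns:
        raise ValueError(f"column {column!r} not present in table")
    out = mean_table.copy()
    vals = pd.to_numeric(out[column], errors="coerce").to_numpy(dtype=float)
    q = posterior_q(fit, vals)
    out["q"] = q
    out["is_hit"] = pd.Series(q >= 0.5, index=out.index).fillna(False)
    return out
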