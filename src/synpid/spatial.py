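"""Spatial decay of pairwise quantities: correlation length and lambda_eff.

Pairwise scalars (Pearson correlation of the binary activity, or Z-scored
synergy/redundancy) are averaged in logarithmically spaced inter-neuron
distance bins and the binned curve is fitted with the exponential decay

    C(d) = C_inf + (C0 - C_inf) * exp(-d / lambda),

where C0 is the near-distance value, C_inf the asymptotic baseline (the
non-zero far-distance correlation typical of mesoscale calcium data) and
lambda the correlation length in micrometres.  Two derived summaries:

* the normalised curve (C(d) - C_inf) / (C0 - C_inf) = exp(-d / lambda),
  for comparing decay shapes across recordings;
* the effective information length, the normalised area under the fitted
  curve between d0 and dmax,

      lambda_eff = (1 / C0) * integral_{d0}^{dmax} C(d) dd,

  a bounded summary of spatial extent that stays meaningful when the
  fitted lambda runs beyond the field of view (as it does for slowly
  decaying Z-scored components).

The same binning/fitting path applies unchanged to any per-pair scalar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceBinnedCurve",
    "DecayFit",
    "EffectiveLength",
    "pairwise_pearson",
    "bin_by_distance",
    "fit_exponential_decay",
    "normalized_curve",
    "effective_length",
    "effective_length_trapezoid",
]


@dataclass(frozen=True)
class DistanceBinnedCurve:
    """Per-bin means of a pairwise scalar over log-spaced distance bins.

    ``mean_value`` is NaN for bins with fewer than ``min_pairs_per_bin``
    pairs; such bins are retained but treated as unoccupied.
    """

    bin_edges: np.ndarray     # (n_bins + 1,) micrometres, strictly increasing
    bin_centers: np.ndarray   # (n_bins,) geometric centres
    mean_value: np.ndarray    # (n_bins,)
    pair_count: np.ndarray    # (n_bins,)
    min_pairs_per_bin: int

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.mean_value)


@dataclass(frozen=True)
class DecayFit:
    """Exponential-decay fit C(d) = c_inf + (c0 - c_inf) exp(-d / lam)."""

    c0: float
    c_inf: float
    lam: float                 # micrometres
    covariance: np.ndarray     # (3, 3) parameter covariance (c0, c_inf, lam)
    rss: float
    converged: bool
    unidentifiable: bool = False

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.c_inf + (self.c0 - self.c_inf) * np.exp(-d / self.lam)


@dataclass(frozen=True)
class EffectiveLength:
    lambda_eff: float   # micrometres
    d0: float
    dmax: float
    undefined: bool = False


def pairwise_pearson(raster) -> pd.DataFrame:
    """Pearson r of every neuron pair of a binary raster.

    Returns columns (i, j, value) over pairs i < j.  Constant neurons have
    undefined r; their pairs are excluded and the exclusion count logged.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2 or raster.shape[0] < 3:
        raise ValueError("raster must be (T, N) with T >= 3")
    n = raster.shape[1]
    constant = raster.std(axis=0) < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(raster, rowvar=False)
    ii, jj = np.triu_indices(n, k=1)
    keep = ~(constant[ii] | constant[jj])
    if (~keep).sum():
        logger.info("excluded %d pairs involving %d constant neurons",
                    int((~keep).sum()), int(constant.sum()))
    return pd.DataFrame(
        {"i": ii[keep], "j": jj[keep], "value": corr[ii[keep], jj[keep]]}
    )


def _pair_distances(pairs: pd.DataFrame, positions: pd.DataFrame) -> np.ndarray:
    xy = positions.set_index("neuron_id")[["x_um", "y_um"]]
    a = xy.loc[pairs["i"].to_numpy()].to_numpy(float)
    b = xy.loc[pairs["j"].to_numpy()].to_numpy(float)
    return np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1])


def bin_by_distance(
    pairs: pd.DataFrame,
    positions: pd.DataFrame | None = None,
    value_col: str = "value",
    n_bins: int = 20,
    d_min: float = 10.0,
    d_max_bin: float | None = None,
    min_pairs_per_bin: int = 50,
) -> DistanceBinnedCurve:
    """Average a per-pair scalar in log-spaced distance bins.

    ``pairs`` needs columns i, j and ``value_col``; distances come from a
    ``distance_um`` column if present, else from ``positions``.  Pairs
    outside [d_min, d_max_bin] are dropped.  Unweighted mean per bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if d_min <= 0:
        raise ValueError("d_min must be positive (log-spaced bins)")
    if "distance_um" in pairs.columns:
        dist = pairs["distance_um"].to_numpy(float)
    elif positions is not None:
        dist = _pair_distances(pairs, positions)
    else:
        raise ValueError("need positions or a distance_um column")
    values = pairs[value_col].to_numpy(float)
    finite = np.isfinite(values)
    dist, values = dist[finite], values[finite]
    if d_max_bin is None:
        d_max_bin = float(dist.max())
    edges = np.geomspace(d_min, d_max_bin, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    idx = np.digitize(dist, edges) - 1
    inside = (idx >= 0) & (idx < n_bins) & (dist <= d_max_bin)
    idx, values = idx[inside], values[inside]
    count = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(count >= max(min_pairs_per_bin, 1),
                         sums / np.maximum(count, 1), np.nan)
    return DistanceBinnedCurve(
        bin_edges=edges, bin_centers=centers, mean_value=means,
        pair_count=count, min_pairs_per_bin=min_pairs_per_bin,
    )


def _decay_model(d, c0, c_inf, lam):
    return c_inf + (c0 - c_inf) * np.exp(-d / lam)


def fit_exponential_decay(
    curve: DistanceBinnedCurve, weighted: bool = False
) -> DecayFit:
    """Nonlinear least squares fit of the exponential decay to bin means.

    Initial guesses: c0 = first occupied mean, c_inf = last occupied mean,
    lam = occupied span / 3; lam is bounded in (1, 10 * span].  A flat
    curve (spread of means below 1e-12) is unidentifiable: lam is NaN and
    the flag set.
    """
    occ = curve.occupied
    if occ.sum() < 4:
        raise ValueError(f"need >= 4 occupied bins, have {int(occ.sum())}")
    d = curve.bin_centers[occ]
    y = curve.mean_value[occ]
    if np.std(y) < 1e-12:
        return DecayFit(c0=float(y[0]), c_inf=float(y[0]), lam=float("nan"),
                        covariance=np.full((3, 3), np.nan), rss=0.0,
                        converged=False, unidentifiable=True)
    span = d[-1] - d[0]
    p0 = [y[0], y[-1], span / 3]
    sigma = 1.0 / np.sqrt(curve.pair_count[occ]) if weighted else None
    try:
        popt, pcov = optimize.curve_fit(
            _decay_model, d, y, p0=p0, sigma=sigma,
            bounds=([-np.inf, -np.inf, 1.0], [np.inf, np.inf, 10 * span]),
            maxfev=20_000,
        )
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((3, 3), np.nan)
        converged = False
    resid = y - _decay_model(d, *popt)
    fit = DecayFit(c0=float(popt[0]), c_inf=float(popt[1]),
                   lam=float(popt[2]), covariance=pcov,
                   rss=float(resid @ resid), converged=converged)
    if fit.c0 < fit.c_inf:
        logger.warning("fitted c0 < c_inf (%g < %g): rising curve",
                       fit.c0, fit.c_inf)
    return fit


def normalized_curve(curve: DistanceBinnedCurve, fit: DecayFit) -> DistanceBinnedCurve:
    """Rescale bin means to (C(d) - C_inf) / (C0 - C_inf)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    denom = fit.c0 - fit.c_inf
    if abs(denom) < 1e-15:
        raise ValueError("c0 equals c_inf: normalised curve unidentifiable")
    return replace(curve, mean_value=(curve.mean_value - fit.c_inf) / denom)


def effective_length(
    fit: DecayFit, d0: float = 100.0, dmax: float = 1500.0
) -> EffectiveLength:
    """Normalised area under the fitted decay between d0 and dmax.

    Computed by adaptive quadrature of the fitted C(d); agreement with the
    closed-form antiderivative to 1e-9 is enforced as a consistency check.
    """
    if d0 >= dmax:
        raise ValueError("d0 must be smaller than dmax")
    if not fit.converged or not np.isfinite(fit.lam):
        raise ValueError("effective length requires a converged fit")
    if fit.c0 <= 0:
        return EffectiveLength(float("nan"), d0, dmax, undefined=True)
    area, _ = integrate.quad(fit.predict, d0, dmax,
                             epsabs=1e-12, epsrel=1e-12)
    lam_eff = area / fit.c0
    closed = (
        fit.c_inf * (dmax - d0)
        + (fit.c0 - fit.c_inf) * fit.lam
        * (np.exp(-d0 / fit.lam) - np.exp(-dmax / fit.lam))
    ) / fit.c0
    if abs(lam_eff - closed) > 1e-9 * max(1.0, abs(closed)):
        raise AssertionError("quadrature disagrees with closed form")
    return EffectiveLength(float(lam_eff), d0, dmax)


def effective_length_trapezoid(
    curve: DistanceBinnedCurve, d0: float = 100.0, dmax: float = 1500.0
) -> EffectiveLength:
    """Model-free variant: trapezoidal area of the binned curve itself.

    Integrates the occupied bin means (linearly interpolated over bin
    centres, clamped to the window covered by data) and normalises by the
    curve's value at the left edge of the window.  Well-defined for flat
    or non-monotone curves where the exponential fit is unidentifiable;
    undefined (flagged) when the left-edge value is not positive.
    """
    if d0 >= dmax:
        raise ValueError("d0 must be smaller than dmax")
    occ = curve.occupied
    if occ.sum() < 2:
        raise ValueError("need >= 2 occupied bins")
    d = curve.bin_centers[occ]
    y = curve.mean_value[occ]
    lo = max(d0, float(d[0]))
    hi = min(dmax, float(d[-1]))
    if lo >= hi:
        raise ValueError("integration window does not overlap the data")
    grid = np.unique(np.concatenate([[lo, hi], d[(d > lo) & (d < hi)]]))
    vals = np.interp(grid, d, y)
    c0 = vals[0]
    if c0 <= 0:
        return EffectiveLength(float("nan"), d0, dmax, undefined=True)
    return EffectiveLength(float(np.trapezoid(vals, grid) / c0), d0, dmax)
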