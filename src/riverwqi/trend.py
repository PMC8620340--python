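"""Monotonic-trend screening and smoothing for annual monitoring series.

The screening pairs the Mann-Kendall test (does a monotonic trend exist?)
with Sen's slope estimator (how steep is it?), the standard nonparametric
combination for short hydrological series.  The Kruskal-Wallis test checks
whether the same parameter recorded at different sites (or years) shares one
distribution.  Loess with tricube weights smooths each series at several
neighbourhood spans for visual trend comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class TrendError(ValueError):
    pass


@dataclass
class TrendResult:
    """Mann-Kendall decision and Sen slope for one series."""

    series_id: str
    n: int
    S: int
    variance_S: float
    z: float
    p_value: float
    alpha: float
    decision: str  # increasing | decreasing | no_trend
    sen_slope: float | None


@dataclass
class LoessFit:
    span_alpha: float
    degree: int
    fitted: np.ndarray


def _clean(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    return x[~np.isnan(x)]


def mk_statistic(x: np.ndarray) -> int:
    """S = sum over i<j of sign(x_j - x_i)."""
    n = len(x)
    s = 0
    for i in range(n - 1):
        s += int(np.sign(x[i + 1:] - x[i]).sum())
    return s


def _tie_corrected_variance(x: np.ndarray) -> float:
    n = len(x)
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(x, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5)
    return var / 18.0


def _exact_s_distribution(n: int) -> dict[int, float]:
    """Exact null distribution of S for n distinct values.

    Built from the inversion-count generating polynomial
    prod_{i=1..n} (1 + x + ... + x^(i-1)); S = n(n-1)/2 - 2*inversions.
    """
    poly = np.array([1.0])
    for i in range(2, n + 1):
        poly = np.convolve(poly, np.ones(i))
    poly /= poly.sum()
    m = n * (n - 1) // 2
    return {m - 2 * k: p for k, p in enumerate(poly)}


def mann_kendall(
    series,
    alpha: float = 0.05,
    series_id: str = "",
    exact: bool = False,
    force_sen: bool = False,
) -> TrendResult:
    """Two-sided Mann-Kendall trend test with tie-corrected variance.

    The test statistic S depends only on the signs of pairwise differences,
    so the decision is invariant under strictly increasing transforms.  The
    normal approximation with continuity correction is used by default; for
    n <= 10 with no ties, ``exact=True`` uses the exact permutation null.

    Sen's slope is attached only when the null is rejected (matching the
    dash convention of trend tables), unless ``force_sen``.
    """
    x = _clean(series)
    n = len(x)
    if n < 4:
        raise TrendError(f"need n >= 4 non-missing values, got {n}")
    s = mk_statistic(x)
    var = _tie_corrected_variance(x)
    if var <= 0:  # all values tied
        z, p = 0.0, 1.0
    elif exact and n <= 10 and len(np.unique(x)) == n:
        # the symmetric permutation null covers both tails already
        dist = _exact_s_distribution(n)
        p = min(1.0, sum(pr for sv, pr in dist.items() if abs(sv) >= abs(s)))
        z = (s - np.sign(s)) / math.sqrt(var) if s != 0 else 0.0
    else:
        if exact and n <= 10:
            warnings.warn("ties present; falling back to normal approximation",
                          stacklevel=2)
        if s > 0:
            z = (s - 1) / math.sqrt(var)
        elif s < 0:
            z = (s + 1) / math.sqrt(var)
        else:
            z = 0.0
        p = 2 * stats.norm.sf(abs(z))
    if p <= alpha and s != 0:
        decision = "increasing" if s > 0 else "decreasing"
    else:
        decision = "no_trend"
    slope = sen_slope(x) if (decision != "no_trend" or force_sen) else None
    return TrendResult(
        series_id=series_id, n=n, S=s, variance_S=var, z=z, p_value=float(p),
        alpha=alpha, decision=decision, sen_slope=slope,
    )


def sen_slope(series) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(j - i), i < j.

    Missing values are skipped pairwise; indices keep their original
    positions so gaps widen the denominator.
    """
    x = np.asarray(series, dtype=float)
    idx = np.arange(len(x))
    ok = ~np.isnan(x)
    x, idx = x[ok], idx[ok]
    if len(x) < 2:
        raise TrendError("need at least one valid pair for Sen's slope")
    slopes = [
        (x[j] - x[i]) / (idx[j] - idx[i])
        for i in range(len(x) - 1)
        for j in range(i + 1, len(x))
    ]
    return float(np.median(slopes))


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-ranks) and chi-square p-value.

    Groups that are entirely missing are dropped with a warning.
    """
    cleaned = []
    for g in groups:
        arr = _clean(g)
        if len(arr) == 0:
            warnings.warn("dropping all-missing group", stacklevel=2)
            continue
        cleaned.append(arr)
    if len(cleaned) < 2:
        raise TrendError("Kruskal-Wallis needs at least 2 non-empty groups")
    if sum(len(g) for g in cleaned) < 5:
        raise TrendError("total n >= 5 required for the chi-square approximation")
    if all(np.all(g == cleaned[0][0]) for g in cleaned):
        return 0.0, 1.0  # identical constants: no evidence of any difference
    h, p = stats.kruskal(*cleaned)
    return float(h), float(p)


def loess_fit(x, y, span_alpha: float, degree: int = 2) -> LoessFit:
    """Locally weighted polynomial regression with tricube weights.

    At each target point the ``ceil(span_alpha * n)`` nearest neighbours (by
    |x| distance) receive tricube weights w = (1 - (d/d_max)^3)^3 and a
    degree-1 or degree-2 polynomial is fitted by weighted least squares; the
    fitted value at the target is returned, aligned to input order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise TrendError("degree must be 1 or 2")
    n = len(x)
    q = int(math.ceil(span_alpha * n))
    if q < degree + 1:
        raise TrendError(
            f"span {span_alpha} gives {q} neighbours; need >= {degree + 1}"
        )
    q = min(q, n)
    fitted = np.empty(n)
    for t in range(n):
        d = np.abs(x - x[t])
        nn = np.argsort(d, kind="stable")[:q]
        dmax = d[nn].max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = np.clip(1 - (d[nn] / dmax) ** 3, 0, None) ** 3
            w[w <= 0] = 1e-12  # keep the boundary neighbour in the solve
        design = np.vander(x[nn] - x[t], degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[nn] * sw, rcond=None)
        fitted[t] = beta[0]
    return LoessFit(span_alpha=span_alpha, degree=degree, fitted=fitted)


def flatten_panel(panel, parameter: str, order: str = "station_major") -> np.ndarray:
    """Flatten one parameter's panel into a single series for loess.

    ``station_major`` concatenates each station's years in station order (the
    spatio-temporal variation curve); ``year_major`` interleaves stations
    within each year.
    """
    df = panel.data[panel.data["parameter"] == parameter]
    if order == "station_major":
        keys = [(s, y) for s in panel.stations for y in panel.periods]
    elif order == "year_major":
        keys = [(s, y) for y in panel.periods for s in panel.stations]
    else:
        raise TrendError(f"unknown flattening order {order!r}")
    lookup = {(r["station"], r["year"]): r["value"] for _, r in df.iterrows()}
    return np.array([lookup.get(k, np.nan) for k in keys])
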