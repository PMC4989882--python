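"""Root-to-tip regression: the temporal-signal model.

Under a strict molecular clock the expected genetic divergence of tip *i*
from the root is

    E[d_i] = u * (t_i - t_r)

where ``u`` is the substitution rate (substitutions/site/year), ``t_i`` the
sampling time and ``t_r`` the time of the root. Ordinary least squares of
``d_i`` on ``t_i`` therefore estimates ``u`` as the slope and ``t_r`` as the
x-intercept. A *negative* fitted rate is a legal outcome and signals that the
data carry little or no temporal signal; it is reported, never raised.

Because tips share ancestry, the points are not independent: no p-values or
confidence intervals are computed anywhere in this package, and R² is
reported only as an informal measure of dispersion around the line.

All sums are accumulated on centred variables, which keeps the fit stable
when times are calendar years (~2e3) and distances are small (~1e-2), up to
very large numbers of tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import DegenerateRegressionError, IsochronousDataError

__all__ = ["RttPoint", "RegressionFit", "fit_root_to_tip", "regression_report"]


@dataclass(frozen=True)
class RttPoint:
    """One regression point: a tip's sampling time and root-to-tip distance,
    plus its signed residual (observed minus fitted distance)."""

    label: str
    time: float        # t_i, decimal years (internal forward axis)
    distance: float    # d_i, substitutions/site
    residual: float    # substitutions/site


@dataclass(frozen=True)
class RegressionFit:
    """Summary of the OLS fit of distance on time.

    ``x_intercept`` is the root-time point estimate -intercept/slope; it is
    NaN when the slope is exactly zero. ``r_squared`` is defined as 0 when
    the distances have zero variance.
    """

    slope: float          # u, substitutions/site/year
    intercept: float      # substitutions/site at t = 0
    x_intercept: float    # t_r, years (NaN if slope == 0)
    correlation: float    # Pearson r
    r_squared: float
    rss: float            # residual sum of squares, (subs/site)^2
    n: int


def fit_root_to_tip(
    points: Sequence[Tuple[str, float, float]],
) -> Tuple[RegressionFit, List[RttPoint]]:
    """Fit the clock regression to labelled (time, distance) points.

    Parameters
    ----------
    points:
        Sequence of ``(label, t_i, d_i)`` triples, one per tip.

    Returns the fit summary and the per-tip points with residuals.

    Raises
    ------
    DegenerateRegressionError
        Fewer than 3 points.
    IsochronousDataError
        All sampling times identical — use the isochronous analysis
        (variance of root-to-tip distances) instead.
    """
    n = len(points)
    if n < 3:
        raise DegenerateRegressionError(
            f"root-to-tip regression needs at least 3 tips, got {n}"
        )
    labels = [p[0] for p in points]
    t = np.asarray([p[1] for p in points], dtype=float)
    d = np.asarray([p[2] for p in points], dtype=float)
    if np.ptp(t) == 0.0:
        raise IsochronousDataError(
            "all sampling times are identical; the regression on time is "
            "undefined — use isochronous mode (variance of root-to-tip "
            "distances) instead"
        )

    t_mean = t.mean()
    d_mean = d.mean()
    tc = t - t_mean
    dc = d - d_mean
    ctt = float(tc @ tc)
    ctd = float(tc @ dc)
    cdd = float(dc @ dc)

    slope = ctd / ctt
    intercept = d_mean - slope * t_mean
    if slope == 0.0:
        x_intercept = math.nan
    else:
        x_intercept = -intercept / slope
    if cdd == 0.0:
        correlation = 0.0
        r_squared = 0.0
    else:
        correlation = ctd / math.sqrt(ctt * cdd)
        # rounding on (near-)collinear data can push |r| past 1
        correlation = min(1.0, max(-1.0, correlation))
        r_squared = correlation * correlation
    residuals = dc - slope * tc
    rss = float(residuals @ residuals)

    fit = RegressionFit(
        slope=slope,
        intercept=intercept,
        x_intercept=x_intercept,
        correlation=correlation,
        r_squared=r_squared,
        rss=rss,
        n=n,
    )
    rtt = [
        RttPoint(label=lbl, time=float(ti), distance=float(di),
                 residual=float(ri))
        for lbl, ti, di, ri in zip(labels, t, d, residuals)
    ]
    return fit, rtt


def regression_report(
    fit: RegressionFit, points: Sequence[RttPoint]
) -> Dict[str, object]:
    """Structured summary of a fit, suitable for JSON serialisation.

    Deliberately excludes p-values and confidence intervals: regression
    points share phylogenetic ancestry and are not independent, so those
    quantities would not be valid. R² is labelled as an informal dispersion
    measure for the same reason.
    """
    res = np.asarray([p.residual for p in points], dtype=float)
    return {
        "n": fit.n,
        "slope": fit.slope,
        "slope_units": "substitutions/site/year",
        "intercept": fit.intercept,
        "x_intercept": None if math.isnan(fit.x_intercept) else fit.x_intercept,
        "x_intercept_meaning": "root time point estimate (years)",
        "correlation": fit.correlation,
        "r_squared": fit.r_squared,
        "r_squared_note": (
            "informal dispersion measure; points are phylogenetically "
            "correlated, not suitable for hypothesis testing"
        ),
        "rss": fit.rss,
        "residual_mean": float(res.mean()),
        "residual_sd": float(res.std(ddof=0)),
    }
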