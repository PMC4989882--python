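"""Data-quality diagnostics for root-to-tip regressions.

Two anomaly geometries matter when screening heterochronous data:

* a large *y-residual*: the tip is far more (or less) diverged than its
  sampling date predicts — sequencing/assembly/alignment problems,
  recombination or hypermutation push a point above the line; archived
  ("frozen") strains that stopped evolving in storage fall below it;
* a large *x-displacement*: the horizontal gap between the tip's sampling
  time and the time at which the regression line reaches the tip's
  divergence — the signature of a mislabelled or contaminated sample whose
  recorded date does not match its divergence.

Ancestor traces make the distinction visible: each tip's point is connected
to the point on the regression line whose divergence equals the root-to-tip
distance of the tip's immediate ancestor. A frozen strain's trace runs far
back in time; a merely noisy tip's trace stays short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import DegenerateRegressionError, TipTempoError
from .regression import RegressionFit, RttPoint
from .tree import PhyloTree

__all__ = [
    "TraceSegment",
    "Side",
    "TipFlag",
    "ancestor_traces",
    "classify_tips",
    "residual_summary",
]


@dataclass(frozen=True)
class TraceSegment:
    """Geometry of one ancestor trace.

    The trace connects the tip's regression point ``(time, distance)`` to
    the point on the fitted line with divergence equal to the parent node's
    root-to-tip distance: ``(trace_time, parent_divergence)`` where
    ``trace_time = t_r + parent_divergence / u``.
    """

    label: str
    time: float
    distance: float
    parent_divergence: float
    trace_time: float


class Side(Enum):
    ABOVE = "above"   # more diverged than expected for the sampling date
    BELOW = "below"   # less diverged (residual exactly 0 is BELOW, a fixed
                      # convention for determinism)


@dataclass(frozen=True)
class TipFlag:
    label: str
    side: Side
    y_residual: float          # substitutions/site
    x_displacement: float      # years; NaN when the slope is 0
    flagged: bool              # |standardised y-residual| > k


def ancestor_traces(
    tree: PhyloTree,
    fit: RegressionFit,
    points: Sequence[RttPoint],
) -> List[TraceSegment]:
    """Compute the ancestor trace for every tip.

    The parent divergence is measured on the same rooted tree that produced
    the regression distances. Requires a nonzero slope: with no temporal
    trend the projection onto the line is undefined.
    """
    if fit.slope == 0.0 or math.isnan(fit.slope):
        raise TipTempoError(
            "ancestor traces undefined without a temporal trend (slope is 0)"
        )
    depths = tree.depths()
    parent_div: Dict[str, float] = {}
    for tip in tree.tips:
        parent_div[tip.label] = depths[tip.parent] if tip.parent else 0.0
    out: List[TraceSegment] = []
    for p in points:
        d_p = parent_div[p.label]
        trace_time = (d_p - fit.intercept) / fit.slope
        out.append(
            TraceSegment(
                label=p.label,
                time=p.time,
                distance=p.distance,
                parent_divergence=d_p,
                trace_time=trace_time,
            )
        )
    return out


def classify_tips(
    points: Sequence[RttPoint],
    fit: RegressionFit,
    k: float = 3.0,
) -> List[TipFlag]:
    """Classify every tip relative to the regression line.

    ``side`` is ABOVE iff the y-residual is strictly positive. A tip is
    ``flagged`` when its |y-residual| exceeds ``k`` standard deviations of
    the residual distribution (population SD). ``x_displacement`` is
    ``t_i - (t_r + d_i/u)``, the horizontal distance from the point to the
    line; NaN when the slope is zero. The default k = 3 is a screening
    threshold only — raw residuals are always reported so users can apply
    their own judgement.
    """
    if k <= 0:
        raise ValueError("threshold k must be positive")
    res = np.asarray([p.residual for p in points], dtype=float)
    sd = float(res.std(ddof=0))
    # residual spread at the level of float rounding on the distances is
    # an exact fit, not dispersion: never flag in that regime
    scale = max((abs(p.distance) for p in points), default=0.0)
    floor = scale * 1e-9
    out: List[TipFlag] = []
    for p in points:
        if fit.slope != 0.0 and not math.isnan(fit.slope):
            x_disp = p.time - (p.distance - fit.intercept) / fit.slope
        else:
            x_disp = math.nan
        out.append(
            TipFlag(
                label=p.label,
                side=Side.ABOVE if p.residual > 0.0 else Side.BELOW,
                y_residual=p.residual,
                x_displacement=x_disp,
                flagged=bool(sd > floor and abs(p.residual) > k * sd),
            )
        )
    return out


def residual_summary(
    points: Sequence[RttPoint],
) -> Dict[str, object]:
    """Histogram and scatter data for the residuals panel.

    Histogram bins follow the Freedman–Diaconis rule with a floor of 5
    bins; an all-equal residual vector collapses to a single bin centred on
    the common value. The scatter pairs (fitted value, residual) are sorted
    by fitted value.
    """
    if len(points) < 3:
        raise DegenerateRegressionError(
            "residual summary needs at least 3 points"
        )
    res = np.asarray([p.residual for p in points], dtype=float)
    fitted = np.asarray(
        [p.distance - p.residual for p in points], dtype=float
    )
    if np.ptp(res) == 0.0:
        centre = float(res[0])
        half = max(abs(centre), 1.0) * 1e-12
        edges = np.array([centre - half, centre + half])
        counts = np.array([len(res)])
        rule = "single bin (all residuals identical)"
    else:
        edges = np.histogram_bin_edges(res, bins="fd")
        if len(edges) - 1 < 5:
            edges = np.histogram_bin_edges(res, bins=5)
        counts, edges = np.histogram(res, bins=edges)
        rule = "Freedman-Diaconis, minimum 5 bins"
    order = np.argsort(fitted, kind="stable")
    scatter: List[Tuple[float, float]] = [
        (float(fitted[i]), float(res[i])) for i in order
    ]
    return {
        "bin_rule": rule,
        "bin_edges": [float(e) for e in edges],
        "counts": [int(c) for c in counts],
        "scatter": scatter,
    }
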