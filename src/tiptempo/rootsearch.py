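"""Best-fitting-root search by exact quadratic minimisation.

Moving the root to a point at distance ``y = x*b`` from the parent end of an
edge of length ``b`` changes every tip's root-to-tip distance by an affine
function of ``x``: tips below the edge get ``d_i(x) = dist(child, i) +
b*(1-x)`` and all other tips get ``d_i(x) = dist(parent, i) + b*x``. Both
rooting criteria —

* RSS: the residual sum of squares of the OLS regression of distance on
  sampling time (heterochronous data), and
* VARIANCE: the population variance of the root-to-tip distances
  (isochronous data)

— depend on the distances only through the moments Σd, Σd², Σt·d, which are
polynomials of degree ≤ 2 in ``x``. Each per-edge objective is therefore an
exact quadratic, minimised in closed form; no iterative search and no
materialised rerooting is needed during the scan.

The per-edge moment aggregates are computed for *all* edges with two tree
traversals (a tip-to-root "down" pass and a root-to-tip "up" pass), so the
whole-tree search costs O(edges) after O(tips) precomputation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional

import numpy as np

from .dates import TipDateSet
from .errors import IsochronousDataError, MissingDatesError, TipTempoError
from .regression import RegressionFit, RttPoint, fit_root_to_tip
from .tree import Node, PhyloTree, RootPlacement, reroot, root_to_tip_distances

logger = logging.getLogger(__name__)

__all__ = [
    "Criterion",
    "EdgeObjective",
    "BestRootResult",
    "objective_at",
    "optimize_on_edge",
    "find_best_root",
]


class Criterion(Enum):
    RSS = "rss"            # heterochronous: residual sum of squares
    VARIANCE = "variance"  # isochronous: variance of root-to-tip distances


@dataclass(frozen=True)
class EdgeObjective:
    """The rooting objective restricted to one edge, as a quadratic
    ``a*x^2 + b*x + c`` in the placement fraction ``x`` (from the parent
    end), together with its constrained minimiser on [0, 1]."""

    child: Node
    a: float
    b: float
    c: float
    argmin: float
    value: float

    def __call__(self, x: float) -> float:
        return self.a * x * x + self.b * x + self.c


@dataclass
class BestRootResult:
    placement: RootPlacement          # on the ORIGINAL tree
    tree: PhyloTree                   # rerooted copy
    criterion: Criterion
    objective: float                  # criterion value at the optimum
    fit: Optional[RegressionFit] = None       # RSS criterion only
    points: Optional[List[RttPoint]] = None   # RSS criterion only
    variance: Optional[float] = None          # VARIANCE criterion only


# ---------------------------------------------------------------------------
# moment bookkeeping
# ---------------------------------------------------------------------------

# stats over a set of tips, distances measured from a reference point:
# (n, St, Sd, Sdd, Std) with S* plain sums; times are globally centred.
_ZERO = (0.0, 0.0, 0.0, 0.0, 0.0)


def _shift(stats, length: float):
    """Re-reference the distances of a tip set through an edge of ``length``
    (every distance grows by ``length``)."""
    n, st, sd, sdd, std = stats
    return (
        n,
        st,
        sd + n * length,
        sdd + 2.0 * length * sd + n * length * length,
        std + length * st,
    )


def _add(a, b):
    return tuple(x + y for x, y in zip(a, b))


class _EdgeSearch:
    """Precomputed per-edge moment aggregates for one tree + date set."""

    def __init__(self, tree: PhyloTree, dates: Optional[TipDateSet],
                 criterion: Criterion):
        self.tree = tree
        self.criterion = criterion
        tips = tree.tips
        if criterion is Criterion.RSS:
            if dates is None:
                raise MissingDatesError(
                    "the RSS criterion requires sampling dates for all tips"
                )
            atimes = dates.analysis_times()
            missing = [t.label for t in tips if t.label not in atimes]
            if missing:
                raise MissingDatesError(
                    "tips without dates: " + ", ".join(sorted(missing)),
                    missing_in_dates=missing,
                )
            raw = np.asarray([atimes[t.label] for t in tips], dtype=float)
            if np.ptp(raw) == 0.0:
                raise IsochronousDataError(
                    "all sampling times identical: the RSS criterion is "
                    "undefined — use the VARIANCE (isochronous) criterion"
                )
            self.t_mean = float(raw.mean())
            centred = raw - self.t_mean
            self.ctt = float(centred @ centred)
            times = {t.label: c for t, c in zip(tips, centred)}
        else:
            # times unused; keep zeros so the moment algebra is uniform
            self.t_mean = 0.0
            self.ctt = math.nan
            times = {t.label: 0.0 for t in tips}

        # down pass: stats over clade(v), distances from v
        down: Dict[Node, tuple] = {}
        for node in tree.postorder():
            if node.is_leaf:
                ti = times[node.label]
                down[node] = (1.0, ti, 0.0, 0.0, 0.0)
            else:
                acc = _ZERO
                for ch in node.children:
                    acc = _add(acc, _shift(down[ch], ch.length))
                down[node] = acc
        # up pass: stats over tips outside clade(v), distances from parent(v)
        up: Dict[Node, tuple] = {}
        for node in tree.preorder():
            for ch in node.children:
                acc = _ZERO if node is tree.root else _shift(up[node],
                                                             node.length)
                for sib in node.children:
                    if sib is not ch:
                        acc = _add(acc, _shift(down[sib], sib.length))
                up[ch] = acc
        self.down = down
        self.up = up

    def value(self, child: Node, fraction: float) -> float:
        """Criterion value for the root at ``fraction`` along the edge
        identified by ``child`` (from the parent end)."""
        b = child.length
        y = fraction * b
        inside = _shift(self.down[child], b - y)
        outside = _shift(self.up[child], y)
        n, st, sd, sdd, std = _add(inside, outside)
        cdd = sdd - sd * sd / n
        if self.criterion is Criterion.VARIANCE:
            return cdd / n
        ctd = std - st * sd / n
        return cdd - ctd * ctd / self.ctt


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def objective_at(
    tree: PhyloTree,
    placement: RootPlacement,
    dates: Optional[TipDateSet],
    criterion: Criterion,
) -> float:
    """Evaluate the rooting criterion at one candidate placement.

    Equivalent to rerooting the tree at ``placement`` and computing the
    criterion on the rerooted tree, but performed analytically via the
    moment decomposition (no tree is materialised).
    """
    search = _EdgeSearch(tree, dates, criterion)
    return search.value(placement.child, placement.fraction)


def optimize_on_edge(
    tree: PhyloTree,
    edge: Node,
    dates: Optional[TipDateSet],
    criterion: Criterion,
    _search: Optional[_EdgeSearch] = None,
) -> EdgeObjective:
    """Minimise the rooting criterion over one edge (identified by its
    child node).

    The exact quadratic is recovered from evaluations at x ∈ {0, ½, 1};
    a convex quadratic is minimised at its clipped vertex, otherwise the
    better endpoint wins (ties go to the smaller fraction). Zero-length
    edges are degenerate — every fraction is equivalent and 0 is reported.
    """
    search = _search if _search is not None else _EdgeSearch(tree, dates,
                                                             criterion)
    f0 = search.value(edge, 0.0)
    if edge.length == 0.0:
        return EdgeObjective(child=edge, a=0.0, b=0.0, c=f0,
                             argmin=0.0, value=f0)
    fh = search.value(edge, 0.5)
    f1 = search.value(edge, 1.0)
    a = 2.0 * (f0 + f1 - 2.0 * fh)
    b = -3.0 * f0 + 4.0 * fh - f1
    c = f0
    if a > 0.0:
        x = min(1.0, max(0.0, -b / (2.0 * a)))
    else:
        x = 0.0 if f0 <= f1 else 1.0
    value = search.value(edge, x)  # direct evaluation at the minimiser
    return EdgeObjective(child=edge, a=a, b=b, c=c, argmin=x, value=value)


def find_best_root(
    tree: PhyloTree,
    dates: Optional[TipDateSet],
    criterion: Criterion,
) -> BestRootResult:
    """Search every edge for the globally best-fitting root.

    Returns the winning placement (on the input tree), a rerooted copy, and
    the refitted regression (RSS criterion) or the root-to-tip distance
    variance (VARIANCE criterion). The objective at the optimum is never
    worse than at the input rooting, since the input root lies in the
    search domain. Ties are broken by preorder edge index, then by the
    smaller fraction, so results are reproducible across runs.

    A negative fitted rate at the best root is reported with a warning —
    it indicates little or no temporal signal, not an error.
    """
    if tree.n_tips < 3:
        raise TipTempoError("best-root search needs at least 3 tips")
    search = _EdgeSearch(tree, dates, criterion)
    best: Optional[EdgeObjective] = None
    for child in tree.edges():
        eo = optimize_on_edge(tree, child, dates, criterion, _search=search)
        if best is None or eo.value < best.value:
            best = eo
    assert best is not None
    placement = RootPlacement(child=best.child, fraction=best.argmin)
    rerooted = reroot(tree, placement)

    result = BestRootResult(
        placement=placement,
        tree=rerooted,
        criterion=criterion,
        objective=best.value,
    )
    dists = root_to_tip_distances(rerooted)
    if criterion is Criterion.RSS:
        atimes = dates.analysis_times()
        fit, points = fit_root_to_tip(
            [(lbl, atimes[lbl], dist) for lbl, dist in dists.items()]
        )
        result.fit = fit
        result.points = points
        if fit.slope < 0:
            logger.warning(
                "best-fitting root yields a NEGATIVE rate (%.3g): the data "
                "contain little or no temporal signal", fit.slope,
            )
    else:
        vals = np.asarray(list(dists.values()), dtype=float)
        result.variance = float(vals.var(ddof=0))
    return result
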