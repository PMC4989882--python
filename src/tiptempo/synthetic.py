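"""Clock-tree simulator with known ground truth.

Generates heterochronous trees the way the regression model assumes they
arise: tips are sampled at known calendar times, a genealogy is built
backward in time by random pairwise coalescences with exponential waiting
times, and every branch's genetic length is its time duration multiplied by
the substitution rate (optionally perturbed by a lognormal per-branch
multiplier, the usual relaxed-clock picture). With zero rate noise the
root-to-tip distances lie exactly on the line ``d = u (t - t_r)``, so slope,
x-intercept and R² of the regression recover the simulated truth to machine
precision — the yardstick every other module is tested against.

Three anomaly types mirror the data-quality problems the diagnostics are
built to expose:

* ``Frozen``: an archived strain — its recorded date is advanced by the
  storage time while its divergence is unchanged (under-diverged for its
  date; large negative y-residual);
* ``Misdated``: the recorded date is shifted (large x-displacement);
* ``Divergent``: extra genetic distance on the terminal branch, as a
  recombinant or low-quality sequence would show (large positive
  y-residual).

A single integer seed determines everything, including anomaly noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .dates import TimeDirection, TipDateSet
from .errors import TipTempoError
from .tree import Node, PhyloTree, RootPlacement, reroot

__all__ = [
    "Frozen",
    "Misdated",
    "Divergent",
    "SimulationConfig",
    "simulate_clock_tree",
    "inject_anomaly",
    "revert_anomaly",
    "scramble_root",
    "make_ultrametric",
]


@dataclass(frozen=True)
class Frozen:
    """Archived strain: date advanced by ``storage_years``; divergence
    untouched."""
    tip: str
    storage_years: float


@dataclass(frozen=True)
class Misdated:
    """Annotation error: date shifted by ``shift_years`` (either sign)."""
    tip: str
    shift_years: float


@dataclass(frozen=True)
class Divergent:
    """Excess divergence: ``extra_distance`` (subs/site) added to the
    terminal branch."""
    tip: str
    extra_distance: float


Anomaly = Union[Frozen, Misdated, Divergent]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated data set.

    Defaults describe a typical rapidly evolving RNA-virus data set: 50
    tips sampled over a 15-year window, rate 3e-3 substitutions/site/year,
    a root a decade before the first samples, and a strict clock
    (``rate_noise`` 0; set a lognormal sigma such as 0.05 for mild
    relaxed-clock scatter on per-branch rate multipliers).

    ``pop_size`` is the coalescent time-scale (years); waiting times
    between joins are exponential with rate k(k-1)/(2*pop_size) for k
    active lineages. By default it is a quarter of the gap between the
    sampling window start and the root time, which keeps almost all
    coalescences inside that gap; lineages still uncoalesced at
    ``root_time`` join there in a single (possibly multifurcating) root, so
    the realised root time always equals ``root_time``.
    """

    n_tips: int = 50
    root_time: float = 1990.0
    sampling_window: Tuple[float, float] = (2000.0, 2015.0)
    rate: float = 3e-3                # u, substitutions/site/year
    rate_noise: float = 0.0           # lognormal sigma on branch multipliers
    anomalies: Tuple[Anomaly, ...] = ()
    seed: int = 0
    pop_size: Optional[float] = None

    def __post_init__(self):
        if self.n_tips < 3:
            raise TipTempoError("n_tips must be >= 3")
        lo, hi = self.sampling_window
        if not lo < hi:
            raise TipTempoError("sampling window must be non-empty")
        if lo <= self.root_time:
            raise TipTempoError(
                f"sampling window starts at {lo} but the root is at "
                f"{self.root_time}; tips cannot predate the root"
            )
        if self.rate <= 0:
            raise TipTempoError("rate must be positive")
        if self.rate_noise < 0:
            raise TipTempoError("rate_noise must be >= 0")


def simulate_clock_tree(
    config: SimulationConfig,
) -> Tuple[PhyloTree, TipDateSet, Dict[str, object]]:
    """Simulate one clock tree; returns (tree, dates, truth record).

    The tree is returned rooted at the TRUE root. ``truth`` records the
    rate, root time, per-tip sampling times and every injected anomaly.
    Identical configs produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tips
    lo, hi = config.sampling_window
    tip_times = rng.uniform(lo, hi, size=n)
    width = max(3, len(str(n)))
    labels = [f"t{i + 1:0{width}d}" for i in range(n)]

    node_time: Dict[Node, float] = {}
    leaves = []
    for lbl, t in zip(labels, tip_times):
        leaf = Node(label=lbl)
        node_time[leaf] = float(t)
        leaves.append(leaf)

    ne = config.pop_size
    if ne is None:
        ne = (lo - config.root_time) / 4.0

    # backward-in-time event loop: lineages become active when the clock
    # passes their sampling time; active pairs coalesce at exponential waits
    order = sorted(leaves, key=lambda nd: node_time[nd], reverse=True)
    active: List[Node] = []
    idx = 0
    cur = node_time[order[0]]

    def join(members: Sequence[Node], at: float) -> Node:
        parent = Node(label=None)
        node_time[parent] = at
        for m in members:
            m.parent = parent
            parent.children.append(m)
        return parent

    while True:
        if len(active) == 2 and idx == n:
            # final coalescence pinned to the configured root time
            root = join(active, config.root_time)
            break
        if len(active) < 2:
            tip = order[idx]
            idx += 1
            cur = node_time[tip]
            active.append(tip)
            continue
        k = len(active)
        wait = rng.exponential(2.0 * ne / (k * (k - 1)))
        cand = cur - wait
        if idx < n and node_time[order[idx]] >= cand:
            tip = order[idx]
            idx += 1
            cur = node_time[tip]
            active.append(tip)
            continue
        if cand <= config.root_time:
            # ran out of time: everything still active joins at the root
            root = join(active, config.root_time)
            break
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = join([active[i], active[j]], cand)
        active = [a for idx2, a in enumerate(active) if idx2 not in (i, j)]
        active.append(parent)
        cur = cand

    tree = PhyloTree(root)
    # genetic branch lengths: duration x rate x optional lognormal multiplier
    for node in tree.preorder():
        if node.parent is None:
            continue
        duration = node_time[node] - node_time[node.parent]
        mult = rng.lognormal(0.0, config.rate_noise) if config.rate_noise > 0 else 1.0
        node.length = config.rate * duration * mult

    dates = TipDateSet(
        times={lbl: float(t) for lbl, t in zip(labels, tip_times)},
        direction=TimeDirection.FORWARD,
    )
    truth: Dict[str, object] = {
        "rate": config.rate,
        "root_time": config.root_time,
        "rate_noise": config.rate_noise,
        "n_tips": n,
        "seed": config.seed,
        "tip_times": dict(dates.times),
        "anomalies": [],
    }
    for anomaly in config.anomalies:
        tree, dates, record = inject_anomaly(tree, dates, anomaly)
        truth["anomalies"].append(record)
    return tree, dates, truth


def inject_anomaly(
    tree: PhyloTree, dates: TipDateSet, anomaly: Anomaly
) -> Tuple[PhyloTree, TipDateSet, Dict[str, object]]:
    """Apply one anomaly; inputs are not mutated.

    Returns new (tree, dates) plus a truth record describing the edit.
    """
    if anomaly.tip not in dates.times or anomaly.tip not in set(
        tree.tip_labels
    ):
        raise TipTempoError(f"unknown tip {anomaly.tip!r}")
    new_times = dict(dates.times)
    new_tree = tree
    if isinstance(anomaly, Frozen):
        new_times[anomaly.tip] += anomaly.storage_years
        record = {"type": "frozen", "tip": anomaly.tip,
                  "storage_years": anomaly.storage_years}
    elif isinstance(anomaly, Misdated):
        new_times[anomaly.tip] += anomaly.shift_years
        record = {"type": "misdated", "tip": anomaly.tip,
                  "shift_years": anomaly.shift_years}
    elif isinstance(anomaly, Divergent):
        new_tree = tree.copy()
        for tip in new_tree.tips:
            if tip.label == anomaly.tip:
                tip.length += anomaly.extra_distance
                break
        record = {"type": "divergent", "tip": anomaly.tip,
                  "extra_distance": anomaly.extra_distance}
    else:  # pragma: no cover
        raise TipTempoError(f"unknown anomaly type {anomaly!r}")
    return new_tree, TipDateSet(times=new_times,
                                direction=dates.direction), record


def revert_anomaly(
    tree: PhyloTree, dates: TipDateSet, anomaly: Anomaly
) -> Tuple[PhyloTree, TipDateSet, Dict[str, object]]:
    """Apply the inverse edit of ``anomaly`` (exact round-trip)."""
    if isinstance(anomaly, Frozen):
        inverse: Anomaly = Frozen(anomaly.tip, -anomaly.storage_years)
    elif isinstance(anomaly, Misdated):
        inverse = Misdated(anomaly.tip, -anomaly.shift_years)
    else:
        inverse = Divergent(anomaly.tip, -anomaly.extra_distance)
    new_tree, new_dates, _ = inject_anomaly(tree, dates, inverse)
    return new_tree, new_dates, {"reverted": True}


def make_ultrametric(tree: PhyloTree) -> PhyloTree:
    """Equalise all root-to-tip distances by lengthening terminal branches.

    Turns a clock tree with heterochronous tips into the isochronous
    presentation (every tip equidistant from the root, as if all were
    sampled at the latest time while evolving at the same rate). The true
    root is then the unique point with zero root-to-tip distance variance.
    """
    out = tree.copy()
    depths = out.depths()
    target = max(depths[t] for t in out.tips)
    for tip in out.tips:
        tip.length += target - depths[tip]
    return out


def scramble_root(
    tree: PhyloTree, seed: int
) -> Tuple[PhyloTree, RootPlacement]:
    """Reroot at a uniformly random interior point of a random edge —
    the "arbitrarily rooted" presentation a distance-based or ML tree
    arrives in. Returns the rerooted tree and the placement used."""
    rng = np.random.default_rng(seed)
    edges = tree.edges()
    child = edges[int(rng.integers(len(edges)))]
    fraction = float(rng.uniform(0.05, 0.95))
    placement = RootPlacement(child=child, fraction=fraction)
    return reroot(tree, placement), placement
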