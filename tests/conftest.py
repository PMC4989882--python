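"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check:

* tip-tip distances come from dendropy's phylogenetic distance matrix on
  the serialised newick, not from the package's own tree walk;
* OLS fits come from scipy.stats.linregress;
* rooting objectives come from explicitly rerooting the tree and refitting,
  with per-edge affine distance structure recovered from two endpoint
  reroots (and verified by a third).
"""

from __future__ import annotations

import dendropy
import numpy as np
import pytest
from scipy import stats

import tiptempo as tt


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def dendropy_tip_distances(newick_text: str) -> dict:
    """Tip-tip path lengths via dendropy (independent of tiptempo's walk)."""
    dtree = dendropy.Tree.get(data=newick_text, schema="newick",
                              preserve_underscores=True)
    pdm = dtree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(dtree.taxon_namespace)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[frozenset((a.label, b.label))] = pdm.patristic_distance(a, b)
    return out


def parent_chain_distances(tree: tt.PhyloTree) -> dict:
    """Root-to-tip distances by an explicit per-tip upward walk."""
    out = {}
    for tip in tree.tips:
        total, node = 0.0, tip
        while node.parent is not None:
            total += node.length
            node = node.parent
        out[tip.label] = total
    return out


def scipy_ols(t, d):
    """Independent OLS: slope, intercept, r, rss."""
    res = stats.linregress(t, d)
    pred = res.intercept + res.slope * np.asarray(t)
    rss = float(np.sum((np.asarray(d) - pred) ** 2))
    return res.slope, res.intercept, res.rvalue, rss


def explicit_objective(tree, placement, dates, criterion):
    """Criterion value by literally rerooting and recomputing."""
    rerooted = tt.reroot(tree, placement)
    dists = tt.root_to_tip_distances(rerooted)
    if criterion is tt.Criterion.VARIANCE:
        return float(np.var(list(dists.values())))
    times = dates.analysis_times()
    labels = sorted(dists)
    _, _, _, rss = scipy_ols([times[l] for l in labels],
                             [dists[l] for l in labels])
    return rss


def edge_distance_profile(tree, child):
    """Per-tip distances as an affine function of the placement fraction,
    recovered from explicit reroots at the edge's two ends and verified by
    a third at the midpoint. Returns (labels, d0, d1)."""
    d0map = tt.root_to_tip_distances(
        tt.reroot(tree, tt.RootPlacement(child, 0.0)))
    d1map = tt.root_to_tip_distances(
        tt.reroot(tree, tt.RootPlacement(child, 1.0)))
    labels = sorted(d0map)
    d0 = np.array([d0map[l] for l in labels])
    d1 = np.array([d1map[l] for l in labels])
    if child.length > 0:
        dhmap = tt.root_to_tip_distances(
            tt.reroot(tree, tt.RootPlacement(child, 0.5)))
        dh = np.array([dhmap[l] for l in labels])
        assert np.allclose(dh, 0.5 * (d0 + d1), atol=1e-12), \
            "tip distances are not affine along the edge"
    return labels, d0, d1


def grid_rss(tree, child, dates, fractions):
    """Vectorised RSS over a grid of fractions on one edge, built on the
    explicit-reroot distance profile."""
    labels, d0, d1 = edge_distance_profile(tree, child)
    times = dates.analysis_times()
    t = np.array([times[l] for l in labels])
    tc = t - t.mean()
    ctt = float(tc @ tc)
    fr = np.asarray(fractions)
    D = d0[:, None] + fr[None, :] * (d1 - d0)[:, None]   # tips x grid
    Dc = D - D.mean(axis=0, keepdims=True)
    ctd = tc @ Dc
    cdd = np.sum(Dc * Dc, axis=0)
    return cdd - ctd * ctd / ctt


def grid_variance(tree, child, fractions):
    labels, d0, d1 = edge_distance_profile(tree, child)
    fr = np.asarray(fractions)
    D = d0[:, None] + fr[None, :] * (d1 - d0)[:, None]
    return np.var(D, axis=0)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def three_tip_tree():
    return tt.read_newick("((A:1,B:2):0.5,C:3);")


@pytest.fixture
def star_tree():
    return tt.read_newick("(A:1,B:1,C:1);")


@pytest.fixture
def noisefree_sim():
    cfg = tt.SimulationConfig(n_tips=20, rate=3e-3, rate_noise=0.0, seed=11)
    return tt.simulate_clock_tree(cfg)


@pytest.fixture
def noisy_sim():
    cfg = tt.SimulationConfig(n_tips=15, rate=3e-3, rate_noise=0.1, seed=23)
    return tt.simulate_clock_tree(cfg)


def fit_tree(tree, dates):
    """Convenience: regression on a tree's current rooting."""
    dists = tt.root_to_tip_distances(tree)
    times = dates.analysis_times()
    return tt.fit_root_to_tip(
        [(l, times[l], dists[l]) for l in sorted(dists)]
    )
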