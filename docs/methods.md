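# Methods

## The model

Given a rooted phylogeny whose branch lengths are genetic distances
(substitutions/site) and a sampling time `t_i` for every tip, a strict
molecular clock with rate `u` implies

    E[d_i] = u (t_i − t_r)

where `d_i` is the root-to-tip distance of tip `i` and `t_r` the time of the
root. Ordinary least squares of `d_i` on `t_i` estimates `u` as the slope
and `t_r` as the x-intercept (−intercept/slope). A tight linear trend
supports a strict clock; the same trend with more scatter suggests
branch-to-branch rate variation (a relaxed clock); no trend — or a negative
slope — means the data carry little usable temporal signal. A negative
fitted rate is therefore reported with a warning, never treated as an
error.

Because tips share ancestry, the regression points are **not independent**.
The package deliberately computes no p-values and no confidence intervals,
and labels R² an informal dispersion measure. This is a data-exploration
instrument, not a hypothesis test.

## Best-fitting root

An unrooted (or arbitrarily rooted) input leaves `t_r` and the distance
vector undefined, so the root is chosen to optimise a criterion over every
point of every edge:

* **RSS** (heterochronous data): residual sum of squares of the regression;
* **VARIANCE** (isochronous data): population variance of the root-to-tip
  distances.

Place the root at distance `x·b` from the parent end of an edge of length
`b`. Each tip's distance is affine in `x`: `dist(child, tip) + b(1−x)` for
tips below the edge, `dist(parent, tip) + b·x` for the rest. Both criteria
depend on the distances only through Σd, Σd² and Σt·d, so each per-edge
objective is an **exact quadratic** in `x`. The implementation evaluates it
at x ∈ {0, ½, 1}, reconstructs the quadratic, and minimises in closed form
(clipped vertex for a convex quadratic, better endpoint otherwise, ties to
the smaller fraction). No iterative 1-D search, no materialised rerooting
during the scan, and the result is deterministic.

The per-edge moment aggregates come from two traversals: a post-order pass
accumulating each clade's tip moments referenced to its root, and a
pre-order pass accumulating the complement referenced to each edge's
parent. Moments shift through an edge of length L in O(1)
(`Σ(d+L)² = Σd² + 2LΣd + nL²`, etc.), so the whole-tree scan is O(edges)
after O(tips) setup, and scales to very large trees. Sampling times are
centred before accumulating, which keeps calendar-year magnitudes (~2·10³)
away from catastrophic cancellation against distances (~10⁻²).

Global tie-breaks are fixed (preorder edge index, then smaller fraction);
zero-length edges are degenerate and report fraction 0. The input rooting
is itself a point of the search domain, so the returned objective is never
worse than the input's.

### Edge/fraction conventions

An edge is always identified by its **child** node and a fraction is
measured from the **parent** end. Rerooting at fraction exactly 0 or 1
places the root on the existing node with no zero-length edge — with one
exception: fraction 1 on a terminal edge keeps a zero-length pendant edge,
because collapsing the root onto a leaf would remove a taxon. A former
root left with a single child is always suppressed (its two incident edges
fused, lengths summed), so output trees contain no degree-2 nodes and the
unrooted tip-to-tip metric is preserved exactly.

## Dates

Sampling times are decimal years. Calendar dates convert leap-aware as
`year + (day_of_year − ½)/days_in_year`; partial dates map to the midpoint
of the stated period (bare year → +0.5; year-month → month midpoint). The
midpoint rule minimises the worst-case dating error but is a convention —
it shifts `t_r` estimates relative to a start-of-period rule, so it is
stated here prominently. Ages ("years before present", larger = older) are
supported via a direction flag: internally `t = −age`, so slope and R² are
unchanged and the x-intercept is negated back on output. Tips without
dates are an error unless explicitly dropped (`--drop-undated`), because
silently excluding them hides exactly the data problems the diagnostics
look for.

## Diagnostics

Per tip the package reports the signed **y-residual** (observed minus
fitted distance) and the **x-displacement** `t_i − (t_r + d_i/u)` — the
horizontal gap between the point and the line, defined when the slope is
nonzero. Over-divergence for the date (recombination, assembly or
alignment error, hypermutation) shows as a large positive residual;
archived/"frozen" strains that stopped evolving in storage show large
negative residuals; mislabelled or contaminated samples show large
x-displacements. **Ancestor traces** connect each tip's point to the point
on the fitted line whose divergence equals the tip's immediate ancestor's
root-to-tip distance; the trace time is `(d_parent − intercept)/slope` and
lies exactly on the line.

Tips are classed ABOVE/BELOW the line (residual exactly 0 → BELOW, an
arbitrary fixed convention), and flagged when |residual| exceeds
`k × SD(residuals)` (population SD; default k = 3, exposed as
`--outlier-k`). Two numerical guards: the flag never fires when the
residual SD is below 1e-9 × the largest distance (a fit perfect to float
rounding has no meaningful dispersion), and raw residuals are always
written out so users can apply their own threshold. Residual histograms
use the Freedman–Diaconis rule with a floor of five bins; an all-equal
residual vector collapses to a single bin.

No automated attribution of cause is attempted — the flags are leads for
human investigation, not verdicts.

## The simulator

`simulate_clock_tree` generates the conditions the method assumes. Tip
times are uniform on the sampling window (default 2000–2015, n = 50).
Going backward in time, lineages activate at their sampling times and
coalesce pairwise with exponential waits at rate `k(k−1)/(2·pop_size)`;
`pop_size` defaults to a quarter of the gap between the window start and
the root time so coalescence essentially always completes inside that gap.
Any lineages still active at the configured root time join there in a
single (possibly multifurcating) node, and the final pair always joins
exactly at the root time — so the realised root time equals the configured
one deterministically and the truth record is exact. Branch genetic
lengths are `rate × duration`, optionally multiplied by a lognormal(0, σ)
per-branch factor (median-1 relaxed-clock scatter; σ is the `rate_noise`
parameter). Default rate 3e-3 subs/site/year is typical of rapidly
evolving RNA viruses.

With `rate_noise = 0` the distances are exactly collinear with the times,
so slope, root time and R² = 1 are recovered to numerical precision; this
exactness anchors most oracles in the test suite. What the simulator does
**not** emulate: tree-estimation error (topology and branch-length noise
from finite alignments), systematic rate change through time, lineage
effects (local clocks), and recombination's topological signature. Passing
tests therefore demonstrate correctness of the regression/rooting
machinery on clock-generated trees, not robustness to phylogenetic error
on real data.

Anomalies are deterministic edits with recorded truth: `Frozen` advances a
tip's date by the storage time (divergence unchanged), `Misdated` shifts a
date, `Divergent` lengthens a terminal branch. On noise-free trees their
residual signatures follow the OLS hat matrix exactly — a shift of `s`
years produces a residual of `−u·s·(1−h_jj)`, extra distance `Δ` produces
`Δ(1−h_jj)` — and the test suite asserts those closed forms.

## Problem sizes and tolerances

The simulation-based checks use 10–50 tips, 10–100 replicates and
2001-point reference grids — sizes at which the brute-force oracles
(explicit reroot + independent OLS refit) are exact and fast while the
quantities measured (agreement to 1e-8…1e-12, detection rates over 100
replicates) are already stable. The analytic search itself is O(edges)
and is exercised up to 100 tips in the round-trip tests; nothing in it is
size-limited.

Key defaults: outlier threshold k = 3; negative branch lengths rejected
unless `--clamp-negative` (clamping can mask exactly the problems the tool
exists to reveal); missing branch lengths read as 0 with a warning (common
for root edges); newick output at repr precision (≥ 17 significant digits)
so write→read round-trips are exact.
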