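"""Optional matplotlib views: regression scatter with the fitted line and
ancestor traces, plus a residual histogram. Import lazily — plotting is
never required for an analysis to succeed."""

from __future__ import annotations

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .report import AnalysisReport


def plot_analysis(report: "AnalysisReport", path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    ax = axes[0]
    if report.points is not None and report.fit is not None:
        t = [p.time for p in report.points]
        d = [p.distance for p in report.points]
        ax.scatter(t, d, s=14, color="#333333", zorder=3)
        lo, hi = min(t), max(t)
        pad = 0.05 * (hi - lo)
        xs = [lo - pad, hi + pad]
        fit = report.fit
        ax.plot(xs, [fit.intercept + fit.slope * x for x in xs],
                color="#aa2222", lw=1.5, zorder=2)
        for seg in report.traces or []:
            ax.plot([seg.time, seg.trace_time],
                    [seg.distance, seg.parent_divergence],
                    color="#2a9d2a", lw=0.6, alpha=0.7, zorder=1)
        ax.set_xlabel("sampling time (years)")
        ax.set_ylabel("root-to-tip distance (subs/site)")
        ax.set_title(f"slope={fit.slope:.4g}  R²={fit.r_squared:.3f}")
        res = [p.residual for p in report.points]
        axes[1].hist(res, bins="auto", color="#4466aa")
        axes[1].set_xlabel("residual (subs/site)")
        axes[1].set_title("residuals")
    else:
        hist = report.stats.get("distance_histogram", {})
        edges = hist.get("bin_edges", [])
        counts = hist.get("counts", [])
        if len(edges) > 1:
            ax.stairs(counts, edges, fill=True, color="#4466aa")
        ax.set_xlabel("root-to-tip distance (subs/site)")
        ax.set_title("isochronous distance distribution")
        axes[1].axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
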