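"""End-to-end analysis workflow and report assembly.

``analyze`` ties the modules together: load tree → attach dates →
(optionally) search for the best-fitting root → fit the root-to-tip
regression → diagnostics → write output files. ``validate`` is the
pre-flight check: it reports tip/date mismatches, duplicate labels,
negative or missing branch lengths and unparseable dates without running
any analysis.

Every warning emitted during a run is collected into the report JSON so
machine consumers see exactly what an interactive user would.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np

from . import diagnostics as diag
from .dates import (
    DateRule,
    TimeDirection,
    TipDateSet,
    extract_dates_from_labels,
    load_dates_table,
    validate_date_coverage,
)
from .errors import IsochronousDataError, TipTempoError
from .regression import RegressionFit, RttPoint, fit_root_to_tip, regression_report
from .rootsearch import Criterion, find_best_root
from .tree import PhyloTree, read_newick, root_to_tip_distances, write_newick

logger = logging.getLogger(__name__)

__all__ = ["AnalysisOptions", "AnalysisReport", "analyze", "validate"]


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: List[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


@dataclass
class AnalysisOptions:
    best_root: bool = False
    criterion: Criterion = Criterion.RSS
    outlier_k: float = 3.0
    clamp_negative: bool = False
    drop_undated: bool = False
    plot: bool = False


@dataclass
class AnalysisReport:
    """Assembled results of one run; ``stats`` is the JSON-stable record."""

    mode: str                          # "heterochronous" | "isochronous"
    rooting: str                       # "user-supplied" | "best-fit"
    stats: Dict[str, object]
    tree: PhyloTree
    fit: Optional[RegressionFit] = None
    points: Optional[List[RttPoint]] = None
    flags: Optional[List[diag.TipFlag]] = None
    traces: Optional[List[diag.TraceSegment]] = None
    warnings: List[str] = field(default_factory=list)
    output_files: List[str] = field(default_factory=list)


def _resolve_dates(
    tree: PhyloTree,
    date_source: Union[None, str, TipDateSet, DateRule],
    backward: bool,
) -> Optional[TipDateSet]:
    direction = TimeDirection.BACKWARD if backward else TimeDirection.FORWARD
    if date_source is None:
        return None
    if isinstance(date_source, TipDateSet):
        return date_source
    if isinstance(date_source, str):
        return load_dates_table(date_source, direction=direction)
    # a DelimiterRule / RegexRule: extract from the tip labels themselves
    return extract_dates_from_labels(tree.tip_labels, date_source,
                                     direction=direction)


def analyze(
    tree_source: Union[str, PhyloTree],
    date_source: Union[None, str, TipDateSet, DateRule] = None,
    out_prefix: Optional[str] = None,
    options: Optional[AnalysisOptions] = None,
    backward: bool = False,
) -> AnalysisReport:
    """Run the full workflow.

    ``tree_source`` is a newick path or an in-memory tree; ``date_source``
    is a dates-table path, a TipDateSet, a label-extraction rule, or None
    for isochronous mode. When ``out_prefix`` is given the standard output
    files (PREFIX.rooted.nwk, PREFIX.rtt.tsv, PREFIX.diagnostics.tsv,
    PREFIX.stats.json, optionally PREFIX.plot.svg) are written.
    """
    options = options or AnalysisOptions()
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("tiptempo")
    pkg_logger.addHandler(collector)
    try:
        if isinstance(tree_source, str):
            with open(tree_source) as fh:
                tree = read_newick(fh.read(),
                                   clamp_negative=options.clamp_negative)
            tree_name = tree_source
        else:
            tree = tree_source
            tree_name = "<in-memory tree>"

        dates = _resolve_dates(tree, date_source, backward)
        if dates is not None:
            dates = validate_date_coverage(
                tree.tip_labels, dates, drop_undated=options.drop_undated
            )
            if dates.is_isochronous():
                raise IsochronousDataError(
                    "all tips share one sampling time; rerun without dates "
                    "(isochronous mode) to analyse root-to-tip distance "
                    "variance instead"
                )
        mode = "heterochronous" if dates is not None else "isochronous"
        # rooting criterion follows the mode; dated data may still opt into
        # variance rooting, but RSS without dates is impossible
        criterion = options.criterion
        if mode == "isochronous":
            criterion = Criterion.VARIANCE

        rooting = "user-supplied"
        placement_record = None
        if options.best_root:
            result = find_best_root(tree, dates, criterion)
            rooting = "best-fit"
            analysis_tree = result.tree
            placement_record = {
                "edge_child": result.placement.child.label
                or "internal node",
                "fraction_from_parent": result.placement.fraction,
                "objective": result.objective,
                "criterion": criterion.value,
            }
        else:
            analysis_tree = tree

        dists = root_to_tip_distances(analysis_tree)
        stats: Dict[str, object] = {
            "input": {"tree": tree_name, "n_tips": analysis_tree.n_tips,
                      "date_source": type(date_source).__name__
                      if date_source is not None else None},
            "mode": mode,
            "rooting": rooting,
            "placement": placement_record,
        }

        fit = points = flags = traces = None
        if mode == "heterochronous":
            atimes = dates.analysis_times()
            fit, points = fit_root_to_tip(
                [(lbl, atimes[lbl], d) for lbl, d in sorted(dists.items())
                 if lbl in atimes]  # undated tips only survive --drop-undated
            )
            if fit.slope < 0:
                logger.warning(
                    "negative evolutionary rate estimated (%.4g): the data "
                    "contain little or no temporal signal", fit.slope,
                )
            stats["regression"] = regression_report(fit, points)
            if dates.direction is TimeDirection.BACKWARD:
                # x-intercept back on the user's years-before-present axis
                reg = stats["regression"]
                if reg["x_intercept"] is not None:
                    reg["x_intercept_backward"] = -reg["x_intercept"]
            flags = diag.classify_tips(points, fit, k=options.outlier_k)
            if fit.slope != 0.0:
                traces = diag.ancestor_traces(analysis_tree, fit, points)
            stats["residuals"] = diag.residual_summary(points)
            stats["flagged_tips"] = [f.label for f in flags if f.flagged]
        else:
            vals = np.asarray(list(dists.values()), dtype=float)
            stats["distance_variance"] = float(vals.var(ddof=0))
            stats["distance_histogram"] = _distance_histogram(vals)

        report = AnalysisReport(
            mode=mode, rooting=rooting, stats=stats, tree=analysis_tree,
            fit=fit, points=points, flags=flags, traces=traces,
        )
        report.warnings = list(collector.messages)
        stats["warnings"] = report.warnings

        if out_prefix is not None:
            _write_outputs(report, out_prefix, options)
        return report
    finally:
        pkg_logger.removeHandler(collector)


def _distance_histogram(vals: np.ndarray) -> Dict[str, object]:
    if np.ptp(vals) == 0.0:
        centre = float(vals[0])
        return {"bin_edges": [centre, centre], "counts": [int(len(vals))]}
    counts, edges = np.histogram(vals, bins="auto")
    return {"bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts]}


def _write_outputs(report: AnalysisReport, prefix: str,
                   options: AnalysisOptions) -> None:
    outdir = os.path.dirname(os.path.abspath(prefix))
    os.makedirs(outdir, exist_ok=True)

    tree_path = prefix + ".rooted.nwk"
    with open(tree_path, "w") as fh:
        fh.write(write_newick(report.tree) + "\n")
    report.output_files.append(tree_path)

    if report.points is not None:
        rtt_path = prefix + ".rtt.tsv"
        with open(rtt_path, "w") as fh:
            fh.write("tip\tdate\tdistance\tresidual\n")
            for p in report.points:
                fh.write(f"{p.label}\t{p.time!r}\t{p.distance!r}\t"
                         f"{p.residual!r}\n")
        report.output_files.append(rtt_path)

    if report.flags is not None:
        diag_path = prefix + ".diagnostics.tsv"
        trace_by_label = {t.label: t for t in (report.traces or [])}
        with open(diag_path, "w") as fh:
            fh.write("tip\tdate\tdistance\tresidual\tx_displacement\tside\t"
                     "flagged\tparent_divergence\ttrace_time\n")
            pts = {p.label: p for p in report.points}
            for f in report.flags:
                p = pts[f.label]
                tr = trace_by_label.get(f.label)
                pdiv = repr(tr.parent_divergence) if tr else ""
                ttime = repr(tr.trace_time) if tr else ""
                fh.write(
                    f"{f.label}\t{p.time!r}\t{p.distance!r}\t"
                    f"{f.y_residual!r}\t{f.x_displacement!r}\t"
                    f"{f.side.value}\t{f.flagged}\t{pdiv}\t{ttime}\n"
                )
        report.output_files.append(diag_path)

    stats_path = prefix + ".stats.json"
    with open(stats_path, "w") as fh:
        json.dump(report.stats, fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")
    report.output_files.append(stats_path)

    if options.plot:
        try:
            from .plotting import plot_analysis
            plot_path = prefix + ".plot.svg"
            plot_analysis(report, plot_path)
            report.output_files.append(plot_path)
        except Exception as exc:  # plotting must never fail the analysis
            logger.warning("plotting failed (analysis unaffected): %s", exc)


def _json_default(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {obj!r}")


def validate(
    tree_source: str,
    date_source: Union[None, str, TipDateSet, DateRule] = None,
    backward: bool = False,
    clamp_negative: bool = False,
) -> Dict[str, object]:
    """Pre-flight data check; always returns a record, never raises for
    content problems (they are reported inside the record)."""
    problems: List[Dict[str, object]] = []
    record: Dict[str, object] = {"problems": problems, "ok": True}
    tree = None
    try:
        with open(tree_source) as fh:
            text = fh.read()
        # clamp while validating so a negative length doesn't hide the
        # remaining checks; it is still reported below
        tree = read_newick(text, clamp_negative=True)
    except TipTempoError as exc:
        problems.append({"kind": "tree", "detail": str(exc)})
    if tree is not None:
        import re as _re
        for m in _re.finditer(r":\s*(-[\d.eE+-]+)", text):
            problems.append({
                "kind": "negative_branch_length",
                "detail": f"negative length {m.group(1)} in newick input",
            })
        labels = tree.tip_labels
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        for d in dupes:
            problems.append({"kind": "duplicate_label", "detail": d})
        record["n_tips"] = tree.n_tips

    dates = None
    if date_source is not None and tree is not None:
        try:
            dates = _resolve_dates(tree, date_source, backward)
        except TipTempoError as exc:
            problems.append({"kind": "dates", "detail": str(exc)})
    if dates is not None and tree is not None:
        tips = set(tree.tip_labels)
        dated = set(dates.times)
        for lbl in sorted(tips - dated):
            problems.append({"kind": "tip_without_date", "detail": lbl})
        for lbl in sorted(dated - tips):
            problems.append({"kind": "date_without_tip", "detail": lbl})
    record["ok"] = not problems
    return record
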