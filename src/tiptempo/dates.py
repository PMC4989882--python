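"""Tip sampling times: parsing, extraction and the time-direction convention.

Sampling times are decimal years. Calendar dates are converted leap-aware:
an ISO date maps to ``year + (day_of_year - 0.5) / days_in_year`` (midday of
the stated day); partial dates map to the midpoint of the stated period, so
a bare year ``"2003"`` becomes 2003.5 and ``"2003-06"`` the middle of June.
The midpoint convention minimises the worst-case dating error and is stated
prominently because it shifts root-time estimates relative to a
start-of-period convention.

Two direction conventions exist in the field. FORWARD: larger values are
later calendar times (e.g. 2004.2 after 1999.7). BACKWARD: values are ages,
years before present, so larger values are *older* (common for ancient-DNA
data). Internally all analyses use forward time; :meth:`TipDateSet.analysis_times`
maps BACKWARD values v to t = -v so that later sampling always has larger t.
"""

from __future__ import annotations

import calendar
import csv
import datetime as _dt
import io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Union

from .errors import (
    DateConflictError,
    DateParseError,
    LabelExtractionError,
    MissingDatesError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimeDirection",
    "TipDateSet",
    "parse_decimal_date",
    "extract_dates_from_labels",
    "load_dates_table",
    "validate_date_coverage",
]


class TimeDirection(Enum):
    FORWARD = "forward"        # larger value = later calendar time
    BACKWARD = "backward"      # value = years before present (larger = older)


@dataclass
class TipDateSet:
    """Map from tip label to decimal time plus a direction convention."""

    times: Dict[str, float] = field(default_factory=dict)
    direction: TimeDirection = TimeDirection.FORWARD

    def analysis_times(self) -> Dict[str, float]:
        """Times on the internal forward axis (later sampling = larger t).

        Under BACKWARD, t = -(years before present); slope and R² of any
        regression are unchanged by this sign flip while the x-intercept is
        negated back on output.
        """
        if self.direction is TimeDirection.FORWARD:
            return dict(self.times)
        return {k: -v for k, v in self.times.items()}

    def display_time(self, analysis_time: float) -> float:
        """Map an internal-axis time back to the user's convention."""
        if self.direction is TimeDirection.FORWARD:
            return analysis_time
        return -analysis_time

    def __len__(self) -> int:
        return len(self.times)

    def is_isochronous(self) -> bool:
        vals = list(self.times.values())
        return len(set(vals)) <= 1


_DECIMAL_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")
_ISO_RE = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_YM_RE = re.compile(r"^(\d{4})-(\d{1,2})$")
_YEAR_RE = re.compile(r"^\d{4}$")


def _days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def parse_decimal_date(text: str) -> float:
    """Convert a date string to decimal years.

    Accepted forms: plain decimal ("2003.45", passed through), ISO date
    ("2003-06-14"), year-month ("2003-06", month midpoint) and bare year
    ("2003", year midpoint → 2003.5). Anything else raises
    :class:`DateParseError`; ambiguous formats are never guessed.
    """
    s = text.strip()
    if _YEAR_RE.match(s):
        return float(s) + 0.5
    if _DECIMAL_RE.match(s):
        return float(s)
    m = _ISO_RE.match(s)
    if m:
        year, month, day = (int(g) for g in m.groups())
        try:
            date = _dt.date(year, month, day)
        except ValueError as exc:
            raise DateParseError(f"invalid calendar date {text!r}: {exc}")
        doy = date.timetuple().tm_yday
        return year + (doy - 0.5) / _days_in_year(year)
    m = _YM_RE.match(s)
    if m:
        year, month = int(m.group(1)), int(m.group(2))
        if not 1 <= month <= 12:
            raise DateParseError(f"invalid month in {text!r}")
        first = _dt.date(year, month, 1).timetuple().tm_yday
        ndays = calendar.monthrange(year, month)[1]
        # midpoint of the month
        return year + (first - 1 + ndays / 2.0) / _days_in_year(year)
    raise DateParseError(f"unrecognized date format: {text!r}")


DateRule = Union["DelimiterRule", "RegexRule"]


@dataclass(frozen=True)
class DelimiterRule:
    """Split the label on ``delimiter`` and read field ``index`` (negative
    counts from the end, python-style)."""
    delimiter: str
    index: int


@dataclass(frozen=True)
class RegexRule:
    """A regular expression with one capturing group holding the date."""
    pattern: str


def extract_dates_from_labels(
    labels: Sequence[str],
    rule: DateRule,
    direction: TimeDirection = TimeDirection.FORWARD,
) -> TipDateSet:
    """Extract one sampling time per tip label.

    Every label must match the rule; otherwise a
    :class:`LabelExtractionError` is raised listing ALL offending labels,
    not just the first.
    """
    times: Dict[str, float] = {}
    failures: List[str] = []
    if isinstance(rule, RegexRule):
        rx = re.compile(rule.pattern)
    for label in labels:
        raw: Optional[str] = None
        if isinstance(rule, DelimiterRule):
            if rule.delimiter in label:
                parts = label.split(rule.delimiter)
                try:
                    raw = parts[rule.index]
                except IndexError:
                    raw = None
        else:
            m = rx.search(label)
            if m:
                raw = m.group(1) if m.groups() else m.group(0)
        if raw is None:
            failures.append(label)
            continue
        try:
            times[label] = parse_decimal_date(raw)
        except DateParseError:
            failures.append(label)
    if failures:
        raise LabelExtractionError(
            "labels not matching the date rule: " + ", ".join(failures),
            failures,
        )
    return TipDateSet(times=times, direction=direction)


def load_dates_table(
    source: Union[str, io.TextIOBase, Iterable[Sequence[str]]],
    direction: TimeDirection = TimeDirection.FORWARD,
) -> TipDateSet:
    """Load a tab-delimited table of (tip label, date[, ...extra columns]).

    ``source`` may be a path, an open text stream, or an iterable of rows.
    A header row is auto-detected: the first row whose date field fails to
    parse is taken as a header and skipped. Extra columns are ignored with a
    logged notice. A tip appearing twice with conflicting dates raises
    :class:`DateConflictError`.
    """
    if isinstance(source, str):
        with open(source, newline="") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
    elif isinstance(source, io.TextIOBase):
        rows = list(csv.reader(source, delimiter="\t"))
    else:
        rows = [list(r) for r in source]

    times: Dict[str, float] = {}
    extra_noted = False
    for i, row in enumerate(rows):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise DateParseError(
                f"row {i + 1} has fewer than 2 columns: {row!r}"
            )
        if len(row) > 2 and not extra_noted:
            logger.info("extra columns beyond (label, date) ignored")
            extra_noted = True
        label, raw = row[0].strip(), row[1].strip()
        try:
            value = parse_decimal_date(raw)
        except DateParseError:
            if i == 0:
                logger.info("first row %r looks like a header; skipped", row)
                continue
            raise
        if label in times and times[label] != value:
            raise DateConflictError(
                f"tip {label!r} assigned conflicting dates "
                f"{times[label]} and {value}"
            )
        times[label] = value
    return TipDateSet(times=times, direction=direction)


def validate_date_coverage(
    tip_labels: Iterable[str], dates: TipDateSet, drop_undated: bool = False
) -> TipDateSet:
    """Check that tree tips and dated tips coincide.

    Returns a TipDateSet restricted to the tree's tips. Tips without dates
    are an error unless ``drop_undated`` is set (dropped tips are logged);
    dates for tips absent from the tree are always reported.
    """
    labels = set(tip_labels)
    dated = set(dates.times)
    missing_in_dates = labels - dated
    missing_in_tree = dated - labels
    if missing_in_tree:
        logger.warning(
            "dates provided for %d label(s) not in the tree: %s",
            len(missing_in_tree), ", ".join(sorted(missing_in_tree)),
        )
    if missing_in_dates and not drop_undated:
        raise MissingDatesError(
            "tips without dates: " + ", ".join(sorted(missing_in_dates)),
            missing_in_dates=missing_in_dates,
            missing_in_tree=missing_in_tree,
        )
    if missing_in_dates:
        logger.warning(
            "dropping %d undated tip(s): %s",
            len(missing_in_dates), ", ".join(sorted(missing_in_dates)),
        )
    kept = {k: v for k, v in dates.times.items() if k in labels}
    return TipDateSet(times=kept, direction=dates.direction)
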