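"""Time-to-onset analysis and subgroup (sex, age) re-screening.

Time to onset (TTO) is the calendar-day difference between the target
drug's therapy start date (THER.START_DT) and the adverse-event onset date
(DEMO.EVENT_DT).  Reports with blank dates, partial or invalid dates (6- or
4-digit YYYYMM/YYYY forms), or an event date before the start date are
excluded — each exclusion carries an explicit status, nothing is dropped
silently.  The start date is day 0, so 2020-01-01 → 2020-02-14 is 44 days.

Subgroup screening restricts the ENTIRE database (cohort and background)
to one stratum, rebuilds the contingency tables and reruns the four-way
screen, so each stratum's expected counts come from its own background.
Strata whose cohort falls below a configurable report floor are excluded
with a notice (sparse strata produce unstable disproportionality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseReport, age_bin_label, age_in_years, match_target_drug, percentage
from .signal_stats import ScreenConfig, SignalResult, screen

__all__ = [
    "INCLUDED",
    "EXCLUDED_MISSING",
    "EXCLUDED_PARTIAL",
    "EXCLUDED_EVENT_BEFORE_START",
    "DEFAULT_TTO_BINS",
    "TTORecord",
    "TTOSummary",
    "SubgroupScreen",
    "compute_tto",
    "tto_for_cohort",
    "summarize_tto",
    "stratum_label",
    "subgroup_screen",
]

INCLUDED = "included"
EXCLUDED_MISSING = "excluded_missing"
EXCLUDED_PARTIAL = "excluded_partial_date"
EXCLUDED_EVENT_BEFORE_START = "excluded_event_before_start"

#: Closed day intervals; None upper bound = unbounded. Day 0 and day 30
#: both fall in the first bin ("within the first month").
DEFAULT_TTO_BINS: tuple[tuple[int, int | None], ...] = (
    (0, 30),
    (31, 60),
    (61, 90),
    (91, 180),
    (181, 365),
    (366, None),
)


def bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


@dataclass(frozen=True)
class TTORecord:
    """Onset interval for one report with its inclusion status."""

    primaryid: str
    start_dt: str
    event_dt: str
    days: int | None
    status: str

    def __post_init__(self) -> None:
        if (self.days is not None) != (self.status == INCLUDED):
            raise ValueError("days must be present exactly when status is 'included'")
        if self.days is not None and self.days < 0:
            raise ValueError("included records cannot have negative days")


def _parse_full_date(raw: str):
    """Return a date, or the sentinel 'missing'/'partial' classification."""
    s = (raw or "").strip()
    if not s:
        return "missing"
    if len(s) != 8 or not s.isdigit():
        return "partial"
    try:
        return datetime.strptime(s, "%Y%m%d").date()
    except ValueError:
        return "partial"  # e.g. 20200230: invalid calendar date


def compute_tto(start_dt: str, event_dt: str, primaryid: str = "") -> TTORecord:
    """Classify one (start, event) date pair; pure and total.

    Both dates must be full valid YYYYMMDD.  Blank dates dominate the
    classification (excluded_missing), then partial/invalid dates, then the
    event-before-start rule.
    """
    s = _parse_full_date(start_dt)
    e = _parse_full_date(event_dt)
    if s == "missing" or e == "missing":
        status, days = EXCLUDED_MISSING, None
    elif s == "partial" or e == "partial":
        status, days = EXCLUDED_PARTIAL, None
    elif e < s:
        status, days = EXCLUDED_EVENT_BEFORE_START, None
    else:
        status, days = INCLUDED, (e - s).days
    return TTORecord(primaryid, (start_dt or "").strip(), (event_dt or "").strip(), days, status)


def tto_for_cohort(
    cohort: Sequence[CaseReport], drug_terms: Sequence[str]
) -> list[TTORecord]:
    """One TTO record per cohort report.

    When a report carries several therapy start dates for the target drug
    the EARLIEST valid full date is used (first initiation); if none parses
    fully, the first non-blank one stands in so the record is classified as
    partial rather than missing.
    """
    out = []
    for rep in cohort:
        candidates = [
            d.start_dt for d in rep.drugs if match_target_drug(d.name, drug_terms)
        ]
        valid = sorted(
            c.strip() for c in candidates if not isinstance(_parse_full_date(c), str)
        )
        if valid:
            start = valid[0]
        else:
            nonblank = [c for c in candidates if c.strip()]
            start = nonblank[0] if nonblank else ""
        out.append(compute_tto(start, rep.event_dt, rep.primaryid))
    return out


@dataclass(frozen=True)
class TTOSummary:
    """Median/IQR and binned distribution of included onset intervals."""

    n_included: int
    median: float | None
    q1: float | None
    q3: float | None
    bins: tuple[tuple[str, int, float], ...]  # (label, count, pct)
    excluded: Mapping[str, int] = field(default_factory=dict)


def summarize_tto(
    records: Sequence[TTORecord],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_TTO_BINS,
) -> TTOSummary:
    """Quantiles (linear-interpolation convention) and bin counts over the
    included records; percentages use the included count as denominator."""
    days = np.array([r.days for r in records if r.status == INCLUDED], dtype=float)
    excluded = {
        s: sum(1 for r in records if r.status == s)
        for s in (EXCLUDED_MISSING, EXCLUDED_PARTIAL, EXCLUDED_EVENT_BEFORE_START)
    }
    n = days.size
    if n == 0:
        return TTOSummary(0, None, None, None, tuple(
            (bin_label(lo, hi), 0, 0.0) for lo, hi in bins
        ), excluded)
    q1, med, q3 = np.quantile(days, [0.25, 0.5, 0.75])  # linear (type 7)
    out_bins = []
    for lo, hi in bins:
        mask = days >= lo if hi is None else (days >= lo) & (days <= hi)
        cnt = int(mask.sum())
        out_bins.append((bin_label(lo, hi), cnt, percentage(cnt, n)))
    return TTOSummary(int(n), float(med), float(q1), float(q3), tuple(out_bins), excluded)


def stratum_label(report: CaseReport, stratifier: str, age_bins=(18.0, 65.0)) -> str:
    """Stratum of one report for 'sex' or 'age_bin' stratification."""
    if stratifier == "sex":
        return report.sex if report.sex in ("F", "M") else "missing"
    if stratifier == "age_bin":
        return age_bin_label(age_in_years(report.age_value, report.age_unit), age_bins)
    raise ValueError(f"unknown stratifier {stratifier!r}; expected 'sex' or 'age_bin'")


@dataclass(frozen=True)
class SubgroupScreen:
    """Per-stratum screen results plus exclusion notices and a ranked
    top-k PT comparison table."""

    stratifier: str
    results: Mapping[str, list[SignalResult]]
    excluded: Mapping[str, str]
    cohort_sizes: Mapping[str, int]
    top_terms: pd.DataFrame


def subgroup_screen(
    event_rows: pd.DataFrame,
    cohort_ids: Iterable[str],
    reports: Sequence[CaseReport],
    stratifier: str,
    level: str = "PT",
    *,
    config: ScreenConfig | None = None,
    age_bins: Sequence[float] = (18.0, 65.0),
    min_cohort_reports: int = 10,
    top_k: int = 15,
) -> SubgroupScreen:
    """Rescreen each stratum of the full database independently.

    Strata with fewer than ``min_cohort_reports`` cohort reports are
    excluded with a notice (mirrors dropping an under-reported age band).
    The union of all strata (including "missing") reproduces the overall
    database, so stratification loses no reports.
    """
    cohort_ids = set(cohort_ids)
    labels: dict[str, list[str]] = {}
    for rep in reports:
        labels.setdefault(stratum_label(rep, stratifier, age_bins), []).append(rep.primaryid)

    results: dict[str, list[SignalResult]] = {}
    excluded: dict[str, str] = {}
    cohort_sizes: dict[str, int] = {}
    top_rows = []
    for label in sorted(labels):
        ids = set(labels[label])
        sub_cohort = cohort_ids & ids
        cohort_sizes[label] = len(sub_cohort)
        if len(sub_cohort) < min_cohort_reports:
            excluded[label] = (
                f"stratum {label!r} excluded: {len(sub_cohort)} cohort reports "
                f"< floor {min_cohort_reports}"
            )
            continue
        sub_rows = event_rows[event_rows["primaryid"].isin(ids)]
        res = screen(sub_rows, sub_cohort, level, config=config)
        results[label] = res
        ranked = sorted(res, key=lambda r: (-r.table.a, r.term))[:top_k]
        for rank, r in enumerate(ranked, start=1):
            top_rows.append(
                {"stratum": label, "rank": rank, "term": r.term, "a": r.table.a,
                 "retained": r.retained}
            )
    top_terms = pd.DataFrame(top_rows, columns=["stratum", "rank", "term", "a", "retained"])
    return SubgroupScreen(stratifier, results, excluded, cohort_sizes, top_terms)
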