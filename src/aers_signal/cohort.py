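"""Case assembly, deduplication and target-drug cohort extraction.

A spontaneous-report database accumulates several versions of the same case
across quarterly releases (same CASEID, new PRIMARYID and FDA receipt
date).  Deduplication keeps, per CASEID, the version with the latest FDA_DT
and, among ties, the highest numeric PRIMARYID.

The analysis cohort is every deduplicated report in which a drug name
matches the target term list with a role in the configured role filter
(default: primary suspect only).  Matching is substring-based on a
normalized name because FAERS drugname strings carry dose and form text
("LONSURF 20MG TABLET").
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
import re
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import PtSocMap, RawRecord, normalize_term

__all__ = [
    "ROLE_CODES",
    "DrugEntry",
    "CaseReport",
    "CohortSpec",
    "assemble_case_reports",
    "deduplicate",
    "normalize_drug_name",
    "match_target_drug",
    "extract_cohort",
    "code_events",
    "unmapped_tally",
    "age_in_years",
    "age_bin_label",
    "age_bin_labels",
    "percentage",
    "descriptive_summary",
]

ROLE_CODES = ("PS", "SS", "C", "I")

#: Calendar conversion factors to years for FAERS AGE_COD values.
AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization - Initial or Prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention",
    "OT": "Other Serious",
}

REPORTER_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "HP": "Health Professional",
    "RN": "Nurse",
    "LW": "Lawyer",
}


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a case: raw name, role code, therapy start date."""

    name: str
    role: str
    start_dt: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"drug role must be one of {ROLE_CODES}, got {self.role!r}")


@dataclass(frozen=True)
class CaseReport:
    """A single (possibly not yet deduplicated) adverse-event report."""

    primaryid: str
    caseid: str
    fda_dt: str = ""
    event_dt: str = ""
    sex: str = ""  # "F", "M" or "" (missing)
    age_value: float | None = None
    age_unit: str = ""
    country: str = ""
    reporter: str = ""  # occupation code
    outcomes: frozenset[str] = frozenset()
    drugs: tuple[DrugEntry, ...] = ()
    reactions: frozenset[str] = frozenset()
    indications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.caseid:
            raise ValueError("caseid must be non-empty")


def assemble_case_reports(tables: Mapping[str, Sequence[RawRecord]]) -> list[CaseReport]:
    """Join the seven raw tables into one :class:`CaseReport` per PRIMARYID.

    DEMO defines the report universe; DRUG/REAC/OUTC/THER/INDI rows attach
    by primaryid, therapy start dates attach to drugs via the drug sequence
    number.  Reports appear in DEMO file order.
    """
    by_pid: dict[str, dict[str, list[RawRecord]]] = defaultdict(lambda: defaultdict(list))
    for tid in ("DRUG", "REAC", "OUTC", "THER", "INDI"):
        for rec in tables.get(tid, ()):  # optional tables may be absent
            by_pid[rec["primaryid"]][tid].append(rec)

    reports: list[CaseReport] = []
    for demo in tables.get("DEMO", ()):
        pid = demo["primaryid"]
        rows = by_pid.get(pid, {})
        starts = {
            r.get("dsg_drug_seq"): r.get("start_dt", "").strip()
            for r in rows.get("THER", ())
        }
        drugs = []
        for r in rows.get("DRUG", ()):
            role = r.get("role_cod", "").strip().upper()
            if role not in ROLE_CODES:
                continue  # unknown role codes are ignored, not fatal
            drugs.append(
                DrugEntry(
                    name=r.get("drugname", "").strip(),
                    role=role,
                    start_dt=starts.get(r.get("drug_seq"), ""),
                )
            )
        age_raw = demo.get("age", "").strip()
        try:
            age_value: float | None = float(age_raw)
        except ValueError:
            age_value = None
        sex = demo.get("sex", "").strip().upper()
        reports.append(
            CaseReport(
                primaryid=pid,
                caseid=demo.get("caseid", "").strip(),
                fda_dt=demo.get("fda_dt", "").strip(),
                event_dt=demo.get("event_dt", "").strip(),
                sex=sex if sex in ("F", "M") else "",
                age_value=age_value,
                age_unit=demo.get("age_cod", "").strip().upper(),
                country=demo.get("reporter_country", "").strip(),
                reporter=demo.get("occp_cod", "").strip().upper(),
                outcomes=frozenset(
                    r.get("outc_cod", "").strip().upper()
                    for r in rows.get("OUTC", ())
                    if r.get("outc_cod", "").strip()
                ),
                drugs=tuple(drugs),
                reactions=frozenset(
                    r.get("pt", "").strip() for r in rows.get("REAC", ()) if r.get("pt", "").strip()
                ),
                indications=tuple(
                    r.get("indi_pt", "").strip()
                    for r in rows.get("INDI", ())
                    if r.get("indi_pt", "").strip()
                ),
            )
        )
    return reports


def _fda_key(fda_dt: str) -> int:
    # Unparseable FDA_DT sorts lowest so any dated version beats it.
    s = fda_dt.strip()
    return int(s) if len(s) == 8 and s.isdigit() else -1


def _pid_key(primaryid: str):
    # Numeric compare when possible; malformed ids sort below all numeric.
    return (1, int(primaryid)) if primaryid.isdigit() else (0, primaryid)


def _caseid_key(caseid: str):
    return (0, int(caseid), "") if caseid.isdigit() else (1, 0, caseid)


def deduplicate(reports: Sequence[CaseReport]) -> list[CaseReport]:
    """One report per CASEID: latest FDA_DT, ties broken by highest
    PRIMARYID.  Output sorted by ascending caseid; idempotent and
    insensitive to input order."""
    best: dict[str, CaseReport] = {}
    for rep in reports:
        cur = best.get(rep.caseid)
        if cur is None or (_fda_key(rep.fda_dt), _pid_key(rep.primaryid)) > (
            _fda_key(cur.fda_dt),
            _pid_key(cur.primaryid),
        ):
            best[rep.caseid] = rep
    return [best[c] for c in sorted(best, key=_caseid_key)]


_NON_ALNUM = re.compile(r"[^A-Z0-9]+")


def normalize_drug_name(name: str) -> str:
    """Uppercase; punctuation and whitespace runs collapse to single spaces."""
    return _NON_ALNUM.sub(" ", name.upper()).strip()


def match_target_drug(drug_name: str, drug_terms: Sequence[str]) -> bool:
    """True iff any normalized term occurs as a substring of the normalized
    drug name (FAERS names embed dose/form text, so equality is too strict).

    Comparison ignores punctuation and spacing entirely, so "TAS-102",
    "TAS 102" and "TAS102" all match one another.
    """
    name = _NON_ALNUM.sub("", drug_name.upper())
    return any(
        _NON_ALNUM.sub("", t.upper()) in name for t in drug_terms if t.strip()
    )


@dataclass(frozen=True)
class CohortSpec:
    """What counts as a target-drug report and how to stratify it."""

    drug_terms: tuple[str, ...]
    role_filter: frozenset[str] = frozenset({"PS"})
    age_bins: tuple[float, ...] = (18.0, 65.0)  # cut points: <18, 18-<65, >=65
    stratifiers: tuple[str, ...] = ("sex", "age_bin")

    def __post_init__(self) -> None:
        if not self.drug_terms:
            raise ValueError("drug_terms must be non-empty")
        bad = set(self.role_filter) - set(ROLE_CODES)
        if bad:
            raise ValueError(f"unknown role codes in role_filter: {sorted(bad)}")
        if list(self.age_bins) != sorted(set(self.age_bins)):
            raise ValueError("age_bins must be strictly increasing")


def extract_cohort(
    deduped: Sequence[CaseReport], spec: CohortSpec
) -> tuple[list[CaseReport], list[CaseReport]]:
    """Partition deduplicated reports into (cohort, background).

    Cohort membership: at least one drug matching ``spec.drug_terms`` with a
    role in ``spec.role_filter``.  Every input report lands in exactly one
    of the two outputs.
    """
    if not spec.drug_terms:
        raise ValueError("drug_terms must be non-empty")
    cohort, background = [], []
    for rep in deduped:
        hit = any(
            d.role in spec.role_filter and match_target_drug(d.name, spec.drug_terms)
            for d in rep.drugs
        )
        (cohort if hit else background).append(rep)
    return cohort, background


def code_events(reports: Sequence[CaseReport], pt_map: PtSocMap) -> pd.DataFrame:
    """Event table: one row per unique (report, PT) pair.

    A PT repeated within one report counts once (set semantics).  PTs are
    canonicalized to collapsed-whitespace uppercase; unmapped PTs carry
    SOC = "UNMAPPED" and can be tallied with :func:`unmapped_tally`.
    """
    rows = []
    for rep in reports:
        terms = sorted({normalize_term(pt) for pt in rep.reactions})
        for t in terms:
            soc = pt_map.lookup(t)
            rows.append((rep.primaryid, t.upper(), soc if soc is not None else "UNMAPPED"))
    return pd.DataFrame(rows, columns=["primaryid", "pt", "soc"])


def unmapped_tally(event_rows: pd.DataFrame) -> Counter:
    """Counts per preferred term that had no organ-class mapping."""
    sub = event_rows[event_rows["soc"] == "UNMAPPED"]
    return Counter(sub["pt"].tolist())


def age_in_years(age_value: float | None, age_unit: str) -> float | None:
    """Convert a FAERS age/unit pair to years; unknown unit or missing
    value → None.  A blank unit with a value present is taken as years,
    which is the dominant FAERS convention."""
    if age_value is None:
        return None
    unit = (age_unit or "").strip().upper()
    if unit == "":
        return float(age_value)
    factor = AGE_UNIT_YEARS.get(unit)
    if factor is None:
        return None
    return float(age_value) * factor


def age_bin_labels(age_bins: Sequence[float]) -> list[str]:
    cuts = [_fmt_cut(c) for c in age_bins]
    labels = [f"<{cuts[0]}"]
    labels += [f"{cuts[i]}-<{cuts[i + 1]}" for i in range(len(cuts) - 1)]
    labels.append(f">={cuts[-1]}")
    return labels


def _fmt_cut(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else str(c)


def age_bin_label(years: float | None, age_bins: Sequence[float] = (18.0, 65.0)) -> str:
    """Bin an age in years into the configured non-overlapping, exhaustive
    bins; missing/unconvertible ages get the "missing" bin."""
    if years is None:
        return "missing"
    labels = age_bin_labels(age_bins)
    for i, cut in enumerate(age_bins):
        if years < cut:
            return labels[i]
    return labels[-1]


def percentage(count: int, denom: int) -> float:
    """100·count/denom, rounded half-up to 2 decimals (exact decimal
    arithmetic, so printed report percentages reproduce bit-for-bit)."""
    if denom == 0:
        return 0.0
    return float((Decimal(count) * 100 / Decimal(denom)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def _cat_frame(counts: Mapping[str, int], denom: int, order: Iterable[str] | None = None) -> pd.DataFrame:
    keys = list(order) if order is not None else sorted(counts, key=lambda k: (-counts[k], k))
    return pd.DataFrame(
        {
            "category": keys,
            "count": [counts.get(k, 0) for k in keys],
            "pct": [percentage(counts.get(k, 0), denom) for k in keys],
        }
    )


def descriptive_summary(
    cohort: Sequence[CaseReport],
    *,
    age_bins: Sequence[float] = (18.0, 65.0),
    top_indications: int = 7,
    top_countries: int = 5,
) -> dict[str, pd.DataFrame]:
    """Clinical-characteristics summary of the cohort.

    Returns one frame per section (sex, age, outcome, indication, reporter,
    country, year), each with category / count / pct columns.  Percentages
    use the cohort size as denominator — a report with several outcome
    codes contributes to each outcome row — except indications, whose
    denominator is the total number of indication entries (reports list one
    indication per suspect drug, so report count is not a natural base).
    Top-k lists rank by count with alphabetical tie-break.
    """
    n = len(cohort)

    sex_counts = Counter("Female" if r.sex == "F" else "Male" if r.sex == "M" else "Missing" for r in cohort)
    sex = _cat_frame(sex_counts, n, ["Female", "Male", "Missing"])

    bins = list(age_bin_labels(age_bins)) + ["missing"]
    age_counts = Counter(
        age_bin_label(age_in_years(r.age_value, r.age_unit), age_bins) for r in cohort
    )
    age = _cat_frame(age_counts, n, bins)

    out_counts: Counter = Counter()
    n_no_outcome = 0
    for r in cohort:
        if not r.outcomes:
            n_no_outcome += 1
        for code in r.outcomes:
            out_counts[OUTCOME_LABELS.get(code, code)] += 1
    out_order = [OUTCOME_LABELS[c] for c in ("DE", "LT", "DS", "HO", "OT", "CA", "RI") if OUTCOME_LABELS[c] in out_counts]
    out_counts["Missing"] = n_no_outcome
    outcome = _cat_frame(out_counts, n, out_order + ["Missing"])

    indi_counts: Counter = Counter()
    for r in cohort:
        for ind in r.indications:
            indi_counts[normalize_term(ind).upper()] += 1
    total_indi = sum(indi_counts.values())
    top_ind = sorted(indi_counts, key=lambda k: (-indi_counts[k], k))[:top_indications]
    indication = _cat_frame(indi_counts, total_indi, top_ind)

    rep_counts = Counter(REPORTER_LABELS.get(r.reporter, "Missing" if not r.reporter else r.reporter) for r in cohort)
    reporter = _cat_frame(rep_counts, n)

    country_counts = Counter(r.country if r.country else "Missing" for r in cohort)
    top_c = sorted(country_counts, key=lambda k: (-country_counts[k], k))[:top_countries]
    country = _cat_frame(country_counts, n, top_c)

    year_counts = Counter(
        r.fda_dt[:4] if len(r.fda_dt) >= 4 and r.fda_dt[:4].isdigit() else "unknown"
        for r in cohort
    )
    year = _cat_frame(year_counts, n, sorted(year_counts))

    return {
        "sex": sex,
        "age": age,
        "outcome": outcome,
        "indication": indication,
        "reporter": reporter,
        "country": country,
        "year": year,
    }
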