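"""Synthetic FAERS-dialect databases with controlled statistical structure.

The generator emulates the seven-file quarterly structure — duplicate
CASEIDs with differing FDA receipt dates, drug role codes, partial and
missing event dates, demographics, outcome codes — around a drug–event
count model with known ground truth:

* Drug and event marginals are Zipf-distributed (spontaneous-report
  databases are heavy-tailed; exponent configurable).
* A configurable share of reports carries the target drug as primary
  suspect.  For those reports, *implanted* events have their sampling odds
  multiplied by a relative risk ρ (odds multiplication keeps the event
  distribution proper for any ρ; ρ = 1 everywhere gives a pure null
  database for calibration studies).
* True onset intervals are log-normal (default median 44 days with
  σ_log ≈ 1.17, giving an IQR of roughly 20–97 days); date corruption
  (partial/missing event dates) is applied *after* the truth is captured,
  so exclusion logic is testable against known intent.

Everything is driven by one seeded generator: the same seed yields a
byte-identical file set.  ``small_fixture`` is a separate hand-written
≤15-report database that exercises every edge case (both dedup tie rules,
an SS-role target drug, an unmapped PT, a partial date, an event before
therapy start, a multi-outcome report) with hand-enumerated expected
outputs frozen in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import age_bin_label
from .faers_io import DEFAULT_SCHEMAS, PtSocMap, RawRecord, write_table

__all__ = [
    "TARGET_DRUG_NAME",
    "TARGET_DRUG_TERMS",
    "SimConfig",
    "GroundTruth",
    "SyntheticFaers",
    "generate",
    "small_fixture",
    "FIXTURE_PT_SOC_PAIRS",
]

TARGET_DRUG_NAME = "TRIFLURIDINE/TIPIRACIL"
TARGET_DRUG_TERMS = ("TRIFLURIDINE/TIPIRACIL", "TAS102", "FTD/TPI", "LONSURF")

_EPOCH = date(2016, 1, 1)
_INDICATIONS = (
    ("COLON CANCER", 0.35),
    ("COLORECTAL CANCER METASTATIC", 0.20),
    ("RECTAL CANCER", 0.15),
    ("PRODUCT USED FOR UNKNOWN INDICATION", 0.30),
)
_OCCUPATIONS = (("CN", 0.42), ("MD", 0.15), ("PH", 0.19), ("OT", 0.19), ("HP", 0.05))
_COUNTRIES = (("US", 0.82), ("CA", 0.08), ("JP", 0.04), ("FR", 0.03), ("DK", 0.03))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic database.

    Defaults reflect a mid-sized oncology-drug slice of a spontaneous
    reporting database: 5,000 reports, heavy-tailed vocabularies of 150
    drugs and 200 events, ~10% of reports naming the target drug as
    primary suspect, ~2.5 events per report, 5% duplicated cases, onset
    intervals log-normal around a 44-day median, and demographic/outcome
    rates in the vicinity of published colorectal-cancer cohorts.
    """

    n_reports: int = 5000
    n_drugs: int = 150
    n_events: int = 200
    drug_zipf_s: float = 1.5
    event_zipf_s: float = 1.5
    target_drug_share: float = 0.10
    implanted_signals: tuple[tuple[int, float], ...] = ()
    events_per_report_mean: float = 2.5
    max_events_per_report: int = 8
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.05
    missing_event_dt_rate: float = 0.30
    sex_p: tuple[float, float, float] = (0.42, 0.57, 0.01)  # F, M, missing
    age_mean: float = 62.0
    age_sd: float = 12.0
    age_missing_rate: float = 0.25
    outcome_probs: tuple[tuple[str, float], ...] = (
        ("DE", 0.42), ("LT", 0.006), ("DS", 0.0016), ("HO", 0.22), ("OT", 0.10)
    )
    tto_median_days: float = 44.0
    tto_sigma_log: float = 1.17
    n_socs: int = 12
    #: Restrict implantation to one age stratum (e.g. ">=65"); None = all.
    implant_age_bin: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        probs = [self.target_drug_share, self.duplicate_rate, self.partial_date_rate,
                 self.missing_event_dt_rate, self.age_missing_rate, *self.sex_p,
                 *(p for _, p in self.outcome_probs)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for idx, rho in self.implanted_signals:
            if not 0 <= idx < self.n_events:
                raise ValueError(
                    f"implanted event index {idx} outside vocabulary of {self.n_events}"
                )
            if rho < 0:
                raise ValueError("implanted relative risk must be >= 0")


@dataclass
class GroundTruth:
    """What the generator intended, recorded before any corruption."""

    survivors: dict[str, str] = field(default_factory=dict)  # caseid -> primaryid
    implanted: list[tuple[str, float]] = field(default_factory=list)  # (PT name, rho)
    target_primaryids: set[str] = field(default_factory=set)  # survivor pids, target PS
    strata: dict[str, dict[str, str]] = field(default_factory=dict)  # pid -> labels
    tto_days: dict[str, int] = field(default_factory=dict)  # pid -> true days

    def to_json(self) -> str:
        return json.dumps(
            {
                "survivors": self.survivors,
                "implanted": self.implanted,
                "target_primaryids": sorted(self.target_primaryids),
                "strata": self.strata,
                "tto_days": self.tto_days,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticFaers:
    """A generated seven-table file set plus its ground truth."""

    tables: dict[str, list[RawRecord]]
    pt_soc_pairs: tuple[tuple[str, str], ...]
    truth: GroundTruth
    config: SimConfig | None = None

    @property
    def pt_soc_map(self) -> PtSocMap:
        return PtSocMap.from_pairs(self.pt_soc_pairs)

    def write(self, out_dir: str | Path) -> Path:
        """Write the seven $-delimited tables, the PT→SOC mapping and
        truth.json into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tid, records in self.tables.items():
            write_table(records, out / f"{tid}.txt", DEFAULT_SCHEMAS[tid])
        import csv

        with open(out / "pt_soc_map.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["pt", "soc"])
            w.writerows(self.pt_soc_pairs)
        (out / "truth.json").write_text(self.truth.to_json() + "\n", encoding="utf-8")
        return out


def _rec(tid: str, line_no: int, **values: str) -> RawRecord:
    cols = DEFAULT_SCHEMAS[tid].columns
    unknown = set(values) - set(cols)
    if unknown:
        raise KeyError(f"unknown columns for {tid}: {sorted(unknown)}")
    return RawRecord(tid, {c: values.get(c, "") for c in cols}, "synthetic", line_no)


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.power(np.arange(1, n + 1, dtype=float), s)
    return w / w.sum()


def _weighted_code(rng: np.random.Generator, pairs: Sequence[tuple[str, float]]) -> str:
    codes = [c for c, _ in pairs]
    p = np.array([p for _, p in pairs], dtype=float)
    return codes[int(rng.choice(len(codes), p=p / p.sum()))]


def _date_str(d: date) -> str:
    return d.strftime("%Y%m%d")


def generate(config: SimConfig) -> SyntheticFaers:
    """Generate one synthetic FAERS database; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    drug_w = _zipf_weights(config.n_drugs, config.drug_zipf_s)
    event_w = _zipf_weights(config.n_events, config.event_zipf_s)
    target_event_w = event_w.copy()
    for idx, rho in config.implanted_signals:
        target_event_w[idx] *= rho  # odds multiplication
    target_event_w = target_event_w / target_event_w.sum()

    pt_names = [f"EVENT_{i:04d}" for i in range(config.n_events)]
    pt_soc_pairs = tuple(
        (pt_names[i], f"SOC_{i % config.n_socs + 1:02d}") for i in range(config.n_events)
    )
    geom_p = min(1.0, 1.0 / max(config.events_per_report_mean, 1.0))

    tables: dict[str, list[RawRecord]] = {tid: [] for tid in DEFAULT_SCHEMAS}
    truth = GroundTruth(
        implanted=[(pt_names[i], float(r)) for i, r in config.implanted_signals]
    )

    n = config.n_reports
    n_dup = int(round(config.duplicate_rate * n))
    dup_idx = set(rng.choice(n, size=n_dup, replace=False).tolist()) if n_dup else set()

    def emit(pid: str, caseid: str, fda: date, body: dict) -> None:
        ln = len(tables["DEMO"]) + 2
        tables["DEMO"].append(
            _rec(
                "DEMO", ln,
                primaryid=pid, caseid=caseid, fda_dt=_date_str(fda),
                event_dt=body["event_dt"], sex=body["sex"], age=body["age"],
                age_cod=body["age_cod"], occp_cod=body["occp"],
                reporter_country=body["country"],
            )
        )
        for seq, (name, role) in enumerate(body["drugs"], start=1):
            tables["DRUG"].append(
                _rec("DRUG", len(tables["DRUG"]) + 2, primaryid=pid, caseid=caseid,
                     drug_seq=str(seq), role_cod=role, drugname=name)
            )
        tables["THER"].append(
            _rec("THER", len(tables["THER"]) + 2, primaryid=pid, caseid=caseid,
                 dsg_drug_seq="1", start_dt=body["start_dt"], end_dt="")
        )
        for pt in body["events"]:
            tables["REAC"].append(
                _rec("REAC", len(tables["REAC"]) + 2, primaryid=pid, caseid=caseid, pt=pt)
            )
        for code in body["outcomes"]:
            tables["OUTC"].append(
                _rec("OUTC", len(tables["OUTC"]) + 2, primaryid=pid, caseid=caseid,
                     outc_cod=code)
            )
        tables["RPSR"].append(
            _rec("RPSR", len(tables["RPSR"]) + 2, primaryid=pid, caseid=caseid,
                 rpsr_cod="FGN")
        )
        tables["INDI"].append(
            _rec("INDI", len(tables["INDI"]) + 2, primaryid=pid, caseid=caseid,
                 indi_drug_seq="1", indi_pt=body["indication"])
        )

    for i in range(n):
        caseid = str(100000 + i)
        is_target = rng.random() < config.target_drug_share

        if is_target:
            drugs = [(TARGET_DRUG_NAME, "PS")]
        else:
            drugs = [(f"DRUG_{int(rng.choice(config.n_drugs, p=drug_w)):04d}", "PS")]
        for _ in range(int(rng.integers(0, 3))):
            drugs.append((f"DRUG_{int(rng.choice(config.n_drugs, p=drug_w)):04d}", "C"))

        u_sex = rng.random()
        pf, pm, _ = config.sex_p
        sex = "F" if u_sex < pf else "M" if u_sex < pf + pm else ""
        if rng.random() < config.age_missing_rate:
            age, age_cod = "", ""
        else:
            age_v = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 95.0))
            age, age_cod = str(int(round(age_v))), "YR"
        bin_of_report = age_bin_label(float(age) if age else None)

        implant_here = is_target and (
            config.implant_age_bin is None or bin_of_report == config.implant_age_bin
        )
        k = 1 + min(int(rng.geometric(geom_p)) - 1, config.max_events_per_report - 1)
        w = target_event_w if implant_here else event_w
        events = sorted({pt_names[int(j)] for j in rng.choice(config.n_events, size=k, p=w)})

        start = _EPOCH + timedelta(days=int(rng.integers(0, 2557)))  # 2016-2022
        days = int(round(float(rng.lognormal(math.log(config.tto_median_days),
                                             config.tto_sigma_log))))
        event_d = start + timedelta(days=days)
        u = rng.random()
        if u < config.missing_event_dt_rate:
            event_dt = ""
        elif u < config.missing_event_dt_rate + config.partial_date_rate:
            event_dt = _date_str(event_d)[:6]  # YYYYMM partial
        else:
            event_dt = _date_str(event_d)

        outcomes = [c for c, p in config.outcome_probs if rng.random() < p]

        fda = _EPOCH + timedelta(days=int(rng.integers(0, 2900)))
        body = {
            "event_dt": event_dt, "sex": sex, "age": age, "age_cod": age_cod,
            "occp": _weighted_code(rng, _OCCUPATIONS),
            "country": _weighted_code(rng, _COUNTRIES),
            "drugs": drugs, "events": events,
            "start_dt": _date_str(start),
            "outcomes": outcomes,
            "indication": _weighted_code(rng, _INDICATIONS),
        }

        pid1 = caseid + "1"
        emit(pid1, caseid, fda, body)
        survivor = pid1
        if i in dup_idx:
            pid2 = caseid + "2"
            # half the duplicates tie on FDA_DT (higher-primaryid rule),
            # half carry a later receipt date (latest-FDA_DT rule)
            fda2 = fda if rng.random() < 0.5 else fda + timedelta(days=int(rng.integers(10, 200)))
            emit(pid2, caseid, fda2, body)
            survivor = pid2

        truth.survivors[caseid] = survivor
        truth.strata[survivor] = {
            "sex": sex if sex else "missing",
            "age_bin": bin_of_report,
        }
        if is_target:
            truth.target_primaryids.add(survivor)
            truth.tto_days[survivor] = days

    return SyntheticFaers(tables, pt_soc_pairs, truth, config)


# ---------------------------------------------------------------------------
# Hand-written micro-fixture
# ---------------------------------------------------------------------------

FIXTURE_PT_SOC_PAIRS: tuple[tuple[str, str], ...] = (
    ("Anaemia", "Blood and lymphatic system disorders"),
    ("Nausea", "Gastrointestinal disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Death", "General disorders and administration site conditions"),
    ("Fatigue", "General disorders and administration site conditions"),
)
# "MYSTERY SYNDROME" is deliberately absent: it exercises the unmapped-PT path.


def small_fixture() -> SyntheticFaers:
    """Hand-written 12-case / 14-version database covering every edge:

    * caseid 100 — two versions, later FDA_DT wins (primaryid 1002);
    * caseid 101 — two versions, identical FDA_DT, higher primaryid wins;
      its event date precedes therapy start (TTO exclusion);
    * caseid 102 — target drug with role SS only → background;
    * caseid 103 — partial event date; unmapped PT; multi-outcome report;
    * caseid 104 — missing event date; target matched via generic name;
    * caseid 110 — clean 10-day onset interval; age ≥ 65;
    * remaining cases — background reports for the contingency margins.
    """
    rows: dict[str, list[RawRecord]] = {tid: [] for tid in DEFAULT_SCHEMAS}

    def add(tid: str, **values: str) -> None:
        rows[tid].append(_rec(tid, len(rows[tid]) + 2, **values))

    def demo(pid, caseid, fda, event, sex, age, age_cod, occp="MD", country="US"):
        add("DEMO", primaryid=pid, caseid=caseid, fda_dt=fda, event_dt=event,
            sex=sex, age=age, age_cod=age_cod, occp_cod=occp, reporter_country=country)

    def drug(pid, caseid, seq, role, name):
        add("DRUG", primaryid=pid, caseid=caseid, drug_seq=seq, role_cod=role, drugname=name)

    def reac(pid, caseid, *pts):
        for pt in pts:
            add("REAC", primaryid=pid, caseid=caseid, pt=pt)

    def outc(pid, caseid, *codes):
        for c in codes:
            add("OUTC", primaryid=pid, caseid=caseid, outc_cod=c)

    def ther(pid, caseid, seq, start):
        add("THER", primaryid=pid, caseid=caseid, dsg_drug_seq=seq, start_dt=start, end_dt="")

    def indi(pid, caseid, pt):
        add("INDI", primaryid=pid, caseid=caseid, indi_drug_seq="1", indi_pt=pt)

    def rpsr(pid, caseid):
        add("RPSR", primaryid=pid, caseid=caseid, rpsr_cod="FGN")

    # caseid 100: duplicate, later FDA_DT wins; clean 44-day onset
    for pid, fda in (("1001", "20200101"), ("1002", "20200301")):
        demo(pid, "100", fda, "20200214", "F", "63", "YR", occp="CN")
        drug(pid, "100", "1", "PS", "LONSURF 20MG TABLET")
        ther(pid, "100", "1", "20200101")
        reac(pid, "100", "NAUSEA", "Anaemia")
        outc(pid, "100", "HO")
        indi(pid, "100", "COLON CANCER")
        rpsr(pid, "100")

    # caseid 101: duplicate with identical FDA_DT; event precedes start
    for pid in ("1011", "1012"):
        demo(pid, "101", "20200401", "20200101", "M", "7", "DEC")
        drug(pid, "101", "1", "PS", "TAS102")
        ther(pid, "101", "1", "20200301")
        reac(pid, "101", "DEATH")
        outc(pid, "101", "DE")
        indi(pid, "101", "RECTAL CANCER")
        rpsr(pid, "101")

    # caseid 102: target drug only as secondary suspect -> background
    demo("1021", "102", "20200501", "", "M", "55", "YR")
    drug("1021", "102", "1", "PS", "CAPECITABINE")
    drug("1021", "102", "2", "SS", "LONSURF")
    ther("1021", "102", "1", "20200401")
    reac("1021", "102", "NAUSEA")

    # caseid 103: partial event date, unmapped PT, two outcome codes
    demo("1031", "103", "20200601", "202003", "F", "", "", occp="PH")
    drug("1031", "103", "1", "PS", "LONSURF")
    ther("1031", "103", "1", "20200115")
    reac("1031", "103", "FATIGUE", "MYSTERY SYNDROME")
    outc("1031", "103", "DE", "HO")
    indi("1031", "103", "COLON CANCER")

    # caseid 104: missing event date; generic-name match
    demo("1041", "104", "20200701", "", "M", "45", "YR")
    drug("1041", "104", "1", "PS", "TRIFLURIDINE\\TIPIRACIL")
    ther("1041", "104", "1", "20200401")
    reac("1041", "104", "DIARRHOEA")
    outc("1041", "104", "OT")
    indi("1041", "104", "COLORECTAL CANCER METASTATIC")

    # background reports
    for pid, caseid, pts, codes in (
        ("1051", "105", ("NAUSEA", "DEATH"), ("DE",)),
        ("1061", "106", ("ANAEMIA",), ()),
        ("1071", "107", ("FATIGUE",), ()),
        ("1081", "108", ("DEATH",), ("DE",)),
        ("1091", "109", ("VOMITING",), ()),
    ):
        demo(pid, caseid, "20210101", "", "M", "60", "YR")
        drug(pid, caseid, "1", "PS", "CAPECITABINE" if int(pid) % 2 else "OXALIPLATIN")
        reac(pid, caseid, *pts)
        outc(pid, caseid, *codes)

    # caseid 110: clean short onset, elderly patient
    demo("1101", "110", "20210701", "20210611", "F", "70", "YR", occp="CN", country="JP")
    drug("1101", "110", "1", "PS", "LONSURF")
    ther("1101", "110", "1", "20210601")
    reac("1101", "110", "NAUSEA")
    outc("1101", "110", "OT")
    indi("1101", "110", "COLON CANCER")

    # caseid 111: background report with the unmapped PT
    demo("1111", "111", "20210801", "", "", "", "", occp="")
    drug("1111", "111", "1", "PS", "OXALIPLATIN")
    reac("1111", "111", "NAUSEA", "MYSTERY SYNDROME")

    truth = GroundTruth(
        survivors={
            "100": "1002", "101": "1012", "102": "1021", "103": "1031",
            "104": "1041", "105": "1051", "106": "1061", "107": "1071",
            "108": "1081", "109": "1091", "110": "1101", "111": "1111",
        },
        target_primaryids={"1002", "1012", "1031", "1041", "1101"},
    )
    return SyntheticFaers(rows, FIXTURE_PT_SOC_PAIRS, truth, None)
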