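"""Run orchestration: ingest → dedup → cohort → screen → subgroup/TTO → report.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and
produces a deterministic output bundle: Table-1 style descriptive CSV, SOC-
and PT-level signal CSVs, per-stratum subgroup CSVs, TTO summary and audit
CSVs, and a JSON manifest with per-stage row counts.  Identical config and
inputs yield byte-identical outputs; wall-clock information goes to the log
stream only, never into the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cohort as co
from . import faers_io as fio
from . import signal_stats as ss
from . import strata_tto as st

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run"]

log = logging.getLogger("aers_signal")

TABLE_FILENAMES = {tid: f"{tid}.txt" for tid in fio.TABLE_IDS}
REQUIRED_TABLES = ("DEMO", "DRUG", "REAC")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name and the manifest
    accumulated so far."""

    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.manifest = manifest or {}


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; loadable from YAML via :meth:`from_yaml`."""

    input_dir: str
    output_dir: str
    pt_soc_map: str
    drug_terms: tuple[str, ...]
    role_filter: tuple[str, ...] = ("PS",)
    age_bins: tuple[float, ...] = (18.0, 65.0)
    subgroups: tuple[str, ...] = ("sex", "age_bin")
    subgroup_min_cohort: int = 10
    subgroup_top_k: int = 15
    top_indications: int = 7
    top_countries: int = 5
    screen: ss.ScreenConfig = field(default_factory=ss.ScreenConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        screen_raw = raw.pop("screen", {}) or {}
        screen = ss.ScreenConfig(**screen_raw)
        for key in ("drug_terms", "role_filter", "age_bins", "subgroups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(screen=screen, **raw)


@dataclass
class RunManifest:
    """Per-stage count bookkeeping; the count algebra must balance
    (reports read − duplicates removed = deduplicated, cohort + background
    = deduplicated, etc.)."""

    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _read_tables(input_dir: Path) -> dict[str, list[fio.RawRecord]]:
    tables = {}
    for tid, fname in TABLE_FILENAMES.items():
        path = input_dir / fname
        if path.exists():
            tables[tid] = fio.read_table(path, fio.DEFAULT_SCHEMAS[tid])
        elif tid in REQUIRED_TABLES:
            raise FileNotFoundError(f"required table file missing: {path}")
        else:
            log.warning("optional table %s absent at %s", tid, path)
    return tables


def run(
    config: RunConfig,
    *,
    tables: Mapping[str, Sequence[fio.RawRecord]] | None = None,
    pt_map: fio.PtSocMap | None = None,
) -> RunManifest:
    """Execute the full analysis and write the output bundle.

    ``tables``/``pt_map`` may be supplied directly (e.g. from the synthetic
    generator) to bypass file ingestion; otherwise the seven table files
    and the mapping are read from the configured paths.  Startup validation
    happens before any output is written, so a bad config leaves no
    partial bundle.
    """
    from . import __version__

    manifest = RunManifest(config=_config_dict(config), version=__version__)
    out_dir = Path(config.output_dir)
    log.info("run: input=%s map=%s output=%s", config.input_dir, config.pt_soc_map, out_dir)

    # -- startup validation: no partial outputs on a bad config
    if tables is None and not Path(config.input_dir).is_dir():
        raise PipelineError("startup", f"input_dir {config.input_dir!r} does not exist")
    if pt_map is None and not Path(config.pt_soc_map).is_file():
        raise PipelineError("startup", f"pt_soc_map {config.pt_soc_map!r} does not exist")
    if not config.drug_terms:
        raise PipelineError("startup", "drug_terms must be non-empty")

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise PipelineError(name, str(exc), dataclasses.asdict(manifest)) from exc
        return wrap

    # ingest
    if tables is None:
        tables = stage("ingest")(_read_tables, Path(config.input_dir))
    if pt_map is None:
        pt_map = stage("ingest")(fio.load_pt_soc_map, config.pt_soc_map)
    manifest.counts["rows"] = {tid: len(recs) for tid, recs in tables.items()}

    # dedup
    reports = stage("dedup")(co.assemble_case_reports, tables)
    deduped = stage("dedup")(co.deduplicate, reports)
    manifest.counts["reports_read"] = len(reports)
    manifest.counts["duplicates_removed"] = len(reports) - len(deduped)
    manifest.counts["deduplicated"] = len(deduped)

    # cohort
    spec = co.CohortSpec(
        drug_terms=tuple(config.drug_terms),
        role_filter=frozenset(config.role_filter),
        age_bins=tuple(config.age_bins),
    )
    cohort, background = stage("cohort")(co.extract_cohort, deduped, spec)
    cohort_ids = {r.primaryid for r in cohort}
    manifest.counts["cohort"] = len(cohort)
    manifest.counts["background"] = len(background)

    # coding
    event_rows = stage("coding")(co.code_events, deduped, pt_map)
    unmapped = co.unmapped_tally(event_rows)
    manifest.counts["event_pairs_pt"] = int(event_rows[["primaryid", "pt"]].drop_duplicates().shape[0])
    manifest.counts["event_pairs_soc"] = int(event_rows[["primaryid", "soc"]].drop_duplicates().shape[0])
    manifest.counts["unmapped_pts"] = {k: int(v) for k, v in sorted(unmapped.items())}

    out_dir.mkdir(parents=True, exist_ok=True)

    # descriptives
    summary = stage("descriptives")(
        co.descriptive_summary, cohort,
        age_bins=config.age_bins,
        top_indications=config.top_indications,
        top_countries=config.top_countries,
    )
    table1 = pd.concat(
        [df.assign(section=name) for name, df in summary.items()], ignore_index=True
    )[["section", "category", "count", "pct"]]
    _write_csv(table1, out_dir / "table1.csv")

    # screening
    for level, fname in (("SOC", "signals_soc.csv"), ("PT", "signals_pt.csv")):
        results = stage("screen")(
            ss.screen, event_rows, cohort_ids, level, config=config.screen
        )
        frame = ss.results_frame(results)
        _write_csv(frame, out_dir / fname)
        manifest.counts[f"terms_{level.lower()}"] = len(results)
        manifest.counts[f"retained_{level.lower()}"] = int(sum(r.retained for r in results))

    # subgroups
    for stratifier in config.subgroups:
        sub = stage("subgroup")(
            st.subgroup_screen, event_rows, cohort_ids, deduped, stratifier, "PT",
            config=config.screen, age_bins=config.age_bins,
            min_cohort_reports=config.subgroup_min_cohort, top_k=config.subgroup_top_k,
        )
        for label, res in sub.results.items():
            safe = label.replace("<", "lt").replace(">=", "ge").replace("/", "_")
            _write_csv(ss.results_frame(res), out_dir / f"subgroup_{stratifier}_{safe}.csv")
        _write_csv(sub.top_terms, out_dir / f"subgroup_{stratifier}_top_terms.csv")
        manifest.notices.extend(sorted(sub.excluded.values()))
        manifest.counts[f"subgroup_{stratifier}_cohort_sizes"] = dict(sorted(sub.cohort_sizes.items()))

    # time to onset
    tto_records = stage("tto")(st.tto_for_cohort, cohort, list(config.drug_terms))
    tto_summary = st.summarize_tto(tto_records)
    audit = pd.DataFrame(
        [
            {"primaryid": r.primaryid, "start_dt": r.start_dt, "event_dt": r.event_dt,
             "days": "" if r.days is None else r.days, "status": r.status}
            for r in tto_records
        ],
        columns=["primaryid", "start_dt", "event_dt", "days", "status"],
    )
    _write_csv(audit, out_dir / "tto_records.csv")
    summary_rows = [
        {"metric": "n_included", "value": tto_summary.n_included},
        {"metric": "median_days", "value": _fmt(tto_summary.median)},
        {"metric": "q1_days", "value": _fmt(tto_summary.q1)},
        {"metric": "q3_days", "value": _fmt(tto_summary.q3)},
    ]
    for label, cnt, pct in tto_summary.bins:
        summary_rows.append({"metric": f"bin_{label}_count", "value": cnt})
        summary_rows.append({"metric": f"bin_{label}_pct", "value": pct})
    for status, cnt in tto_summary.excluded.items():
        summary_rows.append({"metric": status, "value": cnt})
    _write_csv(pd.DataFrame(summary_rows), out_dir / "tto_summary.csv")
    manifest.counts["tto"] = {
        "included": tto_summary.n_included,
        **{k: int(v) for k, v in tto_summary.excluded.items()},
    }

    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    log.info("run complete: %d cohort reports, bundle in %s", len(cohort), out_dir)
    return manifest


def _fmt(x) -> str:
    if x is None:
        return ""
    return f"{x:.1f}".rstrip("0").rstrip(".")


def _config_dict(config: RunConfig) -> dict:
    # filesystem paths are machine-specific, not analysis parameters: they
    # go to the log, not into the (byte-stable) manifest echo
    d = dataclasses.asdict(config)
    for key in ("input_dir", "output_dir", "pt_soc_map"):
        d.pop(key, None)
    d["screen"] = dataclasses.asdict(config.screen)
    return d


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed float format keeps bundles byte-stable across reruns
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
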