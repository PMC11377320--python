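"""End-to-end orchestration: ingest → dedup → cohort → tables → statistics
→ classification → report files.

A run is driven by a single YAML config file; every analysis choice that
materially changes results (counting unit, chi-square variant, the
positivity thresholds, zero-cell policy, onset bins) is a config key with
an explicit default.  Outputs are plain tab-separated text with fixed float
formatting and fixed sort orders, so re-running an identical config on
identical inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_builder, descriptives, dpa_core, synthetic_faers
from .faers_ingest import (CaseReport, IngestLog, REQUIRED_COLUMNS,
                           deduplicate, link_tables, read_quarter)

logger = logging.getLogger("pvsignal")

FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and analysis choices of one pipeline run."""

    input_dir: str
    target: str
    output_dir: str
    synonyms_path: str | None = None
    pt_soc_map_path: str | None = None
    counting_unit: str = "event"
    soc_within_case_dedup: bool = False
    chi2_yates: bool = True
    zero_cell_continuity: bool = False
    ror_min: float = 3.0
    prr_min: float = 2.0
    ebgm05_min: float = 2.0
    ic025_min: float = 0.0
    a_min: int = 3
    tto_edges: tuple[int, ...] = descriptives.DEFAULT_TTO_EDGES
    indication_merge_path: str | None = None
    seed: int = 0

    def criteria(self) -> dpa_core.SignalCriteria:
        return dpa_core.SignalCriteria(
            ror_min=self.ror_min, prr_min=self.prr_min,
            ebgm05_min=self.ebgm05_min, ic025_min=self.ic025_min,
            a_min=self.a_min)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "tto_edges" in data:
            data["tto_edges"] = tuple(data["tto_edges"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tto_edges"] = list(self.tto_edges)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return all problems that would make :func:`run` fail; [] if runnable."""
    problems: list[str] = []
    indir = Path(config.input_dir)
    if not indir.is_dir():
        problems.append(f"input_dir does not exist: {indir}")
    else:
        for table in REQUIRED_COLUMNS:
            if not (indir / f"{table}.txt").is_file():
                problems.append(f"missing table file: {indir / (table + '.txt')}")
    for name in ("synonyms_path", "pt_soc_map_path", "indication_merge_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).is_file():
            problems.append(f"{name} does not exist: {p}")
    if not config.target.strip():
        problems.append("target drug label is empty")
    if config.counting_unit not in ("event", "case"):
        problems.append(f"counting_unit must be 'event' or 'case', "
                        f"got {config.counting_unit!r}")
    for name in ("ror_min", "prr_min", "ebgm05_min", "ic025_min", "a_min"):
        if getattr(config, name) < 0:
            problems.append(f"{name} must be non-negative")
    if list(config.tto_edges) != sorted(set(config.tto_edges)) \
            or (config.tto_edges and config.tto_edges[0] != 0):
        problems.append("tto_edges must be strictly increasing and start at 0")
    return problems


@dataclass
class RunResult:
    cases: list[CaseReport]
    target_cases: list[CaseReport]
    mgps_fit: dpa_core.MgpsFit
    soc_frame: pd.DataFrame | None
    pt_frame: pd.DataFrame
    outputs: dict[str, Path]
    log: IngestLog


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_cases(input_dir: str | Path,
               log: IngestLog | None = None) -> list[CaseReport]:
    """Read, link and deduplicate one dataset directory."""
    indir = Path(input_dir)
    paths = {t: indir / f"{t}.txt" for t in REQUIRED_COLUMNS}
    tables = read_quarter(paths, log)
    return deduplicate(link_tables(tables, log), log)


def analyze(cases: Sequence[CaseReport], target: str,
            synonyms: Mapping[str, str] | None = None,
            level: str = "PT",
            pt_soc_map: Mapping[str, str] | None = None,
            criteria: dpa_core.SignalCriteria = dpa_core.SignalCriteria(),
            counting_unit: str = "event",
            soc_within_case_dedup: bool = False,
            chi2_yates: bool = True,
            zero_cell_continuity: bool = False,
            mgps_fit: dpa_core.MgpsFit | None = None
            ) -> tuple[pd.DataFrame, dpa_core.MgpsFit]:
    """Full disproportionality analysis of one target drug at one level.

    The MGPS prior is fit over all (PS drug, event) cells of the database
    at the same level unless a pre-fit result is supplied.
    """
    if mgps_fit is None:
        all_tables = cohort_builder.build_all_drug_tables(
            cases, level=level, pt_soc_map=pt_soc_map, synonyms=synonyms,
            counting_unit=counting_unit,
            soc_within_case_dedup=soc_within_case_dedup)
        mgps_fit = dpa_core.fit_mgps(all_tables)
    target_cases, background = cohort_builder.select_target_cohort(
        cases, target, synonyms)
    tables = cohort_builder.build_tables(
        target_cases, background, level=level, pt_soc_map=pt_soc_map,
        counting_unit=counting_unit,
        soc_within_case_dedup=soc_within_case_dedup)
    frame = dpa_core.statistics_frame(tables, mgps_fit.params,
                                      criteria=criteria, yates=chi2_yates,
                                      continuity=zero_cell_continuity)
    frame = frame.sort_values(["a", "label"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    return frame, mgps_fit


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n")


def _table1_frame(cases: Sequence[CaseReport]) -> pd.DataFrame:
    rows = []
    for var, rule in (("sex", "known-only"), ("age-bucket", "known-only"),
                      ("reporter", "known-only"), ("country", "known-only"),
                      ("route", "known-only"), ("outcome", "all-rows")):
        s = descriptives.summarize_categorical(cases, var, rule)
        for cat, count, pct in s.rows:
            rows.append({"variable": var, "category": cat,
                         "count": count, "percentage": pct})
    return pd.DataFrame(rows)


def run(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline and write the report bundle."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", ValueError("; ".join(problems)))

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log = IngestLog()
    outputs: dict[str, Path] = {"config": outdir / "config.yaml"}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 — re-raised with stage name
            raise PipelineError(name, exc) from exc

    cases = stage("ingest", load_cases, config.input_dir, log)
    synonyms = (cohort_builder.load_synonyms(config.synonyms_path)
                if config.synonyms_path else None)
    pt_soc_map = (cohort_builder.load_pt_soc_map(config.pt_soc_map_path)
                  if config.pt_soc_map_path else None)
    target = cohort_builder.normalize_drug_name(config.target, synonyms)
    criteria = config.criteria()

    pt_frame, pt_fit = stage(
        "dpa-pt", analyze, cases, target, synonyms=synonyms, level="PT",
        criteria=criteria, counting_unit=config.counting_unit,
        chi2_yates=config.chi2_yates,
        zero_cell_continuity=config.zero_cell_continuity)
    outputs["pt_signals_full"] = outdir / "pt_signals_full.tsv"
    _write_tsv(pt_frame, outputs["pt_signals_full"])
    outputs["pt_signals_positive"] = outdir / "pt_signals_positive.tsv"
    _write_tsv(pt_frame[pt_frame["signal"] == "positive"],
               outputs["pt_signals_positive"])

    soc_frame = None
    if pt_soc_map is not None:
        soc_frame, _ = stage(
            "dpa-soc", analyze, cases, target, synonyms=synonyms,
            level="SOC", pt_soc_map=pt_soc_map, criteria=criteria,
            counting_unit=config.counting_unit,
            soc_within_case_dedup=config.soc_within_case_dedup,
            chi2_yates=config.chi2_yates,
            zero_cell_continuity=config.zero_cell_continuity)
        outputs["soc_signals"] = outdir / "soc_signals.tsv"
        _write_tsv(soc_frame, outputs["soc_signals"])

    target_cases, _bg = cohort_builder.select_target_cohort(
        cases, target, synonyms)

    outputs["table1"] = outdir / "table1.tsv"
    _write_tsv(stage("descriptives", _table1_frame, target_cases),
               outputs["table1"])

    annual = stage("descriptives", descriptives.annual_counts, target_cases)
    outputs["annual_counts"] = outdir / "annual_counts.tsv"
    _write_tsv(pd.DataFrame(annual, columns=["year", "count"]),
               outputs["annual_counts"])

    tto = stage("descriptives", descriptives.time_to_onset, target_cases,
                config.tto_edges, target=target, synonyms=synonyms)
    tto_rows = [{"bin": b, "count": k, "percentage": p}
                for b, k, p in tto.bins]
    outputs["tto"] = outdir / "tto.tsv"
    _write_tsv(pd.DataFrame(tto_rows), outputs["tto"])
    with open(outdir / "tto_summary.txt", "w") as fh:
        fh.write(f"n_with_onset\t{len(tto.lags_days)}\n"
                 f"n_missing\t{tto.n_missing}\n"
                 f"n_negative_excluded\t{tto.n_negative_excluded}\n"
                 f"median_days\t{tto.median:.2f}\n"
                 f"q1_days\t{tto.q1:.2f}\nq3_days\t{tto.q3:.2f}\n")
    outputs["tto_summary"] = outdir / "tto_summary.txt"

    merge_map = (cohort_builder.load_two_column_map(config.indication_merge_path)
                 if config.indication_merge_path else None)
    indications = stage("descriptives", descriptives.summarize_indications,
                        target_cases, merge_map)
    outputs["indications"] = outdir / "indications.tsv"
    _write_tsv(pd.DataFrame(indications, columns=["indication", "count"]),
               outputs["indications"])

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"rows_read\t{sorted(log.rows_read.items())}\n"
                 f"duplicates_removed\t{log.duplicates_removed}\n"
                 f"dropped_no_events\t{log.dropped_no_events}\n"
                 f"dropped_orphan_rows\t{log.dropped_orphan_rows}\n"
                 f"malformed_dates\t{log.malformed_dates}\n"
                 f"cases_after_dedup\t{len(cases)}\n"
                 f"target_cohort_cases\t{len(target_cases)}\n"
                 f"mgps_loglik\t{pt_fit.loglik:.6f}\n"
                 f"mgps_converged\t{pt_fit.converged}\n")
    outputs["run_log"] = outdir / "run_log.txt"

    return RunResult(cases=list(cases), target_cases=target_cases,
                     mgps_fit=pt_fit, soc_frame=soc_frame, pt_frame=pt_frame,
                     outputs=outputs, log=log)


# ---------------------------------------------------------------------------
# Replicate studies against the generator's ground truth
# ---------------------------------------------------------------------------

def detection_replicate(config: synthetic_faers.GeneratorConfig,
                        criteria: dpa_core.SignalCriteria =
                        dpa_core.SignalCriteria()) -> pd.DataFrame:
    """One in-memory generate→analyze pass over every (drug, PT) pair.

    Returns a frame with one row per pair carrying the statistics, the
    positivity flag and the true λ.
    """
    cases, truth = synthetic_faers.generate_cases(config)
    tables = cohort_builder.build_all_drug_tables(cases, level="PT")
    fit = dpa_core.fit_mgps(tables)
    frame = dpa_core.statistics_frame(tables, fit.params, criteria=criteria)
    drugs_pts = list(tables)
    frame["drug"] = [d for d, _ in drugs_pts]
    frame["pt"] = [p for _, p in drugs_pts]
    frame["true_lambda"] = [truth.lam(d, p) for d, p in drugs_pts]
    return frame


def detection_study(base: synthetic_faers.GeneratorConfig, n_replicates: int,
                    seed: int,
                    criteria: dpa_core.SignalCriteria =
                    dpa_core.SignalCriteria()) -> dict[str, float]:
    """Planted-signal sensitivity and null flag rate over seeded replicates.

    Each replicate regenerates the dataset with a fresh seed derived from
    ``seed`` and re-runs cohorting, MGPS fitting and classification from
    scratch.  Returns the fraction of planted pairs flagged (sensitivity)
    and the fraction of non-planted pairs flagged (null rate).
    """
    rng = np.random.default_rng(seed)
    planted_flagged = planted_total = 0
    null_flagged = null_total = 0
    for _ in range(n_replicates):
        rep = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        frame = detection_replicate(rep, criteria)
        planted = frame["true_lambda"] > 1.0
        pos = frame["signal"] == "positive"
        planted_flagged += int((planted & pos).sum())
        planted_total += int(planted.sum())
        null_flagged += int((~planted & pos).sum())
        null_total += int((~planted).sum())
    return {
        "sensitivity": planted_flagged / planted_total if planted_total else float("nan"),
        "null_flag_rate": null_flagged / null_total if null_total else float("nan"),
        "n_replicates": n_replicates,
        "planted_pairs": planted_total,
        "null_pairs": null_total,
    }
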