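"""Synthetic FAERS-style datasets with known ground truth.

Spontaneous-report databases cannot be redistributed, so every downstream
stage of this package is exercised against synthetic extracts that mimic the
structural features that matter for disproportionality analysis: the
multi-table case structure keyed on case/report ids, drug role codes, MedDRA
preferred terms grouped under system organ classes, demographics, outcome
codes, therapy-start and onset dates, duplicate report versions, and —
crucially — planted drug–event associations with a known relative reporting
rate λ.

Event model.  Each preferred term occurs on a case independently with
probability ``min(1, λ·background_rate)``, where λ = 1 except for planted
(drug, PT) pairs of cases whose primary-suspect drug is the planted drug.
Because spontaneous reports list several terms, each case is then topped up
with uniformly drawn extra terms until it carries at least ``1 + Poisson(1)``
distinct terms.  The top-up is blind to the case's drug, so it adds the same
marginal reporting rate to every (drug, PT) pair and leaves non-planted
pairs consistent with independence; it slightly dilutes (never inflates)
planted disproportionality.

Report ids are ``case_id·100 + version`` so "latest report per case" is well
defined; injected duplicates change only the report id (version 2) and the
receipt date (30 days later).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_ingest import CaseReport, DrugRecord

EPOCH = _dt.date(2000, 1, 1)

_SEXES = np.array(["F", "M", ""])
_SEX_P = np.array([0.45, 0.50, 0.05])
_SEX_NAME = {"F": "female", "M": "male", "": "unknown"}

_COUNTRIES = np.array(["US", "JP", "CA", "FR", "DE", "GB", "IT", "CN", "ES", "XX"])
_COUNTRY_P = np.array([0.50, 0.07, 0.06, 0.06, 0.05, 0.05, 0.04, 0.03, 0.03, 0.11])

_REPORTERS = np.array(["MD", "PH", "OT", "CN", "RN", ""])
_REPORTER_P = np.array([0.30, 0.27, 0.14, 0.13, 0.01, 0.15])
_REPORTER_NAME = {"MD": "physician", "PH": "pharmacist",
                  "OT": "other health-professional", "CN": "consumer",
                  "RN": "registered nurse", "": "unknown"}

_ROUTES = np.array(["Oral", "Other", "Intravenous", ""])
_ROUTE_P = np.array([0.60, 0.25, 0.05, 0.10])

_OUTCOME_CODES = np.array(["HO", "DE", "LT", "DS", "CA", "RI", "OT"])
_OUTCOME_P = np.array([0.30, 0.15, 0.05, 0.02, 0.005, 0.005, 0.30])
_OUTCOME_NAME = {"HO": "hospitalization", "DE": "death", "LT": "life-threatening",
                 "DS": "disability", "CA": "congenital anomaly",
                 "RI": "required intervention", "OT": "other serious"}


class GeneratorConfigError(ValueError):
    """A generator configuration field is out of range or inconsistent."""


@dataclass(frozen=True)
class GroundTruth:
    """The planted associations a generated dataset contains."""

    planted_pairs: frozenset[tuple[str, str]]
    true_lambda: Mapping[tuple[str, str], float]

    def lam(self, drug: str, pt: str) -> float:
        """Relative reporting rate of (drug, pt); 1.0 unless planted."""
        return self.true_lambda.get((drug, pt), 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic dataset.

    ``background_rate`` is the per-PT baseline probability that a case
    reports that term before top-up; ``planted_signals`` lists
    (drug label, PT label, λ) triples with λ the relative reporting rate.
    """

    n_cases: int = 1000
    n_drugs: int = 8
    n_pts: int = 30
    n_socs: int = 6
    background_rate: float = 0.02
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    duplicate_fraction: float = 0.0
    missing_age_fraction: float = 0.1
    missing_tto_fraction: float = 0.2
    n_indications: int = 6
    year_range: tuple[int, int] = (2014, 2023)
    mean_tto_days: float = 60.0
    seed: int = 0

    def drug_labels(self) -> list[str]:
        # no punctuation: labels survive drug-name normalization unchanged
        return [f"DRUG{i + 1:02d}" for i in range(self.n_drugs)]

    def pt_labels(self) -> list[str]:
        return [f"PT_{i + 1:03d}" for i in range(self.n_pts)]

    def soc_labels(self) -> list[str]:
        return [f"SOC_{i + 1:02d}" for i in range(self.n_socs)]

    def pt_soc_map(self) -> dict[str, str]:
        """Default primary-SOC assignment: PT i belongs to SOC (i mod n_socs)."""
        socs = self.soc_labels()
        return {pt: socs[i % self.n_socs]
                for i, pt in enumerate(self.pt_labels())}

    def indication_labels(self) -> list[str]:
        return [f"IND_{i + 1:02d}" for i in range(self.n_indications)]

    def validate(self) -> None:
        def _check(cond: bool, msg: str) -> None:
            if not cond:
                raise GeneratorConfigError(msg)

        _check(self.n_cases > 0, "n_cases must be a positive integer")
        _check(self.n_drugs > 0, "n_drugs must be a positive integer")
        _check(self.n_pts > 0, "n_pts must be a positive integer")
        _check(0 < self.n_socs <= self.n_pts,
               "n_socs must be in [1, n_pts]")
        _check(0.0 < self.background_rate < 1.0,
               "background_rate must lie in (0, 1)")
        _check(0.0 <= self.duplicate_fraction < 1.0,
               "duplicate_fraction must lie in [0, 1)")
        _check(0.0 <= self.missing_age_fraction < 1.0,
               "missing_age_fraction must lie in [0, 1)")
        _check(0.0 <= self.missing_tto_fraction < 1.0,
               "missing_tto_fraction must lie in [0, 1)")
        _check(self.n_indications > 0, "n_indications must be positive")
        drugs, pts = set(self.drug_labels()), set(self.pt_labels())
        for d, p, lam in self.planted_signals:
            _check(d in drugs, f"planted_signals: unknown drug label {d!r}")
            _check(p in pts, f"planted_signals: unknown PT label {p!r}")
            _check(lam >= 0, f"planted_signals: λ must be ≥ 0 for ({d}, {p})")

    def ground_truth(self) -> GroundTruth:
        lam = {(d, p): float(l) for d, p, l in self.planted_signals}
        return GroundTruth(planted_pairs=frozenset(lam), true_lambda=lam)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cases(config: GeneratorConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Generate the in-memory, already-deduplicated case list.

    This is the ground-truth view of the dataset: for cases that are later
    re-emitted as duplicates, the surviving (latest) report version is the
    one returned here, so ``link_tables`` + ``deduplicate`` over the written
    tables reproduces this list exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drug_labels()
    pts = config.pt_labels()
    inds = config.indication_labels()

    ps_idx = rng.integers(0, config.n_drugs, size=n)
    sex = rng.choice(_SEXES, size=n, p=_SEX_P)
    age = np.clip(np.round(rng.normal(55.0, 18.0, size=n)), 1, 95).astype(int)
    age_missing = rng.random(n) < config.missing_age_fraction
    wt = np.round(np.clip(rng.normal(72.0, 15.0, size=n), 35, 150), 1)
    wt_missing = rng.random(n) < 0.10
    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    reporter = rng.choice(_REPORTERS, size=n, p=_REPORTER_P)
    route = rng.choice(_ROUTES, size=n, p=_ROUTE_P)
    # Zipf-flavoured indication mix: a dominant label plus a tail.
    ind_w = 1.0 / np.arange(1, config.n_indications + 1)
    ind_idx = rng.choice(config.n_indications, size=n, p=ind_w / ind_w.sum())

    y0, y1 = config.year_range
    start0 = (_dt.date(y0, 1, 1) - EPOCH).days
    start1 = (_dt.date(y1, 12, 31) - EPOCH).days
    start_days = rng.integers(start0, start1 + 1, size=n)
    tto = np.maximum(0, np.round(rng.exponential(config.mean_tto_days, size=n))).astype(int)
    tto_missing = rng.random(n) < config.missing_tto_fraction
    onset_days = start_days + tto
    receipt_days = onset_days + rng.integers(0, 61, size=n)

    # Per-PT occurrence probabilities, with planted pairs boosted for the
    # cases whose PS drug matches.
    prob = np.full((n, config.n_pts), config.background_rate)
    drug_pos = {d: i for i, d in enumerate(drugs)}
    pt_pos = {p: i for i, p in enumerate(pts)}
    for d, p, lam in config.planted_signals:
        mask = ps_idx == drug_pos[d]
        prob[mask, pt_pos[p]] = min(1.0, lam * config.background_rate)
    occ = rng.random((n, config.n_pts)) < prob

    target_n_events = np.minimum(1 + rng.poisson(1.0, size=n), config.n_pts)
    # Pre-draw a shuffled PT order per case for deterministic top-up.
    for i in range(n):
        deficit = target_n_events[i] - int(occ[i].sum())
        if deficit > 0:
            candidates = np.flatnonzero(~occ[i])
            extra = rng.choice(candidates, size=deficit, replace=False)
            occ[i, extra] = True
        elif deficit <= 0 and not occ[i].any():  # pragma: no cover
            occ[i, rng.integers(0, config.n_pts)] = True

    n_extra_drugs = rng.poisson(0.7, size=n)
    extra_roles = np.array(["SS", "C", "I"])

    outc_draw = rng.random((n, len(_OUTCOME_CODES))) < _OUTCOME_P

    n_dup = int(np.floor(config.duplicate_fraction * n))
    dup_ids = set(rng.choice(n, size=n_dup, replace=False).tolist()) if n_dup else set()

    cases: list[CaseReport] = []
    for i in range(n):
        case_id = i + 1
        is_dup = i in dup_ids
        version = 2 if is_dup else 1
        receipt = receipt_days[i] + (30 if is_dup else 0)
        ps_name = drugs[ps_idx[i]]
        start = None if tto_missing[i] else EPOCH + _dt.timedelta(int(start_days[i]))
        drug_records = [DrugRecord(
            drug_name_raw=ps_name, drug_name_normalized=ps_name, role="PS",
            route=str(route[i]) or None, therapy_start_date=start,
            indication_pt=inds[ind_idx[i]])]
        for j in range(n_extra_drugs[i]):
            other = drugs[int(rng.integers(0, config.n_drugs))]
            drug_records.append(DrugRecord(
                drug_name_raw=other, drug_name_normalized=other,
                role=str(rng.choice(extra_roles)), route=None,
                therapy_start_date=None, indication_pt=None))
        events = tuple(pts[k] for k in np.flatnonzero(occ[i]))
        outcomes = tuple(sorted(_OUTCOME_NAME[c]
                                for c in _OUTCOME_CODES[outc_draw[i]]))
        cases.append(CaseReport(
            case_id=case_id,
            report_id=case_id * 100 + version,
            receipt_date=EPOCH + _dt.timedelta(int(receipt)),
            sex=_SEX_NAME[str(sex[i])],
            age_years=None if age_missing[i] else float(age[i]),
            weight_kg=None if wt_missing[i] else float(wt[i]),
            country=str(country[i]),
            reporter=_REPORTER_NAME[str(reporter[i])],
            outcomes=outcomes,
            drugs=tuple(drug_records),
            events=events,
            event_onset_date=EPOCH + _dt.timedelta(int(onset_days[i])),
        ))
    return cases, config.ground_truth()


def _fmt_date(d: _dt.date | None) -> str:
    return d.strftime("%Y%m%d") if d is not None else ""


def cases_to_tables(cases: Sequence[CaseReport],
                    duplicate_case_ids: set[int] = frozenset()
                    ) -> dict[str, pd.DataFrame]:
    """Render cases as the six raw FAERS-dialect tables.

    For each case id in ``duplicate_case_ids`` an earlier report version
    (version 1, receipt 30 days before) is emitted in addition to the
    surviving version, in every table, so the dataset contains true
    duplicates for the deduplication stage to remove.
    """
    name_back = {v: k for k, v in _SEX_NAME.items()}
    rep_back = {v: k for k, v in _REPORTER_NAME.items()}
    out_back = {v: k for k, v in _OUTCOME_NAME.items()}

    rows: dict[str, list[dict]] = {t: [] for t in
                                   ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI")}

    def emit(case: CaseReport, report_id: int, receipt: _dt.date | None) -> None:
        pid = str(report_id)
        cid = str(case.case_id)
        rows["DEMO"].append({
            "primaryid": pid, "caseid": cid,
            "fda_dt": _fmt_date(receipt),
            "event_dt": _fmt_date(case.event_onset_date),
            "sex": name_back[case.sex],
            "age": "" if case.age_years is None else f"{case.age_years:g}",
            "age_cod": "" if case.age_years is None else "YR",
            "wt": "" if case.weight_kg is None else f"{case.weight_kg:g}",
            "occr_country": case.country or "",
            "occp_cod": rep_back[case.reporter],
        })
        for d in case.drugs:
            rows["DRUG"].append({"primaryid": pid, "caseid": cid,
                                 "drugname": d.drug_name_raw,
                                 "role_cod": d.role, "route": d.route or ""})
            rows["THER"].append({"primaryid": pid, "caseid": cid,
                                 "start_dt": _fmt_date(d.therapy_start_date)})
            rows["INDI"].append({"primaryid": pid, "caseid": cid,
                                 "indi_pt": d.indication_pt or ""})
        for pt in case.events:
            rows["REAC"].append({"primaryid": pid, "caseid": cid, "pt": pt})
        for oc in case.outcomes:
            rows["OUTC"].append({"primaryid": pid, "caseid": cid,
                                 "outc_cod": out_back[oc]})

    for case in cases:
        if case.case_id in duplicate_case_ids:
            early = (case.receipt_date - _dt.timedelta(30)
                     if case.receipt_date else None)
            emit(case, case.case_id * 100 + 1, early)
        emit(case, case.report_id, case.receipt_date)

    return {t: pd.DataFrame(r) for t, r in rows.items()}


def generate_dataset(config: GeneratorConfig
                     ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate the six raw quarterly tables plus the ground truth."""
    cases, truth = generate_cases(config)
    dup_ids = {c.case_id for c in cases if c.report_id % 100 == 2}
    return cases_to_tables(cases, duplicate_case_ids=dup_ids), truth


def write_dataset(tables: Mapping[str, pd.DataFrame], outdir: str | Path,
                  truth: GroundTruth | None = None,
                  config: GeneratorConfig | None = None) -> dict[str, Path]:
    """Write the tables (and optional ground-truth manifest) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = outdir / f"{name}.txt"
        df.to_csv(p, sep="$", index=False, lineterminator="\n")
        paths[name] = p
    if truth is not None:
        with open(outdir / "manifest.txt", "w") as fh:
            fh.write("drug\tpt\tlambda\n")
            for (d, p) in sorted(truth.planted_pairs):
                fh.write(f"{d}\t{p}\t{truth.true_lambda[(d, p)]:g}\n")
    if config is not None:
        socs = config.pt_soc_map()
        with open(outdir / "pt_soc_map.txt", "w") as fh:
            fh.write("pt\tsoc\n")
            for pt in config.pt_labels():
                fh.write(f"{pt}\t{socs[pt]}\n")
        with open(outdir / "synonyms.txt", "w") as fh:
            fh.write("raw\tcanonical\n")
            for d in config.drug_labels():
                fh.write(f"{d}\t{d}\n")
    return paths


# ---------------------------------------------------------------------------
# Hand-written small fixture
# ---------------------------------------------------------------------------

#: Documented expectations for :func:`fixture_small` (hand-counted).
FIXTURE_EXPECTED = {
    "raw_demo_rows": 20,
    "cases_after_dedup": 18,
    "duplicate_case_ids": (3, 12),
    # report versions that must survive deduplication
    "surviving_report_ids": {3: 302, 12: 1202},
    "missing_age_case": 5,
    "target_drug": "TEMOZOLOMIDE",
    # cases whose PS drug normalizes to TEMOZOLOMIDE, after dedup
    "target_case_ids": (1, 2, 3, 4, 5, 6, 7, 8),
    "planted_pt": "THROMBOCYTOPENIA",
    # event-level 2x2 for THROMBOCYTOPENIA at PT level, after dedup:
    # target cohort carries 14 distinct (case, PT) pairs, 6 of them the
    # planted PT; background carries 15 pairs, 1 of them the planted PT.
    "planted_pt_table": {"a": 6, "b": 8, "c": 1, "d": 14},
    # per-case event lists after dedup (case 3 keeps version 302's events)
    "events": {
        1: ("THROMBOCYTOPENIA", "NAUSEA"),
        2: ("THROMBOCYTOPENIA",),
        3: ("THROMBOCYTOPENIA", "HEADACHE"),
        4: ("NAUSEA", "RASH"),
        5: ("THROMBOCYTOPENIA",),
        6: ("THROMBOCYTOPENIA", "SEIZURE"),
        7: ("ANAEMIA", "NAUSEA"),
        8: ("THROMBOCYTOPENIA", "ANAEMIA"),
        9: ("HEADACHE",),
        10: ("NAUSEA",),
        11: ("RASH", "HEADACHE"),
        12: ("NAUSEA", "SEIZURE"),
        13: ("HEADACHE",),
        14: ("THROMBOCYTOPENIA", "NAUSEA"),
        15: ("RASH",),
        16: ("SEIZURE", "HEADACHE"),
        17: ("NAUSEA",),
        18: ("ANAEMIA", "RASH"),
    },
}

#: PT -> primary SOC map for the fixture's six terms.
FIXTURE_PT_SOC = {
    "THROMBOCYTOPENIA": "BLOOD AND LYMPHATIC SYSTEM DISORDERS",
    "ANAEMIA": "BLOOD AND LYMPHATIC SYSTEM DISORDERS",
    "NAUSEA": "GASTROINTESTINAL DISORDERS",
    "HEADACHE": "NERVOUS SYSTEM DISORDERS",
    "SEIZURE": "NERVOUS SYSTEM DISORDERS",
    "RASH": "SKIN AND SUBCUTANEOUS TISSUE DISORDERS",
}

#: Raw-name synonyms used by the fixture's DRUG table.
FIXTURE_SYNONYMS = {
    "TEMODAR": "TEMOZOLOMIDE",
    "TEMODAL": "TEMOZOLOMIDE",
    "TEMOZOLOMIDE": "TEMOZOLOMIDE",
}


def fixture_small() -> dict[str, pd.DataFrame]:
    """A 20-row hand-written dataset: 18 cases, two duplicated, one planted
    signal (TEMOZOLOMIDE × THROMBOCYTOPENIA) and one missing-age case.

    All post-deduplication expectations are hand-counted in
    :data:`FIXTURE_EXPECTED`.
    """
    target_raw = ["Temodar", "TEMODAL", "Temozolomide", " Temodar®",
                  "TEMOZOLOMIDE", "temodal", "TEMODAR", "Temozolomide "]
    other_drugs = ["ASPIRIN", "IBUPROFEN", "METFORMIN", "ASPIRIN", "METFORMIN",
                   "IBUPROFEN", "ASPIRIN", "METFORMIN", "IBUPROFEN", "ASPIRIN"]
    events = FIXTURE_EXPECTED["events"]

    demo, drug, reac, ther, outc, indi = [], [], [], [], [], []

    def add_case(case_id: int, report_id: int, fda: str, sex: str, age: str,
                 drugname: str, evts: tuple[str, ...], *, event_dt: str,
                 start_dt: str, ind: str, outcome: str = "HO") -> None:
        pid, cid = str(report_id), str(case_id)
        demo.append({"primaryid": pid, "caseid": cid, "fda_dt": fda,
                     "event_dt": event_dt, "sex": sex, "age": age,
                     "age_cod": "YR" if age else "", "wt": "70",
                     "occr_country": "US", "occp_cod": "MD"})
        drug.append({"primaryid": pid, "caseid": cid, "drugname": drugname,
                     "role_cod": "PS", "route": "Oral"})
        ther.append({"primaryid": pid, "caseid": cid, "start_dt": start_dt})
        indi.append({"primaryid": pid, "caseid": cid, "indi_pt": ind})
        for pt in evts:
            reac.append({"primaryid": pid, "caseid": cid, "pt": pt})
        if outcome:
            outc.append({"primaryid": pid, "caseid": cid, "outc_cod": outcome})

    for cid in range(1, 19):
        is_target = cid <= 8
        name = target_raw[cid - 1] if is_target else other_drugs[cid - 9]
        ind = "GLIOMA" if is_target else "PAIN"
        age = "" if cid == 5 else str(40 + cid)
        add_case(cid, cid * 100 + 1, f"2020{cid:02d}15"[:8] if cid <= 12
                 else f"20210{cid - 12}15", "F" if cid % 2 else "M", age,
                 name, events[cid], event_dt="20200601",
                 start_dt="20200401", ind=ind)

    # Duplicate versions: same case, later receipt date, higher report id.
    # Case 3's later version revises its event list (the one that must win).
    add_case(3, 302, "20201201", "F", "43", "Temozolomide", events[3],
             event_dt="20200601", start_dt="20200401", ind="GLIOMA")
    add_case(12, 1202, "20211201", "M", "52", "ASPIRIN", events[12],
             event_dt="20200601", start_dt="20200401", ind="PAIN")
    # The stale version-1 rows for case 3 carry a different event list so a
    # wrong dedup choice is detectable.
    for r in reac:
        if r["caseid"] == "3" and r["primaryid"] == "301":
            r["pt"] = "NAUSEA" if r["pt"] == "THROMBOCYTOPENIA" else r["pt"]

    return {"DEMO": pd.DataFrame(demo), "DRUG": pd.DataFrame(drug),
            "REAC": pd.DataFrame(reac), "THER": pd.DataFrame(ther),
            "OUTC": pd.DataFrame(outc), "INDI": pd.DataFrame(indi)}
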