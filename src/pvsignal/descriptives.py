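"""Descriptive summaries of a report cohort.

Baseline characteristic tables, annual report counts, the time-to-onset
distribution and indication tallies.  Percentages everywhere are rounded
half-up to two decimals, matching how published summary tables behave.

Two denominator rules exist for categorical summaries:

* ``known-only`` — percentages over rows with a known value (the unknowns
  are dropped from the denominator);
* ``all-rows`` — percentages over the full tally including unknowns.  For
  the ``outcome`` variable a case can carry several outcome codes, so the
  tally (and the all-rows denominator) is over outcome codes, not cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort_builder import normalize_drug_name
from .faers_ingest import CaseReport

logger = logging.getLogger("pvsignal")

SUPPORTED_VARIABLES = ("sex", "age-bucket", "reporter", "country", "route",
                       "outcome")

AGE_BUCKETS = ("<20", "20-40", "40-60", ">=60", "unknown")

#: Default onset bins in days: [0,30], (30,60], (60,90], (90,180],
#: (180,365], (365,730], (730, inf).
DEFAULT_TTO_EDGES = (0, 30, 60, 90, 180, 365, 730)


def percentage(count: float, denominator: float) -> float:
    """100·count/denominator rounded half-up to 2 decimals."""
    if denominator == 0:
        return float("nan")
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoricalSummary:
    variable: str
    #: (category, count, percentage) sorted by descending count
    rows: tuple[tuple[str, int, float], ...]
    denominator: int
    denominator_rule: str


@dataclass(frozen=True)
class TimeToOnset:
    """Onset lags in days with quartiles and binned counts."""

    lags_days: tuple[int, ...]
    median: float
    q1: float
    q3: float
    #: (bin label, count, percentage of non-missing)
    bins: tuple[tuple[str, int, float], ...]
    n_missing: int
    n_negative_excluded: int


def age_bucket(age_years: float | None) -> str:
    """Left-closed age buckets; exactly 20/40/60 go to the higher bucket."""
    if age_years is None:
        return "unknown"
    if age_years < 20:
        return "<20"
    if age_years < 40:
        return "20-40"
    if age_years < 60:
        return "40-60"
    return ">=60"


def _values(case: CaseReport, variable: str) -> list[str | None]:
    if variable == "sex":
        return [None if case.sex == "unknown" else case.sex]
    if variable == "age-bucket":
        b = age_bucket(case.age_years)
        return [None if b == "unknown" else b]
    if variable == "reporter":
        return [None if case.reporter == "unknown" else case.reporter]
    if variable == "country":
        return [case.country]
    if variable == "route":
        ps = next((d for d in case.drugs if d.role == "PS"), None)
        return [ps.route if ps else None]
    if variable == "outcome":
        return list(case.outcomes)  # multi-valued; may be empty
    raise ValueError(
        f"unknown variable {variable!r}; supported: {SUPPORTED_VARIABLES}")


def summarize_categorical(cases: Iterable[CaseReport], variable: str,
                          denominator_rule: str = "known-only"
                          ) -> CategoricalSummary:
    """Tally one baseline variable with percentages.

    Unknown values appear as an ``unknown`` row; under ``known-only`` they
    are excluded from the denominator (and carry no percentage weight in
    the reported rows' sum to 100).
    """
    if denominator_rule not in ("known-only", "all-rows"):
        raise ValueError("denominator_rule must be 'known-only' or 'all-rows'")
    if variable not in SUPPORTED_VARIABLES:
        raise ValueError(
            f"unknown variable {variable!r}; supported: {SUPPORTED_VARIABLES}")
    counts: dict[str, int] = {}
    n_known = 0
    n_all = 0
    for case in cases:
        for v in _values(case, variable):
            if v is None:
                counts["unknown"] = counts.get("unknown", 0) + 1
            else:
                counts[v] = counts.get(v, 0) + 1
                n_known += 1
            n_all += 1
    denom = n_known if denominator_rule == "known-only" else n_all
    rows = []
    for cat, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if denominator_rule == "known-only" and cat == "unknown":
            rows.append((cat, k, float("nan")))
        else:
            rows.append((cat, k, percentage(k, denom)))
    return CategoricalSummary(variable=variable, rows=tuple(rows),
                              denominator=denom,
                              denominator_rule=denominator_rule)


def annual_counts(cases: Iterable[CaseReport]) -> list[tuple[int, int]]:
    """Report counts by calendar year of receipt; missing dates excluded."""
    counts: dict[int, int] = {}
    missing = 0
    for case in cases:
        if case.receipt_date is None:
            missing += 1
            continue
        y = case.receipt_date.year
        counts[y] = counts.get(y, 0) + 1
    if missing:
        logger.info("annual_counts: %d reports without receipt date", missing)
    return sorted(counts.items())


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo}d"
    if lo == 0:
        return f"0-{hi}d"
    return f"{lo + 1}-{hi}d"


def time_to_onset(cases: Sequence[CaseReport],
                  edges: Sequence[int] = DEFAULT_TTO_EDGES,
                  target: str | None = None,
                  synonyms: Mapping[str, str] | None = None) -> TimeToOnset:
    """Onset lag (event date − earliest therapy start) per case, in days.

    When ``target`` is given, only therapy starts of drugs normalizing to
    it are considered; otherwise the earliest start across all drugs is
    used.  Cases with a missing date are counted missing; negative lags
    (event before therapy) are excluded and counted separately.
    """
    lags: list[int] = []
    n_missing = 0
    n_negative = 0
    for case in cases:
        starts = [d.therapy_start_date for d in case.drugs
                  if d.therapy_start_date is not None
                  and (target is None
                       or normalize_drug_name(d.drug_name_raw, synonyms) == target)]
        if not starts or case.event_onset_date is None:
            n_missing += 1
            continue
        lag = (case.event_onset_date - min(starts)).days
        if lag < 0:
            n_negative += 1
            continue
        lags.append(lag)
    if n_negative:
        logger.info("time_to_onset: excluded %d negative lags", n_negative)

    if lags:
        arr = np.asarray(lags, dtype=float)
        q1, med, q3 = (float(v) for v in np.percentile(arr, [25, 50, 75]))
    else:
        q1 = med = q3 = float("nan")

    n = len(lags)
    bins: list[tuple[str, int, float]] = []
    bounds = list(edges) + [None]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi is None:
            k = sum(1 for x in lags if x > lo)
        elif lo == 0:
            k = sum(1 for x in lags if 0 <= x <= hi)
        else:
            k = sum(1 for x in lags if lo < x <= hi)
        bins.append((_bin_label(lo, hi), k, percentage(k, n) if n else float("nan")))
    return TimeToOnset(lags_days=tuple(lags), median=med, q1=q1, q3=q3,
                       bins=tuple(bins), n_missing=n_missing,
                       n_negative_excluded=n_negative)


def summarize_indications(cases: Iterable[CaseReport],
                          merge_map: Mapping[str, str] | None = None
                          ) -> list[tuple[str, int]]:
    """Tally indications of primary-suspect drugs, merged through a map.

    Differently-named indications that denote the same condition (e.g. all
    glioma variants) are merged by the caller-supplied map; unmapped labels
    pass through unchanged.  Sorted by descending count.
    """
    merge_map = merge_map or {}
    counts: dict[str, int] = {}
    for case in cases:
        for d in case.drugs:
            if d.role == "PS" and d.indication_pt:
                group = merge_map.get(d.indication_pt, d.indication_pt)
                counts[group] = counts.get(group, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
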