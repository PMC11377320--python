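"""Target-drug cohort selection and 2×2 contingency-table construction.

A disproportionality analysis compares how often an event is reported with
the drug of interest against how often it is reported with everything else.
The cohort is defined by drug role: a case belongs to the target cohort iff
at least one of its drugs with role PS (primary suspect) normalizes to the
target label; every other case — including cases where the target appears
only as secondary suspect or concomitant — is background.

Counting unit.  By default each distinct (case, event-label) pair counts
once (``counting_unit="event"``): a case reporting thrombocytopenia twice
contributes 1 to that PT, a case reporting two different PTs contributes 1
to each.  Under this rule the per-label cell ``a`` sums across labels to the
cohort's total pair count, so all tables at one level share the same
target margin ``a+b``.  Case-level counting (each case counts once per
label it carries, margin = number of cases) is available by flag.

At SOC level the default is pure aggregation: a case contributing two PTs
of the same system organ class counts twice, so SOC cells are exactly the
sums of their member-PT cells.  Within-case SOC deduplication is a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .faers_ingest import CaseReport

_PUNCT = re.compile(r"[^A-Z0-9 ]+")
_WS = re.compile(r"\s+")


class CohortError(ValueError):
    """Cohort or table construction failed (e.g. unmapped PTs at SOC level)."""


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts of one drug–event pair against the rest.

    a: target drug AND event; b: target drug, other events;
    c: event with other drugs; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def normalize_drug_name(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Uppercase, trim, strip punctuation, collapse spaces, map synonyms.

    Unmapped names are returned in normalized form, so the operation is
    idempotent whether or not the name is in the synonym table.
    """
    name = _WS.sub(" ", _PUNCT.sub(" ", raw.upper())).strip()
    if synonyms:
        return synonyms.get(name, name)
    return name


def load_two_column_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Load a two-column delimited text file (with header) into a dict."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, value = line.split(sep)[:2]
            mapping[key.strip()] = value.strip()
    return mapping


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Synonym table: raw (normalized) name -> canonical label."""
    raw = load_two_column_map(path)
    return {normalize_drug_name(k): v.strip().upper() for k, v in raw.items()}


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """PT -> primary SOC assignment table."""
    return load_two_column_map(path)


def case_has_target_ps(case: CaseReport, target: str,
                       synonyms: Mapping[str, str] | None = None) -> bool:
    return any(d.role == "PS" and
               normalize_drug_name(d.drug_name_raw, synonyms) == target
               for d in case.drugs)


def select_target_cohort(cases: Iterable[CaseReport], target: str,
                         synonyms: Mapping[str, str] | None = None
                         ) -> tuple[list[CaseReport], list[CaseReport]]:
    """Partition cases into (target-PS cohort, background).

    The partition is exhaustive and disjoint; ``target`` must already be the
    canonical label (i.e. a value of the synonym table).
    """
    target_cases: list[CaseReport] = []
    background: list[CaseReport] = []
    for case in cases:
        (target_cases if case_has_target_ps(case, target, synonyms)
         else background).append(case)
    return target_cases, background


def _case_labels(case: CaseReport, level: str,
                 pt_soc_map: Mapping[str, str] | None,
                 soc_within_case_dedup: bool) -> list[str]:
    pts = sorted(set(case.events))  # within-case PT dedup always applies
    if level == "PT":
        return pts
    assert pt_soc_map is not None
    socs = [pt_soc_map[p] for p in pts]
    return sorted(set(socs)) if soc_within_case_dedup else sorted(socs)


def build_tables(target_cases: Sequence[CaseReport],
                 background_cases: Sequence[CaseReport],
                 level: str = "PT",
                 pt_soc_map: Mapping[str, str] | None = None,
                 counting_unit: str = "event",
                 soc_within_case_dedup: bool = False
                 ) -> dict[str, ContingencyTable]:
    """Build one 2×2 table per observed event label at PT or SOC level."""
    if level not in ("PT", "SOC"):
        raise CohortError(f"level must be 'PT' or 'SOC', got {level!r}")
    if counting_unit not in ("event", "case"):
        raise CohortError(
            f"counting_unit must be 'event' or 'case', got {counting_unit!r}")
    if level == "SOC":
        if pt_soc_map is None:
            raise CohortError("SOC level requires a PT->SOC map")
        observed = {p for cs in (target_cases, background_cases)
                    for c in cs for p in c.events}
        unmapped = sorted(observed - set(pt_soc_map))
        if unmapped:
            raise CohortError(f"PTs without SOC assignment: {unmapped}")

    def tally(cases: Sequence[CaseReport]) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        margin = 0
        for case in cases:
            labels = _case_labels(case, level, pt_soc_map, soc_within_case_dedup)
            if counting_unit == "case":
                labels = sorted(set(labels))
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
            margin += len(labels) if counting_unit == "event" else 0
        if counting_unit == "case":
            margin = len(cases)
        return counts, margin

    t_counts, t_margin = tally(target_cases)
    b_counts, b_margin = tally(background_cases)
    tables: dict[str, ContingencyTable] = {}
    for lab in sorted(set(t_counts) | set(b_counts)):
        a = t_counts.get(lab, 0)
        c = b_counts.get(lab, 0)
        tables[lab] = ContingencyTable(a=a, b=t_margin - a,
                                       c=c, d=b_margin - c)
    return tables


def build_all_drug_tables(cases: Sequence[CaseReport],
                          level: str = "PT",
                          pt_soc_map: Mapping[str, str] | None = None,
                          synonyms: Mapping[str, str] | None = None,
                          counting_unit: str = "event",
                          soc_within_case_dedup: bool = False
                          ) -> dict[tuple[str, str], ContingencyTable]:
    """2×2 tables for every (PS drug, event label) pair in the database.

    Cases are keyed by their first primary-suspect drug.  This is the input
    surface for empirical-Bayes hyperparameter fitting, which pools the
    whole database rather than a single drug's slice.
    """
    if level == "SOC":
        if pt_soc_map is None:
            raise CohortError("SOC level requires a PT->SOC map")
        unmapped = sorted({p for c in cases for p in c.events} - set(pt_soc_map))
        if unmapped:
            raise CohortError(f"PTs without SOC assignment: {unmapped}")

    counts: dict[str, dict[str, int]] = {}
    margins: dict[str, int] = {}
    for case in cases:
        ps = next((d for d in case.drugs if d.role == "PS"), None)
        if ps is None:
            continue
        drug = normalize_drug_name(ps.drug_name_raw, synonyms)
        labels = _case_labels(case, level, pt_soc_map, soc_within_case_dedup)
        if counting_unit == "case":
            labels = sorted(set(labels))
        dc = counts.setdefault(drug, {})
        for lab in labels:
            dc[lab] = dc.get(lab, 0) + 1
        margins[drug] = margins.get(drug, 0) + (
            len(labels) if counting_unit == "event" else 1)

    total_counts: dict[str, int] = {}
    for dc in counts.values():
        for lab, k in dc.items():
            total_counts[lab] = total_counts.get(lab, 0) + k
    total_margin = sum(margins.values())

    out: dict[tuple[str, str], ContingencyTable] = {}
    for drug in sorted(counts):
        dc, m = counts[drug], margins[drug]
        for lab in sorted(total_counts):
            a = dc.get(lab, 0)
            c = total_counts[lab] - a
            out[(drug, lab)] = ContingencyTable(
                a=a, b=m - a, c=c, d=total_margin - m - c)
    return out
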