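"""New-user cohort selection for oral 5-ASA treatment.

A cohort member is a *new user*: their first observed 5-ASA fill (the index
fill) is preceded by a 90-day washout with no 5-ASA dispensing and with
observable drug-plan eligibility, they carry no Crohn's disease diagnosis
(ICD-9 555.x) anywhere in their medical claims, and their eligibility
continuously covers the 365-day observation window starting at the index
date.  Exclusions are applied in a fixed order (washout -> Crohn's ->
coverage) and counted in an attrition log so sample-selection tables are
reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .claims_model import DrugClass, Product, Sex, write_table
from .config import DEFAULT_WASHOUT_DAYS, DEFAULT_WINDOW_DAYS

__all__ = [
    "CohortMember",
    "AttritionLog",
    "find_new_users",
    "apply_exclusions",
    "build_cohort",
    "cohort_to_frame",
    "cohort_from_frame",
    "write_cohort_table",
    "read_cohort_table",
]

WINDOW_DAYS = DEFAULT_WINDOW_DAYS


@dataclass(frozen=True)
class CohortMember:
    """A new 5-ASA user with an index date and a 365-day observation window."""

    patient_id: str
    index_date: dt.date
    index_product: Product
    sex: Sex
    age_at_index: int

    @property
    def window_start(self) -> dt.date:
        return self.index_date

    @property
    def window_end(self) -> dt.date:
        return self.index_date + dt.timedelta(days=WINDOW_DAYS - 1)


@dataclass
class AttritionLog:
    """Counts removed per exclusion rule, in application order."""

    n_candidates: int = 0
    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, rule: str, n_removed: int) -> None:
        self.steps.append((rule, n_removed))

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.steps)

    @property
    def n_members(self) -> int:
        return self.n_candidates - self.n_removed

    def to_text(self) -> str:
        lines = [f"patients with >=1 5-ASA fill: {self.n_candidates}"]
        remaining = self.n_candidates
        for rule, n in self.steps:
            remaining -= n
            lines.append(f"excluded by {rule}: {n} (remaining {remaining})")
        lines.append(f"cohort members: {self.n_members}")
        return "\n".join(lines)


def _eligibility_covers(periods: list[tuple[dt.date, dt.date]], start: dt.date, end: dt.date) -> bool:
    """True iff the union of closed periods covers every day of [start, end].

    Periods abutting or overlapping are merged; a one-day hole fails.
    """
    if start > end:
        return True
    cursor = start
    for p_start, p_end in sorted(periods):
        if p_start > cursor:
            return False
        if p_end >= cursor:
            cursor = p_end + dt.timedelta(days=1)
        if cursor > end:
            return True
    return cursor > end


def find_new_users(
    dispensing: pd.DataFrame,
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    eligibility: pd.DataFrame | None = None,
    all_drugs_washout: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Identify at most one index event per patient.

    The candidate index is each patient's earliest 5-ASA fill.  It qualifies
    when no disqualifying fill (5-ASA only by default; any drug under
    ``all_drugs_washout``) occurs in the ``washout_days`` before it *and*,
    when ``eligibility`` is given, the patient is continuously eligible over
    that pre-index washout interval (otherwise the washout is unobservable
    — left-truncated history — and the patient is excluded).

    Returns ``(candidates, n_washout_excluded)`` where candidates has columns
    ``patient_id, index_date, index_product``.
    """
    asa = dispensing[dispensing["drug_class"] == DrugClass.FIVE_ASA.value]
    if asa.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "index_product"]), 0

    elig_periods: dict[str, list[tuple[dt.date, dt.date]]] = {}
    if eligibility is not None:
        for row in eligibility.itertuples(index=False):
            elig_periods.setdefault(str(row.patient_id), []).append(
                (row.start_date, row.end_date)
            )

    firsts = asa.sort_values(["patient_id", "dispense_date"], kind="mergesort").drop_duplicates(
        "patient_id", keep="first"
    )
    rows: list[tuple[str, dt.date, str]] = []
    n_excluded = 0
    for first in firsts.itertuples(index=False):
        pid = str(first.patient_id)
        index_date: dt.date = first.dispense_date
        washout_start = index_date - dt.timedelta(days=washout_days)
        washout_end = index_date - dt.timedelta(days=1)
        ok = True
        if all_drugs_washout:
            prior = dispensing[
                (dispensing["patient_id"] == first.patient_id)
                & (dispensing["dispense_date"] >= washout_start)
                & (dispensing["dispense_date"] <= washout_end)
            ]
            ok = prior.empty
        # earliest 5-ASA fill has no prior 5-ASA fill by construction
        if ok and eligibility is not None:
            ok = _eligibility_covers(elig_periods.get(pid, []), washout_start, washout_end)
        if ok:
            rows.append((pid, index_date, first.product))
        else:
            n_excluded += 1
    candidates = pd.DataFrame(rows, columns=["patient_id", "index_date", "index_product"])
    return candidates.sort_values("patient_id", kind="mergesort").reset_index(drop=True), n_excluded


def apply_exclusions(
    candidates: pd.DataFrame,
    medical: pd.DataFrame,
    eligibility: pd.DataFrame,
    patients: pd.DataFrame,
    attrition: AttritionLog | None = None,
) -> tuple[list[CohortMember], AttritionLog]:
    """Apply Crohn's-diagnosis and 1-year-coverage exclusions, in that order.

    Crohn's (ICD-9 555.0–555.9) is screened over the patient's entire
    available medical-claims history.  Coverage requires eligibility over the
    full closed window [index_date, index_date + 364 d].
    """
    attrition = attrition or AttritionLog(n_candidates=len(candidates))

    crohns_ids = set()
    if not medical.empty:
        is_crohns = medical["icd9_code"].str.match(r"^555(\.\d{1,2})?$")
        crohns_ids = set(medical.loc[is_crohns, "patient_id"].astype(str))

    elig_periods: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for row in eligibility.itertuples(index=False):
        elig_periods.setdefault(str(row.patient_id), []).append((row.start_date, row.end_date))

    demo = patients.set_index(patients["patient_id"].astype(str))

    kept_after_crohns = []
    n_crohns = 0
    for row in candidates.itertuples(index=False):
        if str(row.patient_id) in crohns_ids:
            n_crohns += 1
        else:
            kept_after_crohns.append(row)
    attrition.record("Crohn's disease diagnosis (ICD-9 555.x)", n_crohns)

    members: list[CohortMember] = []
    n_coverage = 0
    for row in kept_after_crohns:
        pid = str(row.patient_id)
        window_end = row.index_date + dt.timedelta(days=WINDOW_DAYS - 1)
        if not _eligibility_covers(elig_periods.get(pid, []), row.index_date, window_end):
            n_coverage += 1
            continue
        rec = demo.loc[pid]
        members.append(
            CohortMember(
                patient_id=pid,
                index_date=row.index_date,
                index_product=Product(row.index_product),
                sex=Sex(rec["sex"]),
                age_at_index=row.index_date.year - int(rec["birth_year"]),
            )
        )
    attrition.record("drug-plan coverage < 1 year post-index", n_coverage)
    return members, attrition


def build_cohort(
    dispensing: pd.DataFrame,
    medical: pd.DataFrame,
    eligibility: pd.DataFrame,
    patients: pd.DataFrame,
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    all_drugs_washout: bool = False,
) -> tuple[list[CohortMember], AttritionLog]:
    """Full selection: washout -> Crohn's -> coverage, with attrition counts."""
    candidates, n_washout = find_new_users(
        dispensing, washout_days=washout_days, eligibility=eligibility,
        all_drugs_washout=all_drugs_washout,
    )
    attrition = AttritionLog(n_candidates=len(candidates) + n_washout)
    attrition.record(f"washout violated (<{washout_days} d observable 5-ASA-free history)", n_washout)
    members, attrition = apply_exclusions(candidates, medical, eligibility, patients, attrition)
    return members, attrition


# ---------------------------------------------------------------------------
# (De)serialization

_COHORT_COLUMNS = ["patient_id", "index_date", "index_product", "sex", "age_at_index"]


def cohort_to_frame(members: list[CohortMember]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.patient_id, m.index_date, m.index_product.value, m.sex.value, m.age_at_index)
            for m in members
        ],
        columns=_COHORT_COLUMNS,
    )


def cohort_from_frame(frame: pd.DataFrame) -> list[CohortMember]:
    return [
        CohortMember(
            patient_id=str(r.patient_id),
            index_date=r.index_date if isinstance(r.index_date, dt.date) else dt.date.fromisoformat(str(r.index_date)),
            index_product=Product(r.index_product),
            sex=Sex(r.sex),
            age_at_index=int(r.age_at_index),
        )
        for r in frame.itertuples(index=False)
    ]


def write_cohort_table(members: list[CohortMember], path: str | Path, delimiter: str = ",") -> None:
    write_table(cohort_to_frame(members), path, delimiter=delimiter)


def read_cohort_table(path: str | Path, delimiter: str = ",") -> list[CohortMember]:
    frame = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    frame["index_date"] = frame["index_date"].map(dt.date.fromisoformat)
    return cohort_from_frame(frame)
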