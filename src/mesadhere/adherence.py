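"""Medication possession ratio (MPR) over the 365-day observation window.

MPR = days of 5-ASA supply dispensed in the window / 365, with the final
fill truncated at the window end and the numerator capped at 365.  A
day-coverage variant (PDC with carry-forward stockpiling, which cannot
double-count overlapping supply) is available for sensitivity analysis.
Adherence is classified at the inclusive >=80% threshold, with >=50% as a
complementary cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Literal, Mapping, Sequence

import pandas as pd

from ._rounding import pct
from .claims_model import DrugClass, Product
from .cohort import WINDOW_DAYS, CohortMember

__all__ = ["AdherenceResult", "compute_mpr", "compute_mpr_all", "adherence_summary"]

MprPolicy = Literal["sum", "pdc"]


class PartitionError(ValueError):
    """A grouping does not partition the members (overlap or omission)."""


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: str
    index_product: Product
    days_supplied: int
    mpr: float
    adherent_80: bool
    adherent_50: bool


def _window_offsets(member: CohortMember, fills: pd.DataFrame, index_product_only: bool) -> list[tuple[int, int]]:
    """Qualifying fills as (day offset from index, days_supply), sorted."""
    out = []
    for row in fills.itertuples(index=False):
        if row.drug_class != DrugClass.FIVE_ASA.value:
            continue
        if index_product_only and row.product != member.index_product.value:
            continue
        t = (row.dispense_date - member.index_date).days
        if 0 <= t < WINDOW_DAYS:
            out.append((t, int(row.days_supply)))
    out.sort()
    return out


def compute_mpr(
    member: CohortMember,
    fills: pd.DataFrame,
    policy: MprPolicy = "sum",
    index_product_only: bool = False,
) -> AdherenceResult:
    """MPR for one member from that patient's dispensing rows.

    ``policy="sum"`` is the classic MPR: sum of days_supply of qualifying
    fills, each fill truncated at the window end, capped at 365.
    ``policy="pdc"`` counts distinct covered days with carry-forward
    stockpiling (supply from an early refill is banked and consumed after
    the previous fill runs out).

    All 5-ASA products count by default; ``index_product_only`` restricts to
    the index product.  Raises ``ValueError`` when no qualifying fill exists
    (a cohort member always has the index fill, so this flags inconsistent
    inputs).
    """
    offsets = _window_offsets(member, fills, index_product_only)
    if not offsets:
        raise ValueError(
            f"patient {member.patient_id!r}: no qualifying 5-ASA fill in window; "
            "inconsistent cohort/dispensing inputs"
        )
    if policy == "sum":
        days = sum(min(s, WINDOW_DAYS - t) for t, s in offsets)
        days = min(WINDOW_DAYS, days)
    elif policy == "pdc":
        days = 0
        runout = -1  # last covered day offset
        for t, s in offsets:
            start = max(t, runout + 1)
            runout = start + s - 1
            days += max(0, min(runout, WINDOW_DAYS - 1) - start + 1)
    else:
        raise ValueError(f"unknown MPR policy {policy!r}")
    mpr = days / WINDOW_DAYS
    return AdherenceResult(
        patient_id=member.patient_id,
        index_product=member.index_product,
        days_supplied=days,
        mpr=mpr,
        adherent_80=mpr >= 0.80,
        adherent_50=mpr >= 0.50,
    )


def compute_mpr_all(
    members: Sequence[CohortMember],
    dispensing: pd.DataFrame,
    policy: MprPolicy = "sum",
    index_product_only: bool = False,
) -> pd.DataFrame:
    """MPR for every member; returns one row per member.

    Columns: patient_id, index_product, days_supplied, mpr, adherent_80,
    adherent_50.  Order-independent with respect to dispensing row order.
    """
    by_patient = dict(tuple(dispensing.groupby("patient_id", sort=False)))
    empty = dispensing.iloc[0:0]
    rows = []
    for m in members:
        res = compute_mpr(m, by_patient.get(m.patient_id, empty), policy, index_product_only)
        rows.append(
            (res.patient_id, res.index_product.value, res.days_supplied, res.mpr,
             res.adherent_80, res.adherent_50)
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "index_product", "days_supplied", "mpr",
                 "adherent_80", "adherent_50"],
    )


def adherence_summary(
    results: pd.DataFrame,
    grouping: Mapping[Hashable, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-group adherent counts and percentages at both thresholds.

    ``grouping`` maps a group label to the patient_ids it contains and must
    partition the results exactly (every patient in exactly one group);
    ``None`` summarizes everyone as one "overall" row.  Percentages are
    round-half-up at one decimal.
    """
    if grouping is None:
        grouping = {"overall": list(results["patient_id"])}
    groups = {label: [str(i) for i in ids] for label, ids in grouping.items()}
    all_ids = list(results["patient_id"].astype(str))
    seen: set[str] = set()
    for label, ids in groups.items():
        id_set = set(ids)
        dup = seen & id_set
        if dup:
            raise PartitionError(f"patients in multiple groups: {sorted(dup)[:5]}")
        seen |= id_set
    missing = set(all_ids) - seen
    if missing:
        raise PartitionError(f"patients missing from grouping: {sorted(missing)[:5]}")

    indexed = results.set_index(results["patient_id"].astype(str))
    rows = []
    for label, ids in groups.items():
        sub = indexed.loc[ids] if ids else indexed.iloc[0:0]
        n = len(sub)
        n80 = int(sub["adherent_80"].sum())
        n50 = int(sub["adherent_50"].sum())
        rows.append(
            (label, n, n80, pct(n80, n) if n else float("nan"),
             n50, pct(n50, n) if n else float("nan"))
        )
    return pd.DataFrame(
        rows, columns=["group", "n", "n_adherent_80", "pct_80", "n_adherent_50", "pct_50"]
    )
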