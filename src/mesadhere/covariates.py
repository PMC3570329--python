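"""Determinant covariates: demographics, comorbidity markers, chronic disease score.

Comorbidity is assessed from the medication profile, not diagnoses: a
comorbidity flag is true when at least one marker-class fill (e.g. an
antidiabetic for diabetes) occurs in the lookback — by default the 365 days
before the index date through the end of the observation window.  The
chronic disease score (CDS) sums configurable integer weights over the
*distinct* medication classes observed in the same lookback, with optional
combination adjustments, and is dichotomized at a configurable cut
(default 6, the source cohort's median; ``median_cut`` recomputes the cut
from the data at hand).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .claims_model import CodeMap, DrugClass, Sex
from .cohort import CohortMember
from .config import (
    DEFAULT_CDS_COMBOS,
    DEFAULT_CDS_CUT,
    DEFAULT_CDS_POINTS,
    DEFAULT_COVARIATE_LOOKBACK_DAYS,
    COMORBIDITY_CATEGORIES,
    default_code_map,
)

__all__ = ["CdsWeightTable", "CovariateVector", "compute_cds", "derive_covariates",
           "derive_covariates_all", "covariates_to_frame"]


@dataclass(frozen=True)
class CdsWeightTable:
    """Integer points per medication class plus co-occurrence adjustments."""

    points: Mapping[str, int]
    combos: Sequence[tuple[frozenset[str], int]] = ()

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.points.values()):
            raise ValueError("CDS points must be non-negative")

    def score(self, classes: set[str]) -> int:
        total = sum(self.points.get(c, 0) for c in classes)
        for combo, delta in self.combos:
            if combo <= classes:
                total += delta
        return total

    @classmethod
    def from_yaml(cls, path) -> "CdsWeightTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        combos = tuple(
            (frozenset(c["classes"]), int(c["delta"])) for c in raw.get("combos", [])
        )
        return cls(points={str(k): int(v) for k, v in raw["points"].items()}, combos=combos)


DEFAULT_CDS_TABLE = CdsWeightTable(points=dict(DEFAULT_CDS_POINTS), combos=DEFAULT_CDS_COMBOS)


@dataclass(frozen=True)
class CovariateVector:
    patient_id: str
    male: bool
    age_ge_60: bool
    hypertension: bool
    heart_disease: bool
    respiratory_illness: bool
    diabetes: bool
    cds_score: int
    cds_high: bool
    prior_steroid: bool
    current_steroid: bool


def compute_cds(
    fills: pd.DataFrame,
    weights: CdsWeightTable = DEFAULT_CDS_TABLE,
    code_map: CodeMap | None = None,
    strict: bool = False,
) -> int:
    """CDS for one patient's fills: each observed medication class counts once.

    Under ``strict``, a COMORBIDITY_MARKER fill whose code maps to no CDS
    class raises a config error instead of being ignored.
    """
    code_map = code_map or default_code_map()
    classes: set[str] = set()
    for code in fills["drug_code"].unique():
        entry = code_map.lookup(str(code))
        if entry.cds_class is not None:
            classes.add(entry.cds_class)
        elif strict and entry.drug_class is DrugClass.COMORBIDITY_MARKER:
            raise KeyError(f"drug code {code!r} has no CDS class under strict scoring")
    return weights.score(classes)


def derive_covariates(
    member: CohortMember,
    fills: pd.DataFrame,
    weights: CdsWeightTable = DEFAULT_CDS_TABLE,
    code_map: CodeMap | None = None,
    cds_cut: int = DEFAULT_CDS_CUT,
    lookback_days: int = DEFAULT_COVARIATE_LOOKBACK_DAYS,
) -> CovariateVector:
    """All determinant covariates for one member.

    Steroid exposure: *prior* = any corticosteroid fill in the 365 days
    before index; *current* = any corticosteroid fill inside the 365-day
    observation window.  Age >=60 is inclusive.
    """
    code_map = code_map or default_code_map()
    lb_start = member.index_date - dt.timedelta(days=lookback_days)
    in_lookback = fills[
        (fills["dispense_date"] >= lb_start) & (fills["dispense_date"] <= member.window_end)
    ]

    markers = {cat: False for cat in COMORBIDITY_CATEGORIES}
    for code in in_lookback["drug_code"].unique():
        entry = code_map.lookup(str(code))
        if entry.marker in markers:
            markers[entry.marker] = True

    steroid_dates = [
        row.dispense_date
        for row in fills.itertuples(index=False)
        if row.drug_class == DrugClass.CORTICOSTEROID.value
    ]
    prior = any(lb_start <= d <= member.index_date - dt.timedelta(days=1) for d in steroid_dates)
    current = any(member.index_date <= d <= member.window_end for d in steroid_dates)

    score = compute_cds(in_lookback, weights, code_map)
    return CovariateVector(
        patient_id=member.patient_id,
        male=member.sex is Sex.MALE,
        age_ge_60=member.age_at_index >= 60,
        hypertension=markers["hypertension"],
        heart_disease=markers["heart_disease"],
        respiratory_illness=markers["respiratory_illness"],
        diabetes=markers["diabetes"],
        cds_score=score,
        cds_high=score >= cds_cut,
        prior_steroid=prior,
        current_steroid=current,
    )


def derive_covariates_all(
    members: Sequence[CohortMember],
    dispensing: pd.DataFrame,
    weights: CdsWeightTable = DEFAULT_CDS_TABLE,
    code_map: CodeMap | None = None,
    cds_cut: int | None = DEFAULT_CDS_CUT,
    lookback_days: int = DEFAULT_COVARIATE_LOOKBACK_DAYS,
    median_cut: bool = False,
) -> pd.DataFrame:
    """Covariate vectors for the whole cohort as a frame.

    ``median_cut=True`` recomputes the CDS dichotomization threshold as the
    cohort median score (ceiling of the median for non-integer medians) and
    overrides ``cds_cut``.
    """
    code_map = code_map or default_code_map()
    by_patient = dict(tuple(dispensing.groupby("patient_id", sort=False)))
    empty = dispensing.iloc[0:0]
    vecs = [
        derive_covariates(
            m, by_patient.get(m.patient_id, empty), weights, code_map,
            cds_cut=0, lookback_days=lookback_days,
        )
        for m in members
    ]
    if median_cut:
        import math

        scores = sorted(v.cds_score for v in vecs)
        cut = math.ceil(pd.Series(scores).median()) if scores else 0
    else:
        cut = DEFAULT_CDS_CUT if cds_cut is None else cds_cut
    frame = covariates_to_frame(vecs)
    frame["cds_high"] = frame["cds_score"] >= cut
    frame.attrs["cds_cut"] = cut
    return frame


def covariates_to_frame(vectors: Sequence[CovariateVector]) -> pd.DataFrame:
    return pd.DataFrame([vars(v).copy() for v in vectors])
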