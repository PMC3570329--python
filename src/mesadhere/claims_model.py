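"""Domain types and delimited-text I/O for pharmacy / medical claims data.

The package works on four delimited tables (comma by default, tab accepted):

``dispensing.csv``
    one pharmacy fill per row — ``patient_id, dispense_date, drug_code,
    quantity, days_supply``.  Product and therapeutic class are *derived*
    from ``drug_code`` through a :class:`CodeMap`, mirroring how real claims
    extracts carry raw drug identifiers rather than study categories.
``medical.csv``
    one medical service per row — ``patient_id, service_date, icd9_code``.
``eligibility.csv``
    drug-plan coverage intervals — ``patient_id, start_date, end_date``.
``patients.csv``
    demographics — ``patient_id, sex, birth_year[, region]``.

Dates are ISO 8601 (``YYYY-MM-DD``) everywhere.  Date intervals are closed:
a fill on day *d* with ``days_supply`` *s* covers days *d* … *d+s−1*.

Readers return :class:`pandas.DataFrame` objects with a fixed column schema
(the "ordered collection" of records); :func:`claims_from_frame` and friends
convert to/from lists of frozen dataclass records when a typed object per
row is more convenient than a frame.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "Product",
    "DrugClass",
    "Sex",
    "FIVE_ASA_PRODUCTS",
    "DispensingClaim",
    "MedicalClaim",
    "EligibilityPeriod",
    "PatientRecord",
    "CodeMap",
    "ClaimsSchemaError",
    "ClaimsRowError",
    "read_dispensing_claims",
    "read_medical_claims",
    "read_eligibility",
    "read_patients",
    "claims_to_frame",
    "claims_from_frame",
    "write_table",
]


class Product(str, enum.Enum):
    """Oral 5-ASA brands marketed in Quebec, plus OTHER for non-5-ASA drugs."""

    ASACOL_OR_GENERIC = "ASACOL_OR_GENERIC"
    PENTASA = "PENTASA"
    SALOFALK = "SALOFALK"
    MEZAVANT = "MEZAVANT"
    OTHER = "OTHER"


class DrugClass(str, enum.Enum):
    FIVE_ASA = "FIVE_ASA"
    CORTICOSTEROID = "CORTICOSTEROID"
    COMORBIDITY_MARKER = "COMORBIDITY_MARKER"
    OTHER = "OTHER"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


FIVE_ASA_PRODUCTS = frozenset(
    {Product.ASACOL_OR_GENERIC, Product.PENTASA, Product.SALOFALK, Product.MEZAVANT}
)

_ICD9_RE = re.compile(r"^\d{3}(\.\d{1,2})?$")


class ClaimsSchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ClaimsRowError(ValueError):
    """A data row violates a record invariant; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class DispensingClaim:
    """One pharmacy fill: who, when, which drug, how many days of supply."""

    patient_id: str
    dispense_date: dt.date
    drug_code: str
    product: Product
    drug_class: DrugClass
    quantity: int
    days_supply: int

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")
        if self.quantity < 1:
            raise ValueError(f"quantity must be >= 1, got {self.quantity}")
        is_asa_product = self.product in FIVE_ASA_PRODUCTS
        if is_asa_product != (self.drug_class is DrugClass.FIVE_ASA):
            raise ValueError(
                f"product {self.product.value} inconsistent with drug_class "
                f"{self.drug_class.value}: a 5-ASA product iff class FIVE_ASA"
            )

    @property
    def supply_end(self) -> dt.date:
        """Last day covered by this fill (closed interval)."""
        return self.dispense_date + dt.timedelta(days=self.days_supply - 1)


@dataclass(frozen=True)
class MedicalClaim:
    patient_id: str
    service_date: dt.date
    icd9_code: str

    def __post_init__(self) -> None:
        if not _ICD9_RE.match(self.icd9_code):
            raise ValueError(f"malformed ICD-9 code: {self.icd9_code!r}")


@dataclass(frozen=True)
class EligibilityPeriod:
    patient_id: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("eligibility start_date after end_date")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: Sex
    birth_year: int
    region: str | None = None


# ---------------------------------------------------------------------------
# Drug-code mapping


@dataclass(frozen=True)
class CodeEntry:
    product: Product
    drug_class: DrugClass
    marker: str | None = None  # comorbidity category (hypertension, ...)
    cds_class: str | None = None  # chronic-disease-score medication class


class CodeMap:
    """Maps raw drug codes to study categories (product, class, markers).

    Extensible via YAML so the four-product default can be widened without
    code changes::

        codes:
          MEZAVANT: {product: MEZAVANT, drug_class: FIVE_ASA}
          METFORMIN:
            drug_class: COMORBIDITY_MARKER
            marker: diabetes
            cds_class: diabetes
    """

    def __init__(self, entries: Mapping[str, CodeEntry], strict: bool = False):
        self._entries = dict(entries)
        self.strict = strict

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def lookup(self, code: str) -> CodeEntry:
        entry = self._entries.get(code)
        if entry is None:
            if self.strict:
                raise KeyError(f"unknown drug code {code!r} under strict mapping")
            return CodeEntry(Product.OTHER, DrugClass.OTHER)
        return entry

    @classmethod
    def from_yaml(cls, path: str | Path, strict: bool = False) -> "CodeMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = {}
        for code, spec in (raw.get("codes") or {}).items():
            entries[str(code)] = CodeEntry(
                product=Product(spec.get("product", "OTHER")),
                drug_class=DrugClass(spec.get("drug_class", "OTHER")),
                marker=spec.get("marker"),
                cds_class=spec.get("cds_class"),
            )
        return cls(entries, strict=strict)


# ---------------------------------------------------------------------------
# Readers

DISPENSING_COLUMNS = ["patient_id", "dispense_date", "drug_code", "quantity", "days_supply"]
MEDICAL_COLUMNS = ["patient_id", "service_date", "icd9_code"]
ELIGIBILITY_COLUMNS = ["patient_id", "start_date", "end_date"]
PATIENT_COLUMNS = ["patient_id", "sex", "birth_year"]

BadRowPolicy = Literal["error", "skip"]


def _read_raw(path: str | Path, required: Sequence[str], delimiter: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ClaimsSchemaError(f"{path}: empty file, header row required") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ClaimsSchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def _parse_date(value: str, column: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ClaimsRowError(f"unparseable {column} {value!r} (expected YYYY-MM-DD)", line) from exc


def _parse_positive_int(value: str, column: str, line: int) -> int:
    try:
        parsed = int(value)
    except ValueError as exc:
        raise ClaimsRowError(f"non-integer {column} {value!r}", line) from exc
    if parsed < 1:
        raise ClaimsRowError(f"non-positive {column} {parsed}", line)
    return parsed


def read_dispensing_claims(
    path: str | Path,
    code_map: CodeMap | None = None,
    delimiter: str = ",",
    on_bad_row: BadRowPolicy = "error",
) -> pd.DataFrame:
    """Read pharmacy fills, derive product / drug class, sort by patient & date.

    Returns a frame with columns ``patient_id, dispense_date, drug_code,
    product, drug_class, quantity, days_supply`` sorted by
    ``(patient_id, dispense_date)``.  Malformed rows raise
    :class:`ClaimsRowError` with the 1-based file line, or are skipped with a
    logged warning under ``on_bad_row="skip"``.
    """
    if code_map is None:
        from .config import default_code_map

        code_map = default_code_map()
    raw = _read_raw(path, DISPENSING_COLUMNS, delimiter)
    rows, bad = [], 0
    for i, rec in enumerate(raw.itertuples(index=False)):
        line = i + 2  # 1-based; header is line 1
        try:
            date = _parse_date(rec.dispense_date, "dispense_date", line)
            quantity = _parse_positive_int(rec.quantity, "quantity", line)
            days_supply = _parse_positive_int(rec.days_supply, "days_supply", line)
        except ClaimsRowError:
            if on_bad_row == "skip":
                bad += 1
                log.warning("%s: skipping malformed dispensing row at line %d", path, line)
                continue
            raise
        entry = code_map.lookup(rec.drug_code)
        rows.append(
            (rec.patient_id, date, rec.drug_code, entry.product.value,
             entry.drug_class.value, quantity, days_supply)
        )
    if bad:
        log.warning("%s: skipped %d malformed row(s)", path, bad)
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "dispense_date", "drug_code", "product",
                 "drug_class", "quantity", "days_supply"],
    )
    return frame.sort_values(["patient_id", "dispense_date"], kind="mergesort").reset_index(drop=True)


def read_medical_claims(
    path: str | Path, delimiter: str = ",", on_bad_row: BadRowPolicy = "error"
) -> pd.DataFrame:
    raw = _read_raw(path, MEDICAL_COLUMNS, delimiter)
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False)):
        line = i + 2
        try:
            date = _parse_date(rec.service_date, "service_date", line)
            if not _ICD9_RE.match(rec.icd9_code):
                raise ClaimsRowError(f"malformed ICD-9 code {rec.icd9_code!r}", line)
        except ClaimsRowError:
            if on_bad_row == "skip":
                log.warning("%s: skipping malformed medical row at line %d", path, line)
                continue
            raise
        rows.append((rec.patient_id, date, rec.icd9_code))
    frame = pd.DataFrame(rows, columns=["patient_id", "service_date", "icd9_code"])
    return frame.sort_values(["patient_id", "service_date"], kind="mergesort").reset_index(drop=True)


def read_eligibility(
    path: str | Path, delimiter: str = ",", on_bad_row: BadRowPolicy = "error"
) -> pd.DataFrame:
    raw = _read_raw(path, ELIGIBILITY_COLUMNS, delimiter)
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False)):
        line = i + 2
        try:
            start = _parse_date(rec.start_date, "start_date", line)
            end = _parse_date(rec.end_date, "end_date", line)
            if start > end:
                raise ClaimsRowError("start_date after end_date", line)
        except ClaimsRowError:
            if on_bad_row == "skip":
                log.warning("%s: skipping malformed eligibility row at line %d", path, line)
                continue
            raise
        rows.append((rec.patient_id, start, end))
    frame = pd.DataFrame(rows, columns=ELIGIBILITY_COLUMNS)
    return frame.sort_values(["patient_id", "start_date"], kind="mergesort").reset_index(drop=True)


def read_patients(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    raw = _read_raw(path, PATIENT_COLUMNS, delimiter)
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False)):
        line = i + 2
        try:
            sex = Sex(rec.sex)
        except ValueError as exc:
            raise ClaimsRowError(f"unknown sex {rec.sex!r}", line) from exc
        birth_year = _parse_positive_int(rec.birth_year, "birth_year", line)
        region = getattr(rec, "region", "") or None
        rows.append((rec.patient_id, sex.value, birth_year, region))
    frame = pd.DataFrame(rows, columns=["patient_id", "sex", "birth_year", "region"])
    return frame.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Record <-> frame converters and generic writer


def claims_to_frame(claims: Iterable[DispensingClaim]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.patient_id, c.dispense_date, c.drug_code, c.product.value,
             c.drug_class.value, c.quantity, c.days_supply)
            for c in claims
        ],
        columns=["patient_id", "dispense_date", "drug_code", "product",
                 "drug_class", "quantity", "days_supply"],
    )


def claims_from_frame(frame: pd.DataFrame) -> list[DispensingClaim]:
    return [
        DispensingClaim(
            patient_id=str(r.patient_id),
            dispense_date=_as_date(r.dispense_date),
            drug_code=str(r.drug_code),
            product=Product(r.product),
            drug_class=DrugClass(r.drug_class),
            quantity=int(r.quantity),
            days_supply=int(r.days_supply),
        )
        for r in frame.itertuples(index=False)
    ]


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, (pd.Timestamp, dt.datetime)):
        return value.date()
    return dt.date.fromisoformat(str(value))


def write_table(frame: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a frame as delimited UTF-8 text with ISO dates (round-trip safe)."""
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        elif out[col].map(lambda v: isinstance(v, dt.date)).any():
            out[col] = out[col].map(lambda v: v.isoformat() if isinstance(v, dt.date) else v)
    out.to_csv(path, sep=delimiter, index=False, encoding="utf-8")
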