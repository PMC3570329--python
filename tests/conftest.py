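from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from mesadhere.claims_model import DrugClass, Product, Sex
from mesadhere.cohort import CohortMember

INDEX = dt.date(2006, 3, 15)

DISPENSING_COLUMNS = [
    "patient_id", "dispense_date", "drug_code", "product", "drug_class",
    "quantity", "days_supply",
]

_PRODUCT_CODE = {
    Product.ASACOL_OR_GENERIC: "ASACOL",
    Product.PENTASA: "PENTASA",
    Product.SALOFALK: "SALOFALK",
    Product.MEZAVANT: "MEZAVANT",
}


def member(
    pid: str = "P1",
    index_date: dt.date = INDEX,
    product: Product = Product.ASACOL_OR_GENERIC,
    sex: Sex = Sex.FEMALE,
    age: int = 55,
) -> CohortMember:
    return CohortMember(
        patient_id=pid, index_date=index_date, index_product=product,
        sex=sex, age_at_index=age,
    )


def fills_frame(
    fills: list[tuple[int, int]],
    pid: str = "P1",
    index_date: dt.date = INDEX,
    product: Product = Product.ASACOL_OR_GENERIC,
    other: list[tuple[int, int, Product]] | None = None,
) -> pd.DataFrame:
    """Dispensing frame from (day-offset, days_supply) tuples for one patient.

    ``other`` adds fills of different products as (offset, supply, product).
    """
    rows = []
    for t, s in fills:
        rows.append(
            (pid, index_date + dt.timedelta(days=t), _PRODUCT_CODE[product],
             product.value, DrugClass.FIVE_ASA.value, s, s)
        )
    for t, s, prod in other or []:
        cls = DrugClass.FIVE_ASA if prod in _PRODUCT_CODE else DrugClass.OTHER
        rows.append(
            (pid, index_date + dt.timedelta(days=t), _PRODUCT_CODE.get(prod, "X"),
             prod.value, cls.value, s, s)
        )
    return pd.DataFrame(rows, columns=DISPENSING_COLUMNS)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated bundle shared by read-only tests."""
    from mesadhere.synthetic import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_patients=400, seed=20210)
    population, dispensing, medical, truth = simulate_dataset(cfg)
    return cfg, population, dispensing, medical, truth
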