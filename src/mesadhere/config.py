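"""Default study configuration: drug-code map, CDS weights, covariate windows.

Everything here is overridable from YAML; the defaults describe the drug
codes the bundled claims simulator emits and a medication-based
chronic-disease-score table adapted from the Von Korff approach (weights per
distinct medication class observed, plus combination adjustments).  The
shipped weights are a documented adaptation, not a canonical table; analyses
that need a specific scoring system should supply their own
:class:`~mesadhere.covariates.CdsWeightTable` via config.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from .claims_model import CodeEntry, CodeMap, DrugClass, Product

COMORBIDITY_CATEGORIES = ("hypertension", "heart_disease", "respiratory_illness", "diabetes")

# drug code -> (product, class, comorbidity marker, CDS medication class)
_DEFAULT_CODES: Mapping[str, CodeEntry] = {
    # oral 5-ASA products
    "ASACOL": CodeEntry(Product.ASACOL_OR_GENERIC, DrugClass.FIVE_ASA),
    "MESALAMINE_GENERIC": CodeEntry(Product.ASACOL_OR_GENERIC, DrugClass.FIVE_ASA),
    "PENTASA": CodeEntry(Product.PENTASA, DrugClass.FIVE_ASA),
    "SALOFALK": CodeEntry(Product.SALOFALK, DrugClass.FIVE_ASA),
    "MEZAVANT": CodeEntry(Product.MEZAVANT, DrugClass.FIVE_ASA),
    # systemic corticosteroids
    "PREDNISONE": CodeEntry(Product.OTHER, DrugClass.CORTICOSTEROID),
    "BUDESONIDE": CodeEntry(Product.OTHER, DrugClass.CORTICOSTEROID),
    "HYDROCORTISONE": CodeEntry(Product.OTHER, DrugClass.CORTICOSTEROID),
    # comorbidity medication markers
    "HCTZ": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "hypertension", "hypertension"),
    "RAMIPRIL": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "hypertension", "hypertension"),
    "AMLODIPINE": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "hypertension", "hypertension"),
    "FUROSEMIDE": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "heart_disease", "cardiac"),
    "DIGOXIN": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "heart_disease", "cardiac"),
    "WARFARIN": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "heart_disease", "cardiac"),
    "SALBUTAMOL": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "respiratory_illness", "respiratory"),
    "FLUTICASONE_INH": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "respiratory_illness", "respiratory"),
    "METFORMIN": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "diabetes", "diabetes"),
    "GLYBURIDE": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "diabetes", "diabetes"),
    "INSULIN": CodeEntry(Product.OTHER, DrugClass.COMORBIDITY_MARKER, "diabetes", "diabetes"),
    # everything else
    "ACETAMINOPHEN": CodeEntry(Product.OTHER, DrugClass.OTHER),
}

# CDS medication-class weights (adaptation; see module docstring)
DEFAULT_CDS_POINTS: Mapping[str, int] = {
    "cardiac": 4,
    "hypertension": 1,
    "respiratory": 2,
    "diabetes": 2,
    "epilepsy": 2,
    "rheumatologic": 1,
    "ulcer": 1,
}
# combination adjustments: +delta when every class in the set is present
DEFAULT_CDS_COMBOS: tuple[tuple[frozenset[str], int], ...] = (
    (frozenset({"cardiac", "hypertension"}), 1),
)
DEFAULT_CDS_CUT = 6  # dichotomization threshold (cohort median in the source data)

DEFAULT_WASHOUT_DAYS = 90
DEFAULT_GRACE_DAYS = 60
DEFAULT_WINDOW_DAYS = 365
DEFAULT_COVARIATE_LOOKBACK_DAYS = 365


def default_code_map(strict: bool = False) -> CodeMap:
    return CodeMap(_DEFAULT_CODES, strict=strict)


def load_code_map(path: str | Path | None, strict: bool = False) -> CodeMap:
    """Load a YAML code map, or the default when ``path`` is None."""
    if path is None:
        return default_code_map(strict=strict)
    return CodeMap.from_yaml(path, strict=strict)


def dump_default_code_map(path: str | Path) -> None:
    """Write the built-in code map as YAML (a starting point for overrides)."""
    payload = {
        "codes": {
            code: {
                k: v
                for k, v in {
                    "product": e.product.value,
                    "drug_class": e.drug_class.value,
                    "marker": e.marker,
                    "cds_class": e.cds_class,
                }.items()
                if v is not None
            }
            for code, e in _DEFAULT_CODES.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
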