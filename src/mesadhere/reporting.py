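"""Aggregate reports: study-population table, prescription-characteristics
table, adherence/persistence summaries, determinants table, chi-square
comparisons, and the end-to-end pipeline driver.

All printed percentages and ratios use round-half-up at one decimal so the
tables are bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import pct, round_half_up
from .adherence import adherence_summary, compute_mpr_all
from .claims_model import (
    DrugClass,
    Product,
    Sex,
    read_dispensing_claims,
    read_eligibility,
    read_medical_claims,
    read_patients,
    write_table,
)
from .cohort import CohortMember, build_cohort, cohort_to_frame
from .config import load_code_map
from .covariates import DEFAULT_CDS_TABLE, derive_covariates_all
from .determinants import fit_determinants
from .persistence import build_episodes, episodes_to_frame, km_estimate, persistence_summary

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "chisq_compare", "demographics_table",
           "prescriptions_table", "age_bands", "sex_groups", "product_groups"]

AGE_BANDS = ("<20", "20-39", "40-59", "60-79", "80+")


def _age_band(age: int) -> str:
    if age < 20:
        return "<20"
    if age < 40:
        return "20-39"
    if age < 60:
        return "40-59"
    if age < 80:
        return "60-79"
    return "80+"


def age_bands(members: Sequence[CohortMember]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {b: [] for b in AGE_BANDS}
    for m in members:
        groups[_age_band(m.age_at_index)].append(m.patient_id)
    return groups


def sex_groups(members: Sequence[CohortMember]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {"male": [], "female": []}
    for m in members:
        groups["male" if m.sex is Sex.MALE else "female"].append(m.patient_id)
    return groups


def product_groups(members: Sequence[CohortMember]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for m in members:
        groups.setdefault(m.index_product.value, []).append(m.patient_id)
    return groups


def demographics_table(members: Sequence[CohortMember], covariates: pd.DataFrame) -> pd.DataFrame:
    """Study-population table: age bands, sex, comorbidity rates (n and %)."""
    n = len(members)
    rows: list[tuple[str, int, float]] = []
    bands = age_bands(members)
    for band in AGE_BANDS:
        rows.append((f"age {band}", len(bands[band]), pct(len(bands[band]), n)))
    sexes = sex_groups(members)
    rows.append(("male", len(sexes["male"]), pct(len(sexes["male"]), n)))
    rows.append(("female", len(sexes["female"]), pct(len(sexes["female"]), n)))
    for cat in ("hypertension", "heart_disease", "respiratory_illness", "diabetes"):
        k = int(covariates[cat].sum())
        rows.append((cat, k, pct(k, n)))
    table = pd.DataFrame(rows, columns=["characteristic", "n", "pct"])
    ages = [m.age_at_index for m in members]
    table.attrs["mean_age"] = round_half_up(float(np.mean(ages)), 1) if ages else float("nan")
    table.attrs["sd_age"] = round_half_up(float(np.std(ages, ddof=1)), 1) if len(ages) > 1 else float("nan")
    return table


def prescriptions_table(members: Sequence[CohortMember], dispensing: pd.DataFrame) -> pd.DataFrame:
    """Prescription characteristics per product over each member's window.

    Users = members with >=1 fill of the product inside their window (a
    member who switches counts as a user of both products), so per-product
    user counts can exceed the cohort size in total, as in real extracts.
    Columns: users, n_scripts, scripts_per_patient (1 dp), mean/SD quantity,
    mean/SD duration, median duration.
    """
    window = {m.patient_id: (m.index_date, m.window_end) for m in members}
    asa = dispensing[dispensing["drug_class"] == DrugClass.FIVE_ASA.value]
    rows = []
    for product in (Product.ASACOL_OR_GENERIC, Product.PENTASA, Product.SALOFALK, Product.MEZAVANT):
        sub_rows = []
        for r in asa[asa["product"] == product.value].itertuples(index=False):
            bounds = window.get(str(r.patient_id))
            if bounds and bounds[0] <= r.dispense_date <= bounds[1]:
                sub_rows.append((str(r.patient_id), int(r.quantity), int(r.days_supply)))
        users = len({pid for pid, _, _ in sub_rows})
        n_scripts = len(sub_rows)
        qty = np.array([q for _, q, _ in sub_rows], dtype=float)
        dur = np.array([d for _, _, d in sub_rows], dtype=float)
        rows.append(
            (
                product.value,
                users,
                n_scripts,
                round_half_up(n_scripts / users, 1) if users else float("nan"),
                round_half_up(float(qty.mean()), 1) if n_scripts else float("nan"),
                round_half_up(float(qty.std(ddof=1)), 1) if n_scripts > 1 else float("nan"),
                round_half_up(float(dur.mean()), 1) if n_scripts else float("nan"),
                round_half_up(float(dur.std(ddof=1)), 1) if n_scripts > 1 else float("nan"),
                float(np.median(dur)) if n_scripts else float("nan"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["product", "users", "n_scripts", "scripts_per_patient",
                 "mean_quantity", "sd_quantity", "mean_duration", "sd_duration",
                 "median_duration"],
    )


def chisq_compare(successes: Sequence[int], totals: Sequence[int]) -> tuple[float, float]:
    """Pearson chi-square on a k x 2 success/failure table (no continuity correction)."""
    if len(successes) < 2 or len(successes) != len(totals):
        raise ValueError("need >=2 groups with matching success/total counts")
    if any(t <= 0 for t in totals):
        raise ValueError("all group totals must be > 0")
    table = np.array([[s, t - s] for s, t in zip(successes, totals)], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        log.warning("chi-square: expected cell count < 1; asymptotics unreliable")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Pipeline driver


@dataclass
class RunConfig:
    dispensing_path: Path
    medical_path: Path
    eligibility_path: Path
    patients_path: Path
    out_dir: Path
    code_map_path: Path | None = None
    washout_days: int = 90
    grace_days: int = 60
    mpr_policy: str = "sum"
    index_product_only: bool = False
    all_drugs_washout: bool = False
    any_asa_closes_gap: bool = True
    require_abandonment: bool = False
    median_cut: bool = False
    removal_alpha: float = 0.05
    combined_blocks: bool = False
    seed: int = 0
    skip_bad_rows: bool = False
    delimiter: str = ","

    def manifest(self) -> dict:
        out = {}
        for key, value in vars(self).items():
            out[key] = str(value) if isinstance(value, Path) else value
        return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run cohort -> adherence -> persistence -> covariates -> determinants
    and write every table plus a run manifest to ``config.out_dir``.

    Deterministic and idempotent: identical inputs and config give
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    on_bad = "skip" if config.skip_bad_rows else "error"
    code_map = load_code_map(config.code_map_path)

    log.info("stage=read inputs")
    dispensing = read_dispensing_claims(
        config.dispensing_path, code_map, config.delimiter, on_bad
    )
    medical = read_medical_claims(config.medical_path, config.delimiter, on_bad)
    eligibility = read_eligibility(config.eligibility_path, config.delimiter, on_bad)
    patients = read_patients(config.patients_path, config.delimiter)

    log.info("stage=cohort in=%d patients", patients["patient_id"].nunique())
    members, attrition = build_cohort(
        dispensing, medical, eligibility, patients,
        washout_days=config.washout_days, all_drugs_washout=config.all_drugs_washout,
    )
    log.info("stage=cohort out=%d members", len(members))

    adherence = compute_mpr_all(
        members, dispensing, policy=config.mpr_policy,
        index_product_only=config.index_product_only,
    )
    episodes = build_episodes(
        members, dispensing, grace_days=config.grace_days,
        any_asa_closes_gap=config.any_asa_closes_gap,
        require_abandonment=config.require_abandonment,
    )
    covariates = derive_covariates_all(
        members, dispensing, DEFAULT_CDS_TABLE, code_map, median_cut=config.median_cut
    )

    episode_frame = episodes_to_frame(episodes)
    analysis = (
        covariates.merge(adherence[["patient_id", "adherent_80"]], on="patient_id")
        .merge(episode_frame[["patient_id", "persistent_at_365"]], on="patient_id")
    )
    determinant_results = fit_determinants(
        analysis, removal_alpha=config.removal_alpha, combined=config.combined_blocks
    )
    det_frames = []
    for (outcome, block), res in determinant_results.items():
        frame = res.to_frame()
        frame.insert(0, "outcome", outcome)
        frame.insert(1, "block", block)
        det_frames.append(frame)

    by_product = product_groups(members)
    adh_by_product = adherence_summary(adherence, by_product)
    pers_by_product = persistence_summary(episodes, by_product)
    km_frames = []
    for label, pids in sorted(by_product.items()):
        eps = [e for e in episodes if e.patient_id in set(pids)]
        curve = km_estimate(eps).to_frame()
        curve.insert(0, "group", label)
        km_frames.append(curve)
    km_all = km_estimate(episodes).to_frame()
    km_all.insert(0, "group", "overall")
    km_frames.append(km_all)

    paths = {
        "cohort": out / "cohort.csv",
        "attrition": out / "attrition.txt",
        "adherence": out / "adherence.csv",
        "episodes": out / "episodes.csv",
        "km": out / "km.csv",
        "adherence_by_product": out / "adherence_by_product.csv",
        "persistence_by_product": out / "persistence_by_product.csv",
        "demographics": out / "table_population.csv",
        "prescriptions": out / "table_prescriptions.csv",
        "determinants": out / "determinants.csv",
        "covariates": out / "covariates.csv",
        "manifest": out / "run_manifest.json",
    }
    write_table(cohort_to_frame(members), paths["cohort"], config.delimiter)
    paths["attrition"].write_text(attrition.to_text() + "\n")
    write_table(adherence, paths["adherence"], config.delimiter)
    write_table(episode_frame, paths["episodes"], config.delimiter)
    write_table(pd.concat(km_frames, ignore_index=True), paths["km"], config.delimiter)
    write_table(adh_by_product, paths["adherence_by_product"], config.delimiter)
    write_table(pers_by_product, paths["persistence_by_product"], config.delimiter)
    demo = demographics_table(members, covariates)
    write_table(demo, paths["demographics"], config.delimiter)
    write_table(prescriptions_table(members, dispensing), paths["prescriptions"], config.delimiter)
    write_table(pd.concat(det_frames, ignore_index=True), paths["determinants"], config.delimiter)
    write_table(covariates, paths["covariates"], config.delimiter)
    paths["manifest"].write_text(json.dumps(config.manifest(), indent=2, sort_keys=True) + "\n")
    return paths
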