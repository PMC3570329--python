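"""Synthetic pharmacy/medical claims with the refill structure the analysis assumes.

The generator emulates a provincial-drug-plan extract of new oral 5-ASA
users: an index fill, a refill stream whose cadence is governed by a
latent *refill promptness* class, per-product stopping hazards, occasional
product switches, corticosteroid co-dispensing, comorbidity-marker
co-medications, and an age/sex mix typical of a publicly insured UC
population.

Mechanism
---------
Each patient carries a latent prompt-refiller indicator drawn from a
logistic model, ``logit P(prompt) = intercept + sum(beta_k * x_k)`` over
binary covariates (male, age>=60, current corticosteroid use).  Prompt
refillers draw small extra delays beyond supply runout (lognormal, mean
~2 d by default); slow refillers draw large ones (mean ~25 d).  Because the
two delay regimes are well separated relative to the 80% MPR threshold,
the configured coefficients are, by construction, the true conditional
log-odds of downstream adherence — which is what makes parameter-recovery
tests meaningful.  At each runout the patient stops refilling with
probability ``1 - exp(-hazard * cycle)`` (per-product daily hazard) or
switches to a different 5-ASA product with a per-refill probability; a
switch emits a single fill of the new product and ends the stream.

Defaults follow the published descriptive profile of Quebec public-plan
5-ASA users (sex/age mix, comorbidity prevalences, 30-day median supply,
per-product stopping hazards backed out of printed 1-year persistence via
an exponential approximation).  Everything is a config knob; limit settings
(zero hazard, zero delay) produce exactly gapless streams.

Output is fully deterministic given the seed: population-level draws and
fill-level draws use independent child streams of one ``SeedSequence``.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .claims_model import Product, Sex, write_table

__all__ = ["RefillDelayModel", "SimulationConfig", "SimulatedPopulation",
           "generate_population", "generate_claims", "simulate_dataset",
           "write_claims_files"]

PRODUCT_CODES: Mapping[Product, str] = {
    Product.ASACOL_OR_GENERIC: "ASACOL",
    Product.PENTASA: "PENTASA",
    Product.SALOFALK: "SALOFALK",
    Product.MEZAVANT: "MEZAVANT",
}
# tablets/day by product, so quantities track days_supply realistically
_TABLETS_PER_DAY = {
    Product.ASACOL_OR_GENERIC: 6.1,
    Product.PENTASA: 5.6,
    Product.SALOFALK: 6.1,
    Product.MEZAVANT: 2.8,
}
_AGE_BANDS = ("<20", "20-39", "40-59", "60-79", "80+")
_AGE_RANGES = {"<20": (12, 19), "20-39": (20, 39), "40-59": (40, 59),
               "60-79": (60, 79), "80+": (80, 94)}
_MARKER_CODES = {
    "hypertension": ("HCTZ", "RAMIPRIL", "AMLODIPINE"),
    "heart_disease": ("FUROSEMIDE", "DIGOXIN", "WARFARIN"),
    "respiratory_illness": ("SALBUTAMOL", "FLUTICASONE_INH"),
    "diabetes": ("METFORMIN", "GLYBURIDE", "INSULIN"),
}
_BENIGN_ICD9 = ("401.9", "486", "558.9", "786.50")

_OBS_HORIZON = 424  # index day + 364 window days + 60-day gap-evaluation tail


class ConfigError(ValueError):
    """An invalid simulation configuration (bad probability vector, ...)."""


@dataclass(frozen=True)
class RefillDelayModel:
    """Extra days beyond runout before the next fill, by promptness class.

    Draws are ``max(0, round(X))`` with X lognormal with the given mean and
    log-scale dispersion; a mean of exactly 0 yields delay 0 (the gapless
    limit holds exactly, not in distribution).
    """

    prompt_mean_days: float = 2.0
    nonprompt_mean_days: float = 25.0
    sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.prompt_mean_days < 0 or self.nonprompt_mean_days < 0 or self.sigma < 0:
            raise ConfigError("delay means and dispersion must be non-negative")


def _check_probvec(name: str, probs: Mapping) -> None:
    vals = list(probs.values())
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities must sum to 1 (got {sum(vals)!r})")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 2000
    seed: int = 0
    product_shares: Mapping[Product, float] = field(
        default_factory=lambda: {
            # proportional to published per-product user counts
            Product.ASACOL_OR_GENERIC: 699 / 1871,
            Product.PENTASA: 208 / 1871,
            Product.SALOFALK: 817 / 1871,
            Product.MEZAVANT: 147 / 1871,
        }
    )
    sex_male_prob: float = 0.434
    age_group_probs: Mapping[str, float] = field(
        default_factory=lambda: {"<20": 0.036, "20-39": 0.170, "40-59": 0.307,
                                 "60-79": 0.437, "80+": 0.050}
    )
    days_supply_median: int = 30
    days_supply_probs: Mapping[int, float] = field(
        default_factory=lambda: {7: 0.15, 15: 0.20, 30: 0.55, 60: 0.10}
    )
    refill_delay_model: RefillDelayModel = field(default_factory=RefillDelayModel)
    discont_hazard_per_product: Mapping[Product, float] = field(
        default_factory=lambda: {
            # daily hazards ~ -ln(S_365)/365 from 1-year persistence
            Product.ASACOL_OR_GENERIC: 2.0e-3,
            Product.PENTASA: 2.3e-3,
            Product.SALOFALK: 2.2e-3,
            Product.MEZAVANT: 9.0e-4,
        }
    )
    switch_prob_per_refill: float = 0.01
    promptness_intercept: float = -0.45
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.25, "age_ge_60": 0.47, "current_steroid": 0.34}
    )
    comorbidity_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {"hypertension": 0.501, "heart_disease": 0.413,
                                 "respiratory_illness": 0.339, "diabetes": 0.327}
    )
    corticosteroid_use_probs: Mapping[str, float] = field(
        default_factory=lambda: {"prior": 0.300, "current": 0.326}
    )
    # exclusion-path knobs, zero by default so coverage filters pass untouched
    crohns_prob: float = 0.0
    left_truncated_prob: float = 0.0  # eligibility starts only 30 d pre-index
    short_coverage_prob: float = 0.0  # eligibility ends 200 d post-index
    index_start: dt.date = dt.date(2005, 1, 1)
    index_end: dt.date = dt.date(2009, 12, 31)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        _check_probvec("product_shares", self.product_shares)
        _check_probvec("age_group_probs", self.age_group_probs)
        _check_probvec("days_supply_probs", self.days_supply_probs)
        for p in (self.sex_male_prob, self.switch_prob_per_refill, self.crohns_prob,
                  self.left_truncated_prob, self.short_coverage_prob,
                  *self.comorbidity_prevalences.values(),
                  *self.corticosteroid_use_probs.values()):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p!r} outside [0, 1]")
        if any(h < 0 for h in self.discont_hazard_per_product.values()):
            raise ConfigError("discontinuation hazards must be >= 0")
        if set(self.age_group_probs) != set(_AGE_BANDS):
            raise ConfigError(f"age_group_probs must cover bands {_AGE_BANDS}")


@dataclass
class SimulatedPopulation:
    """Population-level draws plus the claim-stream seed; input to generate_claims."""

    config: SimulationConfig
    patients: pd.DataFrame  # patient_id, sex, birth_year, region
    eligibility: pd.DataFrame  # patient_id, start_date, end_date
    attributes: pd.DataFrame  # per-patient latent attributes (ground truth)
    claims_seed: np.random.SeedSequence


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Draw demographics, index dates, latent classes, and eligibility periods."""
    pop_seed, claims_seed = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(pop_seed)
    n = config.n_patients

    pids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    male = rng.random(n) < config.sex_male_prob
    bands = rng.choice(_AGE_BANDS, size=n, p=[config.age_group_probs[b] for b in _AGE_BANDS])
    ages = np.array(
        [rng.integers(_AGE_RANGES[b][0], _AGE_RANGES[b][1] + 1) for b in bands], dtype=int
    )
    span = (config.index_end - config.index_start).days + 1
    index_dates = np.array(
        [config.index_start + dt.timedelta(days=int(d)) for d in rng.integers(0, span, size=n)]
    )
    products = rng.choice(
        [p.value for p in PRODUCT_CODES],
        size=n,
        p=[config.product_shares[p] for p in PRODUCT_CODES],
    )

    comorb = {
        cat: rng.random(n) < prev for cat, prev in config.comorbidity_prevalences.items()
    }
    prior_steroid = rng.random(n) < config.corticosteroid_use_probs["prior"]
    current_steroid = rng.random(n) < config.corticosteroid_use_probs["current"]

    age_ge_60 = ages >= 60
    eta = np.full(n, config.promptness_intercept, dtype=float)
    covariate_values = {"male": male.astype(float), "age_ge_60": age_ge_60.astype(float),
                        "current_steroid": current_steroid.astype(float)}
    for name, beta in config.covariate_effects.items():
        if name not in covariate_values:
            raise ConfigError(f"unknown covariate effect {name!r}")
        eta += beta * covariate_values[name]
    prompt = rng.random(n) < _sigmoid(eta)

    left_trunc = rng.random(n) < config.left_truncated_prob
    short_cov = rng.random(n) < config.short_coverage_prob
    crohns = rng.random(n) < config.crohns_prob

    birth_years = np.array([d.year for d in index_dates]) - ages
    patients = pd.DataFrame(
        {"patient_id": pids, "sex": np.where(male, Sex.MALE.value, Sex.FEMALE.value),
         "birth_year": birth_years, "region": "QC"}
    )
    elig_start = [
        d - dt.timedelta(days=30 if lt else 365) for d, lt in zip(index_dates, left_trunc)
    ]
    elig_end = [
        d + dt.timedelta(days=200 if sc else _OBS_HORIZON)
        for d, sc in zip(index_dates, short_cov)
    ]
    eligibility = pd.DataFrame(
        {"patient_id": pids, "start_date": elig_start, "end_date": elig_end}
    )
    attributes = pd.DataFrame(
        {
            "patient_id": pids,
            "index_date": index_dates,
            "index_product": products,
            "male": male,
            "age_at_index": ages,
            "age_ge_60": age_ge_60,
            "prompt": prompt,
            "prior_steroid": prior_steroid,
            "current_steroid": current_steroid,
            "left_truncated": left_trunc,
            "short_coverage": short_cov,
            "crohns": crohns,
            **{cat: flags for cat, flags in comorb.items()},
        }
    )
    return SimulatedPopulation(
        config=config, patients=patients, eligibility=eligibility,
        attributes=attributes, claims_seed=claims_seed,
    )


_MAX_FILLS = 96  # enough pre-drawn refill decisions for a 7-day supply floor


def _delay_draws(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if sigma == 0:
        return np.full(size, int(round(mean)))
    mu = np.log(mean) - sigma**2 / 2.0
    return np.maximum(0, np.round(rng.lognormal(mu, sigma, size=size))).astype(int)


def generate_claims(
    population: SimulatedPopulation, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Materialize dispensing and medical claims for a generated population.

    Returns ``(dispensing, medical, truth)``.  Dispensing carries both the
    raw file columns and the derived ``product``/``drug_class`` columns so
    in-memory pipelines can skip a write/read round trip; the truth frame
    records each patient's latent class and true event day for testing.
    """
    config = config or population.config
    rng = np.random.default_rng(population.claims_seed)
    delay_cfg = config.refill_delay_model
    supply_vals = np.array(list(config.days_supply_probs), dtype=int)
    supply_probs = [config.days_supply_probs[int(v)] for v in supply_vals]
    products = list(PRODUCT_CODES)

    disp_rows: list[tuple] = []
    med_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for patient in population.attributes.itertuples(index=False):
        pid = patient.patient_id
        index_date: dt.date = patient.index_date
        product = Product(patient.index_product)
        hazard = config.discont_hazard_per_product[product]
        mean_delay = (
            delay_cfg.prompt_mean_days if patient.prompt else delay_cfg.nonprompt_mean_days
        )

        supplies = rng.choice(supply_vals, size=_MAX_FILLS, p=supply_probs)
        delays = _delay_draws(rng, mean_delay, delay_cfg.sigma, _MAX_FILLS)
        stop_u = rng.random(_MAX_FILLS)
        switch_u = rng.random(_MAX_FILLS)

        def emit(t: int, prod: Product, s: int) -> None:
            qty = max(1, int(round(s * _TABLETS_PER_DAY[prod])))
            disp_rows.append(
                (pid, index_date + dt.timedelta(days=t), PRODUCT_CODES[prod],
                 prod.value, "FIVE_ASA", qty, int(s))
            )

        t, stop_day, switch_day = 0, None, None
        for k in range(_MAX_FILLS):
            s = int(supplies[k])
            emit(t, product, s)
            runout = t + s - 1
            delay = int(delays[k])
            cycle = s + delay
            p_stop = 1.0 - np.exp(-hazard * cycle) if hazard > 0 else 0.0
            if stop_u[k] < p_stop:
                stop_day = runout + 1
                break
            t_next = runout + 1 + delay
            if t_next > _OBS_HORIZON:
                break
            if switch_u[k] < config.switch_prob_per_refill:
                other = products[:]
                other.remove(product)
                new_prod = other[int(rng.integers(0, len(other)))]
                emit(t_next, new_prod, int(supplies[min(k + 1, _MAX_FILLS - 1)]))
                switch_day = t_next
                break
            t = t_next

        # corticosteroid co-dispensing
        for flag, lo, hi in ((patient.prior_steroid, -365, -1),
                             (patient.current_steroid, 0, 364)):
            if flag:
                for day in rng.integers(lo, hi + 1, size=int(rng.integers(1, 4))):
                    disp_rows.append(
                        (pid, index_date + dt.timedelta(days=int(day)), "PREDNISONE",
                         Product.OTHER.value, "CORTICOSTEROID", 28, 14)
                    )
        # comorbidity-marker co-medications
        for cat, codes in _MARKER_CODES.items():
            if getattr(patient, cat):
                for day in rng.integers(-365, 365, size=int(rng.integers(2, 5))):
                    code = codes[int(rng.integers(0, len(codes)))]
                    disp_rows.append(
                        (pid, index_date + dt.timedelta(days=int(day)), code,
                         Product.OTHER.value, "COMORBIDITY_MARKER", 30, 30)
                    )
        # medical claims: benign visits, plus Crohn's coding when configured
        for day in rng.integers(-365, 365, size=int(rng.integers(0, 3))):
            code = _BENIGN_ICD9[int(rng.integers(0, len(_BENIGN_ICD9)))]
            med_rows.append((pid, index_date + dt.timedelta(days=int(day)), code))
        if patient.crohns:
            code = f"555.{int(rng.integers(0, 10))}"
            med_rows.append(
                (pid, index_date + dt.timedelta(days=int(rng.integers(-365, 365))), code)
            )

        truth_rows.append((pid, bool(patient.prompt), stop_day, switch_day))

    dispensing = pd.DataFrame(
        disp_rows,
        columns=["patient_id", "dispense_date", "drug_code", "product",
                 "drug_class", "quantity", "days_supply"],
    ).sort_values(["patient_id", "dispense_date"], kind="mergesort").reset_index(drop=True)
    medical = pd.DataFrame(
        med_rows, columns=["patient_id", "service_date", "icd9_code"]
    ).sort_values(["patient_id", "service_date"], kind="mergesort").reset_index(drop=True)
    truth = population.attributes.merge(
        pd.DataFrame(truth_rows, columns=["patient_id", "prompt_check", "stop_day", "switch_day"])
        .drop(columns=["prompt_check"]),
        on="patient_id",
    )
    return dispensing, medical, truth


def simulate_dataset(config: SimulationConfig):
    """One-call convenience: population + claims for a config."""
    population = generate_population(config)
    dispensing, medical, truth = generate_claims(population, config)
    return population, dispensing, medical, truth


def write_claims_files(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write dispensing/medical/eligibility/patients CSVs plus a truth sidecar.

    The truth sidecar (latent classes, true event days, configured effects)
    exists for testing and validation only; the analysis pipeline never
    reads it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    population, dispensing, medical, truth = simulate_dataset(config)
    paths = {
        "dispensing": out / "dispensing.csv",
        "medical": out / "medical.csv",
        "eligibility": out / "eligibility.csv",
        "patients": out / "patients.csv",
        "truth": out / "truth.csv",
    }
    write_table(dispensing.drop(columns=["product", "drug_class"]), paths["dispensing"])
    write_table(medical, paths["medical"])
    write_table(population.eligibility, paths["eligibility"])
    write_table(population.patients, paths["patients"])
    write_table(truth, paths["truth"])
    effects = {"promptness_intercept": config.promptness_intercept,
               **{k: float(v) for k, v in config.covariate_effects.items()}}
    (out / "truth_effects.json").write_text(json.dumps(effects, indent=2))
    return paths
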