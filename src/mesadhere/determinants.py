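"""Stepwise backward logistic regression for adherence / persistence determinants.

Two independent covariate blocks are fit per binary outcome, mirroring the
usual claims-study layout: a demographics block (male, age>=60, prior and
current corticosteroid use) and a comorbidity block (hypertension, heart
disease, respiratory illness, diabetes, high chronic disease score).
Backward elimination refits after removing the covariate with the largest
Wald p-value while that p exceeds ``removal_alpha`` (default 0.05); removed
covariates are reported as "NS".  Odds ratios are exp(coefficient) with
Wald 95% intervals exp(coefficient +/- 1.96*SE).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "Outcome",
    "CovariateBlock",
    "ModelSpec",
    "LogisticFit",
    "DeterminantResult",
    "FitError",
    "DEMOGRAPHICS_COVARIATES",
    "COMORBIDITY_COVARIATES",
    "fit_logistic",
    "stepwise_backward",
    "fit_determinants",
]

Z_95 = 1.959963984540054  # Phi^{-1}(0.975)

DEMOGRAPHICS_COVARIATES = ("male", "age_ge_60", "prior_steroid", "current_steroid")
COMORBIDITY_COVARIATES = (
    "hypertension", "heart_disease", "respiratory_illness", "diabetes", "cds_high"
)


class Outcome(str, enum.Enum):
    ADHERENT_80 = "adherent_80"
    PERSISTENT_365 = "persistent_at_365"


class CovariateBlock(str, enum.Enum):
    DEMOGRAPHICS = "DEMOGRAPHICS"
    COMORBIDITIES = "COMORBIDITIES"

    @property
    def covariates(self) -> tuple[str, ...]:
        return (
            DEMOGRAPHICS_COVARIATES
            if self is CovariateBlock.DEMOGRAPHICS
            else COMORBIDITY_COVARIATES
        )


@dataclass(frozen=True)
class ModelSpec:
    outcome: Outcome
    covariate_block: CovariateBlock
    removal_alpha: float = 0.05


class FitError(RuntimeError):
    """The ML fit failed (separation, rank deficiency); names the culprit."""


@dataclass(frozen=True)
class CovariateEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    """Per-covariate ORs with Wald 95% CIs from one ML logistic fit."""

    estimates: Mapping[str, CovariateEstimate]
    intercept: float
    log_likelihood: float

    def odds_ratio(self, covariate: str) -> float:
        return self.estimates[covariate].odds_ratio


@dataclass(frozen=True)
class DeterminantResult:
    """Stepwise output: retained covariates with estimates, dropped ones as NS."""

    spec: ModelSpec
    retained: Mapping[str, CovariateEstimate]
    dropped: tuple[str, ...]  # reported "NS"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.spec.covariate_block.covariates:
            if name in self.retained:
                e = self.retained[name]
                rows.append(
                    (name, round(e.odds_ratio, 2), round(e.ci_low, 2),
                     round(e.ci_high, 2), e.p_value)
                )
            else:
                rows.append((name, "NS", "", "", ""))
        return pd.DataFrame(
            rows, columns=["covariate", "odds_ratio", "ci_low", "ci_high", "p_value"]
        )


def _check_design(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify an offending column for the error message
        for j, name in enumerate(X.columns):
            sub = np.column_stack([np.ones(len(X)), X.iloc[:, : j + 1].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise FitError(f"design is rank deficient at covariate {name!r}")
        raise FitError("design is rank deficient")


def fit_logistic(y: pd.Series | np.ndarray, X: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic fit of binary ``y`` on binary covariates ``X``.

    Raises :class:`FitError` on rank deficiency or (quasi-)separation,
    naming the covariate involved.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_design(X)
    design = sm.add_constant(X.astype(float), has_constant="add")
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is re-detected below and surfaced as FitError
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            result = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"logistic fit failed ({exc}); check covariates "
                       f"{list(X.columns)} for separation") from exc
    bse = result.bse
    for name in X.columns:
        if not np.isfinite(bse[name]) or bse[name] > 1e3 or abs(result.params[name]) > 30:
            raise FitError(f"separation suspected at covariate {name!r} "
                           f"(|coef|={abs(result.params[name]):.1f}, SE={bse[name]:.3g})")
    estimates = {}
    for name in X.columns:
        beta, se = float(result.params[name]), float(bse[name])
        estimates[name] = CovariateEstimate(
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z_95 * se)),
            ci_high=float(np.exp(beta + Z_95 * se)),
            p_value=float(result.pvalues[name]),
        )
    return LogisticFit(
        estimates=estimates,
        intercept=float(result.params["const"]),
        log_likelihood=float(result.llf),
    )


def stepwise_backward(
    spec: ModelSpec, data: pd.DataFrame, covariates: Sequence[str] | None = None
) -> DeterminantResult:
    """Backward elimination at ``spec.removal_alpha`` on one covariate block.

    ``data`` holds the outcome column and all block covariates as booleans.
    Deterministic: on exact p ties the first-listed covariate is removed.
    An empty final model (all NS) is allowed.
    """
    covariates = list(covariates if covariates is not None else spec.covariate_block.covariates)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    y = data[spec.outcome.value].astype(float)

    current = covariates
    fit: LogisticFit | None = None
    while current:
        fit = fit_logistic(y, data[current].astype(float))
        pvals = [(fit.estimates[c].p_value, i) for i, c in enumerate(current)]
        worst_p, worst_i = max(pvals, key=lambda t: (t[0], -t[1]))
        if worst_p > spec.removal_alpha:
            current = current[:worst_i] + current[worst_i + 1 :]
            fit = None
        else:
            break
    retained = {} if fit is None else dict(fit.estimates)
    dropped = tuple(c for c in covariates if c not in retained)
    return DeterminantResult(spec=spec, retained=retained, dropped=dropped)


def fit_determinants(
    data: pd.DataFrame,
    removal_alpha: float = 0.05,
    combined: bool = False,
) -> dict[tuple[str, str], DeterminantResult]:
    """Fit every (outcome, block) stepwise model on a merged analysis frame.

    ``data`` = covariates joined with adherence and episode outcomes
    (columns ``adherent_80`` and ``persistent_at_365``).  With ``combined``
    both blocks are pooled into a single model per outcome (sensitivity
    analysis).
    """
    out: dict[tuple[str, str], DeterminantResult] = {}
    blocks = (
        [(CovariateBlock.DEMOGRAPHICS, DEMOGRAPHICS_COVARIATES + COMORBIDITY_COVARIATES)]
        if combined
        else [(b, b.covariates) for b in CovariateBlock]
    )
    for outcome in Outcome:
        for block, covs in blocks:
            spec = ModelSpec(outcome=outcome, covariate_block=block, removal_alpha=removal_alpha)
            out[(outcome.value, block.value)] = stepwise_backward(spec, data, covs)
    return out
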