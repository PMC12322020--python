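"""Tiered regression models for the cohort's association analyses.

Three nested adjustment tiers mirror the usual epidemiological reporting
pattern: Model 1 unadjusted; Model 2 adds demographic/socioeconomic covariates
(age, gender, BMI, IQ, household income); Model 3 additionally adjusts for the
psychosocial covariates and the baseline (wave-1) levels of the mental-health
scores.  Continuous-exposure coefficients are reported per 1 SD of the exposure
so effect sizes are comparable across strata; the modified-Poisson risk-ratio
model (log-link Poisson with robust sandwich errors) covers binary outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

__all__ = [
    "MODEL2_COVARIATES",
    "MODEL3_EXTRA",
    "ModelSpec",
    "EffectEstimate",
    "tier_roster",
    "fit_linear_model",
    "fit_exposure_mediator_model",
    "fit_poisson_rr",
    "AssociationModel",
    "AssociationResults",
]

MODEL2_COVARIATES = ("age", "gender", "bmi", "iq", "income")
MODEL3_EXTRA = (
    "loneliness",
    "physical_punishment",
    "rel_mother",
    "rel_father",
    "rel_friends",
    "neighborhood_cohesion",
    "gender_nonconforming",
)
_BASELINE_COLS = ("smfq_w1", "anxiety_w1", "apss_w1", "who5_w1")


def tier_roster(tier: int, kind: str = "outcome") -> list[str]:
    """Covariate roster for an adjustment tier.

    ``kind='outcome'`` (mediator -> mental health): tier 3 adds the exposure
    score and the four baseline mental-health scores.  ``kind='mediator'``
    (exposure -> mediator): tier 3 instead adds baseline time spent gaming and
    problematic internet use.
    """
    if tier == 1:
        return []
    if tier == 2:
        return list(MODEL2_COVARIATES)
    if tier == 3:
        roster = list(MODEL2_COVARIATES) + list(MODEL3_EXTRA)
        if kind == "outcome":
            roster += ["exposure_score", *_BASELINE_COLS]
        elif kind == "mediator":
            roster += ["time_gaming", "problematic_internet"]
        else:
            raise ValueError(f"unknown roster kind {kind!r}")
        return roster
    raise ValueError(f"tier must be 1, 2 or 3, got {tier}")


@dataclass
class ModelSpec:
    """Which adjustment tier and codings a fit uses."""

    tier: int = 3
    exposure_coding: str = "continuous-per-SD"  # or "dichotomous"
    outcome_coding: str = "continuous"  # or "binary"
    roster_kind: str = "outcome"
    covariates: list[str] | None = None  # explicit roster overrides the tier
    exposure_sd: float | None = None  # reuse an overall SD in stratified fits

    def resolve_roster(self) -> list[str]:
        if self.covariates is not None:
            return list(self.covariates)
        return tier_roster(self.tier, self.roster_kind)


@dataclass
class EffectEstimate:
    """A point estimate with its uncertainty and provenance tags."""

    point: float
    ci_low: float
    ci_high: float
    se: float
    scale: str  # "beta-per-SD" | "beta" | "RD" | "RR"
    model: str = ""
    stratum: str = "overall"
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.scale == "RR" and self.point <= 0:
            raise ValueError("risk ratio must be positive")
        if self.scale != "RR" and not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("point estimate outside its confidence interval")


def _design(table: pd.DataFrame, exposure: str, covariates: list[str]) -> pd.DataFrame:
    cols = [exposure] + [c for c in covariates if c != exposure]
    X = table[cols].astype(float).copy()
    X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns pivoted last by a rank-revealing QR
        _, r, piv = scipy.linalg.qr(arr, pivoting=True, mode="economic")
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_linear_model(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    spec: ModelSpec | None = None,
) -> EffectEstimate:
    """OLS of a continuous outcome on the exposure plus the tier's roster.

    With ``exposure_coding='continuous-per-SD'`` the reported coefficient is the
    raw slope times the exposure SD (from ``spec.exposure_sd`` when given, else
    the analysis sample), with the Wald CI scaled the same way.
    """
    spec = spec or ModelSpec()
    covs = spec.resolve_roster()
    if table[[outcome, exposure, *covs]].isna().any().any():
        raise ValueError("table contains missing values; impute first")
    X = _design(table, exposure, covs)
    _check_rank(X)
    res = sm.OLS(table[outcome].astype(float), X).fit()

    if spec.exposure_coding == "continuous-per-SD":
        sd = spec.exposure_sd
        if sd is None:
            sd = float(table[exposure].std(ddof=1))
        scale_factor, scale_tag = sd, "beta-per-SD"
    else:
        scale_factor, scale_tag = 1.0, "beta"

    coef = float(res.params[exposure]) * scale_factor
    se = float(res.bse[exposure]) * scale_factor
    lo, hi = (float(v) * scale_factor for v in res.conf_int().loc[exposure])
    return EffectEstimate(
        point=coef, ci_low=lo, ci_high=hi, se=se, scale=scale_tag,
        model=f"model{spec.tier}", p_value=float(res.pvalues[exposure]),
    )


def fit_exposure_mediator_model(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    exposure: str = "exposure_score",
    mediator: str = "mediator_score",
) -> EffectEstimate:
    """Regression of the mediator score on the exposure (tier-3 roster swaps the
    baseline mental-health scores for baseline gaming-time/internet-use)."""
    spec = spec or ModelSpec(roster_kind="mediator")
    if spec.covariates is None and spec.roster_kind != "mediator":
        spec = ModelSpec(
            tier=spec.tier, exposure_coding=spec.exposure_coding,
            outcome_coding=spec.outcome_coding, roster_kind="mediator",
            exposure_sd=spec.exposure_sd,
        )
    return fit_linear_model(table, mediator, exposure, spec)


def fit_poisson_rr(
    table: pd.DataFrame,
    binary_outcome: str,
    binary_exposure: str,
    spec: ModelSpec | None = None,
) -> EffectEstimate:
    """Modified-Poisson risk ratio: log-link Poisson on a binary outcome with
    robust (HC0 sandwich) standard errors."""
    spec = spec or ModelSpec()
    for col, label in ((binary_outcome, "outcome"), (binary_exposure, "exposure")):
        vals = set(table[col].dropna().unique())
        if not vals <= {0, 1}:
            raise ValueError(f"{label} column {col!r} is not binary 0/1")
    y = table[binary_outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"outcome {binary_outcome!r} is constant")
    covs = spec.resolve_roster()
    X = _design(table, binary_exposure, covs)
    _check_rank(X)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
    coef = float(res.params[binary_exposure])
    se = float(res.bse[binary_exposure])
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    return EffectEstimate(
        point=float(np.exp(coef)), ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        se=se, scale="RR", model=f"model{spec.tier}",
        p_value=float(res.pvalues[binary_exposure]),
    )


class AssociationModel:
    """Tiered association model bound to a completed cohort table.

    Parameters
    ----------
    data : completed (no missing cells) cohort table
    outcome : outcome column; continuous unless ``spec.outcome_coding='binary'``
    exposure : exposure column
    spec : ModelSpec (tier, codings, optional explicit roster)

    ``fit()`` returns :class:`AssociationResults`.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, exposure: str,
                 spec: ModelSpec | None = None):
        self.data = data
        self.outcome = outcome
        self.exposure = exposure
        self.spec = spec or ModelSpec()

    def fit(self) -> "AssociationResults":
        if self.spec.outcome_coding == "binary":
            est = fit_poisson_rr(self.data, self.outcome, self.exposure, self.spec)
        else:
            est = fit_linear_model(self.data, self.outcome, self.exposure, self.spec)
        return AssociationResults(self, est)

    def fit_stratified(self, by: str = "gender") -> dict:
        """Refit within each stratum of ``by``, reusing the overall exposure SD
        so per-SD coefficients stay comparable across strata."""
        overall_sd = float(self.data[self.exposure].std(ddof=1))
        roster = [c for c in self.spec.resolve_roster() if c != by]
        out = {}
        for g, sub in self.data.groupby(by):
            spec = ModelSpec(
                **{**self.spec.__dict__, "exposure_sd": overall_sd, "covariates": roster}
            )
            res = AssociationModel(sub, self.outcome, self.exposure, spec).fit()
            res.estimate.stratum = str(g)
            out[g] = res
        return out


@dataclass
class AssociationResults:
    model: AssociationModel = field(repr=False)
    estimate: EffectEstimate

    def summary(self) -> pd.DataFrame:
        e = self.estimate
        return pd.DataFrame(
            [{
                "outcome": self.model.outcome,
                "exposure": self.model.exposure,
                "model": e.model,
                "stratum": e.stratum,
                "scale": e.scale,
                "estimate": e.point,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "se": e.se,
                "p": e.p_value,
            }]
        )
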