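"""Doubly robust risk-difference / risk-ratio estimation with IPW + g-formula.

The estimator combines a logistic propensity model (inverse probability
weights) with a weighted canonical-link logistic outcome model whose
predictions are then standardized over the sample covariate distribution
(g-formula).  The combination is consistent when either model is correctly
specified.  Percentile-bootstrap confidence intervals resample subjects and
rerun both stages.  Gender heterogeneity is summarized by standardized
joint-category risk ratios with RERI (additive scale) and RRR (multiplicative
scale); E-values quantify the unmeasured confounding needed to explain an
observed risk ratio away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import SeparationError, fit_logistic, predict_logistic
from .association import tier_roster

__all__ = [
    "PropensityWeights",
    "DRResult",
    "InteractionResult",
    "EValueResult",
    "fit_propensity",
    "dr_standardize",
    "bootstrap_ci",
    "reri_rrr",
    "e_value",
    "DoublyRobustModel",
    "DRResults",
]


@dataclass
class PropensityWeights:
    """Per-subject propensity scores and inverse probability weights
    (1/e for the treated, 1/(1-e) for the untreated)."""

    propensity: np.ndarray
    weight: np.ndarray
    treatment: str = "treatment"

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.weight)) or np.any(self.weight <= 0):
            raise ValueError("weights must be positive and finite")


@dataclass
class DRResult:
    """Standardized risks under each treatment level and their contrasts."""

    risk1: float
    risk0: float
    rd: float
    rr: float | None  # None when risk0 == 0 (ratio undefined)
    rd_ci: tuple[float, float] | None = None
    rr_ci: tuple[float, float] | None = None
    n_boot: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rd <= 1.0:
            raise ValueError("risk difference outside [-1, 1]")
        if self.rr is not None and self.rr <= 0:
            raise ValueError("risk ratio must be positive")


@dataclass
class InteractionResult:
    """Joint-category risk ratios vs the common reference plus RERI/RRR."""

    rr10: float
    rr01: float
    rr11: float
    reri: float
    rrr: float
    reri_ci: tuple[float, float] | None = None
    rrr_ci: tuple[float, float] | None = None
    reference: str = "(untreated, boys)"


@dataclass
class EValueResult:
    """E-value for a risk ratio and for the CI bound closer to the null."""

    evalue_point: float
    evalue_ci: float | None = None


def _design(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = table[columns].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(table)), X])


def fit_propensity(
    table: pd.DataFrame,
    covariates: list[str],
    treatment: str = "treatment",
    clip_bounds: tuple[float, float] | None = None,
) -> PropensityWeights:
    """Logistic propensity model for a binary treatment; returns scores and
    unstabilized inverse probability weights.

    Quasi-separation (fitted probabilities numerically 0/1) is signaled with
    the affected subject count unless ``clip_bounds`` is given, in which case
    propensities are clipped into that interval instead (positivity trimming
    for small samples)."""
    t = table[treatment].to_numpy(dtype=float)
    if not set(np.unique(t)) <= {0.0, 1.0}:
        raise ValueError(f"treatment {treatment!r} is not binary 0/1")
    if t.min() == t.max():
        raise ValueError(f"treatment {treatment!r} has an empty arm")
    X = _design(table, covariates)
    beta = fit_logistic(X, t)
    ps = predict_logistic(X, beta)
    if clip_bounds is not None:
        ps = np.clip(ps, *clip_bounds)
    else:
        n_extreme = int(np.sum((ps < 1e-8) | (ps > 1 - 1e-8)))
        if n_extreme > 0:
            raise SeparationError(n_extreme)
    w = np.where(t == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    return PropensityWeights(propensity=ps, weight=w, treatment=treatment)


def dr_standardize(
    table: pd.DataFrame,
    weights: PropensityWeights | None,
    outcome: str,
    covariates: list[str],
    treatment: str = "treatment",
) -> DRResult:
    """Weighted-outcome-model g-formula standardization.

    Fits a logistic model of the binary outcome on treatment plus covariates,
    weighted by the inverse probability weights (``weights=None`` gives the
    plain unweighted g-formula), then averages each subject's predicted outcome
    probability with treatment forced to 1 and to 0 over the whole sample.
    """
    y = table[outcome].to_numpy(dtype=float)
    t = table[treatment].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary 0/1")
    if t.min() == t.max():
        raise ValueError(f"treatment {treatment!r} has an empty arm")

    Xc = table[covariates].to_numpy(dtype=float) if covariates else np.empty((len(table), 0))
    X = np.column_stack([np.ones(len(table)), t, Xc])
    w = None if weights is None else weights.weight

    if y.min() == y.max():
        # degenerate outcome: risks equal the constant outcome in both arms
        risk = float(y[0])
        rr = 1.0 if risk > 0 else None
        return DRResult(risk1=risk, risk0=risk, rd=0.0, rr=rr)

    beta = fit_logistic(X, y, sample_weight=w)

    X1 = X.copy()
    X1[:, 1] = 1.0
    X0 = X.copy()
    X0[:, 1] = 0.0
    risk1 = float(predict_logistic(X1, beta).mean())
    risk0 = float(predict_logistic(X0, beta).mean())
    rr = (risk1 / risk0) if risk0 > 0 else None
    return DRResult(risk1=risk1, risk0=risk0, rd=risk1 - risk0, rr=rr)


def bootstrap_ci(
    estimator,
    table: pd.DataFrame,
    n_boot: int,
    seed: int,
    max_drop_fraction: float = 0.10,
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap 95% CIs for a table-valued estimator.

    ``estimator(table) -> dict[str, float]``.  Subjects are resampled with
    replacement; replicates that fail (separation, empty arm, undefined ratio)
    are dropped and counted, escalating to an error past ``max_drop_fraction``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(table)
    draws: dict[str, list[float]] = {}
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        rep = table.iloc[idx].reset_index(drop=True)
        try:
            vals = estimator(rep)
        except (SeparationError, ValueError, np.linalg.LinAlgError):
            dropped += 1
            continue
        if any(v is None or not np.isfinite(v) for v in vals.values()):
            dropped += 1
            continue
        for k, v in vals.items():
            draws.setdefault(k, []).append(float(v))
    if dropped > max_drop_fraction * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap replicates failed (> {max_drop_fraction:.0%})"
        )
    if dropped:
        warnings.warn(f"{dropped}/{n_boot} bootstrap replicates dropped", stacklevel=2)
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in draws.items()
    }


def _joint_risks(
    table: pd.DataFrame,
    outcome: str,
    treatment: str,
    modifier: str,
    covariates: list[str],
    reference_modifier: float,
    weights: PropensityWeights | None,
) -> dict[tuple[int, int], float]:
    """Standardized risks for the four treatment x modifier categories from a
    weighted logistic model with a product term; risks are averaged over the
    full sample with (treatment, modifier) forced to each joint level."""
    y = table[outcome].to_numpy(dtype=float)
    t = table[treatment].to_numpy(dtype=float)
    g = (table[modifier].to_numpy(dtype=float) != reference_modifier).astype(float)
    covs = [c for c in covariates if c not in (treatment, modifier)]
    Xc = table[covs].to_numpy(dtype=float) if covs else np.empty((len(table), 0))
    X = np.column_stack([np.ones(len(table)), t, g, t * g, Xc])
    w = None if weights is None else weights.weight
    beta = fit_logistic(X, y, sample_weight=w)

    risks = {}
    for tt in (0, 1):
        for gg in (0, 1):
            Xi = X.copy()
            Xi[:, 1] = tt
            Xi[:, 2] = gg
            Xi[:, 3] = tt * gg
            risks[(tt, gg)] = float(predict_logistic(Xi, beta).mean())
    return risks


def reri_rrr(
    table: pd.DataFrame,
    outcome: str,
    treatment: str = "treatment",
    modifier: str = "gender",
    covariates: list[str] | None = None,
    weights: PropensityWeights | None = None,
    reference_modifier: float = 1.0,
    n_boot: int = 0,
    seed: int = 0,
    clip_bounds: tuple[float, float] | None = None,
) -> InteractionResult:
    """Additive (RERI) and multiplicative (RRR) interaction between treatment
    and a binary modifier on standardized joint-category risk ratios.

    RERI = RR11 - RR10 - RR01 + 1;  RRR = RR11 / (RR10 * RR01).
    The common reference is (untreated, modifier == ``reference_modifier``);
    with gender coded 1 = boy the default reference is (low gaming, boys).
    Percentile-bootstrap CIs are computed when ``n_boot`` > 0.
    """
    covariates = covariates or []
    for tt in (0, 1):
        for gg_ref in (True, False):
            sel = (table[treatment] == tt) & (
                (table[modifier] == reference_modifier) == gg_ref
            )
            if not sel.any():
                raise ValueError(
                    f"empty joint category (treatment={tt}, reference={gg_ref})"
                )

    def compute(tab: pd.DataFrame) -> dict[str, float]:
        w = None
        if weights is not None:
            ps_covs = [c for c in covariates if c != treatment]
            w = fit_propensity(tab, ps_covs, treatment, clip_bounds=clip_bounds)
        risks = _joint_risks(
            tab, outcome, treatment, modifier, covariates, reference_modifier, w
        )
        r00 = risks[(0, 0)]
        if r00 <= 0:
            raise ValueError("reference-category risk is zero")
        rr10 = risks[(1, 0)] / r00
        rr01 = risks[(0, 1)] / r00
        rr11 = risks[(1, 1)] / r00
        return {
            "rr10": rr10,
            "rr01": rr01,
            "rr11": rr11,
            "reri": rr11 - rr10 - rr01 + 1.0,
            "rrr": rr11 / (rr10 * rr01),
        }

    point = compute(table)
    reri_ci = rrr_ci = None
    if n_boot > 0:
        cis = bootstrap_ci(compute, table, n_boot, seed)
        reri_ci, rrr_ci = cis["reri"], cis["rrr"]
    ref_label = f"({treatment}=0, {modifier}={reference_modifier:g})"
    return InteractionResult(
        rr10=point["rr10"], rr01=point["rr01"], rr11=point["rr11"],
        reri=point["reri"], rrr=point["rrr"],
        reri_ci=reri_ci, rrr_ci=rrr_ci, reference=ref_label,
    )


def e_value(rr: float, ci_low: float | None = None, ci_high: float | None = None) -> EValueResult:
    """E-value for a risk ratio: RR + sqrt(RR * (RR - 1)) after mapping
    protective ratios to 1/RR.  The CI E-value uses the bound closer to the
    null and is 1 when the interval crosses 1."""
    if rr <= 0:
        raise ValueError(f"risk ratio must be positive, got {rr}")

    def _ev(r: float) -> float:
        r = 1.0 / r if r < 1.0 else r
        return float(r + np.sqrt(r * (r - 1.0)))

    ev_ci = None
    if ci_low is not None and ci_high is not None:
        if ci_low <= 0:
            raise ValueError("ci_low must be positive")
        if ci_low <= 1.0 <= ci_high:
            ev_ci = 1.0
        else:
            bound = ci_low if rr >= 1.0 else ci_high
            ev_ci = _ev(bound)
    return EValueResult(evalue_point=_ev(rr), evalue_ci=ev_ci)


class DoublyRobustModel:
    """Doubly robust model for the effect of a binary treatment on a binary
    outcome, bound to a completed cohort table.

    Parameters
    ----------
    data : completed table
    outcome : binary 0/1 outcome column
    treatment : binary 0/1 treatment column
    covariates : adjustment roster (defaults to the fully adjusted tier-3 one)
    truncate_weights : optional (low, high) percentile pair for IPW truncation

    ``fit(n_boot=1000, seed=...)`` returns :class:`DRResults` with percentile-
    bootstrap CIs; ``fit(n_boot=0)`` skips them.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        treatment: str,
        covariates: list[str] | None = None,
        truncate_weights: tuple[float, float] | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        self.treatment = treatment
        self.covariates = (
            list(covariates) if covariates is not None else tier_roster(3, "outcome")
        )
        self.truncate_weights = truncate_weights

    def _estimate(self, table: pd.DataFrame) -> dict[str, float]:
        # with truncation requested, extreme propensities are clipped rather
        # than treated as a separation failure
        clip = (1e-6, 1 - 1e-6) if self.truncate_weights is not None else None
        w = fit_propensity(table, self.covariates, self.treatment, clip_bounds=clip)
        if self.truncate_weights is not None:
            lo, hi = np.percentile(w.weight, self.truncate_weights)
            w = PropensityWeights(
                propensity=w.propensity,
                weight=np.clip(w.weight, lo, hi),
                treatment=w.treatment,
            )
        res = dr_standardize(table, w, self.outcome, self.covariates, self.treatment)
        return {
            "risk1": res.risk1, "risk0": res.risk0,
            "rd": res.rd, "rr": res.rr if res.rr is not None else np.nan,
        }

    def fit(self, n_boot: int = 1000, seed: int = 0) -> "DRResults":
        point = self._estimate(self.data)
        rd_ci = rr_ci = None
        if n_boot > 0:
            cis = bootstrap_ci(self._estimate, self.data, n_boot, seed)
            rd_ci, rr_ci = cis["rd"], cis["rr"]
        result = DRResult(
            risk1=point["risk1"], risk0=point["risk0"], rd=point["rd"],
            rr=None if np.isnan(point["rr"]) else point["rr"],
            rd_ci=rd_ci, rr_ci=rr_ci, n_boot=n_boot,
        )
        return DRResults(self, result)

    def interaction(
        self,
        modifier: str = "gender",
        reference_modifier: float = 1.0,
        n_boot: int = 0,
        seed: int = 0,
    ) -> InteractionResult:
        """RERI/RRR heterogeneity of the treatment effect across a modifier."""
        clip = (1e-6, 1 - 1e-6) if self.truncate_weights is not None else None
        w = fit_propensity(
            self.data, [c for c in self.covariates if c != self.treatment],
            self.treatment, clip_bounds=clip,
        )
        return reri_rrr(
            self.data, self.outcome, self.treatment, modifier,
            covariates=self.covariates, weights=w,
            reference_modifier=reference_modifier, n_boot=n_boot, seed=seed,
            clip_bounds=clip,
        )


@dataclass
class DRResults:
    model: DoublyRobustModel = field(repr=False)
    result: DRResult

    @property
    def rd(self) -> float:
        return self.result.rd

    @property
    def rr(self) -> float | None:
        return self.result.rr

    def e_value(self) -> EValueResult:
        if self.result.rr is None:
            raise ValueError("risk ratio undefined; E-value unavailable")
        lo, hi = (self.result.rr_ci if self.result.rr_ci is not None else (None, None))
        return e_value(self.result.rr, lo, hi)

    def summary(self) -> pd.DataFrame:
        r = self.result
        rows = [
            {"quantity": "risk1", "estimate": r.risk1, "ci_low": None, "ci_high": None},
            {"quantity": "risk0", "estimate": r.risk0, "ci_low": None, "ci_high": None},
            {"quantity": "rd", "estimate": r.rd,
             "ci_low": r.rd_ci[0] if r.rd_ci else None,
             "ci_high": r.rd_ci[1] if r.rd_ci else None},
            {"quantity": "rr", "estimate": r.rr,
             "ci_low": r.rr_ci[0] if r.rr_ci else None,
             "ci_high": r.rr_ci[1] if r.rr_ci else None},
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "outcome", self.model.outcome)
        df.insert(1, "treatment", self.model.treatment)
        return df
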