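"""Regression-based causal mediation with exposure-mediator interaction.

Two linear models are fitted on the completed table: a mediator model
M = alpha0 + alpha1*A + alpha2'C and an outcome model
Y = theta0 + theta1*A + theta2*M + theta3*A*M + theta4'C.  Under the usual
sequential-ignorability assumptions the natural (pure) direct and total
indirect effects of the exposure contrast a0 -> a1, evaluated at a covariate
point cbar, have closed forms:

    PDE = (theta1 + theta3 * E[M | a0, cbar]) * (a1 - a0)
    TIE = (theta2 + theta3 * a1) * alpha1 * (a1 - a0)
    TE  = PDE + TIE,   proportion mediated = TIE / TE

Standard errors come from the delta method on the stacked coefficient vector
(the two models' coefficient blocks treated as independent); a percentile
bootstrap and a Monte-Carlo counterfactual oracle are provided as independent
checks.  With theta3 = 0 the TIE reduces to the classical
product-of-coefficients alpha1 * theta2 and its delta-method SE to the Sobel
formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import MODEL2_COVARIATES, MODEL3_EXTRA, _check_rank

__all__ = [
    "MEDIATION_COVARIATES",
    "MediatorModel",
    "OutcomeModel",
    "MediationResult",
    "MCOracle",
    "fit_mediation_models",
    "two_way_decompose",
    "delta_method_ci",
    "mc_counterfactual_oracle",
    "proportion_mediated",
    "MediationModel",
    "MediationResults",
]

#: fully adjusted roster for the exposure -> mediator -> outcome system:
#: demographics, psychosocial covariates, baseline gaming-time/internet-use and
#: the four baseline mental-health scores.
MEDIATION_COVARIATES = (
    *MODEL2_COVARIATES,
    *MODEL3_EXTRA,
    "time_gaming",
    "problematic_internet",
    "smfq_w1",
    "anxiety_w1",
    "apss_w1",
    "who5_w1",
)

_Z975 = 1.959963984540054


@dataclass
class MediatorModel:
    """Linear mediator model M ~ A + C with its coefficient covariance."""

    alpha0: float
    alpha1: float
    alpha2: pd.Series  # per-covariate coefficients
    sigma_m: float
    cov: pd.DataFrame  # covariance of (const, exposure, covariates)

    def __post_init__(self) -> None:
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")

    def expected_mediator(self, a: float, cbar: pd.Series) -> float:
        return float(self.alpha0 + self.alpha1 * a + self.alpha2 @ cbar[self.alpha2.index])


@dataclass
class OutcomeModel:
    """Linear outcome model Y ~ A + M + A:M + C with coefficient covariance."""

    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: pd.Series
    cov: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.cov.to_numpy()
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("coefficient covariance must be symmetric")
        if np.linalg.eigvalsh((c + c.T) / 2).min() < -1e-8:
            raise ValueError("coefficient covariance must be positive semidefinite")


@dataclass
class MediationResult:
    """Two-way decomposition TE = PDE + TIE for the contrast a0 -> a1."""

    te: float
    pde: float
    tie: float
    pm: float | None  # TIE/TE; None when TE == 0
    a0: float
    a1: float
    cbar: pd.Series = field(repr=False)
    se: dict[str, float] | None = None
    ci: dict[str, tuple[float, float]] | None = None
    p_tie: float | None = None
    pm_flag: str | None = None  # set when pm is unstable (opposite signs, tiny te)

    def __post_init__(self) -> None:
        if abs(self.te - (self.pde + self.tie)) > 1e-10 * max(1.0, abs(self.te)):
            raise ValueError("te must equal pde + tie")


@dataclass
class MCOracle:
    """Monte-Carlo counterfactual estimates of the direct/indirect effects."""

    nde: float
    nie: float
    nde_se: float
    nie_se: float


def fit_mediation_models(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    exposure: str = "exposure_score",
    mediator: str = "mediator_score",
) -> tuple[MediatorModel, OutcomeModel]:
    """OLS fits of the mediator and outcome models with retained covariances."""
    covs = list(covariates) if covariates is not None else list(MEDIATION_COVARIATES)
    used = [outcome, exposure, mediator, *covs]
    if table[used].isna().any().any():
        raise ValueError("table contains missing values; impute first")

    a = table[exposure].astype(float)
    m = table[mediator].astype(float)
    C = table[covs].astype(float)

    Xm = pd.concat([pd.Series(1.0, index=table.index, name="const"), a, C], axis=1)
    _check_rank(Xm)
    mfit = sm.OLS(m, Xm).fit()

    Xy = pd.concat(
        [
            pd.Series(1.0, index=table.index, name="const"),
            a,
            m,
            (a * m).rename("exposure_x_mediator"),
            C,
        ],
        axis=1,
    )
    _check_rank(Xy)
    yfit = sm.OLS(table[outcome].astype(float), Xy).fit()

    mm = MediatorModel(
        alpha0=float(mfit.params["const"]),
        alpha1=float(mfit.params[exposure]),
        alpha2=mfit.params[covs],
        sigma_m=float(np.sqrt(mfit.scale)),
        cov=pd.DataFrame(
            mfit.cov_params(), index=Xm.columns, columns=Xm.columns
        ),
    )
    om = OutcomeModel(
        theta0=float(yfit.params["const"]),
        theta1=float(yfit.params[exposure]),
        theta2=float(yfit.params[mediator]),
        theta3=float(yfit.params["exposure_x_mediator"]),
        theta4=yfit.params[covs],
        cov=pd.DataFrame(
            yfit.cov_params(), index=Xy.columns, columns=Xy.columns
        ),
    )
    return mm, om


def two_way_decompose(
    mm: MediatorModel,
    om: OutcomeModel,
    a0: float,
    a1: float,
    cbar: pd.Series,
) -> MediationResult:
    """Closed-form two-way decomposition at covariate point ``cbar``."""
    if a1 == a0:
        raise ValueError("exposure levels a0 and a1 must differ")
    em0 = mm.expected_mediator(a0, cbar)
    delta = a1 - a0
    pde = (om.theta1 + om.theta3 * em0) * delta
    tie = (om.theta2 + om.theta3 * a1) * mm.alpha1 * delta
    te = pde + tie

    pm = None
    flag = None
    if te == 0:
        flag = "te is zero; proportion mediated undefined"
    else:
        pm = tie / te
        if np.sign(te) != np.sign(tie) and tie != 0:
            flag = "te and tie have opposite signs; proportion mediated unstable"
    return MediationResult(te=te, pde=pde, tie=tie, pm=pm, a0=a0, a1=a1,
                           cbar=cbar, pm_flag=flag)


def _gradients(
    mm: MediatorModel, om: OutcomeModel, a0: float, a1: float, cbar: pd.Series
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Gradients of (pde, tie, te) w.r.t. the two coefficient blocks, ordered as
    the fitted covariance matrices (mediator: const, A, C...; outcome: const, A,
    M, A:M, C...)."""
    delta = a1 - a0
    em0 = mm.expected_mediator(a0, cbar)
    cvals = cbar[mm.alpha2.index].to_numpy(dtype=float)
    k = len(cvals)

    # mediator block: d/d(alpha0, alpha1, alpha2)
    g_pde_m = np.concatenate(([om.theta3 * delta, om.theta3 * a0 * delta],
                              om.theta3 * delta * cvals))
    g_tie_m = np.zeros(2 + k)
    g_tie_m[1] = (om.theta2 + om.theta3 * a1) * delta

    # outcome block: d/d(theta0, theta1, theta2, theta3, theta4)
    g_pde_y = np.concatenate(([0.0, delta, 0.0, em0 * delta], np.zeros(k)))
    g_tie_y = np.concatenate(([0.0, 0.0, mm.alpha1 * delta, a1 * mm.alpha1 * delta],
                              np.zeros(k)))

    gm = {"pde": g_pde_m, "tie": g_tie_m, "te": g_pde_m + g_tie_m}
    gy = {"pde": g_pde_y, "tie": g_tie_y, "te": g_pde_y + g_tie_y}
    return gm, gy


def delta_method_ci(
    mm: MediatorModel,
    om: OutcomeModel,
    a0: float,
    a1: float,
    cbar: pd.Series,
) -> tuple[dict[str, float], dict[str, tuple[float, float]]]:
    """Delta-method SEs and normal-theory 95% CIs for te/pde/tie.

    The two coefficient blocks are treated as independent (separately fitted
    models), so var(effect) = g_m' S_m g_m + g_y' S_y g_y.
    """
    Sm = mm.cov.to_numpy(dtype=float)
    Sy = om.cov.to_numpy(dtype=float)
    for S, label in ((Sm, "mediator"), (Sy, "outcome")):
        if not np.all(np.isfinite(S)):
            raise ValueError(f"{label} coefficient covariance is not finite")
    gm, gy = _gradients(mm, om, a0, a1, cbar)
    point = two_way_decompose(mm, om, a0, a1, cbar)
    vals = {"te": point.te, "pde": point.pde, "tie": point.tie}

    ses, cis = {}, {}
    for eff in ("te", "pde", "tie"):
        var = float(gm[eff] @ Sm @ gm[eff] + gy[eff] @ Sy @ gy[eff])
        se = float(np.sqrt(max(var, 0.0)))
        ses[eff] = se
        cis[eff] = (vals[eff] - _Z975 * se, vals[eff] + _Z975 * se)
    return ses, cis


def mc_counterfactual_oracle(
    mm: MediatorModel,
    om: OutcomeModel,
    cbar: pd.Series,
    a0: float,
    a1: float,
    n_draws: int = 100_000,
    seed: int = 0,
) -> MCOracle:
    """Monte-Carlo counterfactual estimates of the pure direct and total
    indirect effects by simulating M(a0), M(a1) from the mediator model's
    Gaussian law and pushing the draws through the outcome model.  Serves as an
    independent check of the closed forms (exact in expectation for linear
    models)."""
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    em0 = mm.expected_mediator(a0, cbar)
    em1 = mm.expected_mediator(a1, cbar)
    m0 = rng.normal(em0, mm.sigma_m, n_draws)
    m1 = rng.normal(em1, mm.sigma_m, n_draws)

    cterm = float(om.theta4 @ cbar[om.theta4.index])

    def y(a: float, m: np.ndarray) -> np.ndarray:
        return om.theta0 + om.theta1 * a + om.theta2 * m + om.theta3 * a * m + cterm

    nde_draws = y(a1, m0) - y(a0, m0)
    nie_draws = y(a1, m1) - y(a1, m0)
    return MCOracle(
        nde=float(nde_draws.mean()),
        nie=float(nie_draws.mean()),
        nde_se=float(nde_draws.std(ddof=1) / np.sqrt(n_draws)),
        nie_se=float(nie_draws.std(ddof=1) / np.sqrt(n_draws)),
    )


def proportion_mediated(te: float, tie: float) -> float:
    """Proportion mediated = TIE / TE, as a percentage."""
    if te == 0:
        raise ZeroDivisionError("total effect is zero; proportion mediated undefined")
    return 100.0 * tie / te


class MediationModel:
    """Causal mediation model (exposure -> mediator -> outcome) bound to a
    completed cohort table.

    The exposure contrast defaults to mean -> mean + 1 SD of the exposure on
    the analysis sample; the covariate evaluation point defaults to the sample
    covariate means.  ``fit()`` returns :class:`MediationResults` carrying the
    decomposition, delta-method CIs and the proportion mediated.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        exposure: str = "exposure_score",
        mediator: str = "mediator_score",
        covariates: list[str] | None = None,
        a0: float | None = None,
        a1: float | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        self.exposure = exposure
        self.mediator = mediator
        self.covariates = (
            list(covariates) if covariates is not None else list(MEDIATION_COVARIATES)
        )
        mean = float(self.data[exposure].mean())
        sd = float(self.data[exposure].std(ddof=1))
        self.a0 = mean if a0 is None else a0
        self.a1 = mean + sd if a1 is None else a1

    def fit(self) -> "MediationResults":
        mm, om = fit_mediation_models(
            self.data, self.outcome, self.covariates, self.exposure, self.mediator
        )
        cbar = self.data[self.covariates].astype(float).mean()
        res = two_way_decompose(mm, om, self.a0, self.a1, cbar)
        ses, cis = delta_method_ci(mm, om, self.a0, self.a1, cbar)
        res.se, res.ci = ses, cis
        if ses["tie"] > 0:
            z = res.tie / ses["tie"]
            res.p_tie = float(2 * stats.norm.sf(abs(z)))
        return MediationResults(self, mm, om, res)

    def fit_stratified(self, by: str = "gender") -> dict:
        """Refit both models within each stratum (dropping the stratifier from
        the roster), keeping the overall-sample a0/a1 for comparability."""
        covs = [c for c in self.covariates if c != by]
        out = {}
        for g, sub in self.data.groupby(by):
            sub_model = MediationModel(
                sub, self.outcome, self.exposure, self.mediator,
                covariates=covs, a0=self.a0, a1=self.a1,
            )
            out[g] = sub_model.fit()
        return out


@dataclass
class MediationResults:
    model: MediationModel = field(repr=False)
    mediator_model: MediatorModel = field(repr=False)
    outcome_model: OutcomeModel = field(repr=False)
    result: MediationResult

    @property
    def proportion_mediated(self) -> float:
        return proportion_mediated(self.result.te, self.result.tie)

    def mc_oracle(self, n_draws: int = 100_000, seed: int = 0) -> MCOracle:
        return mc_counterfactual_oracle(
            self.mediator_model, self.outcome_model, self.result.cbar,
            self.result.a0, self.result.a1, n_draws=n_draws, seed=seed,
        )

    def bootstrap_ci(self, n_boot: int = 1000, seed: int = 0) -> dict[str, tuple[float, float]]:
        """Percentile-bootstrap CIs for te/pde/tie (resampling subjects and
        refitting both models per replicate); an independent check on the
        delta-method intervals.  Replicate fits use plain least squares on the
        prebuilt design matrices, which is numerically identical to the OLS
        point fits."""
        md = self.model
        data = md.data
        a = data[md.exposure].to_numpy(dtype=float)
        m = data[md.mediator].to_numpy(dtype=float)
        y = data[md.outcome].to_numpy(dtype=float)
        C = data[md.covariates].to_numpy(dtype=float)
        n = len(data)
        ones = np.ones(n)
        Xm = np.column_stack([ones, a, C])
        Xy = np.column_stack([ones, a, m, a * m, C])
        a0, a1 = self.result.a0, self.result.a1
        delta = a1 - a0

        rng = np.random.default_rng(seed)
        draws = {"te": [], "pde": [], "tie": []}
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            alpha = np.linalg.lstsq(Xm[idx], m[idx], rcond=None)[0]
            theta = np.linalg.lstsq(Xy[idx], y[idx], rcond=None)[0]
            cbar = C[idx].mean(axis=0)
            em0 = alpha[0] + alpha[1] * a0 + alpha[2:] @ cbar
            pde = (theta[1] + theta[3] * em0) * delta
            tie = (theta[2] + theta[3] * a1) * alpha[1] * delta
            draws["pde"].append(pde)
            draws["tie"].append(tie)
            draws["te"].append(pde + tie)
        return {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in draws.items()
        }

    def summary(self) -> pd.DataFrame:
        r = self.result
        rows = []
        for eff in ("te", "pde", "tie"):
            rows.append({
                "outcome": self.model.outcome,
                "effect": eff,
                "estimate": getattr(r, eff),
                "se": r.se[eff] if r.se else None,
                "ci_low": r.ci[eff][0] if r.ci else None,
                "ci_high": r.ci[eff][1] if r.ci else None,
            })
        df = pd.DataFrame(rows)
        df.attrs["proportion_mediated_pct"] = (
            None if r.pm is None else 100.0 * r.pm
        )
        df.attrs["p_tie"] = r.p_tie
        return df
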