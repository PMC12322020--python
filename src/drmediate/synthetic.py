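"""Synthetic three-wave adolescent cohort generator.

Emulates the statistical structure the downstream causal analyses assume: twelve
wave-1 covariates with realistic marginals, a confounded exposure score
(hyperactivity/inattention, 0-10), a mediator symptom count at wave 2
(problematic online gaming, 0-9) on a confounded, exposure-driven pathway, and
four wave-3 mental-health outcome scores (SMFQ 0-26, CBCL-anxiety 0-28, APSS
0-7 in half-point steps, WHO-5 0-100 in steps of four) generated from a linear
structural model with an exposure-mediator interaction plus baseline-outcome
carryover.  Missingness can be layered on MCAR or MAR-on-observed
(gender/exposure driven).  Closed-form true effects accompany every
configuration so estimators can be checked against ground truth.

The structural equations operate on a latent continuous scale; scores are then
rounded to each instrument's grid and clipped to its range.  Closed-form true
effects are exact on the latent scale (``discretize=False``) and approximate
after discretization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "OUTCOMES",
    "CONFOUNDERS",
    "VARIABLE_SCHEMA",
    "GenerationConfig",
    "TrueEffects",
    "DRGenerationConfig",
    "generate_cohort",
    "apply_missingness",
    "true_effects",
    "generate_dr_cohort",
    "write_cohort",
    "read_cohort",
]

OUTCOMES = ("smfq", "anxiety", "apss", "who5")

#: wave-1 covariates entering the structural equations (standardized internally)
CONFOUNDERS = (
    "age",
    "gender",
    "bmi",
    "iq",
    "income",
    "loneliness",
    "physical_punishment",
    "rel_mother",
    "rel_father",
    "rel_friends",
    "neighborhood_cohesion",
    "gender_nonconforming",
    "time_gaming",
    "problematic_internet",
)

# Target marginal (mean, sd) used both to simulate covariates and to
# standardize them inside the structural equations. Binary variables store
# (p, sqrt(p*(1-p))). Chosen to match the cohort's published wave-1 summaries.
_MARGINALS: dict[str, tuple[float, float]] = {
    "age": (12.2, 0.28),
    "gender": (0.531, float(np.sqrt(0.531 * 0.469))),  # 1 = boy
    "bmi": (17.9, 2.51),
    "iq": (110.0, 14.9),
    "income": (1.096, 0.672),  # 3-level ordinal coded 0/1/2, P=(.184,.535,.280)
    "loneliness": (0.158, float(np.sqrt(0.158 * 0.842))),
    "physical_punishment": (0.330, float(np.sqrt(0.330 * 0.670))),
    "rel_mother": (3.79, 0.986),
    "rel_father": (3.43, 1.19),
    "rel_friends": (3.52, 0.922),
    "neighborhood_cohesion": (12.9, 2.89),
    "gender_nonconforming": (0.279, float(np.sqrt(0.279 * 0.721))),
    "time_gaming": (0.291, float(np.sqrt(0.291 * 0.709))),
    "problematic_internet": (3.94, 4.16),
}

_INCOME_P = (0.184, 0.535, 0.281)

# Wave-1 (baseline) outcome marginals: mean, sd.
_BASELINE_MARGINALS = {
    "smfq": (3.84, 4.49),
    "anxiety": (2.39, 2.87),
    "apss": (0.581, 0.828),
    "who5": (75.3, 18.9),
}

#: per-variable (kind, low, high, grid) used for clipping/rounding and by the
#: imputer; kind is "continuous", "binary" or "ordinal"; grid is the score step.
VARIABLE_SCHEMA: dict[str, tuple[str, float, float, float | None]] = {
    "age": ("continuous", 10.0, 15.0, None),
    "gender": ("binary", 0, 1, 1),
    "bmi": ("continuous", 10.0, 40.0, None),
    "iq": ("continuous", 40.0, 180.0, 1),
    "income": ("ordinal", 0, 2, 1),
    "loneliness": ("binary", 0, 1, 1),
    "physical_punishment": ("binary", 0, 1, 1),
    "rel_mother": ("ordinal", 1, 5, 1),
    "rel_father": ("ordinal", 1, 5, 1),
    "rel_friends": ("ordinal", 1, 5, 1),
    "neighborhood_cohesion": ("ordinal", 4, 20, 1),
    "gender_nonconforming": ("binary", 0, 1, 1),
    "time_gaming": ("binary", 0, 1, 1),
    "problematic_internet": ("ordinal", 0, 33, 1),
    "exposure_score": ("ordinal", 0, 10, 1),
    "mediator_score": ("ordinal", 0, 9, 1),
    "smfq_w1": ("ordinal", 0, 26, 1),
    "anxiety_w1": ("ordinal", 0, 28, 1),
    "apss_w1": ("ordinal", 0, 7, 0.5),
    "who5_w1": ("ordinal", 0, 100, 4),
    "smfq_w3": ("ordinal", 0, 26, 1),
    "anxiety_w3": ("ordinal", 0, 28, 1),
    "apss_w3": ("ordinal", 0, 7, 0.5),
    "who5_w3": ("ordinal", 0, 100, 4),
}


def _default_missing_rates() -> dict[str, float]:
    # Wave-1 rates follow the cohort's published missing fractions; the
    # mediator and wave-3 outcomes follow the follow-up rates (84.1%, 82.5%).
    return {
        "bmi": 0.195,
        "iq": 0.199,
        "income": 0.234,
        "loneliness": 0.205,
        "physical_punishment": 0.134,
        "rel_mother": 0.128,
        "rel_father": 0.128,
        "rel_friends": 0.128,
        "neighborhood_cohesion": 0.056,
        "gender_nonconforming": 0.205,
        "time_gaming": 0.055,
        "problematic_internet": 0.064,
        "exposure_score": 0.058,
        "smfq_w1": 0.218,
        "anxiety_w1": 0.141,
        "apss_w1": 0.199,
        "who5_w1": 0.096,
        "mediator_score": 0.159,
        "smfq_w3": 0.175,
        "anxiety_w3": 0.175,
        "apss_w3": 0.175,
        "who5_w3": 0.175,
    }


def _default_conf_to_exposure() -> dict[str, float]:
    return {
        "gender": 0.70,
        "iq": -0.35,
        "loneliness": 0.35,
        "physical_punishment": 0.40,
        "rel_mother": -0.20,
        "time_gaming": 0.25,
        "problematic_internet": 0.30,
    }


def _default_conf_to_mediator() -> dict[str, float]:
    return {
        "gender": 0.30,
        "iq": -0.10,
        "loneliness": 0.15,
        "time_gaming": 0.35,
        "problematic_internet": 0.45,
    }


def _default_conf_to_outcome() -> dict[str, dict[str, float]]:
    return {
        "smfq": {
            "gender": -0.80,
            "loneliness": 1.20,
            "physical_punishment": 0.50,
            "rel_mother": -0.50,
            "rel_friends": -0.80,
            "problematic_internet": 0.80,
        },
        "anxiety": {
            "gender": -0.20,
            "loneliness": 0.50,
            "physical_punishment": 0.30,
            "rel_mother": -0.30,
            "problematic_internet": 0.30,
        },
        "apss": {
            "loneliness": 0.15,
            "physical_punishment": 0.10,
            "problematic_internet": 0.15,
        },
        "who5": {
            "loneliness": -6.0,
            "physical_punishment": -3.0,
            "rel_mother": 3.0,
            "rel_friends": 5.0,
            "problematic_internet": -4.0,
        },
    }


@dataclass
class GenerationConfig:
    """All simulator coefficients, noise scales, missingness rates and the seed.

    Structural-coefficient conventions: confounder coefficients act on
    covariates standardized by the fixed target marginals (so they are in
    outcome units per covariate SD); ``alpha1`` is in mediator units per
    exposure unit; ``theta1``/``theta2``/``theta3`` are per-outcome dictionaries
    in outcome units per exposure unit, per mediator unit and per
    exposure x mediator unit respectively.
    """

    n_subjects: int = 3171
    seed: int = 0
    # exposure model
    exposure_intercept: float = 3.3
    conf_to_exposure: dict[str, float] = field(default_factory=_default_conf_to_exposure)
    noise_sd_exposure: float = 1.9
    # mediator model
    alpha0: float = 1.2
    alpha1: float = 0.08
    conf_to_mediator: dict[str, float] = field(default_factory=_default_conf_to_mediator)
    noise_sd_mediator: float = 1.3
    # outcome models (per outcome)
    theta0: dict[str, float] = field(
        default_factory=lambda: {"smfq": 3.4, "anxiety": 1.8, "apss": 0.42, "who5": 76.4}
    )
    theta1: dict[str, float] = field(
        default_factory=lambda: {"smfq": 0.052, "anxiety": 0.112, "apss": 0.018, "who5": -0.37}
    )
    theta2: dict[str, float] = field(
        default_factory=lambda: {"smfq": 0.34, "anxiety": 0.17, "apss": 0.04, "who5": -1.30}
    )
    theta3: dict[str, float] = field(
        default_factory=lambda: {"smfq": 0.02, "anxiety": 0.01, "apss": 0.003, "who5": -0.05}
    )
    conf_to_outcome: dict[str, dict[str, float]] = field(default_factory=_default_conf_to_outcome)
    carryover: dict[str, float] = field(
        default_factory=lambda: {"smfq": 0.35, "anxiety": 0.35, "apss": 0.35, "who5": 0.35}
    )
    noise_sd_outcome: dict[str, float] = field(
        default_factory=lambda: {"smfq": 3.8, "anxiety": 2.5, "apss": 0.7, "who5": 15.0}
    )
    noise_sd_baseline: dict[str, float] = field(
        default_factory=lambda: {"smfq": 4.04, "anxiety": 2.77, "apss": 0.794, "who5": 16.2}
    )
    # missingness
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    missing_mechanism: str = "MCAR"  # "MCAR" | "MAR-on-observed"
    # if False, return latent continuous scores (no rounding/clipping); the
    # closed-form TrueEffects are exact only on this scale
    discretize: bool = True
    # if True, the outcome equations use the dichotomized mediator (high
    # gaming, score >= 4) in place of the continuous score
    binary_mediator_effect: bool = False

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in ("noise_sd_exposure", "noise_sd_mediator"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for d, label in ((self.noise_sd_outcome, "noise_sd_outcome"),
                         (self.noise_sd_baseline, "noise_sd_baseline")):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"{label}[{k!r}] must be positive, got {v}")
        for k, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missing_rates[{k!r}] must be in [0, 1], got {v}")
        if self.missing_mechanism not in ("MCAR", "MAR-on-observed"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        for d, label in ((self.conf_to_exposure, "conf_to_exposure"),
                         (self.conf_to_mediator, "conf_to_mediator")):
            for k in d:
                if k not in CONFOUNDERS:
                    raise ValueError(f"{label}: unknown covariate {k!r}")
        for o in OUTCOMES:
            for dd, label in ((self.theta0, "theta0"), (self.theta1, "theta1"),
                              (self.theta2, "theta2"), (self.theta3, "theta3")):
                if o not in dd:
                    raise ValueError(f"{label} missing entry for outcome {o!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GenerationConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class TrueEffects:
    """Ground-truth effect values implied by a generator configuration.

    ``te``/``pde``/``tie`` are on the latent outcome scale for the exposure
    contrast a0 -> a1; ``rd``/``rr`` (when set) are the true marginal risk
    difference/ratio of a binary-treatment configuration.
    """

    te: float
    pde: float
    tie: float
    rd: float | None = None
    rr: float | None = None
    risk1: float | None = None
    risk0: float | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.te, self.pde + self.tie, rtol=0, atol=1e-12):
            raise ValueError("te must equal pde + tie")


def _standardize(cov: pd.DataFrame) -> pd.DataFrame:
    """Standardize covariates by the fixed target marginals (not the sample)."""
    z = pd.DataFrame(index=cov.index)
    for v in CONFOUNDERS:
        m, s = _MARGINALS[v]
        z[v] = (cov[v] - m) / s
    return z


def _lincomb(z: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    out = np.zeros(len(z))
    for v, c in coefs.items():
        out += c * z[v].to_numpy(dtype=float)
    return out


def _to_grid(x: np.ndarray, lo: float, hi: float, step: float) -> np.ndarray:
    # round-half-up to the grid, then clip
    g = np.floor(x / step + 0.5) * step
    return np.clip(g, lo, hi)


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cov = pd.DataFrame(index=pd.RangeIndex(n))
    cov["age"] = rng.normal(*_MARGINALS["age"], n)
    cov["gender"] = rng.binomial(1, _MARGINALS["gender"][0], n)
    cov["bmi"] = np.clip(rng.normal(*_MARGINALS["bmi"], n), 10, 40)
    cov["iq"] = np.round(rng.normal(*_MARGINALS["iq"], n))
    cov["income"] = rng.choice(3, size=n, p=_INCOME_P)
    for v in ("loneliness", "physical_punishment", "gender_nonconforming", "time_gaming"):
        cov[v] = rng.binomial(1, _MARGINALS[v][0], n)
    for v in ("rel_mother", "rel_father", "rel_friends"):
        cov[v] = _to_grid(rng.normal(*_MARGINALS[v], n), 1, 5, 1)
    cov["neighborhood_cohesion"] = _to_grid(
        rng.normal(*_MARGINALS["neighborhood_cohesion"], n), 4, 20, 1
    )
    mu, sd = _MARGINALS["problematic_internet"]
    shape = (mu / sd) ** 2
    cov["problematic_internet"] = _to_grid(
        rng.gamma(shape, sd**2 / mu, n), 0, 33, 1
    )
    return cov.astype(float)


def generate_cohort(config: GenerationConfig) -> pd.DataFrame:
    """Generate a complete (no-missingness) cohort table.

    Columns: ``subject_id``, the twelve wave-1 covariates, ``exposure_score``
    (wave 1), ``mediator_score`` (wave 2), baseline outcome scores
    ``{outcome}_w1`` and wave-3 outcome scores ``{outcome}_w3``.  Deterministic
    given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    cov = _simulate_covariates(n, rng)
    z = _standardize(cov)

    a_lat = (
        config.exposure_intercept
        + _lincomb(z, config.conf_to_exposure)
        + rng.normal(0, config.noise_sd_exposure, n)
    )
    a = _to_grid(a_lat, 0, 10, 1) if config.discretize else a_lat

    m_lat = (
        config.alpha0
        + config.alpha1 * a
        + _lincomb(z, config.conf_to_mediator)
        + rng.normal(0, config.noise_sd_mediator, n)
    )
    m = _to_grid(m_lat, 0, 9, 1) if config.discretize else m_lat

    table = pd.DataFrame({"subject_id": np.arange(n)})
    table = pd.concat([table, cov], axis=1)
    table["exposure_score"] = a
    table["mediator_score"] = m

    m_for_outcome = (m >= 4).astype(float) if config.binary_mediator_effect else m

    for o in OUTCOMES:
        base_mean, _ = _BASELINE_MARGINALS[o]
        y1_lat = (
            base_mean
            + _lincomb(z, config.conf_to_outcome.get(o, {}))
            + rng.normal(0, config.noise_sd_baseline[o], n)
        )
        _, lo, hi, step = VARIABLE_SCHEMA[f"{o}_w1"]
        y1 = _to_grid(y1_lat, lo, hi, step) if config.discretize else y1_lat
        table[f"{o}_w1"] = y1

        y3_lat = (
            config.theta0[o]
            + config.theta1[o] * a
            + config.theta2[o] * m_for_outcome
            + config.theta3[o] * a * m_for_outcome
            + _lincomb(z, config.conf_to_outcome.get(o, {}))
            + config.carryover[o] * (y1 - base_mean)
            + rng.normal(0, config.noise_sd_outcome[o], n)
        )
        _, lo, hi, step = VARIABLE_SCHEMA[f"{o}_w3"]
        table[f"{o}_w3"] = _to_grid(y3_lat, lo, hi, step) if config.discretize else y3_lat

    return table


def apply_missingness(table: pd.DataFrame, config: GenerationConfig) -> pd.DataFrame:
    """Blank cells per ``config.missing_rates`` under MCAR or MAR-on-observed.

    Under MAR-on-observed the missingness logit of every variable except gender
    and the exposure score shifts with (centered, scaled) gender and exposure;
    gender and exposure themselves are blanked MCAR so the conditioning
    variables stay observed for imputation.  The seed is derived from
    ``config.seed`` so generate + blank is reproducible end to end.
    """
    config.validate()
    rng = np.random.default_rng((config.seed + 1_000_003) % 2**31)
    out = table.copy()
    n = len(out)

    if config.missing_mechanism == "MAR-on-observed":
        g = out["gender"].to_numpy(dtype=float)
        zg = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        a = out["exposure_score"].to_numpy(dtype=float)
        za = (a - a.mean()) / (a.std() if a.std() > 0 else 1.0)

    for col, rate in config.missing_rates.items():
        if col not in out.columns or rate == 0.0:
            continue
        if rate == 1.0:
            out[col] = np.nan
            continue
        if config.missing_mechanism == "MCAR" or col in ("gender", "exposure_score", "age"):
            mask = rng.random(n) < rate
        else:
            p = expit(logit(rate) + 0.4 * zg + 0.4 * za)
            mask = rng.random(n) < p
        out.loc[mask, col] = np.nan
    return out


def true_effects(
    config: GenerationConfig,
    a0: float,
    a1: float,
    cbar: dict[str, float] | None = None,
    outcome: str = "smfq",
) -> TrueEffects:
    """Closed-form true effects for the exposure contrast a0 -> a1 (latent scale).

    pde = (theta1 + theta3 * E[M | a0, cbar]) * (a1 - a0)
    tie = (theta2 + theta3 * a1) * alpha1 * (a1 - a0)

    ``cbar`` is a covariate value vector on the raw scale (defaults to the
    configured target means, for which the standardized terms vanish).
    """
    config.validate()
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if cbar is None:
        zbar = {v: 0.0 for v in CONFOUNDERS}
    else:
        zbar = {v: (cbar[v] - _MARGINALS[v][0]) / _MARGINALS[v][1] for v in cbar}
    em0 = config.alpha0 + config.alpha1 * a0 + sum(
        c * zbar.get(v, 0.0) for v, c in config.conf_to_mediator.items()
    )
    t1, t2, t3 = config.theta1[outcome], config.theta2[outcome], config.theta3[outcome]
    pde = (t1 + t3 * em0) * (a1 - a0)
    tie = (t2 + t3 * a1) * config.alpha1 * (a1 - a0)
    return TrueEffects(te=pde + tie, pde=pde, tie=tie)


# ---------------------------------------------------------------------------
# Binary-treatment cohort with exact counterfactual risks
# ---------------------------------------------------------------------------


@dataclass
class DRGenerationConfig:
    """Configuration for a binary-treatment cohort with logistic assignment
    and outcome models, so marginal counterfactual risks have a closed form
    (mean of per-subject model probabilities under each arm)."""

    n_subjects: int = 3000
    seed: int = 0
    propensity_intercept: float = -2.3
    propensity_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "gender": 0.45,
            "iq": -0.25,
            "loneliness": 0.30,
            "time_gaming": 0.35,
            "problematic_internet": 0.40,
        }
    )
    outcome_intercept: float = -1.9
    treatment_effect: float = 0.7  # log-odds shift of the outcome under treatment
    outcome_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "gender": -0.35,
            "loneliness": 0.55,
            "physical_punishment": 0.25,
            "rel_friends": -0.30,
            "problematic_internet": 0.35,
        }
    )

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for d, label in ((self.propensity_coefs, "propensity_coefs"),
                         (self.outcome_coefs, "outcome_coefs")):
            for k in d:
                if k not in CONFOUNDERS:
                    raise ValueError(f"{label}: unknown covariate {k!r}")


def generate_dr_cohort(config: DRGenerationConfig) -> tuple[pd.DataFrame, TrueEffects]:
    """Generate (covariates, binary treatment, binary outcome) plus exact truth.

    Treatment ~ Bernoulli(expit(propensity linear predictor)); outcome ~
    Bernoulli(expit(outcome linear predictor)).  True marginal risks are the
    cohort averages of the outcome-model probabilities with treatment forced to
    1 and 0; rd/rr follow.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cov = _simulate_covariates(n, rng)
    z = _standardize(cov)

    ps = expit(config.propensity_intercept + _lincomb(z, config.propensity_coefs))
    t = rng.binomial(1, ps)

    lp_base = config.outcome_intercept + _lincomb(z, config.outcome_coefs)
    p1 = expit(lp_base + config.treatment_effect)
    p0 = expit(lp_base)
    p_obs = np.where(t == 1, p1, p0)
    y = rng.binomial(1, p_obs)

    table = pd.DataFrame({"subject_id": np.arange(n)})
    table = pd.concat([table, cov], axis=1)
    table["treatment"] = t
    table["outcome"] = y

    risk1, risk0 = float(p1.mean()), float(p0.mean())
    truth = TrueEffects(
        te=risk1 - risk0, pde=risk1 - risk0, tie=0.0,
        rd=risk1 - risk0, rr=risk1 / risk0, risk1=risk1, risk0=risk0,
    )
    return table, truth


# ---------------------------------------------------------------------------
# CSV round trip with sidecar config
# ---------------------------------------------------------------------------


def write_cohort(table: pd.DataFrame, path, config: GenerationConfig | None = None) -> None:
    """Write the cohort as CSV (missing cells empty); config to a sidecar JSON."""
    path = Path(path)
    table.to_csv(path, index=False)
    if config is not None:
        path.with_suffix(".config.json").write_text(config.to_json())


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
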