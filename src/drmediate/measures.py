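"""Scale scoring, dichotomization at case cut-offs, T-scores and Cronbach's alpha.

The instruments covered are the SDQ hyperactivity/inattention subscale (0-10),
a nine-item problematic online gaming symptom count (0-9), the SMFQ depression
scale (0-26), a 14-item CBCL anxiety subset (0-28), the APSS psychotic-experience
screener (0-7 in half-point steps) and the WHO-5 well-being index (0-100 in steps
of four).  Scale structure and cut-offs are shipped as a YAML registry
(``data/scales.yaml``) so the definitions are data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScaleSpec",
    "CutoffRules",
    "load_registry",
    "get_scale",
    "get_cutoffs",
    "score_scale",
    "dichotomize_gaming",
    "t_score",
    "dichotomize_outcome",
    "reverse_wellbeing",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Structure of one instrument: items, admissible levels, total range."""

    name: str
    item_count: int
    item_levels: tuple[float, ...]
    total_range: tuple[float, float]
    transform: str = "identity"  # "identity" | "multiply-by-4"
    direction: str = "higher-worse"

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "multiply-by-4"):
            raise ValueError(f"unknown transform {self.transform!r}")
        factor = 4.0 if self.transform == "multiply-by-4" else 1.0
        top = self.item_count * max(self.item_levels) * factor
        if top != self.total_range[1]:
            raise ValueError(
                f"scale {self.name!r}: max attainable total {top} does not match "
                f"declared range top {self.total_range[1]}"
            )


@dataclass(frozen=True)
class CutoffRules:
    """Case-definition thresholds for the four dichotomized outcomes and the mediator."""

    gaming_high_min: int = 4
    smfq_case_min: int = 8
    anxiety_t_min: float = 65.0
    apss_definite_min_items: int = 1
    who5_diminished_max: float = 50.0
    who5_strict: bool = False  # True -> diminished iff score < cutoff instead of <=


def load_registry() -> dict:
    """Load the shipped YAML registry of scales and cut-offs."""
    text = resources.files("drmediate").joinpath("data/scales.yaml").read_text()
    return yaml.safe_load(text)


def get_scale(name: str) -> ScaleSpec:
    reg = load_registry()["scales"]
    if name not in reg:
        raise KeyError(f"unknown scale {name!r}; known: {sorted(reg)}")
    d = reg[name]
    return ScaleSpec(
        name=name,
        item_count=int(d["item_count"]),
        item_levels=tuple(float(v) for v in d["item_levels"]),
        total_range=(float(d["total_range"][0]), float(d["total_range"][1])),
        transform=d["transform"],
        direction=d["direction"],
    )


def get_cutoffs() -> CutoffRules:
    d = load_registry()["cutoffs"]
    return CutoffRules(
        gaming_high_min=int(d["gaming_high_min"]),
        smfq_case_min=int(d["smfq_case_min"]),
        anxiety_t_min=float(d["anxiety_t_min"]),
        apss_definite_min_items=int(d["apss_definite_min_items"]),
        who5_diminished_max=float(d["who5_diminished_max"]),
    )


def score_scale(item_responses, spec: ScaleSpec) -> float:
    """Total score for one subject: sum of item responses, transformed per spec.

    Rejects missing items and responses outside the admissible levels (naming
    the offending item index); pro-rating of incomplete item sets is deliberately
    not offered — item-level missingness is resolved upstream by imputation.
    """
    arr = np.asarray(item_responses, dtype=float)
    if arr.ndim != 1 or arr.size != spec.item_count:
        raise ValueError(
            f"scale {spec.name!r} expects {spec.item_count} items, got {arr.size}"
        )
    if np.isnan(arr).any():
        idx = int(np.flatnonzero(np.isnan(arr))[0])
        raise ValueError(f"scale {spec.name!r}: missing response at item {idx}")
    levels = np.asarray(spec.item_levels)
    bad = ~np.isclose(arr[:, None], levels[None, :]).any(axis=1)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"scale {spec.name!r}: response {arr[idx]} at item {idx} not in levels "
            f"{spec.item_levels}"
        )
    total = float(arr.sum())
    if spec.transform == "multiply-by-4":
        total *= 4.0
    lo, hi = spec.total_range
    assert lo <= total <= hi
    return total


def dichotomize_gaming(score, rules: CutoffRules | None = None):
    """Classify a gaming symptom count as 'low' (0-3) or 'high' (4-9).

    Accepts a scalar or array; returns 0/1 (int) with 1 = high degree.
    """
    rules = rules or CutoffRules()
    arr = np.asarray(score, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("gaming score contains missing values")
    if ((arr < 0) | (arr > 9)).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("gaming score must be an integer in [0, 9]")
    out = (arr >= rules.gaming_high_min).astype(int)
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


def t_score(x, ref_mean: float, ref_sd: float):
    """Linear T standardization: 50 + 10*(x - ref_mean)/ref_sd."""
    if ref_sd <= 0:
        raise ValueError(f"ref_sd must be positive, got {ref_sd}")
    return 50.0 + 10.0 * (np.asarray(x, dtype=float) - ref_mean) / ref_sd


def reverse_wellbeing(score):
    """Reflect a WHO-5 score so that higher means worse: 100 - score."""
    arr = np.asarray(score, dtype=float)
    finite = arr[~np.isnan(arr)]
    if ((finite < 0) | (finite > 100)).any():
        raise ValueError("WHO-5 score outside [0, 100]")
    out = 100.0 - arr
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


def dichotomize_outcome(
    scores: pd.DataFrame,
    rules: CutoffRules | None = None,
    reference_stats: dict | None = None,
    apss_items: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Case indicators for the four outcomes from their (wave-3) total scores.

    Parameters
    ----------
    scores
        Columns ``smfq``, ``anxiety``, ``apss``, ``who5`` (any subset).
    rules
        Cut-off thresholds; defaults to the shipped registry values.
    reference_stats
        For the anxiety T-score: ``{"mean": m, "sd": s}`` or a mapping
        ``{gender_value: {"mean": m, "sd": s}}`` used with a ``gender`` column in
        ``scores`` for gender-specific standardization. Required when ``anxiety``
        is present.
    apss_items
        Optional subjects x items matrix of APSS responses (0 / 0.5 / 1). When
        given, the psychotic case rule is exact: at least
        ``apss_definite_min_items`` items scored 1.0. When absent, the case rule
        falls back to total >= ``apss_definite_min_items`` (a convention: a total
        of 1.0 can also arise from two half-point responses).

    Returns
    -------
    DataFrame with 0/1 columns among ``depression_case``, ``anxiety_case``,
    ``psychotic_case``, ``low_wellbeing_case``, aligned to ``scores.index``.
    """
    rules = rules or CutoffRules()
    out = pd.DataFrame(index=scores.index)

    if "smfq" in scores:
        s = scores["smfq"]
        _check_range(s, 0, 26, "smfq")
        out["depression_case"] = (s >= rules.smfq_case_min).astype(int)

    if "anxiety" in scores:
        if reference_stats is None:
            raise ValueError("anxiety dichotomization requires reference_stats for the T-score")
        s = scores["anxiety"]
        _check_range(s, 0, 28, "anxiety")
        if "mean" in reference_stats:
            t = t_score(s, reference_stats["mean"], reference_stats["sd"])
            t = pd.Series(np.asarray(t), index=scores.index)
        else:
            if "gender" not in scores:
                raise ValueError("gender-specific reference_stats need a 'gender' column")
            t = pd.Series(np.nan, index=scores.index)
            for g, st in reference_stats.items():
                mask = scores["gender"] == g
                t[mask] = t_score(s[mask], st["mean"], st["sd"])
        out["anxiety_case"] = (t >= rules.anxiety_t_min).astype(int)

    if "apss" in scores or apss_items is not None:
        if apss_items is not None:
            n_def = (np.isclose(apss_items.to_numpy(dtype=float), 1.0)).sum(axis=1)
            out["psychotic_case"] = (n_def >= rules.apss_definite_min_items).astype(int)
        else:
            s = scores["apss"]
            _check_range(s, 0, 7, "apss")
            out["psychotic_case"] = (s >= rules.apss_definite_min_items).astype(int)

    if "who5" in scores:
        s = scores["who5"]
        _check_range(s, 0, 100, "who5")
        if rules.who5_strict:
            out["low_wellbeing_case"] = (s < rules.who5_diminished_max).astype(int)
        else:
            out["low_wellbeing_case"] = (s <= rules.who5_diminished_max).astype(int)

    return out


def _check_range(s: pd.Series, lo: float, hi: float, name: str) -> None:
    if s.isna().any():
        raise ValueError(f"{name}: missing scores; impute before dichotomizing")
    if ((s < lo) | (s > hi)).any():
        raise ValueError(f"{name}: score outside [{lo}, {hi}]")


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum of item variances / variance of total).

    ``item_matrix`` is subjects x items with no missing entries; variances are
    computed with ddof=1. Raises if the total score has zero variance (alpha
    undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing values")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
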