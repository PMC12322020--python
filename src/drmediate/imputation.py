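"""Iterative random-forest imputation of missing cells (missForest-style).

Variables are initialized with their observed mean (continuous) or mode
(categorical), then cycled in ascending order of missingness: each variable is
regressed on all others with a random forest trained on its observed rows and
its missing cells are replaced by the forest's predictions.  Iteration stops at
the first rise of the missForest difference statistic (computed separately for
continuous and categorical variables) or after ``max_iterations``, returning
the imputation from the last iteration before the rise.  Observed cells are
never modified; imputed values are snapped to each variable's grid and clipped
to its range when a schema is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .synthetic import VARIABLE_SCHEMA

__all__ = ["ImputationConfig", "rf_impute"]


@dataclass
class ImputationConfig:
    """Settings for the iterative random-forest imputer."""

    max_iterations: int = 10
    n_trees: int = 100
    seed: int = 0
    convergence: float = 0.0  # extra relative-change threshold; 0 = missForest rule only

    def validate(self) -> None:
        if self.max_iterations < 1:
            raise ValueError(f"max_iterations must be >= 1, got {self.max_iterations}")
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.convergence < 0:
            raise ValueError(f"convergence must be >= 0, got {self.convergence}")


def _is_categorical(col: str, values: pd.Series) -> bool:
    if col in VARIABLE_SCHEMA and VARIABLE_SCHEMA[col][0] == "binary":
        return True
    obs = values.dropna().unique()
    return len(obs) <= 2


def _snap(col: str, values: np.ndarray) -> np.ndarray:
    """Clip to the variable's range and round to its grid, when known."""
    if col not in VARIABLE_SCHEMA:
        return values
    _, lo, hi, step = VARIABLE_SCHEMA[col]
    if step is not None:
        values = np.floor(values / step + 0.5) * step
    return np.clip(values, lo, hi)


def rf_impute(
    table: pd.DataFrame,
    config: ImputationConfig | None = None,
    id_columns: tuple[str, ...] = ("subject_id",),
    log: list | None = None,
) -> pd.DataFrame:
    """Return a completed copy of ``table`` with every missing cell imputed.

    ``id_columns`` are carried through untouched and never used as predictors.
    When ``log`` is a list, one dict per iteration with the difference
    statistics and per-variable missing counts is appended to it.
    """
    config = config or ImputationConfig()
    config.validate()

    ids = [c for c in id_columns if c in table.columns]
    work = table.drop(columns=ids).astype(float).copy()
    if work.shape[1] < 2:
        raise ValueError("need at least 2 variables to impute from")

    obs_counts = work.notna().sum()
    empty = obs_counts[obs_counts == 0]
    if len(empty):
        raise ValueError(f"fully-missing column(s): {list(empty.index)}")
    if np.isinf(work.to_numpy()).any():
        bad = [c for c in work.columns if np.isinf(work[c].dropna()).any()]
        raise ValueError(f"non-finite observed values in column(s): {bad}")

    miss_mask = work.isna()
    miss_counts = miss_mask.sum()
    targets = [c for c in miss_counts.sort_values(kind="stable").index if miss_counts[c] > 0]
    if not targets:
        return table.copy()

    cat_cols = {c for c in work.columns if _is_categorical(c, work[c])}

    # initial fill: mean / mode
    filled = work.copy()
    for c in work.columns:
        if miss_counts[c] == 0:
            continue
        obs = work[c].dropna()
        init = obs.mode().iloc[0] if c in cat_cols else obs.mean()
        filled.loc[miss_mask[c], c] = init

    rng = np.random.default_rng(config.seed)
    prev = filled.copy()
    best = filled.copy()
    prev_diff_cont = np.inf
    prev_diff_cat = np.inf

    for it in range(config.max_iterations):
        for c in targets:
            mask = miss_mask[c]
            X = filled.drop(columns=[c])
            y_obs = work.loc[~mask, c]
            seed_i = int(rng.integers(0, 2**31 - 1))
            if c in cat_cols:
                model = RandomForestClassifier(
                    n_estimators=config.n_trees, random_state=seed_i, n_jobs=1
                )
                model.fit(X.loc[~mask], y_obs.astype(int))
                pred = model.predict(X.loc[mask]).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=config.n_trees, random_state=seed_i, n_jobs=1
                )
                model.fit(X.loc[~mask], y_obs)
                pred = _snap(c, model.predict(X.loc[mask]))
            filled.loc[mask, c] = pred

        # missForest difference statistics over imputed cells
        cont = [c for c in targets if c not in cat_cols]
        cat = [c for c in targets if c in cat_cols]
        diff_cont = 0.0
        if cont:
            new = filled[cont].to_numpy()
            old = prev[cont].to_numpy()
            denom = float((new**2).sum())
            diff_cont = float(((new - old) ** 2).sum() / denom) if denom > 0 else 0.0
        diff_cat = 0.0
        n_cat_miss = int(miss_mask[cat].to_numpy().sum()) if cat else 0
        if n_cat_miss:
            changed = sum(
                int((filled.loc[miss_mask[c], c] != prev.loc[miss_mask[c], c]).sum())
                for c in cat
            )
            diff_cat = changed / n_cat_miss

        if log is not None:
            log.append({
                "iteration": it + 1,
                "diff_continuous": diff_cont,
                "diff_categorical": diff_cat,
                "missing_counts": miss_counts[targets].to_dict(),
            })

        rose = (diff_cont > prev_diff_cont) or (diff_cat > prev_diff_cat)
        if it > 0 and rose:
            filled = best  # last iteration before the rise
            break
        converged = (
            it > 0
            and config.convergence > 0
            and diff_cont <= config.convergence
            and diff_cat <= config.convergence
        )
        best = filled.copy()
        prev = filled.copy()
        prev_diff_cont, prev_diff_cat = diff_cont, diff_cat
        if converged:
            break

    out = table.copy()
    for c in targets:
        out.loc[miss_mask[c], c] = filled.loc[miss_mask[c], c]
    # observed cells are untouched by construction
    return out
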