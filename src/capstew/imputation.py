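"""Chained imputation with predictive mean matching (PMM).

Missing covariates are filled variable-by-variable in order of increasing
missingness: each round regresses the target on all other variables with a
pluggable regressor (random forest by default), then replaces each missing
cell with the *observed* value of a donor drawn from the ``k`` observed
rows whose predictions are nearest to the missing row's prediction.
Because donors are observed values, imputations always lie in the observed
support — a binary flag stays binary, a count stays integral.

This is single imputation: downstream variances carry no between-
imputation component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor


@dataclass
class ImputationReport:
    missing_before: dict[str, int]
    missing_after: dict[str, int]
    iterations: int
    converged: bool
    k_donors: int
    seed: int
    regressor: str
    warnings: list[str] = field(default_factory=list)


def _make_regressor(tag: str | Callable, seed: int):
    if callable(tag):
        return tag()
    if tag == "random_forest":
        return RandomForestRegressor(
            n_estimators=50, min_samples_leaf=3, random_state=seed, n_jobs=1
        )
    if tag == "knn":
        return KNeighborsRegressor(n_neighbors=5)
    raise ValueError(f"unknown regressor tag {tag!r}")


def impute_chained_pmm(
    table: pd.DataFrame,
    predictor_model: str | Callable = "random_forest",
    k_donors: int = 5,
    max_iter: int = 10,
    seed: int = 0,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Fill missing numeric cells by chained regression + PMM.

    ``columns`` limits imputation to the named variables (default: every
    numeric column with missing values).  Observed cells are never
    altered; the same seed yields an identical completed table.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    report_warnings: list[str] = []

    if columns is None:
        columns = [
            c
            for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c]) and table[c].isna().any()
        ]
    for c in columns:
        if not pd.api.types.is_numeric_dtype(table[c]):
            raise TypeError(f"column {c!r} is not numeric; encode it before imputing")
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
        frac = table[c].isna().mean()
        if frac >= 0.5:
            msg = f"column {c!r} is {frac:.0%} missing; imputations will be weak"
            warnings.warn(msg)
            report_warnings.append(msg)

    missing_before = {c: int(table[c].isna().sum()) for c in columns}
    predictors = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if not any(table[c].notna().all() for c in predictors):
        raise ValueError("need at least one fully observed numeric variable")
    targets = sorted(
        (c for c in columns if missing_before[c] > 0), key=lambda c: missing_before[c]
    )
    if not targets:
        return out, ImputationReport(
            missing_before=missing_before,
            missing_after=dict(missing_before),
            iterations=0,
            converged=True,
            k_donors=k_donors,
            seed=seed,
            regressor=str(predictor_model),
        )

    masks = {c: table[c].isna().to_numpy() for c in targets}
    # initial fill: observed median, refined by the chained rounds below
    work = out[predictors].astype(float).copy()
    for c in predictors:
        if work[c].isna().any():
            work.loc[work[c].isna(), c] = work[c].median()

    converged = False
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        changed = False
        for c in targets:
            mask = masks[c]
            X = work.drop(columns=c).to_numpy()
            obs_y = table[c].to_numpy(dtype=float)[~mask]
            reg = _make_regressor(predictor_model, int(rng.integers(0, 2**31 - 1)))
            reg.fit(X[~mask], obs_y)
            pred_obs = reg.predict(X[~mask])
            pred_mis = reg.predict(X[mask])
            k = min(k_donors, pred_obs.size)
            new_vals = np.empty(pred_mis.size)
            for i, p in enumerate(pred_mis):
                nearest = np.argpartition(np.abs(pred_obs - p), k - 1)[:k]
                new_vals[i] = obs_y[nearest[rng.integers(0, k)]]
            old_vals = work.loc[mask, c].to_numpy()
            if not np.array_equal(old_vals, new_vals):
                changed = True
            work.loc[mask, c] = new_vals
        if not changed:
            converged = True
            break
    if not converged:
        msg = f"imputation did not stabilize within {max_iter} iterations; last round returned"
        report_warnings.append(msg)

    for c in targets:
        filled = table[c].copy().astype(float)
        filled[masks[c]] = work.loc[masks[c], c]
        out[c] = filled

    missing_after = {c: int(out[c].isna().sum()) for c in columns}
    return out, ImputationReport(
        missing_before=missing_before,
        missing_after=missing_after,
        iterations=iterations,
        converged=converged,
        k_donors=k_donors,
        seed=seed,
        regressor=str(predictor_model),
        warnings=report_warnings,
    )
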