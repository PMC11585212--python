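"""Statistical layer: risk-ratio effect measures for binary adherence outcomes.

The central estimator is *modified Poisson regression*: a log-link Poisson
model applied to a 0/1 outcome with a cluster-robust (sandwich) variance,
which estimates risk ratios directly.  With one observation per cluster and
an independence working correlation this coincides with a Poisson GEE, the
standard approach for adherence analyses where odds ratios would overstate
effects at the high outcome prevalences involved (about 80% non-adherence
for therapy duration).

Also provided: 2x2 risk ratios with Katz log-scale confidence intervals,
Pearson chi-squared and Wilcoxon rank-sum tests, covariate binarization,
population attributable fractions, natural-spline logistic probability
curves, and bootstrap median / Wald proportion differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit

Z95 = float(sps.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# 2x2 tables


@dataclass(frozen=True)
class TwoByTwo:
    """Counts for exposure x outcome: a/b exposed with/without the event,
    c/d unexposed with/without the event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EffectEstimate:
    """A risk ratio with 95% CI on the log (Katz/Wald) scale."""

    rr: float
    ci_low: float
    ci_high: float
    se_log: float
    p_value: float
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


def two_by_two(exposure: Sequence, outcome: Sequence) -> TwoByTwo:
    """Cross-tabulate binary exposure and outcome vectors."""
    e = np.asarray(exposure, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    return TwoByTwo(
        a=int(np.sum(e & y)),
        b=int(np.sum(e & ~y)),
        c=int(np.sum(~e & y)),
        d=int(np.sum(~e & ~y)),
    )


def risk_ratio_2x2(t: TwoByTwo) -> EffectEstimate:
    """Risk ratio with Katz log-method 95% CI and chi-squared p-value.

    RR = [a/(a+b)] / [c/(c+d)];
    CI = exp(ln RR +/- 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
    A zero-risk arm falls back to adding 0.5 to every cell (flagged).
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("both exposure arms need observations")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if t.a == 0 or t.c == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    _, p = pearson_chisq(t)
    return EffectEstimate(
        rr=rr,
        ci_low=rr * np.exp(-Z95 * se),
        ci_high=rr * np.exp(Z95 * se),
        se_log=se,
        p_value=p,
        continuity_corrected=corrected,
    )


def pearson_chisq(t: TwoByTwo, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 table, 1 df, no Yates correction by
    default."""
    table = t.as_array()
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margin in 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(table, correction=continuity)
    return float(stat), float(p)


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Returns the rank-sum statistic W for the first sample and a two-sided
    p-value: exact enumeration when the combined sample size is <= 10 and
    tie-free, otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; rank-sum test uninformative")
        w = x.size * (pooled.size + 1) / 2.0
        return float(w), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)


# ---------------------------------------------------------------------------
# binarization


@dataclass(frozen=True)
class BinarizationRule:
    variable: str
    cutoff: float
    direction: Literal["greater_than", "at_least"] = "greater_than"
    units: str = ""
    provenance: str = "literature"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError(f"non-finite cutoff for {self.variable}")

    def apply(self, values: pd.Series) -> pd.Series:
        if self.direction == "greater_than":
            out = values > self.cutoff
        else:
            out = values >= self.cutoff
        return out.astype("Int64").where(values.notna())


#: Shipped cutoffs for the regression covariates: CRP and NEWS2/PSI/CFS/
#: CRB-65/SOFA from established clinical cutpoints, length of stay at two
#: days from the observed probability pattern.
DEFAULT_BINARIZATION_RULES: tuple[BinarizationRule, ...] = (
    BinarizationRule("crp_max_mg_L", 100.0, "greater_than", "mg/L", "literature"),
    BinarizationRule("length_of_stay_h", 48.0, "greater_than", "h", "pattern-based"),
    BinarizationRule("clinical_frailty_scale", 4.0, "greater_than", "points", "literature"),
    BinarizationRule("crb65_score", 2.0, "greater_than", "points", "literature"),
    BinarizationRule("sofa", 2.0, "at_least", "points", "literature"),
    BinarizationRule("news2", 4.0, "greater_than", "points", "literature"),
    BinarizationRule("psi", 90.0, "greater_than", "points", "literature"),
)


def binarize(
    table: pd.DataFrame,
    rules: Sequence[BinarizationRule] = DEFAULT_BINARIZATION_RULES,
    median_for: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert named numeric columns to 0/1 per their rules.

    Columns in ``median_for`` without an explicit rule are cut at their
    observed median (direction greater-than); a constant column under the
    median rule is an error.  Returns the transformed table and an
    applied-rule report.
    """
    out = table.copy()
    applied = []
    ruled = {r.variable: r for r in rules if r.variable in table.columns}
    for name in median_for:
        if name in ruled:
            continue
        values = table[name]
        cutoff = float(values.median())
        if values.dropna().nunique() <= 1:
            raise ValueError(f"variable {name!r} is constant; median rule undefined")
        ruled[name] = BinarizationRule(name, cutoff, "greater_than", "", "median")
    for name, rule in ruled.items():
        out[name] = rule.apply(table[name])
        applied.append(
            {
                "variable": name,
                "cutoff": rule.cutoff,
                "direction": rule.direction,
                "units": rule.units,
                "provenance": rule.provenance,
            }
        )
    return out, pd.DataFrame(applied)


# ---------------------------------------------------------------------------
# modified Poisson regression


@dataclass
class RegressionResult:
    """Exponentiated coefficients (risk ratios) with robust Wald CIs."""

    estimates: dict[str, EffectEstimate]
    n_obs: int
    converged: bool
    iterations: int
    covariance_type: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": term,
                "rr": e.rr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "se_log": e.se_log,
                "p": e.p_value,
            }
            for term, e in self.estimates.items()
        ]
        return pd.DataFrame(rows)


class SeparationError(RuntimeError):
    pass


def modified_poisson(
    y: Sequence[int],
    X: pd.DataFrame,
    cluster_ids: Sequence | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
) -> RegressionResult:
    """Fit a log-link Poisson model to a binary outcome with sandwich SEs.

    Coefficients are estimated by IRLS; the variance is the cluster-robust
    sandwich estimator (one cluster per patient by default, i.e. a Poisson
    GEE with independence working correlation).  Exponentiated coefficients
    are risk ratios; on a saturated 2x2 layout the single-covariate RR
    equals the direct 2x2 estimate exactly.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X = pd.DataFrame(X).astype(float)
    if add_intercept and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if cluster_ids is None:
        cluster_ids = np.arange(len(y))
    groups = pd.factorize(np.asarray(cluster_ids))[0]
    model = sm.GLM(y, X, family=sm.families.Poisson())
    fit = model.fit(
        maxiter=max_iter, cov_type="cluster", cov_kwds={"groups": groups}
    )
    converged = bool(getattr(fit, "converged", True))
    if np.any(np.abs(fit.params.to_numpy()) > 15):
        bad = X.columns[np.argmax(np.abs(fit.params.to_numpy()))]
        raise SeparationError(f"separation suspected on column {bad!r}")
    estimates = {}
    for term in X.columns:
        b = float(fit.params[term])
        se = float(fit.bse[term])
        z = b / se if se > 0 else np.inf
        estimates[term] = EffectEstimate(
            rr=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * se)),
            ci_high=float(np.exp(b + Z95 * se)),
            se_log=se,
            p_value=float(2 * sps.norm.sf(abs(z))),
        )
    return RegressionResult(
        estimates=estimates,
        n_obs=int(len(y)),
        converged=converged,
        iterations=int(getattr(fit, "fit_history", {}).get("iteration", max_iter)),
        covariance_type="cluster-robust sandwich",
    )


# ---------------------------------------------------------------------------
# population attributable fraction


@dataclass(frozen=True)
class PAFEstimate:
    paf: float
    ci_low: float | None
    ci_high: float | None
    method: str
    n_boot: int

    def __post_init__(self) -> None:
        if self.paf > 1:
            raise ValueError("PAF cannot exceed 1")
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("CI bounds out of order")

    @property
    def protective(self) -> bool:
        return self.paf < 0


def paf(
    rr_adjusted: float,
    exposed_fraction_among_cases: float,
    resample_source: Callable[[np.random.Generator], tuple[float, float]] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> PAFEstimate:
    """Population attributable fraction by the case-load (Miettinen)
    formula PAF = p_c * (RR - 1) / RR, with p_c the exposure prevalence
    among cases and RR the adjusted risk ratio.

    ``resample_source``, when given, is called once per bootstrap
    replicate and must return a freshly re-estimated (RR, p_c) pair from a
    resampled dataset; the CI is the percentile interval of the replicate
    PAFs.  A RR below 1 yields a negative PAF (protective exposure).
    """
    if rr_adjusted <= 0:
        raise ValueError("rr_adjusted must be > 0")
    if not 0 <= exposed_fraction_among_cases <= 1:
        raise ValueError("exposed_fraction_among_cases must be in [0, 1]")
    point = exposed_fraction_among_cases * (rr_adjusted - 1.0) / rr_adjusted
    ci_low = ci_high = None
    used_boot = 0
    if resample_source is not None:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            try:
                rr_b, pc_b = resample_source(rng)
            except (ValueError, ArithmeticError, RuntimeError):
                # degenerate resample (empty cell, separation); drop it
                continue
            reps.append(pc_b * (rr_b - 1.0) / rr_b)
        if len(reps) < max(100, n_boot // 2):
            raise RuntimeError(
                f"only {len(reps)}/{n_boot} bootstrap replicates usable"
            )
        ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
        ci_low, ci_high = float(ci_low), float(ci_high)
        used_boot = len(reps)
    return PAFEstimate(
        paf=float(point),
        ci_low=ci_low,
        ci_high=ci_high,
        method="miettinen_case_load",
        n_boot=used_boot,
    )


def paf_bootstrap_source(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str],
) -> Callable[[np.random.Generator], tuple[float, float]]:
    """Full-pipeline resampler for :func:`paf`: each call resamples the
    rows with replacement, refits the modified Poisson model and
    recomputes the exposure prevalence among cases."""

    cols = [exposure, *covariates]

    def source(rng: np.random.Generator) -> tuple[float, float]:
        idx = rng.integers(0, len(data), size=len(data))
        boot = data.iloc[idx]
        fit = modified_poisson(boot[outcome].to_numpy(), boot[cols])
        cases = boot[boot[outcome] == 1]
        p_c = float(cases[exposure].mean()) if len(cases) else 0.0
        return fit.estimates[exposure].rr, p_c

    return source


# ---------------------------------------------------------------------------
# natural-spline logistic curves


@dataclass
class SplineCurve:
    """Fitted probability curve over a grid with pointwise Wald CI."""

    grid: np.ndarray
    probability: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    df: int
    quasi_separation: bool
    params: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid,
                "probability": self.probability,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def spline_logistic_curve(
    x: Sequence[float],
    y: Sequence[int],
    df: int = 4,
    grid: Sequence[float] | None = None,
    n_grid: int = 100,
    alpha: float = 0.05,
) -> SplineCurve:
    """Logistic regression of a binary outcome on a natural cubic spline
    of one continuous predictor.

    Internal knots sit at equally spaced quantiles of ``x`` with boundary
    knots at the data range (patsy's ``cr`` basis); the fit is IRLS via a
    binomial GLM.  Returns probability and pointwise Wald CI over a grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 50:
        raise ValueError("spline fit needs at least 50 observations")
    if df < 2:
        raise ValueError("df must be >= 2")
    if df >= np.unique(x).size:
        raise ValueError("df must be below the number of unique x values")
    design = patsy.dmatrix("cr(x, df=df)", {"x": x, "df": df}, return_type="dataframe")
    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    mu = fit.fittedvalues
    quasi_sep = bool(
        np.any(np.abs(fit.params) > 15) or np.all((mu < 1e-6) | (mu > 1 - 1e-6))
    )
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    (grid_design,) = patsy.build_design_matrices(
        [design.design_info], {"x": grid, "df": df}
    )
    gd = np.asarray(grid_design)
    eta = gd @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", gd, fit.cov_params().to_numpy(), gd))
    zcrit = float(sps.norm.ppf(1 - alpha / 2))
    return SplineCurve(
        grid=grid,
        probability=expit(eta),
        ci_low=expit(eta - zcrit * se),
        ci_high=expit(eta + zcrit * se),
        df=df,
        quasi_separation=quasi_sep,
        params=fit.params.to_numpy(),
    )


# ---------------------------------------------------------------------------
# medians and proportions


def median_difference(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Difference of sample medians with a seeded bootstrap percentile CI
    and a permutation p-value (label shuffling)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    observed = float(np.median(x) - np.median(y))
    reps = np.empty(n_boot)
    for i in range(n_boot):
        bx = x[rng.integers(0, x.size, x.size)]
        by = y[rng.integers(0, y.size, y.size)]
        reps[i] = np.median(bx) - np.median(by)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    pooled = np.concatenate([x, y])
    count = 0
    for _ in range(n_boot):
        perm = rng.permutation(pooled)
        diff = np.median(perm[: x.size]) - np.median(perm[x.size :])
        if abs(diff) >= abs(observed) - 1e-12:
            count += 1
    p = (count + 1) / (n_boot + 1)
    return {
        "difference": observed,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_value": float(p),
        "n_boot": n_boot,
        "seed": seed,
    }


def proportion_difference(
    t1: tuple[int, int], t2: tuple[int, int]
) -> dict:
    """Difference of two proportions (count/total pairs) with a Wald 95%
    CI: p1 - p2 +/- 1.96 * sqrt(p1 q1 / n1 + p2 q2 / n2)."""
    (k1, n1), (k2, n2) = t1, t2
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    p1, p2 = k1 / n1, k2 / n2
    diff = p1 - p2
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return {
        "difference": float(diff),
        "ci_low": float(diff - Z95 * se),
        "ci_high": float(diff + Z95 * se),
        "se": float(se),
    }
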