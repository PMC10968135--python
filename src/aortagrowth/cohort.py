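"""Cohort statistics for the growth / no-growth comparison.

The battery mirrors standard practice in small clinical CFD cohorts:

* continuous variables are gated per group by the Shapiro–Wilk normality
  test at alpha = 0.05 — both groups normal gives an unpaired two-sample
  Student t test (mean +/- SD reported), otherwise Mann–Whitney U
  (median [IQR] reported);
* categorical variables use Fisher's exact test when any expected cell of a
  2x2 table is below 5, chi-square otherwise;
* Spearman rank correlation (average ranks for ties) for ordinal
  association;
* growth prediction by univariate logistic regression on *annualized*
  predictors — the baseline stress metric multiplied by the inter-exam
  interval in years — reported as odds ratio with Wald 95 % CI;
* optional bidirectional stepwise (AIC) multivariate selection.

Missing values are dropped per variable and every result records the n
actually used, since intersection-region metrics are genuinely missing for
patients without a high-pressure/high-shear overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupComparison",
    "LogisticResult",
    "compare_continuous",
    "compare_categorical",
    "spearman",
    "univariate_logistic_annualized",
    "stepwise_multivariate",
    "summarize_cohort",
    "load_cohort",
    "save_cohort",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str                      # "t" | "mann_whitney" | "chi_square" | "fisher"
    p_value: float
    n_per_group: tuple
    center: tuple = ()             # mean or median per group
    spread: tuple = ()             # SD or (q1, q3) per group
    shapiro_p: tuple = ()          # the gate inputs, recorded for audit
    def as_dict(self) -> dict:
        return {"variable": self.variable, "test": self.test,
                "p_value": self.p_value, "n_per_group": list(self.n_per_group),
                "center": list(self.center), "spread": list(self.spread),
                "shapiro_p": list(self.shapiro_p)}


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    return values[~groups], values[groups]


def compare_continuous(values, groups, variable: str = "",
                       alpha: float = ALPHA) -> GroupComparison:
    """Normality-gated two-group comparison of a continuous variable.

    ``groups`` is a boolean growth label aligned with ``values``; missing
    values (NaN) are dropped pairwise.  The Shapiro–Wilk p values that drove
    the test choice are recorded in the result.
    """
    g0, g1 = _split_groups(values, groups)
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError(f"variable '{variable}': a group is empty after "
                         "dropping missing values")
    if min(len(g0), len(g1)) < 3:
        raise ValueError(f"variable '{variable}': need >= 3 values per group "
                         "for the normality gate")
    sw0 = sps.shapiro(g0).pvalue
    sw1 = sps.shapiro(g1).pvalue
    normal = sw0 > alpha and sw1 > alpha
    if normal:
        p = sps.ttest_ind(g0, g1, equal_var=True).pvalue
        center = (float(np.mean(g0)), float(np.mean(g1)))
        spread = (float(np.std(g0, ddof=1)), float(np.std(g1, ddof=1)))
        test = "t"
    else:
        p = sps.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
        center = (float(np.median(g0)), float(np.median(g1)))
        spread = (tuple(np.percentile(g0, [25, 75])),
                  tuple(np.percentile(g1, [25, 75])))
        test = "mann_whitney"
    return GroupComparison(variable, test, float(p), (len(g0), len(g1)),
                           center, spread, (float(sw0), float(sw1)))


def compare_categorical(counts, variable: str = "") -> GroupComparison:
    """Association test on a 2 x k contingency table.

    Fisher's exact test when the table is 2x2 and any expected cell is below
    5; Pearson chi-square otherwise.  Two-tailed p.
    """
    table = np.asarray(counts)
    if table.ndim != 2 or np.any(table < 0) or not np.issubdtype(
            table.dtype, np.integer):
        raise ValueError("counts must be a non-negative integer table")
    if table.sum() == 0:
        raise ValueError(f"variable '{variable}': all-zero table")
    expected = (table.sum(axis=1, keepdims=True)
                * table.sum(axis=0, keepdims=True) / table.sum())
    if table.shape == (2, 2) and expected.min() < 5:
        p = sps.fisher_exact(table, alternative="two-sided")[1]
        test = "fisher"
    else:
        p = sps.chi2_contingency(table, correction=False)[1]
        test = "chi_square"
    return GroupComparison(variable, test, float(p),
                           tuple(int(x) for x in table.sum(axis=1)))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise ValueError("rank correlation undefined: zero rank variance")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class LogisticResult:
    predictor: str
    odds_ratio: Optional[float]
    ci95: tuple
    p_value: Optional[float]
    n_used: int
    separated: bool = False
    coef: Optional[float] = None
    ci_type: str = "wald"

    def as_dict(self) -> dict:
        return {"predictor": self.predictor, "odds_ratio": self.odds_ratio,
                "ci95": list(self.ci95), "p_value": self.p_value,
                "n_used": self.n_used, "separated": self.separated,
                "ci_type": self.ci_type}


def _fit_logit(x: np.ndarray, y: np.ndarray, name: str,
               ci: str = "wald") -> LogisticResult:
    exog = sm.add_constant(x.reshape(-1, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y.astype(float), exog).fit(disp=False, maxiter=200)
        except Exception:
            return LogisticResult(name, None, (None, None), None, len(y),
                                  separated=True)
    beta = fit.params[1]
    se = fit.bse[1]
    # perfect/quasi separation: the per-SD log-odds or its SE diverges
    x_sd = max(float(np.std(x)), 1e-300)
    if not np.isfinite(beta) or not np.isfinite(se) \
            or abs(beta) * x_sd > 25.0 or se * x_sd > 25.0:
        return LogisticResult(name, None, (None, None), None, len(y),
                              separated=True)
    if ci == "profile":
        lo, hi = _profile_ci(fit, x, y)
    else:
        z = sps.norm.ppf(0.975)
        lo, hi = beta - z * se, beta + z * se
    p = 2.0 * sps.norm.sf(abs(beta / se))
    return LogisticResult(name, float(np.exp(beta)),
                          (float(np.exp(lo)), float(np.exp(hi))),
                          float(p), len(y), coef=float(beta), ci_type=ci)


def _profile_ci(fit, x, y, alpha: float = ALPHA) -> tuple[float, float]:
    """Profile-likelihood CI for the slope via bisection on the deviance."""
    from scipy.optimize import brentq
    beta, se = fit.params[1], fit.bse[1]
    ll_max = fit.llf
    crit = sps.chi2.ppf(1 - alpha, 1) / 2.0

    def prof(b):
        offset = b * x
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sm.GLM(y.astype(float), np.ones((len(y), 1)),
                       family=sm.families.Binomial(), offset=offset).fit()
        return m.llf - (ll_max - crit)

    lo, hi = beta, beta
    try:
        lo = brentq(prof, beta - 10 * se, beta)
        hi = brentq(prof, beta, beta + 10 * se)
    except ValueError:
        pass
    return lo, hi


def univariate_logistic_annualized(metric, dt_years, outcome,
                                   predictor: str = "",
                                   ci: str = "wald") -> LogisticResult:
    """Logistic regression of growth on an annualized stress predictor.

    Fits ``logit P(growth) = b0 + b1 * metric * dt``; rows with a missing
    metric are dropped and the n used is recorded.  OR = exp(b1) with a Wald
    95 % CI by default (``ci="profile"`` for profile likelihood).
    """
    metric = np.asarray(pd.to_numeric(pd.Series(metric), errors="coerce"),
                        dtype=float)
    dt = np.asarray(dt_years, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    keep = np.isfinite(metric) & np.isfinite(dt)
    metric, dt, y = metric[keep], dt[keep], y[keep]
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    x = metric * dt
    if np.ptp(x) == 0:
        return LogisticResult(predictor, None, (None, None), None, len(y),
                              separated=True)
    return _fit_logit(x, y, predictor, ci=ci)


def stepwise_multivariate(table: pd.DataFrame, candidates: Sequence[str],
                          outcome: str = "growth"
                          ) -> tuple[list[str], list[LogisticResult]]:
    """Bidirectional stepwise logistic selection on AIC from the null model.

    At each round the single add-or-drop move with the largest AIC decrease
    is taken (ties broken by candidate order); candidates whose fit fails or
    separates are skipped with a warning.  Returns the selected variables and
    their per-variable Wald results in the final model.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    df = table[[outcome, *candidates]].dropna()
    if len(df) < 10:
        raise ValueError("need n >= 10 complete rows for stepwise selection")
    y = df[outcome].astype(float).to_numpy()

    def fit_aic(cols):
        exog = sm.add_constant(df[list(cols)].to_numpy(dtype=float)) \
            if cols else np.ones((len(df), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, exog).fit(disp=False, maxiter=200)
        if not np.all(np.isfinite(fit.bse)):
            raise FloatingPointError("unstable fit")
        return fit.aic

    selected: list[str] = []
    current = fit_aic(selected)
    while True:
        moves = []
        for c in candidates:
            cols = ([*selected, c] if c not in selected
                    else [s for s in selected if s != c])
            try:
                moves.append((fit_aic(cols), cols))
            except Exception:
                warnings.warn(f"candidate '{c}' skipped (unstable or "
                              "separated fit)", stacklevel=2)
        best = min(moves, key=lambda m: m[0], default=None)
        if best is None or best[0] >= current - 1e-9:
            break
        current, selected = best[0], best[1]

    results = []
    if selected:
        exog = sm.add_constant(df[selected].to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, exog).fit(disp=False, maxiter=200)
        z = sps.norm.ppf(0.975)
        for i, name in enumerate(selected, start=1):
            beta, se = fit.params[i], fit.bse[i]
            results.append(LogisticResult(
                name, float(np.exp(beta)),
                (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
                float(2 * sps.norm.sf(abs(beta / se))), len(df),
                coef=float(beta)))
    return selected, results


# -- cohort-level reporting -------------------------------------------------

METRIC_COLUMNS = (
    "P100_mean", "P_max", "tau5_mean", "tau7_mean", "tau5_max", "tau7_max",
    "tau5_100_mean", "tau7_100_mean", "tau5_100_max", "tau7_100_max",
)

DEFAULT_ANNUALIZED = ("P100_mean", "P_max", "tau7_100_mean", "tau7_100_max")


def summarize_cohort(table: pd.DataFrame,
                     annualize: Sequence[str] = DEFAULT_ANNUALIZED,
                     covariates: Sequence[str] = ()) -> dict:
    """Descriptive and inferential summary of a growth cohort.

    Expects one row per patient with at least ``growth`` (bool),
    ``dt_years``, ``v1_cm3``, ``v2_cm3``; uses metric columns and optional
    diameter columns (``d1_mm``, ``d2_mm``) when present.  Returns a nested
    dict with volume/diameter summaries, per-metric group comparisons
    (per-metric n), and annualized univariate logistic results.
    """
    growth = table["growth"].astype(bool).to_numpy()
    out: dict = {"n_total": int(len(table)),
                 "n_growth": int(growth.sum()),
                 "n_no_growth": int((~growth).sum())}

    pct = 100.0 * (table["v2_cm3"] - table["v1_cm3"]) / table["v1_cm3"]
    vol: dict = {"pct_change_mean_by_group": (
        float(pct[~growth].mean()) if (~growth).any() else None,
        float(pct[growth].mean()) if growth.any() else None),
        "n_grew": int((pct >= 5.0).sum())}
    if "d1_mm" in table and "d2_mm" in table:
        d_change = (table["d2_mm"] - table["d1_mm"]).to_numpy(dtype=float)
        if np.isfinite(d_change).sum() >= 3:
            try:
                rho, p = spearman(d_change, pct.to_numpy(dtype=float))
                vol["spearman_diameter_vs_volume_change"] = {"rho": rho,
                                                             "p": p}
            except ValueError:  # zero rank variance (e.g. static cohort)
                vol["spearman_diameter_vs_volume_change"] = None
    out["volumes"] = vol

    single_class = not (growth.any() and (~growth).any())
    if single_class:
        out["notice"] = ("single-outcome cohort: group comparisons and "
                         "regression skipped")
        return out

    comparisons = {}
    for col in (*covariates, *METRIC_COLUMNS):
        if col not in table:
            continue
        vals = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        if np.isfinite(vals[growth]).sum() < 3 or \
                np.isfinite(vals[~growth]).sum() < 3:
            continue
        comparisons[col] = compare_continuous(vals, growth, variable=col
                                              ).as_dict()
    out["group_comparisons"] = comparisons

    logit = {}
    for col in annualize:
        if col not in table:
            continue
        try:
            res = univariate_logistic_annualized(
                table[col], table["dt_years"], growth, predictor=col)
        except ValueError:
            continue
        logit[col] = res.as_dict()
    out["annualized_logistic"] = logit
    return out


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (missing metrics as empty cells)."""
    df = pd.read_csv(path)
    if "growth" in df:
        df["growth"] = df["growth"].astype(bool)
    return df


def save_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
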