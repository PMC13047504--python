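"""Cohort-level inference on per-subject, per-region coupling metrics.

The statistical plan: (i) multiple linear regression of each coupling
metric on age with sex as a covariate, metric = b0 + b1*age + b2*sex;
(ii) a quadratic-age check (centered age squared added to the linear model)
with a keep/drop decision after FDR across regions; (iii) Pearson
correlations of the coupling metrics with age and with the iron surrogate
R2_b=0, corrected as a single Benjamini-Hochberg family per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ModelFit", "CorrelationResult", "fit_linear_model", "test_quadratic_age",
    "pearson_correlation", "adjust_fdr", "cohort_statistics", "CohortStatistics",
    "METRICS",
]

METRICS = ("k_adc_te", "k_r2_b")


@dataclass(frozen=True)
class ModelFit:
    """OLS fit summary: coefficient arrays are ordered like ``names``."""

    names: tuple
    coef: np.ndarray
    stderr: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    resid_var: float
    n: int
    #: zero residual variance: coefficient t-tests are not meaningful
    degenerate: bool = False

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {"coef": self.coef[i], "stderr": self.stderr[i],
                "t": self.tvalues[i], "p": self.pvalues[i]}


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p and (optionally) FDR q."""

    r: float
    p: float
    n: int
    q: float | None = None


def _check_design(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a column whose removal does not reduce the rank
        for i, name in enumerate(names):
            reduced = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"design matrix is rank deficient: column "
                                 f"'{name}' is collinear with the others")
        raise ValueError("design matrix is rank deficient")


def _ols(y, X: np.ndarray, names: tuple) -> ModelFit:
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _check_design(X, names)
    fit = sm.OLS(y, X).fit()
    scale = max(1.0, float(np.mean(y ** 2)))
    degenerate = fit.df_resid <= 0 or fit.ssr <= np.finfo(float).eps * n * scale
    return ModelFit(
        names=names,
        coef=np.asarray(fit.params),
        stderr=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        resid_var=float(fit.mse_resid),
        n=int(n),
        degenerate=bool(degenerate),
    )


def fit_linear_model(y, age, sex) -> ModelFit:
    """OLS of a coupling metric on age (years, uncentered) and sex (0/1)."""
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    X = sm.add_constant(np.column_stack([age, sex]), has_constant="add")
    return _ols(y, X, ("const", "age", "sex"))


def test_quadratic_age(y, age, sex) -> ModelFit:
    """Linear model augmented with a centered-and-squared age term.

    Age is centered before squaring to limit collinearity with the linear
    term.  The caller collects the ``age2`` p-values across regions and
    applies FDR before the keep/drop decision (see ``cohort_statistics``).
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    ac = age - age.mean()
    X = sm.add_constant(np.column_stack([ac, ac ** 2, sex]), has_constant="add")
    return _ols(y, X, ("const", "age", "age2", "sex"))


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-test p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, where p_(1) <= ... <=
    p_(m) are the sorted p-values.  Implemented directly from the step-up
    definition (cross-checked against statsmodels in the test suite).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _fdr_with_missing(p: np.ndarray) -> np.ndarray:
    """BH over the available entries; NaN p-values stay NaN."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = adjust_fdr(p[ok])
    return q


# ---------------------------------------------------------------------------
# full cohort analysis

@dataclass
class CohortStatistics:
    """All inference tables for one cohort run.

    ``correlations``: one row per (region, metric-pair) with r, p and the
    family-wise BH q (single family across every correlation in the run).
    ``linear_models`` / ``quadratic``: per region x metric coefficient
    summaries; ``quadratic`` carries the FDR-corrected age^2 q and the
    keep/drop decision.
    """

    correlations: pd.DataFrame
    linear_models: pd.DataFrame
    quadratic: pd.DataFrame
    alpha: float
    n_dropped: int = 0


def cohort_statistics(table: pd.DataFrame, alpha: float = 0.05) -> CohortStatistics:
    """Run the full statistical plan on a cohort metrics table.

    ``table`` columns: subject_id, age, sex, region, k_adc_te, k_r2_b,
    r2_b0.  Rows with any missing metric are dropped (complete-case
    analysis, count reported).
    """
    required = {"subject_id", "age", "sex", "region", "k_adc_te", "k_r2_b", "r2_b0"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    n_before = len(table)
    table = table.dropna(subset=["k_adc_te", "k_r2_b", "r2_b0"])
    n_dropped = n_before - len(table)

    regions = list(dict.fromkeys(table["region"]))
    corr_rows, lin_rows, quad_rows = [], [], []
    for region in regions:
        d = table[table["region"] == region]
        for metric in METRICS:
            for other, other_col in (("age", "age"), ("r2_b0", "r2_b0")):
                c = pearson_correlation(d[metric], d[other_col])
                corr_rows.append({"region": region, "x": metric, "y": other,
                                  "r": c.r, "p": c.p, "n": c.n})
            lin_row = {"region": region, "metric": metric, "n": len(d)}
            try:
                lin = fit_linear_model(d[metric], d["age"], d["sex"])
                lin_row.update({"beta_const": lin["const"]["coef"],
                                "beta_age": lin["age"]["coef"], "p_age": lin["age"]["p"],
                                "beta_sex": lin["sex"]["coef"], "p_sex": lin["sex"]["p"]})
            except ValueError:
                # too few rows for the covariate model; correlations still stand
                lin_row.update({"beta_const": np.nan, "beta_age": np.nan,
                                "p_age": np.nan, "beta_sex": np.nan, "p_sex": np.nan})
            lin_rows.append(lin_row)
            quad_row = {"region": region, "metric": metric, "n": len(d)}
            try:
                quad = test_quadratic_age(d[metric], d["age"], d["sex"])
                quad_row.update({"beta_age2": quad["age2"]["coef"],
                                 "p_age2": quad["age2"]["p"]})
            except ValueError:
                quad_row.update({"beta_age2": np.nan, "p_age2": np.nan})
            quad_rows.append(quad_row)
        c = pearson_correlation(d["r2_b0"], d["age"])
        corr_rows.append({"region": region, "x": "r2_b0", "y": "age",
                          "r": c.r, "p": c.p, "n": c.n})

    correlations = pd.DataFrame(corr_rows)
    correlations["q"] = adjust_fdr(correlations["p"].to_numpy())
    quadratic = pd.DataFrame(quad_rows)
    quadratic["q_age2"] = _fdr_with_missing(quadratic["p_age2"].to_numpy())
    quadratic["keep_quadratic"] = quadratic["q_age2"] < alpha
    return CohortStatistics(correlations, pd.DataFrame(lin_rows), quadratic,
                            alpha, n_dropped)
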