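"""Cohort-level statistics for the apathy / small-vessel-disease analysis.

Covers the neuropsychiatric group assignment from AES and CESD cut scores,
Holm-corrected bivariate correlations, standardized mediation path analysis
(total effect beta vs direct effect beta-prime after conditioning on the
mediator), standardized multiple regression, type-II ANCOVA with Tukey HSD
or Fisher (unadjusted) post hocs, contingency chi-square with pairwise odds
ratios, and the log1p transform applied to skewed lesion measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GROUPS",
    "MediationResult",
    "assign_group",
    "holm_adjust",
    "correlate",
    "mediation_path",
    "multiple_regression_standardized",
    "ancova_type2",
    "posthoc_tukey",
    "group_contingency",
    "log_transform",
]

GROUPS = ("apathy", "depression", "comorbid", "control")

AES_CUT = 34  # apathy present if AES >= 34
CESD_CUT = 16  # depressive symptoms present if CESD >= 16


def assign_group(aes: float, cesd: float) -> str:
    """Neuropsychiatric group from AES and CESD cut scores (both inclusive >=)."""
    apathetic = aes >= AES_CUT
    depressed = cesd >= CESD_CUT
    if apathetic and depressed:
        return "comorbid"
    if apathetic:
        return "apathy"
    if depressed:
        return "depression"
    return "control"


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-down Holm-adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def log_transform(values: Sequence[float], kind: str = "wmh") -> np.ndarray:
    """log(1 + x) for skewed non-negative lesion measures (WMH volume, LI counts)."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{kind} values must be non-negative")
    return np.log1p(x)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable")
    return (x - x.mean()) / sd


def correlate(
    table: pd.DataFrame, target: str, columns: Sequence[str]
) -> pd.DataFrame:
    """Pearson correlations of ``target`` with each column, with Holm adjustment.

    Zero-variance columns get NaN and are excluded from the adjustment.
    """
    rows = []
    for col in columns:
        x = np.asarray(table[col], dtype=float)
        if x.std() == 0 or np.asarray(table[target], dtype=float).std() == 0:
            rows.append({"variable": col, "r": np.nan, "p": np.nan})
        else:
            r, p = sps.pearsonr(table[target], x)
            rows.append({"variable": col, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    finite = out["p"].notna()
    if finite.any():
        out.loc[finite, "p_holm"] = holm_adjust(out.loc[finite, "p"].to_numpy())
    return out


@dataclass
class MediationResult:
    """Total vs direct standardized effects of X on Y around mediator(s) M."""

    beta_total: float
    beta_direct: float
    indirect: float
    p_total: float
    p_direct: float
    a: Union[float, np.ndarray] = 0.0  # X -> M path(s)
    b: Union[float, np.ndarray] = 0.0  # M -> Y | X path(s)


def _standardized_ols(y: np.ndarray, X_cols: list) -> sm.regression.linear_model.RegressionResultsWrapper:
    Z = np.column_stack([_zscore(c) for c in X_cols])
    return sm.OLS(_zscore(y), sm.add_constant(Z)).fit()


def mediation_path(
    x: Sequence[float],
    m: Union[Sequence[float], Sequence[Sequence[float]]],
    y: Sequence[float],
    covariates: Optional[Sequence[Sequence[float]]] = None,
) -> MediationResult:
    """Sequential standardized OLS path analysis.

    ``beta_total`` is the coefficient of X in y ~ x (+ covariates);
    ``beta_direct`` the coefficient of X in y ~ x + m (+ covariates). For a
    single mediator without covariates, beta_total = beta_direct + a*b is an
    exact path-algebra identity. ``m`` may be a single vector or a sequence
    of mediator vectors entered simultaneously.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m_arr = np.asarray(m, dtype=float)
    mediators = [m_arr] if m_arr.ndim == 1 else [np.asarray(col) for col in m_arr]
    covs = [np.asarray(c, dtype=float) for c in (covariates or [])]
    if len(x) <= 1 + len(mediators) + len(covs) + 2:
        raise ValueError("too few observations for the path model")

    fit_total = _standardized_ols(y, [x] + covs)
    fit_direct = _standardized_ols(y, [x] + mediators + covs)
    a = np.array(
        [_standardized_ols(mk, [x] + covs).params[1] for mk in mediators]
    )
    b = np.asarray(fit_direct.params[2 : 2 + len(mediators)])
    indirect = float(a @ b)
    single = len(mediators) == 1
    return MediationResult(
        beta_total=float(fit_total.params[1]),
        beta_direct=float(fit_direct.params[1]),
        indirect=indirect,
        p_total=float(fit_total.pvalues[1]),
        p_direct=float(fit_direct.pvalues[1]),
        a=float(a[0]) if single else a,
        b=float(b[0]) if single else b,
    )


def multiple_regression_standardized(
    y: Sequence[float], predictors: dict
) -> pd.DataFrame:
    """Standardized multiple OLS; one row per predictor with beta and p."""
    names = list(predictors)
    fit = _standardized_ols(np.asarray(y, dtype=float),
                            [np.asarray(predictors[k], dtype=float) for k in names])
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("collinear predictors")
    return pd.DataFrame(
        {"predictor": names,
         "beta": fit.params[1:],
         "p": fit.pvalues[1:]}
    )


def ancova_type2(
    outcome: Sequence[float],
    group: Sequence[str],
    covariates: Optional[dict] = None,
) -> pd.DataFrame:
    """One-way ANCOVA with type II sums of squares.

    Type II tests each term against the model containing all other terms
    (no interactions), which is the appropriate decomposition for the
    unbalanced group sizes of observational cohorts. Returns one row per
    term with sum_sq, df, F and p.
    """
    covariates = covariates or {}
    group = pd.Series(group)
    if group.value_counts().min() < 1 or group.nunique() < 2:
        raise ValueError("each group level needs observations")
    data = pd.DataFrame({"outcome": np.asarray(outcome, dtype=float), "group": group.values})
    terms = []
    for k, v in covariates.items():
        data[k] = np.asarray(v, dtype=float)
        terms.append(k)
    formula = "outcome ~ C(group)" + "".join(f" + {t}" for t in terms)
    fit = ols(formula, data=data).fit()
    tab = anova_lm(fit, typ=2)
    tab = tab.rename(index={"C(group)": "group"})
    tab.index.name = "term"
    return tab.reset_index().rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p"})


def posthoc_tukey(
    outcome: Sequence[float],
    group: Sequence[str],
    covariates: Optional[dict] = None,
    method: str = "tukey",
) -> pd.DataFrame:
    """Pairwise comparisons of covariate-adjusted group means.

    ``method='tukey'`` uses the studentized-range (honest significant
    difference) adjustment; ``method='fisher'`` returns unadjusted pairwise
    t-tests on the same adjusted means (Fisher's protected LSD).
    """
    covariates = covariates or {}
    group = pd.Series(group).astype(str)
    levels = sorted(group.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    # Design: group indicators (cell means coding) + centred covariates, so
    # each group coefficient is the covariate-adjusted group mean.
    G = np.column_stack([(group == lev).astype(float) for lev in levels])
    X = G
    for v in covariates.values():
        v = np.asarray(v, dtype=float)
        X = np.column_stack([X, v - v.mean()])
    fit = sm.OLS(y, X).fit()
    cov = fit.cov_params()
    df_resid = n - X.shape[1]
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(X.shape[1])
            c[i], c[j] = 1.0, -1.0
            diff = float(c @ fit.params)
            se = float(np.sqrt(c @ cov @ c))
            if method == "tukey":
                q = abs(diff) / (se / np.sqrt(2.0))
                p = float(sps.studentized_range.sf(q, k, df_resid))
            elif method == "fisher":
                p = float(2 * sps.t.sf(abs(diff) / se, df_resid))
            else:
                raise ValueError("method must be 'tukey' or 'fisher'")
            rows.append({"group1": levels[i], "group2": levels[j],
                         "diff": diff, "se": se, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


@dataclass
class ContingencyResult:
    chi2: float
    p: float
    dof: int
    odds_ratios: pd.DataFrame = field(default_factory=pd.DataFrame)


def group_contingency(
    table: pd.DataFrame, pairs: Optional[Sequence[tuple]] = None
) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) plus pairwise odds ratios.

    ``table`` is groups x 2 categories of non-negative integer counts. For
    each named pair of groups a 2x2 odds ratio with a Wald p-value is
    computed.
    """
    counts = table.to_numpy(dtype=float)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    rows = []
    for g1, g2 in pairs or []:
        sub = table.loc[[g1, g2]].to_numpy(dtype=float)
        a, b = sub[0]
        c, d = sub[1]
        if min(a, b, c, d) == 0:
            raise ValueError("zero cell in 2x2 odds ratio")
        orat = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = abs(np.log(orat)) / se
        rows.append({"group1": g1, "group2": g2, "odds_ratio": orat,
                     "p": float(2 * sps.norm.sf(z))})
    return ContingencyResult(float(chi2), float(p), int(dof), pd.DataFrame(rows))
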