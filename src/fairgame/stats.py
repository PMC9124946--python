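"""The statistical battery: variance gate, t-tests, effect sizes, regressions
and the a-priori power computation.

Conventions: group comparisons first test homoscedasticity with Levene's
test (classical, mean-centered); Student's pooled t when variances pass,
Welch otherwise; Bonferroni adjustment for families of comparisons;
Cohen's d on the pooled SD with the usual verbal categories
(0.2 / 0.5 / 0.8), generalized eta squared categorized at 0.01 / 0.06 / 0.14.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TTestResult", "RegressionFit", "PowerSpec",
    "levene", "bonferroni", "cohens_d", "d_category", "eta_category",
    "test_means", "eta_g2", "fit_poly", "power_rm_interaction",
    "required_sample_size",
]


def levene(groups, center: str = "mean"):
    """Levene's homoscedasticity test (one-way ANOVA on |deviations|).

    ``center='mean'`` is the classical Levene statistic; ``'median'`` gives
    the Brown-Forsythe variant.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene's test needs >= 2 groups with >= 2 values each")
    W, p = sps.levene(*groups, center=center)
    return float(W), float(p)


def bonferroni(p: float, m: int = 1) -> float:
    """min(1, m*p); monotone and capped."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return float(min(1.0, m * p))


def cohens_d(a, b) -> float:
    """Cohen's d with pooled SD; sign follows mean(a) - mean(b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def d_category(d: float) -> str:
    x = abs(d)
    if x < 0.2:
        return "negligible"
    if x < 0.5:
        return "small"
    if x < 0.8:
        return "medium"
    return "large"


def eta_category(eta: float) -> str:
    if eta < 0.01:
        return "negligible"
    if eta < 0.06:
        return "small"
    if eta < 0.14:
        return "medium"
    return "large"


@dataclass
class TTestResult:
    variant: str          # "student" or "welch"
    t: float
    df: float
    p: float
    p_adjusted: float
    d: float
    d_category: str
    levene_F: float
    levene_p: float
    n1: int
    n2: int
    degenerate: bool = False


def test_means(a, b, gate_alpha: float = 0.05, m_comparisons: int = 1) -> TTestResult:
    """Two-sample comparison with the Levene gate.

    Variances equal at ``gate_alpha`` -> Student's pooled t; otherwise
    Welch.  Two-sided p, Bonferroni-adjusted for ``m_comparisons``.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
    if degenerate and a.mean() == b.mean():
        return TTestResult("student", np.nan, len(a) + len(b) - 2, np.nan,
                           np.nan, 0.0, "negligible", 0.0, 1.0,
                           len(a), len(b), degenerate=True)
    lf, lp = levene([a, b])
    welch = lp < gate_alpha
    res = sps.ttest_ind(a, b, equal_var=not welch)
    d = cohens_d(a, b)
    return TTestResult("welch" if welch else "student",
                       float(res.statistic), float(res.df),
                       float(res.pvalue), bonferroni(res.pvalue, m_comparisons),
                       d, d_category(d), lf, lp, len(a), len(b))


def eta_g2(ss_effect: float, ss_error_terms) -> tuple[float, str]:
    """Generalized eta squared from a sums-of-squares decomposition.

    ``ss_error_terms`` lists every error stratum SS of the design (subject,
    residual, ...).  Returns (value, category); NaN when all SS vanish.
    """
    if ss_effect < 0 or any(s < 0 for s in np.atleast_1d(ss_error_terms)):
        raise ValueError("sums of squares must be nonnegative")
    denom = ss_effect + float(np.sum(ss_error_terms))
    if denom == 0:
        return float("nan"), "undefined"
    val = ss_effect / denom
    return float(val), eta_category(val)


@dataclass
class RegressionFit:
    degree: int
    coefficients: np.ndarray     # ascending powers
    F: float
    df: tuple[int, int]
    p: float
    r2: float
    r2_adjusted: float
    pearson_r: float | None = None
    r_ci95: tuple[float, float] | None = None


def fit_poly(x, y, degree: int = 1) -> RegressionFit:
    """Least-squares polynomial fit with overall F vs the intercept model.

    For degree 1 the Pearson correlation and its Fisher-z 95% CI are
    attached.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if n <= degree + 1:
        raise ValueError("not enough observations for the requested degree")
    X = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design (constant x?)")
    model = sm.OLS(y, X).fit()
    r = ci = None
    if degree == 1:
        r = float(sps.pearsonr(x, y).statistic)
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959963984540054 * se)),
              float(np.tanh(z + 1.959963984540054 * se)))
    return RegressionFit(
        degree=degree, coefficients=np.asarray(model.params),
        F=float(model.fvalue), df=(int(model.df_model), int(model.df_resid)),
        p=float(model.f_pvalue), r2=float(model.rsquared),
        r2_adjusted=float(model.rsquared_adj), pearson_r=r, r_ci95=ci)


@dataclass(frozen=True)
class PowerSpec:
    """Within-between interaction power settings (repeated-measures F)."""

    n_groups: int = 2
    n_measurements: int = 2
    effect_size_f: float = 0.33
    alpha: float = 0.05
    corr_rep_measures: float = 0.5
    nonsphericity: float = 1.0

    def __post_init__(self):
        if self.effect_size_f < 0:
            raise ValueError("effect size f must be >= 0")
        if not 0 <= self.corr_rep_measures < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.nonsphericity <= 1:
            raise ValueError("epsilon must be in (0, 1]")


def power_rm_interaction(spec: PowerSpec, n_total: int) -> float:
    """Achieved power of the group-by-measurement interaction F test.

    Noncentral-F power with df1 = (g-1)(m-1)eps, df2 = (N-g)(m-1)eps and
    noncentrality lambda = f^2 N m eps / (1 - rho).
    """
    g, m, eps = spec.n_groups, spec.n_measurements, spec.nonsphericity
    if n_total <= g:
        raise ValueError("N must exceed the number of groups")
    df1 = (g - 1) * (m - 1) * eps
    df2 = (n_total - g) * (m - 1) * eps
    lam = spec.effect_size_f ** 2 * n_total * m * eps / (1.0 - spec.corr_rep_measures)
    crit = sps.f.isf(spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, target_power: float = 0.95,
                         n_max: int = 10 ** 6) -> int:
    """Smallest total N reaching ``target_power``."""
    n = spec.n_groups + 1
    while n <= n_max:
        if power_rm_interaction(spec, n) >= target_power:
            return n
        n += 1
    raise ValueError(f"target power unreachable at N <= {n_max}")
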