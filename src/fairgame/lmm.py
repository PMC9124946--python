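"""Random-intercept linear mixed models with Satterthwaite denominator df.

The designs in this package share one structure: repeated measurements
(electrodes, bootstrap observers, trials) nested in participants, with up to
two crossed fixed factors plus their interaction.  The model is

    y = X beta + Z b + e,   b ~ N(0, s2_b I),   e ~ N(0, s2_e I)

with a participant random intercept.  The fit profiles the residual
variance: with theta = s2_b / s2_e, each participant block has
V_i = s2_e (I + theta J), whose inverse and determinant are closed-form
(Woodbury), so the (RE)ML criterion is a 1-D optimization in log(theta).

Type-III F tests use sum-to-zero (effect) coding.  Denominator degrees of
freedom follow Satterthwaite: for a contrast l, df = 2 f^2 / Var(f) with
f = l' Cov(beta) l and Var(f) by the delta method, using the finite-
difference gradient of f and the inverse observed information of the
variance parameters.  Multi-df effects combine eigencontrast dfs the way
lmerTest does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MixedFit", "design_matrix", "fit_lmm", "anova_like",
           "generalized_eta_squared"]

_THETA_BOUNDS = (-16.0, 16.0)   # bounds on log(theta)


def _effect_code(values: pd.Series) -> tuple[np.ndarray, list[str], list]:
    """Sum-to-zero coding: L-1 columns, last level coded -1 everywhere."""
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise ValueError(f"factor with a single level: {levels}")
    cols = np.zeros((len(values), len(levels) - 1))
    arr = np.asarray(values)
    for j, lev in enumerate(levels[:-1]):
        cols[arr == lev, j] = 1.0
    cols[arr == levels[-1], :] = -1.0
    names = [f"{values.name}[{lev}]" for lev in levels[:-1]]
    return cols, names, levels


def design_matrix(table: pd.DataFrame, fixed: list[str],
                  interaction: bool = True):
    """Fixed-effect design with effect coding.

    Returns ``(X, names, assign)`` where ``assign`` maps effect name ->
    column indices of X.
    """
    if not 1 <= len(fixed) <= 2:
        raise ValueError("one or two fixed factors supported")
    blocks = [np.ones((len(table), 1))]
    names = ["Intercept"]
    assign: dict[str, list[int]] = {}
    coded = {}
    for f in fixed:
        cols, cn, _ = _effect_code(table[f])
        assign[f] = list(range(len(names), len(names) + cols.shape[1]))
        blocks.append(cols)
        names.extend(cn)
        coded[f] = (cols, cn)
    if interaction and len(fixed) == 2:
        a, b = fixed
        ca, na = coded[a]
        cb, nb = coded[b]
        inter = np.einsum("ni,nj->nij", ca, cb).reshape(len(table), -1)
        inames = [f"{x}:{y}" for x in na for y in nb]
        assign[f"{a}:{b}"] = list(range(len(names), len(names) + inter.shape[1]))
        blocks.append(inter)
        names.extend(inames)
    X = np.hstack(blocks)
    return X, names, assign


@dataclass
class MixedFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    s2_b: float
    s2_e: float
    reml: bool
    names: list[str]
    assign: dict
    singular: bool
    loglik: float
    n_obs: int
    n_groups: int
    table: pd.DataFrame = field(repr=False)
    response: str = ""
    fixed: tuple = ()
    group_col: str = ""
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _gidx: list = field(repr=False, default=None)


def _group_blocks(X, y, gidx, theta):
    """Accumulate X'WX, X'Wy, y'Wy and log det(I + theta J) terms."""
    p = X.shape[1]
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    ytwy = 0.0
    logdet = 0.0
    for idx in gidx:
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        c = theta / (1.0 + theta * ni)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        xtwx += Xi.T @ Xi - c * np.outer(sx, sx)
        xtwy += Xi.T @ yi - c * sx * sy
        ytwy += yi @ yi - c * sy * sy
        logdet += np.log1p(theta * ni)
    return xtwx, xtwy, ytwy, logdet


def _profile_criterion(log_theta, X, y, gidx, reml):
    theta = np.exp(log_theta)
    n, p = X.shape
    xtwx, xtwy, ytwy, logdet = _group_blocks(X, y, gidx, theta)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = max(ytwy - beta @ xtwy, 1e-300)
    if reml:
        sign, ld_x = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(rss / (n - p)) + logdet + ld_x
    return n * np.log(rss / n) + logdet


def _m2l_full(vb, ve, X, y, gidx, reml):
    """-2 log (restricted) likelihood at explicit variance components."""
    if ve <= 0 or vb < 0:
        return np.inf
    theta = vb / ve
    n, p = X.shape
    xtwx, xtwy, ytwy, logdet = _group_blocks(X, y, gidx, theta)
    beta = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - beta @ xtwy
    out = n * np.log(ve) + logdet + rss / ve
    if reml:
        sign, ld_x = np.linalg.slogdet(xtwx / ve)
        out += ld_x
    return out


def fit_lmm(table: pd.DataFrame, response: str, fixed: list[str],
            group_col: str = "participant", interaction: bool = True,
            reml: bool = True) -> MixedFit:
    """Fit the random-intercept model by profiled (RE)ML."""
    table = table.dropna(subset=[response]).reset_index(drop=True)
    y = table[response].to_numpy(dtype=float)
    X, names, assign = design_matrix(table, list(fixed), interaction)
    groups = table[group_col].to_numpy()
    gidx = [np.where(groups == g)[0] for g in pd.unique(groups)]
    if len(gidx) < 2:
        raise ValueError("need at least 2 participants")
    n, p = X.shape

    grid = np.linspace(*_THETA_BOUNDS, 17)
    vals = np.array([_profile_criterion(lt, X, y, gidx, reml) for lt in grid])
    if (max(len(idx) for idx in gidx) == 1
            or vals.max() - vals.min() < 1e-8 * (1.0 + abs(vals.min()))):
        # theta unidentified (e.g. one observation per participant): only
        # s2_b + s2_e matters; pin theta = 0, reproducing the classical fit
        theta, singular = 0.0, False
    else:
        lo = grid[max(int(np.argmin(vals)) - 1, 0)]
        hi = grid[min(int(np.argmin(vals)) + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            _profile_criterion, bounds=(lo, hi), method="bounded",
            args=(X, y, gidx, reml), options={"xatol": 1e-8})
        log_theta = float(res.x)
        singular = log_theta <= _THETA_BOUNDS[0] + 1e-3
        if singular:
            warnings.warn("random-intercept variance estimated at zero "
                          "(singular fit); pinning it to 0", RuntimeWarning)
            theta = 0.0
        else:
            theta = np.exp(log_theta)

    xtwx, xtwy, ytwy, _ = _group_blocks(X, y, gidx, theta)
    beta = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - beta @ xtwy
    s2_e = rss / (n - p) if reml else rss / n
    s2_b = theta * s2_e
    cov_beta = s2_e * np.linalg.inv(xtwx)
    crit = _profile_criterion(np.log(theta) if theta > 0 else -50.0,
                              X, y, gidx, reml)
    return MixedFit(beta=beta, cov_beta=cov_beta, s2_b=s2_b, s2_e=s2_e,
                    reml=reml, names=names, assign=assign, singular=singular,
                    loglik=-0.5 * crit, n_obs=n, n_groups=len(gidx),
                    table=table, response=response, fixed=tuple(fixed),
                    group_col=group_col, _X=X, _y=y, _gidx=gidx)


# ---------------------------------------------------------------------------
# Satterthwaite machinery
# ---------------------------------------------------------------------------

def _contrast_var(l, vb, ve, X, gidx):
    theta = vb / ve if ve > 0 else 0.0
    p = X.shape[1]
    xtwx = np.zeros((p, p))
    for idx in gidx:
        Xi = X[idx]
        ni = len(idx)
        c = theta / (1.0 + theta * ni)
        sx = Xi.sum(axis=0)
        xtwx += Xi.T @ Xi - c * np.outer(sx, sx)
    return ve * (l @ np.linalg.solve(xtwx, l))


def _vcov_varpar(fit: MixedFit) -> np.ndarray:
    """Asymptotic covariance of (s2_b, s2_e) from the observed information.

    When the random-intercept variance is pinned at zero the problem is
    1-D in s2_e and the s2_b row/column is zero.
    """
    X, y, gidx, reml = fit._X, fit._y, fit._gidx, fit.reml
    vb, ve = fit.s2_b, fit.s2_e

    def f(v):
        return _m2l_full(v[0], v[1], X, y, gidx, reml)

    if fit.singular or vb <= 0:
        h = 1e-4 * ve
        d2 = (f([0.0, ve + h]) - 2 * f([0.0, ve]) + f([0.0, ve - h])) / h ** 2
        A = np.zeros((2, 2))
        if d2 > 0:
            A[1, 1] = 2.0 / d2
        return A

    v0 = np.array([vb, ve])
    hs = 1e-4 * v0
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * hs[i]
            ej = np.eye(2)[j] * hs[j]
            H[i, j] = (f(v0 + ei + ej) - f(v0 + ei - ej)
                       - f(v0 - ei + ej) + f(v0 - ei - ej)) / (4 * hs[i] * hs[j])
            H[j, i] = H[i, j]
    # rcond cuts the structural null direction of designs where only a sum
    # of variance components is identified (e.g. one observation per group)
    return 2.0 * np.linalg.pinv(H, rcond=1e-6, hermitian=True)


def _satterthwaite_1df(l, fit: MixedFit, A: np.ndarray) -> float:
    vb, ve = fit.s2_b, fit.s2_e
    X, gidx = fit._X, fit._gidx
    fval = _contrast_var(l, vb, ve, X, gidx)
    g = np.zeros(2)
    for i, v in enumerate((vb, ve)):
        h = 1e-6 * v if v > 0 else 1e-10
        up = _contrast_var(l, vb + (h if i == 0 else 0), ve + (h if i == 1 else 0), X, gidx)
        dn = _contrast_var(l, vb - (h if i == 0 else 0), ve - (h if i == 1 else 0), X, gidx)
        g[i] = (up - dn) / (2 * h)
    denom = g @ A @ g
    if denom <= 0:
        return float(fit.n_obs - fit._X.shape[1])
    return float(np.clip(2.0 * fval ** 2 / denom, 1.0, 1e7))


def anova_like(fit: MixedFit, eta: bool = True) -> pd.DataFrame:
    """Type-III F table with Satterthwaite denominator df.

    One row per fixed effect (main effects and, if present, the
    interaction); optionally annotated with generalized eta squared computed
    from the matching sums-of-squares decomposition.
    """
    A = _vcov_varpar(fit)
    rows = []
    etas = generalized_eta_squared(fit.table, fit.response, list(fit.fixed),
                                   fit.group_col) if eta else {}
    for effect, cols in fit.assign.items():
        L = np.zeros((len(cols), len(fit.beta)))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        q = L.shape[0]
        C = L @ fit.cov_beta @ L.T
        est = L @ fit.beta
        try:
            Fval = float(est @ np.linalg.solve(C, est) / q)
        except np.linalg.LinAlgError:
            rows.append({"effect": effect, "F": np.nan, "df1": q,
                         "df2": np.nan, "p": np.nan, "estimable": False})
            continue
        # eigencontrast combination of per-1df Satterthwaite dfs
        w, P = np.linalg.eigh(C)
        nus = []
        for i in range(q):
            if w[i] <= 0:
                continue
            li = P[:, i] @ L
            nus.append(_satterthwaite_1df(li, fit, A))
        nus = [nu for nu in nus if nu > 2]
        if len(nus) == q and q >= 1:
            E = sum(nu / (nu - 2) for nu in nus)
            df2 = 2 * E / (E - q) if E > q else fit.n_obs - len(fit.beta)
        elif nus:
            df2 = min(nus)
        else:
            df2 = fit.n_obs - len(fit.beta)
        pval = float(stats.f.sf(Fval, q, df2))
        row = {"effect": effect, "F": Fval, "df1": q, "df2": float(df2),
               "p": pval, "estimable": True}
        if eta:
            row["eta_g2"] = etas.get(effect, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def generalized_eta_squared(table: pd.DataFrame, response: str,
                            fixed: list[str], group_col: str) -> dict:
    """Generalized eta squared per fixed effect.

    SS_effect is the Type-III sum of squares from the fixed-effect design;
    the denominator adds the participant stratum and the residual, the two
    error variances measured in these designs.
    """
    tab = table.dropna(subset=[response]).reset_index(drop=True)
    y = tab[response].to_numpy(dtype=float)
    X, names, assign = design_matrix(tab, list(fixed), interaction=len(fixed) == 2)

    def rss(M):
        b, res, *_ = np.linalg.lstsq(M, y, rcond=None)
        return float(((y - M @ b) ** 2).sum())

    rss_fixed = rss(X)
    # add participant indicator block
    pid = pd.get_dummies(tab[group_col]).to_numpy(dtype=float)
    rss_full = rss(np.hstack([X, pid]))
    ss_subject = max(rss_fixed - rss_full, 0.0)
    ss_error = rss_full
    out = {}
    for effect, cols in assign.items():
        keep = [i for i in range(X.shape[1]) if i not in cols]
        ss_eff = max(rss(X[:, keep]) - rss_fixed, 0.0)
        denom = ss_eff + ss_subject + ss_error
        out[effect] = ss_eff / denom if denom > 0 else np.nan
    return out
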