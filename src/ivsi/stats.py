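"""Statistical layer: group comparisons, longitudinal mixed models, FDR,
reproducibility statistics, and a priori power analysis.

The longitudinal model is a linear mixed-effects model with experimental
group and postoperative day as fixed effects and a random intercept per
animal, fitted by REML with Satterthwaite degrees of freedom — the same
model lme4/lmerTest fit for repeated-measures strain metrics.  Because no
Python library combines a REML random-intercept fit with Satterthwaite
p-values, the fit (profiled one-dimensional REML) and the Satterthwaite
approximation (delta method on the REML variance estimates) are implemented
here and cross-checked against lme4/lmerTest in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as spstats
from statsmodels.stats.multitest import multipletests

from .core_io import (DomainError, SampleSizeError, StatResult,
                      validate_cohort_table)

logger = logging.getLogger("ivsi")

__all__ = [
    "LMMSpec", "PowerSpec", "welch_t", "cohens_d", "required_n_per_group",
    "fit_lmm", "bh_fdr", "icc_agreement", "bland_altman", "power_two_sample_t",
    "welch_by_day",
]


@dataclass
class LMMSpec:
    """Mixed-model layout: response name, group + day fixed effects, random
    intercept per animal, Satterthwaite df, 95% Wald-t CIs."""

    metric_name: str = ""
    ci_level: float = 0.95
    df_method: str = "satterthwaite"   # or "residual"


@dataclass
class PowerSpec:
    """A priori power-analysis settings for a two-sample t-test."""

    alpha: float = 0.05
    power: float = 0.80
    tails: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise DomainError("power must be in (0, 1)")
        if self.tails not in (1, 2):
            raise DomainError("tails must be 1 or 2")


# ---------------------------------------------------------------------------
# Two-sample comparisons and power
# ---------------------------------------------------------------------------

def welch_t(x, y, *, ci_level: float = 0.95) -> StatResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df and a
    mean-difference confidence interval.

    Degenerate input (zero variance in both samples) falls back to the
    convention t=0, p=1 for equal means, p=0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise SampleSizeError("each sample needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("samples must be finite")
    diff = float(np.mean(x) - np.mean(y))
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if diff == 0.0:
            return StatResult(estimate=0.0, ci_low=0.0, ci_high=0.0,
                              statistic=0.0, df=float(x.size + y.size - 2),
                              p_value=1.0, method="welch_t")
        return StatResult(estimate=diff, ci_low=diff, ci_high=diff,
                          statistic=float(np.sign(diff)) * np.inf,
                          df=float(x.size + y.size - 2), p_value=0.0,
                          method="welch_t")
    res = spstats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(ci_level)
    return StatResult(estimate=diff, ci_low=float(ci.low),
                      ci_high=float(ci.high), statistic=float(res.statistic),
                      df=float(res.df), p_value=float(res.pvalue),
                      method="welch_t")


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Cohen's d from summary statistics of two equal-sized groups:
    |mean difference| / pooled SD, pooled SD = sqrt((sd_a^2 + sd_b^2)/2)."""
    if sd_a <= 0 or sd_b <= 0:
        raise DomainError("standard deviations must be positive")
    return abs(mean_a - mean_b) / np.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)


def power_two_sample_t(d: float, n_per_group: int,
                       spec: PowerSpec | None = None) -> float:
    """Exact power of the two-sample t-test at effect size d and n/group,
    under the noncentral t with ncp = d*sqrt(n/2) and df = 2n - 2."""
    spec = spec or PowerSpec()
    if n_per_group < 2:
        raise DomainError("need n >= 2 per group (df >= 1)")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    if spec.tails == 2:
        tc = spstats.t.ppf(1 - spec.alpha / 2, df)
        return float(1 - spstats.nct.cdf(tc, df, ncp)
                     + spstats.nct.cdf(-tc, df, ncp))
    tc = spstats.t.ppf(1 - spec.alpha, df)
    return float(1 - spstats.nct.cdf(tc, df, ncp))


def required_n_per_group(d: float, spec: PowerSpec | None = None,
                         n_max: int = 100000) -> int:
    """Smallest n per group at which the two-sample t-test reaches the
    requested power (exact noncentral-t; n >= 2 so that df >= 1)."""
    spec = spec or PowerSpec()
    if d <= 0:
        raise DomainError("effect size must be positive")
    n = 2
    while power_two_sample_t(d, n, spec) < spec.power:
        n += 1
        if n > n_max:
            raise DomainError(f"required n exceeds {n_max}")
    return n


# ---------------------------------------------------------------------------
# Linear mixed model (random intercept, REML, Satterthwaite)
# ---------------------------------------------------------------------------

def _group_stats(X: np.ndarray, y: np.ndarray, idx: list[np.ndarray]):
    """Per-animal sufficient statistics for the random-intercept model."""
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Xs = np.stack([X[ix].sum(axis=0) for ix in idx])          # (g, p)
    ys = np.array([y[ix].sum() for ix in idx])                # (g,)
    ns = np.array([len(ix) for ix in idx], dtype=float)       # (g,)
    return XtX, Xty, yty, Xs, ys, ns


def _gls_pieces(lam: float, suff):
    """X'W^-1 X, X'W^-1 y, y'W^-1 y and log|W| for W = I + lam*ZZ'."""
    XtX, Xty, yty, Xs, ys, ns = suff
    k = lam / (1.0 + lam * ns)                                # (g,)
    XtWX = XtX - (Xs.T * k) @ Xs
    XtWy = Xty - Xs.T @ (k * ys)
    ytWy = yty - float(k @ (ys ** 2))
    logdetW = float(np.sum(np.log1p(lam * ns)))
    return XtWX, XtWy, ytWy, logdetW


def _reml_profile(lam: float, suff, n_obs: int, p: int) -> float:
    """Negative profiled REML log-likelihood as a function of lam."""
    XtWX, XtWy, ytWy, logdetW = _gls_pieces(lam, suff)
    sign, logdetX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n_obs - p)
    return 0.5 * ((n_obs - p) * np.log(sigma2) + logdetW + logdetX)


def _reml_loglik(theta: np.ndarray, suff, n_obs: int, p: int) -> float:
    """REML log-likelihood (up to a constant) at variance components
    theta = (sigma_b^2, sigma_e^2)."""
    sb2, se2 = theta
    if se2 <= 0 or sb2 < 0:
        return -np.inf
    lam = sb2 / se2
    XtWX, XtWy, ytWy, logdetW = _gls_pieces(lam, suff)
    sign, logdetX = np.linalg.slogdet(XtWX / se2)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    return -0.5 * (n_obs * np.log(se2) + logdetW + logdetX + rss / se2)


def _coef_var(theta: np.ndarray, suff) -> np.ndarray:
    """Fixed-effect covariance (X' V^-1 X)^-1 at variance components theta."""
    sb2, se2 = theta
    lam = sb2 / se2
    XtWX, _, _, _ = _gls_pieces(lam, suff)
    return np.linalg.inv(XtWX / se2)


def fit_lmm(table: pd.DataFrame, spec: LMMSpec | None = None
            ) -> list[StatResult]:
    """REML fit of value ~ group + day + (1 | animal) on a long cohort table.

    Returns one StatResult per fixed effect (intercept, group[TAC], day)
    with Satterthwaite degrees of freedom, Wald-t CIs and p-values.  A
    singular fit (random-intercept variance estimated at zero) is flagged in
    the method tag, not fatal; if the variance-component Hessian is
    ill-conditioned the df fall back to the residual value with a warning.
    """
    spec = spec or LMMSpec()
    table = validate_cohort_table(table)
    if spec.metric_name:
        table = table[table.metric_name == spec.metric_name]
    if table.empty:
        raise SampleSizeError("no rows for the requested metric")
    groups = sorted(table.group.unique())
    if len(groups) == 2:
        per_group = table.groupby("group")["animal_id"].nunique()
        if (per_group < 2).any():
            raise SampleSizeError("need >= 2 animals per group")
    y = table["value"].to_numpy(dtype=float)
    n_obs = y.size
    cols = [np.ones(n_obs)]
    names = ["intercept"]
    if len(groups) == 2:
        cols.append((table.group == "TAC").to_numpy(dtype=float))
        names.append("group[TAC]")
    if table.day.nunique() >= 2:
        cols.append(table.day.to_numpy(dtype=float))
        names.append("day")
    X = np.column_stack(cols)
    p = X.shape[1]
    animal_codes = pd.factorize(table.animal_id)[0]
    idx = [np.flatnonzero(animal_codes == g)
           for g in range(animal_codes.max() + 1)]
    suff = _group_stats(X, y, idx)

    # degenerate exact fit: zero residual noise and zero random intercepts
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale = max(1.0, float(np.max(np.abs(y))))
    if float(np.max(np.abs(y - X @ beta_ols))) < 1e-10 * scale:
        logger.warning("exact linear fit: variance components are zero")
        return [StatResult(estimate=float(b), ci_low=float(b),
                           ci_high=float(b), statistic=np.inf * np.sign(b)
                           if b else 0.0, df=float(n_obs - p),
                           p_value=0.0 if b else 1.0,
                           method="lmm_degenerate_exact_fit", effect=nm,
                           metric=spec.metric_name)
                for b, nm in zip(beta_ols, names)]

    res = optimize.minimize_scalar(
        lambda lt: _reml_profile(np.exp(lt), suff, n_obs, p),
        bounds=(-20.0, 20.0), method="bounded",
        options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    singular = lam < 1e-7
    XtWX, XtWy, ytWy, _ = _gls_pieces(lam, suff)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    se2 = rss / (n_obs - p)
    sb2 = lam * se2
    theta = np.array([sb2, se2])
    C = _coef_var(theta, suff)

    # Satterthwaite: df_j = 2 f^2 / (g' A g), f = Var(beta_j), g = grad f,
    # A = covariance of the variance components from the REML information.
    resid_df = float(n_obs - p)
    dfs = np.full(p, resid_df)
    method = "lmm_reml_satterthwaite"
    if spec.df_method == "satterthwaite":
        try:
            h = np.maximum(1e-8, 1e-5 * np.maximum(theta, se2))
            # keep finite-difference points inside the parameter domain
            if theta[0] > 0:
                h[0] = min(h[0], theta[0] / 2)
            h[1] = min(h[1], theta[1] / 2)
            H = np.zeros((2, 2))
            f0 = _reml_loglik(theta, suff, n_obs, p)
            with np.errstate(invalid="ignore"):
                for i in range(2):
                    for j in range(2):
                        ei = np.eye(2)[i] * h[i]
                        ej = np.eye(2)[j] * h[j]
                        H[i, j] = (
                            _reml_loglik(theta + ei + ej, suff, n_obs, p)
                            - _reml_loglik(theta + ei - ej, suff, n_obs, p)
                            - _reml_loglik(theta - ei + ej, suff, n_obs, p)
                            + _reml_loglik(theta - ei - ej, suff, n_obs, p)
                        ) / (4 * h[i] * h[j])
            if not np.all(np.isfinite(H)) or np.isinf(f0):
                raise np.linalg.LinAlgError("non-finite REML Hessian")
            A = np.linalg.inv(-H)
            for j_c in range(p):
                grad = np.zeros(2)
                for i in range(2):
                    ei = np.eye(2)[i] * h[i]
                    grad[i] = (_coef_var(theta + ei, suff)[j_c, j_c]
                               - _coef_var(theta - ei, suff)[j_c, j_c]
                               ) / (2 * h[i])
                denom = float(grad @ A @ grad)
                if denom > 0:
                    dfc = 2.0 * C[j_c, j_c] ** 2 / denom
                    if np.isfinite(dfc) and dfc > 0:
                        dfs[j_c] = min(dfc, resid_df * 10)
        except np.linalg.LinAlgError:
            logger.warning("ill-conditioned variance Hessian; "
                           "falling back to residual df")
            method = "lmm_reml_residual_df"
    else:
        method = "lmm_reml_residual_df"
    if singular:
        method += "_singular"
        logger.warning("singular fit: random-intercept variance ~ 0")

    out = []
    alpha = 1.0 - spec.ci_level
    for j_c, name in enumerate(names):
        se = float(np.sqrt(C[j_c, j_c]))
        tstat = float(beta[j_c] / se)
        df_j = float(dfs[j_c])
        pval = float(2 * spstats.t.sf(abs(tstat), df_j))
        tcrit = float(spstats.t.ppf(1 - alpha / 2, df_j))
        out.append(StatResult(
            estimate=float(beta[j_c]), ci_low=float(beta[j_c] - tcrit * se),
            ci_high=float(beta[j_c] + tcrit * se), statistic=tstat, df=df_j,
            p_value=pval, method=method, effect=name,
            metric=spec.metric_name))
    return out


def lmm_variance_components(table: pd.DataFrame,
                            spec: LMMSpec | None = None) -> dict:
    """Random-intercept and residual variance of the REML fit (diagnostics)."""
    spec = spec or LMMSpec()
    table = validate_cohort_table(table)
    if spec.metric_name:
        table = table[table.metric_name == spec.metric_name]
    y = table["value"].to_numpy(dtype=float)
    n_obs = y.size
    cols = [np.ones(n_obs)]
    if table.group.nunique() == 2:
        cols.append((table.group == "TAC").to_numpy(dtype=float))
    if table.day.nunique() >= 2:
        cols.append(table.day.to_numpy(dtype=float))
    X = np.column_stack(cols)
    p = X.shape[1]
    animal_codes = pd.factorize(table.animal_id)[0]
    idx = [np.flatnonzero(animal_codes == g)
           for g in range(animal_codes.max() + 1)]
    suff = _group_stats(X, y, idx)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    if float(np.max(np.abs(y - X @ beta_ols))) < \
            1e-10 * max(1.0, float(np.max(np.abs(y)))):
        return {"sigma2_intercept": 0.0, "sigma2_resid": 0.0,
                "singular": True}
    res = optimize.minimize_scalar(
        lambda lt: _reml_profile(np.exp(lt), suff, n_obs, p),
        bounds=(-20.0, 20.0), method="bounded", options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    XtWX, XtWy, ytWy, _ = _gls_pieces(lam, suff)
    beta = np.linalg.solve(XtWX, XtWy)
    se2 = (ytWy - float(beta @ XtWy)) / (n_obs - p)
    return {"sigma2_intercept": lam * se2, "sigma2_resid": se2,
            "singular": lam < 1e-7}


def welch_by_day(table: pd.DataFrame, metric_name: str) -> dict:
    """Welch comparison of sham vs TAC at each postoperative day.

    Returns {day: StatResult} with estimate = mean(sham) - mean(TAC).
    """
    table = validate_cohort_table(table)
    table = table[table.metric_name == metric_name]
    if table.empty:
        raise SampleSizeError(f"no rows for metric {metric_name!r}")
    out = {}
    for day, sub in table.groupby("day"):
        x = sub[sub.group == "sham"]["value"].to_numpy()
        y = sub[sub.group == "TAC"]["value"].to_numpy()
        res = welch_t(x, y)
        res.metric = metric_name
        res.effect = f"day{day}"
        out[int(day)] = res
    return out


# ---------------------------------------------------------------------------
# Multiplicity, agreement
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def icc_agreement(ratings: np.ndarray) -> StatResult:
    """Two-way absolute-agreement single-measure ICC, i.e. ICC(A,1).

    ``ratings`` is a complete subjects x raters matrix.  The estimate, the
    F statistic and the 95% CI come from the two-way random-effects ANOVA
    (pingouin's ICC2 line).
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 5 or r.shape[1] < 2:
        raise SampleSizeError("need >= 5 subjects and >= 2 raters")
    if np.any(~np.isfinite(r)):
        raise DomainError("ratings matrix must be complete and finite")
    if np.ptp(r) == 0:
        raise DomainError("ICC undefined for a constant ratings matrix")
    import pingouin as pg  # deferred: slow import
    n_sub, n_rat = r.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_rat),
        "rater": np.tile(np.arange(n_rat), n_sub),
        "score": r.ravel(),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = pg.intraclass_corr(data=long, targets="subject",
                                 raters="rater",
                                 ratings="score").set_index("Type")
    key = "ICC(A,1)" if "ICC(A,1)" in icc.index else "ICC2"
    row = icc.loc[key]
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    est = float(row["ICC"])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        lo = hi = est  # degenerate ANOVA (e.g. identical raters)
    pval = float(row["pval"])
    if not np.isfinite(pval):
        pval = 0.0
    return StatResult(estimate=est, ci_low=min(lo, est), ci_high=max(hi, est),
                      statistic=float(row["F"]), df=float(row["df1"]),
                      p_value=pval, method="icc_a1")


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland–Altman agreement: bias = mean(x - y), limits of agreement
    bias ± 1.96 sd(x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("paired samples must have equal length")
    if x.size < 3:
        raise SampleSizeError("Bland–Altman needs n >= 3 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd
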