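"""Between-/within-center variance decomposition and intraclass correlation.

The ICC is the proportion of a variable's total variance that lies
between groups (here, recruitment centers): ``sigma2_b / (sigma2_b +
sigma2_w)``.  Three entry points: raw continuous data (REML mixed model
or method of moments), published per-group summary statistics (means
and SDs only), and dichotomous variables (latent-scale random-intercept
logistic model, where the within variance is the logistic variance
pi^2/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = ["ICCResult", "icc_continuous", "icc_from_summary", "icc_binary"]

_LOGISTIC_VAR = np.pi ** 2 / 3.0


@dataclass(frozen=True)
class ICCResult:
    sigma2_between: float
    sigma2_within: float
    icc: float
    n_groups: int
    method: str
    boundary: bool = False


def _result(b: float, w: float, n_groups: int, method: str, boundary=False) -> ICCResult:
    b = max(float(b), 0.0)  # truncate negative method-of-moments estimates
    total = b + float(w)
    icc = b / total if total > 0 else 0.0
    return ICCResult(b, float(w), icc, n_groups, method, boundary)


def icc_continuous(values, groups, method: str = "reml") -> ICCResult:
    """Variance components of a continuous variable across groups.

    ``method="reml"`` fits a random-intercept linear model by REML;
    ``method="moments"`` uses the large-group approximation (variance of
    group means over between + mean within-group variance) that
    :func:`icc_from_summary` applies to published tables — the two are
    identical given the same data summaries.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups)).reset_index(drop=True)
    ok = values.notna()
    values, groups = values[ok], groups[ok]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for an ICC")
    if method == "moments":
        gm = values.groupby(groups).mean()
        gv = values.groupby(groups).var(ddof=1).dropna()
        return _result(np.var(gm.to_numpy(), ddof=0), gv.mean(), len(labels), "moments")
    if method != "reml":
        raise ValueError("method must be 'reml' or 'moments'")
    import statsmodels.api as sm

    md = sm.MixedLM(values.to_numpy(), np.ones((len(values), 1)),
                    groups=groups.to_numpy())
    with np.errstate(all="ignore"):
        res = md.fit(reml=True)
    between = float(np.asarray(res.cov_re)[0, 0])
    return _result(between, float(res.scale), len(labels), "reml")


def icc_from_summary(group_means, group_sds, weights=None) -> ICCResult:
    """ICC from published per-group means and SDs.

    Method of moments with the large-group approximation: the between
    variance is the (optionally weighted) population variance of the
    group means — the sampling variance of each mean is ignored, which
    is negligible when groups hold thousands of subjects — and the
    within variance is the (weighted) mean of the squared SDs.
    """
    m = np.asarray(group_means, dtype=float)
    s = np.asarray(group_sds, dtype=float)
    if m.shape != s.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("group_means and group_sds must be equal-length vectors, length >= 2")
    if np.any(s < 0):
        raise ValueError("standard deviations must be non-negative")
    if weights is None:
        w = np.ones_like(m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != m.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, same length, not all zero")
    w = w / w.sum()
    mbar = float(w @ m)
    sigma2_b = float(w @ (m - mbar) ** 2)
    sigma2_w = float(w @ s ** 2)
    return _result(sigma2_b, sigma2_w, m.size, "summary")


def icc_binary(values, groups, scale: str = "latent") -> ICCResult:
    """ICC of a dichotomous variable across groups.

    ``scale="latent"`` (default) fits a random-intercept logistic model
    by Laplace approximation and reports ``sigma2_b / (sigma2_b +
    pi^2/3)``; ``scale="linear"`` treats the 0/1 values as continuous
    (linear probability decomposition).  Fully separated groups push the
    between variance to its optimization bound; the result is then
    flagged as a boundary solution.
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(np.asarray(groups))
    if not set(np.unique(values[~np.isnan(values)])) <= {0.0, 1.0}:
        raise ValueError("values must be 0/1")
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok].reset_index(drop=True)
    if values.min() == values.max():
        raise ValueError("variable is constant (all 0 or all 1)")
    codes, labels = pd.factorize(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if scale == "linear":
        res = icc_continuous(values, groups, method="moments")
        return ICCResult(res.sigma2_between, res.sigma2_within, res.icc,
                         res.n_groups, "binary-linear")
    if scale != "latent":
        raise ValueError("scale must be 'latent' or 'linear'")

    n1 = np.bincount(codes, weights=values)
    n = np.bincount(codes).astype(float)
    LOG_SD_MAX = 5.0

    def group_laplace(b0: float, var: float) -> float:
        total = 0.0
        for j in range(len(n)):
            u = 0.0
            for _ in range(60):  # Newton for the group mode
                p = 1.0 / (1.0 + np.exp(-(b0 + u)))
                g = n1[j] - n[j] * p - u / var
                h = n[j] * p * (1 - p) + 1.0 / var
                step = g / h
                u += step
                if abs(step) < 1e-12:
                    break
            p = 1.0 / (1.0 + np.exp(-(b0 + u)))
            eta = b0 + u
            ll = n1[j] * eta - n[j] * np.log1p(np.exp(eta))
            h = n[j] * p * (1 - p) + 1.0 / var
            total += ll - 0.5 * u * u / var - 0.5 * np.log(var) - 0.5 * np.log(h)
        return total

    def nll(par):
        b0, log_sd = par
        if abs(log_sd) > LOG_SD_MAX or abs(b0) > 30:
            return 1e10
        return -group_laplace(b0, np.exp(2 * log_sd))

    p0 = values.mean()
    x0 = np.array([np.log(p0 / (1 - p0)), np.log(0.5)])
    res = scipy.optimize.minimize(nll, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    b0, log_sd = res.x
    var = float(np.exp(2 * log_sd))
    # flagged when the between-SD sits at the optimization cap or the groups
    # are effectively separated (latent ICC beyond 0.95)
    boundary = bool(log_sd > LOG_SD_MAX - 0.51
                    or var / (var + _LOGISTIC_VAR) >= 0.95)
    return ICCResult(var, _LOGISTIC_VAR, var / (var + _LOGISTIC_VAR),
                     len(labels), "binary-latent", boundary)
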