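"""Multilevel piecewise-exponential hazards model via Poisson likelihood.

The disease model: person-period event indicators are Poisson with

    ln mu_ijk = ln t_ijk + alpha_k + delta0_j + delta1_j * sex_ij
                + (X_ij - Xbar_.j) betaW_j + (Xbar_.j - Xbar_..) betaB
                + (Z_ij - Zbar_.j)' gammaW + (Zbar_.j - Zbar_..)' gammaB

where center j carries random effects (u0j, u1j, uWj) ~ MVN(0, Sigma)
on the intercept, the sex contrast and the within-center exposure
slope.  Estimation maximizes the Laplace-approximated marginal
likelihood: the outer optimizer moves the log-Cholesky factor of Sigma
(guaranteeing a PSD covariance), while for each candidate Sigma the
fixed effects and the center modes are obtained by a joint penalized
Newton solve, so the objective is the marginal log-likelihood evaluated
at the conditionally optimal fixed effects.  For a degenerate Sigma the
model collapses to plain fixed-effects Poisson regression, which also
serves as initialization.

Internally the person-period table is collapsed to one row per subject
(event flag, interval-occupancy times, exit interval): the Poisson
likelihood of the expanded table depends on the data only through these
sufficient statistics, which makes likelihood evaluations O(n_subjects)
rather than O(n_rows).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .person_period import AgeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "FitResult", "RateRatio", "fit", "marginal_loglik",
    "predict_rr", "derived_quantities", "compare_variance_components",
]

_RE_NAMES = ("intercept", "sex", "exposure")
_VAR_THRESHOLD = 1e-8  # variances below this are reported as boundary zeros


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which columns enter the fixed design and which random terms are on.

    ``fixed_terms`` are subject-level covariate columns (already centered
    or aggregated as desired); an intercept, the sex indicator and the
    age-interval contrasts are always included.  ``model_level`` is an
    optional tag for the conventional model ladder (1: random intercepts
    only, 2: + individual covariates, 3: centered individual + aggregate
    covariates, 4: + random exposure slope).
    """

    fixed_terms: tuple[str, ...] = ()
    random_intercept: bool = True
    random_sex_slope: bool = True
    random_exposure_slope: bool = False
    exposure_within: str | None = None  # column carrying the random slope
    model_level: int | None = None

    def __post_init__(self) -> None:
        if self.random_exposure_slope and not self.exposure_within:
            raise ValueError("random_exposure_slope requires exposure_within column name")
        if self.random_exposure_slope and not self.random_intercept:
            raise ValueError("exposure slope without random intercept is not supported")

    @property
    def n_random(self) -> int:
        return sum([self.random_intercept, self.random_sex_slope, self.random_exposure_slope])

    @property
    def random_names(self) -> tuple[str, ...]:
        flags = (self.random_intercept, self.random_sex_slope, self.random_exposure_slope)
        return tuple(n for n, f in zip(_RE_NAMES, flags) if f)

    @classmethod
    def for_level(
        cls,
        level: int,
        exposure: str = "exposure_q",
        individual: tuple[str, ...] = (),
        aggregate: tuple[str, ...] = (),
    ) -> "ModelSpec":
        """Build a spec on the conventional 4-model ladder.

        Levels 3-4 expect ``<var>__within`` / ``<var>__between`` columns
        from :func:`pwemix.design.center_covariates` to exist.
        """
        if level == 1:
            return cls(model_level=1)
        if level == 2:
            return cls(fixed_terms=(exposure, *individual), model_level=2)
        within = tuple(f"{v}__within" for v in (exposure, *individual))
        terms = within + (f"{exposure}__between",) + tuple(aggregate)
        if level == 3:
            return cls(fixed_terms=terms, model_level=3)
        if level == 4:
            return cls(fixed_terms=terms, model_level=4,
                       random_exposure_slope=True,
                       exposure_within=f"{exposure}__within")
        raise ValueError("model level must be 1, 2, 3 or 4")


@dataclass(frozen=True)
class RateRatio:
    variable: str
    increment: float
    rr: float
    ci_low: float
    ci_high: float


# --------------------------------------------------------------------------
# collapsed sufficient statistics
# --------------------------------------------------------------------------

class _Collapsed:
    """Per-subject sufficient statistics of the person-period Poisson model."""

    def __init__(self, pp: pd.DataFrame, spec: ModelSpec, grid: AgeGrid):
        req = ["subject_id", "center_id", "sex", "interval", "t", "d"]
        missing = [c for c in req if c not in pp.columns]
        if missing:
            raise ValueError(f"person-period table missing columns: {missing}")
        for term in spec.fixed_terms:
            if term not in pp.columns:
                raise ValueError(f"fixed term {term!r} not in person-period table")
        if (pp["t"].to_numpy() <= 0).any():
            raise ValueError("offsets t must be strictly positive")

        used = list(dict.fromkeys(["sex", *spec.fixed_terms]))
        if spec.exposure_within:
            used.append(spec.exposure_within)
            used = list(dict.fromkeys(used))
        keep = pp[used].notna().all(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d person-period rows with missing covariates", n_drop)
            pp = pp.loc[keep]

        pp = pp.sort_values(["center_id", "subject_id", "interval"], kind="mergesort")
        subj, subj_index = pd.factorize(pp["subject_id"], sort=False)
        # the per-subject collapse requires covariates constant within subject;
        # interval-varying columns (e.g. exposure x age-indicator products)
        # force exact row-level units instead (Poisson factorizes over rows)
        varying = False
        for col in used:
            vals = pp[col].to_numpy()
            firsts = np.zeros(len(subj_index), dtype=vals.dtype)
            firsts_idx = np.zeros(len(subj_index), dtype=int)
            firsts_idx[subj[::-1]] = np.arange(len(pp))[::-1]
            firsts = vals[firsts_idx]
            if not np.array_equal(firsts[subj], vals):
                varying = True
                break
        if varying:
            subj = np.arange(len(pp))
            subj_index = pd.RangeIndex(len(pp))
        n = len(subj_index)
        S = grid.n_intervals
        interval = pp["interval"].to_numpy(dtype=int)
        if interval.min() < 0 or interval.max() >= S:
            raise ValueError("interval index outside the age grid")
        t = pp["t"].to_numpy(dtype=float)
        d_row = pp["d"].to_numpy(dtype=int)

        self.Tocc = np.zeros((n, S))
        self.Tocc[subj, interval] = t
        self.d = np.zeros(n, dtype=int)
        self.kexit = np.zeros(n, dtype=int)
        ev = d_row == 1
        self.d[subj[ev]] = 1
        self.kexit[subj[ev]] = interval[ev]
        self.const = float(np.sum(np.log(t[ev])))

        first = np.zeros(n, dtype=int)
        first[subj[::-1]] = np.arange(len(pp))[::-1]
        firstrows = pp.iloc[first]
        self.sex = firstrows["sex"].to_numpy(dtype=float)
        self.center, self.center_index = pd.factorize(firstrows["center_id"], sort=True)

        cols = [np.ones(n), self.sex]
        names = ["intercept", "sex"]
        for term in spec.fixed_terms:
            cols.append(firstrows[term].to_numpy(dtype=float))
            names.append(term)
        X = np.column_stack(cols)
        X, names, dropped = _drop_collinear(X, names)
        if dropped:
            logger.warning("dropped collinear fixed-effect columns: %s", dropped)
        self.X = X
        self.beta_names = names
        self.dropped = dropped

        wcols = []
        if spec.random_intercept:
            wcols.append(np.ones(n))
        if spec.random_sex_slope:
            wcols.append(self.sex)
        if spec.random_exposure_slope:
            wcols.append(firstrows[spec.exposure_within].to_numpy(dtype=float))
        self.W = np.column_stack(wcols) if wcols else np.zeros((n, 0))

        present = np.nonzero(self.Tocc.sum(axis=0) > 0)[0]
        self.alpha_idx = [k for k in present if k != grid.reference_interval]
        self.S = S
        self.J = len(self.center_index)
        self.n = n
        self.slices = [np.nonzero(self.center == j)[0] for j in range(self.J)]
        self.n_rows = len(pp)
        self.n_events = int(self.d.sum())
        # per-center event totals for the alpha gradient
        self.event_by_k = np.bincount(self.kexit[self.d == 1], minlength=S).astype(float)


def _drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8):
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * max(diag[0], 1.0)))
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in sorted(piv[rank:])]
    return X[:, keep], [names[i] for i in keep], dropped


# --------------------------------------------------------------------------
# log-Cholesky covariance parameterization
# --------------------------------------------------------------------------

def _n_theta(q: int) -> int:
    return q * (q + 1) // 2


def _theta_to_chol(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[idx]) if i == j else theta[idx]
            idx += 1
    return L


def _theta_to_sigma(theta: np.ndarray, q: int) -> np.ndarray:
    L = _theta_to_chol(theta, q)
    return L @ L.T


# --------------------------------------------------------------------------
# penalized joint Newton (alpha, beta, u | Sigma) and Laplace objective
# --------------------------------------------------------------------------

class _State:
    def __init__(self, alpha, beta, u):
        self.alpha = alpha  # full length-S vector, reference pinned to 0
        self.beta = beta
        self.u = u          # (J, q)


def _model_quantities(data: _Collapsed, alpha, beta, u):
    psi = data.X @ beta
    if data.W.shape[1]:
        psi = psi + np.sum(data.W * u[data.center], axis=1)
    A = np.exp(alpha)
    Emat = data.Tocc * A
    with np.errstate(over="ignore"):
        mu_mat = np.exp(psi)[:, None] * Emat
    m = mu_mat.sum(axis=1)
    return psi, mu_mat, m


def _penalized_loglik(data: _Collapsed, state: _State, Sinv: np.ndarray):
    psi, mu_mat, m = _model_quantities(data, state.alpha, state.beta, state.u)
    if not np.all(np.isfinite(m)):
        return -np.inf, mu_mat, m
    ll = (data.const
          + float(np.sum(state.alpha[data.kexit] * data.d))
          + float(psi @ data.d) - float(m.sum()))
    if data.W.shape[1]:
        ll -= 0.5 * float(np.einsum("jq,qr,jr->", state.u, Sinv, state.u))
    return ll, mu_mat, m


def _joint_newton(data: _Collapsed, state: _State, Sinv: np.ndarray,
                  tol: float = 1e-10, max_iter: int = 100,
                  update_fixed: bool = True):
    """Maximize the penalized log-likelihood over (alpha, beta, u) or u only."""
    q = data.W.shape[1]
    nf = len(data.alpha_idx) if update_fixed else 0
    p = data.X.shape[1] if update_fixed else 0
    dim = nf + p + data.J * q
    h, mu_mat, m = _penalized_loglik(data, state, Sinv)
    if not np.isfinite(h):
        raise FloatingPointError("non-finite penalized log-likelihood at start")

    stalls = 0
    for it in range(max_iter):
        grad = np.zeros(dim)
        H = np.zeros((dim, dim))
        col_mu = mu_mat.sum(axis=0)
        if update_fixed:
            ai = data.alpha_idx
            grad[:nf] = data.event_by_k[ai] - col_mu[ai]
            grad[nf:nf + p] = data.X.T @ (data.d - m)
            H[:nf, :nf] = np.diag(col_mu[ai])
            Hab = mu_mat[:, ai].T @ data.X
            H[:nf, nf:nf + p] = Hab
            H[nf:nf + p, :nf] = Hab.T
            H[nf:nf + p, nf:nf + p] = data.X.T @ (m[:, None] * data.X)
        if q:
            for j, rows in enumerate(data.slices):
                s = nf + p + j * q
                Wj = data.W[rows]
                mj = m[rows]
                grad[s:s + q] = Wj.T @ (data.d[rows] - mj) - Sinv @ state.u[j]
                Huu = Wj.T @ (mj[:, None] * Wj) + Sinv
                H[s:s + q, s:s + q] = Huu
                if update_fixed:
                    Hau = mu_mat[np.ix_(rows, data.alpha_idx)].T @ Wj
                    H[:nf, s:s + q] = Hau
                    H[s:s + q, :nf] = Hau.T
                    Hbu = data.X[rows].T @ (mj[:, None] * Wj)
                    H[nf:nf + p, s:s + q] = Hbu
                    H[s:s + q, nf:nf + p] = Hbu.T

        gnorm = np.max(np.abs(grad)) if dim else 0.0
        if gnorm < 1e-9:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            try:
                step = scipy.linalg.solve(H, grad, assume_a="pos")
            except scipy.linalg.LinAlgError:
                step = scipy.linalg.lstsq(H + 1e-8 * np.eye(dim), grad)[0]
        if not np.all(np.isfinite(step)):
            step = scipy.linalg.lstsq(H + 1e-6 * np.eye(dim), grad)[0]

        scale = 1.0
        for _ in range(40):
            cand = _State(state.alpha.copy(), state.beta.copy(), state.u.copy())
            if update_fixed:
                cand.alpha[data.alpha_idx] += scale * step[:nf]
                cand.beta += scale * step[nf:nf + p]
            if q:
                cand.u += scale * step[nf + p:].reshape(data.J, q)
            h_new, mu_new, m_new = _penalized_loglik(data, cand, Sinv)
            if np.isfinite(h_new) and h_new >= h - 1e-12:
                break
            scale *= 0.5
        else:
            raise FloatingPointError("inner Newton line search failed")
        improved = h_new - h
        state, h, mu_mat, m = cand, h_new, mu_new, m_new
        if improved < tol * (1.0 + abs(h)):
            stalls += 1
            # a stalled objective with a small (data-scale) gradient means
            # the remaining parameter error is negligible
            if gnorm < 1e-6 or stalls >= 2:
                break
        else:
            stalls = 0
    else:
        if gnorm > 1e-3:
            raise RuntimeError(
                f"inner Newton failed to converge (last |grad| = {gnorm:.2e})")
    return state, h, mu_mat, m


def _laplace_value(data: _Collapsed, state: _State, h: float, m: np.ndarray,
                   Sigma: np.ndarray, Sinv: np.ndarray) -> float:
    """Laplace marginal log-likelihood given the penalized optimum."""
    q = data.W.shape[1]
    if q == 0:
        return h
    sign, ld_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    total = h - 0.5 * data.J * ld_sigma
    for rows in data.slices:
        Wj = data.W[rows]
        Huu = Wj.T @ (m[rows][:, None] * Wj) + Sinv
        sgn, ld = np.linalg.slogdet(Huu)
        if sgn <= 0:
            return -np.inf
        total -= 0.5 * ld
    return total


# --------------------------------------------------------------------------
# public likelihood and fit
# --------------------------------------------------------------------------

def _unpack(params: np.ndarray, data: _Collapsed, q: int):
    nf, p, nt = len(data.alpha_idx), data.X.shape[1], _n_theta(q)
    if params.size != nf + p + nt:
        raise ValueError(f"params has length {params.size}, expected {nf + p + nt}")
    alpha = np.zeros(data.S)
    alpha[data.alpha_idx] = params[:nf]
    beta = np.asarray(params[nf:nf + p], dtype=float)
    theta = np.asarray(params[nf + p:], dtype=float)
    return alpha, beta, theta


def marginal_loglik(
    params: np.ndarray,
    person_periods: pd.DataFrame,
    spec: ModelSpec,
    grid: AgeGrid | None = None,
) -> float:
    """Laplace-approximated marginal log-likelihood at a parameter vector.

    ``params`` concatenates the free age contrasts (intervals present in
    the data, reference excluded, ascending), the fixed effects in the
    order ``intercept, sex, *spec.fixed_terms`` (minus any dropped
    collinear columns) and the log-Cholesky parameters of the random
    effects covariance (row-wise lower triangle, log diagonal).  For
    each center the mode of the joint density in the random effects is
    found by Newton iterations; the value sums the joint log-density at
    the mode and the Gaussian curvature correction.
    """
    grid = grid or AgeGrid()
    data = _Collapsed(person_periods, spec, grid)
    q = spec.n_random
    alpha, beta, theta = _unpack(np.asarray(params, dtype=float), data, q)
    psi = data.X @ beta
    if not np.all(np.isfinite(psi)):
        bad = np.nonzero(~np.isfinite(psi))[0][:5]
        raise ValueError(f"non-finite linear predictor for subject rows {bad.tolist()}")
    if q == 0:
        state = _State(alpha, beta, np.zeros((data.J, 0)))
        h, _, _ = _penalized_loglik(data, state, np.zeros((0, 0)))
        return h
    Sigma = _theta_to_sigma(theta, q)
    Sinv = np.linalg.inv(Sigma + 1e-300 * np.eye(q))
    state = _State(alpha, beta, np.zeros((data.J, q)))
    try:
        state, h, _, m = _joint_newton(data, state, Sinv, update_fixed=False, max_iter=50)
    except RuntimeError as exc:
        raise RuntimeError(f"inner Newton failed for a center mode: {exc}") from exc
    return _laplace_value(data, state, h, m, Sigma, Sinv)


@dataclass
class FitResult:
    """Maximum-likelihood fit of the multilevel piecewise-exponential model."""

    spec: ModelSpec
    grid: AgeGrid
    alpha: pd.Series                 # full length-S log relative hazards (ref = 0)
    beta: pd.Series                  # named fixed effects
    se_alpha: pd.Series
    se_beta: pd.Series
    vc: dict[str, float]             # sigma2_intercept, cov_intercept_sex, ...
    vc_se: dict[str, float]
    theta: np.ndarray
    cov_theta: np.ndarray | None
    loglik: float
    converged: bool
    boundary: bool
    n_iter: int
    posterior_modes: pd.DataFrame
    n_rows: int
    n_events: int
    dropped_columns: list[str]
    alpha_idx: list[int] = field(default_factory=list)
    #: covariance of the free fixed effects, order (alpha_free..., beta...)
    cov_fixed: np.ndarray | None = None
    #: marginal log-likelihood at each accepted outer iterate
    outer_trace: list[float] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        """Flat vector accepted by :func:`marginal_loglik` for this spec."""
        return np.concatenate([self.alpha.to_numpy()[self.alpha_idx],
                               self.beta.to_numpy(), self.theta])

    def coefficient_table(self) -> pd.DataFrame:
        """Flat coefficient table: term, estimate, SE, RR and 95% CI."""
        rows = []
        for name, est, se in zip(self.beta.index, self.beta, self.se_beta):
            level = "aggregate" if ("__between" in name or "__ctrmean" in name
                                    or "__pct" in name or name == "cos_latitude") \
                else "individual"
            rows.append((name, est, se, level))
        for k, (est, se) in enumerate(zip(self.alpha, self.se_alpha)):
            rows.append((f"age[{self.grid.labels()[k]}]", est, se, "age"))
        df = pd.DataFrame(rows, columns=["term", "estimate", "se", "level"])
        df["rr"] = np.exp(df["estimate"])
        df["ci_low"] = np.exp(df["estimate"] - 1.96 * df["se"])
        df["ci_high"] = np.exp(df["estimate"] + 1.96 * df["se"])
        vc_rows = [(f"vc[{k}]", v, self.vc_se.get(k, np.nan), "random", np.nan, np.nan, np.nan)
                   for k, v in self.vc.items()]
        return pd.concat([df, pd.DataFrame(vc_rows, columns=df.columns)], ignore_index=True)


def fit(
    person_periods: pd.DataFrame,
    spec: ModelSpec,
    grid: AgeGrid | None = None,
    init: np.ndarray | None = None,
    compute_vc_se: bool = True,
    outer_ftol: float = 1e-8,
    outer_gtol: float = 1e-5,
    max_outer: int = 500,
) -> FitResult:
    """Fit the model by maximizing the Laplace marginal likelihood.

    The covariance parameters move in an outer quasi-Newton loop
    (L-BFGS-B on the log-Cholesky scale with finite-difference
    gradients); fixed effects and center modes are re-solved exactly for
    every candidate covariance, warm-started from the previous solve.
    Fixed-effect standard errors come from the joint Hessian at the
    optimum; variance-component standard errors from a numerical Hessian
    of the profiled marginal likelihood over the covariance parameters
    (delta method onto the variance scale).
    """
    grid = grid or AgeGrid()
    data = _Collapsed(person_periods, spec, grid)
    q = spec.n_random
    nf, p = len(data.alpha_idx), data.X.shape[1]

    # ---- initialization: fixed-effects Poisson fit (Sigma = 0 limit) ----
    state0 = _State(np.zeros(data.S), np.zeros(p), np.zeros((data.J, 0)))
    state0.beta[0] = np.log(max(data.n_events, 1) / data.Tocc.sum())
    data_fe = data
    W_saved = data.W
    data_fe.W = np.zeros((data.n, 0))
    state0, h0, _, _ = _joint_newton(data_fe, state0, np.zeros((0, 0)))
    data.W = W_saved

    if q == 0:
        return _finalize_fixed_only(data, spec, grid, state0, h0)

    theta0 = np.zeros(_n_theta(q))
    diag_pos = np.cumsum([i + 1 for i in range(q)]) - 1
    theta0[diag_pos] = np.log(0.1)  # variances start at 0.01, covariances at 0
    if init is not None:
        alpha_i, beta_i, theta_i = _unpack(np.asarray(init, dtype=float), data, q)
        state0 = _State(alpha_i, beta_i, np.zeros((data.J, 0)))
        theta0 = theta_i

    warm = {"state": _State(state0.alpha.copy(), state0.beta.copy(), np.zeros((data.J, q))),
            "best": -np.inf}
    trace: list[float] = []

    def objective(theta: np.ndarray) -> float:
        Sigma = _theta_to_sigma(theta, q)
        Sinv = np.linalg.inv(Sigma)
        st = warm["state"]
        st = _State(st.alpha.copy(), st.beta.copy(), st.u.copy())
        try:
            st, h, _, m = _joint_newton(data, st, Sinv)
        except (RuntimeError, FloatingPointError):
            return 1e10
        warm["state"] = st
        val = _laplace_value(data, st, h, m, Sigma, Sinv)
        if not np.isfinite(val):
            return 1e10
        trace.append(val)
        if val > warm["best"]:
            warm["best"] = val
        return -val

    # diagonal lower bound log(1e-4): variance 1e-8, the boundary threshold
    bounds = [(-9.25, 4.0) if i in diag_pos else (-5.0, 5.0)
              for i in range(_n_theta(q))]
    accepted: list[float] = []

    def record(xk):
        accepted.append(-objective(xk))

    res = scipy.optimize.minimize(
        objective, theta0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": outer_ftol, "gtol": outer_gtol, "maxiter": max_outer,
                 "eps": 1e-5},
        callback=record,
    )
    theta_hat = res.x
    converged = bool(res.success) or res.status == 0

    Sigma = _theta_to_sigma(theta_hat, q)
    Sinv = np.linalg.inv(Sigma)
    state, h, mu_mat, m = _joint_newton(data, warm["state"], Sinv)
    loglik = _laplace_value(data, state, h, m, Sigma, Sinv)

    # ---- fixed-effect SEs from the joint Hessian ----
    cov_fix = _fixed_cov(data, mu_mat, m, Sinv)
    se = np.sqrt(np.clip(np.diag(cov_fix), 0.0, None))
    se_alpha = np.full(data.S, np.nan)
    se_alpha[data.alpha_idx] = se[:nf]
    se_beta = se[nf:nf + p]

    # ---- variance-component covariance by profiled numerical Hessian ----
    cov_theta = None
    vc_se: dict[str, float] = {}
    names = spec.random_names
    vc = _sigma_to_dict(Sigma, names)
    boundary = any(Sigma[i, i] < _VAR_THRESHOLD for i in range(q))
    if boundary:
        for i, nm in enumerate(names):
            if Sigma[i, i] < _VAR_THRESHOLD:
                vc[f"sigma2_{nm}"] = 0.0
    if compute_vc_se and converged and not boundary:
        cov_theta = _profiled_theta_cov(objective, theta_hat)
        if cov_theta is not None:
            vc_se = _vc_delta_se(theta_hat, cov_theta, q, names)
    if not converged:
        logger.warning("outer optimization did not converge: %s", res.message)
        se_alpha[:] = np.nan
        se_beta = np.full(p, np.nan)

    modes = pd.DataFrame(state.u, columns=[f"u_{n}" for n in names])
    modes.insert(0, "center_id", data.center_index)

    return FitResult(
        spec=spec, grid=grid,
        alpha=pd.Series(state.alpha, index=[f"age_{k}" for k in range(data.S)]),
        beta=pd.Series(state.beta, index=data.beta_names),
        se_alpha=pd.Series(se_alpha, index=[f"age_{k}" for k in range(data.S)]),
        se_beta=pd.Series(se_beta, index=data.beta_names),
        vc=vc, vc_se=vc_se, theta=theta_hat, cov_theta=cov_theta,
        loglik=float(loglik), converged=converged, boundary=boundary,
        n_iter=int(res.nit), posterior_modes=modes,
        n_rows=data.n_rows, n_events=data.n_events,
        dropped_columns=data.dropped, alpha_idx=list(data.alpha_idx),
        cov_fixed=cov_fix, outer_trace=accepted,
    )


def _finalize_fixed_only(data, spec, grid, state, h) -> FitResult:
    _, mu_mat, m = _model_quantities(data, state.alpha, state.beta,
                                     np.zeros((data.J, 0)))
    cov_fix = _fixed_cov(data, mu_mat, m, np.zeros((0, 0)))
    se = np.sqrt(np.clip(np.diag(cov_fix), 0.0, None))
    nf, p = len(data.alpha_idx), data.X.shape[1]
    se_alpha = np.full(data.S, np.nan)
    se_alpha[data.alpha_idx] = se[:nf]
    return FitResult(
        spec=spec, grid=grid,
        alpha=pd.Series(state.alpha, index=[f"age_{k}" for k in range(data.S)]),
        beta=pd.Series(state.beta, index=data.beta_names),
        se_alpha=pd.Series(se_alpha, index=[f"age_{k}" for k in range(data.S)]),
        se_beta=pd.Series(se[nf:nf + p], index=data.beta_names),
        vc={}, vc_se={}, theta=np.zeros(0), cov_theta=None,
        loglik=float(h), converged=True, boundary=False, n_iter=0,
        posterior_modes=pd.DataFrame({"center_id": data.center_index}),
        n_rows=data.n_rows, n_events=data.n_events,
        dropped_columns=data.dropped, alpha_idx=list(data.alpha_idx),
        cov_fixed=cov_fix,
    )


def _fixed_cov(data: _Collapsed, mu_mat, m, Sinv):
    """(alpha, beta) block of the inverse joint negative Hessian."""
    nf, p, q = len(data.alpha_idx), data.X.shape[1], data.W.shape[1]
    dim = nf + p + data.J * q
    H = np.zeros((dim, dim))
    ai = data.alpha_idx
    col_mu = mu_mat.sum(axis=0)
    H[:nf, :nf] = np.diag(col_mu[ai])
    Hab = mu_mat[:, ai].T @ data.X
    H[:nf, nf:nf + p] = Hab
    H[nf:nf + p, :nf] = Hab.T
    H[nf:nf + p, nf:nf + p] = data.X.T @ (m[:, None] * data.X)
    for j, rows in enumerate(data.slices):
        if q == 0:
            break
        s = nf + p + j * q
        Wj = data.W[rows]
        mj = m[rows]
        H[s:s + q, s:s + q] = Wj.T @ (mj[:, None] * Wj) + Sinv
        Hau = mu_mat[np.ix_(rows, ai)].T @ Wj
        H[:nf, s:s + q] = Hau
        H[s:s + q, :nf] = Hau.T
        Hbu = data.X[rows].T @ (mj[:, None] * Wj)
        H[nf:nf + p, s:s + q] = Hbu
        H[s:s + q, nf:nf + p] = Hbu.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
        try:
            Hinv = scipy.linalg.inv(H)
        except scipy.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
    return Hinv[:nf + p, :nf + p]


def _profiled_theta_cov(neg_loglik, theta_hat, step: float = 1e-3):
    nt = theta_hat.size
    H = np.zeros((nt, nt))
    f0 = neg_loglik(theta_hat)
    hsteps = step * np.maximum(1.0, np.abs(theta_hat))
    for i in range(nt):
        for j in range(i, nt):
            ei = np.zeros(nt); ei[i] = hsteps[i]
            ej = np.zeros(nt); ej[j] = hsteps[j]
            if i == j:
                f1 = neg_loglik(theta_hat + ei)
                f2 = neg_loglik(theta_hat - ei)
                H[i, i] = (f1 - 2 * f0 + f2) / hsteps[i] ** 2
            else:
                fpp = neg_loglik(theta_hat + ei + ej)
                fpm = neg_loglik(theta_hat + ei - ej)
                fmp = neg_loglik(theta_hat - ei + ej)
                fmm = neg_loglik(theta_hat - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hsteps[i] * hsteps[j])
    try:
        eig = np.linalg.eigvalsh(H)
        if eig.min() <= 0:
            return None
        return scipy.linalg.inv(H)
    except scipy.linalg.LinAlgError:
        return None


def _sigma_to_dict(Sigma: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    out = {}
    for i, ni in enumerate(names):
        out[f"sigma2_{ni}"] = float(Sigma[i, i])
    for i in range(len(names)):
        for j in range(i):
            out[f"cov_{names[j]}_{names[i]}"] = float(Sigma[i, j])
    return out


def _vc_delta_se(theta, cov_theta, q, names, step: float = 1e-6):
    keys = list(_sigma_to_dict(_theta_to_sigma(theta, q), names))

    def vec(th):
        return np.array(list(_sigma_to_dict(_theta_to_sigma(th, q), names).values()))

    J = np.zeros((len(keys), theta.size))
    for i in range(theta.size):
        e = np.zeros(theta.size)
        e[i] = step * max(1.0, abs(theta[i]))
        J[:, i] = (vec(theta + e) - vec(theta - e)) / (2 * e[i])
    var = np.clip(np.diag(J @ cov_theta @ J.T), 0.0, None)
    return dict(zip(keys, np.sqrt(var)))


# --------------------------------------------------------------------------
# derived reporting
# --------------------------------------------------------------------------

def predict_rr(fit_result: FitResult, variable: str, increment: float = 1.0) -> RateRatio:
    """Rate ratio and Wald 95% CI per ``increment`` units of a covariate."""
    if variable not in fit_result.beta.index:
        raise KeyError(f"variable {variable!r} not among fitted terms "
                       f"{list(fit_result.beta.index)}")
    b = float(fit_result.beta[variable])
    se = float(fit_result.se_beta[variable])
    lo, hi = increment * b - 1.96 * abs(increment) * se, increment * b + 1.96 * abs(increment) * se
    return RateRatio(variable, increment, float(np.exp(increment * b)),
                     float(np.exp(lo)), float(np.exp(hi)))


def derived_quantities(fit_result: FitResult) -> dict[str, float | None]:
    """Sex-specific outcome variances and intercept/slope correlations.

    Men's between-center outcome variance is ``sigma0^2``; women's is
    ``sigma0^2 + sigma1^2 + 2*sigma01`` because women combine the
    intercept and the sex-contrast random effects.  When a random
    exposure slope is present, the intercept-slope covariance is
    ``sigmaW0`` in men and ``sigmaW0 + sigmaW1`` in women; correlations
    divide by the corresponding standard deviations.  Delta-method SEs
    are attached where a covariance of the variance parameters is
    available.
    """
    names = fit_result.spec.random_names
    q = len(names)
    if q == 0:
        raise ValueError("fit has no random effects")

    def quantities(theta):
        S = _theta_to_sigma(theta, q)
        out = {"var_men": S[0, 0]}
        i_sex = names.index("sex") if "sex" in names else None
        i_exp = names.index("exposure") if "exposure" in names else None
        if i_sex is not None:
            out["var_women"] = S[0, 0] + S[i_sex, i_sex] + 2 * S[0, i_sex]
        if i_exp is not None:
            out["cov_intercept_slope_men"] = S[0, i_exp]
            denom = np.sqrt(S[0, 0] * S[i_exp, i_exp])
            out["corr_intercept_slope_men"] = S[0, i_exp] / denom if denom > 0 else np.nan
            if i_sex is not None:
                cw = S[0, i_exp] + S[i_sex, i_exp]
                vw = out["var_women"]
                out["cov_intercept_slope_women"] = cw
                dw = np.sqrt(max(vw, 0.0) * S[i_exp, i_exp])
                out["corr_intercept_slope_women"] = cw / dw if dw > 0 else np.nan
        return out

    vals = quantities(fit_result.theta)
    out: dict[str, float | None] = {k: float(v) for k, v in vals.items()}
    if fit_result.cov_theta is not None:
        keys = list(vals)

        def vec(th):
            return np.array([quantities(th)[k] for k in keys])

        th = fit_result.theta
        Jm = np.zeros((len(keys), th.size))
        for i in range(th.size):
            e = np.zeros(th.size)
            e[i] = 1e-6 * max(1.0, abs(th[i]))
            Jm[:, i] = (vec(th + e) - vec(th - e)) / (2 * e[i])
        var = np.clip(np.diag(Jm @ fit_result.cov_theta @ Jm.T), 0.0, None)
        for k, v in zip(keys, np.sqrt(var)):
            out[f"se_{k}"] = float(v) if np.isfinite(v) else None
    return out


def compare_variance_components(vc_a, vc_b, ndigits: int | None = 0) -> dict[str, float | None]:
    """Percent change 100 * (VC_a - VC_b) / VC_a per shared random term.

    Accepts :class:`FitResult` objects or plain ``{term: variance}``
    mappings (e.g. variance components read off a published table).
    Terms with ``VC_a = 0`` are reported as ``None`` (undefined).
    """
    da = vc_a.vc if isinstance(vc_a, FitResult) else dict(vc_a)
    db = vc_b.vc if isinstance(vc_b, FitResult) else dict(vc_b)
    shared = [k for k in da if k in db]
    if not shared:
        raise ValueError("no shared variance components to compare")
    out: dict[str, float | None] = {}
    for k in shared:
        if da[k] == 0:
            out[k] = None
            continue
        pct = 100.0 * (da[k] - db[k]) / da[k]
        out[k] = round(pct, ndigits) if ndigits is not None else pct
        if ndigits == 0 and out[k] is not None:
            out[k] = float(int(out[k]))
    return out
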