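"""Independent oracles for validating the fitting machinery.

Everything here is deliberately simple and slow: brute-force adaptive
Gauss-Hermite quadrature for the random-intercept marginal likelihood,
and direct maximization of the piecewise-exponential survival
log-likelihood.  Neither shares code with the estimation path it
validates.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.special

from pwemix.person_period import AgeGrid, survival_loglik_oracle


def agh_random_intercept_loglik(
    pp, grid: AgeGrid, alpha_free, beta, columns, var, n_nodes: int = 61
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood, random intercept only.

    ``beta`` covers (intercept, sex, *columns); ``alpha_free`` the age
    contrasts for occupied non-reference intervals, ascending.  Includes
    the same additive constant sum(d * log t) as the package likelihood.
    """
    alpha = np.zeros(grid.n_intervals)
    occupied = sorted(pp["interval"].unique())
    ai = [k for k in occupied if k != grid.reference_interval]
    alpha[ai] = alpha_free
    x, w = scipy.special.roots_hermite(n_nodes)
    total = 0.0
    for _, grp in pp.groupby("center_id", sort=True):
        X = np.column_stack([np.ones(len(grp)), grp["sex"].to_numpy()]
                            + [grp[c].to_numpy(dtype=float) for c in columns])
        eta0 = (np.log(grp["t"].to_numpy()) + alpha[grp["interval"].to_numpy()]
                + X @ np.asarray(beta, dtype=float))
        d = grp["d"].to_numpy()

        def neg_joint(u):
            eta = eta0 + u
            return -(np.sum(d * eta - np.exp(eta))
                     - 0.5 * u * u / var - 0.5 * np.log(2 * np.pi * var))

        res = scipy.optimize.minimize_scalar(
            neg_joint, bounds=(-15, 15), method="bounded",
            options={"xatol": 1e-13})
        mode = res.x
        curv = np.sum(np.exp(eta0 + mode)) + 1.0 / var
        sig = 1.0 / np.sqrt(curv)
        nodes = mode + np.sqrt(2.0) * sig * x
        vals = np.array([-neg_joint(u) for u in nodes])
        total += np.log(np.sum(w * np.exp(vals + x ** 2))) + np.log(np.sqrt(2.0) * sig)
    return float(total)


def direct_survival_mle(records, grid: AgeGrid, columns, alpha_idx):
    """Maximize the survival log-likelihood directly over (alpha, beta).

    Returns (alpha_free, beta, loglik) with beta over (intercept, sex,
    *columns).  Uses BFGS on the exact piecewise-exponential likelihood
    evaluated from subject records, bypassing any person-period table.
    """
    X = np.column_stack([np.ones(len(records)), records["sex"].to_numpy()]
                        + [records[c].to_numpy(dtype=float) for c in columns])
    p = X.shape[1]
    nf = len(alpha_idx)
    S = grid.n_intervals
    edges = np.concatenate([[-np.inf], grid.boundaries, [np.inf]])
    entry = records["age_entry"].to_numpy(dtype=float)
    exit_ = records["age_exit"].to_numpy(dtype=float)
    occ = np.clip(np.minimum(exit_[:, None], edges[None, 1:])
                  - np.maximum(entry[:, None], edges[None, :-1]), 0.0, None)
    d = records["event"].to_numpy(dtype=int)
    k_exit = grid.interval_of(np.nextafter(exit_, entry))
    d_by_k = np.bincount(k_exit[d == 1], minlength=S).astype(float)

    def neg(par):
        alpha = np.zeros(S)
        alpha[list(alpha_idx)] = par[:nf]
        lh = alpha[None, :] + (X @ par[nf:])[:, None]
        return -survival_loglik_oracle(records, grid, lh)

    def neg_grad(par):
        alpha = np.zeros(S)
        alpha[list(alpha_idx)] = par[:nf]
        haz = np.exp(alpha[None, :] + (X @ par[nf:])[:, None])
        expected = occ * haz  # (n, S) expected events per interval
        g_alpha = d_by_k - expected.sum(axis=0)
        g_beta = X.T @ (d - expected.sum(axis=1))
        return -np.concatenate([g_alpha[list(alpha_idx)], g_beta])

    x0 = np.zeros(nf + p)
    x0[nf] = -3.0
    res = scipy.optimize.minimize(neg, x0, jac=neg_grad, method="BFGS",
                                  options={"gtol": 1e-11, "maxiter": 5000})
    return res.x[:nf], res.x[nf:], -res.fun
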