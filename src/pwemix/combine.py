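"""Bootstrap propagation of calibration uncertainty, combined by Rubin's rule.

Replacing a questionnaire exposure by calibrated values E(T | Q, Z)
makes the disease-model coefficients depend on an estimated calibration
model; their naive standard errors ignore that estimation step.  The
calibration subsample is therefore resampled with replacement B times
(stratified within center, preserving the calibration design); for each
replicate the calibration model is refitted, calibrated values are
re-predicted, and the disease model is refitted.  Rubin's rule combines
the replicates: total variance = mean within-replicate variance +
(1 + 1/B) x between-replicate variance of the estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import fit_calibration, predict_expected_intake
from .glmm import FitResult
from .person_period import AgeGrid
from .pipeline import fit_level

logger = logging.getLogger(__name__)

__all__ = ["CombinedEstimate", "rubin_combine", "bootstrap_calibrated_fits",
           "rubin_combine_fits"]


@dataclass(frozen=True)
class CombinedEstimate:
    point: float          # mean of the replicate estimates
    within_var: float     # mean within-replicate variance
    between_var: float    # sample variance of the estimates (divisor B-1)
    total_var: float      # within + (1 + 1/B) * between
    se: float
    n_replicates: int


def rubin_combine(estimates, variances) -> CombinedEstimate:
    """Combine B replicate estimates and their variances by Rubin's rule."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.ndim != 1 or est.shape != var.shape:
        raise ValueError("estimates and variances must be equal-length vectors")
    B = est.size
    if B < 2:
        raise ValueError("Rubin's rule needs at least 2 replicates")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    wbar = float(var.mean())
    bvar = float(est.var(ddof=1))
    total = wbar + (1.0 + 1.0 / B) * bvar
    return CombinedEstimate(float(est.mean()), wbar, bvar, total, float(np.sqrt(total)), B)


def bootstrap_calibrated_fits(
    cohort: pd.DataFrame,
    level: int = 3,
    B: int = 10,
    seed: int = 0,
    grid: AgeGrid | None = None,
    exposure: str = "exposure_q",
    recall_col: str = "recall",
    confounders: tuple[str, ...] = (),
    aggregate: tuple[str, ...] = (),
    calib_covariates: tuple[str, ...] = (),
    centering: str = "center_sex",
    stratified: bool = True,
    center_col: str = "center_id",
    **fit_kwargs,
) -> list[FitResult]:
    """B calibrated refits of the disease model under subsample resampling.

    Each replicate resamples the calibration subsample with replacement
    (within center when ``stratified``), refits the calibration
    regression, re-predicts E(T | Q, Z) for the whole cohort under the
    column name ``<exposure>__cal`` and refits the model ladder rung
    ``level`` on the calibrated exposure.  Deterministic given ``seed``.
    Replicates whose disease-model fit does not converge are dropped
    with a warning; more than 20% dropped is an error.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    sub = cohort[cohort[recall_col].notna()]
    if sub.empty:
        raise ValueError("no calibration subsample (no non-missing recall values)")
    rng = np.random.default_rng(seed)
    fits: list[FitResult] = []
    n_failed = 0
    for b in range(B):
        if stratified:
            parts = []
            for _, grp in sub.groupby(center_col, sort=True):
                idx = rng.integers(0, len(grp), size=len(grp))
                parts.append(grp.iloc[idx])
            resampled = pd.concat(parts, ignore_index=True)
        else:
            idx = rng.integers(0, len(sub), size=len(sub))
            resampled = sub.iloc[idx].reset_index(drop=True)
        model = fit_calibration(resampled, q_col=exposure, recall_col=recall_col,
                                covariates=calib_covariates, center_col=center_col)
        cal = predict_expected_intake(model, cohort, center_col=center_col)
        boot_cohort = cohort.assign(**{f"{exposure}__cal": cal})
        result = fit_level(boot_cohort, level, exposure=f"{exposure}__cal",
                           confounders=confounders, aggregate=aggregate,
                           grid=grid, centering=centering, **fit_kwargs)
        if not result.converged:
            n_failed += 1
            warnings.warn(f"bootstrap replicate {b} did not converge; dropped", stacklevel=2)
            continue
        fits.append(result)
    if n_failed > 0.2 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed to converge")
    return fits


def rubin_combine_fits(fits: list[FitResult], terms: list[str] | None = None) -> pd.DataFrame:
    """Rubin-combined coefficient table across replicate fits.

    One row per fixed-effect term with the combined point estimate, SE,
    RR and 95% CI; the ``se_source`` column records ``rubin(B)``.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 replicate fits")
    terms = terms or list(fits[0].beta.index)
    rows = []
    for term in terms:
        est = [float(f.beta[term]) for f in fits]
        var = [float(f.se_beta[term]) ** 2 for f in fits]
        c = rubin_combine(est, var)
        rows.append((term, c.point, c.se, np.exp(c.point),
                     np.exp(c.point - 1.96 * c.se), np.exp(c.point + 1.96 * c.se),
                     f"rubin({c.n_replicates})"))
    return pd.DataFrame(rows, columns=["term", "estimate", "se", "rr",
                                       "ci_low", "ci_high", "se_source"])
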