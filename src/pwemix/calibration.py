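"""Linear regression calibration for error-prone dietary exposures.

A questionnaire measurement Q carries systematic (center-specific) and
random error; a reference instrument R (a single standardized 24-hour
recall) is assumed unbiased for true intake T but noisy.  In the
calibration subsample, R is regressed by ordinary least squares on Q,
confounders Z, day-of-week and season of the recall, and center fixed
effects.  The fitted conditional expectation E(T | Q, Z) is then
predicted for every cohort member and replaces Q in the disease model,
de-attenuating the individual-level coefficient.

Day-of-week and season only exist for recall measurements, so cohort-
wide predictions hold them at their subsample means (equivalently,
predictions are marginalized over them); a subject's calibrated value
therefore never depends on an undefined recall day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["CalibrationModel", "fit_calibration", "predict_expected_intake",
           "calibration_shrinkage_report"]


@dataclass
class CalibrationModel:
    """OLS calibration fit for one dietary variable."""

    q_col: str
    params: pd.Series
    se: pd.Series
    residual_var: float
    n: int
    covariates: tuple[str, ...]
    weekday_means: pd.Series      # subsample means of the weekday dummies
    season_means: pd.Series
    center_levels: list | None    # None when center fixed effects are off
    dropped: list[str]

    @property
    def slope(self) -> float:
        return float(self.params[self.q_col])

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"nutrient": self.q_col, "term": self.params.index,
             "estimate": self.params.to_numpy(),
             "se": self.se.reindex(self.params.index).to_numpy()}
        )


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(pd.unique(series.dropna()))
    cols = {f"{prefix}_{lev:g}" if isinstance(lev, float) else f"{prefix}_{lev}":
            (series == lev).astype(float) for lev in levels[1:]}  # first level = reference
    return pd.DataFrame(cols, index=series.index)


def fit_calibration(
    subsample: pd.DataFrame,
    q_col: str = "exposure_q",
    recall_col: str = "recall",
    covariates: tuple[str, ...] = (),
    weekday_col: str = "recall_weekday",
    season_col: str = "recall_season",
    center_col: str = "center_id",
    include_center: bool = True,
) -> CalibrationModel:
    """Regress the reference instrument on the questionnaire and covariates.

    ``subsample`` is restricted to rows with a non-missing recall; the
    regression uses Q, the listed confounder columns, day-of-week and
    season indicator contrasts, and (by default) center fixed effects.
    Collinear columns are dropped with a log message.
    """
    rows = subsample[subsample[recall_col].notna()].copy()
    if weekday_col in rows.columns and rows[weekday_col].notna().any():
        wd = _dummies(rows[weekday_col], "weekday")
        se_dummies = _dummies(rows[season_col], "season")
    else:
        wd = pd.DataFrame(index=rows.index)
        se_dummies = pd.DataFrame(index=rows.index)

    parts = [pd.Series(1.0, index=rows.index, name="intercept"),
             rows[q_col].astype(float)]
    parts += [rows[c].astype(float) for c in covariates]
    design = pd.concat(parts + [wd, se_dummies], axis=1)
    center_levels = None
    if include_center:
        center_levels = sorted(pd.unique(rows[center_col]))
        cdum = pd.DataFrame(
            {f"center_{lev}": (rows[center_col] == lev).astype(float)
             for lev in center_levels[1:]}, index=rows.index)
        design = pd.concat([design, cdum], axis=1)

    complete = design.notna().all(axis=1) & rows[recall_col].notna()
    design, y = design[complete], rows.loc[complete, recall_col].astype(float)
    if len(design) <= design.shape[1]:
        raise ValueError(
            f"calibration subsample too small: n={len(design)} rows for "
            f"{design.shape[1]} parameters")

    # drop collinear columns (QR with pivoting), keep names
    Xv = design.to_numpy(dtype=float)
    import scipy.linalg
    _, r, piv = scipy.linalg.qr(Xv, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > 1e-8 * max(diag[0], 1.0)))
    keep = sorted(piv[:rank])
    dropped = [design.columns[i] for i in sorted(piv[rank:])]
    if dropped:
        logger.warning("calibration: dropped collinear columns %s", dropped)
    design = design.iloc[:, keep]

    ols = sm.OLS(y, design).fit()
    resid_var = float(ols.scale) if len(design) > design.shape[1] else 0.0
    return CalibrationModel(
        q_col=q_col,
        params=ols.params,
        se=ols.bse,
        residual_var=max(resid_var, 0.0),
        n=len(design),
        covariates=tuple(covariates),
        weekday_means=wd.loc[complete].mean() if wd.shape[1] else pd.Series(dtype=float),
        season_means=se_dummies.loc[complete].mean() if se_dummies.shape[1] else pd.Series(dtype=float),
        center_levels=center_levels,
        dropped=dropped,
    )


def predict_expected_intake(
    model: CalibrationModel,
    cohort: pd.DataFrame,
    center_col: str = "center_id",
) -> pd.Series:
    """Calibrated intake E(T | Q, Z) for every subject with complete Q and Z.

    Recall-specific covariates (weekday, season) are held at their
    calibration-subsample means; center fixed effects use the subject's
    own center.  Rows with missing predictors get NaN (excluded
    downstream with a logged count).
    """
    parts = {"intercept": pd.Series(1.0, index=cohort.index)}
    parts[model.q_col] = cohort[model.q_col].astype(float)
    for c in model.covariates:
        parts[c] = cohort[c].astype(float)
    design = pd.DataFrame(parts)
    for name, mean in model.weekday_means.items():
        design[name] = mean
    for name, mean in model.season_means.items():
        design[name] = mean
    if model.center_levels is not None:
        for lev in model.center_levels[1:]:
            design[f"center_{lev}"] = (cohort[center_col] == lev).astype(float)
    design = design.reindex(columns=model.params.index)
    if design.isna().any().any():
        n_bad = int(design.isna().any(axis=1).sum())
        logger.info("predict_expected_intake: %d rows with missing predictors -> NaN", n_bad)
    pred = design.to_numpy(dtype=float) @ model.params.to_numpy()
    return pd.Series(pred, index=cohort.index, name=f"{model.q_col}__cal")


def calibration_shrinkage_report(
    raw: pd.Series,
    calibrated: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Within/between variance and ICC of raw vs calibrated columns.

    Calibration shrinks the within-center component (predictions are
    fitted values), so the calibrated ICC is expected to be larger.
    """
    from .icc import icc_continuous

    rows = []
    for name, col in (("raw", raw), ("calibrated", calibrated)):
        ok = col.notna()
        res = icc_continuous(col[ok], groups[ok], method="moments")
        rows.append((name, res.sigma2_between, res.sigma2_within, res.icc))
    return pd.DataFrame(rows, columns=["column", "between_var", "within_var", "icc"])
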