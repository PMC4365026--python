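"""Convenience wiring from a subject-level cohort table to fitted models.

The model ladder:

1. sex-specific random intercepts, age effects only;
2. + individual-level covariates (entered as overall values);
3. individual covariates centered on group means, plus between-center
   exposure contrast and aggregate covariates;
4. + a random slope on the within-center exposure deviation.
"""

from __future__ import annotations

import pandas as pd

from .design import center_covariates
from .glmm import FitResult, ModelSpec, fit
from .person_period import AgeGrid, expand

__all__ = ["build_model_frame", "fit_level", "fit_ladder"]


def build_model_frame(
    cohort: pd.DataFrame,
    exposure: str,
    confounders: tuple[str, ...] = (),
    centering: str = "center_sex",
) -> pd.DataFrame:
    """Attach ``__within`` / ``__between`` columns for exposure and confounders."""
    return center_covariates(cohort, [exposure, *confounders], grouping=centering).table


def fit_level(
    cohort: pd.DataFrame,
    level: int,
    exposure: str = "exposure_q",
    confounders: tuple[str, ...] = (),
    aggregate: tuple[str, ...] = (),
    grid: AgeGrid | None = None,
    centering: str = "center_sex",
    **fit_kwargs,
) -> FitResult:
    """Fit one rung of the model ladder from a subject-level cohort table."""
    grid = grid or AgeGrid()
    table = cohort
    if level >= 3:
        table = build_model_frame(cohort, exposure, confounders, centering)
    pp = expand(table, grid)
    spec = ModelSpec.for_level(level, exposure, tuple(confounders), tuple(aggregate))
    return fit(pp, spec, grid, **fit_kwargs)


def fit_ladder(
    cohort: pd.DataFrame,
    levels: tuple[int, ...] = (1, 2, 3, 4),
    **kwargs,
) -> dict[int, FitResult]:
    return {lv: fit_level(cohort, lv, **kwargs) for lv in levels}
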