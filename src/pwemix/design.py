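"""Within/between design construction for multilevel hazard models.

Group-mean centering splits each individual-level covariate X into a
within-group deviation ``X - mean_g(X)`` and a between-group contrast
``mean_g(X) - grand mean``, so that one model can carry both the
individual-level and the aggregate (ecologic) component of an
association.  Aggregate covariates (center means, center percentages of
a binary trait, cosine of latitude) and product terms (exposure x
age-interval indicators for proportional-hazards checks, aggregate x
within products for cross-level interaction) are built here as plain
columns so the fitting module stays agnostic of their origin.

Naming convention: ``<var>__within``, ``<var>__between``,
``<var>__ctrmean`` for the stored group mean, ``<var>__pct`` for binary
percentages, ``<a>_x_<b>`` for products.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CenteredDesign", "center_covariates", "build_aggregate_covariates",
           "build_interactions"]

_GROUPINGS = {"center": ["center_id"], "center_sex": ["center_id", "sex"]}


@dataclass
class CenteredDesign:
    """Centered columns plus the means needed to reconstruct the input."""

    table: pd.DataFrame            # input plus <var>__within/__between/__ctrmean
    group_means: pd.DataFrame      # one row per group per variable
    grand_means: dict[str, float]
    grouping: str
    weighting: str

    def columns_for(self, var: str) -> tuple[str, str]:
        return f"{var}__within", f"{var}__between"


def center_covariates(
    table: pd.DataFrame,
    columns: list[str],
    grouping: str = "center_sex",
    weighting: str = "subject",
) -> CenteredDesign:
    """Split covariates into within-group and between-group components.

    Parameters
    ----------
    grouping
        ``"center"`` groups by center only; ``"center_sex"`` (default)
        centers on sex- and center-specific means.
    weighting
        ``"subject"`` computes the grand mean over subjects; ``"group"``
        averages the group means (affects only the intercept's
        interpretation).

    Within each group, ``within + between + grand mean`` reconstructs
    the original value exactly, and the within column averages to zero.
    Missing values are excluded pairwise from the means and yield
    missing centered values.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; use one of {sorted(_GROUPINGS)}")
    if weighting not in ("subject", "group"):
        raise ValueError("weighting must be 'subject' or 'group'")
    keys = _GROUPINGS[grouping]
    missing_keys = [k for k in keys if k not in table.columns]
    if missing_keys:
        raise ValueError(f"grouping columns absent from table: {missing_keys}")

    out = table.copy()
    gm_frames = []
    grand: dict[str, float] = {}
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
        vals = table[col].astype(float)
        n_miss = int(vals.isna().sum())
        if n_miss:
            logger.info("center_covariates: %d missing values in %s excluded pairwise", n_miss, col)
        means = vals.groupby([table[k] for k in keys]).transform("mean")
        if weighting == "subject":
            g = float(vals.mean())
        else:
            g = float(vals.groupby([table[k] for k in keys]).mean().mean())
        out[f"{col}__within"] = vals - means
        out[f"{col}__between"] = means - g
        out[f"{col}__ctrmean"] = means
        if np.nanmax(np.abs(out[f"{col}__between"])) < 1e-12:
            warnings.warn(f"column {col!r} has no between-group variation", stacklevel=2)
        grand[col] = g
        gm = vals.groupby([table[k] for k in keys]).mean().rename(col)
        gm_frames.append(gm)
    group_means = pd.concat(gm_frames, axis=1).reset_index() if gm_frames else pd.DataFrame()
    return CenteredDesign(out, group_means, grand, grouping, weighting)


def build_aggregate_covariates(
    table: pd.DataFrame,
    mean_columns: list[str] | None = None,
    percent_columns: list[str] | None = None,
    latitude_column: str | None = None,
    grouping: str = "center",
) -> pd.DataFrame:
    """Attach center-level covariates, broadcast back to subject rows.

    Continuous columns get per-group means (``<var>__ctrmean``), binary
    columns per-group percentages (``<var>__pct``, 0-100), and a
    latitude column in degrees is transformed to ``cos_latitude``.
    """
    keys = _GROUPINGS[grouping]
    out = table.copy()
    for col in mean_columns or []:
        out[f"{col}__ctrmean"] = table[col].astype(float).groupby(
            [table[k] for k in keys]).transform("mean")
    for col in percent_columns or []:
        vals = table[col]
        uniq = set(pd.unique(vals.dropna()))
        if not uniq <= {0, 1}:
            raise ValueError(f"percentage column {col!r} is not binary 0/1 (values {sorted(uniq)[:5]})")
        out[f"{col}__pct"] = 100.0 * vals.astype(float).groupby(
            [table[k] for k in keys]).transform("mean")
    if latitude_column is not None:
        out["cos_latitude"] = np.cos(np.deg2rad(table[latitude_column].astype(float)))
    return out


def build_interactions(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Append elementwise product columns ``<a>_x_<b>`` for each pair.

    Covers both the proportional-hazards check (exposure x age-interval
    indicator) and cross-level interaction (aggregate x within product);
    either use is just a fixed-effect product column downstream.
    """
    out = table.copy()
    for a, b in pairs:
        for c in (a, b):
            if c not in table.columns:
                raise ValueError(f"column {c!r} not in table")
        out[f"{a}_x_{b}"] = table[a].astype(float) * table[b].astype(float)
    return out


def interval_indicators(person_periods: pd.DataFrame, drop: int | None = None) -> pd.DataFrame:
    """One 0/1 column ``age_k`` per age interval present, optionally dropping one."""
    out = person_periods.copy()
    for k in sorted(person_periods["interval"].unique()):
        if drop is not None and k == drop:
            continue
        out[f"age_{k}"] = (person_periods["interval"] == k).astype(float)
    return out
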