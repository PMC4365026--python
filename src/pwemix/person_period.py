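"""Person-period (counting-process) expansion on the age scale.

A piecewise-exponential survival model with hazard constant within
predefined age intervals is likelihood-equivalent to a Poisson regression
on an expanded table with one row per subject x occupied interval, an
event indicator ``d`` on the last occupied row, and the time at risk in
the interval entering as a log offset ``t``.  :func:`expand` builds that
table; :func:`survival_loglik_oracle` evaluates the survival likelihood
directly from subject records, bypassing the Poisson representation, and
exists so the equivalence can be verified rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgeGrid", "expand", "survival_loglik_oracle"]

#: Default age-interval boundaries (years).  Seven intervals: <50, 50-54,
#: 55-59, 60-64, 65-69, 70-74, >=75; the 60-64 interval is the reference.
DEFAULT_BOUNDARIES = (50.0, 55.0, 60.0, 65.0, 70.0, 75.0)


@dataclass(frozen=True)
class AgeGrid:
    """Partition of the age axis into ``S = len(boundaries) + 1`` intervals.

    Interval ``k`` (0-based) covers ``[boundaries[k-1], boundaries[k])``;
    the first and last intervals are open-ended.  ``reference_interval``
    is the 0-based index of the interval whose log relative hazard is
    pinned to zero in the disease model.
    """

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES
    reference_interval: int = 3

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 1 or not np.all(np.isfinite(b)):
            raise ValueError("age grid needs at least one finite boundary")
        if not np.all(np.diff(b) > 0):
            raise ValueError("age-grid boundaries must be strictly increasing")
        if not 0 <= self.reference_interval < b.size + 1:
            raise ValueError(
                f"reference_interval {self.reference_interval} outside 0..{b.size}"
            )
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) + 1

    def interval_of(self, age: np.ndarray | float) -> np.ndarray:
        """0-based interval index; half-open [tau_{k-1}, tau_k) convention."""
        return np.searchsorted(self.boundaries, np.asarray(age, dtype=float), side="right")

    def labels(self) -> list[str]:
        b = self.boundaries
        out = [f"<{b[0]:g}"]
        out += [f"{lo:g}-{hi:g}" for lo, hi in zip(b[:-1], b[1:])]
        out.append(f">={b[-1]:g}")
        return out


def _occupancy(entry: np.ndarray, exit_: np.ndarray, grid: AgeGrid) -> np.ndarray:
    """(n, S) matrix of time spent in each age interval between entry and exit."""
    edges = np.concatenate([[-np.inf], grid.boundaries, [np.inf]])
    lo = np.maximum(entry[:, None], edges[None, :-1])
    hi = np.minimum(exit_[:, None], edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def expand(records: pd.DataFrame, grid: AgeGrid | None = None) -> pd.DataFrame:
    """Expand subject records into the person-period table.

    Parameters
    ----------
    records
        One row per subject with at least ``subject_id``, ``center_id``,
        ``sex``, ``age_entry``, ``age_exit`` and ``event``; any further
        columns (exposures, confounders) are carried over unchanged.
    grid
        Age grid; defaults to the standard 7-interval grid.

    Returns
    -------
    DataFrame with one row per subject x occupied interval carrying
    ``interval`` (0-based index), ``interval_label``, the offset ``t``
    (years at risk in the interval) and the event flag ``d`` placed on
    the last occupied row only.  Total person-time is conserved exactly.
    """
    grid = grid or AgeGrid()
    req = ["subject_id", "age_entry", "age_exit", "event"]
    missing = [c for c in req if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")

    entry = records["age_entry"].to_numpy(dtype=float)
    exit_ = records["age_exit"].to_numpy(dtype=float)
    bad = ~(np.isfinite(entry) & np.isfinite(exit_)) | (exit_ <= entry)
    if bad.any():
        ids = records.loc[bad, "subject_id"].tolist()[:10]
        raise ValueError(
            f"{int(bad.sum())} record(s) with non-finite ages or age_exit <= age_entry "
            f"(first offenders: {ids})"
        )

    occ = _occupancy(entry, exit_, grid)          # (n, S)
    occupied = occ > 0.0
    n_rows = occupied.sum(axis=1)
    subj_idx = np.repeat(np.arange(len(records)), n_rows)
    interval = np.nonzero(occupied)[1]
    t = occ[occupied]

    # event flag on the last occupied interval of each subject
    last = np.zeros(occupied.shape, dtype=bool)
    last[np.arange(len(records)), grid.interval_of(np.nextafter(exit_, entry))] = True
    d = (last[occupied] & np.repeat(records["event"].to_numpy(dtype=int), n_rows).astype(bool)).astype(int)

    carried = records.drop(columns=["age_entry", "age_exit", "event"]).iloc[subj_idx].reset_index(drop=True)
    labels = np.asarray(grid.labels(), dtype=object)
    out = pd.DataFrame(
        {
            "interval": interval,
            "interval_label": labels[interval],
            "t": t,
            "d": d,
        }
    )
    return pd.concat([carried, out], axis=1)


def survival_loglik_oracle(
    records: pd.DataFrame,
    grid: AgeGrid,
    log_hazard: np.ndarray,
) -> float:
    """Exact piecewise-exponential survival log-likelihood from subject records.

    ``log_hazard`` is either a length-S vector (shared hazard) or an
    (n_subjects, S) matrix of subject-specific log hazards on the grid.
    Returns ``sum_i [ d_i * log lambda_i(exit) - integral of lambda_i over
    follow-up ]`` computed directly, without person-period expansion.
    """
    entry = records["age_entry"].to_numpy(dtype=float)
    exit_ = records["age_exit"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    lh = np.asarray(log_hazard, dtype=float)
    if lh.ndim == 1:
        lh = np.broadcast_to(lh, (len(records), lh.size))
    if not np.all(np.isfinite(lh) | ((lh == -np.inf))):
        raise ValueError("log hazards must be finite (or -inf for zero hazard)")

    occ = _occupancy(entry, exit_, grid)
    cumhaz = np.sum(occ * np.exp(lh), axis=1)
    k_exit = AgeGrid.interval_of(grid, np.nextafter(exit_, entry))
    lh_exit = lh[np.arange(len(records)), k_exit]
    return float(np.sum(d * lh_exit) - np.sum(cumhaz))
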