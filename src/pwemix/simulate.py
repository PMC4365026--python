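"""Synthetic multicenter cohort generator.

Generates cohorts with the structure the disease and calibration models
assume: centers with multivariate-normal random effects on the log
baseline hazard (intercept, sex contrast, exposure slope), a continuous
true exposure split into between-center and within-center variance, an
error-prone questionnaire instrument with center-specific systematic
error, an unbiased but noisy reference instrument observed on a random
subsample, and piecewise-constant hazards on the age scale with
administrative censoring.

Randomness is stream-seeded: one master seed spawns an independent
substream per center (center effects first, then subject-level draws in
a fixed order), so adding centers or resizing a later center never
perturbs the draws of earlier centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .person_period import AgeGrid

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_event_times"]


def _as_per_center(value, n_centers: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_centers, float(arr))
    if arr.shape != (n_centers,):
        raise ValueError(f"{name} must be scalar or length n_centers={n_centers}")
    return arr


@dataclass
class SimulationConfig:
    """Ground-truth parameters for a synthetic multicenter cohort.

    Defaults emulate a large European multicenter nutrition cohort with
    a rare outcome on the age time scale: 28 centers, mostly-female
    enrolment, a dietary exposure in g/day with moderate center-level
    clustering (true-intake ICC = 4.5/(4.5+18) = 0.2), a questionnaire
    with center-specific additive and multiplicative error around an
    average slope of 0.6, and a reference instrument that is unbiased
    for true intake but dominated by day-to-day noise, observed on an
    8% subsample.
    """

    n_centers: int = 28
    subjects_per_center: int | Sequence[int] = 1500
    sex_fraction: float | Sequence[float] = 0.7  # P(sex = 1), 1 = women
    #: 3x3 covariance of (u0 intercept, u1 sex contrast, uW exposure slope)
    random_effects_cov: np.ndarray = field(
        default_factory=lambda: np.diag([0.03, 0.03, 0.003])
    )
    baseline_log_hazard: float = -7.0  # log events / person-year, reference interval, men
    #: log relative hazards per age interval; entry at the reference interval is 0
    log_relative_hazards: Sequence[float] = (-1.6, -1.0, -0.5, 0.0, 0.35, 0.65, 0.9)
    sex_log_rr: float = np.log(0.66)  # fixed sex contrast (delta_1)
    beta_within: float = np.log(0.90) / 10.0  # log-RR per exposure unit, individual level
    beta_between: float = np.log(0.90) / 10.0  # log-RR per unit of center mean
    gamma_within: Sequence[float] = ()
    gamma_between: Sequence[float] = ()
    confounder_sds: Sequence[float] = ()  # one entry per confounder column z1, z2, ...
    exposure_grand_mean: float = 22.0
    exposure_between_var: float = 4.5
    exposure_within_var: float = 18.0
    #: per-center questionnaire error Q = a_j + b_j * T + eps; None draws
    #: a_j ~ N(4, 1.5^2), b_j ~ N(0.6, 0.1^2) from the center streams
    questionnaire_intercepts: float | Sequence[float] | None = None
    questionnaire_slopes: float | Sequence[float] | None = None
    questionnaire_noise_var: float = 10.0
    recall_noise_var: float = 50.0  # reference instrument R = T + noise
    recall_subsample_fraction: float = 0.08
    entry_age_range: tuple[float, float] = (35.0, 70.0)
    censoring_age: float = 80.0
    max_followup: float = 13.0  # administrative end of follow-up, years after entry
    grid: AgeGrid = field(default_factory=AgeGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.random_effects_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("random_effects_cov must be a symmetric 3x3 matrix")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10:
            raise ValueError("random_effects_cov must be positive semi-definite")
        self.random_effects_cov = cov
        nj = np.asarray(self.subjects_per_center)
        if np.any(nj <= 0):
            raise ValueError("subjects_per_center must be positive (empty centers not allowed)")
        for name in ("exposure_between_var", "exposure_within_var",
                     "questionnaire_noise_var", "recall_noise_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.recall_subsample_fraction <= 1.0:
            raise ValueError("recall_subsample_fraction must be in (0, 1]")
        alphas = np.asarray(self.log_relative_hazards, dtype=float)
        if alphas.size != self.grid.n_intervals:
            raise ValueError("log_relative_hazards length must equal number of age intervals")
        if alphas[self.grid.reference_interval] != 0.0:
            raise ValueError("log relative hazard at the reference interval must be 0")
        if len(self.gamma_within) != len(self.confounder_sds) or \
                len(self.gamma_between) != len(self.confounder_sds):
            raise ValueError("gamma_within/gamma_between must match confounder_sds in length")
        if not self.entry_age_range[0] < self.entry_age_range[1] < self.censoring_age:
            raise ValueError("need entry_age_range[0] < entry_age_range[1] < censoring_age")


def _psd_cholesky(A: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Lower-triangular factor L with L L' = A for PSD A.

    Equals the ordinary Cholesky factor for positive-definite input;
    degenerate directions (zero pivots) give exactly-zero columns, so a
    zero covariance yields exactly zero random effects.
    """
    n = A.shape[0]
    L = np.zeros((n, n))
    for j in range(n):
        d = A[j, j] - L[j, :j] @ L[j, :j]
        if d <= tol:
            continue
        L[j, j] = np.sqrt(d)
        for i in range(j + 1, n):
            L[i, j] = (A[i, j] - L[i, :j] @ L[j, :j]) / L[j, j]
    return L


def simulate_event_times(
    log_hazard_by_interval: Sequence[float],
    entry_age: float,
    censoring_age: float,
    rng: np.random.Generator,
    grid: AgeGrid | None = None,
) -> tuple[float, int]:
    """Draw one piecewise-exponential event time by hazard inversion.

    Returns ``(age_exit, event)``; ``event = 0`` with ``age_exit =
    censoring_age`` when the drawn time exceeds the censoring age.  A
    log hazard of ``-inf`` encodes zero hazard in that interval.
    """
    if not entry_age < censoring_age:
        raise ValueError("entry_age must be below censoring_age")
    lh = np.asarray(log_hazard_by_interval, dtype=float)
    if np.any(np.isnan(lh)) or np.any(lh == np.inf):
        raise ValueError("log hazards must be < +inf and not NaN")
    grid = grid or AgeGrid()
    target = rng.exponential()
    ages, events = _invert_cumulative_hazard(
        np.exp(lh)[None, :], np.asarray([entry_age]), np.asarray([censoring_age]),
        np.asarray([target]), grid,
    )
    return float(ages[0]), int(events[0])


def _invert_cumulative_hazard(rates, entry, cens, target, grid: AgeGrid):
    """Vectorized inverse-CDF sampling under subject-specific piecewise rates.

    rates: (n, S) hazards per interval; target: Exp(1) draws.
    """
    edges = np.concatenate([[-np.inf], grid.boundaries, [np.inf]])
    lo = np.maximum(entry[:, None], edges[None, :-1])
    hi = np.minimum(cens[:, None], edges[None, 1:])
    occ = np.clip(hi - lo, 0.0, None)
    contrib = occ * rates
    contrib[np.broadcast_to(rates, occ.shape) == 0.0] = 0.0  # 0 * inf guard
    cum = np.cumsum(contrib, axis=1)
    total = cum[:, -1]
    event = target < total
    k = np.argmax(cum >= target[:, None], axis=1)  # first interval reaching target
    prev = np.where(k > 0, cum[np.arange(len(k)), k - 1], 0.0)
    start = lo[np.arange(len(k)), k]
    rate_k = rates[np.arange(len(k)), k]
    with np.errstate(divide="ignore", invalid="ignore"):
        age_event = start + (target - prev) / rate_k
    ages = np.where(event, age_event, cens)
    return ages, event.astype(int)


def simulate_cohort(
    config: SimulationConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Generate one synthetic cohort as a subject-level table.

    Columns: subject_id, center_id, sex, age_entry, age_exit, event,
    exposure_q, true_intake, recall / recall_weekday / recall_season
    (NaN outside the reference subsample) and z1..zK confounders.  With
    ``return_truth=True`` also returns the realized center-level random
    effects and questionnaire error parameters for recovery tests.
    """
    J = config.n_centers
    nj = _as_per_center(config.subjects_per_center, J, "subjects_per_center").astype(int)
    sexfrac = _as_per_center(config.sex_fraction, J, "sex_fraction")
    master = np.random.SeedSequence(config.seed)
    center_seeds = master.spawn(J)

    chol = _psd_cholesky(config.random_effects_cov)
    alphas = np.asarray(config.log_relative_hazards, dtype=float)
    rates_base = np.exp(config.baseline_log_hazard + alphas)
    gW = np.asarray(config.gamma_within, dtype=float)
    gB = np.asarray(config.gamma_between, dtype=float)
    zsd = np.asarray(config.confounder_sds, dtype=float)
    nz = zsd.size

    frames: list[pd.DataFrame] = []
    truth_rows = []
    offset = 0
    for j in range(J):
        rng = np.random.default_rng(center_seeds[j])
        n = nj[j]
        # --- center-level draws, fixed order ---
        u = chol @ rng.standard_normal(3)  # (u0, u1, uW)
        a_j = (rng.normal(4.0, 1.5) if config.questionnaire_intercepts is None
               else _as_per_center(config.questionnaire_intercepts, J, "questionnaire_intercepts")[j])
        b_j = (rng.normal(0.6, 0.1) if config.questionnaire_slopes is None
               else _as_per_center(config.questionnaire_slopes, J, "questionnaire_slopes")[j])
        mu_T = rng.normal(config.exposure_grand_mean, np.sqrt(config.exposure_between_var))
        mu_Z = rng.normal(0.0, zsd) if nz else np.zeros(0)
        # --- subject-level draws, fixed order ---
        sex = (rng.random(n) < sexfrac[j]).astype(int)
        entry = rng.uniform(*config.entry_age_range, size=n)
        T = mu_T + rng.normal(0.0, np.sqrt(config.exposure_within_var), size=n)
        Q = a_j + b_j * T + rng.normal(0.0, np.sqrt(config.questionnaire_noise_var), size=n)
        Z = mu_Z + rng.normal(0.0, 1.0, size=(n, nz)) * zsd if nz else np.zeros((n, 0))
        in_sub = rng.random(n) < config.recall_subsample_fraction
        R = T + rng.normal(0.0, np.sqrt(config.recall_noise_var), size=n)
        weekday = rng.integers(1, 8, size=n)
        season = rng.integers(1, 5, size=n)
        target = rng.exponential(size=n)

        psi = (
            u[0]
            + (config.sex_log_rr + u[1]) * sex
            + (config.beta_within + u[2]) * (T - mu_T)
            + config.beta_between * (mu_T - config.exposure_grand_mean)
        )
        if nz:
            psi = psi + (Z - mu_Z) @ gW + mu_Z @ gB
        rates = rates_base[None, :] * np.exp(psi)[:, None]
        cens = np.minimum(config.censoring_age, entry + config.max_followup)
        age_exit, event = _invert_cumulative_hazard(rates, entry, cens, target, config.grid)

        df = pd.DataFrame(
            {
                "subject_id": np.arange(offset, offset + n),
                "center_id": j,
                "sex": sex,
                "age_entry": entry,
                "age_exit": age_exit,
                "event": event,
                "exposure_q": Q,
                "true_intake": T,
                "recall": np.where(in_sub, R, np.nan),
                "recall_weekday": np.where(in_sub, weekday, np.nan),
                "recall_season": np.where(in_sub, season, np.nan),
            }
        )
        for c in range(nz):
            df[f"z{c + 1}"] = Z[:, c]
        frames.append(df)
        truth_rows.append(
            dict(center_id=j, u0=u[0], u1=u[1], uW=u[2],
                 q_intercept=a_j, q_slope=b_j, exposure_center_mean=mu_T)
        )
        offset += n

    cohort = pd.concat(frames, ignore_index=True)
    if not return_truth:
        return cohort
    truth = {
        "config": config,
        "centers": pd.DataFrame(truth_rows),
    }
    return cohort, truth
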