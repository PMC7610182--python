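"""Lifetime smoking index: construction and half-life calibration.

The index collapses smoking status, intensity (cigarettes/day), duration and
time since cessation into a single non-negative exposure score

    score = (1 - 0.5**(dur/tau)) * 0.5**(tsc/tau) * ln(cpd + 1)

where ``tau`` is a half-life (years) capturing the exponentially decaying
effect of past smoking on health outcomes. Never smokers score 0; a current
smoker of infinite duration approaches the ceiling ``ln(cpd + 1)``.

The half-life is not observed: :func:`calibrate_half_life` scans a grid of
candidate values and picks the one whose index best predicts a binary health
outcome (logistic regression by default, optionally a Cox time-to-event fit).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("smokemr")

VALID_STATUS = ("never", "former", "current")
CPD_MIN, CPD_MAX = 1, 150  # plausibility window for ever-smokers


class MissingDataError(ValueError):
    """A smoking history lacks a field required for its status."""


class CalibrationError(RuntimeError):
    """Half-life calibration is impossible (no events or no exposure variance)."""


@dataclass(frozen=True)
class SmokingHistory:
    """One participant's self-reported smoking exposure record.

    Ages are in years; ``cpd`` is cigarettes per day (1 g loose tobacco is
    counted as one cigarette). Fields irrelevant to the status are ``None``.
    """

    status: Literal["never", "former", "current"]
    cpd: Optional[float] = None
    age_init: Optional[float] = None
    age_cess: Optional[float] = None
    age_assess: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise ValueError(f"unknown smoking status {self.status!r}")
        if self.status == "never":
            if self.cpd not in (None, 0) or self.age_init is not None or self.age_cess is not None:
                raise ValueError("never smokers must have cpd/age_init/age_cess missing or zero")
            return
        if self.cpd is not None and not (CPD_MIN <= self.cpd <= CPD_MAX):
            raise ValueError(f"cpd {self.cpd} outside plausible range [{CPD_MIN}, {CPD_MAX}]")
        if self.status == "current" and self.age_cess is not None:
            raise ValueError("current smokers cannot have an age of cessation")
        # ordering checks only when the relevant ages are present
        if self.status == "former" and None not in (self.age_init, self.age_cess, self.age_assess):
            if not (self.age_init <= self.age_cess <= self.age_assess):
                raise ValueError("former smoker requires age_init <= age_cess <= age_assess")
        if self.status == "current" and None not in (self.age_init, self.age_assess):
            if self.age_init > self.age_assess:
                raise ValueError("current smoker requires age_init <= age_assess")


@dataclass(frozen=True)
class HalfLifeConfig:
    """Half-life constant and the candidate grid used for calibration."""

    tau: float = 18.0
    tau_grid: Sequence[float] = field(default_factory=lambda: tuple(range(2, 42, 2)))

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        grid = tuple(self.tau_grid)
        if any(t <= 0 for t in grid):
            raise ValueError("all grid values must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("tau_grid must be strictly increasing")
        object.__setattr__(self, "tau_grid", grid)


def derive_exposure_times(h: SmokingHistory) -> tuple[float, float]:
    """Return (duration of smoking, time since cessation), both in years.

    Never smokers return ``(0.0, nan)`` — time since cessation is undefined
    for someone who never smoked. Current smokers have ``tsc = 0``.

    Raises :class:`MissingDataError` naming the first missing field required
    by the record's status.
    """
    if h.status == "never":
        return 0.0, math.nan
    for name in _required_ages(h.status):
        if getattr(h, name) is None:
            raise MissingDataError(f"{h.status} smoker is missing required field {name!r}")
    if h.status == "current":
        return h.age_assess - h.age_init, 0.0
    return h.age_cess - h.age_init, h.age_assess - h.age_cess


def _required_ages(status: str) -> tuple[str, ...]:
    return ("age_init", "age_assess") if status == "current" else ("age_init", "age_cess", "age_assess")


def lifetime_smoking_index(
    dur: float, tsc: float, cpd: float, tau: float = 18.0
) -> float:
    """Evaluate the lifetime smoking index.

    Parameters
    ----------
    dur : smoking duration in years (>= 0).
    tsc : time since cessation in years (>= 0; 0 for current smokers).
        ``nan`` is accepted when ``dur == 0`` (never smokers) and yields 0.
    cpd : cigarettes smoked per day (>= 0).
    tau : half-life in years (> 0).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if cpd < 0:
        raise ValueError("cpd must be non-negative")
    if dur < 0:
        raise ValueError("dur must be non-negative")
    if dur == 0 or cpd == 0:
        return 0.0
    if not tsc >= 0:  # catches nan for ever smokers
        raise ValueError("tsc must be non-negative for ever smokers")
    return (1.0 - 0.5 ** (dur / tau)) * 0.5 ** (tsc / tau) * math.log(cpd + 1.0)


def score_history(h: SmokingHistory, tau: float = 18.0) -> float:
    """Lifetime smoking index for one history record."""
    dur, tsc = derive_exposure_times(h)
    if h.status == "never":
        return 0.0
    return lifetime_smoking_index(dur, tsc, h.cpd, tau)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["id", "status", "cpd", "age_init", "age_cess", "age_assess"]


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV (columns id, status, cpd, age_init, age_cess,
    age_assess; empty field = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "status": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    return df


def histories_from_frame(df: pd.DataFrame) -> tuple[list[SmokingHistory], pd.Index]:
    """Convert a cohort table to history records.

    Former smokers with a missing cessation age cannot be scored; they are
    excluded with a logged count rather than imputed. Returns the histories
    and the index of rows retained.
    """

    def _get(row, col):
        v = row[col]
        return None if pd.isna(v) else float(v)

    histories, kept = [], []
    n_excluded = 0
    for i, row in df.iterrows():
        status = str(row["status"]).strip().lower()
        if status == "former" and pd.isna(row["age_cess"]):
            n_excluded += 1
            continue
        h = SmokingHistory(
            status=status,
            cpd=None if status == "never" else _get(row, "cpd"),
            age_init=None if status == "never" else _get(row, "age_init"),
            age_cess=_get(row, "age_cess") if status == "former" else None,
            age_assess=_get(row, "age_assess"),
        )
        histories.append(h)
        kept.append(i)
    if n_excluded:
        logger.warning("excluded %d former smokers with missing age_cess", n_excluded)
    return histories, pd.Index(kept)


def score_cohort(df: pd.DataFrame, tau: float = 18.0) -> pd.DataFrame:
    """Append a ``score`` column (lifetime smoking index) to a cohort table.

    Rows that cannot be scored (former smokers without a cessation age) get
    ``NaN``.
    """
    histories, kept = histories_from_frame(df)
    out = df.copy()
    out["score"] = np.nan
    out.loc[kept, "score"] = [score_history(h, tau) for h in histories]
    return out


# ---------------------------------------------------------------------------
# Half-life calibration
# ---------------------------------------------------------------------------

def calibrate_half_life(
    cohort: Sequence[SmokingHistory] | pd.DataFrame,
    outcome: np.ndarray | pd.Series | pd.DataFrame,
    grid: HalfLifeConfig | Sequence[float] = HalfLifeConfig(),
    criterion: Literal["logistic", "cox"] = "logistic",
    duration_col: str = "time",
    flat_tol: float = 1e-6,
) -> tuple[float, pd.DataFrame]:
    """Choose the half-life whose index best predicts a health outcome.

    For every candidate ``tau`` the cohort is scored, a single-predictor model
    of the outcome on the score is fitted, and its log-likelihood recorded.
    The returned ``tau`` maximises the log-likelihood (minimises deviance);
    ties break toward the smaller candidate.

    ``criterion="logistic"`` fits a logistic regression on a binary outcome.
    ``criterion="cox"`` fits a Cox proportional-hazards model; ``outcome``
    must then be a DataFrame with an event indicator column ``event`` and a
    follow-up time column (``duration_col``).

    Returns ``(tau_star, fit_table)`` where the fit table has one row per
    candidate with its log-likelihood and deviance. A flat profile (no
    association between smoking and outcome) triggers a warning but still
    returns the argmax (the smallest candidate).
    """
    if isinstance(cohort, pd.DataFrame):
        histories, kept = histories_from_frame(cohort)
        outcome = _align_outcome(outcome, kept)
    else:
        histories = list(cohort)
    if isinstance(grid, HalfLifeConfig):
        taus = grid.tau_grid
    else:
        taus = tuple(HalfLifeConfig(tau_grid=tuple(grid)).tau_grid)

    if criterion == "cox":
        event = np.asarray(outcome["event"], dtype=float)
        time = np.asarray(outcome[duration_col], dtype=float)
    else:
        event = np.asarray(outcome, dtype=float).ravel()
        time = None
    if len(event) != len(histories):
        raise ValueError("cohort and outcome are not aligned")
    if event.sum() == 0:
        raise CalibrationError("no events in the outcome: calibration impossible")
    if not any(h.status != "never" for h in histories):
        raise CalibrationError("no ever-smokers in the cohort: no exposure variance")

    rows = []
    for tau in taus:
        score = np.array([score_history(h, tau) for h in histories])
        if np.ptp(score) == 0:
            raise CalibrationError("index has no variance: calibration impossible")
        rows.append((tau, _fit_loglik(score, event, time, criterion)))
    fit = pd.DataFrame(rows, columns=["tau", "loglik"])
    fit["deviance"] = -2.0 * fit["loglik"]
    if fit["loglik"].max() - fit["loglik"].min() < flat_tol:
        warnings.warn(
            "fit profile is flat across the tau grid: the outcome carries no "
            "information about the half-life",
            RuntimeWarning,
            stacklevel=2,
        )
    # idxmax returns the first maximum; grid is increasing so ties go small
    tau_star = float(fit.loc[fit["loglik"].idxmax(), "tau"])
    return tau_star, fit


def _align_outcome(outcome, kept: pd.Index):
    if isinstance(outcome, (pd.Series, pd.DataFrame)):
        return outcome.loc[kept]
    arr = np.asarray(outcome)
    return arr[np.asarray(kept, dtype=int)]


def _fit_loglik(score, event, time, criterion) -> float:
    if criterion == "logistic":
        X = sm.add_constant(score)
        res = sm.GLM(event, X, family=sm.families.Binomial()).fit()
        return float(res.llf)
    if criterion == "cox":
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"score": score, "time": time, "event": event})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        return float(cph.log_likelihood_)
    raise ValueError(f"unknown calibration criterion {criterion!r}")
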