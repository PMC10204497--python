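"""Median-stratified Kaplan–Meier / log-rank screening of imaging biomarkers.

Each overlap statistic (and each combined biomarker) is evaluated as a
candidate survival biomarker: the cohort is split at the sample median of
the biomarker, Kaplan–Meier curves are estimated for the two subgroups for
overall survival (OS) and progression-free survival (PFS), and a two-group
log-rank test (chi-square, 1 df, two-sided) compares the survival
distributions. Because median stratification depends only on ranks, any
strictly increasing transform of a biomarker (e.g. Jaccard vs. Dice, which
are monotonically related) yields identical subgroups and identical
p-values.

Ties at the median go to the low group — a deterministic rule, disclosed in
each result. No multiple-testing correction is applied across the biomarker
battery; the number of tests performed is reported so users can apply their
own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DegenerateTestError, EstimationError, StratificationError

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "ScreenResult",
    "km_curve",
    "logrank_test",
    "stratify_by_median",
    "screen_cohort",
    "load_survival_table",
]

ENDPOINTS = {"OS": ("os_months", "os_event"), "PFS": ("pfs_months", "pfs_event")}


@dataclass
class SurvivalRecord:
    """One patient's survival endpoints (months) with event indicators."""

    patient_id: str
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.os_months < 0 or self.pfs_months < 0:
            raise ValueError("survival times must be non-negative")


@dataclass
class KMCurve:
    """A Kaplan–Meier step function with censoring marks.

    ``times``/``survival`` give the right-continuous step representation
    starting at (0, 1); ``censor_times`` are the censored observation times.
    """

    times: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray
    n: int

    def __call__(self, t: float) -> float:
        """Survival probability at time t (right-continuous)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])


@dataclass
class ScreenResult:
    """One biomarker x endpoint screen."""

    biomarker: str
    endpoint: str
    median_cutoff: float
    n_low: int
    n_high: int
    logrank_statistic: float
    p_value: float
    km_low: KMCurve
    km_high: KMCurve
    tie_warning: bool = False
    n_tests_in_battery: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "endpoint": self.endpoint,
            "median_cutoff": self.median_cutoff,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "logrank_statistic": self.logrank_statistic,
            "p_value": self.p_value,
            "tie_warning": self.tie_warning,
            "n_tests_in_battery": self.n_tests_in_battery,
        }


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit (Kaplan–Meier) survival estimate.

    Censored subjects reduce the risk set without introducing a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise EstimationError("cannot estimate a survival curve from no subjects")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = np.asarray(sf.index, dtype=float)
    s = np.asarray(sf.iloc[:, 0], dtype=float)
    if t.size == 0 or t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return KMCurve(t, s, censor_times=np.sort(times[~events]), n=int(times.size))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) with a two-sided p-value."""
    ta, ea = np.asarray(times_a, dtype=float), np.asarray(events_a, dtype=bool)
    tb, eb = np.asarray(times_b, dtype=float), np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise DegenerateTestError("both groups must be nonempty")
    if not ea.any() and not eb.any():
        raise DegenerateTestError("no observed events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def stratify_by_median(values: Sequence[float]) -> tuple[np.ndarray, float, bool]:
    """Split values at the sample median; low iff value <= cutoff.

    Returns ``(labels, cutoff, tie_warning)`` where labels are "low"/"high".
    For an odd number of distinct values the groups differ in size by
    exactly one. Ties exactly at the cutoff all go to the low group; when
    such ties make the split unequal beyond the odd-n imbalance, a warning
    is emitted and flagged in the return value.
    """
    vals = np.asarray(values, dtype=float)
    if np.isnan(vals).any():
        raise ValueError("stratify_by_median expects non-missing values")
    n = vals.size
    if n < 4:
        raise StratificationError(f"need >= 4 non-missing values, got {n}")
    if np.all(vals == vals[0]):
        raise StratificationError("all biomarker values identical; no split possible")
    cutoff = float(np.median(vals))
    labels = np.where(vals <= cutoff, "low", "high")
    n_low = int(np.count_nonzero(labels == "low"))
    tie_warning = abs(n_low - (n - n_low)) > 1
    if tie_warning:
        warnings.warn(
            f"ties at the median cutoff {cutoff}: groups of {n_low} (low) and "
            f"{n - n_low} (high); tied values assigned low",
            stacklevel=2,
        )
    return labels, cutoff, tie_warning


def _one_screen(df: pd.DataFrame, biomarker: str, endpoint: str,
                fixed_cutoff: Optional[float] = None) -> ScreenResult:
    tcol, ecol = ENDPOINTS[endpoint]
    sub = df[[biomarker, tcol, ecol]].dropna(subset=[biomarker])
    vals = sub[biomarker].to_numpy(dtype=float)
    if fixed_cutoff is None:
        labels, cutoff, tied = stratify_by_median(vals)
    else:
        if vals.size < 4:
            raise StratificationError(f"need >= 4 non-missing values, got {vals.size}")
        cutoff, tied = float(fixed_cutoff), False
        labels = np.where(vals <= cutoff, "low", "high")
        if (labels == "low").all() or (labels == "high").all():
            raise StratificationError(
                f"fixed cutoff {cutoff} puts every subject in one group"
            )
    low, high = labels == "low", labels == "high"
    t = sub[tcol].to_numpy(dtype=float)
    e = sub[ecol].to_numpy(dtype=bool)
    stat, p = logrank_test(t[low], e[low], t[high], e[high])
    return ScreenResult(
        biomarker=biomarker,
        endpoint=endpoint,
        median_cutoff=cutoff,
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        logrank_statistic=stat,
        p_value=p,
        km_low=km_curve(t[low], e[low]),
        km_high=km_curve(t[high], e[high]),
        tie_warning=tied,
    )


def screen_cohort(cohort: pd.DataFrame, biomarkers: Iterable[str],
                  endpoints: Iterable[str] = ("OS", "PFS"),
                  include_direction: bool = True,
                  ) -> tuple[list[ScreenResult], list[tuple[str, str, str]]]:
    """Screen every (biomarker, endpoint) pair by median stratification.

    ``cohort`` is a table with one row per patient carrying survival columns
    (os_months, os_event, pfs_months, pfs_event) and one column per
    biomarker. When ``include_direction`` is set and a signed volume-change
    column is present, a growth-vs-reduction stratification (fixed cutoff at
    0) is screened as an additional biomarker. Per-biomarker failures are
    recorded and the screen continues.

    Returns ``(results, failures)`` with failures as
    ``(biomarker, endpoint, reason)`` triples.
    """
    if cohort["patient_id"].duplicated().any():
        raise ValueError("patient_id values must be unique")
    results: list[ScreenResult] = []
    failures: list[tuple[str, str, str]] = []
    jobs: list[tuple[str, Optional[float]]] = [(b, None) for b in biomarkers]
    if include_direction and "volume_change_signed" in cohort.columns:
        jobs.append(("volume_change_signed", 0.0))
    for biomarker, fixed in jobs:
        for endpoint in endpoints:
            name = biomarker if fixed is None else "volume_direction"
            try:
                res = _one_screen(cohort, biomarker, endpoint, fixed_cutoff=fixed)
                res.biomarker = name
                results.append(res)
            except (StratificationError, DegenerateTestError, EstimationError,
                    KeyError) as exc:
                failures.append((name, endpoint, str(exc)))
    for res in results:
        res.n_tests_in_battery = len(results)
    return results, failures


def load_survival_table(path) -> pd.DataFrame:
    """Read the cohort survival CSV and validate its schema."""
    df = pd.read_csv(path)
    required = {"patient_id", "os_months", "os_event", "pfs_months", "pfs_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str)
    for c in ("os_event", "pfs_event"):
        df[c] = df[c].astype(bool)
    if (df[["os_months", "pfs_months"]] < 0).any().any():
        raise ValueError("survival times must be non-negative")
    return df
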