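"""Survival stratification by signature score: Kaplan–Meier and log-rank.

Cohorts carry one signature score per patient; stratification splits at
either the cohort-mean score or at zero (for scores that are already
centered), with the boundary value always assigned to the low group.
Estimation and testing are delegated to :mod:`lifelines`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalCohort",
    "KMEstimate",
    "LogRankResult",
    "read_survival_cohort",
    "dichotomize_by_score",
    "kaplan_meier",
    "logrank_test",
]

HIGH, LOW = "high", "low"


@dataclass
class SurvivalCohort:
    """Per-patient follow-up time, event indicator and signature score.

    ``data`` columns: ``time`` (>= 0), ``event`` (1 = event, 0 = censored),
    ``score``; optional ``group`` column added by stratification.
    """

    data: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        for col in ("time", "event", "score"):
            if col not in self.data.columns:
                raise ValueError(f"cohort is missing column {col!r}")
        if (self.data["time"] < 0).any():
            raise ValueError("follow-up times must be >= 0")
        if not self.data["event"].isin((0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_labeled(self) -> bool:
        return "group" in self.data.columns


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if s.size and (s[0] > 1 + 1e-12 or np.any(np.diff(s) > 1e-12) or np.any(s < -1e-12)):
            raise ValueError("survival must start <= 1, be non-increasing and in [0, 1]")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def read_survival_cohort(path: str | Path, time_unit: str = "months") -> SurvivalCohort:
    """Read a cohort TSV with columns patient_id, time, event, score."""
    frame = pd.read_csv(path, sep="\t")
    required = {"time", "event", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "patient_id" in frame.columns:
        frame = frame.set_index("patient_id")
    return SurvivalCohort(frame, time_unit=time_unit)


def dichotomize_by_score(cohort: SurvivalCohort, mode: str = "mean_split") -> SurvivalCohort:
    """Label patients ``high``/``low`` by signature score.

    ``mean_split`` uses the cohort mean as cut point, ``zero_split`` uses 0
    (for compendium-centered scores).  Scores strictly above the cut point
    go high; the boundary goes low.  An empty group is an error suggesting
    the other mode.
    """
    if mode not in ("mean_split", "zero_split"):
        raise ValueError(f"unknown split mode {mode!r}")
    if len(cohort) < 2:
        raise ValueError("need at least 2 patients to stratify")
    cut = float(cohort.data["score"].mean()) if mode == "mean_split" else 0.0
    labels = np.where(cohort.data["score"] > cut, HIGH, LOW)
    n_high, n_low = int((labels == HIGH).sum()), int((labels == LOW).sum())
    if n_high == 0 or n_low == 0:
        other = "zero_split" if mode == "mean_split" else "mean_split"
        raise ValueError(
            f"{mode} at {cut:g} leaves an empty group "
            f"(high={n_high}, low={n_low}); try mode={other!r}"
        )
    log.info("%s at %.4g: high=%d low=%d", mode, cut, n_high, n_low)
    data = cohort.data.copy()
    data["group"] = labels
    return SurvivalCohort(data, time_unit=cohort.time_unit)


def kaplan_meier(cohort: SurvivalCohort, group: str | None = None) -> KMEstimate:
    """Product-limit estimate for one stratum (or the whole cohort).

    Censored observations reduce the risk set without producing steps; the
    returned grid holds the distinct event times only.
    """
    data = cohort.data
    if group is not None:
        if not cohort.is_labeled:
            raise ValueError("cohort has no group labels; stratify first")
        data = data[data["group"] == group]
        if data.empty:
            raise ValueError(f"group {group!r} has no patients")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], event_observed=data["event"])
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    return KMEstimate(times=times, survival=survival, at_risk=at_risk)


def logrank_test(cohort: SurvivalCohort) -> LogRankResult:
    """Two-group log-rank test (1 df, hypergeometric variance).

    Requires a labeled cohort with exactly two non-empty groups and at
    least one event overall in each group-comparison sense.
    """
    if not cohort.is_labeled:
        raise ValueError("cohort has no group labels; stratify first")
    groups = cohort.data["group"].unique().tolist()
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, found {groups}")
    a = cohort.data[cohort.data["group"] == groups[0]]
    b = cohort.data[cohort.data["group"] == groups[1]]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if cohort.data["event"].sum() == 0:
        raise ValueError("log-rank undefined with no events")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes={str(groups[0]): len(a), str(groups[1]): len(b)},
    )
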