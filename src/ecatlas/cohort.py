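"""Retrospective-cohort machinery: inclusion and exposure rules, cause-of-
death imputation, competing-risk cumulative incidence, log-rank tests,
Kaplan-Meier summaries, 2:1 covariate matching and hazard-ratio conversion.

Event coding throughout: 0 censored, 1 breast-cancer-specific event,
2 competing event (death of other causes). Time is in years since
diagnosis. A patient enters the treatment (metformin) group only after a
continuous intake interval strictly longer than the exposure cutoff
(default 1 year); patients who started but discontinued earlier are
excluded from the analysis rather than counted as controls, as are patients
missing any matching covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

REQUIRED_COVARIATES = ("age", "bmi", "stage", "grade")


def parse_exposure(text: str) -> list[tuple[float, float]]:
    """Parse semicolon-separated ``start-stop`` intervals (years)."""
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for part in text.split(";"):
        start, stop = (float(x) for x in part.split("-"))
        if stop < start:
            raise ValueError(f"ill-ordered exposure interval {part!r}")
        out.append((start, stop))
    return sorted(out)


def assign_groups(
    records: pd.DataFrame, min_exposure_years: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion and exposure rules.

    Returns (analysis cohort with a ``group`` column in {metformin, control},
    exclusion report with a ``reason`` per excluded patient). Exclusion
    reasons: ``missing_metadata`` (any required covariate absent) and
    ``early_discontinuation`` (some exposure but no continuous interval
    strictly longer than ``min_exposure_years``).
    """
    df = records.copy()
    intervals = df["exposure"].map(parse_exposure)
    longest = intervals.map(lambda iv: max((b - a for a, b in iv), default=0.0))
    exposed_enough = longest > min_exposure_years
    any_exposure = intervals.map(len) > 0

    missing = df[list(REQUIRED_COVARIATES)].isna().any(axis=1)
    early_stop = any_exposure & ~exposed_enough & ~missing

    reason = np.full(len(df), "", dtype=object)
    reason[early_stop.to_numpy()] = "early_discontinuation"
    reason[missing.to_numpy()] = "missing_metadata"
    excluded = df[reason != ""].copy()
    excluded["reason"] = reason[reason != ""]

    kept = df[reason == ""].copy()
    kept["group"] = np.where(exposed_enough[reason == ""], "metformin", "control")
    return kept, excluded[["patient_id", "reason"]]


def impute_cause(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve deaths of unknown cause: disease-related (event 1) in the
    presence of relapse, other-cause (event 2) in its absence. Known causes
    are untouched."""
    df = records.copy()
    unknown = ~df["cause_known"].astype(bool)
    if (unknown & (df["event"] == 0)).any():
        raise ValueError("unknown cause of death recorded on a censored patient")
    df.loc[unknown, "event"] = np.where(df.loc[unknown, "relapse_observed"], 1, 2)
    df.loc[unknown, "cause_known"] = True
    return df


@dataclass
class CIFEstimate:
    """Aalen-Johansen cumulative incidence step function for one event type."""

    times: np.ndarray  # event/censoring times (sorted, unique)
    cif: np.ndarray  # CIF at each time (right-continuous step)
    at_risk: pd.Series  # at-risk counts at the requested report times
    event_of_interest: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[idx])


def cumulative_incidence(
    records: pd.DataFrame,
    event_of_interest: int = 1,
    report_times: tuple[float, ...] = (5.0, 8.0, 10.0, 14.0),
) -> CIFEstimate:
    """Aalen-Johansen estimator under competing risks.

    CIF(t) = sum over event times t_i <= t of S(t_i-) * d_event(t_i)/n(t_i),
    with S the all-cause Kaplan-Meier survival. Competing events remove
    patients from the risk set but do not contribute incidence of the event
    of interest.
    """
    time = records["time_years"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time)
    n = len(time)

    cif = np.zeros(len(uniq))
    surv = 1.0
    acc = 0.0
    at_risk_fn = []
    for i, t in enumerate(uniq):
        n_at_risk = int((time >= t).sum())
        d_int = int(((time == t) & (event == event_of_interest)).sum())
        d_all = int(((time == t) & (event != 0)).sum())
        if n_at_risk > 0:
            acc += surv * d_int / n_at_risk
            surv *= 1.0 - d_all / n_at_risk
        cif[i] = acc
        at_risk_fn.append(n_at_risk)
    at_risk = pd.Series(
        {t: int((time >= t).sum()) for t in report_times}, name="at_risk"
    )
    return CIFEstimate(times=uniq, cif=cif, at_risk=at_risk,
                       event_of_interest=event_of_interest)


def logrank(
    records: pd.DataFrame,
    group_col: str = "group",
    event_of_interest: int = 1,
) -> tuple[float, float]:
    """Two-group log-rank on the event of interest; competing events are
    censored for the purpose of this test (documented convention)."""
    groups = records[group_col].unique()
    if len(groups) != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    a = records[records[group_col] == groups[0]]
    b = records[records[group_col] == groups[1]]
    for g, sub in ((groups[0], a), (groups[1], b)):
        if sub["time_years"].sum() <= 0:
            raise ValueError(f"group {g!r} has no at-risk time")
    res = _ll_logrank(
        a["time_years"],
        b["time_years"],
        event_observed_A=(a["event"] == event_of_interest).astype(int),
        event_observed_B=(b["event"] == event_of_interest).astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def km_summaries(
    records: pd.DataFrame,
    times: tuple[float, ...] = (5.0, 10.0, 14.0),
    event_of_interest: int = 1,
) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival with log-log confidence intervals
    at the requested years; times beyond the last follow-up are flagged."""
    kmf = KaplanMeierFitter()
    kmf.fit(
        records["time_years"],
        (records["event"] == event_of_interest).astype(int),
    )
    last = records["time_years"].max()
    rows = []
    for t in times:
        s = float(kmf.predict(t))
        ci = kmf.confidence_interval_survival_function_
        idx = ci.index[ci.index <= t]
        lo, hi = (ci.loc[idx[-1]].tolist() if len(idx) else (np.nan, np.nan))
        rows.append(
            {"time": t, "survival": s, "ci_lower": lo, "ci_upper": hi,
             "beyond_follow_up": t > last}
        )
    return pd.DataFrame(rows)


def match_controls(
    treated: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 2,
    exact: tuple[str, ...] = ("stage", "grade"),
    numeric: tuple[str, ...] = ("age", "bmi"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy nearest-neighbour matching without replacement.

    Controls must match exactly on ``exact`` covariates; among exact matches
    the standardized Euclidean distance over ``numeric`` covariates is
    minimized. Up to ``ratio`` controls per treated patient; ties and the
    processing order break deterministically by patient id. Returns
    (matches with columns treated_id/control_id/distance, report of
    under-matched treated patients).
    """
    if pool.empty:
        raise ValueError("empty control pool")
    overlap = set(treated["patient_id"]) & set(pool["patient_id"])
    if overlap:
        raise ValueError("pool must be disjoint from treated")
    both = pd.concat([treated, pool])
    scale = {c: both[c].std(ddof=0) or 1.0 for c in numeric}

    avail = pool.set_index("patient_id", drop=False).sort_index()
    matches = []
    short = []
    for _, t in treated.sort_values("patient_id").iterrows():
        cand = avail
        for c in exact:
            cand = cand[cand[c] == t[c]]
        d = np.sqrt(
            sum(((cand[c] - t[c]) / scale[c]) ** 2 for c in numeric)
        ).astype(float)
        order = np.lexsort((cand["patient_id"].to_numpy(), d.to_numpy()))
        chosen = cand.iloc[order[:ratio]]
        for _, ctrl in chosen.iterrows():
            matches.append(
                {
                    "treated_id": t["patient_id"],
                    "control_id": ctrl["patient_id"],
                    "distance": float(
                        np.sqrt(
                            sum(((ctrl[c] - t[c]) / scale[c]) ** 2 for c in numeric)
                        )
                    ),
                }
            )
        avail = avail.drop(chosen["patient_id"])
        if len(chosen) < ratio:
            short.append(
                {"treated_id": t["patient_id"], "n_controls": len(chosen)}
            )
    return pd.DataFrame(matches), pd.DataFrame(short)


def hazard_reduction(hr: float) -> float:
    """Convert a hazard ratio to a percent hazard reduction, (1 - hr) * 100;
    negative when hr > 1."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return (1.0 - hr) * 100.0
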