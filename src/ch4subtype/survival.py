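"""Cognitive progression milestones and time-to-event analysis.

Six prespecified cognitive milestones are screened at every study visit:

1. MoCA below 21 (global cognitive impairment),
2. MDS-UPDRS item 1.1 (cognition) response >= 3,
3. MDS-UPDRS item 1.2 (hallucinations/psychosis) response >= 3,
4. MDS-UPDRS item 1.5 (apathy) response >= 3,
5. clinician-diagnosed dementia (boolean flag column),
6. composite dementia categorization (boolean flag column).

A subject's event time is the first visit month at which *any* criterion
holds; subjects never meeting one are right-censored at their last visit.  A
single qualifying visit triggers the event (no persistence requirement), and
a milestone met already at the baseline visit yields time 0 and is kept,
flagged, rather than dropped.

Group contrasts use the Kaplan-Meier product-limit estimator and the log-rank
test; the adjusted association between low Ch4 and progression uses a Cox
proportional-hazards model (Efron tie handling by default — ties are
guaranteed by the 6-month visit grid) with Wald 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "MilestoneCriteria",
    "MilestoneEvent",
    "CoxResult",
    "detect_milestones",
    "detect_milestones_table",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "plot_km",
]

MILESTONE_ORDER = (
    "moca_lt_cutoff",
    "updrs_1_1",
    "updrs_1_2",
    "updrs_1_5",
    "dementia_clinical",
    "dementia_composite",
)


@dataclass(frozen=True)
class MilestoneCriteria:
    """Cutoffs defining the six cognitive milestones."""

    moca_cutoff: float = 21.0          # milestone if MoCA < cutoff
    updrs_1_1_cutoff: float = 3.0      # milestone if item response >= cutoff
    updrs_1_2_cutoff: float = 3.0
    updrs_1_5_cutoff: float = 3.0
    dementia_clinical_col: str = "dementia_clinical"
    dementia_composite_col: str = "dementia_composite"

    def __post_init__(self) -> None:
        if not 0 <= self.moca_cutoff <= 30:
            raise ValueError("MoCA cutoff must be in [0, 30]")
        for name in ("updrs_1_1_cutoff", "updrs_1_2_cutoff", "updrs_1_5_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise ValueError(f"{name} must be within the 0-4 item range")


@dataclass(frozen=True)
class MilestoneEvent:
    subject_id: object
    time: float                     # months from baseline
    event: bool                     # True = milestone reached
    first_milestone_type: str       # one of MILESTONE_ORDER or "none"
    at_baseline: bool = False       # milestone already present at month 0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event/censoring time must be >= 0")
        if not self.event and self.first_milestone_type != "none":
            raise ValueError("censored records carry no milestone type")


def _criteria_held(row: pd.Series, criteria: MilestoneCriteria) -> str | None:
    """First milestone (in fixed order) satisfied at one visit, else None."""
    checks = (
        ("moca_lt_cutoff",
         "moca" in row and pd.notna(row["moca"]) and row["moca"] < criteria.moca_cutoff),
        ("updrs_1_1",
         "updrs_1_1" in row and pd.notna(row["updrs_1_1"])
         and row["updrs_1_1"] >= criteria.updrs_1_1_cutoff),
        ("updrs_1_2",
         "updrs_1_2" in row and pd.notna(row["updrs_1_2"])
         and row["updrs_1_2"] >= criteria.updrs_1_2_cutoff),
        ("updrs_1_5",
         "updrs_1_5" in row and pd.notna(row["updrs_1_5"])
         and row["updrs_1_5"] >= criteria.updrs_1_5_cutoff),
        ("dementia_clinical",
         criteria.dementia_clinical_col in row
         and bool(row[criteria.dementia_clinical_col])),
        ("dementia_composite",
         criteria.dementia_composite_col in row
         and bool(row[criteria.dementia_composite_col])),
    )
    for name, hit in checks:
        if hit:
            return name
    return None


def detect_milestones(
    visits: pd.DataFrame,
    criteria: MilestoneCriteria = MilestoneCriteria(),
    subject_id=None,
) -> MilestoneEvent:
    """Scan one subject's visit history for the first cognitive milestone.

    ``visits`` holds one row per visit with a ``visit_month`` column plus any
    of the milestone columns (``moca``, ``updrs_1_1``, ``updrs_1_2``,
    ``updrs_1_5`` and the dementia flag columns).  Visits must be sorted by
    time with a baseline (month 0 first) present.
    """
    if len(visits) == 0:
        raise ValueError("empty visit record")
    months = visits["visit_month"].to_numpy(dtype=float)
    if np.any(np.diff(months) <= 0):
        raise ValueError("visit months must be strictly increasing")
    if subject_id is None:
        subject_id = visits["subject_id"].iloc[0] if "subject_id" in visits else None
    for _, row in visits.iterrows():
        hit = _criteria_held(row, criteria)
        if hit is not None:
            t = float(row["visit_month"])
            return MilestoneEvent(
                subject_id=subject_id, time=t, event=True,
                first_milestone_type=hit, at_baseline=(t == months[0]),
            )
    return MilestoneEvent(
        subject_id=subject_id, time=float(months[-1]), event=False,
        first_milestone_type="none",
    )


def detect_milestones_table(
    visits: pd.DataFrame, criteria: MilestoneCriteria = MilestoneCriteria()
) -> pd.DataFrame:
    """Per-subject milestone events from a long-format visit table."""
    if "subject_id" not in visits.columns:
        raise ValueError("visit table needs a subject_id column")
    rows = []
    for sid, grp in visits.groupby("subject_id", sort=True):
        ev = detect_milestones(
            grp.sort_values("visit_month"), criteria, subject_id=sid
        )
        rows.append({
            "subject_id": sid, "time": ev.time, "event": ev.event,
            "first_milestone_type": ev.first_milestone_type,
            "at_baseline": ev.at_baseline,
        })
    return pd.DataFrame(rows)


def km_estimate(events: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve from an events table.

    ``events`` needs ``time`` and ``event`` columns.  Returns a step-function
    table (``time``, ``survival``, ``at_risk``) starting at S(0) = 1.
    """
    if len(events) == 0:
        raise ValueError("no event records")
    t = events["time"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=events["event"].to_numpy(dtype=bool))
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "survival": surv.iloc[:, 0].to_numpy(dtype=float),
        "at_risk": at_risk.to_numpy(dtype=float),
    })


def logrank_test(events_a: pd.DataFrame, events_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2 with 1 df, p-value)."""
    if len(events_a) == 0 or len(events_b) == 0:
        raise ValueError("both groups need at least one subject")
    res = _ll_logrank(
        events_a["time"].to_numpy(dtype=float),
        events_b["time"].to_numpy(dtype=float),
        event_observed_A=events_a["event"].to_numpy(dtype=bool),
        event_observed_B=events_b["event"].to_numpy(dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% intervals."""

    table: pd.DataFrame          # index = covariate; hr, ci_low, ci_high, p, coef, se
    ties: str
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def cox_fit(
    events: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_cols=("low_ch4", "age", "sex", "moca"),
    ties: str = "efron",
) -> CoxResult:
    """Multivariable Cox proportional-hazards fit.

    ``events`` (subject_id, time, event) is joined to ``covariates``
    (subject_id + the covariate columns).  Efron tie handling by default,
    Breslow by flag.  Constant covariates and non-convergence raise.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = events.merge(covariates, on="subject_id", how="inner")
    if len(df) < len(events):
        raise ValueError("covariate table does not cover every subject")
    cols = list(covariate_cols)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariate columns {missing}")
    if df[cols].isna().any().any():
        bad = [c for c in cols if df[c].isna().any()]
        raise ValueError(f"missing covariate values in {bad}")
    for c in cols:
        if df[c].nunique() < 2:
            raise ValueError(
                f"covariate '{c}' is identical for all subjects; "
                "its coefficient is unidentifiable"
            )
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError("need at least 2 observed events")
    fit_df = df[["time", "event"] + cols].astype(float)
    if ties == "efron":
        cph = CoxPHFitter()
        try:
            cph.fit(fit_df, duration_col="time", event_col="event")
        except Exception as exc:  # lifelines raises ConvergenceError subtypes
            raise RuntimeError(f"Cox partial-likelihood fit failed: {exc}") from exc
        summ = cph.summary
        table = pd.DataFrame({
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        })
    else:
        import statsmodels.duration.hazard_regression as hr

        model = hr.PHReg(
            fit_df["time"].to_numpy(),
            fit_df[cols].to_numpy(),
            status=fit_df["event"].to_numpy(),
            ties="breslow",
        )
        try:
            res = model.fit()
        except Exception as exc:
            raise RuntimeError(f"Cox partial-likelihood fit failed: {exc}") from exc
        coef = res.params
        se = res.bse
        zcrit = 1.959963984540054
        table = pd.DataFrame({
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - zcrit * se),
            "ci_high": np.exp(coef + zcrit * se),
            "p": res.pvalues,
        }, index=cols)
    return CoxResult(table=table, ties=ties, n=len(df), n_events=n_events)


def plot_km(events_by_group: dict, path=None, title="Time to first cognitive milestone"):
    """Step plot of one KM curve per group (e.g. low vs normal Ch4).

    ``events_by_group`` maps a group label to its events table.  Returns the
    matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, events in events_by_group.items():
        km = km_estimate(events)
        ax.step(km["time"], km["survival"], where="post", label=str(label))
    ax.set_xlabel("months from baseline")
    ax.set_ylabel("milestone-free probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
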