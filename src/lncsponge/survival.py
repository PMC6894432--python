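"""Kaplan-Meier validation of candidate lncRNAs.

Patients are split at the median tumor expression of each candidate (ties go
to the low group), survival in the two groups is summarized with the
product-limit estimator, and the groups are compared with the two-group
log-rank test. A candidate is flagged when the high-expression group has
significantly worse survival, the pattern expected of a tumor-promoting
lncRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClinicalTable, ExpressionMatrix, ValidationError


@dataclass
class KMCurve:
    """Product-limit survival step function over distinct event times."""

    times: np.ndarray  # distinct event times, sorted
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def area(self, horizon: float | None = None) -> float:
        """Restricted mean survival time up to ``horizon`` (default: last
        observed event time)."""
        if self.times.size == 0:
            return float(horizon) if horizon is not None else 0.0
        horizon = float(horizon) if horizon is not None else float(self.times[-1])
        grid = np.concatenate([[0.0], self.times, [horizon]])
        surv = np.concatenate([[1.0], self.survival, [self.survival[-1]]])
        area = 0.0
        for i in range(len(grid) - 1):
            lo, hi = grid[i], min(grid[i + 1], horizon)
            if hi <= lo:
                continue
            area += surv[i] * (hi - lo)
        return float(area)


@dataclass
class LogRankResult:
    chi_square: float
    p: float
    n_a: int
    n_b: int
    df: int = 1


def median_split(expression: pd.Series, clinical: ClinicalTable) -> pd.Series:
    """Label each patient 'high' (strictly above median) or 'low'.

    ``expression`` is one value per patient (tumor sample); patients without
    survival data are dropped before the median is taken.
    """
    df = clinical.data
    with_surv = set(df.loc[df["survival_time"].notna(), "patient_id"])
    values = expression[[p for p in expression.index if p in with_surv]].astype(float)
    if len(values) < 4:
        raise ValidationError("median_split needs >= 4 patients with survival data")
    if np.ptp(values.to_numpy()) == 0:
        raise ValidationError("all-equal expression: no median split exists")
    median = float(values.median())
    return pd.Series(np.where(values > median, "high", "low"), index=values.index)


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size or times.size == 0:
        raise ValidationError("times and events must be equal-length, non-empty")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValidationError("events must be 0 (censored) or 1 (death)")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    n = times.size
    at_risk, d, surv = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d.append(d_i)
        surv.append(s)
    return KMCurve(
        times=event_times,
        at_risk=np.array(at_risk),
        events=np.array(d),
        survival=np.array(surv),
    )


def logrank_test(group_a: tuple, group_b: tuple) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group a are compared
    with the expectation under the hypergeometric margin; the statistic is
    (sum(O - E))**2 / sum(V) on 1 df.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank test needs >= 1 event")
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    event_times = np.unique(all_times[all_events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_times >= t
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (group == 0)).sum())
        d_tot = int(((all_times == t) & (all_events == 1)).sum())
        d_a = int(((all_times == t) & (all_events == 1) & (group == 0)).sum())
        e_a = d_tot * n_a / n_tot
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += (
                d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogRankResult(chi_square=float(chi2), p=p, n_a=int(ta.size), n_b=int(tb.size))


def patient_expression(
    expr: ExpressionMatrix, clinical: ClinicalTable, gene_id: str
) -> pd.Series:
    """Mean tumor-sample expression of one gene per patient."""
    df = clinical.data
    tumor = df[df["condition"] == "tumor"]
    tumor = tumor[tumor["sample_id"].isin(expr.data.columns)]
    row = expr.data.loc[gene_id]
    values = tumor.groupby("patient_id")["sample_id"].apply(
        lambda s: float(row[list(s)].mean())
    )
    return values


def survival_screen(
    candidates,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Median-split log-rank screen of each candidate lncRNA.

    Returns a frame with columns chi_square, p, n_high, n_low, high_worse,
    flagged, testable. A candidate missing from the matrix or with no events
    is marked untestable instead of failing.
    """
    df = clinical.data
    surv = (
        df[df["survival_time"].notna()]
        .drop_duplicates("patient_id")
        .set_index("patient_id")[["survival_time", "event"]]
    )
    columns = ["chi_square", "p", "n_high", "n_low", "high_worse", "flagged", "testable"]
    rows = []
    if not len(candidates):
        empty = pd.DataFrame(columns=columns)
        empty.index.name = "candidate"
        return empty
    for gene in candidates:
        base = {"candidate": gene, "chi_square": np.nan, "p": np.nan,
                "n_high": 0, "n_low": 0, "high_worse": False,
                "flagged": False, "testable": False}
        if gene not in expr.data.index:
            rows.append(base)
            continue
        try:
            values = patient_expression(expr, clinical, gene)
            labels = median_split(values, clinical)
            patients = [p for p in labels.index if p in surv.index]
            labels = labels[patients]
            hi = surv.loc[labels.index[labels == "high"]]
            lo = surv.loc[labels.index[labels == "low"]]
            result = logrank_test(
                (hi["survival_time"].to_numpy(), hi["event"].to_numpy().astype(int)),
                (lo["survival_time"].to_numpy(), lo["event"].to_numpy().astype(int)),
            )
            km_hi = km_estimate(hi["survival_time"], hi["event"].astype(int))
            km_lo = km_estimate(lo["survival_time"], lo["event"].astype(int))
            horizon = float(
                max(hi["survival_time"].max(), lo["survival_time"].max())
            )
            high_worse = km_hi.area(horizon) < km_lo.area(horizon)
            base.update(
                chi_square=result.chi_square, p=result.p,
                n_high=result.n_a, n_low=result.n_b,
                high_worse=bool(high_worse),
                flagged=bool(high_worse and result.p < p_max),
                testable=True,
            )
        except ValidationError:
            pass
        rows.append(base)
    return pd.DataFrame(rows).set_index("candidate")
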