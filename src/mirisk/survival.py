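"""Time-to-progression analysis: cohort assembly, Kaplan-Meier, log-rank.

Time to progression (TTP) is the number of days between the first tumor
diagnosis and the first documented metastasis; metastasis-free patients are
censored at last follow-up.  The cohort rule mirrors the metachronous design:
patients enter only if their metastasis appeared at least one year after
diagnosis or they have more than one year of metastasis-free follow-up, so
synchronous metastatic cases never contribute events.

The product-limit estimator and the two-group log-rank test are implemented
from first principles (hypergeometric variance, chi-square 1-df P-value).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as _spdist

from .datamodel import ExpressionMatrix, SampleSheet, ValidationError

METACHRONOUS_DAYS = 365


@dataclass
class SurvivalCohort:
    sample_ids: list[str]
    time_days: np.ndarray  # positive ints
    event: np.ndarray  # bool
    group: str = "all"

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=int)
        self.event = np.asarray(self.event, dtype=bool)
        n = len(self.sample_ids)
        if self.time_days.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("cohort arrays must match sample_ids length")
        if n and self.time_days.min() <= 0:
            raise ValidationError("time_days must be positive")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, mask: np.ndarray, group: str | None = None) -> "SurvivalCohort":
        mask = np.asarray(mask, dtype=bool)
        return SurvivalCohort(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            time_days=self.time_days[mask],
            event=self.event[mask],
            group=self.group if group is None else group,
        )


@dataclass
class KMCurve:
    times: np.ndarray  # strictly increasing distinct event times
    survival: np.ndarray  # S(t) just after each event time; starts at 1 before
    at_risk: np.ndarray
    n_events: np.ndarray
    group: str = "all"


def assemble_ttp(sheet: SampleSheet) -> tuple[SurvivalCohort, list[tuple[str, str]]]:
    """Build the TTP cohort from a sample sheet, logging exclusions.

    Included: (event and time >= 365 days) or (no event and time > 365 days).
    Excluded with reason codes: synchronous metastases (event before one
    year) and event-free patients with insufficient follow-up.  Serum-only
    samples (healthy controls) are skipped.
    """
    ids: list[str] = []
    times: list[int] = []
    events: list[bool] = []
    excluded: list[tuple[str, str]] = []
    for r in sheet:
        if r.serum_group == "H":
            excluded.append((r.sample_id, "healthy_control"))
            continue
        if r.event:
            if r.followup_days >= METACHRONOUS_DAYS:
                ids.append(r.sample_id)
                times.append(r.followup_days)
                events.append(True)
            else:
                excluded.append((r.sample_id, "synchronous_metastasis"))
        else:
            if r.followup_days > METACHRONOUS_DAYS:
                ids.append(r.sample_id)
                times.append(r.followup_days)
                events.append(False)
            else:
                excluded.append((r.sample_id, "short_followup"))
    cohort = SurvivalCohort(
        sample_ids=ids,
        time_days=np.array(times, dtype=int),
        event=np.array(events, dtype=bool),
    )
    return cohort, excluded


def km_estimate(cohort: SurvivalCohort) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Subjects censored exactly at an event time remain in the risk set at that
    time (the standard convention).
    """
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    t = cohort.time_days
    e = cohort.event
    event_times = np.unique(t[e])
    surv = []
    risk = []
    dts = []
    s = 1.0
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & e).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        risk.append(n_i)
        dts.append(d_i)
    return KMCurve(
        times=event_times.astype(float),
        survival=np.array(surv, dtype=float),
        at_risk=np.array(risk, dtype=int),
        n_events=np.array(dts, dtype=int),
        group=cohort.group,
    )


LOGRANK_EXACT_MAX_N = 20


def logrank_test(
    cohort_a: SurvivalCohort, cohort_b: SurvivalCohort, method: str = "chi2"
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p).

    At each distinct pooled event time, the expected events in group A come
    from the pooled risk set and the variance is hypergeometric.  The default
    P-value is the chi-square 1-df tail of the statistic (the convention of
    mainstream survival software); for small cohorts ``method="exact"``
    enumerates every assignment of subjects to groups and returns the exact
    conditional P(chi2* >= chi2_obs), which the chi-square tail only
    approximates to O(1/n).
    """
    if method not in ("chi2", "exact"):
        raise ValueError(f"unknown method {method!r}")
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise ValidationError("both groups must be non-empty")
    t = np.concatenate([cohort_a.time_days, cohort_b.time_days]).astype(float)
    e = np.concatenate([cohort_a.event, cohort_b.event])
    na = len(cohort_a)
    in_a = np.concatenate(
        [np.ones(na, dtype=bool), np.zeros(len(cohort_b), dtype=bool)]
    )
    chi2 = _logrank_chi2(t, e, in_a)
    if method == "exact":
        n = t.size
        if n > LOGRANK_EXACT_MAX_N:
            raise ValidationError(
                f"exact log-rank limited to n <= {LOGRANK_EXACT_MAX_N} subjects"
            )
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), na):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            if _logrank_chi2(t, e, m) >= chi2 - 1e-12:
                count += 1
            total += 1
        return chi2, count / total
    p = float(_spdist.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return chi2, p


def _logrank_chi2(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> float:
    """Log-rank chi-square statistic on pooled arrays (group mask ``in_a``)."""
    event_times = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = time >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((time == ti) & event).sum())
        d_a = int(((time == ti) & event & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0.0:
        return 0.0
    return float(o_minus_e * o_minus_e / var)


def median_split_km(
    expr: ExpressionMatrix, mirna_id: str, cohort: SurvivalCohort
) -> tuple[KMCurve, KMCurve, tuple[float, float]]:
    """Dichotomize a cohort at the median expression of one miRNA and compare.

    Values strictly above the within-cohort median define the high group;
    at-median values go to low (the exact complement of "above the median").
    """
    values = expr.row(mirna_id)
    lookup = dict(zip(expr.sample_ids, values))
    missing = [s for s in cohort.sample_ids if s not in lookup]
    if missing:
        raise ValidationError(f"cohort samples missing from matrix: {missing[:5]}")
    v = np.array([lookup[s] for s in cohort.sample_ids], dtype=float)
    if np.any(np.isnan(v)):
        keep = ~np.isnan(v)
        cohort = cohort.subset(keep)
        v = v[keep]
    if v.size == 0 or np.all(v == v[0]):
        raise ValidationError(f"degenerate split: {mirna_id!r} constant in cohort")
    med = float(np.median(v))
    high_mask = v > med
    high = cohort.subset(high_mask, group="high")
    low = cohort.subset(~high_mask, group="low")
    result = logrank_test(high, low)
    return km_estimate(high), km_estimate(low), result
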