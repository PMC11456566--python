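"""Survival analysis for classifier evaluation.

Implements the product-limit (Kaplan-Meier) estimator, the k-group
log-rank test, and Pearson's chi-square with Yates' continuity correction
from their standard formulas, plus a report generator that evaluates a
transcriptional classifier's groups (per-group curves, pairwise log-rank
tests, median survival).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .synthetic import SurvivalRecord

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogrankResult",
    "SurvivalError",
    "km_estimate",
    "logrank_test",
    "chisq_yates",
    "median_survival",
    "evaluate_classifier_survival",
]


class SurvivalError(ValueError):
    pass


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with at least one event, in
    increasing order; ``survival[i]`` is S(t) just after ``event_times[i]``;
    ``at_risk[i]`` and ``events[i]`` are n_i and d_i at that time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """S(t): the step function evaluated at time t (1 before any event)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class LogrankResult:
    """Log-rank comparison of k survival groups (chi-square, k-1 df)."""

    chi2: float
    p: float
    df: int
    groups: list[str]
    observed: dict[str, float]
    expected: dict[str, float]


def _validate(records: Sequence[SurvivalRecord]) -> None:
    for r in records:
        if r.time <= 0:
            raise SurvivalError(f"non-positive time for {r.sample_id}")
        if r.event not in (0, 1):
            raise SurvivalError(f"event must be 0/1 for {r.sample_id}")


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Events tied at the same time are aggregated; a censored-only input
    yields S identically 1 (no event times).
    """
    if not records:
        raise SurvivalError("km_estimate requires at least one record")
    _validate(records)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events == 1])
    surv = []
    at_risk = []
    d_counts = []
    s = 1.0
    for t in event_times:
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    return KMCurve(
        event_times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        events=np.array(d_counts),
        n_total=len(records),
    )


def logrank_test(groups: Mapping[str, Sequence[SurvivalRecord]]) -> LogrankResult:
    """Log-rank test across two or more groups.

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation; the statistic is the quadratic
    form of the summed observed-minus-expected vector against its
    covariance (last group dropped), chi-square with k-1 df.
    """
    labels = [g for g in groups if len(groups[g]) > 0]
    if len(labels) < 2:
        raise SurvivalError("log-rank requires at least 2 non-empty groups")
    for g in labels:
        _validate(groups[g])
    times = {g: np.array([r.time for r in groups[g]]) for g in labels}
    events = {g: np.array([r.event for r in groups[g]]) for g in labels}
    all_times = np.concatenate([times[g] for g in labels])
    all_events = np.concatenate([events[g] for g in labels])
    event_times = np.unique(all_times[all_events == 1])
    if event_times.size == 0:
        raise SurvivalError("log-rank undefined with zero events")

    k = len(labels)
    o_minus_e = np.zeros(k)
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        n_g = np.array([(times[g] >= t).sum() for g in labels], dtype=float)
        d_g = np.array(
            [((times[g] == t) & (events[g] == 1)).sum() for g in labels], dtype=float
        )
        n_t = n_g.sum()
        d_t = d_g.sum()
        e_g = n_g * d_t / n_t
        observed += d_g
        expected += e_g
        o_minus_e += d_g - e_g
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1) / n_t**2
            cov += factor * (np.diag(n_g * n_t) - np.outer(n_g, n_g))
    # drop the last group (covariance matrix of all k is singular)
    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogrankResult(
        chi2=chi2,
        p=p,
        df=k - 1,
        groups=labels,
        observed=dict(zip(labels, observed)),
        expected=dict(zip(labels, expected)),
    )


def chisq_yates(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table with Yates' continuity correction.

    statistic = sum((max(|O - E| - 1/2, 0))^2 / E), p from the chi-square
    upper tail with 1 df.  All marginals must be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise SurvivalError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise SurvivalError("table counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise SurvivalError("chi-square undefined with a zero marginal")
    expected = np.outer(row, col) / obs.sum()
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, 1))
    return statistic, p


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or None if never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def evaluate_classifier_survival(
    labels: Mapping[str, str], records: Sequence[SurvivalRecord]
) -> dict:
    """Survival report for classifier groups.

    Joins each record to its sample's label, estimates a KM curve and
    median survival per group, and runs pairwise log-rank tests between
    all label pairs (skipped when only one label is present).
    """
    unmatched = [r.sample_id for r in records if r.sample_id not in labels]
    if unmatched:
        raise SurvivalError(f"records without a label: {unmatched[:10]}")
    by_group: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        by_group.setdefault(labels[r.sample_id], []).append(r)
    report: dict = {"groups": {}, "pairwise_logrank": {}}
    curves = {}
    for g, recs in sorted(by_group.items()):
        curve = km_estimate(recs)
        curves[g] = curve
        report["groups"][g] = {
            "n": len(recs),
            "n_events": int(sum(r.event for r in recs)),
            "median_survival": median_survival(curve),
            "km": {
                "event_times": curve.event_times.tolist(),
                "survival": curve.survival.tolist(),
                "at_risk": curve.at_risk.tolist(),
            },
        }
    for a, b in combinations(sorted(by_group), 2):
        result = logrank_test({a: by_group[a], b: by_group[b]})
        report["pairwise_logrank"][f"{a}|{b}"] = {
            "chi2": result.chi2,
            "p": result.p,
        }
    return report
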