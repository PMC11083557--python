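"""Survival stratification: median splits, composite risk, KM, log-rank.

Subjects are split at the median of a marker's methylation and of its
expression; a gene-specific composite risk rule (e.g. hypomethylated
AND highly expressed) defines the high-risk stratum.  The Kaplan-Meier
product-limit estimator and the Mantel-Haenszel log-rank test are
implemented from scratch; an established survival library serves only
as an independent oracle in the test suite.

The optional data-driven cutoff scan mimics "auto-selected optimal
cut-off" stratifiers: it minimises the log-rank p over candidate
cutoffs within a quantile band.  Because minimum-p selection is
anti-conservative, a permutation-adjusted p is always reported
alongside the uncorrected one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"
HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time, event indicator, group label."""

    subject_id: str
    time: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"{self.subject_id}: negative follow-up time")
        if self.event not in (0, 1):
            raise DataError(f"{self.subject_id}: event must be 0 or 1")


@dataclass(frozen=True)
class RiskRule:
    """Pairing of methylation and expression groups defining high risk.

    ``methylation_direction`` is "hypo" (below-median methylation) or
    "hyper"; ``expression_direction`` is "high" or "low".
    """

    gene_id: str
    methylation_direction: str
    expression_direction: str

    def __post_init__(self) -> None:
        if self.methylation_direction not in ("hypo", "hyper"):
            raise ConfigError("methylation_direction must be 'hypo' or 'hyper'")
        if self.expression_direction not in (HIGH, LOW):
            raise ConfigError("expression_direction must be 'high' or 'low'")


@dataclass
class KMCurve:
    """Product-limit estimate: distinct event times, S(t), at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def probability_at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def median_split(values: pd.Series) -> pd.Series:
    """Label subjects high/low relative to the median (ties go low)."""
    values = values.astype(float)
    if len(values) < 2:
        raise DataError("median_split: need >= 2 subjects")
    if values.nunique() == 1:
        raise DataError("degenerate split: all values identical")
    med = values.median()
    return pd.Series(np.where(values > med, HIGH, LOW), index=values.index)


def composite_risk(
    meth_labels: pd.Series, expr_labels: pd.Series, rule: RiskRule
) -> pd.Series:
    """Combine median-split labels into high/low composite risk.

    The "hypomethylation group" is the below-median methylation group,
    so rule direction "hypo" matches methylation label "low".  A subject
    is high risk iff both its methylation and expression labels match
    the rule; every other combination is low risk.
    """
    if set(meth_labels.index) != set(expr_labels.index):
        missing = set(meth_labels.index) ^ set(expr_labels.index)
        raise DataError(f"subjects missing a label: {sorted(missing)}")
    expr_labels = expr_labels.reindex(meth_labels.index)
    meth_match = LOW if rule.methylation_direction == "hypo" else HIGH
    high = (meth_labels == meth_match) & (expr_labels == rule.expression_direction)
    return pd.Series(np.where(high, HIGH_RISK, LOW_RISK), index=meth_labels.index)


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("no subjects")
    if (times < 0).any():
        raise DataError("negative follow-up time")
    if not np.isin(events, (0, 1)).all():
        raise DataError("event indicators must be 0 or 1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); subjects
    censored exactly at an event time count as at risk at that time.
    """
    times, events = _as_arrays(times, events)
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
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_counts, dtype=int),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test.

    At each distinct event time the observed events in group 1 are
    compared with the hypergeometric expectation given the at-risk
    margins; chi-square = (sum O - sum E)^2 / sum V on 1 df.  Zero total
    variance yields p = 1 with a warning.
    """
    times, events = _as_arrays(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise DataError(f"logrank_test requires exactly 2 groups, got {labels.size}")
    g1 = groups == labels[0]
    if events.sum() == 0:
        logger.warning("log-rank: no events observed; p = 1")
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        logger.warning("log-rank: zero total variance; p = 1")
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def optimal_cutoff(
    values: pd.Series,
    times,
    events,
    quantile_range: tuple[float, float] = (0.2, 0.8),
    n_permutations: int = 200,
    seed: int | None = 0,
) -> dict:
    """Minimum-p cutoff scan with permutation-adjusted significance.

    Candidate cutoffs are the observed values within the quantile band;
    subjects with value > cutoff are labelled high.  Returns the cutoff
    minimising the uncorrected log-rank p, the labels, and a
    permutation-adjusted p obtained by re-running the full scan on
    value permutations (accounting for the selection).
    """
    values = values.astype(float)
    times, events = _as_arrays(times, events)
    if len(values) < 10:
        raise DataError("optimal_cutoff: need >= 10 subjects")
    lo, hi = np.quantile(values, quantile_range)
    candidates = np.unique(values[(values >= lo) & (values <= hi)])

    def scan(vals: np.ndarray) -> tuple[float, float]:
        best_p, best_cut = np.inf, None
        for c in candidates:
            labels = np.where(vals > c, HIGH, LOW)
            if len(np.unique(labels)) < 2:
                continue
            _, p = logrank_test(times, events, labels)
            if p < best_p:
                best_p, best_cut = p, float(c)
        return best_p, best_cut

    vals = values.to_numpy()
    best_p, best_cut = scan(vals)
    if best_cut is None:
        raise DataError("no valid cutoff: all candidate splits degenerate")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm_p, _ = scan(rng.permutation(vals))
        if perm_p <= best_p:
            hits += 1
    adjusted_p = (1 + hits) / (n_permutations + 1)
    labels = pd.Series(np.where(vals > best_cut, HIGH, LOW), index=values.index)
    return {
        "cutoff": best_cut,
        "labels": labels,
        "p_uncorrected": best_p,
        "p_permutation": adjusted_p,
        "n_permutations": n_permutations,
    }


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a clinical table TSV (subject, time, event, extra columns)."""
    df = pd.read_csv(path, sep="\t")
    required = ["subject", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"clinical table missing columns: {missing}")
    return df.set_index("subject")
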