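"""Scoring of clusterings and subtypes.

NMI and best-match accuracy compare partitions; the chi-square test links
a clustering to an external categorical annotation (e.g. histology); the
k-sample log-rank test and Kaplan-Meier estimator quantify survival
separation between subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import linear_sum_assignment

from .clustering import ClusterAssignment

__all__ = [
    "SurvivalTable",
    "TestResult",
    "KaplanMeierCurve",
    "nmi",
    "matched_accuracy",
    "chi_square_association",
    "logrank_test",
    "kaplan_meier_curve",
]


@dataclass
class SurvivalTable:
    """Right-censored survival data: time in days, event 1=death, 0=censored."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == self.time.size == self.event.size):
            raise ValueError("sample_ids, time and event must have equal length")
        if np.any(self.time < 0):
            raise ValueError("survival times must be >= 0")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicators must be 0 or 1")


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    df: int


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # event times where the curve drops (0 prepended)
    survival: np.ndarray  # S(t) at and after each time

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])


def _as_labels(a) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(a, ClusterAssignment):
        return np.asarray(a.labels), list(a.sample_ids)
    return np.asarray(a), None


def _check_same_samples(a, b) -> tuple[np.ndarray, np.ndarray]:
    la, ida = _as_labels(a)
    lb, idb = _as_labels(b)
    if ida is not None and idb is not None:
        if set(ida) != set(idb):
            raise ValueError("labelings cover different sample sets")
        if ida != idb:  # align b to a's order
            pos = {s: i for i, s in enumerate(idb)}
            lb = lb[[pos[s] for s in ida]]
    elif la.size != lb.size:
        raise ValueError("labelings have different lengths")
    return la, lb


def nmi(a, b, average_method: str = "arithmetic") -> float:
    """Normalised mutual information between two labelings, in [0, 1].

    Mutual information (natural log) normalised by the arithmetic mean of
    the two label entropies by default (``"max"``, ``"sqrt"`` and ``"min"``
    variants available).  Two single-cluster labelings are identical
    partitions, so the degenerate 0/0 case evaluates to 1.
    """
    la, lb = _check_same_samples(a, b)
    n = la.size
    if n == 0:
        raise ValueError("empty labelings")
    table = pd.crosstab(la, lb).to_numpy(dtype=float)
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = float(np.sum(pij[nz] * (np.log(pij[nz]) - np.log(np.outer(pi, pj)[nz]))))
    ha = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    hb = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    norm = {
        "arithmetic": (ha + hb) / 2.0,
        "max": max(ha, hb),
        "min": min(ha, hb),
        "sqrt": np.sqrt(ha * hb),
    }[average_method]
    if norm <= 0:
        return 1.0 if ha == hb == 0 else 0.0
    return float(np.clip(mi / norm, 0.0, 1.0))


def matched_accuracy(pred, truth) -> float:
    """Clustering accuracy under the best one-to-one label matching.

    Cluster labels are arbitrary, so agreement is maximised over label
    permutations via optimal assignment on the confusion matrix.
    """
    lp, lt = _check_same_samples(pred, truth)
    cats_p = np.unique(lp)
    cats_t = np.unique(lt)
    conf = np.zeros((cats_p.size, cats_t.size))
    for i, cp in enumerate(cats_p):
        for j, ct in enumerate(cats_t):
            conf[i, j] = np.sum((lp == cp) & (lt == ct))
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / lp.size)


def chi_square_association(a, b) -> TestResult:
    """Pearson chi-square association between two categorical labelings.

    No continuity correction; all-zero rows/columns of the contingency
    table are dropped with a warning.
    """
    la, lb = _check_same_samples(a, b)
    table = pd.crosstab(la, lb).to_numpy(dtype=float)
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping empty rows/columns from contingency table", stacklevel=2)
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("chi-square association needs >= 2 categories on each side")
    stat, p, df, _ = scipy.stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p), df=int(df))


def logrank_test(groups, surv: SurvivalTable) -> TestResult:
    """k-sample log-rank test for survival differences between groups.

    Observed-minus-expected events per group are accumulated over the
    pooled event times with the hypergeometric variance; the statistic is
    chi-square with k-1 degrees of freedom.
    """
    lg, idg = _as_labels(groups)
    if idg is not None and idg != list(surv.sample_ids):
        pos = {s: i for i, s in enumerate(surv.sample_ids)}
        missing = [s for s in idg if s not in pos]
        if missing:
            raise ValueError(f"survival table is missing samples {missing[:5]}")
        order = [pos[s] for s in idg]
        time, event = surv.time[order], surv.event[order]
    else:
        if lg.size != surv.time.size:
            raise ValueError("group labels and survival table differ in length")
        time, event = surv.time, surv.event
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one observed event")
    uniq = np.unique(lg)
    if uniq.size < 2:
        raise ValueError("log-rank test needs >= 2 groups")

    from lifelines.statistics import multivariate_logrank_test

    df_in = pd.DataFrame({"time": time, "event": event, "group": lg})
    res = multivariate_logrank_test(df_in["time"], df_in["group"], df_in["event"])
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=int(uniq.size - 1),
    )


def kaplan_meier_curve(surv: SurvivalTable) -> KaplanMeierCurve:
    """Product-limit survival estimate; censored subjects leave the risk
    set without a drop.  S(0) = 1 and the curve is non-increasing."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(surv.time, surv.event)
    sf = km.survival_function_
    times = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    if times.size == 0 or times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        vals = np.concatenate([[1.0], vals])
    return KaplanMeierCurve(times=times, survival=vals)
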