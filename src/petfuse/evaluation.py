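"""Survival-prediction metrics, Kaplan-Meier estimation and the log-rank test.

The metric suite for one experimental arm is RMSLE, MAPE (%), Pearson r with
its two-sided p-value, and the concordance index. The concordance index uses
Harrell's censoring-aware form: a pair is comparable when the smaller
observed time is an event; a risk tie counts 1/2. With no censoring and no
ties this reduces to the plain rank-agreement indicator sum. RMSLE, MAPE and
Pearson compare predicted with actual times and are therefore computed on
event-observed patients only (a censored time is a lower bound, not an
actual time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError


def _check_pair(actual, predicted):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ParameterError("actual and predicted must be 1-D arrays of equal length")
    return a, p


def rmsle(actual, predicted) -> float:
    """sqrt(mean((log(yhat + 1) - log(y + 1))^2))."""
    a, p = _check_pair(actual, predicted)
    if (a < 0).any() or (p < 0).any():
        raise ParameterError("RMSLE requires non-negative times")
    return float(np.sqrt(np.mean((np.log1p(p) - np.log1p(a)) ** 2)))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, 100/n * sum(|y - yhat| / y)."""
    a, p = _check_pair(actual, predicted)
    if (a <= 0).any():
        raise ParameterError("MAPE requires strictly positive actual times")
    return float(100.0 * np.mean(np.abs(a - p) / a))


def pearson(actual, predicted) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform."""
    a, p = _check_pair(actual, predicted)
    if a.size < 3:
        raise ParameterError("Pearson correlation requires n >= 3")
    if a.std() == 0 or p.std() == 0:
        raise DegenerateInputError("Pearson correlation is undefined for a constant vector")
    r, pval = stats.pearsonr(a, p)
    return float(r), float(pval)


def c_index(time, event, risk) -> tuple[float, int]:
    """Harrell's concordance index; returns ``(C, n_comparable)``.

    Pair (i, j) with ``t_i < t_j`` is comparable iff patient i had the event;
    it is concordant when ``risk_i > risk_j``, and a risk tie scores 1/2.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    r = np.asarray(risk, dtype=float)
    if not (t.shape == e.shape == r.shape) or t.ndim != 1:
        raise ParameterError("time, event and risk must be 1-D arrays of equal length")
    dt = t[:, None] < t[None, :]  # i strictly earlier than j
    comparable = dt & (e[:, None] == 1)
    n_c = int(comparable.sum())
    if n_c == 0:
        raise DegenerateInputError("no comparable pairs (all censored or all times tied)")
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    concordant = float(higher[comparable].sum()) + 0.5 * float(tied[comparable].sum())
    return concordant / n_c, n_c


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray  # distinct event/censoring times, ascending, starting at 0
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # number at risk just before each time
    group: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(time, event, group: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Steps occur at distinct event times; censored-only times reduce the
    at-risk count without a step. ``S(0) = 1``.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if t.size == 0:
        raise ParameterError("km_estimate requires at least one observation")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    times = [0.0]
    surv = [1.0]
    at_risk = [t.size]
    s = 1.0
    for u in uniq:
        n_at = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        if d > 0:
            s *= 1.0 - d / n_at
        times.append(float(u))
        surv.append(s)
        at_risk.append(n_at)
    return KMCurve(np.asarray(times), np.asarray(surv), np.asarray(at_risk), group)


def log_rank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi2, p)`` with 1 df.

    At each distinct pooled event time the observed events in group A are
    compared with their expectation under the pooled hazard, with the usual
    hypergeometric variance.
    """
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a).astype(int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b).astype(int)
    if ta.size == 0 or tb.size == 0:
        raise ParameterError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise DegenerateInputError("log-rank test requires at least one event")
    pooled = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for u in pooled:
        n1 = int((ta >= u).sum())
        n2 = int((tb >= u).sum())
        d1 = int(((ta == u) & (ea == 1)).sum())
        d2 = int(((tb == u) & (eb == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        expected = d * n1 / n
        o_minus_e += d1 - expected
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class MetricsReport:
    """One table row: the four metrics plus cohort bookkeeping."""

    rmsle: float
    mape: float
    pearson_r: float
    pearson_p: float
    c_index: float
    n: int
    n_events: int
    n_comparable_pairs: int

    def as_dict(self) -> dict:
        return {
            "rmsle": self.rmsle,
            "mape": self.mape,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "c_index": self.c_index,
            "n": self.n,
            "n_events": self.n_events,
            "n_comparable_pairs": self.n_comparable_pairs,
        }


def evaluate_arm(predicted_time, risk, time, event) -> MetricsReport:
    """Compute the metric row for one arm.

    RMSLE/MAPE/Pearson use event-observed patients; the concordance index
    uses every comparable pair including censored ones.
    """
    pt = np.asarray(predicted_time, dtype=float)
    rk = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    obs = e == 1
    if obs.sum() < 3:
        raise DegenerateInputError("need at least 3 event-observed patients for the metric row")
    r, p = pearson(t[obs], pt[obs])
    c, n_c = c_index(t, e, rk)
    return MetricsReport(
        rmsle=rmsle(t[obs], pt[obs]),
        mape=mape(t[obs], pt[obs]),
        pearson_r=r,
        pearson_p=p,
        c_index=c,
        n=int(t.size),
        n_events=int(obs.sum()),
        n_comparable_pairs=n_c,
    )
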