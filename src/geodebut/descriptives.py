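"""Exploratory survival analysis: Kaplan-Meier curves, log-rank tests,
early-debut prevalence tables with Pearson chi-square tests.

Conventions: the Kaplan-Meier estimator and the log-rank test are the
classical unweighted versions; survey weights enter only the prevalence
percentages (counts stay unweighted, matching the usual presentation of
survey tables where the Pearson test is computed on raw counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EARLY_DEBUT_AGE = 15.0


class EstimationError(ValueError):
    """Raised when an estimator's preconditions fail (e.g. no events)."""


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve over the distinct event times of one stratum."""

    times: np.ndarray  # distinct event times, sorted
    at_risk: np.ndarray  # n_j
    events: np.ndarray  # d_j
    survival: np.ndarray  # S(t_j)
    se: np.ndarray  # Greenwood standard errors
    stratum: str = "overall"

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "se": self.se,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def early_debut_indicator(time_years, event) -> np.ndarray:
    """1 iff the debut event was observed before age 15.

    Censored records are 0 by construction: every participant is at least
    15 at interview, so anyone censored has not debuted before 15.
    """
    t = np.asarray(time_years, dtype=float)
    d = np.asarray(event)
    return ((d == 1) & (t < EARLY_DEBUT_AGE)).astype(int)


def km_estimate(records: pd.DataFrame, stratum: str = "overall") -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    Ties are pooled at their common time; censorings at an event time
    remain in the risk set for that event (standard convention).
    """
    t = records["time_years"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    if d.sum() == 0:
        raise EstimationError(f"no events in stratum {stratum!r}")

    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = len(t)

    event_times = np.unique(t[d == 1])
    # at risk at t_j: all with t_i >= t_j (left searchsorted on sorted t)
    n_at_risk = n - np.searchsorted(t, event_times, side="left")
    d_j = np.array([int(d[t == et].sum()) for et in event_times])

    frac = 1.0 - d_j / n_at_risk
    surv = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * sum d/(n(n-d)) over past event times
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d_j / (n_at_risk * (n_at_risk - d_j))
    terms = np.where(n_at_risk == d_j, np.nan, terms)  # SE undefined when S hits 0
    gw = np.cumsum(np.nan_to_num(terms, nan=0.0))
    se = surv * np.sqrt(gw)
    return KMCurve(
        times=event_times,
        at_risk=n_at_risk,
        events=d_j,
        survival=surv,
        se=se,
        stratum=stratum,
    )


def survival_median(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or None if never reached."""
    hit = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[hit[0]]) if hit.size else None


def logrank_test(records: pd.DataFrame, group: str) -> LogRankResult:
    """Classical K-group log-rank test.

    At each pooled event time the observed event count per group is
    compared with its expectation under the null of identical hazards; the
    quadratic form uses the multivariate hypergeometric covariance, and
    the statistic is referred to chi-square with K-1 degrees of freedom.
    """
    if group not in records.columns:
        raise EstimationError(f"unknown group covariate {group!r}")
    labels, codes = np.unique(records[group].to_numpy(), return_inverse=True)
    k = len(labels)
    if k < 2:
        raise EstimationError("log-rank needs >= 2 groups")
    t = records["time_years"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    if d.sum() == 0:
        raise EstimationError("no events")

    event_times = np.unique(t[d == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n_j = int(at_risk.sum())
        n_gj = np.bincount(codes[at_risk], minlength=k).astype(float)
        ev = (t == et) & (d == 1)
        d_j = int(ev.sum())
        d_gj = np.bincount(codes[ev], minlength=k).astype(float)
        observed += d_gj
        expected += d_j * n_gj / n_j
        if n_j > 1:
            scale = d_j * (n_j - d_j) / (n_j - 1)
            p = n_gj / n_j
            cov += scale * (np.diag(p) - np.outer(p, p))

    z = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(v) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return LogRankResult(statistic=stat, df=df, p_value=p)


def prevalence_table(records: pd.DataFrame, covariate: str) -> pd.DataFrame:
    """Early-debut prevalence by level of one covariate.

    Counts are unweighted; percentages are survey-weighted row
    percentages; the Pearson chi-square (no continuity correction) is
    computed on the unweighted level-by-outcome table.  Rows with a
    missing covariate value are excluded listwise; empty levels are
    dropped with a warning.
    """
    if covariate not in records.columns:
        raise EstimationError(f"unknown covariate {covariate!r}")
    df = records.loc[records[covariate].notna()].copy()
    n_dropped = len(records) - len(df)
    if n_dropped:
        logger.warning("%s: %d record(s) with missing values excluded", covariate, n_dropped)
    df["early"] = early_debut_indicator(df["time_years"], df["event"])

    rows = []
    counts = []
    for level, sub in df.groupby(covariate, sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby drops empties
            logger.warning("%s: level %r has no records, dropped", covariate, level)
            continue
        yes_n = int(sub["early"].sum())
        no_n = len(sub) - yes_n
        w = sub["weight"].to_numpy(dtype=float)
        w_yes = float(w[sub["early"] == 1].sum())
        w_tot = float(w.sum())
        rows.append(
            {
                "covariate": covariate,
                "level": level,
                "n": len(sub),
                "yes_n": yes_n,
                "yes_pct_weighted": 100.0 * w_yes / w_tot,
                "no_n": no_n,
                "no_pct_weighted": 100.0 * (1.0 - w_yes / w_tot),
            }
        )
        counts.append([yes_n, no_n])

    table = np.asarray(counts)
    if table.shape[0] >= 2 and table.sum(axis=0).min() > 0:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, p = np.nan, np.nan
    out = pd.DataFrame(rows)
    out["chi2"] = chi2
    out["p"] = p
    return out
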