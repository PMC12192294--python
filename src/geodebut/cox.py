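"""Cox proportional-hazards fitting and the Poisson-with-offset reduction.

The partial likelihood is maximized by Newton-Raphson with Breslow tie
handling; survey weights enter both the partial likelihood and the
Breslow baseline-hazard denominator.  The censored-survival problem is
then reduced to Poisson form: with N_i(t) the counting process and Y_i(t)
the at-risk process evaluated at t = infinity, the event indicator
N_i = delta_i is treated as a Poisson response with known offset
log Lambda_hat(t_i), where Lambda_hat is the Breslow cumulative baseline
hazard.  An unpenalized log-linear fit of this frame approximately
recovers the Cox coefficients, and the frame is the substrate on which
the geoadditive mixed model is built.

Breslow (not Efron) ties throughout: with ages recorded in whole years
ties are heavy, and the Breslow baseline is exactly the quantity the
offset reduction plugs in, so the choice is material and deliberate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from geodebut.design import DesignError, check_full_rank, dummy_code

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""


@dataclass
class CoxFit:
    """Partial-likelihood estimates and Breslow baseline hazard."""

    beta: pd.Series  # log hazard ratios per design column
    cov: pd.DataFrame  # inverse observed information
    loglik: float
    n_iter: int
    converged: bool
    baseline_times: np.ndarray | None = None  # distinct event times
    baseline_cumhaz: np.ndarray | None = None  # Lambda0 at those times

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        z = 1.959963984540054
        return pd.DataFrame(
            {
                "term": self.beta.index,
                "beta": self.beta.to_numpy(),
                "se": se,
                "HR": np.exp(self.beta.to_numpy()),
                "CI_low": np.exp(self.beta.to_numpy() - z * se),
                "CI_high": np.exp(self.beta.to_numpy() + z * se),
            }
        )


@dataclass
class PoissonFrame:
    """Poisson reduction of the censored data: response, offset, design.

    Rows align one-to-one with the retained records (those with a
    positive cumulative baseline hazard at their observed time).
    """

    X: pd.DataFrame  # dummy-coded covariates, no intercept
    N: np.ndarray  # event indicators (response)
    offset: np.ndarray  # log Lambda_hat_i
    weight: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    cluster: np.ndarray
    records_index: pd.Index
    time: np.ndarray | None = None  # observed durations, for risk-set variance
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.N)


def _risk_set_sums(t_sorted, d_sorted, w_sorted, eta_sorted, X_sorted, need_hessian=True):
    """Breslow building blocks per distinct event time.

    Arrays must be sorted by time ascending.  Risk-set sums S0, S1, S2
    are over everyone with t >= t_j, computed with suffix cumulative sums.
    """
    r = w_sorted * np.exp(eta_sorted)
    event_times = np.unique(t_sorted[d_sorted == 1])
    # index of the first record with t >= t_j
    first = np.searchsorted(t_sorted, event_times, side="left")

    s0_suffix = np.cumsum(r[::-1])[::-1]
    s0 = s0_suffix[first]
    rx = X_sorted * r[:, None]
    s1_suffix = np.cumsum(rx[::-1], axis=0)[::-1]
    s1 = s1_suffix[first]
    s2 = None
    if need_hessian:
        p = X_sorted.shape[1]
        rxx = rx[:, :, None] * X_sorted[:, None, :]
        s2_suffix = np.cumsum(rxx[::-1], axis=0)[::-1]
        s2 = s2_suffix[first]
    # weighted event count and weighted covariate sum among D_j
    wd = np.zeros(len(event_times))
    xd = np.zeros((len(event_times), X_sorted.shape[1]))
    ev = d_sorted == 1
    grp = np.searchsorted(event_times, t_sorted[ev])
    np.add.at(wd, grp, w_sorted[ev])
    np.add.at(xd, grp, w_sorted[ev, None] * X_sorted[ev])
    return event_times, wd, xd, s0, s1, s2


def fit_cox(
    records: pd.DataFrame,
    covariate_spec: Mapping[str, Sequence[str]],
    use_weights: bool = True,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> CoxFit:
    """Maximize the (weighted) Breslow partial likelihood by Newton-Raphson.

    Starts from beta = 0; converges when the largest absolute score
    component falls below ``score_tol`` or the relative log-likelihood
    change below ``ll_tol``.  The covariance is the inverse observed
    information.
    """
    Xdf = dummy_code(records, covariate_spec)
    names = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)
    t = records["time_years"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    w = records["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(t))
    if d.sum() == 0:
        raise DesignError("no events in data")
    check_full_rank(X, names)

    order = np.argsort(t, kind="stable")
    ts, ds, ws, Xs = t[order], d[order], w[order], X[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll_prev = -np.inf
    trace = []
    if p == 0:  # null model: only the Breslow baseline is of interest
        _, wd, xd, s0, _, _ = _risk_set_sums(ts, ds, ws, np.zeros(len(ts)), Xs, need_hessian=False)
        ll = float(-np.sum(wd * np.log(s0)))
        return CoxFit(
            beta=pd.Series(beta, index=names, dtype=float),
            cov=pd.DataFrame(np.zeros((0, 0))),
            loglik=ll,
            n_iter=0,
            converged=True,
        )
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        _, wd, xd, s0, s1, s2 = _risk_set_sums(ts, ds, ws, eta, Xs)
        ll = float(np.sum(xd @ beta) - np.sum(wd * np.log(s0)))
        sbar = s1 / s0[:, None]
        score = xd.sum(axis=0) - (wd[:, None] * sbar).sum(axis=0)
        info = np.einsum("j,jkl->kl", wd, s2 / s0[:, None, None]) - np.einsum(
            "j,jk,jl->kl", wd, sbar, sbar
        )
        trace.append((it, ll, float(np.max(np.abs(score)))))
        if np.max(np.abs(score)) < score_tol:
            ll_prev = ll
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise DesignError(f"singular information matrix: {exc}") from exc
        # halve the step if the likelihood would not improve
        for _ in range(30):
            cand = beta + step
            eta_c = Xs @ cand
            _, wd_c, xd_c, s0_c, _, _ = _risk_set_sums(ts, ds, ws, eta_c, Xs, need_hessian=False)
            ll_c = float(np.sum(xd_c @ cand) - np.sum(wd_c * np.log(s0_c)))
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= ll_tol * (abs(ll_prev) + 1e-12):
            ll_prev = ll
            break
        ll_prev = ll
    else:
        raise ConvergenceError(f"no convergence after {max_iter} iterations; trace={trace}")

    eta = Xs @ beta
    _, wd, xd, s0, s1, s2 = _risk_set_sums(ts, ds, ws, eta, Xs)
    ll = float(np.sum(xd @ beta) - np.sum(wd * np.log(s0)))
    sbar = s1 / s0[:, None]
    info = np.einsum("j,jkl->kl", wd, s2 / s0[:, None, None]) - np.einsum(
        "j,jk,jl->kl", wd, sbar, sbar
    )
    cov = np.linalg.inv(info)
    return CoxFit(
        beta=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        n_iter=len(trace),
        converged=True,
    )


def breslow_cumhaz(
    fit: CoxFit,
    records: pd.DataFrame,
    covariate_spec: Mapping[str, Sequence[str]],
    use_weights: bool = True,
) -> tuple[CoxFit, np.ndarray]:
    """Breslow cumulative baseline hazard and its value at each record.

    Lambda0(t) = sum over event times t_j <= t of the weighted event
    count divided by the weighted risk-set sum of exp(x'beta).  Returns
    the fit with the baseline step function attached and the per-record
    vector Lambda0(t_i).
    """
    Xdf = dummy_code(records, covariate_spec)
    X = Xdf.to_numpy(dtype=float)
    t = records["time_years"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    w = records["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(t))
    beta = fit.beta.reindex(Xdf.columns).to_numpy(dtype=float)

    order = np.argsort(t, kind="stable")
    ts, ds, ws, Xs = t[order], d[order], w[order], X[order]
    eta = Xs @ beta
    event_times, wd, _, s0, _, _ = _risk_set_sums(ts, ds, ws, eta, Xs, need_hessian=False)
    increments = wd / s0
    cumhaz = np.cumsum(increments)

    idx = np.searchsorted(event_times, t, side="right") - 1
    lam = np.where(idx >= 0, cumhaz[np.clip(idx, 0, None)], 0.0)
    fit.baseline_times = event_times
    fit.baseline_cumhaz = cumhaz
    return fit, lam


def to_poisson_frame(
    records: pd.DataFrame,
    lam: np.ndarray,
    covariate_spec: Mapping[str, Sequence[str]],
) -> PoissonFrame:
    """Assemble the Poisson frame (N_i = delta_i, offset = log Lambda_i).

    Records censored before the first event time have Lambda_i = 0 and no
    finite offset; they are dropped with a logged count.  No intercept
    column is included: the baseline hazard already accounts for it.
    """
    keep = lam > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d record(s) with zero cumulative baseline hazard", n_dropped)
    if not keep.any():
        raise DesignError("all records have zero cumulative baseline hazard")
    sub = records.loc[keep]
    Xdf = dummy_code(sub, covariate_spec)
    return PoissonFrame(
        X=Xdf,
        N=sub["event"].to_numpy(dtype=float),
        offset=np.log(lam[keep]),
        weight=sub["weight"].to_numpy(dtype=float),
        lon=sub["lon"].to_numpy(dtype=float),
        lat=sub["lat"].to_numpy(dtype=float),
        cluster=sub["cluster"].to_numpy(),
        records_index=sub.index,
        time=sub["time_years"].to_numpy(dtype=float),
        n_dropped=n_dropped,
    )
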