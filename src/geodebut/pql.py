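"""Penalized quasi-likelihood fitting of the geoadditive Poisson model.

The Poisson-offset frame is extended with the low-rank kriging basis and
fitted as a generalized linear mixed model,

    N_i | u ~ Poisson( exp{ (X beta + Z u)_i } * Lambda_i ),
    u ~ N(0, sigma_u^2 I),

by the Breslow-Clayton working-model iteration: a Gaussian linearization
of the Poisson likelihood is solved as a ridge-penalized weighted least
squares in (beta, u), and the random-effect variance sigma_u^2 is
refreshed by the standard REML-type ratio.  Survey weights (normalized to
mean 1 so their arbitrary scale cannot distort the variance component)
multiply the working weights throughout.

The covariance range tau is profiled out with a golden-section search on
the working model's restricted likelihood, and families are compared by
AIC / AICc / BIC with the effective degrees of freedom given by the trace
of the working-model hat matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from geodebut.kriging import (
    BasisMatrices,
    CovarianceSpec,
    KnotSet,
    assemble_design,
)

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054

SIGMA2_FLOOR = 1e-10


class PQLError(RuntimeError):
    """Raised on divergence of the PQL iteration."""


@dataclass
class PQLControl:
    max_iter: int = 200
    rel_tol: float = 1e-6
    sigma2_init: float = 0.1
    fix_sigma2: bool = False  # freeze the variance component at sigma2_init


@dataclass
class TauControl:
    """Golden-section profile search control for the range parameter."""

    max_outer: int = 3
    rel_tol_factor: float = 1e-3  # tolerance = factor * d_max
    flat_tol: float = 1e-8  # profile spread below this => flat, fall back
    n_grid: int = 10  # coarse log-spaced scan to bracket the optimum


@dataclass
class GeoadditiveFit:
    """Fitted geoadditive Poisson mixed model."""

    beta: pd.Series  # fixed effects: covariates + lon + lat
    u: np.ndarray  # spline coefficients
    sigma2_u: float
    tau: float | None
    family: str | None
    loglik: float  # weighted Poisson log-likelihood at convergence
    reml: float  # working-model restricted log-likelihood
    edf: float
    aic: float
    aicc: float
    bic: float
    cov_beta: pd.DataFrame
    n: int
    n_iter: int
    converged: bool
    knots: KnotSet | None = None
    coord_means: tuple[float, float] = (0.0, 0.0)
    fit_id: str = ""
    iteration_log: list = dc_field(default_factory=list)
    tau_profile: list = dc_field(default_factory=list)  # (tau, working REML)
    # converged working-model quantities, kept for the range profile
    _X: np.ndarray | None = None
    _y_star: np.ndarray | None = None
    _W: np.ndarray | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta.to_numpy())), index=self.beta.index)


def _profile_corrected_information(B, BtWB, g, w, time, N):
    """Information for (beta, u) with the baseline offsets treated as estimated.

    The one-row-per-person Poisson frame plugs in the Breslow cumulative
    baseline hazard as a known offset, which overstates the information:
    in the full joint model (one Poisson cell per subject and event time,
    with the log baseline increments as free parameters) profiling those
    increments out subtracts, at each event time, the weighted risk-set
    outer product of the mean design row.  The corrected information

        I = B' W B - sum_j wd_j  Bbar_j Bbar_j'

    (Bbar_j the exp(g)-weighted mean of B over the risk set at event time
    t_j, wd_j the weighted event mass) coincides with the Cox observed
    information when no spatial term is present, so Wald intervals built
    from it attain nominal coverage.
    """
    order = np.argsort(time, kind="stable")
    ts, Ns, ws = time[order], N[order], w[order]
    Bs = B[order]
    r = ws * np.exp(g[order])
    event_times = np.unique(ts[Ns == 1])
    first = np.searchsorted(ts, event_times, side="left")
    s0 = np.cumsum(r[::-1])[::-1][first]
    s1 = np.cumsum((r[:, None] * Bs)[::-1], axis=0)[::-1][first]
    bbar = s1 / s0[:, None]
    wd = np.zeros(len(event_times))
    ev = Ns == 1
    np.add.at(wd, np.searchsorted(event_times, ts[ev]), ws[ev])
    return BtWB - np.einsum("j,jk,jl->kl", wd, bbar, bbar)


def _working_reml(y_star, W, X, Z, sigma2, beta_hat=None) -> float:
    """Restricted log-likelihood of the Gaussian working model.

    V = W^-1 + sigma2 Z Z'; REML = -0.5 (log|V| + log|X'V^-1 X| +
    r' V^-1 r) with r the GLS residual, computed through the Woodbury
    identity so only K-dimensional factorizations are needed.  If
    ``beta_hat`` is omitted the GLS solution at this V is used.
    """
    if Z is None or sigma2 <= SIGMA2_FLOOR:
        def vinv(M):
            return (W[:, None] * M) if M.ndim == 2 else (W * M)

        logdet_V = -float(np.sum(np.log(W)))
    else:
        K = Z.shape[1]
        WZ = W[:, None] * Z
        A = np.eye(K) / sigma2 + Z.T @ WZ  # K x K
        cho = np.linalg.cholesky(A)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(cho))))
        logdet_V = -float(np.sum(np.log(W))) + logdet_A + K * np.log(sigma2)

        def vinv(M):
            WM = (W[:, None] * M) if M.ndim == 2 else (W * M)
            s = np.linalg.solve(A, Z.T @ WM)
            corr = Z @ s
            return WM - ((W[:, None] * corr) if M.ndim == 2 else (W * corr))

    Vinv_X = vinv(X)
    xtvx = X.T @ Vinv_X
    if beta_hat is None:
        beta_hat = np.linalg.solve(xtvx, Vinv_X.T @ y_star)
    r = y_star - X @ beta_hat
    quad = float(r @ vinv(r))
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet_V + logdet_xtvx + quad)


def _reml_profile_sigma2(y_star, W, X, Z) -> tuple[float, float]:
    """Maximize the Gaussian working REML over sigma_u^2 at fixed tau.

    Returns (best sigma2, REML value); Brent search on log sigma2.
    """
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda ls: -_working_reml(y_star, W, X, Z, float(np.exp(ls))),
        bounds=(np.log(1e-8), np.log(1e4)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x)), float(-res.fun)


def fit_pql(
    basis: BasisMatrices,
    control: PQLControl | None = None,
) -> GeoadditiveFit:
    """Breslow-Clayton PQL fit of the Poisson mixed model.

    Iterates (a) the working response y* = eta - offset + (N - mu)/mu,
    (b) the penalized weighted least-squares solve for (beta, u) with
    penalty ||u||^2 / sigma_u^2 and observation weights w_i mu_i, and
    (c) the REML-type variance update
    sigma_u^2 = u'u / (K - tr(S_uu)/sigma_u^2), until the relative change
    in (beta, u, sigma_u^2) falls below the tolerance.

    With no spatial basis (Z of zero columns) the fit reduces exactly to
    the weighted Poisson log-linear model with offset.
    """
    control = control or PQLControl()
    X = basis.X.to_numpy(dtype=float)
    names = list(basis.X.columns)
    Z = basis.Z if basis.Z is not None and basis.Z.shape[1] > 0 else None
    N = np.asarray(basis.N, dtype=float)
    offset = np.asarray(basis.offset, dtype=float)
    w = np.asarray(basis.weight, dtype=float)
    w = w / w.mean()  # scale invariance of the estimating equations
    n, p = X.shape
    K = 0 if Z is None else Z.shape[1]
    B = X if Z is None else np.hstack([X, Z])

    theta = np.zeros(p + K)
    sigma2 = control.sigma2_init if K else np.inf
    eta = offset.copy()
    log: list[tuple] = []
    pinned = False
    for it in range(1, control.max_iter + 1):
        mu = np.exp(eta)
        if not np.all(np.isfinite(mu)):
            raise PQLError(f"divergence at iteration {it}: non-finite mean; log={log}")
        y_star = (eta - offset) + (N - mu) / mu
        Wobs = w * mu
        BtWB = B.T @ (Wobs[:, None] * B)
        BtWy = B.T @ (Wobs * y_star)
        P = np.zeros((p + K, p + K))
        if K and not pinned:
            P[p:, p:] = np.eye(K) / sigma2
        elif K and pinned:
            P[p:, p:] = np.eye(K) / SIGMA2_FLOOR
        Ainv = np.linalg.inv(BtWB + P)
        theta_new = Ainv @ BtWy

        sigma2_new = sigma2
        if K and not pinned and not control.fix_sigma2:
            u = theta_new[p:]
            S_uu = Ainv[p:, p:]
            denom = K - np.trace(S_uu) / sigma2
            if denom <= 0:
                denom = 1e-8
            sigma2_new = float(u @ u) / denom
            if sigma2_new < SIGMA2_FLOOR:
                logger.warning(
                    "sigma_u^2 pinned at lower bound %g: fit reduces to fixed effects", SIGMA2_FLOOR
                )
                sigma2_new = SIGMA2_FLOOR
                pinned = True

        delta = np.max(np.abs(theta_new - theta)) / (1.0 + np.max(np.abs(theta_new)))
        dsig = abs(sigma2_new - sigma2) / (1.0 + abs(sigma2_new)) if K else 0.0
        theta, sigma2 = theta_new, sigma2_new
        eta = B @ theta + offset
        log.append((it, float(sigma2 if K else 0.0), float(delta)))
        if max(delta, dsig) < control.rel_tol:
            converged = True
            break
    else:
        converged = False
        logger.warning("PQL did not converge in %d iterations", control.max_iter)

    mu = np.exp(eta)
    y_star = (eta - offset) + (N - mu) / mu
    Wobs = w * mu
    BtWB = B.T @ (Wobs[:, None] * B)
    P = np.zeros((p + K, p + K))
    if K:
        P[p:, p:] = np.eye(K) / (SIGMA2_FLOOR if pinned else sigma2)
    Ainv = np.linalg.inv(BtWB + P)
    edf = float(np.trace(Ainv @ BtWB))
    loglik = float(np.sum(w * (N * eta - mu)))  # log N! = 0 for N in {0,1}
    reml = _working_reml(y_star, Wobs, X, Z, 0.0 if (pinned or not K) else sigma2, theta[:p])

    # covariance: account for the Breslow offsets being estimated, not known
    if basis.time is not None:
        I_corr = _profile_corrected_information(B, BtWB, eta - offset, w, basis.time, N)
        cov_all = np.linalg.inv(I_corr + P)
    else:
        cov_all = Ainv

    aic = -2.0 * loglik + 2.0 * edf
    if n > edf + 1:
        aicc = aic + 2.0 * edf * (edf + 1.0) / (n - edf - 1.0)
    else:
        aicc = np.nan
        logger.warning("AICc undefined: n <= edf + 1")
    bic = -2.0 * loglik + np.log(n) * edf

    return GeoadditiveFit(
        beta=pd.Series(theta[:p], index=names),
        u=theta[p:].copy(),
        sigma2_u=float(0.0 if not K else sigma2),
        tau=basis.cov_spec.tau if K else None,
        family=basis.cov_spec.family if K else None,
        loglik=loglik,
        reml=reml,
        edf=edf,
        aic=aic,
        aicc=aicc,
        bic=bic,
        cov_beta=pd.DataFrame(cov_all[:p, :p], index=names, columns=names),
        n=n,
        n_iter=len(log),
        converged=converged,
        knots=basis.knots,
        coord_means=basis.coord_means,
        iteration_log=log,
        _X=X,
        _y_star=y_star,
        _W=Wobs,
    )


def _golden_section(f, lo: float, hi: float, tol: float) -> tuple[float, float, list]:
    """Golden-section maximization of f on [lo, hi]; returns (x*, f*, evals)."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    evals = []

    def fe(x):
        v = f(x)
        evals.append((x, v))
        return v

    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fe(c), fe(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fe(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fe(d)
    x = c if fc >= fd else d
    fx = max(fc, fd)
    return x, fx, evals


def estimate_tau(
    frame,
    covariate_spec: Mapping[str, Sequence[str]],
    knots: KnotSet,
    family: str,
    control: TauControl | None = None,
    pql_control: PQLControl | None = None,
    project_km: bool = False,
) -> tuple[float, GeoadditiveFit]:
    """Two-stage profile estimation of the covariance range tau.

    Stage one fits the mixed model at a fixed tau and records the working
    model's restricted log-likelihood; stage two maximizes that profile
    over tau on [d_min, d_max], the observed range of pairwise distances:
    a coarse log-spaced scan brackets the optimum (the profile can be
    multimodal, with a spurious shoulder at large ranges where a huge
    variance component compensates a nearly flat basis), then
    golden-section search refines within the bracket.  The stages
    alternate (each search reuses the variance component found at the
    current optimum) until tau moves by less than the tolerance.  A flat
    profile falls back to tau = d_max, the classical fixed choice.
    """
    control = control or TauControl()
    pql_control = pql_control or PQLControl()
    locs = np.unique(np.column_stack([frame.lon, frame.lat]), axis=0)
    if len(locs) < 2:
        raise ValueError("tau estimation needs >= 2 distinct locations")
    d = cdist(locs, locs)
    d_max = float(d.max())
    pos = d[d > 0]
    d_min = float(pos.min())
    if not (d_max > d_min):
        raise ValueError("degenerate search interval for tau")
    tol = control.rel_tol_factor * d_max

    def make_basis(tau: float):
        return assemble_design(
            frame, covariate_spec, knots, CovarianceSpec(family, float(tau)),
            project_km=project_km,
        )

    # stage 1 seed: PQL fit at the midpoint range, to fix the Gaussian
    # working response on which the tau profile is evaluated coherently
    tau_hat = float(np.sqrt(d_min * d_max))
    fit = fit_pql(make_basis(tau_hat), pql_control)
    profile_trace: list[tuple[float, float]] = []
    for _ in range(control.max_outer):
        X = fit._X
        y_star, W = fit._y_star, fit._W
        cache: dict[float, tuple[float, float]] = {}

        def profile(tau: float) -> float:
            tau = float(tau)
            if tau not in cache:
                Z = make_basis(tau).Z
                cache[tau] = _reml_profile_sigma2(y_star, W, X, Z)
            return cache[tau][1]

        grid = np.geomspace(d_min, d_max, control.n_grid)
        grid_vals = np.array([profile(t) for t in grid])
        if grid_vals.max() - grid_vals.min() < control.flat_tol * (
            1.0 + abs(grid_vals.mean())
        ):
            logger.info("flat tau profile: falling back to tau = d_max = %g", d_max)
            x = float(d_max)
            profile(x)
        else:
            i = int(np.argmax(grid_vals))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            if hi - lo < tol:
                x = float(grid[i])
            else:
                x, _, _ = _golden_section(profile, float(lo), float(hi), tol)
        profile_trace = sorted(cache.items())
        sigma2_at_x = max(cache[float(x)][0], SIGMA2_FLOOR * 10)
        converged_tau = abs(x - tau_hat) < tol
        tau_hat = float(x)
        # stage 2: refit the mixed model at the new tau, refreshing the
        # working response for the next profile round
        fit = fit_pql(
            make_basis(tau_hat),
            PQLControl(
                max_iter=pql_control.max_iter,
                rel_tol=pql_control.rel_tol,
                sigma2_init=sigma2_at_x,
                fix_sigma2=pql_control.fix_sigma2,
            ),
        )
        if converged_tau:
            break
    fit.tau_profile = [(t, v[1]) for t, v in profile_trace]
    return tau_hat, fit


def information_criteria(fit: GeoadditiveFit, n: int | None = None) -> tuple[float, float, float]:
    """AIC, AICc, BIC from the weighted Poisson log-likelihood and edf."""
    n = n or fit.n
    aic = -2.0 * fit.loglik + 2.0 * fit.edf
    aicc = aic + 2.0 * fit.edf * (fit.edf + 1.0) / (n - fit.edf - 1.0) if n > fit.edf + 1 else np.nan
    bic = -2.0 * fit.loglik + np.log(n) * fit.edf
    return aic, aicc, bic


def select_covariance(
    frame,
    covariate_spec: Mapping[str, Sequence[str]],
    knots: KnotSet,
    families: Sequence[str],
    control: TauControl | None = None,
    pql_control: PQLControl | None = None,
    project_km: bool = False,
) -> tuple[pd.DataFrame, GeoadditiveFit]:
    """Estimate tau and fit per family; rank by AICc, BIC as tiebreak.

    Returns the comparison table (one row per successful family) and the
    best family's fit.  Families whose fit fails are logged and excluded.
    """
    if not families:
        raise ValueError("family list is empty")
    rows = []
    fits: dict[str, GeoadditiveFit] = {}
    for fam in families:
        try:
            tau_hat, fit = estimate_tau(
                frame, covariate_spec, knots, fam, control, pql_control, project_km
            )
        except Exception as exc:  # noqa: BLE001 - a family may legitimately fail
            logger.warning("family %r failed: %s", fam, exc)
            continue
        fits[fam] = fit
        rows.append(
            {
                "family": fam,
                "tau": tau_hat,
                "sigma2_u": fit.sigma2_u,
                "edf": fit.edf,
                "loglik": fit.loglik,
                "AIC": fit.aic,
                "AICc": fit.aicc,
                "BIC": fit.bic,
            }
        )
    if not rows:
        raise PQLError("all covariance families failed to fit")
    table = pd.DataFrame(rows).sort_values(["AICc", "BIC"], kind="stable").reset_index(drop=True)
    best = fits[table.loc[0, "family"]]
    return table, best


def hazard_ratios(
    fit: GeoadditiveFit,
    level: float = 0.95,
    covariate_spec: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Adjusted hazard ratios exp(beta) with Wald confidence intervals.

    One row per fixed-effect column (covariate levels and the two
    coordinate terms); reference levels, when a covariate spec is given,
    appear as marker rows with an empty estimate.
    """
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se
    rows = []
    ref_rows = {}
    if covariate_spec:
        for name, levels in covariate_spec.items():
            ref_rows[f"{name}[{levels[1]}]" if len(levels) > 1 else name] = (name, levels[0])
    for term in fit.beta.index:
        if term in ref_rows:
            name, ref = ref_rows[term]
            rows.append(
                {
                    "term": f"{name}[{ref}]",
                    "beta": np.nan,
                    "se": np.nan,
                    "aHR": np.nan,
                    "CI_low": np.nan,
                    "CI_high": np.nan,
                    "reference": True,
                }
            )
        b, s = float(fit.beta[term]), float(se[term])
        rows.append(
            {
                "term": term,
                "beta": b,
                "se": s,
                "aHR": np.exp(b),
                "CI_low": np.exp(b - z * s),
                "CI_high": np.exp(b + z * s),
                "reference": False,
            }
        )
    return pd.DataFrame(rows)
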