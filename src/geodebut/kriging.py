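"""Low-rank kriging spline basis for the spatial smooth.

The bivariate smooth S(s) is expanded as a linear part in the coordinates
plus a radial spline, S(s) = s'beta_s + sum_k u_k z_k(s), whose basis is
derived from a generalized covariance function g_tau evaluated at
data-to-knot and knot-to-knot distances:

    Z = C(s, kappa) @ C(kappa, kappa)^(-1/2)

with C(a, b)_{ij} = g_tau(||a_i - b_j||).  Six isotropic covariance
families are supported; knots are placed by a space-filling (maximin)
selection among the distinct observed locations, with the knot count
following Ruppert's rule K = max(20, min(n/4, 150)).

Distances are Euclidean in the raw coordinate units (degrees for
lat/lon data); an optional local equirectangular projection to
kilometres is available for users at latitudes where one degree of
longitude is much shorter than one of latitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from geodebut.design import DesignError, check_full_rank

FAMILIES = ("exponential", "gaussian", "matern", "spherical", "circular", "inverse_quadratic")


class CovarianceError(ValueError):
    """Raised for invalid covariance specifications or degenerate bases."""


@dataclass(frozen=True)
class CovarianceSpec:
    """Isotropic generalized covariance family with range parameter tau."""

    family: str
    tau: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CovarianceError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not (self.tau > 0):
            raise CovarianceError(f"range parameter tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class KnotSet:
    """Selected knot locations with the maximin objective achieved."""

    knots: np.ndarray  # (K, 2)
    seed: int
    objective: float  # minimum inter-knot distance

    @property
    def k(self) -> int:
        return len(self.knots)


@dataclass
class BasisMatrices:
    """Design matrices for the geoadditive Poisson mixed model.

    X holds the dummy-coded covariates plus mean-centered coordinate
    columns (no intercept: the baseline-hazard offset plays that role);
    Z is the n-by-K radial spline basis.
    """

    X: pd.DataFrame
    Z: np.ndarray
    N: np.ndarray
    offset: np.ndarray
    weight: np.ndarray
    knots: KnotSet
    cov_spec: CovarianceSpec
    coord_means: tuple[float, float]  # (lon mean, lat mean) used for centering
    locations: np.ndarray = field(default=None)  # (n, 2) as (lon, lat)
    time: np.ndarray | None = None  # observed durations (risk-set structure)


def knot_count(n: int) -> int:
    """Ruppert's rule for the number of spline knots.

    K = max(20, min(floor(n/4), 150)); monotone in n and clamped to
    [20, 150].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(max(20, min(n // 4, 150)))


def select_knots(candidates: np.ndarray, k: int, seed: int = 0) -> KnotSet:
    """Space-filling (maximin) knot selection among candidate locations.

    Duplicated candidates are collapsed first.  A greedy max-min
    ("coffee-house") pass seeds the set: start from the point nearest the
    candidates' centroid, then repeatedly add the candidate farthest from
    the current set.  Pairwise swap improvement then replaces a selected
    point by an unselected one whenever the swap increases the minimum
    inter-knot distance, until no swap improves it.  Deterministic given
    the seed (which only breaks exact ties in the greedy pass).
    """
    cand = np.unique(np.asarray(candidates, dtype=float), axis=0)
    if len(cand) < k:
        raise DesignError(f"only {len(cand)} distinct candidate locations for K={k} knots")
    if len(cand) == k:
        return KnotSet(knots=cand, seed=seed, objective=_min_dist(cand))

    rng = np.random.default_rng(seed)
    d = cdist(cand, cand)

    centroid = cand.mean(axis=0)
    start = int(np.argmin(((cand - centroid) ** 2).sum(axis=1)))
    selected = [start]
    min_to_sel = d[start].copy()
    for _ in range(k - 1):
        best = np.flatnonzero(min_to_sel == min_to_sel.max())
        nxt = int(rng.choice(best)) if len(best) > 1 else int(best[0])
        selected.append(nxt)
        min_to_sel = np.minimum(min_to_sel, d[nxt])

    sel = set(selected)
    improved = True
    while improved:
        improved = False
        sel_idx = np.array(sorted(sel))
        sub = d[np.ix_(sel_idx, sel_idx)]
        np.fill_diagonal(sub, np.inf)
        obj = sub.min()
        # the knots realizing the current minimum are the binding ones
        binding = sel_idx[np.unique(np.argwhere(sub == obj))]
        others = [j for j in range(len(cand)) if j not in sel]
        for out in binding:
            rest = np.array(sorted(sel - {out}))
            rest_sub = d[np.ix_(rest, rest)]
            np.fill_diagonal(rest_sub, np.inf)
            rest_min = rest_sub.min()
            for inc in others:
                new_obj = min(rest_min, d[inc, rest].min())
                if new_obj > obj + 1e-15:
                    sel.remove(out)
                    sel.add(inc)
                    improved = True
                    break
            if improved:
                break

    sel_idx = np.array(sorted(sel))
    knots = cand[sel_idx]
    return KnotSet(knots=knots, seed=seed, objective=_min_dist(knots))


def _min_dist(points: np.ndarray) -> float:
    if len(points) < 2:
        return np.inf
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def gcov(spec: CovarianceSpec, h) -> np.ndarray:
    """Generalized covariance g_tau at distance(s) h >= 0.

    Families (tau the range): exponential exp(-h/tau); gaussian
    exp(-h^2/tau^2); Matern at smoothness 3/2, (1 + h/tau) exp(-h/tau);
    spherical (1 - 1.5 h/tau + 0.5 h^3/tau^3) on h < tau, else 0;
    circular (2/pi)(arccos v - v sqrt(1 - v^2)) with v = min(h/tau, 1);
    inverse quadratic 1/(1 + h^2/tau^2).  All equal 1 at h = 0.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise CovarianceError("distances must be non-negative")
    r = h / spec.tau
    if spec.family == "exponential":
        return np.exp(-r)
    if spec.family == "gaussian":
        return np.exp(-(r**2))
    if spec.family == "matern":
        return (1.0 + r) * np.exp(-r)
    if spec.family == "spherical":
        return np.where(r < 1.0, 1.0 - 1.5 * r + 0.5 * r**3, 0.0)
    if spec.family == "circular":
        v = np.minimum(r, 1.0)
        return (2.0 / np.pi) * (np.arccos(v) - v * np.sqrt(np.clip(1.0 - v**2, 0.0, None)))
    if spec.family == "inverse_quadratic":
        return 1.0 / (1.0 + r**2)
    raise CovarianceError(f"unknown family {spec.family!r}")  # pragma: no cover


def _inv_sqrt_psd(C: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root with eigenvalue flooring.

    Eigenvalues below eps times the largest are treated as null
    directions and contribute zero, which keeps the basis finite for
    near-singular knot covariance matrices (e.g. very large tau).
    """
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    lam_max = vals.max()
    if lam_max <= 0:
        raise CovarianceError("knot covariance matrix has no positive eigenvalues")
    inv_sqrt = np.where(vals > eps * lam_max, 1.0 / np.sqrt(np.clip(vals, 1e-300, None)), 0.0)
    return (vecs * inv_sqrt) @ vecs.T


def build_Z(locations: np.ndarray, knots: KnotSet, spec: CovarianceSpec) -> np.ndarray:
    """Radial spline basis Z = C(s, kappa) C(kappa, kappa)^(-1/2)."""
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    C_sk = gcov(spec, cdist(locs, knots.knots))
    C_kk = gcov(spec, cdist(knots.knots, knots.knots))
    return C_sk @ _inv_sqrt_psd(C_kk)


def project_equirectangular(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Local equirectangular projection of (lon, lat) degrees to km."""
    lat0 = np.deg2rad(np.mean(lat))
    x = 111.32 * np.cos(lat0) * np.asarray(lon, dtype=float)
    y = 110.57 * np.asarray(lat, dtype=float)
    return np.column_stack([x, y])


def assemble_design(
    frame,
    covariate_spec: Mapping[str, Sequence[str]],
    knots: KnotSet,
    cov_spec: CovarianceSpec,
    project_km: bool = False,
) -> BasisMatrices:
    """Fixed and random design matrices from a Poisson frame.

    X holds the frame's dummy-coded covariates plus the two coordinate
    columns, each centered at its mean (no intercept).  Z comes from
    :func:`build_Z` at the frame's locations.  The frame's columns are
    validated against ``covariate_spec``.
    """
    expected = [
        f"{name}[{level}]" for name, levels in covariate_spec.items() for level in levels[1:]
    ]
    if list(frame.X.columns) != expected:
        raise DesignError(
            f"frame columns {list(frame.X.columns)} do not match spec columns {expected}"
        )
    Xcov = frame.X
    if project_km:
        locs = project_equirectangular(frame.lon, frame.lat)
    else:
        locs = np.column_stack([frame.lon, frame.lat])
    mean_x, mean_y = float(locs[:, 0].mean()), float(locs[:, 1].mean())
    X = Xcov.copy()
    X["lon"] = locs[:, 0] - mean_x
    X["lat"] = locs[:, 1] - mean_y
    check_full_rank(X.to_numpy(dtype=float), list(X.columns))
    # knots must live in the same coordinate system as the (possibly
    # projected) locations; the pipeline selects them from these very points
    Z = build_Z(locs, knots, cov_spec)
    return BasisMatrices(
        X=X,
        Z=Z,
        N=frame.N,
        offset=frame.offset,
        weight=frame.weight,
        knots=knots,
        cov_spec=cov_spec,
        coord_means=(mean_x, mean_y),
        locations=locs,
        time=getattr(frame, "time", None),
    )
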