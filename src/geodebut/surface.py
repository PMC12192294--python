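"""Prediction and export of the spatial log-hazard-ratio surface.

The mapped quantity is the total spatial effect — the linear coordinate
terms plus the radial smooth, S(s) = s' beta_s + sum_k u_k z_k(s) —
mean-centered over the masked grid, because without an absolute baseline
reference only spatial contrasts in log(HR) are meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from geodebut.kriging import CovarianceSpec, KnotSet, build_Z
from geodebut.pql import GeoadditiveFit
from geodebut.synthetic import StudyDomain


class SurfaceError(ValueError):
    pass


@dataclass
class HazardSurface:
    """Gridded spatial log-hazard-ratio field."""

    lon: np.ndarray  # flattened grid
    lat: np.ndarray
    log_hr: np.ndarray  # centered over the mask; NaN off-mask values kept
    masked: np.ndarray  # True = outside the mask (excluded from centering)
    resolution: tuple[int, int]
    fit_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lon": self.lon, "lat": self.lat, "log_hr": self.log_hr, "masked": self.masked}
        )


def make_grid(
    domain: StudyDomain, resolution: int | tuple[int, int] = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regular lattice over the domain bounds with off-mask points flagged.

    Returns (lon, lat, masked) flattened arrays; spacing along each axis
    is (width)/(resolution-1), so the lattice includes both bound edges.
    """
    if isinstance(resolution, int):
        resolution = (resolution, resolution)
    rx, ry = resolution
    if rx < 2 or ry < 2:
        raise SurfaceError("resolution must be >= 2 per axis")
    xmin, xmax, ymin, ymax = domain.bounds
    gx, gy = np.meshgrid(np.linspace(xmin, xmax, rx), np.linspace(ymin, ymax, ry))
    gx, gy = gx.ravel(), gy.ravel()
    masked = ~domain.contains(gx, gy)
    if masked.all():
        raise SurfaceError("mask excludes every grid point")
    return gx, gy, masked


def convex_hull_domain(lon: np.ndarray, lat: np.ndarray) -> StudyDomain:
    """Bounding box of the data with its convex hull as the mask."""
    pts = np.column_stack([lon, lat])
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":  # collinear data: no area, fall back to box
        return StudyDomain(
            bounds=(float(lon.min()), float(lon.max()), float(lat.min()), float(lat.max()))
        )
    coords = tuple(hull.exterior.coords)
    return StudyDomain(
        bounds=(float(lon.min()), float(lon.max()), float(lat.min()), float(lat.max())),
        mask=coords,
    )


def predict_log_hr(
    fit: GeoadditiveFit,
    grid: tuple[np.ndarray, np.ndarray, np.ndarray],
    knots: KnotSet | None = None,
    cov_spec: CovarianceSpec | None = None,
    resolution: tuple[int, int] | None = None,
    include_linear: bool = True,
) -> HazardSurface:
    """Spatial log(HR) surface at the grid points, centered over the mask.

    The prediction is the centered-coordinate linear part times the
    fitted coordinate coefficients, plus Z(grid) u_hat with Z built
    against the fit's knots and covariance; ``include_linear`` switches
    the coordinate terms off to map the smooth alone.
    """
    gx, gy, masked = grid
    knots = knots if knots is not None else fit.knots
    if knots is None:
        raise SurfaceError("fit carries no knots and none were supplied")
    if cov_spec is None:
        if fit.family is None or fit.tau is None:
            raise SurfaceError("fit has no spatial component")
        cov_spec = CovarianceSpec(fit.family, fit.tau)

    vals = np.zeros(len(gx))
    if include_linear:
        mx, my = fit.coord_means
        vals += (gx - mx) * float(fit.beta.get("lon", 0.0))
        vals += (gy - my) * float(fit.beta.get("lat", 0.0))
    if len(fit.u):
        Zg = build_Z(np.column_stack([gx, gy]), knots, cov_spec)
        vals += Zg @ fit.u

    # center over the mask only; off-mask values are kept (flagged) for CSV
    vals = vals - vals[~masked].mean()
    return HazardSurface(
        lon=gx,
        lat=gy,
        log_hr=vals,
        masked=masked,
        resolution=resolution or (0, 0),
        fit_id=fit.fit_id,
    )


def export_surface(surface: HazardSurface, path, fmt: str = "csv") -> None:
    """Write the surface as CSV (all points, flagged) or GeoJSON (mask only).

    CSV columns: lon, lat, log_hr, masked.  GeoJSON is a
    FeatureCollection of Point features with a ``log_hr`` property,
    masked points excluded.  Values round-trip losslessly via repr-level
    precision.
    """
    if fmt == "csv":
        df = surface.to_frame()
        df.to_csv(path, index=False, float_format="%.17g")
        return
    if fmt == "geojson":
        feats = []
        for x, y, v, m in zip(surface.lon, surface.lat, surface.log_hr, surface.masked):
            if m:
                continue
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": {"log_hr": float(v)},
                }
            )
        doc = {"type": "FeatureCollection", "features": feats}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
        return
    raise SurfaceError(f"unknown format {fmt!r}")


def read_surface_csv(path) -> HazardSurface:
    """Inverse of :func:`export_surface` for the CSV format."""
    df = pd.read_csv(path)
    return HazardSurface(
        lon=df["lon"].to_numpy(dtype=float),
        lat=df["lat"].to_numpy(dtype=float),
        log_hr=df["log_hr"].to_numpy(dtype=float),
        masked=df["masked"].to_numpy(dtype=bool),
        resolution=(0, 0),
    )
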