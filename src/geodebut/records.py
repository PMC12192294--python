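"""Person-level survival records: schema, validation, CSV input/output.

A cohort is a :class:`pandas.DataFrame` with one row per person and the
fixed columns ``id, cluster, lat, lon, time_years, event, weight`` plus one
column per categorical covariate.  ``time_years`` is the observed duration
t_i = min(T_i, C_i): the age at first sex if the event was observed
(``event`` = 1) or the age at interview if censored (``event`` = 0).
``weight`` is the survey weight (inverse selection probability); all
persons in a cluster share the cluster's point location (``lat``, ``lon``).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "id",
    "cluster",
    "lat",
    "lon",
    "time_years",
    "event",
    "weight",
)


class RecordValidationError(ValueError):
    """Raised when a records table violates the schema contract."""


def validate_records(
    records: pd.DataFrame,
    covariates: Sequence[str] = (),
    max_reject_fraction: float = 0.05,
) -> pd.DataFrame:
    """Validate a records table, dropping invalid rows with diagnostics.

    Rows with missing time/event/location, non-positive time or weight, or
    an event flag outside {0, 1} are rejected with per-column counts
    logged.  The run aborts if more than ``max_reject_fraction`` of rows
    are rejected.

    Returns the validated (possibly reduced) table with numeric dtypes
    coerced.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise RecordValidationError(f"missing required columns: {missing}")
    for cov in covariates:
        if cov not in records.columns:
            raise RecordValidationError(f"unknown covariate column: {cov!r}")

    df = records.copy()
    n_in = len(df)
    if n_in == 0:
        raise RecordValidationError("records table is empty")

    bad = pd.Series(False, index=df.index)
    reasons: dict[str, int] = {}

    def _flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        k = int(mask.sum())
        if k:
            reasons[reason] = k
            rows = df.index[mask][:5].tolist()
            logger.warning("rejected %d row(s): %s (e.g. rows %s)", k, reason, rows)
        bad |= mask

    for col in ("time_years", "event", "weight", "lat", "lon"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    _flag(df[["time_years", "event", "lat", "lon", "weight"]].isna().any(axis=1), "missing value")
    _flag(df["time_years"] <= 0, "non-positive time_years")
    _flag(~df["event"].isin([0, 1]), "event not in {0,1}")
    _flag(df["weight"] <= 0, "non-positive weight")
    _flag(~np.isfinite(df["lat"]) | ~np.isfinite(df["lon"]), "non-finite location")

    n_bad = int(bad.sum())
    if n_bad > max_reject_fraction * n_in:
        raise RecordValidationError(
            f"{n_bad}/{n_in} rows rejected (> {max_reject_fraction:.0%}): {reasons}"
        )
    out = df.loc[~bad].copy()
    out["event"] = out["event"].astype(int)
    return out


def read_records(
    path,
    column_mapping: Mapping[str, str] | None = None,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a records CSV, optionally renaming columns to the schema.

    ``column_mapping`` maps schema names (``time_years``, ``event``, ...)
    to the column names used in the file.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise RecordValidationError(f"no data rows in {path}")
    if column_mapping:
        rename = {src: dst for dst, src in column_mapping.items() if src in df.columns}
        unknown = [src for src in column_mapping.values() if src not in df.columns]
        if unknown:
            raise RecordValidationError(f"mapped columns not in file: {unknown}")
        df = df.rename(columns=rename)
    return validate_records(df, covariates=covariates)


def write_records(records: pd.DataFrame, path) -> None:
    """Write records to CSV (UTF-8, header, no index)."""
    records.to_csv(path, index=False, encoding="utf-8")
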