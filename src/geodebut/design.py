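"""Dummy coding of categorical covariates against declared reference levels."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised for rank deficiency or unseen covariate levels."""


def dummy_code(
    records: pd.DataFrame, covariate_spec: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Indicator columns for every non-reference covariate level.

    ``covariate_spec`` maps covariate name to its ordered levels, the
    first being the reference.  Column names are ``name[level]``.  A value
    outside the declared levels raises :class:`DesignError`.
    """
    cols: dict[str, np.ndarray] = {}
    for name, levels in covariate_spec.items():
        if name not in records.columns:
            raise DesignError(f"covariate {name!r} not in records")
        vals = records[name].astype(str).to_numpy()
        unseen = set(vals) - set(map(str, levels))
        if unseen:
            raise DesignError(f"covariate {name!r}: unseen level(s) {sorted(unseen)}")
        for level in levels[1:]:
            cols[f"{name}[{level}]"] = (vals == str(level)).astype(float)
    return pd.DataFrame(cols, index=records.index)


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the offending columns if X is column-rank deficient."""
    if X.shape[1] == 0:
        return
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        raise DesignError(f"constant column(s) in design: {const}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of dependent columns by QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        dependent = [names[piv[j]] for j in range(len(diag)) if diag[j] < 1e-10 * diag[0]]
        dependent += [names[j] for j in piv[len(diag):]]
        raise DesignError(f"collinear column(s) in design: {dependent}")
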