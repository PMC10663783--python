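"""Helpers for choosing null-region boundaries.

Choosing the boundary of a null region — the smallest effect worth caring
about — is a substantive judgment: cost-benefit (utility) analysis, minimal
clinically important differences, and practical-significance arguments all
live outside any computation.  The one boundary-setting approach this module
implements is the *ambient noise level* (also called the crud estimate): in
very large samples, conceptually unrelated variables still correlate at some
nonzero magnitude, and the typical size of those incidental correlations is a
defensible floor for a meaningful effect.  The estimator here is the mean
absolute off-diagonal correlation of a large correlation matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["AmbientNoiseEstimate", "estimate_ambient_noise", "correlation_matrix_from_data"]


@dataclass(frozen=True)
class AmbientNoiseEstimate:
    """Mean absolute off-diagonal correlation and the region half-width it suggests.

    ``suggested_delta`` is on the correlation scale; converting it to other
    effect measures is left to the user.
    """

    mean_abs_r: float
    n_pairs: int
    method: str
    suggested_delta: float


def estimate_ambient_noise(corr) -> AmbientNoiseEstimate:
    """Ambient-noise level from a correlation matrix.

    The estimate is the mean of ``|r|`` over the strict upper triangle of the
    matrix (``m*(m-1)/2`` pairs for ``m`` variables); the suggested MET/EqT
    half-width ``delta`` is that mean, taken directly on the correlation
    scale.  Sign is discarded because a symmetric null region cares only
    about magnitude, and signed means of incidental correlations cancel.
    """
    if isinstance(corr, pd.DataFrame):
        mat = corr.to_numpy(dtype=float)
    else:
        mat = np.asarray(corr, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DataError(f"correlation matrix must be square, got shape {mat.shape}")
    m = mat.shape[0]
    if m < 3:
        raise DataError(f"need at least 3 variables for an ambient-noise estimate, got {m}")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise DataError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise DataError("correlation matrix must have a unit diagonal")
    if np.any(np.abs(mat) > 1 + 1e-12):
        raise DataError("correlation entries must lie in [-1, 1]")

    iu = np.triu_indices(m, k=1)
    offdiag = mat[iu]
    mean_abs = float(np.mean(np.abs(offdiag)))
    if mean_abs == 0.0:
        warnings.warn(
            "ambient noise level is 0: a zero-width null region degenerates to the "
            "point null of traditional NHST",
            stacklevel=2,
        )
    return AmbientNoiseEstimate(
        mean_abs_r=mean_abs,
        n_pairs=int(m * (m - 1) // 2),
        method="mean_abs_offdiagonal",
        suggested_delta=mean_abs,
    )


def correlation_matrix_from_data(df: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the numeric columns of a raw-data table."""
    numeric = df.select_dtypes(include="number")
    if numeric.shape[1] < 3:
        raise DataError(
            f"need at least 3 numeric columns to form a correlation matrix, "
            f"got {numeric.shape[1]}"
        )
    return numeric.corr(method="pearson")
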