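"""Sample projection by SVD of the row-centered gene-set Z-value matrix.

The input is a set x sample matrix of gene-set Z scores (one column per
biological sample, one row per gene set). Each row is centered to mean zero
across samples (optionally scaled to unit variance) and the singular value
decomposition of the centered matrix is taken. Sample coordinates are the
right singular vectors scaled by their singular values; the fraction of
variance per component is the normalized squared singular value. Component
signs are fixed deterministically (the largest-magnitude loading of each
component is made positive) so outputs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateProjectionError

logger = logging.getLogger(__name__)

__all__ = ["ProjectionResult", "project_samples"]


@dataclass(frozen=True)
class ProjectionResult:
    """Sample coordinates and variance fractions from the SVD projection."""

    sample_ids: tuple[str, ...]
    coordinates: pd.DataFrame      # samples x PC1..PCk
    variance_fraction: np.ndarray  # per kept component, nonincreasing
    components_kept: int
    loadings: pd.DataFrame | None = None  # sets x PC1..PCk (unit columns)


def project_samples(zmatrix: pd.DataFrame, components: int | None = None,
                    *, scale: bool = False,
                    return_loadings: bool = False) -> ProjectionResult:
    """Project samples by SVD of the row-centered Z matrix.

    ``scale=True`` additionally divides each centered row by its standard
    deviation (rows with zero spread are dropped with a warning).
    """
    if zmatrix.shape[0] < 2 or zmatrix.shape[1] < 2:
        raise ConfigurationError("need >= 2 rows and >= 2 samples")
    if zmatrix.index.has_duplicates or zmatrix.columns.has_duplicates:
        raise ConfigurationError("duplicate row or sample labels")
    X = zmatrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ConfigurationError("matrix contains non-finite values")
    rows = list(map(str, zmatrix.index))
    samples = tuple(map(str, zmatrix.columns))

    Xc = X - X.mean(axis=1, keepdims=True)
    if scale:
        sd = Xc.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance rows before scaling",
                           int((~keep).sum()))
        Xc = Xc[keep] / sd[keep, None]
        rows = [r for r, k in zip(rows, keep) if k]
        if Xc.shape[0] < 2:
            raise DegenerateProjectionError("fewer than 2 informative rows")
    if not np.any(Xc):
        raise DegenerateProjectionError("centered matrix is identically zero")

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(S.size):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]

    total = float(np.sum(S ** 2))
    var_frac = S ** 2 / total
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    k = min(components or rank, S.size)
    cols = [f"PC{j + 1}" for j in range(k)]
    coords = pd.DataFrame(Vt[:k].T * S[:k], index=list(samples), columns=cols)
    loadings = (pd.DataFrame(U[:, :k], index=rows, columns=cols)
                if return_loadings else None)
    return ProjectionResult(samples, coords, var_frac[:k], k, loadings)
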