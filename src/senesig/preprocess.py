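"""Quantile normalization and detection-p filtering.

Mirrors the standard Illumina BeadArray preprocessing contract: arrays are
background-corrected upstream, brought onto a common intensity
distribution by quantile normalization, and reduced to reliably detected
probes by thresholding the per-cell detection p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, ValidationError
from .matrix import ExpressionMatrix

__all__ = ["quantile_normalize", "detection_filter"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    The reference distribution is the row-wise mean of the per-column
    sorted value vectors; each value is replaced by the reference value
    at its within-column rank. Ties within a column receive the mean of
    the reference values over their tied rank positions, which makes the
    transform idempotent.

    Raises
    ------
    ValidationError
        If fewer than two samples are present or values are missing.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    if np.isnan(X).any():
        raise ValidationError("missing values are not supported; supply a complete matrix")

    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        # cumulative reference sums give the tie-group mean in O(n log n)
        lo = rankdata(col, method="min").astype(np.intp) - 1
        hi = rankdata(col, method="max").astype(np.intp)
        csum = np.concatenate([[0.0], np.cumsum(reference)])
        out[:, j] = (csum[hi] - csum[lo]) / (hi - lo)

    values = pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(values, matrix.detection_p)


def detection_filter(matrix: ExpressionMatrix, alpha: float = 0.05,
                     min_detected: int | str = "all") -> ExpressionMatrix:
    """Retain probes detected (p <= alpha) in at least ``min_detected`` samples.

    ``min_detected="all"`` (the default) keeps a probe only when it is
    detected in every sample of the matrix, the conservative reading of a
    condition-level detection filter.
    """
    if not (0 < alpha <= 1):
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    if matrix.detection_p is None:
        raise ValidationError("matrix carries no detection p-values")
    if min_detected == "all":
        needed = matrix.n_samples
    else:
        needed = int(min_detected)
        if not (1 <= needed <= matrix.n_samples):
            raise ConfigurationError(
                f"min_detected must be in [1, {matrix.n_samples}], got {min_detected}")
    detected = (matrix.detection_p.to_numpy() <= alpha).sum(axis=1)
    keep = matrix.probe_ids[detected >= needed]
    return matrix.subset_probes(keep)
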