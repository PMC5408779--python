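"""Small statistical utilities for pattern readouts."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["two_means_split", "bimodality", "BIMODALITY_FLAG_THRESHOLD"]

#: Conventional Sarle threshold: a uniform distribution scores 5/9, values
#: above it suggest bimodality.
BIMODALITY_FLAG_THRESHOLD = 5.0 / 9.0


def two_means_split(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Deterministic 1-D 2-means partition into low (0) and high (1) classes.

    Lloyd iteration initialized at the min/max of the data; returns the
    labels and the decision boundary (midpoint of the two final means).
    Degenerate (constant) input labels everything low with the boundary at
    the common value.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a nonempty 1-D array")
    if np.ptp(x) == 0:
        return np.zeros(x.size, dtype=int), float(x[0])
    c0, c1 = float(x.min()), float(x.max())
    for _ in range(200):
        boundary = 0.5 * (c0 + c1)
        hi = x > boundary
        new0 = float(x[~hi].mean()) if (~hi).any() else c0
        new1 = float(x[hi].mean()) if hi.any() else c1
        if new0 == c0 and new1 == c1:
            break
        c0, c1 = new0, new1
    boundary = 0.5 * (c0 + c1)
    return (x > boundary).astype(int), float(boundary)


def bimodality(samples: np.ndarray) -> float:
    """Sarle's bimodality coefficient with small-sample correction.

    ``b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))`` with sample
    skewness ``g1`` and sample excess kurtosis ``g2``.  A symmetric
    two-point distribution scores 1, a normal sample about 1/3, a uniform
    sample 5/9; values above 5/9 conventionally flag bimodality.  Returns
    NaN for degenerate (zero-variance) samples.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("bimodality requires at least 10 samples")
    if np.ptp(x) == 0 or np.var(x) == 0:
        return float("nan")
    g1 = sps.skew(x, bias=False)
    g2 = sps.kurtosis(x, fisher=True, bias=False)
    denom = g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    if denom <= 0:
        return float("nan")
    return float((g1**2 + 1.0) / denom)
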