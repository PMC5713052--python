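"""First-order histogram statistics of enhanced gray-scale images.

The gray-level distribution P(I) of an 8-bit image summarises its texture:
the mean locates overall brightness, and the central moments

    mu_k = sum_I (I - m1)^k P(I),   k = 2, 3, 4

give variance, asymmetry and peakedness.  Skewness and kurtosis are
reported in their standardised (dimensionless) forms mu3 / mu2^1.5 and
mu4 / mu2^2 (non-excess: a Gaussian histogram gives 3), matching the scale
of the published 25-eye feature table.  The four-vector (mean, std,
skewness, kurtosis) per eye is the classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["HistogramStats", "gray_histogram", "first_order_stats", "extract_features"]

FEATURE_COLUMNS = ["mean", "std", "skewness", "kurtosis"]


@dataclass
class HistogramStats:
    """First-order statistics of a gray-level probability distribution."""

    P: np.ndarray
    m1: float
    mu2: float
    mu3: float
    mu4: float
    std: float
    skewness: float
    kurtosis: float


def gray_histogram(img: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Gray-level probability distribution P(I) = count(I) / total pixels.

    The image must hold integer values in ``[0, n_levels - 1]``.
    """
    img = np.asarray(img)
    values = img.ravel()
    if values.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.floor(values)):
            raise ValueError("image values must be integers")
        values = values.astype(np.int64)
    if values.min() < 0 or values.max() >= n_levels:
        raise ValueError(f"gray levels outside [0, {n_levels - 1}]")
    counts = np.bincount(values, minlength=n_levels)
    return counts / values.size


def first_order_stats(P: np.ndarray) -> HistogramStats:
    """Mean and central moments mu2-mu4 of a gray-level distribution.

    Degenerate distributions (mu2 = 0) report skewness = kurtosis = 0 by
    convention.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 1 or P.min() < 0 or abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("P must be a 1-D probability distribution")
    levels = np.arange(P.size, dtype=np.float64)
    m1 = float(np.sum(levels * P))
    centred = levels - m1
    mu2 = float(np.sum(centred**2 * P))
    mu3 = float(np.sum(centred**3 * P))
    mu4 = float(np.sum(centred**4 * P))
    if mu2 > 0:
        std = float(np.sqrt(mu2))
        skewness = mu3 / mu2**1.5
        kurtosis = mu4 / mu2**2
    else:
        std = skewness = kurtosis = 0.0
    return HistogramStats(P, m1, mu2, mu3, mu4, std, skewness, kurtosis)


def extract_features(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    eye_ids: Sequence | None = None,
    n_levels: int = 256,
) -> pd.DataFrame:
    """One (mean, std, skewness, kurtosis) row per enhanced 8-bit image.

    Returns a table with columns ``eye_id, label, mean, std, skewness,
    kurtosis`` — the same layout as the packaged 25-eye fixture.
    """
    if len(images) == 0:
        raise ValueError("no images given")
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    if eye_ids is None:
        eye_ids = list(range(1, len(images) + 1))
    rows = []
    for eid, img, lab in zip(eye_ids, images, labels):
        s = first_order_stats(gray_histogram(img, n_levels))
        rows.append(
            {
                "eye_id": eid,
                "label": lab,
                "mean": s.m1,
                "std": s.std,
                "skewness": s.skewness,
                "kurtosis": s.kurtosis,
            }
        )
    return pd.DataFrame(rows)
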