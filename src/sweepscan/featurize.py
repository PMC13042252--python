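"""Window featurization: 12 statistics x k subwindows, row-normalized.

A feature window is split into k equal adjacent subwindows (default 11,
central index (k-1)/2).  Each statistic is computed per subwindow, then
each statistic's row is transformed into a spatial profile: if the row's
minimum is negative the row is shifted so the minimum becomes zero, and
the row is divided by its sum.  An all-zero row (after the shift) maps to
the uniform profile 1/k.  The shift is applied before division — dividing
a row that sums to zero or a negative value is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import GenomicInterval, GenotypeMatrix
from .popgen_stats import N_STATS, STAT_NAMES, stat_vector

DEFAULT_SUBWINDOWS = 11


def subwindow_partition(window: GenomicInterval, k: int) -> list[GenomicInterval]:
    """Split ``window`` into k adjacent equal intervals covering it exactly."""
    length = len(window)
    if k < 1:
        raise ValueError("k must be >= 1")
    if length % k != 0:
        raise ValueError(f"window length {length} not divisible by k={k}")
    step = length // k
    return [
        GenomicInterval(window.chrom, window.start + i * step, window.start + (i + 1) * step)
        for i in range(k)
    ]


def raw_stat_matrix(
    gm: GenotypeMatrix,
    subwindows: list[GenomicInterval],
    max_ld_sites: int | None = None,
) -> np.ndarray:
    """12 x k matrix: column j is the statistic vector of subwindow j."""
    cols = [
        stat_vector(gm.slice(sub), max_ld_sites=max_ld_sites) for sub in subwindows
    ]
    return np.column_stack(cols)


def normalize_rows(raw: np.ndarray) -> np.ndarray:
    """Shift-to-nonnegative then divide each row by its sum.

    Rows whose entries are all zero after the shift (including constant
    rows that shift to zero, which cannot carry spatial signal) become the
    uniform row 1/k.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("non-finite entries in raw statistic matrix")
    k = raw.shape[1]
    out = raw.copy()
    row_min = out.min(axis=1, keepdims=True)
    out = np.where(row_min < 0, out - row_min, out)
    sums = out.sum(axis=1, keepdims=True)
    uniform = np.full(k, 1.0 / k)
    with np.errstate(divide="ignore", invalid="ignore"):
        normed = out / sums
    normed = np.where(sums > 0, normed, uniform)
    return normed


@dataclass
class FeatureMatrix:
    """Classifier input: row-normalized 12 x k statistic profiles."""

    values: np.ndarray
    window: GenomicInterval | None = None
    masked_fraction: float = 0.0

    def flatten(self) -> np.ndarray:
        return self.values.ravel()

    @staticmethod
    def feature_names(k: int = DEFAULT_SUBWINDOWS) -> list[str]:
        return [f"{s}_{j}" for s in STAT_NAMES for j in range(k)]


def featurize_window(
    gm: GenotypeMatrix,
    window: GenomicInterval | None = None,
    k: int = DEFAULT_SUBWINDOWS,
    masked_fraction: float = 0.0,
    max_ld_sites: int | None = None,
) -> FeatureMatrix:
    """Compute the normalized feature matrix for one genotype window."""
    window = window or gm.interval
    subs = subwindow_partition(window, k)
    raw = raw_stat_matrix(gm, subs, max_ld_sites=max_ld_sites)
    return FeatureMatrix(normalize_rows(raw), window=window, masked_fraction=masked_fraction)


class WindowFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn-style transformer over genotype windows.

    ``transform`` maps a sequence of GenotypeMatrix objects to an
    (n, 12 * k) array of flattened normalized feature matrices, suitable
    for downstream estimators.
    """

    def __init__(self, k: int = DEFAULT_SUBWINDOWS, max_ld_sites: int | None = None):
        self.k = k
        self.max_ld_sites = max_ld_sites

    def fit(self, X, y=None) -> "WindowFeaturizer":
        self.n_features_out_ = N_STATS * self.k
        return self

    def transform(self, X) -> np.ndarray:
        rows = [
            featurize_window(gm, k=self.k, max_ld_sites=self.max_ld_sites).flatten()
            for gm in X
        ]
        return np.vstack(rows) if rows else np.empty((0, N_STATS * self.k))
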