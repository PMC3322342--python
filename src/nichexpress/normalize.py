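"""Normalization of raw intensities to M/A values and log2 matrices.

Two-color arrays are expressed as per-gene M (log2 ratio, positive =
germarium-enriched after undoing any dye flip) and A (mean log2 intensity),
then centered with a robust intensity-dependent local-regression fit of M on
A.  Single-channel matrices are quantile-normalized onto common order
statistics and returned on the log2 scale.  Both normalizers are
scikit-learn style transformers so they can be fit on one data set and
applied to another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .synthdata import TwoColorArray


@dataclass
class MATable:
    """Per-replicate M and A values on a shared gene order.

    ``M`` and ``A`` are gene x replicate DataFrames with identical shape and
    labels.  Channel log2 intensities are recoverable exactly:
    log2(germarium) = A + M/2 and log2(testis) = A - M/2.
    """

    M: pd.DataFrame
    A: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.M.index.equals(self.A.index) or not self.M.columns.equals(
            self.A.columns
        ):
            raise ValueError("M and A must share gene order and replicate labels")

    @property
    def gene_ids(self) -> pd.Index:
        return self.M.index

    @property
    def n_replicates(self) -> int:
        return self.M.shape[1]

    def log2_germarium(self) -> pd.DataFrame:
        return self.A + self.M / 2.0

    def log2_testis(self) -> pd.DataFrame:
        return self.A - self.M / 2.0

    @classmethod
    def from_arrays(cls, arrays: Sequence[TwoColorArray]) -> "MATable":
        cols_m, cols_a, names = [], [], []
        for arr in arrays:
            m, a = compute_ma(arr)
            cols_m.append(m)
            cols_a.append(a)
            names.append(f"rep{arr.replicate_id}")
        M = pd.concat(cols_m, axis=1)
        A = pd.concat(cols_a, axis=1)
        M.columns = A.columns = names
        return cls(M, A)


def compute_ma(array: TwoColorArray) -> Tuple[pd.Series, pd.Series]:
    """M/A values for one hybridization.

    M = log2(germarium channel / testis channel) after undoing the dye flip;
    A = half-sum of the log2 channel intensities.
    """
    for name, chan in (("ch1", array.intensity_ch1), ("ch2", array.intensity_ch2)):
        bad = chan.index[~(chan.values > 0)]
        if len(bad):
            raise ValueError(
                f"nonpositive intensity in channel {name} for gene(s) "
                f"{list(bad[:5])} (replicate {array.replicate_id})"
            )
    l1 = np.log2(array.intensity_ch1.values)
    l2 = np.log2(array.intensity_ch2.values)
    m = l2 - l1 if array.dye_flipped else l1 - l2
    a = 0.5 * (l1 + l2)
    idx = array.intensity_ch1.index
    return pd.Series(m, index=idx, name="M"), pd.Series(a, index=idx, name="A")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def _local_fit(
    x: np.ndarray,
    y: np.ndarray,
    robust_w: np.ndarray,
    x0: float,
    k: int,
    degree: int,
) -> float:
    """Tricube-weighted polynomial fit of y on x evaluated at x0."""
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1]
    if h <= 0:
        # massive ties at x0: average the co-located points
        w = (d == 0) * robust_w
        if w.sum() <= 0:
            w = (d == 0).astype(float)
        return float(np.average(y, weights=w))
    w = _tricube(d / h) * robust_w
    mask = w > 0
    if mask.sum() <= degree:
        w = _tricube(d / h)
        mask = w > 0
    xm = x[mask] - x0
    ym = y[mask]
    wm = w[mask]
    # Vandermonde normal equations, degree+1 unknowns
    z = np.vander(xm, degree + 1, increasing=True)
    zw = z * wm[:, None]
    try:
        beta = np.linalg.solve(z.T @ zw, zw.T @ ym)
    except np.linalg.LinAlgError:
        return float(np.average(ym, weights=wm))
    return float(beta[0])


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    iterations: int = 3,
    degree: int = 2,
    n_grid: int = 120,
) -> Tuple[np.ndarray, np.ndarray]:
    """Robust loess curve of y on x, returned as a (grid, fitted) pair.

    The curve is fit at ``n_grid`` quantile-spaced anchor points with
    tricube-weighted local polynomial regression (neighborhood = the
    ``ceil(span * n)`` nearest points) and ``iterations`` bisquare
    robustness reweights; values elsewhere are linear interpolations.
    Robustness weights use the global median absolute residual; when the
    bulk of the residuals collapses to zero (noise-free data) only
    zero-residual points keep weight, so planted outliers are excluded
    exactly.
    """
    n = len(x)
    if n < 10:
        raise ValueError(f"loess needs >= 10 genes, got {n}")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"window of {k} genes is too small for a degree-{degree} local fit; "
            f"use a larger span"
        )
    # anchors: quantile-spaced (dense where the data are) plus evenly
    # spaced (bounds the interpolation gap in sparse A regions)
    qs = np.linspace(0.0, 1.0, min(n_grid, n))
    grid = np.unique(
        np.concatenate(
            [np.quantile(x, qs), np.linspace(x.min(), x.max(), min(n_grid, n))]
        )
    )
    robust_w = np.ones(n)
    fitted = np.zeros(n)
    for it in range(iterations + 1):
        grid_y = np.array([_local_fit(x, y, robust_w, g, k, degree) for g in grid])
        fitted = np.interp(x, grid, grid_y)
        if it == iterations:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s < 1e-14:
            robust_w = (np.abs(resid) <= 1e-12).astype(float)
        else:
            robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return grid, grid_y


class LoessNormalizer(BaseEstimator, TransformerMixin):
    """Intensity-dependent centering of two-color M values.

    Fits a robust loess curve of M on A per replicate and subtracts it;
    A values are never changed.  This is the intensity-dependent component
    of within-array normalization (no spatial/print-tip correction).

    Parameters
    ----------
    span:
        Fraction of genes in each local neighborhood.
    iterations:
        Number of bisquare robustness reweights.
    degree:
        Local polynomial degree.  The default (2) follows classical loess
        and removes smooth curvature, e.g. a quadratic dye bias, without
        the curvature bias a local-linear fit would leave behind.
    n_grid:
        Number of anchor points at which the curve is evaluated.
    """

    def __init__(
        self,
        span: float = 0.3,
        iterations: int = 3,
        degree: int = 2,
        n_grid: int = 120,
    ) -> None:
        self.span = span
        self.iterations = iterations
        self.degree = degree
        self.n_grid = n_grid

    def fit(self, ma: MATable, y=None) -> "LoessNormalizer":
        curves = {}
        for rep in ma.M.columns:
            grid, grid_y = loess_fit(
                ma.A[rep].values,
                ma.M[rep].values,
                span=self.span,
                iterations=self.iterations,
                degree=self.degree,
                n_grid=self.n_grid,
            )
            curves[rep] = (grid, grid_y)
        self.curves_ = curves
        self.replicates_ = list(ma.M.columns)
        return self

    def transform(self, ma: MATable) -> MATable:
        if not hasattr(self, "curves_"):
            raise ValueError("LoessNormalizer is not fitted")
        new_m = ma.M.copy()
        for rep in ma.M.columns:
            grid, grid_y = self.curves_[rep]
            new_m[rep] = ma.M[rep].values - np.interp(ma.A[rep].values, grid, grid_y)
        return MATable(new_m, ma.A.copy())


def loess_normalize(
    ma: MATable, span: float = 0.3, iterations: int = 3, degree: int = 2
) -> MATable:
    """Subtract a robust loess fit of M on A from each replicate."""
    return LoessNormalizer(span=span, iterations=iterations, degree=degree).fit_transform(ma)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every sample onto common order statistics, returning log2 values.

    The reference distribution is the rank-wise mean of the sorted linear
    intensity columns seen at fit time.  Transforming replaces each value by
    the reference value at its (average, tie-aware) rank, then applies log2,
    so within-sample ranks are preserved exactly.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "QuantileNormalizer":
        values = self._validate(X)
        self.reference_ = np.sort(values, axis=0).mean(axis=1)
        self.n_rows_ = values.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            raise ValueError("QuantileNormalizer is not fitted")
        values = self._validate(X, n_samples_min=1)
        if values.shape[0] != self.n_rows_:
            raise ValueError(
                f"matrix has {values.shape[0]} genes but the normalizer was fit "
                f"on {self.n_rows_}"
            )
        positions = np.arange(1, self.n_rows_ + 1, dtype=float)
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            ranks = rankdata(values[:, j], method="average")
            out[:, j] = np.interp(ranks, positions, self.reference_)
        result = np.log2(out)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(result, index=X.index, columns=X.columns)
        return pd.DataFrame(result)

    @staticmethod
    def _validate(X, n_samples_min: int = 2) -> np.ndarray:
        values = X.values if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[1] < n_samples_min:
            raise ValueError(f"need a 2D matrix with >= {n_samples_min} samples")
        if not np.all(values > 0):
            raise ValueError("quantile normalization requires strictly positive entries")
        return values


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a gene x sample matrix of positive intensities;
    the result is on the log2 scale with identical per-sample order
    statistics (the across-sample means)."""
    return QuantileNormalizer().fit_transform(matrix)


@dataclass
class ConcordanceResult:
    mean: float
    min: float
    max: float
    pairwise: List[Tuple[str, str, float]]


def replicate_concordance(matrix: pd.DataFrame) -> ConcordanceResult:
    """Mean and range of pairwise Pearson correlation between replicate
    columns of a gene x replicate log2 matrix."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 replicates for concordance")
    values = matrix.values
    sds = values.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(
                f"replicate {matrix.columns[j]!r} has zero variance; "
                f"correlation undefined"
            )
    corr = np.corrcoef(values.T)
    pairs = []
    names = list(matrix.columns)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((names[i], names[j], float(corr[i, j])))
    rs = [r for _, _, r in pairs]
    return ConcordanceResult(
        mean=float(np.mean(rs)), min=float(np.min(rs)), max=float(np.max(rs)), pairwise=pairs
    )
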