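"""Spectral binning: convert peak lists into a standardized intensity matrix.

Each spectrum becomes a fixed-length vector on an m/z grid (default
45.0–704.5 Da at 0.1 Da resolution, 6596 bins).  Peak m/z values are rounded
half-up to the grid resolution, a bin takes the maximum intensity among its
peaks, and the vector is normalised by its own maximum so the largest entry
is exactly 1.  The resulting matrix is extremely sparse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SpectralMatrix
from .records import SpectrumRecord

logger = logging.getLogger(__name__)

# absolute slack for the half-up rounding; float representation errors at
# m/z scale are ~1e-13, genuine quarter-step cases are >= 0.025 away
_ROUND_EPS = 1e-7


@dataclass(frozen=True)
class BinGrid:
    """Uniform m/z grid with bin centres mz_min + j*step.

    With the defaults (45.0, 704.5, 0.1) the grid has exactly 6596 bins.
    Column labels are centres at one decimal; internally bin identity is the
    integer index, avoiding floating-point drift.
    """

    mz_min: float = 45.0
    mz_max: float = 704.5
    step: float = 0.1
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        object.__setattr__(
            self, "n_bins", int(round((self.mz_max - self.mz_min) / self.step)) + 1
        )

    def centers(self) -> np.ndarray:
        return self.mz_min + self.step * np.arange(self.n_bins)

    def labels(self) -> list[str]:
        decimals = max(0, int(np.ceil(-np.log10(self.step))))
        return [f"{c:.{decimals}f}" for c in self.centers()]

    def assign(self, mz: np.ndarray) -> np.ndarray:
        """Half-up rounding to bin indices; out-of-range values get -1."""
        mz = np.asarray(mz, dtype=float)
        j = np.floor((mz - self.mz_min) / self.step + 0.5 + _ROUND_EPS).astype(int)
        j[(j < 0) | (j >= self.n_bins)] = -1
        return j


def make_grid(mz_min: float = 45.0, mz_max: float = 704.5, step: float = 0.1) -> BinGrid:
    """Construct a :class:`BinGrid`; see the class for the bin-count rule."""
    return BinGrid(mz_min=mz_min, mz_max=mz_max, step=step)


def spectrum_to_vector(record: SpectrumRecord, grid: BinGrid) -> np.ndarray:
    """Bin one spectrum onto the grid and normalise to max 1.

    Each bin takes the maximum intensity among the peaks rounding into it;
    peaks rounding outside [mz_min, mz_max] are dropped.  If every peak is
    out of range an all-zero vector is returned with a warning.
    """
    if not record.peaks:
        raise ValueError(f"record {record.record_id} has no peaks")
    mz = np.array([p.mz for p in record.peaks])
    inten = np.array([p.intensity for p in record.peaks])
    j = grid.assign(mz)
    ok = j >= 0
    vec = np.zeros(grid.n_bins)
    if not ok.any():
        warnings.warn(
            f"record {record.record_id}: all peaks outside the m/z grid",
            stacklevel=2,
        )
        return vec
    np.maximum.at(vec, j[ok], inten[ok])
    vmax = vec.max()
    if vmax > 0:
        vec /= vmax
    return vec


class SpectrumBinner(BaseEstimator, TransformerMixin):
    """Transformer from spectral records to a sparse binned matrix.

    Stateless apart from the grid; `fit` exists for pipeline compatibility.

    Parameters
    ----------
    mz_min, mz_max, step : float
        Grid bounds and resolution in Da.
    """

    def __init__(self, mz_min: float = 45.0, mz_max: float = 704.5, step: float = 0.1):
        self.mz_min = mz_min
        self.mz_max = mz_max
        self.step = step

    def fit(self, X: Sequence[SpectrumRecord], y=None) -> "SpectrumBinner":
        self.grid_ = make_grid(self.mz_min, self.mz_max, self.step)
        return self

    def transform(self, X: Sequence[SpectrumRecord]) -> SpectralMatrix:
        if not hasattr(self, "grid_"):
            self.fit(X)
        grid = self.grid_
        rows, cols, vals = [], [], []
        row_ids = []
        for i, rec in enumerate(X):
            vec = spectrum_to_vector(rec, grid)
            nz = np.nonzero(vec)[0]
            rows.extend([i] * len(nz))
            cols.extend(nz.tolist())
            vals.extend(vec[nz].tolist())
            row_ids.append(rec.record_id)
        mat = sp.coo_matrix(
            (vals, (rows, cols)), shape=(len(row_ids), grid.n_bins)
        ).tocsr()
        return SpectralMatrix(row_ids=row_ids, col_labels=grid.labels(), X=mat)


def sparsity(matrix: SpectralMatrix | np.ndarray | sp.spmatrix) -> float:
    """Fraction of exactly-zero entries of the matrix."""
    if isinstance(matrix, SpectralMatrix):
        X = matrix.X
    else:
        X = matrix
    if sp.issparse(X):
        n_total = X.shape[0] * X.shape[1]
        if n_total == 0:
            raise ValueError("empty matrix")
        n_nonzero = int((X != 0).sum())
    else:
        X = np.asarray(X)
        n_total = X.size
        if n_total == 0:
            raise ValueError("empty matrix")
        n_nonzero = int(np.count_nonzero(X))
    return 1.0 - n_nonzero / n_total
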