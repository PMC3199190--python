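"""Temporal design construction and polynomial detrending.

Builds the two-column design matrix used throughout the pipeline — the block
paradigm convolved with a canonical double-gamma hemodynamic response
function (HRF) and with its temporal derivative, mean corrected, Euclidean
normalized and mutually orthogonalized — and provides the cubic-detrending
and BOLD-removal projections applied to every voxel time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import (
    DegenerateDesignError,
    DomainError,
    LengthError,
    ShapeError,
)

__all__ = [
    "HrfParams",
    "DesignMatrix",
    "TrendBasis",
    "hrf_double_gamma",
    "build_design",
    "trend_basis",
    "cubic_detrend",
    "remove_bold",
]

#: degree of the polynomial trend removed from every series
TREND_DEGREE = 3

#: time step (s) of the fine grid on which HRF convolution is carried out
_FINE_DT = 0.1


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the canonical double-gamma HRF.

    The response is a difference of two gamma densities: a positive lobe
    peaking around 5 s and a delayed negative undershoot.  Delays and
    dispersions are in seconds.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0


@dataclass
class DesignMatrix:
    """Temporal regressors ``X`` (nt x k) and contrast vector ``c``.

    Columns are zero mean, unit Euclidean norm and mutually orthogonal.
    """

    X: np.ndarray
    c: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.X.ndim != 2:
            raise ShapeError("design matrix must be 2-D (nt x k)")
        if self.c.shape != (self.X.shape[1],):
            raise ShapeError("contrast length must equal design column count")
        if not np.any(self.c):
            raise DegenerateDesignError("contrast vector must be nonzero")

    @property
    def nt(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path) -> None:
        """Write the regressors (one column per regressor) for inspection."""
        import pandas as pd

        cols = {f"regressor_{j + 1}": self.X[:, j] for j in range(self.k)}
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass
class TrendBasis:
    """Orthonormal basis of polynomials up to degree 3 on ``nt`` samples."""

    P: np.ndarray = field(repr=False)

    @property
    def nt(self) -> int:
        return self.P.shape[0]


def hrf_double_gamma(time_grid_s, params: HrfParams | None = None) -> np.ndarray:
    """Evaluate the double-gamma HRF on a grid of nonnegative times.

    Parameters
    ----------
    time_grid_s
        Nonnegative, strictly increasing times in seconds.
    params
        HRF parameters; the canonical set is used when omitted.

    Returns
    -------
    ndarray
        ``h(t)`` sampled on the grid.  ``h(0) = 0`` and the peak lies near
        5 s for the default parameters.
    """
    params = params or HrfParams()
    t = np.asarray(time_grid_s, dtype=float)
    if t.ndim != 1:
        raise DomainError("time grid must be 1-D")
    if np.any(t < 0):
        raise DomainError("HRF is defined for nonnegative times only")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DomainError("time grid must be strictly increasing")
    peak = sps.gamma.pdf(
        t,
        params.peak_delay / params.peak_dispersion,
        scale=params.peak_dispersion,
    )
    under = sps.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    return peak - params.undershoot_ratio * under


def _paradigm_indicator(paradigm, times: np.ndarray) -> np.ndarray:
    """Evaluate a paradigm as a 0/1 function of time (seconds).

    Accepts any object with an ``indicator_at(times)`` method (see
    :class:`permfmri.data_io.Paradigm`) or a per-volume 0/1 vector, in which
    case each entry is held over one TR inferred from the time grid.
    """
    if hasattr(paradigm, "indicator_at"):
        return np.asarray(paradigm.indicator_at(times), dtype=float)
    vec = np.asarray(paradigm, dtype=float)
    if vec.ndim != 1:
        raise ShapeError("per-volume paradigm must be a 1-D 0/1 vector")
    # Per-volume vector: map each time to the volume containing it.
    duration = times[-1] + (times[1] - times[0]) if times.size > 1 else 1.0
    tr = duration / vec.size
    idx = np.clip((times / tr).astype(int), 0, vec.size - 1)
    return vec[idx]


def build_design(
    paradigm,
    nt: int,
    tr: float,
    contrast=(1.0, 0.0),
    hrf_params: HrfParams | None = None,
) -> DesignMatrix:
    """Build the two-regressor design matrix for a block paradigm.

    Column 1 is the paradigm indicator convolved with the HRF, column 2 the
    indicator convolved with the HRF's temporal derivative (central finite
    differences on a fine 0.1 s grid).  Both are sampled at the volume
    acquisition times ``i * tr``, mean corrected and unit normalized, and
    column 2 is orthogonalized against column 1 (Gram-Schmidt).

    Raises
    ------
    DegenerateDesignError
        If the paradigm carries no task variance (e.g. always on/off).
    """
    if nt < 2:
        raise DomainError("need at least two volumes")
    if tr <= 0:
        raise DomainError("TR must be positive")
    params = hrf_params or HrfParams()

    t_fine = np.arange(0.0, nt * tr, _FINE_DT)
    indicator = _paradigm_indicator(paradigm, t_fine)
    # Amplitude invariance: any positive scaling of the paradigm gives the
    # same design after normalization; enforce a clean 0/1 scale up front.
    if np.ptp(indicator) == 0:
        # all-off or constant-on: no task variance survives mean correction
        raise DegenerateDesignError(
            "paradigm is constant and carries no task-related variance"
        )
    indicator = indicator / np.max(np.abs(indicator))

    t_hrf = np.arange(0.0, params.duration + _FINE_DT, _FINE_DT)
    hrf = hrf_double_gamma(t_hrf, params)
    dhrf = np.gradient(hrf, _FINE_DT)

    sample_idx = np.clip(
        np.round(np.arange(nt) * tr / _FINE_DT).astype(int), 0, t_fine.size - 1
    )
    cols = []
    for kernel in (hrf, dhrf):
        conv = np.convolve(indicator, kernel)[: t_fine.size] * _FINE_DT
        cols.append(conv[sample_idx])
    X = np.column_stack(cols)

    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    if norms[0] < 1e-8 * max(1.0, np.max(np.abs(X))) or norms[0] == 0.0:
        raise DegenerateDesignError(
            "paradigm has no task-related variance after mean correction"
        )
    X[:, 0] /= norms[0]
    # Gram-Schmidt: remove the HRF component from the derivative regressor.
    X[:, 1] -= (X[:, 0] @ X[:, 1]) * X[:, 0]
    n2 = np.linalg.norm(X[:, 1])
    if n2 < 1e-10:
        raise DegenerateDesignError("derivative regressor is degenerate")
    X[:, 1] /= n2
    return DesignMatrix(X=X, c=np.asarray(contrast, dtype=float), tr=tr)


def trend_basis(nt: int, degree: int = TREND_DEGREE) -> TrendBasis:
    """Orthonormal polynomial basis of degree 0..``degree`` on ``nt`` samples.

    Built from powers of normalized time on [-1, 1] (Legendre-like for
    conditioning) and orthonormalized by QR; spans exactly the polynomials
    up to ``degree``.
    """
    if nt < degree + 2:
        raise LengthError(f"need at least {degree + 2} samples, got {nt}")
    u = np.linspace(-1.0, 1.0, nt)
    V = np.vander(u, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return TrendBasis(P=Q)


def cubic_detrend(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares polynomial trend up to degree 3.

    ``series`` may be 1-D ``(nt,)`` or 2-D ``(nt, n_series)``; the returned
    residual is orthogonal to all polynomials of degree <= 3 (including the
    mean).  The operation is an orthogonal projection, hence idempotent.
    """
    y = np.asarray(series, dtype=float)
    nt = y.shape[0]
    if nt < TREND_DEGREE + 2:
        raise LengthError(f"series of length {nt} is too short to detrend")
    P = trend_basis(nt).P
    return y - P @ (P.T @ y)


def remove_bold(series: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Remove the ordinary-least-squares fit of the design from a series.

    Used to build residual (null) data before AR estimation: the returned
    residual is orthogonal to every column of ``X``.
    """
    y = np.asarray(series, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ShapeError("series length must equal design row count")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta
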