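"""Voxelwise AR modelling, whitening and whiteness diagnostics.

fMRI noise is temporally autocorrelated, so the time samples are not
exchangeable and cannot be permuted directly.  This module estimates an
AR(p) model per voxel (Yule-Walker), pools the coefficients spatially by
certainty-weighted (normalized) convolution so estimates from outside the
brain never leak in, whitens the series to exchangeable innovations, and
re-imposes the noise structure on permuted innovations by simulating the AR
model (inverse whitening).  Residual whiteness is verified with the
Ljung-Box portmanteau test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .exceptions import (
    DegenerateSeriesError,
    DomainError,
    EmptyMaskError,
    LengthError,
    ShapeError,
    StationarityError,
)

__all__ = [
    "ARField",
    "WhitenessReport",
    "autocorrelation",
    "yule_walker",
    "normalized_convolve",
    "smooth_ar_field",
    "whiten_series",
    "inverse_whiten",
    "iterative_whiten",
    "ljung_box_q",
    "ljung_box_critical",
    "whiteness_map",
]

#: coefficient vectors with a characteristic root of modulus >= this are
#: shrunk radially so the largest root has modulus _STATIONARY_TARGET
_STATIONARY_LIMIT = 0.99
_STATIONARY_TARGET = 0.98


@dataclass
class ARField:
    """Per-voxel AR(p) coefficients as ``p`` spatial volumes.

    ``coeffs`` has shape ``spatial_shape + (p,)``; coefficients are zero
    outside the brain mask.  ``history`` optionally keeps the per-iteration
    coefficient fields of an iterated whitening run, in application order —
    these define the exactly invertible composed whitening operator, while
    ``coeffs`` is the accumulated operator truncated to order ``p``.
    """

    coeffs: np.ndarray = field(repr=False)
    order: int
    history: list | None = field(default=None, repr=False)

    @property
    def spatial_shape(self) -> tuple:
        return self.coeffs.shape[:-1]


# ---------------------------------------------------------------------------
# autocorrelation and Yule-Walker estimation
# ---------------------------------------------------------------------------


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (divide-by-nt) sample autocorrelations at lags 1..max_lag.

    ``series`` may be ``(nt,)`` or ``(nt, n_series)``.  The biased estimator
    keeps the implied autocovariance sequence positive semidefinite, which
    guarantees a solvable Yule-Walker system.  Returns shape ``(max_lag,)``
    or ``(n_series, max_lag)``.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    nt = y.shape[0]
    if max_lag >= nt:
        raise LengthError("max_lag must be smaller than the series length")
    y = y - y.mean(axis=0)
    c0 = np.einsum("tv,tv->v", y, y) / nt
    r = np.empty((y.shape[1], max_lag))
    good = c0 > 0
    for k in range(1, max_lag + 1):
        ck = np.einsum("tv,tv->v", y[k:], y[:-k]) / nt
        with np.errstate(invalid="ignore", divide="ignore"):
            r[:, k - 1] = np.where(good, ck / np.where(good, c0, 1.0), 0.0)
    return r[0] if squeeze else r


def _autocovariance_raw(S: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocovariances about zero at lags 0..max_lag; ``S`` (nt, nv)."""
    nt, nv = S.shape
    c = np.empty((nv, max_lag + 1))
    c[:, 0] = np.einsum("tv,tv->v", S, S) / nt
    for k in range(1, max_lag + 1):
        c[:, k] = np.einsum("tv,tv->v", S[k:], S[:-k]) / nt
    return c


def _lag_operator(nt: int, k: int) -> np.ndarray:
    """Symmetrized lag-k quadratic form: ``c_k = r' A_k r / nt``."""
    if k == 0:
        return np.eye(nt)
    A = np.zeros((nt, nt))
    idx = np.arange(nt - k)
    A[idx + k, idx] = 0.5
    A[idx, idx + k] += 0.5
    return A


def projection_debias_matrix(nt: int, Z: np.ndarray, max_lag: int) -> np.ndarray:
    """Bias matrix of autocovariance estimates after projecting out ``Z``.

    When regressors (trends, task) have been removed from a series by
    least squares, the residual's sample autocovariances are systematically
    distorted: ``E[c_hat_k] = sum_l M[k, l] gamma_l`` with ``gamma`` the true
    autocovariances (truncated at ``max_lag``).  Solving with ``M^-1``
    recovers approximately unbiased estimates, without which the AR model
    fitted to the residuals absorbs the projection artifact and the
    surrogate data built from it are under-dispersed.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != nt:
        raise ShapeError("projection basis must have nt rows")
    Qz, _ = np.linalg.qr(Z)
    Q = np.eye(nt) - Qz @ Qz.T
    A = [_lag_operator(nt, k) for k in range(max_lag + 1)]
    QAQ = [Q @ a @ Q for a in A]
    M = np.empty((max_lag + 1, max_lag + 1))
    for k in range(max_lag + 1):
        for l in range(max_lag + 1):
            B = A[l] if l == 0 else 2.0 * A[l]
            M[k, l] = np.einsum("ij,ji->", QAQ[k], B) / nt
    return M


def _debiased_autocorrelation(
    S: np.ndarray, p: int, M_inv: np.ndarray
) -> np.ndarray:
    """Projection-debiased sample autocorrelations r(1..p) per series."""
    K = M_inv.shape[0] - 1
    c = _autocovariance_raw(S, K)
    g = c @ M_inv.T
    good = g[:, 0] > 0
    r = np.empty((S.shape[1], p))
    r[good] = g[good, 1 : p + 1] / g[good, :1]
    if not np.all(good):
        # fall back to the uncorrected estimate for pathological voxels
        r[~good] = autocorrelation(S[:, ~good], p)
    return np.clip(r, -0.999, 0.999)


def _yule_walker_from_r(r: np.ndarray, p: int) -> np.ndarray:
    """Solve the p x p Toeplitz Yule-Walker system per row of ``r``.

    ``r`` is ``(n_series, max_lag >= p)`` of sample autocorrelations.
    """
    n = r.shape[0]
    if p == 1:
        return r[:, :1].copy()
    # Toeplitz matrix T[i, j] = r(|i-j|) with r(0) = 1.
    lag = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    rfull = np.concatenate([np.ones((n, 1)), r[:, : p - 1]], axis=1)
    T = rfull[:, lag]
    rhs = r[:, :p]
    # Tiny ridge keeps near-degenerate voxels solvable.
    T = T + 1e-10 * np.eye(p)
    return np.linalg.solve(T, rhs[..., None])[..., 0]


def yule_walker(series: np.ndarray, p: int) -> np.ndarray:
    """Estimate AR(p) coefficients of one series by the Yule-Walker equations.

    Solves the Toeplitz system of biased sample autocorrelations for
    ``a_1..a_p``.  Raises :class:`DegenerateSeriesError` for a constant
    series (zero variance).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ShapeError("yule_walker expects a single 1-D series")
    if y.shape[0] <= 2 * p:
        raise LengthError("series length must exceed 2 * p")
    if not np.all(np.isfinite(y)):
        raise DomainError("series contains non-finite values")
    if np.ptp(y) == 0:
        raise DegenerateSeriesError("constant series has no AR structure")
    r = autocorrelation(y, p)[None, :]
    return _yule_walker_from_r(r, p)[0]


def _ar_max_root_modulus(coeffs: np.ndarray) -> np.ndarray:
    """Largest characteristic-root modulus per coefficient row.

    ``coeffs`` is ``(n, p)``; the AR process is stationary iff the value is
    strictly below 1.
    """
    a = np.atleast_2d(np.asarray(coeffs, dtype=float))
    n, p = a.shape
    if p == 1:
        return np.abs(a[:, 0])
    comp = np.zeros((n, p, p))
    comp[:, 0, :] = a
    idx = np.arange(p - 1)
    comp[:, idx + 1, idx] = 1.0
    return np.abs(np.linalg.eigvals(comp)).max(axis=1)


def project_stationary(coeffs: np.ndarray) -> np.ndarray:
    """Shrink coefficient vectors radially until comfortably stationary.

    A vector whose largest characteristic root has modulus >= 0.99 is
    rescaled (``a_k <- a_k * s**k``) so the largest root lands at 0.98,
    preventing divergent surrogate data from rare unstable estimates.
    """
    a = np.asarray(coeffs, dtype=float)
    squeeze = a.ndim == 1
    a2 = np.atleast_2d(a).copy()
    mod = _ar_max_root_modulus(a2)
    bad = mod >= _STATIONARY_LIMIT
    if np.any(bad):
        p = a2.shape[1]
        s = _STATIONARY_TARGET / mod[bad]
        a2[bad] *= s[:, None] ** np.arange(1, p + 1)
    return a2[0] if squeeze else a2


# ---------------------------------------------------------------------------
# normalized convolution and AR-field smoothing
# ---------------------------------------------------------------------------


def normalized_convolve(
    volume: np.ndarray,
    certainty: np.ndarray,
    kernel: np.ndarray,
    return_flags: bool = False,
):
    """Certainty-weighted smoothing: ``((c * s) conv f) / (c conv f)``.

    Values where the certainty is zero (e.g. outside the brain) never
    contribute, so a field that is constant inside the mask stays constant
    up to the mask edge instead of being attenuated.  Voxels whose smoothed
    certainty is zero are set to 0 (and flagged when ``return_flags``).
    """
    s = np.asarray(volume, dtype=float)
    c = np.asarray(certainty, dtype=float)
    f = np.asarray(kernel, dtype=float)
    if s.shape != c.shape:
        raise ShapeError("volume and certainty must have the same shape")
    if s.ndim != f.ndim:
        raise ShapeError("kernel dimensionality must match the volume")
    if np.any(c < 0) or np.any(c > 1):
        raise DomainError("certainty values must lie in [0, 1]")
    if not np.any(c):
        raise EmptyMaskError("certainty field is identically zero")
    num = ndimage.convolve(c * s, f, mode="constant")
    den = ndimage.convolve(c, f, mode="constant")
    defined = den > 1e-12 * np.max(np.abs(den))
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=defined)
    if return_flags:
        return out, ~defined
    return out


def smooth_ar_field(
    ar_field: ARField,
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size=(1.0, 1.0, 1.0),
) -> ARField:
    """Spatially pool AR coefficients with a Gaussian of the given FWHM.

    Each coefficient volume is smoothed by normalized convolution with the
    brain mask as certainty (certainty 1 inside, 0 outside), then the
    pooled vectors are projected back to stationarity.
    """
    from .spatial import gaussian_kernel  # local import to avoid a cycle

    if fwhm_mm <= 0:
        raise DomainError("fwhm_mm must be positive")
    mask = np.asarray(mask, dtype=bool)
    kern = gaussian_kernel(fwhm_mm, voxel_size, dims=mask.ndim)
    p = ar_field.order
    out = np.zeros_like(ar_field.coeffs)
    cert = mask.astype(float)
    for k in range(p):
        out[..., k] = np.where(
            mask, normalized_convolve(ar_field.coeffs[..., k], cert, kern), 0.0
        )
    flat = out[mask]
    out[mask] = project_stationary(flat)
    return ARField(coeffs=out, order=p)


# ---------------------------------------------------------------------------
# whitening transforms
# ---------------------------------------------------------------------------


def _as_matrix(series):
    y = np.asarray(series, dtype=float)
    if y.ndim == 1:
        return y[:, None], True
    return y, False


def _as_coeff_matrix(coeffs, n_series):
    a = np.asarray(coeffs, dtype=float)
    if a.ndim == 1:
        a = np.broadcast_to(a, (n_series, a.size))
    return a


def whiten_series(series: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Apply the AR whitening filter ``e_t = y_t - sum_k a_k y_{t-k}``.

    Samples before the series start are treated as zero, so the first ``p``
    outputs are only partially whitened.  ``series`` may be ``(nt,)`` or
    ``(nt, nv)``; ``coeffs`` may be shared ``(p,)`` or per-series
    ``(nv, p)``.
    """
    y, squeeze = _as_matrix(series)
    a = _as_coeff_matrix(coeffs, y.shape[1])
    p = a.shape[1]
    if y.shape[0] <= p:
        raise LengthError("series length must exceed the AR order")
    e = y.copy()
    for k in range(1, p + 1):
        e[k:] -= a[:, k - 1] * y[:-k]
    return e[:, 0] if squeeze else e


def inverse_whiten(innovations: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Simulate the AR model with the given innovations (zero initial state).

    ``y_t = sum_k a_k y_{t-k} + e_t``: the exact algebraic inverse of
    :func:`whiten_series` for any coefficients, required to be stationary so
    surrogate series cannot diverge.
    """
    e, squeeze = _as_matrix(innovations)
    a = _as_coeff_matrix(coeffs, e.shape[1])
    if np.any(_ar_max_root_modulus(a) >= 1.0):
        raise StationarityError("AR coefficients are non-stationary")
    y = _inverse_whiten_batch(e[None], a)[0]
    return y[:, 0] if squeeze else y


def _inverse_whiten_batch(innovations: np.ndarray, a: np.ndarray) -> np.ndarray:
    """AR simulation for a batch: ``innovations`` is (B, nt, nv), ``a`` (nv, p)."""
    e = innovations
    p = a.shape[1]
    y = e.copy()
    nt = e.shape[1]
    for t in range(nt):
        kmax = min(p, t)
        for k in range(1, kmax + 1):
            y[:, t] += a[:, k - 1] * y[:, t - k]
    return y


def _poly_accumulate(a_list: list[np.ndarray], p: int):
    """Compose whitening filters: product of ``1 - sum_k a_k z^-k`` polys.

    Returns the accumulated AR coefficients truncated to order ``p`` and the
    largest absolute truncated coefficient (the truncation error).
    """
    nv = a_list[0].shape[0]
    phi = np.zeros((nv, 1))
    phi[:, 0] = 1.0
    for a in a_list:
        cur = np.concatenate([np.ones((nv, 1)), -a], axis=1)
        new = np.zeros((nv, phi.shape[1] + cur.shape[1] - 1))
        for j in range(cur.shape[1]):
            new[:, j : j + phi.shape[1]] += cur[:, j : j + 1] * phi
        phi = new
    acc = -phi[:, 1 : p + 1]
    trunc = np.abs(phi[:, p + 1 :]).max() if phi.shape[1] > p + 1 else 0.0
    return acc, trunc


def iterative_whiten(
    data: np.ndarray,
    mask: np.ndarray,
    design=None,
    order: int = 4,
    iters: int = 3,
    fwhm_mm: float = 8.0,
    voxel_size=(1.0, 1.0, 1.0),
    debias: bool = True,
):
    """Iterated estimate-smooth-whiten loop on residual 4-D data.

    Per iteration the AR(p) parameters are re-estimated on the current
    residuals, spatially pooled (normalized convolution, 8 mm FWHM by
    default; pass ``fwhm_mm=0`` or ``None`` to disable), and applied.  Three
    iterations accumulate the whitening operator; the returned
    :class:`ARField` carries the accumulated coefficients truncated to
    ``order`` plus the exact per-iteration ``history`` used for inverse
    whitening.

    Parameters
    ----------
    data
        4-D array (x, y, z, t), already detrended and BOLD-removed.
    mask
        3-D boolean brain mask.
    design
        The design matrix (or its regressor array) removed from the data,
        used together with the cubic trend basis for projection-bias
        correction of the autocovariance estimates (``debias``).
    """
    from .design import trend_basis

    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4 or data.shape[:3] != mask.shape:
        raise ShapeError("data must be 4-D with spatial shape equal to mask")
    S = data[mask].T  # (nt, nv)
    Z = trend_basis(S.shape[0]).P
    if design is not None:
        Xd = design.X if hasattr(design, "X") else np.asarray(design, dtype=float)
        Z = np.hstack([Z, Xd])
    W, hist, acc = _iterative_whiten_masked(
        S,
        mask,
        order=order,
        iters=iters,
        fwhm_mm=fwhm_mm,
        voxel_size=voxel_size,
        project_out=Z if debias else None,
    )
    out = np.zeros_like(data)
    out[mask] = W.T
    coeffs = np.zeros(mask.shape + (order,))
    coeffs[mask] = acc
    history = []
    for a in hist:
        vol = np.zeros(mask.shape + (order,))
        vol[mask] = a
        history.append(vol)
    return out, ARField(coeffs=coeffs, order=order, history=history)


def _iterative_whiten_masked(
    S: np.ndarray,
    mask: np.ndarray,
    order: int = 4,
    iters: int = 3,
    fwhm_mm: float | None = 8.0,
    voxel_size=(1.0, 1.0, 1.0),
    project_out: np.ndarray | None = None,
):
    """Masked-matrix core of :func:`iterative_whiten`.

    ``S`` is (nt, nv) with nv the in-mask voxel count.  ``project_out`` is
    the regressor basis (trends + design) already removed from ``S``; when
    given, autocovariance estimates are projection-debiased before the
    Yule-Walker solve, with the basis carried through the whitening filters
    (using the spatial-mean filter as a shared approximation).  Returns the
    final innovations, the per-iteration coefficient list (application
    order) and the accumulated order-``order`` coefficients.
    """
    if iters < 1:
        raise DomainError("iters must be >= 1")
    nt, nv = S.shape
    if nt <= 2 * order:
        raise LengthError("series length must exceed 2 * AR order")
    cur = S
    hist = []
    Z = project_out
    # lag window of the bias solve: wide enough to capture the covariance
    # mass that the projection redistributes, short enough to keep the
    # debiased estimates from amplifying sampling noise
    max_lag = max(order + 1, min(12, nt // 4))
    for _ in range(iters):
        if Z is not None:
            M = projection_debias_matrix(nt, Z, max_lag)
            r = _debiased_autocorrelation(cur, order, np.linalg.inv(M))
        else:
            r = autocorrelation(cur, order)
        a = project_stationary(_yule_walker_from_r(r, order))
        if fwhm_mm:
            fld = np.zeros(mask.shape + (order,))
            fld[mask] = a
            fld = smooth_ar_field(
                ARField(coeffs=fld, order=order), mask, fwhm_mm, voxel_size
            )
            a = fld.coeffs[mask]
        hist.append(a)
        cur = whiten_series(cur, a)
        if Z is not None:
            # carry the projected-out basis through the (mean) filter so the
            # next iteration's bias correction matches the whitened series
            Z = whiten_series(Z, a.mean(axis=0))
    acc, trunc = _poly_accumulate(hist, order)
    if trunc > 1e-6:
        warnings.warn(
            f"accumulated whitening operator truncated to order {order}; "
            f"largest dropped coefficient {trunc:.2e}",
            RuntimeWarning,
            stacklevel=2,
        )
    acc = project_stationary(acc)
    return cur, hist, acc


def _inverse_whiten_sequence(E: np.ndarray, hist: list[np.ndarray]) -> np.ndarray:
    """Invert an iterated whitening exactly: inverse filters in reverse order.

    ``E`` is (B, nt, nv) permuted innovations, ``hist`` the per-iteration
    coefficient list from :func:`_iterative_whiten_masked`.
    """
    Y = E
    for a in reversed(hist):
        Y = _inverse_whiten_batch(Y, a)
    return Y


# ---------------------------------------------------------------------------
# Ljung-Box whiteness diagnostics
# ---------------------------------------------------------------------------


def ljung_box_q(autocorr_at_lags: np.ndarray, nt: int, h: int | None = None):
    """Ljung-Box portmanteau statistic from sample autocorrelations.

    ``Q = nt (nt + 2) sum_{k=1..h} r(k)^2 / (nt - k)``.  ``autocorr_at_lags``
    holds ``r(1..h)`` in its last axis (any leading batch shape).
    """
    r = np.asarray(autocorr_at_lags, dtype=float)
    h = r.shape[-1] if h is None else h
    if h < 1:
        raise DomainError("h must be >= 1")
    if nt <= h:
        raise DomainError("nt must exceed h")
    k = np.arange(1, h + 1)
    return nt * (nt + 2) * np.sum(r[..., :h] ** 2 / (nt - k), axis=-1)


def ljung_box_critical(h: int, p: int, level: float = 0.05) -> float:
    """Chi-square critical value with ``h - p`` degrees of freedom.

    ``p`` is the order of the AR model used for whitening; ``h`` must exceed
    ``p``, otherwise the degrees of freedom are zero or negative.
    """
    df = h - p
    if df < 1:
        raise DomainError("need h > p for positive degrees of freedom")
    return float(sps.chi2.ppf(1.0 - level, df))


@dataclass
class WhitenessReport:
    """Per-voxel Ljung-Box nonwhiteness flags across tested lag counts."""

    h_values: np.ndarray
    flags: np.ndarray = field(repr=False)  # (n_h, nx, ny, nz) bool
    counts: np.ndarray  # flagged voxels per h
    mean_count: float

    def nonwhite_mask(self) -> np.ndarray:
        """Voxels flagged at any tested lag count."""
        return np.any(self.flags, axis=0)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"h": self.h_values, "count": self.counts}).to_csv(
            path, index=False
        )


def whiteness_map(
    data: np.ndarray,
    mask: np.ndarray,
    p: int,
    h_range=None,
    smooth_fwhm_mm: float | None = None,
    voxel_size=(1.0, 1.0, 1.0),
    level: float = 0.05,
) -> WhitenessReport:
    """Flag nonwhite voxels with the Ljung-Box test over several lag counts.

    For each lag count ``h`` the statistic is compared against the
    chi-square critical value with ``h - p`` degrees of freedom at the given
    level.  When ``smooth_fwhm_mm`` is set, the per-lag autocorrelation
    volumes are pooled by normalized convolution before computing Q — the
    appropriate variant when the whitening itself used pooled coefficients.
    Reports the flagged count per ``h`` and the mean across the tested
    ``h`` values.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4 or data.shape[:3] != mask.shape:
        raise ShapeError("data must be 4-D with spatial shape equal to mask")
    nt = data.shape[3]
    if h_range is None:
        h_range = range(p + 1, 11)
    h_values = np.asarray(list(h_range), dtype=int)
    if h_values.size == 0 or np.any(h_values <= p):
        raise DomainError("every tested h must exceed the AR order p")
    hmax = int(h_values.max())

    S = data[mask].T
    r = autocorrelation(S, hmax)  # (nv, hmax)
    if smooth_fwhm_mm:
        cert = mask.astype(float)
        from .spatial import gaussian_kernel

        kern = gaussian_kernel(smooth_fwhm_mm, voxel_size, dims=3)
        for k in range(hmax):
            vol = np.zeros(mask.shape)
            vol[mask] = r[:, k]
            sm = ndimage.convolve(cert * vol, kern, mode="constant")
            den = ndimage.convolve(cert, kern, mode="constant")
            r[:, k] = (sm / np.where(den > 0, den, 1.0))[mask]

    flags = np.zeros((h_values.size,) + mask.shape, dtype=bool)
    counts = np.zeros(h_values.size, dtype=int)
    for i, h in enumerate(h_values):
        q = ljung_box_q(r[:, :h], nt)
        crit = ljung_box_critical(int(h), p, level)
        fl = q > crit
        flags[i][mask] = fl
        counts[i] = int(fl.sum())
    return WhitenessReport(
        h_values=h_values,
        flags=flags,
        counts=counts,
        mean_count=float(counts.mean()),
    )
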