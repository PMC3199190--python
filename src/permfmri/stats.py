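"""Voxelwise detection statistics: GLM t-values and (restricted) CCA.

The GLM correlates each voxel series with one multidimensional temporal
variable (HRF regressor and derivative) and summarizes a contrast with a
t-value.  CCA generalizes this to two multidimensional variables: the same
temporal basis on one side, and on the other the voxel's responses under a
bank of spatial filters, so the analysis picks the spatial smoothing —
scale and, in 2D, orientation — that maximizes the correlation.  The
restricted variant constrains the spatial weights to be nonnegative (the
synthesized filter stays a lowpass) and the HRF weight to be nonnegative
(no inverted responses), solved exactly by active-set enumeration.

Covariances are second moments about zero: pipeline data are detrended
(zero mean by construction) before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .exceptions import (
    DegenerateDesignError,
    DegeneracyError,
    DomainError,
    ShapeError,
    StationarityError,
)
from .spatial import FilterBank, MaskedSmoother

__all__ = [
    "GlmFit",
    "CcaResult",
    "glm_tstat",
    "glm_tstat_matrix",
    "prewhiten_glm",
    "cca_max",
    "restricted_cca_max",
    "cca_map",
    "cca_null_density",
    "cca_null_cdf",
]

_RIDGE = 1e-10


@dataclass
class GlmFit:
    """OLS fit summary for one voxel: coefficients, residual variance, t."""

    beta_hat: np.ndarray
    resid_var: float
    tvalue: float
    #: residual variance was zero; the t-value is an infinite sentinel
    flagged: bool = False


@dataclass
class CcaResult:
    """Largest (restricted) canonical correlation and its weight pair."""

    rho: float
    beta: np.ndarray
    gamma: np.ndarray
    restricted: bool


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


def glm_tstat(series: np.ndarray, X: np.ndarray, c: np.ndarray) -> GlmFit:
    """Contrast t-value for one series by ordinary least squares.

    ``beta = (X'X)^-1 X'Y``; residual variance uses the unbiased
    denominator ``nt - k``; ``t = c'beta / sqrt(var * c'(X'X)^-1 c)``.
    """
    y = np.asarray(series, dtype=float)
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ShapeError("series length must equal design row count")
    nt, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise DegenerateDesignError("design matrix is rank deficient")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    var = float(resid @ resid) / (nt - k)
    denom2 = var * float(c @ np.linalg.solve(XtX, c))
    if denom2 <= 1e-24 * float(y @ y) / nt:
        return GlmFit(
            beta_hat=beta,
            resid_var=var,
            tvalue=float(np.sign(c @ beta)) * np.inf,
            flagged=True,
        )
    return GlmFit(
        beta_hat=beta,
        resid_var=var,
        tvalue=float(c @ beta) / np.sqrt(denom2),
    )


def glm_tstat_matrix(S: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized contrast t-values for many series (``S`` is (nt, nv))."""
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=float)
    nt, k = X.shape
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ S)  # (k, nv)
    # residual sum of squares without forming residuals explicitly
    rss = np.einsum("tv,tv->v", S, S) - np.einsum("kv,kv->v", X.T @ S, B)
    rss = np.maximum(rss, 0.0)
    var = rss / (nt - k)
    cc = float(c @ np.linalg.solve(XtX, c))
    num = c @ B
    denom = np.sqrt(var * cc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            denom > 0,
            num / np.where(denom > 0, denom, 1.0),
            np.where(num >= 0, np.inf, -np.inf),
        )
    return t


def prewhiten_glm(data: np.ndarray, X: np.ndarray, phi: float | None = None):
    """Global AR(1) prewhitening of data and design, as used before the GLM.

    Applies ``y_t <- y_t - phi y_{t-1}`` (zero initial condition) to every
    series and to every design column, so a noiseless signal keeps its
    coefficients exactly.  When ``phi`` is not supplied it is estimated as
    the median lag-1 autocorrelation of the OLS residuals across series.

    Returns ``(data_w, X_w, phi)``.
    """
    from .whitening import autocorrelation

    Y = np.asarray(data, dtype=float)
    X = np.asarray(X, dtype=float)
    squeeze = Y.ndim == 1
    Ymat = Y[:, None] if squeeze else Y
    if Ymat.shape[0] != X.shape[0]:
        raise ShapeError("series length must equal design row count")
    if phi is None:
        B = np.linalg.lstsq(X, Ymat, rcond=None)[0]
        resid = Ymat - X @ B
        phi = float(np.median(autocorrelation(resid, 1)))
    if abs(phi) >= 1.0:
        raise StationarityError("|phi| must be < 1")

    def _filt(M):
        out = M.copy()
        out[1:] -= phi * M[:-1]
        return out

    Yw = _filt(Ymat)
    return (Yw[:, 0] if squeeze else Yw), _filt(X), phi


# ---------------------------------------------------------------------------
# CCA core
# ---------------------------------------------------------------------------


def _inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    """Batched symmetric inverse square root with eigenvalue clipping."""
    w, V = np.linalg.eigh(C)
    wmax = np.maximum(w[..., -1:], 0.0)
    floor = np.maximum(wmax * 1e-12, 1e-300)
    w = np.maximum(w, floor)
    return (V / np.sqrt(w)[..., None, :]) @ np.swapaxes(V, -1, -2)


def _ridge(C: np.ndarray) -> np.ndarray:
    d = C.shape[-1]
    tr = np.trace(C, axis1=-2, axis2=-1)[..., None, None]
    return C + (_RIDGE * tr / d + 1e-300) * np.eye(d)


def _best_cc(Cxx, Cxy, Cyy):
    """Largest canonical correlation of batched covariance triplets.

    ``Cxx`` (n, n) shared; ``Cxy`` (nv, n, m); ``Cyy`` (nv, m, m).
    Returns (rho, beta, gamma) with gamma normalized in the Cyy metric and
    beta in the Cxx metric.
    """
    iCxx = np.linalg.inv(_ridge(Cxx))
    W = _inv_sqrt_psd(_ridge(Cyy))  # (nv, m, m)
    Cyx = np.swapaxes(Cxy, -1, -2)
    M = W @ Cyx @ iCxx @ Cxy @ W
    M = 0.5 * (M + np.swapaxes(M, -1, -2))
    w, U = np.linalg.eigh(M)
    rho2 = np.clip(w[..., -1], 0.0, 1.0)
    u = U[..., -1]
    gamma = np.einsum("...ij,...j->...i", W, u)
    beta = np.einsum("ij,...j->...i", iCxx, np.einsum("...nm,...m->...n", Cxy, gamma))
    # normalize beta in the Cxx metric
    bn = np.sqrt(
        np.maximum(np.einsum("...i,ij,...j->...", beta, Cxx, beta), 1e-300)
    )
    beta = beta / bn[..., None]
    return np.sqrt(rho2), beta, gamma


def _rcca_batch(
    X: np.ndarray,
    F: np.ndarray,
    nonneg_gamma: bool = True,
    nonneg_beta1: bool = True,
):
    """Restricted CCA for many voxels at once.

    ``X`` is (nt, n) temporal basis, ``F`` is (nt, nv, m) spatially filtered
    data.  Maximizes the canonical correlation subject to elementwise
    ``gamma >= 0`` and ``beta_1 >= 0`` by enumerating active-constraint
    subsets (each an unconstrained CCA on a reduced basis) and keeping the
    best feasible solution.  Returns (rho, beta, gamma).
    """
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    nt, n = X.shape
    _, nv, m = F.shape
    if nt <= n + m:
        raise DomainError("need nt > n + m samples")
    Cxx = X.T @ X / nt
    Cxy = np.einsum("tn,tvm->vnm", X, F) / nt
    Cyy = np.einsum("tvm,tvk->vmk", F, F) / nt

    tol = 1e-9
    best_rho = np.zeros(nv)
    best_beta = np.zeros((nv, n))
    best_gamma = np.zeros((nv, m))
    found = np.zeros(nv, dtype=bool)

    if not nonneg_gamma:
        subsets = [tuple(range(m))]
    else:
        subsets = [
            s for size in range(1, m + 1) for s in combinations(range(m), size)
        ]
    temporal_modes = [("full", np.arange(n))]
    if nonneg_beta1 and n >= 2:
        temporal_modes.append(("nohrf", np.arange(1, n)))

    for s in subsets:
        sel = np.asarray(s)
        Cyy_s = Cyy[:, sel[:, None], sel[None, :]]
        for mode, tsel in temporal_modes:
            Cxx_t = Cxx[np.ix_(tsel, tsel)]
            Cxy_st = Cxy[:, tsel[:, None], sel[None, :]]
            rho, beta_t, gamma_s = _best_cc(Cxx_t, Cxy_st, Cyy_s)

            beta = np.zeros((nv, n))
            beta[:, tsel] = beta_t
            gamma = np.zeros((nv, m))
            gamma[:, sel] = gamma_s

            if nonneg_gamma or nonneg_beta1:
                feas = np.zeros(nv, dtype=bool)
                out_beta = beta
                out_gamma = gamma
                for sign in (1.0, -1.0):
                    b = sign * beta
                    g = sign * gamma
                    ok = np.ones(nv, dtype=bool)
                    if nonneg_gamma:
                        ok &= np.all(g >= -tol, axis=1)
                    if nonneg_beta1 and mode == "full":
                        ok &= b[:, 0] >= -tol
                    new = ok & ~feas
                    if np.any(new):
                        out_beta = np.where(new[:, None], b, out_beta)
                        out_gamma = np.where(new[:, None], g, out_gamma)
                        feas |= ok
                beta, gamma = out_beta, out_gamma
            else:
                feas = np.ones(nv, dtype=bool)

            better = feas & (~found | (rho > best_rho))
            best_rho = np.where(better, rho, best_rho)
            best_beta = np.where(better[:, None], beta, best_beta)
            best_gamma = np.where(better[:, None], gamma, best_gamma)
            found |= feas

    if not np.all(found):
        raise DegeneracyError("no feasible nonzero spatial weighting found")
    return best_rho, best_beta, best_gamma


def cca_max(xt: np.ndarray, ys: np.ndarray) -> CcaResult:
    """Largest (unrestricted) canonical correlation between two bases.

    ``xt`` is (nt, n), ``ys`` is (nt, m); second moments are taken about
    zero.  Solves the generalized eigenproblem and returns the maximizing
    weight pair, each unit-norm in its own covariance metric.
    """
    xt = np.atleast_2d(np.asarray(xt, dtype=float).T).T
    ys = np.atleast_2d(np.asarray(ys, dtype=float).T).T
    rho, beta, gamma = _rcca_batch(
        xt, ys[:, None, :], nonneg_gamma=False, nonneg_beta1=False
    )
    return CcaResult(
        rho=float(rho[0]), beta=beta[0], gamma=gamma[0], restricted=False
    )


def restricted_cca_max(
    xt: np.ndarray,
    ys: np.ndarray,
    nonneg_gamma: bool = True,
    nonneg_beta1: bool = True,
) -> CcaResult:
    """Restricted CCA: nonnegative spatial weights, nonnegative HRF weight.

    The feasible optimum is found exactly by enumerating the faces of the
    constraint set; it never exceeds the unrestricted maximum.
    """
    xt = np.atleast_2d(np.asarray(xt, dtype=float).T).T
    ys = np.atleast_2d(np.asarray(ys, dtype=float).T).T
    rho, beta, gamma = _rcca_batch(
        xt, ys[:, None, :], nonneg_gamma=nonneg_gamma, nonneg_beta1=nonneg_beta1
    )
    return CcaResult(
        rho=float(rho[0]), beta=beta[0], gamma=gamma[0], restricted=True
    )


def cca_map(
    data: np.ndarray,
    mask: np.ndarray,
    design,
    filterbank: FilterBank,
    return_weights: bool = False,
    restricted: bool = True,
):
    """Restricted-CCA correlation map over all in-mask voxels.

    ``data`` must be unsmoothed (the bank performs the smoothing) and
    already detrended.  Each volume is filtered with every kernel of the
    bank (mask-aware; 2D banks act slicewise), the filtered responses at a
    voxel form its spatial variable, and the largest restricted canonical
    correlation against the temporal design is returned as a volume.
    ``restricted=False`` drops the nonnegativity constraints and computes
    ordinary CCA (useful for comparisons with regression or with the
    analytic null law, which describe the unrestricted statistic).
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4 or data.shape[:3] != mask.shape:
        raise ShapeError("data must be (x, y, z, t) with matching mask")
    X = design.X if hasattr(design, "X") else np.asarray(design, dtype=float)
    nt = data.shape[3]
    if X.shape[0] != nt:
        raise ShapeError("design rows must equal the volume count")

    vols = np.moveaxis(data, 3, 0) * mask[None]
    nv = int(mask.sum())
    F = np.empty((nt, nv, filterbank.n_filters))
    for j, kern in enumerate(filterbank.kernels):
        sm = MaskedSmoother(mask, kern)
        F[:, :, j] = sm.smooth_volumes(vols)[:, mask]
    rho, beta, gamma = _rcca_batch(
        X, F, nonneg_gamma=restricted, nonneg_beta1=restricted
    )
    out = np.zeros(mask.shape)
    out[mask] = rho
    if return_weights:
        gvol = np.zeros(mask.shape + (filterbank.n_filters,))
        gvol[mask] = gamma
        return out, gvol
    return out


# ---------------------------------------------------------------------------
# analytic null density of canonical correlations
# ---------------------------------------------------------------------------


def cca_null_density(r_vector, N: int, n: int, m: int) -> float:
    """Unnormalized joint null density of the sample canonical correlations.

    For independent Gaussian variables of dimensions ``n`` and ``m`` with
    ``N`` samples, the ordered coefficients ``1 > r_1 > ... > r_m > 0`` have
    joint density proportional to

    ``prod_i (r_i^2)^((n-m-1)/2) (1 - r_i^2)^((N-n-m-1)/2)
    prod_{j>i} (r_i^2 - r_j^2)``

    taken with respect to the squared coefficients ``r_i^2``.
    """
    r = np.atleast_1d(np.asarray(r_vector, dtype=float))
    if r.size != m:
        raise DomainError("r_vector must have length m")
    if N <= n + m:
        raise DomainError("need N > n + m")
    if np.any(r <= 0) or np.any(r >= 1) or np.any(np.diff(r) >= 0):
        raise DomainError("need 1 > r_1 > ... > r_m > 0")
    r2 = r**2
    f = np.prod(r2 ** ((n - m - 1) / 2.0) * (1.0 - r2) ** ((N - n - m - 1) / 2.0))
    for i in range(m):
        for j in range(i + 1, m):
            f *= r2[i] - r2[j]
    return float(f)


def cca_null_cdf(r_points, N: int, n: int, m: int, grid: int = 4001):
    """CDF of the largest null canonical correlation, normalized numerically.

    Integrates the joint density on a grid over the squared coefficients
    (supported for ``m <= 2``) and evaluates ``P(r_1 <= r)`` at
    ``r_points``.
    """
    if m not in (1, 2):
        raise DomainError("numerical normalization implemented for m <= 2")
    r_points = np.atleast_1d(np.asarray(r_points, dtype=float))
    # midpoint rule in theta = r^2: robust to the integrable endpoint
    # behaviour and exact about the head mass near theta = 0
    edges = np.linspace(0.0, 1.0, grid)
    mid = 0.5 * (edges[:-1] + edges[1:])
    w = np.diff(edges)
    if m == 1:
        mass = mid ** ((n - 2) / 2.0) * (1.0 - mid) ** ((N - n - 2) / 2.0) * w
    else:
        # m == 2: joint density over ordered (th1 > th2), marginalize th2
        t1 = mid[:, None]
        t2 = mid[None, :]
        dens = (
            (t1 * t2) ** ((n - 3) / 2.0)
            * ((1.0 - t1) * (1.0 - t2)) ** ((N - n - 3) / 2.0)
            * np.where(t1 > t2, t1 - t2, 0.0)
        )
        mass = (dens * w[None, :]).sum(axis=1) * w
    cdf = np.concatenate([[0.0], np.cumsum(mass)])
    cdf /= cdf[-1]
    return np.interp(r_points**2, edges, cdf)
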