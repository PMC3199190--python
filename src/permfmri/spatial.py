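"""Spatial smoothing kernels and the CCA filter banks.

Provides FWHM-parameterized Gaussian kernels for fixed GLM smoothing, the
four-filter 2D bank (one small isotropic plus three anisotropic Gaussians
60 degrees apart) that lets CCA synthesize oriented lowpass filters, the
scale-adaptive 3D pair (isotropic Gaussian and its derivative with respect
to the width), and mask-aware application of any of them by normalized
convolution.

All kernels are sampled in millimetre coordinates so anisotropic voxels are
handled transparently; supports are odd-sized and centred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .exceptions import DomainError, EmptyMaskError, ResolutionError, ShapeError
from .whitening import normalized_convolve

__all__ = [
    "FWHM_TO_SIGMA",
    "FilterBank",
    "gaussian_kernel",
    "glm_filter_bank",
    "cca_filter_bank_2d",
    "cca_filters_3d",
    "smooth_dataset",
    "fit_isotropic_fwhm",
    "MaskedSmoother",
]

#: sigma = FWHM / sqrt(8 ln 2)
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

#: anisotropy (long:short axis) of the 2D bank's oriented filters
_ANISOTROPY = 2.0

#: small isotropic filter sigma as a fraction of the oriented long-axis sigma
_SMALL_FRAC = 0.6


@dataclass
class FilterBank:
    """Ordered set of spatial smoothing kernels.

    ``mode`` is ``"glm"`` (one nonnegative unit-sum Gaussian), ``"cca2d"``
    (four kernels: small isotropic + three anisotropic) or ``"cca3d"`` (two
    kernels: isotropic Gaussian + its width derivative, which sums to ~0).
    """

    kernels: list = field(repr=False)
    dims: int
    fwhm_max_mm: float
    labels: list
    mode: str

    def __post_init__(self) -> None:
        expected = {"glm": 1, "cca2d": 4, "cca3d": 2}
        if self.mode not in expected:
            raise DomainError(f"unknown filter-bank mode {self.mode!r}")
        if len(self.kernels) != expected[self.mode]:
            raise ShapeError(
                f"{self.mode} bank must hold {expected[self.mode]} kernels"
            )
        for k in self.kernels:
            if k.ndim != self.dims:
                raise ShapeError("kernel dimensionality must match bank dims")
            if any(s % 2 == 0 for s in k.shape):
                raise ShapeError("kernel supports must be odd-sized")

    @property
    def n_filters(self) -> int:
        return len(self.kernels)

    def stacked(self) -> np.ndarray:
        return np.stack(self.kernels)

    def save_txt(self, path_prefix: str) -> None:
        """Dump each kernel as a plain-text grid for visual inspection."""
        for label, k in zip(self.labels, self.kernels):
            np.savetxt(
                f"{path_prefix}_{label}.txt",
                k.reshape(k.shape[0], -1),
                header=f"shape={k.shape}",
            )


def _axis_sigmas(fwhm_mm: float, voxel_size, dims: int) -> np.ndarray:
    vox = np.asarray(voxel_size, dtype=float)[:dims]
    if vox.size != dims:
        raise ShapeError("voxel_size must provide one spacing per axis")
    if fwhm_mm <= 0:
        raise DomainError("fwhm_mm must be positive")
    sigma = fwhm_mm * FWHM_TO_SIGMA / vox
    if np.any(fwhm_mm / vox < 0.1):
        raise ResolutionError("FWHM below 0.1 voxel cannot be represented")
    return sigma


def gaussian_kernel(fwhm_mm: float, voxel_size, dims: int = 3) -> np.ndarray:
    """Isotropic (in mm) Gaussian kernel, unit sum, support radius 3 sigma.

    ``sigma = fwhm / sqrt(8 ln 2)`` converted to voxel units per axis, so
    the kernel is isotropic in millimetres even for anisotropic voxels.
    """
    sigma = _axis_sigmas(fwhm_mm, voxel_size, dims)
    radii = np.maximum(np.ceil(3.0 * sigma).astype(int), 1)
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) for r in radii], indexing="ij"
    )
    expo = sum((g / s) ** 2 for g, s in zip(grids, sigma))
    kern = np.exp(-0.5 * expo)
    return kern / kern.sum()


def glm_filter_bank(fwhm_mm: float, voxel_size, dims: int = 3) -> FilterBank:
    """Single-Gaussian bank used for fixed GLM smoothing."""
    kern = gaussian_kernel(fwhm_mm, voxel_size, dims)
    return FilterBank(
        kernels=[kern],
        dims=dims,
        fwhm_max_mm=fwhm_mm,
        labels=[f"gauss{fwhm_mm:g}mm"],
        mode="glm",
    )


#: subpixel sampling factor for bank kernels: their sigmas can be well below
#: one voxel, so kernels are cell-averaged to avoid aliasing
_OVERSAMPLE = 5


def _subpixel_axes(radius_vox, voxel_size):
    """Oversampled per-axis coordinates (mm) covering each voxel cell."""
    off = (np.arange(_OVERSAMPLE) - (_OVERSAMPLE - 1) / 2.0) / _OVERSAMPLE
    axes = []
    for r, d in zip(radius_vox, voxel_size):
        centers = np.arange(-r, r + 1)
        axes.append(((centers[:, None] + off[None, :]) * d))
    return axes


def _cell_average(fine: np.ndarray, dims: int) -> np.ndarray:
    """Average an oversampled evaluation (n1, os, n2, os, ...) back to the
    voxel grid."""
    return fine.mean(axis=tuple(range(1, 2 * dims, 2)))


def _elliptical_gaussian_2d(
    sigma_long_mm: float,
    sigma_short_mm: float,
    theta: float,
    voxel_size,
    radius_vox,
) -> np.ndarray:
    """Unit-sum 2D Gaussian with given axis sigmas (mm) and orientation.

    Evaluated on a subpixel grid and cell-averaged, so narrow axes are
    represented without aliasing.
    """
    ax, ay = _subpixel_axes(radius_vox, voxel_size)
    gx, gy = np.meshgrid(ax.ravel(), ay.ravel(), indexing="ij")
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * gx + st * gy  # along the long axis
    v = -st * gx + ct * gy
    fine = np.exp(-0.5 * ((u / sigma_long_mm) ** 2 + (v / sigma_short_mm) ** 2))
    fine = fine.reshape(ax.shape[0], _OVERSAMPLE, ay.shape[0], _OVERSAMPLE)
    kern = _cell_average(fine, 2)
    return kern / kern.sum()


def fit_isotropic_fwhm(kernel: np.ndarray, voxel_size) -> float:
    """Least-squares best-fit isotropic-Gaussian FWHM (mm) of a kernel.

    Fits the width and amplitude of an isotropic Gaussian (cell-averaged on
    the kernel's own support, like all bank kernels), minimizing the L2
    error.  Used for bank calibration and
    for measuring the effective width of synthesized CCA filters.
    """
    kernel = np.asarray(kernel, dtype=float)
    dims = kernel.ndim
    radii = [(s - 1) // 2 for s in kernel.shape]
    vox = np.asarray(voxel_size, dtype=float)[:dims]
    axes = _subpixel_axes(radii, vox)
    grids = np.meshgrid(*[a.ravel() for a in axes], indexing="ij")
    r2 = sum(g**2 for g in grids)
    fine_shape = sum(((a.shape[0], _OVERSAMPLE) for a in axes), ())

    def _model(sigma_mm: float) -> np.ndarray:
        return _cell_average(
            np.exp(-0.5 * r2 / sigma_mm**2).reshape(fine_shape), dims
        )

    def resid(sigma_mm: float) -> float:
        g = _model(sigma_mm)
        amp = np.sum(g * kernel) / np.sum(g * g)
        return float(np.sum((amp * g - kernel) ** 2))

    span = max(r.max() for r in np.atleast_1d(radii)) * vox.max()
    res = optimize.minimize_scalar(
        resid, bounds=(0.05, max(2.0 * span, 1.0)), method="bounded"
    )
    return float(res.x) / FWHM_TO_SIGMA


def cca_filter_bank_2d(fwhm_max_mm: float, voxel_size) -> FilterBank:
    """Four-filter 2D bank: small isotropic + three anisotropic Gaussians.

    The anisotropic (2:1 axis ratio) filters point at 0, 60 and 120
    degrees; the small isotropic filter has 0.6 times the long-axis width.  The long-axis sigma is
    calibrated numerically so that the equal-weight combination of all four
    filters — the largest filter CCA can create — best fits an isotropic
    Gaussian of FWHM ``fwhm_max_mm``.  All kernels are nonnegative with unit
    sum, so any nonnegative weighting is a plausible lowpass filter.
    """
    if fwhm_max_mm <= 0:
        raise DomainError("fwhm_max_mm must be positive")
    vox = np.asarray(voxel_size, dtype=float)[:2]
    sigma_max_mm = fwhm_max_mm * FWHM_TO_SIGMA
    thetas = [0.0, np.pi / 3.0, 2.0 * np.pi / 3.0]

    def build(scale: float):
        sig_e = scale * sigma_max_mm
        # support covers 3 sigma of the largest axis on every kernel
        # 5 sigma: the square support must truncate negligible mass at
        # every orientation, or synthesized-filter energies lose the
        # 60-degree symmetry
        radius = np.maximum(np.ceil(5.0 * sig_e / vox).astype(int), 1)
        small_sig = _SMALL_FRAC * sig_e
        small = _elliptical_gaussian_2d(small_sig, small_sig, 0.0, vox, radius)
        aniso = [
            _elliptical_gaussian_2d(sig_e, sig_e / _ANISOTROPY, th, vox, radius)
            for th in thetas
        ]
        return [small] + aniso

    def fitted_minus_target(scale: float) -> float:
        combo = np.mean(build(scale), axis=0)
        return fit_isotropic_fwhm(combo, vox) - fwhm_max_mm

    scale = optimize.brentq(fitted_minus_target, 0.9, 3.0, xtol=1e-4)
    kernels = build(scale)
    return FilterBank(
        kernels=kernels,
        dims=2,
        fwhm_max_mm=fwhm_max_mm,
        labels=["small_iso", "aniso_0", "aniso_60", "aniso_120"],
        mode="cca2d",
    )


def cca_filters_3d(fwhm_max_mm: float, voxel_size) -> FilterBank:
    """Scale-adaptive 3D pair: isotropic Gaussian + its width derivative.

    Kernel 1 is an isotropic Gaussian at ``sigma0 = fwhm_max / (2 sqrt(8 ln 2))``
    (half the target width, so widening combinations can reach
    ``fwhm_max_mm``); kernel 2 is the analytic derivative of the normalized
    Gaussian family with respect to sigma, sampled at ``sigma0`` on the same
    support.  Combinations ``g + w dg/dsigma`` approximate Gaussians of
    width ``sigma0 + w`` to first order, giving isotropic but
    scale-adaptive smoothing.
    """
    if fwhm_max_mm <= 0:
        raise DomainError("fwhm_max_mm must be positive")
    vox = np.asarray(voxel_size, dtype=float)[:3]
    sigma0 = fwhm_max_mm * FWHM_TO_SIGMA / 2.0
    if np.any(fwhm_max_mm / vox < 0.1):
        raise ResolutionError("FWHM below 0.1 voxel cannot be represented")
    # generous support so widened combinations are still well represented
    radii = np.maximum(np.ceil(6.0 * sigma0 / vox).astype(int), 2)
    axes = _subpixel_axes(radii, vox)
    grids = np.meshgrid(*[a.ravel() for a in axes], indexing="ij")
    r2 = sum(g**2 for g in grids)
    norm = (2.0 * np.pi * sigma0**2) ** -1.5 * float(np.prod(vox))
    g_fine = norm * np.exp(-0.5 * r2 / sigma0**2)
    dg_fine = g_fine * (r2 / sigma0**3 - 3.0 / sigma0)
    fine_shape = sum(((a.shape[0], _OVERSAMPLE) for a in axes), ())
    g = _cell_average(g_fine.reshape(fine_shape), 3)
    dg = _cell_average(dg_fine.reshape(fine_shape), 3)
    g = g / g.sum()
    return FilterBank(
        kernels=[g, dg],
        dims=3,
        fwhm_max_mm=fwhm_max_mm,
        labels=["iso", "dsigma"],
        mode="cca3d",
    )


class MaskedSmoother:
    """Mask-aware smoothing operator with a precomputed certainty field.

    Wraps normalized convolution for repeated application of one kernel to
    many volumes (FFT-based, batched over time).  2D kernels are applied
    slicewise.  Zero-sum kernels (the width-derivative filter) fall back to
    plain convolution of the mask-zeroed data, for which the normalizing
    ratio is undefined.
    """

    def __init__(self, mask: np.ndarray, kernel: np.ndarray):
        self.mask = np.asarray(mask, dtype=bool)
        self.kernel = np.asarray(kernel, dtype=float)
        if self.kernel.ndim not in (2, 3):
            raise ShapeError("kernel must be 2-D or 3-D")
        cert = self.mask.astype(float)
        self.normalize = abs(self.kernel.sum()) > 0.1
        if self.kernel.ndim == 3:
            self._kern4 = self.kernel[None]
            self._axes = (1, 2, 3)
        else:
            self._kern4 = self.kernel[None, :, :, None]
            self._axes = (1, 2)
        if self.normalize:
            den = signal.fftconvolve(
                cert[None], self._kern4, mode="same", axes=self._axes
            )[0]
            den = np.where(self.mask, den, 1.0)
            # inside a sane mask the smoothed certainty is bounded away
            # from zero; guard against pathological masks anyway
            self._inv_den = np.where(den > 1e-12, 1.0 / den, 0.0)
        else:
            self._inv_den = None

    def smooth_volumes(self, vols: np.ndarray) -> np.ndarray:
        """Smooth a stack of volumes ``(nt, nx, ny, nz)``, zero outside mask.

        Input volumes must already be zero outside the mask (certainty
        weighting); the output is masked again.
        """
        out = signal.fftconvolve(vols, self._kern4, mode="same", axes=self._axes)
        if self.normalize:
            out *= self._inv_den[None]
        out *= self.mask[None]
        return out

    def smooth_series(self, S: np.ndarray) -> np.ndarray:
        """Smooth masked series ``(nt, nv)`` via scatter/smooth/gather."""
        nt = S.shape[0]
        vols = np.zeros((nt,) + self.mask.shape)
        vols[:, self.mask] = S
        return self.smooth_volumes(vols)[:, self.mask]


def smooth_dataset(data: np.ndarray, mask: np.ndarray, kernel: np.ndarray):
    """Smooth every volume of 4-D data inside the mask.

    Uses normalized convolution with the mask as certainty, so values inside
    the mask are invariant to whatever lies outside it; output is zero
    outside the mask.  For a 2-D kernel each slice is smoothed separately.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4 or data.shape[:3] != mask.shape:
        raise ShapeError("data must be (x, y, z, t) with matching mask")
    if not np.any(mask):
        raise EmptyMaskError("mask contains no voxels")
    sm = MaskedSmoother(mask, kernel)
    vols = np.moveaxis(data, 3, 0) * mask[None]
    out = sm.smooth_volumes(vols)
    return np.ascontiguousarray(np.moveaxis(out, 0, 3))


# keep the precise-by-construction reference path available for oracles
def smooth_dataset_direct(data, mask, kernel):
    """Reference implementation of :func:`smooth_dataset` via direct
    spatial-domain normalized convolution (slower, used as an oracle)."""
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    cert = mask.astype(float)
    out = np.zeros_like(data)
    for t in range(data.shape[3]):
        vol = data[..., t] * cert
        if kernel.ndim == 3:
            res = normalized_convolve(vol, cert, kernel)
        else:
            res = np.zeros_like(vol)
            for z in range(vol.shape[2]):
                if not np.any(cert[:, :, z]):
                    continue
                res[:, :, z] = normalized_convolve(
                    vol[:, :, z], cert[:, :, z], kernel
                )
        out[..., t] = np.where(mask, res, 0.0)
    return out
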