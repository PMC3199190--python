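"""NIfTI input/output, paradigms, brain masks and synthetic fMRI data.

The synthetic generator emulates a block-design acquisition of the kind the
pipeline targets — 64 x 64 x 22 voxels, 80 volumes, TR 2 s, 3.75 mm
isotropic voxels, roughly 20 000 brain voxels, 20 s on / 20 s off blocks —
with polynomial scanner drift, spatially varying AR noise and
HRF-convolved block activation, and returns the ground-truth activation
map alongside the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import nibabel as nib

from . import design as _design
from .exceptions import (
    DimensionalityError,
    DomainError,
    EmptyMaskError,
    ShapeError,
    StationarityError,
)
from .whitening import _ar_max_root_modulus, _inverse_whiten_batch

__all__ = [
    "FmriDataset",
    "Paradigm",
    "SyntheticSpec",
    "read_fmri",
    "write_fmri",
    "make_mask",
    "generate_synthetic",
    "smooth_random_field",
]

#: default mask threshold as a fraction of the maximum mean intensity
DEFAULT_MASK_FRACTION = 0.2

#: minimum time points: twice (default AR order 4 + trend degree 3)
MIN_VOLUMES = 2 * (4 + 3)

_BURN_IN = 100  # AR simulation burn-in samples


@dataclass
class FmriDataset:
    """4-D BOLD data (x, y, z, t) with brain mask, TR and voxel size.

    The array order follows the (x, y, z, t) storage convention with x
    fastest; indices are 0-based; the NIfTI affine is preserved on I/O but
    never interpreted (no resampling).
    """

    data: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    tr: float
    voxel_size: tuple
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise DimensionalityError("data must be 4-D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ShapeError("mask shape must equal the spatial data shape")
        if not np.any(self.mask):
            raise EmptyMaskError("mask contains no voxels")
        if self.tr <= 0:
            raise DomainError("TR must be positive")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise DomainError("voxel_size must be three positive spacings")
        if self.data.shape[3] < MIN_VOLUMES:
            raise ShapeError(
                f"need at least {MIN_VOLUMES} volumes for AR(4) whitening "
                "after cubic detrending"
            )
        if not np.all(np.isfinite(self.data[self.mask])):
            raise DomainError("non-finite values inside the brain mask")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def nt(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_series(self) -> np.ndarray:
        """In-mask voxel series as an (nt, n_voxels) matrix."""
        return self.data[self.mask].T


@dataclass
class Paradigm:
    """Block stimulus paradigm: (onset, duration) pairs or a 0/1 vector.

    Block onsets are in seconds, nonnegative, strictly increasing and
    non-overlapping.  The per-volume indicator form needs ``tr`` to be
    evaluated in continuous time.
    """

    blocks: list | None = None
    indicator: np.ndarray | None = None
    tr: float | None = None

    def __post_init__(self) -> None:
        if (self.blocks is None) == (self.indicator is None):
            raise DomainError("provide exactly one of blocks or indicator")
        if self.blocks is not None:
            blocks = [(float(o), float(d)) for o, d in self.blocks]
            onsets = [o for o, _ in blocks]
            if any(o < 0 for o in onsets):
                raise DomainError("block onsets must be nonnegative")
            if any(d <= 0 for _, d in blocks):
                raise DomainError("block durations must be positive")
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise DomainError("block onsets must be strictly increasing")
            for (o1, d1), (o2, _) in zip(blocks, blocks[1:]):
                if o1 + d1 > o2:
                    raise DomainError("blocks must not overlap")
            self.blocks = blocks
        else:
            vec = np.asarray(self.indicator, dtype=float)
            if vec.ndim != 1 or not np.all(np.isin(vec, (0.0, 1.0))):
                raise DomainError("indicator must be a 1-D 0/1 vector")
            self.indicator = vec

    @classmethod
    def block_design(
        cls, on_s: float = 20.0, off_s: float = 20.0, duration_s: float = 160.0,
        start_with_rest: bool = False,
    ) -> "Paradigm":
        """Periodic on/off paradigm (default 20 s activity, 20 s rest)."""
        blocks = []
        t = off_s if start_with_rest else 0.0
        while t + on_s <= duration_s:
            blocks.append((t, on_s))
            t += on_s + off_s
        if not blocks:
            raise DomainError("paradigm does not fit into the scan duration")
        return cls(blocks=blocks)

    @classmethod
    def from_tsv(cls, path) -> "Paradigm":
        """Read onset/duration pairs from a TSV with header columns
        ``onset`` and ``duration`` (seconds)."""
        df = pd.read_csv(path, sep="\t")
        if not {"onset", "duration"} <= set(df.columns):
            raise DomainError("paradigm TSV needs 'onset' and 'duration' columns")
        return cls(blocks=list(zip(df["onset"], df["duration"])))

    @classmethod
    def from_indicator_file(cls, path, tr: float | None = None) -> "Paradigm":
        """Read a one-column per-volume 0/1 file."""
        vec = np.loadtxt(path, ndmin=1)
        return cls(indicator=vec, tr=tr)

    def to_tsv(self, path) -> None:
        if self.blocks is None:
            raise DomainError("indicator paradigms have no block table")
        pd.DataFrame(self.blocks, columns=["onset", "duration"]).to_csv(
            path, sep="\t", index=False
        )

    def validate_for(self, nt: int, tr: float) -> None:
        """Check every block ends before the scan end (``nt * tr`` s)."""
        if self.blocks is not None:
            end = nt * tr
            if any(o + d > end for o, d in self.blocks):
                raise DomainError("a block extends past the end of the scan")
        elif self.indicator is not None and self.indicator.size != nt:
            raise ShapeError("indicator length must equal the volume count")

    def indicator_at(self, times) -> np.ndarray:
        """Evaluate the paradigm as a 0/1 function of time (seconds)."""
        t = np.asarray(times, dtype=float)
        if self.blocks is not None:
            out = np.zeros_like(t)
            for onset, dur in self.blocks:
                out[(t >= onset) & (t < onset + dur)] = 1.0
            return out
        if self.tr is None:
            raise DomainError("indicator paradigm needs tr for time lookup")
        idx = np.clip((t / self.tr).astype(int), 0, self.indicator.size - 1)
        return self.indicator[idx]

    def indicator_vector(self, nt: int, tr: float) -> np.ndarray:
        """Per-volume 0/1 vector sampled at volume times ``i * tr``."""
        return self.indicator_at(np.arange(nt) * tr)


def read_fmri(path_volume, path_mask=None) -> FmriDataset:
    """Read a 4-D NIfTI volume (and optional 3-D mask) into a dataset.

    TR is taken from the 4th header zoom; without a mask file the mask is
    all-true.
    """
    img = nib.load(str(path_volume))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionalityError(
            f"expected a 4-D volume, got {data.ndim}-D"
        )
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if path_mask is not None:
        mimg = nib.load(str(path_mask))
        mask = np.asanyarray(mimg.dataobj) > 0
        if mask.ndim != 3:
            raise DimensionalityError("mask must be 3-D")
        if mask.shape != data.shape[:3]:
            raise ShapeError(
                f"mask shape {mask.shape} does not match volume "
                f"{data.shape[:3]}"
            )
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return FmriDataset(
        data=data, mask=mask, tr=tr, voxel_size=voxel_size, affine=img.affine
    )


def write_fmri(dataset: FmriDataset, path_volume, path_mask=None) -> None:
    """Write a dataset (and optionally its mask) as NIfTI-1 files."""
    img = nib.Nifti1Image(dataset.data, dataset.affine)
    img.header.set_zooms(tuple(dataset.voxel_size) + (dataset.tr,))
    img.to_filename(str(path_volume))
    if path_mask is not None:
        mimg = nib.Nifti1Image(
            dataset.mask.astype(np.uint8), dataset.affine
        )
        mimg.header.set_zooms(tuple(dataset.voxel_size))
        mimg.to_filename(str(path_mask))


def write_map(volume: np.ndarray, dataset: FmriDataset, path) -> None:
    """Write a 3-D (or 4-D weight) map in the dataset's geometry."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=float), dataset.affine)
    img.to_filename(str(path))


def make_mask(mean_volume: np.ndarray, threshold_fraction: float = DEFAULT_MASK_FRACTION):
    """Segment the brain by simple intensity thresholding.

    A voxel is brain iff its mean intensity is at least
    ``threshold_fraction`` times the maximum mean intensity.
    """
    vol = np.asarray(mean_volume, dtype=float)
    if not np.all(np.isfinite(vol)):
        raise DomainError("mean volume must be finite")
    if not 0.0 < threshold_fraction < 1.0:
        raise DomainError("threshold_fraction must lie in (0, 1)")
    peak = vol.max()
    if peak <= 0:
        raise EmptyMaskError("all-zero volume yields an empty mask")
    return vol >= threshold_fraction * peak


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic block-design fMRI dataset.

    ``ar_coeffs`` may be ``None`` (white noise), a length-p list applied to
    every voxel, or an array of shape ``shape + (p,)`` for spatially varying
    noise; the AR polynomial must be stationary everywhere.  ``noise_sd``
    is the innovation standard deviation.  ``activation_amplitude`` scales
    the peak of the HRF-convolved block response in units of ``noise_sd``.
    ``trend_coeffs`` are polynomial coefficients (degree 0..3) in normalized
    time on [-1, 1], added inside the brain.  ``rician`` replaces the signal
    with the magnitude of a complex-valued version (off by default; the
    pipeline itself never assumes it).
    """

    shape: tuple = (64, 64, 22)
    nt: int = 80
    tr: float = 2.0
    voxel_size: tuple = (3.75, 3.75, 3.75)
    ar_coeffs: object = None
    trend_coeffs: tuple = (100.0, 1.0, 0.5, 0.25)
    activation_amplitude: float = 0.0
    active_region: object = None
    noise_sd: float = 1.0
    seed: int = 0
    mask: object = None  # None -> central ellipsoid (~25% of the volume)
    rician: bool = False

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("ar_coeffs", "active_region", "mask"):
            if isinstance(d[key], np.ndarray):
                d[key] = d[key].tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("shape", "voxel_size", "trend_coeffs"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("ar_coeffs", "active_region", "mask"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key])
        return cls(**d)


def _ellipsoid_mask(shape) -> np.ndarray:
    """Central ellipsoid covering roughly a quarter of the volume, emulating
    the ~20 000 brain voxels of a 64 x 64 x 22 acquisition."""
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij"
    )
    return sum(g**2 for g in grids) * (1.0 / 0.9**2) <= 1.0


def smooth_random_field(
    shape, mean: float, amplitude: float, fwhm_vox: float = 6.0, seed: int = 0
) -> np.ndarray:
    """Smooth Gaussian random field: ``mean`` plus correlated fluctuation.

    Convenience for building spatially varying AR coefficient volumes with
    a known, smooth pattern; ``amplitude`` is the fluctuation standard
    deviation after smoothing.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(
        rng.standard_normal(shape), fwhm_vox / np.sqrt(8 * np.log(2))
    )
    sd = f.std()
    if sd > 0:
        f = f / sd
    return mean + amplitude * f


def _bold_response(paradigm: Paradigm, nt: int, tr: float) -> np.ndarray:
    """Peak-normalized HRF-convolved paradigm sampled at volume times."""
    dt = 0.1
    t_fine = np.arange(0.0, nt * tr, dt)
    ind = paradigm.indicator_at(t_fine)
    hrf = _design.hrf_double_gamma(np.arange(0.0, 32.0 + dt, dt))
    conv = np.convolve(ind, hrf)[: t_fine.size] * dt
    peak = np.max(np.abs(conv))
    if peak > 0:
        conv = conv / peak
    idx = np.clip(np.round(np.arange(nt) * tr / dt).astype(int), 0, t_fine.size - 1)
    return conv[idx]


def generate_synthetic(spec: SyntheticSpec, paradigm: Paradigm):
    """Generate a synthetic dataset and its ground-truth activation map.

    Each in-brain voxel series is polynomial trend + (if active)
    ``activation_amplitude * noise_sd`` times the peak-normalized
    HRF-convolved paradigm + AR-filtered Gaussian innovations of standard
    deviation ``noise_sd`` (burn-in discarded, so the noise is effectively
    stationary).  Outside the brain only faint background noise remains.
    Identical seeds give bit-identical outputs.

    Returns ``(FmriDataset, truth)`` with ``truth`` a 3-D boolean array.
    """
    shape = tuple(spec.shape)
    nt = int(spec.nt)
    if spec.noise_sd <= 0:
        raise DomainError("noise_sd must be positive")
    if spec.activation_amplitude < 0:
        raise DomainError("activation_amplitude must be >= 0")
    paradigm.validate_for(nt, spec.tr)

    mask = (
        _ellipsoid_mask(shape)
        if spec.mask is None
        else np.asarray(spec.mask, dtype=bool)
    )
    if mask.shape != shape:
        raise ShapeError("mask shape must equal spec.shape")
    if spec.active_region is None:
        truth = np.zeros(shape, dtype=bool)
    else:
        truth = np.asarray(spec.active_region, dtype=bool)
        if truth.shape != shape:
            raise ShapeError("active_region shape must equal spec.shape")
        if np.any(truth & ~mask):
            raise DomainError("active_region must lie inside the brain mask")

    nv = int(np.prod(shape))
    rng = np.random.default_rng(spec.seed)

    # AR coefficients per voxel (flattened), or None for white noise
    a = None
    if spec.ar_coeffs is not None:
        arr = np.asarray(spec.ar_coeffs, dtype=float)
        if arr.ndim == 1:
            a = np.broadcast_to(arr, (nv, arr.size)).copy()
        elif arr.shape[:-1] == shape:
            a = arr.reshape(nv, arr.shape[-1])
        else:
            raise ShapeError("ar_coeffs must be (p,) or shape + (p,)")
        if np.any(_ar_max_root_modulus(a) >= 1.0):
            raise StationarityError("ar_coeffs describe a non-stationary process")

    def _noise() -> np.ndarray:
        e = rng.standard_normal((_BURN_IN + nt, nv)) * spec.noise_sd
        if a is None:
            return e[_BURN_IN:]
        return _inverse_whiten_batch(e[None], a)[0][_BURN_IN:]

    series = _noise()  # (nt, nv)

    u = np.linspace(-1.0, 1.0, nt)
    trend = sum(
        c * u**k for k, c in enumerate(spec.trend_coeffs[:4])
    ) * np.ones(nt)
    flat_mask = mask.ravel()
    series[:, flat_mask] += trend[:, None]

    if spec.activation_amplitude > 0 and np.any(truth):
        bold = _bold_response(paradigm, nt, spec.tr)
        series[:, truth.ravel()] += (
            spec.activation_amplitude * spec.noise_sd * bold[:, None]
        )

    # faint background outside the brain
    series[:, ~flat_mask] *= 0.01

    if spec.rician:
        imag = rng.standard_normal(series.shape) * spec.noise_sd
        series = np.sqrt(series**2 + imag**2)

    data = series.T.reshape(shape + (nt,))
    ds = FmriDataset(
        data=data,
        mask=mask,
        tr=spec.tr,
        voxel_size=tuple(spec.voxel_size),
    )
    return ds, truth
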