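"""The random permutation test with maximum-statistic FWE control.

Surrogate null datasets are built by detrending, removing the fitted BOLD
component, whitening each voxel series with spatially pooled AR models,
permuting the exchangeable innovations (the same permutation for every
voxel, preserving spatial structure), and re-imposing the noise model by
inverse whitening.  Smoothing and the detection statistic are applied
inside every permutation — smoothing beforehand would alter the AR
estimates and the per-voxel null — and only the maximum statistic over the
brain is kept per permutation.  The sorted maxima yield family-wise-error
corrected thresholds and p-values, plus Bonferroni and random-field-theory
thresholds for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from . import design as _design
from . import spatial as _spatial
from . import stats as _stats
from . import whitening as _whitening
from .data_io import FmriDataset, Paradigm
from .exceptions import DomainError, EmptyMaskError, ShapeError

__all__ = [
    "PermutationPlan",
    "PermutationConfig",
    "MaxNullDistribution",
    "CorrectedResult",
    "make_plan",
    "count_permutations",
    "run_permutation_test",
    "corrected_pvalue",
    "bonferroni_threshold",
    "rft_threshold",
    "relative_sd_pvalue",
    "FweCalibrationConfig",
    "FweCalibrationResult",
    "fwe_calibration",
    "ThresholdVariabilityConfig",
    "threshold_variability",
]


# ---------------------------------------------------------------------------
# permutation bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class PermutationPlan:
    """Np x Nt matrix of random time permutations, reproducible from seed."""

    indices: np.ndarray = field(repr=False)
    seed: int
    n_permutations: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.ndim != 2 or idx.shape[0] != self.n_permutations:
            raise ShapeError("indices must be (Np, Nt)")
        self.indices = idx

    @property
    def nt(self) -> int:
        return self.indices.shape[1]


def make_plan(nt: int, np_: int, seed: int) -> PermutationPlan:
    """Draw ``np_`` uniform random permutations of ``0..nt-1``.

    The identity permutation is not excluded (its probability, 1/nt!, is
    negligible for realistic series lengths).
    """
    if np_ < 1:
        raise DomainError("need at least one permutation")
    if nt < 2:
        raise DomainError("need at least two time points")
    rng = np.random.default_rng(seed)
    idx = rng.permuted(
        np.tile(np.arange(nt), (np_, 1)), axis=1
    )
    return PermutationPlan(indices=idx, seed=seed, n_permutations=np_)


def count_permutations(nt: int) -> int:
    """Exact number of distinct time permutations (``nt!``)."""
    if nt < 1:
        raise DomainError("nt must be >= 1")
    return math.factorial(nt)


@dataclass
class MaxNullDistribution:
    """Sorted maximum test statistics across permutations."""

    maxima: np.ndarray = field(repr=False)
    statistic_label: str

    def __post_init__(self) -> None:
        m = np.sort(np.asarray(self.maxima, dtype=float))
        if not np.all(np.isfinite(m)):
            raise DomainError("maxima must be finite")
        self.maxima = m

    @property
    def n_permutations(self) -> int:
        return self.maxima.size

    def threshold(self, alpha: float) -> float:
        """Corrected threshold: 1-based ascending-sort position
        ``ceil((1 - alpha) * Np)`` (position 9500 for Np=10000, alpha=0.05)."""
        np_ = self.n_permutations
        if not 0.0 < alpha < 1.0:
            raise DomainError("alpha must lie in (0, 1)")
        if np_ < 1.0 / alpha:
            warnings.warn(
                "fewer permutations than 1/alpha: the threshold is the "
                "largest observed maximum and the corrected level is "
                "unresolved",
                RuntimeWarning,
                stacklevel=2,
            )
        pos = math.ceil((1.0 - alpha) * np_)
        return float(self.maxima[min(pos, np_) - 1])

    def pvalue(self, stat) -> np.ndarray:
        """Corrected p-value(s): fraction of maxima >= the statistic."""
        return corrected_pvalue(stat, self.maxima)


@dataclass
class CorrectedResult:
    """Original statistic map with corrected threshold and p-values."""

    stat_map: np.ndarray = field(repr=False)
    threshold: float
    pmap: np.ndarray = field(repr=False)
    alpha: float
    mask: np.ndarray = field(repr=False, default=None)

    def significant(self) -> np.ndarray:
        """Voxels whose statistic exceeds the corrected threshold."""
        sig = self.stat_map > self.threshold
        if self.mask is not None:
            sig &= self.mask
        return sig


def corrected_pvalue(t_voxel, maxima, np_: int | None = None) -> np.ndarray:
    """Exact count-based corrected p: ``sum(t_max_i >= t) / Np``.

    Ties count toward the numerator.  ``t_voxel`` may be a scalar or array;
    values are in {0, 1/Np, ..., 1}.
    """
    m = np.sort(np.asarray(maxima, dtype=float))
    if np_ is not None and m.size != np_:
        raise ShapeError("maxima length must equal np_")
    t = np.asarray(t_voxel, dtype=float)
    count = m.size - np.searchsorted(m, t, side="left")
    out = count / m.size
    return float(out) if np.isscalar(t_voxel) else out


# ---------------------------------------------------------------------------
# configuration and pipeline state
# ---------------------------------------------------------------------------


@dataclass
class PermutationConfig:
    """Knobs of the permutation test.

    ``statistic`` is ``glm`` (t-value, fixed Gaussian smoothing of
    ``fwhm_mm``), ``cca2d`` (restricted CCA with the four-filter slicewise
    bank) or ``cca3d`` (restricted CCA with the isotropic scale-adaptive
    pair); for the CCA modes ``fwhm_mm`` is the largest filter the analysis
    can synthesize.  ``glm_whiten_each_perm`` repeats the global AR(1) GLM
    prewhitening inside every permutation — needed only when comparing
    against parametric (Bonferroni/RFT) thresholds.  ``preprocess=False``
    permutes the raw series directly with no detrending or whitening, the
    configuration used for white-noise calibration runs.
    """

    statistic: str = "glm"
    fwhm_mm: float = 8.0
    smooth_dims: int = 3
    ar_order: int = 4
    whiten_iters: int = 3
    ar_smooth_fwhm_mm: float = 8.0
    n_permutations: int = 10000
    alpha: float = 0.05
    seed: int = 0
    glm_whiten_each_perm: bool = False
    exclude_nonwhite: bool = False
    two_sided: bool = False
    preprocess: bool = True
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.statistic not in ("glm", "cca2d", "cca3d"):
            raise DomainError("statistic must be glm, cca2d or cca3d")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError("alpha must lie in (0, 1)")
        if not 1 <= self.ar_order <= 8:
            raise DomainError("ar_order must lie in 1..8")


class _Pipeline:
    """Prepared state shared by the original analysis and all permutations."""

    def __init__(self, dataset: FmriDataset, paradigm: Paradigm, config: PermutationConfig):
        self.config = config
        self.mask = dataset.mask.copy()
        self.tr = dataset.tr
        self.voxel_size = dataset.voxel_size
        self.nt = dataset.nt
        paradigm.validate_for(self.nt, self.tr)
        self.design = _design.build_design(paradigm, self.nt, self.tr)
        self.X = self.design.X
        self.c = self.design.c
        self._build(dataset)

    # -- preparation -------------------------------------------------------

    def _build(self, dataset: FmriDataset) -> None:
        cfg = self.config
        S = dataset.data[self.mask].T  # (nt, nv)
        self.phi = 0.0

        if cfg.preprocess:
            D = _design.cubic_detrend(S)
            R = D - self.X @ (np.linalg.lstsq(self.X, D, rcond=None)[0])
            W, hist, acc = _whitening._iterative_whiten_masked(
                R,
                self.mask,
                order=cfg.ar_order,
                iters=cfg.whiten_iters,
                fwhm_mm=cfg.ar_smooth_fwhm_mm or None,
                voxel_size=self.voxel_size,
                project_out=np.hstack(
                    [_design.trend_basis(self.nt).P, self.X]
                ),
            )
            if cfg.exclude_nonwhite:
                keep = self._white_voxels(W)
                if not np.any(keep):
                    raise EmptyMaskError("no voxels left after whiteness exclusion")
                if not np.all(keep):
                    flat = np.zeros(self.mask.sum(), dtype=bool)
                    flat[keep] = True
                    newmask = np.zeros_like(self.mask)
                    newmask[self.mask] = flat
                    self.mask = newmask
                    S = S[:, keep]
                    D = D[:, keep]
                    W = W[:, keep]
                    hist = [a[keep] for a in hist]
                    acc = acc[keep]
            self.detrended = D
            self.innovations = W
            self.hist = hist
            self.ar_accumulated = acc
            if cfg.statistic == "glm" and cfg.glm_whiten_each_perm:
                # global AR(1) coefficient, estimated once on the residuals
                # and reused for the original map and every permutation
                _, _, self.phi = _stats.prewhiten_glm(R, self.X)
        else:
            self.detrended = S
            self.innovations = S
            self.hist = []
            self.ar_accumulated = None

        self._setup_smoothers()

    def _white_voxels(self, W: np.ndarray) -> np.ndarray:
        """Boolean keep-vector: voxels passing the Ljung-Box test."""
        cfg = self.config
        data = np.zeros(self.mask.shape + (self.nt,))
        data[self.mask] = W.T
        report = _whitening.whiteness_map(
            data,
            self.mask,
            p=cfg.ar_order,
            smooth_fwhm_mm=cfg.ar_smooth_fwhm_mm or None,
            voxel_size=self.voxel_size,
        )
        return ~report.nonwhite_mask()[self.mask]

    def _setup_smoothers(self) -> None:
        cfg = self.config
        self.bank = None
        self.glm_smoother = None
        if cfg.statistic == "glm":
            if cfg.fwhm_mm and cfg.fwhm_mm > 0:
                bank = _spatial.glm_filter_bank(
                    cfg.fwhm_mm, self.voxel_size, dims=cfg.smooth_dims
                )
                self.glm_smoother = _spatial.MaskedSmoother(
                    self.mask, bank.kernels[0]
                )
        elif cfg.statistic == "cca2d":
            self.bank = _spatial.cca_filter_bank_2d(cfg.fwhm_mm, self.voxel_size)
        else:
            self.bank = _spatial.cca_filters_3d(cfg.fwhm_mm, self.voxel_size)
        if self.bank is not None:
            self.bank_smoothers = [
                _spatial.MaskedSmoother(self.mask, k) for k in self.bank.kernels
            ]

    # -- statistics --------------------------------------------------------

    def _stat_glm(self, S: np.ndarray) -> np.ndarray:
        """GLM t-values for one masked dataset (nt, nv).

        Applied identically to the observed data and to every surrogate:
        without per-permutation prewhitening the statistic is a pseudo-t,
        which is fine for the permutation test as long as observed and null
        values are the same quantity.
        """
        if self.glm_smoother is not None:
            S = self.glm_smoother.smooth_series(S)
        X = self.X
        if self.config.glm_whiten_each_perm:
            S, X, _ = _stats.prewhiten_glm(S, X, phi=self.phi)
        return _stats.glm_tstat_matrix(S, X, self.c)

    def _stat_cca(self, S: np.ndarray) -> np.ndarray:
        """Restricted-CCA correlations for one masked dataset (nt, nv)."""
        nv = S.shape[1]
        F = np.empty((self.nt, nv, self.bank.n_filters))
        for j, sm in enumerate(self.bank_smoothers):
            F[:, :, j] = sm.smooth_series(S)
        rho, _, _ = _stats._rcca_batch(self.X, F)
        return rho

    def original_stat(self) -> np.ndarray:
        """Statistic of the observed data over the in-mask voxels."""
        if self.config.statistic == "glm":
            S = self.detrended if self.config.preprocess else self.innovations
            return self._stat_glm(S)
        return self._stat_cca(self.detrended)

    def _reduce_max(self, stat: np.ndarray) -> float:
        if self.config.two_sided:
            return float(np.max(np.abs(stat)))
        return float(np.max(stat))

    # -- permutation execution --------------------------------------------

    def max_stats(self, rows: np.ndarray) -> np.ndarray:
        """Maximum statistic for each permutation row (any subset/order)."""
        cfg = self.config
        fast = (
            cfg.statistic == "glm"
            and not cfg.preprocess
            and self.glm_smoother is None
            and not cfg.glm_whiten_each_perm
        )
        if fast:
            return self._max_stats_fast(rows)
        out = np.empty(rows.shape[0])
        W = self.innovations
        for start in range(0, rows.shape[0], cfg.batch_size):
            idx = rows[start : start + cfg.batch_size]
            E = W[idx]  # (B, nt, nv)
            if cfg.preprocess:
                Y = _whitening._inverse_whiten_sequence(E, self.hist)
            else:
                Y = E
            for b in range(idx.shape[0]):
                y = Y[b]
                if cfg.preprocess:
                    y = _design.cubic_detrend(y)
                if cfg.statistic == "glm":
                    stat = self._stat_glm(y)
                else:
                    stat = self._stat_cca(y)
                out[start + b] = self._reduce_max(stat)
        return out

    def _max_stats_fast(self, rows: np.ndarray) -> np.ndarray:
        """Vectorized raw-permutation GLM path (calibration runs).

        Permutation leaves each voxel's sum of squares invariant, so only
        the regression coefficients have to be recomputed per permutation.
        """
        X, c = self.X, self.c
        nt, k = X.shape
        W = self.innovations
        XtX = X.T @ X
        M = np.linalg.solve(XtX, X.T)  # (k, nt)
        cM = np.linalg.solve(XtX, c)
        cc = float(c @ cM)
        ss0 = np.einsum("tv,tv->v", W, W)
        out = np.empty(rows.shape[0])
        batch = max(1, min(64, int(2e7 / max(W.size, 1))))
        for start in range(0, rows.shape[0], batch):
            idx = rows[start : start + batch]
            Y = W[idx]  # (B, nt, nv)
            B = np.einsum("kt,btv->bkv", M, Y)
            fit = np.einsum("bkv,kj,bjv->bv", B, XtX, B)
            var = np.maximum(ss0[None] - fit, 0.0) / (nt - k)
            t = np.einsum("k,bkv->bv", c, B) / np.sqrt(np.maximum(var * cc, 1e-300))
            if self.config.two_sided:
                np.abs(t, out=t)
            out[start : start + idx.shape[0]] = t.max(axis=1)
        return out


# ---------------------------------------------------------------------------
# the complete test
# ---------------------------------------------------------------------------


def run_permutation_test(
    dataset: FmriDataset,
    paradigm: Paradigm,
    config: PermutationConfig | None = None,
):
    """Run the complete single-subject permutation test.

    Computes the original statistic map, builds the surrogate-null maximum
    distribution (smoothing and statistic inside each permutation), and
    derives the corrected threshold and per-voxel corrected p-values.

    Returns ``(CorrectedResult, MaxNullDistribution)``.
    """
    config = config or PermutationConfig()
    pipe = _Pipeline(dataset, paradigm, config)
    plan = make_plan(pipe.nt, config.n_permutations, config.seed)
    maxima = pipe.max_stats(plan.indices)
    null = MaxNullDistribution(
        maxima=maxima, statistic_label=config.statistic
    )
    stat = pipe.original_stat()
    stat_map = np.zeros(pipe.mask.shape)
    stat_map[pipe.mask] = stat
    pmap = np.ones(pipe.mask.shape)
    pmap[pipe.mask] = null.pvalue(np.abs(stat) if config.two_sided else stat)
    threshold = null.threshold(config.alpha)
    result = CorrectedResult(
        stat_map=stat_map,
        threshold=threshold,
        pmap=pmap,
        alpha=config.alpha,
        mask=pipe.mask,
    )
    return result, null


# ---------------------------------------------------------------------------
# parametric comparison thresholds and permutation-count calculus
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, n_voxels: int, df: int):
    """Bonferroni-corrected t threshold and the per-comparison rate.

    Returns ``(threshold, alpha / n_voxels)``; with one voxel this is the
    uncorrected Student-t quantile.
    """
    if n_voxels < 1 or df < 1:
        raise DomainError("need n_voxels >= 1 and df >= 1")
    rate = alpha / n_voxels
    return float(sps.t.isf(rate, df)), rate


def _resel_counts(mask: np.ndarray, fwhm_vox: np.ndarray) -> np.ndarray:
    """Resolution-element counts R_0..R_3 of a voxel mask.

    Lattice counting: voxels, in-mask neighbour pairs per axis, fully
    in-mask 2x2 faces per plane, and 2x2x2 cubes, combined into the
    standard intrinsic-volume estimates scaled by the smoothness.
    """
    m = mask.astype(bool)
    fx, fy, fz = fwhm_vox
    P = m.sum()
    Ex = (m[:-1] & m[1:]).sum()
    Ey = (m[:, :-1] & m[:, 1:]).sum()
    Ez = (m[:, :, :-1] & m[:, :, 1:]).sum()
    Fxy = (m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]).sum()
    Fxz = (
        m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]
    ).sum()
    Fyz = (
        m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]
    ).sum()
    C = (
        m[:-1, :-1, :-1]
        & m[1:, :-1, :-1]
        & m[:-1, 1:, :-1]
        & m[:-1, :-1, 1:]
        & m[1:, 1:, :-1]
        & m[1:, :-1, 1:]
        & m[:-1, 1:, 1:]
        & m[1:, 1:, 1:]
    ).sum()
    R0 = P - (Ex + Ey + Ez) + (Fxy + Fxz + Fyz) - C
    R1 = (
        (Ex - Fxy - Fxz + C) / fx
        + (Ey - Fxy - Fyz + C) / fy
        + (Ez - Fxz - Fyz + C) / fz
    )
    R2 = (Fxy - C) / (fx * fy) + (Fxz - C) / (fx * fz) + (Fyz - C) / (fy * fz)
    R3 = C / (fx * fy * fz)
    return np.array([R0, R1, R2, R3], dtype=float)


def _t_ec_densities(t: float, df: int) -> np.ndarray:
    """Euler-characteristic densities rho_0..rho_3 of a t-field."""
    nu = float(df)
    base = (1.0 + t * t / nu) ** (-(nu - 1.0) / 2.0)
    l2 = 4.0 * np.log(2.0)
    rho0 = sps.t.sf(t, df)
    rho1 = np.sqrt(l2) / (2.0 * np.pi) * base
    g = math.lgamma((nu + 1.0) / 2.0) - math.lgamma(nu / 2.0)
    rho2 = (
        l2
        / (2.0 * np.pi) ** 1.5
        * math.exp(g)
        / np.sqrt(nu / 2.0)
        * t
        * base
    )
    rho3 = (
        l2**1.5 / (2.0 * np.pi) ** 2 * base * ((nu - 1.0) / nu * t * t - 1.0)
    )
    return np.array([rho0, rho1, rho2, rho3])


def expected_euler_characteristic(t: float, mask, fwhm_mm, voxel_size, df: int) -> float:
    """Expected EC of the thresholded t-field over the mask."""
    vox = np.asarray(voxel_size, dtype=float)[:3]
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)) / vox
    R = _resel_counts(np.asarray(mask, dtype=bool), fwhm)
    return float(R @ _t_ec_densities(t, df))


def rft_threshold(alpha: float, mask, fwhm_est_mm, voxel_size, df: int) -> float:
    """Random-field-theory corrected t threshold (comparison only).

    Solves ``E[EC(t)] = alpha`` for a t-field over the mask, with the
    smoothness expressed as FWHM in mm (scalar or per axis).  Warns when
    the smoothness is below one voxel, where the continuous-field
    approximation is unreliable.
    """
    vox = np.asarray(voxel_size, dtype=float)[:3]
    fwhm = np.broadcast_to(np.asarray(fwhm_est_mm, dtype=float), (3,))
    if np.any(fwhm <= 0):
        raise DomainError("fwhm_est_mm must be positive")
    if np.any(fwhm < vox):
        warnings.warn(
            "estimated smoothness below one voxel: random-field assumptions "
            "are violated and the threshold is unreliable",
            RuntimeWarning,
            stacklevel=2,
        )

    def f(t: float) -> float:
        return expected_euler_characteristic(t, mask, fwhm, vox, df) - alpha

    lo = float(sps.t.isf(alpha, df))
    hi = 100.0
    if f(lo) <= 0:  # tiny search region: uncorrected quantile already enough
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def relative_sd_pvalue(p: float, np_: int) -> float:
    """Relative standard deviation of an estimated (one-sided) p-value.

    ``sqrt(p (1 - p) / Np) / p``: the resolution of a permutation test with
    ``Np`` permutations at significance level ``p``.
    """
    if not 0.0 < p < 1.0:
        raise DomainError("p must lie in (0, 1)")
    if np_ < 1:
        raise DomainError("np_ must be >= 1")
    return math.sqrt(p * (1.0 - p) / np_) / p


# ---------------------------------------------------------------------------
# calibration experiments
# ---------------------------------------------------------------------------


@dataclass
class FweCalibrationConfig:
    """White-noise familywise-error calibration experiment.

    A corrected threshold is computed by permutation on one Gaussian
    white-noise dataset (all preprocessing removed), then fresh white-noise
    datasets are generated and the fraction containing any statistic above
    the threshold is measured; for a correct threshold the rate matches
    ``alpha``.
    """

    shape: tuple = (20, 20, 10)
    nt: int = 80
    tr: float = 2.0
    n_permutations: int = 10000
    n_datasets: int = 10000
    alpha: float = 0.05
    fwhm_mm: float = 0.0
    smooth_dims: int = 3
    two_sided: bool = False
    seed: int = 0
    #: fresh datasets generated per batch (memory: batch * nt * n_voxels)
    batch_datasets: int = 50


@dataclass
class FweCalibrationResult:
    threshold: float
    count: int
    rate: float
    n_datasets: int
    expected_count: float


def fwe_calibration(config: FweCalibrationConfig | None = None) -> FweCalibrationResult:
    """Measure the empirical familywise error of the permutation threshold.

    Uses the two-regressor block design (HRF + temporal derivative) at the
    configured geometry.  The threshold dataset and the fresh datasets use
    independent random streams derived from the seed.
    """
    cfg = config or FweCalibrationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_thresh, s_plan, s_fresh = ss.spawn(3)

    paradigm = Paradigm.block_design(
        on_s=10 * cfg.tr, off_s=10 * cfg.tr, duration_s=cfg.nt * cfg.tr
    )
    mask = np.ones(cfg.shape, dtype=bool)
    nv = int(np.prod(cfg.shape))

    rng0 = np.random.default_rng(s_thresh)
    data0 = rng0.standard_normal(cfg.shape + (cfg.nt,))
    ds0 = FmriDataset(
        data=data0, mask=mask, tr=cfg.tr, voxel_size=(3.75, 3.75, 3.75)
    )
    pcfg = PermutationConfig(
        statistic="glm",
        fwhm_mm=cfg.fwhm_mm,
        smooth_dims=cfg.smooth_dims,
        n_permutations=cfg.n_permutations,
        alpha=cfg.alpha,
        seed=int(s_plan.generate_state(1)[0] % (2**31)),
        preprocess=False,
        two_sided=cfg.two_sided,
    )
    pipe = _Pipeline(ds0, paradigm, pcfg)
    plan = make_plan(cfg.nt, cfg.n_permutations, pcfg.seed)
    null = MaxNullDistribution(pipe.max_stats(plan.indices), "glm")
    threshold = null.threshold(cfg.alpha)

    # fresh datasets, analysed with the identical statistic path
    rngf = np.random.default_rng(s_fresh)
    count = 0
    done = 0
    while done < cfg.n_datasets:
        nb = min(cfg.batch_datasets, cfg.n_datasets - done)
        Y = rngf.standard_normal((nb, cfg.nt, nv))
        for b in range(nb):
            stat = pipe._stat_glm(Y[b])
            mx = np.max(np.abs(stat)) if cfg.two_sided else np.max(stat)
            if mx > threshold:
                count += 1
        done += nb
    rate = count / cfg.n_datasets
    return FweCalibrationResult(
        threshold=threshold,
        count=count,
        rate=rate,
        n_datasets=cfg.n_datasets,
        expected_count=cfg.alpha * cfg.n_datasets,
    )


@dataclass
class ThresholdVariabilityConfig:
    """Repeat the permutation test on one dataset to measure threshold sd."""

    shape: tuple = (10, 10, 4)
    nt: int = 80
    tr: float = 2.0
    n_permutations: int = 1000
    n_replicates: int = 100
    alpha: float = 0.05
    seed: int = 0
    preprocess: bool = False


@dataclass
class ThresholdVariabilityResult:
    thresholds: np.ndarray
    sd: float
    n_permutations: int


def threshold_variability(
    config: ThresholdVariabilityConfig | None = None,
    dataset: FmriDataset | None = None,
    paradigm: Paradigm | None = None,
) -> ThresholdVariabilityResult:
    """Distribution of corrected thresholds across replicate tests.

    The dataset is fixed (white noise by default); each replicate redraws
    the permutation plan.  The sd supports the 1/sqrt(Np) accuracy law:
    ten times more permutations shrink it by sqrt(10).
    """
    cfg = config or ThresholdVariabilityConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_data, *s_reps = ss.spawn(1 + cfg.n_replicates)
    if dataset is None:
        rng = np.random.default_rng(s_data)
        dataset = FmriDataset(
            data=rng.standard_normal(cfg.shape + (cfg.nt,)),
            mask=np.ones(cfg.shape, dtype=bool),
            tr=cfg.tr,
            voxel_size=(3.75, 3.75, 3.75),
        )
    if paradigm is None:
        paradigm = Paradigm.block_design(
            on_s=10 * cfg.tr, off_s=10 * cfg.tr, duration_s=cfg.nt * cfg.tr
        )
    pcfg = PermutationConfig(
        statistic="glm",
        fwhm_mm=0.0,
        n_permutations=cfg.n_permutations,
        alpha=cfg.alpha,
        preprocess=cfg.preprocess,
    )
    pipe = _Pipeline(dataset, paradigm, pcfg)
    thresholds = np.empty(cfg.n_replicates)
    for i, s in enumerate(s_reps):
        seed = int(s.generate_state(1)[0] % (2**31))
        plan = make_plan(dataset.nt, cfg.n_permutations, seed)
        null = MaxNullDistribution(pipe.max_stats(plan.indices), "glm")
        thresholds[i] = null.threshold(cfg.alpha)
    return ThresholdVariabilityResult(
        thresholds=thresholds,
        sd=float(thresholds.std(ddof=1)),
        n_permutations=cfg.n_permutations,
    )
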