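"""Scalar and map QC metrics.

Per-TR series: the Euclidean-norm motion index (Enorm), outlier
fractions, censor vectors and motion summaries, pre-steady-state
detection.  Scalars and maps: global correlation (GCOR), temporal SNR,
correlation with the brain-average residual (corr_brain), radial
correlation, and seed-based correlation maps.

Unit convention: Enorm mixes rotation degrees and translation mm as-is
(1 degree of head rotation moves the cortical surface by roughly 1 mm
at a ~57 mm radius), so the motion-parameter column order in
:mod:`qcfmri.dataio` is load-bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .dataio import CensorVector, EpiSeries, MotionTrace, VolumeGrid, \
    parse_coordinate_label
from .regmodel import BrainMask, _legendre_baseline

__all__ = [
    "MotionSummary",
    "ScalarMap",
    "PreSteadyReport",
    "compute_enorm",
    "compute_outlier_fractions",
    "make_censor",
    "detect_pre_steady",
    "compute_gcor",
    "compute_tsnr",
    "compute_corr_brain",
    "compute_radcor",
    "seed_correlation_map",
    "ghost_score",
    "dropout_score",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.3548


@dataclass
class MotionSummary:
    """Censor vector plus the motion summaries derived from it."""

    enorm: np.ndarray
    outfrac: np.ndarray
    censor: CensorVector
    censor_fraction: float
    avg_censored_motion: float
    max_censored_displacement: float


@dataclass
class ScalarMap:
    """A grid-matched 3D QC map (tsnr, corr_brain, radcor or seedcorr)."""

    data: np.ndarray
    label: str
    mask: np.ndarray | None = None

    LABELS = ("tsnr", "corr_brain", "radcor", "seedcorr")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.label not in self.LABELS:
            raise ValueError(f"unknown map label {self.label!r}")
        if self.label != "tsnr":
            inside = self.data if self.mask is None else self.data[self.mask]
            if inside.size and (np.nanmax(np.abs(inside)) > 1.0 + 1e-9):
                raise ValueError("correlation map exceeds [-1, 1]")


@dataclass
class PreSteadyReport:
    """Leading-TR outlier evidence for pre-steady-state volumes."""

    flagged: bool
    n_leading_trs: int
    evidence: np.ndarray

    def __post_init__(self) -> None:
        if self.n_leading_trs < 0:
            raise ValueError("n_leading_trs must be >= 0")


# --------------------------------------------------------------------------
# motion and censoring
# --------------------------------------------------------------------------

def compute_enorm(motion: MotionTrace) -> np.ndarray:
    """Euclidean norm of the first differences of the six motion
    parameters; ``e[0] = 0`` by convention."""
    p = motion.params
    e = np.zeros(p.shape[0])
    if p.shape[0] > 1:
        e[1:] = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return e


def _mask_of(mask: BrainMask | np.ndarray) -> np.ndarray:
    return mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, bool)


def _l1_polyfit(B: np.ndarray, series: np.ndarray,
                n_iter: int = 8) -> np.ndarray:
    """Per-voxel L1 (least absolute deviation) polynomial trend via
    iteratively reweighted least squares.

    An L1 fit keeps genuine outliers from dragging the trend toward
    themselves, which a plain least-squares fit does badly on short
    runs with bright leading volumes.
    """
    n, k = B.shape
    coef = np.linalg.lstsq(B, series.T, rcond=None)[0]   # (k, V) start
    for _ in range(n_iter):
        resid = series - (B @ coef).T                     # (V, n)
        w = 1.0 / np.maximum(np.abs(resid), 1e-8)         # L1 weights
        # weighted normal equations per voxel
        Bw = np.einsum("vn,nk->vnk", w, B)                # (V, n, k)
        G = np.einsum("vnk,nl->vkl", Bw, B)               # (V, k, k)
        b = np.einsum("vnk,vn->vk", Bw, series)           # (V, k)
        coef = np.linalg.solve(G, b[..., None])[..., 0].T
    return (B @ coef).T


def compute_outlier_fractions(epi: EpiSeries | np.ndarray,
                              mask: BrainMask | np.ndarray,
                              alpha: float = 0.001,
                              polort: int | None = None) -> np.ndarray:
    """Per-TR fraction of in-mask voxels that are trend outliers.

    Each voxel is detrended with the run's Legendre baseline; a sample
    is an outlier when its absolute deviation from the trend exceeds
    ``Q * sqrt(pi/2) * MAD``, where MAD is the median absolute
    deviation and Q the upper-tail normal quantile at ``alpha/n_vols``.
    Voxels with MAD = 0 never count as outliers.
    """
    data = epi.data if isinstance(epi, EpiSeries) else np.asarray(epi, float)
    tr = epi.tr_s if isinstance(epi, EpiSeries) else 1.0
    m = _mask_of(mask)
    n = data.shape[-1]
    if n < 5:
        raise ValueError("need at least 5 volumes for outlier detection")
    series = data[m]                       # (V, n)
    p = polort if polort is not None else 1 + int(n * tr // 150)
    B = _legendre_baseline(n, p)           # (n, p+1)
    trend = _l1_polyfit(B, series)
    dev = np.abs(series - trend)
    mad = np.median(dev, axis=1, keepdims=True)
    q = stats.norm.isf(alpha / n)
    thresh = q * np.sqrt(np.pi / 2.0) * mad
    out = (dev > thresh) & (mad > 0)
    return out.mean(axis=0)


def make_censor(enorm: np.ndarray, outfrac: np.ndarray,
                motion: MotionTrace,
                L_motion: float = 0.2, L_out: float = 0.05) -> MotionSummary:
    """Censor TRs by motion and outlier limits and summarize.

    A TR ``t`` with ``enorm[t] > L_motion`` censors both ``t`` and
    ``t-1`` (Enorm measures the t-1 -> t transition); ``outfrac[t] >
    L_out`` censors ``t`` alone.  ``max_censored_displacement`` is the
    largest 6-parameter Euclidean distance between any two retained
    TRs.
    """
    enorm = np.asarray(enorm, float)
    outfrac = np.asarray(outfrac, float)
    if enorm.size != outfrac.size:
        raise ValueError("enorm and outlier series lengths differ")
    if L_motion <= 0 or L_out <= 0:
        raise ValueError("censor limits must be positive")
    n = enorm.size
    keep = np.ones(n, dtype=int)
    over = np.flatnonzero(enorm > L_motion)
    keep[over] = 0
    keep[np.clip(over - 1, 0, None)] = 0
    keep[outfrac > L_out] = 0
    censor = CensorVector(keep=keep)

    retained = censor.retained_indices()
    avg_motion = float(enorm[retained].mean()) if retained.size else float("nan")
    if retained.size >= 2:
        pts = motion.params[retained]
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
        max_disp = float(np.sqrt(d2.max()))
    else:
        max_disp = 0.0
    return MotionSummary(
        enorm=enorm, outfrac=outfrac, censor=censor,
        censor_fraction=censor.censor_fraction,
        avg_censored_motion=avg_motion,
        max_censored_displacement=max_disp)


def detect_pre_steady(outfrac: np.ndarray, k_max: int = 5,
                      floor: float = 0.02) -> PreSteadyReport:
    """Flag leading TRs whose outlier fraction is far above background.

    Counts TRs contiguous from TR 0 (at most ``k_max``) whose outlier
    fraction exceeds ``max(2 * median of the remaining TRs, floor)``.
    """
    outfrac = np.asarray(outfrac, float)
    if outfrac.size < 2 * k_max:
        raise ValueError("series too short for pre-steady-state check")
    background = np.median(outfrac[k_max:])
    limit = max(2.0 * background, floor)
    n_lead = 0
    for v in outfrac[:k_max]:
        if v > limit:
            n_lead += 1
        else:
            break
    return PreSteadyReport(flagged=n_lead > 0, n_leading_trs=n_lead,
                           evidence=outfrac[:max(n_lead, k_max)].copy())


# --------------------------------------------------------------------------
# correlation and SNR metrics
# --------------------------------------------------------------------------

def _series_in_mask(data, mask) -> np.ndarray:
    data = data.data if isinstance(data, EpiSeries) else np.asarray(data, float)
    if data.ndim == 4:
        return data[_mask_of(mask)]
    return data  # already (V, t)


def compute_gcor(residuals, mask=None) -> float:
    """Global correlation: the average over all pairs (self-pairs
    included) of temporal correlations among in-mask voxels.

    Computed by the fast identity ``GCOR = || mean_v u_v ||^2`` where
    ``u_v`` is each voxel's demeaned, unit-L2-normalized series.
    Zero-variance voxels are excluded.
    """
    if residuals_ndim(residuals) == 4 and mask is None:
        raise ValueError("mask required for 4D input")
    series = (_series_in_mask(residuals, mask) if mask is not None
              else np.asarray(residuals, float))
    series = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(series, axis=1)
    ok = norms > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 in-mask voxels with nonzero variance")
    u = series[ok] / norms[ok][:, None]
    g = u.mean(axis=0)
    return float(g @ g)


def residuals_ndim(x) -> int:
    return x.data.ndim if isinstance(x, EpiSeries) else np.asarray(x).ndim


def compute_tsnr(fitted: np.ndarray, residuals: np.ndarray,
                 mask: BrainMask | np.ndarray) -> tuple[ScalarMap, float]:
    """Temporal SNR: mean of the modeled series over the residual
    standard deviation, per voxel; plus the in-mask average.

    Voxels with zero residual sd get TSNR 0 (degenerate, flagged by the
    zero rather than an inf)."""
    fitted = np.asarray(fitted, float)
    residuals = np.asarray(residuals, float)
    if fitted.shape[-1] < 3:
        raise ValueError("need >= 3 retained TRs for TSNR")
    mean = fitted.mean(axis=-1)
    sd = residuals.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / sd, 0.0)
    m = _mask_of(mask)
    avg = float(tsnr[m].mean())
    return ScalarMap(data=tsnr, label="tsnr", mask=m), avg


def _corr_with(series4d: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of every voxel's series with one reference."""
    x = series4d - series4d.mean(axis=-1, keepdims=True)
    r = ref - ref.mean()
    rn = np.linalg.norm(r)
    xn = np.linalg.norm(x, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((xn > 0) & (rn > 0),
                       np.tensordot(x, r, axes=([-1], [0])) / (xn * rn), 0.0)
    return np.clip(out, -1.0, 1.0)


def compute_corr_brain(residuals: np.ndarray,
                       mask: BrainMask | np.ndarray) -> ScalarMap:
    """Correlate each voxel (full FOV, unmasked display philosophy)
    with the in-mask average residual series."""
    residuals = np.asarray(residuals, float)
    m = _mask_of(mask)
    g = residuals[m].mean(axis=0)
    return ScalarMap(data=_corr_with(residuals, g), label="corr_brain", mask=m)


def compute_radcor(series, mask, fwhm_mm: float = 40.0,
                   voxel_size_mm=(1.0, 1.0, 1.0)) -> ScalarMap:
    """Radial correlation: each voxel vs a Gaussian-weighted local
    average of the data (mask-normalized convolution, center included).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if isinstance(series, EpiSeries):
        voxel_size_mm = series.grid.voxel_size_mm
        series = series.data
    series = np.asarray(series, float)
    m = _mask_of(mask).astype(float)
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / v for v in voxel_size_mm]

    wsum = ndimage.gaussian_filter(m, sigma_vox, mode="constant")
    local = np.empty_like(series)
    for t in range(series.shape[-1]):
        num = ndimage.gaussian_filter(series[..., t] * m, sigma_vox,
                                      mode="constant")
        with np.errstate(divide="ignore", invalid="ignore"):
            local[..., t] = np.where(wsum > 1e-12, num / wsum, 0.0)

    x = series - series.mean(axis=-1, keepdims=True)
    y = local - local.mean(axis=-1, keepdims=True)
    xn = np.linalg.norm(x, axis=-1)
    yn = np.linalg.norm(y, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((xn > 0) & (yn > 0),
                     np.sum(x * y, axis=-1) / (xn * yn), 0.0)
    return ScalarMap(data=np.clip(r, -1, 1), label="radcor",
                     mask=m.astype(bool))


def seed_correlation_map(residuals: np.ndarray, grid: VolumeGrid,
                         seed_mm, radius_mm: float = 6.0) -> ScalarMap:
    """Seed-based correlation map over the full FOV.

    ``seed_mm`` is an RAS+ mm triple or a label like ``"5L, 49P, 40S"``.
    The seed series is the mean residual over voxels within
    ``radius_mm`` of the seed (the seed voxel alone when radius is 0).
    """
    if isinstance(seed_mm, str):
        seed_mm = parse_coordinate_label(seed_mm)
    seed_mm = np.asarray(seed_mm, float)
    residuals = np.asarray(residuals, float)

    vox = grid.mm_to_voxel(seed_mm)
    dims = np.asarray(grid.dims)
    if np.any(vox < -0.5) or np.any(vox > dims - 0.5):
        raise ValueError(f"seed {seed_mm} falls outside the field of view")

    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    coords = grid.voxel_to_mm(np.column_stack(
        [ii.ravel(), jj.ravel(), kk.ravel()]))
    dist = np.linalg.norm(coords - seed_mm, axis=1).reshape(tuple(dims))
    ball = dist <= max(radius_mm, 0.0)
    if not ball.any():
        nearest = np.round(vox).astype(int)
        ball[tuple(np.clip(nearest, 0, dims - 1))] = True
    seed_series = residuals[ball].mean(axis=0)
    if not np.any(seed_series != seed_series.mean()):
        raise ValueError("seed series has zero variance")
    return ScalarMap(data=_corr_with(residuals, seed_series),
                     label="seedcorr", mask=None)


# --------------------------------------------------------------------------
# artifact scores (feed the warns block)
# --------------------------------------------------------------------------

def ghost_score(epi: EpiSeries | np.ndarray, mask: BrainMask | np.ndarray,
                pe_axis: int = 1) -> float:
    """Nyquist-ghost evidence: mean intensity in the half-FOV-shifted
    copy of the brain mask (outside the brain) relative to the mean
    intensity in far background, minus 1.

    A value near 0 means the shifted region looks like background; a
    ghost raises it in proportion to the ghost amplitude.
    """
    data = epi.data if isinstance(epi, EpiSeries) else np.asarray(epi, float)
    mean = data.mean(axis=-1) if data.ndim == 4 else data
    m = _mask_of(mask)
    shifted = np.roll(m, mean.shape[pe_axis] // 2, axis=pe_axis)
    ghost_region = shifted & ~m
    background = ~m & ~shifted
    if not ghost_region.any() or not background.any():
        return 0.0
    bg = float(mean[background].mean())
    gr = float(mean[ghost_region].mean())
    if bg <= 0:
        return float(gr > 0) * np.inf if gr > 0 else 0.0
    return gr / bg - 1.0


def dropout_score(epi: EpiSeries | np.ndarray,
                  mask: BrainMask | np.ndarray,
                  rel_threshold: float = 0.5) -> float:
    """Fraction of in-mask voxels whose mean intensity falls below
    ``rel_threshold`` times the in-mask median (signal-dropout
    evidence).  The mask should be hole-filled so attenuated regions
    remain inside it."""
    data = epi.data if isinstance(epi, EpiSeries) else np.asarray(epi, float)
    mean = data.mean(axis=-1) if data.ndim == 4 else data
    m = _mask_of(mask)
    vals = mean[m]
    med = np.median(vals)
    if med <= 0:
        return 0.0
    return float(np.mean(vals < rel_threshold * med))
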