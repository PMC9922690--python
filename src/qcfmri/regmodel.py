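"""Masking, scaling, design-matrix construction and censored OLS fitting.

The modeling pipeline mirrors a standard single-subject fMRI analysis:

1. a brain-coverage mask from the mean EPI (used for statistics only —
   data remain unmasked);
2. scaling of each voxel time series to a temporal mean of 100, so
   coefficients read as percent BOLD change;
3. a design matrix with per-run Legendre polynomial baselines (order
   ``p = 1 + floor(run_seconds / 150)``), per-run motion regressors
   (optionally with first-difference derivatives), and duration-
   modulated stimulus regressors built from a peak-1 gamma response
   ``g(tau) = (tau/4)^4 * exp(4 - tau)``, scaled so that a 2 s block
   peaks at exactly 1 (longer events produce larger responses);
4. ordinary least squares per voxel after deleting censored rows, with
   contrast t-statistics and a partial F test of the regressors of
   interest against the baseline+motion reduced model.

Serial correlation is deliberately ignored (plain OLS); censoring is by
row deletion so that the degrees-of-freedom accounting matches
``df_remain = retained TRs - rank(X)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage, stats

from .dataio import CensorVector, EpiSeries, EventTable, MotionTrace

__all__ = [
    "BrainMask",
    "DesignMatrix",
    "GLMFit",
    "ContrastSpec",
    "BasisConfig",
    "compute_automask",
    "scale_to_mean100",
    "build_design",
    "fit_glm",
    "gamma_response",
    "block_response_peak",
]

#: cap on the full-F statistic when residual variance underflows
F_CAP = 1e6


@dataclass
class BrainMask:
    """Binary EPI brain-coverage mask (single connected component)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty brain mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


GROUPS = ("baseline", "motion", "interest")


@dataclass
class DesignMatrix:
    """Labeled regressor columns over all TRs of all runs."""

    X: np.ndarray                      # (total TRs, n_columns)
    labels: list[str]
    groups: list[str]                  # one of GROUPS per column
    run_index: np.ndarray              # run id per row (0-based)
    column_run: list[int | None]       # owning run per column, None = all
    tr_s: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.run_index = np.asarray(self.run_index, dtype=int)
        if self.X.shape[0] != self.run_index.size:
            raise ValueError("row count does not match run index")
        if not (len(self.labels) == len(self.groups) == self.X.shape[1]
                == len(self.column_run)):
            raise ValueError("column metadata lengths disagree")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown column group {g!r}")
        for run in np.unique(self.run_index):
            cols = [i for i, (g, r) in enumerate(zip(self.groups,
                                                     self.column_run))
                    if g == "baseline" and r == run]
            if not cols:
                raise ValueError(f"run {run} has no baseline columns")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def columns_of(self, *groups: str) -> np.ndarray:
        sel = [i for i, g in enumerate(self.groups) if g in groups]
        return np.asarray(sel, dtype=int)

    def submatrix(self, *groups: str) -> np.ndarray:
        return self.X[:, self.columns_of(*groups)]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.X, columns=self.labels)

    def save_tsv(self, path) -> None:
        header = "\t".join(self.labels)
        np.savetxt(str(path), self.X, delimiter="\t", header=header,
                   comments="", fmt="%.6g")


@dataclass
class ContrastSpec:
    """A named linear combination of the regressors of interest."""

    label: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("contrast needs at least one nonzero weight")


@dataclass
class GLMFit:
    """Censored-OLS results: coefficients, stats, residuals, DF summary."""

    coef: dict[str, np.ndarray]            # per interest column / contrast
    tstat: dict[str, np.ndarray]           # per contrast
    full_f: np.ndarray | None              # partial F over interest group
    full_f_capped: bool
    fitted: np.ndarray                     # (voxels..., retained TRs)
    residuals: np.ndarray                  # (voxels..., retained TRs)
    retained: np.ndarray                   # retained TR indices
    df_used: int
    df_remain: int
    df_fraction: float
    n_total_trs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.df_fraction <= 1.0):
            raise ValueError("df_fraction must lie in [0, 1]")


# --------------------------------------------------------------------------
# masking and scaling
# --------------------------------------------------------------------------

def compute_automask(epi: EpiSeries, clip_frac: float = 0.5) -> BrainMask:
    """Threshold the mean volume, keep the largest connected component
    and fill holes.

    The clip level is ``clip_frac`` times the 90th percentile of the
    nonzero mean intensities — a robust stand-in for the upper-intensity
    histogram mode separating head from background.
    """
    mean = epi.data.mean(axis=3)
    nz = mean[mean > 0]
    if nz.size == 0:
        raise ValueError("cannot mask all-nonpositive data")
    clip = clip_frac * np.percentile(nz, 90)
    rough = mean > clip
    labels, n = ndimage.label(rough)
    if n == 0:
        raise ValueError("empty mask after thresholding")
    sizes = ndimage.sum_labels(rough, labels, index=np.arange(1, n + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    return BrainMask(mask=ndimage.binary_fill_holes(keep))


def scale_to_mean100(epi: EpiSeries, mask: BrainMask,
                     cap: float = 200.0) -> EpiSeries:
    """Scale each voxel time series to a temporal mean of 100.

    Values are capped at ``cap`` (default 200, i.e. +100% signal
    change); voxels with nonpositive mean are zeroed.  The data stay
    unmasked — every voxel with signal is scaled, the mask only defines
    where downstream statistics are computed.
    """
    mean = epi.data.mean(axis=3)
    scaled = np.zeros_like(epi.data)
    ok = mean > 0
    scaled[ok] = 100.0 * epi.data[ok] / mean[ok][..., None]
    np.clip(scaled, None, cap, out=scaled)
    return EpiSeries(grid=epi.grid, data=scaled, tr_s=epi.tr_s,
                     n_vols=epi.n_vols, slice_timing_s=epi.slice_timing_s,
                     datum=epi.datum, run_id=epi.run_id)


# --------------------------------------------------------------------------
# stimulus response basis
# --------------------------------------------------------------------------

def gamma_response(tau_s: np.ndarray) -> np.ndarray:
    """Peak-1 gamma impulse response, g(tau) = (tau/4)^4 exp(4 - tau)."""
    tau = np.asarray(tau_s, dtype=float)
    out = np.zeros_like(tau)
    pos = tau >= 0
    out[pos] = (tau[pos] / 4.0) ** 4 * np.exp(4.0 - tau[pos])
    return out

_FINE_DT = 0.05  # s, resolution of the convolution grid


def _block_response(duration_s: float, t_max_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized response to a single block of the given duration,
    on the fine grid starting at onset."""
    t = np.arange(0, t_max_s + _FINE_DT, _FINE_DT)
    g = gamma_response(t)
    n_on = max(1, int(round(duration_s / _FINE_DT)))
    box = np.zeros_like(t)
    box[:n_on] = 1.0
    resp = np.convolve(box, g)[: t.size] * _FINE_DT
    return t, resp


def block_response_peak(duration_s: float, t_max_s: float = 60.0) -> float:
    """Peak of the unnormalized block response for one duration."""
    _, resp = _block_response(duration_s, t_max_s)
    return float(resp.max())


@dataclass
class BasisConfig:
    """Design-matrix construction options."""

    motion_derivatives: bool = True
    polort: int | None = None          # None = 1 + floor(run_seconds/150)
    normalize_duration_s: float = 2.0  # block duration whose peak is 1


def _legendre_baseline(n_trs: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_trs)
    cols = [legendre.Legendre.basis(k)(x) for k in range(order + 1)]
    return np.column_stack(cols)


def _event_regressor(events, n_trs: int, tr_s: float,
                     norm_duration_s: float) -> tuple[np.ndarray, bool]:
    """Sampled duration-modulated response for one class in one run.

    Returns the regressor and a flag for events truncated at run end.
    """
    run_len_s = n_trs * tr_s
    amp = 1.0 / block_response_peak(norm_duration_s)
    t_fine = np.arange(0, run_len_s + 32.0, _FINE_DT)
    signal = np.zeros_like(t_fine)
    truncated = False
    for _, ev in events.iterrows():
        onset = float(ev["onset"])
        dur = float(ev["duration"])
        if onset >= run_len_s:
            truncated = True
            continue
        if onset + dur > run_len_s:
            truncated = True
            dur = run_len_s - onset
        _, resp = _block_response(max(dur, _FINE_DT), 32.0 + dur)
        i0 = int(round(onset / _FINE_DT))
        n = min(resp.size, signal.size - i0)
        signal[i0:i0 + n] += amp * resp[:n]
    sample = np.round(np.arange(n_trs) * tr_s / _FINE_DT).astype(int)
    return signal[sample], truncated


def build_design(epi_runs: list[EpiSeries], motion: MotionTrace,
                 events: list[EventTable] | None = None,
                 basis_cfg: BasisConfig | None = None) -> DesignMatrix:
    """Assemble baseline, motion and stimulus regressors over all runs.

    Baselines and motion regressors are per-run (zero outside their
    run); stimulus regressors for each class span runs, each run's
    segment built from that run's events.  Events extending past the
    run end are truncated with a warning.
    """
    import warnings

    cfg = basis_cfg or BasisConfig()
    n_per_run = [e.n_vols for e in epi_runs]
    total = sum(n_per_run)
    if motion.n_vols != total:
        raise ValueError(
            f"motion rows ({motion.n_vols}) do not match total TRs ({total})")
    if events is not None and len(events) != len(epi_runs):
        raise ValueError("need one event table per run")

    run_index = np.concatenate([np.full(n, i) for i, n in enumerate(n_per_run)])
    cols: list[np.ndarray] = []
    labels: list[str] = []
    groups: list[str] = []
    col_run: list[int | None] = []

    offsets = np.concatenate([[0], np.cumsum(n_per_run)])
    for r, epi in enumerate(epi_runs):
        run_seconds = epi.n_vols * epi.tr_s
        p = cfg.polort if cfg.polort is not None else 1 + int(run_seconds // 150)
        base = _legendre_baseline(epi.n_vols, p)
        for k in range(base.shape[1]):
            col = np.zeros(total)
            col[offsets[r]:offsets[r + 1]] = base[:, k]
            cols.append(col)
            labels.append(f"run{r + 1}_poly{k}")
            groups.append("baseline")
            col_run.append(r)

    # motion regressors are demeaned per run (their mean is baseline's
    # job); columns with no variation in a run are dropped rather than
    # left to make the design rank deficient
    mot_names = ["roll", "pitch", "yaw", "dS", "dL", "dP"]
    for r in range(len(epi_runs)):
        seg = motion.params[offsets[r]:offsets[r + 1]]
        blocks = [(seg, "")]
        if cfg.motion_derivatives:
            blocks.append((np.vstack([np.zeros(6), np.diff(seg, axis=0)]),
                           "d"))
        for block, prefix in blocks:
            centered = block - block.mean(axis=0)
            for k, name in enumerate(mot_names):
                if np.allclose(centered[:, k], 0.0):
                    continue
                col = np.zeros(total)
                col[offsets[r]:offsets[r + 1]] = centered[:, k]
                cols.append(col)
                labels.append(f"run{r + 1}_{prefix}{name}")
                groups.append("motion")
                col_run.append(r)

    if events is not None:
        classes = sorted({c for tab in events for c in tab.classes})
        for cls in classes:
            col = np.zeros(total)
            for r, (epi, tab) in enumerate(zip(epi_runs, events)):
                reg, truncated = _event_regressor(
                    tab.for_class(cls), epi.n_vols, epi.tr_s,
                    cfg.normalize_duration_s)
                if truncated:
                    warnings.warn(
                        f"{cls}: event(s) extend past end of run {r + 1}; "
                        "truncated", stacklevel=2)
                col[offsets[r]:offsets[r + 1]] = reg
            cols.append(col)
            labels.append(cls)
            groups.append("interest")
            col_run.append(None)

    return DesignMatrix(X=np.column_stack(cols), labels=labels, groups=groups,
                        run_index=run_index, column_run=col_run,
                        tr_s=epi_runs[0].tr_s)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _name_collinear_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    """Columns whose removal restores full rank (reported on failure)."""
    bad = []
    rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            bad.append(labels[j])
    return bad


def fit_glm(epi: EpiSeries | np.ndarray, X: DesignMatrix,
            censor: CensorVector | None = None,
            contrasts: list[ContrastSpec] | None = None) -> GLMFit:
    """Per-voxel OLS after deleting censored rows.

    ``full_f`` is the partial F statistic of the interest group against
    the baseline+motion reduced model (absent when there are no
    interest columns).  Contrast t statistics come from the coefficient
    covariance.  With (numerically) zero residual variance the F map is
    capped at ``F_CAP`` and flagged instead of returning NaN/inf.
    """
    data = epi.data if isinstance(epi, EpiSeries) else np.asarray(epi, float)
    if data.ndim == 2:   # (voxels, t) matrix input
        Y = data.T
        spatial_shape = (data.shape[0],)
    else:
        spatial_shape = data.shape[:3]
        Y = data.reshape(-1, data.shape[3]).T
    n = Y.shape[0]
    if n != X.n_rows:
        raise ValueError("data length does not match design rows")

    keep = (np.ones(n, dtype=int) if censor is None
            else np.asarray(censor.keep, dtype=int))
    if keep.size != n:
        raise ValueError("censor length does not match design rows")
    retained = np.flatnonzero(keep == 1)

    Xr = X.X[retained]
    Yr = Y[retained]
    rank = np.linalg.matrix_rank(Xr)
    if rank < Xr.shape[1]:
        bad = _name_collinear_columns(Xr, X.labels)
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient after censoring; "
            f"collinear columns: {bad}")
    if retained.size <= rank:
        raise ValueError("fewer retained TRs than design rank")

    beta, _, _, _ = np.linalg.lstsq(Xr, Yr, rcond=None)
    fitted = Xr @ beta
    resid = Yr - fitted
    df_remain = retained.size - rank
    rss = np.sum(resid ** 2, axis=0)
    sigma2 = rss / df_remain

    XtX_inv = np.linalg.pinv(Xr.T @ Xr)

    coef: dict[str, np.ndarray] = {}
    tstat: dict[str, np.ndarray] = {}
    interest_cols = X.columns_of("interest")
    for j in interest_cols:
        coef[X.labels[j]] = beta[j].reshape(spatial_shape)

    for spec in contrasts or []:
        c = np.zeros(X.X.shape[1])
        for name, w in spec.weights.items():
            if name not in X.labels:
                raise KeyError(f"contrast {spec.label!r} references unknown "
                               f"column {name!r}")
            c[X.labels.index(name)] = w
        est = c @ beta
        var = float(c @ XtX_inv @ c) * sigma2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, est / np.sqrt(var), 0.0)
        coef[spec.label] = est.reshape(spatial_shape)
        tstat[spec.label] = t.reshape(spatial_shape)

    full_f = None
    capped = False
    if interest_cols.size:
        reduced = np.delete(Xr, interest_cols, axis=1)
        beta_r, _, _, _ = np.linalg.lstsq(reduced, Yr, rcond=None)
        rss_r = np.sum((Yr - reduced @ beta_r) ** 2, axis=0)
        q = interest_cols.size
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_r - rss) / q) / (rss / df_remain)
        f = np.where(np.isfinite(f), f, F_CAP)
        if np.any(f >= F_CAP):
            capped = True
        full_f = np.clip(f, 0.0, F_CAP).reshape(spatial_shape)

    return GLMFit(
        coef=coef, tstat=tstat, full_f=full_f, full_f_capped=capped,
        fitted=fitted.T.reshape(spatial_shape + (retained.size,)),
        residuals=resid.T.reshape(spatial_shape + (retained.size,)),
        retained=retained,
        df_used=rank, df_remain=int(df_remain),
        df_fraction=df_remain / n, n_total_trs=n)
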