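"""Static QC report rendering.

Montages with transparent thresholding and cluster outlines, anatomical
edge overlays for alignment review, motion/regressor plots, the
residual grayplot, the warnings list and the quantitative summary
table, assembled into a per-subject HTML page with sidecar
ratings/comments JSON.

Transparent thresholding shows subthreshold overlay values with
increasing transparency instead of hiding them: per-pixel alpha is
``min(1, (|v|/threshold)^gamma)``, reaching full opacity at the
threshold, and suprathreshold clusters are outlined.  The full field
of view is always shown — nothing is masked away, so artifacts outside
the brain stay visible.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "TransparencySpec",
    "MontageSpec",
    "compute_alpha",
    "extract_edges",
    "grayplot_matrix",
    "render_overlay_montage",
    "render_edges_montage",
    "render_grayplot",
    "render_motion_plot",
    "build_report",
    "QC_BLOCKS",
]

QC_BLOCKS = ("vorig", "ve2a", "vstat", "mot", "regr", "radcor",
             "warns", "qsumm")

_PLANE_AXES = {"axial": 2, "sagittal": 0, "coronal": 1}


@dataclass
class TransparencySpec:
    """Alpha rule for overlay display."""

    threshold: float
    gamma: float = 2.0
    outline: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class MontageSpec:
    """Slice-montage layout."""

    plane: str = "axial"
    n_slices: int = 9
    percentile_range: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if self.plane not in _PLANE_AXES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def compute_alpha(values: np.ndarray, tspec: TransparencySpec) -> np.ndarray:
    """Per-value alpha: ``min(1, (|v|/threshold)^gamma)``."""
    return np.minimum(1.0, (np.abs(values) / tspec.threshold) ** tspec.gamma)


def _slice_positions(shape, axis: int, n_slices: int,
                     mask: np.ndarray | None) -> np.ndarray:
    if mask is not None and mask.any():
        idx = np.any(mask, axis=tuple(a for a in range(3) if a != axis))
        lo, hi = np.flatnonzero(idx)[[0, -1]]
    else:
        lo, hi = 0, shape[axis] - 1
    return np.unique(np.linspace(lo, hi, n_slices).round().astype(int))


def _take_slice(vol: np.ndarray, axis: int, index: int) -> np.ndarray:
    return np.take(vol, index, axis=axis).T  # transpose for display


def _cluster_outline(supra2d: np.ndarray) -> np.ndarray:
    """1-pixel boundary of suprathreshold clusters in a slice."""
    if not supra2d.any():
        return supra2d
    return supra2d & ~ndimage.binary_erosion(supra2d)


def render_overlay_montage(underlay: np.ndarray, overlay: np.ndarray | None,
                           tspec: TransparencySpec | None,
                           mspec: MontageSpec,
                           out_path: str | Path,
                           mask: np.ndarray | None = None,
                           title: str = "") -> Path:
    """Write a slice montage with a transparently-thresholded overlay.

    Slices are spaced evenly across the mask bounding box (full volume
    when no mask).  Suprathreshold clusters are outlined in black; the
    colorbar range is the in-mask percentile interval of the overlay
    (symmetric for signed maps).
    """
    underlay = np.asarray(underlay, float)
    if overlay is not None:
        overlay = np.asarray(overlay, float)
        if overlay.shape != underlay.shape:
            raise ValueError("underlay/overlay grids differ; resample first")
    axis = _PLANE_AXES[mspec.plane]
    positions = _slice_positions(underlay.shape, axis, mspec.n_slices, mask)

    ncol = min(len(positions), 3)
    nrow = int(np.ceil(len(positions) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow),
                             squeeze=False)
    vmax_u = np.percentile(underlay, 98) or 1.0

    if overlay is not None:
        region = overlay[mask] if (mask is not None and mask.any()) \
            else overlay.ravel()
        lo, hi = np.percentile(region, mspec.percentile_range)
        if (region < 0).any():
            bound = max(abs(lo), abs(hi)) or 1.0
            vmin_o, vmax_o = -bound, bound
            cmap = "coolwarm"
        else:
            vmin_o, vmax_o = 0.0, hi or 1.0
            cmap = "hot"

    im = None
    for ax, pos in zip(axes.ravel(), positions):
        ax.imshow(_take_slice(underlay, axis, pos), cmap="gray",
                  vmin=0, vmax=vmax_u, origin="lower")
        if overlay is not None:
            sl = _take_slice(overlay, axis, pos)
            if tspec is not None:
                alpha = compute_alpha(sl, tspec)
                im = ax.imshow(sl, cmap=cmap, vmin=vmin_o, vmax=vmax_o,
                               alpha=alpha, origin="lower")
                if tspec.outline:
                    edge = _cluster_outline(np.abs(sl) >= tspec.threshold)
                    yy, xx = np.nonzero(edge)
                    ax.plot(xx, yy, ".", color="black", markersize=0.8)
            else:
                im = ax.imshow(sl, cmap=cmap, vmin=vmin_o, vmax=vmax_o,
                               alpha=0.6, origin="lower")
        ax.set_title(f"{mspec.plane[:3]} {pos}", fontsize=6)
        ax.axis("off")
    for ax in axes.ravel()[len(positions):]:
        ax.axis("off")
    if im is not None:
        fig.colorbar(im, ax=axes, shrink=0.7)
    if title:
        fig.suptitle(title, fontsize=9)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=90)
    plt.close(fig)
    return out_path


def extract_edges(edge_source: np.ndarray,
                  mask: np.ndarray | None = None,
                  percentile: float = 90.0) -> np.ndarray:
    """Anatomical edge mask: gradient magnitude thresholded at its
    in-mask percentile, skeletonized to 1-voxel lines (slice-wise)."""
    src = np.asarray(edge_source, float)
    grads = np.gradient(src)
    gmag = np.sqrt(sum(g ** 2 for g in grads))
    region = gmag[mask] if (mask is not None and mask.any()) else \
        gmag[gmag > 0]
    if region.size == 0:
        return np.zeros_like(src, dtype=bool)
    thr = np.percentile(region, percentile)
    strong = gmag >= thr
    skel = np.zeros_like(strong)
    for k in range(src.shape[2]):
        skel[:, :, k] = morphology.skeletonize(strong[:, :, k])
    return skel


def render_edges_montage(underlay: np.ndarray, edge_source: np.ndarray,
                         out_path: str | Path,
                         mspec: MontageSpec | None = None,
                         mask: np.ndarray | None = None) -> Path:
    """EPI underlay with anatomical edges drawn on top — the
    alignment-review view.  Edges come from the edge source only, so
    bright rims in the underlay (e.g. CSF) cannot change them."""
    underlay = np.asarray(underlay, float)
    edge_source = np.asarray(edge_source, float)
    if edge_source.shape != underlay.shape:
        raise ValueError("volumes must share a grid; resample first")
    mspec = mspec or MontageSpec()
    edges = extract_edges(edge_source, mask)
    axis = _PLANE_AXES[mspec.plane]
    positions = _slice_positions(underlay.shape, axis, mspec.n_slices, mask)

    ncol = min(len(positions), 3)
    nrow = int(np.ceil(len(positions) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow),
                             squeeze=False)
    vmax_u = np.percentile(underlay, 98) or 1.0
    for ax, pos in zip(axes.ravel(), positions):
        ax.imshow(_take_slice(underlay, axis, pos), cmap="gray",
                  vmin=0, vmax=vmax_u, origin="lower")
        yy, xx = np.nonzero(_take_slice(edges, axis, pos))
        ax.plot(xx, yy, ".", color="orange", markersize=0.8)
        ax.axis("off")
    for ax in axes.ravel()[len(positions):]:
        ax.axis("off")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=90)
    plt.close(fig)
    return out_path


def grayplot_matrix(residuals: np.ndarray, mask: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Voxels x time matrix for the grayplot.

    Each in-mask voxel's residual series is demeaned and scaled by its
    own sd; rows are ordered by correlation with the mask-mean residual
    (descending).  Returns (matrix, row order into the masked voxels).
    """
    series = residuals[np.asarray(mask, bool)]
    z = series - series.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    ok = sd > 0
    z[ok] /= sd[ok][:, None]
    g = series.mean(axis=0)
    g = g - g.mean()
    gn = np.linalg.norm(g)
    # rows of z have norm sqrt(n); Pearson r = z.g / (sqrt(n) ||g||)
    corr = np.where(ok & (gn > 0),
                    (z @ g) / (np.sqrt(z.shape[1]) * max(gn, 1e-300)), 0.0)
    order = np.argsort(-corr, kind="stable")
    return z[order], order


def render_grayplot(residuals: np.ndarray, mask: np.ndarray,
                    out_path: str | Path,
                    censor_keep: np.ndarray | None = None) -> Path:
    """Voxels x time residual heatmap with censored TRs marked."""
    mat, _ = grayplot_matrix(residuals, mask)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.imshow(mat, aspect="auto", cmap="gray", vmin=-2.5, vmax=2.5,
              interpolation="nearest")
    if censor_keep is not None:
        for t in np.flatnonzero(np.asarray(censor_keep) == 0):
            ax.axvline(t, color="red", alpha=0.5, linewidth=0.8)
    ax.set_xlabel("TR")
    ax.set_ylabel("voxels (sorted)")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=90)
    plt.close(fig)
    return out_path


def render_motion_plot(enorm: np.ndarray, outfrac: np.ndarray,
                       out_path: str | Path,
                       censor_keep: np.ndarray | None = None,
                       L_motion: float = 0.2, L_out: float = 0.05) -> Path:
    fig, axes = plt.subplots(2, 1, figsize=(6, 3.5), sharex=True)
    axes[0].plot(enorm, lw=0.9)
    axes[0].axhline(L_motion, color="red", ls="--", lw=0.8)
    axes[0].set_ylabel("Enorm (mm)")
    axes[1].plot(outfrac, lw=0.9, color="tab:orange")
    axes[1].axhline(L_out, color="red", ls="--", lw=0.8)
    axes[1].set_ylabel("outlier frac")
    axes[1].set_xlabel("TR")
    if censor_keep is not None:
        for t in np.flatnonzero(np.asarray(censor_keep) == 0):
            for ax in axes:
                ax.axvspan(t - 0.5, t + 0.5, color="red", alpha=0.15, lw=0)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=90)
    plt.close(fig)
    return out_path


# --------------------------------------------------------------------------
# HTML assembly
# --------------------------------------------------------------------------

_BLOCK_TITLES = {
    "vorig": "Original data",
    "ve2a": "EPI-to-anatomical alignment",
    "vstat": "Statistics and seed maps",
    "mot": "Motion and censoring",
    "regr": "Regression modeling",
    "radcor": "Radial correlation",
    "warns": "Warnings",
    "qsumm": "Quantitative summary",
}


def build_report(out_dir: str | Path, subject_id: str,
                 block_images: dict[str, list[Path]] | None = None,
                 warns: list[str] | None = None,
                 qsumm: dict[str, object] | None = None,
                 ratings: dict[str, dict] | None = None) -> Path:
    """Assemble the per-subject QC page.

    Blocks appear in their fixed order; a block with no artifacts is
    rendered as "not computed".  Ratings/comments are serialized to a
    sidecar ``<subject>_ratings.json`` rather than embedded in HTML.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block_images = block_images or {}
    if not block_images and warns is None and qsumm is None:
        raise ValueError("at least one QC block's artifacts are required")

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>QC report: {html.escape(subject_id)}</title>",
        "<style>body{font-family:sans-serif;margin:2em}"
        "h2{border-bottom:1px solid #888}"
        "table{border-collapse:collapse}td,th{border:1px solid #bbb;"
        "padding:3px 8px}img{max-width:640px;display:block;margin:4px 0}"
        ".warn{color:#a00}</style></head><body>",
        f"<h1>QC report: {html.escape(subject_id)}</h1>",
    ]
    for block in QC_BLOCKS:
        parts.append(f"<h2 id='{block}'>{block} &mdash; "
                     f"{_BLOCK_TITLES[block]}</h2>")
        if block == "warns":
            if warns is None:
                parts.append("<p>not computed</p>")
            elif not warns:
                parts.append("<p>no warnings</p>")
            else:
                parts.append("<ul>" + "".join(
                    f"<li class='warn'>{html.escape(w)}</li>" for w in warns)
                    + "</ul>")
        elif block == "qsumm":
            if qsumm is None:
                parts.append("<p>not computed</p>")
            else:
                parts.append("<table><tr><th>key</th><th>value</th></tr>")
                for k, v in qsumm.items():
                    parts.append(f"<tr><td>{html.escape(str(k))}</td>"
                                 f"<td>{html.escape(str(v))}</td></tr>")
                parts.append("</table>")
        else:
            images = block_images.get(block, [])
            if not images:
                parts.append("<p>not computed</p>")
            for img in images:
                rel = Path(img).name
                parts.append(f"<img src='{html.escape(rel)}' alt='{block}'>")
    parts.append("</body></html>")

    html_path = out_dir / f"{subject_id}_qc.html"
    html_path.write_text("\n".join(parts))

    ratings_path = out_dir / f"{subject_id}_ratings.json"
    payload = {block: {"rating": None, "comment": ""} for block in QC_BLOCKS}
    for block, entry in (ratings or {}).items():
        payload[block] = entry
    ratings_path.write_text(json.dumps(payload, indent=2))
    return html_path
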