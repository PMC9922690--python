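"""Volume registration with selectable cost functions, and the
left-right flip check built on it.

Costs (lower is always better):

``ls``
    mean squared intensity difference over the overlap.
``nmi``
    negated normalized mutual information, ``-(H(A)+H(B))/H(A,B)``,
    from a 32x32 joint histogram.
``lpc`` / ``lpa``
    (absolute) local Pearson correlation over non-overlapping cubic
    blocks of the fixed grid: ``lpc = -sum(w_b r_b)/sum(w_b)`` and
    ``lpa = 1 - sum(w_b |r_b|)/sum(w_b)``, with ``r_b`` the Pearson
    correlation of the two images' intensities within block ``b`` and
    ``w_b`` the in-mask voxel count.  Blocks are cubes (edge 5 resampled
    voxels by default); blocks with fewer than 10 in-mask voxels are
    skipped.

Registration is deterministic: a multi-resolution schedule (downsample
x4, x2, x1) with a coarse grid search over translations at the coarsest
level followed by Nelder-Mead simplex refinement of all parameters.

The flip check registers both the original EPI reference and its
left-right mirror to the anatomical and compares the two best costs.
Because local-correlation costs are signed, the decision margin is
applied to the cost gap relative to the cost magnitude scale rather
than multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .dataio import AnatVolume, EpiSeries, deoblique_affine

__all__ = [
    "AffineTransform",
    "FlipResult",
    "CostError",
    "compute_cost",
    "register",
    "flip_check",
    "mirror_lr",
]

COSTS = ("ls", "nmi", "lpa", "lpc")


class CostError(RuntimeError):
    """Cost could not be evaluated (e.g. empty overlap)."""


# --------------------------------------------------------------------------
# transform model
# --------------------------------------------------------------------------

def _rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    rx, ry, rz = np.radians([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def params_to_matrix(params: np.ndarray, model: str,
                     center_mm: np.ndarray | None = None) -> np.ndarray:
    """4x4 mm-space map for a parameter vector.

    The matrix maps fixed-space mm coordinates to moving-space mm
    coordinates (the resampling direction).  Rotation/scale/shear act
    about ``center_mm`` (default: the origin).
    """
    params = np.asarray(params, dtype=float)
    if model == "rigid6":
        if params.size != 6:
            raise ValueError("rigid6 takes 6 parameters")
        A = _rotation_matrix(*params[:3])
    elif model == "affine12":
        if params.size != 12:
            raise ValueError("affine12 takes 12 parameters")
        R = _rotation_matrix(*params[:3])
        S = np.diag(params[6:9])
        H = np.array([[1, params[9], params[10]],
                      [0, 1, params[11]],
                      [0, 0, 1]], dtype=float)
        A = R @ S @ H
    else:
        raise ValueError(f"unknown transform model {model!r}")
    c = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = params[3:6] + c - A @ c
    return M


@dataclass
class AffineTransform:
    """Rigid (6-parameter) or full affine (12-parameter) mm-space map."""

    model: str
    params: np.ndarray
    matrix: np.ndarray
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    converged: bool = True

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        ref = params_to_matrix(self.params, self.model, self.center_mm)
        if not np.allclose(ref, self.matrix, atol=1e-6):
            raise ValueError("matrix inconsistent with parameters")

    @classmethod
    def identity(cls, model: str = "rigid6") -> "AffineTransform":
        n = 6 if model == "rigid6" else 12
        params = np.zeros(n)
        if model == "affine12":
            params[6:9] = 1.0
        return cls(model=model, params=params,
                   matrix=params_to_matrix(params, model))

    @classmethod
    def from_params(cls, params, model: str = "rigid6",
                    center_mm=None, converged: bool = True) -> "AffineTransform":
        center = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
        return cls(model=model, params=np.asarray(params, float),
                   matrix=params_to_matrix(params, model, center),
                   center_mm=center, converged=converged)


# --------------------------------------------------------------------------
# volumes and resampling
# --------------------------------------------------------------------------

def _as_volume(obj) -> tuple[np.ndarray, np.ndarray]:
    """Accept AnatVolume, EpiSeries (mean volume), (data, affine), or array."""
    if isinstance(obj, AnatVolume):
        return obj.data, obj.grid.affine
    if isinstance(obj, EpiSeries):
        return obj.data.mean(axis=3), obj.grid.affine
    if isinstance(obj, tuple) and len(obj) == 2:
        return np.asarray(obj[0], float), np.asarray(obj[1], float)
    arr = np.asarray(obj, float)
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")
    return arr, np.eye(4)


def _resample(moving: np.ndarray, mov_affine: np.ndarray,
              fixed_shape: tuple, fix_affine: np.ndarray,
              matrix_mm: np.ndarray) -> np.ndarray:
    """Sample the moving image on the fixed grid through a mm-space map.

    Returns NaN outside the moving volume's footprint.
    """
    # fixed voxel -> fixed mm -> moving mm -> moving voxel
    full = np.linalg.inv(mov_affine) @ matrix_mm @ fix_affine
    return ndimage.affine_transform(
        moving, full[:3, :3], offset=full[:3, 3],
        output_shape=tuple(fixed_shape), order=1,
        mode="constant", cval=np.nan)


def _volume_center_mm(shape, affine) -> np.ndarray:
    c_vox = (np.asarray(shape, float) - 1) / 2
    return (affine @ np.append(c_vox, 1.0))[:3]


# --------------------------------------------------------------------------
# cost functions
# --------------------------------------------------------------------------

def _nmi_cost(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    hab = entropy(p.ravel())
    if hab == 0:
        return -2.0  # both images constant on the overlap: degenerate
    return -(entropy(pa) + entropy(pb)) / hab


def _block_pearson_cost(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
                        block_edge: int, min_voxels: int,
                        absolute: bool) -> float:
    nx, ny, nz = a.shape
    num = 0.0
    den = 0.0
    for i0 in range(0, nx, block_edge):
        for j0 in range(0, ny, block_edge):
            for k0 in range(0, nz, block_edge):
                m = mask[i0:i0 + block_edge, j0:j0 + block_edge,
                         k0:k0 + block_edge]
                w = int(m.sum())
                if w < min_voxels:
                    continue
                x = a[i0:i0 + block_edge, j0:j0 + block_edge,
                      k0:k0 + block_edge][m]
                y = b[i0:i0 + block_edge, j0:j0 + block_edge,
                      k0:k0 + block_edge][m]
                sx = x.std()
                sy = y.std()
                if sx == 0 or sy == 0:
                    continue
                r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
                num += w * (abs(r) if absolute else r)
                den += w
    if den == 0:
        raise CostError("no usable blocks for local Pearson cost")
    return 1.0 - num / den if absolute else -num / den


def _fixed_mask(fixed: np.ndarray) -> np.ndarray:
    """Foreground mask of the fixed image for local-correlation blocks."""
    finite = np.isfinite(fixed)
    if not finite.any():
        return finite
    hi = np.percentile(fixed[finite], 95)
    return finite & (fixed > 0.05 * hi)


def compute_cost(moving, fixed, t: AffineTransform | None = None,
                 cost: str = "ls", block_edge: int = 5,
                 min_block_voxels: int = 10) -> float:
    """Evaluate an alignment cost for ``moving`` resampled onto ``fixed``.

    Lower is better for every cost.  Raises :class:`CostError` when the
    transformed volumes do not overlap.
    """
    if cost not in COSTS:
        raise ValueError(f"unknown cost {cost!r}; choose from {COSTS}")
    mov_data, mov_aff = _as_volume(moving)
    fix_data, fix_aff = _as_volume(fixed)
    if t is None:
        t = AffineTransform.identity()
    resamp = _resample(mov_data, mov_aff, fix_data.shape, fix_aff, t.matrix)
    valid = np.isfinite(resamp)
    if not valid.any():
        raise CostError("empty overlap between volumes")
    if cost == "ls":
        return float(np.mean((resamp[valid] - fix_data[valid]) ** 2))
    if cost == "nmi":
        return _nmi_cost(resamp[valid], fix_data[valid])
    mask = _fixed_mask(np.where(valid, fix_data, np.nan)) & valid
    return _block_pearson_cost(resamp, fix_data, mask, block_edge,
                               min_block_voxels, absolute=(cost == "lpa"))


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

def _downsample(data: np.ndarray, affine: np.ndarray, factor: int
                ) -> tuple[np.ndarray, np.ndarray]:
    if factor == 1:
        return data, affine
    sm = ndimage.uniform_filter(data, size=factor, mode="nearest")
    down = sm[::factor, ::factor, ::factor]
    aff = affine.copy()
    aff[:3, :3] = aff[:3, :3] * factor
    return down, aff


def register(moving, fixed, model: str = "rigid6", cost: str = "ls",
             levels: int = 3, shift_range_mm: float = 10.0,
             maxiter: int = 150) -> AffineTransform:
    """Find the transform minimizing ``cost`` for moving -> fixed.

    Deterministic multi-resolution scheme: at the coarsest level a grid
    search over translations within ``±shift_range_mm`` seeds a
    derivative-free Nelder-Mead refinement of all parameters, repeated
    at each finer level.  If the simplex does not converge within
    ``maxiter`` iterations at the finest level the best-found transform
    is returned with ``converged=False``.
    """
    mov_data, mov_aff = _as_volume(moving)
    fix_data, fix_aff = _as_volume(fixed)
    if mov_data.size == 0 or fix_data.size == 0:
        raise ValueError("empty volume")
    center = _volume_center_mm(fix_data.shape, fix_aff)

    n_par = 6 if model == "rigid6" else 12
    params = np.zeros(n_par)
    if model == "affine12":
        params[6:9] = 1.0

    factors = [2 ** (levels - 1 - i) for i in range(levels)]  # e.g. 4,2,1
    converged = True
    for li, factor in enumerate(factors):
        mv, mv_aff = _downsample(mov_data, mov_aff, factor)
        fx, fx_aff = _downsample(fix_data, fix_aff, factor)

        def objective(p):
            try:
                t = AffineTransform.from_params(p, model, center)
                resamp = _resample(mv, mv_aff, fx.shape, fx_aff, t.matrix)
                valid = np.isfinite(resamp)
                if valid.mean() < 0.05:
                    return 1e6
                if cost == "ls":
                    return float(np.mean((resamp[valid] - fx[valid]) ** 2))
                if cost == "nmi":
                    return _nmi_cost(resamp[valid], fx[valid])
                mask = _fixed_mask(np.where(valid, fx, np.nan)) & valid
                return _block_pearson_cost(resamp, fx, mask, 5, 10,
                                           absolute=(cost == "lpa"))
            except CostError:
                return 1e6

        if li == 0:
            step = float(np.max(np.linalg.norm(fx_aff[:3, :3], axis=0)))
            grid = np.arange(-shift_range_mm, shift_range_mm + 1e-9, step)
            best = (objective(params), params.copy())
            for tx in grid:
                for ty in grid:
                    for tz in grid:
                        trial = params.copy()
                        trial[3:6] = (tx, ty, tz)
                        c = objective(trial)
                        if c < best[0]:
                            best = (c, trial)
            params = best[1]

        # explicit initial simplex: sensible physical steps per parameter
        # (the default 5%-relative simplex collapses around zero params)
        steps = np.array([2.0, 2.0, 2.0, 2.0 * factor, 2.0 * factor,
                          2.0 * factor] + ([0.05, 0.05, 0.05,
                                            0.02, 0.02, 0.02]
                                           if n_par == 12 else []))
        simplex = np.vstack([params] + [params + steps[j] * np.eye(n_par)[j]
                                        for j in range(n_par)])
        res = optimize.minimize(
            objective, params, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 0.01 * factor,
                     "fatol": 1e-10, "initial_simplex": simplex})
        params = res.x
        if li == len(factors) - 1:
            converged = bool(res.success)

    return AffineTransform.from_params(params, model, center,
                                       converged=converged)


# --------------------------------------------------------------------------
# flip check
# --------------------------------------------------------------------------

@dataclass
class FlipResult:
    """Outcome of the left-right flip check."""

    cost_orig: float
    cost_flipped: float
    guess: str  # NO_FLIP | DO_FLIP | UNCERTAIN
    warn_level: str  # none | medium | severe

    def __post_init__(self) -> None:
        if self.guess not in ("NO_FLIP", "DO_FLIP", "UNCERTAIN"):
            raise ValueError(f"bad flip guess {self.guess!r}")


def mirror_lr(data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Mirror a volume about the grid's mid-sagittal plane.

    The left-right voxel axis is the one whose affine column has the
    dominant x (RAS) component; flipping indices along it mirrors the
    image in mm about the grid center plane (grids are deobliqued first,
    so columns are axis-aligned).
    """
    aff = deoblique_affine(affine)
    lr_axis = int(np.argmax(np.abs(aff[0, :3])))
    return np.flip(data, axis=lr_axis).copy()


def flip_check(epi_ref, anat, cost: str = "lpc", margin_rel: float = 0.05,
               levels: int = 3, maxiter: int = 200,
               shift_range_mm: float = 6.0,
               out_dir: str | Path | None = None) -> FlipResult:
    """Check for a left-right flip between the EPI and the anatomical.

    Registers both the original EPI reference and its left-right mirror
    to the anatomical, then compares the achieved costs.  Let
    ``gap = cost_orig - cost_flipped`` and ``scale`` the larger cost
    magnitude: DO_FLIP when ``gap > margin_rel*scale``, NO_FLIP when
    ``gap < -margin_rel*scale``, otherwise UNCERTAIN with a medium
    warning (the two branches are too close to call).  A registration
    failure on either branch yields UNCERTAIN with a severe warning.
    """
    if margin_rel <= 0:
        raise ValueError("margin_rel must be positive")
    epi_data, epi_aff = _as_volume(epi_ref)
    mirrored = mirror_lr(epi_data, epi_aff)

    costs = []
    failed = False
    for data in (epi_data, mirrored):
        try:
            t = register((data, epi_aff), anat, model="rigid6", cost=cost,
                         levels=levels, maxiter=maxiter,
                         shift_range_mm=shift_range_mm)
            c = compute_cost((data, epi_aff), anat, t, cost=cost)
        except (CostError, ValueError):
            c = np.nan
            failed = True
        costs.append(c)
    cost_orig, cost_flipped = costs

    if failed or not np.isfinite(costs).all():
        result = FlipResult(cost_orig=float(cost_orig),
                            cost_flipped=float(cost_flipped),
                            guess="UNCERTAIN", warn_level="severe")
    else:
        gap = cost_orig - cost_flipped
        scale = max(abs(cost_orig), abs(cost_flipped), 1e-12)
        if gap > margin_rel * scale:
            result = FlipResult(cost_orig, cost_flipped, "DO_FLIP", "medium")
        elif gap < -margin_rel * scale:
            result = FlipResult(cost_orig, cost_flipped, "NO_FLIP", "none")
        else:
            result = FlipResult(cost_orig, cost_flipped, "UNCERTAIN", "medium")

    if out_dir is not None:
        _render_flip_images(epi_data, mirrored, _as_volume(anat)[0],
                            Path(out_dir))
    return result


def _render_flip_images(orig: np.ndarray, mirrored: np.ndarray,
                        anat: np.ndarray, out_dir: Path) -> None:
    """Side-by-side axial midslices for visual verification."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    for name, vol in (("epi_orig", orig), ("epi_flipped", mirrored)):
        fig, axes = plt.subplots(1, 2, figsize=(6, 3))
        axes[0].imshow(vol[:, :, vol.shape[2] // 2].T, origin="lower",
                       cmap="gray")
        axes[0].set_title(name)
        axes[1].imshow(anat[:, :, anat.shape[2] // 2].T, origin="lower",
                       cmap="gray")
        axes[1].set_title("anat")
        for ax in axes:
            ax.axis("off")
        fig.savefig(out_dir / f"flipcheck_{name}.png", dpi=80)
        plt.close(fig)
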