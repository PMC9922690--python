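"""Core dataset model and on-disk formats.

Every other module consumes the containers defined here: 4D EPI time
series and 3D anatomicals (NIfTI-1 via nibabel), rigid-body motion
parameter tables, event timing tables (BIDS ``events.tsv`` or a simple
columnar dialect), and per-TR censor vectors.

Conventions
-----------
* Motion parameter columns are ordered as three rotations in **degrees**
  (roll, pitch, yaw) followed by three translations in **mm**
  (dS, dL, dP).  The Euclidean-norm motion metric mixes these units
  as-is, so the order is load-bearing.
* Voxel indices are 0-based; mm coordinates follow the NIfTI RAS+
  convention of the affine.  Left/posterior/inferior labels such as
  ``"5L, 49P, 40S"`` are converted explicitly (see
  :func:`parse_coordinate_label`).
* ``scl_slope``/``scl_inter`` scaling is applied on load; ``datum``
  records the on-disk storage type.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "EpiSeries",
    "AnatVolume",
    "MotionTrace",
    "EventTable",
    "CensorVector",
    "FormatError",
    "DimensionalityError",
    "load_epi",
    "load_anat",
    "load_motion",
    "load_events",
    "load_censor",
    "save_epi",
    "save_anat",
    "save_censor",
    "save_motion",
    "orientation_from_affine",
    "obliquity_deg_from_affine",
    "deoblique_affine",
    "parse_coordinate_label",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class DimensionalityError(FormatError):
    """An image has the wrong number of dimensions for the requested role."""


# --------------------------------------------------------------------------
# grid geometry helpers
# --------------------------------------------------------------------------

def orientation_from_affine(affine: np.ndarray) -> str:
    """Three-letter axis code (e.g. ``RAS``, ``LPI``) for an affine.

    Each letter names the anatomical direction toward which the
    corresponding voxel axis points, per nibabel's axis-code convention.
    """
    return "".join(nib.orientations.aff2axcodes(affine))


def obliquity_deg_from_affine(affine: np.ndarray) -> float:
    """Largest angle (degrees) between a voxel axis and its nearest
    cardinal anatomical axis.  0 for axis-aligned grids."""
    R = np.asarray(affine, dtype=float)[:3, :3]
    norms = np.linalg.norm(R, axis=0)
    if np.any(norms == 0):
        raise ValueError("affine has a zero column")
    cosines = np.max(np.abs(R / norms), axis=0)
    ang = np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
    ang_max = float(np.max(ang))
    return 0.0 if ang_max < np.degrees(1e-4) else ang_max


def deoblique_affine(affine: np.ndarray) -> np.ndarray:
    """Replace the rotation part by the nearest axis-aligned matrix,
    preserving voxel sizes and the coordinate origin."""
    A = np.asarray(affine, dtype=float).copy()
    R = A[:3, :3]
    norms = np.linalg.norm(R, axis=0)
    out = np.zeros_like(R)
    for j in range(3):
        i = int(np.argmax(np.abs(R[:, j])))
        out[i, j] = np.sign(R[i, j]) * norms[j]
    A[:3, :3] = out
    return A


_LABEL_SIGNS = {"R": (0, +1), "L": (0, -1), "A": (1, +1), "P": (1, -1),
                "S": (2, +1), "I": (2, -1)}


def parse_coordinate_label(label: str) -> np.ndarray:
    """Convert a label like ``"5L, 49P, 40S"`` to RAS+ mm coordinates.

    Returns a length-3 array (x, y, z) where x is toward the right,
    y anterior and z superior.
    """
    parts = [p.strip() for p in label.split(",")]
    if len(parts) != 3:
        raise ValueError(f"expected three comma-separated terms: {label!r}")
    xyz = np.full(3, np.nan)
    for p in parts:
        m = re.fullmatch(r"([-+]?\d+(?:\.\d+)?)\s*([RLAPSI])", p)
        if not m:
            raise ValueError(f"cannot parse coordinate term {p!r}")
        value = float(m.group(1))
        axis, sign = _LABEL_SIGNS[m.group(2)]
        if not np.isnan(xyz[axis]):
            raise ValueError(f"axis specified twice in {label!r}")
        xyz[axis] = sign * value
    if np.any(np.isnan(xyz)):
        raise ValueError(f"label {label!r} does not cover all three axes")
    return xyz


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """Geometry of a 3D voxel grid: dims, spacing, orientation, affine."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    orientation: str
    affine: np.ndarray
    obliquity_deg: float
    qform_code: int = 0
    sform_code: int = 0

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 in every axis")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @classmethod
    def from_affine(cls, dims: Sequence[int], affine: np.ndarray,
                    qform_code: int = 0, sform_code: int = 0) -> "VolumeGrid":
        affine = np.asarray(affine, dtype=float)
        vox = tuple(float(v) for v in np.linalg.norm(affine[:3, :3], axis=0))
        return cls(
            dims=tuple(int(d) for d in dims),
            voxel_size_mm=vox,
            orientation=orientation_from_affine(affine),
            affine=affine,
            obliquity_deg=obliquity_deg_from_affine(affine),
            qform_code=int(qform_code),
            sform_code=int(sform_code),
        )

    @property
    def oblique(self) -> bool:
        return self.obliquity_deg > 0.0

    def mm_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Map RAS+ mm coordinates to (fractional) voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz_mm = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        homog = np.c_[xyz_mm, np.ones(len(xyz_mm))]
        return np.squeeze((homog @ inv.T)[:, :3])

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return np.squeeze((homog @ self.affine.T)[:, :3])


@dataclass
class EpiSeries:
    """A 4D EPI run: voxel grid, data (x, y, z, t), TR and header metadata."""

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float
    n_vols: int
    slice_timing_s: list[float] | None = None
    datum: str = "float32"
    run_id: str = "run-01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionalityError("EPI data must be 4D (x, y, z, t)")
        if self.data.shape[3] != self.n_vols:
            raise ValueError("time dimension does not match n_vols")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.slice_timing_s is not None:
            if len(self.slice_timing_s) != self.grid.dims[2]:
                raise ValueError("slice timing length must equal nz")
            if any(t < 0 or t >= self.tr_s for t in self.slice_timing_s):
                raise ValueError("slice timing offsets must lie in [0, TR)")

    @property
    def duration_s(self) -> float:
        return self.n_vols * self.tr_s


@dataclass
class AnatVolume:
    """A 3D anatomical volume on its grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError("anatomical data must be 3D")
        if self.data.shape != tuple(self.grid.dims):
            raise ValueError("data shape does not match grid dims")


@dataclass
class MotionTrace:
    """Per-TR rigid-body motion estimates: 3 rotations (deg), 3 translations (mm)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise FormatError(
                f"motion table must have 6 columns, got {self.params.shape[1]}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_vols(self) -> int:
        return self.params.shape[0]


@dataclass
class EventTable:
    """Stimulus events for one run: onset, duration, class label, response time."""

    events: pd.DataFrame
    run_id: str = "run-01"

    COLUMNS = ("onset", "duration", "trial_type", "response_time")

    def __post_init__(self) -> None:
        df = self.events.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col == "response_time" else None
        df = df[list(self.COLUMNS)]
        if len(df):
            if (df["onset"] < 0).any():
                raise ValueError("negative event onset")
            if not np.all(np.isfinite(df["duration"].to_numpy(dtype=float))):
                raise ValueError("event durations must be finite")
            df = df.sort_values("onset", kind="stable").reset_index(drop=True)
        self.events = df

    def __len__(self) -> int:
        return len(self.events)

    @property
    def classes(self) -> list[str]:
        return sorted(self.events["trial_type"].dropna().unique().tolist())

    def for_class(self, label: str) -> pd.DataFrame:
        return self.events[self.events["trial_type"] == label]


@dataclass
class CensorVector:
    """Per-TR keep flags: 1 = retained, 0 = censored."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=int)
        if self.keep.ndim != 1:
            raise ValueError("censor vector must be 1D")
        if not np.isin(self.keep, (0, 1)).all():
            raise ValueError("censor values must be 0 or 1")

    @property
    def n_vols(self) -> int:
        return self.keep.size

    @property
    def n_censored(self) -> int:
        return int(self.keep.size - self.keep.sum())

    @property
    def censor_fraction(self) -> float:
        return self.n_censored / self.keep.size

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep == 1)


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various ImageFileErrors
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path} is not a NIfTI-1/2 image")
    return img


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    hdr = img.header
    return VolumeGrid.from_affine(
        dims=img.shape[:3],
        affine=img.affine,
        qform_code=int(hdr["qform_code"]),
        sform_code=int(hdr["sform_code"]),
    )


def _slice_timing(img: nib.Nifti1Image, tr_s: float) -> list[float] | None:
    try:
        times = img.header.get_slice_times()
    except Exception:
        return None
    times = [float(t) for t in times]
    if not times or any(t < 0 or t >= tr_s for t in times):
        return None
    return times


def load_epi(path: str | Path, run_id: str | None = None) -> EpiSeries:
    """Load a 3D+time NIfTI as an :class:`EpiSeries`.

    Raises :class:`DimensionalityError` for a 3D-only file (the caller
    may load it with :func:`load_anat` instead) and :class:`FormatError`
    for non-NIfTI inputs.  Intensity scaling (``scl_slope``/``scl_inter``)
    is applied; ``datum`` records the on-disk storage type.
    """
    img = _load_nifti(path)
    if img.ndim != 4:
        raise DimensionalityError(
            f"{path}: expected a 4D time series, got {img.ndim}D")
    tr_s = float(img.header.get_zooms()[3])
    if tr_s <= 0:
        tr_s = 1.0  # header without timing info; document as fallback
    return EpiSeries(
        grid=_grid_from_img(img),
        data=np.asarray(img.get_fdata(), dtype=float),
        tr_s=tr_s,
        n_vols=img.shape[3],
        slice_timing_s=_slice_timing(img, tr_s),
        datum=img.get_data_dtype().name,
        run_id=run_id or Path(path).name.split(".")[0],
    )


def load_anat(path: str | Path, deoblique: bool = False) -> AnatVolume:
    """Load a 3D anatomical NIfTI.

    With ``deoblique=True`` the affine's rotation part is replaced by the
    nearest axis-aligned matrix (origin preserved); this is always an
    explicit choice, never silent.
    """
    img = _load_nifti(path)
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D anatomical, got {img.ndim}D")
    grid = _grid_from_img(img)
    if deoblique and grid.oblique:
        grid = VolumeGrid.from_affine(
            grid.dims, deoblique_affine(grid.affine),
            grid.qform_code, grid.sform_code)
    return AnatVolume(grid=grid, data=np.asarray(img.get_fdata(), dtype=float))


def save_epi(epi: EpiSeries, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(epi.data.astype(dtype), epi.grid.affine)
    img.header.set_zooms((*epi.grid.voxel_size_mm, epi.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def save_anat(anat: AnatVolume, path: str | Path, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(anat.data.astype(dtype), anat.grid.affine), str(path))


# --------------------------------------------------------------------------
# text-table I/O
# --------------------------------------------------------------------------

def load_motion(path: str | Path) -> MotionTrace:
    """Read a whitespace-delimited 6-column motion parameter file.

    Lines starting with ``#`` are comments.  Column order: roll, pitch,
    yaw (degrees), then dS, dL, dP (mm).
    """
    try:
        arr = np.loadtxt(str(path), comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric table: {exc}") from exc
    if arr.shape[1] != 6:
        raise FormatError(
            f"{path}: motion file must have 6 columns, got {arr.shape[1]}")
    return MotionTrace(params=arr)


def save_motion(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), trace.params, fmt="%.6f")


def load_censor(path: str | Path) -> CensorVector:
    """Read a single-column 0/1 censor file (1 = keep)."""
    arr = np.loadtxt(str(path), comments="#", ndmin=2)
    if arr.shape[1] != 1:
        raise FormatError(
            f"{path}: censor file must have a single column, got {arr.shape[1]}")
    return CensorVector(keep=arr[:, 0])


def save_censor(censor: CensorVector, path: str | Path) -> None:
    np.savetxt(str(path), censor.keep[:, None], fmt="%d")


DEFAULT_DURATION_MAX_S = {"Task": 4.0, "Control": 2.0}


def _apply_duration_rule(df: pd.DataFrame, duration_rule: str,
                         max_s: dict[str, float]) -> pd.DataFrame:
    if duration_rule == "column":
        return df
    if duration_rule != "response_time_clipped":
        raise ValueError(f"unknown duration rule {duration_rule!r}")
    out = df.copy()
    out["duration"] = out["duration"].astype(float)
    for i, row in out.iterrows():
        cap = max_s.get(row["trial_type"], row["duration"])
        rt = row.get("response_time", np.nan)
        if pd.notna(rt) and float(rt) <= cap:
            out.at[i, "duration"] = float(rt)
        else:
            out.at[i, "duration"] = cap
    return out


def load_events(path: str | Path, dialect: str = "bids",
                duration_rule: str = "column",
                duration_max_s: dict[str, float] | None = None,
                run_id: str | None = None,
                default_duration_s: float = 0.0,
                class_label: str = "Task") -> EventTable:
    """Read an event timing file.

    Parameters
    ----------
    dialect:
        ``"bids"`` — tab-separated with onset/duration/trial_type columns
        (response_time optional); ``"columnar"`` — one run per line, each
        token ``onset`` or ``onset:duration`` (a bare onset takes
        ``default_duration_s``), all events assigned ``class_label``.
    duration_rule:
        ``"column"`` uses the duration column as-is.
        ``"response_time_clipped"`` sets duration to the response time
        when present and no larger than the class maximum, else to the
        class maximum (defaults: Task 4 s, Control 2 s).
    """
    path = Path(path)
    max_s = dict(DEFAULT_DURATION_MAX_S if duration_max_s is None
                 else duration_max_s)
    if dialect == "bids":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["onset", "duration", "trial_type"])
        for col in ("onset", "duration", "trial_type"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        if "response_time" in df.columns:
            df["response_time"] = pd.to_numeric(df["response_time"],
                                                errors="coerce")
        df = _apply_duration_rule(df, duration_rule, max_s)
    elif dialect == "columnar":
        text = path.read_text()
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for tok in line.split():
                if tok in ("*", "-1:1"):  # conventional empty-run markers
                    continue
                if ":" in tok:
                    onset_s, dur_s = tok.split(":", 1)
                else:
                    onset_s, dur_s = tok, str(default_duration_s)
                try:
                    rows.append({"onset": float(onset_s),
                                 "duration": float(dur_s),
                                 "trial_type": class_label})
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: bad timing token {tok!r}") from exc
            break  # single-run reader; one line per run
        df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    else:
        raise ValueError(f"unknown events dialect {dialect!r}")
    return EventTable(events=df, run_id=run_id or path.name.split(".")[0])


def save_events_bids(table: EventTable, path: str | Path) -> None:
    df = table.events.copy()
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="n/a")
    Path(path).write_text(buf.getvalue())
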