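"""Seeded synthetic-data generator: anatomical phantoms, 4D EPI with
controllable artifacts, motion schedules, correlated "network" signals
and task responses, plus matching event tables and ground truth.

The generator emulates the ingredients a QC pipeline must detect:

* an ellipsoidal head with internal structure and a deliberately
  left-right-asymmetric feature (so flip checks are decidable);
* EPI runs at baseline 100 with slow polynomial drift and AR(1) noise;
* spatially coherent latent "network" signals with a controllable
  global-correlation footprint;
* rigid-body motion (slow wander and step spikes), Nyquist ghosting
  (a half-FOV shifted copy along the phase-encode axis), regional
  signal dropout, pre-steady-state leading volumes, and whole-volume
  left-right flips;
* task responses built from the same duration-modulated basis the
  modeling module uses, with known betas.

Everything is deterministic per seed; the returned
:class:`TruthRecord` carries the exact motion, betas, masks and
artifact inventory for parameter-recovery tests.

Default conditions: TR 2 s, 150 volumes, 3 mm voxels, baseline 100,
noise sd 2 (percent-signal units, i.e. voxelwise tSNR around 50) and
AR(1) rho 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dataio import AnatVolume, EpiSeries, EventTable, MotionTrace, VolumeGrid
from .regmodel import _event_regressor

__all__ = [
    "NetworkBlob",
    "GhostSpec",
    "DropoutSpec",
    "PreSteadySpec",
    "PhantomSpec",
    "TruthRecord",
    "make_anat_phantom",
    "make_epi",
    "make_events",
    "step_motion",
    "latent_sd_for_gcor",
    "centered_affine",
]


def centered_affine(dims, voxel_size_mm) -> np.ndarray:
    """RAS+ axis-aligned affine with the grid center at the mm origin."""
    dims = np.asarray(dims, float)
    vox = np.asarray(voxel_size_mm, float)
    aff = np.diag([*vox, 1.0])
    aff[:3, 3] = -(dims - 1) / 2.0 * vox
    return aff


@dataclass
class NetworkBlob:
    """A spherical region sharing one latent time course."""

    center_vox: tuple[float, float, float]
    radius_vox: float
    latent_sd: float


@dataclass
class GhostSpec:
    amplitude_frac: float = 0.1   # fraction of the signal copied
    pe_axis: int = 1              # phase-encode axis

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude_frac < 1.0):
            raise ValueError("ghost amplitude fraction must be in [0, 1)")


@dataclass
class DropoutSpec:
    center_vox: tuple[float, float, float]
    radius_vox: float
    attenuation: float = 0.3      # multiplier inside the region


@dataclass
class PreSteadySpec:
    n_trs: int = 3
    gain: float = 1.4             # intensity factor on the leading TRs


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject."""

    dims: tuple[int, int, int] = (20, 20, 14)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_vols: int = 150
    tr_s: float = 2.0
    baseline: float = 100.0
    drift_coefs: tuple[float, ...] = (0.0, 1.0)   # Legendre-style, % units
    noise_sd: float = 2.0
    ar1_rho: float = 0.3
    blobs: list[NetworkBlob] = field(default_factory=list)
    motion: np.ndarray | None = None              # (n_vols, 6) schedule
    ghost: GhostSpec | None = None
    dropout: DropoutSpec | None = None
    pre_steady: PreSteadySpec | None = None
    flip: bool = False
    events: list[EventTable] | None = None        # single-run: one table
    betas: dict[str, float] = field(default_factory=dict)  # % signal change

    # anatomical phantom geometry
    anat_dims: tuple[int, int, int] = (24, 24, 18)
    anat_voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("AR(1) rho must lie in (-1, 1)")
        for b in self.blobs:
            c = np.asarray(b.center_vox, float)
            if np.any(c < 0) or np.any(c >= np.asarray(self.dims, float)):
                raise ValueError("network blob center outside grid")
        if self.motion is not None:
            motion = np.asarray(self.motion, float)
            if motion.shape != (self.n_vols, 6):
                raise ValueError("motion schedule must be (n_vols, 6)")


@dataclass
class TruthRecord:
    """Ground truth for one generated subject."""

    seed: int
    motion: np.ndarray
    betas: dict[str, float]
    blob_masks: dict[int, np.ndarray]
    head_mask: np.ndarray
    artifacts: dict[str, object]
    flip: bool


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _ellipsoid(dims, center_frac=(0.5, 0.5, 0.5), semi_frac=(0.4, 0.42, 0.38)
               ) -> np.ndarray:
    dims = np.asarray(dims, float)
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    c = center_frac * dims
    a = semi_frac * dims
    q = sum(((g - ci) / ai) ** 2 for g, ci, ai in zip(grids, c, a))
    return q <= 1.0


def _sphere(dims, center, radius) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    q = sum((g - ci) ** 2 for g, ci in zip(grids, center))
    return q <= radius ** 2


def _asymmetric_feature(dims, head: np.ndarray) -> np.ndarray:
    """A block on the left half of the head only (x = first axis,
    RAS affine puts low indices on the left)."""
    nx, ny, nz = dims
    feat = np.zeros(dims, dtype=bool)
    feat[max(nx // 8, 1): nx // 3,
         ny // 3: 2 * ny // 3,
         nz // 3: 2 * nz // 3] = True
    return feat & head


def _anterior_feature(dims, head: np.ndarray) -> np.ndarray:
    """A band in the anterior third of the head (y = second axis).

    Together with the left-lateral feature this makes the phantom
    asymmetric in two axes, so a left-right mirror cannot be imitated
    by any rigid rotation — a property real heads have (frontal vs
    occipital anatomy) and flip detection depends on.
    """
    nx, ny, nz = dims
    feat = np.zeros(dims, dtype=bool)
    feat[nx // 3: 2 * nx // 3,
         3 * ny // 4:,
         nz // 4: 3 * nz // 4] = True
    return feat & head


def _head_profile(dims, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Intensity profile in [0, ~1.35] plus the head mask."""
    head = _ellipsoid(dims)
    inner = _ellipsoid(dims, semi_frac=(0.12, 0.12, 0.12))
    feat = _asymmetric_feature(dims, head)
    texture = ndimage.gaussian_filter(rng.standard_normal(dims), 1.5)
    profile = np.where(head, 1.0 + 0.1 * texture, 0.0)
    profile[inner & head] *= 0.55          # ventricle stand-in
    profile[feat] *= 1.35                  # left-lateralized bright feature
    profile[_anterior_feature(dims, head)] *= 0.65  # frontal dark band
    return profile, head


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def make_anat_phantom(spec: PhantomSpec, seed: int) -> AnatVolume:
    """Ellipsoidal anatomical phantom with internal structure and a
    left-right-asymmetric feature; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    profile, _ = _head_profile(spec.anat_dims, rng)
    data = 1000.0 * profile
    grid = VolumeGrid.from_affine(
        spec.anat_dims, centered_affine(spec.anat_dims,
                                        spec.anat_voxel_size_mm),
        qform_code=1, sform_code=1)
    return AnatVolume(grid=grid, data=data)


def step_motion(n_vols: int, spikes: list[tuple[int, np.ndarray]] | None = None,
                wander_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Motion schedule: optional slow random-walk wander plus
    persistent step displacements at given TRs.

    A step at TR ``t`` shifts the parameters from ``t`` onward, so the
    Euclidean-norm series shows a single spike at ``t``.
    """
    rng = np.random.default_rng(seed)
    params = np.zeros((n_vols, 6))
    if wander_sd > 0:
        steps = rng.normal(0.0, wander_sd, size=(n_vols, 6))
        steps[0] = 0.0
        params = np.cumsum(steps, axis=0)
    for t, delta in spikes or []:
        params[t:] += np.asarray(delta, float)
    return params


def latent_sd_for_gcor(target_gcor: float, noise_sd: float,
                       blob_fraction: float) -> float:
    """Latent-signal sd for a single blob to hit a target GCOR.

    With a fraction ``f`` of mask voxels sharing latent signal of
    variance ``s^2`` on top of independent noise of variance ``n^2``,
    the pairwise correlation inside the blob is ``s^2/(s^2+n^2)`` and
    GCOR is approximately ``f^2`` times that, so
    ``s^2 = t n^2 / (f^2 - t)``.
    """
    f2 = blob_fraction ** 2
    if target_gcor >= f2:
        raise ValueError("target GCOR unreachable with this blob fraction")
    return float(noise_sd * np.sqrt(target_gcor / (f2 - target_gcor)))


def _ar1_noise(rng, shape_v, n_vols, sd, rho) -> np.ndarray:
    if sd == 0:
        return np.zeros((shape_v, n_vols))
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    e = rng.normal(0.0, innov_sd, size=(shape_v, n_vols))
    noise = np.empty_like(e)
    noise[:, 0] = rng.normal(0.0, sd, size=shape_v)
    for t in range(1, n_vols):
        noise[:, t] = rho * noise[:, t - 1] + e[:, t]
    return noise


def _apply_motion(volume: np.ndarray, params: np.ndarray,
                  voxel_size_mm) -> np.ndarray:
    """Resample one volume by a rigid 6-parameter motion state
    (rotations in degrees about the grid center, translations in mm)."""
    if not np.any(params):
        return volume
    rx, ry, rz = np.radians(params[:3])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    vox = np.asarray(voxel_size_mm, float)
    center = (np.asarray(volume.shape, float) - 1) / 2.0
    # voxel-space map: scale to mm, rotate+translate, scale back
    S = np.diag(vox)
    Sinv = np.diag(1.0 / vox)
    A = Sinv @ R @ S
    shift_vox = Sinv @ params[3:6]
    offset = center - A @ center - shift_vox
    return ndimage.affine_transform(volume, np.linalg.inv(A),
                                    offset=np.linalg.inv(A) @ -offset,
                                    order=1, mode="constant", cval=0.0)


def make_epi(spec: PhantomSpec, seed: int) -> tuple[EpiSeries, TruthRecord]:
    """Generate one EPI run and its ground truth.

    Construction order: static head profile at the baseline level, plus
    polynomial drift, network latent signals, task responses and AR(1)
    noise; then per-TR rigid resampling by the motion schedule; then
    ghosting, dropout, pre-steady-state gain and optional left-right
    flip.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    dims = spec.dims
    n = spec.n_vols

    profile, head = _head_profile(dims, rng)
    data = np.empty(dims + (n,))
    base = spec.baseline * profile

    # slow drift, percent of baseline, shared across the head
    x = np.linspace(-1.0, 1.0, n)
    drift = np.zeros(n)
    for k, c in enumerate(spec.drift_coefs):
        if k > 0:   # constant term lives in `baseline`
            drift += c * np.polynomial.legendre.Legendre.basis(k)(x)
    data[:] = base[..., None] + (profile[..., None] *
                                 (spec.baseline / 100.0) * drift[None, None,
                                                                 None, :])

    blob_masks: dict[int, np.ndarray] = {}
    for bi, blob in enumerate(spec.blobs):
        bmask = _sphere(dims, blob.center_vox, blob.radius_vox) & head
        blob_masks[bi] = bmask
        latent = rng.normal(0.0, blob.latent_sd, size=n)
        data[bmask] += (spec.baseline / 100.0) * latent[None, :]

    if spec.events is not None:
        for tab in spec.events:
            for cls in tab.classes:
                beta = spec.betas.get(cls, 0.0)
                if beta == 0.0:
                    continue
                reg, _ = _event_regressor(tab.for_class(cls), n, spec.tr_s,
                                          norm_duration_s=2.0)
                data[head] += (spec.baseline / 100.0) * beta * reg[None, :]

    noise = _ar1_noise(rng, int(head.sum()), n, spec.noise_sd, spec.ar1_rho)
    data[head] += (spec.baseline / 100.0) * noise

    motion = (np.zeros((n, 6)) if spec.motion is None
              else np.asarray(spec.motion, float))
    if np.any(motion):
        for t in range(n):
            data[..., t] = _apply_motion(data[..., t], motion[t],
                                         spec.voxel_size_mm)

    artifacts: dict[str, object] = {}
    if spec.ghost is not None:
        shift = dims[spec.ghost.pe_axis] // 2
        data = data + spec.ghost.amplitude_frac * np.roll(
            data, shift, axis=spec.ghost.pe_axis)
        artifacts["ghost"] = spec.ghost
    if spec.dropout is not None:
        region = _sphere(dims, spec.dropout.center_vox, spec.dropout.radius_vox)
        data[region] *= spec.dropout.attenuation
        artifacts["dropout"] = spec.dropout
    if spec.pre_steady is not None:
        k = spec.pre_steady.n_trs
        data[..., :k] *= spec.pre_steady.gain
        artifacts["pre_steady"] = spec.pre_steady
    if spec.flip:
        data = np.flip(data, axis=0).copy()
        artifacts["flip"] = True

    grid = VolumeGrid.from_affine(
        dims, centered_affine(dims, spec.voxel_size_mm),
        qform_code=1, sform_code=1)
    epi = EpiSeries(grid=grid, data=data, tr_s=spec.tr_s, n_vols=n,
                    datum="float32", run_id="synth")
    truth = TruthRecord(seed=seed, motion=motion, betas=dict(spec.betas),
                        blob_masks=blob_masks, head_mask=head,
                        artifacts=artifacts, flip=spec.flip)
    return epi, truth


# --------------------------------------------------------------------------
# event generation
# --------------------------------------------------------------------------

def make_events(seed: int, n_events: int, classes: list[str],
                isi_law: tuple, duration_law: tuple,
                run_length_s: float, start_s: float = 10.0,
                allow_overlap: bool = False) -> EventTable:
    """Generate a sorted event table for one run.

    Laws are ``("regular", value)`` or ``("uniform", lo, hi)``;
    ``isi_law`` draws onset separations, ``duration_law`` draws event
    durations.  Classes alternate deterministically through ``classes``.
    Raises if the events do not fit into ``run_length_s``.
    """
    rng = np.random.default_rng(seed)

    def draw(law, size):
        kind = law[0]
        if kind == "regular":
            return np.full(size, float(law[1]))
        if kind == "uniform":
            return rng.uniform(float(law[1]), float(law[2]), size=size)
        raise ValueError(f"unknown law {kind!r}")

    seps = draw(isi_law, n_events - 1) if n_events > 1 else np.empty(0)
    durs = draw(duration_law, n_events)
    onsets = start_s + np.concatenate([[0.0], np.cumsum(seps)])
    if onsets[-1] + durs[-1] > run_length_s:
        raise ValueError(
            f"events extend to {onsets[-1] + durs[-1]:.1f}s, past the "
            f"{run_length_s:.1f}s run")
    if not allow_overlap and n_events > 1 and np.any(seps < durs[:-1]):
        raise ValueError("events overlap; pass allow_overlap=True to keep")
    import pandas as pd
    rows = pd.DataFrame({
        "onset": onsets,
        "duration": durs,
        "trial_type": [classes[i % len(classes)] for i in range(n_events)],
    })
    return EventTable(events=rows, run_id="synth")
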