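"""Getting to know your data (GTKYD).

Summarizes per-dataset header and data properties (matrix size,
orientation, voxel size, datum, qform/sform codes, obliquity, TR,
volume counts, intensity range, slice-timing presence) and audits them
across a group: fields where a subject deviates from the group standard
(the modal value) are listed, and absolute-value anomalies (very large
maxima, missing slice timing, oblique acquisition, strongly anisotropic
voxels) are noted.  This stage informs; it never includes or excludes
subjects by itself.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import AnatVolume, EpiSeries

__all__ = [
    "PropertyRecord",
    "ConsistencyReport",
    "GtkydConfig",
    "summarize_properties",
    "group_consistency",
    "records_to_frame",
    "format_report",
]

#: decimals used when comparing float-valued header fields for equality
FLOAT_DECIMALS = 3


@dataclass
class GtkydConfig:
    """Absolute-value 'reasonableness' thresholds (group-independent)."""

    large_max_threshold: float = 1e5
    anisotropy_threshold: float = 1.5


@dataclass
class PropertyRecord:
    """Header/data summary for one subject's EPI runs or anatomical."""

    subject_id: str
    dataset_role: str  # "epi" | "anat"
    matrix_size: tuple[int, int, int]
    orientation: str
    voxel_size_mm: tuple[float, float, float]
    datum: str
    qform_code: int
    sform_code: int
    oblique: bool
    n_runs: int
    min_val: float
    max_val: float
    tr_s: float | None = None
    n_vols_per_run: tuple[int, ...] | None = None
    has_slice_timing: bool | None = None

    def __post_init__(self) -> None:
        if self.dataset_role not in ("epi", "anat"):
            raise ValueError(f"bad dataset role {self.dataset_role!r}")
        if self.min_val > self.max_val:
            raise ValueError("min_val exceeds max_val")


#: fields audited for group consistency, per role
CONSISTENCY_FIELDS = {
    "epi": ["matrix_size", "orientation", "voxel_size_mm", "datum",
            "qform_code", "sform_code", "oblique", "n_runs", "tr_s",
            "n_vols_per_run", "has_slice_timing"],
    "anat": ["matrix_size", "orientation", "voxel_size_mm", "datum",
             "qform_code", "sform_code", "oblique", "n_runs"],
}


@dataclass
class Deviation:
    subject_id: str
    fieldname: str
    value: object
    group_std: object


@dataclass
class ConsistencyReport:
    role: str
    group_std: dict[str, object]
    deviations: list[Deviation]
    notes: list[str] = field(default_factory=list)


def summarize_properties(epi_runs: list[EpiSeries], anat: AnatVolume,
                         subject_id: str = "sub-01",
                         ) -> tuple[PropertyRecord, PropertyRecord]:
    """Build the (EPI, anatomical) property records for one subject.

    ``n_runs`` for the EPI record counts the supplied series; min/max
    are taken over all voxels of all runs.
    """
    if not epi_runs:
        raise ValueError("at least one EPI run is required")
    first = epi_runs[0]
    epi_rec = PropertyRecord(
        subject_id=subject_id,
        dataset_role="epi",
        matrix_size=tuple(first.grid.dims),
        orientation=first.grid.orientation,
        voxel_size_mm=tuple(round(v, FLOAT_DECIMALS)
                            for v in first.grid.voxel_size_mm),
        datum=first.datum,
        qform_code=first.grid.qform_code,
        sform_code=first.grid.sform_code,
        oblique=first.grid.oblique,
        n_runs=len(epi_runs),
        min_val=float(min(np.min(e.data) for e in epi_runs)),
        max_val=float(max(np.max(e.data) for e in epi_runs)),
        tr_s=round(first.tr_s, FLOAT_DECIMALS),
        n_vols_per_run=tuple(e.n_vols for e in epi_runs),
        has_slice_timing=first.slice_timing_s is not None,
    )
    anat_rec = PropertyRecord(
        subject_id=subject_id,
        dataset_role="anat",
        matrix_size=tuple(anat.grid.dims),
        orientation=anat.grid.orientation,
        voxel_size_mm=tuple(round(v, FLOAT_DECIMALS)
                            for v in anat.grid.voxel_size_mm),
        datum="float32",
        qform_code=anat.grid.qform_code,
        sform_code=anat.grid.sform_code,
        oblique=anat.grid.oblique,
        n_runs=1,
        min_val=float(np.min(anat.data)),
        max_val=float(np.max(anat.data)),
    )
    return epi_rec, anat_rec


def _canon(value):
    """Canonicalize a field value for modal comparison (round floats)."""
    if isinstance(value, float):
        return round(value, FLOAT_DECIMALS)
    if isinstance(value, tuple):
        return tuple(_canon(v) for v in value)
    return value


def group_consistency(records: list[PropertyRecord],
                      config: GtkydConfig | None = None) -> ConsistencyReport:
    """Audit a group of same-role records against their modal values.

    The group standard for each field is the mode; ties are broken by
    first-seen value and the tie itself is reported as a note.  Absolute
    checks: ``max_val`` above ``large_max_threshold``, missing slice
    timing, obliquity, and voxel anisotropy (max/min edge ratio) above
    ``anisotropy_threshold``.
    """
    if len(records) < 2:
        raise ValueError("group consistency needs >= 2 records")
    roles = {r.dataset_role for r in records}
    if len(roles) != 1:
        raise ValueError("all records in one call must share a role")
    role = roles.pop()
    config = config or GtkydConfig()

    group_std: dict[str, object] = {}
    deviations: list[Deviation] = []
    notes: list[str] = []

    for fieldname in CONSISTENCY_FIELDS[role]:
        values = [_canon(getattr(r, fieldname)) for r in records]
        counts = Counter(values)
        top = counts.most_common()
        std = top[0][0]
        if len(top) > 1 and top[1][1] == top[0][1]:
            # tie: first-seen among the tied values wins; report the tie
            tied = {v for v, c in top if c == top[0][1]}
            std = next(v for v in values if v in tied)
            notes.append(f"{fieldname}: no clear group standard "
                         f"({len(tied)} values tied at {top[0][1]})")
        group_std[fieldname] = std
        seen: set[str] = set()
        for rec, val in zip(records, values):
            if val != std and rec.subject_id not in seen:
                deviations.append(Deviation(rec.subject_id, fieldname, val, std))
                seen.add(rec.subject_id)

    for rec in records:
        if rec.max_val > config.large_max_threshold:
            notes.append(f"{rec.subject_id}: large max value "
                         f"{rec.max_val:.3g} (> {config.large_max_threshold:.3g})")
        if role == "epi" and rec.has_slice_timing is False:
            notes.append(f"{rec.subject_id}: no slice timing in header")
        if rec.oblique:
            notes.append(f"{rec.subject_id}: oblique acquisition")
        vox = rec.voxel_size_mm
        if min(vox) > 0 and max(vox) / min(vox) > config.anisotropy_threshold:
            notes.append(f"{rec.subject_id}: anisotropic voxels "
                         f"{vox[0]:g}x{vox[1]:g}x{vox[2]:g} mm")

    return ConsistencyReport(role=role, group_std=group_std,
                             deviations=deviations, notes=notes)


def records_to_frame(records: list[PropertyRecord]) -> pd.DataFrame:
    """One row per subject, one column per property (TSV-friendly)."""
    rows = []
    for r in records:
        d = dict(r.__dict__)
        d["matrix_size"] = "x".join(map(str, r.matrix_size))
        d["voxel_size_mm"] = "x".join(f"{v:g}" for v in r.voxel_size_mm)
        if r.n_vols_per_run is not None:
            d["n_vols_per_run"] = ",".join(map(str, r.n_vols_per_run))
        rows.append(d)
    return pd.DataFrame(rows)


_FIELD_TITLES = {
    "matrix_size": "matrix size diff", "orientation": "orientation diff",
    "voxel_size_mm": "voxel size diff", "datum": "datum diff",
    "qform_code": "qform_code diff", "sform_code": "sform_code diff",
    "oblique": "obliquity diff", "n_runs": "diff num of EPI",
    "tr_s": "TR diff", "n_vols_per_run": "diff length of EPI",
    "has_slice_timing": "slice timing diff",
}


def format_report(report: ConsistencyReport) -> str:
    """Plain-text rendering: one line per deviation, grouped by field."""
    lines = [f"GTKYD consistency report ({report.role})", ""]
    by_field: dict[str, list[Deviation]] = {}
    for d in report.deviations:
        by_field.setdefault(d.fieldname, []).append(d)
    if not by_field:
        lines.append("no deviations from group standard")
    for fieldname, devs in by_field.items():
        title = _FIELD_TITLES.get(fieldname, f"{fieldname} diff")
        for d in devs:
            lines.append(f"{title}\t{d.subject_id} has {d.value}, "
                         f"from group std {d.group_std}")
    if report.notes:
        lines.append("")
        lines.append("notes:")
        lines.extend(f"  {n}" for n in report.notes)
    return "\n".join(lines) + "\n"
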