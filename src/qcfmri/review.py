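"""The quantitative review engine (APQUANT).

Per-subject review dictionaries collect the scalar QC outputs of the
other modules under canonical key strings (e.g. ``'censor fraction'``,
``'global correlation (GCOR)'``), so that published checklist tables
paste in unchanged.  Checklist rules pair a key with a comparator
(VARY, GE, GT, LE, LT, EQ) and a severity level; applying a checklist
yields a full table (one subject per row) plus the sub-table of flagged
subjects with reasons.  Categorization combines quantitative flags with
manual qualitative labels into include / exclude / uncertain.

QC labels are hierarchical strings ``STAGE.type[.subtype](detail)``,
e.g. ``APQUANT.excl('censor fraction')`` or
``APQUAL.regr.TSNR_final-artifact``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReviewDictionary",
    "ChecklistRule",
    "ChecklistResult",
    "SubjectEvaluation",
    "QCLabel",
    "MISSING",
    "CANONICAL_KEYS",
    "collect_review_dict",
    "apply_checklist",
    "default_checklists",
    "categorize",
    "parse_qc_label",
    "format_qc_label",
]

#: sentinel distinguishing "not computed" from a numeric zero
MISSING = "MISSING"

#: canonical review-field keys
CANONICAL_KEYS = (
    "censor fraction",
    "average censored motion",
    "max censored displacement",
    "global correlation (GCOR)",
    "TSNR average",
    "final DF fraction",
    "flip guess",
    "fraction TRs censored",
    "num regs of interest",
    "final voxel resolution",
    "num TRs per run",
    "AFNI version",
)

FLIP_VALUES = ("DO_FLIP", "NO_FLIP", "UNCERTAIN")

#: decimals for float equality in VARY comparisons
VARY_DECIMALS = 3


@dataclass
class ReviewDictionary:
    """One subject's key -> value QC summary."""

    subject_id: str
    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        flip = self.values.get("flip guess")
        if flip not in (None, MISSING) and flip not in FLIP_VALUES:
            raise ValueError(f"bad flip guess value {flip!r}")
        for k, v in self.values.items():
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"non-finite value for {k!r}")

    def get(self, key: str):
        return self.values.get(key, MISSING)

    def is_missing(self, key: str) -> bool:
        return self.get(key) == MISSING


def collect_review_dict(subject_id: str, *,
                        motion_summary=None, gcor=None, tsnr_average=None,
                        glm_fit=None, flip_result=None,
                        stim_censor=None, n_regs_interest=None,
                        voxel_size_mm=None, n_trs_per_run=None,
                        software_version=None) -> ReviewDictionary:
    """Assemble the canonical review dictionary from module outputs.

    Every canonical key is populated; anything unavailable is recorded
    as :data:`MISSING` (feeding the summary-table "missing" check), not
    silently zero.  In particular a resting-state run with no stimulus
    regressors has ``'fraction TRs censored'`` MISSING, never 0.
    """
    vals: dict[str, object] = {k: MISSING for k in CANONICAL_KEYS}
    if motion_summary is not None:
        vals["censor fraction"] = float(motion_summary.censor_fraction)
        vals["average censored motion"] = float(
            motion_summary.avg_censored_motion)
        vals["max censored displacement"] = float(
            motion_summary.max_censored_displacement)
    if gcor is not None:
        vals["global correlation (GCOR)"] = float(gcor)
    if tsnr_average is not None:
        vals["TSNR average"] = float(tsnr_average)
    if glm_fit is not None:
        vals["final DF fraction"] = float(glm_fit.df_fraction)
    if flip_result is not None:
        vals["flip guess"] = flip_result.guess
    if stim_censor is not None:
        frac = stim_censor.max_fraction()
        vals["fraction TRs censored"] = (float(frac) if frac is not None
                                         else MISSING)
    if n_regs_interest is not None:
        vals["num regs of interest"] = int(n_regs_interest)
    if voxel_size_mm is not None:
        vals["final voxel resolution"] = "x".join(
            f"{v:.3f}" for v in voxel_size_mm)
    if n_trs_per_run is not None:
        vals["num TRs per run"] = ",".join(str(int(n)) for n in n_trs_per_run)
    if software_version is not None:
        vals["AFNI version"] = str(software_version)
    return ReviewDictionary(subject_id=subject_id, values=vals)


# --------------------------------------------------------------------------
# checklist rules
# --------------------------------------------------------------------------

COMPARATORS = ("VARY", "GE", "GT", "LE", "LT", "EQ")
LEVELS = ("consistency", "warning", "exclusion")


@dataclass(frozen=True)
class ChecklistRule:
    """One checklist entry: key, comparator, threshold, severity level."""

    key: str
    comparator: str
    threshold: object = None
    level: str = "warning"

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.comparator == "VARY" and self.threshold is not None:
            raise ValueError("VARY rules carry no threshold")
        if self.comparator != "VARY" and self.threshold is None:
            raise ValueError(f"{self.comparator} rule needs a threshold")

    def describe(self) -> str:
        if self.comparator == "VARY":
            return f"'{self.key}' VARY"
        return f"'{self.key}' {self.comparator} {self.threshold}"


def default_checklists(mode: str) -> dict[str, list[ChecklistRule]]:
    """The published consistency / warning / exclusion checklists.

    ``mode`` is ``"rest"`` or ``"task"``; the task exclusion list adds
    the per-stimulus censor-fraction rule.
    """
    if mode not in ("rest", "task"):
        raise ValueError(f"mode must be 'rest' or 'task', got {mode!r}")
    consistency = [
        ChecklistRule("AFNI version", "VARY", level="consistency"),
        ChecklistRule("num regs of interest", "VARY", level="consistency"),
        ChecklistRule("final voxel resolution", "VARY", level="consistency"),
        ChecklistRule("num TRs per run", "VARY", level="consistency"),
    ]
    warning = [
        ChecklistRule("final DF fraction", "LE", 0.7, "warning"),
        ChecklistRule("censor fraction", "GE", 0.15, "warning"),
        ChecklistRule("average censored motion", "GE", 0.1, "warning"),
        ChecklistRule("max censored displacement", "GE", 6, "warning"),
        ChecklistRule("global correlation (GCOR)", "GE", 0.15, "warning"),
        ChecklistRule("TSNR average", "LT", 150, "warning"),
    ]
    exclusion = [
        ChecklistRule("final DF fraction", "LE", 0.6, "exclusion"),
        ChecklistRule("censor fraction", "GE", 0.2, "exclusion"),
        ChecklistRule("average censored motion", "GE", 0.15, "exclusion"),
        ChecklistRule("max censored displacement", "GE", 8, "exclusion"),
        ChecklistRule("global correlation (GCOR)", "GE", 0.20, "exclusion"),
        ChecklistRule("flip guess", "EQ", "DO_FLIP", "exclusion"),
    ]
    if mode == "task":
        exclusion.append(
            ChecklistRule("fraction TRs censored", "GE", 0.2, "exclusion"))
    return {"consistency": consistency, "warning": warning,
            "exclusion": exclusion}


@dataclass
class Flag:
    subject_id: str
    rule: ChecklistRule
    value: object
    missing: bool = False

    def reason(self) -> str:
        if self.missing:
            return f"'{self.rule.key}' missing"
        return self.rule.describe()


@dataclass
class ChecklistResult:
    full_table: pd.DataFrame
    flagged: pd.DataFrame
    flags: list[Flag]
    vary_keys: list[str]

    def flags_for(self, subject_id: str) -> list[Flag]:
        return [f for f in self.flags if f.subject_id == subject_id]


def _vary_canon(value):
    if isinstance(value, float):
        return round(value, VARY_DECIMALS)
    return value


def _compare(value, comparator: str, threshold) -> bool:
    if comparator == "EQ":
        if isinstance(threshold, str):
            return str(value) == threshold
        return np.isclose(float(value), float(threshold))
    v = float(value)
    t = float(threshold)
    return {"GE": v >= t, "GT": v > t, "LE": v <= t, "LT": v < t}[comparator]


def apply_checklist(dicts: list[ReviewDictionary],
                    rules: list[ChecklistRule]) -> ChecklistResult:
    """Evaluate rules over a group of review dictionaries.

    VARY rules flag a key when more than one distinct value appears
    across subjects (floats rounded to 3 decimals first); threshold
    rules flag per subject.  A rule referencing a key that is missing
    for a subject produces a "missing" flag for that subject.
    """
    if not dicts:
        raise ValueError("need at least one review dictionary")
    keys = list(dict.fromkeys([r.key for r in rules]))
    rows = []
    for d in dicts:
        rows.append({"subject": d.subject_id,
                     **{k: d.get(k) for k in keys}})
    full = pd.DataFrame(rows).set_index("subject")

    flags: list[Flag] = []
    vary_keys: list[str] = []
    for rule in rules:
        if rule.comparator == "VARY":
            present = [(d.subject_id, _vary_canon(d.get(rule.key)))
                       for d in dicts if not d.is_missing(rule.key)]
            for d in dicts:
                if d.is_missing(rule.key):
                    flags.append(Flag(d.subject_id, rule, MISSING,
                                      missing=True))
            if len({v for _, v in present}) > 1:
                vary_keys.append(rule.key)
                for sid, v in present:
                    flags.append(Flag(sid, rule, v))
        else:
            for d in dicts:
                if d.is_missing(rule.key):
                    flags.append(Flag(d.subject_id, rule, MISSING,
                                      missing=True))
                elif _compare(d.get(rule.key), rule.comparator,
                              rule.threshold):
                    flags.append(Flag(d.subject_id, rule, d.get(rule.key)))

    flagged_rows = []
    for d in dicts:
        mine = [f for f in flags if f.subject_id == d.subject_id]
        if mine:
            flagged_rows.append({
                "subject": d.subject_id,
                **{k: d.get(k) for k in keys},
                "reasons": "; ".join(f.reason() for f in mine)})
    flagged = pd.DataFrame(flagged_rows)
    if len(flagged):
        flagged = flagged.set_index("subject")
    return ChecklistResult(full_table=full, flagged=flagged, flags=flags,
                           vary_keys=vary_keys)


# --------------------------------------------------------------------------
# QC labels and categorization
# --------------------------------------------------------------------------

STAGES = ("GTKYD", "APQUANT", "APQUAL", "GUI", "STIM")

_LABEL_RE = re.compile(
    r"^(?P<stage>[A-Z]+)"
    r"\.(?P<type>[A-Za-z_][\w\-]*)"
    r"(?:\.(?P<subtype>[A-Za-z_][\w\-]*))?"
    r"(?:\((?P<detail>.*)\))?$")


@dataclass(frozen=True)
class QCLabel:
    """Hierarchical QC label: STAGE.type[.subtype](detail)."""

    stage: str
    type: str
    subtype: str | None = None
    detail: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown QC stage {self.stage!r}")


def parse_qc_label(s: str) -> QCLabel:
    """Parse ``STAGE.type[.subtype](detail)``; errors carry position."""
    m = _LABEL_RE.match(s.strip())
    if not m:
        dot = s.find(".")
        pos = dot if dot >= 0 else 0
        raise ValueError(f"malformed QC label {s!r} (near position {pos})")
    stage = m.group("stage")
    if stage not in STAGES:
        raise ValueError(
            f"malformed QC label {s!r}: unknown stage {stage!r} at position 0")
    return QCLabel(stage=stage, type=m.group("type"),
                   subtype=m.group("subtype"), detail=m.group("detail"))


def format_qc_label(label: QCLabel) -> str:
    out = f"{label.stage}.{label.type}"
    if label.subtype:
        out += f".{label.subtype}"
    if label.detail is not None:
        out += f"({label.detail})"
    return out


@dataclass
class SubjectEvaluation:
    """Final include / exclude / uncertain verdict with its triggers."""

    subject_id: str
    category: str
    triggers: list[str]

    def __post_init__(self) -> None:
        if self.category not in ("include", "exclude", "uncertain"):
            raise ValueError(f"bad category {self.category!r}")


def categorize(subject_id: str, flags: list[Flag],
               manual_labels: list[tuple[QCLabel, str]] | None = None
               ) -> SubjectEvaluation:
    """Combine quantitative flags and manual labels into a verdict.

    ``manual_labels`` pairs each qualitative label (APQUAL / GUI /
    STIM / GTKYD finding) with the rater's severity, ``"exclusion"``
    or ``"warning"`` — the label itself does not encode severity, the
    rater's judgment does.  Any exclusion-level trigger (quantitative
    or manual) excludes; otherwise any warning-level trigger makes the
    subject uncertain; otherwise include.  Missing-value flags count as
    warnings.
    """
    triggers_excl: list[str] = []
    triggers_warn: list[str] = []
    for f in flags:
        if f.subject_id != subject_id:
            continue
        if f.missing:
            triggers_warn.append(format_qc_label(QCLabel(
                "APQUANT", "missing", detail=repr(f.rule.key))))
        elif f.rule.level == "exclusion":
            triggers_excl.append(format_qc_label(QCLabel(
                "APQUANT", "excl", detail=repr(f.rule.key))))
        else:
            ltype = "warn" if f.rule.level == "warning" else "vary"
            triggers_warn.append(format_qc_label(QCLabel(
                "APQUANT", ltype, detail=repr(f.rule.key))))
    for label, level in manual_labels or []:
        if level == "exclusion":
            triggers_excl.append(format_qc_label(label))
        elif level == "warning":
            triggers_warn.append(format_qc_label(label))
        else:
            raise ValueError(f"manual label level must be 'exclusion' or "
                             f"'warning', got {level!r}")
    if triggers_excl:
        return SubjectEvaluation(subject_id, "exclude", triggers_excl)
    if triggers_warn:
        return SubjectEvaluation(subject_id, "uncertain", triggers_warn)
    return SubjectEvaluation(subject_id, "include", [])
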