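"""Task-timing QC: duration and interstimulus-interval statistics,
design-matrix correlation and condition-number diagnostics, and
per-stimulus censor fractions.

The interstimulus interval (ISI) is defined strictly as onset
separation minus the preceding event's duration; rest before the first
event and after the last one are reported separately and excluded from
the ISI statistics.  Condition numbers are the ratio of the largest to
smallest eigenvalue of X'X computed on unit-L2-normalized columns of
each sub-model, so they are invariant to column scaling and readable
across models of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CensorVector, EventTable
from .regmodel import DesignMatrix

__all__ = [
    "TimingStats",
    "XmatDiagnostics",
    "StimCensorReport",
    "duration_stats",
    "isi_stats",
    "xmat_diagnostics",
    "stim_censor_fraction",
]


def _four_stats(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {"min": float(values.min()), "mean": float(values.mean()),
            "max": float(values.max()), "stdev": sd,
            "n": int(values.size)}


@dataclass
class TimingStats:
    """min/mean/max/stdev summaries of durations, onset separations
    and interstimulus intervals."""

    durations: pd.DataFrame | None = None      # rows: (subject, class)
    separations: pd.DataFrame | None = None    # rows: subject
    isi: pd.DataFrame | None = None            # rows: subject
    edge_rest: pd.DataFrame | None = None      # pre-first / post-last rest
    warnings: list[str] = field(default_factory=list)


def duration_stats(events_by_subject: dict[str, list[EventTable]]
                   ) -> TimingStats:
    """Per-(subject, class) and pooled stimulus-duration statistics.

    Classes with no events for a subject are simply absent from the
    table.  The pooled row (subject ``"ALL"``) weights every event
    equally.
    """
    rows = []
    pooled: dict[str, list[float]] = {}
    for subject, tables in events_by_subject.items():
        per_class: dict[str, list[float]] = {}
        for tab in tables:
            for cls in tab.classes:
                durs = tab.for_class(cls)["duration"].to_numpy(float)
                per_class.setdefault(cls, []).extend(durs)
                pooled.setdefault(cls, []).extend(durs)
        for cls, durs in per_class.items():
            if durs:
                rows.append({"subject": subject, "class": cls,
                             **_four_stats(np.asarray(durs))})
    for cls, durs in pooled.items():
        if durs:
            rows.append({"subject": "ALL", "class": cls,
                         **_four_stats(np.asarray(durs))})
    return TimingStats(durations=pd.DataFrame(rows))


def isi_stats(events_by_subject: dict[str, list[EventTable]],
              run_length_s: float | None = None) -> TimingStats:
    """Onset-separation and ISI statistics per subject and pooled.

    Events of all classes are pooled and time-sorted per run.
    ``ISI_k = onset_{k+1} - onset_k - duration_k``; a negative ISI
    (overlapping events) is kept in the statistics but recorded as a
    warning.  Pre-first rest (first onset) and post-last rest
    (run end minus last offset, when the run length is known) appear in
    ``edge_rest`` and never in the ISI statistics.
    """
    sep_rows, isi_rows, edge_rows = [], [], []
    warnings: list[str] = []
    all_seps: list[float] = []
    all_isis: list[float] = []
    for subject, tables in events_by_subject.items():
        seps: list[float] = []
        isis: list[float] = []
        for tab in tables:
            df = tab.events.sort_values("onset")
            onsets = df["onset"].to_numpy(float)
            durs = df["duration"].to_numpy(float)
            if onsets.size >= 1:
                post = (run_length_s - (onsets[-1] + durs[-1])
                        if run_length_s is not None else np.nan)
                edge_rows.append({"subject": subject, "run": tab.run_id,
                                  "pre_first_rest_s": float(onsets[0]),
                                  "post_last_rest_s": float(post)})
            if onsets.size < 2:
                continue
            s = np.diff(onsets)
            i = s - durs[:-1]
            neg = np.flatnonzero(i < 0)
            for k in neg:
                warnings.append(
                    f"{subject}/{tab.run_id}: events at {onsets[k]:g}s and "
                    f"{onsets[k + 1]:g}s overlap (ISI {i[k]:g}s)")
            seps.extend(s)
            isis.extend(i)
        if seps:
            sep_rows.append({"subject": subject, **_four_stats(np.array(seps))})
            isi_rows.append({"subject": subject, **_four_stats(np.array(isis))})
            all_seps.extend(seps)
            all_isis.extend(isis)
    if all_seps:
        sep_rows.append({"subject": "ALL", **_four_stats(np.array(all_seps))})
        isi_rows.append({"subject": "ALL", **_four_stats(np.array(all_isis))})
    return TimingStats(separations=pd.DataFrame(sep_rows),
                       isi=pd.DataFrame(isi_rows),
                       edge_rest=pd.DataFrame(edge_rows),
                       warnings=warnings)


@dataclass
class XmatDiagnostics:
    """Pairwise-correlation and condition-number design diagnostics."""

    corr: pd.DataFrame                  # over non-constant columns
    warnings: list[tuple[str, str, float, str]]  # (col_a, col_b, r, level)
    condition_numbers: dict[str, float]

    def __post_init__(self) -> None:
        C = self.corr.to_numpy(float)
        if C.size and not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")


_SUBMODELS = {
    "baseline": ("baseline",),
    "motion": ("motion",),
    "interest": ("interest",),
    "baseline+motion": ("baseline", "motion"),
    "full": ("baseline", "motion", "interest"),
}


def _condition_number(X: np.ndarray) -> float:
    """lambda_max / lambda_min of X'X on unit-L2-normalized columns."""
    norms = np.linalg.norm(X, axis=0)
    ok = norms > 0
    if not ok.any():
        return float("nan")
    U = X[:, ok] / norms[ok]
    eig = np.linalg.eigvalsh(U.T @ U)
    lam_min = eig[0]
    lam_max = eig[-1]
    if lam_min <= 1e-12 * max(lam_max, 1.0):
        return float("inf")
    return float(lam_max / lam_min)


def xmat_diagnostics(X: DesignMatrix, warn_r: float = 0.4) -> XmatDiagnostics:
    """Pairwise correlations and sub-model condition numbers.

    Correlations are Pearson r over all non-constant column pairs,
    excluding baseline-with-baseline pairs (per-run polynomial baselines
    correlate by construction and are not informative).  Pairs with
    ``|r| >= warn_r`` are listed as warnings ("high" below 0.9,
    "severe" at or above).  Condition numbers cover the baseline,
    motion, interest, baseline+motion and full sub-models.
    """
    if X.X.shape[1] < 2:
        raise ValueError("need at least two design columns")
    variable = [j for j in range(X.X.shape[1]) if X.X[:, j].std() > 0]
    for j in range(X.X.shape[1]):
        if j not in variable and X.groups[j] != "baseline":
            raise ValueError(
                f"zero-variance non-baseline column {X.labels[j]!r}")
    cols = X.X[:, variable]
    names = [X.labels[j] for j in variable]
    grp = [X.groups[j] for j in variable]
    Z = cols - cols.mean(axis=0)
    norms = np.linalg.norm(Z, axis=0)
    C = (Z / norms).T @ (Z / norms)
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    corr = pd.DataFrame(C, index=names, columns=names)

    warns = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if grp[a] == "baseline" and grp[b] == "baseline":
                continue
            r = float(C[a, b])
            if abs(r) >= warn_r:
                level = "severe" if abs(r) >= 0.9 else "high"
                warns.append((names[a], names[b], r, level))

    cond = {}
    for name, groups in _SUBMODELS.items():
        sel = X.columns_of(*groups)
        cond[name] = _condition_number(X.X[:, sel]) if sel.size else float("nan")

    return XmatDiagnostics(corr=corr, warnings=warns, condition_numbers=cond)


@dataclass
class StimCensorReport:
    """Per-class fraction of stimulus-response TRs that were censored."""

    fractions: dict[str, float | None]
    warnings: list[str] = field(default_factory=list)

    def max_fraction(self) -> float | None:
        vals = [v for v in self.fractions.values() if v is not None]
        return max(vals) if vals else None


def stim_censor_fraction(X: DesignMatrix, censor: CensorVector,
                         support_eps: float = 0.01) -> StimCensorReport:
    """For each stimulus class, the censored share of its response
    support (TRs where the ideal regressor exceeds ``support_eps``
    times its peak)."""
    interest = X.columns_of("interest")
    if interest.size == 0:
        raise ValueError("design has no regressors of interest")
    if censor.n_vols != X.n_rows:
        raise ValueError("censor length does not match design rows")
    fractions: dict[str, float | None] = {}
    warnings: list[str] = []
    keep = censor.keep.astype(bool)
    for j in interest:
        reg = X.X[:, j]
        peak = np.max(np.abs(reg))
        support = np.abs(reg) > support_eps * peak if peak > 0 else \
            np.zeros_like(reg, dtype=bool)
        if not support.any():
            fractions[X.labels[j]] = None
            warnings.append(f"{X.labels[j]}: empty response support")
            continue
        fractions[X.labels[j]] = float((~keep[support]).mean())
    return StimCensorReport(fractions=fractions, warnings=warnings)
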