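"""End-to-end "quick QC" driver for one subject.

Runs the full chain — property summary, automask and scaling, design
and censored OLS (nuisance-only for resting state), motion and
correlation metrics, the flip check, the review dictionary and the
static report — writing a per-subject results directory.  QC flags
are data findings, not errors: the driver succeeds even when a subject
would be excluded.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .align import flip_check
from .config import PipelineConfig
from .dataio import (AnatVolume, CensorVector, EpiSeries, EventTable,
                     MotionTrace, save_censor)
from .gtkyd import summarize_properties
from .metrics import (compute_corr_brain, compute_enorm, compute_gcor,
                      compute_outlier_fractions, compute_radcor,
                      compute_tsnr, detect_pre_steady, make_censor)
from .regmodel import (BasisConfig, ContrastSpec, build_design,
                       compute_automask, fit_glm, scale_to_mean100)
from .report import (MontageSpec, TransparencySpec, build_report,
                     render_edges_montage, render_grayplot,
                     render_motion_plot, render_overlay_montage)
from .review import ReviewDictionary, collect_review_dict
from .stim import stim_censor_fraction, xmat_diagnostics

__all__ = ["run_quick_qc", "QuickQcResult"]

log = logging.getLogger("qcfmri")


class QuickQcResult(dict):
    """Dict of pipeline outputs with attribute access."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as exc:
            raise AttributeError(name) from exc


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_quick_qc(epi_runs: list[EpiSeries], anat: AnatVolume,
                 motion: MotionTrace, config: PipelineConfig,
                 out_dir: str | Path,
                 events: list[EventTable] | None = None,
                 subject_id: str = "sub-01") -> QuickQcResult:
    """Run the full QC chain on one subject and write the results
    directory.  Returns the in-memory outputs (review dictionary,
    motion summary, GLM fit, flip result, maps)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "qc.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("qcfmri %s config %s subject %s", __version__,
                 _config_hash(config), subject_id)
        if config.mode == "task" and events is None:
            raise ValueError("task mode requires event tables")

        epi_rec, anat_rec = summarize_properties(epi_runs, anat, subject_id)

        mask = compute_automask(epi_runs[0])
        scaled = [scale_to_mean100(run, mask) for run in epi_runs]

        enorm = compute_enorm(motion)
        outfrac = np.concatenate([
            compute_outlier_fractions(run, mask) for run in epi_runs])
        summary = make_censor(enorm, outfrac, motion,
                              L_motion=config.L_motion, L_out=config.L_out)
        save_censor(summary.censor, out_dir / "censor.1D")
        np.savetxt(out_dir / "enorm.1D", enorm[:, None], fmt="%.6f")
        press = detect_pre_steady(outfrac)

        X = build_design(
            scaled, motion,
            events=events if config.mode == "task" else None,
            basis_cfg=BasisConfig(motion_derivatives=config.motion_derivatives))
        X.save_tsv(out_dir / "design.tsv")
        contrasts = None
        if config.mode == "task":
            classes = sorted({c for tab in events for c in tab.classes})
            if len(classes) == 2:
                # put the task-like class first for the readable contrast
                b, a = classes if classes != ["Control", "Task"] \
                    else ("Control", "Task")
                contrasts = [
                    ContrastSpec(f"{a} - {b}", {a: 1.0, b: -1.0}),
                    ContrastSpec(f"0.5*({a} + {b})", {a: 0.5, b: 0.5}),
                ]
        data = np.concatenate([run.data for run in scaled], axis=3)
        full = EpiSeries(grid=scaled[0].grid, data=data,
                         tr_s=scaled[0].tr_s, n_vols=data.shape[3])
        fit = fit_glm(full, X, summary.censor, contrasts)

        gcor = compute_gcor(fit.residuals[mask.mask])
        tsnr_map, tsnr_avg = compute_tsnr(fit.fitted, fit.residuals, mask)
        corr_brain = compute_corr_brain(fit.residuals, mask)
        radcor = compute_radcor(fit.residuals, mask,
                                fwhm_mm=config.radcor_fwhm_mm,
                                voxel_size_mm=scaled[0].grid.voxel_size_mm)

        flip = flip_check(epi_runs[0], anat, cost=config.cost,
                          margin_rel=config.flip_margin_rel)

        xdiag = xmat_diagnostics(X)
        stim_rep = None
        if config.mode == "task" and X.columns_of("interest").size:
            stim_rep = stim_censor_fraction(X, summary.censor)

        review = collect_review_dict(
            subject_id,
            motion_summary=summary, gcor=gcor, tsnr_average=tsnr_avg,
            glm_fit=fit, flip_result=flip, stim_censor=stim_rep,
            n_regs_interest=int(X.columns_of("interest").size),
            voxel_size_mm=scaled[0].grid.voxel_size_mm,
            n_trs_per_run=[run.n_vols for run in epi_runs],
            software_version=__version__)
        (out_dir / "review.json").write_text(
            json.dumps({"subject_id": review.subject_id,
                        "values": review.values}, indent=2))

        warns: list[str] = []
        if flip.guess != "NO_FLIP":
            warns.append(f"flip: guess {flip.guess} "
                         f"(cost orig {flip.cost_orig:.4f}, "
                         f"flipped {flip.cost_flipped:.4f}), "
                         f"level {flip.warn_level}")
        if press.flagged:
            warns.append(f"press: {press.n_leading_trs} apparent "
                         "pre-steady-state volume(s) at the start")
        for a, b, r, level in xdiag.warnings:
            warns.append(f"regr_mat: corr({a}, {b}) = {r:.2f} [{level}]")
        if summary.censor_fraction >= 0.15:
            warns.append(f"censor: fraction {summary.censor_fraction:.2f}")

        images = {}
        if config.report:
            mean0 = epi_runs[0].data.mean(axis=3)
            mspec = MontageSpec(n_slices=6)
            images["vorig"] = [render_overlay_montage(
                mean0, None, None, mspec, out_dir / "vorig.png",
                mask=mask.mask, title="mean EPI")]
            images["mot"] = [render_motion_plot(
                enorm, outfrac, out_dir / "mot.png",
                censor_keep=summary.censor.keep,
                L_motion=config.L_motion, L_out=config.L_out)]
            images["regr"] = [
                render_overlay_montage(
                    mean0, tsnr_map.data, None, mspec,
                    out_dir / "tsnr.png", mask=mask.mask, title="TSNR"),
                render_overlay_montage(
                    mean0, corr_brain.data, TransparencySpec(threshold=0.3),
                    mspec, out_dir / "corr_brain.png", mask=mask.mask,
                    title="corr_brain"),
                render_grayplot(fit.residuals, mask.mask,
                                out_dir / "grayplot.png",
                                censor_keep=summary.censor.keep[fit.retained]),
            ]
            images["radcor"] = [render_overlay_montage(
                mean0, radcor.data, TransparencySpec(threshold=0.7), mspec,
                out_dir / "radcor.png", mask=mask.mask, title="radcor")]
            build_report(out_dir, subject_id, block_images=images,
                         warns=warns, qsumm=review.values)
        log.info("quick QC complete for %s", subject_id)
    except Exception:
        log.exception("quick QC failed for %s", subject_id)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    return QuickQcResult(
        review=review, motion_summary=summary, glm_fit=fit, flip=flip,
        gcor=gcor, tsnr_avg=tsnr_avg, tsnr_map=tsnr_map,
        corr_brain=corr_brain, radcor=radcor, pre_steady=press,
        design=X, xmat=xdiag, mask=mask,
        properties=(epi_rec, anat_rec), out_dir=out_dir)
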