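# qcfmri

Hierarchical quality control for fMRI studies: scripted, reproducible
versions of the checks an analyst runs between data acquisition and
group analysis, for both resting-state and task designs.

Subject-level fMRI data fail in many distinct ways — excessive head
motion, scanner ghosting, signal dropout, left-right flipped headers,
pre-steady-state volumes, collinear task designs — and no single
statistic catches them all. `qcfmri` organizes QC into stages:

1. **Property audit ("getting to know your data")** — summarize every
   dataset's header and data properties (matrix size, orientation,
   voxel size, datum, qform/sform codes, obliquity, TR, volume counts,
   intensity range) and report deviations from the group's modal value
   plus absolute-value anomalies. Informative only; never excludes.
2. **Quantitative review** — compute per-subject scalar metrics, put
   them in a review dictionary under canonical keys, and apply
   checklist rules (`'censor fraction' GE 0.2`, `'flip guess' EQ
   DO_FLIP`, ...) at consistency / warning / exclusion severity to
   partition subjects into include / exclude / uncertain.
3. **Image-based review** — montages with transparent thresholding,
   anatomical edge overlays on the EPI, grayplots, motion traces and
   seed-correlation maps, assembled into a static per-subject HTML
   report with sidecar ratings.
4. **Stimulus-timing diagnostics** — duration and interstimulus-interval
   statistics, design-matrix pairwise correlations and sub-model
   condition numbers, and per-class censored-response fractions.

A seeded synthetic phantom generator produces EPI/anatomical pairs with
controllable motion, network signals, ghosting, dropout, pre-steady
volumes and flips — with exact ground truth — so every detector is
testable end to end.

## Core quantities

With motion parameters $p_t \in \mathbb{R}^6$ (three rotations in
degrees, three translations in mm):

- **Enorm**: $e_t = \lVert p_t - p_{t-1}\rVert_2$, $e_0 = 0$. A TR with
  $e_t > L$ censors both $t{-}1$ and $t$ (default $L$: 0.2 mm rest,
  0.3 mm task); a TR whose outlier fraction exceeds 5% is censored
  alone.
- **Outlier fraction**: per voxel, an L1-fitted Legendre polynomial
  trend; sample $t$ is an outlier when
  $|v_t - \hat v_t| > Q\,\sqrt{\pi/2}\,\mathrm{MAD}$ with
  $Q = \Phi^{-1}(1 - 0.001/N)$.
- **GCOR**: with $u_v$ each in-mask voxel's demeaned unit-norm series,
  $\mathrm{GCOR} = \lVert \tfrac1V \sum_v u_v \rVert^2$ — identically
  the mean of all $V^2$ pairwise temporal correlations.
- **TSNR**: mean(model fit) / sd(residual), per voxel, averaged in the
  mask.
- **corr_brain / radcor / seed maps**: each voxel's correlation with
  the brain-average residual, with a Gaussian-weighted (FWHM 40 mm)
  local average, or with a seed-ball mean, over the full unmasked FOV.
- **GLM**: per-run Legendre baselines of order
  $p = 1 + \lfloor \text{run seconds}/150 \rfloor$, per-run
  (demeaned) motion regressors and derivatives, duration-modulated
  stimulus regressors built from the peak-one gamma
  $g(\tau) = (\tau/4)^4 e^{4-\tau}$ scaled so a 2 s block peaks at 1;
  censored-row OLS, contrast t maps, a partial F over the regressors
  of interest, and `df_fraction = (retained TRs − rank X)/total TRs`.
- **Flip check**: register the EPI reference and its mid-sagittal
  mirror to the anatomical (multi-resolution grid search +
  Nelder-Mead over `ls`/`nmi`/`lpa`/`lpc` costs; `lpc` is the signed
  block-wise local Pearson correlation) and compare costs: DO_FLIP /
  NO_FLIP / UNCERTAIN with a relative margin.

## Worked example

```python
import numpy as np
from qcfmri.config import PipelineConfig
from qcfmri.dataio import MotionTrace
from qcfmri.pipeline import run_quick_qc
from qcfmri.synthgen import (PhantomSpec, make_anat_phantom, make_epi,
                             step_motion)

# a 60-TR resting phantom with slow wander and one 0.5 mm motion step
motion = step_motion(60, spikes=[(20, [0, 0, 0, 0.5, 0, 0])],
                     wander_sd=0.005, seed=1)
spec = PhantomSpec(n_vols=60, noise_sd=1.5, motion=motion)
epi, truth = make_epi(spec, seed=1)
anat = make_anat_phantom(spec, seed=1)

res = run_quick_qc([epi], anat, MotionTrace(truth.motion),
                   PipelineConfig(mode="rest"), "qc_sub-01",
                   subject_id="sub-01")
for key in ("censor fraction", "average censored motion",
            "global correlation (GCOR)", "TSNR average",
            "final DF fraction", "flip guess"):
    print(f"{key:32s} {res.review.get(key)}")
print("censored TRs:",
      list(np.flatnonzero(res.motion_summary.censor.keep == 0)))
```

prints

```
censor fraction                  0.03333333333333333
average censored motion          0.010297702143822569
global correlation (GCOR)        0.001343071011156045
TSNR average                     89.30989665686894
final DF fraction                0.7333333333333333
flip guess                       NO_FLIP
censored TRs: [19, 20]
```

The 0.5 mm step at TR 20 censors the bracketing pair (19, 20) — Enorm
measures the 19→20 transition — giving a censor fraction of 2/60; the
remaining motion is the small wander (≈0.01 mm per TR); GCOR is near
zero because no shared network signal was injected; the flip check
correctly reports NO_FLIP, and a full HTML report with montages,
motion plots and the grayplot lands in `qc_sub-01/`.

The same pipeline is available from the shell:

```sh
qcfmri synth --seed 1 --out subj/
qcfmri proc --epi subj/epi.nii.gz --anat subj/anat.nii.gz \
            --motion subj/motion.1D --mode rest --out subj/qc/
qcfmri review --dicts 'subj/qc/review.json' --mode rest --out group/
```

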