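# gaitval

**Concurrent validity and rater reliability of 2D video-based sagittal gait
analysis, reproduced end-to-end on synthetic walking trials.**

Clinical gait labs increasingly use low-cost single-camera (2D) video systems
to measure level walking, but a sagittal camera can only measure *relative
marker angles* in its calibration plane, detects gait events from marker
kinematics rather than force plates, and suffers central-projection errors
for anything off that plane. How trustworthy are its outputs compared with a
marker-based 3D optoelectronic reference — and how much do the raters who
palpate and place the markers, and the day-to-day variability of gait
itself, add on top? `gaitval` rebuilds that whole measurement-comparison
study as a tested, fully synthetic pipeline: a walking simulator with exact
ground truth stands in for the human cohort, both measurement routes are
implemented, and the agreement statistics produce the familiar validity and
reliability tables with no external data.

It is aimed at biomechanists and methodologists who want to study *how* such
validity/reliability numbers arise — which noise source moves which
statistic — and at anyone needing a well-tested reference implementation of
the agreement-statistics core.

## What is inside

* **`gaitval.synthetic`** — a sagittal gait simulator: foot-rooted rigid-chain
  construction with exact contact phases, two-link inverse kinematics,
  pelvis riding a smoothed reachability envelope, Plug-in-Gait-style lower
  body markers plus a great-trochanter marker, double-bump vertical ground
  reaction forces, and noise channels for soft-tissue/shoe artifact,
  tracking jitter, rater-dependent marker placement, and day-to-day /
  trial-to-trial gait variability. Every trial carries ground-truth events,
  joint-angle cycles and spatio-temporal parameters.
* **`gaitval.projection`** — pinhole side camera (640×480, 3.36 m × 1.58 m
  field at 2.5 m → 0.53/0.33 cm per pixel), planar calibration from a
  one-metre square, and the `D/d` central-projection scale law.
* **`gaitval.kinematics`, `gaitval.events`, `gaitval.stp`** — zero-lag
  6 Hz Butterworth filtering, relative segment angles, heel-strike /
  toe-off detection from heel and second-toe markers (2D route) or a 20 N
  force threshold (3D route), 101-point cycle normalization, and the
  spatio-temporal parameters with six-trial averaging.
* **`gaitval.reference3d`** — static-calibration joint centres and
  joint-centre-based sagittal angles: the 3D reference route.
* **`gaitval.agreement`** — the statistics core, statsmodels-style:
  `ReliabilityModel(...).fit()` → ICC(2,k)/(3,k) (absolute agreement,
  average measures) with F-bound CIs and p-values, SEM = SD·√(1−ICC),
  MDC95 = SEM·1.96·√2, repeated-measures ANOVA with η²;
  `MethodComparison(...).fit()` → paired t-test, Cohen's d and Bland–Altman
  limits of agreement, with a `plot_bland_altman()` helper. Plus the 2-SD
  outlier screen and CV%.
* **`gaitval.study`** — the full design: three raters on day 1 (randomized
  order), rater 3 again after a 1–18-day washout, six trials per session,
  camera-dropout flags, and the three output tables (validity, inter-rater,
  test–retest).
* **`gaitval` CLI** — `simulate`, `extract-2d`, `extract-3d`, `run-study`,
  `validity`, `reliability`.

## The statistics in brief

For an *n* subjects × *k* conditions matrix of one gait parameter, the
two-way ANOVA mean squares (subjects MSR, conditions MSC, error MSE) give
the absolute-agreement average-measures intraclass correlation

    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

labelled ICC(2,k) when conditions are random raters and ICC(3,k) when they
are fixed (two systems, two days). Measurement precision follows as
SEM = SD·√(1−ICC) with SD = √(SS_total/(n−1)), and the minimum detectable
change as MDC95 = SEM·1.96·√2. Method bias is read from paired t-tests,
Cohen's d, and Bland–Altman bias ± 1.96·SD of the differences.

## Worked example

```python
from gaitval import StudyConfig, run_study

result = run_study(StudyConfig(n_subjects=6, n_trials=3), seed=2)
print(result.summary())
```

prints:

```
Study run (seed 2, n=6 analysed subjects, 0 excluded by the 2-SD screen)
concurrent validity (2D vs 3D), left leg:
    stride_time: ICC(3,k)= 0.95 delta=+0.0167 d=+0.61
    toe_off_pct: ICC(3,k)= 0.61 delta=-0.842 d=-0.56
  stride_length: ICC(3,k)= 0.96 delta=-0.0234 d=-15.93
       velocity: ICC(3,k)= 0.93 delta=-0.0441 d=-1.46
        rom_hip: ICC(3,k)= 0.95 delta=-4.08 d=-1.86
       rom_knee: ICC(3,k)= 0.50 delta=-1.03 d=-0.70
      rom_ankle: ICC(3,k)= 0.92 delta=-0.409 d=-0.55
     rom_pelvis: ICC(3,k)= 0.13 delta=+2.26 d=+1.38
```

Reading it: the 2D route tracks the 3D reference closely for stride time,
stride length and velocity (ICC ≥ 0.93), with a small systematic stride
shortfall of ~2 cm (−1.6%) from the residual central-projection scale error
— tiny in absolute terms, but because it is systematic across subjects the
standardized difference d is enormous, the same pattern that makes
clinically negligible biases "statistically significant" in such studies.
Hip range of motion comes out ~4° *lower* in 2D (the 2D thigh is measured
from the soft-tissue-afflicted trochanter marker instead of a pelvis-derived
hip centre), and the pelvis tilt range is *inflated* by over 2° with a
collapsed ICC (the short, depth-asymmetric pelvis marker segment is the one
most distorted by central projection). Toe-off bias is within ±1% of the
cycle for a single small cohort like this one; averaged over many seeds the
marker-based toe-off lands systematically *later* than the force-plate
event. These are exactly the qualitative failure modes practitioners report
for single-camera gait analysis.

Every `run_study` output also carries the inter-rater and test–retest
tables (`result.interrater_table`, `result.retest_table`) with ICC, SEM,
MDC95, CV and the condition-effect ANOVA, and `result.to_csv(dir)` writes
byte-reproducible CSVs.

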