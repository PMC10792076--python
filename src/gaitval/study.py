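"""Full study orchestration: simulate a cohort, run both measurement routes,
assemble validity and reliability tables.

Reproduces the design of a concurrent-validity / rater-reliability study of
2D video gait analysis against a 3D optoelectronic reference:

* day 1 — three raters independently apply the marker set to each subject
  (order randomized per subject); six valid trials per session; both the 2D
  and 3D systems record simultaneously;
* day 2 — rater 3 repeats the procedure after a washout of 1–18 days
  (mean ≈ 6), with day-to-day gait variability applied.

Outputs mirror the three headline tables of such a study:

* **validity** — 2D vs 3D per parameter and side (mean/SD per method,
  ICC(3,k) with CI and p, paired t-test, Cohen's d, Bland–Altman);
* **inter-rater reliability** — 3D outcomes across the three raters
  (ICC(2,k), SEM, MDC95, CV, repeated-measures ANOVA with eta²);
* **test–retest reliability** — 3D outcomes of rater 3 across the two days
  (ICC(3,k), SEM, MDC95, paired t-test, Cohen's d).

Everything is deterministic per seed; two runs with the same configuration
and seed produce byte-identical CSV output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import agreement as ag
from . import kinematics as kin
from .errors import DataError, GaitvalError
from .pipelines import (extract_parameters_2d, extract_parameters_3d,
                        trial_pixels_to_sagittal)
from .projection import CameraModel, calibration_from_camera
from .reference3d import static_calibration
from .synthetic import (CohortConfig, NoiseModel, RaterModel, TrialRecording,
                        forward_kinematics, generate_static_trial,
                        generate_subject)

__all__ = ["StudyConfig", "StudyResult", "run_study", "camera_dropout"]

#: parameters reported per table; step parameters are 3D-only
VALIDITY_PARAMS = ("stride_time", "toe_off_pct", "stride_length", "velocity",
                   "rom_hip", "rom_knee", "rom_ankle", "rom_pelvis")
RELIABILITY_PARAMS = ("stride_time", "toe_off_pct", "stride_length",
                      "step_length", "step_time", "velocity",
                      "rom_hip", "rom_knee", "rom_ankle", "rom_pelvis")


@dataclass
class StudyConfig:
    """Design parameters of one simulated study run."""

    n_subjects: int = 19
    n_raters: int = 3
    n_trials: int = 6
    n_strides: int = 3
    retest_rater: int = 3            # 1-based index of the rater who returns
    washout_days: tuple = (1, 18)    # uniform range, mean ~ its midpoint
    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    rater_marker_offset_sd: float = 0.005
    rater_application_jitter_sd: float = 0.003
    rater_anthropometric_sd: float = 0.003
    hip_reference: str = "pelvis"
    filter_cutoff: float = 6.0
    outlier_screen: bool = True
    enable_dropout: bool = True
    compute_2d: bool = True

    def __post_init__(self):
        if self.n_subjects < 3:
            raise DataError("need at least 3 subjects for any agreement statistic")
        if self.n_raters < 2:
            raise DataError("need at least 2 raters")
        if self.n_trials < 1:
            raise DataError("need at least 1 trial per session")
        if not (1 <= self.retest_rater <= self.n_raters):
            raise DataError("retest_rater out of range")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StudyResult:
    """Assembled study output: three tables plus per-cell provenance."""

    validity_table: pd.DataFrame
    interrater_table: pd.DataFrame
    retest_table: pd.DataFrame
    measurements: pd.DataFrame       # long format: every session average
    run_metadata: dict

    def to_csv(self, out_dir) -> None:
        """Write all tables; a header comment records the seed and config."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = (f"# seed={self.run_metadata['seed']} "
                  f"config={self.run_metadata['config_hash']} "
                  f"version={self.run_metadata['version']}\n")
        for name, df in (("validity", self.validity_table),
                         ("interrater", self.interrater_table),
                         ("retest", self.retest_table),
                         ("measurements", self.measurements)):
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False, lineterminator="\n",
                          float_format="%.10g")

    def summary(self) -> str:
        lines = [f"Study run (seed {self.run_metadata['seed']}, "
                 f"n={self.run_metadata['n_analysed']} analysed subjects, "
                 f"{self.run_metadata['n_excluded']} excluded by the 2-SD screen)"]
        v = self.validity_table
        lines.append("concurrent validity (2D vs 3D), left leg:")
        for _, row in v[v.side == "left"].iterrows():
            lines.append(f"  {row.parameter:>13}: ICC(3,k)={row.icc:5.2f} "
                         f"delta={row.mean_diff:+.3g} d={row.cohens_d:+.2f}")
        return "\n".join(lines)


def camera_dropout(trial: TrialRecording, camera: CameraModel, side: str,
                   t_start: float, t_stop: float) -> dict[str, bool]:
    """Per-marker availability flags for the analysed cycle.

    A marker is available when its projected trajectory stays inside the
    image bounds over [t_start, t_stop]. Downstream parameters that depend
    on an unavailable marker must be reported unavailable for that trial.
    """
    if not trial.pixels_2d or side not in trial.pixels_2d:
        raise DataError(f"trial has no 2D stream for side {side!r}")
    if not trial.pixels_2d[side]:
        raise DataError("empty 2D stream")
    i0 = max(0, int(np.floor(t_start * trial.fs_2d)))
    i1 = int(np.ceil(t_stop * trial.fs_2d)) + 1
    out = {}
    for name, pix in trial.pixels_2d[side].items():
        seg = pix[i0:i1]
        if seg.size == 0:
            out[name] = False
            continue
        inside = ((seg[:, 0] >= 0) & (seg[:, 0] <= camera.image_width - 1)
                  & (seg[:, 1] >= 0) & (seg[:, 1] <= camera.image_height - 1))
        out[name] = bool(inside.all())
    return out


#: parameters invalidated when a marker drops out of the camera view
_MARKER_DEPENDENCIES = {
    "ANK": ("rom_ankle", "rom_knee"),
    "TOE2": ("rom_ankle", "toe_off_pct"),
    "HEEL": ("rom_ankle", "stride_time", "stride_length", "velocity",
             "toe_off_pct"),
    "KNE": ("rom_knee", "rom_hip"),
    "TROCH": ("rom_hip",),
    "ASI": ("rom_pelvis", "rom_hip"),
    "PSI": ("rom_pelvis", "rom_hip"),
}


def run_study(config: StudyConfig | None = None, seed: int = 0) -> StudyResult:
    """Execute the full simulated study. Deterministic per seed."""
    from . import __version__

    cfg = config or StudyConfig()
    master = np.random.default_rng([int(seed) & 0x7FFFFFFF, 424242])

    raters = [RaterModel(rater_id=i + 1,
                         marker_offset_sd=cfg.rater_marker_offset_sd,
                         application_jitter_sd=cfg.rater_application_jitter_sd,
                         anthropometric_sd=cfg.rater_anthropometric_sd)
              for i in range(cfg.n_raters)]
    cameras = {"right": CameraModel(side="right"),
               "left": CameraModel(side="left")}
    calibs = {s: calibration_from_camera(cam) for s, cam in cameras.items()}
    fspec = kin.FilterSpec(cutoff=cfg.filter_cutoff)

    rows = []
    washouts = []
    for si in range(cfg.n_subjects):
        subj_seed = int(master.integers(0, 2 ** 31 - 1))
        subject = generate_subject(cfg.cohort, rng_seed=subj_seed,
                                   subject_id=f"S{si + 1:02d}")
        rater_order = master.permutation(cfg.n_raters)
        washout = float(master.uniform(*cfg.washout_days))
        washouts.append(washout)
        day2_cad = float(np.exp(master.normal(0.0, cfg.noise.day_effect_sd)))
        day2_str = float(np.exp(master.normal(0.0, cfg.noise.day_effect_sd)))

        sessions = [(1, raters[r]) for r in rater_order]
        sessions.append((2, raters[cfg.retest_rater - 1]))

        for day, rater in sessions:
            srng = np.random.default_rng(
                [subj_seed, day, rater.rater_id, 777])
            placement = rater.draw_placement(srng)
            anthro = rater.measure_anthropometrics(subject, srng)
            static = generate_static_trial(
                subject, rater, cfg.noise,
                rng_seed=int(srng.integers(0, 2 ** 31 - 1)),
                placement=placement)
            center_model = static_calibration(static.markers_3d, anthro)
            cad_f = day2_cad if day == 2 else 1.0
            str_f = day2_str if day == 2 else 1.0

            per_trial: dict[tuple, list] = {}
            for ti in range(cfg.n_trials):
                trial = forward_kinematics(
                    subject, cfg.n_strides, rater, cfg.noise,
                    rng_seed=int(srng.integers(0, 2 ** 31 - 1)),
                    placement=placement, cadence_factor=cad_f,
                    stride_factor=str_f, cameras=cameras)
                for side in ("left", "right"):
                    try:
                        p3, _ = extract_parameters_3d(trial, center_model,
                                                      side, filter_spec=fspec)
                        per_trial.setdefault((side, "3D"), []).append(p3)
                    except GaitvalError:
                        pass
                    if cfg.compute_2d:
                        try:
                            sag = trial_pixels_to_sagittal(trial, side,
                                                           calibs[side])
                            p2, _ = extract_parameters_2d(
                                sag, trial.fs_2d, side, filter_spec=fspec,
                                hip_reference=cfg.hip_reference, center_x=0.0)
                            if cfg.enable_dropout:
                                _apply_dropout(p2, trial, cameras[side], side)
                            per_trial.setdefault((side, "2D"), []).append(p2)
                        except GaitvalError:
                            pass

            for (side, source), plist in per_trial.items():
                if not plist:
                    continue
                from .stp import average_trials
                avg = average_trials(plist)
                row = {"subject": subject.subject_id, "rater": rater.rater_id,
                       "day": day, "side": side, "source": source,
                       "n_trials": len(plist)}
                row.update({p: getattr(avg, p) for p in RELIABILITY_PARAMS})
                rows.append(row)

    measurements = pd.DataFrame(rows)
    if measurements.empty:
        raise DataError("study produced no successful measurements")

    # ---- outlier screen (2-SD, once, on the retest rater's day-1 3D data)
    ref = measurements[(measurements.rater == cfg.retest_rater)
                       & (measurements.day == 1)
                       & (measurements.source == "3D")]
    screen_cols = [p for p in ("stride_time", "stride_length", "velocity")
                   if p in ref]
    wide = ref.pivot_table(index="subject", values=screen_cols, aggfunc="mean")
    excluded: list[str] = []
    if cfg.outlier_screen and len(wide) >= 3:
        kept_idx, out_idx = ag.outlier_screen(wide.to_numpy())
        excluded = [wide.index[i] for i in out_idx]
    analysed = measurements[~measurements.subject.isin(excluded)]

    validity = _validity_table(analysed, cfg)
    interrater = _interrater_table(analysed, cfg)
    retest = _retest_table(analysed, cfg)

    meta = {
        "seed": int(seed),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "n_subjects": cfg.n_subjects,
        "n_analysed": int(analysed.subject.nunique()),
        "n_excluded": len(excluded),
        "excluded_subjects": excluded,
        "mean_washout_days": float(np.mean(washouts)),
    }
    return StudyResult(validity_table=validity, interrater_table=interrater,
                       retest_table=retest, measurements=analysed,
                       run_metadata=meta)


def _apply_dropout(params, trial, camera, side):
    """Invalidate parameters whose markers left the image during the cycle."""
    mid = trial.duration / 2.0
    half = 0.65 * params.stride_time if np.isfinite(params.stride_time) else 0.7
    flags = camera_dropout(trial, camera, side, mid - half, mid + half)
    prefix = side[0].upper()
    for base, dependent in _MARKER_DEPENDENCIES.items():
        if not flags.get(prefix + base, True):
            for p in dependent:
                setattr(params, p, float("nan"))


def _pivot(df: pd.DataFrame, param: str, column: str) -> pd.DataFrame:
    return df.pivot_table(index="subject", columns=column, values=param,
                          aggfunc="mean")


def _validity_table(df: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """2D vs 3D agreement on the retest rater's day-1 session."""
    rows = []
    sub = df[(df.rater == cfg.retest_rater) & (df.day == 1)]
    for side in ("left", "right"):
        for param in VALIDITY_PARAMS:
            wide = _pivot(sub[sub.side == side], param, "source").dropna()
            if len(wide) < 3 or not {"2D", "3D"} <= set(wide.columns):
                continue
            a, b = wide["2D"].to_numpy(), wide["3D"].to_numpy()
            res = ag.MethodComparison(a, b, parameter=param).fit()
            bias, lo, hi = res.agreement.bland_altman
            rows.append({
                "side": side, "parameter": param, "n": len(wide),
                "mean_3d": b.mean(), "sd_3d": b.std(ddof=1),
                "mean_2d": a.mean(), "sd_2d": a.std(ddof=1),
                "icc": res.icc,
                "icc_ci_low": res.icc_result.ci95[0] if res.icc_result else np.nan,
                "icc_ci_high": res.icc_result.ci95[1] if res.icc_result else np.nan,
                "icc_p": res.icc_result.p if res.icc_result else np.nan,
                "t_p": res.agreement.t_p,
                "mean_diff": res.agreement.mean_diff,
                "cohens_d": res.agreement.cohens_d,
                "loa_low": lo, "loa_high": hi,
            })
    return pd.DataFrame(rows)


def _interrater_table(df: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Consistency of the 3D outcomes across raters (day 1)."""
    rows = []
    sub = df[(df.day == 1) & (df.source == "3D")]
    for side in ("left", "right"):
        for param in RELIABILITY_PARAMS:
            wide = _pivot(sub[sub.side == side], param, "rater").dropna()
            if len(wide) < 3 or wide.shape[1] < 2:
                continue
            try:
                res = ag.ReliabilityModel(wide, model="ICC2k",
                                          parameter=param,
                                          condition_kind="raters").fit()
            except GaitvalError:
                continue
            row = {"side": side, "parameter": param, "n": len(wide),
                   "k": wide.shape[1],
                   "icc": res.icc,
                   "icc_ci_low": res.icc_result.ci95[0],
                   "icc_ci_high": res.icc_result.ci95[1],
                   "icc_p": res.icc_result.p,
                   "sem": res.sem, "mdc95": res.mdc95,
                   "eta2": res.metrics.eta2, "anova_p": res.metrics.anova_p}
            for _, cs in res.condition_stats().iterrows():
                j = int(cs.condition)
                row[f"mean_r{j}"] = cs["mean"]
                row[f"sd_r{j}"] = cs["sd"]
                row[f"cv_r{j}"] = cs["cv_pct"]
            rows.append(row)
    return pd.DataFrame(rows)


def _retest_table(df: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Test–retest consistency of the retest rater's 3D outcomes."""
    rows = []
    sub = df[(df.rater == cfg.retest_rater) & (df.source == "3D")]
    for side in ("left", "right"):
        for param in RELIABILITY_PARAMS:
            wide = _pivot(sub[sub.side == side], param, "day").dropna()
            if len(wide) < 3 or wide.shape[1] != 2:
                continue
            try:
                rel = ag.ReliabilityModel(wide, model="ICC3k", parameter=param,
                                          condition_kind="days").fit()
            except GaitvalError:
                continue
            test, retest_v = wide[1].to_numpy(), wide[2].to_numpy()
            pair = ag.paired_agreement(test, retest_v)
            rows.append({
                "side": side, "parameter": param, "n": len(wide),
                "mean_test": test.mean(), "sd_test": test.std(ddof=1),
                "mean_retest": retest_v.mean(), "sd_retest": retest_v.std(ddof=1),
                "icc": rel.icc,
                "icc_ci_low": rel.icc_result.ci95[0],
                "icc_ci_high": rel.icc_result.ci95[1],
                "icc_p": rel.icc_result.p,
                "sem": rel.sem, "mdc95": rel.mdc95,
                "t_p": pair.t_p, "mean_diff": pair.mean_diff,
                "cohens_d": pair.cohens_d,
            })
    return pd.DataFrame(rows)
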