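"""Agreement and reliability statistics for method-comparison and rater studies.

The unit of analysis is a ratings matrix: ``n`` subjects by ``k`` conditions
(two measurement systems, three raters, or two days), one gait parameter per
matrix. Everything downstream of that matrix — intraclass correlations from
the two-way ANOVA decomposition, SEM/MDC95, repeated-measures ANOVA with
eta-squared, paired t-tests with Cohen's d, Bland–Altman limits of agreement,
coefficient of variation, and the two-standard-deviation outlier screen — is
implemented here.

Two model/results pairs mirror the two study questions:

* :class:`ReliabilityModel` — consistency of one parameter across k
  conditions, fitted to the subjects-by-conditions matrix; yields ICC with
  95% CI and p, SEM, MDC95, eta² and the condition-effect ANOVA p.
* :class:`MethodComparison` — paired agreement of two measurement methods;
  yields the mean difference with paired t-test and Cohen's d, Bland–Altman
  bias and limits of agreement, and the two-column ICC.

ICC definitions follow McGraw & Wong's absolute-agreement, average-measures
forms: ICC(A,k) from a two-way model, labelled ``ICC2k`` when raters are
treated as random (inter-rater question) and ``ICC3k`` when fixed (method
comparison, test–retest). The two labels share one estimator; only the
inferential interpretation differs. Confidence intervals use the F-bounds of
the single-measure coefficient stepped up by the Spearman–Brown relation —
the same intervals standard statistical packages print for these options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UndefinedStatisticError

__all__ = [
    "RatingsMatrix",
    "IccResult",
    "ReliabilityMetrics",
    "AgreementResult",
    "ReliabilityModel",
    "ReliabilityResults",
    "MethodComparison",
    "MethodComparisonResults",
    "two_way_anova",
    "icc_two_way",
    "sem_mdc",
    "paired_agreement",
    "rm_anova_eta2",
    "outlier_screen",
    "cv_percent",
    "classify_icc",
]

# Acceptability cut-offs for ICC point estimates.
ICC_ACCEPTABLE_VALIDITY = 0.7
ICC_ACCEPTABLE_RELIABILITY = 0.75
ICC_ACCEPTABLE_INDIVIDUAL = 0.9


# ---------------------------------------------------------------------------
# containers


@dataclass
class RatingsMatrix:
    """n subjects x k conditions of one parameter, complete cases only.

    Parameters
    ----------
    values : array-like, shape (n, k)
        One gait parameter, in its native units.
    condition_kind : {"methods", "raters", "days"}
        What the columns are.
    subjects, conditions : sequences, optional
        Row / column labels.
    """

    values: np.ndarray
    condition_kind: str = "raters"
    subjects: list | None = None
    conditions: list | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DataError("ratings matrix must be 2-dimensional (subjects x conditions)")
        if not np.all(np.isfinite(v)):
            # complete-cases policy: rows with any missing value are dropped
            keep = np.all(np.isfinite(v), axis=1)
            v = v[keep]
            if self.subjects is not None:
                self.subjects = [s for s, k in zip(self.subjects, keep) if k]
        n, k = v.shape
        if n < 3:
            raise DataError(f"need at least 3 complete subjects, got {n}")
        if k < 2:
            raise DataError(f"need at least 2 conditions, got {k}")
        self.values = v
        if self.condition_kind not in ("methods", "raters", "days"):
            raise DataError(f"unknown condition_kind {self.condition_kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject: str, condition: str, value: str,
                  condition_kind: str = "raters") -> "RatingsMatrix":
        wide = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="mean")
        return cls(wide.to_numpy(), condition_kind=condition_kind,
                   subjects=list(wide.index), conditions=list(wide.columns))


@dataclass
class IccResult:
    """Intraclass correlation with its ANOVA decomposition."""

    icc: float
    ci95: tuple[float, float]
    p: float
    model: str                     # "(2,k) two-way random" | "(3,k) two-way mixed"
    definition: str = "absolute agreement"
    unit: str = "average measures"
    anova_ss: dict = field(default_factory=dict)
    n: int = 0
    k: int = 0

    def __str__(self):
        lo, hi = self.ci95
        return f"ICC{self.model.split()[0]} = {self.icc:.3f} (95% CI {lo:.3f} to {hi:.3f}, p = {self.p:.3g})"


@dataclass
class ReliabilityMetrics:
    """SEM / MDC95 family, in the units of the analysed parameter."""

    sem: float
    sd_total: float
    mdc95: float
    cv_pct: float | None = None
    eta2: float | None = None
    anova_p: float | None = None


@dataclass
class AgreementResult:
    """Paired two-method agreement: mean difference, effect size, Bland–Altman."""

    mean_diff: float
    cohens_d: float
    t_p: float
    bland_altman: tuple[float, float, float]   # bias, loa_lower, loa_upper
    sd_diff: float
    n: int
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# core decompositions


def two_way_anova(values: np.ndarray) -> dict:
    """Two-way crossed ANOVA (subjects x conditions, one observation per cell).

    Returns sums of squares, degrees of freedom and mean squares for the
    subject (rows), condition (columns) and residual strata. This single
    decomposition feeds the ICC, eta-squared and SEM computations, so the
    identity ``ss_total = ss_rows + ss_cols + ss_error`` holds exactly.
    """
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((v - grand) ** 2))
    ss_error = ss_total - ss_rows - ss_cols
    df_rows, df_cols = n - 1, k - 1
    df_error = (n - 1) * (k - 1)
    return {
        "ss_rows": ss_rows, "ss_cols": ss_cols, "ss_error": ss_error, "ss_total": ss_total,
        "df_rows": df_rows, "df_cols": df_cols, "df_error": df_error,
        "ms_rows": ss_rows / df_rows, "ms_cols": ss_cols / df_cols,
        "ms_error": ss_error / df_error,
        "n": n, "k": k,
    }


_MODEL_LABELS = {
    "ICC2k": "(2,k) two-way random",
    "ICC3k": "(3,k) two-way mixed",
}


def icc_two_way(matrix: RatingsMatrix | np.ndarray, model: str = "ICC2k",
                alpha: float = 0.05) -> IccResult:
    """Absolute-agreement, average-measures intraclass correlation.

    ``model`` selects the label/interpretation: ``"ICC2k"`` (conditions a
    random sample of raters) or ``"ICC3k"`` (conditions fixed: two systems or
    two days). Both use the ICC(A,k) estimator

        (MSR - MSE) / (MSR + (MSC - MSE) / n)

    with MSR/MSC/MSE the subject/condition/error mean squares. The p-value is
    the F test of between-subject variance (MSR/MSE); the CI comes from the
    exact F-bounds of the single-measure coefficient stepped up by
    Spearman–Brown.

    Raises
    ------
    UndefinedStatisticError
        If the between-subject variance is zero (constant rows), where the
        coefficient is undefined.
    """
    if model not in _MODEL_LABELS:
        raise DataError(f"unknown ICC model {model!r}; use 'ICC2k' or 'ICC3k'")
    if not isinstance(matrix, RatingsMatrix):
        matrix = RatingsMatrix(matrix)
    an = two_way_anova(matrix.values)
    n, k = an["n"], an["k"]
    msr, msc, mse = an["ms_rows"], an["ms_cols"], an["ms_error"]

    if an["ss_rows"] <= 1e-12 * max(an["ss_total"], 1.0):
        raise UndefinedStatisticError(
            "ICC undefined: no between-subject variance in the ratings matrix")

    denom = msr + (msc - mse) / n
    if denom == 0.0:
        raise UndefinedStatisticError("ICC undefined: degenerate ANOVA decomposition")
    icc_ak = (msr - mse) / denom

    # p-value: F test that subject variance is zero
    if mse == 0.0:
        p = 0.0
    else:
        f_obs = msr / mse
        p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))

    ci = _icc_agreement_ci(msr, msc, mse, n, k, alpha)

    return IccResult(icc=float(icc_ak), ci95=ci, p=p, model=_MODEL_LABELS[model],
                     anova_ss={key: an[key] for key in
                               ("ss_rows", "ss_cols", "ss_error", "ss_total")},
                     n=n, k=k)


def _icc_agreement_ci(msr, msc, mse, n, k, alpha=0.05):
    """McGraw–Wong F-bounds for ICC(A,1), stepped up to ICC(A,k)."""
    denom1 = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom1 <= 0 or mse == 0.0:
        # perfect agreement: degenerate interval at the point estimate
        return (1.0, 1.0) if mse == 0.0 else (np.nan, np.nan)
    icc_a1 = (msr - mse) / denom1
    one_minus = max(1.0 - icc_a1, 1e-12)
    a = (k * icc_a1) / (n * one_minus)
    b = 1.0 + (k * icc_a1 * (n - 1)) / (n * one_minus)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower1 = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper1 = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)

    def step_up(r1):
        return k * r1 / (1.0 + (k - 1) * r1)

    lo, hi = step_up(lower1), step_up(upper1)
    return (float(min(lo, hi)), float(max(lo, hi)))


def sem_mdc(icc: float, total_ss: float, n: int) -> ReliabilityMetrics:
    """Standard error of measurement and minimum detectable change.

    ``SD = sqrt(SS_total / (n - 1))`` with the total sum of squares taken from
    the ICC's ANOVA; ``SEM = SD * sqrt(1 - ICC)``; ``MDC95 = SEM * 1.96 * sqrt(2)``.
    """
    if n < 2:
        raise DataError("SEM requires at least 2 subjects")
    if total_ss < 0:
        raise DataError("total sum of squares must be non-negative")
    sd_total = float(np.sqrt(total_ss / (n - 1)))
    sem = sd_total * float(np.sqrt(max(0.0, 1.0 - icc)))
    mdc95 = sem * 1.96 * float(np.sqrt(2.0))
    return ReliabilityMetrics(sem=sem, sd_total=sd_total, mdc95=mdc95)


def rm_anova_eta2(matrix: RatingsMatrix | np.ndarray) -> tuple[float, float]:
    """Repeated-measures condition effect: (eta², p).

    eta² = SS_conditions / SS_total from the two-way decomposition; p from the
    condition F test (MSC/MSE).
    """
    if not isinstance(matrix, RatingsMatrix):
        matrix = RatingsMatrix(matrix)
    an = two_way_anova(matrix.values)
    if an["ss_total"] == 0.0:
        return 0.0, 1.0
    eta2 = an["ss_cols"] / an["ss_total"]
    if an["ms_error"] == 0.0:
        p = 1.0 if an["ss_cols"] == 0.0 else 0.0
    else:
        f_obs = an["ms_cols"] / an["ms_error"]
        p = float(stats.f.sf(f_obs, an["df_cols"], an["df_error"]))
    return float(eta2), p


def paired_agreement(a, b) -> AgreementResult:
    """Paired agreement of two methods measured on the same subjects.

    Returns the mean difference Δ = mean(a - b), Cohen's d for paired data
    (Δ / SD of differences), the paired t-test p-value, and Bland–Altman bias
    with 95% limits of agreement (bias ± 1.96 · SD of differences).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired samples must be 1-D and of equal length")
    if a.size < 3:
        raise DataError("paired agreement requires at least 3 pairs")
    d = a - b
    delta = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    flags = []
    if sd_diff == 0.0:
        if delta == 0.0:
            cohens_d, t_p = 0.0, 1.0
        else:
            cohens_d, t_p = np.nan, np.nan
            flags.append("zero-variance differences: Cohen's d and t-test undefined")
    else:
        cohens_d = delta / sd_diff
        t_p = float(stats.ttest_rel(a, b).pvalue)
    loa = 1.96 * sd_diff
    return AgreementResult(mean_diff=delta, cohens_d=float(cohens_d), t_p=t_p,
                           bland_altman=(delta, delta - loa, delta + loa),
                           sd_diff=sd_diff, n=a.size, flags=flags)


def outlier_screen(values, n_sd: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Two-SD outlier screen over one or several per-subject outcomes.

    A subject is excluded when *any* screened outcome deviates more than
    ``n_sd`` sample standard deviations (subject included in mean and SD)
    from the sample mean. Applied once, never iterated. Returns
    ``(kept_indices, excluded_indices)``.

    With fewer than 3 subjects the screen is disabled with a warning.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[0] == 1 and np.asarray(values).ndim == 1:
        v = v.T
    n = v.shape[0]
    if n <= 2:
        warnings.warn("outlier screen disabled: fewer than 3 subjects", stacklevel=2)
        return np.arange(n), np.array([], dtype=int)
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, np.abs(v - mean) / sd, 0.0)
    bad = np.any(z > n_sd, axis=1)
    return np.flatnonzero(~bad), np.flatnonzero(bad)


def cv_percent(values) -> float:
    """Coefficient of variation, percent: 100 · SD / mean (sample SD)."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m <= 0:
        raise UndefinedStatisticError(f"CV undefined for non-positive mean ({m:.4g})")
    return float(100.0 * v.std(ddof=1) / m)


def classify_icc(icc: float, context: str = "reliability") -> str:
    """Label an ICC against the study's acceptability cut-offs.

    validity > 0.7, reliability > 0.75 are 'acceptable'; > 0.9 additionally
    qualifies for decisions about an individual.
    """
    cut = {"validity": ICC_ACCEPTABLE_VALIDITY,
           "reliability": ICC_ACCEPTABLE_RELIABILITY}[context]
    if icc > ICC_ACCEPTABLE_INDIVIDUAL:
        return "acceptable (individual decisions)"
    if icc > cut:
        return "acceptable"
    return "not acceptable"


# ---------------------------------------------------------------------------
# model / results layer


class ReliabilityModel:
    """Reliability of one gait parameter across k conditions.

    Parameters
    ----------
    data : RatingsMatrix, DataFrame or (n, k) array
        Subjects in rows, conditions (raters / days / methods) in columns.
    model : {"ICC2k", "ICC3k"}
        Two-way random (inter-rater) or two-way mixed (test–retest, method)
        absolute-agreement average-measures coefficient.
    parameter, unit : str
        Names used in the summary table.
    """

    def __init__(self, data, model: str = "ICC2k", parameter: str = "parameter",
                 unit: str = "", condition_kind: str = "raters"):
        if isinstance(data, RatingsMatrix):
            self.matrix = data
        elif isinstance(data, pd.DataFrame):
            self.matrix = RatingsMatrix(data.to_numpy(), condition_kind=condition_kind,
                                        subjects=list(data.index),
                                        conditions=list(data.columns))
        else:
            self.matrix = RatingsMatrix(np.asarray(data), condition_kind=condition_kind)
        self.model = model
        self.parameter = parameter
        self.unit = unit

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject: str, condition: str, value: str,
                  **kwargs) -> "ReliabilityModel":
        return cls(RatingsMatrix.from_long(df, subject, condition, value,
                                           condition_kind=kwargs.pop("condition_kind", "raters")),
                   **kwargs)

    def fit(self) -> "ReliabilityResults":
        icc = icc_two_way(self.matrix, model=self.model)
        metrics = sem_mdc(icc.icc, icc.anova_ss["ss_total"], icc.n)
        eta2, anova_p = rm_anova_eta2(self.matrix)
        metrics.eta2, metrics.anova_p = eta2, anova_p
        return ReliabilityResults(self, icc, metrics)


class ReliabilityResults:
    """Fitted reliability analysis: ICC, SEM/MDC95, eta², condition effect."""

    def __init__(self, model: ReliabilityModel, icc: IccResult,
                 metrics: ReliabilityMetrics):
        self.model = model
        self.icc_result = icc
        self.metrics = metrics

    @property
    def icc(self) -> float:
        return self.icc_result.icc

    @property
    def sem(self) -> float:
        return self.metrics.sem

    @property
    def mdc95(self) -> float:
        return self.metrics.mdc95

    def condition_stats(self) -> pd.DataFrame:
        """Mean, SD and CV% per condition (the left block of the study tables)."""
        v = self.model.matrix.values
        labels = self.model.matrix.conditions or list(range(1, v.shape[1] + 1))
        rows = []
        for j, lab in enumerate(labels):
            col = v[:, j]
            try:
                cv = cv_percent(col)
            except UndefinedStatisticError:
                cv = np.nan
            rows.append({"condition": lab, "mean": col.mean(),
                         "sd": col.std(ddof=1), "cv_pct": cv})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r, m = self.icc_result, self.metrics
        unit = f" {self.model.unit}" if self.model.unit else ""
        lines = [
            f"Reliability analysis: {self.model.parameter}",
            f"  model: ICC{r.model}, {r.definition}, {r.unit}",
            f"  n = {r.n} subjects, k = {r.k} conditions",
            f"  ICC = {r.icc:.3f}  (95% CI {r.ci95[0]:.3f} to {r.ci95[1]:.3f}, p = {r.p:.4f})",
            f"  SEM = {m.sem:.4g}{unit}   MDC95 = {m.mdc95:.4g}{unit}",
            f"  condition effect: eta2 = {m.eta2:.3f}, p = {m.anova_p:.4f}",
            f"  classification: {classify_icc(r.icc, 'reliability')}",
        ]
        return "\n".join(lines)


class MethodComparison:
    """Concurrent validity of an index method against a reference.

    ``a`` is the index method (e.g. 2D video), ``b`` the reference (3D).
    ``fit`` returns the paired agreement statistics together with the
    two-column ICC(3,k).
    """

    def __init__(self, a, b, parameter: str = "parameter", unit: str = ""):
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.parameter = parameter
        self.unit = unit

    def fit(self) -> "MethodComparisonResults":
        agreement = paired_agreement(self.a, self.b)
        mat = RatingsMatrix(np.column_stack([self.b, self.a]), condition_kind="methods")
        icc_flag = None
        try:
            icc = icc_two_way(mat, model="ICC3k")
        except UndefinedStatisticError as exc:
            icc, icc_flag = None, str(exc)
        return MethodComparisonResults(self, agreement, icc, icc_flag)


class MethodComparisonResults:
    """Fitted method comparison: Δ, Cohen's d, t-test, Bland–Altman, ICC."""

    def __init__(self, model: MethodComparison, agreement: AgreementResult,
                 icc: IccResult | None, icc_flag: str | None = None):
        self.model = model
        self.agreement = agreement
        self.icc_result = icc
        self.icc_flag = icc_flag

    @property
    def mean_diff(self) -> float:
        return self.agreement.mean_diff

    @property
    def cohens_d(self) -> float:
        return self.agreement.cohens_d

    @property
    def icc(self) -> float:
        return self.icc_result.icc if self.icc_result is not None else np.nan

    def bland_altman_data(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": (self.model.a + self.model.b) / 2.0,
            "diff": self.model.a - self.model.b,
        })

    def plot_bland_altman(self, ax=None):
        """Bland–Altman plot: differences vs pair means, bias and 95% LoA."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.bland_altman_data()
        bias, lo, hi = self.agreement.bland_altman
        ax.scatter(data["mean"], data["diff"], s=18, color="0.3")
        ax.axhline(bias, color="tab:blue", label=f"bias = {bias:.3g}")
        for y in (lo, hi):
            ax.axhline(y, color="tab:red", linestyle="--")
        ax.set_xlabel(f"pair mean ({self.model.unit})" if self.model.unit else "pair mean")
        ax.set_ylabel("difference (index - reference)")
        ax.set_title(f"Bland-Altman: {self.model.parameter}")
        ax.legend(loc="best")
        return ax

    def summary(self) -> str:
        ag = self.agreement
        bias, lo, hi = ag.bland_altman
        unit = f" {self.model.unit}" if self.model.unit else ""
        lines = [
            f"Method comparison: {self.model.parameter} (n = {ag.n})",
            f"  mean difference = {ag.mean_diff:.4g}{unit}  (t-test p = {ag.t_p:.4f}, d = {ag.cohens_d:.2f})",
            f"  limits of agreement: {lo:.4g} to {hi:.4g}{unit}",
        ]
        if self.icc_result is not None:
            r = self.icc_result
            lines.append(f"  ICC(3,k) = {r.icc:.3f} (95% CI {r.ci95[0]:.3f} to {r.ci95[1]:.3f}, "
                         f"p = {r.p:.4f}) -> {classify_icc(r.icc, 'validity')}")
        else:
            lines.append(f"  ICC: undefined ({self.icc_flag})")
        if ag.flags:
            lines.extend(f"  flag: {f}" for f in ag.flags)
        return "\n".join(lines)
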