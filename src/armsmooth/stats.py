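"""Reliability and comparison statistics for jerk metrics.

Reliability follows the single-measurement intraclass correlation under the
two-way ANOVA decomposition (Shrout–Fleiss forms): ICC(3,1) (consistency,
trial-to-trial repeatability within a session) and ICC(2,1) (absolute
agreement, between sessions/observers), with the standard error of
measurement SEM = SD·√(1 − ICC) and the 95% minimal detectable change
MDC95 = 1.96·√2·SEM.  Negative ICC estimates are reported as computed, not
clamped.

Group comparisons use one value per subject (the median of the 9
session × trial values), a two-sided Wilcoxon signed-rank test on the paired
jerks, Bonferroni correction over the comparison family, and the mean jerk
ratio across subjects as the descriptive effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateTestError,
    InvalidArgumentError,
    MissingDataError,
    UndefinedICCError,
)

ICC_CLASS_BINS = ((0.40, "poor"), (0.60, "fair"), (0.745, "good"))


def icc_classify(value: float) -> str:
    """Reliability label: <0.40 poor, 0.40–0.59 fair, 0.60–0.74 good, >0.74 excellent."""
    for upper, label in ICC_CLASS_BINS:
        if value < upper:
            return label
    return "excellent"


@dataclass
class ReliabilityReport:
    icc: float
    icc_class: str
    sem: float
    mdc95: float


@dataclass
class ComparisonResult:
    mean_ratio: float
    p_raw: float
    p_adj: float
    family_size: int
    acceptance_level: str
    n: int


def _anova_mean_squares(matrix: np.ndarray):
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidArgumentError("need a (subjects >= 2) x (measurements >= 2) grid")
    if np.any(~np.isfinite(x)):
        raise MissingDataError("rating matrix contains missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse, ss_total


def icc(matrix: np.ndarray, design: str = "ICC31") -> float:
    """Single-measurement intraclass correlation of a subjects × raters grid.

    ``design='ICC31'``: consistency, (MSR − MSE) / (MSR + (k−1)·MSE).
    ``design='ICC21'``: absolute agreement,
    (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).
    """
    n, k, msr, msc, mse, ss_total = _anova_mean_squares(matrix)
    if ss_total == 0:
        raise UndefinedICCError("zero total variance: ICC undefined")
    if design == "ICC31":
        denom = msr + (k - 1) * mse
    elif design == "ICC21":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise InvalidArgumentError(f"unknown ICC design {design!r}")
    if denom == 0:
        raise UndefinedICCError("degenerate ANOVA decomposition")
    return float((msr - mse) / denom)


def sem_mdc(sd_pooled: float, icc_value: float) -> tuple[float, float]:
    """SEM = SD·√(1 − ICC) and MDC95 = 1.96·√2·SEM."""
    if sd_pooled < 0:
        raise InvalidArgumentError("sd_pooled must be non-negative")
    if icc_value > 1:
        raise InvalidArgumentError("ICC cannot exceed 1")
    sem = sd_pooled * math.sqrt(1 - icc_value)
    return sem, 1.96 * math.sqrt(2.0) * sem


def reliability_report(matrix: np.ndarray, design: str = "ICC31") -> ReliabilityReport:
    """ICC + classification + SEM/MDC95 for one rating matrix.

    The pooled SD is the across-subject SD of the measurement occasions
    entering the ICC (all cells of the matrix).
    """
    value = icc(matrix, design)
    sd = float(np.std(np.asarray(matrix, float), ddof=1))
    sem, mdc = sem_mdc(sd, min(value, 1.0))
    return ReliabilityReport(icc=value, icc_class=icc_classify(value), sem=sem, mdc95=mdc)


def subject_medians(
    jerk_table: pd.DataFrame,
    value_col: str = "jerk",
    subject_col: str = "subject",
) -> pd.Series:
    """One value per subject: the median over its session × trial values."""
    if jerk_table.empty:
        raise MissingDataError("empty jerk table")
    counts = jerk_table.groupby(subject_col)[value_col].count()
    if (counts == 0).any():
        raise MissingDataError("subject with zero values")
    return jerk_table.groupby(subject_col)[value_col].median()


def paired_comparison(
    x, y, family_size: int = 1, zero_method: str = "wilcox"
) -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank with Bonferroni correction.

    ``x`` and ``y`` are per-subject values of the two conditions; the mean
    jerk ratio mean(x/(x+y)) is reported descriptively.  Zero differences
    are dropped (Wilcoxon's method); the exact null distribution is used for
    n ≤ 25 remaining pairs without ties, a continuity-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D arrays")
    if len(x) < 6:
        raise InvalidArgumentError("need at least 6 pairs")
    if family_size < 1:
        raise InvalidArgumentError("family_size must be >= 1")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise DegenerateTestError("all paired differences are zero")
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        x, y, zero_method=zero_method, alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    p_raw = float(res.pvalue)
    p_adj = min(1.0, p_raw * family_size)
    if p_adj < 0.01:
        level = "<0.01"
    elif p_adj < 0.05:
        level = "<0.05"
    else:
        level = "ns"
    with np.errstate(invalid="ignore"):
        ratios = x / (x + y)
    return ComparisonResult(
        mean_ratio=float(np.nanmean(ratios)),
        p_raw=p_raw,
        p_adj=p_adj,
        family_size=family_size,
        acceptance_level=level,
        n=len(x),
    )


# ---------------------------------------------------------------------------
# cohort-level reliability battery


def _pivot(df: pd.DataFrame, index, columns, value="jerk") -> np.ndarray:
    wide = df.pivot_table(index=index, columns=columns, values=value)
    wide = wide.dropna(axis=0, how="any")  # complete-case per analysis unit
    return wide.to_numpy()


def reliability_suite(jerk_table: pd.DataFrame) -> pd.DataFrame:
    """Reliability battery per movement × metric.

    Expects a tidy table with columns subject, session, observer, movement,
    trial, arm, phase, jerk.  For each movement and each (arm, phase) metric
    it reports:

    * intra-session trial-to-trial repeatability: ICC(3,1) across the 3
      trials, subject × session units as rows;
    * inter-session intra-observer reliability: ICC(2,1) across the two
      same-observer sessions (per-session trial medians);
    * inter-session inter-observer reliability: ICC(2,1) between the first
      observer's value (median of their sessions) and the second observer's.
    """
    required = {"subject", "session", "observer", "movement", "trial", "arm", "phase", "jerk"}
    missing = required - set(jerk_table.columns)
    if missing:
        raise InvalidArgumentError(f"jerk table lacks columns {sorted(missing)}")
    rows = []
    for (movement, arm, phase), df in jerk_table.groupby(["movement", "arm", "phase"]):
        entry = {"movement": movement, "arm": arm, "phase": phase}
        try:
            intra = _pivot(df, index=["subject", "session"], columns="trial")
            rep = reliability_report(intra, "ICC31")
            entry.update(
                icc_intra=rep.icc, icc_intra_class=rep.icc_class,
                sem_intra=rep.sem, mdc_intra=rep.mdc95,
            )
        except (InvalidArgumentError, MissingDataError, UndefinedICCError):
            pass
        med = (
            df.groupby(["subject", "session", "observer"])["jerk"].median().reset_index()
        )
        observers = sorted(med["observer"].unique())
        intra_obs = med[med["observer"] == observers[0]]
        try:
            inter_sess = _pivot(intra_obs, index="subject", columns="session")
            if inter_sess.shape[1] >= 2:
                rep = reliability_report(inter_sess, "ICC21")
                entry.update(
                    icc_inter_intraobs=rep.icc, sem_inter_intraobs=rep.sem,
                    mdc_inter_intraobs=rep.mdc95,
                )
        except (InvalidArgumentError, MissingDataError, UndefinedICCError):
            pass
        if len(observers) >= 2:
            per_obs = (
                med.groupby(["subject", "observer"])["jerk"].median().reset_index()
            )
            try:
                inter_obs = _pivot(per_obs, index="subject", columns="observer")
                rep = reliability_report(inter_obs, "ICC21")
                entry.update(
                    icc_inter_interobs=rep.icc, sem_inter_interobs=rep.sem,
                    mdc_inter_interobs=rep.mdc95,
                )
            except (InvalidArgumentError, MissingDataError, UndefinedICCError):
                pass
        rows.append(entry)
    return pd.DataFrame(rows)
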