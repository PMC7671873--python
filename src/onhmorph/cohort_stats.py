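"""Repeatability and diurnal change-from-baseline statistics.

Design notes
------------
* Repeatability for a duplicate design uses the within-subject standard
  deviation ``Sw = sqrt(sum(d_i^2) / (2n))`` with ``d_i`` the difference of a
  subject's two replicates, and the coefficient of repeatability
  ``2.77 * Sw``.  CV is ``100 * Sw / |grand mean|`` (the absolute value
  matters for signed parameters whose mean is near zero).
* ``baseline_contrasts`` performs a one-way repeated-measures ANOVA across
  time points followed by many-to-one (Dunnett-type) comparisons of every
  time point against the first column (the 7 a.m. seated baseline).  With a
  balanced within-subject design the contrast statistics are equicorrelated
  (rho = 1/2) t variables on the ANOVA error degrees of freedom; adjusted
  p-values are taken from a cached Monte-Carlo sample of the max-|t| null
  distribution (>= 100,000 draws, fixed seed), which keeps results
  deterministic without external quantile tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AnalysisError

REPEATABILITY_FACTOR = 2.77  # 1.96 * sqrt(2), expected bound on |x1 - x2|
DUNNETT_NSIM = 200_000


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatabilityResult:
    parameter: str
    sw: float
    repeatability: float  # 2.77 * sw
    cv_percent: float
    grand_mean: float
    n_subjects: int


def repeatability(pairs, parameter: str = "") -> RepeatabilityResult:
    """Within-subject SD, coefficient of repeatability and CV from an
    (n_subjects, 2) array of duplicate measurements.

    Also accepts a long DataFrame with columns ``subject_id``/``value``
    (exactly two rows per subject).
    """
    if isinstance(pairs, pd.DataFrame):
        counts = pairs.groupby("subject_id")["value"].count()
        if not (counts == 2).all():
            raise AnalysisError(
                "repeatability: every subject needs exactly 2 replicates "
                f"(got counts {sorted(counts.unique())})"
            )
        wide = pairs.pivot_table(
            index="subject_id", columns=pairs.groupby("subject_id").cumcount(),
            values="value",
        )
        arr = wide.to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise AnalysisError("repeatability: expected an (n, 2) array of duplicates")
    if arr.shape[0] < 2:
        raise AnalysisError("repeatability: need >= 2 subjects")
    if not np.all(np.isfinite(arr)):
        raise AnalysisError("repeatability: non-finite measurement")
    n = arr.shape[0]
    d = arr[:, 0] - arr[:, 1]
    sw = float(np.sqrt((d ** 2).sum() / (2.0 * n)))
    grand = float(arr.mean())
    cv = 100.0 * sw / abs(grand) if grand != 0 else float("inf")
    return RepeatabilityResult(
        parameter=parameter,
        sw=sw,
        repeatability=REPEATABILITY_FACTOR * sw,
        cv_percent=cv,
        grand_mean=grand,
        n_subjects=n,
    )


# ---------------------------------------------------------------------------
# Change from baseline
# ---------------------------------------------------------------------------

@dataclass
class ChangeTable:
    """Per-subject deltas from the 7 a.m. seated baseline plus summaries."""

    deltas: pd.DataFrame    # subject_id, time_label, posture, parameter, delta
    summary: pd.DataFrame   # parameter, time_label, posture, mean, sd, se, n
    excluded_subjects: list = field(default_factory=list)


def change_from_baseline(
    cohort: pd.DataFrame,
    parameters: Sequence[str],
    baseline_label: str = "7a",
    baseline_posture: str = "SEATED",
) -> ChangeTable:
    """Subtract each subject's baseline row from every session row.

    Subjects without a baseline row are excluded (listwise, logged in
    ``excluded_subjects``).  Rows flagged ``replicate != 1`` are ignored.
    """
    df = cohort.copy()
    if "replicate" in df.columns:
        df = df[df["replicate"] == 1]
    is_base = (df["time_label"] == baseline_label) & (df["posture"] == baseline_posture)
    base = df[is_base].set_index("subject_id")
    dup = base.index[base.index.duplicated()]
    if len(dup):
        raise AnalysisError(f"multiple baseline rows for subjects {sorted(set(dup))}")
    excluded = sorted(set(df["subject_id"]) - set(base.index))
    df = df[df["subject_id"].isin(base.index)]

    rows = []
    for param in parameters:
        if param not in df.columns:
            raise AnalysisError(f"change_from_baseline: unknown parameter {param!r}")
        delta = df[param].to_numpy(dtype=float) - base.loc[
            df["subject_id"], param
        ].to_numpy(dtype=float)
        rows.append(pd.DataFrame({
            "subject_id": df["subject_id"].to_numpy(),
            "time_label": df["time_label"].to_numpy(),
            "posture": df["posture"].to_numpy(),
            "parameter": param,
            "delta": delta,
        }))
    deltas = pd.concat(rows, ignore_index=True)

    def _summarise(g: pd.DataFrame) -> pd.Series:
        v = g["delta"].dropna()
        n = len(v)
        sd = float(v.std(ddof=1)) if n > 1 else float("nan")
        return pd.Series({
            "mean": float(v.mean()) if n else float("nan"),
            "sd": sd,
            "se": sd / np.sqrt(n) if n > 1 else float("nan"),
            "n": n,
        })

    summary = (
        deltas.groupby(["parameter", "time_label", "posture"])
        .apply(_summarise, include_groups=False)
        .reset_index()
    )
    return ChangeTable(deltas=deltas, summary=summary, excluded_subjects=excluded)


# ---------------------------------------------------------------------------
# RM-ANOVA + Dunnett-type contrasts vs baseline
# ---------------------------------------------------------------------------

_MAXT_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _maxt_null_sample(n_contrasts: int, df_error: int, nsim: int = DUNNETT_NSIM) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_j |T_j| where T is a ``n_contrasts``-
    variate t with ``df_error`` degrees of freedom and pairwise correlation
    1/2 (balanced many-to-one contrasts).  Deterministic per (k, df, nsim)."""
    key = (n_contrasts, df_error, nsim)
    if key not in _MAXT_CACHE:
        rng = np.random.default_rng([n_contrasts, df_error, nsim, 771_204])
        # Z_j = (X_j - X_0)/sqrt(2) with X iid N(0,1) gives corr 1/2
        x = rng.standard_normal((nsim, n_contrasts + 1))
        z = (x[:, 1:] - x[:, :1]) / np.sqrt(2.0)
        w = rng.chisquare(df_error, size=nsim)
        t = z / np.sqrt(w / df_error)[:, None]
        _MAXT_CACHE[key] = np.sort(np.abs(t).max(axis=1))
    return _MAXT_CACHE[key]


def dunnett_critical_value(n_contrasts: int, df_error: int, alpha: float = 0.05) -> float:
    """Two-sided many-to-one critical value at family-wise level ``alpha``."""
    sample = _maxt_null_sample(n_contrasts, df_error)
    return float(np.quantile(sample, 1.0 - alpha))


@dataclass
class ContrastResult:
    """RM-ANOVA over time plus many-to-one contrasts vs the baseline column."""

    f_statistic: float
    df_time: int
    df_error: int
    p_anova: float
    t_statistics: np.ndarray          # (k-1,)
    p_adjusted: np.ndarray            # (k-1,) family-wise adjusted
    mean_differences: np.ndarray      # (k-1,) time mean minus baseline mean
    n_subjects: int
    method: str = f"monte_carlo_many_to_one(nsim={DUNNETT_NSIM})"


def rm_anova_dunnett(data: np.ndarray) -> ContrastResult:
    """Core contrast engine on a complete (n_subjects, k_times) matrix whose
    first column is the baseline."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise AnalysisError("need an (n_subjects, k>=2) matrix")
    arr = arr[np.all(np.isfinite(arr), axis=1)]  # listwise deletion
    n, k = arr.shape
    if n < 3:
        raise AnalysisError(f"need >= 3 complete subjects, got {n}")

    grand = arr.mean()
    time_means = arr.mean(axis=0)
    subj_means = arr.mean(axis=1)
    ss_time = n * ((time_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df_time = k - 1
    df_err = (k - 1) * (n - 1)
    mse = ss_err / df_err
    if mse <= 0 or not np.isfinite(mse):
        raise AnalysisError("zero within-subject variance: contrasts undefined")
    f_stat = (ss_time / df_time) / mse
    p_anova = float(stats.f.sf(f_stat, df_time, df_err))

    diffs = time_means[1:] - time_means[0]
    tstats = diffs / np.sqrt(2.0 * mse / n)
    null = _maxt_null_sample(k - 1, df_err)
    exceed = null.size - np.searchsorted(null, np.abs(tstats), side="left")
    p_adj = (exceed + 1.0) / (null.size + 1.0)
    return ContrastResult(
        f_statistic=float(f_stat),
        df_time=df_time,
        df_error=df_err,
        p_anova=p_anova,
        t_statistics=tstats,
        p_adjusted=p_adj,
        mean_differences=diffs,
        n_subjects=n,
    )


def baseline_contrasts(
    cohort: pd.DataFrame,
    parameter: str,
    session_order: Sequence[tuple[str, str]],
    baseline: tuple[str, str] = ("7a", "SEATED"),
) -> ContrastResult:
    """Many-to-one comparisons of each session against the baseline session.

    ``session_order`` lists the post-baseline sessions as (time_label,
    posture) pairs; subjects missing any listed session are dropped listwise.
    """
    df = cohort
    if "replicate" in df.columns:
        df = df[df["replicate"] == 1]
    sessions = [baseline] + [s for s in session_order if tuple(s) != tuple(baseline)]
    subjects = sorted(df["subject_id"].unique())
    mat = np.full((len(subjects), len(sessions)), np.nan)
    for j, (tl, post) in enumerate(sessions):
        sub = df[(df["time_label"] == tl) & (df["posture"] == post)]
        sub = sub.set_index("subject_id")[parameter]
        for i, sid in enumerate(subjects):
            if sid in sub.index:
                mat[i, j] = sub.loc[sid]
    return rm_anova_dunnett(mat)


# ---------------------------------------------------------------------------
# Regression and group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def ols(x, y) -> OlsResult:
    """Simple ordinary least squares y ~ x with the slope's two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise AnalysisError(f"ols: need >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise AnalysisError("ols: x is constant")
    res = stats.linregress(x, y)
    return OlsResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


@dataclass(frozen=True)
class MultipleOlsResult:
    coefficients: np.ndarray  # (const, x1, x2)
    p_values: np.ndarray
    r2: float
    f_p_value: float
    n: int


def multiple_ols(y, x1, x2) -> MultipleOlsResult:
    """OLS with two predictors and per-coefficient two-sided tests."""
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)])
    keep = np.isfinite(y) & np.all(np.isfinite(design), axis=1)
    y, design = y[keep], design[keep]
    if y.size < 4:
        raise AnalysisError(f"multiple_ols: need >= 4 points, got {y.size}")
    exog = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise AnalysisError("multiple_ols: design matrix is rank deficient")
    fit = sm.OLS(y, exog).fit()
    return MultipleOlsResult(
        coefficients=np.asarray(fit.params),
        p_values=np.asarray(fit.pvalues),
        r2=float(fit.rsquared),
        f_p_value=float(fit.f_pvalue),
        n=int(y.size),
    )


@dataclass(frozen=True)
class GroupCompareResult:
    t_statistic: float
    p_value: float
    mean_difference: float
    n1: int
    n2: int
    paired: bool


def group_compare(values, groups, paired: bool = False, subjects=None) -> GroupCompareResult:
    """Two-sided t comparison of exactly two groups.

    Unpaired by default; with ``paired=True`` observations are aligned on
    ``subjects`` (or positionally when ``subjects`` is None).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise AnalysisError(f"group_compare: need exactly 2 groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if paired:
        if subjects is not None:
            subjects = np.asarray(subjects)
            sa = pd.Series(a, index=subjects[groups == labels[0]])
            sb = pd.Series(b, index=subjects[groups == labels[1]])
            common = sa.index.intersection(sb.index)
            a, b = sa.loc[common].to_numpy(), sb.loc[common].to_numpy()
        if a.size != b.size:
            raise AnalysisError("group_compare: paired groups must align")
        if a.size < 2:
            raise AnalysisError("group_compare: need >= 2 pairs")
        d = a - b
        if np.allclose(d, 0):
            return GroupCompareResult(0.0, 1.0, 0.0, a.size, b.size, True)
        t, p = stats.ttest_rel(a, b)
    else:
        if min(a.size, b.size) < 2:
            raise AnalysisError("group_compare: each group needs n >= 2")
        t, p = stats.ttest_ind(a, b)
    return GroupCompareResult(
        t_statistic=float(t),
        p_value=float(p),
        mean_difference=float(a.mean() - b.mean()),
        n1=int(a.size),
        n2=int(b.size),
        paired=paired,
    )
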