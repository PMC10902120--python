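"""The study's statistical layer.

Inter-rater agreement (Pearson r), one-way repeated-measures ANOVA over
the four within-subject conditions of a tissue, Bonferroni-adjusted
pairwise paired t-tests, EMG associations (Kendall's tau-b and an
identity-link Gaussian model, i.e. ordinary least squares of T2 on the
numeric grade), the magic-angle regression, and the paired-t
power/sample-size computation based on the noncentral t distribution.

The condition table is a wide DataFrame: rows = subjects, columns = the
four conditions of one tissue (normal/abnormal x standard/DLR), values =
mean ROI T2 in ms.  The design is fully paired; incomplete rows are an
error rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "PairwiseResult",
    "RmAnovaResult",
    "PowerSpec",
    "pearson_corr",
    "kendall_tau",
    "rm_anova_oneway",
    "pairwise_paired_t_bonferroni",
    "linear_assoc",
    "angle_regression",
    "paired_t_power",
    "paired_t_sample_size",
    "condition_table",
]


def condition_table(cohort: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Pivot a long cohort table into the wide per-tissue condition table.

    Rater replicates are averaged (the study used the mean of both raters
    for all comparisons).  Columns are ``{group}_{recon}`` for
    group in (abnormal, normal) and recon in (standard, dlr).
    """
    sub = cohort[cohort["condition"].str.endswith(tissue)].copy()
    if sub.empty:
        raise ValueError(f"no rows for tissue {tissue!r}")
    sub["group"] = sub["condition"].str.replace(f"_{tissue}", "", regex=False)
    wide = (
        sub.groupby(["subject_id", "group", "recon"])["t2_ms"]
        .mean()
        .unstack(["group", "recon"])
    )
    wide.columns = [f"{g}_{r}" for g, r in wide.columns]
    order = [f"{g}_{r}" for g in ("abnormal", "normal") for r in ("standard", "dlr")]
    return wide[[c for c in order if c in wide.columns]]


def _check_table(table: pd.DataFrame) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete rows: the paired design requires complete cases")
    return x


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RmAnovaResult:
    f_value: float
    df_effect: float
    df_error: float
    p_value: float
    gg_epsilon: float | None = None


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    k = x.shape[1]
    S = np.cov(x, rowvar=False)
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    Sc = C @ S @ C
    lam = np.linalg.eigvalsh(Sc)
    num = lam.sum() ** 2
    den = (k - 1) * (lam**2).sum()
    return float(num / den)


def rm_anova_oneway(table: pd.DataFrame, correction: str | None = None) -> RmAnovaResult:
    """Classical one-way within-subjects ANOVA.

    F has df (k-1, (k-1)(n-1)).  No sphericity correction by default;
    ``correction="gg"`` applies the Greenhouse-Geisser epsilon to the
    degrees of freedom of the p-value.
    """
    x = _check_table(table)
    n, k = x.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile(np.arange(k), n),
            "y": x.ravel(),
        }
    )
    res = AnovaRM(long, depvar="y", subject="subject", within=["cond"]).fit()
    row = res.anova_table.iloc[0]
    f = float(row["F Value"])
    df1, df2 = float(row["Num DF"]), float(row["Den DF"])
    p = float(row["Pr > F"])
    eps = None
    if correction == "gg":
        eps = _gg_epsilon(x)
        p = float(stats.f.sf(f, eps * df1, eps * df2))
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return RmAnovaResult(f, df1, df2, p, eps)


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    t_statistic: float
    p_raw: float
    p_adjusted: float
    error: str | None = None


def pairwise_paired_t_bonferroni(table: pd.DataFrame) -> list[PairwiseResult]:
    """All pairwise two-sided paired t-tests with Bonferroni adjustment.

    For k conditions there are m = k(k-1)/2 pairs and adjusted
    p = min(1, m * raw p).  A pair whose difference vector has zero
    variance is reported with an error message instead of a statistic.
    """
    x = _check_table(table)
    cols = list(table.columns)
    k = x.shape[1]
    m = k * (k - 1) // 2
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            d = x[:, i] - x[:, j]
            if np.std(d) == 0:
                out.append(
                    PairwiseResult(cols[i], cols[j], np.nan, np.nan, np.nan,
                                   error="zero-variance difference vector")
                )
                continue
            t, p = stats.ttest_rel(x[:, i], x[:, j])
            out.append(
                PairwiseResult(cols[i], cols[j], float(t), float(p),
                               min(1.0, m * float(p)))
            )
    return out


@dataclass(frozen=True)
class LinearAssociation:
    slope: float
    intercept: float
    p_value: float
    r: float


def linear_assoc(t2, grade) -> LinearAssociation:
    """OLS of T2 on a numeric ordinal grade (identity-link Gaussian model).

    The slope is in ms per grade, with a two-sided p for slope = 0.
    """
    t2 = np.asarray(t2, dtype=float)
    g = np.asarray(grade, dtype=float)
    if len(t2) != len(g) or len(t2) < 3:
        raise ValueError("need equal-length inputs of at least 3 points")
    if np.std(g) == 0:
        raise ValueError("constant grades: slope undefined")
    res = stats.linregress(g, t2)
    return LinearAssociation(
        float(res.slope), float(res.intercept), float(res.pvalue), float(res.rvalue)
    )


def angle_regression(angle_deg, t2) -> tuple[float, float, float]:
    """OLS of T2 on the nerve-to-B0 angle: (slope ms/deg, r, p)."""
    a = np.asarray(angle_deg, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if len(a) != len(t2) or len(a) < 3:
        raise ValueError("need equal-length inputs of at least 3 points")
    if np.std(a) == 0:
        raise ValueError("zero variance in angle")
    res = stats.linregress(a, t2)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


@dataclass(frozen=True)
class PowerSpec:
    """Paired-difference power computation inputs.

    Defaults reproduce the study's power analysis: a detectable mean
    paired difference of 5.5 ms with SD of differences 6.9 ms at two-sided
    alpha 0.05 and 80% power.
    """

    delta_ms: float = 5.5
    sd_diff_ms: float = 6.9
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.delta_ms <= 0 or self.sd_diff_ms <= 0:
            raise ValueError("delta and sd must be positive")


def paired_t_power(n: int, spec: PowerSpec) -> float:
    """Exact power of the two-sided paired t-test at sample size n.

    Uses the noncentral t distribution with df = n - 1 and noncentrality
    (delta / sd) * sqrt(n).
    """
    if n < 2:
        return 0.0
    df = n - 1
    ncp = spec.delta_ms / spec.sd_diff_ms * np.sqrt(n)
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def paired_t_sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest n >= 2 whose paired-t power reaches the target."""
    for n in range(2, n_max + 1):
        if paired_t_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"target power {spec.power} unreachable within n <= {n_max}")
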