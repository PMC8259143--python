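"""Two-group comparison statistics, agreement and ROC analysis.

The comparison suite mirrors common radiology-study practice (as produced by
SPSS-style analyses): Pearson chi-square without continuity correction for
categorical variables; for quantitative variables a normality check
(Lilliefors-corrected Kolmogorov–Smirnov) dispatching to the equal-variance
pooled two-sample t test when both groups look normal, otherwise to the
Mann–Whitney U test reported as a tie-corrected Z; two-way random-effects
absolute-agreement single-measures ICC for inter-observer agreement; and
nonparametric (rank) AUC with a Hanley–McNeil 95% confidence interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonResult",
    "ROCResult",
    "pearson_chi_square",
    "pooled_t_from_summary",
    "pooled_t",
    "mann_whitney_z",
    "ks_normality",
    "compare_groups",
    "icc_agreement",
    "roc_auc",
]


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison."""

    variable: str
    test: str  # "pooled-t" | "mann-whitney" | "chi-square"
    statistic: float
    p_value: float
    df: float | None = None
    group_summaries: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class ROCResult:
    """Nonparametric AUC with Hanley–McNeil 95% CI."""

    auc: float
    ci_lower: float
    ci_upper: float
    positive_class: str
    direction: str  # "greater": higher scores indicate the positive class
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.auc <= self.ci_upper):
            raise ValueError("CI bounds do not bracket the AUC")


def pearson_chi_square(counts, variable: str = "") -> ComparisonResult:
    """Pearson chi-square on a contingency table, no continuity correction.

    Parameters
    ----------
    counts : array-like, shape (r, c)
        Nonnegative integer counts; typically 2x2 (category x diagnosis).

    Raises
    ------
    ValueError
        On negative/non-integer counts or a zero row/column total.
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be a 2-D table of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total in contingency table")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return ComparisonResult(variable=variable, test="chi-square",
                            statistic=float(chi2), p_value=float(p), df=float(df))


def pooled_t_from_summary(m1, s1, n1, m2, s2, n2,
                          variable: str = "") -> ComparisonResult:
    """Equal-variance two-sample t test from group summary statistics.

    Degrees of freedom ``n1 + n2 - 2``; the pooled variance weights each
    group's variance by ``n - 1``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return ComparisonResult(
        variable=variable, test="pooled-t", statistic=float(t),
        p_value=float(p), df=float(n1 + n2 - 2),
        group_summaries={"group1": {"mean": m1, "sd": s1, "n": n1},
                         "group2": {"mean": m2, "sd": s2, "n": n2}})


def pooled_t(x, y, variable: str = "") -> ComparisonResult:
    """Pooled t test on raw samples (routes through the summary-statistic path)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pooled_t_from_summary(x.mean(), x.std(ddof=1), x.size,
                                 y.mean(), y.std(ddof=1), y.size,
                                 variable=variable)


def _mwu_exact_p(x: np.ndarray, y: np.ndarray, u1: float) -> float:
    """Two-sided exact p by enumerating all rank assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    count = 0
    total = 0
    u_obs = min(u1, len(x) * len(y) - u1)
    for idx in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2
        u = min(u, n1 * len(y) - u)
        if u <= u_obs + 1e-9:
            count += 1
        total += 1
    return count / total


def mann_whitney_z(x, y, variable: str = "", method: str = "auto") -> ComparisonResult:
    """Mann–Whitney U test, reported as a tie-corrected normal Z.

    ``method``: "exact" enumerates all rank assignments (valid without ties),
    "asymptotic" uses the tie-corrected normal approximation without
    continuity correction (the Z that SPSS prints), and "auto" picks exact
    for small tie-free samples (both n <= 8).

    Raises
    ------
    ValueError
        If either sample is empty, or all values are tied across both samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values tied across both samples")
    n1, n2 = x.size, y.size
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    # tie-corrected normal approximation, no continuity correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        raise ValueError("degenerate rank variance (all values tied)")
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(sigma2)

    has_ties = np.any(tie_counts > 1)
    if method == "auto":
        method = "exact" if (max(n1, n2) <= 8 and not has_ties) else "asymptotic"
    if method == "exact":
        if has_ties:
            raise ValueError("exact enumeration requires tie-free samples")
        p = _mwu_exact_p(x, y, u1)
    elif method == "asymptotic":
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown method: {method!r}")
    return ComparisonResult(variable=variable, test="mann-whitney",
                            statistic=float(z), p_value=float(min(p, 1.0)),
                            extras={"u": float(u1), "method": method})


def ks_normality(x, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Kolmogorov–Smirnov normality check with Lilliefors correction.

    The normal's mean and SD are estimated from the sample, so critical
    values follow Lilliefors' distribution (the behavior of standard
    statistics packages). Returns ``(statistic, p, is_normal)`` where the
    flag compares ``p`` against ``alpha`` and drives the t-vs-Mann-Whitney
    dispatch.

    Raises
    ------
    ValueError
        If ``n < 4`` or the sample has zero variance.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("normality check requires n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample; normality undefined")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p), bool(p >= alpha)


#: Categorical variables and their level coded as 1 in contingency order.
CATEGORICAL_LEVELS = {
    "gender": ("male", "female"),
    "location": ("left", "right"),
    "growth_pattern": ("endophytic", "exophytic"),
    "pseudocapsule": (1, 0),
    "cystic": (1, 0),
    "angular": (1, 0),
}


def compare_groups(table: pd.DataFrame, variable: str,
                   label_col: str = "label",
                   positive_class: str = "ccRCC",
                   alpha: float = 0.05) -> ComparisonResult:
    """Dispatch the appropriate two-group test for one table column.

    Categorical columns go to Pearson chi-square on the level x class
    contingency table. Quantitative columns are tested for normality in each
    class; the pooled t test is used when both pass, the Mann–Whitney U
    (as Z) otherwise.

    Raises
    ------
    ValueError
        If the variable or either class is absent.
    """
    if variable not in table.columns:
        raise ValueError(f"variable {variable!r} not in table")
    labels = table[label_col]
    classes = [positive_class] + sorted(set(labels.unique()) - {positive_class})
    if len(classes) != 2 or any((labels == c).sum() == 0 for c in classes):
        raise ValueError("exactly two non-empty classes required")
    col = table[variable]
    is_categorical = (variable in CATEGORICAL_LEVELS
                      or col.dtype == object or col.dtype == bool
                      or str(col.dtype) == "category")
    g1 = col[labels == classes[0]]
    g2 = col[labels == classes[1]]
    if is_categorical:
        levels = CATEGORICAL_LEVELS.get(variable)
        ct = pd.crosstab(col, labels)
        if levels is not None:
            ct = ct.reindex(index=list(levels), columns=classes, fill_value=0)
        else:
            ct = ct[classes]
        res = pearson_chi_square(ct.to_numpy(), variable=variable)
        res.group_summaries = {str(c): ct[c].to_dict() for c in ct.columns}
        return res
    x = g1.to_numpy(dtype=float)
    y = g2.to_numpy(dtype=float)
    if min(x.size, y.size) < 4:
        # too few observations to assess normality: rank test
        res = mann_whitney_z(x, y, variable=variable, method="asymptotic")
        res.extras.update({"normality_p": None})
    else:
        _, p1, norm1 = ks_normality(x, alpha=alpha)
        _, p2, norm2 = ks_normality(y, alpha=alpha)
        if norm1 and norm2:
            res = pooled_t(x, y, variable=variable)
        else:
            res = mann_whitney_z(x, y, variable=variable,
                                 method="asymptotic")
        res.extras.update({"normality_p": (p1, p2)})
    res.group_summaries = {
        classes[0]: {"mean": x.mean(), "sd": x.std(ddof=1), "n": x.size},
        classes[1]: {"mean": y.mean(), "sd": y.std(ddof=1), "n": y.size}}
    return res


def icc_agreement(measurements) -> float:
    """Inter-observer agreement as ICC(A,1).

    Two-way random-effects, absolute-agreement, single-measures intraclass
    correlation on a lesions x observers array (or wide DataFrame).

    Raises
    ------
    ValueError
        With fewer than 2 observers, fewer than 3 lesions, or missing cells.
    """
    arr = np.asarray(measurements, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a lesions x observers array with >= 2 observers")
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 lesions")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing cells in the measurement table")
    n, k = arr.shape
    if np.allclose(arr, arr[:, [0]]):
        return 1.0  # identical observer columns: perfect agreement
    long = pd.DataFrame({
        "target": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "rating": arr.ravel(),
    })
    res = pg.intraclass_corr(long, targets="target", raters="rater",
                             ratings="rating")
    return float(res.set_index("Type").loc["ICC(A,1)", "ICC"])


def roc_auc(scores, labels, positive_class: str = "ccRCC") -> ROCResult:
    """Nonparametric (rank) AUC with Hanley–McNeil 95% CI.

    Oriented so the reported AUC is >= 0.5: if higher scores associate with
    the negative class, the score direction is flipped and recorded in
    ``direction``.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_class).astype(int)
    n1 = int(y.sum())
    n2 = int((1 - y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    a = float(roc_auc_score(y, scores))
    direction = "greater"
    if a < 0.5:
        a = 1.0 - a
        direction = "less"
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se = np.sqrt((a * (1 - a) + (n1 - 1) * (q1 - a * a)
                  + (n2 - 1) * (q2 - a * a)) / (n1 * n2))
    lo = float(np.clip(a - 1.959963984540054 * se, 0.0, 1.0))
    hi = float(np.clip(a + 1.959963984540054 * se, 0.0, 1.0))
    return ROCResult(auc=a, ci_lower=lo, ci_upper=hi,
                     positive_class=str(positive_class), direction=direction,
                     n_positive=n1, n_negative=n2)
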