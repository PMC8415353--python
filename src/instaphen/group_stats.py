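"""Group-comparison statistics: normality-gated two-sample tests, effect
sizes, regression, and a robust between-within (mixed) ANOVA on trimmed means.

The primary analysis compares participant-level feature means between the two
groups (cases vs. controls).  Each feature is tested with Welch's t-test when
both samples look Gaussian (Shapiro-Wilk) and contain no extreme outlier
(beyond 3 IQR from the nearest quartile), and with the Mann-Whitney U test
otherwise.  Standardized effect sizes (Cohen's d with pooled SD, Hedges g
small-sample correction, normal-approximation CI) accompany every row.

Temporal proportion profiles (4 time-of-day bins or 7 weekdays per subject)
are tested with a heteroscedasticity-robust mixed factorial ANOVA: Johansen-
type Q statistics on 20%-trimmed means with winsorized covariances, giving a
main effect of condition (within), of group (between), and their interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05

#: multiplier on the IQR beyond the quartiles defining an *extreme* outlier
EXTREME_IQR_FACTOR = 3.0

#: largest n1*n2 for which the Mann-Whitney p is computed by exact enumeration
MW_EXACT_LIMIT = 400


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------


def _has_extreme_outlier(x: np.ndarray, factor: float = EXTREME_IQR_FACTOR) -> bool:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return bool(np.any(x > q3 + factor * iqr) or np.any(x < q1 - factor * iqr))


def normality_gate(x, y, alpha: float = ALPHA_DEFAULT) -> str:
    """Choose ``"welch_t"`` or ``"mann_whitney"`` for a pair of samples.

    Welch's t is used iff both samples pass Shapiro-Wilk at ``alpha`` and
    neither contains an extreme outlier; otherwise the rank test is used.
    Constant samples count as non-normal.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("normality gate needs n >= 3 per sample")
    for s in (x, y):
        if np.ptp(s) == 0:  # Shapiro is undefined for constant data
            return "mann_whitney"
        if sps.shapiro(s).pvalue < alpha:
            return "mann_whitney"
        if _has_extreme_outlier(s):
            return "mann_whitney"
    return "welch_t"


def welch_t_from_stats(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> tuple[float, float, float]:
    """Welch's t, Satterthwaite df and two-sided p from summary statistics."""
    if sd_x == 0 and sd_y == 0:
        raise ValueError("both samples have zero variance")
    vx, vy = sd_x**2 / n_x, sd_y**2 / n_y
    t = (mean_x - mean_y) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (n_x - 1) + vy**2 / (n_y - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; (t, df, two-sided p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs n >= 2 per sample")
    return welch_t_from_stats(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U for the first sample, with two-sided p.

    U1 = R1 - n1(n1+1)/2 with midranks for ties.  The p-value is exact
    (enumeration) for tie-free samples with n1*n2 <= 400 and otherwise uses
    the normal approximation with tie correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("mann_whitney_u needs n >= 1 per sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    method = "exact" if (n1 * n2 <= MW_EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


def cohens_d(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> float:
    """Cohen's d with the pooled (n-1 weighted) SD; sign is mean_x - mean_y."""
    if n_x < 2 or n_y < 2:
        raise ValueError("cohens_d needs n >= 2 per group")
    pooled = math.sqrt(
        ((n_x - 1) * sd_x**2 + (n_y - 1) * sd_y**2) / (n_x + n_y - 2)
    )
    if pooled == 0:
        raise ValueError("pooled SD is zero")
    return (mean_x - mean_y) / pooled


def hedges_g(d: float, n_total: int) -> float:
    """Small-sample corrected standardized mean difference g = d*J(N)."""
    if n_total < 4:
        raise ValueError("hedges_g needs total n >= 4")
    return d * (1.0 - 3.0 / (4.0 * n_total - 9.0))


def d_confidence_interval(
    d: float, n_x: int, n_y: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation CI for d: d +/- z * SE(d)."""
    se = math.sqrt((n_x + n_y) / (n_x * n_y) + d**2 / (2.0 * (n_x + n_y)))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return d - z * se, d + z * se


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with two-sided p; NaN for constants."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_corr needs paired samples of n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Secondary regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    #: term -> (coefficient, t, p)
    coefficients: dict[str, tuple[float, float, float]]
    f_statistic: float
    df1: int
    df2: int
    f_pvalue: float
    r_squared: float


def ols_regression(response, predictors: pd.DataFrame) -> RegressionResult:
    """OLS of a participant-level feature on the covariate design.

    ``predictors`` holds one column per term (e.g. group, sex, age and race
    dummies); an intercept is added.  Raises on a rank-deficient design,
    naming the collinear columns.
    """
    import statsmodels.api as sm

    y = np.asarray(response, float)
    x = predictors.astype(float)
    if len(y) <= x.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        bad = [
            c
            for c in x.columns
            if np.linalg.matrix_rank(design.drop(columns=[c]).values)
            == np.linalg.matrix_rank(design.values)
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    coeffs = {
        term: (float(fit.params[term]), float(fit.tvalues[term]), float(fit.pvalues[term]))
        for term in design.columns
    }
    return RegressionResult(
        coefficients=coeffs,
        f_statistic=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        f_pvalue=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
    )


# ---------------------------------------------------------------------------
# Robust mixed (between-within) ANOVA on trimmed means
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTest:
    statistic: float
    df1: float
    df2: float
    pvalue: float


@dataclass(frozen=True)
class RobustAnovaResult:
    within: QTest       # main effect of the repeated condition
    between: QTest      # main effect of group
    interaction: QTest  # condition x group
    trim: float


def _trimmed_mean(col: np.ndarray, g: int) -> float:
    s = np.sort(col)
    return float(s[g: len(s) - g].mean())


def _winsorized_cov(x: np.ndarray, g: int) -> np.ndarray:
    w = np.empty_like(x)
    n = x.shape[0]
    for k in range(x.shape[1]):
        s = np.sort(x[:, k])
        w[:, k] = np.clip(x[:, k], s[g], s[n - g - 1])
    return np.cov(w, rowvar=False, ddof=1)


def _johansen_q(cmat: np.ndarray, theta: np.ndarray, v: np.ndarray,
                h: list[int], n_cond: int) -> QTest:
    """Johansen-type Q test of C theta = 0 with estimate covariance v.

    The statistic is referred to an F(q, q(q+2)/(3A)) distribution after
    scaling by c = q + 2A - 6A/(q+2), A being the usual weighted trace term
    summed over independent groups.
    """
    q = cmat.shape[0]
    m = cmat @ v @ cmat.T
    try:
        minv = np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "contrast covariance is singular; the design needs more subjects "
            "per group than within-subject conditions"
        ) from exc
    stat = float(theta @ cmat.T @ minv @ cmat @ theta)
    r = v @ cmat.T @ minv @ cmat
    p = v.shape[0]
    a = 0.0
    for j, hj in enumerate(h):
        sel = np.zeros(p)
        sel[j * n_cond: (j + 1) * n_cond] = 1.0
        mtem = r * sel[np.newaxis, :]  # R @ diag(indicator of group j block)
        a += (np.trace(mtem @ mtem) + np.trace(mtem) ** 2) / (hj - 1)
    a *= 0.5
    cval = q + 2.0 * a - 6.0 * a / (q + 2.0)
    df2 = q * (q + 2.0) / (3.0 * a) if a > 0 else np.inf
    fstat = stat / cval
    pval = float(sps.f.sf(fstat, q, df2))
    return QTest(statistic=fstat, df1=float(q), df2=float(df2), pvalue=pval)


def _successive_contrasts(k: int) -> np.ndarray:
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, i], c[i, i + 1] = 1.0, -1.0
    return c


def robust_mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "subject",
    between: str = "group",
    trim: float = 0.20,
) -> RobustAnovaResult:
    """Between-within factorial ANOVA on trimmed means (Johansen-type Q).

    ``data`` is a long table with one row per subject x condition.  Each
    group's condition-mean vector is estimated by per-condition trimmed means
    with a winsorized covariance matrix, and the three hypotheses (condition,
    group, interaction) are tested with heteroscedasticity-robust Q
    statistics and approximate F reference distributions.  With ``trim=0``
    this reduces to Johansen's classical heteroscedastic mixed model.
    """
    if not 0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    wide = data.pivot_table(index=subject, columns=within, values=dv, sort=False)
    conditions = [c for c in pd.unique(data[within]) if c in wide.columns]
    wide = wide[conditions]
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every condition")
    group_of = data.groupby(subject, sort=False)[between].first()
    groups = list(pd.unique(group_of.loc[wide.index]))
    if len(groups) < 2:
        raise ValueError("need at least 2 between-subject groups")
    n_cond = len(conditions)

    theta, blocks, h = [], [], []
    for gname in groups:
        x = wide.loc[group_of.loc[wide.index] == gname].to_numpy(float)
        n = x.shape[0]
        g = int(np.floor(trim * n))
        hj = n - 2 * g
        if hj < 2:
            raise ValueError(f"group {gname!r}: too few subjects after trimming")
        theta.extend(_trimmed_mean(x[:, k], g) for k in range(n_cond))
        blocks.append((n - 1) * _winsorized_cov(x, g) / (hj * (hj - 1)))
        h.append(hj)
    theta = np.asarray(theta)
    p = len(groups) * n_cond
    v = np.zeros((p, p))
    for j, b in enumerate(blocks):
        v[j * n_cond:(j + 1) * n_cond, j * n_cond:(j + 1) * n_cond] = b

    cj = _successive_contrasts(len(groups))
    ck = _successive_contrasts(n_cond)
    ij = np.ones((1, len(groups)))
    ik = np.ones((1, n_cond))
    return RobustAnovaResult(
        within=_johansen_q(np.kron(ij, ck), theta, v, h, n_cond),
        between=_johansen_q(np.kron(cj, ik), theta, v, h, n_cond),
        interaction=_johansen_q(np.kron(cj, ck), theta, v, h, n_cond),
        trim=trim,
    )


# ---------------------------------------------------------------------------
# Comparison table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """One report row: group summaries, gated test and effect sizes."""

    feature_name: str
    n_hv: int
    n_ssd: int
    mean_hv: float
    sd_hv: float
    mean_ssd: float
    sd_ssd: float
    test_used: str
    statistic: float
    df: float | None
    p_two_sided: float
    cohens_d: float
    ci95_d: tuple[float, float]
    hedges_g: float


def gated_comparison(
    x_ssd, y_hv, feature_name: str = "", alpha: float = ALPHA_DEFAULT
) -> GroupComparison:
    """Full gated comparison of one feature (case sample first).

    Effect sizes use the case-minus-control sign convention, so features
    elevated in controls come out negative.
    """
    x = np.asarray(x_ssd, float)
    y = np.asarray(y_hv, float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    test = normality_gate(x, y, alpha=alpha)
    if test == "welch_t":
        stat, df, p = welch_t(x, y)
    else:
        stat, p = mann_whitney_u(x, y)
        df = None
    d = cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
    return GroupComparison(
        feature_name=feature_name,
        n_hv=len(y),
        n_ssd=len(x),
        mean_hv=float(y.mean()),
        sd_hv=float(y.std(ddof=1)),
        mean_ssd=float(x.mean()),
        sd_ssd=float(x.std(ddof=1)),
        test_used=test,
        statistic=float(stat),
        df=df,
        p_two_sided=float(p),
        cohens_d=d,
        ci95_d=d_confidence_interval(d, len(x), len(y)),
        hedges_g=hedges_g(d, len(x) + len(y)),
    )


def build_comparison_table(
    features: pd.DataFrame,
    group_col: str = "group",
    feature_names: list[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Per-feature gated group comparisons as a tidy report table.

    ``features`` holds one row per participant with feature columns plus a
    group-label column ('SSD'/'HV').  Missing values are dropped pairwise;
    a feature with fewer than 3 finite values in either group yields a
    flagged row with NaN statistics rather than an error.  The optional
    Benjamini-Hochberg column adjusts the p values across rows.
    """
    if feature_names is None:
        feature_names = [c for c in features.columns if c != group_col]
    is_ssd = features[group_col] == "SSD"
    if is_ssd.sum() < 2 or (~is_ssd).sum() < 2:
        raise ValueError("need >= 2 participants per group")
    rows = []
    for name in feature_names:
        x = features.loc[is_ssd, name].to_numpy(float)
        y = features.loc[~is_ssd, name].to_numpy(float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < 3 or len(y) < 3:
            rows.append(
                {
                    "feature": name,
                    "n_hv": len(y),
                    "n_ssd": len(x),
                    "test_used": "insufficient_data",
                }
            )
            continue
        try:
            cmp_ = gated_comparison(x, y, feature_name=name, alpha=alpha)
        except ValueError:  # e.g. a feature constant in both groups
            rows.append(
                {
                    "feature": name,
                    "n_hv": len(y),
                    "n_ssd": len(x),
                    "mean_hv": float(y.mean()),
                    "sd_hv": float(y.std(ddof=1)),
                    "mean_ssd": float(x.mean()),
                    "sd_ssd": float(x.std(ddof=1)),
                    "test_used": "degenerate",
                }
            )
            continue
        rows.append(
            {
                "feature": name,
                "n_hv": cmp_.n_hv,
                "n_ssd": cmp_.n_ssd,
                "mean_hv": cmp_.mean_hv,
                "sd_hv": cmp_.sd_hv,
                "mean_ssd": cmp_.mean_ssd,
                "sd_ssd": cmp_.sd_ssd,
                "test_used": cmp_.test_used,
                "statistic": cmp_.statistic,
                "df": cmp_.df,
                "p": cmp_.p_two_sided,
                "cohens_d": cmp_.cohens_d,
                "ci95_lo": cmp_.ci95_d[0],
                "ci95_hi": cmp_.ci95_d[1],
                "hedges_g": cmp_.hedges_g,
            }
        )
    table = pd.DataFrame(rows)
    if benjamini_hochberg and "p" in table:
        from statsmodels.stats.multitest import multipletests

        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, "p"].to_numpy(), method="fdr_bh"
            )[1]
        table["p_bh"] = adj
    return table


def format_comparison_table(table: pd.DataFrame) -> str:
    """Fixed-width text rendering of a comparison table (2-dp summaries)."""
    cols = [
        ("feature", "Feature", "{}"),
        ("mean_hv", "HV Mean", "{:.2f}"),
        ("sd_hv", "HV SD", "{:.2f}"),
        ("mean_ssd", "SSD Mean", "{:.2f}"),
        ("sd_ssd", "SSD SD", "{:.2f}"),
        ("p", "p", "{:.3f}"),
        ("df", "df", "{:.2f}"),
        ("cohens_d", "Cohen's D", "{:.2f}"),
        ("ci95_lo", "CI lo", "{:.2f}"),
        ("ci95_hi", "CI hi", "{:.2f}"),
        ("hedges_g", "Hedges g", "{:.2f}"),
    ]
    lines = []
    header = "  ".join(f"{h:>10}" for _, h, _ in cols)
    lines.append(header)
    lines.append("-" * len(header))
    for _, row in table.iterrows():
        cells = []
        for key, _, fmt in cols:
            val = row.get(key)
            cells.append(
                f"{'':>10}" if val is None or (isinstance(val, float) and not np.isfinite(val))
                else f"{fmt.format(val):>10}"
            )
        lines.append("  ".join(cells))
    return "\n".join(lines)
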