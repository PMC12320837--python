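"""Downstream association statistics for the community types.

Opportunistic-pathogen burdens (the HACEK genera — Haemophilus,
Aggregatibacter, Cardiobacterium, Eikenella, Kingella — and
Fusobacterium) by microbiota type, normality-gated two-group comparisons
(Wilcoxon rank-sum unless both Anderson-Darling and Shapiro-Wilk fail to
reject normality in both groups, then Welch's t-test), Spearman
correlations between cluster cumulative abundances and serum cytokine
levels, and a logistic-regression check that host covariates (sex, age,
disease class) do not confound the type assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .contamination import benjamini_hochberg
from .community_typing import cumulative_abundance
from .core_tables import RelAbundanceTable

__all__ = [
    "HACEK_PREFIXES",
    "hacek_abundance",
    "group_compare",
    "GroupComparison",
    "cytokine_correlation",
    "covariate_check",
]

# Genus-name prefixes matched tolerantly against SILVA-L6 label dialects
HACEK_PREFIXES: tuple[str, ...] = (
    "Haemophilus",
    "Aggregatibacter",
    "Cardiobacterium",
    "Eikenella",
    "Kingella",
)


def hacek_abundance(
    rel: RelAbundanceTable, prefixes: tuple[str, ...] = HACEK_PREFIXES
) -> pd.Series:
    """Cumulative relative abundance of HACEK-group genera per sample.

    Matching is by genus-name prefix so SILVA suffix variants (e.g.
    "Haemophilus parainfluenzae group") still count.
    """
    members = [t for t in rel.taxa if any(t.startswith(p) for p in prefixes)]
    if not members:
        return pd.Series(0.0, index=rel.samples, name="hacek")
    return cumulative_abundance(rel, members).rename("hacek")


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    test: str  # "wilcoxon" | "t"
    statistic: float
    p: float
    direction: str  # "a>b" | "a<b" | "none"


def _normal_ok(x: np.ndarray, alpha: float) -> bool:
    """True when neither Anderson-Darling nor Shapiro-Wilk rejects normality."""
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    sw_p = stats.shapiro(x).pvalue
    try:
        ad_ok = stats.anderson(x, dist="norm", method="interpolate").pvalue > alpha
    except TypeError:  # older scipy: compare against tabulated critical values
        ad = stats.anderson(x, dist="norm")
        crit = dict(zip(ad.significance_level, ad.critical_values))
        ad_ok = ad.statistic < crit.get(alpha * 100, crit[min(crit)])
    return sw_p > alpha and ad_ok


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    normality_alpha: float = 0.05,
    force_test: str | None = None,
) -> GroupComparison:
    """Two-group comparison with a normality-gated choice of test.

    Welch's t-test is used only when both groups pass both normality
    tests; otherwise the two-sided Wilcoxon rank-sum (Mann-Whitney) test,
    exact for small tie-free samples.
    """
    groups = groups.loc[values.index]
    labs = sorted(groups.astype(str).unique())
    if len(labs) != 2:
        raise ValueError(f"need exactly 2 groups, got {labs}")
    xa = values[groups.astype(str) == labs[0]].dropna().to_numpy(dtype=float)
    xb = values[groups.astype(str) == labs[1]].dropna().to_numpy(dtype=float)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("each group needs >= 3 non-missing values")
    if force_test is not None:
        test = force_test
    else:
        test = (
            "t"
            if _normal_ok(xa, normality_alpha) and _normal_ok(xb, normality_alpha)
            else "wilcoxon"
        )
    if test == "t":
        res = stats.ttest_ind(xa, xb, equal_var=False)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    else:
        raise ValueError(f"unknown test {force_test!r}")
    ma, mb = float(np.median(xa)), float(np.median(xb))
    direction = "none" if ma == mb else ("a>b" if ma > mb else "a<b")
    return GroupComparison(
        group_a=labs[0],
        group_b=labs[1],
        n_a=len(xa),
        n_b=len(xb),
        median_a=ma,
        median_b=mb,
        test=test,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        direction=direction,
    )


def compare_endpoints(
    endpoints: pd.DataFrame, groups: pd.Series, normality_alpha: float = 0.05
) -> pd.DataFrame:
    """Run :func:`group_compare` per endpoint column and BH-adjust across endpoints."""
    rows = []
    for col in endpoints.columns:
        gc = group_compare(endpoints[col], groups, normality_alpha)
        rows.append({"endpoint": col, **gc.__dict__})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def cytokine_correlation(
    cluster_cum: pd.Series, cytokine: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between cluster cumulative abundance and a cytokine.

    Missing values are dropped pairwise; requires >= 5 complete pairs and a
    non-constant cytokine.
    """
    joined = pd.concat([cluster_cum, cytokine], axis=1, join="inner").dropna()
    if len(joined) < 5:
        raise ValueError(f"need >= 5 complete pairs, got {len(joined)}")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if y.nunique() < 2 or x.nunique() < 2:
        raise ValueError("correlation undefined for a constant variable")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def covariate_check(
    types: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Logistic regression of type on host covariates; per-covariate odds ratios.

    Two type levels are assumed (the multinomial model reduces to binary
    logistic).  Constant covariates are dropped with a warning column;
    complete separation is detected and reported instead of silently
    fitted.
    """
    types = types.loc[covariates.index]
    levels = sorted(types.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 type levels, got {levels}")
    if len(types) < 10:
        raise ValueError("need >= 10 subjects")
    y = (types.astype(str) == levels[1]).astype(float)
    dropped = [c for c in covariates.columns if covariates[c].nunique() < 2]
    x = pd.get_dummies(covariates.drop(columns=dropped), drop_first=True).astype(float)
    rest = [c for c in x.columns if x[c].nunique() < 2]
    dropped += rest
    x = x.drop(columns=rest)
    rows = []
    if x.shape[1] == 0:
        return pd.DataFrame(rows, columns=["covariate", "odds_ratio", "ci_low", "ci_high", "p", "note"])
    xc = sm.add_constant(x)
    separated = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, xc).fit(disp=0, maxiter=200)
    except Exception:
        separated = True
        fit = None
    for c in x.columns:
        if separated or fit is None:
            rows.append(
                {
                    "covariate": c,
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "note": "complete separation; consider a penalized fit",
                }
            )
            continue
        beta = fit.params[c]
        se = fit.bse[c]
        rows.append(
            {
                "covariate": c,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": float(fit.pvalues[c]),
                "note": "",
            }
        )
    for c in dropped:
        rows.append(
            {
                "covariate": c,
                "odds_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "note": "dropped: no variance",
            }
        )
    return pd.DataFrame(rows)
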