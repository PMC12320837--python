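"""Contamination control for low-biomass samples.

Blank extraction/amplification controls carry far fewer reads than
biological samples and a distinct taxonomic composition dominated by
reagent and environment contaminants.  This module compares read counts
between sample groups (pairwise Wilcoxon rank-sum with Benjamini-Hochberg
correction), separates controls from biological samples by PCA of
clr-transformed profiles with 95% confidence ellipses, ranks the taxa that
discriminate the classes by PLS-DA VIP scores, scores each sample's
cumulative contaminant fraction, and flags biological samples that are
compositionally indistinguishable from controls.

Exclusion rule: a biological sample is flagged when its first-two-PC
coordinate falls inside the controls' 95% ellipse (chi-square quantile of
the 2-D Gaussian fitted to control scores) OR its cumulative contaminant
relative abundance exceeds a configurable threshold (default 0.25).  A
nucleic-acid yield below the configured floor is recorded as a
corroborating reason only, never a sole cause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .config import AnalysisConfig
from .core_tables import ClrTable, RelAbundanceTable

__all__ = [
    "compare_read_counts",
    "control_separation",
    "PCASummary",
    "plsda_discriminative_taxa",
    "vip_scores",
    "contaminant_fraction",
    "flag_excluded_samples",
    "ContaminationReport",
]


def compare_read_counts(totals: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests on per-sample read totals.

    Groups with fewer than 2 samples are skipped with a warning; p-values
    are BH-adjusted across the tested pairs.
    """
    groups = groups.loc[totals.index]
    sizes = groups.value_counts()
    usable = [g for g in sizes.index if sizes[g] >= 2]
    skipped = [g for g in sizes.index if sizes[g] < 2]
    if skipped:
        warnings.warn(f"skipping groups with < 2 samples: {skipped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples")
    rows = []
    for ga, gb in combinations(sorted(map(str, usable)), 2):
        xa = totals[groups.astype(str) == ga].to_numpy(dtype=float)
        xb = totals[groups.astype(str) == gb].to_numpy(dtype=float)
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": float(np.median(xa)),
                "median_b": float(np.median(xb)),
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, never below the raw p)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class PCASummary:
    scores: pd.DataFrame  # samples x (PC1, PC2)
    loadings: pd.DataFrame  # taxa x PCs
    explained_variance_ratio: np.ndarray
    ellipses: dict[str, dict]  # label -> {mean, cov, chi2_quantile}
    top_taxa: dict[str, list[str]]  # PC -> taxa by |loading|
    labels: pd.Series


def control_separation(
    clr: ClrTable,
    labels: pd.Series,
    n_components: int = 2,
    n_top: int = 10,
    ellipse_level: float = 0.95,
) -> PCASummary:
    """PCA biplot summary of clr profiles with per-label 95% confidence ellipses."""
    labels = labels.loc[clr.samples]
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError(f"each label needs >= 3 samples, got {counts.to_dict()}")
    x = clr.data.to_numpy(dtype=float).T  # samples x taxa
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"rank-deficient input: reducing components to {k}", stacklevel=2
        )
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=clr.samples, columns=cols)
    load = pd.DataFrame(pca.components_.T, index=clr.taxa, columns=cols)
    chi2_q = stats.chi2.ppf(ellipse_level, df=2)
    ellipses = {}
    for lab in counts.index:
        pts = scores_df.loc[labels == lab, cols[: min(2, k)]].to_numpy()
        ellipses[str(lab)] = {
            "mean": pts.mean(axis=0),
            "cov": np.cov(pts, rowvar=False),
            "chi2_quantile": chi2_q,
        }
    top = {c: load[c].abs().sort_values(ascending=False).head(n_top).index.tolist() for c in cols}
    return PCASummary(
        scores=scores_df,
        loadings=load,
        explained_variance_ratio=pca.explained_variance_ratio_,
        ellipses=ellipses,
        top_taxa=top,
        labels=labels,
    )


def vip_scores(pls: PLSRegression, x: np.ndarray) -> np.ndarray:
    """Variable-importance-in-projection scores of a fitted PLS2 model.

    Normalised so that the mean of the squared VIPs over features is 1.
    """
    t = pls.x_scores_
    w = pls.x_weights_
    q = pls.y_loadings_
    p_feat = w.shape[0]
    # explained sum of squares of Y per component
    ss = (t**2).sum(axis=0) * (q**2).sum(axis=0)
    wnorm = w / np.sqrt((w**2).sum(axis=0, keepdims=True))
    vip = np.sqrt(p_feat * ((wnorm**2) @ ss) / ss.sum())
    return vip


def plsda_discriminative_taxa(
    clr: ClrTable,
    labels: pd.Series,
    n_components: int = 2,
    n_top: int = 23,
) -> pd.DataFrame:
    """Rank taxa discriminating classes by PLS-DA VIP score.

    Fits PLS2 regression of the clr matrix on a one-hot class matrix and
    ranks taxa by VIP over the first ``n_components`` latent variables.
    """
    labels = labels.loc[clr.samples]
    classes = sorted(labels.astype(str).unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = clr.data.to_numpy(dtype=float).T
    y = np.column_stack([(labels.astype(str) == c).to_numpy(float) for c in classes])
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(x, y)
    vip = vip_scores(pls, x)
    out = pd.DataFrame({"taxon": clr.taxa, "vip": vip}).sort_values(
        "vip", ascending=False, kind="mergesort"
    )
    return out.head(min(n_top, len(out))).reset_index(drop=True)


def contaminant_fraction(
    rel: RelAbundanceTable, contaminant_taxa
) -> pd.Series:
    """Cumulative relative abundance of the contaminant taxon set per sample."""
    contaminant_taxa = set(contaminant_taxa)
    if not contaminant_taxa:
        raise ValueError("contaminant taxon set is empty")
    present = [t for t in rel.taxa if t in contaminant_taxa]
    if not present:
        return pd.Series(0.0, index=rel.samples, name="contaminant_fraction")
    return rel.data.loc[present].sum(axis=0).rename("contaminant_fraction")


@dataclass
class ContaminationReport:
    read_count_tests: pd.DataFrame | None
    pca: PCASummary | None
    discriminative_taxa: pd.DataFrame | None
    contaminant_fractions: pd.Series
    excluded: pd.DataFrame  # sample_id, reason


def _inside_ellipse(point: np.ndarray, ellipse: dict) -> bool:
    diff = point - ellipse["mean"]
    cov = np.atleast_2d(ellipse["cov"])
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(cov)
    return float(diff @ inv @ diff) <= ellipse["chi2_quantile"]


def flag_excluded_samples(
    pca: PCASummary,
    fractions: pd.Series,
    yields: pd.Series | None = None,
    cfg: AnalysisConfig | None = None,
    control_label: str = "control",
    biological_label: str = "biological",
) -> pd.DataFrame:
    """Flag biological samples indistinguishable from controls.

    Criteria (OR): PC1/PC2 coordinate inside the controls' 95% ellipse;
    contaminant fraction above ``cfg.exclusion_fraction``.  Low yield is
    annotated as a corroborating reason on already-flagged samples.
    Returns a frame with sample_id and reason in {composition, fraction,
    both}, plus a low_yield boolean.
    """
    if pca is None:
        raise ValueError("PCA summary required")
    cfg = cfg or AnalysisConfig()
    if control_label not in pca.ellipses:
        raise ValueError(f"no ellipse for label {control_label!r}")
    ellipse = pca.ellipses[control_label]
    rows = []
    bio = pca.labels[pca.labels == biological_label].index
    pc_cols = list(pca.scores.columns[:2])
    for sid in bio:
        point = pca.scores.loc[sid, pc_cols].to_numpy(dtype=float)
        by_comp = _inside_ellipse(point, ellipse)
        by_frac = float(fractions.get(sid, 0.0)) > cfg.exclusion_fraction
        if not (by_comp or by_frac):
            continue
        reason = "both" if (by_comp and by_frac) else ("composition" if by_comp else "fraction")
        low_yield = bool(
            yields is not None
            and sid in yields.index
            and pd.notna(yields[sid])
            and float(yields[sid]) < cfg.yield_floor_ng_ul
        )
        rows.append({"sample_id": sid, "reason": reason, "low_yield": low_yield})
    return pd.DataFrame(rows, columns=["sample_id", "reason", "low_yield"])
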