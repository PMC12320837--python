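"""Paired DNA/RNA transcriptional-activity profiling.

16S rRNA gene (DNA) profiles describe which taxa are present; 16S rRNA
transcript (RNA/cDNA) profiles describe which are transcriptionally
active.  For each taxon this module computes the log2 ratio of mean RNA to
mean DNA relative abundance at a location, tests the DNA-vs-RNA difference
on the clr scale with a linear mixed model (location and amplicon as fixed
effects, subject as random intercept — the Gaussian identity-link case of
a GLMM), adjusts across taxa with Benjamini-Hochberg, and classifies taxa
as ``active`` (log2 ratio >= +0.6, q < 0.1), ``inactive`` (<= -0.6,
q < 0.1) or ``ns``.

Phantom taxa — detected above threshold only in RNA-derived profiles and
never in any DNA profile — are removed up front as reverse-transcription /
amplification artifacts.

Within each taxon's model, DNA-vs-RNA contrasts per location are reported
both raw and with a single-step max-|z| (Tukey-family) adjustment over the
contrast set; the across-taxa BH adjustment is applied to the raw contrast
p-values, separately per location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

from .config import AnalysisConfig
from .contamination import benjamini_hochberg
from .core_tables import (
    FeatureTable,
    RelAbundanceTable,
    clr_transform,
    prevalence_filter,
    to_relative,
)

__all__ = [
    "phantom_filter",
    "fit_taxon_lmm",
    "TaxonFit",
    "activity_table",
    "profile_activity",
]


def phantom_filter(
    dna: RelAbundanceTable,
    rna: RelAbundanceTable,
    threshold: float = 0.01,
) -> tuple[list[str], list[str]]:
    """Split taxa into (kept, removed) by the phantom-taxon rule.

    A taxon is a phantom when its relative abundance exceeds ``threshold``
    (fraction scale; default 1%) in at least one RNA sample while being
    exactly zero in every DNA sample.
    """
    shared = [t for t in dna.taxa if t in set(rna.taxa)]
    removed = []
    for t in shared:
        if (rna.data.loc[t] > threshold).any() and (dna.data.loc[t] == 0).all():
            removed.append(t)
    kept = [t for t in shared if t not in set(removed)]
    return kept, removed


@dataclass
class TaxonFit:
    taxon: str
    converged: bool
    formula: str
    emm: pd.DataFrame  # location, amplicon, emm, se
    contrasts: pd.DataFrame  # location, estimate, se, z, p_raw, p_tukey, ci_low, ci_high
    r2_marginal: float
    r2_conditional: float
    note: str = ""


def _tukey_adjust(z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step max-|z| adjustment over a set of correlated contrasts."""
    k = len(z)
    if k == 1:
        return 2 * stats.norm.sf(np.abs(z))
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=corr, allow_singular=True)
    out = np.empty(k)
    for i, zi in enumerate(np.abs(z)):
        inside = mvn.cdf(np.full(k, zi), lower_limit=np.full(k, -zi))
        out[i] = min(1.0, max(0.0, 1.0 - float(inside)))
    return out


def fit_taxon_lmm(values: pd.Series, meta: pd.DataFrame) -> TaxonFit | None:
    """Fit the per-taxon mixed model and DNA-vs-RNA contrasts per location.

    ``values`` holds the taxon's clr values indexed by sample id; ``meta``
    must carry subject_id, location and amplicon for those samples.  The
    model is ``clr ~ location * amplicon`` with a random intercept per
    subject, fitted by REML; with a single location or amplicon level the
    design degrades gracefully.  Returns None when the model cannot be fit.
    """
    m = meta.set_index("sample_id").loc[values.index]
    df = pd.DataFrame(
        {
            "y": values.to_numpy(dtype=float),
            "location": m["location"].to_numpy(),
            "amplicon": m["amplicon"].to_numpy(),
            "subject": m["subject_id"].to_numpy(),
        }
    )
    n_loc = df["location"].nunique()
    n_amp = df["amplicon"].nunique()
    if df["subject"].nunique() < 3:
        return None
    if n_loc < 2 and n_amp < 2:
        return None
    if n_loc >= 2 and n_amp >= 2:
        formula = "y ~ C(location) * C(amplicon)"
    elif n_amp >= 2:
        formula = "y ~ C(amplicon)"
    else:
        formula = "y ~ C(location)"
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject"])
            res = model.fit(reml=True)
        except Exception:
            return None
        if not res.converged and "*" in formula:
            formula = formula.replace("*", "+")
            note = "interaction dropped (singular fit)"
            try:
                model = smf.mixedlm(formula, df, groups=df["subject"])
                res = model.fit(reml=True)
            except Exception:
                return None
        if not res.converged:
            return None

    design_info = model.data.design_info
    beta = res.fe_params.to_numpy()
    cov = res.cov_params().to_numpy()[: len(beta), : len(beta)]

    cells = pd.DataFrame(
        [
            {"location": loc, "amplicon": amp}
            for loc in sorted(df["location"].unique())
            for amp in sorted(df["amplicon"].unique())
        ]
    )
    x_cells = np.asarray(patsy.build_design_matrices([design_info], cells)[0])
    emm = cells.copy()
    emm["emm"] = x_cells @ beta
    emm["se"] = np.sqrt(np.einsum("ij,jk,ik->i", x_cells, cov, x_cells))

    contrasts = pd.DataFrame(
        columns=["location", "estimate", "se", "z", "p_raw", "p_tukey", "ci_low", "ci_high"]
    )
    if n_amp >= 2:
        rows = []
        lmat = []
        for loc in sorted(df["location"].unique()):
            x_rna = np.asarray(
                patsy.build_design_matrices(
                    [design_info], pd.DataFrame({"location": [loc], "amplicon": ["RNA"]})
                )[0]
            )[0]
            x_dna = np.asarray(
                patsy.build_design_matrices(
                    [design_info], pd.DataFrame({"location": [loc], "amplicon": ["DNA"]})
                )[0]
            )[0]
            lvec = x_rna - x_dna
            est = float(lvec @ beta)
            se = float(np.sqrt(lvec @ cov @ lvec))
            rows.append({"location": loc, "estimate": est, "se": se})
            lmat.append(lvec)
        lmat = np.array(lmat)
        contrasts = pd.DataFrame(rows)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrasts["z"] = contrasts["estimate"] / contrasts["se"]
        contrasts["p_raw"] = 2 * stats.norm.sf(np.abs(contrasts["z"]))
        ccov = lmat @ cov @ lmat.T
        d = np.sqrt(np.diag(ccov))
        corr = ccov / np.outer(d, d)
        contrasts["p_tukey"] = _tukey_adjust(contrasts["z"].to_numpy(), corr)
        zc = stats.norm.ppf(0.975)
        contrasts["ci_low"] = contrasts["estimate"] - zc * contrasts["se"]
        contrasts["ci_high"] = contrasts["estimate"] + zc * contrasts["se"]

    # variance-partition R^2: fixed / total and (fixed + random) / total
    fitted_fixed = model.exog @ beta
    var_f = float(np.var(fitted_fixed))
    var_r = float(res.cov_re.to_numpy()[0, 0]) if res.cov_re.size else 0.0
    var_e = float(res.scale)
    total = var_f + var_r + var_e
    return TaxonFit(
        taxon=str(values.name),
        converged=True,
        formula=formula,
        emm=emm,
        contrasts=contrasts,
        r2_marginal=var_f / total if total > 0 else np.nan,
        r2_conditional=(var_f + var_r) / total if total > 0 else np.nan,
        note=note,
    )


def activity_table(
    dna: RelAbundanceTable,
    rna: RelAbundanceTable,
    fits: dict[str, TaxonFit | None],
    cfg: AnalysisConfig,
    location: str,
    dna_samples: list[str] | None = None,
    rna_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Build the per-location volcano table of ActivityRecords.

    The log2 ratio divides the arithmetic-mean RNA relative abundance by
    the arithmetic-mean DNA relative abundance per taxon; q-values are BH
    over the per-taxon DNA-vs-RNA contrast p-values at this location.
    """
    dna_cols = dna_samples or dna.samples
    rna_cols = rna_samples or rna.samples
    rows = []
    for taxon in dna.taxa:
        if taxon not in set(rna.taxa):
            continue
        fit = fits.get(taxon)
        mean_dna = float(dna.data.loc[taxon, dna_cols].mean())
        mean_rna = float(rna.data.loc[taxon, rna_cols].mean())
        if mean_dna == 0:
            rows.append(
                {
                    "taxon": taxon,
                    "mean_rel_dna": mean_dna,
                    "mean_rel_rna": mean_rna,
                    "log2_ratio": np.nan,
                    "estimate": np.nan,
                    "p": np.nan,
                    "excluded_reason": "zero mean DNA abundance",
                }
            )
            continue
        log2_ratio = float(np.log2(mean_rna / mean_dna)) if mean_rna > 0 else -np.inf
        p = np.nan
        est = np.nan
        ci_low = ci_high = np.nan
        if fit is not None and len(fit.contrasts):
            row = fit.contrasts[fit.contrasts["location"] == location]
            if len(row):
                p = float(row["p_raw"].iloc[0])
                est = float(row["estimate"].iloc[0])
                ci_low = float(row["ci_low"].iloc[0])
                ci_high = float(row["ci_high"].iloc[0])
        rows.append(
            {
                "taxon": taxon,
                "mean_rel_dna": mean_dna,
                "mean_rel_rna": mean_rna,
                "log2_ratio": log2_ratio,
                "estimate": est,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p": p,
                "excluded_reason": "",
            }
        )
    out = pd.DataFrame(rows)
    if not len(out):
        return out
    testable = out["p"].notna()
    out["q"] = np.nan
    if testable.any():
        out.loc[testable, "q"] = benjamini_hochberg(out.loc[testable, "p"].to_numpy())
    cut, qcut = cfg.log2_ratio_cut, cfg.q_cut
    def classify(r):
        if pd.isna(r["q"]) or pd.isna(r["log2_ratio"]):
            return "ns"
        if r["log2_ratio"] >= cut and r["q"] < qcut:
            return "active"
        if r["log2_ratio"] <= -cut and r["q"] < qcut:
            return "inactive"
        return "ns"
    out["class"] = out.apply(classify, axis=1)
    return out


def profile_activity(
    counts: FeatureTable,
    meta: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    phantom_threshold: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """End-to-end activity profiling: filters, mixed models, volcano tables.

    Applies the phantom-taxon and prevalence filters, clr-transforms the
    pseudocounted retained composition, fits one mixed model per taxon,
    and returns one volcano table per location.
    """
    cfg = cfg or AnalysisConfig()
    m = meta.set_index("sample_id")
    bio = [
        s
        for s in counts.samples
        if m.loc[s, "sample_class"] == "biological" and m.loc[s, "control_type"] == "none"
    ]
    counts = counts.subset_samples(bio)
    dna_ids = [s for s in bio if m.loc[s, "amplicon"] == "DNA"]
    rna_ids = [s for s in bio if m.loc[s, "amplicon"] == "RNA"]
    rel_raw = to_relative(counts, pseudocount=0)
    dna_raw = RelAbundanceTable(rel_raw.data[dna_ids])
    rna_raw = RelAbundanceTable(rel_raw.data[rna_ids])
    kept, _phantoms = phantom_filter(dna_raw, rna_raw, phantom_threshold)
    rel_kept = RelAbundanceTable(rel_raw.data.loc[kept])
    rel_prev = prevalence_filter(
        rel_kept, cfg.prevalence_min_rel, cfg.prevalence_min_samples
    )
    retained = rel_prev.taxa
    sub_counts = FeatureTable(counts.data.loc[retained].copy())
    rel_pc = to_relative(sub_counts, pseudocount=cfg.pseudocount)
    clr = clr_transform(rel_pc)

    fits: dict[str, TaxonFit | None] = {}
    for taxon in retained:
        fits[taxon] = fit_taxon_lmm(clr.data.loc[taxon], meta)

    dna_rel = RelAbundanceTable(rel_raw.data.loc[retained, dna_ids])
    rna_rel = RelAbundanceTable(rel_raw.data.loc[retained, rna_ids])
    out = {}
    for loc in sorted(m.loc[bio, "location"].unique()):
        d_ids = [s for s in dna_ids if m.loc[s, "location"] == loc]
        r_ids = [s for s in rna_ids if m.loc[s, "location"] == loc]
        if not d_ids or not r_ids:
            continue
        out[loc] = activity_table(
            dna_rel, rna_rel, fits, cfg, loc, dna_samples=d_ids, rna_samples=r_ids
        )
    return out
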