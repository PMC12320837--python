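"""Co-occurrence clustering and cluster-dominance community typing.

The upper-GI microbiota of saliva, stomach and duodenum is organised
around two inversely correlated blocks of co-occurring genera, anchored by
Prevotella 7 and Neisseria.  This module discovers such blocks by
hierarchical clustering of Spearman co-occurrence (distance = 1 - rho,
dendrogram cut at height 1, silhouette-validated), extracts a named
anchor's cluster, and types samples by the ratio of the two clusters'
cumulative relative abundances: a sample is the ``Prevotella7`` type when
the Prevotella 7 cluster's cumulative abundance is at least 2.5-fold that
of the Neisseria cluster, and ``low_both`` flags samples where both
cumulative abundances fall below 10%.

Cluster definitions are portable: a typing run may re-discover clusters
from the cohort at hand or load the packaged reference member lists
(10 + 13 genera), which is what re-typing an external cohort requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_samples

from .config import AnalysisConfig
from .core_tables import RelAbundanceTable
from .synthetic import reference_clusters  # packaged member lists

__all__ = [
    "spearman_matrix",
    "cluster_taxa",
    "TaxonClusterSet",
    "anchor_cluster",
    "assign_type",
    "TypingRecord",
    "cumulative_abundance",
    "type_cohort",
    "cross_site_consistency",
    "cross_site_taxon_correlation",
    "reference_clusters",
]


def spearman_matrix(rel: RelAbundanceTable, min_samples: int = 5) -> pd.DataFrame:
    """Pairwise Spearman rho over samples, for taxa occurring in >= ``min_samples`` samples.

    Constant taxa (zero rank variance) are dropped with the low-occurrence
    taxa, since their correlation is undefined.
    """
    if len(rel.samples) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples, got {len(rel.samples)}"
        )
    data = rel.data
    occ = (data > 0).sum(axis=1)
    keep = data.index[(occ >= min_samples) & (data.std(axis=1) > 0)]
    sub = data.loc[keep]
    if len(keep) < 2:
        raise ValueError("fewer than 2 taxa pass the occurrence filter")
    rho, _ = spearmanr(sub.to_numpy(), axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=keep, columns=keep)


@dataclass
class TaxonClusterSet:
    rho: pd.DataFrame
    distance: pd.DataFrame  # 1 - rho, in [0, 2]
    linkage_matrix: np.ndarray
    labels: pd.Series  # taxon -> cluster id
    silhouette: pd.Series  # taxon -> silhouette width (0 for singletons)
    n_strong_correlations: int  # pairs with |rho| > strong_corr_cut

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def cluster_taxa(rho: pd.DataFrame, cfg: AnalysisConfig | None = None) -> TaxonClusterSet:
    """Agglomerative clustering of taxa on d = 1 - rho, cut at ``cfg.cut_height``.

    Merges at distance exactly equal to the cut height are kept (strict
    inequality splits), matching ``scipy.fcluster`` distance-criterion
    semantics.  Singleton clusters get silhouette width 0.
    """
    cfg = cfg or AnalysisConfig()
    taxa = list(rho.index)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa to cluster")
    d = 1.0 - rho.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    method = "ward" if cfg.linkage_method == "ward" else cfg.linkage_method
    z = linkage(squareform(d, checks=False), method=method)
    labels = fcluster(z, t=cfg.cut_height, criterion="distance")
    sil = np.zeros(len(taxa))
    if 1 < len(np.unique(labels)) < len(taxa):
        sil = silhouette_samples(d, labels, metric="precomputed")
        # silhouette of singleton clusters is 0 by convention
        for cid, cnt in zip(*np.unique(labels, return_counts=True)):
            if cnt == 1:
                sil[labels == cid] = 0.0
    iu = np.triu_indices(len(taxa), k=1)
    strong = int((np.abs(rho.to_numpy()[iu]) > cfg.strong_corr_cut).sum())
    return TaxonClusterSet(
        rho=rho,
        distance=pd.DataFrame(d, index=taxa, columns=taxa),
        linkage_matrix=z,
        labels=pd.Series(labels, index=taxa, name="cluster"),
        silhouette=pd.Series(sil, index=taxa, name="silhouette"),
        n_strong_correlations=strong,
    )


def anchor_cluster(cs: TaxonClusterSet, anchor: str) -> list[str]:
    """Members of the anchor genus's cluster with silhouette width > 0.

    The anchor itself is always included, whatever its silhouette.
    """
    if anchor not in cs.labels.index:
        raise KeyError(
            f"anchor {anchor!r} not among clustered taxa; available: "
            f"{sorted(cs.labels.index)}"
        )
    cid = cs.labels[anchor]
    members = [
        t
        for t in cs.members(cid)
        if t == anchor or cs.silhouette[t] > 0
    ]
    return members


@dataclass
class TypingRecord:
    subject_id: str
    location: str
    amplicon: str
    sample_id: str
    p7_cum: float
    neis_cum: float
    ratio: float  # inf when neis_cum == 0 and p7_cum > 0; nan when both 0
    type: str  # "Prevotella7" | "other"
    low_both: bool
    degenerate: bool = False  # neis_cum == 0 edge case


def assign_type(
    p7_cum: float, neis_cum: float, cfg: AnalysisConfig | None = None
) -> tuple[str, float, bool, bool]:
    """Apply the cluster-dominance rule: (type, ratio, low_both, degenerate).

    ``Prevotella7`` iff p7_cum >= fold_threshold * neis_cum ("at least
    2.5-fold"); with neis_cum == 0 the ratio is undefined and the call
    falls back to p7_cum > 0.  low_both is set independently when both
    cumulative abundances are below the low-both threshold.
    """
    cfg = cfg or AnalysisConfig()
    if not (0 <= p7_cum <= 1 and 0 <= neis_cum <= 1):
        raise ValueError("cumulative abundances must lie in [0, 1]")
    degenerate = neis_cum == 0
    if degenerate:
        ratio = np.inf if p7_cum > 0 else np.nan
        typ = "Prevotella7" if p7_cum > 0 else "other"
    else:
        ratio = p7_cum / neis_cum
        typ = "Prevotella7" if p7_cum >= cfg.fold_threshold * neis_cum else "other"
    low_both = p7_cum < cfg.low_both_threshold and neis_cum < cfg.low_both_threshold
    return typ, float(ratio), low_both, degenerate


def cumulative_abundance(rel: RelAbundanceTable, members) -> pd.Series:
    """Per-sample sum of relative abundances over a taxon set.

    Members absent from the table contribute 0.
    """
    members = list(members)
    if not members:
        raise ValueError("member set is empty")
    present = [t for t in members if t in set(rel.taxa)]
    if not present:
        return pd.Series(0.0, index=rel.samples, name="cumulative")
    return rel.data.loc[present].sum(axis=0).rename("cumulative")


def type_cohort(
    rel: RelAbundanceTable,
    meta: pd.DataFrame,
    p7_members,
    neis_members,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Type every sample by the two clusters' cumulative-abundance ratio."""
    cfg = cfg or AnalysisConfig()
    p7 = cumulative_abundance(rel, p7_members)
    ne = cumulative_abundance(rel, neis_members)
    m = meta.set_index("sample_id")
    rows = []
    for sid in rel.samples:
        typ, ratio, low_both, degen = assign_type(float(p7[sid]), float(ne[sid]), cfg)
        rows.append(
            {
                "sample_id": sid,
                "subject_id": m.loc[sid, "subject_id"] if sid in m.index else "",
                "location": m.loc[sid, "location"] if sid in m.index else "",
                "amplicon": m.loc[sid, "amplicon"] if sid in m.index else "",
                "p7_cum": float(p7[sid]),
                "neis_cum": float(ne[sid]),
                "ratio": ratio,
                "type": typ,
                "low_both": low_both,
                "degenerate": degen,
            }
        )
    return pd.DataFrame(rows)


def cross_site_consistency(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject agreement of assigned types between sampled locations.

    Expects the frame produced by :func:`type_cohort` (one amplicon at a
    time is the meaningful unit).  Subjects typed at fewer than 2 locations
    are excluded and reported with ``n_locations``.
    """
    rows = []
    for (subject, amplicon), grp in records.groupby(["subject_id", "amplicon"]):
        types = grp.set_index("location")["type"]
        locs = sorted(types.index)
        row = {
            "subject_id": subject,
            "amplicon": amplicon,
            "n_locations": len(locs),
            "consistent": None,
            "n_switches": None,
        }
        if len(locs) >= 2:
            pairs = list(combinations(locs, 2))
            switches = sum(types[a] != types[b] for a, b in pairs)
            row["consistent"] = switches == 0
            row["n_switches"] = switches
        rows.append(row)
    return pd.DataFrame(rows)


def cross_site_taxon_correlation(
    site_a: RelAbundanceTable,
    site_b: RelAbundanceTable,
    taxon_subset=None,
) -> tuple[float, float]:
    """Spearman correlation of per-taxon mean relative abundance between two sites."""
    shared = [t for t in site_a.taxa if t in set(site_b.taxa)]
    if taxon_subset is not None:
        subset = set(taxon_subset)
        shared = [t for t in shared if t in subset]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared taxa, got {len(shared)}")
    ma = site_a.data.loc[shared].mean(axis=1)
    mb = site_b.data.loc[shared].mean(axis=1)
    rho, p = spearmanr(ma, mb)
    return float(rho), float(p)
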