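"""Alpha/beta diversity and permutation testing.

Shannon entropy per sample, Bray-Curtis dissimilarity, classical PCoA, a
seed-deterministic ANOSIM permutation test, within-subject between-location
dissimilarities, and the shared-taxa fraction between paired samples.

ANOSIM uses the standard rank statistic
``R = (mean between-group rank - mean within-group rank) / (M / 2)`` with
``M = n(n-1)/2`` pairwise distances, and the permutation p-value carries
the +1 correction ``p = (1 + #{R_perm >= R_obs}) / (1 + n_perm)`` so p can
never be 0 (at 999 permutations the floor is 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core_tables import RelAbundanceTable

__all__ = [
    "shannon",
    "bray_curtis",
    "pcoa",
    "PCoAResult",
    "anosim",
    "within_subject_bcd",
    "shared_taxa_fraction",
]


def shannon(rel: RelAbundanceTable, base: float = 2.0) -> pd.Series:
    """Shannon index H = -sum p_i log_base p_i per sample (zero terms drop out)."""
    values = rel.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(values > 0, values * np.log(values), 0.0)
    h = -terms.sum(axis=0) / np.log(base)
    return pd.Series(h, index=rel.samples, name="shannon")


def bray_curtis(rel: RelAbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    if len(rel.samples) < 2:
        raise ValueError("need at least 2 samples")
    x = rel.data.to_numpy(dtype=float).T  # samples x taxa
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=rel.samples, columns=rel.samples)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes, positive eigenvalues only
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives reported)
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame) -> PCoAResult:
    """Classical metric MDS of a square dissimilarity matrix.

    Double-centers -d^2/2 and eigendecomposes; coordinates are returned for
    strictly positive eigenvalues, negative eigenvalues are reported as-is.
    Axis signs are fixed so the largest-|value| coordinate on each axis is
    positive.
    """
    dm = np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals[np.abs(evals) < 1e-12] = 0.0
    pos = evals > 0
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    total = evals[pos].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=evals,
        proportion_explained=(evals[pos] / total) if total > 0 else evals[pos],
    )


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    d: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """ANOSIM test of group separation on a dissimilarity matrix.

    Returns (R, p).  Deterministic for a given seed.
    """
    labels = np.asarray(pd.Series(groups))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if len(labels) != n:
        raise ValueError("group labels do not match distance matrix size")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm[iu])
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, same)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, same_p) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(r_obs), float(p)


def within_subject_bcd(
    d: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-subject Bray-Curtis dissimilarity between location pairs.

    One row per (subject, amplicon, location pair) with both locations
    sampled; missing pairs are skipped and reported via the returned
    frame's complement.
    """
    meta = meta.set_index("sample_id")
    rows = []
    for (subject, amplicon), grp in meta[meta["sample_class"] == "biological"].groupby(
        ["subject_id", "amplicon"]
    ):
        locs = {
            row["location"]: sid
            for sid, row in grp.iterrows()
            if sid in d.index
        }
        wanted = pairs or list(combinations(sorted(locs), 2))
        for la, lb in wanted:
            if la in locs and lb in locs:
                rows.append(
                    {
                        "subject_id": subject,
                        "amplicon": amplicon,
                        "location_a": la,
                        "location_b": lb,
                        "bcd": float(d.loc[locs[la], locs[lb]]),
                    }
                )
    return pd.DataFrame(rows, columns=["subject_id", "amplicon", "location_a", "location_b", "bcd"])


def shared_taxa_fraction(
    source: pd.Series,
    target: pd.Series,
    min_rel: float = 0.0,
) -> float | None:
    """Fraction of taxa detected in ``source`` that are also detected in ``target``.

    Detection means relative abundance strictly above ``min_rel`` (default:
    any non-zero value).  Returns None when the source detects nothing.
    """
    src = set(source.index[source > min_rel])
    if not src:
        return None
    tgt = set(target.index[target > min_rel])
    return len(src & tgt) / len(src)
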