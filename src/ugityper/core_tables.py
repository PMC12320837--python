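"""Genus-level feature tables and the shared compositional transforms.

The whole pipeline operates on genus (L6) count tables: taxa as rows,
samples as columns, non-negative integer counts.  This module provides the
table containers, TSV/BIOM 2.1 I/O, the per-sample metadata registry, and
the transforms every downstream stage shares — rarefaction, pseudocounted
relative abundance, the centered log-ratio (clr) transform, and the
prevalence filter.

Compositional conventions
-------------------------
Relative abundances are fractions (columns sum to 1).  The pseudocount is
added to zero *count* cells only, before normalisation, so non-zero counts
are untouched and the resulting fractions remain directly interpretable.
clr(x)_i = ln(x_i / g(x)) with g the geometric mean over taxa of one
sample; clr columns sum to 0 and are invariant to per-sample
rescaling.  The prevalence filter keeps taxa with relative abundance
strictly above ``min_rel`` in at least ``min_samples`` samples and does not
renormalise by default.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "FeatureTable",
    "RelAbundanceTable",
    "ClrTable",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "validate_metadata",
    "rarefy",
    "to_relative",
    "clr_transform",
    "prevalence_filter",
]

logger = logging.getLogger(__name__)

LOCATIONS = ("esophagus", "stomach", "duodenum", "saliva")
AMPLICONS = ("DNA", "RNA")
SAMPLE_CLASSES = ("biological", "control")
CONTROL_TYPES = (
    "B:DNA-PCR",
    "B:RNA-RT-PCR",
    "B:RNA-PCR",
    "B:RT-PCR",
    "B:PCR",
    "E/S/D:RNA-PCR",
    "none",
)

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "host",
    "location",
    "amplicon",
    "sample_class",
    "control_type",
)


class ValidationError(ValueError):
    """Raised when a table or metadata frame violates its invariants."""


@dataclass
class FeatureTable:
    """Genus x sample matrix of non-negative integer counts."""

    data: pd.DataFrame  # index: taxa, columns: sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate taxon labels")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric counts")
        if (values < 0).any():
            raise ValidationError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("non-integer counts")
        self.data = self.data.astype(np.int64)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy())


@dataclass
class RelAbundanceTable:
    """Per-sample proportions on the same axes as a FeatureTable."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any() or (values > 1 + 1e-12).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=0)
        # all-retained tables sum to 1; prevalence-filtered tables sum to <= 1
        if (sums > 1 + 1e-9).any():
            raise ValidationError("sample columns sum to more than 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ClrTable:
    """Centered log-ratio values; each sample column sums to zero."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.to_numpy(dtype=float).sum(axis=0)
        if not np.all(np.abs(sums) < 1e-6):
            raise ValidationError("clr columns must sum to 0")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# I/O


def read_feature_table(path: str | Path, format: str = "tsv") -> FeatureTable:
    """Read a genus count table from TSV (taxa rows) or BIOM 2.1 (HDF5).

    Duplicate taxon rows are merged by summation with a warning.  A TSV
    whose first column holds sample ids instead of taxa can be fixed by the
    caller via transposition; orientation auto-detection lives in the
    pipeline layer where metadata is available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise ValidationError(f"malformed TSV {path}: {exc}") from exc
        bad = df.apply(pd.to_numeric, errors="coerce")
        if bad.isna().any().any():
            row, col = next(
                (r, c) for r, c in zip(*np.where(bad.isna().to_numpy()))
            )
            raise ValidationError(
                f"non-numeric count at taxon {df.index[row]!r}, "
                f"sample {df.columns[col]!r} in {path}"
            )
        df = bad
    elif format == "biom":
        df = _read_biom(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("merging duplicate taxon labels by summation: %s", dupes)
        df = df.groupby(level=0, sort=False).sum()
    df.index.name = None
    df.columns.name = None
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.data.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom(path: Path) -> pd.DataFrame:
    # minimal BIOM v2.1 (HDF5) reader: observation-major CSR matrix
    with h5py.File(path, "r") as h5:
        taxa = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["observation/ids"][:]]
        samples = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["sample/ids"][:]]
        grp = h5["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(taxa), len(samples)),
        )
    return pd.DataFrame(mat.toarray(), index=taxa, columns=samples)


def _write_biom(table: FeatureTable, path: Path) -> None:
    import datetime

    mat = sparse.csr_matrix(table.data.to_numpy(dtype=float))
    matc = mat.tocsc()
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = "http://biom-format.org"
        h5.attrs["format-version"] = (2, 1)
        h5.attrs["generated-by"] = "ugityper"
        h5.attrs["creation-date"] = datetime.datetime.now().isoformat()
        h5.attrs["shape"] = mat.shape
        h5.attrs["nnz"] = mat.nnz
        obs = h5.create_group("observation")
        obs.create_dataset("ids", data=[t.encode() for t in table.taxa])
        om = obs.create_group("matrix")
        om.create_dataset("data", data=mat.data)
        om.create_dataset("indices", data=mat.indices)
        om.create_dataset("indptr", data=mat.indptr)
        obs.create_group("metadata")
        obs.create_group("group-metadata")
        smp = h5.create_group("sample")
        smp.create_dataset("ids", data=[s.encode() for s in table.samples])
        sm = smp.create_group("matrix")
        sm.create_dataset("data", data=matc.data)
        sm.create_dataset("indices", data=matc.indices)
        sm.create_dataset("indptr", data=matc.indptr)
        smp.create_group("metadata")
        smp.create_group("group-metadata")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame) -> None:
    missing = set(REQUIRED_METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing required columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    for col, allowed in (
        ("host", ("mouse", "human")),
        ("location", LOCATIONS),
        ("amplicon", AMPLICONS),
        ("sample_class", SAMPLE_CLASSES),
        ("control_type", CONTROL_TYPES),
    ):
        bad = set(meta[col]) - set(allowed)
        if bad:
            raise ValidationError(f"invalid values in metadata column {col}: {sorted(bad)}")
    controls = meta[meta["sample_class"] == "control"]
    if (controls["control_type"] == "none").any():
        raise ValidationError("control samples must carry a control_type")
    bio = meta[meta["sample_class"] == "biological"]
    key = bio[["subject_id", "location", "amplicon"]]
    # E/S/D:RNA-PCR rows are DNA-contamination checks on biological material
    # and may duplicate a subject/location/amplicon cell
    ordinary = bio[bio["control_type"] == "none"]
    if ordinary[["subject_id", "location", "amplicon"]].duplicated().any():
        raise ValidationError(
            "(subject_id, location, amplicon) must be unique among biological samples"
        )


# ---------------------------------------------------------------------------
# Transforms


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream keyed on (seed, sample id) so sample order is irrelevant
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode())])
    )


def rarefy(
    table: FeatureTable, depth: int, seed: int
) -> tuple[FeatureTable, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and returned
    as the second element.  Deterministic for a given seed regardless of
    sample order.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be > 0, got {depth}")
    totals = table.sample_totals()
    dropped = [s for s in table.samples if totals[s] < depth]
    kept = [s for s in table.samples if totals[s] >= depth]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    out = np.zeros((len(table.taxa), len(kept)), dtype=np.int64)
    counts = table.data.to_numpy()
    col_of = {s: j for j, s in enumerate(table.samples)}
    for j, sid in enumerate(kept):
        col = counts[:, col_of[sid]]
        rng = _sample_rng(seed, sid)
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return FeatureTable(pd.DataFrame(out, index=table.taxa, columns=kept)), dropped


def to_relative(table: FeatureTable, pseudocount: float = 1.0) -> RelAbundanceTable:
    """Convert counts to proportions, pseudocounting zero cells only."""
    values = table.data.to_numpy(dtype=float)
    if values.sum(axis=0).min() + pseudocount * len(table.taxa) <= 0:
        raise ValidationError("empty sample: zero total count and zero pseudocount")
    values = np.where(values == 0, pseudocount, values)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("sample with non-positive total after pseudocounting")
    return RelAbundanceTable(
        pd.DataFrame(values / totals, index=table.taxa, columns=table.samples)
    )


def clr_transform(rel: RelAbundanceTable) -> ClrTable:
    """Centered log-ratio transform of strictly positive compositions."""
    values = rel.data.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValidationError(
            "clr requires strictly positive values; apply a pseudocount upstream"
        )
    logs = np.log(values)
    centered = logs - logs.mean(axis=0, keepdims=True)
    return ClrTable(pd.DataFrame(centered, index=rel.taxa, columns=rel.samples))


def prevalence_filter(
    rel: RelAbundanceTable,
    min_rel: float = 0.001,
    min_samples: int = 3,
    renormalize: bool = False,
) -> RelAbundanceTable:
    """Keep taxa with relative abundance strictly > ``min_rel`` in >= ``min_samples`` samples."""
    values = rel.data.to_numpy(dtype=float)
    keep = (values > min_rel).sum(axis=1) >= min_samples
    out = rel.data.loc[keep].copy()
    if renormalize:
        out = out / out.sum(axis=0)
    return RelAbundanceTable(out)
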