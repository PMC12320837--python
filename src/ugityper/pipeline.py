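"""End-to-end orchestration of the upper-GI microbiota analysis.

Stage order follows the analysis logic: contamination gate on unrarefied
profiles, rarefaction, alpha/beta diversity, DNA/RNA activity profiling,
co-occurrence clustering and community typing, then the association
statistics.  Every stage writes a TSV/JSON report, exclusions carry reason
codes, and a RunManifest records the config snapshot, input digests,
per-stage sample/taxon counts and the seed, so a rerun on identical inputs
is bit-reproducible.

Also holds the adapter that turns an external species-level count table
(e.g. an external duodenal-aspirate cohort) into a genus-level
FeatureTable consumable by the typing stage with the packaged reference
clusters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import profile_activity
from .associations import compare_endpoints, cytokine_correlation, hacek_abundance
from .config import AnalysisConfig, ConfigError
from .contamination import (
    compare_read_counts,
    contaminant_fraction,
    control_separation,
    flag_excluded_samples,
    plsda_discriminative_taxa,
)
from .core_tables import (
    FeatureTable,
    RelAbundanceTable,
    clr_transform,
    prevalence_filter,
    rarefy,
    read_feature_table,
    read_metadata,
    to_relative,
    validate_metadata,
)
from .diversity import anosim, bray_curtis, pcoa, shannon, within_subject_bcd
from .community_typing import (
    anchor_cluster,
    cluster_taxa,
    cross_site_consistency,
    reference_clusters,
    spearman_matrix,
    type_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["run_full", "RunManifest", "reimagine_adapter"]


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]  # path -> sha256
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    stage_counts: dict[str, dict] = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_full(
    table_path: str | Path,
    meta_path: str | Path,
    out_dir: str | Path,
    cfg: AnalysisConfig | None = None,
    contaminant_taxa: list[str] | None = None,
    cluster_mode: str = "discover",
    typing_location: str = "saliva",
) -> Path:
    """Run contamination gate -> rarefaction -> diversity -> activity ->
    typing -> associations, writing per-stage reports under ``out_dir``.

    ``cluster_mode`` is either ``discover`` (Spearman clustering of the
    cohort at the typing location) or a path to a cluster-membership JSON
    (``{"clusters": {"Prevotella 7": [...], "Neisseria": [...]}}``).
    """
    cfg = cfg or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg.to_dict(),
        inputs={str(table_path): _digest(table_path), str(meta_path): _digest(meta_path)},
        seed=cfg.rng_seed,
        started=datetime.now(timezone.utc).isoformat(),
    )

    table = read_feature_table(table_path)
    meta = read_metadata(meta_path)
    missing = set(table.samples) - set(meta["sample_id"])
    if missing:
        raise ConfigError(f"samples absent from metadata: {sorted(missing)[:5]} ...")
    m = meta.set_index("sample_id")
    manifest.stage_counts["input"] = {
        "taxa": len(table.taxa),
        "samples": len(table.samples),
    }

    # --- stage 1: contamination gate (unrarefied, as controls are shallow)
    labels = m.loc[table.samples, "sample_class"]
    excluded_ids: list[str] = []
    if (labels == "control").sum() >= 3 and (labels == "biological").sum() >= 3:
        totals = table.sample_totals()
        groups = m.loc[table.samples].apply(
            lambda r: r["control_type"] if r["sample_class"] == "control" else "biological",
            axis=1,
        )
        try:
            rc = compare_read_counts(totals, groups)
            rc.to_csv(out / "contamination_read_counts.tsv", sep="\t", index=False)
        except ValueError:
            logger.warning("read-count comparison skipped (degenerate grouping)")
        rel_unrar = to_relative(table, cfg.pseudocount)
        clr = clr_transform(rel_unrar)
        pca = control_separation(clr, labels)
        disc = plsda_discriminative_taxa(clr, labels)
        disc.to_csv(out / "contamination_discriminative_taxa.tsv", sep="\t", index=False)
        if contaminant_taxa is None:
            # discriminative AND control-enriched: VIP alone also ranks taxa
            # that mark biological samples
            ctrl_ids = labels.index[labels == "control"]
            bio_all = labels.index[labels == "biological"]
            contaminant_taxa = [
                t
                for t in disc["taxon"]
                if clr.data.loc[t, ctrl_ids].mean() > clr.data.loc[t, bio_all].mean()
            ][:10]
        rel_raw = to_relative(table, 0)
        fracs = contaminant_fraction(rel_raw, contaminant_taxa)
        yields = (
            m["yield_ng_ul"] if "yield_ng_ul" in m.columns else None
        )
        flags = flag_excluded_samples(pca, fracs, yields, cfg)
        flags.to_csv(out / "contamination_exclusions.tsv", sep="\t", index=False)
        fracs.to_frame().to_csv(out / "contaminant_fractions.tsv", sep="\t")
        excluded_ids = flags["sample_id"].tolist()
        manifest.exclusions += [
            {"stage": "contamination", **row} for row in flags.to_dict("records")
        ]
    else:
        logger.warning("no controls present: contamination stage skipped")

    bio_ids = [
        s
        for s in table.samples
        if m.loc[s, "sample_class"] == "biological"
        and m.loc[s, "control_type"] == "none"
        and s not in set(excluded_ids)
    ]
    table_bio = table.subset_samples(bio_ids)
    manifest.stage_counts["contamination_gate"] = {"samples": len(bio_ids)}

    # --- stage 2: rarefaction (host-specific depth)
    hosts = m.loc[bio_ids, "host"].unique()
    depth = cfg.rarefaction_depth(hosts[0]) if len(hosts) == 1 else min(
        cfg.rarefaction_depth(h) for h in hosts
    )
    rare, dropped = rarefy(table_bio, depth, cfg.rng_seed)
    manifest.exclusions += [
        {"stage": "rarefaction", "sample_id": s, "reason": "low_depth"} for s in dropped
    ]
    manifest.stage_counts["rarefaction"] = {
        "depth": depth,
        "samples": len(rare.samples),
        "dropped": len(dropped),
    }
    rel = to_relative(rare, 0)

    # --- stage 3: diversity
    sh = shannon(rel, cfg.shannon_log_base)
    sh.to_frame().to_csv(out / "alpha_shannon.tsv", sep="\t")
    bc = bray_curtis(rel)
    bc.to_csv(out / "bray_curtis.tsv", sep="\t")
    coords = pcoa(bc)
    coords.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    loc_groups = m.loc[rare.samples, "location"]
    amp_groups = m.loc[rare.samples, "amplicon"]
    anosim_out = {}
    for name, grp in (("location", loc_groups), ("amplicon", amp_groups)):
        if grp.nunique() >= 2 and grp.value_counts().min() >= 2:
            r, p = anosim(bc, grp, cfg.anosim_permutations, cfg.rng_seed)
            anosim_out[name] = {"R": r, "p": p, "permutations": cfg.anosim_permutations}
    (out / "anosim.json").write_text(json.dumps(anosim_out, indent=2))
    wsb = within_subject_bcd(bc, meta)
    wsb.to_csv(out / "within_subject_bcd.tsv", sep="\t", index=False)

    # --- stage 4: activity profiling (uses unrarefied counts, paired filters)
    volcanoes = profile_activity(table_bio, meta, cfg)
    for loc, tab in volcanoes.items():
        tab.to_csv(out / f"activity_{loc}.tsv", sep="\t", index=False)
    manifest.stage_counts["activity"] = {
        loc: int(len(tab)) for loc, tab in volcanoes.items()
    }

    # --- stage 5: clustering + typing (DNA samples, rarefied relative abundances)
    dna_ids = [s for s in rare.samples if m.loc[s, "amplicon"] == "DNA"]
    rel_dna = RelAbundanceTable(rel.data[dna_ids])
    if cluster_mode == "discover":
        loc_ids = [s for s in dna_ids if m.loc[s, "location"] == typing_location]
        rel_loc = RelAbundanceTable(rel.data[loc_ids])
        rho = spearman_matrix(rel_loc, cfg.corr_min_samples)
        cs = cluster_taxa(rho, cfg)
        p7_members = anchor_cluster(cs, "Prevotella 7")
        neis_members = anchor_cluster(cs, "Neisseria")
        cs.silhouette.to_frame().join(cs.labels).to_csv(
            out / "cluster_silhouette.tsv", sep="\t"
        )
    else:
        ref = json.loads(Path(cluster_mode).read_text())["clusters"]
        p7_members = ref["Prevotella 7"]
        neis_members = ref["Neisseria"]
    (out / "cluster_members.json").write_text(
        json.dumps({"Prevotella 7": p7_members, "Neisseria": neis_members}, indent=2)
    )
    records = type_cohort(rel_dna, meta, p7_members, neis_members, cfg)
    records.to_csv(out / "typing_records.tsv", sep="\t", index=False)
    consistency = cross_site_consistency(records)
    consistency.to_csv(out / "typing_consistency.tsv", sep="\t", index=False)
    manifest.stage_counts["typing"] = {
        "samples": len(records),
        "prevotella7": int((records["type"] == "Prevotella7").sum()),
        "low_both": int(records["low_both"].sum()),
    }

    # --- stage 6: associations
    hacek = hacek_abundance(rel_dna)
    fuso = (
        rel_dna.data.loc["Fusobacterium"]
        if "Fusobacterium" in rel_dna.data.index
        else pd.Series(0.0, index=rel_dna.samples)
    )
    endpoints = pd.DataFrame({"hacek": hacek, "fusobacterium": fuso})
    type_by_sample = records.set_index("sample_id")["type"]
    assoc = None
    if type_by_sample.loc[endpoints.index].nunique() == 2:
        counts = type_by_sample.loc[endpoints.index].value_counts()
        if counts.min() >= 3:
            assoc = compare_endpoints(endpoints, type_by_sample)
            assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    cyto_cols = [c for c in meta.columns if c.startswith("cytokine_")]
    cyto_out = {}
    if cyto_cols:
        from .community_typing import cumulative_abundance

        p7_cum = cumulative_abundance(rel_dna, p7_members)
        subj_cum = p7_cum.groupby(m.loc[p7_cum.index, "subject_id"]).mean()
        for c in cyto_cols:
            per_subj = meta.drop_duplicates("subject_id").set_index("subject_id")[c]
            try:
                rho_c, p_c = cytokine_correlation(subj_cum, per_subj)
                cyto_out[c] = {"rho": rho_c, "p": p_c}
            except ValueError as exc:
                cyto_out[c] = {"error": str(exc)}
    (out / "cytokine_correlations.json").write_text(json.dumps(cyto_out, indent=2))

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "run_manifest.json")
    return out


def reimagine_adapter(
    species_counts: pd.DataFrame,
    genus_map: dict[str, str] | pd.Series,
) -> tuple[FeatureTable, list[str]]:
    """Aggregate an external species-level count table to genus level.

    ``species_counts`` has species labels as the index and sample columns;
    ``genus_map`` maps species label -> genus label in the reference
    cluster dialect.  Unmapped species are summed into an ``unmapped``
    bucket and their labels returned.  Raises when nothing maps.
    """
    if isinstance(genus_map, pd.Series):
        genus_map = genus_map.to_dict()
    if not genus_map:
        raise ValueError("empty species-to-genus mapping")
    mapped = species_counts.index.to_series().map(genus_map)
    unmapped = species_counts.index[mapped.isna()].tolist()
    if mapped.notna().sum() == 0:
        raise ValueError("no species could be mapped to a genus")
    if unmapped:
        logger.warning("%d species unmapped; routed to 'unmapped'", len(unmapped))
    genus = mapped.fillna("unmapped")
    agg = species_counts.groupby(genus.to_numpy()).sum()
    return FeatureTable(agg), unmapped
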