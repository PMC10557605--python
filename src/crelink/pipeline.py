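"""End-to-end orchestration: simulate -> CCVs -> atlas -> TF -> linkage ->
TRS -> MPRA -> per-locus report, with a run manifest for reproducibility.

The report has one row per merged locus: CCV counts, colocalized CCV counts,
the locus category call, CCVs supported by an allelic TF, and linked genes by
their maximum evidence level.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import ccv as ccv_mod
from . import io as io_mod
from . import linkage, motif, mpra, tf as tf_mod, trs as trs_mod
from .simulate import (
    SimConfig,
    generate_footprint_track,
    generate_gwas_locus,
    generate_motif_scenes,
    generate_mpra_table,
    generate_multiome,
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    started: float
    stages: Dict[str, Dict] = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = {"time": time.time(), **info}

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash, "seed": self.seed, "started": self.started, "stages": self.stages}, indent=1, sort_keys=True)


def config_hash(config: SimConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    report: pd.DataFrame
    tiers: pd.DataFrame
    links: pd.DataFrame
    modules: List[set]
    trs_by_type: pd.DataFrame
    mpra_results: pd.DataFrame
    truth: object
    manifest: RunManifest


def run_pipeline(config: SimConfig, outdir: Optional[str | Path] = None) -> PipelineResult:
    """Run every stage in dependency order on the synthetic study."""
    config.validate()
    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed, started=time.time())

    # ------------------------------------------------------------------ data
    matrices, atlas, truth = generate_multiome(config)
    manifest.record("simulate", n_cells=len(matrices.barcodes), n_peaks=config.n_peaks)

    # one GWAS locus anchored at each planted link peak
    starts, ends = config.peak_coords()
    loci = []
    for i, (peak, gene, _) in enumerate(config.planted_links):
        anchor = int((starts[peak] + ends[peak]) // 2)
        loci.append(generate_gwas_locus(config, locus_id=f"L{i}", anchor_pos=anchor))

    # ------------------------------------------------------------------- ccv
    ccv_sets, coords = [], []
    for locus in loci:
        ccv_sets.append(ccv_mod.compile_ccvs(locus.variants, locus.locus_id))
        coords.append(locus.variants[["variant_id", "chrom", "pos", "ref", "alt"]])
    coords = pd.concat(coords, ignore_index=True)
    groups, ccv_table = ccv_mod.merge_loci(ccv_sets, coords)
    truth.true_ccvs = set(ccv_table["variant_id"])
    manifest.record("ccv", n_loci=len(groups), n_ccvs=len(ccv_table))

    # ----------------------------------------------------------------- atlas
    annotated = atlas_mod.annotate_atlas(matrices.peaks, matrices.genes)
    promoter_of = dict(
        annotated.loc[annotated["annotation"] == "promoter", ["name", "promoter_gene"]].values
    )
    overlaps = atlas_mod.colocalize(ccv_table, matrices.peaks, atlas.detected_in)
    calls = {
        p: atlas_mod.assign_specificity(p, atlas.detected_in[p], config.taxonomy)
        for p in atlas.detected_in
    }
    manifest.record("atlas", n_overlaps=len(overlaps))

    # -------------------------------------------------------------------- tf
    pwms_raw, scenes, motif_truth = generate_motif_scenes(config)
    truth.true_allelic_tfs = motif_truth
    predictions = []
    for _, sc in scenes.iterrows():
        predictions.extend(
            motif.predict_allelic_tfs(
                sc["variant_id"], sc["window"], sc["ref"], sc["alt"],
                int(sc["offset_in_window"]),
                {name: motif.Pwm(name, mat) for name, mat in pwms_raw.items()},
            )
        )
    allelic = {(p.variant_id, p.tf_name) for p in predictions if p.allelic}
    track = generate_footprint_track(config)
    fp = tf_mod.footprint(track.site_counts, track.bias, track.positions, track.core_mask)
    manifest.record("tf", n_allelic=len(allelic), footprint_significant=fp.significant)

    # --------------------------------------------------------------- linkage
    emb = linkage.lsi_embedding(matrices.atac, seed=config.seed)
    meta, _ = linkage.make_metacells(matrices.atac, emb, k=10, seed=config.seed)
    edges = linkage.coaccessibility(meta, matrices.peaks)
    modules = linkage.detect_modules(edges, seed=config.seed)
    links, _skipped = linkage.link_peaks_to_genes(
        matrices.atac, matrices.rna, matrices.peaks, matrices.genes
    )
    assignments = linkage.assign_tiers(
        overlaps, modules, edges, promoter_of, links, matrices.peaks, matrices.genes
    )
    tiers = linkage.tiers_table(assignments)
    manifest.record("linkage", n_edges=len(edges), n_modules=len(modules), n_links=len(links))

    # ------------------------------------------------------------------- trs
    weights, _acct = trs_mod.variant_peak_weights(ccv_table, overlaps, list(matrices.peaks["name"]))
    if weights.sum() > 0:
        raw_z = trs_mod.colocalization_zscores(
            matrices.atac, weights, matrices.peaks["gc"].to_numpy(), seed=config.seed
        )
        graph = trs_mod.knn_graph(emb, k=30)
        scores, _ = trs_mod.propagate(raw_z, graph)
        trs_by_type = trs_mod.compare_groups(scores, matrices.cells)
    else:
        trs_by_type = pd.DataFrame(columns=["cell_type", "mean_trs", "n", "category", "rank"])
    manifest.record("trs", n_cell_types=len(trs_by_type))

    # ------------------------------------------------------------------ mpra
    mpra_table = generate_mpra_table(config, variant_ids=[s.lead_id for s in loci])
    mpra_results = mpra.test_variants(mpra_table)
    manifest.record("mpra", n_variants=len(mpra_results))

    # ---------------------------------------------------------------- report
    report = _locus_report(ccv_table, overlaps, calls, allelic, tiers)
    manifest.record("report", n_rows=len(report))

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io_mod.write_multiome(matrices, out / "multiome")
        io_mod.write_atlas_beds(atlas, out / "atlas")
        io_mod.write_ground_truth(truth, out / "ground_truth.json")
        ccv_table.to_csv(out / "ccvs.tsv", sep="\t", index=False)
        overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        links.to_csv(out / "links.tsv", sep="\t", index=False)
        tiers.to_csv(out / "tiers.tsv", sep="\t", index=False)
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        mpra_results.to_csv(out / "mpra.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(manifest.to_json())

    return PipelineResult(
        report=report,
        tiers=tiers,
        links=links,
        modules=modules,
        trs_by_type=trs_by_type,
        mpra_results=mpra_results,
        truth=truth,
        manifest=manifest,
    )


def _locus_report(
    ccv_table: pd.DataFrame,
    overlaps: pd.DataFrame,
    calls: Dict[str, atlas_mod.SpecificityCall],
    allelic: set,
    tiers: pd.DataFrame,
) -> pd.DataFrame:
    if len(ccv_table) == 0:
        return pd.DataFrame(
            columns=["locus", "n_ccvs", "n_colocalized", "category", "n_allelic_tf_ccvs"]
            + [f"genes_level_{k}" for k in range(1, 7)]
        )
    ov = overlaps.merge(ccv_table[["variant_id", "merged_locus"]], on="variant_id", how="left")
    tier_locus = tiers.merge(ov[["variant_id", "merged_locus"]].drop_duplicates(), on="variant_id", how="left")
    rows = []
    for locus, grp in ccv_table.groupby("merged_locus"):
        lov = ov.loc[ov["merged_locus"] == locus]
        category = (
            atlas_mod.summarize_locus(lov, calls) if len(lov) else "none"
        )
        allelic_variants = {v for (v, _t) in allelic}
        lt = tier_locus.loc[tier_locus["merged_locus"] == locus]
        genes_by_level = {
            k: sorted(lt.loc[lt["max_level"] == k, "gene"].unique()) for k in range(1, 7)
        }
        rows.append(
            {
                "locus": locus,
                "n_ccvs": len(grp),
                "n_colocalized": lov["variant_id"].nunique(),
                "category": category,
                "n_allelic_tf_ccvs": len(set(grp["variant_id"]) & allelic_variants),
                **{f"genes_level_{k}": ",".join(v) for k, v in genes_by_level.items()},
            }
        )
    return pd.DataFrame(rows)
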