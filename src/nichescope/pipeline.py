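"""Stage orchestration: io → niches → dynamics → expression → trends →
metabolomics → taxonomy, with a machine-readable run report.

Each stage reads the TSV schemas written by :mod:`nichescope.simulate` (or
user-supplied tables in the same schemas), writes its result tables under the
output directory, and appends row counts, sub-seeds and warnings to the run
report.  Outputs are identical on re-run with the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, dynamics, expression, metabolomics, niches, taxonomy, trends
from .metabolomics import MetaboliteRun
from .simulate import FRACTIONS

log = logging.getLogger("nichescope")

STAGES = ["io", "niches", "dynamics", "expression", "trends", "metabolomics", "taxonomy"]


@dataclass
class PipelineConfig:
    data_dir: Path
    out_dir: Path
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 999
    min_cluster_size: int = 5
    k_override: int | None = None
    exclude_window: list[str] | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


def _sub_seed(seed: int, stage: str) -> int:
    return (seed * 131 + STAGES.index(stage) + 1) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and return the run report."""
    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "skipped": []}
    d = cfg.data_dir

    enabled = [s for s in STAGES if s in cfg.stages]
    for s in STAGES:
        if s not in enabled:
            report["skipped"].append(s)

    deps = {
        "niches": ["io"],
        "dynamics": ["io", "niches"],
        "expression": ["io", "niches"],
        "trends": ["io"],
        "metabolomics": [],
        "taxonomy": [],
    }
    for s in list(enabled):
        missing = [u for u in deps.get(s, []) if u not in enabled]
        if missing:
            note = f"stage {s} skipped: upstream {missing} disabled"
            log.warning(note)
            report["skipped"].append(s)
            enabled.remove(s)

    state: dict = {}

    if "io" in enabled:
        ann = core_io.read_annotations(d / "annotations.tsv")
        quality = core_io.read_quality(d / "quality.tsv")
        kept = core_io.filter_mags(quality)
        selected = core_io.select_rmags([q for q in quality if q.mag_id in set(kept)])
        contig_depth = core_io.read_depth(d / "contig_depth_mg.tsv")
        mapping = core_io.read_tsv_mapping = pd.read_csv(
            d / "contig_mapping.tsv", sep="\t", dtype=str
        )
        rmag_mg = core_io.rmag_depth(
            contig_depth, dict(zip(mapping["contig_id"], mapping["rmag_id"]))
        )
        gene_mg = core_io.compute_depth(core_io.read_depth(d / "depth_mg.tsv"))
        gene_mt = core_io.compute_depth(core_io.read_depth(d / "depth_mt.tsv"))
        mp = pd.read_csv(d / "mp_counts.tsv", sep="\t", index_col="gene_id")
        manifest = core_io.read_manifest(d / "manifest.tsv")
        state.update(
            annotations=ann, quality=quality, selected=selected, rmag_mg=rmag_mg,
            gene_mg=gene_mg, gene_mt=gene_mt, mp=mp, manifest=manifest,
        )
        # MT depth aggregated to rMAG level from gene tables (length-weighted)
        ann_u = ann.drop_duplicates("gene_id").set_index("gene_id")
        gmap = ann_u["rmag_id"]
        lengths = ann_u["length_bp"]

        def _agg(gene_depth: pd.DataFrame) -> pd.DataFrame:
            ln = lengths.reindex(gene_depth.index)
            summed = gene_depth.mul(ln, axis=0)
            num = summed.groupby(gmap.reindex(gene_depth.index)).sum()
            den = ln.groupby(gmap.reindex(gene_depth.index)).sum()
            return num.div(den, axis=0)

        state["rmag_mt"] = _agg(gene_mt)
        report["stages"]["io"] = {
            "n_genes": len(ann),
            "n_rmags_selected": len(selected),
            "n_samples": rmag_mg.shape[1],
        }

    if "niches" in enabled:
        seed = _sub_seed(cfg.seed, "niches")
        matrix = niches.build_ko_presence(state["annotations"])
        dist = niches.jaccard_distances(matrix)
        emb, var = niches.classical_mds(dist, dims=2)
        k, curve = niches.choose_k_elbow(emb, seed=seed, k_override=cfg.k_override)
        assign = niches.kmeans_assign(emb, k, seed=seed)
        enr = niches.fisher_enrichment(matrix, assign.labels, alpha=cfg.alpha)
        unions, regions = niches.ko_set_overlaps(matrix, assign.labels)
        core_io.write_tsv(
            assign.labels.rename("cluster").reset_index(), cfg.out_dir / "funcs.tsv"
        )
        core_io.write_tsv(emb.reset_index(), cfg.out_dir / "embedding.tsv")
        core_io.write_tsv(enr, cfg.out_dir / "enrichment.tsv")
        core_io.write_tsv(
            pd.DataFrame(
                [
                    {"funcs": "+".join(map(str, sorted(s))), "n_kos": c}
                    for s, c in sorted(regions.items(), key=lambda kv: -kv[1])
                ]
            ),
            cfg.out_dir / "overlaps.tsv",
        )
        state.update(matrix=matrix, embedding=emb, assignment=assign)
        shared_all = regions.get(frozenset(sorted(assign.labels.unique())), 0)
        report["stages"]["niches"] = {
            "seed": seed,
            "k": k,
            "n_enriched": int(enr["enriched"].sum()),
            "kos_shared_by_all": int(shared_all),
            "variance_explained": [float(v) for v in var],
        }

    if "dynamics" in enabled:
        seed = _sub_seed(cfg.seed, "dynamics")
        rel = dynamics.relative_abundance(state["rmag_mg"])
        dist = dynamics.correlation_distance_matrix(rel)
        labels = state["assignment"].labels.reindex(dist.index)
        f, r2, p = dynamics.permanova(dist, labels, n_perm=cfg.n_perm, seed=seed)
        disp, f_disp, p_disp = dynamics.dispersion_test(
            dist, labels, n_perm=cfg.n_perm, seed=seed
        )
        stab_all = dynamics.temporal_stability(rel)
        stab_excl = dynamics.temporal_stability(rel, exclude_window=cfg.exclude_window)
        bc, emb, _ = dynamics.braycurtis_pcoa(rel)
        abiotic = pd.read_csv(d / "abiotic.tsv", sep="\t", index_col="sample_id")
        envfit = dynamics.fit_factors(emb, abiotic, n_perm=cfg.n_perm, seed=seed)
        spear = dynamics.spearman_associations(rel, abiotic)
        core_io.write_tsv(rel.reset_index(), cfg.out_dir / "abundance.tsv")
        core_io.write_tsv(dist.reset_index(), cfg.out_dir / "dist_corr.tsv")
        core_io.write_tsv(
            pd.DataFrame([{"pseudo_F": f, "R2": r2, "p": p}]),
            cfg.out_dir / "permanova.tsv",
        )
        core_io.write_tsv(
            pd.DataFrame([{"F": f_disp, "p": p_disp}]), cfg.out_dir / "dispersion.tsv"
        )
        stab_df = pd.DataFrame(
            [
                {
                    "rmag_id": a.rmag_id,
                    "stability_all": a.stability,
                    "stability_excl": b.stability,
                }
                for a, b in zip(stab_all, stab_excl)
            ]
        )
        core_io.write_tsv(stab_df, cfg.out_dir / "stability.tsv")
        core_io.write_tsv(emb.reset_index(), cfg.out_dir / "pcoa.tsv")
        core_io.write_tsv(envfit, cfg.out_dir / "envfit.tsv")
        core_io.write_tsv(spear, cfg.out_dir / "spearman.tsv")
        state.update(rel_abundance=rel)
        report["stages"]["dynamics"] = {
            "seed": seed,
            "permanova_R2": r2,
            "permanova_p": p,
            "dispersion_p": p_disp,
            "mean_stability": float(stab_df["stability_all"].mean()),
            "mean_stability_excl": float(stab_df["stability_excl"].mean()),
        }

    if "expression" in enabled:
        seed = _sub_seed(cfg.seed, "expression")
        samples = list(state["gene_mg"].columns)
        labels_rows = {}
        activities = {}
        for s in samples:
            act = expression.ko_activity_call(
                state["gene_mg"][s],
                state["gene_mt"][s],
                state["mp"][s] if s in state["mp"].columns else pd.Series(dtype=float),
                state["annotations"],
            )
            activities[s] = act
            labels_rows[s] = expression.cluster_expression_profiles(
                act, min_cluster_size=cfg.min_cluster_size, seed=seed
            )
        clusters = pd.DataFrame(labels_rows).T
        clusters.index.name = "timepoint"
        cond = state["manifest"].set_index("sample_id")["condition"]
        per_rmag, grouped = expression.mtmg_ratio(
            state["rmag_mg"], state["rmag_mt"], state["assignment"].labels, cond
        )
        core_io.write_tsv(
            clusters.reset_index().melt(
                id_vars="timepoint", var_name="rmag_id", value_name="cluster"
            ),
            cfg.out_dir / "clusters.tsv",
        )
        core_io.write_tsv(per_rmag.reset_index(), cfg.out_dir / "mtmg_ratios.tsv")
        core_io.write_tsv(grouped, cfg.out_dir / "mtmg_ratio_summary.tsv")
        state.update(activities=activities, clusters=clusters)
        report["stages"]["expression"] = {
            "seed": seed,
            "n_timepoints": len(samples),
            "mean_clusters_per_tp": float(
                np.mean([len(set(v[v > 0])) for _, v in clusters.iterrows()])
            ),
        }

    if "trends" in enabled:
        tr = trends.foam_trend(state["gene_mt"], state["mp"], state["annotations"])
        core_io.write_tsv(tr, cfg.out_dir / "foam_trends.tsv")
        report["stages"]["trends"] = {
            "n_categories": int(tr["foam_l1"].nunique()),
        }

    if "metabolomics" in enabled:
        removed_all = {}
        normalized = {}
        for fraction in FRACTIONS:
            inten = pd.read_csv(
                d / f"{fraction}.tsv", sep="\t", index_col="metabolite_id"
            )
            manifest = pd.read_csv(d / f"{fraction}_manifest.tsv", sep="\t")
            run = MetaboliteRun(inten, manifest, fraction=fraction)
            run, removed = metabolomics.blank_filter(run)
            run = metabolomics.prevalence_filter(run)
            run, _ = metabolomics.drift_normalize(run)
            removed_all[fraction] = removed
            normalized[fraction] = run
            core_io.write_tsv(
                run.intensities.reset_index(), cfg.out_dir / f"normalized_{fraction}.tsv"
            )
        ratios, shared = metabolomics.intra_extra_ratio(
            normalized["intra_polar"], normalized["extra_polar"]
        )
        core_io.write_tsv(ratios.reset_index(), cfg.out_dir / "ratios.tsv")
        core_io.write_tsv(
            pd.DataFrame(
                [
                    {"fraction": f, "metabolite_id": m}
                    for f, ms in removed_all.items()
                    for m in ms
                ]
            ),
            cfg.out_dir / "removed_contaminants.tsv",
        )
        report["stages"]["metabolomics"] = {
            "n_removed": sum(len(v) for v in removed_all.values()),
            "n_ratio_metabolites": len(shared),
        }

    if "taxonomy" in enabled:
        markers = pd.read_csv(d / "markers.tsv", sep="\t")
        genome_tax = pd.read_csv(d / "genome_tax.tsv", sep="\t")
        cons = taxonomy.consensus_table(markers)
        lineage = taxonomy.merge_assignments(genome_tax, cons)
        core_io.write_tsv(lineage, cfg.out_dir / "lineage.tsv")
        report["stages"]["taxonomy"] = {
            "n_calls": len(lineage),
            "n_flagged": int(lineage["remove_flag"].sum()),
        }

    report["n_stages_run"] = len(report["stages"])
    with open(cfg.out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
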