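"""Fundamental niche typing of the synthetic community.

KO presence/absence → Jaccard distances → 2-D classical MDS → elbow-selected
k-means functional clusters (FunCs), with per-cluster KO enrichment, UpSet-
style set overlaps, and a Procrustes/PROTEST comparison of the gene-level
embedding against the full-repertoire embedding (standing in for the
whole-genome distance ordination).

Requires analysis/01_simulate_community.py to have been run.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from nichescope import core_io, niches
from nichescope.simulate import SimulationConfig, simulate_repertoires

DATA = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    ann = core_io.read_annotations(DATA / "annotations.tsv")
    matrix = niches.build_ko_presence(ann)
    dist = niches.jaccard_distances(matrix)
    emb, var = niches.classical_mds(dist, dims=2)
    k, curve = niches.choose_k_elbow(emb, seed=20)
    assign = niches.kmeans_assign(emb, k, seed=20)

    truth = pd.read_csv(DATA / "truth/types.tsv", sep="\t", index_col="rmag_id")
    ari = adjusted_rand_score(
        truth.loc[assign.labels.index, "type"], assign.labels.values
    )

    enrich = niches.fisher_enrichment(matrix, assign.labels)
    unions, regions = niches.ko_set_overlaps(matrix, assign.labels)

    # full-repertoire embedding as the genome-scale reference configuration
    cfg = SimulationConfig(seed=20)
    full_matrix, _ = simulate_repertoires(cfg)
    full_emb, _ = niches.classical_mds(
        niches.jaccard_distances(full_matrix), dims=2
    )
    m2, corr, p = niches.procrustes_protest(emb, full_emb, n_perm=999, seed=20)

    RESULTS.mkdir(exist_ok=True)
    assign.labels.rename("cluster").reset_index().to_csv(
        RESULTS / "02_funcs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"funcs": "+".join(map(str, sorted(s))), "n_kos": c}
            for s, c in sorted(regions.items(), key=lambda kv: -kv[1])
        ]
    ).to_csv(RESULTS / "02_ko_overlaps.tsv", sep="\t", index=False)
    stats = pd.DataFrame(
        [
            ("elbow_k", k),
            ("ari_vs_planted_types", round(ari, 4)),
            ("variance_explained_axis1", round(float(var[0]), 4)),
            ("variance_explained_axis2", round(float(var[1]), 4)),
            ("n_enriched_ko_cluster_pairs", int(enrich["enriched"].sum())),
            ("kos_shared_by_all_funcs",
             regions.get(frozenset(assign.labels.unique()), 0)),
            ("procrustes_m2", round(m2, 4)),
            ("procrustes_corr", round(corr, 4)),
            ("protest_p", p),
        ],
        columns=["statistic", "value"],
    )
    stats.to_csv(RESULTS / "02_niche_stats.tsv", sep="\t", index=False)
    print(stats.to_string(index=False))
    print(f"per-FunC union sizes: {unions}")


if __name__ == "__main__":
    main()
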