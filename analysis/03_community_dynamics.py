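"""Community dynamics of the synthetic time-series.

Relative abundances from contig-level metagenomic depth, correlation
distances between abundance profiles, PERMANOVA and dispersion tests against
the FunC assignment, temporal stability with and without the disturbance
window, and a Bray–Curtis ordination with abiotic-factor vector fitting.

Requires analysis/01 and analysis/02 to have been run.
"""

from pathlib import Path

import pandas as pd

from nichescope import core_io, dynamics

DATA = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    contig_depth = core_io.read_depth(DATA / "contig_depth_mg.tsv")
    mapping = pd.read_csv(DATA / "contig_mapping.tsv", sep="\t", dtype=str)
    rmag_mg = core_io.rmag_depth(
        contig_depth, dict(zip(mapping["contig_id"], mapping["rmag_id"]))
    )
    rel = dynamics.relative_abundance(rmag_mg)
    dist = dynamics.correlation_distance_matrix(rel)

    funcs = pd.read_csv(RESULTS / "02_funcs.tsv", sep="\t", index_col="rmag_id")
    labels = funcs["cluster"].reindex(dist.index)
    f, r2, p = dynamics.permanova(dist, labels, n_perm=999, seed=20)
    _, f_disp, p_disp = dynamics.dispersion_test(dist, labels, n_perm=999, seed=20)

    window = [rel.columns[i] for i in range(30, 34)]
    incl = dynamics.temporal_stability(rel)
    excl = dynamics.temporal_stability(rel, exclude_window=window)
    stab = pd.DataFrame(
        {
            "rmag_id": [r.rmag_id for r in incl],
            "stability_incl": [r.stability for r in incl],
            "stability_excl": [r.stability for r in excl],
        }
    )

    bc, emb, _ = dynamics.braycurtis_pcoa(rel)
    abiotic = pd.read_csv(DATA / "abiotic.tsv", sep="\t", index_col="sample_id")
    envfit = dynamics.fit_factors(emb, abiotic, n_perm=999, seed=20)

    RESULTS.mkdir(exist_ok=True)
    stab.to_csv(RESULTS / "03_stability.tsv", sep="\t", index=False)
    envfit.to_csv(RESULTS / "03_envfit.tsv", sep="\t", index=False)
    stats = pd.DataFrame(
        [
            ("permanova_pseudo_F", round(f, 3)),
            ("permanova_R2", round(r2, 4)),
            ("permanova_p", p),
            ("dispersion_F", round(f_disp, 3)),
            ("dispersion_p", p_disp),
            ("mean_stability_incl", round(stab["stability_incl"].mean(), 3)),
            ("mean_stability_excl", round(stab["stability_excl"].mean(), 3)),
            ("n_factors_significant", int((envfit["p"] < 0.05).sum())),
        ],
        columns=["statistic", "value"],
    )
    stats.to_csv(RESULTS / "03_dynamics_stats.tsv", sep="\t", index=False)
    print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
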