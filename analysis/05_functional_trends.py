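"""Pathway-scale trends: FOAM L1 aggregation of MT depth and MP spectral
counts over the time-series and the correlation between the two layers.

Requires analysis/01 to have been run.
"""

from pathlib import Path

import pandas as pd

from nichescope import core_io, trends

DATA = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    ann = core_io.read_annotations(DATA / "annotations.tsv")
    gene_mt = core_io.compute_depth(core_io.read_depth(DATA / "depth_mt.tsv"))
    mp = pd.read_csv(DATA / "mp_counts.tsv", sep="\t", index_col="gene_id")
    out = trends.foam_trend(gene_mt, mp, ann)

    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "05_foam_trends.tsv", sep="\t", index=False)
    per_cat = out.groupby("foam_l1", observed=True).agg(
        r=("r", "first"), mean_mp_rel=("mean_mp_rel", "first")
    )
    print("MT/MP correlation per FOAM L1 category "
          "(ordered by mean MP relative count):")
    print(per_cat.to_string())


if __name__ == "__main__":
    main()
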