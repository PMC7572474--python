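"""Marker-gene consensus taxonomy merged with genome-level assignments,
scored against the planted lineages.

Requires analysis/01 to have been run.
"""

from pathlib import Path

import pandas as pd

from nichescope import taxonomy

DATA = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    markers = pd.read_csv(DATA / "markers.tsv", sep="\t")
    genome_tax = pd.read_csv(DATA / "genome_tax.tsv", sep="\t")
    truth = pd.read_csv(DATA / "truth/lineage.tsv", sep="\t").set_index(
        ["rmag_id", "rank"]
    )["taxon"]

    cons = taxonomy.consensus_table(markers)
    merged = taxonomy.merge_assignments(genome_tax, cons)

    called = merged[merged["taxon"].notna()
                    & (merged["taxon"] != taxonomy.LOW_CONFIDENCE)]
    hits = sum(
        truth.get((row["rmag_id"], row["rank"])) == row["taxon"]
        for _, row in called.iterrows()
    )
    RESULTS.mkdir(exist_ok=True)
    merged.to_csv(RESULTS / "07_lineage.tsv", sep="\t", index=False)
    by_source = called.groupby("source").size()
    print(f"{len(called)} rank-level calls "
          f"({by_source.to_dict()}); accuracy vs planted lineage: "
          f"{hits / len(called):.3f}")
    print(f"{int(merged['remove_flag'].sum())} calls flagged for removal "
          f"(no kingdom-level assignment)")


if __name__ == "__main__":
    main()
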