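"""Metabolomics QC for the four fractions: blank-based contaminant removal,
pool/prevalence filtering, drift normalization with pool QC, and the
intracellular/extracellular ratio table.

Requires analysis/01 to have been run.
"""

from pathlib import Path

import pandas as pd

from nichescope import metabolomics
from nichescope.metabolomics import MetaboliteRun
from nichescope.simulate import FRACTIONS

DATA = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    truth_contam = set(
        pd.read_csv(DATA / "truth/contaminants.tsv", sep="\t")["metabolite_id"]
    )
    normalized = {}
    qc_rows = []
    for fraction in FRACTIONS:
        inten = pd.read_csv(DATA / f"{fraction}.tsv", sep="\t",
                            index_col="metabolite_id")
        manifest = pd.read_csv(DATA / f"{fraction}_manifest.tsv", sep="\t")
        run = MetaboliteRun(inten, manifest, fraction)
        filtered, removed = metabolomics.blank_filter(run)
        filtered = metabolomics.prevalence_filter(filtered)
        norm, flagged = metabolomics.drift_normalize(filtered)
        qc = metabolomics.pool_drift_qc(filtered, norm)
        normalized[fraction] = norm
        qc_rows.append(
            {
                "fraction": fraction,
                "n_removed_contaminants": len(removed),
                "contaminants_exact": set(removed) == truth_contam,
                "n_kept": len(norm.intensities),
                "median_abs_rho_norm": round(abs(qc["rho_norm"].median()), 3),
                "median_cv_raw": round(qc["cv_raw"].median(), 3),
                "median_cv_norm": round(qc["cv_norm"].median(), 3),
            }
        )
    ratios, shared = metabolomics.intra_extra_ratio(
        normalized["intra_polar"], normalized["extra_polar"]
    )
    RESULTS.mkdir(exist_ok=True)
    ratios.reset_index().to_csv(RESULTS / "06_intra_extra_ratios.tsv",
                                sep="\t", index=False)
    qc_df = pd.DataFrame(qc_rows)
    qc_df.to_csv(RESULTS / "06_metabolomics_qc.tsv", sep="\t", index=False)
    print(qc_df.to_string(index=False))
    print(f"{len(shared)} metabolites detected in both polar fractions "
          f"enter the intra/extra ratio table")


if __name__ == "__main__":
    main()
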