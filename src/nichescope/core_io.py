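"""Domain tables, TSV readers/writers, depth aggregation and genome quality filters.

All tabular inputs and outputs are tab-separated files with a mandatory header
row; identifiers are case-sensitive.  Depth-of-coverage of a feature (gene or
contig) in a sample is defined as the summed per-base depth divided by the
feature length.  Missing (feature, sample) pairs are dense zeros after loading,
because the downstream activity-ratio rules need explicit zeros rather than NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("nichescope")

ANNOTATION_COLUMNS = ["gene_id", "rmag_id", "ko_id", "foam_l1", "length_bp"]
DEPTH_COLUMNS = ["feature_id", "sample_id", "summed_depth", "length_bp"]
QUALITY_COLUMNS = ["mag_id", "completeness", "contamination", "kingdom"]
MANIFEST_COLUMNS = ["sample_id", "timepoint", "condition"]


@dataclass(frozen=True)
class QualityRecord:
    """CheckM-style genome quality estimate, stored as fractions in [0, 1]."""

    mag_id: str
    completeness: float
    contamination: float
    taxonomy_kingdom: str | None = None

    def __post_init__(self) -> None:
        for field in ("completeness", "contamination"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{field} of {self.mag_id!r} must be in [0, 1], got {v}"
                )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, rmag_id, ko_id, foam_l1, length_bp).

    ``ko_id`` and ``foam_l1`` may be empty (gene without KO / FOAM assignment).
    Rows may repeat a gene_id only to carry multiple FOAM L1 assignments.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {missing}")
    df["length_bp"] = df["length_bp"].astype(int)
    if (df["length_bp"] < 1).any():
        bad = df.loc[df["length_bp"] < 1, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has non-positive length")
    dup = df.duplicated(subset=["gene_id", "foam_l1"])
    if dup.any():
        raise ValueError(
            f"duplicate (gene_id, foam_l1) rows, e.g. {df.loc[dup, 'gene_id'].iloc[0]!r}"
        )
    return df


def read_depth(path: str | Path) -> pd.DataFrame:
    """Read a long-format depth table (feature_id, sample_id, summed_depth, length_bp)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"feature_id": str, "sample_id": str},
    )
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"depth table {path} lacks columns {missing}")
    return df


def read_quality(path: str | Path, percent: bool = False) -> list[QualityRecord]:
    """Read genome quality records.

    With ``percent=True`` the completeness/contamination columns are given in
    percent and divided by 100 on load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "kingdom": str})
    missing = [c for c in QUALITY_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"quality table {path} lacks columns {missing}")
    scale = 100.0 if percent else 1.0
    records = []
    for row in df.itertuples(index=False):
        kingdom = getattr(row, "kingdom", None)
        if kingdom is not None and (pd.isna(kingdom) or kingdom == ""):
            kingdom = None
        records.append(
            QualityRecord(
                mag_id=row.mag_id,
                completeness=row.completeness / scale,
                contamination=row.contamination / scale,
                taxonomy_kingdom=kingdom,
            )
        )
    return records


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest sample_id values must be unique")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV; readers round-trip writer output bit-exactly."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def compute_depth(records: pd.DataFrame) -> pd.DataFrame:
    """Depth-of-coverage matrix (feature × sample) from a long depth table.

    depth = summed_depth / length_bp.  Features unobserved in a sample get 0.

    Raises on duplicate (feature_id, sample_id) keys and on zero lengths,
    naming the offender.
    """
    df = records
    dup = df.duplicated(subset=["feature_id", "sample_id"])
    if dup.any():
        key = tuple(df.loc[dup, ["feature_id", "sample_id"]].iloc[0])
        raise ValueError(f"duplicate depth record for (feature, sample) = {key}")
    if (df["length_bp"] <= 0).any():
        bad = df.loc[df["length_bp"] <= 0, "feature_id"].iloc[0]
        raise ValueError(f"feature {bad!r} has non-positive length")
    if (df["summed_depth"] < 0).any():
        bad = df.loc[df["summed_depth"] < 0, "feature_id"].iloc[0]
        raise ValueError(f"feature {bad!r} has negative summed depth")
    depth = df["summed_depth"] / df["length_bp"]
    wide = (
        pd.DataFrame(
            {
                "feature_id": df["feature_id"],
                "sample_id": df["sample_id"],
                "depth": depth,
            }
        )
        .pivot(index="feature_id", columns="sample_id", values="depth")
        .fillna(0.0)
    )
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    wide.columns.name = None
    wide.index.name = "feature_id"
    return wide


def rmag_depth(
    contig_depths: pd.DataFrame, contig_to_rmag: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate contig-level depth records to rMAG depth-of-coverage.

    rMAG depth is the contig-length-weighted mean coverage:
    Σ(contig summed_depth) / Σ(contig length) over member contigs.
    ``contig_depths`` is a long table with DEPTH_COLUMNS.  Contigs without an
    rMAG mapping are excluded with a logged count.
    """
    df = contig_depths.copy()
    dup = df.duplicated(subset=["feature_id", "sample_id"])
    if dup.any():
        key = tuple(df.loc[dup, ["feature_id", "sample_id"]].iloc[0])
        raise ValueError(f"duplicate depth record for (feature, sample) = {key}")
    mapped = df["feature_id"].map(contig_to_rmag)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        log.warning(
            "%d contig depth records without rMAG mapping excluded", n_unmapped
        )
        df = df[mapped.notna()]
        mapped = mapped.dropna()
    df = df.assign(rmag_id=mapped.values)

    # a contig's length must be charged once per sample even when the sample
    # has no record for it; build the dense length denominator per rMAG
    contig_len = df.groupby("feature_id")["length_bp"].first()
    rmag_of = {c: contig_to_rmag[c] for c in contig_len.index}
    total_len = contig_len.groupby(rmag_of).sum()

    summed = (
        df.groupby(["rmag_id", "sample_id"])["summed_depth"].sum().unstack(fill_value=0.0)
    )
    out = summed.div(total_len.reindex(summed.index), axis=0)
    out = out.sort_index(axis=0).sort_index(axis=1)
    out.columns.name = None
    out.index.name = "rmag_id"
    return out


def filter_mags(
    quality: Iterable[QualityRecord],
    min_completeness: float = 0.28,
    max_contamination: float = 0.20,
) -> list[str]:
    """MAG retention rule: completeness ≥ 28% and contamination strictly < 20%.

    Input order is preserved; idempotent.
    """
    return [
        q.mag_id
        for q in quality
        if q.completeness >= min_completeness and q.contamination < max_contamination
    ]


def select_rmags(
    quality: Iterable[QualityRecord], min_diff: float = 0.50
) -> list[str]:
    """rMAG selection: completeness − contamination ≥ 0.50 and a kingdom call present."""
    return [
        q.mag_id
        for q in quality
        if (q.completeness - q.contamination) >= min_diff
        and q.taxonomy_kingdom is not None
    ]
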