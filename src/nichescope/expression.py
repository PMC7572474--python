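"""Realized-niche profiling: binary KO expression-status calls, per-time-point
expression-profile clustering, and MT/MG activity ratios.

A KO of a population is called *active* at a time-point if at least one of its
genes shows transcription above the gene-copy baseline (MT/MG depth ratio > 1,
or MT depth > 1 when the gene's MG depth is below one — the fallback avoids
inflating active calls for lowly abundant populations) or proteomic evidence
(≥ 2 peptide spectral counts).  Per time-point, populations are compared by
binary Jaccard distance over their KO activity vectors, embedded in 2-D and
clustered density-based (HDBSCAN, minimum five members per cluster); points in
no cluster carry an explicit noise label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import HDBSCAN

from .niches import classical_mds

log = logging.getLogger("nichescope")

NOISE = 0  # cluster label for rMAGs not assigned to any expression cluster


def gene_active(mg: float, mt: float, mp: int) -> bool:
    """The per-gene activity predicate (pure function of the three levels).

    (MG ≥ 1 and MT/MG > 1) or (MG < 1 and MT > 1) or (MP counts ≥ 2).
    Strict inequalities exactly as stated: "greater than 1", "at least 2".
    """
    if mp >= 2:
        return True
    if mg < 1.0:
        return mt > 1.0
    return mt / mg > 1.0


def ko_activity_call(
    gene_mg: pd.Series,
    gene_mt: pd.Series,
    gene_mp: pd.Series,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Binary rMAG × KO activity matrix at one time-point.

    ``gene_mg``/``gene_mt``/``gene_mp`` are indexed by gene_id for a single
    sample; genes missing from a table count as level 0 (logged summary).
    A KO is active for an rMAG iff any of its genes satisfies the predicate;
    the matrix covers every (rMAG, KO) with at least one annotated gene.
    """
    ann = annotations[annotations["ko_id"].astype(str) != ""]
    ann = ann.drop_duplicates(subset=["gene_id"])
    genes = ann["gene_id"].values
    missing = sum(
        int((~pd.Index(genes).isin(t.index)).sum()) for t in (gene_mg, gene_mt, gene_mp)
    )
    if missing:
        log.info("%d gene/table lookups missing, treated as level 0", missing)
    mg = gene_mg.reindex(genes).fillna(0.0).values.astype(float)
    mt = gene_mt.reindex(genes).fillna(0.0).values.astype(float)
    mp = gene_mp.reindex(genes).fillna(0).values.astype(float)

    low = mg < 1.0
    ratio_rule = np.where(low, mt > 1.0, np.divide(mt, np.maximum(mg, 1e-300)) > 1.0)
    active = ratio_rule | (mp >= 2)

    calls = pd.DataFrame(
        {"rmag_id": ann["rmag_id"].values, "ko_id": ann["ko_id"].values, "active": active}
    )
    mat = (
        calls.groupby(["rmag_id", "ko_id"])["active"].any().astype(np.int8).unstack(
            fill_value=0
        )
    )
    # cells without an annotated gene are undefined: mark -1 then drop to 0-frame
    defined = (
        calls.groupby(["rmag_id", "ko_id"]).size().unstack(fill_value=0) > 0
    )
    mat = mat.where(defined, other=0).astype(np.int8)
    mat.columns.name = None
    return mat


def cluster_expression_profiles(
    activity: pd.DataFrame,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Density-based clustering of per-time-point expression profiles.

    Binary Jaccard distances over rMAG activity vectors → classical MDS to
    2-D → HDBSCAN with ``min_cluster_size`` (= min_samples) members.  Labels
    are positive integers ordered by descending cluster size; noise is 0.
    """
    n = activity.shape[0]
    if n < min_cluster_size:
        return pd.Series(NOISE, index=activity.index, name="cluster")
    x = activity.values.astype(bool)
    d = squareform(pdist(x, metric="jaccard"))
    if np.allclose(d, 0):
        return pd.Series(1, index=activity.index, name="cluster")
    emb, _ = classical_mds(pd.DataFrame(d, index=activity.index,
                                        columns=activity.index), dims=2)
    raw = HDBSCAN(
        min_cluster_size=min_cluster_size, min_samples=min_cluster_size, copy=True
    ).fit_predict(emb.values)
    labels = pd.Series(raw, index=activity.index)
    sizes = labels[labels >= 0].value_counts()
    remap = {old: new + 1 for new, old in enumerate(
        sizes.sort_values(ascending=False, kind="stable").index)}
    out = labels.map(lambda l: remap.get(l, NOISE)).rename("cluster")
    return out


def mtmg_ratio(
    rmag_mg: pd.DataFrame,
    rmag_mt: pd.DataFrame,
    grouping: pd.Series,
    conditions: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MT/MG depth ratios per rMAG, averaged over the samples of a condition.

    ``grouping`` maps rmag_id to a FunC or taxon class; ``conditions`` maps
    sample_id to a condition label.  Samples with MG depth 0 yield undefined
    ratios and are excluded with a logged count.  Returns (per-rMAG condition
    means, per-group summaries with median and quartiles).
    """
    common_r = rmag_mg.index.intersection(rmag_mt.index)
    common_s = rmag_mg.columns.intersection(rmag_mt.columns)
    mg = rmag_mg.loc[common_r, common_s].values.astype(float)
    mt = rmag_mt.loc[common_r, common_s].values.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mg > 0, mt / mg, np.nan)
    n_undef = int(np.isnan(ratio).sum())
    if n_undef:
        log.warning("%d (rMAG, sample) ratios undefined (MG depth 0), excluded", n_undef)
    rat = pd.DataFrame(ratio, index=common_r, columns=common_s)
    cond = conditions.loc[common_s]
    per_rmag = rat.T.groupby(cond.values).mean().T
    per_rmag.index.name = "rmag_id"
    rows = []
    for c in per_rmag.columns:
        for gname, members in grouping.groupby(grouping):
            vals = per_rmag.loc[per_rmag.index.intersection(members.index), c].dropna()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "condition": c,
                    "group": gname,
                    "n": len(vals),
                    "median": float(vals.median()),
                    "q1": float(vals.quantile(0.25)),
                    "q3": float(vals.quantile(0.75)),
                    "mean": float(vals.mean()),
                }
            )
    return per_rmag, pd.DataFrame(rows)


def cluster_ko_frequency(
    clusters_over_time: pd.DataFrame,
    activities: dict,
    focal_rmag: str,
    ko_id: str,
) -> tuple[int, pd.DataFrame]:
    """How often a KO is active in a focal rMAG while that rMAG is co-clustered.

    ``clusters_over_time`` is timepoint × rmag_id with labels (0 = noise);
    ``activities`` maps timepoint -> rMAG × KO activity matrix.  Returns the
    count of timepoints where ``ko_id`` is active in ``focal_rmag`` and the
    focal rMAG sits in a non-noise cluster, plus a companion table of the
    KO's activity frequency among co-clustered rMAGs.
    """
    if focal_rmag not in clusters_over_time.columns:
        raise ValueError(f"unknown focal rMAG {focal_rmag!r}")
    focal_labels = clusters_over_time[focal_rmag]
    if (focal_labels == NOISE).all():
        log.warning("focal rMAG %s is noise at every timepoint", focal_rmag)
        return 0, pd.DataFrame(columns=["timepoint", "n_co", "n_co_active"])
    count = 0
    rows = []
    for tp, labels in clusters_over_time.iterrows():
        lab = labels[focal_rmag]
        if lab == NOISE:
            continue
        act = activities[tp]
        focal_active = (
            focal_rmag in act.index
            and ko_id in act.columns
            and bool(act.loc[focal_rmag, ko_id])
        )
        if focal_active:
            count += 1
        co = [r for r, l in labels.items() if l == lab and r != focal_rmag]
        co_present = [r for r in co if r in act.index]
        n_active = (
            int(act.loc[co_present, ko_id].sum()) if ko_id in act.columns else 0
        )
        rows.append({"timepoint": tp, "n_co": len(co), "n_co_active": n_active})
    return count, pd.DataFrame(rows)
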