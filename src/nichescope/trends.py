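"""Pathway-scale omic trends: FOAM L1 aggregation of transcript depth and
spectral counts over time, and their correlation.

Per category and time-point, gene-level MT depth (resp. MP spectral counts)
is summed and divided by the total over *all* genes of all populations at
that time-point — genes without a FOAM assignment contribute to the
denominator but to no category.  Each category's relative series is then
min–max scaled to [0, 1] and the Pearson correlation between the scaled MT
and MP series is reported.  Min–max scaling leaves Pearson r unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

log = logging.getLogger("nichescope")


def _minmax(series: pd.Series) -> pd.Series:
    lo, hi = series.min(), series.max()
    if hi == lo:
        log.warning("constant category series: scaled to zeros")
        return series * 0.0
    return (series - lo) / (hi - lo)


def foam_trend(
    gene_mt: pd.DataFrame,
    gene_mp: pd.DataFrame,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Relative and scaled MT/MP series per FOAM L1 category, with Pearson r.

    ``gene_mt``/``gene_mp`` are gene × sample matrices.  A gene appearing in
    the annotation table with several FOAM L1 labels is counted in each.
    Output rows are ordered by descending mean MP relative count; r is NaN
    for categories whose scaled series are constant or absent from MP.
    """
    ann = annotations[annotations["foam_l1"].astype(str) != ""]
    if ann.empty:
        raise ValueError("no gene carries a FOAM L1 assignment")
    samples = [s for s in gene_mt.columns if s in set(gene_mp.columns)]
    tot_mt = gene_mt[samples].sum(axis=0)
    tot_mp = gene_mp[samples].sum(axis=0)

    rows = []
    for cat, genes in ann.groupby("foam_l1")["gene_id"]:
        g = list(dict.fromkeys(genes))
        mt_rel = gene_mt.reindex(g).fillna(0.0)[samples].sum(axis=0) / tot_mt
        mp_rel = gene_mp.reindex(g).fillna(0.0)[samples].sum(axis=0) / tot_mp.replace(
            0, np.nan
        )
        mt_scaled = _minmax(mt_rel)
        mp_scaled = _minmax(mp_rel.fillna(0.0))
        if mt_scaled.std() == 0 or mp_scaled.std() == 0 or mp_rel.isna().all():
            r = np.nan
        else:
            r = float(pearsonr(mt_scaled.values, mp_scaled.values)[0])
        for s in samples:
            rows.append(
                {
                    "foam_l1": cat,
                    "sample_id": s,
                    "mt_rel": float(mt_rel[s]),
                    "mp_rel": float(mp_rel[s]) if pd.notna(mp_rel[s]) else np.nan,
                    "mt_scaled": float(mt_scaled[s]),
                    "mp_scaled": float(mp_scaled[s]),
                    "r": r,
                    "mean_mp_rel": float(mp_rel.fillna(0.0).mean()),
                }
            )
    out = pd.DataFrame(rows)
    order = (
        out.groupby("foam_l1")["mean_mp_rel"].first().sort_values(ascending=False).index
    )
    out["foam_l1"] = pd.Categorical(out["foam_l1"], categories=order, ordered=True)
    return out.sort_values(["foam_l1", "sample_id"]).reset_index(drop=True)
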