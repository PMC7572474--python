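"""Fundamental niche typing from genome functional repertoires.

A population's fundamental niche is approximated by its encoded capability:
the set of KEGG ortholog groups (KOs) found on its genome.  Genomes are
compared by binary Jaccard distance between KO presence/absence profiles,
embedded in two dimensions by classical multidimensional scaling, and grouped
into functional clusters (FunCs) by k-means with the number of centroids
chosen by an automated elbow rule over k = 1..9.  Per-cluster KO enrichment
uses a one-sided Fisher exact test with Benjamini–Hochberg correction, and
agreement with an independent (e.g., whole-genome distance based) embedding
is quantified by Procrustes superimposition with a PROTEST permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("nichescope")


@dataclass
class FunCAssignment:
    """k-means functional-cluster labels over a 2-D MDS embedding."""

    labels: pd.Series  # rmag_id -> 1..k, renumbered by descending cluster size
    k: int
    embedding: pd.DataFrame  # rmag_id × (MDS1, MDS2)
    withinss_curve: dict[int, float] | None = None
    variance_explained: np.ndarray | None = None


def build_ko_presence(
    annotations: pd.DataFrame, rmag_ids: list[str] | None = None
) -> pd.DataFrame:
    """Binary rMAG × KO presence matrix: 1 iff ≥1 gene of the rMAG carries the KO.

    Column order is sorted KO ids.  Genes without a KO contribute nothing.
    """
    if len(annotations) == 0:
        raise ValueError("empty annotation set")
    df = annotations[annotations["ko_id"].astype(str) != ""]
    if rmag_ids is None:
        rmag_ids = sorted(annotations["rmag_id"].unique())
    else:
        unknown = set(rmag_ids) - set(annotations["rmag_id"])
        if unknown:
            raise ValueError(f"rmag_ids not in annotations: {sorted(unknown)[:5]}")
    pairs = df[["rmag_id", "ko_id"]].drop_duplicates()
    mat = (
        pd.crosstab(pairs["rmag_id"], pairs["ko_id"])
        .clip(upper=1)
        .reindex(index=rmag_ids, fill_value=0)
    )
    mat = mat[sorted(mat.columns)].astype(np.int8)
    mat.index.name = "rmag_id"
    mat.columns.name = None
    return mat


def jaccard_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise binary Jaccard distance matrix: d = 1 − |a∧b| / |a∨b|.

    A pair of all-zero rows has an undefined 0/0 Jaccard; the distance is
    defined as 0 with a logged warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows")
    x = matrix.values.astype(bool)
    empty = ~x.any(axis=1)
    if empty.sum() >= 2:
        log.warning(
            "%d all-zero rows: their pairwise Jaccard distance is defined as 0",
            int(empty.sum()),
        )
    d = squareform(pdist(x, metric="jaccard"))  # scipy defines 0/0 as 0
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def classical_mds(
    dist: pd.DataFrame | np.ndarray, dims: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS / principal coordinates.

    Double-centers −½ D², takes the top ``dims`` positive eigenvalues and
    returns coordinates ordered by eigenvalue, plus the proportion of
    variance explained per retained axis (relative to the sum of positive
    eigenvalues).  If fewer than ``dims`` positive eigenvalues exist the
    remaining coordinates are zero-padded with a warning.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.values
    else:
        d = np.asarray(dist)
        ids = list(range(d.shape[0]))
    n = d.shape[0]
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    n_pos = int(pos.sum())
    if n_pos < dims:
        log.warning(
            "only %d positive eigenvalues; padding %d axes with zeros",
            n_pos, dims - n_pos,
        )
    coords = np.zeros((n, dims))
    use = min(dims, n_pos)
    coords[:, :use] = evecs[:, :use] * np.sqrt(evals[:use])
    total_pos = evals[pos].sum()
    var_explained = np.zeros(dims)
    if total_pos > 0:
        var_explained[:use] = evals[:use] / total_pos
    emb = pd.DataFrame(
        coords, index=pd.Index(ids, name="rmag_id"),
        columns=[f"MDS{i+1}" for i in range(dims)],
    )
    return emb, var_explained


def _withinss(x: np.ndarray, k: int, seed: int, n_restarts: int = 25) -> tuple[float, np.ndarray]:
    if k == 1:
        centroid = x.mean(axis=0)
        return float(((x - centroid) ** 2).sum()), np.zeros(len(x), dtype=int)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    labels = km.fit_predict(x)
    return float(km.inertia_), labels


def choose_k_elbow(
    embedding: pd.DataFrame,
    k_range: range = range(1, 10),
    seed: int = 0,
    k_override: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Elbow selection of the number of centroids over k = 1..9.

    Runs k-means (25 restarts) for each k, records the total within-cluster
    sum of squares, and picks the k whose curve point has the maximum
    perpendicular distance to the chord joining the curve endpoints (kneedle
    rule).  ``k_override`` bypasses the rule while still reporting the curve.
    A non-increasing curve yields min(k_range) with a warning.
    """
    x = embedding.values if isinstance(embedding, pd.DataFrame) else np.asarray(embedding)
    ks = [k for k in k_range if 1 <= k <= len(x) - 1 or k == 1]
    curve = {k: _withinss(x, k, seed)[0] for k in ks}
    if k_override is not None:
        return int(k_override), curve
    ss = np.array([curve[k] for k in ks], dtype=float)
    if ss[0] <= ss[-1]:
        log.warning("within-SS curve is non-decreasing; falling back to k=%d", ks[0])
        return ks[0], curve
    if ss[0] < 1e-12:
        log.warning("zero within-SS everywhere; k=%d", ks[0])
        return ks[0], curve
    # perpendicular distance from each curve point to the endpoint chord
    p1 = np.array([ks[0], ss[0]])
    p2 = np.array([ks[-1], ss[-1]])
    # normalise axes so the chord geometry is scale-free
    span_k = ks[-1] - ks[0]
    span_s = ss[0] - ss[-1]
    pts = np.column_stack([(np.array(ks) - ks[0]) / span_k, (ss - ss[-1]) / span_s])
    a = pts[-1] - pts[0]
    a = a / np.linalg.norm(a)
    rel = pts - pts[0]
    dist = np.abs(rel[:, 0] * a[1] - rel[:, 1] * a[0])
    return int(ks[int(np.argmax(dist))]), curve


def kmeans_assign(
    embedding: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 25
) -> FunCAssignment:
    """k-means clustering of the embedding into k FunCs.

    k-means++ initialisation with 25 restarts, best within-SS kept; labels
    renumbered 1..k by descending cluster size (ties by first appearance).
    """
    x = embedding.values
    if k > len(x):
        raise ValueError(f"k={k} exceeds number of points {len(x)}")
    _, raw = _withinss(x, k, seed, n_restarts)
    sizes = pd.Series(raw).value_counts()
    order = sizes.sort_values(ascending=False, kind="stable").index
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[l] for l in raw], index=embedding.index, name="cluster"
    )
    return FunCAssignment(labels=labels, k=k, embedding=embedding)


def ko_set_overlaps(
    matrix: pd.DataFrame, labels: pd.Series
) -> tuple[dict[int, int], dict[frozenset[int], int]]:
    """Per-FunC KO union sizes and the UpSet-style exact intersection partition.

    Returns (union_sizes, region_counts) where region_counts maps each
    non-empty FunC subset S to the number of KOs present in exactly the
    FunCs of S.  Region counts sum to the size of the global union.
    """
    clusters = sorted(labels.unique())
    union_sets = {
        c: set(matrix.columns[(matrix.loc[labels[labels == c].index] > 0).any(axis=0)])
        for c in clusters
    }
    union_sizes = {c: len(s) for c, s in union_sets.items()}
    regions: dict[frozenset[int], int] = {}
    all_kos = set().union(*union_sets.values()) if union_sets else set()
    for ko in all_kos:
        member = frozenset(c for c in clusters if ko in union_sets[c])
        regions[member] = regions.get(member, 0) + 1
    return union_sizes, regions


def fisher_enrichment(
    matrix: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact test per (KO, FunC).

    For each KO and cluster the 2×2 table counts rMAGs in/out of the cluster
    with/without the KO; p is the upper hypergeometric tail.  p-values are
    Benjamini–Hochberg adjusted jointly across all (KO, FunC) pairs; a KO is
    enriched in a FunC iff the adjusted p is below ``alpha``.
    """
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for enrichment")
    x = matrix.loc[labels.index].values.astype(bool)
    n = x.shape[0]
    ko_totals = x.sum(axis=0)
    rows = []
    for c in clusters:
        in_c = (labels == c).values
        n_c = int(in_c.sum())
        k_in = x[in_c].sum(axis=0)
        for j, ko in enumerate(matrix.columns):
            big_k = int(ko_totals[j])
            a = int(k_in[j])
            # P[X >= a] for X ~ Hypergeom(N=n, K=big_k, n=n_c)
            p = 1.0 if big_k == 0 else float(hypergeom.sf(a - 1, n, big_k, n_c))
            rows.append(
                {
                    "ko_id": ko,
                    "cluster": c,
                    "in_with": a,
                    "in_without": n_c - a,
                    "out_with": big_k - a,
                    "out_without": n - n_c - (big_k - a),
                    "p": min(p, 1.0),
                }
            )
    res = pd.DataFrame(rows)
    res["p_adj"] = multipletests(res["p"].values, method="fdr_bh")[1]
    res["p_adj"] = np.maximum(res["p_adj"], res["p"])
    res["enriched"] = res["p_adj"] < alpha
    return res


def adjusted_prevalence(
    matrix: pd.DataFrame,
    labels: pd.Series,
    completeness: pd.Series,
    ko_set: set[str],
) -> pd.Series:
    """Completeness-adjusted prevalence of a function within each FunC.

    Proportion of member rMAGs carrying ≥1 KO of ``ko_set``, divided by the
    FunC's mean completeness, capped at 1.
    """
    kos = [k for k in ko_set if k in matrix.columns]
    carrier = (matrix[kos] > 0).any(axis=1) if kos else pd.Series(False, index=matrix.index)
    out = {}
    for c in sorted(labels.unique()):
        members = labels[labels == c].index
        mean_comp = completeness.loc[members].mean()
        if mean_comp <= 0:
            raise ValueError(f"mean completeness of cluster {c} is zero")
        out[c] = min(carrier.loc[members].mean() / mean_comp, 1.0)
    return pd.Series(out, name="adjusted_prevalence")


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes m²: both configurations centred and trace-normalised,
    y rotated/reflected and scaled onto x; returns the minimised residual SS."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate configuration (all points identical)")
    xc /= nx
    yc /= ny
    s = np.linalg.svd(xc.T @ yc, compute_uv=False)
    return float(max(1.0 - s.sum() ** 2, 0.0))


def procrustes_protest(
    x: pd.DataFrame,
    y: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Procrustes superimposition of two embeddings plus PROTEST permutation test.

    Least-squares fit with translation, rotation/reflection and scaling under
    the symmetric (both-matrices trace-normalised) convention; m² is the
    minimised residual sum of squares, correlation = sqrt(1 − m²), and the
    p-value counts permutations of Y's rows with m² ≤ the observed one,
    using the (hits + 1)/(n_perm + 1) convention.
    """
    common = [i for i in x.index if i in set(y.index)]
    if len(common) != len(x.index) or len(common) != len(y.index):
        raise ValueError("embeddings must share the same row ids")
    if len(common) < 3:
        raise ValueError("need at least three rows")
    xa = x.loc[common].values.astype(float)
    ya = y.loc[common].values.astype(float)
    m2 = _procrustes_m2(xa, ya)
    corr = float(np.sqrt(max(1.0 - m2, 0.0)))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(ya))
        if _procrustes_m2(xa, ya[perm]) <= m2:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return m2, corr, p
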