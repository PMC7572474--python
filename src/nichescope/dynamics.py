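"""Community dynamics: abundance profiles, distance structure, group tests,
temporal stability, ordination, and abiotic-factor preprocessing.

Population abundance is inferred from metagenomic depth-of-coverage, converted
to relative abundance per time-point.  Profile similarity uses the correlation
distance d = 1 − (ρ + 1)/2, tested against functional-cluster membership with
PERMANOVA and a multivariate dispersion test.  Temporal stability is the
invariability ratio mean/sd of a population's relative-abundance series.
Bray–Curtis ordination plus post-hoc vector fitting links community structure
to abiotic factors; missing pH-style series are completed by Stineman
interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .niches import classical_mds

log = logging.getLogger("nichescope")


@dataclass
class StabilityResult:
    rmag_id: str
    stability: float | None  # None when the series is constant (sd = 0)
    window: list


def relative_abundance(rmag_depths: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise an rMAG × sample depth table to relative abundances."""
    if (rmag_depths.values < 0).any():
        raise ValueError("depths must be non-negative")
    sums = rmag_depths.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero timepoint(s): {list(zero.index)}")
    return rmag_depths.div(sums, axis=1)


def correlation_distance_matrix(
    profiles: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise profile distance d = 1 − (ρ + 1)/2 ∈ [0, 1].

    ``profiles`` is rMAG × timepoint.  Constant profiles have undefined ρ;
    their distances are recorded as NaN with a warning.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least three timepoints")
    x = profiles.values.astype(float)
    const = x.std(axis=1) == 0
    if const.any():
        log.warning(
            "%d constant profile(s): correlation undefined, distances set NaN",
            int(const.sum()),
        )
    if method == "pearson":
        rho = np.corrcoef(x)
    elif method == "spearman":
        rho, _ = spearmanr(x.T)
        rho = np.atleast_2d(rho)
    else:
        raise ValueError(f"unknown method {method!r}")
    d = 1.0 - (rho + 1.0) / 2.0
    np.fill_diagonal(d, 0.0)
    d[const, :] = np.nan
    d[:, const] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def _permanova_stats(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R² from squared distances and integer group codes.

    SS_total = Σ_{i<j} d²_ij / n;  SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g.
    """
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    labels = np.unique(groups)
    for g in labels:
        idx = np.where(groups == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(labels)
    if ss_within == 0:
        f = np.inf
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = 1.0 - ss_within / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dist: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Permutational multivariate ANOVA (Anderson's partition).

    Returns (pseudo_F, R², p).  p uses the (#{F_perm ≥ F_obs} + 1)/(n_perm+1)
    convention under random label permutation.
    """
    g = groups.loc[dist.index].values
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    d2 = dist.values.astype(float) ** 2
    f_obs, r2 = _permanova_stats(d2, g)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(g))
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return f_obs, r2, p


def dispersion_test(
    dist: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.Series, float, float]:
    """Multivariate homogeneity-of-dispersion test (betadisper-style).

    Embeds the distance matrix by classical MDS on all positive-eigenvalue
    axes, measures each sample's Euclidean distance to its group centroid,
    and applies a one-way F test on those distances with a permutation p.
    """
    g = groups.loc[dist.index]
    labels, counts = np.unique(g.values, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    n = dist.shape[0]
    emb, _ = classical_mds(dist, dims=max(n - 1, 2))
    x = emb.values

    def group_dists(codes: np.ndarray) -> np.ndarray:
        out = np.empty(n)
        for lab in np.unique(codes):
            idx = np.where(codes == lab)[0]
            centroid = x[idx].mean(axis=0)
            out[idx] = np.linalg.norm(x[idx] - centroid, axis=1)
        return out

    def anova_f(vals: np.ndarray, codes: np.ndarray) -> float:
        grand = vals.mean()
        ssb = ssw = 0.0
        for lab in np.unique(codes):
            idx = codes == lab
            ssb += idx.sum() * (vals[idx].mean() - grand) ** 2
            ssw += ((vals[idx] - vals[idx].mean()) ** 2).sum()
        a = len(np.unique(codes))
        if ssw == 0:
            return np.inf
        return (ssb / (a - 1)) / (ssw / (len(vals) - a))

    codes = g.values
    d_obs = group_dists(codes)
    f_obs = anova_f(d_obs, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        # betadisper permutes the centroid-distances among samples
        if anova_f(d_obs, perm) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    per_group = pd.Series(
        {lab: d_obs[codes == lab].mean() for lab in labels},
        name="mean_dist_to_centroid",
    )
    return per_group, f_obs, p


def temporal_stability(
    profiles: pd.DataFrame, exclude_window: list | None = None
) -> list[StabilityResult]:
    """Temporal stability (invariability) per rMAG: mean / sample sd.

    ``exclude_window`` lists timepoint columns to drop (e.g., a disturbance
    window); a constant series has undefined stability and is flagged, not
    dropped.
    """
    cols = list(profiles.columns)
    if exclude_window:
        cols = [c for c in cols if c not in set(exclude_window)]
    if len(cols) < 3:
        raise ValueError("need at least three timepoints after exclusion")
    out = []
    sub = profiles[cols]
    for r, row in sub.iterrows():
        sd = row.std(ddof=1)
        if sd == 0:
            log.warning("constant abundance series for %s: stability undefined", r)
            out.append(StabilityResult(r, None, cols))
        else:
            out.append(StabilityResult(r, float(row.mean() / sd), cols))
    return out


def braycurtis_pcoa(
    abundances: pd.DataFrame, dims: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Bray–Curtis dissimilarity between samples plus classical MDS ordination.

    ``abundances`` is rMAG × sample; distances are between sample columns.
    Returns (distance matrix, embedding, variance explained).
    """
    x = abundances.values.T.astype(float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if (x.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined for pairs of all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    dist = pd.DataFrame(d, index=abundances.columns, columns=abundances.columns)
    emb, var = classical_mds(dist, dims=dims)
    return dist, emb, var


def fit_factors(
    embedding: pd.DataFrame,
    abiotic: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Post-hoc vector fitting of abiotic factors onto a 2-D ordination.

    Each factor (z-scored, pairwise-complete) is regressed on the two
    ordination axes; the arrow is the unit coefficient vector scaled by
    sqrt(R²), with a permutation p-value on R².  Constant factors are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    axes = embedding.values[:, :2]
    for fac in abiotic.columns:
        vals = abiotic[fac].reindex(embedding.index)
        mask = vals.notna().values
        if mask.sum() < 3:
            log.warning("factor %s: fewer than 3 paired observations, skipped", fac)
            continue
        v = vals.values[mask].astype(float)
        if v.std(ddof=1) == 0:
            log.warning("factor %s is constant, skipped", fac)
            continue
        v = zscore(pd.Series(v)).values
        x = axes[mask]
        xc = x - x.mean(axis=0)

        def r2_of(target: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(xc, target - target.mean(), rcond=None)
            pred = xc @ beta
            tss = ((target - target.mean()) ** 2).sum()
            return float((pred**2).sum() / tss), beta

        r2, beta = r2_of(v)
        norm = np.linalg.norm(beta)
        unit = beta / norm if norm > 0 else np.zeros(2)
        arrow = unit * np.sqrt(max(r2, 0.0))
        hits = 0
        for _ in range(n_perm):
            r2p, _ = r2_of(rng.permutation(v))
            if r2p >= r2:
                hits += 1
        rows.append(
            {
                "factor_id": fac,
                "arrow_x": arrow[0],
                "arrow_y": arrow[1],
                "r2": r2,
                "p": (hits + 1) / (n_perm + 1),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def spearman_associations(
    abundances: pd.DataFrame,
    abiotic: pd.DataFrame,
    min_pairs: int = 5,
    adjust: bool = True,
) -> pd.DataFrame:
    """Spearman correlation of each rMAG abundance series with each abiotic factor.

    Tie-corrected ranks; pairwise-complete observations; BH adjustment across
    all (rMAG, factor) pairs (toggleable).  Pairs with fewer than
    ``min_pairs`` observations are skipped and logged.
    """
    rows = []
    for r, series in abundances.iterrows():
        for fac in abiotic.columns:
            pair = pd.concat(
                [series.rename("a"), abiotic[fac].rename("b")], axis=1, join="inner"
            ).dropna()
            if len(pair) < min_pairs:
                log.warning("pair (%s, %s): only %d observations, skipped",
                            r, fac, len(pair))
                continue
            rho, p = spearmanr(pair["a"], pair["b"])
            rows.append({"rmag_id": r, "factor_id": fac, "rho": rho, "p": p})
    res = pd.DataFrame(rows)
    if len(res) and adjust:
        res["p_adj"] = multipletests(res["p"].values, method="fdr_bh")[1]
    elif len(res):
        res["p_adj"] = res["p"]
    return res


def zscore(values: pd.Series) -> pd.Series:
    """(x − mean)/sd with sample sd; missing values preserved; constant → zeros."""
    obs = values.dropna()
    if len(obs) < 2:
        raise ValueError("need at least two non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        log.warning("constant series in zscore: returning zeros")
        out = values.copy()
        out[values.notna()] = 0.0
        return out
    return (values - obs.mean()) / sd


def _stineman_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Slope estimates at the knots: slope of the circle through each point
    and its two neighbours (secant slope where collinear); one-sided
    parabolic extrapolation at the ends."""
    n = len(x)
    dx = np.diff(x)
    s = np.diff(y) / dx
    yp = np.empty(n)
    if n == 2:
        yp[:] = s[0]
        return yp
    for i in range(1, n - 1):
        s1, s2 = s[i - 1], s[i]
        if s1 == s2:
            yp[i] = s1
            continue
        # circle through (x[i-1],y[i-1]), (x[i],y[i]), (x[i+1],y[i+1])
        x1, y1 = x[i - 1] - x[i], y[i - 1] - y[i]
        x2, y2 = x[i + 1] - x[i], y[i + 1] - y[i]
        den = 2.0 * (x1 * y2 - x2 * y1)
        if den == 0:  # collinear
            yp[i] = s1
            continue
        r1 = x1 * x1 + y1 * y1
        r2 = x2 * x2 + y2 * y2
        a = (r1 * y2 - r2 * y1) / den  # centre x-offset
        b = (r2 * x1 - r1 * x2) / den  # centre y-offset
        if b == 0:
            yp[i] = s1
        else:
            # tangent slope of the circle at the middle point
            yp[i] = -a / b
        # guard against wild circle slopes at near-degenerate geometry
        lo, hi = min(s1, s2), max(s1, s2)
        if not (lo <= yp[i] <= hi):
            yp[i] = np.clip(yp[i], lo, hi)
    yp[0] = s[0] + (s[0] - yp[1]) * (0.5 if n > 2 else 0.0)
    yp[-1] = s[-1] + (s[-1] - yp[-2]) * (0.5 if n > 2 else 0.0)
    # endpoint slopes must not oppose the adjacent secant
    if s[0] != 0 and np.sign(yp[0]) != np.sign(s[0]):
        yp[0] = 0.0
    if s[-1] != 0 and np.sign(yp[-1]) != np.sign(s[-1]):
        yp[-1] = 0.0
    return yp


def stineman_interpolate(
    x_obs: np.ndarray, y_obs: np.ndarray, x_new: np.ndarray
) -> np.ndarray:
    """Stineman's rational interpolation.

    Exact on linear segments and free of overshoot: interpolated values stay
    within the bounds of neighbouring knots when the data are monotone.
    Points outside the observed range take the nearest observed value.
    """
    x_obs = np.asarray(x_obs, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if len(x_obs) < 2:
        raise ValueError("need at least two observed points")
    order = np.argsort(x_obs)
    x_obs, y_obs = x_obs[order], y_obs[order]
    yp = _stineman_slopes(x_obs, y_obs)
    out = np.empty(len(x_new), dtype=float)
    for j, xq in enumerate(np.asarray(x_new, dtype=float)):
        if xq <= x_obs[0]:
            out[j] = y_obs[0]
            continue
        if xq >= x_obs[-1]:
            out[j] = y_obs[-1]
            continue
        i = int(np.searchsorted(x_obs, xq, side="right") - 1)
        h = x_obs[i + 1] - x_obs[i]
        s = (y_obs[i + 1] - y_obs[i]) / h
        y_lin = y_obs[i] + s * (xq - x_obs[i])
        dy1 = y_obs[i] + yp[i] * (xq - x_obs[i]) - y_lin
        dy2 = y_obs[i + 1] + yp[i + 1] * (xq - x_obs[i + 1]) - y_lin
        prod = dy1 * dy2
        if prod > 0:
            val = y_lin + prod / (dy1 + dy2)
        elif prod < 0:
            val = y_lin + prod * ((xq - x_obs[i]) + (xq - x_obs[i + 1])) / (
                (dy1 - dy2) * h
            )
        else:
            val = y_lin
        # the defining property of the method is absence of overshoot; the
        # rational form can exceed the knot range marginally when both knot
        # slopes dwarf the interval secant, so enforce the bound
        lo = min(y_obs[i], y_obs[i + 1])
        hi = max(y_obs[i], y_obs[i + 1])
        out[j] = min(max(val, lo), hi)
    return out


def stineman_impute(series: pd.Series) -> pd.Series:
    """Fill gaps in a time series by Stineman interpolation.

    The index must be numeric (or coercible) measurement positions.  Leading
    and trailing gaps are filled with the nearest observed value, with a
    warning.
    """
    x = np.asarray(series.index, dtype=float)
    mask = series.notna().values
    if mask.sum() < 2:
        raise ValueError("need at least two observed points")
    if not mask[0] or not mask[-1]:
        log.warning("leading/trailing gaps filled with nearest observed value")
    filled = stineman_interpolate(x[mask], series.values[mask].astype(float), x)
    out = series.copy().astype(float)
    out[~mask] = filled[~mask]
    return out
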