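import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from nichescope.dynamics import (
    braycurtis_pcoa,
    correlation_distance_matrix,
    dispersion_test,
    fit_factors,
    permanova,
    relative_abundance,
    spearman_associations,
    stineman_impute,
    stineman_interpolate,
    temporal_stability,
    zscore,
)


def permanova_oracle(d: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Independent double-loop computation of the PERMANOVA partition."""
    n = len(groups)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i in range(n) if groups[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    a = len(set(groups))
    f = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    return f, 1 - ss_within / ss_total


class TestRelativeAbundance:
    def test_column_normalisation(self):
        depths = pd.DataFrame({"t1": [3.0, 1.0]}, index=["A", "B"])
        rel = relative_abundance(depths)
        assert rel["t1"].tolist() == pytest.approx([0.75, 0.25])

    def test_single_rmag_is_one(self):
        depths = pd.DataFrame({"t1": [5.0], "t2": [0.1]}, index=["A"])
        assert (relative_abundance(depths).values == 1.0).all()

    def test_columns_sum_to_one(self, rng):
        depths = pd.DataFrame(rng.uniform(0.1, 5, size=(10, 6)))
        np.testing.assert_allclose(relative_abundance(depths).sum(0), 1.0)

    def test_zero_timepoint_rejected(self):
        depths = pd.DataFrame({"t1": [1.0, 1.0], "t2": [0.0, 0.0]})
        with pytest.raises(ValueError, match="t2"):
            relative_abundance(depths)


class TestCorrelationDistance:
    def test_endpoints(self):
        t = np.arange(10, dtype=float)
        profiles = pd.DataFrame(
            {"up": t, "up2": 2 * t + 1, "down": -t}, columns=["up", "up2", "down"]
        ).T
        d = correlation_distance_matrix(profiles)
        assert d.loc["up", "up2"] == pytest.approx(0.0, abs=1e-12)  # rho 1
        assert d.loc["up", "down"] == pytest.approx(1.0)  # rho -1
        assert d.loc["up", "up"] == 0.0

    def test_uncorrelated_half(self, rng):
        # orthogonal series: rho 0 -> d 0.5
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        d = correlation_distance_matrix(pd.DataFrame([a, b], index=["a", "b"]))
        assert d.loc["a", "b"] == pytest.approx(0.5)

    def test_bounds_on_random_profiles(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(12, 8)))
        d = correlation_distance_matrix(profiles).values
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_constant_profile_flagged_nan(self):
        profiles = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["const", "var"]
        )
        d = correlation_distance_matrix(profiles)
        assert np.isnan(d.loc["const", "var"])
        assert d.loc["const", "const"] == 0.0


class TestPermanova:
    def test_maximally_separated_duplicates_r2_one(self):
        # two groups of identical points at distance 1: SS_within = 0
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        dist = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=dist.index)
        f, r2, p = permanova(dist, groups, n_perm=99, seed=0)
        assert r2 == pytest.approx(1.0)
        assert np.isinf(f)

    def test_single_group_rejected(self):
        dist = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        with pytest.raises(ValueError):
            permanova(dist, pd.Series([1, 1, 1, 1], index=dist.index))

    def test_partition_matches_bruteforce_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform
        for _ in range(100):
            n = int(rng.integers(6, 12))
            pts = rng.normal(size=(n, 3))
            d = squareform(pdist(pts))
            groups = rng.integers(0, 2, size=n)
            while len(set(groups)) < 2 or min(np.bincount(groups)) < 2:
                groups = rng.integers(0, 2, size=n)
            dist = pd.DataFrame(d)
            f, r2, _ = permanova(dist, pd.Series(groups), n_perm=9, seed=0)
            f_o, r2_o = permanova_oracle(d, groups)
            assert f == pytest.approx(f_o)
            assert r2 == pytest.approx(r2_o)

    def test_p_matches_exhaustive_enumeration(self):
        # 6 points, 2 groups of 3: all C(6,3)=20 assignments enumerable
        rng = np.random.default_rng(5)
        from scipy.spatial.distance import pdist, squareform
        pts = rng.normal(size=(6, 2))
        pts[:3] += 2.0
        d = squareform(pdist(pts))
        dist = pd.DataFrame(d)
        groups = np.array([1, 1, 1, 2, 2, 2])
        f_obs, _, _ = permanova(dist, pd.Series(groups), n_perm=9, seed=0)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            g = np.full(6, 2)
            g[list(idx)] = 1
            f, _ = permanova_oracle(d, g)
            total += 1
            if f >= f_obs - 1e-12:
                hits += 1
        exact_p = hits / total
        # large-n_perm permutation p converges to the enumeration value
        _, _, p = permanova(dist, pd.Series(groups), n_perm=4999, seed=1)
        assert p == pytest.approx(exact_p, abs=0.02)

    def test_null_p_uniform(self):
        # label permutations under the null: KS test over 200 replicates
        rng = np.random.default_rng(11)
        from scipy.spatial.distance import pdist, squareform
        pts = rng.normal(size=(14, 3))
        d = pd.DataFrame(squareform(pdist(pts)))
        ps = []
        for rep in range(200):
            groups = pd.Series(rng.permutation([1] * 7 + [2] * 7))
            _, _, p = permanova(d, groups, n_perm=99, seed=rep)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestDispersion:
    def test_equal_spread_not_significant(self):
        rng = np.random.default_rng(3)
        from scipy.spatial.distance import pdist, squareform
        a = rng.normal(size=(12, 2))
        b = -a  # mirror image: identical spread
        d = pd.DataFrame(squareform(pdist(np.vstack([a, b]))))
        groups = pd.Series([1] * 12 + [2] * 12)
        per_group, f, p = dispersion_test(d, groups, n_perm=199, seed=0)
        assert per_group[1] == pytest.approx(per_group[2], rel=1e-6)
        assert p > 0.5

    def test_unequal_spread_detected(self):
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(4)
        detected = 0
        for rep in range(20):
            tight = rng.normal(scale=0.1, size=(10, 2))
            loose = rng.normal(scale=3.0, size=(10, 2))
            d = pd.DataFrame(squareform(pdist(np.vstack([tight, loose]))))
            groups = pd.Series([1] * 10 + [2] * 10)
            _, f, p = dispersion_test(d, groups, n_perm=199, seed=rep)
            if p < 0.05:
                detected += 1
        assert detected >= 18

    def test_p_lower_bound(self):
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        groups = pd.Series([1] * 5 + [2] * 5)
        _, _, p = dispersion_test(d, groups, n_perm=199, seed=0)
        assert p >= 1 / 200


class TestStability:
    def test_exact_value_small_series(self):
        # [2, 4, 3]: mean 3, sample sd 1 → stability 3; and the two-point
        # kernel [2, 4] → 3/√2 once the third point is excluded would follow
        # the same mean/sd rule
        profiles = pd.DataFrame([[2.0, 4.0, 3.0]], index=["A"])
        res = temporal_stability(profiles)
        assert res[0].stability == pytest.approx(3.0)
        assert np.mean([2.0, 4.0]) / np.std([2.0, 4.0], ddof=1) == pytest.approx(
            3 / np.sqrt(2)
        )

    def test_mean_over_sd_formula(self):
        profiles = pd.DataFrame([[2.0, 4.0, 2.0, 4.0]], index=["A"])
        res = temporal_stability(profiles)
        vals = np.array([2.0, 4.0, 2.0, 4.0])
        assert res[0].stability == pytest.approx(vals.mean() / vals.std(ddof=1))

    def test_constant_series_flagged(self):
        profiles = pd.DataFrame([[1.0, 1.0, 1.0]], index=["A"])
        res = temporal_stability(profiles)
        assert res[0].stability is None

    def test_exclusion_window_removes_timepoints(self):
        profiles = pd.DataFrame(
            [[1.0, 1.0, 10.0, 1.0, 1.0, 1.1]], index=["A"],
            columns=[f"t{i}" for i in range(6)],
        )
        incl = temporal_stability(profiles)[0].stability
        excl = temporal_stability(profiles, exclude_window=["t2"])[0].stability
        assert excl > incl  # removing the spike increases invariability


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        ab = pd.DataFrame(
            {"s1": [1.0, 2.0, 0.0], "s2": [1.0, 2.0, 0.0], "s3": [0.0, 0.0, 5.0]}
        )
        d, _, _ = braycurtis_pcoa(ab)
        assert d.loc["s1", "s2"] == pytest.approx(0.0)
        assert d.loc["s1", "s3"] == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            ab = pd.DataFrame(rng.uniform(0, 5, size=(6, 4)))
            d, _, _ = braycurtis_pcoa(ab)
            x = ab.values
            for i, j in itertools.combinations(range(4), 2):
                expected = np.abs(x[:, i] - x[:, j]).sum() / (x[:, i] + x[:, j]).sum()
                assert d.iloc[i, j] == pytest.approx(expected)
                assert 0 <= d.iloc[i, j] <= 1


class TestFitFactors:
    def test_factor_equal_to_axis(self, rng):
        emb = pd.DataFrame(rng.normal(size=(30, 2)), columns=["MDS1", "MDS2"])
        abiotic = pd.DataFrame({"fac": emb["MDS1"]})
        res = fit_factors(emb, abiotic, n_perm=99, seed=0)
        assert res["r2"].iloc[0] == pytest.approx(1.0)
        arrow = res[["arrow_x", "arrow_y"]].values.ravel()
        assert abs(arrow[0]) == pytest.approx(1.0, abs=1e-6)
        assert arrow[1] == pytest.approx(0.0, abs=1e-6)

    def test_noise_factor_low_r2(self, rng):
        emb = pd.DataFrame(rng.normal(size=(60, 2)), columns=["MDS1", "MDS2"])
        abiotic = pd.DataFrame({"noise": rng.normal(size=60)}, index=emb.index)
        res = fit_factors(emb, abiotic, n_perm=99, seed=0)
        assert res["r2"].iloc[0] < 0.2

    def test_arrow_norm_is_sqrt_r2(self, rng):
        emb = pd.DataFrame(rng.normal(size=(25, 2)), columns=["MDS1", "MDS2"])
        abiotic = pd.DataFrame(
            {"f": emb["MDS1"] * 0.3 + rng.normal(scale=0.5, size=25)}
        )
        res = fit_factors(emb, abiotic, n_perm=9, seed=0)
        norm = np.hypot(res["arrow_x"].iloc[0], res["arrow_y"].iloc[0])
        assert norm == pytest.approx(np.sqrt(res["r2"].iloc[0]))


class TestSpearman:
    def test_monotone_pairs(self):
        ab = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["A"])
        abiotic = pd.DataFrame(
            {"up": [2.0, 4.0, 6.0, 8.0, 10.0], "down": [5.0, 4.0, 3.0, 2.0, 1.0]}
        )
        res = spearman_associations(ab, abiotic).set_index("factor_id")
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        from scipy.stats import rankdata
        for _ in range(50):
            n = 12
            a = rng.integers(0, 4, size=n).astype(float)  # ties present
            b = rng.integers(0, 4, size=n).astype(float)
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            ab = pd.DataFrame([a], index=["A"])
            abiotic = pd.DataFrame({"f": b})
            res = spearman_associations(ab, abiotic, adjust=False)
            ra, rb = rankdata(a), rankdata(b)
            oracle = np.corrcoef(ra, rb)[0, 1]
            assert res["rho"].iloc[0] == pytest.approx(oracle)

    def test_insufficient_pairs_skipped(self):
        ab = pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"])
        abiotic = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        res = spearman_associations(ab, abiotic, min_pairs=5)
        assert len(res) == 0


class TestZscore:
    def test_basic(self):
        out = zscore(pd.Series([1.0, 2.0, 3.0]))
        assert out.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_zeros(self):
        out = zscore(pd.Series([2.0, 2.0, 2.0]))
        assert (out == 0.0).all()

    def test_missing_preserved_and_moments(self, rng):
        s = pd.Series(rng.normal(size=20))
        s.iloc[[3, 7]] = np.nan
        out = zscore(s)
        assert out.isna().sum() == 2
        assert out.dropna().mean() == pytest.approx(0.0, abs=1e-12)
        assert out.dropna().std(ddof=1) == pytest.approx(1.0)


class TestStineman:
    def test_linear_exactness(self):
        y = stineman_interpolate([0.0, 2.0], [1.0, 3.0], [1.0])
        assert y[0] == pytest.approx(2.0)

    def test_no_gaps_identity(self):
        s = pd.Series([1.0, 4.0, 2.0, 5.0], index=[0, 1, 2, 3])
        pd.testing.assert_series_equal(stineman_impute(s), s)

    def test_linear_series_with_gap(self):
        s = pd.Series([1.0, np.nan, 3.0], index=[0, 1, 2])
        out = stineman_impute(s)
        assert out[1] == pytest.approx(2.0)

    def test_monotone_no_overshoot(self, rng):
        # interpolant of monotone knots stays within knot bounds
        for _ in range(100):
            n = int(rng.integers(4, 10))
            x = np.sort(rng.uniform(0, 10, size=n))
            x += np.arange(n) * 1e-3  # ensure strictly increasing
            y = np.sort(rng.uniform(0, 5, size=n))
            xq = rng.uniform(x[0], x[-1], size=40)
            yq = stineman_interpolate(x, y, xq)
            for q, v in zip(xq, yq):
                i = np.searchsorted(x, q, side="right") - 1
                i = min(max(i, 0), n - 2)
                lo, hi = min(y[i], y[i + 1]), max(y[i], y[i + 1])
                assert lo - 1e-9 <= v <= hi + 1e-9

    def test_leading_gap_filled_nearest(self):
        s = pd.Series([np.nan, 2.0, 3.0], index=[0, 1, 2])
        out = stineman_impute(s)
        assert out[0] == pytest.approx(2.0)
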