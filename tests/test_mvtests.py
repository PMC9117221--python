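"""Distance-matrix tests against exhaustive, closed-form, and skbio oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from oralmicro.mvtests import (
    anosim,
    anosim_units,
    geometric_median,
    homogeneity_test,
    permanova,
    permanova_one_vs_rest,
    twins_vs_siblings,
)


def _euclid_dm(coords, ids=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1:
        coords = coords.T
    ids = ids or [f"s{i}" for i in range(len(coords))]
    return DistanceMatrix(squareform(pdist(coords)), ids)


class TestPermanova:
    def test_exhaustive_enumeration_two_groups(self):
        """Two perfectly separated groups of 3: of the 20 balanced label
        assignments only the true one and its mirror reach the observed
        F, so the exhaustive p-value is 2/20 = 0.1."""
        dm = _euclid_dm([0, 0, 0, 10, 10, 10])
        design = pd.DataFrame({"g": list("aaabbb")}, index=dm.ids)
        res = permanova(dm, design, ["g"], n_perm="exact")
        assert res["g"]["p"] == pytest.approx(0.1)
        assert res["g"]["R2"] > 0.9

    def test_reduces_to_classical_anova_on_1d(self):
        """On Euclidean distances of 1-D data the pseudo-F equals the
        classical one-way ANOVA F exactly."""
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.5, 1, 8)])
        dm = _euclid_dm(y)
        design = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8}, index=dm.ids)
        res = permanova(dm, design, ["g"], n_perm=99)
        f_classic = stats.f_oneway(y[:8], y[8:]).statistic
        assert res["g"]["F"] == pytest.approx(f_classic, rel=1e-10)

    def test_single_factor_statistic_matches_skbio(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (15, 4))
        dm = _euclid_dm(pts)
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        design = pd.DataFrame({"g": labels}, index=dm.ids)
        mine = permanova(dm, design, ["g"], n_perm=99)
        theirs = skbio_permanova(dm, grouping=labels, permutations=99)
        assert mine["g"]["F"] == pytest.approx(theirs["test statistic"],
                                               rel=1e-10)

    def test_r2_partition_sums_to_one(self, small_cohort):
        from oralmicro.diversity import aitchison_distance, clr_transform

        ids = small_cohort.metadata.dropna(subset=["age", "gender"]).index[:60]
        dm = aitchison_distance(clr_transform(small_cohort.counts)).filter(ids)
        meta = small_cohort.metadata.loc[ids]
        res = permanova(dm, meta, ["smoking", "gender", "age"], n_perm=99)
        r2 = res.table.drop(index="total")["R2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_marginal_ss_order_invariant(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, (20, 3))
        dm = _euclid_dm(pts)
        design = pd.DataFrame(
            {"a": rng.normal(size=20), "b": rng.normal(size=20)},
            index=dm.ids,
        )
        design["b"] += 0.6 * design["a"]  # correlated terms
        f1 = permanova(dm, design, ["a", "b"], n_perm=99, seed=0,
                       ss_type="marginal")
        f2 = permanova(dm, design, ["b", "a"], n_perm=99, seed=0,
                       ss_type="marginal")
        assert f1["a"]["F"] == pytest.approx(f2["a"]["F"], rel=1e-10)
        assert f1["b"]["F"] == pytest.approx(f2["b"]["F"], rel=1e-10)
        # sequential SS depends on entry order for correlated terms
        s1 = permanova(dm, design, ["a", "b"], n_perm=99, seed=0)
        s2 = permanova(dm, design, ["b", "a"], n_perm=99, seed=0)
        assert abs(s1["a"]["SS"] - s2["a"]["SS"]) > 1e-8
        # last-entered sequential term equals its marginal SS
        assert s1["b"]["SS"] == pytest.approx(f1["b"]["SS"], rel=1e-10)

    def test_constant_term_dropped(self):
        dm = _euclid_dm(np.arange(8.0))
        design = pd.DataFrame({"g": ["x"] * 8, "y": np.arange(8.0)},
                              index=dm.ids)
        with pytest.warns(UserWarning, match="confounded or constant"):
            res = permanova(dm, design, ["g", "y"], n_perm=99)
        assert res.dropped == ["g"]
        assert "y" in res.terms

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        dm = DistanceMatrix(np.zeros((2, 2)), ["a", "b"])
        dm.data[:] = bad
        design = pd.DataFrame({"g": ["a", "b"]}, index=["a", "b"])
        with pytest.raises(ValueError):
            permanova(dm, design, ["g"], n_perm=99)


class TestOneVsRest:
    def test_binary_split_equals_binary_permanova(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (20, 3))
        pts[:10] += 1.0
        dm = _euclid_dm(pts)
        bins = pd.Series(["young"] * 10 + ["old"] * 10, index=dm.ids)
        design = pd.DataFrame({"cov": rng.normal(size=20)}, index=dm.ids)
        ovr = permanova_one_vs_rest(dm, bins, design, ["cov"], n_perm=99, seed=0)
        design2 = design.copy()
        design2["_is_bin"] = (bins == "young").astype(float)
        direct = permanova(dm, design2, ["_is_bin", "cov"], n_perm=99, seed=0)
        assert ovr["young"]["_is_bin"]["F"] == pytest.approx(
            direct["_is_bin"]["F"], rel=1e-10
        )

    def test_identical_bins_not_significant(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, (24, 3))
        dm = _euclid_dm(pts)
        bins = pd.Series(["a", "b"] * 12, index=dm.ids)
        design = pd.DataFrame(index=dm.ids)
        ovr = permanova_one_vs_rest(dm, bins, design, [], n_perm=199, seed=1)
        assert all(ovr[b]["_is_bin"]["p"] > 0.05 for b in ("a", "b"))

    def test_tiny_bin_rejected(self):
        dm = _euclid_dm(np.arange(10.0))
        bins = pd.Series(["a"] * 2 + ["b"] * 8, index=dm.ids)
        with pytest.raises(ValueError, match="fewer than 3"):
            permanova_one_vs_rest(dm, bins, pd.DataFrame(index=dm.ids), [],
                                  n_perm=99)


class TestGeometricMedian:
    def test_matches_grid_search(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0]])
        med = geometric_median(pts)
        # brute-force grid oracle
        xs = np.linspace(-0.5, 2.5, 301)
        ys = np.linspace(-0.5, 1.5, 201)
        grid = np.array([[x, y] for x in xs for y in ys])
        cost = np.linalg.norm(grid[:, None] - pts[None], axis=2).sum(axis=1)
        best = grid[cost.argmin()]
        assert np.linalg.norm(med - best) < 1e-2
        assert np.linalg.norm(pts - med, axis=1).sum() <= cost.min() + 1e-8

    def test_at_data_point_when_dominant(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        assert np.allclose(geometric_median(pts), [0.0, 0.0], atol=1e-8)


class TestHomogeneity:
    def test_planted_dispersion_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (25, 4))
        b = rng.normal(0, 1, (25, 4)) * 3.0
        dm = _euclid_dm(np.vstack([a, b]))
        groups = pd.Series(["A"] * 25 + ["B"] * 25, index=dm.ids)
        res = homogeneity_test(dm, groups)
        gm = res.group_means()
        assert gm["B"] > gm["A"]
        assert res.anova_p < 0.01

    def test_null_pvalues_roughly_uniform(self):
        """Same spherical Gaussian for both groups: the ANOVA p-value
        should be uniform (KS test at the 1% level over 80 replicates)."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(80):
            pts = rng.normal(0, 1, (30, 3))
            dm = _euclid_dm(pts)
            groups = pd.Series(["A"] * 15 + ["B"] * 15, index=dm.ids)
            ps.append(homogeneity_test(dm, groups).anova_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_euclidean_input_needs_no_negative_correction(self, small_cohort):
        from oralmicro.diversity import aitchison_distance, clr_transform

        dm = aitchison_distance(clr_transform(small_cohort.counts))
        ids = list(dm.ids)[:40]
        groups = pd.Series(["A", "B"] * 20, index=ids)
        res = homogeneity_test(dm.filter(ids), groups)
        assert not res.used_negative_correction

    def test_singleton_group_rejected(self):
        dm = _euclid_dm(np.arange(5.0))
        groups = pd.Series(["A"] * 4 + ["B"], index=dm.ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            homogeneity_test(dm, groups)


class TestAnosim:
    def test_perfectly_separated_pairs_give_r_one(self):
        d = np.array([
            [0.0, 0.1, 5.0, 5.1],
            [0.1, 0.0, 5.2, 5.0],
            [5.0, 5.2, 0.0, 0.2],
            [5.1, 5.0, 0.2, 0.0],
        ])
        dm = DistanceMatrix(d, list("abcd"))
        grouping = pd.Series({"a": "u1", "b": "u1", "c": "u2", "d": "u2"})
        assert anosim(dm, grouping, n_perm=99).r == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 1, (18, 3))
        dm = _euclid_dm(pts)
        labels = ["a", "b", "c"] * 6
        mine = anosim(dm, pd.Series(labels, index=dm.ids), n_perm=99)
        theirs = skbio_anosim(dm, grouping=labels, permutations=99)
        assert mine.r == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 1, (16, 3))
        d = squareform(pdist(pts))
        labels = pd.Series(["a", "b"] * 8, index=[f"s{i}" for i in range(16)])
        r1 = anosim(DistanceMatrix(d, list(labels.index)), labels, n_perm=99).r
        r2 = anosim(DistanceMatrix(d**2, list(labels.index)), labels, n_perm=99).r
        r3 = anosim(DistanceMatrix(np.expm1(d), list(labels.index)), labels,
                    n_perm=99).r
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(200):
            pts = rng.normal(0, 1, (12, 2))
            dm = _euclid_dm(pts)
            labels = pd.Series(rng.permutation(["a"] * 6 + ["b"] * 6),
                               index=dm.ids)
            rs.append(anosim(dm, labels, n_perm=99).r)
        assert abs(np.mean(rs)) < 0.02

    def test_units_inclusion_rule(self, small_cohort):
        """Only samples in a unit of size >= 2 enter; the sibling-shaped
        input (many small units) is a valid shape."""
        from oralmicro.diversity import aitchison_distance, clr_transform

        dm = aitchison_distance(clr_transform(small_cohort.counts))
        units = small_cohort.metadata["family_unit"].replace("", np.nan)
        res = anosim_units(dm, units, n_perm=99, seed=0)
        assert -1.0 <= res.r <= 1.0
        sizes = units.value_counts()
        n_in_units = int(sizes[sizes >= 2].sum())
        assert len(res.within) + len(res.between) == n_in_units * (n_in_units - 1) // 2

    def test_single_unit_rejected(self):
        dm = _euclid_dm(np.arange(4.0))
        units = pd.Series(["u"] * 4, index=dm.ids)
        with pytest.raises(ValueError):
            anosim_units(dm, units, n_perm=99)


class TestTwinsVsSiblings:
    @staticmethod
    def _dm_from_values(twin_vals, sib_vals):
        """Distance matrix of isolated pairs whose within-pair distance
        is the requested value."""
        n_pairs = len(twin_vals) + len(sib_vals)
        ids = []
        coords = []
        for k, v in enumerate(list(twin_vals) + list(sib_vals)):
            # place each pair far from all others on its own axis offset
            base = np.zeros(n_pairs)
            base[k] = 1000.0
            coords.append(base.copy())
            off = base.copy()
            off[k] += v
            coords.append(off)
            ids.extend([f"p{k}a", f"p{k}b"])
        d = squareform(pdist(np.array(coords)))
        return DistanceMatrix(d, ids), [
            (f"p{k}a", f"p{k}b") for k in range(len(twin_vals))
        ], [
            (f"p{k}a", f"p{k}b")
            for k in range(len(twin_vals), n_pairs)
        ]

    def test_identical_distance_multisets_p_one(self):
        dm, tw, sb = self._dm_from_values([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert twins_vs_siblings(dm, tw, sb)["p"] == pytest.approx(1.0)

    def test_complete_separation_matches_exact_enumeration(self):
        """Twins all closer than siblings at n=5 each: exact two-sided
        Mann-Whitney p is 2/C(10,5) = 2/252."""
        dm, tw, sb = self._dm_from_values([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        res = twins_vs_siblings(dm, tw, sb)
        assert res["p"] == pytest.approx(2 / 252)

    def test_exact_p_matches_bruteforce_enumeration(self):
        """Independent oracle: enumerate all C(8,4) group assignments of
        the pooled distances and count |U| as extreme as observed."""
        twin_vals = [1.0, 4.0, 6.0, 9.0]
        sib_vals = [2.0, 7.0, 11.0, 13.0]
        dm, tw, sb = self._dm_from_values(twin_vals, sib_vals)
        res = twins_vs_siblings(dm, tw, sb)
        pooled = np.array(twin_vals + sib_vals)
        n = 4
        u_obs = sum(a < b for a in twin_vals for b in sib_vals)
        stat_obs = min(u_obs, n * n - u_obs)
        count = total = 0
        for comb in itertools.combinations(range(8), n):
            grp_a = pooled[list(comb)]
            grp_b = pooled[[i for i in range(8) if i not in comb]]
            u = sum(a < b for a in grp_a for b in grp_b)
            if min(u, n * n - u) <= stat_obs:
                count += 1
            total += 1
        assert res["p"] == pytest.approx(count / total)

    def test_empty_side_rejected(self):
        dm, tw, sb = self._dm_from_values([1.0], [2.0])
        with pytest.raises(ValueError):
            twins_vs_siblings(dm, [], sb)
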