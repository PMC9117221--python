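"""Eligibility rules, group-size logic, matching, and balance checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oralmicro.io import validate_metadata
from oralmicro.subsampling import (
    AgeBinning,
    eligible_controls,
    subsample_age_bins,
    subsample_binary,
)


def _meta(n, seed=0, regions=("A", "B"), smoking_p=0.3, cf_ids=(), ds_ids=(),
          missing_age_ids=()):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "age": rng.uniform(13, 80, n).round(1),
            "gender": rng.choice(["male", "female"], n),
            "region": rng.choice(regions, n),
            "town_population": rng.integers(1000, 100000, n),
            "smoking": np.where(rng.random(n) < smoking_p, "yes", "no"),
            "cystic_fibrosis": "no",
            "down_syndrome": "no",
        },
        index=idx,
    )
    for i in cf_ids:
        meta.loc[i, "cystic_fibrosis"] = "yes"
    for i in ds_ids:
        meta.loc[i, "down_syndrome"] = "yes"
    for i in missing_age_ids:
        meta.loc[i, "age"] = np.nan
    return validate_metadata(meta)


class TestEligibility:
    def test_chronic_sample_excluded_from_lifestyle_test(self):
        meta = _meta(50, cf_ids=["s0"])
        meta.loc["s0", "smoking"] = "no"
        pool = eligible_controls(meta, "smoking")
        assert "s0" not in pool

    def test_chronic_sample_retained_when_it_is_the_variable(self):
        meta = _meta(60, cf_ids=["s0", "s1", "s2"])
        ens = subsample_binary(meta, "cystic_fibrosis", n_reps=3, min_group=3,
                               seed=0)
        for rep in range(3):
            assert set(ens.sets[rep]["yes"]) == {"s0", "s1", "s2"}

    def test_other_chronic_excluded_from_chronic_yes_group(self):
        meta = _meta(60, cf_ids=["s0", "s1", "s2"], ds_ids=["s1"])
        ens = subsample_binary(meta, "cystic_fibrosis", n_reps=2, min_group=2,
                               seed=0)
        assert "s1" not in ens.sets[0]["yes"]

    def test_missing_age_excluded(self):
        meta = _meta(50, missing_age_ids=["s5"])
        meta.loc["s5", "smoking"] = "no"
        assert "s5" not in eligible_controls(meta, "smoking")

    def test_region_outside_yes_group_excluded(self):
        meta = _meta(90, regions=("A", "B", "C"))
        meta["smoking"] = "no"
        in_a = meta.index[meta["region"] == "A"]
        meta.loc[in_a[: len(in_a) // 2], "smoking"] = "yes"
        pool = eligible_controls(meta, "smoking")
        assert pool  # non-smoking A samples remain
        assert (meta.loc[sorted(pool), "region"] == "A").all()

    def test_unknown_variable_raises(self):
        with pytest.raises(KeyError):
            eligible_controls(_meta(20), "vegetarian")


class TestGroupSizes:
    def test_small_yes_group_sets_both_sizes(self):
        # 40 yes / ~500 eligible no -> every repetition holds 40 + 40
        meta = _meta(540, smoking_p=0.0)
        meta.iloc[:40, meta.columns.get_loc("smoking")] = "yes"
        ens = subsample_binary(_revalidate(meta), "smoking", n_reps=10, seed=1)
        assert ens.group_sizes() == {"yes": 40, "no": 40}

    def test_cap_applies_when_both_groups_large(self):
        # 150 yes / 600 no -> capped at 100 + 100
        meta = _meta(750, smoking_p=0.0)
        meta.iloc[:150, meta.columns.get_loc("smoking")] = "yes"
        ens = subsample_binary(_revalidate(meta), "smoking", n_reps=5, seed=1)
        assert ens.group_sizes() == {"yes": 100, "no": 100}

    def test_too_small_group_refused(self):
        meta = _meta(100, smoking_p=0.0)
        meta.iloc[:4, meta.columns.get_loc("smoking")] = "yes"
        with pytest.raises(ValueError, match="smaller group"):
            subsample_binary(_revalidate(meta), "smoking", n_reps=2, seed=0)


def _revalidate(meta):
    return validate_metadata(meta.drop(columns=["chronic_disorder_any"]))


class TestEnsembleProperties:
    def test_same_seed_identical_ensembles(self):
        meta = _meta(300)
        a = subsample_binary(meta, "smoking", n_reps=5, seed=9)
        b = subsample_binary(meta, "smoking", n_reps=5, seed=9)
        assert a.sets == b.sets
        assert a.rep_seeds == b.rep_seeds

    def test_groups_disjoint_no_duplicates(self):
        meta = _meta(300)
        ens = subsample_binary(meta, "smoking", n_reps=20, seed=3)
        for rep in range(20):
            yes, no = ens.sets[rep]["yes"], ens.sets[rep]["no"]
            assert not set(yes) & set(no)
            assert len(set(yes)) == len(yes) and len(set(no)) == len(no)
        ens.validate()

    def test_controls_cover_pool_when_pool_large(self):
        # single gender/region so matching strata reduce to age bins and
        # the yes group occupies every stratum
        meta = _meta(600, smoking_p=0.0, seed=5, regions=("A",))
        meta["gender"] = "female"
        yes = list(meta.sample(30, random_state=1).index)
        meta.loc[yes, "smoking"] = "yes"
        meta = _revalidate(meta)
        ens = subsample_binary(meta, "smoking", n_reps=100, seed=2)
        drawn = set()
        for rep in range(100):
            drawn |= set(ens.sets[rep]["no"])
        binning = AgeBinning()
        yes_bins = set(binning.assign(meta.loc[yes, "age"]))
        pool = {i for i in eligible_controls(meta, "smoking")
                if binning.assign(meta.loc[[i], "age"]).iloc[0] in yes_bins}
        # every control in a stratum the yes group occupies should be
        # drawn at least once over 100 repetitions
        assert len(drawn & pool) / len(pool) > 0.9

    def test_matching_report_records_distributions(self):
        meta = _meta(300)
        ens = subsample_binary(meta, "smoking", n_reps=2, seed=0)
        rep = ens.matching_report[0]
        assert "age_ks_p" in rep
        assert rep["yes"]["n"] == rep["no"]["n"]

    def test_matched_ages_similar(self):
        """Controls matched on age bins: group age distributions should
        rarely differ (KS at 5%) even though the pool skews young."""
        rng = np.random.default_rng(3)
        n = 500
        meta = _meta(n, seed=3, smoking_p=0.0)
        meta["age"] = np.concatenate([rng.uniform(13, 30, 350),
                                      rng.uniform(30, 80, 150)]).round(1)
        old = meta.index[meta["age"] > 40][:40]
        meta.loc[old, "smoking"] = "yes"
        ens = subsample_binary(_revalidate(meta), "smoking", n_reps=40, seed=1)
        sig = sum(r["age_ks_p"] < 0.05 for r in ens.matching_report)
        assert sig <= 4


class TestAgeBins:
    def test_bin_assignment_edges(self):
        b = AgeBinning()
        got = b.assign(pd.Series([13.0, 19.9, 20.0, 59.9, 60.0, 84.0]))
        assert list(got) == ["13-20", "13-20", "20-30", "50-60", ">60", ">60"]

    def test_quota_oracle_single_stratum(self):
        """One region, one gender: per-bin size is simply min(occupancy, cap)."""
        rng = np.random.default_rng(0)
        per_bin = [30, 12, 8, 15, 9, 11]
        ages = np.concatenate([
            rng.uniform(lo, hi, k) for k, (lo, hi) in zip(
                per_bin, [(13, 20), (20, 30), (30, 40), (40, 50), (50, 60), (60, 80)])
        ])
        meta = validate_metadata(pd.DataFrame({
            "age": ages, "gender": "female", "region": "A",
            "town_population": 1000,
        }, index=[f"s{i}" for i in range(len(ages))]))
        ens = subsample_age_bins(meta, n_reps=4, seed=0)
        labels = AgeBinning().labels
        assert ens.group_sizes() == dict(zip(labels, per_bin))

    def test_sizes_constant_across_reps(self, small_cohort):
        ens = subsample_age_bins(small_cohort.metadata, n_reps=15, seed=1)
        first = ens.group_sizes()
        for rep in range(15):
            assert {g: len(v) for g, v in ens.sets[rep].items()} == first

    def test_empty_bin_refused(self):
        meta = _meta(40)
        meta["age"] = np.linspace(13, 19, 40).round(1)  # all in one bin
        with pytest.raises(ValueError, match="bin"):
            subsample_age_bins(_revalidate(meta), n_reps=2, seed=0)

    def test_region_balance_across_bins(self):
        """Planted region imbalance across ages: after balancing, a
        region x bin chi-square on the drawn sets is non-significant in
        at least 95% of repetitions."""
        rng = np.random.default_rng(7)
        n = 900
        ages = rng.uniform(13, 80, n).round(1)
        # region A dominates the young, B the old
        p_a = np.where(ages < 40, 0.8, 0.3)
        region = np.where(rng.random(n) < p_a, "A", "B")
        meta = validate_metadata(pd.DataFrame({
            "age": ages, "gender": rng.choice(["male", "female"], n),
            "region": region, "town_population": 1000,
        }, index=[f"s{i}" for i in range(n)]))
        ens = subsample_age_bins(meta, n_reps=40, seed=2)
        binning = AgeBinning()
        n_sig = 0
        for rep in range(40):
            labels = ens.labels(rep)
            sub = meta.loc[labels.index]
            ct = pd.crosstab(sub["region"], binning.assign(sub["age"]))
            p = stats.chi2_contingency(ct)[1]
            n_sig += p < 0.05
        assert n_sig <= 2
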