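"""Group-level statistics: rank-sum test (with enumeration oracle),
Bonferroni adjustment, significance labels, group tables, Levene's
test and subgroup partitions."""

from itertools import combinations

import numpy as np
import pytest

import shellbmd as sb
from shellbmd.cohort import animal_site_means, comparisons_to_frame, subgroup_boxplot_data
from shellbmd.synthetic import CohortConfig


def enumerated_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration (no ties assumed)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    w_obs = sum(ranks[v] for v in x)
    ws = [sum(c) for c in combinations([ranks[v] for v in pooled], n)]
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_extreme_split_exact_p(self):
        _, p = sb.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = sb.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=7), rng.normal(size=5)
        _, p1 = sb.wilcoxon_rank_sum(x, y)
        _, p2 = sb.wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    def test_exact_mode_matches_enumeration_small_pools(self):
        """For every split of n <= 6 distinct values, the exact mode
        equals full enumeration."""
        values = np.array([3.1, 1.4, 15.9, 2.6, 5.3, 8.9])
        for total in range(2, 7):
            pool = values[:total]
            for k in range(1, total):
                for combo in combinations(range(total), k):
                    x = pool[list(combo)]
                    y = np.delete(pool, list(combo))
                    _, p = sb.wilcoxon_rank_sum(x, y)
                    assert p == pytest.approx(enumerated_ranksum_p(x, y)), (x, y)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sb.wilcoxon_rank_sum([], [1.0])


class TestBonferroni:
    def test_cap_at_one(self):
        assert sb.bonferroni_adjust([1.0], m=6)[0] == 1.0
        assert sb.bonferroni_adjust([0.2], m=6)[0] == 1.0

    def test_never_decreases_and_monotone(self):
        p = np.array([0.001, 0.02, 0.04, 0.2])
        adj = sb.bonferroni_adjust(p, m=6)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sb.bonferroni_adjust([1.2])


class TestSignificanceLabel:
    @pytest.mark.parametrize(
        "p,label",
        [(0.072, "*"), (6.1e-5, "****"), (1.0, "ns"), (0.05, "**"), (0.001, "****"), (0.1, "*")],
    )
    def test_boundaries_and_examples(self, p, label):
        assert sb.significance_label(p) == label

    def test_monotone_in_p(self):
        order = {"****": 0, "***": 1, "**": 2, "*": 3, "ns": 4}
        ps = np.linspace(0, 1, 201)
        labels = [order[sb.significance_label(p)] for p in ps]
        assert all(a <= b for a, b in zip(labels, labels[1:]))


class TestCompareGroups:
    def _null_cohort(self, seed, pixels=40):
        config = CohortConfig(group_sizes=(12, 4, 3, 4), pixels_per_roi=pixels, seed=seed)
        healthy = [d for d in sb.default_distributions() if d.group == 0]
        null_dists = [
            sb.GroupSiteDistribution(
                group=g, site=d.site, zero_mass=d.zero_mass, shape_k=d.shape_k,
                scale_theta=d.scale_theta, truncation_max=d.truncation_max,
            )
            for g in range(4)
            for d in healthy
        ]
        ms, _ = sb.generate_cohort(config, null_dists)
        return ms, config.animal_groups

    def test_identical_groups_ns(self):
        """Same per-animal means in both groups -> p = 1, label ns."""
        ms, animals = self._null_cohort(seed=0)
        # overwrite with identical values so every animal mean coincides
        for m in ms:
            m.pixel_values = np.full(10, 100.0)
            m.stats = None
        comps = sb.compare_groups_per_site(ms, animals)
        assert all(c.raw_p == 1.0 and c.label == "ns" for c in comps)

    def test_reference_cohort_separates_group0_vs_3(self):
        config = CohortConfig(group_sizes=(12, 4, 3, 4), pixels_per_roi=500, seed=2)
        ms, _ = sb.generate_cohort(config)
        comps = sb.compare_groups_per_site(ms, config.animal_groups)
        frame = comparisons_to_frame(comps)
        sel = frame[(frame.group_a == 0) & (frame.group_b == 3)]
        assert len(sel) == 3
        assert (sel.adj_p <= 0.05).all()

    def test_permutation_null_calibration(self):
        """Random group-label permutations rarely reach adj_p <= 0.05."""
        config = CohortConfig(group_sizes=(12, 4, 3, 4), pixels_per_roi=40, seed=5)
        ms, _ = sb.generate_cohort(config)
        frame = animal_site_means(ms, config.animal_groups)
        gular = frame[frame.site == "gular"].reset_index(drop=True)
        rng = np.random.default_rng(11)
        labels = np.array([config.animal_groups[a] for a in gular.animal_id])
        hits = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            ps = []
            for ga, gb in combinations(range(4), 2):
                _, p = sb.wilcoxon_rank_sum(
                    gular.mean_bmd[perm == ga], gular.mean_bmd[perm == gb]
                )
                ps.append(p)
            if np.min(sb.bonferroni_adjust(ps, m=6)) <= 0.05:
                hits += 1
        assert hits / n_perm <= 0.10

    def test_pixel_unit_mode(self):
        config = CohortConfig(group_sizes=(2, 1, 1, 1), pixels_per_roi=50, seed=4)
        ms, _ = sb.generate_cohort(config)
        comps = sb.compare_groups_per_site(ms, config.animal_groups, unit="pooled_pixels")
        assert len(comps) == 18  # 3 sites x 6 pairs


class TestSummarizeGroups:
    def test_single_roi_row_equals_its_stats(self):
        vals = np.array([10.0, 20.0, 40.0, 70.0])
        m = sb.SiteMeasurement(animal_id=1, site="gular", side="none", pixel_values=vals)
        frame = sb.summarize_groups([m], {1: 0})
        row = frame.iloc[0]
        s = sb.summarize_roi(vals)
        assert row["mean"] == s.mean and row["sd"] == s.sd and row["p99"] == s.p99

    def test_pooled_mean_near_reference(self, fitted_distributions):
        """>= 1e5 pooled healthy gular pixels average within 3 SE of 382."""
        config = CohortConfig(group_sizes=(12, 1, 1, 1), pixels_per_roi=10_000, seed=6)
        ms, _ = sb.generate_cohort(config, fitted_distributions)
        frame = sb.summarize_groups(ms, config.animal_groups)
        row = frame[(frame.group == 0) & (frame.site == "gular")].iloc[0]
        d = [t for t in fitted_distributions if (t.group, t.site) == (0, "gular")][0]
        n = row["pixel_count"]
        assert n >= 100_000
        assert abs(row["mean"] - 382) < 3 * d.sd() / np.sqrt(n) + abs(d.mean() - 382)

    def test_pooled_equals_concatenated(self):
        a = np.arange(10.0)
        b = np.arange(5.0, 25.0)
        ms = [
            sb.SiteMeasurement(animal_id=1, site="ilium", side="left", pixel_values=a),
            sb.SiteMeasurement(animal_id=1, site="ilium", side="right", pixel_values=b),
        ]
        frame = sb.summarize_groups(ms, {1: 2})
        s = sb.summarize_roi(np.concatenate([a, b]))
        row = frame.iloc[0]
        assert row["mean"] == s.mean and row["median"] == s.median and row["sd"] == s.sd

    def test_display_rounding(self):
        m = sb.SiteMeasurement(
            animal_id=1, site="gular", side="none", pixel_values=np.array([10.24, 20.53, 30.87])
        )
        frame = sb.summarize_groups([m], {1: 0}, round_display=True)
        assert float(frame.iloc[0]["mean"]).is_integer()


class TestLevene:
    def test_constant_groups_convention(self):
        stat, p = sb.levene_test([[1.0, 1.0, 1.0], [2.0, 2.0]])
        assert (stat, p) == (0.0, 1.0)

    def test_unequal_variances_detected(self):
        """N(0,1) vs N(0,9), n=50: p < 0.01 in at least 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, p = sb.levene_test([rng.normal(0, 1, 50), rng.normal(0, 3, 50)])
            if p < 0.01:
                hits += 1
        assert hits >= 95

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=30), rng.normal(size=30)
        s1, _ = sb.levene_test([a, b])
        s2, _ = sb.levene_test([a + 100.0, b])
        assert s1 == pytest.approx(s2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sb.levene_test([[1.0], [2.0, 3.0]])


class TestSubgroups:
    def test_partition_by_group_reproduces_group_structure(self):
        config = CohortConfig(group_sizes=(2, 1, 1, 2), pixels_per_roi=20, seed=7)
        ms, _ = sb.generate_cohort(config)
        data = subgroup_boxplot_data(ms, config.animal_groups, lambda a: config.animal_groups[a])
        for site in ("gular", "ilium", "scapula"):
            assert set(data[site]) == {0, 1, 2, 3}
            assert len(data[site][0]) == 2

    def test_two_stratum_partition_of_severe_group(self):
        config = CohortConfig(group_sizes=(1, 1, 1, 4), pixels_per_roi=20, seed=8)
        ms, _ = sb.generate_cohort(config)
        severe = [a for a, g in config.animal_groups.items() if g == 3]
        hatchlings = set(severe[:2])
        ms3 = [m for m in ms if m.animal_id in severe]
        groups3 = {a: 3 for a in severe}
        data = subgroup_boxplot_data(
            ms3, groups3, lambda a: "hatchling" if a in hatchlings else "mature"
        )
        for site in data:
            assert set(data[site]) == {"hatchling", "mature"}
            total = sum(len(v) for v in data[site].values())
            assert total == 4  # strata disjoint and exhaustive
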