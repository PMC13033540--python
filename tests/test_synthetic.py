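"""Generator module: phantom linear mixing, pixel-population law,
cohort plan bookkeeping and determinism."""

import numpy as np
import pytest

import shellbmd as sb
from shellbmd.synthetic import (
    CohortConfig,
    GeometryError,
    SITE_SUMMARY,
    SITES,
    reference_cohort_config,
)


class TestPhantom:
    def test_truth_map_holds_insert_densities(self, noise_free_phantom, phantom_spec):
        _, _, truth = noise_free_phantom
        densest = max(phantom_spec.insert_densities)
        assert densest == 800
        assert np.all(truth[truth > 400] == densest)
        assert set(np.unique(truth)) == {0.0, 100.0, 200.0, 400.0, 800.0}

    def test_linear_mixing_rule_inside_insert(self):
        """HU pair (140, 50) for a 100 mgHA/cm^3 insert with unit background 0."""
        spec = sb.PhantomSpec(
            insert_densities=(100.0,),
            insert_centers=((20.0, 20.0, 12.0),),
            background_hu_pair=(0.0, 0.0),
        )
        basis = sb.AttenuationBasis(ha_slope_pair=(1.40, 0.50), soft_tissue_hu_pair=(0.0, 0.0))
        v50, v200, truth = sb.build_phantom_pair(spec, basis, noise_sd=0.0)
        inside = truth == 100.0
        assert np.allclose(v50.voxels[inside], 140.0)
        assert np.allclose(v200.voxels[inside], 50.0)
        assert np.allclose(v50.voxels[~inside], 0.0)

    def test_zero_density_insert_equals_background(self):
        spec = sb.PhantomSpec(
            insert_densities=(0.0, 400.0),
            insert_centers=((20.0, 20.0, 12.0), (44.0, 44.0, 12.0)),
        )
        v50, v200, truth = sb.build_phantom_pair(spec, noise_sd=0.0)
        # zero-density insert is indistinguishable from background at both energies
        assert np.allclose(v50.voxels[truth == 0.0], spec.background_hu_pair[0])
        assert np.allclose(v200.voxels[truth == 0.0], spec.background_hu_pair[1])

    def test_linear_mixing_conservation_across_energies(self, noise_free_phantom, basis, phantom_spec):
        """(HU(E) - background(E)) / slope(E) recovers the same density at both energies."""
        v50, v200, truth = noise_free_phantom
        d50 = (v50.voxels - phantom_spec.background_hu_pair[0]) / basis.ha_slope_pair[0]
        d200 = (v200.voxels - phantom_spec.background_hu_pair[1]) / basis.ha_slope_pair[1]
        np.testing.assert_allclose(d50, d200, atol=1e-9)
        np.testing.assert_allclose(d50, truth, atol=1e-9)

    def test_seed_determinism(self, phantom_spec, basis):
        a = sb.build_phantom_pair(phantom_spec, basis, noise_sd=15.0, seed=7)
        b = sb.build_phantom_pair(phantom_spec, basis, noise_sd=15.0, seed=7)
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[1].voxels, b[1].voxels)

    def test_overlapping_inserts_rejected(self):
        with pytest.raises(GeometryError):
            sb.PhantomSpec(
                insert_densities=(100.0, 200.0),
                insert_centers=((20.0, 20.0, 12.0), (24.0, 20.0, 12.0)),
            )

    def test_negative_noise_rejected(self, phantom_spec):
        with pytest.raises(ValueError):
            sb.build_phantom_pair(phantom_spec, noise_sd=-1.0)

    def test_basis_requires_falling_mineral_attenuation(self):
        with pytest.raises(ValueError):
            sb.AttenuationBasis(ha_slope_pair=(0.5, 1.4))


class TestPixelLaw:
    def test_degenerate_full_zero_inflation_not_allowed_but_high_pi0_gives_zeros(self):
        d = sb.GroupSiteDistribution(
            group=3, site="gular", zero_mass=0.99, shape_k=1.0, scale_theta=10.0, truncation_max=500.0
        )
        x = sb.sample_group_pixels(d, 5000, seed=0)
        assert (x == 0).mean() > 0.97
        with pytest.raises(ValueError):
            sb.GroupSiteDistribution(
                group=3, site="gular", zero_mass=1.0, shape_k=1.0, scale_theta=10.0, truncation_max=500.0
            )

    def test_exponential_mean_recovery(self):
        """pi0=0, k=1 is an exponential; sample mean near theta at n=1e5."""
        d = sb.GroupSiteDistribution(
            group=0, site="gular", zero_mass=0.0, shape_k=1.0, scale_theta=100.0, truncation_max=1e9
        )
        x = sb.sample_group_pixels(d, 100_000, seed=3)
        assert x.mean() == pytest.approx(100.0, abs=1.5)

    def test_fitted_group0_gular_median(self, fitted_distributions):
        """Sample median of the fitted healthy gular law near the reference 323."""
        d = [t for t in fitted_distributions if (t.group, t.site) == (0, "gular")][0]
        x = sb.sample_group_pixels(d, 100_000, seed=5)
        assert abs(np.median(x) - 323) / 323 < 0.10

    def test_samples_respect_truncation_and_sign(self, fitted_distributions):
        for d in fitted_distributions:
            x = sb.sample_group_pixels(d, 2000, seed=11)
            assert x.min() >= 0.0
            assert x.max() <= d.truncation_max + 1e-9

    @pytest.mark.parametrize("group,site", [(0, "ilium"), (2, "gular"), (3, "gular")])
    def test_analytic_moments_match_sampling(self, fitted_distributions, group, site):
        """Sample mean/SD agree with the analytic mixture moments within 3 SE."""
        d = [t for t in fitted_distributions if (t.group, t.site) == (group, site)][0]
        n = 100_000
        x = sb.sample_group_pixels(d, n, seed=13)
        se_mean = d.sd() / np.sqrt(n)
        assert abs(x.mean() - d.mean()) < 3 * se_mean
        m4 = d.raw_moment(4) - 4 * d.raw_moment(3) * d.mean() + 6 * d.raw_moment(2) * d.mean() ** 2 - 3 * d.mean() ** 4
        se_sd = np.sqrt(max(m4 - d.var() ** 2, 0.0) / (4 * d.var() * n))
        assert abs(x.std(ddof=1) - d.sd()) < 3 * se_sd

    def test_fit_reproduces_summary_rows(self, fitted_distributions):
        """Every fitted law matches its target mean and SD to < 1%."""
        for d in fitted_distributions:
            row = SITE_SUMMARY[(d.group, d.site)]
            assert abs(d.mean() - row["mean"]) / row["mean"] < 0.01
            assert abs(d.sd() - row["sd"]) / row["sd"] < 0.01
            # right skew everywhere: mean exceeds median
            assert d.mean() > d.quantile(0.5)

    def test_zero_mass_grows_with_severity_at_gular(self, fitted_distributions):
        by = {(d.group, d.site): d for d in fitted_distributions}
        assert by[(3, "gular")].zero_mass > by[(2, "gular")].zero_mass > by[(0, "gular")].zero_mass


class TestShellSubject:
    def test_roi_truth_self_consistency(self, fitted_distributions):
        v50, v200, truth, rois = sb.build_shell_subject(
            0, fitted_distributions, seed=21
        )
        assert len(rois) == 5
        ilium_left = [r for r in rois if (r.site, r.side) == ("ilium", "left")][0]
        idx = sb.rasterize_roi(ilium_left, truth)
        values = truth.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
        recorded = truth.provenance["roi_values"]["ilium:left"]
        assert np.array_equal(np.sort(values), np.sort(recorded))
        assert values.mean() == pytest.approx(recorded.mean())

    def test_determinism(self, fitted_distributions):
        a = sb.build_shell_subject(2, fitted_distributions, seed=9)
        b = sb.build_shell_subject(2, fitted_distributions, seed=9)
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[2].voxels, b[2].voxels)
        assert [r.polygon_mm for r in a[3]] == [r.polygon_mm for r in b[3]]

    def test_zero_fraction_matches_zero_mass(self):
        """With pi0=0.5 at the gular site, about half the gular truth pixels are 0."""
        dists = [
            sb.GroupSiteDistribution(
                group=3, site=s, zero_mass=0.5 if s == "gular" else 0.1,
                shape_k=2.0, scale_theta=30.0, truncation_max=400.0,
            )
            for s in SITES
        ]
        # large grid so the painted gular region holds ~1e4 pixels over its 3 slices
        v50, _, truth, rois = sb.build_shell_subject(
            3, dists, shape=(300, 100, 48), seed=2
        )
        gular = [r for r in rois if r.site == "gular"][0]
        idx = sb.rasterize_roi(gular, truth)
        vals = []
        for dk in (-1, 0, 1):
            shifted = idx.copy()
            shifted[:, 2] += dk
            vals.append(truth.voxels[shifted[:, 0], shifted[:, 1], shifted[:, 2]])
        vals = np.concatenate(vals)
        assert vals.size >= 9000
        frac = (vals == 0).mean()
        assert abs(frac - 0.5) < 0.02

    def test_grid_too_small(self, fitted_distributions):
        with pytest.raises(GeometryError):
            sb.build_shell_subject(0, fitted_distributions, shape=(8, 8, 8))

    def test_linear_mixing_on_subject(self, fitted_distributions, basis):
        v50, v200, truth, _ = sb.build_shell_subject(1, fitted_distributions, seed=4)
        np.testing.assert_allclose(
            v50.voxels, basis.soft_tissue_hu_pair[0] + truth.voxels * basis.ha_slope_pair[0]
        )


class TestCohort:
    def test_reference_plan_counts(self, fitted_distributions):
        config = reference_cohort_config(pixels_per_roi=50, seed=0)
        ms, table = sb.generate_cohort(config, fitted_distributions)
        assert config.planned_sites == 115
        assert len(ms) == 110  # 5 motion-missing sites dropped
        assert table["animal_id"].nunique() == 23
        assert len(table) == 110 * 50

    def test_small_cohort_counts(self, fitted_distributions):
        config = CohortConfig(group_sizes=(1, 1, 1, 1), pixels_per_roi=20, seed=0)
        # 4 animals x 5 planned sites, nothing missing
        ms, _ = sb.generate_cohort(config, fitted_distributions)
        assert len(ms) == 20

    def test_determinism_and_missing_independence(self, fitted_distributions):
        base = CohortConfig(group_sizes=(2, 1, 1, 1), pixels_per_roi=30, seed=5)
        again = CohortConfig(group_sizes=(2, 1, 1, 1), pixels_per_roi=30, seed=5)
        ms1, t1 = sb.generate_cohort(base, fitted_distributions)
        ms2, t2 = sb.generate_cohort(again, fitted_distributions)
        assert t1.equals(t2)
        # dropping a slot does not change the pixels of the others
        dropped = CohortConfig(
            group_sizes=(2, 1, 1, 1), pixels_per_roi=30, seed=5,
            missing_sites=((1, "gular", "none"),),
        )
        ms3, _ = sb.generate_cohort(dropped, fitted_distributions)
        key = lambda m: (m.animal_id, m.site, m.side)
        lookup = {key(m): m.pixel_values for m in ms3}
        for m in ms1:
            if key(m) in lookup:
                assert np.array_equal(m.pixel_values, lookup[key(m)])

    def test_missing_site_must_reference_known_animal(self):
        with pytest.raises(ValueError):
            CohortConfig(group_sizes=(1, 1, 1, 1), missing_sites=((99, "gular", "none"),))

    def test_missing_distribution_rejected(self, fitted_distributions):
        partial = [d for d in fitted_distributions if d.site != "ilium"]
        with pytest.raises(ValueError):
            sb.generate_cohort(CohortConfig(group_sizes=(1, 1, 1, 1)), partial)

    def test_side_effect_scales_left_side(self, fitted_distributions):
        config = CohortConfig(
            group_sizes=(1, 1, 1, 1), pixels_per_roi=100, seed=8,
            side_effects={(1, "ilium"): 0.5},
        )
        plain = CohortConfig(group_sizes=(1, 1, 1, 1), pixels_per_roi=100, seed=8)
        ms_a, _ = sb.generate_cohort(config, fitted_distributions)
        ms_b, _ = sb.generate_cohort(plain, fitted_distributions)
        get = lambda ms, side: [m for m in ms if (m.animal_id, m.site, m.side) == (1, "ilium", side)][0]
        assert np.allclose(get(ms_a, "left").pixel_values, 0.5 * get(ms_b, "left").pixel_values)
        assert np.array_equal(get(ms_a, "right").pixel_values, get(ms_b, "right").pixel_values)
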