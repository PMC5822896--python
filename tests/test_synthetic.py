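import dataclasses

import numpy as np
import pytest

from petage.synthetic import (
    DECADE_COUNTS,
    GeneratorSpec,
    RegionBox,
    make_atlas,
    make_cohort,
    make_ic_voxelvalue_map,
    make_sweep_phantom,
    phantom_counts,
)
from petage.volumes import Volume, VolumeGrid


def aging_region_means(cohort, truth):
    flat = cohort.stack.reshape(len(cohort), -1)
    return flat[:, truth.aging_mask.indicator.ravel()].mean(axis=1)


class TestMakeAtlas:
    def test_default_atlas_regions_disjoint_and_nonempty(self, tiny_spec):
        atlas = make_atlas(tiny_spec)
        counts = np.bincount(atlas.labels.ravel())
        for region in atlas.regions:
            assert counts[region.region_id] > 0
        # disjoint by construction: total labelled voxels equals sum of counts
        assert (atlas.labels > 0).sum() == counts[1:].sum()

    def test_deterministic(self, tiny_spec):
        a1 = make_atlas(tiny_spec)
        a2 = make_atlas(tiny_spec)
        assert np.array_equal(a1.labels, a2.labels)

    def test_extent_outside_grid_rejected(self, tiny_spec):
        boxes = (RegionBox(1, "too_big", (0, 0, 0), (99, 2, 2)),)
        spec = dataclasses.replace(tiny_spec, region_boxes=boxes,
                                   aging_region_ids=frozenset({1}),
                                   reference_region_ids=frozenset(),
                                   ad_region_ids=frozenset())
        with pytest.raises(ValueError, match="fit"):
            make_atlas(spec)

    def test_overlapping_extents_rejected(self, tiny_spec):
        boxes = (RegionBox(1, "a", (0, 0, 0), (4, 4, 4)),
                 RegionBox(2, "b", (2, 2, 2), (6, 6, 6)))
        spec = dataclasses.replace(tiny_spec, region_boxes=boxes,
                                   aging_region_ids=frozenset({1}),
                                   reference_region_ids=frozenset({2}),
                                   ad_region_ids=frozenset())
        with pytest.raises(ValueError, match="overlap"):
            make_atlas(spec)


class TestMakeCohort:
    def test_same_seed_identical(self, tiny_spec):
        c1, t1 = make_cohort(tiny_spec, return_truth=True)
        c2, t2 = make_cohort(tiny_spec, return_truth=True)
        assert np.array_equal(c1.stack, c2.stack)
        assert c1.table().equals(c2.table())

    def test_noiseless_flat_cohort_is_constant(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, noise_sd=0.0, decline_per_year=0.0)
        cohort, truth = make_cohort(spec, return_truth=True)
        means = aging_region_means(cohort, truth)
        assert np.allclose(means, means[0])

    def test_noiseless_linear_recovery_is_exact(self, tiny_spec):
        b = -0.0037
        spec = dataclasses.replace(tiny_spec, noise_sd=0.0, decline_per_year=b)
        cohort, truth = make_cohort(spec, return_truth=True)
        slope, intercept = np.polyfit(cohort.ages, aging_region_means(cohort, truth), 1)
        assert slope == pytest.approx(b, abs=1e-12)
        assert intercept == pytest.approx(spec.baseline, abs=1e-10)

    def test_reference_region_is_age_flat(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, noise_sd=0.0)
        cohort, truth = make_cohort(spec, return_truth=True)
        flat = cohort.stack.reshape(len(cohort), -1)
        ref = flat[:, truth.reference_mask.indicator.ravel()].mean(axis=1)
        assert np.allclose(ref, spec.baseline)

    def test_slope_recovery_under_noise_within_2se(self):
        """n=255, ages 20-80, b=-0.004, voxel noise 0.05: the OLS fit of the
        aging-region mean on age recovers the slope within +-2 SE, checked
        over 20 seeds."""
        b = -0.004
        grid = VolumeGrid((16, 20, 16), (4.0, 4.0, 4.0))
        hits = 0
        for seed in range(20):
            spec = GeneratorSpec(n_subjects=255, decline_per_year=b, noise_sd=0.05,
                                 grid=grid, seed=seed)
            cohort, truth = make_cohort(spec, return_truth=True)
            y = aging_region_means(cohort, truth)
            a = cohort.ages
            slope = np.polyfit(a, y, 1)[0]
            resid = y - np.polyval(np.polyfit(a, y, 1), a)
            se = np.sqrt((resid @ resid) / (len(a) - 2) / ((a - a.mean()) @ (a - a.mean())))
            if abs(slope - b) <= 2 * se:
                hits += 1
        assert hits >= 18  # ~95% coverage, allows binomial slack

    def test_ad_deficit_exact_when_noiseless(self, tiny_spec):
        link = dataclasses.replace(tiny_spec.clinical_link, severity_sd=0.0)
        spec = dataclasses.replace(tiny_spec, n_subjects=20, noise_sd=0.0,
                                   decline_per_year=0.0, ad_fraction=0.5,
                                   ad_deficit=0.07, clinical_link=link)
        cohort, truth = make_cohort(spec, return_truth=True)
        flat = cohort.stack.reshape(len(cohort), -1)
        ad_vox = flat[:, truth.ad_mask.indicator.ravel()].mean(axis=1)
        hc = cohort.groups == "HC"
        diff = ad_vox[hc].mean() - ad_vox[~hc].mean()
        assert diff == pytest.approx(0.07, abs=1e-12)

    def test_ages_within_range_and_group_sizes(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, n_subjects=30, ad_fraction=0.4,
                                   age_range=(50.0, 75.0))
        cohort = make_cohort(spec)
        assert cohort.ages.min() >= 50.0 and cohort.ages.max() <= 75.0
        assert (cohort.groups == "AD").sum() == 12

    def test_decade_quota_mode(self):
        spec = GeneratorSpec(n_subjects=255, age_sampling="decades",
                             grid=VolumeGrid((16, 20, 16), (4.0, 4.0, 4.0)), seed=3)
        cohort = make_cohort(spec)
        edges = [20, 30.5, 40.5, 50.5, 60.5, 70.5, 80.001]
        counts = np.histogram(cohort.ages, bins=edges)[0]
        assert tuple(counts) == DECADE_COUNTS

    def test_clinical_marginals_echo_calibration(self):
        spec = GeneratorSpec(n_subjects=400, ad_fraction=0.5, age_range=(55.0, 80.0),
                             grid=VolumeGrid((16, 20, 16), (4.0, 4.0, 4.0)), seed=5)
        tab = make_cohort(spec).table()
        ad = tab.group == "AD"
        assert tab.loc[~ad, "mmse"].mean() == pytest.approx(29.0, abs=0.5)
        assert tab.loc[ad, "mmse"].mean() == pytest.approx(23.2, abs=0.8)
        assert tab.loc[ad, "cdrsb"].mean() == pytest.approx(4.1, abs=0.5)
        assert tab.loc[ad, "fdg"].mean() == pytest.approx(1.1, abs=0.1)

    def test_too_few_subjects_rejected(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, n_subjects=2)
        with pytest.raises(ValueError):
            make_cohort(spec)

    def test_aging_and_reference_must_be_disjoint(self, tiny_spec):
        with pytest.raises(ValueError, match="disjoint"):
            dataclasses.replace(tiny_spec, aging_region_ids=frozenset({69}))

    def test_spec_dict_roundtrip(self, tiny_spec):
        assert GeneratorSpec.from_dict(tiny_spec.to_dict()) == tiny_spec


class TestVoxelValueMap:
    def test_two_plateaus_rescale(self, small_grid):
        vals = np.zeros(small_grid.shape)
        vals[:2] = 0.1
        vals[6:] = 1.0
        vv = make_ic_voxelvalue_map(Volume(small_grid, vals), v_max=38)
        assert set(np.unique(vv.values[:2])) == {4.0}   # ceil(38*0.1) = 4
        assert set(np.unique(vv.values[6:])) == {38.0}
        assert np.all(vv.values[2:6] == 0)

    def test_constant_positive_strength(self, small_grid):
        vv = make_ic_voxelvalue_map(Volume(small_grid, np.full(small_grid.shape, 0.3)),
                                    v_max=38)
        assert np.all(vv.values == 38)

    def test_vmax_one_gives_mask(self, small_grid, rng):
        s = np.abs(rng.normal(size=small_grid.shape))
        vv = make_ic_voxelvalue_map(Volume(small_grid, s), v_max=1)
        assert set(np.unique(vv.values)) <= {0.0, 1.0}

    def test_all_zero_rejected(self, small_grid):
        with pytest.raises(ValueError):
            make_ic_voxelvalue_map(Volume(small_grid, np.zeros(small_grid.shape)))

    def test_monotone_in_strength(self, small_grid, rng):
        s = np.abs(rng.normal(size=small_grid.shape))
        vv = make_ic_voxelvalue_map(Volume(small_grid, s), v_max=38).values.ravel()
        order = np.argsort(s.ravel())
        assert np.all(np.diff(vv[order]) >= 0)


class TestSweepPhantom:
    def test_signal_confined_above_sigma_true(self):
        spec = GeneratorSpec(n_subjects=10, noise_sd=0.0, seed=7)
        cohort, vv, atlas, signal = make_sweep_phantom(spec, sigma_true=15,
                                                       return_truth=True)
        assert np.array_equal(signal.indicator, vv.values >= 15)
        flat = cohort.stack.reshape(len(cohort), -1)
        below = (vv.values.ravel() >= 1) & (vv.values.ravel() < 15)
        assert np.allclose(flat[:, below], spec.baseline)  # flat where vv < sigma_true
        sig_mean = flat[:, signal.indicator.ravel()].mean(axis=1)
        slope = np.polyfit(cohort.ages, sig_mean, 1)[0]
        assert slope == pytest.approx(spec.decline_per_year, abs=1e-12)

    def test_value_histogram_matches_profile(self):
        _, vv, _ = make_sweep_phantom(GeneratorSpec(n_subjects=3, seed=1), sigma_true=5)
        got = np.bincount(vv.values.ravel().astype(int), minlength=39)[1:]
        assert np.array_equal(got, phantom_counts(38))

    def test_phantom_fits_in_small_grids_or_raises(self):
        spec = GeneratorSpec(n_subjects=5, grid=VolumeGrid((8, 10, 8), (4.0, 4.0, 4.0)))
        with pytest.raises(ValueError, match="voxels"):
            make_sweep_phantom(spec, sigma_true=5)
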