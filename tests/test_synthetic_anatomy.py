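import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from pharynxflow.synthetic_anatomy import (
    CohortParams,
    InfeasibleSpecError,
    PhantomSpec,
    RegionSpec,
    REGION_NAMES,
    _hermite_profile,
    apply_retraction,
    build_phantom,
    mean_spec,
    phantom_profile_csv,
    phantom_to_stl,
    sample_cohort,
    segment,
    uniform_tube_spec,
    voxelize,
    voxelize_and_segment,
    VoxelVolume,
)


class TestSpecs:
    def test_region_validation(self):
        with pytest.raises(ValueError):
            RegionSpec("nasopharynx", -1.0, 5.0)
        with pytest.raises(ValueError):
            RegionSpec("nasopharynx", 10.0, 0.0)
        with pytest.raises(ValueError):
            RegionSpec("sinus", 10.0, 5.0)

    def test_phantom_spec_ordering(self):
        r = [RegionSpec(n, 20.0, 5.0) for n in REGION_NAMES]
        with pytest.raises(ValueError):
            PhantomSpec(regions=(r[1], r[0], r[2]), a_min=1.0)

    def test_round_trip_dict(self):
        spec = mean_spec(CohortParams())
        assert PhantomSpec.from_dict(spec.to_dict()) == spec

    def test_mean_area_ratio_matches_table(self):
        # default lengths give A_min/A_mean = 0.69 at the T1 means
        spec = mean_spec(CohortParams())
        assert spec.a_min / spec.mean_area == pytest.approx(0.69, abs=0.005)


class TestBuildPhantom:
    def test_uniform_tube(self):
        ph = build_phantom(uniform_tube_spec(2.0, 80.0))
        assert np.allclose(ph.area * 1e-2, 2.0, rtol=5e-3)
        assert np.allclose(ph.radius, np.sqrt(2.0e2 / np.pi), rtol=3e-3)

    def test_t1_means_round_trip(self, default_params, mean_phantom):
        a_min, z_min = mean_phantom.a_min()
        assert a_min == pytest.approx(2.21, rel=5e-3)
        assert mean_phantom.region_of(z_min) == "hypopharynx"
        assert mean_phantom.region_volume("oropharynx") == pytest.approx(20.83, rel=5e-3)
        assert mean_phantom.region_volume("nasopharynx") == pytest.approx(5.68, rel=5e-3)
        assert mean_phantom.region_volume("hypopharynx") == pytest.approx(8.50, rel=5e-3)

    def test_linearity_doubling(self, default_params):
        spec = mean_spec(default_params)
        doubled = PhantomSpec(
            regions=tuple(
                RegionSpec(r.name, r.length, 2.0 * r.volume) for r in spec.regions
            ),
            a_min=2.0 * spec.a_min,
            a_min_region=spec.a_min_region,
            a_min_frac=spec.a_min_frac,
            inlet_area=2.0 * spec.inlet_area,
        )
        a1 = build_phantom(spec).area
        a2 = build_phantom(doubled).area
        assert np.allclose(a2, 2.0 * a1, rtol=1e-6)

    def test_inlet_area_pinned(self, default_params, mean_phantom):
        # area at the hypopharynx bottom equals the spec inlet area
        spec = mean_spec(default_params)
        assert float(mean_phantom.area[-1]) * 1e-2 == pytest.approx(spec.inlet_area, rel=5e-3)

    def test_volume_conservation_per_region(self, default_params):
        ph = build_phantom(mean_spec(default_params), axial_resolution=4)
        for region in REGION_NAMES:
            target = mean_spec(default_params).region(region).volume
            assert ph.region_volume(region) == pytest.approx(target, rel=5e-3)

    def test_profile_c1_smooth(self, mean_phantom):
        # no slope discontinuities: second differences of the radius stay small
        dr = np.diff(mean_phantom.radius)
        ddr = np.abs(np.diff(dr))
        dz = float(np.diff(mean_phantom.z)[0])
        assert ddr.max() < 10.0 * dz  # curvature bounded, no kinks

    def test_infeasible_spec_raises(self):
        regions = (
            RegionSpec("nasopharynx", 20.0, 4.0),
            RegionSpec("oropharynx", 50.0, 15.0),
            RegionSpec("hypopharynx", 30.0, 8.0),
        )
        bad = PhantomSpec(regions=regions, a_min=5.0, inlet_area=2.5)
        with pytest.raises(InfeasibleSpecError):
            build_phantom(bad)

    def test_resolution_validation(self, default_params):
        with pytest.raises(ValueError):
            build_phantom(mean_spec(default_params), axial_resolution=0.5)

    def test_boundaries_from_lengths(self, default_params, mean_phantom):
        spec = mean_spec(default_params)
        l0, l1, _ = (r.length for r in spec.regions)
        assert mean_phantom.boundaries == pytest.approx((l0, l0 + l1))


class TestHermite:
    def test_matches_scipy_pchip(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            kz = np.sort(rng.uniform(0.0, 100.0, 5))
            if np.any(np.diff(kz) < 1e-2):
                continue
            ka = rng.uniform(50.0, 500.0, 5)
            z = np.linspace(kz[0], kz[-1], 257)
            ours = _hermite_profile(kz, z)(ka)
            ref = PchipInterpolator(kz, ka)(z)
            np.testing.assert_allclose(ours, ref, rtol=1e-10, atol=1e-8)


class TestCohort:
    def test_empty(self, default_params):
        assert sample_cohort(default_params, 0) == []

    def test_negative_n(self, default_params):
        with pytest.raises(ValueError):
            sample_cohort(default_params, -1)

    def test_seed_determinism(self):
        a = sample_cohort(CohortParams(seed=5), 20)
        b = sample_cohort(CohortParams(seed=5), 20)
        assert a == b

    def test_different_seeds_differ(self):
        a = sample_cohort(CohortParams(seed=5), 5)
        b = sample_cohort(CohortParams(seed=6), 5)
        assert a != b

    def test_monotone_narrowing(self, default_params):
        pre = mean_spec(default_params)
        ices = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        posts = [apply_retraction(pre, ice, default_params, rng=None) for ice in ices]
        a_mins = [p.a_min for p in posts]
        v_ors = [p.region("oropharynx").volume for p in posts]
        v_hys = [p.region("hypopharynx").volume for p in posts]
        for seq in (a_mins, v_ors, v_hys):
            assert all(b <= a + 1e-12 for a, b in zip(seq, seq[1:]))
        # post oro/hypo volumes never exceed pre when ice > 0
        assert v_ors[1] <= pre.region("oropharynx").volume
        assert v_hys[1] <= pre.region("hypopharynx").volume

    def test_post_means_reproduce_t2_table(self, default_params):
        post = mean_spec(default_params, post=True)
        assert post.region("oropharynx").volume == pytest.approx(15.64, rel=1e-3)
        assert post.region("hypopharynx").volume == pytest.approx(6.04, rel=1e-3)
        assert post.a_min == pytest.approx(1.51, rel=1e-3)
        assert post.a_min_region == "oropharynx"

    @pytest.mark.slow
    def test_cohort_recovery_large_n(self):
        params = CohortParams(seed=123)
        cases = sample_cohort(params, 10_000)
        n = len(cases)

        def check(values, mean, sd):
            se = sd / np.sqrt(n)
            assert abs(np.mean(values) - mean) < 3 * se

        check([c.pre.region("oropharynx").volume for c in cases], params.v_or_mean, params.v_or_sd)
        check([c.pre.region("hypopharynx").volume for c in cases], params.v_hy_mean, params.v_hy_sd)
        check([c.ice for c in cases], params.ice_mean, params.ice_sd)
        check([c.pre.a_min for c in cases], params.a_min_mean, params.a_min_sd)


class TestVoxels:
    def test_all_tissue_empty_mask(self):
        vol = VoxelVolume(hu=np.full((8, 8, 8), 40.0), voxel_mm=1.0)
        with pytest.warns(UserWarning):
            mask, v = segment(vol)
        assert not mask.any()
        assert v == 0.0

    def test_cylinder_volume_oracle(self, tube_phantom):
        # straight tube: analytic pi R^2 L
        _, vol = voxelize_and_segment(tube_phantom, voxel_mm=0.4)
        r_mm = float(tube_phantom.radius[0])
        analytic = np.pi * r_mm**2 * tube_phantom.length * 1e-3
        assert vol == pytest.approx(analytic, rel=0.02)

    def test_hu_thresholds_select_air_only(self, mean_phantom):
        volume = voxelize(mean_phantom, voxel_mm=1.0)
        mask, _ = segment(volume, -1024.0, -480.0)
        assert np.all(volume.hu[mask] == -1000.0)
        assert np.all(volume.hu[~mask] == 40.0)

    def test_segmentation_convergence(self, tube_phantom):
        r_mm = float(tube_phantom.radius[0])
        analytic = np.pi * r_mm**2 * tube_phantom.length * 1e-3
        # sizes chosen away from staircase plateaus (voxelization error is
        # not monotone pointwise, only in trend)
        errs = []
        for voxel in (2.0, 0.8, 0.4):
            _, vol = voxelize_and_segment(tube_phantom, voxel_mm=voxel)
            errs.append(abs(vol - analytic) / analytic)
        assert errs[0] > errs[1] > errs[2]

    def test_threshold_order_validated(self, tube_phantom):
        with pytest.raises(ValueError):
            voxelize_and_segment(tube_phantom, 0.5, -480.0, -1024.0)

    def test_voxel_size_validated(self, tube_phantom):
        with pytest.raises(ValueError):
            voxelize(tube_phantom, 0.0)


class TestExports:
    def test_profile_csv(self, mean_phantom, tmp_path):
        path = tmp_path / "profile.csv"
        phantom_profile_csv(mean_phantom, path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape[1] == 3
        np.testing.assert_allclose(data[:, 2], np.pi * data[:, 1] ** 2, rtol=1e-9)

    def test_stl_binary_header(self, tmp_path):
        ph = build_phantom(uniform_tube_spec(2.0, 40.0), 1)
        path = tmp_path / "tube.stl"
        phantom_to_stl(ph, path, n_theta=16)
        raw = path.read_bytes()
        n_tri = int.from_bytes(raw[80:84], "little")
        assert len(raw) == 84 + 50 * n_tri

    def test_stl_ascii(self, tmp_path):
        ph = build_phantom(uniform_tube_spec(2.0, 40.0), 1)
        path = tmp_path / "tube_ascii.stl"
        phantom_to_stl(ph, path, n_theta=8, ascii_format=True)
        text = path.read_text()
        assert text.startswith("solid") and text.rstrip().endswith("endsolid phantom")
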