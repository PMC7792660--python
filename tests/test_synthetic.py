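"""Generator contracts: determinism, ground-truth self-consistency, and
the cohort model's correlation structure."""

import numpy as np
import pytest
from scipy import ndimage, stats

from pvsretina.morphometry import component_metrics
from pvsretina.synthetic import (CohortSimParams, GroundTruthPVS,
                                 add_motion_stripes, generate_cohort,
                                 generate_fractal_fixture, generate_pvs_phantom,
                                 generate_retinal_phantom, ground_truth_mask,
                                 spearman_to_pearson)


class TestPhantom:
    def test_zero_tubes_gives_pure_noise(self):
        vol, roi, tubes = generate_pvs_phantom(0, shape=(24, 24, 12), seed=0,
                                               background=100.0, noise_sd=2.0)
        assert tubes == []
        assert vol.data.mean() == pytest.approx(100.0, abs=0.5)
        assert vol.data.std() == pytest.approx(2.0, abs=0.3)

    def test_same_seed_identical_output(self):
        a = generate_pvs_phantom(5, shape=(48, 48, 24), seed=3)
        b = generate_pvs_phantom(5, shape=(48, 48, 24), seed=3)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        assert [t.center for t in a[2]] == [t.center for t in b[2]]

    def test_different_seed_differs(self):
        a = generate_pvs_phantom(5, shape=(48, 48, 24), seed=3)
        b = generate_pvs_phantom(5, shape=(48, 48, 24), seed=4)
        assert not np.array_equal(a[0].data, b[0].data)

    def test_minimum_surface_separation_respected(self, small_phantom):
        from pvsretina.synthetic import _segment_distance

        _, _, tubes = small_phantom
        for i, a in enumerate(tubes):
            for b in tubes[i + 1:]:
                pa, qa = a.endpoints
                pb, qb = b.endpoints
                gap = _segment_distance(pa, qa, pb, qb) - a.radius - b.radius
                assert gap >= 3.0 - 1e-9

    def test_ground_truth_count_equals_halfpeak_components_noiseless(self):
        """Generator self-consistency: the noiseless render's bright
        components above half peak intensity match the tube count."""
        vol, roi, tubes = generate_pvs_phantom(15, shape=(96, 96, 48),
                                               noise_sd=0.0, seed=9,
                                               peak_range=(80.0, 80.0),
                                               background=0.0)
        mask = vol.data > 40.0  # half of the common peak
        _, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 3))
        assert n == 15

    def test_unplaceable_request_reported(self):
        with pytest.raises(RuntimeError, match="could not place"):
            generate_pvs_phantom(200, shape=(32, 32, 16), seed=0,
                                 max_attempts_per_tube=50)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="diameter"):
            GroundTruthPVS((0, 0, 0), (1, 0, 0), 10.0, 1.6, 50.0)
        with pytest.raises(ValueError, match="length"):
            GroundTruthPVS((0, 0, 0), (1, 0, 0), 1.0, 1.0, 50.0)


class TestMotionStripes:
    def test_zero_amplitude_is_identity(self, small_phantom):
        vol, _, _ = small_phantom
        out = add_motion_stripes(vol, n_stripes=10, amplitude=0.0, seed=1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_stripes_are_parallel(self):
        """Fitted principal directions of the stripe components agree."""
        from pvsretina.image import Volume3D
        from pvsretina.segmentation import label_components
        from pvsretina.image import BinaryMask

        base = Volume3D(np.zeros((64, 64, 16)), (1, 1, 2))
        striped = add_motion_stripes(base, n_stripes=12, amplitude=100.0, seed=8)
        mask = BinaryMask(striped.data > 50.0, (1, 1, 2))
        lab = label_components(mask)
        dirs = []
        for comp in lab.components(min_voxels=5):
            dirs.append(comp.principal_direction)
        assert len(dirs) >= 5
        ref = dirs[0]
        for d in dirs[1:]:
            assert abs(float(np.dot(d, ref))) > np.cos(np.deg2rad(5.0))

    def test_stripe_count_validated(self, small_phantom):
        with pytest.raises(ValueError):
            add_motion_stripes(small_phantom[0], n_stripes=0, amplitude=1.0)


class TestRetinalPhantomGen:
    def test_fewer_than_six_vessels_rejected(self):
        with pytest.raises(ValueError, match="big-six"):
            generate_retinal_phantom(n_arterioles=5)

    def test_ring_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_retinal_phantom(image_size=128, od_diameter=80.0)

    def test_determinism_and_width_table_shape(self):
        a = generate_retinal_phantom(seed=5)
        b = generate_retinal_phantom(seed=5)
        np.testing.assert_array_equal(a.artery_map, b.artery_map)
        assert len(a.widths) == 12
        assert (a.widths["width_px"] > 0).all()

    def test_maps_disjoint_within_zone_b(self, retinal_phantom):
        """Vessels may bundle at the disc, but their footprints must be
        disjoint throughout the measurement annulus."""
        ph = retinal_phantom
        yy, xx = np.indices(ph.artery_map.shape)
        r = np.hypot(xx - ph.od_center[0], yy - ph.od_center[1])
        band = (r >= 0.5 * ph.od_diameter) & (r <= 1.0 * ph.od_diameter)
        assert not (ph.artery_map & ph.vein_map & band).any()


class TestFractalFixture:
    def test_power_of_two_required(self):
        with pytest.raises(ValueError):
            generate_fractal_fixture("line", 100)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            generate_fractal_fixture("julia", 64)

    def test_sierpinski_cell_count(self):
        img = generate_fractal_fixture("sierpinski", 128, depth=7)
        assert img.sum() == 3 ** 7


class TestCohort:
    def test_zero_loadings_give_independent_variables(self):
        p = CohortSimParams(n_subjects=5000, seed=1, loadings={}, smoking_effects={})
        df = generate_cohort(p)
        cols = ["pvs_count", "pvs_total_volume", "left_crae", "left_fda", "right_crve"]
        corr = df[cols].corr(method="spearman").to_numpy()
        off = corr[np.triu_indices(len(cols), 1)]
        assert np.abs(off).max() < 0.05

    def test_target_correlation_induced(self):
        df = generate_cohort(CohortSimParams(n_subjects=5000, seed=42))
        rho = stats.spearmanr(df["pvs_count"], df["left_crae"]).statistic
        assert rho == pytest.approx(-0.19, abs=0.03)

    def test_marginal_calibration_two_percent(self):
        df = generate_cohort(CohortSimParams(n_subjects=5000, seed=7))
        assert df["pvs_count"].mean() == pytest.approx(254.4, rel=0.02)
        assert df["pvs_count"].std() == pytest.approx(90.13, rel=0.02)

    def test_smoking_shifts_pvs_width_upward(self):
        df = generate_cohort(CohortSimParams(n_subjects=20000, seed=3))
        smokers = df[df["smoking"] == 1]["pvs_mean_width"]
        non = df[df["smoking"] == 0]["pvs_mean_width"]
        shift = (smokers.mean() - non.mean()) / df["pvs_mean_width"].std()
        assert shift == pytest.approx(0.14, abs=0.05)

    def test_non_psd_loadings_reported_with_eigenvalue(self):
        p = CohortSimParams(loadings={"pvs_count": 1.4})
        with pytest.raises(ValueError, match="eigenvalue"):
            p.validate()

    def test_prevalence_bounds_checked(self):
        p = CohortSimParams(prevalences={"smoking": 1.5})
        with pytest.raises(ValueError, match="prevalence"):
            p.validate()

    def test_determinism(self):
        a = generate_cohort(CohortSimParams(n_subjects=50, seed=9))
        b = generate_cohort(CohortSimParams(n_subjects=50, seed=9))
        assert a.equals(b)

    def test_spearman_to_pearson_inverse(self):
        # round trip through the bivariate-normal rank relation
        for rho in (-0.3, 0.0, 0.19, 0.7):
            pear = spearman_to_pearson(rho)
            back = 6 / np.pi * np.arcsin(pear / 2)
            assert back == pytest.approx(rho, abs=1e-12)
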