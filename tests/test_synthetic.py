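"""Synthetic angiogram and cohort generation."""

import numpy as np
import pytest
from scipy import ndimage

from ccvoids import (
    CCGenParams,
    CohortGenParams,
    GenerationError,
    MYOPIC_CALIBRATION,
    ParameterError,
    SCPGenParams,
    ScanGeometry,
    draw_void_pct,
    generate_cc_image,
    generate_cohort,
    generate_scp_image,
    lognormal_from_median_iqr,
    pixel_to_fundus,
)


@pytest.fixture(scope="module")
def small_geom():
    return ScanGeometry(pixels_per_side=250)


class TestCCImage:
    def test_zero_target_gives_pure_flow_texture(self, small_geom):
        img, mask = generate_cc_image(CCGenParams(target_void_fraction=0.0, seed=1), small_geom)
        assert not mask.any()
        assert img.pixels.mean() > 0.5

    @pytest.mark.parametrize("f", [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4])
    def test_ground_truth_fraction_hits_target(self, f, small_geom):
        _, mask = generate_cc_image(CCGenParams(target_void_fraction=f, seed=2), small_geom)
        assert abs(mask.mean() - f) <= 0.01

    def test_seed_determinism(self, small_geom):
        a = generate_cc_image(CCGenParams(target_void_fraction=0.2, seed=7), small_geom)
        b = generate_cc_image(CCGenParams(target_void_fraction=0.2, seed=7), small_geom)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1], b[1])

    def test_voids_grow_with_eccentricity(self, full_geometry):
        # low fill so components rarely merge; compare mean void size
        # far from (>4 mm) vs near (<1 mm) the fovea
        _, mask = generate_cc_image(
            CCGenParams(target_void_fraction=0.08, seed=5), full_geometry
        )
        labels, k = ndimage.label(mask, structure=np.ones((3, 3)))
        assert k > 50
        rows = np.arange(mask.shape[0])
        pos = pixel_to_fundus(rows[:, None], rows[None, :], full_geometry)
        dist = np.hypot(pos[..., 0], pos[..., 1])
        centroids = ndimage.center_of_mass(mask, labels, np.arange(1, k + 1))
        sizes = np.bincount(labels.ravel())[1:]
        cdist = np.array([dist[int(round(r)), int(round(c))] for r, c in centroids])
        far = sizes[cdist > 4.0].mean()
        near = sizes[cdist < 1.0].mean()
        assert far > near

    def test_unreachable_target_raises(self):
        geom = ScanGeometry(12.0, 20)
        zone = np.zeros((20, 20), bool)
        zone[0, 0] = True
        with pytest.raises(GenerationError):
            generate_cc_image(
                CCGenParams(target_void_fraction=0.9, seed=1), geom,
                zones=[(zone, 2.0)],  # impossible fraction
            )

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            CCGenParams(target_void_fraction=1.5)
        with pytest.raises(ParameterError):
            CCGenParams(flow_mean=0.2, void_mean=0.5)


class TestSCPImage:
    def test_zero_branches_empty_mask(self, small_geom):
        img, mask = generate_scp_image(SCPGenParams(n_branches=0, seed=1), small_geom)
        assert not mask.any()

    def test_seed_determinism(self, small_geom):
        a = generate_scp_image(SCPGenParams(seed=9), small_geom)
        b = generate_scp_image(SCPGenParams(seed=9), small_geom)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1], b[1])

    def test_mask_is_bright_vessel_footprint(self, small_geom):
        img, mask = generate_scp_image(SCPGenParams(seed=3, widths_px=(3, 5)), small_geom)
        assert 0 < mask.mean() < 0.25
        assert img.pixels[mask].mean() > img.pixels[~mask].mean() + 0.4

    def test_invalid_width(self):
        with pytest.raises(ParameterError):
            SCPGenParams(widths_px=(0,))


class TestCalibration:
    def test_median_and_iqr_ratio_roundtrip(self, rng):
        med, q1, q3 = MYOPIC_CALIBRATION["fovea"]
        draws = draw_void_pct(rng.standard_normal(10_000), med, q1, q3)
        assert abs(np.median(draws) - med) <= 0.5
        lo, hi = np.percentile(draws, [25, 75])
        assert hi / lo == pytest.approx(q3 / q1, rel=0.05)

    def test_invalid_quartiles(self):
        with pytest.raises(ParameterError):
            lognormal_from_median_iqr(10.0, 5.0, 5.0)


@pytest.fixture(scope="module")
def tiny_cohort():
    params = CohortGenParams(n_myopic=2, n_control=2, pixels_per_side=250, seed=13)
    return params, generate_cohort(params)


class TestCohort:
    def test_sizes_and_labels(self, tiny_cohort):
        _, (eyes, truth) = tiny_cohort
        assert len(eyes) == 4
        assert sum(e.group == "myopic" for e in eyes) == 2
        assert sum(e.group == "control" for e in eyes) == 2
        assert set(truth["region"]) == set(MYOPIC_CALIBRATION)
        assert len(truth) == 4 * 7

    def test_each_eye_has_five_gaze_scan_pairs(self, tiny_cohort):
        _, (eyes, _) = tiny_cohort
        for eye in eyes:
            assert len(eye.scans) == 10
            assert {(s.slab, s.gaze) for s in eye.scans} == {
                (slab, gaze)
                for slab in ("CC", "SCP")
                for gaze in ("central", "nasal-inferior", "nasal-superior",
                             "temporal-inferior", "temporal-superior")
            }

    def test_ground_truth_matches_drawn_target(self, tiny_cohort):
        _, (_, truth) = tiny_cohort
        # zones land exactly on the drawn target (sub-0.1-pp rounding)
        assert (truth["true_void_pct"] - truth["target_void_pct"]).abs().max() < 0.1

    def test_seed_determinism(self, tiny_cohort):
        params, (eyes, truth) = tiny_cohort
        eyes2, truth2 = generate_cohort(params)
        assert truth.equals(truth2)
        np.testing.assert_array_equal(eyes[0].scans[0].pixels, eyes2[0].scans[0].pixels)

    def test_covariates_plausible(self, tiny_cohort):
        _, (eyes, _) = tiny_cohort
        for eye in eyes:
            lo, hi = (24.0, 30.0) if eye.group == "myopic" else (20.0, 28.0)
            assert lo < eye.axial_length_mm < hi
            assert set(eye.choroidal_thickness_um) == set(MYOPIC_CALIBRATION)

    def test_invalid_cohort_params(self):
        with pytest.raises(ParameterError):
            CohortGenParams(n_myopic=0)
        with pytest.raises(ParameterError):
            CohortGenParams(calibration={"myopic": {"fovea": (10.0, 8.0, 7.0)},
                                         "control": {}})
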