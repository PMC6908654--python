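"""Topographic region geometry and rasterization."""

import math

import numpy as np
import pytest

from ccvoids import (
    ParameterError,
    RegionCoverageError,
    RegionSpec,
    ScanGeometry,
    macular_subfields,
    peripapillary_ring,
    peripheral_circles,
    rasterize_region,
    select_scan_for_region,
)
from ccvoids.regions import region_fully_inside
from ccvoids.synthetic import gaze_offsets


class TestMacularSubfields:
    def test_analytic_areas(self):
        fovea, parafovea, perifovea = macular_subfields((0, 0))
        assert fovea.area_mm2 == pytest.approx(math.pi * 0.75**2)          # 1.767
        assert parafovea.area_mm2 == pytest.approx(math.pi * (1.25**2 - 0.75**2))  # 3.1416
        assert perifovea.area_mm2 == pytest.approx(math.pi * (3.0**2 - 1.25**2))   # 23.366

    def test_rasterized_partition_of_macular_disc(self, full_geometry):
        specs = macular_subfields((0, 0))
        masks = [rasterize_region(s, full_geometry) for s in specs]
        # pairwise disjoint
        assert not (masks[0] & masks[1]).any()
        assert not (masks[0] & masks[2]).any()
        assert not (masks[1] & masks[2]).any()
        # union equals the 6-mm macular disc
        disc = rasterize_region(RegionSpec("macula", "disc", (0, 0), 0, 3.0), full_geometry)
        assert ((masks[0] | masks[1] | masks[2]) == disc).all()

    def test_radius_1mm_point_lies_in_parafovea_only(self):
        fovea, parafovea, perifovea = macular_subfields((0, 0))
        assert not fovea.contains(1.0, 0.0)
        assert parafovea.contains(1.0, 0.0)
        assert not perifovea.contains(1.0, 0.0)


class TestPeripapillaryRing:
    def test_area_and_width(self):
        ring = peripapillary_ring((4.5, 0.0), 0.75)
        assert ring.area_mm2 == pytest.approx(math.pi * (1.25**2 - 0.75**2))
        assert ring.outer_radius_mm - ring.inner_radius_mm == pytest.approx(0.5)

    def test_disc_margin_excluded(self):
        ring = peripapillary_ring((0.0, 0.0), 0.75)
        assert not ring.contains(0.75, 0.0)   # open inner boundary
        assert ring.contains(0.76, 0.0)
        assert ring.contains(1.25, 0.0)       # closed outer boundary

    def test_invalid_radius(self):
        with pytest.raises(ParameterError):
            peripapillary_ring((0, 0), 0.0)


class TestPeripheralCircles:
    @pytest.mark.parametrize("laterality,tx", [("OD", -5.25), ("OS", 5.25)])
    def test_tangency_distance_and_temporal_direction(self, laterality, tx):
        sup, inf, temp = peripheral_circles((0, 0), laterality)
        for c in (sup, inf, temp):
            assert math.hypot(*c.center_mm) == pytest.approx(5.25)
            assert c.outer_radius_mm == 2.25
        assert sup.center_mm == (0.0, 5.25)
        assert inf.center_mm == (0.0, -5.25)
        assert temp.center_mm == (tx, 0.0)

    def test_externally_tangent_to_macula(self, full_geometry):
        geom = ScanGeometry(gaze_offset_mm=(0.0, 3.5))
        sup = peripheral_circles((0, 0), "OD")[0]
        macula = RegionSpec("macula", "disc", (0, 0), 0, 3.0)
        sup_mask = rasterize_region(sup, geom)
        mac_mask = rasterize_region(macula, geom)
        assert not (sup_mask & mac_mask).any()

    def test_unknown_laterality(self):
        with pytest.raises(ParameterError):
            peripheral_circles((0, 0), "XX")


class TestRasterize:
    def test_fovea_mask_area_matches_closed_form(self, full_geometry):
        fovea = macular_subfields((0, 0))[0]
        mask = rasterize_region(fovea, full_geometry)
        area = mask.sum() * full_geometry.pixel_area_mm2
        assert area == pytest.approx(fovea.area_mm2, rel=0.01)

    def test_region_outside_scan_raises(self, full_geometry):
        far = RegionSpec("far", "disc", (20.0, 0.0), 0, 1.0)
        with pytest.raises(RegionCoverageError, match="far"):
            rasterize_region(far, full_geometry)

    def test_halving_pitch_reduces_area_error(self, rng):
        # per-disc error oscillates at O(pitch); the mean over random
        # discs must drop when the pitch halves
        mean_errs = []
        discs = [
            RegionSpec("d", "disc", tuple(rng.uniform(-1, 1, 2)), 0, float(rng.uniform(0.5, 2.5)))
            for _ in range(10)
        ]
        for n in (100, 200):
            g = ScanGeometry(12.0, n)
            errs = [
                abs(rasterize_region(d, g).sum() * g.pixel_area_mm2 - d.area_mm2)
                for d in discs
            ]
            mean_errs.append(np.mean(errs))
        assert mean_errs[1] < mean_errs[0]

    def test_translation_invariance(self):
        g = ScanGeometry(12.0, 120)
        disc = RegionSpec("d", "disc", (0.0, 0.0), 0, 1.5)
        base = rasterize_region(disc, g)
        shift_px = 10
        shift_mm = shift_px * g.pitch_mm
        moved = rasterize_region(disc.translated((shift_mm, 0.0)), g)
        np.testing.assert_array_equal(np.roll(base, shift_px, axis=1), moved)


class TestScanAssignment:
    def test_central_scan_wins_when_it_contains_region(self):
        geoms = {g: ScanGeometry(gaze_offset_mm=off)
                 for g, off in gaze_offsets("OD").items()}
        fovea = macular_subfields((0, 0))[0]
        assert select_scan_for_region(fovea, geoms) == "central"

    def test_peripheral_circles_fall_to_gaze_scans(self):
        geoms = {g: ScanGeometry(gaze_offset_mm=off)
                 for g, off in gaze_offsets("OD").items()}
        sup, inf, temp = peripheral_circles((0, 0), "OD")
        assert not region_fully_inside(sup, geoms["central"])
        gaze_sup = select_scan_for_region(sup, geoms)
        assert gaze_sup in ("nasal-superior", "temporal-superior")
        assert region_fully_inside(sup, geoms[gaze_sup])
        assert "inferior" in select_scan_for_region(inf, geoms)
        assert "temporal" in select_scan_for_region(temp, geoms)
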