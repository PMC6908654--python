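"""Signal-void labeling and per-region metrics."""

import numpy as np
import pytest

from ccvoids import (
    ContractError,
    EmptyRegionError,
    ExclusionMask,
    ScanGeometry,
    TriStateMap,
    label_voids,
    region_void_metrics,
    void_metrics,
)


def flood_fill_count(voids: np.ndarray) -> int:
    """Oracle: count 8-connected components by explicit BFS."""
    seen = np.zeros_like(voids, bool)
    count = 0
    h, w = voids.shape
    for i in range(h):
        for j in range(w):
            if voids[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if 0 <= x < h and 0 <= y < w and voids[x, y] and not seen[x, y]:
                                seen[x, y] = True
                                stack.append((x, y))
    return count


def _tsmap(voids: np.ndarray) -> TriStateMap:
    return TriStateMap(voids.astype(np.uint8))


class TestLabelVoids:
    def test_two_blocks_split_by_flow_column(self):
        voids = np.zeros((5, 5), bool)
        voids[1:3, 0:2] = True
        voids[1:3, 3:5] = True
        labels = label_voids(_tsmap(voids), np.ones((5, 5), bool))
        assert labels.max() == 2

    def test_checkerboard_is_one_component_under_8_connectivity(self):
        voids = np.indices((6, 6)).sum(axis=0) % 2 == 0
        labels = label_voids(_tsmap(voids), np.ones((6, 6), bool))
        assert labels.max() == flood_fill_count(voids) == 1

    def test_no_voids_no_components(self):
        labels = label_voids(_tsmap(np.zeros((4, 4), bool)), np.ones((4, 4), bool))
        assert labels.max() == 0

    def test_min_void_px_filter(self):
        voids = np.zeros((8, 8), bool)
        voids[0, 0] = True          # 1-px speck
        voids[4:6, 4:6] = True      # 4-px block
        ts = _tsmap(voids)
        assert label_voids(ts, np.ones((8, 8), bool)).max() == 2
        assert label_voids(ts, np.ones((8, 8), bool), min_void_px=2).max() == 1

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegionError):
            label_voids(_tsmap(np.zeros((4, 4), bool)), np.zeros((4, 4), bool))

    def test_matches_flood_fill_on_random_grids(self, rng):
        for _ in range(60):
            h, w = rng.integers(2, 13, 2)
            voids = rng.random((h, w)) < rng.uniform(0.2, 0.7)
            labels = label_voids(_tsmap(voids), np.ones((h, w), bool))
            assert labels.max() == flood_fill_count(voids)


class TestVoidMetrics:
    def test_hand_counted_example(self):
        # 10x10 region, one 25-px void, 24-um pitch
        geom = ScanGeometry(field_of_view_mm=0.24, pixels_per_side=10)
        voids = np.zeros((10, 10), bool)
        voids[2:7, 2:7] = True
        labels = label_voids(_tsmap(voids), np.ones((10, 10), bool))
        m = void_metrics(labels, np.ones((10, 10), bool), None, geom)
        assert m.total_void_area_pct == pytest.approx(25.0)
        assert m.void_count == 1
        assert m.void_areas_um2[0] == pytest.approx(25 * 576.0)
        assert m.mean_void_area_um2 == pytest.approx(14400.0)

    def test_all_flow_region(self):
        geom = ScanGeometry(0.24, 10)
        labels = label_voids(_tsmap(np.zeros((10, 10), bool)), np.ones((10, 10), bool))
        m = void_metrics(labels, np.ones((10, 10), bool), None, geom)
        assert m.total_void_area_pct == 0.0
        assert m.void_count == 0

    def test_excluding_void_free_half_doubles_percentage(self):
        geom = ScanGeometry(0.24, 10)
        voids = np.zeros((10, 10), bool)
        voids[0:5, 0:5] = True  # 25 px in the top-left
        region = np.ones((10, 10), bool)
        excl = np.zeros((10, 10), bool)
        excl[5:] = True  # exclude the bottom half (disjoint from voids)
        ts = _tsmap(voids)
        m_full = region_void_metrics(ts, region, geom)
        labels = label_voids(ts, region)
        m_half = void_metrics(labels, region, ExclusionMask(excl), geom)
        assert m_half.total_void_area_pct == pytest.approx(2 * m_full.total_void_area_pct)

    def test_fully_excluded_region_raises(self):
        geom = ScanGeometry(0.24, 10)
        labels = np.zeros((10, 10), int)
        with pytest.raises(EmptyRegionError):
            void_metrics(labels, np.ones((10, 10), bool),
                         ExclusionMask(np.ones((10, 10), bool)), geom)

    def test_conservation_flow_plus_void_is_100pct(self, rng):
        geom = ScanGeometry(0.5, 20)
        for _ in range(20):
            labels_grid = rng.integers(0, 2, (20, 20)).astype(np.uint8)
            labels_grid[rng.random((20, 20)) < 0.2] = 2
            ts = TriStateMap(labels_grid)
            region = rng.random((20, 20)) < 0.8
            if not (region & ~ts.excluded).any():
                continue
            m = region_void_metrics(ts, region, geom)
            flow_px = (ts.flow & region & ~ts.excluded).sum()
            assert m.void_px + flow_px == m.analyzable_px
            assert m.total_void_area_pct + 100.0 * flow_px / m.analyzable_px == pytest.approx(100.0)
            # metric invariant: sum of void areas consistent with percentage
            assert m.void_areas_um2.sum() == pytest.approx(
                m.total_void_area_pct / 100.0 * m.analyzable_area_mm2 * 1e6
            )
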