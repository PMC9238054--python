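import numpy as np
import pytest

from lsfg_superpix.superpixel import (
    SuperpixelSegmentation,
    bin_histogram,
    flow_measures,
    range_map,
    slic_segment,
    superpixel_means,
)

from conftest import make_scan


def grid_segmentation(shape, block):
    """Hand-built label map: rectangular blocks in raster order."""
    ny = -(-shape[0] // block)
    nx = -(-shape[1] // block)
    labels = np.zeros(shape, dtype=int)
    lab = 0
    for by in range(ny):
        for bx in range(nx):
            lab += 1
            labels[by * block:(by + 1) * block, bx * block:(bx + 1) * block] = lab
    return SuperpixelSegmentation(labels=labels, k=lab)


class TestSlic:
    def test_deterministic(self, rng):
        mbr = rng.uniform(0, 30, (64, 128))
        scan = make_scan(mbr)
        a = slic_segment(scan, n_target=100)
        b = slic_segment(scan, n_target=100)
        assert np.array_equal(a.labels, b.labels)

    def test_constant_image_near_equal_areas(self):
        scan = make_scan(np.full((64, 64), 7.0))
        seg = slic_segment(scan, n_target=4)
        sizes = np.bincount(seg.labels.ravel())[1:]
        assert seg.k == 4
        assert sizes.max() <= 2 * scan.mbr.size / 4

    def test_labels_partition_frame(self, rng):
        scan = make_scan(rng.uniform(0, 30, (64, 128)))
        seg = slic_segment(scan, n_target=80)
        assert seg.labels.min() >= 1
        assert np.array_equal(np.unique(seg.labels), np.arange(1, seg.k + 1))

    def test_too_many_segments_rejected(self):
        scan = make_scan(np.ones((32, 32)))
        with pytest.raises(ValueError, match="exceeds pixel count"):
            slic_segment(scan, n_target=2000)

    def test_tiny_scan_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            slic_segment(make_scan(np.ones((16, 100))), n_target=10)


class TestMeans:
    def test_simple_arithmetic(self):
        mbr = np.array([[5.0, 7.0], [9.0, 20.0]])
        labels = np.array([[1, 1], [1, 2]])
        seg = SuperpixelSegmentation(labels=labels, k=2)
        superpixel_means(make_scan(mbr), seg)
        assert seg.mean_mbr[0] == pytest.approx(7.0)
        assert seg.mean_mbr[1] == pytest.approx(20.0)

    def test_low_validity_superpixel_undefined(self):
        mbr = np.array([[5.0, np.nan, np.nan, np.nan, np.nan], [1.0] * 5])
        labels = np.array([[1] * 5, [2] * 5])
        seg = SuperpixelSegmentation(labels=labels, k=2)
        superpixel_means(make_scan(mbr), seg)
        assert not seg.defined[0]  # 20% valid < 50% cutoff
        assert np.isnan(seg.mean_mbr[0])
        assert seg.defined[1]

    def test_conservation_against_per_pixel_sum(self, rng):
        mbr = rng.uniform(0, 30, (40, 40))
        valid = rng.random((40, 40)) > 0.05
        mbr[~valid] = np.nan
        scan = make_scan(mbr, valid)
        seg = grid_segmentation(scan.shape, 8)
        superpixel_means(scan, seg)
        sizes = np.array([
            int((valid & (seg.labels == l)).sum()) for l in range(1, seg.k + 1)
        ])
        defined = seg.defined
        lhs = float(np.sum(sizes[defined] * seg.mean_mbr[defined]))
        union = np.isin(seg.labels, np.flatnonzero(defined) + 1) & valid
        rhs = float(scan.mbr[union].sum())
        assert abs(lhs - rhs) / abs(rhs) < 1e-9


class TestHistogram:
    def make_seg(self, means):
        k = len(means)
        labels = np.arange(1, k + 1).reshape(1, -1)
        seg = SuperpixelSegmentation(labels=labels, k=k)
        seg.mean_mbr = np.asarray(means, dtype=float)
        seg.defined = np.isfinite(seg.mean_mbr)
        return seg

    def test_single_bin(self):
        hist = bin_histogram(self.make_seg([7.0] * 4))
        assert hist.percent == (0.0, 100.0, 0.0, 0.0, 0.0)

    def test_uniform_spread(self):
        hist = bin_histogram(self.make_seg([3.0, 7.0, 12.0, 17.0, 25.0]))
        assert hist.percent == (20.0,) * 5

    def test_edge_value_goes_to_upper_bin(self):
        """A mean of exactly 5 belongs to [5, 10), not < 5; 20 to >= 20."""
        hist = bin_histogram(self.make_seg([5.0, 20.0]))
        assert hist.percent == (0.0, 50.0, 0.0, 0.0, 50.0)

    def test_percentages_sum_to_100(self, rng):
        hist = bin_histogram(self.make_seg(rng.uniform(0, 30, 57)))
        assert sum(hist.percent) == pytest.approx(100.0, abs=1e-9)

    def test_undefined_excluded_from_denominator(self):
        seg = self.make_seg([3.0, 25.0, np.nan, np.nan])
        hist = bin_histogram(seg)
        assert hist.n_defined == 2 and hist.n_undefined == 2
        assert hist.percent[0] == 50.0 and hist.percent[4] == 50.0

    def test_no_defined_superpixels_rejected(self):
        seg = self.make_seg([np.nan, np.nan])
        with pytest.raises(ValueError, match="no defined"):
            bin_histogram(seg)


class TestRangeMaps:
    def test_partition_of_frame(self, rng):
        mbr = rng.uniform(0, 30, (40, 40))
        mbr[rng.random((40, 40)) < 0.3] = np.nan  # force some undefined
        scan = make_scan(mbr)
        seg = grid_segmentation(scan.shape, 5)
        superpixel_means(scan, seg)
        maps = [range_map(seg, b) for b in range(1, 6)]
        union = np.zeros(scan.shape, dtype=bool)
        for i, a in enumerate(maps):
            for b in maps[i + 1:]:
                assert not (a & b).any()  # pairwise disjoint
            union |= a
        undefined_px = np.isin(seg.labels, np.flatnonzero(~seg.defined) + 1)
        assert np.array_equal(union | undefined_px, np.ones(scan.shape, dtype=bool))

    def test_constant_high_flow_fills_top_bin(self):
        scan = make_scan(np.full((40, 40), 25.0))
        seg = grid_segmentation(scan.shape, 10)
        superpixel_means(scan, seg)
        assert range_map(seg, 5).all()

    def test_bad_bin_index(self):
        seg = grid_segmentation((10, 10), 5)
        with pytest.raises(ValueError):
            range_map(seg, 0)


class TestFlowMeasures:
    def test_projection_of_histogram(self):
        seg = TestHistogram().make_seg(
            [3.0] * 10 + [7.0] * 20 + [12.0] * 30 + [17.0] * 25 + [25.0] * 15
        )
        assert flow_measures(seg) == (15.0, 10.0)

    def test_all_vessel_image(self):
        seg = TestHistogram().make_seg([25.0, 30.0])
        assert flow_measures(seg) == (100.0, 0.0)

    def test_flow_reduction_moves_mass_down(self, rng):
        """Dimmed flow cannot lower pct_lt5 and cannot raise pct_ge20."""
        mbr = rng.uniform(0, 30, (48, 96))
        scan = make_scan(mbr)
        seg = slic_segment(scan, n_target=60)
        superpixel_means(scan, seg)
        ge20, lt5 = flow_measures(seg)
        dim = make_scan(0.3 * mbr)
        seg2 = SuperpixelSegmentation(labels=seg.labels.copy(), k=seg.k)
        superpixel_means(dim, seg2)
        ge20_d, lt5_d = flow_measures(seg2)
        assert lt5_d >= lt5
        assert ge20_d <= ge20


def test_oracle_equivalence_hand_labels(rng):
    """Histogram percentages match an exhaustive per-pixel computation."""
    mbr = rng.uniform(0, 30, (50, 50))
    valid = rng.random((50, 50)) > 0.2
    mbr[~valid] = np.nan
    scan = make_scan(mbr, valid)
    seg = grid_segmentation(scan.shape, 7)
    superpixel_means(scan, seg)
    hist = bin_histogram(seg)

    # brute force: python loops, no vectorised shortcuts
    sums = {}
    counts = {}
    totals = {}
    for y in range(50):
        for x in range(50):
            l = seg.labels[y, x]
            totals[l] = totals.get(l, 0) + 1
            if valid[y, x]:
                sums[l] = sums.get(l, 0.0) + mbr[y, x]
                counts[l] = counts.get(l, 0) + 1
    bins = [0, 0, 0, 0, 0]
    n_defined = 0
    for l in totals:
        if counts.get(l, 0) / totals[l] >= 0.5 and counts.get(l, 0) > 0:
            n_defined += 1
            m = sums[l] / counts[l]
            edge_idx = 4 if m >= 20 else int(m // 5)
            bins[edge_idx] += 1
            assert abs(m - seg.mean_mbr[l - 1]) < 1e-9
    assert hist.n_defined == n_defined
    for got, expect in zip(hist.percent, bins):
        assert got == pytest.approx(100.0 * expect / n_defined, abs=1e-9)
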