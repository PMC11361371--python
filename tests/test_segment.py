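"""Segmentation-layer contracts: unsharp masking, thresholding,
component labelling, containment filtering, and cell partitioning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from granulemap.core import BinaryMask, FocusROI
from granulemap.segment import (
    build_cell_regions,
    filter_by_mask,
    label_foci,
    segment_mask,
    unsharp_mask,
)

PX = 0.02


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestUnsharpMask:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 17.0)
        assert np.allclose(unsharp_mask(img, radius=5, weight=0.7), img)

    def test_zero_weight_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (32, 32))
        assert np.allclose(unsharp_mask(img, radius=10, weight=0.0), img)

    def test_weight_one_rejected(self):
        with pytest.raises(ValueError):
            unsharp_mask(np.zeros((8, 8)), weight=1.0)

    def test_delta_amplified_matches_convolution_oracle(self):
        """A bright pixel on black is amplified by about 1/(1-w); the
        exact value is checked against a brute-force Gaussian-kernel
        convolution."""
        from scipy.ndimage import convolve

        n, sigma, w = 121, 10.0, 0.7
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 100.0
        # explicit normalized Gaussian kernel, independent of gaussian_filter
        ax = np.arange(-40, 41)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        kernel = np.outer(k1, k1)
        kernel /= kernel.sum()
        oracle = np.clip((img - w * convolve(img, kernel)) / (1 - w), 0, None)
        ours = unsharp_mask(img, radius=sigma, weight=w)
        center = ours[n // 2, n // 2]
        assert center == pytest.approx(oracle[n // 2, n // 2], rel=1e-4)
        assert center == pytest.approx(100.0 / (1 - w), rel=0.01)


class TestSegmentMask:
    def test_otsu_separates_two_delta_populations(self):
        """Oracle: exhaustive threshold search maximizing between-class
        variance puts the cut between the populations."""
        rng = np.random.default_rng(1)
        img = np.full(1000, 10.0)
        hi = rng.choice(1000, size=100, replace=False)
        img[hi] = 200.0
        img = img.reshape(20, 50)

        # brute-force Otsu over candidate cuts
        vals = img.ravel()
        best = max(
            (np.mean(vals < t) * np.mean(vals >= t)
             * (vals[vals < t].mean() - vals[vals >= t].mean()) ** 2, t)
            for t in [100.0, 50.0, 150.0, 10.5, 199.5]
        )[1]
        assert 10.0 < best < 200.0

        mask = segment_mask(img, method="otsu", min_size=1, pixel_size=PX)
        assert np.array_equal(mask.raster, img == 200.0)
        assert 10.0 < mask.threshold <= 200.0

    def test_threshold_above_max_empty(self):
        img = np.full((16, 16), 5.0)
        mask = segment_mask(img, method="absolute", threshold=10.0, pixel_size=PX)
        assert mask.n_pixels == 0

    def test_empty_image_empty_mask(self):
        mask = segment_mask(np.zeros((16, 16)), method="otsu", pixel_size=PX)
        assert mask.n_pixels == 0

    def test_constant_nonzero_otsu_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            segment_mask(np.full((16, 16), 9.0), method="otsu", pixel_size=PX)

    def test_min_size_removes_small_components(self):
        img = np.zeros((32, 32))
        img[2, 2:6] = 10.0  # 4-pixel line
        img[10, 10:16] = 10.0  # 6-pixel line
        mask = segment_mask(img, method="absolute", threshold=5.0, min_size=5, pixel_size=PX)
        assert mask.n_pixels == 6

    @given(
        hnp.arrays(np.float64, (16, 16), elements=st.floats(0, 100)),
        st.floats(10, 40),
        st.floats(50, 90),
    )
    def test_monotone_in_threshold(self, img, t_lo, t_hi):
        lo = segment_mask(img, method="absolute", threshold=t_lo, min_size=1)
        hi = segment_mask(img, method="absolute", threshold=t_hi, min_size=1)
        assert not (hi.raster & ~lo.raster).any()

    def test_area_equals_pixel_count_times_px2(self):
        mask = BinaryMask(disk_mask((64, 64), (32, 32), 10), PX)
        assert mask.area_um2 == mask.raster.sum() * PX**2


class TestLabelFoci:
    def test_two_disjoint_disks(self):
        raster = disk_mask((64, 64), (16, 16), 5) | disk_mask((64, 64), (48, 48), 5)
        foci = label_foci(BinaryMask(raster, PX))
        assert len(foci) == 2

    def test_diagonal_touch_is_one_component(self):
        raster = np.zeros((8, 8), dtype=bool)
        raster[2, 2] = raster[3, 3] = True  # touch only diagonally
        foci = label_foci(BinaryMask(raster, PX))
        assert len(foci) == 1

    def test_empty_mask_empty_list(self):
        assert label_foci(BinaryMask(np.zeros((8, 8), bool), PX)) == []

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        raster = rng.random((48, 48)) > 0.82
        foci = label_foci(BinaryMask(raster, PX))
        rebuilt = np.zeros_like(raster)
        total = 0
        for f in foci:
            assert not rebuilt[f.pixels[:, 0], f.pixels[:, 1]].any()  # disjoint
            rebuilt[f.pixels[:, 0], f.pixels[:, 1]] = True
            total += f.n_pixels
        assert np.array_equal(rebuilt, raster)
        assert total == raster.sum()


class TestFilterByMask:
    @pytest.fixture()
    def straddling_focus(self):
        """40% of pixels inside the mask, centroid inside."""
        mito = np.zeros((20, 20), dtype=bool)
        mito[:, 10:] = True
        # 2 of 5 pixels inside; centroid column 9.6 rounds into the mask
        pixels = [(10, 9), (11, 9), (12, 9), (10, 10), (10, 11)]
        focus = FocusROI(0, "q", np.array(pixels), PX)
        return focus, BinaryMask(mito, PX)

    def test_rules_on_straddling_focus(self, straddling_focus):
        focus, mito = straddling_focus
        inside = mito.raster[focus.pixels[:, 0], focus.pixels[:, 1]].mean()
        assert inside < 0.5  # precondition: minority of pixels inside
        assert filter_by_mask([focus], mito, "centroid") == [focus]
        assert filter_by_mask([focus], mito, "majority") == []
        assert filter_by_mask([focus], mito, "any") == [focus]

    @pytest.mark.parametrize("rule", ["centroid", "majority", "any"])
    def test_fully_inside_kept_fully_outside_dropped(self, rule):
        mito = BinaryMask(disk_mask((40, 40), (12, 12), 8), PX)
        inside = FocusROI(0, "q", np.argwhere(disk_mask((40, 40), (12, 12), 2)), PX)
        outside = FocusROI(1, "q", np.argwhere(disk_mask((40, 40), (32, 32), 2)), PX)
        kept = filter_by_mask([inside, outside], mito, rule)
        assert [f.focus_id for f in kept] == [0]

    def test_rule_nesting_property(self):
        rng = np.random.default_rng(5)
        mito = BinaryMask(rng.random((40, 40)) > 0.5, PX)
        foci = label_foci(BinaryMask(rng.random((40, 40)) > 0.8, PX))
        ids = {
            rule: {f.focus_id for f in filter_by_mask(foci, mito, rule)}
            for rule in ("centroid", "majority", "any")
        }
        assert ids["majority"] <= ids["any"]
        assert ids["centroid"] <= ids["any"]


class TestBuildCellRegions:
    def _frame(self, centers, r_nuc=4, r_cell=10, shape=(64, 64)):
        dapi = np.zeros(shape)
        body = np.zeros(shape)
        for c in centers:
            dapi[disk_mask(shape, c, r_nuc)] = 200.0
            body[disk_mask(shape, c, r_cell)] = 80.0
        return dapi, body

    def test_three_planted_cells_recovered(self):
        centers = [(15, 15), (15, 48), (48, 30)]
        dapi, body = self._frame(centers)
        cells = build_cell_regions(dapi, body, pixel_size=0.1)
        assert len(cells) == 3
        rebuilt = np.zeros(dapi.shape, dtype=bool)
        for cell in cells:
            assert np.isin(cell.nucleus_idx, cell.cell_idx).all()
            assert not rebuilt.flat[cell.cell_idx].any()
            rebuilt.flat[cell.cell_idx] = True
        assert np.array_equal(rebuilt, body > 0)

    def test_two_nuclei_one_blob_split_with_label_audit(self):
        """Two nuclei sharing one cytoplasm blob are split along the
        nucleus-distance watershed; audited by brute-force label checks:
        regions partition the blob and each holds exactly one nucleus."""
        from skimage.measure import label

        shape = (48, 80)
        dapi = np.zeros(shape)
        body = np.zeros(shape)
        body[disk_mask(shape, (24, 25), 14) | disk_mask(shape, (24, 50), 14)] = 80.0
        dapi[disk_mask(shape, (24, 25), 4)] = 200.0
        dapi[disk_mask(shape, (24, 50), 4)] = 200.0
        assert label(body > 0).max() == 1  # precondition: one blob
        cells = build_cell_regions(dapi, body, pixel_size=0.1)
        assert len(cells) == 2
        seen = np.zeros(shape, dtype=int)
        nuclei = label(dapi > 0, connectivity=2)
        for cell in cells:
            seen.flat[cell.cell_idx] += 1
            labels_in_cell = np.unique(nuclei.flat[cell.nucleus_idx])
            labels_in_cell = labels_in_cell[labels_in_cell > 0]
            assert len(labels_in_cell) == 1
        assert seen.max() == 1
        assert (seen > 0).sum() == (body > 0).sum()

    def test_zero_nuclei_empty_list(self):
        assert build_cell_regions(np.zeros((32, 32)), np.zeros((32, 32)), pixel_size=0.1) == []

    def test_nucleus_without_cytoplasm_flagged(self):
        dapi = np.zeros((32, 32))
        dapi[disk_mask((32, 32), (16, 16), 4)] = 200.0
        cells = build_cell_regions(dapi, None, pixel_size=0.1)
        assert len(cells) == 1
        assert cells[0].unassigned_geometry
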