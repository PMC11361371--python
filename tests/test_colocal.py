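"""Colocalization core: moment-ellipse descriptors against analytic and
independent oracles, pixel-exact overlap, categorization, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from granulemap.colocal import (
    categorize,
    compute_overlap,
    shape_descriptors,
    size_stratified_overlap,
    summarize,
)
from granulemap.core import FocusROI, OverlapRecord

PX = 0.02


def roi_from_mask(raster, focus_id=0, channel="q", px=PX):
    return FocusROI(focus_id, channel, np.argwhere(raster), px)


def disk(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestShapeDescriptors:
    def test_disk_area_and_eccentricity(self):
        f = shape_descriptors(roi_from_mask(disk((64, 64), (32, 32), 10)))
        assert abs(f.area_um2 - np.pi * (10 * PX) ** 2) / (np.pi * (10 * PX) ** 2) < 0.02
        assert f.eccentricity <= 0.1
        # moment-ellipse axes of a disk are its diameter
        assert f.major_axis_um == pytest.approx(2 * 10 * PX, rel=0.1)

    def test_ellipse_eccentricity(self):
        rr, cc = np.mgrid[:96, :96]
        ell = ((rr - 48) / 20.0) ** 2 + ((cc - 48) / 10.0) ** 2 <= 1.0
        f = shape_descriptors(roi_from_mask(ell))
        assert abs(f.eccentricity - np.sqrt(1 - 0.25)) < 0.05
        assert f.minor_axis_um <= f.major_axis_um

    def test_single_pixel_degenerate(self):
        f = shape_descriptors(FocusROI(0, "q", np.array([[5, 5]]), PX))
        assert f.eccentricity == 0.0
        assert f.major_axis_um == f.minor_axis_um == PX
        assert f.degenerate

    def test_collinear_pixels_flagged(self):
        f = shape_descriptors(FocusROI(0, "q", np.array([[3, c] for c in range(8)]), PX))
        assert f.degenerate
        assert 0.0 <= f.eccentricity < 1.0

    def test_matches_regionprops_on_random_blobs(self):
        """Independent cross-check: skimage's moment-ellipse on the same
        components gives the same axes and eccentricity."""
        from skimage.measure import label, regionprops

        rng = np.random.default_rng(9)
        raster = rng.random((64, 64)) > 0.8
        lbl = label(raster, connectivity=2)
        for rp in regionprops(lbl):
            if rp.num_pixels < 3 or rp.axis_minor_length == 0:
                continue
            f = shape_descriptors(roi_from_mask(lbl == rp.label, px=1.0))
            assert f.major_axis_um == pytest.approx(rp.axis_major_length, rel=1e-9)
            assert f.minor_axis_um == pytest.approx(rp.axis_minor_length, rel=1e-9)
            assert f.eccentricity == pytest.approx(rp.eccentricity, abs=1e-9)

    def test_eccentricity_consistent_with_axes(self):
        f = shape_descriptors(roi_from_mask(disk((64, 64), (20, 30), 7)))
        expected = np.sqrt(1 - (f.minor_axis_um / f.major_axis_um) ** 2)
        assert f.eccentricity == pytest.approx(expected, abs=1e-9)


class TestComputeOverlap:
    def test_identical_focus_full_overlap(self):
        m = disk((32, 32), (16, 16), 5)
        rec = compute_overlap([roi_from_mask(m)], [roi_from_mask(m, channel="r")], (32, 32))[0]
        assert rec.overlap_pct == 100.0
        assert rec.category == "complete"

    def test_disjoint_zero_overlap(self):
        q = roi_from_mask(disk((64, 64), (16, 16), 5))
        r = roi_from_mask(disk((64, 64), (48, 48), 5), channel="r")
        rec = compute_overlap([q], [r], (64, 64))[0]
        assert rec.overlap_pct == 0.0
        assert rec.category == "none"

    def test_offset_squares_half_overlap(self):
        a = np.zeros((32, 32), dtype=bool)
        b = np.zeros((32, 32), dtype=bool)
        a[5:15, 5:15] = True
        b[5:15, 10:20] = True
        rec = compute_overlap([roi_from_mask(a)], [roi_from_mask(b, channel="r")], (32, 32))[0]
        assert rec.overlap_pct == 50.0
        assert rec.overlap_area_um2 == 50 * PX**2

    def test_empty_reference_all_zero(self):
        q = roi_from_mask(disk((32, 32), (16, 16), 4))
        rec = compute_overlap([q], [], (32, 32))[0]
        assert rec.overlap_pct == 0.0

    def test_union_accumulates_multiple_references(self):
        q = np.zeros((16, 48), dtype=bool)
        q[6:10, 8:40] = True  # long bar straddling two reference blocks
        r1 = np.zeros_like(q); r1[6:10, 8:16] = True
        r2 = np.zeros_like(q); r2[6:10, 32:40] = True
        rec = compute_overlap(
            [roi_from_mask(q)],
            [roi_from_mask(r1, 0, "r"), roi_from_mask(r2, 1, "r")],
            q.shape,
        )[0]
        assert rec.overlap_pct == pytest.approx(100 * 64 / 128)

    def test_oracle_equivalence_random_pairs(self):
        """Pixel-intersection counts equal a brute-force boolean-raster
        oracle exactly on random blob pairs."""
        from tests.conftest import random_blob

        rng = np.random.default_rng(17)
        for _ in range(50):
            a = random_blob(rng, (48, 48), n_dilate=rng.integers(5, 40))
            b = random_blob(rng, (48, 48), n_dilate=rng.integers(5, 40))
            rec = compute_overlap([roi_from_mask(a)], [roi_from_mask(b, channel="r")], (48, 48))[0]
            brute = int(np.logical_and(a, b).sum())
            assert rec.overlap_area_um2 == pytest.approx(brute * PX**2, abs=1e-12)
            assert rec.overlap_pct == pytest.approx(100.0 * brute / a.sum())

    def test_intersection_area_symmetric(self):
        rng = np.random.default_rng(23)
        a = rng.random((32, 32)) > 0.7
        b = rng.random((32, 32)) > 0.7
        ra = compute_overlap([roi_from_mask(a)], [roi_from_mask(b, channel="r")], (32, 32))[0]
        rb = compute_overlap([roi_from_mask(b)], [roi_from_mask(a, channel="r")], (32, 32))[0]
        assert ra.overlap_area_um2 == rb.overlap_area_um2


class TestCategorize:
    @pytest.mark.parametrize(
        "pct,expected",
        [(0.0, "none"), (100.0, "complete"), (40.0, "partial"),
         (99.0, "complete"), (98.9, "partial"), (0.01, "partial")],
    )
    def test_boundaries(self, pct, expected):
        assert categorize(pct) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(101.0)

    def test_tolerance_configurable(self):
        assert categorize(96.0, complete_tol=5.0) == "complete"
        assert categorize(96.0, complete_tol=1.0) == "partial"


def _records(counts):
    recs = []
    i = 0
    for cat, n in counts.items():
        for _ in range(n):
            pct = {"none": 0.0, "partial": 50.0, "complete": 100.0}[cat]
            rec = OverlapRecord(i, "dsRNA", "BrU", 0.0, pct, category=cat)
            recs.append(rec)
            i += 1
    return recs


class TestSummarize:
    def test_printed_dsrna_vs_bru_composition(self):
        """Counts 32/65/3 of 100 reproduce the 32%/65%/3% composition."""
        s = summarize(_records({"none": 32, "partial": 65, "complete": 3}))
        assert (s.pct_none, s.pct_partial, s.pct_complete) == (32.0, 65.0, 3.0)

    def test_all_none(self):
        s = summarize(_records({"none": 7}))
        assert (s.pct_none, s.pct_partial, s.pct_complete) == (100.0, 0.0, 0.0)

    def test_thirds(self):
        s = summarize(_records({"none": 1, "partial": 1, "complete": 1}))
        assert s.pct_none == pytest.approx(100 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_percentages_sum_to_100(self, a, b, c):
        if a + b + c == 0:
            return
        s = summarize(_records({"none": a, "partial": b, "complete": c}))
        assert s.pct_none + s.pct_partial + s.pct_complete == pytest.approx(100.0)


class TestSizeStratified:
    def test_two_foci_split_by_overlap(self):
        foci = [
            FocusROI(0, "q", np.argwhere(disk((32, 32), (8, 8), 3)), 0.0564),
            FocusROI(1, "q", np.argwhere(disk((32, 32), (24, 24), 5)), 0.0564),
        ]
        recs = [
            OverlapRecord(0, "q", "r", 0.0, 0.0, "none"),
            OverlapRecord(1, "q", "r", 0.01, 50.0, "partial"),
        ]
        table, summary = size_stratified_overlap(recs, foci)
        groups = dict(zip(table.overlap_class, table.focus_id))
        assert groups == {"no overlap": 0, "partial-or-complete": 1}
        assert set(summary.overlap_class) == {"no overlap", "partial-or-complete"}
        assert (summary.n == 1).all()
        assert summary.sd_area_um2.isna().all()  # singleton groups

    def test_all_zero_overlap_one_group(self):
        foci = [FocusROI(i, "q", np.array([[i, i]]), PX) for i in range(3)]
        recs = [OverlapRecord(i, "q", "r", 0.0, 0.0, "none") for i in range(3)]
        table, summary = size_stratified_overlap(recs, foci)
        assert set(table.overlap_class) == {"no overlap"}
        assert len(summary) == 1
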