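"""Foci pipeline: projection, adaptive thresholding, labelling, per-nucleus
counting and foci-positive classification."""

import numpy as np
import pytest

from llpsquant.foci import (
    AnalysisConfig,
    ImageStack,
    adaptive_threshold,
    analyze_stack,
    classify_positive,
    count_foci_per_nucleus,
    label_foci,
    max_project,
    segment_nuclei,
    summarize_field,
    NucleusRecord,
)
from llpsquant.synthetic import FociFieldSpec, make_foci_field


def _stack(voxels, px=0.067, zs=0.21, names=None):
    names = names or [f"ch{i}" for i in range(voxels.shape[0])]
    return ImageStack(voxels=voxels, pixel_size_um=px, z_step_um=zs, channel_names=names)


class TestMaxProject:
    def test_all_zero(self):
        s = _stack(np.zeros((1, 3, 4, 5)))
        assert np.all(max_project(s, "ch0") == 0)

    def test_single_voxel(self):
        v = np.zeros((1, 3, 6, 7))
        v[0, 1, 2, 3] = 9.0
        out = max_project(_stack(v), "ch0")
        assert out[2, 3] == 9.0 and out.sum() == 9.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 100, size=(2, 4, 6, 5))
        out = max_project(_stack(v), "ch1")
        # brute-force oracle: explicit per-pixel loop over z
        expected = np.zeros((6, 5))
        for y in range(6):
            for x in range(5):
                m = 0.0
                for z in range(4):
                    m = max(m, v[1, z, y, x])
                expected[y, x] = m
        assert np.array_equal(out, expected)

    def test_single_slice_idempotent(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 10, size=(1, 1, 8, 8))
        assert np.array_equal(max_project(_stack(v), "ch0"), v[0, 0])

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            max_project(_stack(np.zeros((1, 1, 2, 2))), "nope")


def _gauss_spot(shape, cy, cx, sigma, amplitude, background):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


class TestAdaptiveThreshold:
    def test_constant_image_empty_mask(self):
        assert not adaptive_threshold(np.full((40, 40), 7.0), 15, 3.0).any()

    def test_spot_mask_contained_near_centre(self):
        img = _gauss_spot((64, 64), 32, 32, sigma=1.5, amplitude=100, background=10)
        mask = adaptive_threshold(img, 15, 3.0)
        assert mask.any()
        ys, xs = np.nonzero(mask)
        assert np.all((ys - 32) ** 2 + (xs - 32) ** 2 <= (3 * 1.5) ** 2)

    def test_matches_direct_windowed_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 50, size=(24, 24))
        w, k = 5, 1.5
        mask = adaptive_threshold(img, w, k)
        pad = np.pad(img, w // 2, mode="symmetric")  # scipy's "reflect" convention
        for y in range(24):
            for x in range(24):
                win = pad[y : y + w, x : x + w]
                expect = img[y, x] > win.mean() + k * win.std() + 1e-9 * np.ptp(img)
                assert mask[y, x] == expect, (y, x)

    def test_translation_equivariance(self):
        img1 = _gauss_spot((80, 80), 25, 25, 1.5, 100, 10)
        img2 = _gauss_spot((80, 80), 45, 55, 1.5, 100, 10)
        m1 = adaptive_threshold(img1, 15, 3.0)
        m2 = adaptive_threshold(img2, 15, 3.0)
        assert np.array_equal(np.roll(np.roll(m1, 20, axis=0), 30, axis=1), m2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((10, 10)), 4, 3.0)


class TestLabelFoci:
    def test_empty_mask(self):
        assert label_foci(np.zeros((5, 5), bool), 0.067) == []

    def test_min_area_zero_keeps_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        recs = label_foci(mask, 0.067, min_area_px=0)
        assert len(recs) == 1 and recs[0].area_um2 == pytest.approx(0.067**2)

    def test_two_squares_hand_count(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        recs = label_foci(mask, 0.067)
        assert len(recs) == 2
        for r in recs:
            assert r.area_um2 == pytest.approx(4 * 0.067**2)
        # deterministic raster-order ids
        assert recs[0].centroid_px == (1.5, 1.5)
        assert recs[1].centroid_px == (6.5, 6.5)

    def test_eight_connectivity_joins_diagonals(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(label_foci(mask, 1.0)) == 1


class TestSegmentNuclei:
    def test_one_disc(self):
        img = np.zeros((50, 50))
        yy, xx = np.mgrid[0:50, 0:50]
        img[(yy - 25) ** 2 + (xx - 25) ** 2 <= 100] = 500.0
        rois = segment_nuclei(img, AnalysisConfig(nucleus_threshold=100.0))
        assert len(rois) == 1

    def test_border_nucleus_excluded(self):
        img = np.zeros((60, 60))
        yy, xx = np.mgrid[0:60, 0:60]
        img[(yy - 30) ** 2 + (xx - 30) ** 2 <= 64] = 500.0  # interior
        img[(yy - 0) ** 2 + (xx - 50) ** 2 <= 64] = 500.0  # clipped by border
        cfg = AnalysisConfig(nucleus_threshold=100.0, exclude_border_nuclei=True)
        assert len(segment_nuclei(img, cfg)) == 1
        cfg2 = AnalysisConfig(nucleus_threshold=100.0, exclude_border_nuclei=False)
        assert len(segment_nuclei(img, cfg2)) == 2

    def test_threshold_above_max_gives_empty(self):
        img = np.full((20, 20), 10.0)
        assert segment_nuclei(img, AnalysisConfig(nucleus_threshold=100.0)) == []

    def test_iou_against_generator_truth(self):
        spec = FociFieldSpec(
            field_shape_px=(256, 256), n_z=5, n_nuclei=3,
            foci_per_nucleus=(2, 2, 2), nucleus_radius_um=2.0, seed=8,
        )
        stack, truth = make_foci_field(spec)
        rois = segment_nuclei(max_project(stack, "nuclei"), AnalysisConfig())
        assert len(rois) == 3
        for roi in rois:
            ious = []
            for nid in range(1, 4):
                t = truth.nucleus_masks == nid
                ious.append((roi.mask & t).sum() / (roi.mask | t).sum())
            assert max(ious) >= 0.95


class TestCountingAndClassification:
    def test_no_foci_all_zero(self):
        img = np.zeros((30, 30))
        yy, xx = np.mgrid[0:30, 0:30]
        img[(yy - 15) ** 2 + (xx - 15) ** 2 <= 36] = 500.0
        rois = segment_nuclei(img, AnalysisConfig(nucleus_threshold=100.0))
        recs = count_foci_per_nucleus([], rois)
        assert [r.foci_count for r in recs] == [0]

    def test_focus_outside_every_nucleus_unassigned(self):
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        img[(yy - 20) ** 2 + (xx - 20) ** 2 <= 25] = 500.0
        rois = segment_nuclei(img, AnalysisConfig(nucleus_threshold=100.0))
        mask = np.zeros((40, 40), bool)
        mask[2, 2] = True  # far from the nucleus
        mask[20, 20] = True  # inside
        foci = label_foci(mask, 1.0)
        recs = count_foci_per_nucleus(foci, rois)
        assert recs[0].foci_count == 1
        outside = [f for f in foci if f.centroid_px == (2.0, 2.0)][0]
        assert outside.nucleus_id is None

    def test_count_conservation(self):
        spec = FociFieldSpec(
            field_shape_px=(300, 300), n_z=7, n_nuclei=3,
            foci_per_nucleus=(4, 9, 14), nucleus_radius_um=2.5, seed=21,
        )
        stack, _ = make_foci_field(spec)
        foci, recs, _ = analyze_stack(stack)
        assigned = sum(r.foci_count for r in recs)
        unassigned = sum(1 for f in foci if f.nucleus_id is None)
        assert assigned + unassigned == len(foci)

    @pytest.mark.parametrize(
        "count,cutoff,expected",
        [(20, 20, True), (19, 20, False), (0, 20, False), (40, 20, True), (1, 1, True)],
    )
    def test_positivity_boundary(self, count, cutoff, expected):
        assert classify_positive(count, cutoff) is expected

    def test_raising_cutoff_never_increases_percent_positive(self):
        counts = [0, 3, 10, 19, 20, 21, 25, 40]
        prev = 100.0
        for cutoff in range(1, 45):
            recs = [
                NucleusRecord(i, 1.0, c, classify_positive(c, cutoff))
                for i, c in enumerate(counts)
            ]
            pct = summarize_field(recs).percent_positive
            assert pct <= prev
            prev = pct


class TestSummarizeField:
    def test_all_and_none_positive(self):
        all_pos = [NucleusRecord(i, 1.0, 30, True) for i in range(4)]
        none_pos = [NucleusRecord(i, 1.0, 2, False) for i in range(4)]
        assert summarize_field(all_pos).percent_positive == 100.0
        assert summarize_field(none_pos).percent_positive == 0.0

    def test_three_of_ten(self):
        recs = [NucleusRecord(i, 1.0, 25 if i < 3 else 1, i < 3) for i in range(10)]
        s = summarize_field(recs)
        assert s.percent_positive == pytest.approx(30.0)
        assert s.n_positive == 3 and s.n_nuclei == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_field([])


class TestEndToEnd:
    def test_exact_recovery_at_high_snr(self):
        spec = FociFieldSpec(
            field_shape_px=(512, 512), n_z=9, n_nuclei=5,
            foci_per_nucleus=(3, 10, 19, 20, 25), nucleus_radius_um=4.0, seed=0,
        )
        stack, truth = make_foci_field(spec)
        _, recs, summary = analyze_stack(stack)
        assert sorted(r.foci_count for r in recs) == sorted(truth.foci_per_nucleus)
        # counts 20 and 25 are foci-positive at the default cutoff of 20
        assert summary.n_positive == 2
        assert summary.percent_positive == pytest.approx(40.0)

    def test_count_recovery_rate_over_seeds(self):
        """>= 95% of nuclei get an exact count at amplitude/background >= 10."""
        exact = total = 0
        for seed in range(20):
            spec = FociFieldSpec(
                field_shape_px=(300, 300), n_z=7, n_nuclei=2,
                foci_per_nucleus=(8, 20), nucleus_radius_um=2.8, seed=seed,
            )
            stack, truth = make_foci_field(spec)
            _, recs, _ = analyze_stack(stack)
            m = sorted(r.foci_count for r in recs)
            t = sorted(truth.foci_per_nucleus)
            exact += sum(a == b for a, b in zip(m, t))
            total += len(t)
        assert exact / total >= 0.95
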