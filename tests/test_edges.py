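import numpy as np
import pytest

from glottipress.edges import (
    DetectionConfig,
    EdgePointSet,
    censor_merged_rows,
    compute_gradient,
    detect_edges,
    detect_sequence,
    fill_bright_regions,
    smooth_temporal,
)
from glottipress.geometry import ROI, AttachmentLine


def _flood_fill_oracle(img):
    """Brute-force grayscale hole filling via iterative reconstruction by
    erosion from a border seed (oracle for fill_bright_regions, which works
    on the inverted image)."""
    inv = 1.0 - img
    seed = np.full_like(inv, inv.max())
    seed[0, :] = inv[0, :]
    seed[-1, :] = inv[-1, :]
    seed[:, 0] = inv[:, 0]
    seed[:, -1] = inv[:, -1]
    for _ in range(10 * img.size):
        padded = np.pad(seed, 1, mode="edge")
        # 3x3 square neighborhood (8-connectivity), center included
        eroded = np.minimum.reduce(
            [padded[dy : dy + seed.shape[0], dx : dx + seed.shape[1]]
             for dy in range(3) for dx in range(3)]
        )
        new = np.maximum(eroded, inv)
        if np.array_equal(new, seed):
            break
        seed = new
    return 1.0 - seed


class TestFillBrightRegions:
    def test_constant_frame_unchanged(self):
        f = np.full((8, 8), 0.4)
        np.testing.assert_allclose(fill_bright_regions(f), f)

    def test_interior_bright_blob_attenuated(self):
        f = np.full((10, 10), 0.3)
        f[4:6, 4:6] = 0.9
        out = fill_bright_regions(f)
        assert out[4, 4] == pytest.approx(0.3, abs=1e-9)
        np.testing.assert_allclose(out, _flood_fill_oracle(f), atol=1e-9)

    def test_border_connected_dark_slit_preserved(self):
        f = np.full((10, 10), 0.8)
        f[0:10, 4:6] = 0.1  # dark slit touching both borders
        out = fill_bright_regions(f)
        np.testing.assert_allclose(out, f, atol=1e-9)
        np.testing.assert_allclose(out, _flood_fill_oracle(f), atol=1e-9)

    def test_interior_dark_region_untouched(self):
        # the glottis is dark: filling bright blobs must never erase it
        f = np.full((12, 12), 0.8)
        f[3:9, 5:7] = 0.1
        out = fill_bright_regions(f)
        np.testing.assert_allclose(out, f, atol=1e-9)


class TestComputeGradient:
    def test_constant_frame_zero_field(self):
        field = compute_gradient(np.full((6, 6), 0.7), t_h=0.2)
        assert np.all(field.G == 0)

    def test_vertical_step_direct_convolution_oracle(self):
        f = np.zeros((5, 5))
        f[:, 3:] = 1.0
        field = compute_gradient(f, t_h=0.0)
        # Prewitt x-kernel response at the step columns, reflect padding
        from scipy import ndimage

        gx = ndimage.prewitt(f, axis=1, mode="reflect")
        gy = ndimage.prewitt(f, axis=0, mode="reflect")
        np.testing.assert_allclose(field.G, np.hypot(gx, gy))
        col = field.G[2]
        assert col.argmax() in (2, 3)
        # gradient points from dark to bright: positive x-component
        assert field.gx[2, col.argmax()] > 0

    def test_threshold_one_keeps_only_global_max(self):
        rng = np.random.default_rng(3)
        f = rng.random((9, 9))
        field = compute_gradient(f, t_h=1.0)
        assert np.count_nonzero(field.G) >= 1
        assert np.all(field.G[field.G > 0] == field.G.max())

    def test_intensity_doubling_leaves_relative_mask_unchanged(self):
        f = np.zeros((7, 7))
        f[:, 3:] = 0.4
        f[2, 1] = 0.1
        a = compute_gradient(f, t_h=0.5)
        b = compute_gradient(np.clip(2 * f, 0, 1), t_h=0.5)
        np.testing.assert_array_equal(a.G > 0, b.G > 0)


class TestDetectEdges:
    def _line(self, side):
        return AttachmentLine((4.5, 0), (4.5, 9), side=side)

    def _field_from_row(self, g_row, gx_sign):
        G = np.zeros((10, 10))
        gx = np.zeros((10, 10))
        G[5, : len(g_row)] = g_row
        gx[5, : len(g_row)] = gx_sign * np.asarray(g_row)
        from glottipress.edges import GradientField

        return GradientField(G=G, phase=np.zeros_like(G), gx=gx, gy=np.zeros_like(G))

    def test_weighted_mean_symmetric_mass(self):
        field = self._field_from_row([0, 2, 2, 0, 0], gx_sign=-1)
        # row mass at x=1,2 with equal weight -> midpoint 1.5
        ps = detect_edges(field, self._line("left"), ROI(0, 0, 10, 10))
        row = dict((y, x) for x, y in ps.points)
        assert row[5] == pytest.approx(1.5)

    def test_weighted_mean_oracle(self):
        field = self._field_from_row([0, 1, 3, 0], gx_sign=-1)
        ps = detect_edges(field, self._line("left"), ROI(0, 0, 10, 10))
        row = dict((y, x) for x, y in ps.points)
        assert row[5] == pytest.approx((1 * 1 + 2 * 3) / 4)

    def test_wrong_phase_side_gives_no_points(self):
        field = self._field_from_row([0, 1, 3, 0], gx_sign=+1)  # right-fold polarity
        ps = detect_edges(field, self._line("left"), ROI(0, 0, 10, 10))
        assert ps.D == 0

    def test_closed_glottis_emits_empty_set(self):
        from glottipress.edges import GradientField

        zeros = np.zeros((10, 10))
        field = GradientField(G=zeros, phase=zeros, gx=zeros, gy=zeros)
        ps = detect_edges(field, self._line("left"), ROI(0, 0, 10, 10))
        assert ps.D == 0

    def test_left_right_supports_disjoint(self):
        f = np.full((10, 10), 0.8)
        f[:, 4:6] = 0.1
        field = compute_gradient(f, t_h=0.2)
        left = detect_edges(field, self._line("left"), ROI(0, 0, 10, 10))
        right = detect_edges(field, self._line("right"), ROI(0, 0, 10, 10))
        for (xl, y) in left.points:
            xr = dict((yy, xx) for xx, yy in right.points).get(y)
            assert xr is None or xl < xr


class TestSmoothTemporal:
    def _series(self, values_by_frame, row=5):
        out = []
        for k, v in enumerate(values_by_frame):
            pts = [] if v is None else [(v, row)]
            out.append(EdgePointSet(frame=k, side="left", points=pts))
        return out

    def test_constant_trajectory_unchanged(self):
        series = self._series([2.0] * 7)
        sm = smooth_temporal(series, window=5)
        assert all(s.points[0][0] == pytest.approx(2.0) for s in sm)

    def test_center_value_is_arithmetic_mean(self):
        sm = smooth_temporal(self._series([1, 2, 3, 4, 5]), window=5)
        assert sm[2].points[0][0] == pytest.approx(3.0)

    def test_missing_frames_excluded_from_mean(self):
        # masked mean: the gap contributes nothing, the rest average plainly
        sm = smooth_temporal(self._series([1, None, 3, 4, 5]), window=5)
        assert sm[2].points[0][0] == pytest.approx((1 + 3 + 4 + 5) / 4)
        sm2 = smooth_temporal(self._series([1, 2, None, 4, 5]), window=5)
        assert sm2[3].points[0][0] == pytest.approx((2 + 4 + 5) / 3)

    def test_point_count_preserved(self):
        series = self._series([1, None, 3, None, 5])
        sm = smooth_temporal(series, window=5)
        assert [s.D for s in sm] == [s.D for s in series]


class TestCensorMergedRows:
    def test_close_rows_dropped_from_both(self):
        left = [EdgePointSet(0, "left", [(4.0, 3), (2.0, 4)])]
        right = [EdgePointSet(0, "right", [(5.5, 3), (8.0, 4)])]
        cl, cr = censor_merged_rows(left, right, min_separation=2.0)
        assert [y for _, y in cl[0].points] == [4]
        assert [y for _, y in cr[0].points] == [4]

    def test_one_sided_rows_kept(self):
        left = [EdgePointSet(0, "left", [(4.0, 3)])]
        right = [EdgePointSet(0, "right", [])]
        cl, cr = censor_merged_rows(left, right, min_separation=2.0)
        assert cl[0].D == 1


class TestDetectSequenceOnPhantom:
    def test_edge_localization_rms_open_phase(self, small_phantom, midline_lines, full_roi):
        """Detected sub-pixel edges track the true rendered edge positions
        to within half a pixel while the glottis is open."""
        cfg, seq, gt = small_phantom
        line_l, line_r = midline_lines
        det = DetectionConfig(t_h=0.5, temporal_window=5)
        raw_l = detect_sequence(seq.frames, line_l, full_roi, det, fill=False, smooth=False)
        raw_r = detect_sequence(seq.frames, line_r, full_roi, det, fill=False, smooth=False)
        raw_l, raw_r = censor_merged_rows(raw_l, raw_r, det.min_separation_px)
        sm = smooth_temporal(raw_l, det.temporal_window)
        errs = []
        row_index = {int(y): j for j, y in enumerate(gt.rows)}
        open_frames = np.nonzero(gt.delta_true == 0)[0]
        for k in open_frames:
            for x, y in sm[k].points:
                errs.append(x - gt.edge_left[k, row_index[y]])
        errs = np.array(errs)
        assert len(errs) > 1000
        assert np.sqrt(np.mean(errs**2)) <= 0.5

    def test_detection_collapses_during_contact(self, small_phantom, midline_lines, full_roi):
        cfg, seq, gt = small_phantom
        line_l, line_r = midline_lines
        det = DetectionConfig(t_h=0.5)
        raw_l = detect_sequence(seq.frames, line_l, full_roi, det, fill=False, smooth=False)
        raw_r = detect_sequence(seq.frames, line_r, full_roi, det, fill=False, smooth=False)
        raw_l, _ = censor_merged_rows(raw_l, raw_r, det.min_separation_px)
        contact = gt.delta_true > 0.5
        d_contact = np.array([raw_l[k].D for k in np.nonzero(contact)[0]])
        assert d_contact.max() == 0
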