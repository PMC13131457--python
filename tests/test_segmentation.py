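"""Thresholding, size/shape filtering, soma detection, ROI construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evquant.errors import AnalysisError, ConfigurationError, DegenerateThresholdError
from evquant.imaging import BinaryMask, CalibratedImage
from evquant.segmentation import (
    SizeShapeFilter,
    ThresholdSpec,
    define_cell_roi,
    detect_somata,
    filter_particles,
    threshold_channel,
)
from evquant.synthetic import SomaFieldSpec, generate_soma_field

from conftest import particles_from_labels


def _img(arr, px=65.0, name="ev"):
    return CalibratedImage({name: np.asarray(arr, float)}, px)


class TestThreshold:
    def test_otsu_separates_two_level_image(self, rng):
        arr = np.full(1000, 10.0)
        arr[:100] = 200.0
        rng.shuffle(arr)
        arr = arr.reshape(25, 40)
        mask = threshold_channel(_img(arr), "ev", ThresholdSpec("otsu"))
        np.testing.assert_array_equal(mask.mask, arr == 200.0)
        assert 10.0 < mask.meta["threshold"] < 200.0

    def test_percentile_is_order_statistic(self, rng):
        arr = rng.permutation(np.arange(10000.0)).reshape(100, 100)
        mask = threshold_channel(
            _img(arr), "ev", ThresholdSpec("percentile", percentile=99.0)
        )
        assert mask.n_foreground == 100  # exactly the top 1%
        np.testing.assert_array_equal(mask.mask, arr > np.percentile(arr, 99))

    def test_otsu_matches_exhaustive_between_class_variance(self, rng):
        # random two-mode mixture, oracle maximizes between-class variance
        # over the same 256-level histogram grid
        x = np.concatenate([rng.normal(40, 8, 3000), rng.normal(180, 15, 1000)])
        arr = np.clip(x, 0, 255).reshape(40, 100)
        hist, edges = np.histogram(arr, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        w0 = np.cumsum(hist)[:-1]
        w1 = hist.sum() - w0
        m0 = np.cumsum(hist * centers)[:-1] / np.where(w0 == 0, 1, w0)
        m1 = (np.sum(hist * centers) - np.cumsum(hist * centers)[:-1]) / np.where(
            w1 == 0, 1, w1
        )
        var_b = w0 * w1 * (m0 - m1) ** 2
        oracle_thr = centers[:-1][np.argmax(var_b)]
        mask = threshold_channel(_img(arr), "ev", ThresholdSpec("otsu"))
        assert mask.meta["threshold"] == pytest.approx(oracle_thr, abs=1e-9)

    def test_constant_image_degenerate(self):
        img = _img(np.full((8, 8), 7.0))
        with pytest.raises(DegenerateThresholdError):
            threshold_channel(img, "ev", ThresholdSpec("otsu"))
        mask = threshold_channel(img, "ev", ThresholdSpec("otsu"),
                                 allow_degenerate=True)
        assert mask.n_foreground == 0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            ThresholdSpec("percentile")
        with pytest.raises(ConfigurationError):
            ThresholdSpec("absolute")
        with pytest.raises(ConfigurationError):
            ThresholdSpec("otsu", percentile=50.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_raising_absolute_threshold_never_adds_foreground(self, t1, t2):
        rng = np.random.default_rng(0)
        arr = rng.random((20, 20)) * 100
        lo, hi = sorted((t1, t2))
        m_lo = threshold_channel(_img(arr), "ev",
                                 ThresholdSpec("absolute", absolute_value=lo)).mask
        m_hi = threshold_channel(_img(arr), "ev",
                                 ThresholdSpec("absolute", absolute_value=hi)).mask
        assert not (m_hi & ~m_lo).any()


class TestFilterParticles:
    def _random_particles(self, rng):
        labels = np.zeros((64, 64), np.int32)
        k = 0
        for _ in range(15):
            r, c = rng.integers(2, 58, 2)
            size = int(rng.integers(1, 6))
            if labels[r:r + size + 1, c:c + size + 1].any():
                continue
            k += 1
            labels[r:r + size, c:c + size] = k
        return particles_from_labels(labels, pixel_size_nm=200.0)

    def test_pass_through_filter_is_identity(self, rng):
        ps = self._random_particles(rng)
        out = filter_particles(ps, SizeShapeFilter(0.0, np.inf, 0.0, 1.0))
        assert out.ids == ps.ids

    def test_area_window_boundary_logic(self):
        # areas 0.01, 0.1, 5.0 um^2 -> only 0.1 retained by (0.05, 1.0)
        labels = np.zeros((200, 200), np.int32)
        labels[0, 0] = 1  # 1 px * 0.01 um2
        labels[10:12, 10:15] = 2  # 10 px = 0.1 um2
        labels[50:70, 50:75] = 3  # 500 px = 5 um2
        ps = particles_from_labels(labels, pixel_size_nm=100.0)
        out = filter_particles(
            ps, SizeShapeFilter(0.05, 1.0, 0.0, 1.0)
        )
        assert out.ids == [2]

    def test_matches_brute_force_predicate(self, rng):
        ps = self._random_particles(rng)
        filt = SizeShapeFilter(0.05, 0.5, 0.5, 0.99)
        out = filter_particles(ps, filt)
        expected = [
            p.id
            for p in ps
            if filt.min_area_um2 <= p.area_um2 <= filt.max_area_um2
            and p.solidity >= filt.min_solidity
            and p.eccentricity <= filt.max_eccentricity
        ]
        assert out.ids == expected

    def test_idempotent(self, rng):
        ps = self._random_particles(rng)
        filt = SizeShapeFilter()
        once = filter_particles(ps, filt)
        twice = filter_particles(once, filt)
        assert twice.ids == once.ids


class TestDetectSomata:
    def _ellipse_image(self, a=20, b=10):
        from skimage import draw

        arr = np.zeros((128, 128))
        rr, cc = draw.ellipse(64, 64, a, b)
        arr[rr, cc] = 120.0
        return _img(arr, px=500.0, name="soma_marker"), np.pi * a * b

    def test_single_ellipse_detected_with_analytic_area(self):
        img, area_px = self._ellipse_image()
        lab = detect_somata(img, "soma_marker", ThresholdSpec("otsu"),
                            min_soma_area_um2=10.0)
        assert lab.n_labels == 1
        detected_px = int((lab.labels == 1).sum())
        assert detected_px == pytest.approx(area_px, rel=0.02)

    def test_empty_selection_keeps_nothing(self):
        img, _ = self._ellipse_image()
        lab = detect_somata(img, "soma_marker", ThresholdSpec("otsu"),
                            min_soma_area_um2=10.0, selection=[])
        assert lab.n_labels == 0

    def test_generator_field_one_to_one_centroid_match(self):
        from skimage import measure

        spec = SomaFieldSpec(seed=21, gaussian_sd=0.0, poisson_scaling=0.0)
        img, truth = generate_soma_field(spec)
        lab = detect_somata(img, "soma_marker",
                            ThresholdSpec("otsu", pre_smooth_sigma_px=2.0))
        assert lab.n_labels == spec.n_somata
        det = sorted(tuple(r.centroid) for r in measure.regionprops(lab.labels))
        true = sorted(
            tuple(r.centroid)
            for r in measure.regionprops(truth.masks["soma_marker"])
        )
        for (dr, dc), (tr, tc) in zip(det, true):
            assert abs(dr - tr) < 2 and abs(dc - tc) < 2

    def test_min_area_enforced(self):
        img, _ = self._ellipse_image(a=4, b=3)  # ~38 px = 9.4 um2 at 500 nm
        lab = detect_somata(img, "soma_marker", ThresholdSpec("otsu"),
                            min_soma_area_um2=50.0)
        assert lab.n_labels == 0


class TestCellROI:
    def test_user_mask_passthrough(self, rng):
        m = BinaryMask(rng.random((32, 32)) > 0.5, 65.0)
        roi = define_cell_roi("user_mask", user_mask=m)
        np.testing.assert_array_equal(roi.mask, m.mask)

    def test_hull_of_two_points_contains_segment_with_margin(self):
        m = np.zeros((64, 64), bool)
        m[10, 10] = m[50, 40] = True
        roi = define_cell_roi(
            "hull_of_structures",
            mitochondria=BinaryMask(m, 65.0, role="mitochondria"),
            margin_px=3,
        )
        assert roi.mask[10, 10] and roi.mask[50, 40]
        assert roi.mask[30, 25]  # midpoint of the segment
        assert roi.mask[10, 7]  # dilated by margin

    def test_hull_contains_all_structures(self, rng):
        mito = rng.random((64, 64)) < 0.02
        part = rng.random((64, 64)) < 0.01
        roi = define_cell_roi(
            "hull_of_structures",
            mitochondria=BinaryMask(mito, 65.0),
            particles=BinaryMask(part, 65.0),
            margin_px=5,
        )
        assert (roi.mask | ~mito).all() and (roi.mask | ~part).all()

    def test_empty_union_is_analysis_error(self):
        with pytest.raises(AnalysisError):
            define_cell_roi(
                "hull_of_structures",
                mitochondria=BinaryMask(np.zeros((8, 8), bool), 65.0),
            )
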