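import numpy as np
import pytest

from mmscope.channels import (
    FrameRejected,
    detect_channels,
    extract_channel_regions,
    fit_channel_vectors,
    interpolate_channels,
    ridge_filter,
    threshold_li,
)
from mmscope.config import PipelineConfig
from mmscope.modality import Modality
from mmscope.synthetic import FixtureSpec, generate_series


def exhaustive_li(image):
    """Independent oracle: exhaustive minimum-cross-entropy search over all
    candidate thresholds (midpoints between consecutive distinct values)."""
    v = np.asarray(image, dtype=np.float64).ravel()
    vals = np.unique(v)
    candidates = (vals[:-1] + vals[1:]) / 2.0
    best_t, best_eta = None, np.inf
    for t in candidates:
        eta = 0.0
        for cls in (v[v <= t], v[v > t]):
            if cls.size and cls.sum() > 0:
                eta -= cls.sum() * np.log(cls.mean())
        if eta < best_eta:
            best_t, best_eta = t, eta
    return best_t


class TestRidgeFilter:
    def test_flat_image_gives_no_response(self):
        img = np.full((40, 40), 100.0)
        for modality in Modality:
            response = ridge_filter(img, modality)
            assert response.max() == pytest.approx(0.0, abs=1e-12)

    def test_dark_line_response_peaks_on_line_centre_brightfield(self):
        img = np.full((41, 41), 200.0)
        img[:, 19:22] = 100.0  # 3-px dark vertical line
        response = ridge_filter(img, Modality.BRIGHTFIELD)
        interior = response[5:-5]  # away from boundary effects
        cols = np.argmax(interior, axis=1)
        assert np.all((cols >= 19) & (cols <= 21))

    def test_step_edge_response_peaks_on_edge_phase(self):
        img = np.full((20, 40), 10.0)
        img[:, 20:] = 200.0
        response = ridge_filter(img, Modality.PHASE)
        cols = np.argmax(response[2:-2], axis=1)
        assert np.all((cols >= 19) & (cols <= 20))


class TestThresholdLi:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_cross_entropy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = np.concatenate(
            [rng.normal(10, 8, 6000), rng.normal(200, 15, 2000)]
        )
        img = np.clip(np.round(img), 0, 255).astype(np.uint8).reshape(80, 100)
        t = threshold_li(img)
        t_oracle = exhaustive_li(img)
        np.testing.assert_array_equal(img > t, img > t_oracle)

    def test_bimodal_threshold_between_modes(self):
        img = np.array([[10] * 50 + [200] * 50], dtype=float)
        t = threshold_li(img)
        assert 10 < t < 200

    def test_single_bright_pixel_in_mask(self):
        img = np.zeros((10, 10))
        img[4, 7] = 255.0
        t = threshold_li(img)
        mask = img > t
        assert mask[4, 7] and mask.sum() == 1

    def test_decision_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(11)
        img = np.concatenate([rng.normal(20, 5, 500), rng.normal(180, 10, 300)]).reshape(20, 40)
        base = img > threshold_li(img)
        scaled = 3.5 * img + 40.0
        np.testing.assert_array_equal(scaled > threshold_li(scaled), base)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            threshold_li(np.full((5, 5), 3.0))


class TestExtractChannelRegions:
    def _outline(self, shape, r0, r1, c0, c1, thickness=2):
        mask = np.zeros(shape, dtype=bool)
        mask[r0 : r1 + 1, c0 : c1 + 1] = True
        mask[r0 + thickness : r1 + 1 - thickness, c0 + thickness : c1 + 1 - thickness] = False
        return mask

    def test_closed_outline_yields_interior(self):
        cfg = PipelineConfig(channel_area_range=(50, 50_000))
        mask = self._outline((60, 60), 5, 54, 20, 39)
        interiors = extract_channel_regions(mask, cfg)
        assert interiors.max() == 1
        rr, cc = np.nonzero(interiors)
        assert rr.min() > 5 and rr.max() < 54 and cc.min() > 20 and cc.max() < 39

    def test_small_gap_closed_by_dilation(self):
        cfg = PipelineConfig(channel_area_range=(50, 50_000))
        mask = self._outline((60, 60), 5, 54, 20, 39)
        mask[30:32, 20:22] = False  # 2-px breach, within the closing radius
        interiors = extract_channel_regions(mask, cfg)
        assert interiors.max() == 1

    def test_speck_removed_by_area_filter(self):
        cfg = PipelineConfig(channel_area_range=(50, 50_000))
        mask = np.zeros((60, 60), dtype=bool)
        mask[10, 10:15] = True  # 5-px speck
        interiors = extract_channel_regions(mask, cfg)
        assert interiors.max() == 0

    def test_empty_mask_yields_empty_result(self):
        assert extract_channel_regions(np.zeros((10, 10), bool)).max() == 0


class TestFitChannelVectors:
    def _interior(self, length, width=10):
        img = np.zeros((length + 20, width + 20), dtype=np.int32)
        img[10 : 10 + length, 10 : 10 + width] = 1
        return img

    @pytest.mark.parametrize(
        "length,scale,kept",
        [(250, 1.0, True), (50, 1.0, False), (150, 0.5, True), (450, 1.0, False)],
    )
    def test_length_filter_scales_with_scale_factor(self, length, scale, kept):
        cfg = PipelineConfig(scale_factor=scale)
        infos = fit_channel_vectors(self._interior(length), cfg)
        assert (len(infos) == 1) is kept

    def test_axis_vector_spans_the_region(self):
        infos = fit_channel_vectors(self._interior(200))
        info = infos[0]
        # the axis joins opposite corners, so its length is the diagonal and
        # the perpendicular extent is l*sin(theta) + w*cos(theta) + 1
        diag = np.hypot(199, 9)
        assert info.length_px == pytest.approx(diag, rel=0.02)
        expected_w = 199 * (9 / diag) + 9 * (199 / diag) + 1
        assert info.width_px == pytest.approx(expected_w, abs=1.5)
        assert info.axis_vector[0] > 0  # canonical orientation


class TestInterpolation:
    def _info_at(self, col, length=150.0, width=12.0):
        from mmscope.channels import ChannelInfo

        mask = np.zeros((250, 400), dtype=bool)
        r0 = int(125 - length / 2)
        c0 = int(col - width / 2)
        mask[r0 : r0 + int(length), c0 : c0 + int(width)] = True
        return ChannelInfo(
            id=0,
            centroid=(125.0, float(col)),
            axis_vector=(length, 0.0),
            width_px=width,
            mask=mask,
        )

    def test_two_channels_reject_frame(self):
        with pytest.raises(FrameRejected):
            interpolate_channels([self._info_at(100), self._info_at(140)], (250, 400))

    def test_single_gap_is_stamped(self):
        infos = [self._info_at(c) for c in (100, 120, 160)]  # spacing 20, one gap
        cs = interpolate_channels(infos, (250, 400))
        assert len(cs) == 4
        flags = [c.interpolated for c in cs.channels]
        assert flags == [False, False, True, False]
        assert cs.channels[2].centroid[1] == pytest.approx(140, abs=1)
        assert [c.id for c in cs.channels] == [1, 2, 3, 4]

    def test_complete_set_is_identity(self):
        infos = [self._info_at(c) for c in (100, 140, 180, 220)]
        cs = interpolate_channels(infos, (250, 400))
        assert len(cs) == 4
        assert not any(c.interpolated for c in cs.channels)
        assert cs.spacing_px == pytest.approx(40.0)

    def test_labels_are_disjoint_and_consecutive(self):
        infos = [self._info_at(c) for c in (100, 140, 220)]
        cs = interpolate_channels(infos, (250, 400))
        present = np.unique(cs.labels)
        assert list(present[present > 0]) == [c.id for c in cs.channels]


class TestDetectChannels:
    def test_fixture_channels_found_and_ordered(self, brightfield_series):
        spec, frames, gt = brightfield_series
        cs = detect_channels(frames[0].primary, Modality.BRIGHTFIELD)
        assert len(cs) == spec.n_channels
        cols = [c.centroid[1] for c in cs.channels]
        assert cols == sorted(cols)
        assert [c.id for c in cs.channels] == list(range(1, spec.n_channels + 1))
        assert cs.spacing_px == pytest.approx(spec.pitch, abs=1.0)
        # slight over-stamping keeps recall ~1
        det, tru = cs.labels > 0, gt.channel_labels[0] > 0
        recall = (det & tru).sum() / tru.sum()
        assert recall > 0.99

    def test_rotated_device_still_detected(self):
        spec = FixtureSpec(seed=5, n_frames=1, device_angle=10.0)
        frames, _ = generate_series(spec)
        cs = detect_channels(frames[0].primary, Modality.BRIGHTFIELD)
        assert len(cs) == spec.n_channels

    def test_phase_modality_detected(self, phase_series):
        spec, frames, _ = phase_series
        cs = detect_channels(frames[0].primary, Modality.PHASE)
        assert len(cs) == spec.n_channels

    def test_erased_channel_is_interpolated(self):
        spec = FixtureSpec(seed=4, n_frames=1)
        frames, gt = generate_series(spec)
        img = frames[0].primary.copy()
        m = gt.channel_labels[0] == 4
        rr, cc = np.nonzero(m)
        rng = np.random.default_rng(0)
        sl = (slice(rr.min() - 6, rr.max() + 7), slice(cc.min() - 6, cc.max() + 7))
        img[sl] = np.clip(
            np.round(200 + rng.normal(0, 5, img[sl].shape)), 0, 255
        ).astype(np.uint8)
        cs = detect_channels(img, Modality.BRIGHTFIELD)
        assert len(cs) == spec.n_channels
        interpolated = [c for c in cs.channels if c.interpolated]
        assert len(interpolated) == 1
        assert interpolated[0].id == 4
        assert interpolated[0].centroid[1] == pytest.approx(cc.mean(), abs=2)

    def test_ids_are_a_permutation_and_regions_disjoint(self, brightfield_series):
        _, frames, _ = brightfield_series
        cs = detect_channels(frames[0].primary, Modality.BRIGHTFIELD)
        ids = sorted(c.id for c in cs.channels)
        assert ids == list(range(1, len(cs) + 1))
        # label image can only hold one id per pixel; check each channel
        # has nonempty support
        for cid in ids:
            assert (cs.labels == cid).any()
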