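"""Segmentation-chain tests: differencing, thresholding, cleaning, measurement."""

import numpy as np
import pytest

import cytovisc as cv
from cytovisc.synthetic import render_frame, render_sequence


class TestThresholdMask:
    def test_bimodal_image_split_between_modes(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.5, 0.2, 0.8)
        mask, thr, degenerate = cv.threshold_mask(img)
        assert not degenerate
        assert 0.2 < thr < 0.8
        assert np.array_equal(mask, img > 0.5)

    def test_constant_image_degenerate(self):
        mask, thr, degenerate = cv.threshold_mask(np.full((8, 8), 0.3))
        assert degenerate and not mask.any() and np.isnan(thr)

    def test_nonfinite_rejected(self):
        img = np.zeros((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            cv.threshold_mask(img)

    def test_rendered_cell_pixels_recovered(self, acq_10kpa, render_spec):
        spec = cv.TraceSpec(true_viscosity=50.0, cell_radius=9.0, noise_sd=0.0)
        tr = cv.simulate_trace(spec, acq_10kpa)
        acq = cv.plan_geometry(9.0, acq_10kpa, render_spec)
        stack, gt = render_sequence(tr, acq, render_spec, seed=3, return_masks=True)
        k = len(tr) // 2
        mask = cv.clean_mask(cv.threshold_mask(stack[k])[0])
        inter = (mask & gt[k]).sum()
        union = (mask | gt[k]).sum()
        assert inter / union >= 0.95


class TestDifferenceFrames:
    def test_identical_frames_zero_mask(self):
        stack = np.stack([np.full((16, 16), 0.5)] * 2)
        assert not cv.difference_frames(stack, threshold=0.01).any()

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cv.difference_frames(np.zeros((1, 8, 8)))

    def test_advancing_tongue_changes_only_leading_band(
        self, acq_10kpa, render_spec_noiseless
    ):
        acq = cv.plan_geometry(9.0, acq_10kpa, render_spec_noiseless)
        axis, mouth = acq.require_geometry()
        f0 = render_frame(10.0, 9.0, acq, render_spec_noiseless)
        f1 = render_frame(11.5, 9.0, acq, render_spec_noiseless)  # +3 px
        mask = cv.difference_frames(np.stack([f0, f1]), threshold=0.1)[0]
        assert mask.any()
        # in-channel change is confined to the leading-edge band between the
        # old and new tip (the body side also changes: it shrinks as volume
        # is transferred into the tongue)
        px = render_spec_noiseless.pixel_size
        in_channel = mask[:, mouth:]
        rows, cols = np.nonzero(in_channel)
        rp_px = acq.pipette_radius / px
        assert in_channel.any()
        assert np.all(np.abs(rows - axis) <= rp_px)
        assert cols.min() >= 10.0 / px - rp_px - 1  # behind the old tip cap: static

    def test_pure_noise_pair_false_positive_rate(self):
        # Gaussian tail oracle: P(|d| > 5 sigma_d) ~ 5.7e-7 for d = n2 - n1
        rng = np.random.default_rng(1)
        sigma = 0.01
        a = rng.normal(0.5, sigma, (400, 400))
        b = rng.normal(0.5, sigma, (400, 400))
        mask = cv.difference_frames(np.stack([a, b]), threshold=5 * sigma * np.sqrt(2))
        assert mask.mean() < 3e-6


class TestCleanMask:
    def test_isolated_pixels_removed(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((64, 64), dtype=bool)
        idx = rng.integers(2, 62, (30, 2))
        mask[idx[:, 0], idx[:, 1]] = True
        assert not cv.clean_mask(mask, radius_px=1).any()

    def test_solid_disk_area_preserved(self):
        from skimage.morphology import disk

        mask = np.pad(disk(10).astype(bool), 5)
        cleaned = cv.clean_mask(mask, radius_px=2)
        assert abs(cleaned.sum() - mask.sum()) / mask.sum() < 0.05

    def test_salt_noise_removed_from_rendered_mask(self, acq_10kpa, render_spec_noiseless):
        acq = cv.plan_geometry(8.0, acq_10kpa, render_spec_noiseless)
        frame = render_frame(12.0, 8.0, acq, render_spec_noiseless)
        clean_ref = cv.clean_mask(cv.threshold_mask(frame)[0])
        rng = np.random.default_rng(3)
        noisy = cv.threshold_mask(frame)[0].copy()
        salt = rng.random(noisy.shape) < 0.01
        cleaned = cv.clean_mask(noisy | salt)
        inter = (cleaned & clean_ref).sum()
        union = (cleaned | clean_ref).sum()
        assert inter / union >= 0.98

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            cv.clean_mask(np.ones((4, 4), bool), radius_px=-1)


class TestMeasureCellRadius:
    @pytest.mark.parametrize("rc", [6.0, 8.0, 12.5])
    def test_rendered_radius_recovered_within_2pc(self, rc, acq_10kpa, render_spec_noiseless):
        acq = cv.plan_geometry(rc, acq_10kpa, render_spec_noiseless)
        frame = render_frame(0.0, rc, acq, render_spec_noiseless)
        fit = cv.measure_cell_radius(frame, acq)
        assert fit.radius_um == pytest.approx(rc, rel=0.02)
        assert fit.residual_um < 0.25

    def test_fully_entered_cell_raises(self, acq_10kpa, render_spec_noiseless):
        rc = 8.0
        acq = cv.plan_geometry(rc, acq_10kpa, render_spec_noiseless)
        l_full = cv.full_entry_length(rc, acq.pipette_radius)
        frame = render_frame(l_full, rc, acq, render_spec_noiseless)
        with pytest.raises(ValueError, match="no cell body"):
            cv.measure_cell_radius(frame, acq)


class TestMeasureLp:
    def test_round_trip_within_one_pixel(self, acq_10kpa, render_spec_noiseless):
        spec = cv.TraceSpec(true_viscosity=60.0, cell_radius=9.5, noise_sd=0.0)
        tr = cv.simulate_trace(spec, acq_10kpa)
        acq = cv.plan_geometry(9.5, acq_10kpa, render_spec_noiseless)
        stack = render_sequence(tr, acq, render_spec_noiseless)
        out = cv.measure_Lp(stack, acq, cell_id="rt")
        assert np.max(np.abs(out.lengths - tr.lengths)) <= acq.pixel_size

    def test_first_frame_zero(self, acq_10kpa, render_spec_noiseless):
        acq = cv.plan_geometry(9.0, acq_10kpa, render_spec_noiseless)
        frame = render_frame(0.0, 9.0, acq, render_spec_noiseless)
        out = cv.measure_Lp(np.stack([frame, frame]), acq, cell_radius_um=9.0)
        assert out.lengths[0] == 0.0

    def test_constant_advance_slope(self, acq_10kpa, render_spec_noiseless):
        # tongue advancing exactly 2 px/frame -> slope 2 * pixel_size * frame_rate
        acq = cv.plan_geometry(9.0, acq_10kpa, render_spec_noiseless)
        px, fr = acq.pixel_size, acq.frame_rate
        lps = 2 * px * np.arange(12)
        frames = np.stack(
            [render_frame(lp, 9.0, acq, render_spec_noiseless) for lp in lps]
        )
        out = cv.measure_Lp(frames, acq, cell_radius_um=9.0)
        slope = np.polyfit(out.times, out.lengths, 1)[0]
        assert slope == pytest.approx(2 * px * fr, rel=0.02)

    def test_calibration_equivariance(self, acq_10kpa):
        # halving the resolution at doubled pixel size leaves µm outputs
        # unchanged within one (coarse) pixel equivalent
        from dataclasses import replace

        spec = cv.TraceSpec(true_viscosity=80.0, cell_radius=9.0, noise_sd=0.0)
        tr = cv.simulate_trace(spec, acq_10kpa)
        fine = cv.RenderSpec(photon_noise_sd=0.0)
        coarse = cv.RenderSpec(
            image_size=(fine.image_size[0] // 2, fine.image_size[1] // 2),
            pixel_size=fine.pixel_size * 2, photon_noise_sd=0.0,
        )
        out = {}
        for name, rs, acq0 in (
            ("fine", fine, acq_10kpa),
            ("coarse", coarse, replace(acq_10kpa, pixel_size=1.0)),
        ):
            acq = cv.plan_geometry(9.0, acq0, rs)
            stack = cv.synthetic.render_sequence(tr, acq, rs)
            out[name] = cv.measure_Lp(stack, acq, cell_id=name)
        assert out["fine"].cell_radius == pytest.approx(out["coarse"].cell_radius, abs=1.0)
        assert np.max(np.abs(out["fine"].lengths - out["coarse"].lengths)) <= 1.0 + 0.5

    def test_smoothed_trace_monotone_until_full_entry(self, acq_10kpa, render_spec):
        spec = cv.TraceSpec(true_viscosity=60.0, cell_radius=9.0, noise_sd=0.2)
        tr = cv.simulate_trace(spec, acq_10kpa, seed=9)
        acq = cv.plan_geometry(9.0, acq_10kpa, render_spec)
        stack = cv.synthetic.render_sequence(tr, acq, render_spec, seed=9)
        out = cv.measure_Lp(stack, acq, cell_id="m")
        win = 5
        sm = np.convolve(out.lengths, np.ones(win) / win, mode="valid")
        assert np.all(np.diff(sm) > -acq.pixel_size)
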