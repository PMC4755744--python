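"""Forward encoding model: basis, weights, inversion, tuning curves."""

import numpy as np
import pytest

from popdecode import encoder, taskgen
from popdecode.encoder import TuningCurve


class TestBasis:
    def test_peak_and_zero_crossing(self):
        basis = encoder.build_basis()
        for k, c in enumerate(basis.centers_deg):
            vals = basis.evaluate(np.array([c, (c + 90.0) % 180.0]))
            assert vals[k, 0] == pytest.approx(1.0)
            assert vals[k, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fwhm_matches_grid_oracle(self):
        """FWHM of the power-15 basis equals the value found by brute-force
        search on a 0.01-degree grid (and the closed form)."""
        basis = encoder.build_basis()
        c = basis.centers_deg[0]
        tilts = np.arange(0.0, 90.0, 0.01)
        vals = basis.evaluate((c + tilts) % 180.0)[0]
        half_width = tilts[np.argmin(np.abs(vals - 0.5))]
        closed_form = np.rad2deg(np.arccos(0.5 ** (1 / 15)))
        assert 2 * half_width == pytest.approx(2 * closed_form, abs=0.05)

    def test_periodicity(self):
        basis = encoder.build_basis()
        theta = np.array([13.0, 77.5, 130.0])
        assert np.allclose(basis.evaluate(theta),
                           basis.evaluate((theta + 180.0) % 180.0))


class TestDesign:
    def test_column_at_center_equals_basis_profile(self):
        basis = encoder.build_basis()
        c = basis.centers_deg[3]
        C = encoder.build_design([c], basis, add_constant=False)
        assert np.allclose(C[:, 0], basis.evaluate(np.array([c]))[:, 0])

    def test_full_coverage_rank(self):
        basis = encoder.build_basis()
        C = encoder.build_design(basis.centers_deg, basis, add_constant=False)
        assert np.linalg.matrix_rank(C) == 16

    def test_dimensions(self):
        basis = encoder.build_basis()
        oris = np.tile(basis.centers_deg, 3)
        assert encoder.build_design(oris, basis, False).shape == (16, 48)
        assert encoder.build_design(oris, basis, True).shape == (17, 48)

    def test_out_of_range_rejected(self):
        basis = encoder.build_basis()
        with pytest.raises(ValueError):
            encoder.build_design([185.0], basis)


class TestWeightsAndInversion:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        basis = encoder.build_basis()
        # 16 distinct orientations identify exactly 16 regressors, so the
        # full-rank design here omits the constant row
        C1 = encoder.build_design(np.tile(basis.centers_deg, 4), basis,
                                  add_constant=False)
        W0 = rng.standard_normal((20, 16))
        B1 = W0 @ C1
        W = encoder.estimate_weights(B1, C1)
        assert np.allclose(W, W0, atol=1e-8)
        # and the full inversion returns the design regressor values exactly
        C2 = encoder.invert_channels(W, B1)
        assert np.allclose(C2, C1, atol=1e-8)

    def test_weights_match_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        C1 = rng.standard_normal((5, 40))
        B1 = rng.standard_normal((7, 40))
        W = encoder.estimate_weights(B1, C1)
        oracle = np.stack([np.linalg.lstsq(C1.T, B1[s], rcond=None)[0]
                           for s in range(7)])
        assert np.allclose(W, oracle, atol=1e-10)

    def test_inversion_matches_lstsq_oracle(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((12, 5))
        B2 = rng.standard_normal((12, 9))
        C2 = encoder.invert_channels(W, B2)
        oracle = np.stack([np.linalg.lstsq(W, B2[:, k], rcond=None)[0]
                           for k in range(9)], axis=1)
        assert np.allclose(C2, oracle, atol=1e-10)

    def test_orthonormal_weights_reduce_to_projection(self):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.standard_normal((10, 4)))
        B2 = rng.standard_normal((10, 6))
        assert np.allclose(encoder.invert_channels(Q, B2), Q.T @ B2)


class TestRecenterAndSlope:
    def test_recenter_peaks_at_zero(self):
        basis = encoder.build_basis()
        n = 16
        # every trial: profile peaked at its own presented orientation
        C2 = np.stack([np.roll(basis.evaluate(basis.centers_deg[:1])[:, 0], k)
                       for k in range(n)], axis=1)
        tc = encoder.recenter_average(C2, basis.centers_deg, basis.centers_deg)
        assert tc.offsets_deg[np.argmax(tc.values)] == 0.0

    def test_full_cycle_shift_is_identity(self):
        rng = np.random.default_rng(4)
        prof = rng.standard_normal((16, 1))
        centers = encoder.build_basis().centers_deg
        a = encoder.recenter_average(prof, np.array([centers[0]]), centers)
        b = encoder.recenter_average(prof, np.array([(centers[0] + 180.0)
                                                     % 180.0]), centers)
        assert np.allclose(a.values, b.values)

    def test_random_labels_flatten_curve(self):
        rng = np.random.default_rng(5)
        centers = encoder.build_basis().centers_deg
        prof = np.tile(np.cos(np.deg2rad(2 * centers))[:, None], (1, 4000))
        labels = rng.choice(centers, size=4000)
        tc = encoder.recenter_average(prof, labels, centers)
        assert np.abs(tc.values).max() < 0.05

    def test_slope_of_cosine_matches_polyfit_oracle(self):
        centers = encoder.build_basis().centers_deg
        offsets = np.sort(((centers - centers[0]) + 90) % 180 - 90)
        vals = np.cos(np.deg2rad(2 * offsets))
        curve = TuningCurve(offsets, vals)
        slope = encoder.tuning_slope(curve, smooth_ms=0)
        mags = np.unique(np.abs(offsets))
        folded = [vals[np.abs(offsets) == m].mean() for m in mags]
        oracle = np.polyfit(-mags, folded, 1)[0]
        assert slope == pytest.approx(oracle, abs=1e-12)

    def test_slope_zero_for_flat_curve_and_antisymmetric(self):
        offsets = np.linspace(-78.75, 90, 16)
        flat = TuningCurve(offsets, np.ones(16))
        assert encoder.tuning_slope(flat, smooth_ms=0) == pytest.approx(0.0)
        vals = np.cos(np.deg2rad(2 * offsets))
        up = encoder.tuning_slope(TuningCurve(offsets, vals), smooth_ms=0)
        down = encoder.tuning_slope(TuningCurve(offsets, -vals), smooth_ms=0)
        assert up == pytest.approx(-down)


class TestTemplateInterpolation:
    def test_constant_input_constant_output(self):
        angles = np.array([10, 40, 70, 100, 130, 150, 160, 170.0])
        out = encoder.interpolate_template_channels(
            np.ones(8), angles, np.arange(0, 180, 11.25))
        assert np.allclose(out, 1.0)

    def test_midpoint_is_mean(self):
        angles = np.array([0.0, 40.0])
        vals = np.array([1.0, 3.0])
        out = encoder.interpolate_template_channels(vals, angles,
                                                    np.array([20.0]))
        assert out[0] == pytest.approx(2.0)

    def test_wraparound_matches_bruteforce_oracle(self):
        """The segment from the largest back to the smallest angle follows
        circular linear interpolation."""
        angles = np.array([20.0, 160.0])
        vals = np.array([2.0, 6.0])
        target = 175.0  # 15 deg past 160, gap is 40 deg (160 -> 20+180)
        expect = 6.0 + (2.0 - 6.0) * 15.0 / 40.0
        out = encoder.interpolate_template_channels(vals, angles,
                                                    np.array([target]))
        assert out[0] == pytest.approx(expect)

    def test_duplicate_angles_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            encoder.interpolate_template_channels(
                np.ones(3), np.array([10.0, 10.0, 50.0]), np.array([30.0]))

    def test_matrix_equals_function(self):
        rng = np.random.default_rng(6)
        angles = np.sort(rng.choice(np.arange(0, 180, 11.25), 8,
                                    replace=False))
        target = np.arange(0, 180, 11.25)
        vals = rng.standard_normal(8)
        M = encoder.interpolation_matrix(angles, target)
        assert np.allclose(
            M @ vals,
            encoder.interpolate_template_channels(vals, angles, target))


class TestDecodeTimecourse:
    def test_static_code_recovered_in_window(self, stim_epochs):
        res = encoder.decode_timecourse(stim_epochs, scheme="stimulus")
        t = res.times_ms
        pre = res.slope[t < -50]
        post = res.slope[(t > 100) & (t < 400)]
        assert post.mean() > 5 * max(np.abs(pre).std(), 1e-9)
        assert abs(pre.mean()) < 3 * np.abs(pre).std()

    def test_shuffled_labels_give_null_slope(self, stim_epochs):
        rng = np.random.default_rng(0)
        labels = rng.permutation(
            stim_epochs.trials["stimulus_deg"].to_numpy())
        res = encoder.decode_timecourse(stim_epochs, scheme="stimulus",
                                        labels=labels)
        t = res.times_ms
        post = res.slope[(t > 100) & (t < 400)]
        null_scale = np.abs(res.slope[t < -50]).std()
        assert abs(post.mean()) < 5 * null_scale

    def test_template_scheme_window_specific(self, make_epochs):
        """A template code confined to -100..300 ms elevates the
        template-scheme slope in that window only."""
        ep = make_epochs(seed=21, stim_gain=0.0, template_gain=0.6,
                         template_window_ms=(-100.0, 300.0))
        res = encoder.decode_timecourse(ep, scheme="template")
        t = res.times_ms
        inside = res.slope[(t > -50) & (t < 250)].mean()
        outside = res.slope[t > 450].mean()
        assert inside > 3 * abs(outside)

    def test_all_gains_zero_slope_null(self, make_epochs):
        ep = make_epochs(seed=22, stim_gain=0.0)
        res = encoder.decode_timecourse(ep, scheme="stimulus")
        assert abs(res.slope.mean()) < 3 * res.slope.std()


class TestMultiSubjectRecovery:
    def test_group_tuning_peak_and_positive_slope(self, make_epochs):
        """Across 8 simulated subjects the mean tuning curve peaks at 0 deg
        and the in-window slope is positive (one-sided t)."""
        from scipy import stats as sps
        slopes, peaks = [], []
        for s in range(8):
            ep = make_epochs(seed=30 + s)
            res = encoder.decode_timecourse(ep, scheme="stimulus")
            t = res.times_ms
            win = (t > 100) & (t < 400)
            slopes.append(res.slope[win].mean())
            curve_win = res.tuning.values[:, win].mean(axis=1)
            peaks.append(res.tuning.offsets_deg[np.argmax(curve_win)])
        tstat, p = sps.ttest_1samp(slopes, 0.0, alternative="greater")
        assert p < 0.01
        assert np.median(np.abs(peaks)) <= 11.25
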