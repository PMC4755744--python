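"""Mahalanobis RDMs, geometry fits, MDS and nuisance regression."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from popdecode import encoder, rsa


def _simplex16():
    return rsa.circular_simplex(5.625 + 11.25 * np.arange(16))


class TestConditionMeans:
    def test_two_identical_trials_zero_covariance(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((4, 3, 2))
        data = np.repeat(base, 4, axis=0)          # 4 identical per condition
        labels = np.repeat(np.arange(4), 4)
        cm = rsa.condition_mean_split(data, labels)
        # residuals are exactly zero; shrinkage floors at the (zero) diagonal
        assert np.allclose(cm.covariance, 0.0)
        for s in range(2):
            assert np.allclose(cm.means[s], base)

    def test_split_means_converge_with_trial_count(self):
        rng = np.random.default_rng(1)
        errs = []
        for n in (8, 128):
            data = 1.0 + rng.standard_normal((n * 2, 4, 1))
            labels = np.repeat([0, 1], n)
            cm = rsa.condition_mean_split(data, labels)
            errs.append(np.abs(cm.means[0] - cm.means[1]).mean())
        assert errs[1] < errs[0]

    def test_empty_condition_rejected(self):
        data = np.random.default_rng(2).standard_normal((4, 3, 1))
        with pytest.raises(ValueError, match="fewer than 2"):
            rsa.condition_mean_split(data, np.array([0, 0, 0, 1]))


class TestMahalanobisRDM:
    def test_identity_covariance_equals_euclidean(self):
        rng = np.random.default_rng(3)
        means = rng.standard_normal((6, 5))
        rdm = rsa.mahalanobis_rdm(means, np.eye(5))
        assert np.allclose(rdm, squareform(pdist(means)))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(4)
        means = rng.standard_normal((5, 4))
        A = rng.standard_normal((4, 4))
        rdm = rsa.mahalanobis_rdm(means, A @ A.T + 4 * np.eye(4))
        assert np.allclose(rdm, rdm.T)
        assert np.allclose(np.diag(rdm), 0)
        assert (rdm >= 0).all()

    def test_three_condition_hand_oracle(self):
        """Known 2x2 covariance: d = sqrt(diff' inv(S) diff) by hand."""
        means = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        Sinv = np.linalg.inv(S)
        rdm = rsa.mahalanobis_rdm(means, S)
        for a in range(3):
            for b in range(3):
                d = means[a] - means[b]
                assert rdm[a, b] == pytest.approx(np.sqrt(d @ Sinv @ d))

    def test_singular_covariance_rejected(self):
        means = np.zeros((3, 2))
        with pytest.raises(ValueError, match="positive-definite"):
            rsa.mahalanobis_rdm(means, np.zeros((2, 2)))


class TestCrossTemporalRDMCorrelation:
    def test_identical_rdms_correlate_one(self):
        rng = np.random.default_rng(5)
        rdms = np.abs(rng.standard_normal((3, 6, 6)))
        rdms = (rdms + rdms.transpose(0, 2, 1)) / 2
        for t in range(3):
            np.fill_diagonal(rdms[t], 0)
        corr = rsa.rdm_crosstemporal_correlation(rdms, rdms)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_rdms_correlate_zero(self):
        rng = np.random.default_rng(6)
        rs = []
        for _ in range(200):
            a = squareform(rng.random(15))
            b = squareform(rng.random(15))
            rs.append(rsa.rdm_crosstemporal_correlation(a[None], b[None])[0, 0])
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_rdm_gives_nan(self):
        flat = np.zeros((1, 4, 4))
        rng = np.random.default_rng(7)
        other = squareform(rng.random(6))[None]
        corr = rsa.rdm_crosstemporal_correlation(flat, other)
        assert np.isnan(corr[0, 0])


class TestSimplexFit:
    def test_exact_simplex_coefficient_one(self):
        model = _simplex16()
        coef = rsa.simplex_fit(model, model)
        assert coef == pytest.approx(1.0)

    def test_scaling_linearity(self):
        model = _simplex16()
        assert rsa.simplex_fit(3.0 * model, model) == pytest.approx(3.0)

    def test_random_rdm_coefficient_zero(self):
        rng = np.random.default_rng(8)
        model = _simplex16()
        coefs = [rsa.simplex_fit(squareform(rng.random(120)), model)
                 for _ in range(200)]
        assert abs(np.mean(coefs)) < 0.01


class TestMDS:
    def test_circular_simplex_embeds_on_ordered_circle(self):
        """The exact circular simplex embeds as a circle: radii equal and
        angular order matches the condition order."""
        coords = rsa.mds_embed(_simplex16())
        radii = np.linalg.norm(coords, axis=1)
        assert radii.std() / radii.mean() < 0.05
        ang = np.unwrap(np.arctan2(coords[:, 1], coords[:, 0]))
        steps = np.diff(ang)
        assert (steps > 0).all() or (steps < 0).all()

    def test_zero_matrix_collapses(self):
        coords = rsa.mds_embed(np.zeros((5, 5)))
        assert np.allclose(coords, 0)

    def test_equilateral_triangle(self):
        rdm = np.ones((3, 3)) - np.eye(3)
        coords = rsa.mds_embed(rdm)
        d = squareform(pdist(coords))
        off = d[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0], atol=1e-8)


class TestTemplateStimulusCorrelation:
    def test_shared_geometry_strongly_positive(self):
        angles = np.array([5.625, 28.125, 39.375, 73.125, 95.625, 118.125,
                           140.625, 163.125])
        model = rsa.circular_simplex(angles)
        out = rsa.template_stimulus_rdm_correlation(
            model[None], (2 * model)[None], angles, angles)
        assert out["map"][0, 0] == pytest.approx(1.0)

    def test_mismatched_angle_sets_rejected(self):
        a = np.arange(8) * 11.25
        b = a + 5.0
        with pytest.raises(ValueError, match="match"):
            rsa.template_stimulus_rdm_correlation(
                np.zeros((1, 8, 8)), np.zeros((1, 8, 8)), a, b)

    def test_unrelated_geometries_near_zero(self):
        rng = np.random.default_rng(9)
        angles = np.arange(8) * 22.5 + 5.625
        rs = []
        for _ in range(200):
            a = squareform(rng.random(28))[None]
            b = squareform(rng.random(28))[None]
            rs.append(rsa.template_stimulus_rdm_correlation(
                a, b, angles, angles)["map"][0, 0])
        assert abs(np.mean(rs)) < 0.05


class TestDistanceRDMRegression:
    DELTAS = np.sort(((11.25 * np.arange(16)) + 90) % 180 - 90)

    def test_unsigned_value_distance_worked_examples(self):
        """d(0, -22.5) = 22.5 while d(-22.5, +22.5) = 0."""
        d = rsa.unsigned_value_distance(np.array([0.0, -22.5, 22.5]))
        assert d[0, 1] == pytest.approx(22.5)
        assert d[1, 2] == pytest.approx(0.0)

    def test_pure_simplex_gives_zero_nuisance(self):
        data = rsa.circular_simplex(self.DELTAS)
        out = rsa.distance_rdm_regression(data, self.DELTAS,
                                          response_freq=None)
        assert out["simplex"] == pytest.approx(1.0, abs=1e-8)
        assert out["unsigned_value"] == pytest.approx(0.0, abs=1e-8)

    def test_response_frequency_nuisance_captured(self):
        freq = 0.7 * np.exp(4.5 * (np.cos(np.deg2rad(2 * self.DELTAS)) - 1))
        data = rsa.response_frequency_distance(freq)
        out = rsa.distance_rdm_regression(data, self.DELTAS,
                                          response_freq=freq)
        assert out["response_frequency"] == pytest.approx(1.0, abs=1e-6)
        assert abs(out["simplex"]) < 1e-6


class TestGeometryDissociation:
    def test_rotating_patterns_static_geometry(self, make_epochs):
        """The key dissociation: a rotating stimulus code produces dynamic
        pattern decoding, yet the RDM correlation stays high off-diagonal
        (the geometry is time-stable even though the patterns are not)."""
        ep = make_epochs(seed=95, stim_gain=0.8, stim_dynamics="rotating",
                         stim_rotation_period_ms=400.0)
        data = encoder.preprocess(ep, "stimulus")
        cm = rsa.condition_mean_split(data,
                                      ep.trials["stimulus_deg"].to_numpy())
        rdm0 = rsa.rdm_timecourse(cm.means[0], cm.covariance)
        rdm1 = rsa.rdm_timecourse(cm.means[1], cm.covariance)
        corr = rsa.rdm_crosstemporal_correlation(rdm0, rdm1)
        t = ep.times_ms
        win = (t > 100) & (t < 450)
        block = corr[np.ix_(win, win)]
        off = block[~np.eye(win.sum(), dtype=bool)]
        # off-diagonal RDM correlation stays comparable to the diagonal
        assert off.mean() > 0.5 * np.diag(block).mean()
        assert off.mean() > 0.2
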