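"""Targeted dimensionality reduction and sign-axis analyses."""

import numpy as np
import pytest
from scipy.linalg import polar

from popdecode import statespace, taskgen


class TestPCA:
    def test_rank5_data_concentrates_variance(self, small_trials):
        rng = np.random.default_rng(0)
        n, ns, nt = len(small_trials), 12, 20
        loadings = rng.standard_normal((ns, 5))
        factors = rng.standard_normal((n, 5, nt))
        ep = taskgen.SensorEpochs(
            data=np.einsum("sk,nkt->nst", loadings, factors),
            times_ms=np.arange(nt) * 10.0, trials=small_trials)
        red = statespace.reduce_dimensionality(ep, n_components=12,
                                               smooth_ms=0.0)
        ev = red["explained_variance"]
        assert ev[5:].sum() < 1e-8 * ev[:5].sum()

    def test_variances_match_eigendecomposition_oracle(self, stim_epochs):
        red = statespace.reduce_dimensionality(stim_epochs, n_components=10,
                                               smooth_ms=0.0)
        avg = stim_epochs.data.mean(axis=0).T          # time x sensors
        centered = avg - avg.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(
            centered.T @ centered / (len(centered) - 1)))[::-1]
        assert np.allclose(red["explained_variance"], eigvals[:10], rtol=1e-8)

    def test_too_few_sensors_warns_and_reduces(self, small_trials):
        rng = np.random.default_rng(1)
        ep = taskgen.SensorEpochs(
            data=rng.standard_normal((len(small_trials), 6, 10)),
            times_ms=np.arange(10) * 10.0, trials=small_trials)
        with pytest.warns(UserWarning, match="reducing"):
            red = statespace.reduce_dimensionality(ep, n_components=30,
                                                   smooth_ms=0.0)
        assert red["loadings"].shape == (6, 6)


class TestTaskRegressors:
    def test_sign_axis_worked_values(self, default_trials):
        """sin(2*11.25 deg) = 0.38, antisymmetric; zero at 0 and +/-90."""
        X, names = statespace.build_task_regressors(default_trials)
        sign = X[:, names.index("distance_sign")]
        delta = default_trials["signed_distance_deg"].to_numpy()
        assert sign[np.isclose(delta, 11.25)][0] == pytest.approx(0.38, abs=5e-3)
        assert sign[np.isclose(delta, -11.25)][0] == pytest.approx(-0.38,
                                                                   abs=5e-3)
        assert np.allclose(sign[np.isclose(delta, 0.0)], 0.0)
        assert np.allclose(sign[np.isclose(delta, 90.0)], 0.0, atol=1e-12)

    def test_magnitude_axis_worked_values(self, default_trials):
        X, names = statespace.build_task_regressors(default_trials)
        mag = X[:, names.index("distance_magnitude")]
        delta = default_trials["signed_distance_deg"].to_numpy()
        for d in (11.25, -11.25):
            assert mag[np.isclose(delta, d)][0] == pytest.approx(0.92,
                                                                 abs=5e-3)
        assert np.allclose(mag[np.isclose(delta, 0.0)], 1.0)
        assert np.allclose(mag[np.isclose(delta, 90.0)], -1.0)


class TestOrthogonalization:
    def test_orthonormal_input_unchanged(self):
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.standard_normal((12, 6)))
        assert np.allclose(statespace.symmetric_orthogonalize(Q), Q)

    def test_output_orthonormal(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            B = rng.standard_normal((30, 6))
            Q = statespace.symmetric_orthogonalize(B)
            assert np.allclose(Q.T @ Q, np.eye(6), atol=1e-10)

    def test_matches_polar_decomposition_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            B = rng.standard_normal((30, 6))
            U, _ = polar(B)
            assert np.allclose(statespace.symmetric_orthogonalize(B), U,
                               atol=1e-10)

    def test_rank_deficient_rejected(self):
        B = np.zeros((10, 3))
        B[:, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            statespace.symmetric_orthogonalize(B)


class TestProjection:
    def test_zero_test_data_zero_projection(self):
        rng = np.random.default_rng(5)
        axes = statespace.TaskAxes(
            axes=rng.standard_normal((4, 10, 6)),
            valid=np.ones(4, dtype=bool))
        out = statespace.project_condition_means(np.zeros((16, 10, 4)), axes)
        assert np.allclose(out, 0)

    def test_projection_linearity(self):
        rng = np.random.default_rng(6)
        axes = statespace.TaskAxes(
            axes=rng.standard_normal((4, 10, 6)),
            valid=np.ones(4, dtype=bool))
        means = rng.standard_normal((16, 10, 4))
        assert np.allclose(statespace.project_condition_means(2 * means, axes),
                           2 * statespace.project_condition_means(means, axes))

    def test_sign_code_separates_on_sign_axis_only(self, make_epochs):
        """A sin(2*delta) sensor code separates +/- conditions on the sign
        axis and not on the orthogonal magnitude axis."""
        ep = make_epochs(seed=96, stim_gain=0.0, distance_gain=0.8,
                         distance_onset_ms=0.0, distance_components=("sign",))
        pr = statespace.task_axis_projection(ep, n_components=24)
        div_sign = statespace.sign_axis_divergence(
            pr.projections, pr.condition_values, axis_index=5)
        div_mag = statespace.sign_axis_divergence(
            pr.projections, pr.condition_values, axis_index=4)
        t = ep.times_ms
        late = t > 100
        assert np.nanmean(np.abs(div_sign[:, late])) \
            > 5 * np.nanmean(np.abs(div_mag[:, late]))


class TestSignAxisDivergence:
    def test_antisymmetric_under_pair_swap(self):
        rng = np.random.default_rng(7)
        proj = rng.standard_normal((16, 6, 10))
        cond = np.sort(((11.25 * np.arange(16)) + 90) % 180 - 90)
        d1 = statespace.sign_axis_divergence(proj, cond)
        # swapping the roles of +tilt and -tilt flips the sign
        d2 = statespace.sign_axis_divergence(proj, -cond)
        assert np.allclose(d1, -d2)

    def test_magnitude_only_code_no_divergence(self, make_epochs):
        """A cos(2*delta)-only code (the accumulator signature) leaves the
        sign axis silent."""
        ep = make_epochs(seed=97, stim_gain=0.0, distance_gain=0.8,
                         distance_onset_ms=0.0,
                         distance_components=("magnitude",))
        pr = statespace.task_axis_projection(ep, n_components=24)
        div = statespace.sign_axis_divergence(pr.projections,
                                              pr.condition_values)
        # compare against the scale of the magnitude-axis response
        mag_idx = list(pr.axis_names).index("distance_magnitude")
        mag_scale = np.nanmax(np.abs(pr.projections[:, mag_idx, :]))
        assert np.nanmean(np.abs(div)) < 0.15 * mag_scale

    def test_injected_onset_recovered(self, make_epochs):
        """A sign code switched on at 350 ms produces divergence from
        ~350 ms (within smoothing blur) across simulated subjects."""
        divs = []
        for s in range(6):
            ep = make_epochs(seed=100 + s, stim_gain=0.4, distance_gain=0.6,
                             distance_onset_ms=350.0)
            pr = statespace.task_axis_projection(ep, n_components=24)
            divs.append(statespace.sign_axis_divergence(
                pr.projections, pr.condition_values))
        divs = np.stack(divs)
        res = statespace.sign_axis_divergence_test(divs, n_perm=300, seed=0)
        sig = res.significant_mask
        t = divs.shape[-1]
        times = ep.times_ms
        assert sig.any()
        onset = times[np.flatnonzero(sig)[0]]
        assert abs(onset - 350.0) <= 48.0
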