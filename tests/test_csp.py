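"""CSP: covariance normalization, whitening path, oracle equivalence, features."""

import numpy as np
import pytest
from scipy import linalg

from midecode import MIEEGDataset, SynthConfig, csp_features, csp_fit, generate_mi_dataset
from midecode.csp import (
    CSPModel,
    average_covariance,
    load_csp_model,
    normalized_covariance,
    save_csp_model,
)


def random_dataset(rng, n_channels=4, n_trials=10, n_samples=100) -> MIEEGDataset:
    trials = rng.standard_normal((2 * n_trials, n_channels, n_samples))
    # give the classes different spatial structure
    scale = np.linspace(0.5, 2.0, n_channels)
    trials[:n_trials] *= scale[None, :, None]
    trials[n_trials:] *= scale[None, ::-1, None]
    return MIEEGDataset(
        trials=trials,
        labels=np.r_[np.ones(n_trials, int), np.full(n_trials, 2)],
        sampling_rate=128.0,
        channel_names=[f"c{i}" for i in range(n_channels)],
    )


class TestNormalizedCovariance:
    def test_identity_trial(self):
        np.testing.assert_allclose(
            normalized_covariance(np.eye(2, 3)), np.diag([0.5, 0.5]), atol=1e-15
        )

    def test_hand_computed_2x2(self):
        x = np.array([[1.0, 2.0], [0.0, 1.0]])
        # XX^T = [[5,2],[2,1]], trace 6 — but need channels < samples, pad with zeros
        x = np.hstack([x, np.zeros((2, 1))])
        expected = np.array([[5 / 6, 2 / 6], [2 / 6, 1 / 6]])
        np.testing.assert_allclose(normalized_covariance(x), expected)

    def test_single_channel_is_one(self):
        np.testing.assert_allclose(
            normalized_covariance(np.array([[1.0, -2.0, 3.0]])), [[1.0]]
        )

    def test_zero_trial_rejected(self):
        with pytest.raises(ValueError, match="zero total energy"):
            normalized_covariance(np.zeros((2, 10)))

    def test_psd_symmetric_unit_trace(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cov = normalized_covariance(rng.standard_normal((5, 40)))
            np.testing.assert_allclose(cov, cov.T)
            assert np.trace(cov) == pytest.approx(1.0, abs=1e-14)
            assert np.linalg.eigvalsh(cov).min() >= -1e-12


class TestAverageCovariance:
    def test_single_trial_identity_case(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((3, 30))
        np.testing.assert_allclose(average_covariance([t]), normalized_covariance(t))

    def test_elementwise_mean_of_diagonal_covariances(self):
        # trials constructed with orthogonal rows so covariances are diagonal
        t1 = np.vstack([np.sqrt(0.8) * np.r_[1, 0, 0, 0], np.sqrt(0.2) * np.r_[0, 1, 0, 0]])
        t2 = np.vstack([np.sqrt(0.6) * np.r_[1, 0, 0, 0], np.sqrt(0.4) * np.r_[0, 1, 0, 0]])
        np.testing.assert_allclose(
            average_covariance([t1, t2]), np.diag([0.7, 0.3]), atol=1e-15
        )

    def test_mean_trace_is_one(self):
        rng = np.random.default_rng(4)
        trials = [rng.standard_normal((6, 50)) for _ in range(50)]
        assert np.trace(average_covariance(trials)) == pytest.approx(1.0, abs=1e-12)

    def test_empty_and_inconsistent_rejected(self):
        with pytest.raises(ValueError):
            average_covariance([])
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="inconsistent"):
            average_covariance([rng.standard_normal((3, 20)), rng.standard_normal((4, 20))])


def diagonal_trials(var_a: float, var_b: float, n_samples: int = 64) -> np.ndarray:
    """One trial whose trace-normalized covariance is diag(var_a, var_b)."""
    u = np.zeros(n_samples); u[0] = 1.0
    v = np.zeros(n_samples); v[1] = 1.0
    return np.vstack([np.sqrt(var_a) * u, np.sqrt(var_b) * v])


class TestCSPFit:
    def test_analytic_diagonal_case(self):
        trials = np.stack([diagonal_trials(0.8, 0.2), diagonal_trials(0.2, 0.8)])
        data = MIEEGDataset(
            trials=trials, labels=np.array([1, 2]), sampling_rate=64.0,
            channel_names=["a", "b"],
        )
        model = csp_fit(data, n_pairs=1)
        np.testing.assert_allclose(sorted(model.eigvals, reverse=True), [0.8, 0.2], atol=1e-12)

    def test_whitening_identity_and_complementarity(self, small_dataset):
        model = csp_fit(small_dataset)
        composite = model.W @ (model.R1_bar + model.R2_bar) @ model.W.T
        np.testing.assert_allclose(composite, np.eye(model.n_channels), atol=1e-8)
        # class-2 whitened eigenvalues complement class-1's
        d2 = np.diag(model.W @ model.R2_bar @ model.W.T)
        np.testing.assert_allclose(model.eigvals + d2, 1.0, atol=1e-8)
        assert np.all(np.diff(model.eigvals) <= 1e-12)

    def test_both_class_covariances_diagonalized(self, small_dataset):
        model = csp_fit(small_dataset)
        for r in (model.R1_bar, model.R2_bar):
            m = model.W @ r @ model.W.T
            off = m - np.diag(np.diag(m))
            assert np.abs(off).max() < 1e-8

    def test_matches_generalized_eigenproblem_oracle(self):
        """Whitening-path result equals scipy's generic solver for R1 v = mu R v."""
        rng = np.random.default_rng(17)
        for n_channels in range(3, 9):
            data = random_dataset(rng, n_channels=n_channels)
            model = csp_fit(data, n_pairs=1)
            r = model.R1_bar + model.R2_bar
            mu, v = linalg.eigh(model.R1_bar, r)
            mu, v = mu[::-1], v[:, ::-1]
            np.testing.assert_allclose(model.eigvals, mu, atol=1e-8)
            for k in range(n_channels):
                a = model.W[k] / np.linalg.norm(model.W[k])
                b = v[:, k] / np.linalg.norm(v[:, k])
                assert abs(a @ b) > 1 - 1e-8

    def test_label_swap_reverses_eigenvalues(self, small_dataset):
        model = csp_fit(small_dataset)
        swapped = MIEEGDataset(
            trials=small_dataset.trials,
            labels=np.where(small_dataset.labels == 1, 2, 1),
            sampling_rate=small_dataset.sampling_rate,
            channel_names=small_dataset.channel_names,
        )
        model_swapped = csp_fit(swapped)
        np.testing.assert_allclose(model_swapped.eigvals, (1 - model.eigvals)[::-1], atol=1e-8)

    def test_channel_permutation_equivariance(self, small_dataset):
        perm = np.array([2, 0, 3, 1])
        permuted = MIEEGDataset(
            trials=small_dataset.trials[:, perm, :],
            labels=small_dataset.labels,
            sampling_rate=small_dataset.sampling_rate,
            channel_names=[small_dataset.channel_names[i] for i in perm],
        )
        m1 = csp_fit(small_dataset)
        m2 = csp_fit(permuted)
        np.testing.assert_allclose(m1.eigvals, m2.eigvals, atol=1e-8)
        # filters act identically on permuted data (up to sign)
        for k in range(4):
            a, b = m1.W[k][perm], m2.W[k]
            assert abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)) > 1 - 1e-8

    def test_recovers_true_mixing_patterns(self, planted_dataset):
        """Top/bottom CSP patterns align with the forward model's mu columns."""
        from midecode import bandpass_filter

        data, forward = planted_dataset
        model = csp_fit(bandpass_filter(data, 8, 13))
        patterns = model.patterns

        def cosine(a, b):
            return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))

        # class-1 trials attenuate source 0, so the top class-1-variance
        # component is the class-2 source and the bottom one the class-1 source
        assert cosine(patterns[:, 0], forward.mixing[:, 1]) > 0.95
        assert cosine(patterns[:, -1], forward.mixing[:, 0]) > 0.95

    def test_rank_deficiency_error_names_shrinkage_and_shrinkage_fixes_it(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((6, 1, 50))
        trials = np.repeat(base, 3, axis=1)  # linearly dependent channels
        data = MIEEGDataset(
            trials=trials, labels=np.r_[1, 1, 1, 2, 2, 2],
            sampling_rate=50.0, channel_names=["a", "b", "c"],
        )
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            csp_fit(data, n_pairs=1)
        model = csp_fit(data, n_pairs=1, shrinkage=1e-3)
        assert np.all(np.isfinite(model.W))

    def test_single_class_rejected(self, small_dataset):
        ones = MIEEGDataset(
            trials=small_dataset.trials[small_dataset.labels == 1],
            labels=small_dataset.labels[small_dataset.labels == 1],
            sampling_rate=small_dataset.sampling_rate,
            channel_names=small_dataset.channel_names,
        )
        with pytest.raises(ValueError, match="both classes"):
            csp_fit(ones)


class TestCSPFeatures:
    def identity_model(self) -> CSPModel:
        return CSPModel(
            W=np.eye(2), P=np.eye(2), eigvals=np.array([0.5, 0.5]),
            R1_bar=np.eye(2) / 2, R2_bar=np.eye(2) / 2, n_pairs=1,
        )

    def test_direct_variance_share(self):
        rng = np.random.default_rng(0)
        trial = np.vstack(
            [np.sqrt(3) * rng.standard_normal(4000), rng.standard_normal(4000)]
        )
        f = csp_features(self.identity_model(), trial)
        np.testing.assert_allclose(f, [0.75, 0.25], atol=0.02)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_normalization_and_scale_invariance(self, small_dataset):
        model = csp_fit(small_dataset)
        trial = small_dataset.trials[0]
        f = csp_features(model, trial)
        assert f.shape == (2 * model.n_pairs,)
        assert np.all(f >= 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(csp_features(model, 7.3 * trial), f, atol=1e-12)

    def test_log_variance_option(self, small_dataset):
        model = csp_fit(small_dataset)
        f = csp_features(model, small_dataset.trials[0])
        model.log_variance = True
        np.testing.assert_allclose(csp_features(model, small_dataset.trials[0]), np.log(f))

    def test_shape_mismatch_rejected(self, small_dataset):
        model = csp_fit(small_dataset)
        with pytest.raises(ValueError, match="incompatible"):
            csp_features(model, np.zeros((7, 100)))

    def test_class1_component_variances_follow_eigvals(self, small_dataset):
        """Under class-1 trials, projected variances are ordered like eigvals."""
        model = csp_fit(small_dataset)
        z_power = np.mean(
            [
                (model.W @ (t / np.linalg.norm(t))) ** 2
                for t in small_dataset.class_trials(1)
            ],
            axis=(0, 2),
        )
        assert np.all(np.diff(z_power) <= 1e-9)


def test_model_serialization_round_trip(tmp_path, small_dataset):
    model = csp_fit(small_dataset)
    save_csp_model(model, tmp_path / "model")
    loaded = load_csp_model(tmp_path / "model")
    np.testing.assert_allclose(loaded.W, model.W)
    np.testing.assert_allclose(loaded.eigvals, model.eigvals)
    assert loaded.n_pairs == model.n_pairs
    trial = small_dataset.trials[0]
    np.testing.assert_allclose(csp_features(loaded, trial), csp_features(model, trial))
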