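"""EM correctness for the spherical Gaussian mixture."""

import numpy as np
import pytest

from cidcharge import GmmParams, e_step, fit, log_likelihood, m_step

from oracles import naive_gmm_log_likelihood


def two_component_sample(rng, n=2000, separation=6.0, d=3, mixing=0.4):
    """Draw from a known spherical mixture; returns data and truth."""
    mu0 = np.zeros(d)
    mu1 = np.full(d, separation / np.sqrt(d))
    n1 = int(round(n * mixing))
    x0 = rng.normal(size=(n - n1, d)) + mu0
    x1 = rng.normal(size=(n1, d)) + mu1
    data = np.vstack([x0, x1])
    rng.shuffle(data)
    return data, (mu0, mu1, 1.0 - mixing, mixing)


class TestLogLikelihood:
    def test_single_point_at_mean_closed_form(self):
        params = GmmParams(means=[[0.0]], variances=[1.0], mixing=[1.0])
        assert log_likelihood(np.array([[0.0]]), params) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12
        )

    def test_duplicated_data_doubles_value(self, rng):
        params = GmmParams(means=[[0.0, 0.0], [2.0, 2.0]], variances=[1.0, 0.5], mixing=[0.3, 0.7])
        data = rng.normal(size=(20, 2))
        single = log_likelihood(data, params)
        double = log_likelihood(np.vstack([data, data]), params)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_matches_naive_direct_density(self, rng):
        for _ in range(10):
            k, d = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            params = GmmParams(
                means=rng.normal(size=(k, d)),
                variances=rng.uniform(0.5, 2.0, size=k),
                mixing=np.full(k, 1.0 / k),
            )
            data = rng.normal(size=(15, d))
            assert log_likelihood(data, params) == pytest.approx(
                naive_gmm_log_likelihood(data, params.means, params.variances, params.mixing),
                abs=1e-10,
            )

    def test_non_finite_data_rejected(self):
        params = GmmParams(means=[[0.0]], variances=[1.0], mixing=[1.0])
        with pytest.raises(ValueError):
            log_likelihood(np.array([[np.nan]]), params)


class TestEStep:
    def test_equidistant_point_splits_evenly(self):
        params = GmmParams(
            means=[[-1.0], [1.0]], variances=[1.0, 1.0], mixing=[0.5, 0.5]
        )
        resp = e_step(np.array([[0.0]]), params)
        np.testing.assert_allclose(resp, [[0.5, 0.5]], atol=1e-12)

    def test_dominant_component_near_its_mean(self):
        params = GmmParams(
            means=[[0.0], [12.0]], variances=[1.0, 1.0], mixing=[0.5, 0.5]
        )
        resp = e_step(np.array([[0.0]]), params)
        assert resp[0, 0] > 0.999

    def test_extreme_points_never_underflow_to_error(self):
        params = GmmParams(means=[[0.0], [1.0]], variances=[1e-3, 1e-3], mixing=[0.5, 0.5])
        resp = e_step(np.array([[1e6]]), params)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_ratio(self, rng):
        for _ in range(10):
            params = GmmParams(
                means=rng.normal(size=(3, 2)),
                variances=rng.uniform(0.5, 2.0, size=3),
                mixing=np.array([0.2, 0.3, 0.5]),
            )
            data = rng.normal(size=(8, 2))
            resp = e_step(data, params)
            for n, x in enumerate(data):
                dens = [
                    pk * np.exp(-np.sum((x - mu) ** 2) / (2 * v)) / (2 * np.pi * v)
                    for mu, v, pk in zip(params.means, params.variances, params.mixing)
                ]
                np.testing.assert_allclose(resp[n], np.array(dens) / sum(dens), atol=1e-12)


class TestMStep:
    def test_hard_responsibilities_give_cluster_means(self):
        data = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 10.0], [12.0, 10.0]])
        resp = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        params = m_step(data, resp)
        np.testing.assert_allclose(params.means, [[1.0, 0.0], [11.0, 10.0]], atol=1e-12)
        np.testing.assert_allclose(params.mixing, [0.5, 0.5], atol=1e-12)

    def test_uniform_responsibilities_give_global_mean(self):
        data = np.array([[0.0], [1.0], [5.0]])
        resp = np.full((3, 2), 0.5)
        params = m_step(data, resp)
        np.testing.assert_allclose(params.means, [[2.0], [2.0]], atol=1e-12)

    def test_hand_computed_weighted_update(self):
        data = np.array([[0.0], [1.0], [2.0], [3.0]])
        resp = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        params = m_step(data, resp)
        w0 = 0.9 + 0.8 + 0.2 + 0.1
        mu0 = (0.9 * 0 + 0.8 * 1 + 0.2 * 2 + 0.1 * 3) / w0
        var0 = (0.9 * (0 - mu0) ** 2 + 0.8 * (1 - mu0) ** 2 + 0.2 * (2 - mu0) ** 2 + 0.1 * (3 - mu0) ** 2) / w0
        assert params.means[0, 0] == pytest.approx(mu0, abs=1e-12)
        assert params.variances[0] == pytest.approx(var0, abs=1e-12)
        assert params.mixing[0] == pytest.approx(w0 / 4, abs=1e-12)

    def test_variance_floor_applied(self):
        data = np.array([[0.0], [0.0], [5.0]])
        resp = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        params = m_step(data, resp, var_floor=1e-6)
        assert params.variances[0] == pytest.approx(1e-6)


class TestFit:
    def test_k1_reproduces_closed_form(self, rng):
        data = rng.normal(size=(200, 2)) * 1.7 + 3.0
        result = fit(data, k=1, seed=0, n_restarts=2)
        np.testing.assert_allclose(result.params.means[0], data.mean(axis=0), atol=1e-9)
        expected_var = ((data - data.mean(axis=0)) ** 2).sum(axis=1).mean() / 2
        assert result.params.variances[0] == pytest.approx(expected_var, rel=1e-9)
        assert result.params.mixing[0] == pytest.approx(1.0)
        assert result.converged and result.n_iter <= 2

    def test_recovers_separated_components(self, rng):
        data, (mu0, mu1, p0, p1) = two_component_sample(rng, n=2000, separation=6.0)
        result = fit(data, k=2, seed=1)
        means = result.params.means
        order = np.argsort(means[:, 0])
        np.testing.assert_allclose(means[order][0], mu0, atol=0.1)
        np.testing.assert_allclose(means[order][1], mu1, atol=0.1)
        np.testing.assert_allclose(
            result.params.mixing[order], [p0, p1], atol=0.03
        )

    def test_trace_non_decreasing(self, rng):
        for seed in range(3):
            data, _ = two_component_sample(rng, n=400, separation=3.0)
            result = fit(data, k=2, seed=seed, n_restarts=3)
            trace = np.asarray(result.log_likelihood_trace)
            assert np.all(np.diff(trace) >= -1e-9)

    def test_responsibility_and_mixing_normalization(self, rng):
        data, _ = two_component_sample(rng, n=300)
        result = fit(data, k=2, seed=0)
        np.testing.assert_allclose(result.responsibilities.sum(axis=1), 1.0, atol=1e-12)
        assert abs(result.params.mixing.sum() - 1.0) <= 1e-12

    def test_label_permutation_leaves_likelihood_unchanged(self, rng):
        data, _ = two_component_sample(rng, n=300)
        result = fit(data, k=2, seed=0)
        p = result.params
        swapped = GmmParams(
            means=p.means[::-1].copy(), variances=p.variances[::-1].copy(),
            mixing=p.mixing[::-1].copy(),
        )
        assert log_likelihood(data, swapped) == pytest.approx(
            log_likelihood(data, p), rel=1e-12
        )

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit(rng.normal(size=(1, 2)), k=2)

    def test_agrees_with_sklearn_spherical_mixture(self, rng):
        """Independent cross-check: same model family, external fitter."""
        from sklearn.mixture import GaussianMixture

        data, _ = two_component_sample(rng, n=1500, separation=5.0)
        ours = fit(data, k=2, seed=0)
        ref = GaussianMixture(
            n_components=2, covariance_type="spherical", n_init=5, random_state=0
        ).fit(data)
        ours_means = ours.params.means[np.argsort(ours.params.means[:, 0])]
        ref_means = ref.means_[np.argsort(ref.means_[:, 0])]
        np.testing.assert_allclose(ours_means, ref_means, atol=0.05)
        ref_ll = ref.score(data) * len(data)
        assert ours.log_likelihood == pytest.approx(ref_ll, rel=1e-3)

    def test_serialization_round_trip(self, tmp_path, rng):
        import json

        data, _ = two_component_sample(rng, n=200)
        result = fit(data, k=2, seed=3)
        path = tmp_path / "fit.json"
        result.to_json(path)
        doc = json.loads(path.read_text())
        np.testing.assert_allclose(doc["means"], result.params.means)
        assert doc["seed"] == 3
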