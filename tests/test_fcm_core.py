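import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcmseg.exceptions import (
    DegenerateClusterError,
    InvalidConfigError,
    InvalidInputError,
)
from fcmseg.fcm_core import (
    FCMConfig,
    compute_distances,
    fcm_fit,
    objective,
    update_centers,
    update_membership,
)

from _oracles import naive_centers, naive_fcm, naive_membership, naive_objective


class TestComputeDistances:
    def test_identity_and_exact_cases(self):
        np.testing.assert_allclose(compute_distances([0.0], [0.0]), [[0.0]])
        d = compute_distances([0.2], [0.2, 0.7])
        np.testing.assert_allclose(d, [[0.0], [0.5]])

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.random(8)
        v = rng.random(3)
        d = compute_distances(x, v)
        expect = np.array([[abs(vi - xk) for xk in x] for vi in v])
        np.testing.assert_array_equal(d, expect)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(InvalidInputError):
            compute_distances([], [0.1])
        with pytest.raises(InvalidInputError):
            compute_distances([0.1], [])
        with pytest.raises(InvalidInputError):
            compute_distances([np.nan], [0.1])


class TestUpdateMembership:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([1.0, 1.0], [0.5, 0.5]),  # equidistant symmetry
            ([0.0, 3.0], [1.0, 0.0]),  # coincident-center rule
            ([1.0, 2.0], [0.8, 0.2]),  # 1/(1+(1/2)^2) = 0.8
        ],
    )
    def test_single_column_cases(self, column, expected):
        u = update_membership(np.array(column)[:, None], m=2.0)
        np.testing.assert_allclose(u[:, 0], expected)

    def test_multiple_coincident_centers_split_uniformly(self):
        u = update_membership(np.array([[0.0], [0.0], [2.0]]), m=2.0)
        np.testing.assert_allclose(u[:, 0], [0.5, 0.5, 0.0])

    def test_invalid_fuzzifier_rejected(self):
        with pytest.raises(InvalidConfigError):
            update_membership(np.ones((2, 2)), m=1.0)
        with pytest.raises(InvalidInputError):
            update_membership(-np.ones((2, 2)), m=2.0)

    @pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
    def test_matches_loop_oracle(self, m):
        rng = np.random.default_rng(10)
        d = rng.random((4, 20))
        d[2, 5] = 0.0  # force one coincident pixel
        u = update_membership(d, m)
        np.testing.assert_allclose(u, naive_membership(d, m), atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.random((3, 15))
        d[rng.random((3, 15)) < 0.05] = 0.0
        u = update_membership(d, m=2.0)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-9)
        assert np.all((u >= 0.0) & (u <= 1.0))


class TestUpdateCenters:
    def test_crisp_and_single_point_cases(self):
        u = np.array([[1.0, 1.0]])
        assert update_centers([0.1, 0.3], u, 2.0) == pytest.approx([0.2])
        u1 = np.array([[0.4], [0.6]])
        np.testing.assert_allclose(update_centers([0.4], u1, 2.0), [0.4, 0.4])

    def test_weighted_mean_case(self):
        x = [0.0, 1.0]
        u = np.array([[0.8, 0.2], [0.2, 0.8]])
        v = update_centers(x, u, 2.0)
        assert v[0] == pytest.approx(0.04 / 0.68)
        assert v[1] == pytest.approx(0.64 / 0.68)

    def test_degenerate_cluster_raises(self):
        u = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(DegenerateClusterError):
            update_centers([0.1, 0.9], u, 2.0)

    def test_matches_loop_oracle_and_stays_in_range(self):
        rng = np.random.default_rng(11)
        x = rng.random(20)
        u = rng.random((3, 20))
        u /= u.sum(axis=0)
        v = update_centers(x, u, 2.0)
        np.testing.assert_allclose(v, naive_centers(x, u, 2.0), atol=1e-12)
        assert np.all((v >= x.min()) & (v <= x.max()))


class TestObjective:
    def test_known_values(self):
        assert objective(np.eye(2), np.zeros((2, 2)), 2.0) == 0.0
        assert objective(
            np.array([[0.5], [0.5]]), np.array([[1.0], [1.0]]), 2.0
        ) == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(12)
        u = rng.random((3, 12))
        d = rng.random((3, 12))
        assert objective(u, d, 2.5) == pytest.approx(
            naive_objective(u, d, 2.5), abs=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            objective(np.ones((2, 3)), np.ones((3, 2)), 2.0)


class TestFcmFit:
    def test_well_separated_pairs(self):
        res = fcm_fit([0.0, 0.0, 10.0, 10.0], FCMConfig(c=2, seed=0))
        np.testing.assert_allclose(res.centers, [0.0, 10.0], atol=1e-6)
        own = res.membership[res.labels, np.arange(4)]
        assert np.all(own >= 0.99)
        assert res.converged

    def test_default_config_recorded(self):
        res = fcm_fit([0.0, 0.2, 0.8, 1.0], FCMConfig(c=2, seed=1))
        assert res.config.m == 2.0
        assert res.config.max_iter == 100
        assert res.config.epsilon == pytest.approx(1e-4)
        assert len(res.objective_trace) == res.n_iter

    def test_matches_independent_reference_loop(self):
        """Converged centers equal a naive re-implementation within 1e-6."""
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0.3, 0.03, 100), rng.normal(0.7, 0.03, 100)])
        init = np.array([0.1, 0.9])
        res = fcm_fit(x, FCMConfig(c=2, seed=0), init_centers=init)
        v_ref, _ = naive_fcm(x, 2, 2.0, 100, 1e-4, init)
        np.testing.assert_allclose(res.centers, np.sort(v_ref), atol=1e-6)

    def test_objective_trace_nonincreasing(self):
        rng = np.random.default_rng(5)
        x = rng.random(300)
        res = fcm_fit(x, FCMConfig(c=3, seed=5))
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_idempotent_at_fixed_point(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0.2, 0.02, 80), rng.normal(0.8, 0.02, 80)])
        cfg = FCMConfig(c=2, seed=6, epsilon=1e-7)
        res = fcm_fit(x, cfg)
        assert res.converged
        v = update_centers(x, res.membership, cfg.m)
        u = update_membership(compute_distances(x, v), cfg.m)
        assert np.max(np.abs(u - res.membership)) < cfg.epsilon

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        x = rng.random(50)
        perm = rng.permutation(50)
        init = np.array([0.2, 0.5, 0.9])
        res_a = fcm_fit(x, FCMConfig(c=3), init_centers=init)
        res_b = fcm_fit(x[perm], FCMConfig(c=3), init_centers=init)
        np.testing.assert_allclose(res_a.centers, res_b.centers, atol=1e-12)
        np.testing.assert_allclose(
            res_a.membership[:, perm], res_b.membership, atol=1e-12
        )
        assert res_a.objective_trace[-1] == pytest.approx(
            res_b.objective_trace[-1], abs=1e-12
        )

    def test_seeded_init_reproducible(self):
        rng = np.random.default_rng(8)
        x = rng.random(100)
        r1 = fcm_fit(x, FCMConfig(c=3, seed=9))
        r2 = fcm_fit(x, FCMConfig(c=3, seed=9))
        np.testing.assert_array_equal(r1.centers, r2.centers)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            FCMConfig(c=1)
        with pytest.raises(InvalidConfigError):
            FCMConfig(m=1.0)
        with pytest.raises(InvalidConfigError):
            FCMConfig(epsilon=0.0)
        with pytest.raises(InvalidConfigError):
            FCMConfig(init="magic")
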