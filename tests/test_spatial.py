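import numpy as np
import pytest

from fcmseg.exceptions import InvalidConfigError
from fcmseg.fcm_core import FCMConfig, compute_distances, fcm_fit
from fcmseg.metrics import classification_accuracy_sb
from fcmseg.phantom import PhantomSpec, generate_phantom
from fcmseg.spatial import (
    NeighborhoodSpec,
    effective_distance,
    neighborhood_weights,
    spatial_fcm_fit,
)

from _oracles import naive_effective_distance, naive_neighborhood_weights


class TestNeighborhoodWeights:
    def test_constant_image_gives_unit_weights(self):
        w = neighborhood_weights(np.full((5, 5), 0.3), sigma_g=0.1)
        np.testing.assert_array_equal(w.w, 1.0)

    def test_one_sigma_difference_gives_exp_minus_one(self):
        img = np.zeros((3, 3))
        img[1, 1] = 0.2
        w = neighborhood_weights(img, sigma_g=0.2)
        # every neighbor of the center differs by exactly sigma_g
        center = 1 * 3 + 1
        np.testing.assert_allclose(w.w[:, center], np.exp(-1.0))

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(2)
        img = rng.random((5, 5))
        w = neighborhood_weights(img, NeighborhoodSpec(radius=1), sigma_g=0.25)
        ref = naive_neighborhood_weights(img, radius=1, sigma_g=0.25)
        for k, pairs in ref.items():
            got = sorted((int(i), float(v)) for i, v in zip(w.neighbor_index[:, k], w.w[:, k]))
            exp = sorted(pairs)
            assert [i for i, _ in got] == [i for i, _ in exp]
            np.testing.assert_allclose(
                [v for _, v in got], [v for _, v in exp], atol=1e-12
            )

    def test_invalid_sigma_rejected(self):
        with pytest.raises(InvalidConfigError):
            neighborhood_weights(np.zeros((4, 4)), sigma_g=0.0)
        with pytest.raises(InvalidConfigError):
            NeighborhoodSpec(radius=0)

    def test_default_sigma_is_image_std(self):
        rng = np.random.default_rng(3)
        img = rng.random((6, 6))
        w = neighborhood_weights(img)
        assert w.sigma_g == pytest.approx(float(np.std(img)))


class TestEffectiveDistance:
    def test_beta_zero_is_identity(self):
        rng = np.random.default_rng(4)
        img = rng.random((4, 4))
        d = compute_distances(img.ravel(), [0.2, 0.8])
        w = neighborhood_weights(img)
        out = effective_distance(d, w, beta=0.0)
        np.testing.assert_array_equal(out, d)

    def test_constant_image_unchanged_for_any_beta(self):
        img = np.full((4, 4), 0.4)
        d = compute_distances(img.ravel(), [0.1, 0.9])
        w = neighborhood_weights(img, sigma_g=0.3)
        out = effective_distance(d, w, beta=0.7)
        np.testing.assert_allclose(out, d, atol=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.random((4, 4))
        centers = np.array([0.25, 0.5, 0.75])
        d = compute_distances(img.ravel(), centers)
        w = neighborhood_weights(img, NeighborhoodSpec(radius=1), sigma_g=0.2)
        out = effective_distance(d, w, beta=0.5)
        ref = naive_effective_distance(d, img, radius=1, sigma_g=0.2, beta=0.5)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_invalid_beta_rejected(self):
        img = np.zeros((3, 3))
        d = compute_distances(img.ravel(), [0.1, 0.9])
        w = neighborhood_weights(img, sigma_g=1.0)
        with pytest.raises(InvalidConfigError):
            effective_distance(d, w, beta=1.5)


class TestSpatialFit:
    def test_noiseless_phantom_segmented_perfectly(self, clean_phantom):
        res = spatial_fcm_fit(
            clean_phantom.image, FCMConfig(c=3, seed=0), beta=0.5
        )
        labels = res.labels.reshape(clean_phantom.image.shape)
        assert classification_accuracy_sb(labels, clean_phantom.truth, 3) == 1.0

    def test_beta_zero_reduces_to_plain_fcm(self, noisy_phantom):
        img = noisy_phantom.image
        res_s = spatial_fcm_fit(img, FCMConfig(c=3, seed=1), beta=0.0)
        res_p = fcm_fit(img.ravel(), FCMConfig(c=3, seed=1))
        np.testing.assert_array_equal(res_s.labels, res_p.labels)
        np.testing.assert_array_equal(res_s.centers, res_p.centers)
        np.testing.assert_array_equal(res_s.membership, res_p.membership)

    def test_spatial_beats_plain_on_noisy_phantoms(self):
        """Neighborhood coupling must raise SB under noise (majority of seeds)."""
        wins = 0
        for seed in range(10):
            ph = generate_phantom(
                PhantomSpec(shape=(64, 64), class_sigma=0.08, seed=seed)
            )
            cfg = FCMConfig(c=3, seed=seed)
            sb_s = classification_accuracy_sb(
                spatial_fcm_fit(ph.image, cfg, beta=0.6).labels.reshape(ph.image.shape),
                ph.truth,
                3,
            )
            sb_p = classification_accuracy_sb(
                fcm_fit(ph.image.ravel(), cfg).labels.reshape(ph.image.shape),
                ph.truth,
                3,
            )
            wins += sb_s > sb_p
        assert wins > 5

    def test_objective_trace_nonincreasing(self, noisy_phantom):
        res = spatial_fcm_fit(noisy_phantom.image, FCMConfig(c=3, seed=2), beta=0.6)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_membership_columns_sum_to_one(self, noisy_phantom):
        res = spatial_fcm_fit(noisy_phantom.image, FCMConfig(c=3, seed=2), beta=0.6)
        np.testing.assert_allclose(res.membership.sum(axis=0), 1.0, atol=1e-9)
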