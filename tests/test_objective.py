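import numpy as np
import pytest

from heclip.objective import (
    AugmentationPolicy,
    LossConfig,
    augment_patch,
    expand_epoch,
    image_centric_loss,
    symmetric_clip_loss,
)
from heclip.synthetic import SyntheticConfig, generate_cohort

from .oracles import loop_image_centric_loss, loop_symmetric_clip_loss


def random_batch(rng, b=None, d=None):
    b = b or int(rng.integers(1, 9))
    d = d or int(rng.integers(2, 17))
    return rng.normal(size=(b, d)), rng.normal(size=(b, d))


class TestLossValues:
    def test_orthonormal_batch2_hand_value(self):
        h = np.eye(2)
        assert image_centric_loss(h, h, LossConfig(temperature=1.0)) == pytest.approx(0.58221, abs=1e-4)

    def test_batch_one_is_zero(self, rng):
        h_p = rng.normal(size=(1, 5))
        h_s = rng.normal(size=(1, 5))
        assert image_centric_loss(h_p, h_s) == 0.0
        assert symmetric_clip_loss(h_p, h_s) == 0.0

    def test_low_temperature_limit(self):
        h = np.eye(2)
        assert image_centric_loss(h, h, LossConfig(temperature=0.01)) < 1e-3

    @pytest.mark.parametrize("tau", [0.3, 1.0, 2.5])
    def test_matches_double_loop_oracle(self, rng, tau):
        for _ in range(30):
            h_p, h_s = random_batch(rng)
            cfg = LossConfig(temperature=tau)
            assert image_centric_loss(h_p, h_s, cfg) == pytest.approx(
                loop_image_centric_loss(h_p, h_s, tau), abs=1e-6
            )
            assert symmetric_clip_loss(h_p, h_s, cfg) == pytest.approx(
                loop_symmetric_clip_loss(h_p, h_s, tau), abs=1e-6
            )

    def test_symmetric_loss_terms_equal_when_modalities_agree(self, rng):
        h = rng.normal(size=(5, 7))
        # with h_p == h_s the logit matrix is symmetric, so the image->spot
        # and spot->image cross-entropies coincide and the mean equals either
        from heclip.objective import _log_softmax, _softmax

        logits = h @ h.T
        targets = _softmax(logits, axis=-1)
        term = float((-targets * _log_softmax(logits, axis=-1)).sum(axis=1).mean())
        assert symmetric_clip_loss(h, h) == pytest.approx(term, rel=1e-10)

    def test_shape_and_temperature_errors(self, rng):
        h_p, h_s = random_batch(rng, 4, 8)
        with pytest.raises(ValueError):
            image_centric_loss(h_p, h_s[:3])
        with pytest.raises(ValueError):
            LossConfig(temperature=0.0)


class TestLossProperties:
    def test_soft_ce_lower_bound(self, rng):
        from heclip.objective import _softmax

        for _ in range(20):
            h_p, h_s = random_batch(rng)
            tau = float(rng.uniform(0.3, 2.0))
            loss = image_centric_loss(h_p, h_s, LossConfig(temperature=tau))
            targets = _softmax(h_p @ h_p.T / tau, axis=-1)
            tm = targets.T
            mass = tm.sum(axis=1, keepdims=True)
            # minimum of a soft cross-entropy with (unnormalized) weights t:
            # -sum t log(t / sum t)
            with np.errstate(divide="ignore", invalid="ignore"):
                bound = (-tm * np.log(tm / mass)).sum(axis=1).mean()
            assert loss >= bound - 1e-9

    def test_row_permutation_invariance(self, rng):
        h_p, h_s = random_batch(rng, 6, 8)
        perm = rng.permutation(6)
        for fn in (image_centric_loss, symmetric_clip_loss):
            assert fn(h_p[perm], h_s[perm]) == pytest.approx(fn(h_p, h_s), rel=1e-10)

    @pytest.mark.parametrize("fn", [image_centric_loss, symmetric_clip_loss])
    def test_finite_difference_gradient(self, rng, fn):
        cfg = LossConfig(temperature=0.8, targets_stop_gradient=False)
        h_p = rng.normal(size=(3, 4))
        h_s = rng.normal(size=(3, 4))
        loss, (dh_p, dh_s) = fn(h_p, h_s, cfg, with_grad=True)
        eps = 1e-6
        for arr, grad in ((h_p, dh_p), (h_s, dh_s)):
            num = np.zeros_like(arr)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    bumped = arr.copy()
                    bumped[i, j] += eps
                    bumped_loss = fn(bumped if arr is h_p else h_p, bumped if arr is h_s else h_s, cfg)
                    num[i, j] = (bumped_loss - loss) / eps
            np.testing.assert_allclose(grad, num, atol=1e-4)

    def test_stopped_targets_spot_gradient_still_exact(self, rng):
        # targets depend only on h_p, so the h_s gradient is unaffected by
        # the stop-gradient choice
        h_p = rng.normal(size=(3, 4))
        h_s = rng.normal(size=(3, 4))
        cfg = LossConfig(targets_stop_gradient=True)
        loss, (_, dh_s) = image_centric_loss(h_p, h_s, cfg, with_grad=True)
        eps = 1e-6
        num = np.zeros_like(h_s)
        for i in range(3):
            for j in range(4):
                bumped = h_s.copy()
                bumped[i, j] += eps
                num[i, j] = (image_centric_loss(h_p, bumped, cfg) - loss) / eps
        np.testing.assert_allclose(dh_s, num, atol=1e-4)


class TestAugmentation:
    @pytest.fixture
    def patch(self, rng):
        return rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)

    def test_identity_draw_possible_and_shape_preserved(self, patch):
        policy = AugmentationPolicy(seed=0)
        seen_identity = False
        for s in range(50):
            out = augment_patch(patch, policy, np.random.default_rng(s))
            assert out.shape == patch.shape
            if np.array_equal(out, patch):
                seen_identity = True
        assert seen_identity

    def test_flip_involution(self, patch):
        policy = AugmentationPolicy(vertical_flip=False, rotations=())
        rng_state = np.random.default_rng(3)
        once = augment_patch(patch, policy, np.random.default_rng(99))
        # applying the same drawn op twice restores the original
        again = augment_patch(once, policy, np.random.default_rng(99))
        np.testing.assert_array_equal(again, patch)

    def test_pixel_multiset_preserved(self, patch):
        policy = AugmentationPolicy()
        for s in range(10):
            out = augment_patch(patch, policy, np.random.default_rng(s))
            np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(patch.ravel()))

    def test_non_square_rotation_rejected(self, rng):
        rect = rng.integers(0, 256, size=(8, 16, 3), dtype=np.uint8)
        policy = AugmentationPolicy(rotations=(90,), horizontal_flip=False, vertical_flip=False)
        with pytest.raises(ValueError):
            for s in range(20):
                augment_patch(rect, policy, np.random.default_rng(s))


@pytest.fixture(scope="module")
def cohort():
    cfg = SyntheticConfig(n_spots=20, n_genes=10, n_clusters=2, patch_size=16, n_slices=2, seed=4)
    return generate_cohort(cfg)[0]


class TestExpandEpoch:

    def test_doubles_the_data(self, cohort):
        out = expand_epoch(cohort, AugmentationPolicy(copies_per_epoch=2, seed=1), epoch_index=0)
        assert len(out) == 2 * len(cohort)

    def test_single_copy_preserves_order(self, cohort):
        out = expand_epoch(cohort, AugmentationPolicy(copies_per_epoch=1, seed=1), epoch_index=0)
        assert [p.spot.spot_id for p in out] == cohort.spot_ids()

    def test_expression_untouched(self, cohort):
        out = expand_epoch(cohort, AugmentationPolicy(copies_per_epoch=2, seed=1), epoch_index=0)
        for k, pair in enumerate(out):
            np.testing.assert_array_equal(pair.expression, cohort[k // 2].expression)

    def test_reproducible_under_seed_and_epoch(self, cohort):
        policy = AugmentationPolicy(copies_per_epoch=2, seed=9)
        a = expand_epoch(cohort, policy, epoch_index=3)
        b = expand_epoch(cohort, policy, epoch_index=3)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.patch, pb.patch)

    def test_different_epochs_differ(self, cohort):
        policy = AugmentationPolicy(copies_per_epoch=2, seed=9)
        a = expand_epoch(cohort, policy, epoch_index=0)
        b = expand_epoch(cohort, policy, epoch_index=1)
        assert any(not np.array_equal(pa.patch, pb.patch) for pa, pb in zip(a, b))
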