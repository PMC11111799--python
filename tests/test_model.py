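"""Loss closed forms, Siamese weight-sharing contracts, gradient checks."""

import math

import numpy as np
import pytest

from tbut.model import (
    DTSN,
    LossWeights,
    ModelConfig,
    bce_loss,
    contrastive_loss,
    total_loss,
)

LN2 = math.log(2.0)


class TestLossOracles:
    def test_bce_at_half_is_ln2(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(LN2, abs=1e-6)
        assert bce_loss(np.array([0.5]), np.array([0.0])) == pytest.approx(LN2, abs=1e-6)

    def test_bce_closed_form(self):
        assert bce_loss(np.array([0.9]), np.array([1.0])) == pytest.approx(
            -math.log(0.9), abs=1e-6
        )
        # mean of two equal terms
        assert bce_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0])) == pytest.approx(
            -math.log(0.9), abs=1e-6
        )

    def test_bce_finite_at_extremes(self):
        assert np.isfinite(bce_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0])))

    def test_bce_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            bce_loss(np.array([0.5, 0.5]), np.array([1.0]))

    def test_contrastive_similar_identical_is_zero(self):
        z = np.ones((3, 4))
        assert contrastive_loss(z, z, np.zeros(3)) == 0.0

    def test_contrastive_dissimilar_beyond_margin_is_zero(self):
        z1 = np.zeros((2, 4))
        z2 = np.full((2, 4), 0.5)  # distance 1.0 >= margin
        assert contrastive_loss(z1, z2, np.ones(2), margin=0.01) == 0.0

    def test_contrastive_dissimilar_identical_is_margin_squared(self):
        z = np.ones((1, 8))
        assert contrastive_loss(z, z, np.ones(1), margin=0.01) == pytest.approx(
            1e-4, abs=1e-12
        )

    def test_contrastive_monotone_in_distance(self):
        # dissimilar: non-increasing in distance; similar: non-decreasing
        ds = np.linspace(0, 0.02, 50)
        z2s = [np.array([[d, 0.0]]) for d in ds]
        z1 = np.zeros((1, 2))
        dis = [contrastive_loss(z1, z2, np.ones(1), margin=0.01) for z2 in z2s]
        sim = [contrastive_loss(z1, z2, np.zeros(1), margin=0.01) for z2 in z2s]
        assert all(a >= b - 1e-15 for a, b in zip(dis, dis[1:]))
        assert all(a <= b + 1e-15 for a, b in zip(sim, sim[1:]))

    def test_total_loss_weighted_sum(self):
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 0.0])
        z = np.zeros((2, 4))
        # Lc = 0 for identical similar embeddings
        out = total_loss(p, p, y, y, z, z, np.zeros(2), LossWeights(w1=0.9, w2=0.1))
        assert out == pytest.approx(0.9 * 2 * LN2, abs=1e-6)

    def test_total_loss_weight_zeroing(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 5)
        y = rng.integers(0, 2, 5).astype(float)
        z1, z2 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        Y = rng.integers(0, 2, 5).astype(float)
        only_c = total_loss(p, p, y, y, z1, z2, Y, LossWeights(w1=0.0, w2=1.0))
        assert only_c == pytest.approx(contrastive_loss(z1, z2, Y), abs=1e-12)


@pytest.fixture(scope="module")
def model():
    return DTSN(ModelConfig(), seed=0)


@pytest.fixture(scope="module")
def images():
    rng = np.random.default_rng(42)
    return rng.uniform(size=(4, 1, 32, 32)).astype(np.float32)


class TestSiameseContracts:
    def test_identical_inputs_give_zero_distance(self, model, images):
        out = model.forward_pair(images, images)
        np.testing.assert_array_equal(out.z1, out.z2)
        np.testing.assert_array_equal(out.p1, out.p2)
        assert np.all(out.d == 0.0)

    def test_branch_equals_single(self, model, images):
        out = model.forward_pair(images[:2], images[2:])
        np.testing.assert_array_equal(out.p1, model.forward_single(images[:2]))
        np.testing.assert_array_equal(out.p2, model.forward_single(images[2:]))

    def test_swap_symmetry(self, model, images):
        ab = model.forward_pair(images[:2], images[2:])
        ba = model.forward_pair(images[2:], images[:2])
        np.testing.assert_array_equal(ab.z1, ba.z2)
        np.testing.assert_array_equal(ab.p1, ba.p2)
        np.testing.assert_array_equal(ab.d, ba.d)

    def test_probabilities_in_unit_interval(self, model):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(1000, 1, 32, 32)).astype(np.float32)
        p = model.forward_single(x)
        assert np.all((p >= 0) & (p <= 1))

    def test_resolution_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="expected input"):
            model.forward_single(np.zeros((1, 1, 16, 16), dtype=np.float32))

    def test_unavailable_backbone_rejected(self):
        with pytest.raises(ValueError, match="not available"):
            ModelConfig(backbone="rexnet150")


def _numeric_grad(model, x1, x2, y1, y2, Y, weights, param, idx, eps=5e-4):
    orig = param.value.flat[idx]
    param.value.flat[idx] = orig + eps
    lp = _loss_only(model, x1, x2, y1, y2, Y, weights)
    param.value.flat[idx] = orig - eps
    lm = _loss_only(model, x1, x2, y1, y2, Y, weights)
    param.value.flat[idx] = orig
    return (lp - lm) / (2 * eps)


def _loss_only(model, x1, x2, y1, y2, Y, weights):
    for p in model.parameters():
        p.grad[...] = 0.0
    # forward in training mode without mutating running stats
    import copy

    m = copy.deepcopy(model)
    return m.pair_loss_and_grads(x1, x2, y1, y2, Y, weights)


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        model = DTSN(ModelConfig(embedding_dim=4), seed=1)
        rng = np.random.default_rng(0)
        x1 = rng.uniform(size=(6, 1, 32, 32)).astype(np.float32)
        x2 = rng.uniform(size=(6, 1, 32, 32)).astype(np.float32)
        y1 = rng.integers(0, 2, 6).astype(float)
        y2 = rng.integers(0, 2, 6).astype(float)
        Y = (y1 != y2).astype(float)
        weights = LossWeights(w1=0.9, w2=0.1, margin=0.5)

        import copy

        work = copy.deepcopy(model)
        for p in work.parameters():
            p.grad[...] = 0.0
        work.pair_loss_and_grads(x1, x2, y1, y2, Y, weights)

        checks = 0
        for p_ref, p_work in zip(model.parameters(), work.parameters()):
            for idx in (0, p_ref.value.size // 2):
                num = _numeric_grad(model, x1, x2, y1, y2, Y, weights, p_ref, idx)
                ana = p_work.grad.flat[idx]
                # rel term absorbs finite-difference truncation on the
                # high-curvature batch-norm path; abs term covers near-zero grads
                assert ana == pytest.approx(num, rel=0.05, abs=2e-3), (p_ref.value.shape, idx)
                checks += 1
        assert checks >= 10

    def test_both_branches_reach_shared_parameters(self):
        """A dual-task step differs from either single-branch-only step."""
        from tbut import _nn

        rng = np.random.default_rng(0)
        x1 = rng.uniform(size=(8, 1, 32, 32)).astype(np.float32)
        x2 = rng.uniform(size=(8, 1, 32, 32)).astype(np.float32)
        y1 = np.ones(8)
        y2 = np.zeros(8)
        Y = np.ones(8)

        def step(weights, branch_only=None):
            model = DTSN(ModelConfig(), seed=5)
            opt = _nn.Adam(model.parameters(), lr=1e-2)
            opt.zero_grad()
            if branch_only == 1:
                model.pair_loss_and_grads(x1, x1, y1, y1, np.zeros(8), weights)
            elif branch_only == 2:
                model.pair_loss_and_grads(x2, x2, y2, y2, np.zeros(8), weights)
            else:
                model.pair_loss_and_grads(x1, x2, y1, y2, Y, weights)
            opt.step()
            return np.concatenate([p.value.ravel() for p in model.parameters()])

        w = LossWeights(w1=1.0, w2=0.0)
        dual = step(w)
        assert not np.allclose(dual, step(w, branch_only=1))
        assert not np.allclose(dual, step(w, branch_only=2))

    def test_training_epoch_decreases_loss(self):
        """One pass over 200 synthetic pairs strictly lowers the objective."""
        from tbut import _nn
        from tbut.dataset import sample_pairs
        from tbut.synthetic_data import SimConfig, generate_video
        from tbut.training import _pairs_tensors

        cfg = SimConfig(
            image_size=32,
            open_duration_s=(2.0, 3.0),
            onset_time_s=(0.3, 1.5),
            spot_contrast=0.7,
            spot_growth_px_per_s=8.0,
            noise_sd=0.02,
        )
        rng = np.random.default_rng(0)
        video = generate_video(cfg, rng)
        records = [r for s in video.subtests for r in s.frames]
        pairs = sample_pairs(records, 200, max_gap_frames=30, rng=rng)
        x1, x2, y1, y2, Y = _pairs_tensors(pairs, 32)

        model = DTSN(ModelConfig(), seed=0)
        weights = LossWeights()
        opt = _nn.Adam(model.parameters(), lr=1e-3)

        def full_loss():
            opt.zero_grad()
            loss = model.pair_loss_and_grads(x1, x2, y1, y2, Y, weights)
            opt.zero_grad()
            return loss

        before = full_loss()
        for start in range(0, 200, 32):
            sl = slice(start, start + 32)
            opt.zero_grad()
            model.pair_loss_and_grads(x1[sl], x2[sl], y1[sl], y2[sl], Y[sl], weights)
            opt.step()
        assert full_loss() < before


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, images):
        model = DTSN(ModelConfig(embedding_dim=8), seed=2)
        p_before = model.forward_single(images)
        model.save(tmp_path / "ckpt.npz")
        loaded = DTSN.load(tmp_path / "ckpt.npz")
        assert loaded.config == model.config
        np.testing.assert_array_equal(loaded.forward_single(images), p_before)
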