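"""Encoder architecture, cosine similarity, the contrastive loss, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rrverify.model import (
    LossParams,
    SiameseConfig,
    TrainHyperparams,
    _loss_and_grads,
    build_encoder,
    contrastive_cosine_loss,
    cosine_similarity,
    load_checkpoint,
    save_checkpoint,
    score_pair,
    score_pairs,
    train,
)
from rrverify.pairing import enumerate_pairs
from rrverify.types import DegenerateEmbeddingError, HeartbeatWindow, WindowPair

TINY = SiameseConfig(n_beats=16, conv_channels=(2, 3, 4), linear_dims=(8, 6, 4),
                     dropout_rate=0.0)


def _window(subject, idx, intervals):
    return HeartbeatWindow(np.asarray(intervals, dtype=float), len(intervals),
                           subject, "basal", 6.0, idx)


class TestConfig:
    @pytest.mark.parametrize("n_beats, kernel", [(250, 25), (50, 5), (15, 1)])
    def test_kernel_is_tenth_of_window_length(self, n_beats, kernel):
        assert SiameseConfig(n_beats=n_beats).effective_kernel == kernel

    def test_window_too_short_for_three_pool_stages(self):
        with pytest.raises(ValueError):
            SiameseConfig(n_beats=7)
        SiameseConfig(n_beats=8)  # 8 -> 4 -> 2 -> 1 survives

    def test_loss_params_validation(self):
        with pytest.raises(ValueError):
            LossParams(lam=0.0)
        with pytest.raises(ValueError):
            LossParams(b=1.5)


class TestEncoder:
    def test_eval_forward_is_deterministic(self, rng):
        enc = build_encoder(TINY, seed=0)
        x = rng.normal(0.13, 0.01, (3, 16))
        np.testing.assert_array_equal(enc(x), enc(x))

    def test_branches_share_weights_bitwise(self, rng):
        """The same input embeds identically whichever pair slot it occupies."""
        enc = build_encoder(TINY, seed=0)
        x = rng.normal(0.13, 0.01, 16)
        both = enc(np.stack([x, x]))
        np.testing.assert_array_equal(both[0], both[1])

    def test_untrained_score_is_reproducible_and_symmetric(self, rng):
        from rrverify.model import TrainedModel

        enc = build_encoder(TINY, seed=5)
        model = TrainedModel(TINY, enc, LossParams(), seed=5, epochs_run=0)
        w1 = _window("A", 0, rng.normal(0.13, 0.01, 16))
        w2 = _window("B", 0, rng.normal(0.15, 0.01, 16))
        s12 = score_pair(model, WindowPair(w1, w2))
        s21 = score_pair(model, WindowPair(w2, w1))
        assert s12 == pytest.approx(s21, abs=1e-12)
        assert s12 == pytest.approx(score_pair(model, WindowPair(w1, w2)), abs=0)
        assert score_pair(model, WindowPair(w1, w1)) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self, rng):
        enc = build_encoder(TINY, seed=0)
        with pytest.raises(ValueError):
            enc(rng.normal(size=(2, 20)))


class TestCosine:
    def test_hand_computed_values(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert cosine_similarity([1.0, 0.0], [0.0, 3.0]) == pytest.approx(0.0)
        assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(0.974632, abs=1e-6)

    @given(
        hnp.arrays(np.float64, 6, elements=st.floats(-10, 10)),
        hnp.arrays(np.float64, 6, elements=st.floats(-10, 10)),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_dot_over_norms(self, a, b):
        na = np.sqrt(sum(x * x for x in a))
        nb = np.sqrt(sum(x * x for x in b))
        if na < 1e-6 or nb < 1e-6:
            return
        expected = sum(x * y for x, y in zip(a, b)) / (na * nb)
        assert cosine_similarity(a, b) == pytest.approx(np.clip(expected, -1, 1), abs=1e-6)

    def test_zero_norm_embedding_is_degenerate(self):
        with pytest.raises(DegenerateEmbeddingError):
            cosine_similarity([0.0, 0.0], [1.0, 2.0])


class TestLoss:
    def test_single_positive_identical_embeddings(self):
        e = np.array([1.0, 1.0])
        assert contrastive_cosine_loss([(e, e, 1)], LossParams(lam=1.0, b=0.0)) == pytest.approx(-1.0)

    def test_single_negative_orthogonal_embeddings(self):
        loss = contrastive_cosine_loss(
            [(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 0)], LossParams()
        )
        assert loss == pytest.approx(0.0)

    def test_mixed_batch_mean(self):
        e = np.array([1.0, 0.0])
        batch = [(e, e, 1), (e, -e, 0)]  # positive c=1, negative c=-1
        assert contrastive_cosine_loss(batch, LossParams(lam=1.0, b=0.0)) == pytest.approx(-1.0)

    def test_b_is_an_additive_offset_and_never_reaches_gradients(self, rng):
        """The loss is affine in b with slope -lambda * (positive fraction);
        embedding gradients are identical for any b."""
        E1 = rng.normal(size=(6, 4))
        E2 = rng.normal(size=(6, 4))
        y = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        lam = 2.0
        l_lo, d1_lo, d2_lo = _loss_and_grads(E1, E2, y, LossParams(lam=lam, b=-1.0))
        l_hi, d1_hi, d2_hi = _loss_and_grads(E1, E2, y, LossParams(lam=lam, b=1.0))
        assert l_hi - l_lo == pytest.approx(-lam * 0.5 * 2.0, abs=1e-12)
        np.testing.assert_array_equal(d1_lo, d1_hi)
        np.testing.assert_array_equal(d2_lo, d2_hi)

    def test_gradient_direction_on_2d_embeddings(self):
        """A gradient step raises cosine similarity for a positive pair and
        lowers it for a negative pair (2-D toy encoder = identity map)."""
        e1 = np.array([[1.0, 0.2]])
        e2 = np.array([[0.3, 1.0]])
        for y, direction in ((1, +1), (0, -1)):
            labels = np.array([float(y)])
            c0 = cosine_similarity(e1[0], e2[0])
            _, d1, d2 = _loss_and_grads(e1, e2, labels, LossParams())
            step = 0.05
            c1 = cosine_similarity(e1[0] - step * d1[0], e2[0] - step * d2[0])
            assert direction * (c1 - c0) > 0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            contrastive_cosine_loss([], LossParams())


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients through conv/batchnorm/pool/linear agree with
        central finite differences (away from pre-batchnorm biases, whose
        true gradient is exactly zero)."""
        enc = build_encoder(TINY, seed=3)
        B = 3
        X = rng.normal(0.13, 0.02, (2 * B, 16))
        y = np.array([1.0, 0.0, 1.0])
        lp = LossParams(lam=1.3, b=0.2)

        def loss_now():
            E = enc(X, train=True)
            return _loss_and_grads(E[:B], E[B:], y, lp)[0]

        E = enc(X, train=True)
        _, dE1, dE2 = _loss_and_grads(E[:B], E[B:], y, lp)
        enc.net.zero_grad()
        enc.backward(np.concatenate([dE1, dE2]))
        eps = 1e-6
        checked = 0
        for p, g in zip(enc.net.parameters(), enc.net.gradients()):
            if p.ndim == 1 and np.allclose(g, 0.0, atol=1e-9):
                continue  # bias absorbed by the following batch norm
            for flat in rng.integers(p.size, size=2):
                i = np.unravel_index(flat, p.shape)
                orig = p[i]
                p[i] = orig + eps
                hi = loss_now()
                p[i] = orig - eps
                lo = loss_now()
                p[i] = orig
                fd = (hi - lo) / (2 * eps)
                assert g[i] == pytest.approx(fd, rel=1e-3, abs=1e-7)
                checked += 1
        assert checked >= 10


@pytest.fixture(scope="module")
def toy_pairs():
    rng = np.random.default_rng(0)
    windows = []
    for s, mean in (("A", 0.11), ("B", 0.16)):
        for i in range(6):
            windows.append(_window(s, i, rng.normal(mean, 0.004, 16)))
    return enumerate_pairs(windows, "same", rng)


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self, toy_pairs):
        hp = TrainHyperparams(epochs=0, seed=9, batch_size=4)
        model = train(TINY, LossParams(), toy_pairs, hp)
        fresh = build_encoder(TINY, seed=9)
        for a, b in zip(model.encoder.state_arrays(), fresh.state_arrays()):
            np.testing.assert_array_equal(a, b)
        assert model.loss_history == []

    def test_training_decreases_loss_and_separates_toy_subjects(self, toy_pairs):
        hp = TrainHyperparams(epochs=8, seed=1, batch_size=8, learning_rate=0.02)
        model = train(TINY, LossParams(), toy_pairs, hp)
        assert model.loss_history[-1] < model.loss_history[0]
        scores = score_pairs(model, toy_pairs)
        labels = np.array([p.y for p in toy_pairs])
        assert scores[labels == 1].mean() > scores[labels == 0].mean()

    def test_training_is_seed_reproducible(self, toy_pairs):
        hp = TrainHyperparams(epochs=2, seed=4, batch_size=4)
        m1 = train(TINY, LossParams(), toy_pairs, hp)
        m2 = train(TINY, LossParams(), toy_pairs, hp)
        assert m1.loss_history == m2.loss_history
        for a, b in zip(m1.encoder.state_arrays(), m2.encoder.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip(self, toy_pairs, tmp_path):
        hp = TrainHyperparams(epochs=2, seed=4, batch_size=4)
        model = train(TINY, LossParams(lam=1.5, b=0.25), toy_pairs, hp)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, str(path))
        loaded = load_checkpoint(str(path))
        assert loaded.config == model.config
        assert loaded.loss_params == model.loss_params
        np.testing.assert_array_equal(
            score_pairs(loaded, toy_pairs), score_pairs(model, toy_pairs)
        )
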