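"""Engine-level gradient correctness and model forward/training contracts."""

import numpy as np
import pytest

from gazeattr.model import build_model, desk_config, prepare_records, slice_batch
from gazeattr.nn import LSTM, Conv2d, MaxPool2d, bce_with_logits, sigmoid
from gazeattr.synth import SyntheticSpec, build_dataset
from gazeattr.train import evaluate, train


def finite_difference(loss_fn, w0, indices, eps=1e-6):
    out = {}
    for i in indices:
        wp, wm = w0.copy(), w0.copy()
        wp[i] += eps
        wm[i] -= eps
        out[i] = (loss_fn(wp) - loss_fn(wm)) / (2 * eps)
    return out


@pytest.fixture(scope="module")
def tiny_setup():
    cfg = desk_config(conv_filters=(2,), lstm_hidden=4, input_image_size=(8, 8), epochs=2, batch_size=8)
    spec = SyntheticSpec(n_images=4, n_participants_per_group=2, image_size=(16, 16), seed=0)
    records, _ = build_dataset(spec)
    prep = prepare_records(records, cfg)
    return cfg, records, prep


class TestGradients:
    def test_full_backprop_matches_finite_differences(self, tiny_setup):
        """Analytic gradients agree with central differences on every layer type."""
        cfg, _, prep = tiny_setup
        model = build_model(cfg, seed=1)
        batch = slice_batch(prep, np.arange(3))
        model.zero_grad()
        logits = model.forward(batch, train=False)
        _, dlogits = bce_with_logits(logits, batch["labels"])
        model.backward(dlogits)
        g = model.flat_grad()
        w0 = model.get_flat_params()

        def loss_at(w):
            model.set_flat_params(w)
            z = model.forward(batch, train=False)
            l, _ = bce_with_logits(z, batch["labels"])
            return float(l.sum())

        idx = np.random.default_rng(0).choice(w0.size, size=120, replace=False)
        fd = finite_difference(loss_at, w0, idx)
        for i, fd_i in fd.items():
            denom = max(abs(fd_i), abs(g[i]), 1e-6)
            assert abs(fd_i - g[i]) / denom < 1e-4

    def test_lstm_masking_final_state_matches_short_forward(self, rng):
        """Padded steps carry the state: h[:, -1] equals running only the true steps."""
        lstm = LSTM(2, 5, rng)
        x = rng.normal(size=(1, 7, 2))
        lengths = np.array([4])
        h_padded = lstm.forward(x, lengths)[:, -1]
        h_exact = lstm.forward(x[:, :4], np.array([4]))[:, -1]
        np.testing.assert_allclose(h_padded, h_exact, rtol=0, atol=1e-12)

    def test_maxpool_backward_routes_to_argmax(self, rng):
        pool = MaxPool2d()
        x = rng.normal(size=(1, 1, 4, 4))
        out = pool.forward(x)
        dout = np.ones_like(out)
        dx = pool.backward(dout)
        assert dx.sum() == out.size
        assert ((dx != 0) == (x == np.repeat(np.repeat(out, 2, axis=2), 2, axis=3))).all()

    def test_conv_same_padding_shape(self, rng):
        conv = Conv2d(1, 3, rng)
        out = conv.forward(rng.normal(size=(2, 1, 9, 9)))
        assert out.shape == (2, 3, 9, 9)


class TestModelContracts:
    def test_zeroed_final_layer_outputs_half(self, tiny_setup):
        cfg, _, prep = tiny_setup
        model = build_model(cfg, seed=0)
        model.final.W.value[...] = 0.0
        model.final.b.value[...] = 0.0
        proba = model.predict_proba(slice_batch(prep, np.arange(4)))
        np.testing.assert_allclose(proba, 0.5)

    def test_probabilities_in_open_unit_interval(self, tiny_setup):
        cfg, _, prep = tiny_setup
        model = build_model(cfg, seed=2)
        proba = model.predict_proba(slice_batch(prep, np.arange(len(prep["labels"]))))
        assert ((proba > 0) & (proba < 1)).all()

    def test_batch_permutation_equivariance(self, tiny_setup):
        cfg, _, prep = tiny_setup
        model = build_model(cfg, seed=3)
        idx = np.arange(6)
        z = model.forward(slice_batch(prep, idx))
        perm = np.array([3, 1, 5, 0, 4, 2])
        z_perm = model.forward(slice_batch(prep, idx[perm]))
        np.testing.assert_allclose(z[perm], z_perm, atol=1e-10)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            desk_config(conv_filters=())
        with pytest.raises(ValueError):
            desk_config(lstm_layers=0)

    def test_flat_param_roundtrip(self, tiny_setup):
        cfg, _, _ = tiny_setup
        model = build_model(cfg, seed=4)
        w = model.get_flat_params()
        model.set_flat_params(np.zeros_like(w))
        assert model.get_flat_params().sum() == 0
        model.set_flat_params(w)
        np.testing.assert_array_equal(model.get_flat_params(), w)


class TestTraining:
    def test_checkpoint_per_epoch_and_determinism(self, tiny_setup):
        cfg, _, prep = tiny_setup
        runs = []
        for _ in range(2):
            model = build_model(cfg, seed=5)
            ckpts, history = train(model, prep, cfg, seed=5)
            runs.append((model.get_flat_params(), ckpts, history))
        w_a, ck_a, hist_a = runs[0]
        w_b, ck_b, hist_b = runs[1]
        assert ck_a.k == cfg.epochs and len(hist_a) == cfg.epochs
        np.testing.assert_array_equal(w_a, w_b)
        for (wa, ea), (wb, eb) in zip(ck_a.checkpoints, ck_b.checkpoints):
            np.testing.assert_array_equal(wa, wb)
            assert ea == eb > 0

    def test_checkpoint_replay_reproduces_epoch_metrics(self, tiny_setup):
        """Loading w(i) reproduces the training metrics recorded at epoch i."""
        cfg, _, prep = tiny_setup
        model = build_model(cfg, seed=6)
        ckpts, history = train(model, prep, cfg, seed=6)
        w1, _ = ckpts.checkpoints[0]
        model.set_flat_params(w1)
        rep = evaluate(model, prep, cfg)
        assert rep.accuracy == pytest.approx(history["train_accuracy"].iloc[0])

    def test_single_class_warns_but_trains(self, tiny_setup):
        cfg, records, _ = tiny_setup
        only_td = [r for r in records if r.label == 0]
        prep = prepare_records(only_td, cfg)
        model = build_model(cfg, seed=7)
        with pytest.warns(UserWarning):
            train(model, prep, cfg, seed=7)

    def test_empty_dataset_rejected(self, tiny_setup):
        cfg, _, _ = tiny_setup
        model = build_model(cfg, seed=8)
        with pytest.raises(ValueError):
            train(model, [], cfg, seed=8)

    def test_separable_synthetic_set_is_fit(self):
        """A linearly separable toy set reaches high training accuracy."""
        cfg = desk_config(conv_filters=(4,), lstm_hidden=8, input_image_size=(16, 16), epochs=16)
        spec = SyntheticSpec(
            n_images=6,
            n_participants_per_group=5,
            image_size=(32, 32),
            category_mix={"people": 1.0, "objects": 0.0, "landscapes": 0.0},
            p_social_td=1.0,
            p_social_asd=0.0,
            seed=11,
        )
        records, _ = build_dataset(spec)
        prep = prepare_records(records, cfg)
        model = build_model(cfg, seed=11)
        _, history = train(model, prep, cfg, seed=11)
        assert history["train_accuracy"].iloc[-1] >= 0.9

    def test_checkpoint_save_load_roundtrip(self, tiny_setup, tmp_path):
        cfg, _, prep = tiny_setup
        model = build_model(cfg, seed=9)
        ckpts, _ = train(model, prep, cfg, seed=9)
        ckpts.save(tmp_path / "ck")
        back = ckpts.load(tmp_path / "ck")
        assert back.k == ckpts.k and back.seed == 9
        for (wa, ea), (wb, eb) in zip(ckpts.checkpoints, back.checkpoints):
            np.testing.assert_array_equal(wa, wb)
            assert ea == eb
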