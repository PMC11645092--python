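"""TracIn attribution: oracle equivalence, identities, and rankings."""

import numpy as np
import pytest

from gazeattr.model import build_model, desk_config, prepare_records, slice_batch
from gazeattr.nn import bce_with_logits
from gazeattr.synth import SyntheticSpec, build_dataset
from gazeattr.tracin import (
    influence,
    influence_table,
    per_sample_gradient,
    proponents_opponents,
    rank_self_influence,
    self_influence,
    self_influence_table,
)
from gazeattr.train import CheckpointSet, train


@pytest.fixture(scope="module")
def oracle_setup():
    """Tiny model, small dataset, 4 checkpoints from a real training run."""
    cfg = desk_config(
        conv_filters=(2,), lstm_hidden=4, input_image_size=(8, 8), epochs=4, batch_size=8
    )
    spec = SyntheticSpec(n_images=5, n_participants_per_group=4, image_size=(16, 16), seed=1)
    records, _ = build_dataset(spec)
    records = records[:40]
    prep = prepare_records(records, cfg)
    model = build_model(cfg, seed=1)
    assert model.n_params <= 5000
    ckpts, _ = train(model, prep, cfg, seed=1)
    assert ckpts.k == 4
    return cfg, records, prep, model, ckpts


def brute_force_self_influence(model, ckpts, batch, mode):
    """Naive per-checkpoint accumulation, one backprop at a time."""
    total = 0.0
    saved = model.get_flat_params()
    for w, eta in ckpts.checkpoints:
        model.set_flat_params(w)
        g = per_sample_gradient(model, batch, mode)
        total += eta * float(g @ g)
    model.set_flat_params(saved)
    return total


class TestGradientOracle:
    def test_per_sample_gradient_matches_finite_differences(self, oracle_setup):
        cfg, _, prep, model, ckpts = oracle_setup
        model.set_flat_params(ckpts.checkpoints[1][0])
        batch = slice_batch(prep, np.array([3]))
        g = per_sample_gradient(model, batch, mode="full")
        w0 = model.get_flat_params()

        def loss_at(w):
            model.set_flat_params(w)
            z = model.forward(batch, train=False)
            l, _ = bce_with_logits(z, batch["labels"])
            return float(l.sum())

        eps = 1e-6
        idx = np.random.default_rng(2).choice(w0.size, size=150, replace=False)
        for i in idx:
            wp, wm = w0.copy(), w0.copy()
            wp[i] += eps
            wm[i] -= eps
            fd = (loss_at(wp) - loss_at(wm)) / (2 * eps)
            assert abs(fd - g[i]) / max(abs(fd), abs(g[i]), 1e-6) < 1e-4
        model.set_flat_params(w0)

    def test_duplicate_sample_has_identical_gradient(self, oracle_setup):
        _, _, prep, model, _ = oracle_setup
        batch = slice_batch(prep, np.array([5]))
        g1 = per_sample_gradient(model, batch, mode="full")
        g2 = per_sample_gradient(model, batch, mode="full")
        np.testing.assert_array_equal(g1, g2)

    def test_last_layer_closed_form_matches_backprop(self, oracle_setup):
        """The vectorized (sigmoid(z)-y)*[f,1] form equals backprop gradients."""
        from gazeattr.tracin import _last_layer_grads_batch

        _, _, prep, model, ckpts = oracle_setup
        model.set_flat_params(ckpts.checkpoints[2][0])
        idx = np.arange(10)
        G = _last_layer_grads_batch(model, slice_batch(prep, idx))
        for row, i in zip(G, idx):
            g = per_sample_gradient(model, slice_batch(prep, np.array([i])), mode="last_layer")
            np.testing.assert_allclose(row, g, rtol=1e-12, atol=1e-14)


class TestInfluenceIdentities:
    def test_self_influence_closed_form_two_checkpoints(self, oracle_setup):
        """Hand-checkable accumulation: eta-weighted squared gradient norms."""
        _, _, prep, model, ckpts = oracle_setup
        batch = slice_batch(prep, np.array([0]))
        expected = 0.0
        saved = model.get_flat_params()
        for w, eta in ckpts.checkpoints:
            model.set_flat_params(w)
            g = per_sample_gradient(model, batch, "last_layer")
            expected += eta * np.sum(g * g)
        model.set_flat_params(saved)
        got = self_influence(ckpts, model, batch)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_self_influence_equals_influence_with_itself(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        for i in (0, 7, 21):
            b = slice_batch(prep, np.array([i]))
            si = self_influence(ckpts, model, b)
            inf = influence(ckpts, model, b, b)
            assert si == pytest.approx(inf, rel=1e-12)
            assert si >= 0.0

    def test_influence_symmetry_on_random_pairs(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        rng = np.random.default_rng(3)
        for _ in range(10):
            i, j = rng.integers(0, len(prep["labels"]), size=2)
            a, b = slice_batch(prep, np.array([i])), slice_batch(prep, np.array([j]))
            assert influence(ckpts, model, a, b) == pytest.approx(
                influence(ckpts, model, b, a), rel=1e-12
            )

    def test_cauchy_schwarz_single_checkpoint(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        single = CheckpointSet(ckpts.checkpoints[:1])
        rng = np.random.default_rng(4)
        for _ in range(20):
            i, j = rng.integers(0, len(prep["labels"]), size=2)
            a, b = slice_batch(prep, np.array([i])), slice_batch(prep, np.array([j]))
            lhs = influence(single, model, a, b) ** 2
            rhs = self_influence(single, model, a) * self_influence(single, model, b)
            assert lhs <= rhs * (1 + 1e-10) + 1e-30

    def test_empty_checkpoint_set_rejected(self, oracle_setup):
        _, _, prep, model, _ = oracle_setup
        with pytest.raises(ValueError):
            self_influence(CheckpointSet([]), model, slice_batch(prep, np.array([0])))


class TestProductionVsBruteForce:
    @pytest.mark.parametrize("mode", ["last_layer", "full"])
    def test_table_matches_per_sample_loop(self, oracle_setup, mode):
        """Vectorized production scores equal the naive accumulation to 1e-10."""
        _, _, prep, model, ckpts = oracle_setup
        table = self_influence_table(ckpts, model, prep, mode=mode)
        for i in range(0, len(prep["labels"]), 7):
            naive = brute_force_self_influence(model, ckpts, slice_batch(prep, np.array([i])), mode)
            got = table.self_scores.iloc[i]
            assert abs(got - naive) / max(abs(naive), 1e-30) < 1e-10

    def test_pairwise_table_matches_influence_calls(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        sub_train = slice_batch(prep, np.arange(6))
        sub_test = slice_batch(prep, np.arange(6, 9))
        M = influence_table(ckpts, model, sub_train, sub_test).pairwise
        for i in range(6):
            for j in range(3):
                direct = influence(
                    ckpts, model,
                    slice_batch(prep, np.array([i])),
                    slice_batch(prep, np.array([6 + j])),
                )
                assert M.iloc[i, j] == pytest.approx(direct, rel=1e-10, abs=1e-25)


class TestRankings:
    def test_singleton_ranking(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        one = slice_batch(prep, np.array([0]))
        ranking = rank_self_influence(ckpts, model, one)
        assert len(ranking) == 1 and ranking[0][0] == one["sample_ids"][0]

    def test_ranking_invariant_to_dataset_order(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        idx = np.arange(len(prep["labels"]))
        r1 = rank_self_influence(ckpts, model, slice_batch(prep, idx))
        perm = np.random.default_rng(5).permutation(idx)
        r2 = rank_self_influence(ckpts, model, slice_batch(prep, perm))
        assert [sid for sid, _ in r1] == [sid for sid, _ in r2]

    def test_ranking_descending_with_id_tiebreak(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        ranking = rank_self_influence(ckpts, model, prep)
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)
        for (id1, s1), (id2, s2) in zip(ranking, ranking[1:]):
            if s1 == s2:
                assert id1 < id2

    def test_exact_copy_is_top_proponent_single_checkpoint(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        single = CheckpointSet(ckpts.checkpoints[-1:])
        train_idx = np.arange(12)
        # pick the train sample with the largest gradient norm as the test
        # sample: by Cauchy-Schwarz its exact copy must be the top proponent
        model.set_flat_params(single.checkpoints[0][0])
        norms = [
            np.linalg.norm(per_sample_gradient(model, slice_batch(prep, np.array([i]))))
            for i in train_idx
        ]
        test_i = int(np.argmax(norms))
        pros, _ = proponents_opponents(
            single, model, slice_batch(prep, train_idx),
            slice_batch(prep, np.array([test_i])), top_k=1,
        )
        assert pros[0][0] == prep["sample_ids"][test_i]

    def test_proponents_opponents_carry_scores_and_sizes(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        pros, opps = proponents_opponents(
            ckpts, model, slice_batch(prep, np.arange(20)),
            slice_batch(prep, np.array([25])), top_k=4,
        )
        assert len(pros) == len(opps) == 4
        assert min(s for _, s in pros) >= max(s for _, s in opps)

    def test_top_k_larger_than_train_set_rejected(self, oracle_setup):
        _, _, prep, model, ckpts = oracle_setup
        with pytest.raises(ValueError):
            proponents_opponents(
                ckpts, model, slice_batch(prep, np.arange(3)),
                slice_batch(prep, np.array([4])), top_k=5,
            )
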