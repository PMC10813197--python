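import numpy as np
import pytest

from emrfuse._autodiff import Tensor
from emrfuse.config import SUBSETS, model_profile
from emrfuse.fusion import (MAG, AttentionBacktrack, PredictionHead,
                            SequenceFusion, bce_loss, mag_fuse, predict)


def zeroed(module):
    for p in module.parameters():
        p.data[:] = 0.0
    return module


class TestMAGAlgebra:
    def test_zero_gate_weights_give_half_gate(self, rng):
        mag = MAG(d_primary=3, d_aux=2, rng=rng)
        mag.w_g.weight.data[:] = 0.0
        mag.w_g.bias.data[:] = 0.0
        out = mag(Tensor(rng.normal(size=(5, 3))), Tensor(rng.normal(size=(5, 2))))
        np.testing.assert_allclose(out.gate.data, 0.5)

    def test_zero_displacement_returns_primary_exactly(self, rng):
        mag = MAG(d_primary=3, d_aux=2, rng=rng)
        mag.w_h.weight.data[:] = 0.0
        mag.w_h.bias.data[:] = 0.0
        f_p = Tensor(rng.normal(size=(4, 3)).astype(np.float32))
        out = mag(f_p, Tensor(rng.normal(size=(4, 2))))
        np.testing.assert_array_equal(out.fused.data, f_p.data)
        np.testing.assert_array_equal(out.alpha.data, 0.0)

    def test_alpha_clamps_displacement_to_half(self, rng):
        """F_p=(3,4) so ||F_p||=5; H=(10,0) by construction; beta=1 ->
        alpha = min(1*5/10, 1) = 0.5 and E = F_p + 0.5*H = (8,4)."""
        mag = MAG(d_primary=2, d_aux=2, rng=rng)
        mag.w_g.weight.data[:] = 0.0
        mag.w_g.bias.data[:] = 0.0          # gate = 0.5
        mag.w_h.weight.data[:] = 0.0
        mag.w_h.bias.data[:] = np.array([20.0, 0.0])  # H = 0.5 * 20 = 10
        mag.beta.data = np.asarray(1.0, dtype=np.float32)
        out = mag_fuse(np.array([3.0, 4.0]), np.array([1.0, 1.0]), mag)
        np.testing.assert_allclose(out.alpha.data, [[0.5]], atol=1e-6)
        np.testing.assert_allclose(out.fused.data, [[8.0, 4.0]], atol=1e-5)

    def test_gate_alpha_and_norm_bounds_over_many_draws(self, rng):
        """10^4 random draws: g in (0,1), alpha in [0,1],
        ||alpha*H|| <= beta*||F_p||."""
        mag = MAG(d_primary=8, d_aux=6, rng=rng)
        f_p = Tensor(rng.normal(0, 3, size=(10_000, 8)))
        f_a = Tensor(rng.normal(0, 3, size=(10_000, 6)))
        out = mag(f_p, f_a)
        g, a = out.gate.data, out.alpha.data
        assert np.all((g > 0.0) & (g < 1.0))
        assert np.all((a >= 0.0) & (a <= 1.0))
        lhs = np.linalg.norm(a * out.displacement.data, axis=-1)
        rhs = float(mag.beta.data) * np.linalg.norm(f_p.data, axis=-1)
        assert np.all(lhs <= rhs * (1 + 1e-5) + 1e-6)
        assert np.all(np.isfinite(out.fused.data))

    def test_scalar_gate_mode_uses_one_gate_per_sample(self, rng):
        mag = MAG(d_primary=4, d_aux=4, rng=rng, gate_mode="scalar")
        out = mag(Tensor(rng.normal(size=(3, 4))), Tensor(rng.normal(size=(3, 4))))
        assert out.gate.shape == (3, 1)

    def test_nonfinite_input_rejected(self, rng):
        mag = MAG(d_primary=2, d_aux=2, rng=rng)
        bad = np.array([[np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            mag(Tensor(bad), Tensor(np.ones((1, 2))))


class TestAttentionBacktrack:
    def test_single_window_is_identity(self, rng):
        bt = AttentionBacktrack(4, rng)
        e = Tensor(rng.normal(size=(2, 1, 4)))
        np.testing.assert_array_equal(bt(e).data, e.data)

    def test_weights_sum_to_one_over_history(self, rng):
        bt = AttentionBacktrack(8, rng)
        bt(Tensor(rng.normal(size=(3, 6, 8))))
        w = bt.last_weights
        np.testing.assert_allclose(w[:, 1:].sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(w[:, 0] == 0.0)  # window 1 has no history

    def test_identical_history_shares_weight_equally(self, rng):
        """Query 3 over two identical history vectors: both weights 0.5."""
        bt = AttentionBacktrack(4, rng)
        e = rng.normal(size=(1, 3, 4))
        e[0, 1] = e[0, 0]
        bt(Tensor(e))
        np.testing.assert_allclose(bt.last_weights[0, 2, :2], [0.5, 0.5], atol=1e-6)

    def test_strict_causality_under_future_perturbation(self, rng):
        bt = AttentionBacktrack(4, rng)
        e = rng.normal(size=(1, 5, 4))
        q1 = bt(Tensor(e)).data
        e2 = e.copy()
        e2[0, 3:] += 10.0  # perturb windows 4..5 only
        q2 = bt(Tensor(e2)).data
        np.testing.assert_allclose(q1[0, :3], q2[0, :3], atol=1e-5)

    def test_ablation_switch_is_exact_identity(self, rng):
        bt = AttentionBacktrack(4, rng, enabled=False)
        e = Tensor(rng.normal(size=(2, 5, 4)))
        out = bt(e)
        assert out is e
        assert bt.last_weights is None

    def test_residual_complement_adds_history_context(self, rng):
        bt = AttentionBacktrack(4, rng)
        e = rng.normal(size=(1, 4, 4)).astype(np.float32)
        q = bt(Tensor(e)).data
        np.testing.assert_array_equal(q[0, 0], e[0, 0])  # no history at i=1
        assert np.abs(q[0, 1:] - e[0, 1:]).max() > 1e-6


class TestSequenceFusionAndHead:
    def test_day_zero_prepended_gives_length_eleven(self, rng):
        sf = SequenceFusion(d_static=5, d_model=4, rng=rng)
        seen = {}
        real = sf.lstm

        def spy(seq):
            seen["len"] = seq.shape[1]
            return real(seq)

        sf.lstm = spy
        sf(Tensor(rng.normal(size=(2, 5))), Tensor(rng.normal(size=(2, 10, 4))))
        assert seen["len"] == 11

    def test_zero_parameters_give_zero_z_and_half_prediction(self, rng):
        sf = zeroed(SequenceFusion(d_static=5, d_model=4, rng=rng))
        head = zeroed(PredictionHead(4, rng))
        z = sf(Tensor(rng.normal(size=(2, 5))), Tensor(rng.normal(size=(2, 3, 4))))
        assert np.all(z.data == 0.0)
        np.testing.assert_allclose(predict(z, head).data, 0.5)

    def test_window_order_matters(self, rng):
        sf = SequenceFusion(d_static=None, d_model=4, rng=rng)
        q = rng.normal(size=(1, 6, 4))
        z1 = sf(None, Tensor(q)).data
        z2 = sf(None, Tensor(q[:, ::-1].copy())).data
        assert np.abs(z1 - z2).max() > 1e-6

    def test_known_logit_maps_through_sigmoid(self, rng):
        head = PredictionHead(4, rng)
        head.linear.weight.data[:] = 0.0
        head.linear.bias.data[:] = np.log(3.0)
        out = head(Tensor(np.zeros((1, 4))))
        np.testing.assert_allclose(out.data, 0.75, atol=1e-6)

    def test_prediction_monotone_in_logit(self, rng):
        head = PredictionHead(1, rng)
        head.linear.weight.data[:] = 1.0
        head.linear.bias.data[:] = 0.0
        z = Tensor(np.linspace(-3, 3, 7).reshape(-1, 1))
        out = head(z).data
        assert np.all(np.diff(out) > 0)
        assert np.all((out > 0) & (out < 1))


class TestBCELoss:
    def test_uncertain_prediction_costs_ln2(self):
        loss = bce_loss(np.array([1.0]), Tensor(np.array([0.5])))
        assert loss.item() == pytest.approx(np.log(2), rel=1e-5)

    def test_perfect_predictions_cost_almost_nothing(self):
        loss = bce_loss(np.array([1.0, 0.0]), Tensor(np.array([1.0, 0.0])))
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_batch_mean_of_two_terms(self):
        loss = bce_loss(np.array([1.0, 0.0]), Tensor(np.array([0.5, 0.5])))
        assert loss.item() == pytest.approx(np.log(2), rel=1e-5)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty batch"):
            bce_loss(np.array([]), Tensor(np.array([])))


class TestFullModel:
    @staticmethod
    def build(subset="full", seed=0, **overrides):
        from emrfuse.fusion import MultimodalFusionModel
        cfg = model_profile("desk", d_model=8, d_ff=16, d_note=12,
                            window_token_budget=6, static_token_budget=8,
                            modality_subset=subset, **overrides)
        model = MultimodalFusionModel(cfg, onehot_dim=7, n_temporal_features=3,
                                      window_days=3, vocab_size=20, seed=seed)
        return cfg, model

    @staticmethod
    def batch(rng, B=3, n=10):
        onehot = np.zeros((B, 7), dtype=np.float32)
        onehot[:, [0, 4]] = 1.0
        return {
            "static_onehot": onehot,
            "static_ids": rng.integers(2, 20, size=(B, 8)),
            "static_mask": np.ones((B, 8), dtype=bool),
            "tabular": rng.normal(size=(B, n, 3, 3)).astype(np.float32),
            "note_ids": rng.integers(2, 20, size=(B, n, 6)),
            "note_mask": np.ones((B, n, 6), dtype=bool),
        }

    def test_forward_shapes_and_range(self, rng):
        _, model = self.build()
        out = model(self.batch(rng))
        assert out.y_hat.shape == (3,)
        assert np.all((out.y_hat.data > 0) & (out.y_hat.data < 1))
        assert out.q.shape == (3, 10, 8)
        assert out.e_static.shape == (3, 12)

    @pytest.mark.parametrize("primary_static,primary_temporal", [
        ("static_notes", "temporal_notes"),
        ("static_tabular", "temporal_notes"),
        ("static_notes", "temporal_tabular"),
        ("static_tabular", "temporal_tabular"),
    ])
    def test_primary_modality_selectable(self, rng, primary_static, primary_temporal):
        """All four primary assignments run; the static fused vector lives in
        the primary modality's space (note dim vs one-hot dim)."""
        _, model = self.build(primary_static=primary_static,
                              primary_temporal=primary_temporal)
        out = model(self.batch(rng))
        expected_dim = 12 if primary_static == "static_notes" else 7
        assert out.e_static.shape == (3, expected_dim)
        assert np.all(np.isfinite(out.y_hat.data))

    @pytest.mark.parametrize("subset", list(SUBSETS))
    def test_modality_subsets_run(self, rng, subset):
        _, model = self.build(subset=subset)
        out = model(self.batch(rng))
        assert np.all(np.isfinite(out.y_hat.data))

    def test_static_only_model_never_builds_temporal_encoders(self, rng):
        _, model = self.build(subset="only_static")
        model(self.batch(rng))
        assert model.temporal_tabular_encoder is None
        assert model.temporal_note_encoder is None
        assert model.backtrack is None

    def test_notes_only_model_never_builds_tabular_path(self, rng):
        _, model = self.build(subset="only_notes")
        out = model(self.batch(rng))
        assert model.temporal_tabular_encoder is None
        assert model.static_mag is None and model.temporal_mag is None
        assert out.e_static.shape == (3, 12)

    def test_backtracking_off_passes_fused_windows_through(self, rng):
        _, on = self.build(seed=3)
        _, off = self.build(seed=3, backtracking=False)
        off.load_state_dict(on.state_dict())
        b = self.batch(rng)
        out_on, out_off = on(b), off(b)
        np.testing.assert_array_equal(out_off.q.data, out_off.e_temporal.data)
        assert np.abs(out_on.q.data - out_on.e_temporal.data).max() > 1e-6

    def test_same_seed_same_prediction(self, rng):
        _, m1 = self.build(seed=5)
        _, m2 = self.build(seed=5)
        b = self.batch(rng)
        np.testing.assert_array_equal(m1(b).y_hat.data, m2(b).y_hat.data)
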