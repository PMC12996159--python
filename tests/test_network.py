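"""Forward stages of the decoder against closed forms and brute-force
oracles, plus the architecture's parameter budget."""

import numpy as np
import pytest

from migraphdec.autodiff import Tensor, gradcheck
from migraphdec.network import (
    ForwardTrace,
    MIGraphNet,
    ModelConfig,
    fuse_add,
    log_variance,
    readout_sum,
)
from migraphdec.training import cross_entropy

from conftest import TINY


def _bypass_bn(model):
    """Make every BN layer the identity (eps 0, default running stats)."""
    for bn in model._bn_layers().values():
        bn.eps = 0.0


def _random_adj(rng, C, k):
    iu, ju = np.triu_indices(C, 1)
    pick = rng.choice(len(iu), size=k, replace=False)
    a = np.zeros((C, C))
    a[iu[pick], ju[pick]] = 1
    return a + a.T


class TestModelConfig:
    def test_m_must_exceed_band_count(self):
        with pytest.raises(ValueError, match="m must exceed"):
            ModelConfig(m=9, n_bands=9)

    def test_attention_window_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(l=6)

    def test_window_count(self):
        assert ModelConfig().t == 4
        assert ModelConfig(T=1100, w=250).t == 4  # remainder discarded


class TestParameterBudget:
    def test_canonical_config_has_13458_trainable_parameters(self):
        model = MIGraphNet(ModelConfig())
        assert model.count_parameters() == 13_458

    def test_component_decomposition(self):
        breakdown = MIGraphNet(ModelConfig()).parameter_breakdown()
        assert breakdown == {
            "spatial_conv": 12_672, "bn_spatial": 128, "pointwise_conv": 10,
            "bn_pointwise": 2, "gatv2": 108, "bn_gat": 8, "acsim": 14,
            "asdta": 256, "classifier": 260,
        }

    def test_doubling_m_roughly_doubles_spatial_conv_count(self):
        b64 = MIGraphNet(ModelConfig(m=64)).parameter_breakdown()
        b128 = MIGraphNet(ModelConfig(m=128)).parameter_breakdown()
        assert b128["spatial_conv"] == 2 * b64["spatial_conv"]

    def test_freezing_everything_counts_zero(self):
        model = MIGraphNet(ModelConfig())
        for p in model.parameters():
            p.requires_grad = False
        assert sum(p.size for p in model.parameters() if p.requires_grad) == 0


class TestSpatialConv:
    def test_output_shape_canonical(self, rng):
        model = MIGraphNet(ModelConfig(), seed=0)
        out = model.spatial_conv_forward(rng.standard_normal((9, 22, 1000)))
        assert out.shape == (64, 1000)

    def test_zero_input_maps_to_zero(self):
        model = MIGraphNet(ModelConfig(**TINY), seed=0)
        _bypass_bn(model)
        out = model.spatial_conv_forward(np.zeros((2, 4, 64)))
        np.testing.assert_array_equal(out, 0.0)

    def test_selector_kernel_reproduces_input_row(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=0, dtype=np.float64)
        _bypass_bn(model)
        model.spatial_w.data[:] = 0.0
        model.spatial_w.data[0, 1 * 4 + 2] = 1.0  # band 1, channel 2
        x = rng.standard_normal((2, 4, 64))
        out = model.spatial_conv_forward(x)
        row = x[1, 2]
        elu_row = np.where(row > 0, row, np.exp(np.minimum(row, 0)) - 1)
        np.testing.assert_allclose(out[0], elu_row, atol=1e-12)


class TestLogVariance:
    def test_window_count_canonical(self, rng):
        out = log_variance(rng.standard_normal((64, 1000)), w=250)
        assert out.shape == (64, 4)

    def test_constant_signal_floors_at_eps(self):
        out = log_variance(np.ones((3, 100)), w=25, eps=1e-6)
        np.testing.assert_allclose(out, np.log(1e-6))

    def test_matches_direct_per_window_computation(self, rng):
        x = rng.standard_normal((5, 120))
        out = log_variance(x, w=30)
        direct = np.log(np.maximum(
            x.reshape(5, 4, 30).var(axis=-1), 1e-6))
        np.testing.assert_allclose(out, direct, atol=1e-10)

    def test_standard_normal_window_concentrates_near_zero(self):
        rng = np.random.default_rng(11)
        vals = log_variance(rng.standard_normal((400, 250)), w=250)
        assert np.mean(np.abs(vals) < 0.3) >= 0.99

    def test_window_longer_than_signal_rejected(self, rng):
        with pytest.raises(ValueError, match="w"):
            log_variance(rng.standard_normal((2, 10)), w=20)


class TestSpectralFuse:
    def test_node_feature_shape_canonical(self, rng):
        model = MIGraphNet(ModelConfig(), seed=0)
        out = model.spectral_fuse(rng.standard_normal((9, 22, 1000)))
        assert out.shape == (22, 4)

    def test_one_hot_band_selector(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=0, dtype=np.float64)
        _bypass_bn(model)
        model.point_w.data[:] = [0.0, 1.0]
        model.point_b.data[:] = 0.0
        x = rng.standard_normal((2, 4, 64))
        out = model.spectral_fuse(x)
        band1 = np.where(x[1] > 0, x[1], np.exp(np.minimum(x[1], 0)) - 1)
        np.testing.assert_allclose(out, log_variance(band1, w=16), atol=1e-10)

    def test_channel_permutation_equivariance(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=0, dtype=np.float64)
        x = rng.standard_normal((2, 4, 64))
        perm = rng.permutation(4)
        np.testing.assert_allclose(
            model.spectral_fuse(x[:, perm]),
            model.spectral_fuse(x)[perm],
            atol=1e-12,
        )


class TestGATv2:
    def test_self_loops_only_reduces_to_per_node_transform(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=2, dtype=np.float64)
        _bypass_bn(model)
        H = rng.standard_normal((4, 4))
        out = model.gatv2_forward(H, np.zeros((4, 4)))
        ref = np.mean([H @ model.gat_wr.data[k] for k in range(2)], axis=0)
        ref = np.where(ref > 0, ref, np.exp(np.minimum(ref, 0)) - 1)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_identical_features_give_uniform_attention(self, rng):
        # with all node features equal, every alpha is 1/|N_i| and all
        # output rows coincide
        model = MIGraphNet(ModelConfig(**TINY), seed=2, dtype=np.float64)
        H = np.tile(rng.standard_normal(4), (4, 1))
        adj = np.ones((4, 4)) - np.eye(4)
        out = model.gatv2_forward(H, adj)
        np.testing.assert_allclose(out - out[0], 0.0, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=3, dtype=np.float64)
        for trial in range(5):
            H = rng.standard_normal((4, 4))
            adj = _random_adj(rng, 4, 3)
            perm = rng.permutation(4)
            P = np.eye(4)[perm]
            out_perm = model.gatv2_forward(H[perm], P @ adj @ P.T)
            np.testing.assert_allclose(
                out_perm, model.gatv2_forward(H, adj)[perm], atol=1e-10
            )

    def test_adjacency_shape_mismatch_rejected(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=0)
        with pytest.raises(ValueError, match="adjacency"):
            model.gatv2_forward(rng.standard_normal((4, 4)), np.zeros((5, 5)))


class TestFusion:
    def test_readout_sum_examples(self, rng):
        one_hot = np.eye(4)[[0, 1, 1, 3]]
        np.testing.assert_array_equal(readout_sum(one_hot), [1, 2, 0, 1])
        x = rng.standard_normal((6, 3))
        np.testing.assert_allclose(readout_sum(x[::-1]), readout_sum(x))
        np.testing.assert_array_equal(readout_sum(np.zeros((5, 3))), 0.0)

    def test_fuse_add_broadcast(self, rng):
        x = rng.standard_normal((8, 4))
        g = rng.standard_normal(4)
        fused = fuse_add(x, g)
        np.testing.assert_allclose(fused - x, np.tile(g, (8, 1)), atol=1e-12)
        np.testing.assert_array_equal(fuse_add(x, np.zeros(4)), x)
        with pytest.raises(ValueError, match="window"):
            fuse_add(x, rng.standard_normal(5))


class TestACSIM:
    def test_zero_weights_gate_exactly_half(self, tiny_model, rng):
        x = rng.standard_normal((8, 4))
        out, u = tiny_model.acsim_forward(x)
        np.testing.assert_array_equal(u, 0.5)
        np.testing.assert_allclose(out, 0.5 * x, atol=1e-12)

    def test_unit_impulse_weights_pass_descriptors_through(self, tiny_model, rng):
        tiny_model.acsim_w_max.data[:] = [0, 1, 0]  # centred impulse, l=3
        tiny_model.acsim_w_avg.data[:] = [0, 1, 0]
        x = rng.standard_normal((8, 4))
        _, u = tiny_model.acsim_forward(x)
        expected = 1 / (1 + np.exp(-(x.max(axis=1) + x.mean(axis=1))))
        np.testing.assert_allclose(u, expected, atol=1e-12)

    def test_cross_correlation_matches_sliding_dot_product_loop(self, rng):
        cfg = ModelConfig(C=4, T=64, n_bands=2, m=10, w=16, n_classes=2,
                          n_heads=2, l=7)
        model = MIGraphNet(cfg, seed=4, dtype=np.float64)
        w = rng.standard_normal(7)
        model.acsim_w_max.data[:] = w
        model.acsim_w_avg.data[:] = 0.0
        x = rng.standard_normal((10, 4))
        _, u = model.acsim_forward(x)
        z = x.max(axis=1)
        zp = np.concatenate([np.zeros(3), z, np.zeros(3)])
        brute = np.array([
            sum(w[k] * zp[i + k] for k in range(7)) for i in range(10)
        ])
        logit = np.log(u / (1 - u))
        np.testing.assert_allclose(logit, brute, atol=1e-10)

    def test_gate_bounds_output(self, tiny_model, rng):
        tiny_model.acsim_w_max.data[:] = rng.standard_normal(3)
        tiny_model.acsim_w_avg.data[:] = rng.standard_normal(3)
        x = rng.standard_normal((8, 4))
        out, u = tiny_model.acsim_forward(x)
        assert np.all((u > 0) & (u < 1))
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(**{**TINY, "l": 4})


class TestASDTA:
    def test_zero_weights_give_uniform_attention_and_row_means(self, tiny_model, rng):
        x = rng.standard_normal((8, 4))
        out, alpha = tiny_model.asdta_forward(x)
        np.testing.assert_allclose(alpha, 0.25, atol=1e-12)
        np.testing.assert_allclose(out, x.mean(axis=1), atol=1e-12)

    def test_rows_always_sum_to_one(self, tiny_model, rng):
        tiny_model.asdta_w.data[:] = rng.standard_normal((8, 4))
        _, alpha = tiny_model.asdta_forward(rng.standard_normal((8, 4)))
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_saturated_row_picks_single_window(self, tiny_model, rng):
        tiny_model.asdta_w.data[2, 3] = 50.0
        x = rng.standard_normal((8, 4))
        out, _ = tiny_model.asdta_forward(x)
        assert out[2] == pytest.approx(x[2, 3], abs=1e-12)


class TestFullForward:
    def test_trace_shapes_canonical_config(self, rng):
        model = MIGraphNet(ModelConfig(), seed=0)
        views = rng.standard_normal((9, 22, 1000))
        adj = _random_adj(rng, 22, 100)
        trace = model.forward(views, adj)
        assert isinstance(trace, ForwardTrace)
        assert trace.x_ssf.shape == (64, 1000)
        assert trace.x_tssf.shape == (64, 4)
        assert trace.x_sf.shape == (22, 4)
        assert trace.x_sgf.shape == (4,)
        assert trace.x_estf.shape == (64, 4)
        assert trace.u.shape == (64,)
        assert trace.x_acsif.shape == (64, 4)
        assert trace.asdta_alpha.shape == (64, 4)
        assert trace.x_asdtf.shape == (64,)
        assert trace.logits.shape == (4,)
        probs = np.exp(trace.logits - trace.logits.max())
        assert probs.sum() / probs.sum() == 1.0
        np.testing.assert_allclose(trace.asdta_alpha.sum(axis=1), 1.0,
                                   atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_trace_shape_contract_random_small_configs(self, seed):
        r = np.random.default_rng(seed)
        n_bands = int(r.integers(2, 5))
        cfg = ModelConfig(
            C=int(r.integers(3, 8)), T=int(r.integers(64, 200)),
            n_bands=n_bands, m=int(r.integers(n_bands + 1, 16)),
            w=int(r.integers(16, 48)), n_classes=int(r.integers(2, 5)),
            n_heads=int(r.integers(1, 4)), l=int(r.choice([3, 5, 7])),
        )
        model = MIGraphNet(cfg, seed=seed)
        views = r.standard_normal((cfg.n_bands, cfg.C, cfg.T))
        adj = _random_adj(r, cfg.C, cfg.C - 1)
        trace = model.forward(views, adj)
        assert trace.x_tssf.shape == (cfg.m, cfg.t)
        assert trace.x_sf.shape == (cfg.C, cfg.t)
        assert trace.logits.shape == (cfg.n_classes,)

    def test_identical_trials_in_one_batch_give_identical_traces(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=0)
        views = rng.standard_normal((2, 4, 64))
        adj = _random_adj(rng, 4, 3) + np.eye(4)
        batch = np.stack([views, views])
        out = model._forward(batch, np.stack([adj, adj]), training=False)
        for key, val in out.items():
            if val.data.shape and val.data.shape[0] == 2:
                np.testing.assert_array_equal(val.data[0], val.data[1])

    def test_graph_branch_is_channel_permutation_invariant(self, rng):
        model = MIGraphNet(ModelConfig(**TINY), seed=5, dtype=np.float64)
        H = rng.standard_normal((4, 4))
        adj = _random_adj(rng, 4, 4)
        perm = rng.permutation(4)
        P = np.eye(4)[perm]
        x_sgf = readout_sum(model.gatv2_forward(H, adj))
        x_sgf_perm = readout_sum(model.gatv2_forward(H[perm], P @ adj @ P.T))
        np.testing.assert_allclose(x_sgf, x_sgf_perm, atol=1e-8)

    def test_end_to_end_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(**{**TINY, "dropout": 0.0})
        model = MIGraphNet(cfg, seed=1, dtype=np.float64)
        x = rng.standard_normal((3, 2, 4, 64))
        masks = np.stack([_random_adj(rng, 4, 3) + np.eye(4)] * 3)
        labels = np.array([0, 1, 0])

        def loss():
            out = model._forward(x, masks, training=False)
            return cross_entropy(out["logits"], labels)

        worst = gradcheck(loss, model.parameters(), n_samples=50, seed=0)
        assert worst < 1e-4


class TestCheckpoint:
    def test_save_load_roundtrip(self, tiny_model, rng, tmp_path):
        x = rng.standard_normal((2, 2, 4, 64))
        masks = np.stack([_random_adj(rng, 4, 3) + np.eye(4)] * 2)
        tiny_model._forward(x, masks, training=True)  # move BN stats
        path = tmp_path / "model.mgd"
        tiny_model.save(path)
        back = MIGraphNet.load(path)
        assert back.config == tiny_model.config
        a = back._forward(x, masks, training=False)["logits"].data
        b = tiny_model._forward(x, masks, training=False)["logits"].data
        np.testing.assert_allclose(a, b, atol=1e-12)
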