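"""Architecture analytics (layer count, ERF) and the two-pathway regressor."""

import numpy as np
import pytest

from thermoresp._tensor import Tensor
from thermoresp.net import (
    CONFIGURATIONS, LayerLedger, NetConfig, build_model, effective_receptive_field,
    layer_count, load_model, predict_rr, save_model, spatial_ledger,
)
from thermoresp.windows import ClipPair


def erf_by_matrix_trace(entries):
    """Independent ERF oracle: compose the (all-ones) convolution matrices of
    the stack and measure the nonzero input support of one central output
    unit."""
    bound = sum((k - 1) * int(np.prod([s for _, s in entries][:i]))
                for i, (k, _) in enumerate(entries)) + 1
    length = 4 * bound + 16
    mat = np.eye(length)
    for k, s in entries:
        n_in = mat.shape[0]
        n_out = (n_in - k) // s + 1
        conv = np.zeros((n_out, n_in))
        for o in range(n_out):
            conv[o, o * s : o * s + k] = 1.0
        mat = conv @ mat
    centre = mat.shape[0] // 2
    support = np.nonzero(mat[centre])[0]
    return int(support[-1] - support[0] + 1)


class TestLayerCount:
    @pytest.mark.parametrize("D,d,q,expected", [
        (16, 0, 2, 32),
        (4, 4, 2, 0),
        (4, 1, 2, 6),
    ])
    def test_formula(self, D, d, q, expected):
        assert layer_count(D, d, q) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            layer_count(4, 5, 2)
        with pytest.raises(ValueError):
            layer_count(4, 0, 0)


class TestEffectiveReceptiveField:
    @pytest.mark.parametrize("configuration,expected", [(1, 37), (2, 71), (3, 105)])
    def test_printed_configurations(self, configuration, expected):
        stem, resid = CONFIGURATIONS[configuration]
        cfg = NetConfig(stem_spatial_k=stem, residual_spatial_k=resid)
        assert effective_receptive_field(spatial_ledger(cfg)) == expected

    def test_single_layer(self):
        assert effective_receptive_field(LayerLedger([(5, 1)])) == 5

    def test_strided_stack(self):
        entries = [(7, 2), (3, 1), (3, 1)]
        assert effective_receptive_field(LayerLedger(entries)) == 15
        assert erf_by_matrix_trace(entries) == 15

    def test_matches_brute_force_on_random_stacks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            depth = int(rng.integers(1, 6))
            entries = [(int(rng.integers(1, 6)), int(rng.integers(1, 3)))
                       for _ in range(depth)]
            assert effective_receptive_field(LayerLedger(entries)) == \
                erf_by_matrix_trace(entries)

    def test_monotone_in_kernel_sizes(self):
        erfs = []
        for configuration in (1, 2, 3):
            stem, resid = CONFIGURATIONS[configuration]
            cfg = NetConfig(stem_spatial_k=stem, residual_spatial_k=resid)
            erfs.append(effective_receptive_field(spatial_ledger(cfg)))
        assert erfs[0] < erfs[1] < erfs[2]

    def test_ledger_shape(self):
        ledger = spatial_ledger(NetConfig())
        assert len(ledger.entries) == 17  # stem + 16 bottleneck blocks
        assert all(s == 1 for _, s in ledger.entries)
        deeper = spatial_ledger(NetConfig(backbone="resnet101"))
        assert len(deeper.entries) == 34  # stem + 33 blocks

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValueError):
            effective_receptive_field(LayerLedger([]))


class TestNetConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            NetConfig(stem_spatial_k=4)
        with pytest.raises(ValueError):
            NetConfig(fusion_kernel_t=6)
        with pytest.raises(ValueError):
            NetConfig(alpha=32, beta=16)
        with pytest.raises(ValueError):
            NetConfig(alpha=3, window_len=128)
        with pytest.raises(ValueError):
            NetConfig(backbone="vgg")

    def test_parameter_count_grows_with_configuration(self):
        counts = []
        for configuration in (1, 2, 3):
            stem, resid = CONFIGURATIONS[configuration]
            cfg = NetConfig(window_len=16, alpha=2, beta=8, in_channels=1,
                            width_multiplier=0.0625, fusion_kernel_t=5,
                            stem_spatial_k=stem, residual_spatial_k=resid)
            counts.append(build_model(cfg).n_parameters())
        assert counts[0] < counts[1] < counts[2]

    def test_resnet101_backbone_builds_deeper(self, tiny_net_config):
        from dataclasses import replace

        deep = build_model(replace(tiny_net_config, backbone="resnet101"))
        shallow = build_model(tiny_net_config)
        assert deep.n_parameters() > shallow.n_parameters()
        assert len(deep.sparse_stages[2]) == 23  # 3+4+23+3 bottlenecks

    def test_incompatible_pathway_ratio_rejected(self):
        cfg = NetConfig(window_len=24, alpha=3, beta=8, in_channels=1,
                        width_multiplier=0.0625, fusion_kernel_t=5)
        with pytest.raises(ValueError, match="multiple of alpha"):
            build_model(cfg)


def _clips_for(model_cfg, n, hw=16, seed=0):
    rng = np.random.default_rng(seed)
    clips = []
    for i in range(n):
        dense = rng.random((model_cfg.in_channels, model_cfg.t_dense, hw, hw),
                           dtype=np.float32)
        sparse = rng.random((model_cfg.in_channels, model_cfg.t_sparse, hw, hw),
                            dtype=np.float32)
        clips.append(ClipPair(dense_view=dense, sparse_view=sparse,
                              label_rr=12.0, subject_id=f"S{i}"))
    return clips


class TestTwoPathwayRegressor:
    def test_forward_shape_contract(self, tiny_model, tiny_net_config):
        clips = _clips_for(tiny_net_config, 3)
        preds = predict_rr(tiny_model, clips)
        assert preds.shape == (3,)
        assert np.isfinite(preds).all()

    def test_inference_deterministic_and_batch_independent(self, tiny_model,
                                                           tiny_net_config):
        clips = _clips_for(tiny_net_config, 8, seed=1)
        a = predict_rr(tiny_model, clips, batch_size=8)
        b = predict_rr(tiny_model, clips, batch_size=8)
        one = predict_rr(tiny_model, [clips[3]], batch_size=1)
        assert a == pytest.approx(b)
        assert one[0] == pytest.approx(a[3], abs=1e-5)

    def test_zero_head_predicts_bias(self, tiny_net_config):
        model = build_model(tiny_net_config, seed=0)
        model.init_head_bias(17.5)
        clips = _clips_for(tiny_net_config, 4, seed=2)
        preds = predict_rr(model, clips)
        assert preds == pytest.approx(np.full(4, 17.5), abs=1e-5)

    def test_fully_convolutional_up_to_head(self, tiny_model, tiny_net_config):
        # Doubling the spatial input changes no parameter shapes: the same
        # model accepts 32x32 clips after being built for 16x16.
        shapes = [p.data.shape for p in tiny_model.parameters()]
        clips = _clips_for(tiny_net_config, 2, hw=32, seed=3)
        preds = predict_rr(tiny_model, clips)
        assert preds.shape == (2,)
        assert [p.data.shape for p in tiny_model.parameters()] == shapes

    def test_geometry_mismatch_rejected(self, tiny_model):
        bad = ClipPair(dense_view=np.zeros((3, 8, 16, 16), dtype=np.float32),
                       sparse_view=np.zeros((3, 2, 16, 16), dtype=np.float32),
                       label_rr=10.0, subject_id="S0")
        with pytest.raises(ValueError, match="channels"):
            predict_rr(tiny_model, [bad])

    def test_checkpoint_round_trip(self, tmp_path, tiny_model, tiny_net_config):
        clips = _clips_for(tiny_net_config, 2, seed=4)
        before = predict_rr(tiny_model, clips)
        path = tmp_path / "model.zip"
        save_model(tiny_model, path)
        restored = load_model(path)
        assert restored.config == tiny_net_config
        assert predict_rr(restored, clips) == pytest.approx(before)
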