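"""Architecture builders: shapes, head space, backbones, freeze plans, cost."""

import itertools

import numpy as np
import pytest

import glaucopt as g
from glaucopt.arch import HEAD_RANGES, ACTIVATION_CHOICES, OPTIMIZER_CHOICES


class TestMultibranchExtractor:
    def test_printed_shapes_at_128(self):
        spec = g.build_multibranch_extractor((128, 128, 3))
        assert spec.shape_of("b1_conv2") == (32, 32, 64)
        assert spec.shape_of("b2_conv2") == (32, 32, 128)
        assert spec.shape_of("concat") == (32, 32, 192)
        assert spec.output_shape == (16, 16, 256)

    def test_hand_propagated_shapes_at_64(self):
        spec = g.build_multibranch_extractor((64, 64, 3))
        assert spec.output_shape == (8, 8, 256)

    @pytest.mark.parametrize("shape", [(100, 100, 3), (64, 32, 3)])
    def test_bad_input_side_rejected(self, shape):
        with pytest.raises(ValueError):
            g.build_multibranch_extractor(shape)

    def test_width_scales_channels(self):
        spec = g.build_multibranch_extractor((32, 32, 3), width=0.5)
        assert spec.output_shape == (4, 4, 128)


class TestHead:
    def test_posttuned_multibranch_head_builds(self):
        """The tuned two-branch head (3 blocks, 821 nodes, dropout 0.2,
        no BN, flatten, relu, sgd) is a valid point of the search box."""
        cfg = g.HeadConfig(
            n_dense_blocks=3,
            n_dense_nodes=821,
            dropout_rate=0.2,
            batch_norm=False,
            flatten_type="flatten",
            activation="relu",
            optimizer="sgd",
        )
        spec = g.build_head(cfg, (16, 16, 256))
        assert sum(l.kind == "dense" for l in spec.layers) == 3
        assert spec.layers[-1].kind == "sigmoid-output"

    def test_minimal_config_structure(self):
        cfg = g.HeadConfig(n_dense_blocks=1, n_dense_nodes=32, flatten_type="gap")
        spec = g.build_head(cfg, (16, 16, 256))
        kinds = [l.kind for l in spec.layers]
        assert kinds == ["gap", "dense", "activation", "dropout", "sigmoid-output"]

    def test_flatten_dense_parameter_count(self):
        """Dense over flattened 16x16x256 with 32 nodes has
        (16*16*256 + 1) * 32 = 2,097,184 parameters, confirmed by counting
        the compiled network's actual arrays."""
        cfg = g.HeadConfig(n_dense_blocks=1, n_dense_nodes=32, flatten_type="flatten")
        spec = g.build_head(cfg, (16, 16, 256))
        dense_params = spec.parameter_count() - (32 + 1)  # minus sigmoid output
        assert dense_params == (16 * 16 * 256 + 1) * 32 == 2_097_184
        net = g.compile_network(spec, seed=0)
        layer = net.layers["head_dense1"]
        assert sum(a.size for a in layer.params.values()) == 2_097_184

    def test_every_corner_of_the_box_builds(self):
        corners = itertools.product(
            HEAD_RANGES["n_dense_blocks"],
            HEAD_RANGES["n_dense_nodes"],
            HEAD_RANGES["dropout_rate"],
            (True, False),
            HEAD_RANGES["flatten_type"],
            ACTIVATION_CHOICES,
            OPTIMIZER_CHOICES,
        )
        for blocks, nodes, rate, bn, ft, act, opt in corners:
            cfg = g.HeadConfig(
                n_dense_blocks=blocks,
                n_dense_nodes=nodes,
                dropout_rate=rate,
                batch_norm=bn,
                flatten_type=ft,
                activation=act,
                optimizer=opt,
            )
            spec = g.build_head(cfg, (4, 4, 16))
            assert spec.layers[-1].output_shape == (1,)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_dense_blocks=6), "n_dense_blocks"),
            (dict(n_dense_blocks=0), "n_dense_blocks"),
            (dict(n_dense_nodes=2000), "n_dense_nodes"),
            (dict(dropout_rate=0.6), "dropout_rate"),
            (dict(flatten_type="squash"), "flatten_type"),
            (dict(activation="gelu"), "activation"),
            (dict(optimizer="lbfgs"), "optimizer"),
        ],
    )
    def test_out_of_range_fields_named(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            g.HeadConfig(**kwargs)


class TestBackbones:
    def test_mobilenet_has_13_addressable_blocks(self):
        spec = g.build_backbone("mobilenet", weights="random")
        blocks = [u for u in spec.units() if u.startswith("block")]
        assert blocks == [f"block{i}" for i in range(1, 14)]

    def test_densenet_units_include_transition2_and_block3(self):
        spec = g.build_backbone("densenet201", weights="random")
        units = spec.units()
        assert "transition2" in units and "dense_block3" in units

    def test_unknown_backbone_lists_supported(self):
        with pytest.raises(ValueError, match="densenet201.*mobilenet|mobilenet.*densenet201"):
            g.build_backbone("vgg")

    def test_imagenet_weights_unavailable_offline(self):
        with pytest.raises(ValueError, match="random"):
            g.build_backbone("mobilenet", weights="imagenet")


class TestFreezePlans:
    def test_mobilenet_trainable_blocks_6_to_13(self):
        plan = g.freeze_plan("mobilenet")
        assert plan.trainable_units == [f"block{i}" for i in range(6, 14)]
        assert set(plan.frozen_units) == {"stem"} | {f"block{i}" for i in range(1, 6)}

    def test_densenet_boundary_at_transition2(self):
        plan = g.freeze_plan("densenet201")
        assert "transition2" in plan.frozen_units
        assert "dense_block3" in plan.trainable_units

    @pytest.mark.parametrize("name", ["mobilenet", "densenet201"])
    def test_plan_partitions_backbone_units(self, name):
        plan = g.freeze_plan(name)
        spec = g.build_backbone(name, weights="random")
        plan.validate_against(spec)  # covers and is disjoint
        assert not set(plan.frozen_units) & set(plan.trainable_units)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError, match="frozen and trainable"):
            g.FreezePlan("mobilenet", ["stem", "block1"], ["block1"])


class TestConvCost:
    def test_unit_case_evaluates_to_10(self):
        assert g.depthwise_separable_cost(g.ConvCostSpec(D_F=1, D_K=3, M=1, N=1)) == 10

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValueError, match="M"):
            g.ConvCostSpec(D_F=1, D_K=3, M=0, N=1)

    def test_ratio_to_standard_conv(self):
        """Separable/standard cost ratio equals 1/N + 1/D_K^2 on a grid."""
        for d_f in (1, 4, 16):
            for d_k in (1, 3, 5):
                for m in (1, 8):
                    for n in (1, 16, 64):
                        spec = g.ConvCostSpec(D_F=d_f, D_K=d_k, M=m, N=n)
                        ratio = g.depthwise_separable_cost(spec) / g.standard_conv_cost(spec)
                        assert ratio == pytest.approx(1 / n + 1 / d_k**2, rel=1e-12)


class TestShapeConsistency:
    def test_spec_shapes_match_executed_arrays(self):
        """Recorded spec shapes agree with the shapes of actual forward-pass
        arrays for 20 random head/extractor combinations."""
        rng = np.random.default_rng(0)
        space = g.SearchSpace(include_conv_activation=True)
        for _ in range(20):
            cfg = space.sample(rng)
            cfg = g.HeadConfig(**{**cfg.to_dict(), "n_dense_nodes": int(rng.integers(32, 65))})
            ext = g.build_multibranch_extractor((16, 16, 3), cfg.conv_activation, width=0.1)
            spec = g.build_classifier(ext, cfg)
            net = g.compile_network(spec, seed=0)
            net.forward(rng.random((2, 16, 16, 3)).astype(np.float32))
            for layer in spec.layers:
                got = net._fwd_outputs[layer.name].shape[1:]
                expect = tuple(layer.output_shape) if layer.kind != "sigmoid-output" else ()
                assert got == expect, layer.name

    def test_inconsistent_recorded_shape_rejected(self):
        spec = g.build_multibranch_extractor((32, 32, 3))
        bad = g.LayerSpec("oops", "dense", {"units": 4}, (5,), ["merge_bn"])
        with pytest.raises(ValueError, match="oops"):
            g.ArchitectureSpec((32, 32, 3), spec.layers + [bad])


def test_spec_json_round_trip():
    spec = g.build_multibranch_extractor((64, 64, 3))
    back = g.ArchitectureSpec.from_json(spec.to_json())
    assert back.output_shape == spec.output_shape
    assert [l.name for l in back.layers] == [l.name for l in spec.layers]
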