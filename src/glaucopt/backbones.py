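"""Backbone adapters: MobileNet and DenseNet201 feature extractors.

Both are generated programmatically as declarative layer graphs following
the original architectures' block structure, with each layer tagged by the
unit it belongs to so fine-tuning freeze plans can address whole blocks.
Only the feature-extraction portion is represented — the classifier is
replaced by the tunable head.  Channel schedules are the standard ones:

* MobileNet: 3x3 stem conv (32 channels, stride 2), then 13 depthwise-
  separable blocks with channels 64, 128, 128, 256, 256, 512, 512 x 5,
  1024, 1024 (strides 2 at each width jump).
* DenseNet201: 7x7 stem conv + 3x3 maxpool, dense blocks of 6/12/48/32
  composite layers (1x1 bottleneck to 128 then 3x3 growth 32, concatenated),
  with halving transitions (1x1 conv + 2x2 average pool) between blocks.

Weights are never stored in the spec; they materialize at compile time from
a seeded initializer (pretrained ImageNet weights are unavailable offline).
"""

from __future__ import annotations

from .arch import ArchitectureSpec, LayerSpec, propagate_shape

__all__ = ["mobilenet_spec", "densenet201_spec", "format_unit_map"]

_MOBILENET_BLOCKS = [
    (64, 1),
    (128, 2),
    (128, 1),
    (256, 2),
    (256, 1),
    (512, 2),
    (512, 1),
    (512, 1),
    (512, 1),
    (512, 1),
    (512, 1),
    (1024, 2),
    (1024, 1),
]

_DENSENET201_BLOCKS = (6, 12, 48, 32)
_DENSENET_GROWTH = 32


class _Builder:
    def __init__(self, input_shape):
        self.input_shape = tuple(input_shape)
        self.layers: list[LayerSpec] = []
        self.shapes = {"input": tuple(input_shape)}

    def add(self, name, kind, params, inputs):
        shape = propagate_shape(kind, params, [self.shapes[i] for i in inputs])
        self.layers.append(LayerSpec(name, kind, dict(params), shape, list(inputs)))
        self.shapes[name] = shape
        return name


def mobilenet_spec(input_shape: tuple = (128, 128, 3)) -> ArchitectureSpec:
    """MobileNet feature extractor: stem + 13 depthwise-separable blocks."""
    b = _Builder(input_shape)
    prev = b.add(
        "stem_conv",
        "conv",
        {"filters": 32, "kernel": 3, "stride": 2, "activation": "relu", "unit": "stem"},
        ["input"],
    )
    prev = b.add("stem_bn", "batchnorm", {"unit": "stem"}, [prev])
    for i, (filters, stride) in enumerate(_MOBILENET_BLOCKS, start=1):
        unit = f"block{i}"
        prev = b.add(
            f"{unit}_dw",
            "depthwise-conv",
            {"kernel": 3, "stride": stride, "activation": "relu", "unit": unit},
            [prev],
        )
        prev = b.add(f"{unit}_dw_bn", "batchnorm", {"unit": unit}, [prev])
        prev = b.add(
            f"{unit}_pw",
            "conv",
            {"filters": filters, "kernel": 1, "stride": 1, "activation": "relu", "unit": unit},
            [prev],
        )
        prev = b.add(f"{unit}_pw_bn", "batchnorm", {"unit": unit}, [prev])
    return ArchitectureSpec(tuple(input_shape), b.layers, name="mobilenet")


def densenet201_spec(input_shape: tuple = (128, 128, 3)) -> ArchitectureSpec:
    """DenseNet201 feature extractor: stem, 4 dense blocks, 3 transitions."""
    b = _Builder(input_shape)
    prev = b.add(
        "stem_conv",
        "conv",
        {"filters": 64, "kernel": 7, "stride": 2, "activation": "relu", "unit": "stem"},
        ["input"],
    )
    prev = b.add("stem_bn", "batchnorm", {"unit": "stem"}, [prev])
    prev = b.add("stem_pool", "maxpool", {"pool": 3, "stride": 2, "unit": "stem"}, [prev])

    for bi, n_layers in enumerate(_DENSENET201_BLOCKS, start=1):
        unit = f"dense_block{bi}"
        for li in range(1, n_layers + 1):
            tag = f"{unit}_l{li}"
            x = b.add(f"{tag}_bn1", "batchnorm", {"unit": unit}, [prev])
            x = b.add(
                f"{tag}_conv1",
                "conv",
                {"filters": 4 * _DENSENET_GROWTH, "kernel": 1, "stride": 1,
                 "activation": "relu", "unit": unit},
                [x],
            )
            x = b.add(f"{tag}_bn2", "batchnorm", {"unit": unit}, [x])
            x = b.add(
                f"{tag}_conv2",
                "conv",
                {"filters": _DENSENET_GROWTH, "kernel": 3, "stride": 1,
                 "activation": "relu", "unit": unit},
                [x],
            )
            prev = b.add(f"{tag}_concat", "concat", {"unit": unit}, [prev, x])
        if bi < len(_DENSENET201_BLOCKS):
            unit = f"transition{bi}"
            c = b.shapes[prev][-1]
            x = b.add(f"{unit}_bn", "batchnorm", {"unit": unit}, [prev])
            x = b.add(
                f"{unit}_conv",
                "conv",
                {"filters": c // 2, "kernel": 1, "stride": 1,
                 "activation": "relu", "unit": unit},
                [x],
            )
            prev = b.add(f"{unit}_pool", "avgpool", {"pool": 2, "stride": 2, "unit": unit}, [x])
    prev = b.add("final_bn", "batchnorm", {"unit": "dense_block4"}, [prev])
    return ArchitectureSpec(tuple(input_shape), b.layers, name="densenet201")


def format_unit_map(spec: ArchitectureSpec) -> str:
    """Human-readable unit map (one line per unit: tag, layer span, shape)."""
    lines = [f"# unit map for {spec.name} (input {spec.input_shape})"]
    for unit, names in spec.unit_map().items():
        shape = spec.shape_of(names[-1])
        lines.append(f"{unit}\t{names[0]}..{names[-1]}\t{len(names)} layers\tout {shape}")
    return "\n".join(lines) + "\n"
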