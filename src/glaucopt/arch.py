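"""Network architecture specifications.

An :class:`ArchitectureSpec` is a declarative, ordered layer graph (a small
DAG: each layer names its inputs, so the two-branch extractor and DenseNet
skip connections are representable) with every output shape recorded.  Specs
are what the builders below return; ``glaucopt.nn.network.compile_network``
turns a spec into an executable NumPy model.

The cast of builders mirrors the detection pipeline: a two-branch
convolutional feature extractor trained from scratch, MobileNet/DenseNet201
backbone adapters for transfer learning, a tunable classifier head (the
7-hyperparameter search box), fine-tuning freeze plans, and the
depthwise-separable convolution cost formula

    C = D_K^2 * M * D_F^2  +  M * N * D_F^2

(depthwise term plus 1x1 pointwise term, for a D_F x D_F feature map with
D_K x D_K kernels, M input and N output channels).  The width multiplier
alpha and resolution multiplier rho of the MobileNet family uniformly shrink
channel counts and feature-map sides; they are documented here for context
but only the base cost formula is computed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "HeadConfig",
    "FreezePlan",
    "ConvCostSpec",
    "ACTIVATION_CHOICES",
    "OPTIMIZER_CHOICES",
    "HEAD_RANGES",
    "build_multibranch_extractor",
    "build_head",
    "build_classifier",
    "build_backbone",
    "freeze_plan",
    "depthwise_separable_cost",
    "standard_conv_cost",
    "propagate_shape",
]

ACTIVATION_CHOICES = ("relu", "elu", "tanh", "swish", "softplus")
OPTIMIZER_CHOICES = ("nadam", "rmsprop", "adam", "sgd", "adamax")

#: Search box for the classifier head: 7 tunable hyperparameters
#: (an 8th, the conv activation, applies to the from-scratch extractor only).
HEAD_RANGES = {
    "n_dense_blocks": (1, 5),
    "n_dense_nodes": (32, 1024),
    "dropout_rate": (0.2, 0.5),
    "batch_norm": (True, False),
    "flatten_type": ("flatten", "gap"),
    "activation": ACTIVATION_CHOICES,
    "optimizer": OPTIMIZER_CHOICES,
}

_KINDS = {
    "conv",
    "depthwise-conv",
    "maxpool",
    "avgpool",
    "batchnorm",
    "concat",
    "flatten",
    "gap",
    "dense",
    "dropout",
    "activation",
    "sigmoid-output",
}


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


def propagate_shape(kind: str, params: dict, input_shapes: list[tuple]) -> tuple:
    """Output shape of one layer given its input shapes.

    Spatial layers use "same" padding, so a stride-s layer maps side H to
    ceil(H/s) regardless of kernel size.
    """
    if kind == "concat":
        h, w = input_shapes[0][:2]
        for s in input_shapes:
            if s[:2] != (h, w):
                raise ValueError(f"concat inputs disagree spatially: {input_shapes}")
        return (h, w, sum(s[2] for s in input_shapes))
    (shape,) = input_shapes
    if kind == "conv":
        h, w, _ = shape
        s = params.get("stride", 1)
        return (_ceil_div(h, s), _ceil_div(w, s), params["filters"])
    if kind == "depthwise-conv":
        h, w, c = shape
        s = params.get("stride", 1)
        return (_ceil_div(h, s), _ceil_div(w, s), c)
    if kind in ("maxpool", "avgpool"):
        h, w, c = shape
        s = params.get("stride", params.get("pool", 2))
        return (_ceil_div(h, s), _ceil_div(w, s), c)
    if kind in ("batchnorm", "dropout", "activation"):
        return shape
    if kind == "flatten":
        return (int(math.prod(shape)),)
    if kind == "gap":
        return (shape[-1],)
    if kind == "dense":
        return (params["units"],)
    if kind == "sigmoid-output":
        return (1,)
    raise ValueError(f"unknown layer kind {kind!r}")


def _param_count(kind: str, params: dict, input_shapes: list[tuple]) -> int:
    """Trainable parameter count of one layer (batchnorm: gamma and beta)."""
    if kind == "conv":
        k = params.get("kernel", 3)
        m = input_shapes[0][-1]
        n = params["filters"]
        return (k * k * m + 1) * n
    if kind == "depthwise-conv":
        k = params.get("kernel", 3)
        m = input_shapes[0][-1]
        return (k * k + 1) * m
    if kind == "batchnorm":
        return 2 * input_shapes[0][-1]
    if kind == "dense":
        return (input_shapes[0][0] + 1) * params["units"]
    if kind == "sigmoid-output":
        return input_shapes[0][0] + 1
    return 0


@dataclass
class LayerSpec:
    """One layer of an architecture: name, kind, parameters, recorded shape.

    ``inputs`` lists predecessor layer names; the sentinel ``"input"`` denotes
    the network input.  ``params`` may carry a ``unit`` tag grouping layers
    into freezable units (backbone blocks, transitions, the stem).
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    output_shape: tuple = ()
    inputs: list = field(default_factory=lambda: [])


@dataclass
class ArchitectureSpec:
    input_shape: tuple
    layers: list  # of LayerSpec
    name: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Check name uniqueness, topological order, and shape consistency."""
        seen: dict[str, tuple] = {"input": tuple(self.input_shape)}
        for layer in self.layers:
            if layer.kind not in _KINDS:
                raise ValueError(f"layer {layer.name}: unknown kind {layer.kind!r}")
            if layer.name in seen:
                raise ValueError(f"duplicate layer name {layer.name!r}")
            try:
                in_shapes = [seen[i] for i in layer.inputs]
            except KeyError as e:
                raise ValueError(
                    f"layer {layer.name}: input {e} not defined earlier"
                ) from None
            expected = propagate_shape(layer.kind, layer.params, in_shapes)
            if tuple(layer.output_shape) != tuple(expected):
                raise ValueError(
                    f"layer {layer.name}: recorded shape {layer.output_shape} "
                    f"!= propagated {expected}"
                )
            seen[layer.name] = tuple(layer.output_shape)

    @property
    def output_shape(self) -> tuple:
        return tuple(self.layers[-1].output_shape)

    def shape_of(self, layer_name: str) -> tuple:
        for layer in self.layers:
            if layer.name == layer_name:
                return tuple(layer.output_shape)
        raise KeyError(layer_name)

    def parameter_count(self) -> int:
        """Total trainable parameters implied by the spec."""
        shapes = {"input": tuple(self.input_shape)}
        total = 0
        for layer in self.layers:
            in_shapes = [shapes[i] for i in layer.inputs]
            total += _param_count(layer.kind, layer.params, in_shapes)
            shapes[layer.name] = tuple(layer.output_shape)
        return total

    def units(self) -> list:
        """Ordered distinct unit tags (freeze-plan addressing)."""
        out: list[str] = []
        for layer in self.layers:
            u = layer.params.get("unit")
            if u is not None and u not in out:
                out.append(u)
        return out

    def unit_map(self) -> dict:
        """unit tag -> list of layer names, in order."""
        out: dict[str, list] = {}
        for layer in self.layers:
            u = layer.params.get("unit")
            if u is not None:
                out.setdefault(u, []).append(layer.name)
        return out

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "layers": [
                {**asdict(l), "output_shape": list(l.output_shape)}
                for l in self.layers
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        layers = [
            LayerSpec(
                name=l["name"],
                kind=l["kind"],
                params=l["params"],
                output_shape=tuple(l["output_shape"]),
                inputs=list(l["inputs"]),
            )
            for l in d["layers"]
        ]
        return cls(tuple(d["input_shape"]), layers, name=d.get("name", ""))


# ---------------------------------------------------------------------------
# classifier head configuration


@dataclass(frozen=True)
class HeadConfig:
    """The 7 searched hyperparameters of a classifier head.

    ``conv_activation`` is the extra 8th choice used only when the two-branch
    extractor is trained from scratch (its conv layers share one activation);
    it is ignored for the pretrained backbones.
    """

    n_dense_blocks: int = 1
    n_dense_nodes: int = 32
    dropout_rate: float = 0.2
    batch_norm: bool = False
    flatten_type: str = "flatten"
    activation: str = "relu"
    optimizer: str = "adam"
    conv_activation: str = "relu"

    def __post_init__(self):
        lo, hi = HEAD_RANGES["n_dense_blocks"]
        if not (isinstance(self.n_dense_blocks, (int,)) and lo <= self.n_dense_blocks <= hi):
            raise ValueError(f"n_dense_blocks must be an integer in [{lo}, {hi}], got {self.n_dense_blocks!r}")
        lo, hi = HEAD_RANGES["n_dense_nodes"]
        if not (isinstance(self.n_dense_nodes, (int,)) and lo <= self.n_dense_nodes <= hi):
            raise ValueError(f"n_dense_nodes must be an integer in [{lo}, {hi}], got {self.n_dense_nodes!r}")
        lo, hi = HEAD_RANGES["dropout_rate"]
        if not lo <= self.dropout_rate <= hi:
            raise ValueError(f"dropout_rate must be in [{lo}, {hi}], got {self.dropout_rate!r}")
        if not isinstance(self.batch_norm, bool):
            raise ValueError(f"batch_norm must be True (enabled) or False (disabled), got {self.batch_norm!r}")
        if self.flatten_type not in HEAD_RANGES["flatten_type"]:
            raise ValueError(f"flatten_type must be one of {HEAD_RANGES['flatten_type']}, got {self.flatten_type!r}")
        if self.activation not in ACTIVATION_CHOICES:
            raise ValueError(f"activation must be one of {ACTIVATION_CHOICES}, got {self.activation!r}")
        if self.optimizer not in OPTIMIZER_CHOICES:
            raise ValueError(f"optimizer must be one of {OPTIMIZER_CHOICES}, got {self.optimizer!r}")
        if self.conv_activation not in ACTIVATION_CHOICES:
            raise ValueError(f"conv_activation must be one of {ACTIVATION_CHOICES}, got {self.conv_activation!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HeadConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# builders


def build_multibranch_extractor(
    input_shape: tuple = (128, 128, 3),
    conv_activation: str = "relu",
    width: float = 1.0,
) -> ArchitectureSpec:
    """The two-branch convolutional feature extractor, trained from scratch.

    Branch 1: conv 3x3x32 -> maxpool 2x2/2 -> conv 3x3x64 stride 2.
    Branch 2: conv 3x3x64 -> maxpool 2x2/2 -> conv 3x3x128 stride 2.
    The branches are concatenated along channels, then conv 3x3x256 ->
    maxpool 2x2 -> batchnorm.  On a 128x128x3 input the branch outputs are
    32x32x64 and 32x32x128, the concat 32x32x192 and the final feature map
    16x16x256.  ``width`` scales every channel count (>= 1 channel) to give a
    cheap desk-scale variant with the identical topology.
    """
    h, w, c = input_shape
    if h != w:
        raise ValueError(f"input must be square, got {h}x{w}")
    if h % 8 != 0:
        raise ValueError(f"input side must be divisible by 8, got {h}")
    if conv_activation not in ACTIVATION_CHOICES:
        raise ValueError(f"conv_activation must be one of {ACTIVATION_CHOICES}")

    def ch(n):
        return max(1, round(n * width))

    act = conv_activation
    layers = []

    def add(name, kind, params, inputs):
        in_shapes = [
            tuple(input_shape) if i == "input" else next(
                tuple(l.output_shape) for l in layers if l.name == i
            )
            for i in inputs
        ]
        layers.append(
            LayerSpec(name, kind, params, propagate_shape(kind, params, in_shapes), inputs)
        )

    add("b1_conv1", "conv", {"filters": ch(32), "kernel": 3, "stride": 1, "activation": act}, ["input"])
    add("b1_pool", "maxpool", {"pool": 2, "stride": 2}, ["b1_conv1"])
    add("b1_conv2", "conv", {"filters": ch(64), "kernel": 3, "stride": 2, "activation": act}, ["b1_pool"])
    add("b2_conv1", "conv", {"filters": ch(64), "kernel": 3, "stride": 1, "activation": act}, ["input"])
    add("b2_pool", "maxpool", {"pool": 2, "stride": 2}, ["b2_conv1"])
    add("b2_conv2", "conv", {"filters": ch(128), "kernel": 3, "stride": 2, "activation": act}, ["b2_pool"])
    add("concat", "concat", {}, ["b1_conv2", "b2_conv2"])
    add("merge_conv", "conv", {"filters": ch(256), "kernel": 3, "stride": 1, "activation": act}, ["concat"])
    add("merge_pool", "maxpool", {"pool": 2, "stride": 2}, ["merge_conv"])
    add("merge_bn", "batchnorm", {}, ["merge_pool"])
    return ArchitectureSpec(tuple(input_shape), layers, name="multibranch")


def build_head(config: HeadConfig, feature_shape: tuple) -> ArchitectureSpec:
    """A classifier head over an extracted feature map.

    Flatten or global-average-pool, then ``n_dense_blocks`` repetitions of
    [dense -> activation -> optional batchnorm -> dropout], then the fixed
    single-unit sigmoid output.
    """
    layers = []
    shapes = {"input": tuple(feature_shape)}

    def add(name, kind, params, inputs):
        in_shapes = [shapes[i] for i in inputs]
        shape = propagate_shape(kind, params, in_shapes)
        layers.append(LayerSpec(name, kind, params, shape, inputs))
        shapes[name] = shape
        return name

    prev = add("head_pool", config.flatten_type if config.flatten_type == "flatten" else "gap", {}, ["input"])
    for i in range(1, config.n_dense_blocks + 1):
        prev = add(f"head_dense{i}", "dense", {"units": config.n_dense_nodes}, [prev])
        prev = add(f"head_act{i}", "activation", {"fn": config.activation}, [prev])
        if config.batch_norm:
            prev = add(f"head_bn{i}", "batchnorm", {}, [prev])
        prev = add(f"head_drop{i}", "dropout", {"rate": config.dropout_rate}, [prev])
    add("output", "sigmoid-output", {}, [prev])
    return ArchitectureSpec(tuple(feature_shape), layers, name="head")


def build_classifier(extractor: ArchitectureSpec, config: HeadConfig) -> ArchitectureSpec:
    """Full classifier: extractor layers followed by a head built for them."""
    head = build_head(config, extractor.output_shape)
    tail = extractor.layers[-1].name
    merged = list(extractor.layers)
    for layer in head.layers:
        inputs = [tail if i == "input" else i for i in layer.inputs]
        merged.append(LayerSpec(layer.name, layer.kind, layer.params, layer.output_shape, inputs))
    return ArchitectureSpec(
        extractor.input_shape, merged, name=f"{extractor.name}+head"
    )


def build_backbone(name: str, weights: str = "random", input_shape: tuple = (128, 128, 3)) -> ArchitectureSpec:
    """Feature-extraction portion of a pretrained-style backbone.

    Layers carry ``unit`` tags (MobileNet: ``stem`` plus depthwise-separable
    ``block1``..``block13``; DenseNet201: ``stem``, ``dense_block1``..``4``,
    ``transition1``..``3``) so freeze plans can address them.  No classifier
    is attached.  ``weights="imagenet"`` is unavailable offline and raises;
    use ``weights="random"`` for desk-scale experiments and tests.
    """
    from .backbones import mobilenet_spec, densenet201_spec  # local: keeps arch importable alone

    if weights not in ("imagenet", "random"):
        raise ValueError(f"weights must be 'imagenet' or 'random', got {weights!r}")
    if weights == "imagenet":
        raise ValueError(
            "pretrained ImageNet weights are not available in this offline build; "
            "pass weights='random' (tests and desk-scale runs use random init)"
        )
    key = name.lower()
    if key == "mobilenet":
        return mobilenet_spec(input_shape)
    if key == "densenet201":
        return densenet201_spec(input_shape)
    raise ValueError(f"unknown backbone {name!r}; supported: ['densenet201', 'mobilenet']")


@dataclass
class FreezePlan:
    """Partition of a backbone's feature-extraction units for fine-tuning.

    Frozen units keep their parameters fixed (zero update); trainable units
    follow the ordinary gradient-descent update.
    """

    backbone: str
    frozen_units: list
    trainable_units: list

    def __post_init__(self):
        overlap = set(self.frozen_units) & set(self.trainable_units)
        if overlap:
            raise ValueError(f"units both frozen and trainable: {sorted(overlap)}")

    @property
    def all_units(self) -> list:
        return list(self.frozen_units) + list(self.trainable_units)

    def validate_against(self, spec: ArchitectureSpec) -> None:
        missing = set(spec.units()) - set(self.all_units)
        extra = set(self.all_units) - set(spec.units())
        if missing or extra:
            raise ValueError(
                f"freeze plan does not partition the spec's units "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )


def freeze_plan(backbone_name: str) -> FreezePlan:
    """The fine-tuning partition used for each pretrained backbone.

    MobileNet: stem and depthwise-separable blocks 1-5 frozen, blocks 6-13
    trainable.  DenseNet201: everything through transition 2 frozen, dense
    block 3 to the end of feature extraction trainable.
    """
    key = backbone_name.lower()
    if key == "mobilenet":
        return FreezePlan(
            backbone="mobilenet",
            frozen_units=["stem"] + [f"block{i}" for i in range(1, 6)],
            trainable_units=[f"block{i}" for i in range(6, 14)],
        )
    if key == "densenet201":
        return FreezePlan(
            backbone="densenet201",
            frozen_units=["stem", "dense_block1", "transition1", "dense_block2", "transition2"],
            trainable_units=["dense_block3", "transition3", "dense_block4"],
        )
    raise ValueError(f"unknown backbone {backbone_name!r}; supported: ['densenet201', 'mobilenet']")


# ---------------------------------------------------------------------------
# depthwise-separable convolution cost


@dataclass(frozen=True)
class ConvCostSpec:
    """Cost-formula operands: D_F feature-map side, D_K kernel side, M input
    channels, N output channels.  The MobileNet width multiplier alpha would
    scale M and N and the resolution multiplier rho would scale D_F; both are
    applied upstream of this formula when used at all."""

    D_F: int
    D_K: int
    M: int
    N: int

    def __post_init__(self):
        for f in ("D_F", "D_K", "M", "N"):
            v = getattr(self, f)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{f} must be a positive integer, got {v!r}")


def depthwise_separable_cost(spec: ConvCostSpec) -> int:
    """Multiply-accumulate count of a depthwise-separable convolution:
    D_K^2 * M * D_F^2 (depthwise) + M * N * D_F^2 (pointwise)."""
    return spec.D_K**2 * spec.M * spec.D_F**2 + spec.M * spec.N * spec.D_F**2


def standard_conv_cost(spec: ConvCostSpec) -> int:
    """Cost of the equivalent standard convolution, D_K^2 * M * N * D_F^2.
    The separable/standard ratio is 1/N + 1/D_K^2."""
    return spec.D_K**2 * spec.M * spec.N * spec.D_F**2
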