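"""Declarative 3D CNN architecture specs, shape propagation, parameter counting.

Three VGG-like variants are specified:

* the baseline subject-level classifier: four 3×3×3 same-padded conv blocks
  with 8/16/32/64 channels, each followed by max-pooling (first pool 3³
  stride 3, the rest 2³ stride 2, all ceil-rounded), then fully connected
  layers of 1024/128/2 units with dropout on the first two;
* the patch-level subnetwork: identical except every pool is 2³ stride 2,
  so 48³ patches reach a 3×3×3×64 deep feature map;
* the subject-level fusion head: the flattened deep (Conv4) features of all
  patch-level subnetworks concatenated, then 2048/512/2 dense layers.

Pooling output extents use ceil rounding (same-padded pooling): with floor
rounding the first block of the baseline would map 91→30, not the 31 the
architecture defines. Parameter counts are closed-form
(``conv: C_out·(k³·C_in + 1)``, ``dense: units·(fan_in + 1)``) and must match
the built model's introspected count exactly — see :mod:`patchcascade.nn`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "baseline_spec",
    "patch_subnet_spec",
    "fusion_spec",
    "count_parameters",
    "forward_shapes",
    "pool_output_sizes",
    "conv_feature_size",
    "summary_table",
]

LayerKind = Literal["conv3d", "maxpool3d", "flatten", "dense", "dropout", "concat_inputs"]


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: kind plus the fields that kind requires."""

    kind: LayerKind
    name: str = ""
    kernel: tuple[int, int, int] | None = None
    stride: tuple[int, int, int] | None = None
    channels_out: int | None = None
    units: int | None = None
    padding: Literal["same", "valid"] = "same"
    pool_rounding: Literal["ceil", "floor"] = "ceil"
    activation: Literal["relu", "softmax", "none"] = "none"
    regularization: Literal["l2", "none"] = "none"
    rate: float = 0.0
    input_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind in ("conv3d", "maxpool3d"):
            if self.kernel is None or self.stride is None:
                raise ValueError(f"{self.kind} layer '{self.name}' needs kernel and stride")
        if self.kind == "conv3d" and not self.channels_out:
            raise ValueError(f"conv3d layer '{self.name}' needs channels_out")
        if self.kind == "dense" and not self.units:
            raise ValueError(f"dense layer '{self.name}' needs units")
        if self.kind == "dropout" and not (0.0 <= self.rate < 1.0):
            raise ValueError(f"dropout rate must be in [0,1), got {self.rate}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Named ordered stack of layers with a declared input.

    ``input_shape`` is a 3-tuple of spatial extents for volumetric inputs
    (single channel unless ``input_channels`` says otherwise), or ``None``
    for flat-feature inputs (fusion head), in which case the first layer is
    ``concat_inputs`` carrying the incoming feature lengths.
    """

    name: str
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] | None = None
    input_channels: int = 1

    def validate(self) -> None:
        shapes = forward_shapes(self)
        last = self.layers[-1]
        if not (last.kind == "dense" and last.units == 2 and last.activation == "softmax"):
            raise ValueError(f"{self.name}: final layer must be a 2-unit softmax dense layer")
        del shapes

    def to_json(self) -> str:
        obj = {
            "name": self.name,
            "input_shape": list(self.input_shape) if self.input_shape else None,
            "input_channels": self.input_channels,
            "layers": [asdict(l) for l in self.layers],
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        obj = json.loads(text)
        layers = []
        for ld in obj["layers"]:
            for key in ("kernel", "stride", "input_lengths"):
                if ld.get(key) is not None:
                    ld[key] = tuple(ld[key])
            layers.append(LayerSpec(**ld))
        return cls(
            name=obj["name"],
            layers=tuple(layers),
            input_shape=tuple(obj["input_shape"]) if obj.get("input_shape") else None,
            input_channels=obj.get("input_channels", 1),
        )


@dataclass(frozen=True)
class LayerShape:
    """Propagated output of one layer: volumetric (spatial+channels) or flat units."""

    name: str
    kind: str
    spatial: tuple[int, int, int] | None
    channels: int | None
    units: int | None


def _pool_extent(extent: int, stride: int, rounding: str) -> int:
    if rounding == "ceil":
        return math.ceil(extent / stride)
    return extent // stride


def forward_shapes(
    spec: ArchitectureSpec, input_shape: Sequence[int] | None = None
) -> list[LayerShape]:
    """Propagate shapes through every layer; errors name the offending layer.

    Same-padded stride-1 convolution preserves spatial shape; pooling with
    kernel == stride maps each extent to ``ceil(extent/stride)`` (or floor
    when the layer says so). Any axis reaching zero raises.
    """
    if input_shape is None:
        input_shape = spec.input_shape
    if input_shape is not None:
        spatial: tuple[int, int, int] | None = tuple(int(s) for s in input_shape)
        channels: int | None = spec.input_channels
        units: int | None = None
    else:
        spatial, channels, units = None, None, None

    out: list[LayerShape] = []
    for layer in spec.layers:
        if layer.kind == "concat_inputs":
            units = int(sum(layer.input_lengths or ()))
            spatial, channels = None, None
        elif layer.kind == "conv3d":
            if spatial is None:
                raise ValueError(f"layer '{layer.name}': conv3d needs a volumetric input")
            if layer.padding == "same":
                new = tuple(
                    math.ceil(s / st) for s, st in zip(spatial, layer.stride)
                )
            else:
                new = tuple(
                    (s - k) // st + 1
                    for s, k, st in zip(spatial, layer.kernel, layer.stride)
                )
            spatial, channels = new, layer.channels_out
        elif layer.kind == "maxpool3d":
            if spatial is None:
                raise ValueError(f"layer '{layer.name}': maxpool3d needs a volumetric input")
            spatial = tuple(
                _pool_extent(s, st, layer.pool_rounding)
                for s, st in zip(spatial, layer.stride)
            )
        elif layer.kind == "flatten":
            if spatial is None:
                raise ValueError(f"layer '{layer.name}': flatten needs a volumetric input")
            units = int(channels * math.prod(spatial))
            spatial, channels = None, None
        elif layer.kind == "dense":
            if units is None:
                raise ValueError(f"layer '{layer.name}': dense needs a flat input")
            units = int(layer.units)
        elif layer.kind == "dropout":
            pass
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {layer.kind!r}")
        if spatial is not None and any(s < 1 for s in spatial):
            raise ValueError(
                f"layer '{layer.name}': output extent reached zero ({spatial})"
            )
        out.append(LayerShape(layer.name, layer.kind, spatial, channels, units))
    return out


def pool_output_sizes(spec: ArchitectureSpec) -> list[tuple[int, int, int]]:
    """Spatial size after each pooling layer (the conventional per-block summary)."""
    return [s.spatial for s in forward_shapes(spec) if s.kind == "maxpool3d"]


def conv_feature_size(spec: ArchitectureSpec) -> int:
    """Flattened size of the deepest conv feature map (input to the dense head)."""
    shapes = forward_shapes(spec)
    for shape in shapes:
        if shape.kind == "flatten":
            return shape.units
    raise ValueError(f"{spec.name}: no flatten layer")


def count_parameters(spec: ArchitectureSpec) -> dict[str, int]:
    """Closed-form trainable parameter count per layer.

    ``conv3d: C_out·(∏kernel·C_in + 1)``; ``dense: units·(fan_in + 1)``;
    pooling, dropout, flatten and concatenation contribute zero (and are
    omitted from the result).
    """
    counts: dict[str, int] = {}
    shapes = forward_shapes(spec)
    prev_channels = spec.input_channels
    prev_units: int | None = None
    if spec.input_shape is None:
        prev_units = None  # set by concat_inputs
    for layer, shape in zip(spec.layers, shapes):
        if layer.kind == "conv3d":
            counts[layer.name] = layer.channels_out * (
                math.prod(layer.kernel) * prev_channels + 1
            )
            prev_channels = layer.channels_out
        elif layer.kind == "dense":
            counts[layer.name] = layer.units * (prev_units + 1)
        if shape.units is not None:
            prev_units = shape.units
    return counts


def total_parameters(spec: ArchitectureSpec) -> int:
    return sum(count_parameters(spec).values())


# ---------------------------------------------------------------------------
# Builders


def _conv_block(index: int, channels: int, pool_kernel: int) -> list[LayerSpec]:
    k3 = (3, 3, 3)
    return [
        LayerSpec(
            kind="conv3d",
            name=f"Conv{index}",
            kernel=k3,
            stride=(1, 1, 1),
            channels_out=channels,
            padding="same",
            activation="relu",
            regularization="l2",
        ),
        LayerSpec(
            kind="maxpool3d",
            name=f"Pool{index}",
            kernel=(pool_kernel,) * 3,
            stride=(pool_kernel,) * 3,
            pool_rounding="ceil",
        ),
    ]


def _dense_head(units: Sequence[int], dropout: float, start_index: int = 1) -> list[LayerSpec]:
    layers: list[LayerSpec] = []
    n = len(units)
    for i, u in enumerate(units):
        idx = start_index + i
        last = i == n - 1
        layers.append(
            LayerSpec(
                kind="dense",
                name=f"FC{idx}",
                units=u,
                activation="softmax" if last else "relu",
                regularization="none" if last else "l2",
            )
        )
        if not last:
            layers.append(LayerSpec(kind="dropout", name=f"Drop{idx}", rate=dropout))
    return layers


def baseline_spec(
    input_shape: Sequence[int] = (91, 115, 91),
    channels: Sequence[int] = (8, 16, 32, 64),
    fc_units: Sequence[int] = (1024, 128),
    dropout: float = 0.5,
    first_pool: int = 3,
) -> ArchitectureSpec:
    """The subject-level baseline classifier (whole-volume input).

    Four same-padded 3×3×3 conv blocks with ReLU and L2 regularization,
    pooled 3³/2³/2³/2³ with matching strides and ceil rounding, then dense
    1024/128/2 with dropout 0.5 after the first two dense activations and a
    softmax output.
    """
    if len(channels) != 4:
        raise ValueError("the backbone has exactly four conv blocks")
    layers: list[LayerSpec] = []
    for i, ch in enumerate(channels):
        layers += _conv_block(i + 1, ch, first_pool if i == 0 else 2)
    layers.append(LayerSpec(kind="flatten", name="Flatten"))
    layers += _dense_head(list(fc_units) + [2], dropout)
    spec = ArchitectureSpec(
        name="baseline", layers=tuple(layers), input_shape=tuple(int(s) for s in input_shape)
    )
    spec.validate()
    return spec


def patch_subnet_spec(
    patch_shape: Sequence[int],
    channels: Sequence[int] = (8, 16, 32, 64),
    fc_units: Sequence[int] = (1024, 128),
    dropout: float = 0.5,
) -> ArchitectureSpec:
    """A patch-level subnetwork: the baseline with every pool set to 2³ stride 2.

    The patch must be at least 16 voxels on every axis so the four pooling
    stages retain a nontrivial deep feature map. The dense head
    (``fc_units`` + softmax) is used for patch-level pretraining only; the
    fusion stage consumes the flattened Conv4 features and discards it.
    """
    patch_shape = tuple(int(s) for s in patch_shape)
    if any(s < 16 for s in patch_shape):
        raise ValueError(
            f"patch shape {patch_shape} too small: every axis must be >= 16 "
            "to survive four pooling stages"
        )
    spec = baseline_spec(
        input_shape=patch_shape, channels=channels, fc_units=fc_units,
        dropout=dropout, first_pool=2,
    )
    label = "x".join(str(s) for s in patch_shape)
    spec = ArchitectureSpec(
        name=f"patch-{label}", layers=spec.layers, input_shape=patch_shape
    )
    spec.validate()
    return spec


def fusion_spec(
    patch_subnet_specs: Sequence[ArchitectureSpec],
    fc_units: Sequence[int] = (2048, 512),
    dropout: float = 0.5,
) -> ArchitectureSpec:
    """The subject-level fusion head over concatenated deep patch features.

    Input is the concatenation of the flattened Conv4 feature maps of every
    patch-level subnetwork (whose conv layers are frozen at fusion time);
    the head is dense 2048/512/2 with ReLU+L2 and dropout 0.5 on the first
    two layers and a softmax output.
    """
    if not patch_subnet_specs:
        raise ValueError("fusion needs at least one patch-level subnetwork")
    lengths = tuple(conv_feature_size(s) for s in patch_subnet_specs)
    layers = [LayerSpec(kind="concat_inputs", name="Concat", input_lengths=lengths)]
    layers += _dense_head(list(fc_units) + [2], dropout)
    spec = ArchitectureSpec(name="fusion", layers=tuple(layers), input_shape=None)
    spec.validate()
    return spec


def summary_table(spec: ArchitectureSpec) -> str:
    """Human-readable per-layer summary (kernel, stride, output size, parameters)."""
    shapes = forward_shapes(spec)
    counts = count_parameters(spec)
    rows = [("Layer", "Kernel", "Stride", "Output Size", "Parameters")]
    if spec.input_shape is not None:
        rows.append(("Input", "-", "-", " x ".join(map(str, spec.input_shape)), "-"))
    for layer, shape in zip(spec.layers, shapes):
        if layer.kind == "dropout":
            continue
        kernel = " x ".join(map(str, layer.kernel)) if layer.kernel else "-"
        stride = str(layer.stride[0]) if layer.stride else "-"
        if shape.spatial is not None:
            out = " x ".join(map(str, shape.spatial)) + f" ({shape.channels} ch)"
        else:
            out = f"1 x {shape.units}"
        rows.append((layer.name, kernel, stride, out, f"{counts.get(layer.name, 0):,}"))
    rows.append(("Total", "", "", "", f"{sum(counts.values()):,}"))
    widths = [max(len(r[i]) for r in rows) for i in range(5)]
    return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows)
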