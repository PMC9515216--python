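"""Backbone registry and trainable-parameter accounting.

Two backbones are trainable here: ``tiny-cnn`` (the desk-scale regressor)
and — as a faithful structural plan — ``effnet-b0-plan``, the EfficientNet-B0
stage table (MBConv blocks with squeeze-and-excitation) whose final feature
map is 1280 channels at 7x7 from a 224x224 input.  For the wider comparison
family (ResNets, EfficientNet-B0 with a 1000-way head) the registry counts
trainable parameters by enumerating every conv/BN/FC layer analytically,
which reproduces the standard published counts without instantiating the
networks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import TinyCNN

#: EfficientNet-B0 stage plan: (operator, (H, W) resolution, channels, layers).
EFFNET_B0_STAGES: tuple[tuple[str, tuple[int, int], int, int], ...] = (
    ("Conv3x3", (224, 224), 32, 1),
    ("MBConv1,k3x3", (112, 112), 16, 1),
    ("MBConv6,k3x3", (112, 112), 24, 2),
    ("MBConv6,k5x5", (56, 56), 40, 2),
    ("MBConv6,k3x3", (28, 28), 80, 3),
    ("MBConv6,k5x5", (14, 14), 112, 3),
    ("MBConv6,k5x5", (14, 14), 192, 4),
    ("MBConv6,k3x3", (7, 7), 320, 1),
    ("Conv1x1&Pooling&FC", (7, 7), 1280, 1),
)


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    stage_plan: tuple[tuple[str, tuple[int, int], int, int], ...]
    head: str = "single-output regression"


def backbone_spec(name: str) -> BackboneSpec:
    if name == "tiny-cnn":
        plan = (
            ("Conv3x3/s2", (32, 32), 8, 1),
            ("Conv3x3/s2", (16, 16), 16, 1),
            ("Conv3x3/s1", (16, 16), 16, 1),
            ("Pooling&FC", (16, 16), 16, 1),
        )
        return BackboneSpec("tiny-cnn", plan)
    if name == "effnet-b0-plan":
        return BackboneSpec("effnet-b0-plan", EFFNET_B0_STAGES)
    raise ValueError(f"unknown backbone {name!r}")


# ---------------------------------------------------------------------
# Analytic layer enumeration for the comparison family
# ---------------------------------------------------------------------

def _conv(c_in: int, c_out: int, k: int, bias: bool = False, groups: int = 1) -> int:
    return c_out * (c_in // groups) * k * k + (c_out if bias else 0)


def _bn(c: int) -> int:
    return 2 * c  # scale + shift


def _resnet_params(block: str, layers: list[int], num_classes: int) -> int:
    """Standard ResNet: 7x7 stem, four stages, average pool, FC."""
    expansion = 1 if block == "basic" else 4
    total = _conv(3, 64, 7) + _bn(64)
    c_in = 64
    planes = 64
    for stage, n_blocks in enumerate(layers):
        for b in range(n_blocks):
            c_out = planes * expansion
            downsample = b == 0 and (stage > 0 or c_in != c_out)
            if block == "basic":
                total += _conv(c_in, planes, 3) + _bn(planes)
                total += _conv(planes, planes, 3) + _bn(planes)
            else:
                total += _conv(c_in, planes, 1) + _bn(planes)
                total += _conv(planes, planes, 3) + _bn(planes)
                total += _conv(planes, c_out, 1) + _bn(c_out)
            if downsample:
                total += _conv(c_in, c_out, 1) + _bn(c_out)
            c_in = c_out
        planes *= 2
    total += 512 * expansion * num_classes + num_classes
    return total


def _effnet_b0_params(num_classes: int) -> int:
    """EfficientNet-B0: MBConv blocks with squeeze-and-excitation."""
    total = _conv(3, 32, 3) + _bn(32)  # stem
    # (expand_ratio, kernel, c_in, c_out, n_layers) per MBConv stage
    blocks = (
        (1, 3, 32, 16, 1),
        (6, 3, 16, 24, 2),
        (6, 5, 24, 40, 2),
        (6, 3, 40, 80, 3),
        (6, 5, 80, 112, 3),
        (6, 5, 112, 192, 4),
        (6, 3, 192, 320, 1),
    )
    for expand, k, c_in, c_out, n_layers in blocks:
        for layer in range(n_layers):
            ci = c_in if layer == 0 else c_out
            mid = ci * expand
            if expand != 1:
                total += _conv(ci, mid, 1) + _bn(mid)
            total += _conv(mid, mid, k, groups=mid) + _bn(mid)  # depthwise
            sq = max(1, ci // 4)  # squeeze-and-excitation, ratio 0.25 of block input
            total += _conv(mid, sq, 1, bias=True) + _conv(sq, mid, 1, bias=True)
            total += _conv(mid, c_out, 1) + _bn(c_out)  # project
    total += _conv(320, 1280, 1) + _bn(1280)  # head conv
    total += 1280 * num_classes + num_classes
    return total


def count_parameters(name: str, num_classes: int = 1000) -> int:
    """Trainable-parameter count of a registered architecture.

    ``tiny-cnn`` is counted from the instantiated network (regression head);
    the comparison family uses the analytic enumerators with an ImageNet
    1000-way head by default, matching the published counts.
    """
    if name == "tiny-cnn":
        return TinyCNN().n_params()
    if name in ("effnet-b0-plan", "efficientnet-b0"):
        return _effnet_b0_params(num_classes)
    resnets = {
        "resnet18": ("basic", [2, 2, 2, 2]),
        "resnet34": ("basic", [3, 4, 6, 3]),
        "resnet50": ("bottleneck", [3, 4, 6, 3]),
        "resnet101": ("bottleneck", [3, 4, 23, 3]),
        "resnet152": ("bottleneck", [3, 8, 36, 3]),
    }
    if name in resnets:
        block, layers = resnets[name]
        return _resnet_params(block, layers, num_classes)
    raise ValueError(f"unknown architecture {name!r}")


def params_millions(name: str, num_classes: int = 1000) -> int:
    """Parameter count in millions, rounded — the #Para convention."""
    return round(count_parameters(name, num_classes) / 1e6)
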