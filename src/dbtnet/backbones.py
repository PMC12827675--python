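"""Backbone registry for the dual-branch classifier.

Feature extractors are grouped into *shallow* and *deep* categories by their
layer depth and parameter count: MobileNetV2, AlexNet and ResNet18 are shallow;
ResNet50, ResNeXt50, DenseNet121 and DenseNet201 are deep.  A lightweight
TinyCNN pair is included for fast experiments and testing on synthetic phantoms.

Every builder returns the *feature-extraction* part of the published
architecture (classification heads removed) as an ``nn.Sequential`` whose last
module is flagged ``retain=True`` — its output is the final convolutional
feature map used by Grad-CAM.

Pretrained weights are not bundled; they can be loaded from an external
checkpoint file through the model-level checkpoint API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import nn

SHALLOW = "shallow"
DEEP = "deep"


@dataclass(frozen=True)
class BranchSpec:
    """Registry entry: backbone name, depth category and pooled feature width."""

    name: str
    category: str           # "shallow" or "deep", per the depth/parameter taxonomy
    feature_channels: int   # channels of the final feature map (= dim after 1x1 pool)
    builder: Callable[[np.random.Generator], nn.Sequential] = field(repr=False)


def _conv_bn_relu(cin, cout, k, s, p, rng, relu6=False, groups=1):
    return [nn.Conv2d(cin, cout, k, stride=s, pad=p, groups=groups, bias=False,
                      rng=rng),
            nn.BatchNorm2d(cout),
            nn.ReLU6() if relu6 else nn.ReLU()]


# --------------------------------------------------------------------------
# TinyCNN: small stride-heavy nets for desk-scale phantom experiments
# --------------------------------------------------------------------------

def _tiny_shallow(rng):
    return nn.Sequential(
        *_conv_bn_relu(3, 16, 7, 4, 3, rng),
        nn.MaxPool2d(2),
        *_conv_bn_relu(16, 32, 3, 2, 1, rng),
    )


def _tiny_deep(rng):
    return nn.Sequential(
        *_conv_bn_relu(3, 16, 7, 4, 3, rng),
        nn.MaxPool2d(2),
        *_conv_bn_relu(16, 32, 3, 2, 1, rng),
        *_conv_bn_relu(32, 64, 3, 2, 1, rng),
    )


# --------------------------------------------------------------------------
# AlexNet (feature stack)
# --------------------------------------------------------------------------

def _alexnet(rng):
    return nn.Sequential(
        nn.Conv2d(3, 64, 11, stride=4, pad=2, rng=rng), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(64, 192, 5, pad=2, rng=rng), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(192, 384, 3, pad=1, rng=rng), nn.ReLU(),
        nn.Conv2d(384, 256, 3, pad=1, rng=rng), nn.ReLU(),
        nn.Conv2d(256, 256, 3, pad=1, rng=rng), nn.ReLU(),
        nn.MaxPool2d(3, 2),
    )


# --------------------------------------------------------------------------
# ResNet / ResNeXt
# --------------------------------------------------------------------------

def _basic_block(cin, cout, stride, rng):
    body = nn.Sequential(
        *_conv_bn_relu(cin, cout, 3, stride, 1, rng),
        nn.Conv2d(cout, cout, 3, pad=1, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
            nn.BatchNorm2d(cout))
    return nn.Residual(body, shortcut)


def _bottleneck(cin, planes, stride, rng, groups=1, base_width=64):
    width = int(planes * (base_width / 64.0)) * groups
    cout = planes * 4
    body = nn.Sequential(
        *_conv_bn_relu(cin, width, 1, 1, 0, rng),
        *_conv_bn_relu(width, width, 3, stride, 1, rng, groups=groups),
        nn.Conv2d(width, cout, 1, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
            nn.BatchNorm2d(cout))
    return nn.Residual(body, shortcut)


def _resnet(block_counts, rng, bottleneck=False, groups=1, base_width=64):
    layers = [*_conv_bn_relu(3, 64, 7, 2, 3, rng), nn.MaxPool2d(3, 2, pad=1)]
    cin = 64
    for stage, count in enumerate(block_counts):
        planes = 64 * 2 ** stage
        for i in range(count):
            stride = 2 if stage > 0 and i == 0 else 1
            if bottleneck:
                layers.append(_bottleneck(cin, planes, stride, rng,
                                          groups=groups, base_width=base_width))
                cin = planes * 4
            else:
                layers.append(_basic_block(cin, planes, stride, rng))
                cin = planes
    return nn.Sequential(*layers)


# --------------------------------------------------------------------------
# DenseNet
# --------------------------------------------------------------------------

def _dense_layer(cin, growth, rng):
    return nn.Sequential(
        nn.BatchNorm2d(cin), nn.ReLU(),
        nn.Conv2d(cin, 4 * growth, 1, bias=False, rng=rng),
        nn.BatchNorm2d(4 * growth), nn.ReLU(),
        nn.Conv2d(4 * growth, growth, 3, pad=1, bias=False, rng=rng),
    )


def _densenet(block_counts, rng, growth=32, init_ch=64):
    layers = [*_conv_bn_relu(3, init_ch, 7, 2, 3, rng), nn.MaxPool2d(3, 2, pad=1)]
    cin = init_ch
    for bi, count in enumerate(block_counts):
        block = nn.DenseBlock([_dense_layer(cin + i * growth, growth, rng)
                               for i in range(count)])
        layers.append(block)
        cin += count * growth
        if bi < len(block_counts) - 1:
            layers += [nn.BatchNorm2d(cin), nn.ReLU(),
                       nn.Conv2d(cin, cin // 2, 1, bias=False, rng=rng),
                       nn.AvgPool2d(2)]
            cin //= 2
    layers += [nn.BatchNorm2d(cin), nn.ReLU()]
    return nn.Sequential(*layers)


# --------------------------------------------------------------------------
# MobileNetV2
# --------------------------------------------------------------------------

def _inverted_residual(cin, cout, stride, expand, rng):
    mid = cin * expand
    body = []
    if expand != 1:
        body += _conv_bn_relu(cin, mid, 1, 1, 0, rng, relu6=True)
    body += _conv_bn_relu(mid, mid, 3, stride, 1, rng, relu6=True, groups=mid)
    body += [nn.Conv2d(mid, cout, 1, bias=False, rng=rng), nn.BatchNorm2d(cout)]
    seq = nn.Sequential(*body)
    if stride == 1 and cin == cout:
        return nn.Residual(seq, None, activation="none")
    return seq


def _mobilenet_v2(rng):
    settings = [  # (expansion, channels, repeats, first stride)
        (1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
        (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
    layers = _conv_bn_relu(3, 32, 3, 2, 1, rng, relu6=True)
    cin = 32
    for t, c, n, s in settings:
        for i in range(n):
            layers.append(_inverted_residual(cin, c, s if i == 0 else 1, t, rng))
            cin = c
    layers += _conv_bn_relu(cin, 1280, 1, 1, 0, rng, relu6=True)
    return nn.Sequential(*layers)


# --------------------------------------------------------------------------
# Registry
# --------------------------------------------------------------------------

REGISTRY: dict[str, BranchSpec] = {}


def _register(name, category, channels, builder):
    REGISTRY[name] = BranchSpec(name, category, channels, builder)


_register("tinycnn-shallow", SHALLOW, 32, _tiny_shallow)
_register("tinycnn-deep", DEEP, 64, _tiny_deep)
_register("mobilenetv2", SHALLOW, 1280, _mobilenet_v2)
_register("alexnet", SHALLOW, 256, _alexnet)
_register("resnet18", SHALLOW, 512, lambda rng: _resnet([2, 2, 2, 2], rng))
_register("resnet50", DEEP, 2048,
          lambda rng: _resnet([3, 4, 6, 3], rng, bottleneck=True))
_register("resnext50", DEEP, 2048,
          lambda rng: _resnet([3, 4, 6, 3], rng, bottleneck=True, groups=32,
                              base_width=4))
_register("densenet121", DEEP, 1024, lambda rng: _densenet([6, 12, 24, 16], rng))
_register("densenet201", DEEP, 1920, lambda rng: _densenet([6, 12, 48, 32], rng))

_ALIASES = {"alex": "alexnet", "res18": "resnet18", "res50": "resnet50",
            "mobile": "mobilenetv2", "dense121": "densenet121",
            "dense201": "densenet201"}


def get_spec(name: str) -> BranchSpec:
    """Look up a backbone by (case-insensitive) name; raises with the registry
    listing on an unknown name."""
    key = name.lower().replace("_", "-")
    key = _ALIASES.get(key, key)
    if key not in REGISTRY:
        raise KeyError(
            f"unknown backbone {name!r}; available: {sorted(REGISTRY)}")
    return REGISTRY[key]


def build_backbone(name: str, rng: np.random.Generator) -> nn.Sequential:
    """Instantiate a backbone feature extractor with seeded initialization.

    The returned network's last module carries ``retain=True`` so its output
    (the final convolutional feature map) and its gradient are captured for
    Grad-CAM.
    """
    net = get_spec(name).builder(rng)
    net.layers[-1].retain = True
    return net
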