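"""Network topology configuration.

The architecture is an M-shaped encoder--decoder built from SqueezeNet-style
fire modules.  A :class:`ChannelPlan` records the squeeze/expand widths of
every fire module; :class:`SMSegNetConfig` adds the global topology knobs
(levels, feature flags, class count, input size) and resolves the plan into a
fully explicit :class:`NetworkLayout` in which every fire module knows its
input channel count.  All channel arithmetic for the network lives here, so
the parameter audit, the plan solver and the runtime network share one source
of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources as _importlib_resources
from typing import Sequence

import yaml

__all__ = [
    "ConfigurationError",
    "FireModuleSpec",
    "ChannelPlan",
    "SMSegNetConfig",
    "NetworkLayout",
    "reference_config",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Raised when a network configuration is internally inconsistent."""


@dataclass(frozen=True)
class FireModuleSpec:
    """Channel widths of one squeeze/expand unit.

    ``in_channels`` feeds a 1x1 squeeze convolution of ``squeeze_channels``
    outputs, which feeds parallel 1x1 (``expand1x1_channels``) and 3x3
    (``expand3x3_channels``) expand convolutions.  The module output is the
    channel concatenation of the two expand branches, so its width is always
    ``expand1x1_channels + expand3x3_channels``.
    """

    in_channels: int
    squeeze_channels: int
    expand1x1_channels: int
    expand3x3_channels: int

    def __post_init__(self) -> None:
        for name in ("in_channels", "squeeze_channels",
                     "expand1x1_channels", "expand3x3_channels"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ConfigurationError(
                    f"FireModuleSpec.{name} must be a positive integer, got {v!r}")

    @property
    def out_channels(self) -> int:
        return self.expand1x1_channels + self.expand3x3_channels

    @property
    def n_parameters(self) -> int:
        """Closed-form trainable parameter count of this module.

        n*s1 + s1 (squeeze) + s1*e1 + e1 (1x1 expand) + 9*s1*e3 + e3
        (3x3 expand); every convolution carries one bias per output channel.
        """
        n, s = self.in_channels, self.squeeze_channels
        e1, e3 = self.expand1x1_channels, self.expand3x3_channels
        return n * s + s + s * e1 + e1 + 9 * s * e3 + e3


@dataclass(frozen=True)
class ChannelPlan:
    """Squeeze/expand widths per resolution level.

    ``encoder_expand[l]`` / ``encoder_squeeze[l]`` give the widths shared by
    the two fire modules of encoder level ``l`` (top to bottom); the decoder
    mirrors them at the matching resolution.  Both expand branches of every
    module use the same width (e1 == e3).
    """

    encoder_expand: tuple[int, ...]
    encoder_squeeze: tuple[int, ...]
    bottleneck_expand: int
    bottleneck_squeeze: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "encoder_expand", tuple(self.encoder_expand))
        object.__setattr__(self, "encoder_squeeze", tuple(self.encoder_squeeze))
        if len(self.encoder_expand) != len(self.encoder_squeeze):
            raise ConfigurationError(
                "encoder_expand and encoder_squeeze must have equal length")
        widths = (*self.encoder_expand, *self.encoder_squeeze,
                  self.bottleneck_expand, self.bottleneck_squeeze)
        if any((not isinstance(w, int)) or w < 1 for w in widths):
            raise ConfigurationError("all channel-plan widths must be >= 1")

    @property
    def levels(self) -> int:
        return len(self.encoder_expand)


@dataclass(frozen=True)
class SMSegNetConfig:
    """Full network topology.

    ``levels`` counts the 2x2 pooling stages (a bottleneck sits below the
    deepest one); ``input_size`` is (height, width, channels) of one patch
    and must be divisible by ``2**levels`` in both spatial dimensions.
    """

    plan: ChannelPlan
    num_classes: int = 4
    input_size: tuple[int, int, int] = (128, 128, 1)
    long_skips_enabled: bool = True
    combined_connections_enabled: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_size", tuple(self.input_size))
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        h, w, c = self.input_size
        div = 2 ** self.levels
        if h % div or w % div:
            raise ConfigurationError(
                f"input size {h}x{w} must be divisible by 2^levels = {div}")
        if c < 1:
            raise ConfigurationError("input channel count must be >= 1")

    @property
    def levels(self) -> int:
        return self.plan.levels

    def layout(self) -> "NetworkLayout":
        return NetworkLayout.from_config(self)


@dataclass(frozen=True)
class NetworkLayout:
    """Explicit per-module channel arithmetic for one configuration.

    ``fires`` maps layer names (``enc1.fire1`` ... ``dec1.fire2``) to fully
    resolved :class:`FireModuleSpec` instances in execution order;
    ``classifier_in`` is the channel fan-in of the final 1x1 classifier.
    """

    config: SMSegNetConfig
    fires: tuple[tuple[str, FireModuleSpec], ...]
    encoder_out_channels: tuple[int, ...]   # channels of e_l, top to bottom
    decoder_out_channels: tuple[int, ...]   # channels of d_l, top to bottom
    right_leg_channels: int                 # channels of the fused right leg
    classifier_in: int

    @classmethod
    def from_config(cls, cfg: SMSegNetConfig) -> "NetworkLayout":
        plan, L = cfg.plan, cfg.levels
        in_ch = cfg.input_size[2]
        fires: list[tuple[str, FireModuleSpec]] = []

        def fire(name: str, n: int, s: int, e: int) -> int:
            try:
                spec = FireModuleSpec(n, s, e, e)
            except ConfigurationError as exc:
                raise ConfigurationError(f"{name}: {exc}") from exc
            fires.append((name, spec))
            return spec.out_channels

        # Encoder: two chained fire modules per level; the level output e_l
        # concatenates the pooled fire output with the pooled side input
        # (the raw image at that level's resolution, in_ch channels).
        x = in_ch
        e_ch: list[int] = []
        for l in range(1, L + 1):
            s, e = plan.encoder_squeeze[l - 1], plan.encoder_expand[l - 1]
            out = fire(f"enc{l}.fire1", x, s, e)
            out = fire(f"enc{l}.fire2", out, s, e)
            x = out + in_ch
            e_ch.append(x)

        # Bottleneck at the deepest resolution, two fire modules.  Its output
        # feeds the deepest unpooling, whose recorded indices carry one entry
        # per channel of the deepest encoder fire output, so the bottleneck
        # expand width must equal the deepest encoder expand width.
        if plan.bottleneck_expand != plan.encoder_expand[-1]:
            raise ConfigurationError(
                "bottleneck: expand width must equal the deepest encoder "
                f"expand width ({plan.encoder_expand[-1]}) for index-based "
                f"unpooling, got {plan.bottleneck_expand}")
        out = fire("bottleneck.fire1", x, plan.bottleneck_squeeze,
                   plan.bottleneck_expand)
        out = fire("bottleneck.fire2", out, plan.bottleneck_squeeze,
                   plan.bottleneck_expand)
        x = out

        # Decoder, bottom to top.  Unpooling lifts x to encoder level l's
        # input resolution, where the combined-connection concatenates the
        # encoder stream living there: e_{l-1}, or the raw image at the top.
        # Each decoder block must emit exactly the channel count the next
        # unpooling's indices were recorded with, so decoder level l mirrors
        # the widths of encoder level l-1 (the top level reuses level 1's).
        d_ch: list[int] = [0] * L
        for l in range(L, 0, -1):
            skip = (e_ch[l - 2] if l >= 2 else in_ch)
            n1 = x + (skip if cfg.combined_connections_enabled else 0)
            wi = l - 2 if l >= 2 else 0
            s, e = plan.encoder_squeeze[wi], plan.encoder_expand[wi]
            out = fire(f"dec{l}.fire1", n1, s, e)
            out = fire(f"dec{l}.fire2", out, s, e)
            d_ch[l - 1] = out
            x = out

        # Right leg: seeded by the x2-upsampled bottleneck output, then at
        # every level concatenates the decoder output and (when long skips
        # are enabled) the side input at that resolution.
        r = 2 * plan.bottleneck_expand
        for l in range(L, 0, -1):
            r += d_ch[l - 1] + (in_ch if cfg.long_skips_enabled else 0)

        classifier_in = d_ch[0] + r
        return cls(config=cfg, fires=tuple(fires),
                   encoder_out_channels=tuple(e_ch),
                   decoder_out_channels=tuple(d_ch),
                   right_leg_channels=r, classifier_in=classifier_in)

    @property
    def n_parameters(self) -> int:
        """Closed-form trainable parameter total (fires + 1x1 classifier)."""
        total = sum(spec.n_parameters for _, spec in self.fires)
        total += self.config.num_classes * (self.classifier_in + 1)
        return total


# ---------------------------------------------------------------------------
# Serialization

def _config_to_dict(cfg: SMSegNetConfig) -> dict:
    return {
        "plan": asdict(cfg.plan) | {
            "encoder_expand": list(cfg.plan.encoder_expand),
            "encoder_squeeze": list(cfg.plan.encoder_squeeze),
        },
        "num_classes": cfg.num_classes,
        "input_size": list(cfg.input_size),
        "long_skips_enabled": cfg.long_skips_enabled,
        "combined_connections_enabled": cfg.combined_connections_enabled,
    }


def _config_from_dict(doc: dict) -> SMSegNetConfig:
    plan = ChannelPlan(
        encoder_expand=tuple(doc["plan"]["encoder_expand"]),
        encoder_squeeze=tuple(doc["plan"]["encoder_squeeze"]),
        bottleneck_expand=int(doc["plan"]["bottleneck_expand"]),
        bottleneck_squeeze=int(doc["plan"]["bottleneck_squeeze"]),
    )
    return SMSegNetConfig(
        plan=plan,
        num_classes=int(doc.get("num_classes", 4)),
        input_size=tuple(doc.get("input_size", (128, 128, 1))),
        long_skips_enabled=bool(doc.get("long_skips_enabled", True)),
        combined_connections_enabled=bool(
            doc.get("combined_connections_enabled", True)),
    )


def save_config(cfg: SMSegNetConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> SMSegNetConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def reference_config() -> SMSegNetConfig:
    """The versioned reference configuration shipped with the package."""
    ref = _importlib_resources.files("smsegnet.resources") / "reference_plan.yaml"
    with ref.open() as fh:
        return _config_from_dict(yaml.safe_load(fh))
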