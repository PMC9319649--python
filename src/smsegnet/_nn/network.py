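"""The M-shaped squeeze encoder--decoder network.

Topology (top resolution -> bottom and back):

* **Left leg** — the input patch is repeatedly 2x2 max-pooled; the copy at
  each level's resolution is a *side input*.
* **Encoder level l** — two chained fire modules, then 2x2 max pooling with
  argmax recording; the level output ``e_l`` concatenates the pooled fire
  output with the pooled side input.
* **Bottleneck** — two fire modules at the deepest resolution.
* **Decoder level l** — index-based unpooling (with the encoder's recorded
  argmax positions) lifts the stream one resolution; the combined-connection
  concatenates the encoder stream at that resolution (``e_{l-1}``, or the
  raw patch at the top); two fire modules follow.
* **Right leg** — a running concatenation, seeded by the x2-upsampled
  bottleneck output, of every decoder output plus (when long skips are
  enabled) the side input at that resolution; parameter-free.
* **Classifier** — the top decoder output and the right leg are fused by
  concatenation and mapped to per-class scores by a 1x1 convolution with
  softmax.

All convolutions are stride 1 with shape-preserving zero padding and a bias
per output channel; every squeeze and expand convolution is ReLU-activated.
"""

from __future__ import annotations

import numpy as np

from ..config import SMSegNetConfig, NetworkLayout, FireModuleSpec, ConfigurationError
from . import ops
from .ops import Tensor, PoolingIndices

__all__ = ["SMSegNet", "fire_module_forward", "init_fire_weights"]


def _he_init(rng: np.random.Generator, out_ch: int, in_ch: int, k: int):
    """He fan-in normal initialization for a (out, in, k, k) kernel."""
    std = np.sqrt(2.0 / (in_ch * k * k))
    w = rng.normal(0.0, std, size=(out_ch, in_ch, k, k)).astype(np.float32)
    b = np.zeros(out_ch, dtype=np.float32)
    return w, b


def init_fire_weights(spec: FireModuleSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded He-initialized weights for a standalone fire module."""
    rng = np.random.default_rng(seed)
    w = {}
    w["squeeze.w"], w["squeeze.b"] = _he_init(
        rng, spec.squeeze_channels, spec.in_channels, 1)
    w["expand1.w"], w["expand1.b"] = _he_init(
        rng, spec.expand1x1_channels, spec.squeeze_channels, 1)
    w["expand3.w"], w["expand3.b"] = _he_init(
        rng, spec.expand3x3_channels, spec.squeeze_channels, 3)
    return w


def fire_module_forward(x: np.ndarray, spec: FireModuleSpec,
                        weights: dict[str, np.ndarray]) -> np.ndarray:
    """Run one fire module on an (N, C, H, W) array.

    Squeeze (1x1) then parallel expand (1x1 and zero-padded 3x3), each
    ReLU-activated; the output concatenates the 1x1 branch first, then the
    3x3 branch, giving e1 + e3 channels at unchanged spatial size.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError("fire_module_forward expects an (N, C, H, W) array")
    if x.shape[1] != spec.in_channels:
        raise ConfigurationError(
            f"input has {x.shape[1]} channels but the fire module "
            f"expects {spec.in_channels}")
    t = _fire(Tensor(x), spec, {k: Tensor(v) for k, v in weights.items()})
    return t.data


def _fire(x: Tensor, spec: FireModuleSpec, w: dict[str, Tensor]) -> Tensor:
    s = ops.relu(ops.conv2d(x, w["squeeze.w"], w["squeeze.b"]))
    e1 = ops.relu(ops.conv2d(s, w["expand1.w"], w["expand1.b"]))
    e3 = ops.relu(ops.conv2d(s, w["expand3.w"], w["expand3.b"]))
    return ops.concat([e1, e3])


class SMSegNet:
    """A built network: seeded parameters plus the forward computation.

    Parameters are float32 arrays wrapped in autograd tensors, keyed by
    layer-qualified names (``enc1.fire1.squeeze.w`` ... ``classifier.b``).
    Weight initialization is He fan-in, deterministic in ``seed``.
    """

    def __init__(self, config: SMSegNetConfig, seed: int = 0):
        self.config = config
        self.layout: NetworkLayout = config.layout()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        for name, spec in self.layout.fires:
            for key, arr in (
                ("squeeze", _he_init(rng, spec.squeeze_channels, spec.in_channels, 1)),
                ("expand1", _he_init(rng, spec.expand1x1_channels, spec.squeeze_channels, 1)),
                ("expand3", _he_init(rng, spec.expand3x3_channels, spec.squeeze_channels, 3)),
            ):
                self.params[f"{name}.{key}.w"] = Tensor(arr[0], requires_grad=True)
                self.params[f"{name}.{key}.b"] = Tensor(arr[1], requires_grad=True)
        cw, cb = _he_init(rng, config.num_classes, self.layout.classifier_in, 1)
        self.params["classifier.w"] = Tensor(cw, requires_grad=True)
        self.params["classifier.b"] = Tensor(cb, requires_grad=True)

    # -- forward ------------------------------------------------------------

    def _fire_pair(self, x: Tensor, level_name: str) -> Tensor:
        specs = dict(self.layout.fires)
        for fire_name in (f"{level_name}.fire1", f"{level_name}.fire2"):
            spec = specs[fire_name]
            if x.shape[1] != spec.in_channels:
                raise ConfigurationError(
                    f"{fire_name}: stream has {x.shape[1]} channels, "
                    f"expected {spec.in_channels}")
            w = {k: self.params[f"{fire_name}.{k2}"]
                 for k, k2 in (("squeeze.w", "squeeze.w"), ("squeeze.b", "squeeze.b"),
                               ("expand1.w", "expand1.w"), ("expand1.b", "expand1.b"),
                               ("expand3.w", "expand3.w"), ("expand3.b", "expand3.b"))}
            x = _fire(x, spec, w)
        return x

    def logits(self, x: np.ndarray | Tensor) -> Tensor:
        """Forward pass to pre-softmax class scores (N, C, H, W)."""
        cfg = self.config
        L = cfg.levels
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        n, c, h, w = x.shape
        eh, ew, ec = cfg.input_size
        if (h, w, c) != (eh, ew, ec):
            raise ValueError(
                f"input {h}x{w}x{c} does not match configured size {eh}x{ew}x{ec}")

        # Left leg: side inputs at every resolution.
        side: list[Tensor] = [x]
        for _ in range(L):
            pooled, _idx = ops.max_pool_with_indices(side[-1])
            side.append(pooled)

        # Encoder.
        stream = x
        enc_out: list[Tensor] = []          # e_l, top to bottom
        pool_idx: list[PoolingIndices] = []  # pind_l per level
        for l in range(1, L + 1):
            fm = self._fire_pair(stream, f"enc{l}")
            pooled, idx = ops.max_pool_with_indices(fm)
            pool_idx.append(idx)
            stream = ops.concat([pooled, side[l]])
            enc_out.append(stream)

        # Bottleneck.
        stream = self._fire_pair(stream, "bottleneck")
        bottleneck = stream

        # Decoder with combined-connections.
        dec_out: list[Tensor | None] = [None] * L
        for l in range(L, 0, -1):
            up = ops.max_unpool(stream, pool_idx[l - 1])
            if cfg.combined_connections_enabled:
                skip = enc_out[l - 2] if l >= 2 else side[0]
                up = ops.concat([up, skip])
            stream = self._fire_pair(up, f"dec{l}")
            dec_out[l - 1] = stream

        # Right leg (deep supervision), parameter-free.
        r = ops.upsample2(bottleneck)
        for l in range(L, 0, -1):
            parts = [r, dec_out[l - 1]]
            if cfg.long_skips_enabled:
                parts.append(side[l - 1])
            r = ops.concat(parts)
            if l > 1:
                r = ops.upsample2(r)

        fused = ops.concat([dec_out[0], r])
        return ops.conv2d(fused, self.params["classifier.w"],
                          self.params["classifier.b"])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (N, num_classes, H, W)."""
        return ops.softmax(self.logits(x).data, axis=1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x)

    # -- bookkeeping --------------------------------------------------------

    def n_parameters(self) -> int:
        """Framework count: total size of all trainable arrays."""
        return int(sum(t.data.size for t in self.params.values()))

    def parameter_manifest(self) -> list[tuple[str, tuple[int, ...], int, int]]:
        """Per-array (name, shape, count, cumulative count), in build order."""
        rows, total = [], 0
        for name, t in self.params.items():
            total += t.data.size
            rows.append((name, tuple(t.data.shape), int(t.data.size), total))
        return rows

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def save(self, path) -> None:
        np.savez(path, **{k: t.data for k, t in self.params.items()})

    def load(self, path) -> None:
        with np.load(path) as archive:
            for k, t in self.params.items():
                arr = archive[k]
                if arr.shape != t.data.shape:
                    raise ValueError(f"checkpoint mismatch for {k}: "
                                     f"{arr.shape} vs {t.data.shape}")
                t.data = arr.astype(np.float32)
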