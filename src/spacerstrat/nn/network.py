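"""Hierarchically densely connected U-Net for volumetric dose prediction.

The topology follows the HD U-Net family: within each resolution level a
dense block whose convolutions see the concatenation of every earlier
feature map at that level; across levels, the expansive path concatenates
all same-resolution feature maps from the contracting path.  Downsampling
is 2x2x2 max pooling, upsampling is trilinear interpolation followed by a
convolution, and a final 1x1x1 convolution with linear activation emits the
single dose channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, parameter
from .ops import concat, conv3d, maxpool2, relu, upsample2


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``growth`` is the number of feature maps added by each dense
    convolution; the full-scale preset (5 levels on a 128 x 128 x 64 input)
    reaches an 8 x 8 x 4 bottleneck.
    """

    levels: int = 5
    growth: int = 8
    convs_per_block: int = 2
    kernel: int = 3
    input_channels: int = 5

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ConfigurationError("at least two resolution levels are required")
        if self.growth < 1 or self.convs_per_block < 1:
            raise ConfigurationError("growth and convs_per_block must be >= 1")
        if self.kernel % 2 != 1:
            raise ConfigurationError("kernel size must be odd for same padding")

    @property
    def down_factor(self) -> int:
        return 2 ** (self.levels - 1)

    def check_input_shape(self, shape_zyx) -> None:
        f = self.down_factor
        for name, n in zip("zyx", shape_zyx):
            if n % f != 0:
                raise ConfigurationError(
                    f"input dimension {name}={n} is not divisible by {f} "
                    f"(2^(levels-1) with levels={self.levels})"
                )

    def bottleneck_shape(self, shape_zyx) -> tuple[int, int, int]:
        self.check_input_shape(shape_zyx)
        f = self.down_factor
        return tuple(n // f for n in shape_zyx)

    @classmethod
    def full_scale(cls) -> "NetworkConfig":
        return cls(levels=5, growth=16, convs_per_block=2)

    @classmethod
    def desk_scale(cls) -> "NetworkConfig":
        return cls(levels=3, growth=4, convs_per_block=2)


class HDUNet:
    """Builds parameters eagerly; ``forward`` assembles the tape per call."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self._rng = np.random.default_rng(seed)
        self.params: list[Tensor] = []
        self._build()

    # -- construction -------------------------------------------------------

    def _conv_params(self, cin: int, cout: int, k: int):
        fan_in = cin * k**3
        w = parameter(self._rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k, k)))
        b = parameter(np.zeros(cout))
        self.params += [w, b]
        return w, b, k

    def _build(self) -> None:
        cfg = self.cfg
        k, g = cfg.kernel, cfg.growth

        def dense_block(cin):
            layers = []
            c = cin
            for _ in range(cfg.convs_per_block):
                layers.append(self._conv_params(c, g, k))
                c += g
            return layers, c

        self.encoder = []
        c = cfg.input_channels
        skip_channels = []
        for _ in range(cfg.levels - 1):
            block, c = dense_block(c)
            self.encoder.append(block)
            skip_channels.append(c)
        self.bottleneck, c_bot = dense_block(c)

        self.decoder = []
        c = c_bot
        for lvl in reversed(range(cfg.levels - 1)):
            up = self._conv_params(c, 2 * g, k)
            block, c = dense_block(2 * g + skip_channels[lvl])
            self.decoder.append((up, block))
        self.final = self._conv_params(c, 1, 1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _run_block(x: Tensor, block) -> Tensor:
        feats = [x]
        for w, b, k in block:
            y = relu(conv3d(concat(feats) if len(feats) > 1 else feats[0], w, b, k))
            feats.append(y)
        return concat(feats)

    def forward(self, x: Tensor) -> Tensor:
        self.cfg.check_input_shape(x.shape[2:])
        skips = []
        h = x
        for block in self.encoder:
            h = self._run_block(h, block)
            skips.append(h)
            h = maxpool2(h)
        h = self._run_block(h, self.bottleneck)
        for (up, block), skip in zip(self.decoder, reversed(skips)):
            w, b, k = up
            h = relu(conv3d(upsample2(h), w, b, k))
            h = self._run_block(concat([h, skip]), block)
        w, b, k = self.final
        return conv3d(h, w, b, k)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass without gradient bookkeeping; returns (N, 1, D, H, W)."""
        out = self.forward(Tensor(x))
        return out.data.copy()

    # -- (de)serialisation --------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params]

    def load_state_arrays(self, arrays) -> None:
        if len(arrays) != len(self.params):
            raise ConfigurationError("checkpoint does not match this architecture")
        for p, a in zip(self.params, arrays):
            if p.data.shape != a.shape:
                raise ConfigurationError("checkpoint parameter shapes do not match")
            p.data = np.asarray(a, dtype=np.float32)
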