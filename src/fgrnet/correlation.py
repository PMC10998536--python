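"""Residual 1D-CNN expression feature extractor and the Cnet pair-correlation head.

Each of the three residual blocks runs two convolution blocks on the main
branch and a projection convolution block on the shortcut, where a
convolution block is conv -> ReLU -> BatchNorm -> MaxPool, in that order
(activation deliberately precedes batch normalization).  The shortcut is a
projection (conv + BN + pool), not an identity skip.  Pooling is ceil-mode,
so short profiles (down to length 4) survive all three blocks; the net
length reduction per block equals ``pool_size``, applied once — the first
main-branch convolution block uses a unit pool so that the two branches
emerge with identical shapes and can be summed.

Cnet flattens the concatenated block-3 outputs of the two genes of a pair
and maps them through dense -> dropout -> dense to the correlation
embedding.  It is deliberately asymmetric in (regulator, target) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

MIN_INPUT_LENGTH = 4


@dataclass
class ResidualExtractorConfig:
    channels: tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 3
    pool_size: int = 2
    output_dim: int = 64

    def validate(self) -> None:
        if len(self.channels) != 3:
            raise ValueError("exactly three residual blocks are used; give three channel widths")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.pool_size < 1 or self.output_dim < 1:
            raise ValueError("pool_size and output_dim must be positive")


@dataclass
class CnetConfig:
    hidden_dim: int = 64
    d_corr: int = 64
    dropout: float = 0.5


class _ConvBlock(nn.Layer):
    """conv -> ReLU -> BatchNorm -> MaxPool."""

    def __init__(self, in_ch, out_ch, kernel, pool, rng):
        self.seq = nn.Sequential(
            nn.Conv1d(in_ch, out_ch, kernel, rng),
            nn.ReLU(),
            nn.BatchNorm1d(out_ch),
            nn.MaxPool1d(pool),
        )

    def params(self):
        return self.seq.params()

    def forward(self, x, training=False):
        return self.seq.forward(x, training=training)

    def backward(self, dy):
        return self.seq.backward(dy)


class ResidualBlock(nn.Layer):
    """Projection-shortcut residual block; output = shortcut + main branch."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pool: int,
                 rng: np.random.Generator) -> None:
        self.block_a = _ConvBlock(in_ch, out_ch, kernel, 1, rng)
        self.block_b = _ConvBlock(out_ch, out_ch, kernel, pool, rng)
        self.shortcut = _ConvBlock(in_ch, out_ch, kernel, pool, rng)

    def params(self):
        return self.block_a.params() + self.block_b.params() + self.shortcut.params()

    def forward(self, x, training=False):
        a = self.block_a.forward(x, training=training)
        b = self.block_b.forward(a, training=training)
        s = self.shortcut.forward(x, training=training)
        if s.shape != b.shape:
            raise ValueError(
                f"residual branch shapes differ ({b.shape} vs {s.shape}); "
                "mis-configured pooling")
        return s + b

    def backward(self, dy):
        dx_main = self.block_a.backward(self.block_b.backward(dy))
        dx_short = self.shortcut.backward(dy)
        return dx_main + dx_short


class ResidualExtractor:
    """Three residual blocks + global average pooling + dense layer.

    ``forward_blocks`` exposes the block-3 sequence output (the Cnet input);
    ``forward_features`` adds the pooled dense projection whose width is
    independent of the input profile length.
    """

    def __init__(self, config: ResidualExtractorConfig, rng: np.random.Generator) -> None:
        config.validate()
        self.config = config
        chans = (1,) + tuple(config.channels)
        self.blocks = [
            ResidualBlock(chans[i], chans[i + 1], config.kernel_size,
                          config.pool_size, rng)
            for i in range(3)
        ]
        self.gap = nn.GlobalAvgPool1d()
        self.dense = nn.Dense(config.channels[-1], config.output_dim, rng)

    def params(self):
        out = []
        for b in self.blocks:
            out.extend(b.params())
        return out + self.dense.params()

    def block_params(self):
        out = []
        for b in self.blocks:
            out.extend(b.params())
        return out

    def out_length(self, dim_e: int) -> int:
        length = dim_e
        for _ in range(3):
            length = -(-length // self.config.pool_size)
        return length

    def forward_blocks(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, dimE) profiles -> (N, C3, L3) block-3 feature sequences."""
        if x.shape[1] < MIN_INPUT_LENGTH:
            raise ValueError(
                f"expression profiles of length {x.shape[1]} are too short; "
                f"minimum supported length is {MIN_INPUT_LENGTH}")
        h = x[:, None, :]
        for b in self.blocks:
            h = b.forward(h, training=training)
        return h

    def backward_blocks(self, dy: np.ndarray) -> np.ndarray:
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return dy[:, 0, :]

    def forward_features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, dimE) -> (N, output_dim) expression features (expResNet path)."""
        h = self.forward_blocks(x, training=training)
        return self.dense.forward(self.gap.forward(h, training=training),
                                  training=training)

    def backward_features(self, dy: np.ndarray) -> np.ndarray:
        return self.backward_blocks(self.gap.backward(self.dense.backward(dy)))

    # split heads used when block outputs feed several consumers
    def forward_head(self, h: np.ndarray, training: bool = False) -> np.ndarray:
        return self.dense.forward(self.gap.forward(h, training=training),
                                  training=training)

    def backward_head(self, dy: np.ndarray) -> np.ndarray:
        return self.gap.backward(self.dense.backward(dy))


def extract_expression_features(x: np.ndarray, extractor: ResidualExtractor,
                                training: bool = False) -> np.ndarray:
    """Convenience wrapper: profiles (N, dimE) -> features (N, output_dim)."""
    return extractor.forward_features(np.asarray(x, dtype=np.float64), training=training)


class Cnet:
    """Correlation-embedding network for a gene pair.

    flatten(concat(y3_R, y3_T)) -> dense -> dropout -> dense.  Dropout is
    identity at inference.
    """

    def __init__(self, in_dim: int, config: CnetConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.dense1 = nn.Dense(in_dim, config.hidden_dim, rng)
        self.act = nn.ReLU()
        self.drop = nn.Dropout(config.dropout, rng)
        self.dense2 = nn.Dense(config.hidden_dim, config.d_corr, rng)

    def params(self):
        return self.dense1.params() + self.dense2.params()

    def forward(self, y_r: np.ndarray, y_t: np.ndarray, training: bool = False) -> np.ndarray:
        if y_r.shape != y_t.shape:
            raise ValueError(f"pair feature shapes differ: {y_r.shape} vs {y_t.shape}")
        n = y_r.shape[0]
        flat = np.concatenate([y_r.reshape(n, -1), y_t.reshape(n, -1)], axis=1)
        self._shapes = (y_r.shape, y_t.shape)
        h = self.dense1.forward(flat, training=training)
        h = self.act.forward(h, training=training)
        h = self.drop.forward(h, training=training)
        return self.dense2.forward(h, training=training)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dh = self.drop.backward(self.dense2.backward(dy))
        dflat = self.dense1.backward(self.act.backward(dh))
        shape_r, shape_t = self._shapes
        half = dflat.shape[1] // 2
        return dflat[:, :half].reshape(shape_r), dflat[:, half:].reshape(shape_t)


def cnet_correlation(y_r: np.ndarray, y_t: np.ndarray, net: Cnet,
                     training: bool = False) -> np.ndarray:
    """Correlation embedding of a pair of extracted feature sequences."""
    return net.forward(np.asarray(y_r, dtype=np.float64),
                       np.asarray(y_t, dtype=np.float64), training=training)
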