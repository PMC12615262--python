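"""Sequence encoder: one-hot DNA in, per-bin embeddings out.

The encoder contract mirrors large sequence-to-profile models: a window of
``input_length`` base pairs is encoded into one embedding vector per
``bin_width`` (32 bp) bin, and the center ``output_bins`` bins are kept.
With the full-scale defaults (524,288 bp in, 6,144 bins out at width 32,
embedding width 1,920) the geometry matches the published architecture this
package interoperates with; the trainable :class:`MiniBackbone` honors the
same contract at desk scale and is fully trainable on CPU.

The backbone exposes its adaptable layers by kind, so LoRA adapters
(:func:`scprofile.layers.inject_lora`) can be injected into all
convolutional layers and the attention query/value and MLP projection
matrices, and merged back after training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (BatchNorm1d, ChannelNorm, Conv1d, Dropout, Linear,
                     Module, TransformerBlock)
from .minigrad import Tensor, no_grad

__all__ = [
    "ModelGeometry", "OneHotSequence", "SequenceEmbedding",
    "one_hot", "MiniBackbone", "make_mini_backbone", "embed",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3,
               "a": 0, "c": 1, "g": 2, "t": 3}


@dataclass(frozen=True)
class ModelGeometry:
    """Input/output geometry of the sequence encoder.

    Defaults are the full-scale architecture constants: 524,288 bp of input
    at 32-bp resolution, cropped to the center 6,144 bins (196,608 bp),
    embedding width 1,920.
    """

    input_length: int = 524_288
    bin_width: int = 32
    output_bins: int = 6_144
    embedding_width: int = 1_920

    def __post_init__(self):
        if self.input_length % self.bin_width != 0:
            raise ValueError("input_length must be divisible by bin_width")
        if self.output_bins > self.pre_crop_bins:
            raise ValueError("output_bins exceeds pre-crop bin count")
        if (self.pre_crop_bins - self.output_bins) % 2 != 0:
            raise ValueError("center crop requires an even number of "
                             "cropped bins")

    @property
    def pre_crop_bins(self) -> int:
        return self.input_length // self.bin_width

    @property
    def crop_bins(self) -> int:
        """Bins cropped from each side."""
        return (self.pre_crop_bins - self.output_bins) // 2

    @property
    def output_length(self) -> int:
        return self.output_bins * self.bin_width


@dataclass
class OneHotSequence:
    """One-hot encoded DNA: 4 channels (A, C, G, T) x length.

    N bases map to all-zero columns; ``shift`` records the window offset
    applied (vacated edge zero-padded), ``rc`` whether the encoding is the
    reverse complement.
    """

    matrix: np.ndarray
    shift: int = 0
    rc: bool = False

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SequenceEmbedding:
    """Center-cropped per-bin representation emitted by a backbone."""

    values: np.ndarray  # (output_bins, E)
    geometry: ModelGeometry
    provenance: dict = field(default_factory=dict)


def one_hot(seq: str, shift: int = 0, rc: bool = False) -> OneHotSequence:
    """Encode a DNA string, with optional window shift and reverse complement.

    A positive shift moves the sequence content rightward by ``shift``
    columns (equivalently the window leftward); vacated columns are zero.
    The reverse complement is applied after shifting.
    """
    n = len(seq)
    m = np.zeros((4, n))
    idx = np.fromiter((_BASE_INDEX.get(b, -1) for b in seq), dtype=np.int64,
                      count=n)
    bad = [b for b in set(seq) if b not in _BASE_INDEX and b.upper() != "N"]
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    valid = idx >= 0
    m[idx[valid], np.nonzero(valid)[0]] = 1.0
    if shift > 0:
        shifted = np.zeros_like(m)
        shifted[:, shift:] = m[:, :-shift]
        m = shifted
    elif shift < 0:
        shifted = np.zeros_like(m)
        shifted[:, :shift] = m[:, -shift:]
        m = shifted
    if rc:
        m = m[::-1, ::-1].copy()  # A<->T, C<->G by channel reversal
    return OneHotSequence(matrix=m, shift=shift, rc=rc)


def _positional_encoding(n_bins: int, dim: int) -> np.ndarray:
    pos = np.arange(n_bins)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class MiniBackbone(Module):
    """Desk-scale sequence encoder honoring the embedding contract.

    A wide stride-1 first convolution (the motif layer, optionally seeded
    from PWMs) followed by residual conv blocks with max-pool
    downsampling reduces the input to one position per 32-bp bin; a
    global max-context block and optional transformer blocks (sinusoidal
    positions) mix information across bins; a final trainable linear
    layer with GELU nonlinearity projects to the embedding width, after
    which the center crop is applied.
    """

    def __init__(self, geometry: ModelGeometry, channels: int = 32,
                 n_transformer: int = 1, dropout: float = 0.0,
                 seed: int = 0, norm: str = "layer", pwm_init=None,
                 ctx_mode: str = "add"):
        super().__init__()
        if norm not in ("layer", "batch"):
            raise ValueError("norm must be 'layer' or 'batch'")
        self.geometry = geometry
        self.channels = channels
        self.norm_kind = norm
        if ctx_mode not in ("add", "mul"):
            raise ValueError("ctx_mode must be 'add' or 'mul'")
        self.ctx_mode = ctx_mode
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 7]).generate_state(1)[0])
        n_down = int(np.log2(geometry.bin_width))
        if 2 ** n_down != geometry.bin_width:
            raise ValueError("bin_width must be a power of two")
        # wide stride-1 first convolution (motif layer) and max-pool
        # downsampling: pooling preserves sharp motif activations that
        # strided convolution chains wash out
        convs = []
        bns = []
        in_ch = 4
        for i in range(n_down):
            k = 13 if i == 0 else 5
            convs.append(Conv1d(in_ch, channels, k, rng, stride=1,
                                padding=k // 2))
            bns.append(BatchNorm1d(channels) if norm == "batch"
                       else ChannelNorm(channels))
            in_ch = channels
        self.convs = convs
        self.bns = bns
        if pwm_init:
            self._init_motif_filters(pwm_init)
        self.blocks = [TransformerBlock(channels, mlp_ratio=2, rng=rng,
                                        dropout=dropout)
                       for _ in range(n_transformer)]
        for b in self.blocks:
            b.drop.rng = self._dropout_rng
        # global-context block: window-wide mean features gate every bin,
        # letting regulatory elements anywhere in the window modulate the
        # whole profile without relying on attention routing alone
        self.ctx_in = Linear(channels, channels, rng)
        self.ctx_out = Linear(channels, channels, rng)
        # extra trainable projection layer with GELU, trained from scratch
        self.project = Linear(channels, geometry.embedding_width, rng,
                              kind=None)
        self._pos = _positional_encoding(geometry.pre_crop_bins, channels)
        self.n_forward_calls = 0

    def _init_motif_filters(self, pwms):
        """Seed first-layer filters with PWM match patterns (both strands).

        Stands in for the motif vocabulary a pretrained sequence model
        brings along: downstream layers still have to learn which motifs
        matter, where, and for which cell states.  Raises if the PWM set
        does not fit into the available channels.
        """
        conv = self.convs[0]
        C, _, K = conv.weight.data.shape
        filters = []
        for pwm in pwms:
            for mat in (pwm.matrix, pwm.matrix[::-1, ::-1]):
                filters.append(mat)
        if len(filters) > C:
            raise ValueError(
                f"{len(filters)} motif filters exceed {C} channels")
        for c, mat in enumerate(filters):
            w = len(mat)
            if w > K:
                raise ValueError(f"PWM length {w} exceeds kernel size {K}")
            off = (K - w) // 2
            conv.weight.data[c] *= 0.0
            conv.weight.data[c, :, off:off + w] = (mat.T - 0.25) * 3.0
            peak = ((mat.max(axis=1) - 0.25) * 3.0).sum()
            conv.bias.data[c] = -0.6 * peak

    # -- contract hooks -------------------------------------------------------
    def freeze_norm(self):
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                m.freeze()

    def unfreeze_norm(self):
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                m.unfreeze()

    def set_dropout_enabled(self, enabled: bool):
        for m in self.modules():
            if isinstance(m, Dropout):
                m.enabled = enabled

    # -- forward --------------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        """(B, 4, input_length) -> (B, output_bins, E)."""
        self.n_forward_calls += 1
        if x.shape[-1] != self.geometry.input_length:
            raise ValueError(
                f"backbone expects length {self.geometry.input_length}, "
                f"got {x.shape[-1]}")
        # convolve at full resolution, but downsample before normalization
        # and activation: max pooling selects the strongest local response
        # (e.g. the best motif match), and the elementwise work then runs
        # on half-length maps
        x = self.bns[0](self.convs[0](x).maxpool1d(2)).gelu()
        for conv, bn in zip(self.convs[1:], self.bns[1:]):
            # residual conv blocks: feature channels (e.g. motif detectors
            # from the first layer) persist through the tower
            x = x.maxpool1d(2) + bn(conv(x).maxpool1d(2)).gelu()
        # global context: per-channel MAX over bins (motif presence is a
        # peak signal; mean pooling would dilute it below noise)
        peak = x.maxpool1d(x.shape[-1]).reshape(x.shape[0], x.shape[1])
        g = self.ctx_out(self.ctx_in(peak).gelu())  # (B, C)
        x = x.transpose((0, 2, 1))  # (B, bins, C)
        g = g.reshape(g.shape[0], 1, g.shape[1])
        if self.ctx_mode == "mul":
            # multiplicative gating: an element detected anywhere in the
            # window rescales local features, mirroring how a regulatory
            # element multiplies a gene's rate
            x = x * (1.0 + g)
        else:
            x = x + g
        if self.blocks:
            x = x + self._pos
            for block in self.blocks:
                x = block(x)
        x = self.project(x).gelu()
        c = self.geometry.crop_bins
        if c:
            x = x[:, c:-c, :]
        return x


def make_mini_backbone(geometry: ModelGeometry, channels: int = 32,
                       n_layers: int = 1, seed: int = 0,
                       dropout: float = 0.0, norm: str = "layer",
                       pwm_init=None, ctx_mode: str = "add") -> MiniBackbone:
    """Construct a desk-scale backbone honoring the encoder contract.

    ``n_layers`` counts transformer blocks (0 disables attention); the
    convolutional downsampling depth is fixed by the bin width.  ``norm``
    selects per-position channel normalization (default, batch-size
    independent) or batch normalization with running statistics (the
    full-scale convention, with freeze/unfreeze hooks).  ``pwm_init``
    optionally seeds first-layer filters with PWM match patterns, standing
    in for the motif vocabulary of a pretrained encoder.
    """
    return MiniBackbone(geometry, channels=channels, n_transformer=n_layers,
                        dropout=dropout, seed=seed, norm=norm,
                        pwm_init=pwm_init, ctx_mode=ctx_mode)


def embed(backbone: MiniBackbone, oh: OneHotSequence) -> SequenceEmbedding:
    """Run the backbone in inference mode on a single one-hot sequence."""
    if oh.length != backbone.geometry.input_length:
        raise ValueError(
            f"sequence length {oh.length} does not match geometry "
            f"input_length {backbone.geometry.input_length}")
    was_training = backbone.training
    backbone.eval()
    try:
        with no_grad():
            out = backbone(Tensor(oh.matrix[None]))
    finally:
        backbone.train(was_training)
    return SequenceEmbedding(values=out.data[0],
                             geometry=backbone.geometry,
                             provenance={"shift": oh.shift, "rc": oh.rc})
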