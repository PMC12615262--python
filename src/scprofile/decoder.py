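"""Cell-state-specific decoding of sequence embeddings.

A small hypernetwork (MLP) maps each cell's low-dimensional embedding
(default D = 14) to the weights of that cell's 1x1 convolutional output
filter: for RNA a (E+1, 2, 1) tensor (E filter weights plus a bias, per
strand), for ATAC (E+1, 1, 1).  Decoding is a position-wise linear map of
the per-bin sequence embedding followed by a softplus activation, so
profiles are nonnegative and no information mixes across bins.

:class:`ProfileModel` assembles a backbone with one hypernetwork per assay
and adds an embedding cache so that predicting many cells over the same
genomic window runs the backbone once.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from .backbone import MiniBackbone, OneHotSequence
from .layers import Linear, Module
from .minigrad import Tensor, no_grad

__all__ = [
    "CellEmbedding", "TrackSpec", "HyperNetwork", "generate_decoder_params",
    "decode", "decode_region", "ProfileModel", "CellProfilePrediction",
]

CELL_EMBEDDING_DIM = 14  # default dimensionality of the cell-state space


@dataclass
class CellEmbedding:
    cell_id: str
    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"non-finite embedding for cell {self.cell_id}")


@dataclass(frozen=True)
class TrackSpec:
    """Output head description: stranded RNA coverage or unstranded ATAC."""

    assay: str  # "rna" | "atac"

    def __post_init__(self):
        if self.assay not in ("rna", "atac"):
            raise ValueError("assay must be 'rna' or 'atac'")

    @property
    def n_strands(self) -> int:
        return 2 if self.assay == "rna" else 1


RNA_SPEC = TrackSpec("rna")
ATAC_SPEC = TrackSpec("atac")


class HyperNetwork(Module):
    """MLP: cell embedding (D) -> decoder filter ((E+1) * n_strands).

    One hidden layer with GELU nonlinearity by default; the output is
    reshaped to (E+1, n_strands, 1) per cell — E filter weights plus one
    bias for each strand.
    """

    def __init__(self, embedding_dim: int, seq_embedding_width: int,
                 track_spec: TrackSpec, hidden: int = 48, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.embedding_dim = embedding_dim
        self.seq_embedding_width = seq_embedding_width
        self.track_spec = track_spec
        out_dim = (seq_embedding_width + 1) * track_spec.n_strands
        self.fc1 = Linear(embedding_dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def forward(self, cell_vectors: Tensor) -> Tensor:
        """(N, D) -> (N, E+1, n_strands)."""
        h = self.fc1(cell_vectors).gelu()
        out = self.fc2(h)
        n = out.shape[0]
        return out.reshape(n, self.seq_embedding_width + 1,
                           self.track_spec.n_strands)


def generate_decoder_params(hypernet: HyperNetwork, cell_embedding,
                            track_spec: TrackSpec | None = None) -> np.ndarray:
    """Decoder parameters for one cell, shaped (E+1, n_strands, 1).

    With the full-scale embedding width E = 1,920 this is (1921, 2, 1) for
    RNA and (1921, 1, 1) for ATAC.
    """
    if track_spec is not None and track_spec != hypernet.track_spec:
        raise ValueError("track_spec does not match the hypernetwork's")
    vec = (cell_embedding.vector if isinstance(cell_embedding, CellEmbedding)
           else np.asarray(cell_embedding, dtype=np.float64))
    if vec.ndim != 1 or vec.shape[0] != hypernet.embedding_dim:
        raise ValueError(
            f"cell embedding has dimension {vec.shape}, hypernetwork "
            f"expects ({hypernet.embedding_dim},)")
    with no_grad():
        out = hypernet(Tensor(vec[None]))
    return out.data[0][:, :, None]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def decode(seq_embedding, params_for_cells) -> np.ndarray | Tensor:
    """Position-wise decode: (bins, E) x (N, E+1, S[, 1]) -> (N, S, bins).

    out[c, s, b] = softplus( sum_e emb[b, e] * w[c, e, s] + bias[c, s] ).
    Accepts raw arrays (returns an array) or Tensors (returns a Tensor on
    the autodiff tape, used during training).
    """
    if isinstance(seq_embedding, Tensor) or isinstance(params_for_cells, Tensor):
        emb = seq_embedding if isinstance(seq_embedding, Tensor) else Tensor(seq_embedding)
        par = params_for_cells if isinstance(params_for_cells, Tensor) else Tensor(params_for_cells)
        if par.ndim == 4:
            par = par.reshape(par.shape[0], par.shape[1], par.shape[2])
        E = emb.shape[-1]
        if par.shape[1] != E + 1:
            raise ValueError(
                f"params first axis {par.shape[1]} != embedding width+1 {E + 1}")
        w = par[:, :E, :]        # (N, E, S)
        b = par[:, E:, :]        # (N, 1, S)
        pre = emb @ w + b        # (N, bins, S) via broadcast matmul
        return pre.softplus().transpose((0, 2, 1))
    emb = np.asarray(seq_embedding, dtype=np.float64)
    par = np.asarray(params_for_cells, dtype=np.float64)
    if par.ndim == 4:
        par = par[:, :, :, 0]
    elif par.ndim == 2:
        par = par[None]
    E = emb.shape[-1]
    if par.shape[1] != E + 1:
        raise ValueError(
            f"params first axis {par.shape[1]} != embedding width+1 {E + 1}")
    pre = np.einsum("be,nes->nsb", emb, par[:, :E, :]) + par[:, E:, :].transpose(0, 2, 1)
    return _softplus(pre)


def decode_region(seq_embedding, params_for_cells, bin_slices) -> list:
    """Decode only the given bin slices (e.g. exon-overlapping bins).

    Returns one (N, S, slice_length) array per slice; each equals the full
    decode restricted to that slice exactly, because decoding is
    position-wise.
    """
    emb = np.asarray(seq_embedding, dtype=np.float64)
    n_bins = emb.shape[0]
    out = []
    for sl in bin_slices:
        start, stop = sl.start or 0, sl.stop if sl.stop is not None else n_bins
        if start < 0 or stop > n_bins or start > stop:
            raise ValueError(f"bin slice {sl} out of range [0, {n_bins})")
        out.append(decode(emb[start:stop], params_for_cells))
    return out


@dataclass
class CellProfilePrediction:
    """Per-cell profiles over the output window.

    rna: (N, 2, bins) — plus then minus strand; atac: (N, 1, bins).
    ``transformed`` is True while values are on the squashed training scale.
    """

    rna: np.ndarray | None
    atac: np.ndarray | None
    transformed: bool = True


class _EmbeddingCache:
    def __init__(self, capacity: int):
        self.capacity = capacity
        self._store: OrderedDict = OrderedDict()
        self.hits = 0
        self.misses = 0

    def get(self, key):
        if key in self._store:
            self.hits += 1
            self._store.move_to_end(key)
            return self._store[key]
        self.misses += 1
        return None

    def put(self, key, value):
        if self.capacity <= 0:
            return
        self._store[key] = value
        while len(self._store) > self.capacity:
            self._store.popitem(last=False)


class ProfileModel(Module):
    """Backbone + per-assay hypernetworks, with sequence-embedding caching.

    The cache key includes a weight version, bumped on every optimizer
    step, so stale embeddings are never served after an update.
    """

    def __init__(self, backbone: MiniBackbone, embedding_dim: int = CELL_EMBEDDING_DIM,
                 hypernet_hidden: int = 48, assays: tuple = ("rna", "atac"),
                 seed: int = 0, cache_capacity: int = 8):
        super().__init__()
        self.backbone = backbone
        E = backbone.geometry.embedding_width
        self.embedding_dim = embedding_dim
        self.assays = tuple(assays)
        self.hypernet_rna = (HyperNetwork(embedding_dim, E, RNA_SPEC,
                                          hidden=hypernet_hidden, seed=seed + 1)
                             if "rna" in assays else None)
        self.hypernet_atac = (HyperNetwork(embedding_dim, E, ATAC_SPEC,
                                           hidden=hypernet_hidden, seed=seed + 2)
                              if "atac" in assays else None)
        self.weight_version = 0
        self.cache = _EmbeddingCache(cache_capacity)

    def bump_weight_version(self):
        """Invalidate cached embeddings after any weight update."""
        self.weight_version += 1

    # -- training-time forward (on the tape) ----------------------------------
    def forward_training(self, onehot_batch: np.ndarray,
                         cell_vectors: np.ndarray) -> dict:
        """(B, 4, L), (N, D) -> dict of Tensors (B, N, S, bins)."""
        emb = self.backbone(Tensor(onehot_batch))  # (B, bins, E)
        cells = Tensor(cell_vectors)
        out = {}
        for assay, hn in (("rna", self.hypernet_rna),
                          ("atac", self.hypernet_atac)):
            if hn is None:
                continue
            par = hn(cells)  # (N, E+1, S)
            E = self.backbone.geometry.embedding_width
            w = par[:, :E, :]                       # (N, E, S)
            b = par[:, E:, :]                       # (N, 1, S)
            # (B, 1, bins, E) @ (N, E, S) -> (B, N, bins, S)
            pre = emb.reshape(emb.shape[0], 1, emb.shape[1], emb.shape[2]) @ w + b
            out[assay] = pre.softplus().transpose((0, 1, 3, 2))
        return out

    # -- inference ------------------------------------------------------------
    def _embedding_for(self, oh: OneHotSequence, seq_key=None) -> np.ndarray:
        key = None
        if seq_key is not None:
            key = (seq_key, oh.shift, oh.rc, self.weight_version)
            cached = self.cache.get(key)
            if cached is not None:
                return cached
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                emb = self.backbone(Tensor(oh.matrix[None])).data[0]
        finally:
            self.train(was_training)
        if key is not None:
            self.cache.put(key, emb)
        return emb

    def cached_predict(self, oh: OneHotSequence, cell_vectors: np.ndarray,
                       seq_key=None) -> CellProfilePrediction:
        """Predict transformed-scale profiles for a batch of cells.

        ``seq_key`` identifies the sequence for caching (e.g. an interval
        string); when None, no caching is attempted. Results are identical
        to uncached evaluation.
        """
        emb = self._embedding_for(oh, seq_key=seq_key)
        cells = np.asarray(cell_vectors, dtype=np.float64)
        if cells.ndim == 1:
            cells = cells[None]
        out = {}
        with no_grad():
            for assay, hn in (("rna", self.hypernet_rna),
                              ("atac", self.hypernet_atac)):
                if hn is None:
                    out[assay] = None
                    continue
                par = hn(Tensor(cells)).data  # (N, E+1, S)
                out[assay] = decode(emb, par)
        return CellProfilePrediction(rna=out["rna"], atac=out["atac"],
                                     transformed=True)
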