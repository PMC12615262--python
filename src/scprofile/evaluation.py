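"""Inference-time aggregation and evaluation metrics.

Predictions are made on the forward and reverse-complement strand and
averaged (with position flip and RNA strand swap), then the squashed-scale
transform is inverted to natural-scale coverage.  Gene expression counts
are the sum of the strand-matched RNA track over every 32-bp bin that
overlaps an exon (a bin overlapping by >= 1 bp contributes its full
value); locus accessibility is the sum of the ATAC track over the whole
output window.  Count metrics follow the log2(x + 1) pseudobulk
convention; profile metrics use log(x + 1) on the natural-log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import ModelGeometry, one_hot
from .coverage import GenomicInterval, TargetTransform
from .decoder import CellProfilePrediction, ProfileModel

__all__ = [
    "GeneModel", "read_gtf_genes", "get_sequence", "predict_rc_averaged",
    "gene_counts", "locus_accessibility", "across_gene_correlation",
    "deviation_correlation", "profile_correlation", "knn_average_profiles",
    "rolling_smooth",
]


@dataclass
class GeneModel:
    """A gene with merged, sorted exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: list  # list of GenomicInterval, sorted, non-overlapping
    name: str | None = None

    def __post_init__(self):
        merged = []
        for ex in sorted(self.exons, key=lambda e: e.start):
            if merged and ex.start <= merged[-1].end:
                last = merged[-1]
                merged[-1] = GenomicInterval(last.chrom, last.start,
                                             max(last.end, ex.end), last.strand)
            else:
                merged.append(ex)
        self.exons = merged

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start,
                               self.exons[-1].end, self.strand)

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)


def read_gtf_genes(path: str) -> dict:
    """Assemble GeneModels from a GTF file (exons merged across transcripts).

    Uses pyranges for parsing; GTF 1-based closed coordinates become
    0-based half-open.
    """
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    df = gr.df
    exons = df[df.Feature == "exon"]
    genes: dict = {}
    for gene_id, sub in exons.groupby("gene_id", sort=True):
        chrom = str(sub.Chromosome.iloc[0])
        strand = str(sub.Strand.iloc[0])
        ivs = [GenomicInterval(chrom, int(s), int(e), strand)
               for s, e in zip(sub.Start, sub.End)]
        name = (str(sub.gene_name.iloc[0])
                if "gene_name" in sub.columns else None)
        genes[str(gene_id)] = GeneModel(gene_id=str(gene_id), chrom=chrom,
                                        strand=strand, exons=ivs, name=name)
    return genes


def get_sequence(genome, interval: GenomicInterval) -> str:
    """Fetch the sequence of an interval from a dict or FASTA-like genome."""
    if isinstance(genome, dict):
        seq = genome[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(f"interval {interval} beyond chromosome end")
        return seq[interval.start:interval.end]
    rec = genome[interval.chrom]
    if interval.end > len(rec):
        raise ValueError(f"interval {interval} beyond chromosome end")
    return str(rec[interval.start:interval.end])


def _flip_prediction(pred: dict) -> dict:
    """Reverse positions; swap RNA strand channels."""
    out = {}
    if pred.get("rna") is not None:
        out["rna"] = pred["rna"][:, ::-1, ::-1].copy()
    else:
        out["rna"] = None
    if pred.get("atac") is not None:
        out["atac"] = pred["atac"][:, :, ::-1].copy()
    else:
        out["atac"] = None
    return out


def predict_rc_averaged(model: ProfileModel, interval: GenomicInterval,
                        cell_vectors: np.ndarray, genome,
                        transform: TargetTransform | None = None,
                        seq_key=None) -> CellProfilePrediction:
    """Natural-scale profiles averaged over both strands of the input.

    Runs the model on the sequence and its reverse complement, flips the
    reverse-complement output (position reversal + RNA strand swap),
    averages, then inverts the squashed-scale transform (rescaling ATAC by
    1/atac_scale, i.e. x20 at defaults).
    """
    geometry = model.backbone.geometry
    if len(interval) != geometry.input_length:
        raise ValueError(
            f"interval length {len(interval)} != geometry input length "
            f"{geometry.input_length}")
    transform = transform or TargetTransform()
    seq = get_sequence(genome, interval)
    fwd = model.cached_predict(one_hot(seq), cell_vectors, seq_key=seq_key)
    rev = model.cached_predict(one_hot(seq, rc=True), cell_vectors,
                               seq_key=seq_key)
    flipped = _flip_prediction({"rna": rev.rna, "atac": rev.atac})
    rna = atac = None
    if fwd.rna is not None:
        rna = transform.inverse(0.5 * (fwd.rna + flipped["rna"]), "rna")
    if fwd.atac is not None:
        atac = transform.inverse(0.5 * (fwd.atac + flipped["atac"]), "atac")
    return CellProfilePrediction(rna=rna, atac=atac, transformed=False)


def exon_bin_indices(gene: GeneModel, window: GenomicInterval,
                     bin_width: int = 32) -> tuple[np.ndarray, int]:
    """Output-window bins overlapping any exon (>=1 bp => whole bin).

    Returns (sorted unique bin indices, number of exons entirely outside
    the window).
    """
    n_bins = len(window) // bin_width
    bins: set = set()
    n_outside = 0
    for ex in gene.exons:
        s = max(ex.start, window.start)
        e = min(ex.end, window.end)
        if s >= e:
            n_outside += 1
            continue
        b0 = (s - window.start) // bin_width
        b1 = (e - 1 - window.start) // bin_width
        bins.update(range(b0, min(b1, n_bins - 1) + 1))
    return np.array(sorted(bins), dtype=np.int64), n_outside


def gene_counts(profiles: CellProfilePrediction, gene: GeneModel,
                geometry: ModelGeometry, window: GenomicInterval,
                bin_width: int | None = None) -> np.ndarray:
    """Per-cell expression counts: strand-matched RNA summed over exon bins.

    ``window`` is the model's output window (conventionally centered on the
    gene body); natural-scale profiles are expected.
    """
    if profiles.transformed:
        raise ValueError("gene_counts expects natural-scale profiles")
    if profiles.rna is None:
        raise ValueError("profiles carry no RNA track")
    bw = bin_width or geometry.bin_width
    bins, n_outside = exon_bin_indices(gene, window, bw)
    if len(bins) == 0:
        warnings.warn(f"gene {gene.gene_id}: no exon overlaps the output "
                      f"window; count is 0")
        return np.zeros(profiles.rna.shape[0])
    if n_outside:
        warnings.warn(f"gene {gene.gene_id}: {n_outside} exons outside the "
                      f"output window do not contribute")
    strand_channel = 0 if gene.strand == "+" else 1
    return profiles.rna[:, strand_channel, :][:, bins].sum(axis=1)


def locus_accessibility(profiles: CellProfilePrediction) -> np.ndarray:
    """Per-cell scalar: predicted ATAC signal summed over all output bins."""
    if profiles.atac is None:
        raise ValueError("profiles carry no ATAC track")
    return profiles.atac.sum(axis=(1, 2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def across_gene_correlation(pred: pd.DataFrame, obs: pd.DataFrame,
                            pseudocount: float = 1.0) -> pd.Series:
    """Per-cell-type Pearson over genes of log2(count + 1).

    Rows are cell types, columns genes (aligned by label). Constant rows
    are skipped with a warning (NaN).
    """
    obs = obs.loc[pred.index, pred.columns]
    lp = np.log2(pred.values + pseudocount)
    lo = np.log2(obs.values + pseudocount)
    out = {}
    for i, ct in enumerate(pred.index):
        r = _pearson(lp[i], lo[i])
        if np.isnan(r):
            warnings.warn(f"across_gene_correlation: zero variance for "
                          f"{ct!r}; skipped")
        out[ct] = r
    return pd.Series(out, name="pearson_r")


def deviation_correlation(pred: pd.DataFrame, obs: pd.DataFrame,
                          pseudocount: float = 1.0) -> float:
    """Pearson of double-centered log2 matrices (gene means, then cell-type
    means removed), over all entries — the cell-type-specificity metric."""
    obs = obs.loc[pred.index, pred.columns]

    def center(m):
        m = np.log2(m + pseudocount)
        # double-centering is order-invariant
        m = m - m.mean(axis=1, keepdims=True)  # mean across genes, per cell type
        m = m - m.mean(axis=0, keepdims=True)  # mean across cell types, per gene
        return m

    a, b = center(pred.values), center(obs.values)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("deviation_correlation: degenerate (purely additive) "
                      "matrices; returning NaN")
        return np.nan
    return _pearson(a.ravel(), b.ravel())


def profile_correlation(profiles_a: np.ndarray, profiles_b: np.ndarray,
                        log_base: str = "e",
                        pseudocount: float = 1.0) -> np.ndarray:
    """Per-cell Pearson correlation of log(x + 1) profiles.

    ``profiles_*`` are (n_cells, length); rows are compared pairwise.
    """
    a = np.asarray(profiles_a, dtype=np.float64)
    b = np.asarray(profiles_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("profile arrays must have identical shapes")
    la = np.log(a + pseudocount)
    lb = np.log(b + pseudocount)
    if log_base == "2":
        la, lb = la / np.log(2), lb / np.log(2)
    return np.array([_pearson(la[i], lb[i]) for i in range(a.shape[0])])


def knn_average_profiles(profiles: np.ndarray, embeddings: np.ndarray,
                         k: int = 100) -> np.ndarray:
    """Unweighted mean profile of each cell's k nearest neighbors.

    Neighbors are found by Euclidean distance in the cell-embedding space;
    the cell itself is excluded, so k = 1 returns the nearest neighbor's
    profile.
    """
    from sklearn.neighbors import NearestNeighbors

    n = embeddings.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(embeddings)
    _, idx = nn.kneighbors(embeddings)
    out = np.empty_like(np.asarray(profiles, dtype=np.float64))
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k_eff]
        out[i] = profiles[neigh].mean(axis=0)
    return out


def rolling_smooth(values, window: int = 200) -> np.ndarray:
    """Centered rolling mean along a pseudotime ordering; windows shrink at
    the edges; window = 1 is the identity."""
    s = pd.Series(np.asarray(values, dtype=np.float64))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()
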